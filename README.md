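# biomotion

Dual-pathway biological movement recognition for grayscale video.

The **form pathway** learns a sparse deformable template of oriented
Gabor wavelet elements per action class (shared-sketch / matching-pursuit
selection with local inhibition) and scores frames with a
log-likelihood-ratio match.  The **motion pathway** estimates dense
bidirectional optical flow by minimizing a three-term objective (robust
data term, forward/backward symmetric coupling, total-variation
smoothness) with coarse-to-fine warping, plus a deliberately unsmoothed
SAD block-matching "compressed" flow.  The pathways couple through a
**time-dependent fuzzy division** of the flow field: the frame is split
into four quadrant cells, the location of maximal speed is fuzzified by
triangular membership functions, memberships accumulate across frames
with a memory coefficient, and the aggregated upper/lower-limb scores
gate which action classes remain eligible.  Gated frames are scored by a
**synergetic (order-parameter) classifier** over melted action
prototypes; sequences are labeled by majority vote.

No external benchmark data are required: a seeded synthetic-fixture
module generates oriented-bar training images, wrapped-translation frame
pairs with exact ground-truth flow, and limb-localized blob-actor action
sequences.

## Layout

| module | contents |
| --- | --- |
| `biomotion.gabor` | oriented multi-scale quadrature wavelet dictionary |
| `biomotion.abm` | shared-sketch template learning, saturation, max-pooling, matching |
| `biomotion.flow` | variational bidirectional flow, SAD block flow, speed maps |
| `biomotion.flow_io` | Middlebury `.flo` I/O, 16-bit speed PNGs |
| `biomotion.fuzzy` | quadrant division, triangular memberships, temporal accumulation, gating |
| `biomotion.snn` | sample normalization, (MPOD-)adjoint prototypes, order parameters, melting |
| `biomotion.pipeline` | frame selection, training, classification, model serialization |
| `biomotion.synth` | seeded fixture generators + PNG sequence I/O |
| `biomotion.config` | YAML configuration with documented defaults |
| `biomotion.cli` | `biomotion` command line interface |

## CLI

```bash
# generate fixtures (bars | translate | action)
biomotion synth --kind action --limb-group upper --out data/wave0 --seed 3

# train from a map of <action>/<subject>/frame_XXXX.png directories
biomotion train --map data/train --config config.yaml --out model.bm --seed 0

# classify one ordered image-sequence directory (optional CSV trace)
biomotion classify --model model.bm --frames data/test/seq0 --trace trace.csv

# sequence-level accuracy over <label>/<sequence>/ directories
biomotion eval --model model.bm --dataset data/test --report report.json
```

Exit code 2 flags validation errors; logs go to stderr (`-v`/`-vv`).

Configuration is a single YAML file with sections `gabor`, `abm`,
`flow`, `fuzzy`, `snn`, `pipeline`; every key has a documented default
in `biomotion/config.py` (`save_config(default_config(), "config.yaml")`
writes a fully populated file to edit).

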
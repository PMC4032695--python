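"""End-to-end orchestration: train on an action map, classify sequences.

Per selected frame the motion pathway estimates flow against the
previous frame, updates the fuzzy membership state and gates candidate
classes; the form pathway matches active-basis templates inside a
flow-derived ROI; the synergetic bank scores the normalized frame and
the gated argmax gives the per-frame label.  A sequence label is the
majority vote over frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter, zoom

from . import abm as _abm
from . import fuzzy as _fuzzy
from .config import Config, default_config
from .flow import FlowField, FlowParams, estimate_flow, flow_speed, sad_block_flow
from .gabor import build_dictionary
from .serialize import read_container, write_container
from .snn import (PrototypeBank, RankDeficiencyError, build_action_prototypes,
                  moore_penrose_adjoint, normalize_sample, order_parameters)

__all__ = ["ActionClass", "KTH_CLASSES", "CLASS_GROUPS", "Model",
           "SequenceResult", "select_frames", "train", "classify_sequence",
           "save_model", "load_model", "prepare_frame", "motion_roi"]

logger = logging.getLogger(__name__)

MODEL_VERSION = 1


@dataclass(frozen=True)
class ActionClass:
    name: str
    limb_group: str  # 'upper' | 'lower'


KTH_CLASSES = (
    ActionClass("boxing", "upper"),
    ActionClass("clapping", "upper"),
    ActionClass("waving", "upper"),
    ActionClass("walking", "lower"),
    ActionClass("jogging", "lower"),
    ActionClass("running", "lower"),
)

CLASS_GROUPS = {c.name: c.limb_group for c in KTH_CLASSES}


@dataclass
class FrameResult:
    frame_index: int
    gate: set[str]
    scores: dict[str, float]
    predicted: str
    abm_location: tuple[int, int] | None = None


@dataclass
class SequenceResult:
    per_frame: list[FrameResult]
    final_label: str
    vote_margin: float


@dataclass
class Model:
    frame_shape: tuple[int, int]
    actions: list[str]
    class_groups: dict[str, str]
    templates: dict[str, _abm.ActiveBasisTemplate]
    bank: PrototypeBank
    config: Config


def select_frames(sequence: list, count: int, stride: int) -> list[int]:
    """Indices of ``count`` frames, evenly strided from the start, in order."""
    n = len(sequence)
    if count < 3:
        raise ValueError("count must be >= 3")
    if n < count:
        raise ValueError(f"sequence of {n} frames shorter than count={count}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    eff = min(stride, (n - 1) // (count - 1)) if count > 1 else stride
    return [i * eff for i in range(count)]


def prepare_frame(frame: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Grayscale [0,1] frame resized (antialiased) to the working shape."""
    arr = np.asarray(frame, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.max() > 1.5:
        arr = arr / 255.0
    if arr.shape != tuple(shape):
        fy = shape[0] / arr.shape[0]
        fx = shape[1] / arr.shape[1]
        if fy < 1 or fx < 1:  # smooth before downsampling
            arr = gaussian_filter(arr, (max(0.0, 0.5 / fy - 0.5),
                                        max(0.0, 0.5 / fx - 0.5)))
        arr = zoom(arr, (fy, fx), order=1, mode="nearest", grid_mode=True)
        arr = arr[:shape[0], :shape[1]]
    return arr


def motion_roi(flow: FlowField, quantile: float, dilate: int) -> np.ndarray:
    """Boolean ROI: pixels whose speed exceeds the frame's speed quantile."""
    speed = flow_speed(flow)
    if not np.any(speed > 0):
        return np.ones(speed.shape, dtype=bool)
    thr = np.quantile(speed, quantile)
    mask = speed >= max(thr, 1e-12)
    if dilate > 0:
        mask = binary_dilation(mask, iterations=dilate)
    return mask


def _flow_params(cfg: Config) -> FlowParams:
    f = cfg.flow
    return FlowParams(rho=f.rho, xi=f.xi, n_levels=f.n_levels,
                      n_outer=f.n_outer, n_inner=f.n_inner,
                      n_sweeps=f.n_sweeps, charbonnier_eps=f.charbonnier_eps,
                      presmooth_sigma=f.presmooth_sigma)


def _fuzzy_params(cfg: Config) -> _fuzzy.FuzzyParams:
    f = cfg.fuzzy
    return _fuzzy.FuzzyParams(tau=f.tau, beta=f.beta,
                              beta_prime=f.beta_prime, n_max=f.n_max,
                              margin=f.margin)


def _validate_map(training_map: dict) -> tuple[int, int]:
    if not training_map:
        raise ValueError("training map is empty")
    shape = None
    for action, sequences in training_map.items():
        if not sequences:
            raise ValueError(f"training map: action {action!r} has no sequences")
        for si, seq in enumerate(sequences):
            if len(seq) == 0:
                raise ValueError(
                    f"training map: {action!r}/sequence {si} is empty")
            for f in seq:
                s = np.asarray(f).shape
                if shape is None:
                    shape = s
                elif s != shape:
                    raise ValueError(
                        f"training map: {action!r}/sequence {si} frame shape "
                        f"{s} != {shape}")
    return shape


def train(training_map: dict[str, list[list[np.ndarray]]],
          config: Config | None = None, seed: int = 0) -> Model:
    """Learn ABM templates and the prototype bank from an action map.

    ``training_map`` maps action name -> list of subject sequences (each an
    ordered list of same-shape grayscale frames).  Snippets are evenly
    selected frames per sequence; SSA runs with a motion-derived ROI; the
    synergetic bank melts snippets across subjects, then across snippets.
    """
    if config is None:
        config = default_config()
    frame_shape = _validate_map(training_map)
    pcfg = config.pipeline
    rng = np.random.default_rng(seed)

    if pcfg.mirror_augment:
        training_map = {
            action: list(seqs) + [[np.asarray(f)[:, ::-1] for f in seq]
                                  for seq in seqs]
            for action, seqs in training_map.items()}

    g = config.gabor
    dictionary = build_dictionary(
        n_orientations=g.n_orientations, n_scales=g.n_scales,
        base_size=g.base_size, omega0=g.omega0, scale_step=g.scale_step,
        gamma=g.gamma, sigma_factor=g.sigma_factor)
    bounds = _abm.PerturbationBounds(location=config.abm.location_bound,
                                     orientation=config.abm.orientation_bound)
    inhibition = (config.abm.inhibition_radius
                  if config.abm.inhibition_radius is not None
                  else dictionary.kernel_size(1) // 2)

    snippet_map: dict[str, list[list[np.ndarray]]] = {}
    templates: dict[str, _abm.ActiveBasisTemplate] = {}
    for action in sorted(training_map):
        sequences = training_map[action]
        n_snip = min(config.pipeline.n_snippets,
                     min(len(s) for s in sequences))
        per_snippet: list[list[np.ndarray]] = [[] for _ in range(n_snip)]
        all_frames: list[np.ndarray] = []
        roi = np.zeros(frame_shape, dtype=bool)
        for seq in sequences:
            if n_snip >= 3 and len(seq) >= n_snip:
                stride = max(1, (len(seq) - 1) // max(1, n_snip - 1))
                idx = select_frames(seq, n_snip, stride)
            else:
                idx = list(range(n_snip))
            for s, i in enumerate(idx):
                frame = np.asarray(seq[i], dtype=float)
                per_snippet[s].append(frame)
                all_frames.append(frame)
                if i >= 1:  # motion guidance from the preceding frame
                    guide = sad_block_flow(
                        np.asarray(seq[i - 1], float), frame,
                        block=config.flow.sad_block,
                        search_radius=config.flow.sad_search_radius)
                    roi |= motion_roi(guide, pcfg.speed_quantile, inhibition)
        if not roi.any():
            roi = np.ones(frame_shape, dtype=bool)
        snippet_map[action] = per_snippet
        templates[action] = _abm.train_shared_sketch(
            all_frames, config.abm.n_elements, dictionary,
            inhibition_radius=inhibition, roi=roi, bounds=bounds,
            saturation=config.abm.saturation, rng=rng)

    prototypes = build_action_prototypes(snippet_map, P1=config.snn.p1,
                                         P2=config.snn.p2)
    columns, labels = [], []
    for action in sorted(prototypes):
        protos = prototypes[action]
        retained = (protos["snippets"] + protos["final"]
                    if config.snn.match_mode == "retained"
                    else protos["final"])
        for p in retained:
            columns.append(p.values)
            labels.append(action)
    V = np.stack(columns, axis=1)
    try:
        V_adj = moore_penrose_adjoint(V)
        penalty = None
    except RankDeficiencyError:
        logger.warning("prototype bank rank-deficient; using ridge adjoint")
        M = V.shape[1]
        V_adj = np.linalg.solve(V.T @ V + config.snn.p2 * np.eye(M), V.T)
        penalty = (0.0, config.snn.p2)
    bank = PrototypeBank(V=V, V_adj=V_adj, labels=labels, penalty=penalty)

    actions = sorted(training_map)
    groups = {a: CLASS_GROUPS.get(a, "lower") for a in actions}
    return Model(frame_shape=tuple(frame_shape), actions=actions,
                 class_groups=groups, templates=templates, bank=bank,
                 config=config)


def classify_sequence(frames: list[np.ndarray], model: Model,
                      config: Config | None = None) -> SequenceResult:
    """Classify one ordered frame sequence with the trained model."""
    cfg = config if config is not None else model.config
    if len(frames) < 3:
        raise ValueError("need at least 3 frames")
    frames = [np.asarray(f, dtype=float) for f in frames]
    for f in frames:
        if f.shape != tuple(model.frame_shape):
            raise ValueError(
                f"frame shape {f.shape} != model frame shape "
                f"{model.frame_shape}; resize with prepare_frame first")

    pcfg = cfg.pipeline
    idx = select_frames(frames, min(pcfg.select_count, len(frames)),
                        pcfg.select_stride)
    division = _fuzzy.FlowDivision(*model.frame_shape)
    state = _fuzzy.MembershipState(params=_fuzzy_params(cfg))
    fparams = _flow_params(cfg)
    groups = {a: model.class_groups[a] for a in model.actions}
    inhibition = (cfg.abm.inhibition_radius
                  if cfg.abm.inhibition_radius is not None
                  else model.templates[model.actions[0]].inhibition_radius)

    per_frame: list[FrameResult] = []
    for t in idx:
        if t == 0:
            continue  # no preceding frame for flow yet
        fwd, _ = estimate_flow(frames[t - 1], frames[t], fparams)
        mu, winner = _fuzzy.cell_memberships(fwd, division)
        state = _fuzzy.temporal_update(state, mu, winner)
        scores_lr = _fuzzy.limb_scores(state, cfg.fuzzy.enable_left_right)
        if pcfg.gate_enabled:
            gate = _fuzzy.gate_actions(scores_lr, groups, cfg.fuzzy.margin)
        else:
            gate = set(model.actions)

        roi = motion_roi(fwd, pcfg.speed_quantile, inhibition)
        q = normalize_sample(frames[t])
        eps = order_parameters(q, model.bank).epsilon
        class_scores: dict[str, float] = {}
        for a in model.actions:
            cols = [i for i, lab in enumerate(model.bank.labels) if lab == a]
            class_scores[a] = float(np.max(eps[cols]))

        abm_loc = None
        if gate:
            # form pathway: localize with the best gated template in the ROI
            best_gated = max(sorted(gate), key=lambda a: class_scores[a])
            match = _abm.match_template(frames[t], model.templates[best_gated],
                                        roi=roi)
            abm_loc = match.location
            if pcfg.use_abm_score:
                for a in gate:
                    m = _abm.match_template(frames[t], model.templates[a],
                                            roi=roi)
                    class_scores[a] = class_scores[a] + 0.01 * m.score

        allowed = sorted(gate)
        predicted = max(allowed, key=lambda a: (class_scores[a], a))
        per_frame.append(FrameResult(frame_index=t, gate=set(gate),
                                     scores=class_scores, predicted=predicted,
                                     abm_location=abm_loc))

    if not per_frame:
        raise ValueError("no frames were scored (sequence too short?)")
    votes: dict[str, int] = {}
    sums: dict[str, float] = {}
    for fr in per_frame:
        votes[fr.predicted] = votes.get(fr.predicted, 0) + 1
        sums[fr.predicted] = sums.get(fr.predicted, 0.0) \
            + fr.scores[fr.predicted]
    top = max(votes.values())
    tied = sorted(a for a, v in votes.items() if v == top)
    final = max(tied, key=lambda a: (sums[a], a))
    return SequenceResult(per_frame=per_frame, final_label=final,
                          vote_margin=top / len(per_frame))


def save_model(model: Model, path: str | Path) -> None:
    """Serialize to the versioned container; byte-identical for equal models."""
    meta = {
        "version": MODEL_VERSION,
        "frame_shape": list(model.frame_shape),
        "actions": model.actions,
        "class_groups": model.class_groups,
        "config": model.config.to_dict(),
        "bank_labels": model.bank.labels,
        "bank_penalty": list(model.bank.penalty) if model.bank.penalty else None,
        "templates": {
            a: {"saturation": t.saturation,
                "inhibition_radius": t.inhibition_radius,
                "bounds": [t.bounds.location, t.bounds.orientation]}
            for a, t in sorted(model.templates.items())},
    }
    arrays: dict[str, np.ndarray] = {
        "bank/V": model.bank.V,
        "bank/V_adj": model.bank.V_adj,
    }
    for a, t in sorted(model.templates.items()):
        el = np.array([[e.row, e.col, e.orientation_index, e.scale_index]
                       for e in t.elements], dtype=np.int64).reshape(-1, 4)
        arrays[f"template/{a}/elements"] = el
        arrays[f"template/{a}/weights"] = t.weights
        arrays[f"template/{a}/deltas"] = t.deltas
        arrays[f"template/{a}/log_normalizers"] = t.log_normalizers
    write_container(path, meta, arrays)


def load_model(path: str | Path) -> Model:
    meta, arrays = read_container(path)
    if meta.get("version") != MODEL_VERSION:
        raise ValueError(f"unsupported model version {meta.get('version')}")
    from .config import load_config
    cfg = load_config(overrides=meta["config"])
    g = cfg.gabor
    dictionary = build_dictionary(
        n_orientations=g.n_orientations, n_scales=g.n_scales,
        base_size=g.base_size, omega0=g.omega0, scale_step=g.scale_step,
        gamma=g.gamma, sigma_factor=g.sigma_factor)
    frame_shape = tuple(meta["frame_shape"])
    templates = {}
    for a, tmeta in meta["templates"].items():
        el = arrays[f"template/{a}/elements"]
        templates[a] = _abm.ActiveBasisTemplate(
            elements=[_abm.TemplateElement(int(r), int(c), int(o), int(s))
                      for r, c, o, s in el],
            weights=arrays[f"template/{a}/weights"],
            deltas=arrays[f"template/{a}/deltas"],
            log_normalizers=arrays[f"template/{a}/log_normalizers"],
            bounds=_abm.PerturbationBounds(*tmeta["bounds"]),
            frame_shape=frame_shape, dictionary=dictionary,
            saturation=tmeta["saturation"],
            inhibition_radius=tmeta["inhibition_radius"])
    penalty = tuple(meta["bank_penalty"]) if meta.get("bank_penalty") else None
    bank = PrototypeBank(V=arrays["bank/V"], V_adj=arrays["bank/V_adj"],
                         labels=list(meta["bank_labels"]), penalty=penalty)
    return Model(frame_shape=frame_shape, actions=list(meta["actions"]),
                 class_groups=dict(meta["class_groups"]),
                 templates=templates, bank=bank, config=cfg)
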
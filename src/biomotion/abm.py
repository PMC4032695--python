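"""Active basis model: shared-sketch template learning and matching.

A template is a short ordered list of Gabor elements selected greedily so
that their locally max-pooled, saturated responses summed over all
training frames are maximal, with spatial inhibition around each pick.
The match score is a log-likelihood ratio under an exponential tilt of
the background response distribution:

    score = sum_i lambda_i * h_i  -  sum_i log Z(lambda_i)

where ``h_i`` is the pooled saturated response of element ``i`` and
``lambda_i`` solves ``E_lambda[h] = delta_i`` against a background pool
of responses sampled from the training frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.optimize import brentq
from scipy.special import logsumexp

from .gabor import GaborDictionary, respond

__all__ = [
    "PerturbationBounds", "ActiveBasisTemplate", "MatchResult",
    "saturate", "response_stack", "local_max_pool",
    "train_shared_sketch", "match_template",
]

logger = logging.getLogger(__name__)

_LAMBDA_MAX = 20.0


@dataclass(frozen=True)
class PerturbationBounds:
    """Allowed local shift of an element: +-location px, +-orientation steps."""
    location: int = 2
    orientation: int = 1


@dataclass
class TemplateElement:
    row: int
    col: int
    orientation_index: int
    scale_index: int  # 1-based


@dataclass
class ActiveBasisTemplate:
    elements: list[TemplateElement]
    weights: np.ndarray            # natural parameters lambda_i
    deltas: np.ndarray             # mean pooled responses at selection
    log_normalizers: np.ndarray    # log Z(lambda_i)
    bounds: PerturbationBounds
    frame_shape: tuple[int, int]
    dictionary: GaborDictionary
    saturation: float
    inhibition_radius: int

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def centroid(self) -> tuple[float, float]:
        if not self.elements:
            return (0.0, 0.0)
        return (float(np.mean([e.row for e in self.elements])),
                float(np.mean([e.col for e in self.elements])))


@dataclass
class MatchResult:
    score: float
    location: tuple[int, int]
    offset: tuple[int, int]
    per_element_responses: np.ndarray
    degenerate: bool = False


def saturate(response: np.ndarray, saturation: float,
             normalizer: float | None = None) -> np.ndarray:
    """Whiten then saturate a magnitude response map.

    Whitening divides the squared response by ``normalizer`` (default: its
    own frame mean square), i.e. rescales the magnitude to RMS units; the
    sigmoid is ``zeta * tanh(s / zeta)`` so output is monotone, zero at
    zero, and bounded by ``saturation``.
    """
    if saturation <= 0:
        raise ValueError("saturation must be positive")
    response = np.asarray(response, dtype=float)
    sq = response * response
    if normalizer is None:
        normalizer = float(sq.mean())
    if normalizer <= 0:
        return np.zeros_like(sq)
    s = np.sqrt(sq / normalizer)
    return saturation * np.tanh(s / saturation)


def response_stack(frame: np.ndarray, dictionary: GaborDictionary,
                   saturation: float = 6.0) -> dict[tuple[int, int], np.ndarray]:
    """Saturated response maps keyed by (scale_index, orientation_index).

    One whitening normalizer per frame (mean squared response pooled over
    the whole dictionary) so relative orientation strengths survive.
    """
    raw = {}
    total, count = 0.0, 0
    for el in dictionary.elements:
        r = respond(frame, el)
        raw[(el.scale_index, el.orientation_index)] = r
        total += float((r * r).sum())
        count += r.size
    norm = total / count if count else 1.0
    return {k: saturate(v, saturation, normalizer=norm) for k, v in raw.items()}


def _pooled_map(stack, scale_index, orientation_index, bounds, n_orientations):
    """Max over the +-location window and +-orientation neighbors (wrapping)."""
    size = 2 * bounds.location + 1
    pooled = None
    for do in range(-bounds.orientation, bounds.orientation + 1):
        oi = (orientation_index + do) % n_orientations
        m = maximum_filter(stack[(scale_index, oi)], size=size, mode="constant")
        pooled = m if pooled is None else np.maximum(pooled, m)
    return pooled


def local_max_pool(stack: dict, element_placement: TemplateElement,
                   bounds: PerturbationBounds, n_orientations: int):
    """Max pooled saturated response around a nominal placement.

    Returns ``(value, TemplateElement argmax placement)`` with the
    deterministic tie-break smallest row, then col, then orientation index.
    """
    p = element_placement
    some_map = stack[(p.scale_index, p.orientation_index)]
    H, W = some_map.shape
    best_val = -np.inf
    best = None
    for dr in range(-bounds.location, bounds.location + 1):
        for dc in range(-bounds.location, bounds.location + 1):
            r, c = p.row + dr, p.col + dc
            if not (0 <= r < H and 0 <= c < W):
                continue
            for do in range(-bounds.orientation, bounds.orientation + 1):
                oi = (p.orientation_index + do) % n_orientations
                v = stack[(p.scale_index, oi)][r, c]
                cand = (r, c, oi)
                if v > best_val or (v == best_val and best is not None
                                    and cand < best):
                    best_val = v
                    best = cand
    assert best is not None
    return best_val, TemplateElement(best[0], best[1], best[2], p.scale_index)


def _suppress(stack, row, col, radius, n_orientations, n_scales):
    """Zero every placement within ``radius`` (Chebyshev) of (row, col)."""
    for si in range(1, n_scales + 1):
        for oi in range(n_orientations):
            m = stack[(si, oi)]
            r0, r1 = max(0, row - radius), min(m.shape[0], row + radius + 1)
            c0, c1 = max(0, col - radius), min(m.shape[1], col + radius + 1)
            m[r0:r1, c0:c1] = 0.0


def _fit_lambda(delta: float, background: np.ndarray) -> tuple[float, float]:
    """Solve the natural parameter of the exponential tilt.

    Finds lambda with tilted mean ``E_lambda[h] = delta`` over the
    background sample; returns (lambda, log Z(lambda)).
    """
    h = np.asarray(background, dtype=float)

    def tilted_mean(lam):
        logw = lam * h
        logz = logsumexp(logw) - np.log(h.size)
        return float(np.exp(logsumexp(logw + np.log(np.maximum(h, 1e-300)))
                            - np.log(h.size) - logz))

    lo, hi = 0.0, _LAMBDA_MAX
    if delta <= tilted_mean(lo):
        lam = 0.0
    elif delta >= tilted_mean(hi):
        lam = hi
    else:
        lam = brentq(lambda L: tilted_mean(L) - delta, lo, hi, xtol=1e-10)
    logz = float(logsumexp(lam * h) - np.log(h.size))
    return lam, logz


def train_shared_sketch(training_frames: list[np.ndarray], n_elements: int,
                        dictionary: GaborDictionary,
                        inhibition_radius: int | None = None,
                        roi: np.ndarray | None = None,
                        bounds: PerturbationBounds = PerturbationBounds(),
                        saturation: float = 6.0,
                        rng: np.random.Generator | None = None,
                        ) -> ActiveBasisTemplate:
    """Greedy shared-sketch selection of a sparse Gabor template.

    At each step the placement (row, col, orientation, scale) maximizing
    the pooled saturated response summed over all training frames is
    chosen, then every placement within the inhibition radius is zeroed
    in every frame.  ``roi`` (boolean mask) restricts candidate centers —
    the motion-pathway guidance hook.
    """
    if len(training_frames) == 0:
        raise ValueError("training set must not be empty")
    shapes = {np.asarray(f).shape for f in training_frames}
    if len(shapes) != 1:
        raise ValueError(f"training frames must share one shape, got {shapes}")
    frame_shape = shapes.pop()
    if inhibition_radius is None:
        inhibition_radius = dictionary.kernel_size(1) // 2
    if rng is None:
        rng = np.random.default_rng(0)

    stacks = [response_stack(f, dictionary, saturation) for f in training_frames]
    M = len(stacks)
    n_ori, n_sc = dictionary.n_orientations, dictionary.n_scales
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != frame_shape:
            raise ValueError("roi shape must match frame shape")

    # background pool for the normalizer fit: subsampled saturated responses
    pool = []
    for st in stacks:
        for m in st.values():
            flat = m.ravel()
            idx = rng.choice(flat.size, size=min(500, flat.size), replace=False)
            pool.append(flat[idx])
    background = np.concatenate(pool)

    # selection pools over location only: orientation shifts stay a
    # match-time perturbation, else adjacent orientations tie by sharing
    # the same pooled maximum
    select_bounds = PerturbationBounds(location=bounds.location, orientation=0)
    # nominal centers must stay outside every inhibition neighborhood,
    # otherwise pooling could re-enter a suppressed zone
    unsuppressed = np.ones(frame_shape, dtype=bool)
    elements: list[TemplateElement] = []
    deltas: list[float] = []
    for _ in range(n_elements):
        best_val = 0.0
        best_key = None  # (row, col, ori, scale)
        for si in range(1, n_sc + 1):
            for oi in range(n_ori):
                gain = np.zeros(frame_shape)
                for st in stacks:
                    gain += _pooled_map(st, si, oi, select_bounds, n_ori)
                gain = np.where(unsuppressed, gain, 0.0)
                if roi is not None:
                    gain = np.where(roi, gain, 0.0)
                idx = np.unravel_index(np.argmax(gain), gain.shape)
                v = gain[idx]
                key = (int(idx[0]), int(idx[1]), oi, si)
                if v > best_val or (v == best_val and best_key is not None
                                    and key < best_key):
                    best_val = v
                    best_key = key
        if best_key is None or best_val <= 0.0:
            logger.warning("shared sketch stopped early at %d/%d elements",
                           len(elements), n_elements)
            break
        row, col, oi, si = best_key
        elements.append(TemplateElement(row, col, oi, si))
        deltas.append(best_val / M)
        for st in stacks:
            _suppress(st, row, col, inhibition_radius, n_ori, n_sc)
        r0 = max(0, row - inhibition_radius)
        c0 = max(0, col - inhibition_radius)
        unsuppressed[r0:row + inhibition_radius + 1,
                     c0:col + inhibition_radius + 1] = False

    weights = np.zeros(len(elements))
    log_normalizers = np.zeros(len(elements))
    for i, d in enumerate(deltas):
        weights[i], log_normalizers[i] = _fit_lambda(d, background)

    return ActiveBasisTemplate(
        elements=elements, weights=weights, deltas=np.asarray(deltas),
        log_normalizers=log_normalizers, bounds=bounds,
        frame_shape=frame_shape, dictionary=dictionary,
        saturation=saturation, inhibition_radius=inhibition_radius)


def match_template(frame: np.ndarray, template: ActiveBasisTemplate,
                   roi: np.ndarray | None = None) -> MatchResult:
    """Score a template against a frame over all integer translations.

    The score at offset ``(dy, dx)`` places every element at its nominal
    center shifted by the offset and sums ``lambda_i * pooled_response``
    minus the cached log-normalizers.  Returns the best offset (ties:
    smallest row then col) and the template centroid moved by it, clipped
    to the frame lattice.
    """
    frame = np.asarray(frame, dtype=float)
    if template.n_elements == 0:
        return MatchResult(score=0.0, location=(0, 0), offset=(0, 0),
                           per_element_responses=np.zeros(0), degenerate=True)
    H, W = frame.shape
    stack = response_stack(frame, template.dictionary, template.saturation)
    n_ori = template.dictionary.n_orientations
    score = np.full((2 * H - 1, 2 * W - 1), -np.sum(template.log_normalizers))
    pooled_cache: dict[tuple[int, int], np.ndarray] = {}
    padded: dict[tuple[int, int], np.ndarray] = {}
    for el, lam in zip(template.elements, template.weights):
        key = (el.scale_index, el.orientation_index)
        if key not in pooled_cache:
            pooled_cache[key] = _pooled_map(stack, el.scale_index,
                                            el.orientation_index,
                                            template.bounds, n_ori)
            padded[key] = np.pad(pooled_cache[key],
                                 ((H - 1, H - 1), (W - 1, W - 1)))
        # score[a, b] uses pooled[(a - (H-1)) + row, (b - (W-1)) + col]
        score += lam * padded[key][el.row:el.row + 2 * H - 1,
                                   el.col:el.col + 2 * W - 1]
    if roi is not None:
        cy, cx = template.centroid
        off_y = np.arange(2 * H - 1) - (H - 1)
        off_x = np.arange(2 * W - 1) - (W - 1)
        ly = np.clip(np.round(cy + off_y).astype(int), 0, H - 1)
        lx = np.clip(np.round(cx + off_x).astype(int), 0, W - 1)
        allowed = np.asarray(roi, dtype=bool)[np.ix_(ly, lx)]
        score = np.where(allowed, score, -np.inf)
    idx = np.unravel_index(np.argmax(score), score.shape)
    dy, dx = int(idx[0]) - (H - 1), int(idx[1]) - (W - 1)
    cy, cx = template.centroid
    loc = (int(np.clip(round(cy + dy), 0, H - 1)),
           int(np.clip(round(cx + dx), 0, W - 1)))
    per_el = np.array([
        local_max_pool(stack,
                       TemplateElement(min(max(el.row + dy, 0), H - 1),
                                       min(max(el.col + dx, 0), W - 1),
                                       el.orientation_index, el.scale_index),
                       template.bounds, n_ori)[0]
        for el in template.elements])
    return MatchResult(score=float(score[idx]), location=loc, offset=(dy, dx),
                       per_element_responses=per_el)
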
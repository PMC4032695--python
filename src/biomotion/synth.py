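"""Seeded synthetic fixture generators.

Three kinds of input stand in for external benchmark video: oriented-bar
images (template-learning fixtures), wrapped-translation frame pairs
with exact ground-truth flow, and blob-actor "action" sequences whose
motion energy is confined to the upper or lower half-frame.  Every
generator is a pure function of its spec; a manifest makes each fixture
self-describing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .flow import FlowField

__all__ = ["BarSpec", "TranslateSpec", "ActionSpec", "gen_bar_images",
           "gen_translation_pair", "gen_action_sequence",
           "write_sequence", "read_sequence"]


@dataclass(frozen=True)
class BarSpec:
    shape: tuple[int, int] = (48, 48)
    seed: int = 0
    orientation: float = np.pi / 2      # bar direction, radians
    length: float = 24.0
    width: float = 3.0
    noise_sigma: float = 0.1
    n_images: int = 5
    center_jitter: float = 2.0          # px of per-image center jitter


@dataclass(frozen=True)
class TranslateSpec:
    shape: tuple[int, int] = (64, 64)
    seed: int = 0
    dx: int = 2
    dy: int = 1
    smoothness: float = 3.0             # Gaussian sigma of the texture


@dataclass(frozen=True)
class ActionSpec:
    shape: tuple[int, int] = (64, 64)
    seed: int = 0
    limb_group: str = "upper"           # 'upper' | 'lower'
    n_frames: int = 12
    amplitude: float = 8.0              # px of appendage oscillation
    period: float = 8.0                 # frames per cycle
    phase: float = 0.0
    clutter: float = 0.05               # static background noise level
    blob_sigma: float = 2.5


def _render_bar(shape, center, theta, length, width):
    """Anti-aliased bar: intensity ramps over 1 px at the boundary."""
    H, W = shape
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    x = cols - center[1]
    y = rows - center[0]
    along = x * np.cos(theta) + y * np.sin(theta)
    normal = -x * np.sin(theta) + y * np.cos(theta)
    d_along = np.maximum(np.abs(along) - length / 2.0, 0.0)
    d_norm = np.maximum(np.abs(normal) - width / 2.0, 0.0)
    dist = np.hypot(d_along, d_norm)
    return np.clip(1.0 - dist, 0.0, 1.0)


def gen_bar_images(spec: BarSpec) -> tuple[list[np.ndarray], dict]:
    """Noisy images each containing one oriented bar; manifest has truth."""
    H, W = spec.shape
    diag = float(np.hypot(H, W))
    if spec.length > diag or spec.width > min(H, W):
        raise ValueError(f"bar ({spec.length}x{spec.width}) larger than "
                         f"frame {spec.shape}")
    rng = np.random.default_rng(spec.seed)
    frames, centers = [], []
    for _ in range(spec.n_images):
        jitter = rng.uniform(-spec.center_jitter, spec.center_jitter, size=2)
        center = (H / 2.0 + jitter[0], W / 2.0 + jitter[1])
        img = _render_bar(spec.shape, center, spec.orientation,
                          spec.length, spec.width)
        img = img + spec.noise_sigma * rng.standard_normal(spec.shape)
        frames.append(img)
        centers.append([float(center[0]), float(center[1])])
    manifest = {"kind": "bars", "spec": _spec_dict(spec), "centers": centers,
                "orientation": float(spec.orientation)}
    return frames, manifest


def gen_translation_pair(spec: TranslateSpec,
                         ) -> tuple[np.ndarray, np.ndarray, FlowField]:
    """Smooth texture and its toroidal integer translation.

    Frame2 places each frame1 pixel at (row+dy, col+dx) modulo the frame,
    so ground truth is exactly (u, v) = (dx, dy) everywhere.
    """
    H, W = spec.shape
    if abs(spec.dx) >= min(H, W) / 4 or abs(spec.dy) >= min(H, W) / 4:
        raise ValueError("|dx|, |dy| must be < min(H, W)/4")
    rng = np.random.default_rng(spec.seed)
    tex = gaussian_filter(rng.standard_normal(spec.shape), spec.smoothness,
                          mode="wrap")
    tex = (tex - tex.min()) / (tex.max() - tex.min() + 1e-12)
    frame2 = np.roll(tex, (spec.dy, spec.dx), axis=(0, 1))
    gt = FlowField(u=np.full(spec.shape, float(spec.dx)),
                   v=np.full(spec.shape, float(spec.dy)),
                   mask=np.ones(spec.shape), direction="forward")
    return tex, frame2, gt


def gen_action_sequence(spec: ActionSpec) -> tuple[list[np.ndarray], dict]:
    """Blob actor: static trunk + one oscillating appendage in one half-frame.

    The appendage sweeps horizontally inside the upper (or lower) half, so
    all inter-frame motion energy is confined to that half; per-frame
    motion-energy centroids are recorded in the manifest.
    """
    if spec.n_frames < 6:
        raise ValueError("need at least 6 frames")
    if spec.limb_group not in ("upper", "lower"):
        raise ValueError(f"unknown limb group {spec.limb_group!r}")
    H, W = spec.shape
    rng = np.random.default_rng(spec.seed)
    background = spec.clutter * rng.random(spec.shape)
    rows, cols = np.mgrid[0:H, 0:W].astype(float)

    # static trunk: vertical soft bar through the frame center
    trunk = np.exp(-(((cols - W / 2.0) / 2.5) ** 2)) * \
        np.exp(-(((rows - H / 2.0) / (H / 5.0)) ** 2))

    y0 = H / 4.0 if spec.limb_group == "upper" else 3.0 * H / 4.0
    amp = min(spec.amplitude, W / 2.0 - 2.0 * spec.blob_sigma - 1.0)
    frames = []
    centroids = []
    prev = None
    for t in range(spec.n_frames):
        x0 = W / 2.0 + amp * np.sin(2.0 * np.pi * t / spec.period + spec.phase)
        blob = np.exp(-((rows - y0) ** 2 + (cols - x0) ** 2)
                      / (2.0 * spec.blob_sigma ** 2))
        img = np.clip(background + 0.6 * trunk + blob, 0.0, 1.0)
        frames.append(img)
        if prev is not None:
            diff = np.abs(img - prev)
            total = diff.sum()
            if total > 0:
                centroids.append([float((diff * rows).sum() / total),
                                  float((diff * cols).sum() / total)])
            else:
                centroids.append([float(y0), float(x0)])
        prev = img
    manifest = {"kind": "action", "spec": _spec_dict(spec),
                "label": spec.limb_group, "motion_centroids": centroids}
    return frames, manifest


def _spec_dict(spec) -> dict:
    d = asdict(spec)
    d["shape"] = list(d["shape"])
    return d


def write_sequence(frames: list[np.ndarray], manifest: dict,
                   out_dir: str | Path) -> Path:
    """Write frames as numbered 8-bit grayscale PNGs plus manifest.json."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(frames):
        arr = np.clip(np.asarray(f, dtype=float), 0.0, 1.0)
        iio.imwrite(out / f"frame_{i:04d}.png",
                    (arr * 255.0).round().astype(np.uint8))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_sequence(in_dir: str | Path) -> tuple[list[np.ndarray], dict | None]:
    """Read an ordered image-sequence directory as float frames in [0,1]."""
    import imageio.v3 as iio

    src = Path(in_dir)
    exts = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff", ".pgm"}
    files = sorted(p for p in src.iterdir()
                   if p.suffix.lower() in exts)
    if not files:
        raise ValueError(f"no image frames found in {src}")
    frames = []
    for p in files:
        arr = np.asarray(iio.imread(p), dtype=float)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
        frames.append(arr / 255.0 if arr.max() > 1.0 else arr)
    manifest = None
    mpath = src / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
    return frames, manifest
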
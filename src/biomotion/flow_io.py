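"""Middlebury .flo flow-field I/O and optional 16-bit speed-map PNGs."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .flow import FlowField, flow_speed

__all__ = ["write_flo", "read_flo", "write_speed_png"]

_FLO_MAGIC = 202021.25


def write_flo(field: FlowField, path: str | Path) -> None:
    """Write interleaved little-endian float32 (u, v) with the .flo magic."""
    H, W = field.shape
    with open(path, "wb") as fh:
        np.float32(_FLO_MAGIC).astype("<f4").tofile(fh)
        np.array([W, H], dtype="<i4").tofile(fh)
        data = np.empty((H, W, 2), dtype="<f4")
        data[..., 0] = field.u
        data[..., 1] = field.v
        data.tofile(fh)


def read_flo(path: str | Path) -> FlowField:
    with open(path, "rb") as fh:
        magic = np.fromfile(fh, dtype="<f4", count=1)
        if magic.size != 1 or magic[0] != np.float32(_FLO_MAGIC):
            raise ValueError(f"{path}: not a .flo file (bad magic)")
        W, H = (int(x) for x in np.fromfile(fh, dtype="<i4", count=2))
        data = np.fromfile(fh, dtype="<f4", count=H * W * 2)
        if data.size != H * W * 2:
            raise ValueError(f"{path}: truncated .flo payload")
    data = data.reshape(H, W, 2)
    return FlowField(u=data[..., 0].astype(float),
                     v=data[..., 1].astype(float),
                     mask=np.ones((H, W)), direction="forward")


def write_speed_png(field: FlowField, path: str | Path,
                    scale: float = 1000.0) -> None:
    """Speed map as 16-bit PNG, fixed-point with ``scale`` units per px/frame."""
    import imageio.v3 as iio

    speed = np.clip(flow_speed(field) * scale, 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), speed)
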
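"""Versioned model container: plain-text JSON header + raw binary payload.

Layout::

    b"BIOMOTION1\\n"
    8-byte little-endian header length
    UTF-8 JSON header  {"meta": {...}, "arrays": [{name, dtype, shape}]}
    concatenated C-order array payloads in header order

Writing is fully deterministic (sorted keys, no timestamps), so identical
models serialize byte-identically; round trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_container", "read_container"]

MAGIC = b"BIOMOTION1\n"


def write_container(path: str | Path, meta: dict,
                    arrays: dict[str, np.ndarray]) -> None:
    entries = []
    payloads = []
    for name in sorted(arrays):
        arr = np.ascontiguousarray(arrays[name])
        entries.append({"name": name, "dtype": arr.dtype.str,
                        "shape": list(arr.shape)})
        payloads.append(arr.tobytes())
    header = json.dumps({"meta": meta, "arrays": entries},
                        sort_keys=True, separators=(",", ":")).encode()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(len(header).to_bytes(8, "little"))
        fh.write(header)
        for p in payloads:
            fh.write(p)


def read_container(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    with open(path, "rb") as fh:
        if fh.read(len(MAGIC)) != MAGIC:
            raise ValueError(f"{path}: not a biomotion container")
        hlen = int.from_bytes(fh.read(8), "little")
        header = json.loads(fh.read(hlen).decode())
        arrays = {}
        for entry in header["arrays"]:
            dtype = np.dtype(entry["dtype"])
            count = int(np.prod(entry["shape"])) if entry["shape"] else 1
            buf = fh.read(count * dtype.itemsize)
            arrays[entry["name"]] = np.frombuffer(
                buf, dtype=dtype).reshape(entry["shape"]).copy()
    return header["meta"], arrays
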
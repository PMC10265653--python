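"""Standard-format I/O: multi-page TIFF stacks, CSV tables, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_stack(path, stack: np.ndarray, pixel_size_um: float | None = None,
                metadata: dict | None = None) -> None:
    """Write a (n, H, W) stack as a multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, np.float32))
    side = dict(metadata or {})
    if pixel_size_um is not None:
        side["pixel_size_um"] = pixel_size_um
    if side:
        path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack and its JSON sidecar (empty dict if absent)."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return np.asarray(stack, float), meta


def read_height_map(path) -> np.ndarray:
    """AFM height map from TIFF or whitespace-delimited matrix text (nm)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), float)
    return np.loadtxt(path)


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
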
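"""File I/O: multi-page TIFF stacks, trace/behavior CSV tables, result JSON.

Image stacks are stored frame-major, channel-interleaved, 32-bit float:
a (n_frames, 2, H, W) stack is written as 2·n_frames TIFF pages in the
order (frame0/ch0, frame0/ch1, frame1/ch0, ...).  Masks are written as
single-page uint8 TIFFs (non-zero = inside the imaged region).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (n_frames, n_channels, H, W) or (n_channels, H, W) stack as a
    channel-interleaved multi-page float32 TIFF."""
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim == 3:
        stack = stack[None]
    if stack.ndim != 4:
        raise ValueError("expected (n_frames, n_channels, H, W) stack")
    n_frames, n_ch, h, w = stack.shape
    tifffile.imwrite(path, stack.reshape(n_frames * n_ch, h, w),
                     metadata={"n_frames": n_frames, "n_channels": n_ch})


def read_stack(path, n_channels: int = 2) -> np.ndarray:
    """Read a channel-interleaved multi-page TIFF back to
    (n_frames, n_channels, H, W)."""
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % n_channels:
        raise ValueError(
            f"page count {pages.shape[0]} not divisible by {n_channels} channels"
        )
    n_frames = pages.shape[0] // n_channels
    return pages.reshape(n_frames, n_channels, *pages.shape[1:]).astype(np.float32)


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def read_trace_csv(path) -> pd.DataFrame:
    """Long-format trace table with columns frame, channel, value."""
    df = pd.read_csv(path)
    missing = {"frame", "channel", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return df


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
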
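"""Shared file I/O: TIFF stack layout, flat config files, provenance tables.

Stack layout on disk: one multi-page TIFF, pages ordered z-major /
channel-minor, channel order ``ID, IA, IF`` (donor, direct acceptor, raw
FRET).  The layout and per-channel backgrounds travel in the TIFF
ImageDescription as JSON, so a written stack reads back bit-identically.

All tables are tab-separated text with a header row; every table written
by the pipeline carries provenance comment lines (``# key: value``) with
the resolved config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fret import CHANNEL_ORDER, ChannelStack, FretDataError

__all__ = [
    "read_stack",
    "write_stack",
    "read_config",
    "write_config",
    "write_table",
    "read_table",
    "config_hash",
]


def write_stack(path, stack: ChannelStack) -> None:
    """Write a three-channel stack as a multi-page TIFF (z-major, channel-minor)."""
    pages = []
    for t in range(stack.n_frames):
        for c in CHANNEL_ORDER:
            pages.append(stack.channel(c)[t].astype(np.float32))
    meta = {
        "layout": "z-major,channel-minor",
        "channels": list(CHANNEL_ORDER),
        "n_frames": stack.n_frames,
        "background": {c: float(stack.background.get(c, np.nan)) for c in CHANNEL_ORDER},
    }
    tifffile.imwrite(str(path), np.stack(pages), photometric="minisblack",
                     description=json.dumps(meta))


def read_stack(path) -> ChannelStack:
    """Read a stack written by :func:`write_stack`, validating the layout."""
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    if arr.ndim == 2:
        arr = arr[None]
    n_pages = arr.shape[0]
    if n_pages % len(CHANNEL_ORDER) != 0:
        raise FretDataError(
            f"{path.name}: {n_pages} page(s) is not a multiple of "
            f"{len(CHANNEL_ORDER)} — layout must be z-major/channel-minor "
            f"with channels {CHANNEL_ORDER} per frame (page {n_pages - 1} is the last)"
        )
    background: dict[str, float] = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        if meta.get("channels") not in (None, list(CHANNEL_ORDER)):
            raise FretDataError(
                f"{path.name}: channel order {meta['channels']} does not match "
                f"the documented order {list(CHANNEL_ORDER)}"
            )
        bg = meta.get("background", {})
        background = {c: float(v) for c, v in bg.items() if np.isfinite(v)}
    n_frames = n_pages // len(CHANNEL_ORDER)
    arr = arr.astype(np.float64).reshape(n_frames, len(CHANNEL_ORDER), *arr.shape[1:])
    return ChannelStack(
        ID=arr[:, 0], IA=arr[:, 1], IF=arr[:, 2], background=background
    )


def write_efficiency_map(path, emap: np.ndarray) -> None:
    """Ground-truth (or computed) single-channel map as 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(emap, dtype=np.float32),
                     photometric="minisblack")


def read_efficiency_map(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)


# ---------------------------------------------------------------------------
# flat key-value config
# ---------------------------------------------------------------------------

def write_config(path, values: dict) -> None:
    lines = [f"{k} = {values[k]}" for k in values]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path, known_keys: set[str] | None = None) -> dict[str, str]:
    """Parse ``key = value`` lines; unknown keys are errors (fail-fast)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if known_keys is not None and key not in known_keys:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        out[key] = value
    return out


def config_hash(values: dict) -> str:
    payload = json.dumps({k: str(v) for k, v in sorted(values.items())})
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# provenance-stamped tables
# ---------------------------------------------------------------------------

def write_table(path, frame: pd.DataFrame, provenance: dict | None = None) -> None:
    """TSV with a header row, preceded by ``# key: value`` provenance lines."""
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
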
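"""Shifted-array helpers shared by the scheduled (per-MCS) mechanisms."""

from __future__ import annotations

import numpy as np

#: Moore offsets in raster order.
MOORE_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, -1),
                 (0, 1), (1, -1), (1, 0), (1, 1))
#: von Neumann (first-order) offsets.
VN_OFFSETS = ((-1, 0), (0, -1), (0, 1), (1, 0))


def shifted(arr: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """Array whose entry (r, c) holds arr[r+dr, c+dc] (``fill`` off-grid)."""
    out = np.full_like(arr, fill)
    h, w = arr.shape
    rs = slice(max(0, dr), h + min(0, dr))
    cs = slice(max(0, dc), w + min(0, dc))
    rd = slice(max(0, -dr), h + min(0, -dr))
    cd = slice(max(0, -dc), w + min(0, -dc))
    out[rd, cd] = arr[rs, cs]
    return out


def neighbor_any(mask_or_pred, offsets=MOORE_OFFSETS):
    """OR of shifted copies of a boolean array over the given offsets."""
    out = np.zeros_like(mask_or_pred, dtype=bool)
    for dr, dc in offsets:
        out |= shifted(mask_or_pred, dr, dc, False)
    return out
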
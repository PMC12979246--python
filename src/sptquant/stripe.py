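"""Laser-stripe recruitment quantification.

For each cell and timepoint three region means are taken: Ax over the
irradiated stripe, Cx over the rest of the nucleus (nucleus minus stripe),
and B over a background region outside the cell.  Relative stripe
brightness is Sx = (Ax - B) / (Cx - B); because proteins are not
distributed uniformly in the nucleus, each series is shifted so that its
pre-irradiation value equals exactly 1 (subtract raw[0] - 1 from every
timepoint — an additive shift that preserves all differences between
timepoints).  Cells are aggregated per condition as mean +- SEM,
SEM = SD / sqrt(n cells) with the n-1 sample SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class CellSeries:
    cell_id: str
    timepoints: np.ndarray
    sx_raw: np.ndarray
    sx_norm: np.ndarray


def measure_regions(stack: np.ndarray, stripe_mask: np.ndarray,
                    nucleus_mask: np.ndarray, background_mask: np.ndarray,
                    cell_id: str = "cell") -> pd.DataFrame:
    """Per-timepoint mean brightness of stripe / nucleus-remainder / background.

    ``stripe_mask`` may be 2-D (static) or (T, H, W) when the hand-drawn
    stripe moves with the cell; the nucleus and background masks may
    likewise be 2-D or per-timepoint.  The nucleus remainder is
    nucleus & ~stripe, recomputed per timepoint.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (T, H, W)")
    n_t = stack.shape[0]

    def per_t(mask: np.ndarray, name: str) -> np.ndarray:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            return np.broadcast_to(mask, stack.shape)
        if mask.shape != stack.shape:
            raise ValueError(f"{name} mask shape does not match the stack")
        return mask

    stripe = per_t(stripe_mask, "stripe")
    nucleus = per_t(nucleus_mask, "nucleus")
    bg = per_t(background_mask, "background")
    rows = []
    for t in range(n_t):
        remainder = nucleus[t] & ~stripe[t]
        for name, m in (("stripe", stripe[t]), ("nucleus remainder", remainder),
                        ("background", bg[t])):
            if not m.any():
                raise ValueError(f"empty {name} region at timepoint {t}")
        rows.append({
            "cell_id": cell_id,
            "timepoint": t,
            "ax": float(stack[t][stripe[t]].mean()),
            "cx": float(stack[t][remainder].mean()),
            "b": float(stack[t][bg[t]].mean()),
        })
    return pd.DataFrame(rows)


def compute_sx(ax, cx, b):
    """Relative stripe brightness Sx = (Ax - B) / (Cx - B).

    Accepts scalars or aligned arrays; requires the nucleus to sit above
    background (Cx > B), otherwise the ratio is meaningless.
    """
    ax = np.asarray(ax, dtype=float)
    cx = np.asarray(cx, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(cx <= b):
        raise ValueError("nucleus not above background (Cx <= B)")
    sx = (ax - b) / (cx - b)
    return float(sx) if sx.ndim == 0 else sx


def normalize_series(raw) -> np.ndarray:
    """Shift a raw Sx series so the first (pre-irradiation) timepoint is 1.

    The shift is additive — subtract raw[0] - 1 everywhere — so differences
    between timepoints are preserved exactly.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 1:
        raise ValueError("series needs at least one timepoint")
    return raw - (raw[0] - 1.0)


def quantify_cell(stack, stripe_mask, nucleus_mask, background_mask,
                  cell_id: str = "cell") -> CellSeries:
    """measure_regions -> Sx -> first-timepoint normalization for one cell."""
    meas = measure_regions(stack, stripe_mask, nucleus_mask, background_mask,
                           cell_id=cell_id)
    sx = compute_sx(meas["ax"].to_numpy(), meas["cx"].to_numpy(),
                    meas["b"].to_numpy())
    return CellSeries(
        cell_id=cell_id,
        timepoints=meas["timepoint"].to_numpy(),
        sx_raw=np.asarray(sx, dtype=float),
        sx_norm=normalize_series(sx),
    )


def aggregate_condition(cells: list[CellSeries], condition: str = "",
                        normalized: bool = True) -> pd.DataFrame:
    """Cross-cell mean and SEM per timepoint for one condition.

    SEM = sample SD (ddof=1) / sqrt(n cells); with a single cell the SEM is
    reported as 0 with a warning.  All cells must share the timepoint grid.
    """
    if not cells:
        raise ValueError("no cells to aggregate")
    t0 = cells[0].timepoints
    for c in cells[1:]:
        if len(c.timepoints) != len(t0) or np.any(c.timepoints != t0):
            raise ValueError("cells have mismatched timepoint grids")
    values = np.stack([c.sx_norm if normalized else c.sx_raw for c in cells])
    n = values.shape[0]
    mean = values.mean(axis=0)
    if n == 1:
        log.warning("condition %r has a single cell: SEM reported as 0",
                    condition)
        sem = np.zeros_like(mean)
    else:
        sem = values.std(axis=0, ddof=1) / np.sqrt(n)
    return pd.DataFrame({
        "condition": condition,
        "timepoint": t0,
        "mean": mean,
        "sem": sem,
        "n": n,
    })
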
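"""Per-track diffusion estimation and bound/mobile population statistics.

The apparent diffusion coefficient of a track is estimated from its lag-1
mean squared displacement, D = MSD / (4 * dt) for 2-D motion (single-lag
estimator; displacements spanning a one-frame gap are excluded rather than
rescaled).  A track is classified *bound* when D <= 0.3 um^2/s (inclusive)
and *mobile* otherwise; the bound fraction — the proportion of bound tracks
— is the summary statistic for genome-wide chromatin binding.  Bound
fractions are computed per cell and compared across conditions with a
one-way fixed-effects ANOVA.

With per-axis localization error sigma, the estimator is biased upward:
E[D] = D_true + sigma^2 / dt, and for a track of n independent single-frame
steps, D * 2n / D_eff follows a chi-square distribution with 2n degrees of
freedom (D_eff = D_true + sigma^2/dt).  Those closed forms are used by the
calibration tests, not by the estimator itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import Track

D_THRESHOLD_DEFAULT = 0.3   # um^2/s boundary between bound and mobile


def one_step_msd(track: Track) -> float:
    """Mean squared single-frame displacement of a track, in um^2.

    Only consecutive-frame steps enter the mean; steps across a bridged
    one-frame gap are skipped.  Raises if the track has no single-frame
    step at all.
    """
    if not track.x_um:
        raise ValueError("track carries no micrometre coordinates")
    frames = np.asarray(track.frames)
    x = np.asarray(track.x_um)
    y = np.asarray(track.y_um)
    single = np.diff(frames) == 1
    if not single.any():
        raise ValueError("no single-frame steps")
    dx = np.diff(x)[single]
    dy = np.diff(y)[single]
    return float(np.mean(dx ** 2 + dy ** 2))


def apparent_d(msd: float, frame_interval: float) -> float:
    """D = MSD / (4 * dt) for 2-D Brownian motion."""
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    return msd / (4.0 * frame_interval)


def classify_track(d_app: float, d_threshold: float = D_THRESHOLD_DEFAULT) -> str:
    """'bound' iff d_app <= d_threshold (inclusive), else 'mobile'."""
    if d_app < 0:
        raise ValueError("d_app must be nonnegative")
    return "bound" if d_app <= d_threshold else "mobile"


def analyze_tracks(tracks: list[Track], frame_interval: float,
                   d_threshold: float = D_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Per-track table: track_id, n_steps, msd_um2, d_app, label."""
    rows = []
    for t in tracks:
        frames = np.asarray(t.frames)
        n_single = int((np.diff(frames) == 1).sum())
        msd = one_step_msd(t)
        d = apparent_d(msd, frame_interval)
        rows.append({
            "track_id": t.track_id,
            "n_steps": n_single,
            "msd_um2": msd,
            "d_app": d,
            "label": classify_track(d, d_threshold),
        })
    return pd.DataFrame(rows, columns=["track_id", "n_steps", "msd_um2",
                                       "d_app", "label"])


def bound_fraction(track_diffusions: pd.DataFrame) -> float:
    """Fraction of tracks labeled bound; errors on an empty table."""
    if len(track_diffusions) == 0:
        raise ValueError("no tracks: bound fraction undefined")
    return float((track_diffusions["label"] == "bound").mean())


def default_bin_edges() -> np.ndarray:
    return np.arange(0.0, 2.0 + 1e-9, 0.05)


def d_histogram(d_values, bin_edges=None) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of apparent D with a trailing overflow bin.

    Returns (edges, masses); ``masses`` has ``len(edges)`` entries, the last
    being the mass above the final edge.  Masses sum to 1.
    """
    d = np.asarray(d_values, dtype=float)
    if d.size == 0:
        raise ValueError("no diffusion coefficients to histogram")
    if bin_edges is None:
        bin_edges = default_bin_edges()
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    counts, _ = np.histogram(d, bins=edges)
    overflow = int((d > edges[-1]).sum())
    masses = np.append(counts, overflow) / d.size
    return edges, masses


@dataclass
class CellDiffusionSummary:
    cell_id: str
    condition: str
    n_tracks: int
    bound_fraction: float
    hist_edges: np.ndarray
    hist_masses: np.ndarray


def summarize_cell(cell_id: str, condition: str, per_track: pd.DataFrame,
                   bin_edges=None) -> CellDiffusionSummary:
    edges, masses = d_histogram(per_track["d_app"], bin_edges)
    return CellDiffusionSummary(
        cell_id=cell_id,
        condition=condition,
        n_tracks=len(per_track),
        bound_fraction=bound_fraction(per_track),
        hist_edges=edges,
        hist_masses=masses,
    )


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    group_sds: dict[str, float]


def compare_conditions(fractions_by_condition: dict[str, list[float]]
                       ) -> AnovaResult:
    """One-way fixed-effects ANOVA on per-cell bound fractions.

    Also reports each condition's mean +- SD (sample SD, ddof=1).  Requires
    at least two conditions with at least two cells each.  When every cell
    in every condition carries the same value the F statistic is 0 and
    p = 1 (scipy returns NaN for a zero within-group variance; that
    degenerate case is resolved here).
    """
    if len(fractions_by_condition) < 2:
        raise ValueError("need >= 2 conditions")
    groups = {}
    for label, vals in fractions_by_condition.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"condition {label!r} has < 2 cells")
        groups[label] = arr
    arrays = list(groups.values())
    with warnings.catch_warnings():
        # scipy warns (and returns NaN) when every value is identical; that
        # degenerate case is resolved below as F = 0, p = 1
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0 and ss_between == 0:
        f_stat, p = 0.0, 1.0
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=k - 1,
        df_within=n - k,
        p_value=float(p),
        group_means={l: float(a.mean()) for l, a in groups.items()},
        group_sds={l: float(a.std(ddof=1)) for l, a in groups.items()},
    )


def expected_bound_fraction(f_bound: float, d_bound: float, d_mobile: float,
                            n_steps: int, loc_sigma: float,
                            frame_interval: float,
                            d_threshold: float = D_THRESHOLD_DEFAULT) -> float:
    """Closed-form expected *measured* bound fraction for the mixture model.

    For tracks of ``n_steps`` independent single-frame steps with per-axis
    localization error ``loc_sigma``, the apparent D of a population with
    true coefficient D is D_eff * chi2_{2n} / (2n), D_eff = D + sigma^2/dt.
    Each population therefore crosses the threshold with a chi-square tail
    probability, and the measured bound fraction mixes the two.
    """
    def p_below(d_true: float) -> float:
        d_eff = d_true + loc_sigma ** 2 / frame_interval
        return float(stats.chi2.cdf(2 * n_steps * d_threshold / d_eff,
                                    df=2 * n_steps))

    return f_bound * p_below(d_bound) + (1.0 - f_bound) * p_below(d_mobile)
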
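"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (closed forms, exhaustive enumeration,
iterative least squares) and shares no code with the implementation paths
it validates.
"""

from __future__ import annotations


import numpy as np
from scipy import optimize, special, stats


def pixel_integrated_gaussian(k: int, dx: float, dy: float, sigma: float,
                              photons: float = 1000.0) -> np.ndarray:
    """K x K ROI of an isotropic Gaussian integrated over unit pixels.

    (dx, dy) is the spot offset from the ROI center in pixel-center
    coordinates; x is the column axis.
    """
    c0 = (k - 1) / 2.0
    s = sigma * np.sqrt(2.0)
    cols = np.arange(k)
    fx = 0.5 * (special.erf((cols + 0.5 - (c0 + dx)) / s)
                - special.erf((cols - 0.5 - (c0 + dx)) / s))
    fy = 0.5 * (special.erf((cols + 0.5 - (c0 + dy)) / s)
                - special.erf((cols - 0.5 - (c0 + dy)) / s))
    return photons * np.outer(fy, fx)


def gaussian_fit_localize(roi: np.ndarray, sigma: float) -> tuple[float, float]:
    """Nonlinear least-squares fit of a pixel-integrated Gaussian to an ROI."""
    roi = np.asarray(roi, dtype=float)
    k = roi.shape[0]

    def resid(p):
        dx, dy, amp, bg = p
        return (amp * pixel_integrated_gaussian(k, dx, dy, sigma, 1.0)
                + bg - roi).ravel()

    res = optimize.least_squares(resid, [0.0, 0.0, roi.sum(), roi.min()])
    return float(res.x[0]), float(res.x[1])


def brute_force_assignment(last_xy: np.ndarray, locs: np.ndarray,
                           radius: float) -> list[int]:
    """Exhaustive minimum-cost radius-gated one-to-one assignment.

    Cost = sum of squared linked distances + radius^2 for every unmatched
    track and every unmatched localization.  Returns per-track localization
    index or -1.  Depth-first enumeration of every feasible matching, with
    branches abandoned only once their partial cost already exceeds the
    best complete matching found (all future contributions are >= 0).
    """
    n, m = len(last_xy), len(locs)
    c0 = radius ** 2
    if n == 0 or m == 0:
        return [-1] * n
    d2 = ((np.asarray(last_xy)[:, None, :]
           - np.asarray(locs)[None, :, :]) ** 2).sum(axis=2)
    best_cost = [np.inf]
    best = [[-1] * n]
    assign = [-1] * n

    def rec(i: int, used: frozenset, cost: float) -> None:
        if cost >= best_cost[0]:
            return
        if i == n:
            total = cost + c0 * (m - len(used))
            if total < best_cost[0] - 1e-12:
                best_cost[0] = total
                best[0] = assign.copy()
            return
        for j in range(m):
            if j not in used and d2[i, j] <= c0:
                assign[i] = j
                rec(i + 1, used | {j}, cost + float(d2[i, j]))
        assign[i] = -1
        rec(i + 1, used, cost + c0)

    rec(0, frozenset(), 0.0)
    return best[0]


def brute_force_tracks(loc_table, radius: float = 8.0,
                       memory: int = 1) -> list[list[tuple]]:
    """Mini tracker with exhaustive per-frame assignment.

    ``loc_table`` is a DataFrame with frame, x_px, y_px.  Returns each track
    as a list of (frame, x, y) tuples.
    """
    tracks: list[list[tuple]] = []
    open_tracks: list[dict] = []
    frames = loc_table["frame"].to_numpy()
    if len(frames) == 0:
        return tracks
    by_frame = {int(f): g for f, g in loc_table.groupby("frame")}
    for f in range(int(frames.min()), int(frames.max()) + 1):
        g = by_frame.get(f)
        locs = (np.empty((0, 2)) if g is None
                else g[["x_px", "y_px"]].to_numpy(dtype=float))
        if open_tracks:
            last = np.array([t["pts"][-1][1:] for t in open_tracks])
            assign = brute_force_assignment(last, locs, radius)
        else:
            assign = []
        used = set()
        still_open = []
        for t, j in zip(open_tracks, assign):
            if j >= 0:
                t["pts"].append((f, locs[j][0], locs[j][1]))
                t["age"] = 0
                used.add(j)
                still_open.append(t)
            else:
                t["age"] += 1
                if t["age"] <= memory:
                    still_open.append(t)
        for j in range(len(locs)):
            if j not in used:
                t = {"pts": [(f, locs[j][0], locs[j][1])], "age": 0}
                tracks.append(t)
                still_open.append(t)
        open_tracks = still_open
    return [t["pts"] for t in tracks]


def chi2_mixture_bound_fraction(f_bound: float, d_bound: float, d_mobile: float,
                                n_steps: int, loc_sigma: float, dt: float,
                                threshold: float = 0.3) -> float:
    """Closed-form expected measured bound fraction for the two-population
    model: each population's apparent D is (D + sigma^2/dt) * chi2_{2n}/(2n)."""
    def below(d_true):
        d_eff = d_true + loc_sigma ** 2 / dt
        return stats.chi2.cdf(2 * n_steps * threshold / d_eff, 2 * n_steps)

    return float(f_bound * below(d_bound) + (1 - f_bound) * below(d_mobile))


def track_tuples(tracks) -> set[tuple]:
    """Canonical comparable form of a track list (package or oracle)."""
    out = set()
    for t in tracks:
        if hasattr(t, "frames"):
            pts = tuple((f, round(x, 9), round(y, 9))
                        for f, x, y in zip(t.frames, t.x_px, t.y_px))
        else:
            pts = tuple((f, round(x, 9), round(y, 9)) for f, x, y in t)
        out.add(pts)
    return out
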
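"""Ground-truthed synthetic microscopy: single-molecule movies and stripe stacks.

Two generators live here.

``simulate_trajectories`` + ``render_movie`` emulate a HILO single-molecule
recording of a nuclear protein: a two-population ensemble (chromatin-bound
molecules with a small apparent diffusion coefficient, freely diffusing
molecules with a large one) performs 2-D Brownian motion inside a nuclear
mask, blinks according to a two-state per-frame Markov chain, and is imaged
as pixel-integrated Gaussian spots with Poisson photon statistics on a
uniform Poisson background.

``simulate_stripe_series`` emulates a confocal laser-microirradiation
recording: after a configurable number of pre-irradiation timepoints the
mean brightness of a stripe region inside the nucleus rises along a
single-exponential saturation curve while the rest of the nucleus and the
background stay flat.

Every generator returns its ground truth alongside the images so that each
downstream analysis stage can be checked for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

_SQRT2 = np.sqrt(2.0)


def disk_mask(image_size: int, radius: float | None = None,
              center: tuple[float, float] | None = None) -> np.ndarray:
    """Boolean disk inside an ``image_size`` x ``image_size`` raster.

    Default radius is 40% of the side, the default stand-in for a nucleus
    that fills much of the field of view.
    """
    if radius is None:
        radius = 0.4 * image_size
    if center is None:
        center = (image_size / 2.0, image_size / 2.0)
    rr, cc = np.mgrid[0:image_size, 0:image_size]
    return (rr + 0.5 - center[0]) ** 2 + (cc + 0.5 - center[1]) ** 2 <= radius ** 2


@dataclass
class SptSimConfig:
    """Parameters of one synthetic single-molecule recording.

    Defaults follow the acquisition geometry of the experiments this
    pipeline targets (256 x 256 px at 0.096 um/px, 20 ms/frame, recordings
    of up to 4,000 frames) and a bound/mobile mixture with
    ``d_mobile`` = 0.5 um^2/s, the mode of the mobile population.
    Photophysics (photon yield, background, blink rates) are not reported
    for the dye/illumination used; the defaults are realistic values for a
    bright rhodamine dye under HILO illumination and are documented as
    assumptions in the methods note.
    """

    n_frames: int = 4000
    image_size: int = 256
    pixel_size: float = 0.096          # um per pixel
    frame_interval: float = 0.020      # seconds
    n_molecules: int = 150
    f_bound: float = 0.3
    d_mobile: float = 0.5              # um^2/s
    d_bound: float = 0.02              # um^2/s
    loc_sigma: float = 0.03            # um, per-axis error for truth-only tracks
    psf_sigma: float = 1.0             # px
    photons_per_spot: float = 1000.0
    background: float = 10.0           # photons / px / frame
    k_off_frame: float = 0.12          # P(on -> dark) per frame
    k_on_frame: float = 0.05           # P(dark -> on) per frame
    nucleus_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.image_size < 1:
            raise ValueError("n_frames and image_size must be >= 1")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if not (0.0 <= self.f_bound <= 1.0):
            raise ValueError("f_bound must lie in [0, 1]")
        for name in ("k_off_frame", "k_on_frame"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.d_bound < self.d_mobile):
            raise ValueError("require 0 <= d_bound < d_mobile")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        if self.nucleus_mask is None:
            self.nucleus_mask = disk_mask(self.image_size)
        else:
            self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
            if self.nucleus_mask.shape != (self.image_size, self.image_size):
                raise ValueError("nucleus_mask shape must match image_size")
        if not self.nucleus_mask.any():
            raise ValueError("nucleus_mask is empty: no pixels inside the nucleus")


@dataclass
class GroundTruthTrajectory:
    """True per-frame state of one simulated molecule.

    Positions are in micrometres in a continuous frame whose origin is the
    top-left pixel *corner*; pixel (row 0, col 0) spans [0, 1) x [0, 1) px,
    x is the column axis.  Note the detection stage reports pixel-*center*
    coordinates, which sit 0.5 px below this frame (a constant offset that
    cancels in every displacement).
    """

    molecule_id: int
    state: str                      # "bound" | "mobile"
    positions: np.ndarray           # (n_frames, 2) float, columns (x_um, y_um)
    emitting: np.ndarray            # (n_frames,) bool


@dataclass
class SyntheticMovie:
    frames: np.ndarray              # (n_frames, H, W) uint16 photon counts
    pixel_size: float               # um / px
    frame_interval: float           # s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) stack")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent deterministic streams per stage, all rooted at one seed
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def _inside(mask: np.ndarray, xy_um: np.ndarray, pixel_size: float) -> np.ndarray:
    """Which of the (n, 2) um positions fall on a True mask pixel."""
    col = np.floor(xy_um[:, 0] / pixel_size).astype(int)
    row = np.floor(xy_um[:, 1] / pixel_size).astype(int)
    nr, nc = mask.shape
    ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    out = np.zeros(len(xy_um), dtype=bool)
    out[ok] = mask[row[ok], col[ok]]
    return out


def simulate_trajectories(config: SptSimConfig) -> list[GroundTruthTrajectory]:
    """Draw the bound/mobile ensemble and propagate it through the recording.

    Each molecule is bound with probability ``f_bound`` (state fixed for the
    whole recording).  Per-axis per-frame displacements are
    N(0, 2 * D * frame_interval) with D the state's coefficient.  A step that
    would leave the nuclear mask is reflected by reversing it (which
    preserves the step length, hence the one-step MSD); in the rare case the
    reversed step also exits, the molecule stays put for that frame.
    Blinking follows the (k_off_frame, k_on_frame) two-state chain started
    in its stationary distribution.
    """
    cfg = config
    rng = _rng(cfg.seed, 0)
    mask = cfg.nucleus_mask
    n = cfg.n_molecules

    bound = rng.random(n) < cfg.f_bound
    d_coef = np.where(bound, cfg.d_bound, cfg.d_mobile)
    step_sd = np.sqrt(2.0 * d_coef * cfg.frame_interval)  # um, per axis

    # uniform start positions over mask pixels, uniform within the pixel
    rows, cols = np.nonzero(mask)
    pick = rng.integers(0, len(rows), size=n)
    pos = np.empty((n, 2))
    pos[:, 0] = (cols[pick] + rng.random(n)) * cfg.pixel_size
    pos[:, 1] = (rows[pick] + rng.random(n)) * cfg.pixel_size

    k_off, k_on = cfg.k_off_frame, cfg.k_on_frame
    p_on = 1.0 if (k_off + k_on) == 0 else k_on / (k_on + k_off)
    on = rng.random(n) < p_on

    positions = np.empty((cfg.n_frames, n, 2))
    emitting = np.empty((cfg.n_frames, n), dtype=bool)
    positions[0] = pos
    emitting[0] = on
    for f in range(1, cfg.n_frames):
        step = rng.normal(0.0, 1.0, size=(n, 2)) * step_sd[:, None]
        prop = pos + step
        bad = ~_inside(mask, prop, cfg.pixel_size)
        prop[bad] = pos[bad] - step[bad]           # reflect: reverse the step
        still_bad = ~_inside(mask, prop, cfg.pixel_size)
        prop[still_bad] = pos[still_bad]
        pos = prop
        u = rng.random(n)
        on = np.where(on, u >= k_off, u < k_on)
        positions[f] = pos
        emitting[f] = on

    return [
        GroundTruthTrajectory(
            molecule_id=i,
            state="bound" if bound[i] else "mobile",
            positions=positions[:, i, :].copy(),
            emitting=emitting[:, i].copy(),
        )
        for i in range(n)
    ]


def _pixel_profile(grid: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Integral of a unit 1-D Gaussian over the unit pixels starting at grid."""
    s = sigma * _SQRT2
    return 0.5 * (special.erf((grid + 1.0 - center) / s)
                  - special.erf((grid - center) / s))


def render_movie(trajectories: list[GroundTruthTrajectory],
                 config: SptSimConfig) -> SyntheticMovie:
    """Image the ensemble: pixel-integrated Gaussian spots + Poisson noise.

    Each emitting molecule contributes ``photons_per_spot`` expected photons
    spread over pixels by the exact error-function integral of an isotropic
    Gaussian of sd ``psf_sigma`` px; a uniform ``background`` expectation is
    added and each pixel is Poisson-sampled (per-pixel Poisson sampling of
    the summed expectation is distributionally identical to drawing each
    spot's photon total first and thinning it over pixels).
    """
    cfg = config
    if cfg.psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    rng = _rng(cfg.seed, 1)
    nsz = cfg.image_size
    half = int(np.ceil(4.0 * cfg.psf_sigma)) + 1
    frames = np.empty((cfg.n_frames, nsz, nsz), dtype=np.uint16)
    expected = np.empty((nsz, nsz))
    for f in range(cfg.n_frames):
        expected.fill(cfg.background)
        for tr in trajectories:
            if not tr.emitting[f]:
                continue
            cx = tr.positions[f, 0] / cfg.pixel_size   # continuous px, col axis
            cy = tr.positions[f, 1] / cfg.pixel_size
            c0 = int(np.floor(cx))
            r0 = int(np.floor(cy))
            clo, chi = max(0, c0 - half), min(nsz, c0 + half + 1)
            rlo, rhi = max(0, r0 - half), min(nsz, r0 + half + 1)
            if clo >= chi or rlo >= rhi:
                continue                               # fully outside the image
            px = _pixel_profile(np.arange(clo, chi, dtype=float), cx, cfg.psf_sigma)
            py = _pixel_profile(np.arange(rlo, rhi, dtype=float), cy, cfg.psf_sigma)
            expected[rlo:rhi, clo:chi] += cfg.photons_per_spot * np.outer(py, px)
        frames[f] = np.minimum(rng.poisson(expected), 65535).astype(np.uint16)
    return SyntheticMovie(frames=frames, pixel_size=cfg.pixel_size,
                          frame_interval=cfg.frame_interval)


def noisy_truth_tracks(trajectories: list[GroundTruthTrajectory],
                       config: SptSimConfig) -> list[np.ndarray]:
    """Ground-truth trajectories with iid per-axis localization noise.

    Bypasses rendering/detection: returns one (n_frames, 2) um position
    array per molecule with N(0, loc_sigma) added independently per frame
    and axis.  Used for estimator-calibration studies where the detection
    stage would only add an uncontrolled error scale.
    """
    rng = _rng(config.seed, 3)
    out = []
    for tr in trajectories:
        noise = rng.normal(0.0, config.loc_sigma, size=tr.positions.shape)
        out.append(tr.positions + noise)
    return out


# ---------------------------------------------------------------------------
# stripe-recruitment stacks


@dataclass
class StripeSimConfig:
    """Parameters of one synthetic microirradiation recording.

    Brightness is in arbitrary detector units.  The stripe mean rises as
    ``baseline + amplitude * (1 - exp(-rate * t_post))`` where ``t_post`` is
    1 at the first post-irradiation timepoint; a saturating single
    exponential is the simplest model matching the shape of measured
    recruitment curves.  Defaults give a stripe that saturates near a
    stripe/nucleus ratio of 3, typical of strong recruitment.
    """

    n_timepoints: int = 30
    image_size: int = 512
    pixel_size: float = 0.139          # um / px
    stripe_mask: np.ndarray | None = None
    nucleus_mask: np.ndarray | None = None
    background_mask: np.ndarray | None = None
    recruitment_amplitude: float = 160.0
    recruitment_rate: float = 0.25     # per timepoint
    nucleus_baseline: float = 100.0
    background_level: float = 20.0
    noise_sigma: float = 2.0
    pre_irradiation_timepoints: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.pre_irradiation_timepoints < 1:
            raise ValueError("pre_irradiation_timepoints must be >= 1")
        if self.pre_irradiation_timepoints >= self.n_timepoints:
            raise ValueError(
                "pre_irradiation_timepoints must be < n_timepoints "
                "(there must be at least one post-irradiation timepoint)")
        if self.recruitment_amplitude < 0:
            raise ValueError("recruitment_amplitude must be >= 0")
        n = self.image_size
        if self.nucleus_mask is None:
            self.nucleus_mask = disk_mask(n, radius=0.25 * n)
        else:
            self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        if self.stripe_mask is None:
            stripe = np.zeros((n, n), dtype=bool)
            c = n // 2
            stripe[c - max(1, n // 100): c + max(1, n // 100), :] = True
            self.stripe_mask = stripe & self.nucleus_mask
        else:
            self.stripe_mask = np.asarray(self.stripe_mask, dtype=bool)
        if self.background_mask is None:
            bg = np.zeros((n, n), dtype=bool)
            bg[n // 50: n // 8, n // 50: n // 8] = True
            self.background_mask = bg & ~self.nucleus_mask
        else:
            self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if not self.stripe_mask.any() or not self.nucleus_mask.any() \
                or not self.background_mask.any():
            raise ValueError("stripe, nucleus and background masks must be nonempty")
        if (self.stripe_mask & ~self.nucleus_mask).any():
            raise ValueError("stripe_mask must lie inside nucleus_mask")
        if (self.background_mask & self.nucleus_mask).any():
            raise ValueError("background_mask must not overlap nucleus_mask")


def stripe_true_means(config: StripeSimConfig) -> pd.DataFrame:
    """Noise-free region means and the resulting true Sx(t) curve."""
    t = np.arange(config.n_timepoints)
    t_post = np.clip(t - config.pre_irradiation_timepoints + 1, 0, None)
    stripe = config.nucleus_baseline + np.where(
        t_post > 0,
        config.recruitment_amplitude
        * (1.0 - np.exp(-config.recruitment_rate * t_post)),
        0.0,
    )
    nucleus = np.full_like(stripe, config.nucleus_baseline)
    bg = np.full_like(stripe, config.background_level)
    sx = (stripe - bg) / (nucleus - bg)
    return pd.DataFrame({
        "timepoint": t,
        "stripe_true": stripe,
        "nucleus_true": nucleus,
        "background_true": bg,
        "sx_true": sx,
    })


def simulate_stripe_series(config: StripeSimConfig
                           ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the stripe recording and return (stack, true region means).

    The stack is float64 brightness (T, H, W) with additive Gaussian noise
    of sd ``noise_sigma`` per pixel; write it to disk via
    :func:`sptquant.io.write_movie`, which quantizes to 16-bit.
    """
    cfg = config
    rng = _rng(cfg.seed, 2)
    truth = stripe_true_means(cfg)
    n = cfg.image_size
    stack = np.empty((cfg.n_timepoints, n, n))
    base = np.full((n, n), cfg.background_level)
    base[cfg.nucleus_mask] = cfg.nucleus_baseline
    for i, stripe_mean in enumerate(truth["stripe_true"].to_numpy()):
        frame = base.copy()
        frame[cfg.stripe_mask] = stripe_mean
        frame += rng.normal(0.0, cfg.noise_sigma, size=frame.shape)
        stack[i] = frame
    return stack, truth
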
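"""SRS measurement sensitivity: mean partial paths, depth profiles and maps.

The spatially-resolved (two-detector) measurement sensitivity of a voxel is
the difference of detection-weighted mean partial path lengths

    sensitivity(x, y, z) = L_far(x, y, z) - L_near(x, y, z)   [mm]

where L is the mean geometric path detected photons spend in the voxel
(``L = sum L_i I_i / sum I_i``).  A positive value means that increasing the
absorption there increases the measured spatial slope.  Summing over all
voxels at one depth gives the depth profile whose peak depth D_p defines the
probing depth of a (rho1, rho2) detector pair; sweeping rho1 for several
rho2 and regressing D_p on (rho1, rho2) yields the planar probing-depth law
reported for each tissue model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    EmptyRingError,
    GeometryMismatchError,
    InsufficientStatisticsError,
    NonPositiveProfileError,
    RankDeficientError,
)
from .mc_engine import DetectorAnnuli, RunConfig, TallySet, run_simulation
from .tissue_models import TissueModel

#: Default nominal detector width (mm); the bench probes' detector size is
#: not critical, and 1.0 mm aligns with the 0.5 mm fine-ring grid.
DEFAULT_RING_WIDTH = 1.0


@dataclass(frozen=True)
class SensitivityGrid:
    """Per-voxel (or per-depth-slab) sensitivities L_far - L_near, mm."""

    values: np.ndarray
    pair: tuple[float, float]
    voxel_size: float
    mode: str  # "depth_profile" or "full_3d"

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class DepthProfile:
    """Depth-summed sensitivity: one value per depth slab."""

    depth_centers: np.ndarray
    sensitivity: np.ndarray
    pair: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.depth_centers.shape != self.sensitivity.shape:
            raise GeometryMismatchError("depth/sensitivity length mismatch")
        if np.any(np.diff(self.depth_centers) <= 0):
            raise GeometryMismatchError("depth_centers must strictly increase")

    def normalized(self) -> "DepthProfile":
        m = self.sensitivity.max()
        if m <= 0:
            raise NonPositiveProfileError("profile has no positive maximum")
        return DepthProfile(self.depth_centers, self.sensitivity / m, self.pair)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth_mm": self.depth_centers, "sensitivity_mm": self.sensitivity}
        )


@dataclass(frozen=True)
class ProfileMetrics:
    """Summary depths of one sensitivity profile (all mm).

    ``depth_10pct`` is NaN when the profile never falls to 10% of its peak
    within the model (thin slabs).
    """

    peak_depth: float
    half_range_low: float
    half_range_high: float
    depth_10pct: float


@dataclass(frozen=True)
class DepthMap:
    """Normalized sensitivity-vs-depth curves for every rho1 at fixed rho2."""

    rho2: float
    rho1_values: np.ndarray
    depth_centers: np.ndarray
    normalized_curves: np.ndarray  # shape (n_rho1, n_depth), max 1.0 each
    peak_depths: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rho1_mm": self.rho1_values, "rho2_mm": self.rho2,
             "peak_depth_mm": self.peak_depths}
        )


@dataclass(frozen=True)
class DpRegression:
    """Ordinary least squares D_p = a*rho1 + b*rho2 + c."""

    coef_rho1: float
    coef_rho2: float
    intercept: float
    rmse: float
    n_points: int


# -- mean partial paths and voxel sensitivities ----------------------------

def mean_path_grid(tallies: TallySet, ring: int) -> np.ndarray:
    """Mean partial path length per voxel/slab for one detector ring (mm)."""
    w = float(tallies.detected_weight_by_ring[ring])
    if w <= 0:
        raise EmptyRingError(f"ring {ring} detected no weight", ring=ring)
    return tallies.path_weight_by_ring[ring] / w


def mean_path_interval(tallies: TallySet, r_lo: float, r_hi: float) -> np.ndarray:
    """Mean partial path per slab for the detector annulus [r_lo, r_hi)."""
    w = tallies.interval_weight(r_lo, r_hi)
    if w <= 0:
        raise EmptyRingError(
            f"annulus [{r_lo}, {r_hi}) mm detected no weight"
        )
    return tallies.interval_path_weight(r_lo, r_hi) / w


def sensitivity_grid(
    L_near: np.ndarray, L_far: np.ndarray, pair: tuple[float, float],
    voxel_size: float, mode: str = "depth_profile",
) -> SensitivityGrid:
    """Elementwise L_far - L_near (far detector minus near detector)."""
    L_near = np.asarray(L_near)
    L_far = np.asarray(L_far)
    if L_near.shape != L_far.shape:
        raise GeometryMismatchError(
            f"grid shapes differ: {L_near.shape} vs {L_far.shape}"
        )
    return SensitivityGrid(L_far - L_near, pair, voxel_size, mode)


def depth_profile(grid: SensitivityGrid) -> DepthProfile:
    """Sum sensitivities over all voxels at each depth."""
    v = grid.values
    if v.ndim == 1:
        prof = v.copy()
    else:
        prof = v.sum(axis=tuple(range(v.ndim - 1)))
    dz = grid.voxel_size
    centers = dz * (np.arange(prof.size) + 0.5)
    return DepthProfile(centers, prof, grid.pair)


def pair_depth_profile(
    tallies: TallySet,
    rho1: float,
    rho2: float,
    ring_width: float = DEFAULT_RING_WIDTH,
) -> DepthProfile:
    """Depth-summed sensitivity of the (rho1, rho2) pair from fine-ring tallies.

    Each nominal detector is the annulus [rho - width/2, rho + width/2),
    assembled from the tally's fine rings.
    """
    h = 0.5 * ring_width
    L_a = mean_path_interval(tallies, rho1 - h, rho1 + h)
    L_b = mean_path_interval(tallies, rho2 - h, rho2 + h)
    grid = sensitivity_grid(
        L_a, L_b, (rho1, rho2), tallies.config.voxel_size,
        mode=tallies.config.tally_mode,
    )
    return depth_profile(grid)


# -- profile summary metrics -----------------------------------------------

def _parabolic_peak(x: np.ndarray, y: np.ndarray, i: int,
                    window_frac: float = 0.8) -> float:
    """Parabolic refinement of the argmax.

    A quadratic is least-squares fitted over the contiguous bins whose value
    is at least ``window_frac`` of the maximum (always at least the three
    bins around the argmax, for which the fit is the exact 3-point
    parabola).  The wider window matters for broad sensitivity profiles,
    whose near-maximum plateau can span millimetres: the raw argmax then
    wanders the plateau with Monte Carlo noise, while the fitted vertex
    stays put.  The vertex is clamped to the window.
    """
    lo = i
    while lo > 0 and y[lo - 1] >= window_frac * y[i]:
        lo -= 1
    hi = i
    while hi < y.size - 1 and y[hi + 1] >= window_frac * y[i]:
        hi += 1
    if hi - lo < 2:
        lo = max(0, i - 1)
        hi = min(y.size - 1, i + 1)
    if hi - lo < 2:
        return float(x[i])  # peak at the grid edge: no refinement
    xs = x[lo : hi + 1]
    ys = y[lo : hi + 1]
    a, b, _ = np.linalg.lstsq(
        np.column_stack([xs**2, xs, np.ones_like(xs)]), ys, rcond=None
    )[0]
    if a >= 0:
        return float(x[i])
    return float(np.clip(-b / (2.0 * a), xs[0], xs[-1]))


def profile_metrics(profile: DepthProfile, window_frac: float = 0.8) -> ProfileMetrics:
    """Peak depth, outermost half-maximum range, and 10%-of-peak depth.

    The peak depth is the vertex of a parabola fitted over the bins within
    ``window_frac`` of the maximum (at least the three around the argmax;
    see :func:`_parabolic_peak`); discretization bias stays below half a
    slab.  The half range takes the outermost linear-interpolated crossings
    of 0.5 * max on each side of the peak; the 10% depth scans outward
    (deeper) from the peak only.
    """
    y = np.asarray(profile.sensitivity, dtype=float)
    x = np.asarray(profile.depth_centers, dtype=float)
    ymax = y.max()
    if ymax <= 0:
        raise NonPositiveProfileError("profile has no positive maximum")
    i = int(np.argmax(y))
    peak = _parabolic_peak(x, y, i, window_frac=window_frac)

    half = 0.5 * ymax
    low = x[0]
    for k in range(0, i):
        if y[k] < half <= y[k + 1]:
            t = (half - y[k]) / (y[k + 1] - y[k])
            low = x[k] + t * (x[k + 1] - x[k])
            break
    high = x[-1]
    for k in range(y.size - 2, i - 1, -1):
        if y[k] >= half > y[k + 1]:
            t = (y[k] - half) / (y[k] - y[k + 1])
            high = x[k] + t * (x[k + 1] - x[k])
            break

    lvl10 = 0.10 * ymax
    d10 = float("nan")
    for k in range(i, y.size - 1):
        if y[k] >= lvl10 > y[k + 1]:
            t = (y[k] - lvl10) / (y[k] - y[k + 1])
            d10 = x[k] + t * (x[k + 1] - x[k])
            break
    return ProfileMetrics(
        peak_depth=peak,
        half_range_low=float(low),
        half_range_high=float(high),
        depth_10pct=float(d10),
    )


# -- depth maps and the D_p regression ------------------------------------

def fine_annuli_for(rho_max: float, step: float = 0.5) -> DetectorAnnuli:
    """Contiguous fine rings covering every nominal detector up to rho_max."""
    return DetectorAnnuli.uniform(step, rho_max + 1.0)


def sweep_depth_map(
    model: TissueModel,
    rho2: float,
    config: RunConfig,
    tallies: TallySet | None = None,
    rho1_step: float = 0.5,
    ring_width: float = DEFAULT_RING_WIDTH,
    max_ring_rel_se: float | None = None,
) -> DepthMap:
    """Normalized sensitivity-depth curves for rho1 = 0.5 ... rho2 - 0.5.

    One simulation with fine annuli serves every rho1 (and, via ``tallies``,
    every rho2 of a sweep): pass the same TallySet to reuse it.

    ``max_ring_rel_se`` enables a detectability gate: if the rho2 detector
    ring's intensity has a relative Monte Carlo standard error above the
    bound, the whole map is refused (InsufficientStatisticsError naming the
    ring) — peak depths extracted from a noise-dominated mean-path profile
    are meaningless and would poison any downstream regression.
    """
    if rho2 < 1.0:
        raise GeometryMismatchError("rho2 must be >= 1.0 mm")
    if tallies is None:
        tallies = run_simulation(model, config, fine_annuli_for(rho2))
    if max_ring_rel_se is not None:
        h = 0.5 * ring_width
        rel = tallies.interval_rel_se(rho2 - h, rho2 + h)
        if not rel <= max_ring_rel_se:
            raise InsufficientStatisticsError(
                f"far ring [{rho2 - h}, {rho2 + h}) mm has relative intensity "
                f"error {rel:.3f} > {max_ring_rel_se} "
                f"(detected weight {tallies.interval_weight(rho2 - h, rho2 + h):.3g}); "
                "increase the photon count",
                ring_interval=(rho2 - h, rho2 + h),
                rel_se=rel,
            )
    rho1_values = np.arange(rho1_step, rho2 - rho1_step / 2, rho1_step)
    curves = []
    peaks = []
    depths = None
    for rho1 in rho1_values:
        prof = pair_depth_profile(tallies, rho1, rho2, ring_width).normalized()
        depths = prof.depth_centers
        curves.append(prof.sensitivity)
        peaks.append(profile_metrics(prof).peak_depth)
    return DepthMap(
        rho2=float(rho2),
        rho1_values=rho1_values,
        depth_centers=depths,
        normalized_curves=np.asarray(curves),
        peak_depths=np.asarray(peaks),
    )


def fit_dp_regression(maps) -> DpRegression:
    """Pooled OLS of peak depth on (rho1, rho2) with intercept."""
    rho1 = np.concatenate([m.rho1_values for m in maps])
    rho2 = np.concatenate([np.full(m.rho1_values.size, m.rho2) for m in maps])
    dp = np.concatenate([m.peak_depths for m in maps])
    if dp.size < 3:
        raise RankDeficientError("need at least 3 (rho1, rho2, Dp) points")
    X = np.column_stack([rho1, rho2, np.ones_like(rho1)])
    if np.linalg.matrix_rank(X) < 3:
        raise RankDeficientError(
            "design is rank deficient: points must span both rho1 and rho2"
        )
    beta, *_ = np.linalg.lstsq(X, dp, rcond=None)
    resid = dp - X @ beta
    return DpRegression(
        coef_rho1=float(beta[0]),
        coef_rho2=float(beta[1]),
        intercept=float(beta[2]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_points=int(dp.size),
    )


def maps_to_frame(maps) -> pd.DataFrame:
    return pd.concat([m.to_frame() for m in maps], ignore_index=True)


#: Detectability bound for sweep rows feeding a regression: the far ring's
#: intensity must be known to 2% (relative MC standard error) for its
#: mean-path profile to localize a peak at the sub-slab level.
DEFAULT_MAX_RING_REL_SE = 0.02

#: rho2 values of the published sweep description and of its figure set.
RHO2_SWEEP_TEXT = (5.0, 10.0, 20.0, 30.0)
RHO2_SWEEP_FIGURE = (8.0, 14.0)


def dp_regression_protocol(
    model: TissueModel,
    tallies: TallySet,
    rho2_values=RHO2_SWEEP_TEXT,
    rho2_fallback=RHO2_SWEEP_FIGURE,
    max_ring_rel_se: float | None = DEFAULT_MAX_RING_REL_SE,
    min_levels: int = 3,
    ring_width: float = DEFAULT_RING_WIDTH,
):
    """The probing-depth regression protocol for one tissue model.

    Sweeps every ``rho2_values`` entry, discarding maps whose far ring fails
    the detectability gate (a noise-dominated mean-path profile yields a
    meaningless peak depth that would poison the fit).  If fewer than
    ``min_levels`` rho2 levels survive — the planar fit needs leverage in
    rho2 — the sweep is augmented with the intermediate ``rho2_fallback``
    distances of the published figure set.

    Returns (maps, skipped, regression) where ``skipped`` maps each dropped
    rho2 to the gate error.
    """
    maps: dict[float, DepthMap] = {}
    skipped: dict[float, Exception] = {}

    def attempt(rho2):
        try:
            maps[rho2] = sweep_depth_map(
                model, rho2, None, tallies=tallies, ring_width=ring_width,
                max_ring_rel_se=max_ring_rel_se,
            )
        except InsufficientStatisticsError as err:
            skipped[rho2] = err

    for rho2 in rho2_values:
        attempt(rho2)
    if len(maps) < min_levels:
        for rho2 in rho2_fallback:
            if rho2 not in maps and rho2 not in skipped:
                attempt(rho2)
    if len(maps) < min_levels:
        raise InsufficientStatisticsError(
            f"only {len(maps)} rho2 level(s) pass the detectability gate; "
            "increase the photon count"
        )
    ordered = [maps[k] for k in sorted(maps)]
    return ordered, skipped, fit_dp_regression(ordered)
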
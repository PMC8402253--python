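"""The SRS oximeter computation chain.

From two detected intensities ``I_A`` (near, at rho1) and ``I_B`` (far, at
rho2) per wavelength:

1. spatial slope  S = ln(I_A / I_B) / (rho2 - rho1)  [per mm]
   (a strict "mean-distance" mode dividing by rho = (rho1 + rho2)/2 is
   available; the difference form is the two-point estimate of -d ln I/d rho
   that the diffusion inversion below presumes),
2. absorption inversion, either by the diffusion-approximation closed form

       mu_a = (S - 2/rho)^2 / (3 mu_s')      with rho = (rho1 + rho2)/2,

   valid for source-detector distances large against 1/mu_s', or by a
   Monte-Carlo-generated lookup table slope(mu_a) for short probes where the
   diffusion formula is biased,
3. hemoglobin concentrations from the two-wavelength linear system

       [O2Hb] =  (eps_HHb_830 mu_a770 - eps_HHb_770 mu_a830) / k
       [HHb]  = -(eps_O2Hb_830 mu_a770 - eps_O2Hb_770 mu_a830) / k
       k      =  eps_O2Hb_770 eps_HHb_830 - eps_O2Hb_830 eps_HHb_770,

4. regional oxygen saturation rSO2 = [O2Hb] / ([O2Hb] + [HHb]).

Because rSO2 is a concentration ratio, scaling all intensities of one
wavelength by any positive gain leaves it unchanged.

Concentrations are mmol/L; extinction coefficients are natural-log
mm^-1 per (mmol/L).
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import (
    ConfigValidationError,
    InsufficientStatisticsError,
    NonMonotoneSlopeError,
    ProbeMismatchError,
)
from .mc_engine import (
    DetectorAnnuli,
    RecordedRun,
    RunConfig,
    run_recorded,
)
from .tissue_models import OpticalProperties, homogeneous_model

#: Detector width used when reading MC intensities for the oximeter chain.
OXIMETER_RING_WIDTH = 1.0

#: Probes of the prototype device: (rho1, rho2) in mm.
STANDARD_PROBES = ((3.0, 5.0), (6.0, 8.0), (9.0, 14.0), (20.0, 30.0))


@dataclass(frozen=True)
class ProbeGeometry:
    """A two-detector probe: near (rho1) and far (rho2) distances, mm."""

    rho1: float
    rho2: float
    label: str = ""

    def __post_init__(self):
        if not 0 < self.rho1 < self.rho2:
            raise ConfigValidationError(
                f"need 0 < rho1 < rho2, got {self.rho1}, {self.rho2}"
            )

    @property
    def rho_mean(self) -> float:
        return 0.5 * (self.rho1 + self.rho2)

    @property
    def separation(self) -> float:
        return self.rho2 - self.rho1


@dataclass(frozen=True)
class IntensityPair:
    """Detected intensities (arbitrary linear units) at one wavelength."""

    i_near: float
    i_far: float
    wavelength: int

    def __post_init__(self):
        if not (self.i_near > 0 and self.i_far > 0):
            raise ConfigValidationError("intensities must be > 0")


@dataclass(frozen=True)
class SlopeReading:
    s: float  # per mm
    wavelength: int
    probe: ProbeGeometry


class InversionResult(NamedTuple):
    """Absorption estimate (mm^-1) plus a validity flag.

    ``flagged`` marks a diffusion-inversion ambiguity (slope at or below the
    2/rho zero) or a LUT extrapolation clamp.
    """

    mu_a: float
    flagged: bool


@dataclass(frozen=True)
class ExtinctionTable:
    """Extinction coefficients (mm^-1 per mmol/L) at 770 and 830 nm."""

    eps_o2hb_770: float
    eps_hhb_770: float
    eps_o2hb_830: float
    eps_hhb_830: float

    def __post_init__(self):
        if self.k == 0:
            raise ConfigValidationError(
                "degenerate extinction table: k = 0 (wavelengths not independent)"
            )

    @property
    def k(self) -> float:
        return (
            self.eps_o2hb_770 * self.eps_hhb_830
            - self.eps_o2hb_830 * self.eps_hhb_770
        )

    def eps(self, species: str, wavelength: int) -> float:
        return getattr(self, f"eps_{species.lower()}_{wavelength}")

    @classmethod
    def from_csv(cls, path=None) -> "ExtinctionTable":
        """Load from CSV (columns wavelength_nm, species, extinction_mm1_per_mM).

        With ``path=None`` the bundled table is used.
        """
        if path is None:
            text = (
                resources.files("srsoxi.data")
                .joinpath("hemoglobin_extinction.csv")
                .read_text()
            )
            df = pd.read_csv(io.StringIO(text), comment="#")
        else:
            df = pd.read_csv(path, comment="#")
        vals = {
            (int(r.wavelength_nm), str(r.species).upper()): float(
                r.extinction_mm1_per_mM
            )
            for r in df.itertuples()
        }
        try:
            return cls(
                eps_o2hb_770=vals[(770, "O2HB")],
                eps_hhb_770=vals[(770, "HHB")],
                eps_o2hb_830=vals[(830, "O2HB")],
                eps_hhb_830=vals[(830, "HHB")],
            )
        except KeyError as exc:
            raise ConfigValidationError(
                f"extinction CSV is missing an entry: {exc}"
            ) from None


@dataclass(frozen=True)
class AbsorptionPair:
    """Absorption coefficients at the two wavelengths, mm^-1."""

    mu_a_770: float
    mu_a_830: float
    flagged: bool = False


@dataclass(frozen=True)
class HemoglobinResult:
    """Hemoglobin concentrations (mmol/L) and regional oxygen saturation.

    ``rso2`` is None when total hemoglobin is not positive.  ``low_confidence``
    is set when any concentration is negative, total hemoglobin falls below
    ``total_hb_floor`` (little blood information in the signal), or an
    upstream inversion was flagged.
    """

    o2hb: float
    hhb: float
    rso2: float | None
    low_confidence: bool

    @property
    def total_hb(self) -> float:
        return self.o2hb + self.hhb


#: Below this total hemoglobin (mmol/L) the slope mostly reflects the
#: background/scattering spectrum rather than blood absorption.
DEFAULT_TOTAL_HB_FLOOR = 0.015


# -- slope and absorption inversion ---------------------------------------

def spatial_slope(
    pair: IntensityPair, probe: ProbeGeometry, denominator: str = "difference"
) -> SlopeReading:
    """Two-point spatial intensity slope, per mm.

    ``denominator="difference"`` divides ln(I_A/I_B) by rho2 - rho1 (the
    finite-difference estimate of the decay slope); ``"mean"`` divides by the
    mean distance (strict device-formula mode).
    """
    if denominator == "difference":
        d = probe.separation
    elif denominator == "mean":
        d = probe.rho_mean
    else:
        raise ConfigValidationError(f"unknown denominator {denominator!r}")
    s = math.log(pair.i_near / pair.i_far) / d
    return SlopeReading(s=s, wavelength=pair.wavelength, probe=probe)


def mua_from_slope_diffusion(s: SlopeReading, mu_s_prime: float) -> InversionResult:
    """Diffusion-approximation inversion mu_a = (S - 2/rho)^2 / (3 mu_s').

    The result is flagged when S <= 2/rho: the quadratic form is then on the
    unphysical branch (the true zero-absorption slope is 2/rho).
    """
    if mu_s_prime <= 0:
        raise ConfigValidationError("mu_s_prime must be > 0")
    rho = s.probe.rho_mean
    d = s.s - 2.0 / rho
    return InversionResult((d * d) / (3.0 * mu_s_prime), flagged=d <= 0)


@dataclass(frozen=True)
class SlopeLUT:
    """Monotone slope(mu_a) reference table for one probe and wavelength.

    Generated by Monte Carlo in the probe's own geometry, so it absorbs every
    short-distance and detector-geometry effect that the diffusion closed
    form misses.
    """

    probe: ProbeGeometry
    wavelength: int
    mu_a_grid: np.ndarray
    slope_values: np.ndarray
    mu_s: float
    g: float
    n: float
    config_hash: str = ""

    def __post_init__(self):
        grid = np.asarray(self.mu_a_grid, dtype=float)
        slopes = np.asarray(self.slope_values, dtype=float)
        if grid.size < 4 or np.any(np.diff(grid) <= 0):
            raise ConfigValidationError(
                "mu_a_grid needs >= 4 strictly increasing points"
            )
        if np.any(np.diff(slopes) <= 0):
            raise NonMonotoneSlopeError(
                "slope is not strictly increasing with mu_a; "
                "increase the photon count of the generating run"
            )
        object.__setattr__(self, "mu_a_grid", grid)
        object.__setattr__(self, "slope_values", slopes)

    def forward(self, mu_a) -> np.ndarray:
        """Interpolated slope at mu_a (for constructing synthetic readings)."""
        return np.interp(mu_a, self.mu_a_grid, self.slope_values)

    def invert(self, slope: float) -> InversionResult:
        lo, hi = self.slope_values[0], self.slope_values[-1]
        clamped = not (lo <= slope <= hi)
        mu = float(np.interp(slope, self.slope_values, self.mu_a_grid))
        return InversionResult(mu, flagged=clamped)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mu_a_per_mm": self.mu_a_grid, "slope_per_mm": self.slope_values}
        )


def _pair_intensities_from_recorded(
    rec: RecordedRun, probe: ProbeGeometry, delta_mua_per_slab: np.ndarray,
    ring_width: float = OXIMETER_RING_WIDTH, with_rel_se: bool = False,
):
    """Per-area intensities at both detectors after absorption reweighting.

    ``delta_mua_per_slab`` has one entry per recording slab plus a final
    overflow entry; the base run must use continuous weighting so the
    reweighting exp(-sum delta_mua * L) is exact.  With ``with_rel_se`` the
    relative MC standard errors of the two reweighted intensities are
    returned as well — reweighting concentrates the effective sample on
    short-path photons, so the errors grow with the absorption offset.
    """
    factors = np.exp(-(rec.slab_paths @ delta_mua_per_slab.astype(np.float32)))
    w = rec.weight * factors
    h = 0.5 * ring_width
    out = []
    rel = []
    for rho in (probe.rho1, probe.rho2):
        m = (rec.exit_radius >= rho - h) & (rec.exit_radius < rho + h)
        area = np.pi * ((rho + h) ** 2 - (rho - h) ** 2)
        total = float(w[m].sum())
        out.append(total / area / rec.tallies.launched)
        if with_rel_se:
            rel.append(
                float(np.sqrt(np.sum(w[m] ** 2)) / total) if total > 0 else np.inf
            )
    if with_rel_se:
        return out[0], out[1], rel[0], rel[1]
    return out[0], out[1]


def build_slope_lut(
    props: OpticalProperties,
    probe: ProbeGeometry,
    mu_a_grid,
    config: RunConfig,
    wavelength: int = 770,
    method: str = "reweight",
    thickness: float = 40.0,
    ring_width: float = OXIMETER_RING_WIDTH,
    max_rel_se: float = 0.05,
) -> SlopeLUT:
    """Build the slope(mu_a) reference table for one probe.

    ``props`` fixes the scattering assumption (mu_s, g, n); its mu_a is
    ignored.  ``method="reweight"`` runs a single recorded simulation at the
    lowest grid absorption and reweights stored total paths by
    exp(-(mu_a - mu_a0) L) — exact under continuous weighting and far cheaper
    than one run per node (``method="per_node"``).

    Reweighting to large absorption offsets concentrates the effective
    sample on few short-path photons; nodes whose far-detector intensity has
    a relative MC standard error above ``max_rel_se`` make the table raise
    InsufficientStatisticsError (run more photons, or trim the grid to the
    absorption range the probe can actually resolve).
    """
    mu_a_grid = np.asarray(mu_a_grid, dtype=float)
    if mu_a_grid.size < 4 or np.any(np.diff(mu_a_grid) <= 0):
        raise ConfigValidationError("mu_a_grid needs >= 4 strictly increasing points")
    annuli = DetectorAnnuli.uniform(0.5, probe.rho2 + 1.0)
    h = 0.5 * ring_width
    slopes = np.empty(mu_a_grid.size)
    if method == "reweight":
        base = OpticalProperties(props.mu_s, float(mu_a_grid[0]), props.g, props.n)
        model = homogeneous_model(base, thickness=thickness, wavelength=wavelength,
                                  label="lut_base")
        cfg = RunConfig(**{**config.to_dict(), "weighting": "continuous"})
        rec = run_recorded(model, cfg, annuli, rec_dz=cfg.voxel_size,
                           rec_depth=0.0)  # total path only
        for j, mu in enumerate(mu_a_grid):
            delta = np.array([mu - mu_a_grid[0]])
            i_a, i_b, rel_a, rel_b = _pair_intensities_from_recorded(
                rec, probe, delta, ring_width, with_rel_se=True
            )
            worst = max(rel_a, rel_b)
            if not worst <= max_rel_se:
                raise InsufficientStatisticsError(
                    f"LUT node mu_a={mu:.4g}/mm: far-detector intensity has "
                    f"relative MC error {worst:.3f} > {max_rel_se}; increase "
                    "the photon count or trim the mu_a grid",
                    rel_se=worst,
                )
            slopes[j] = math.log(i_a / i_b) / probe.separation
    elif method == "per_node":
        from .mc_engine import run_simulation

        for j, mu in enumerate(mu_a_grid):
            p = OpticalProperties(props.mu_s, float(mu), props.g, props.n)
            model = homogeneous_model(p, thickness=thickness, wavelength=wavelength,
                                      label="lut_node")
            t = run_simulation(model, config, annuli)
            i_a = t.intensity(probe.rho1 - h, probe.rho1 + h)
            i_b = t.intensity(probe.rho2 - h, probe.rho2 + h)
            slopes[j] = math.log(i_a / i_b) / probe.separation
    else:
        raise ConfigValidationError(f"unknown LUT method {method!r}")
    blob = f"{config.to_dict()}|{props}|{probe}|{method}".encode()
    return SlopeLUT(
        probe=probe,
        wavelength=wavelength,
        mu_a_grid=mu_a_grid,
        slope_values=slopes,
        mu_s=props.mu_s,
        g=props.g,
        n=props.n,
        config_hash=hashlib.sha256(blob).hexdigest()[:16],
    )


def slope_lut_from_recorded(
    rec: RecordedRun,
    probe: ProbeGeometry,
    mu_a_grid,
    base_mu_a: float,
    wavelength: int = 770,
    ring_width: float = OXIMETER_RING_WIDTH,
    max_rel_se: float = 0.05,
) -> SlopeLUT:
    """Slope LUT from an existing continuous-weighting recorded base run.

    ``base_mu_a`` is the (uniform) absorption the base run was generated
    with; grid absorptions reweight every recorded slab plus the overflow.
    """
    mu_a_grid = np.asarray(mu_a_grid, dtype=float)
    if mu_a_grid[0] < base_mu_a - 1e-12:
        raise ConfigValidationError(
            "mu_a_grid must start at or above the base run's absorption "
            "(downweighting is stable; upweighting long paths is not)"
        )
    ncol = rec.slab_paths.shape[1]
    slopes = np.empty(mu_a_grid.size)
    for j, mu in enumerate(mu_a_grid):
        delta = np.full(ncol, mu - base_mu_a)
        i_a, i_b, rel_a, rel_b = _pair_intensities_from_recorded(
            rec, probe, delta, ring_width, with_rel_se=True
        )
        worst = max(rel_a, rel_b)
        if not worst <= max_rel_se:
            raise InsufficientStatisticsError(
                f"LUT node mu_a={mu:.4g}/mm: far-detector intensity has "
                f"relative MC error {worst:.3f} > {max_rel_se}; increase the "
                "photon count or trim the mu_a grid",
                rel_se=worst,
            )
        slopes[j] = math.log(i_a / i_b) / probe.separation
    return SlopeLUT(
        probe=probe,
        wavelength=wavelength,
        mu_a_grid=mu_a_grid,
        slope_values=slopes,
        mu_s=0.0,
        g=0.0,
        n=0.0,
        config_hash="recorded",
    )


def mua_from_slope_lut(s: SlopeReading, lut: SlopeLUT) -> InversionResult:
    """Invert a slope reading through a LUT (monotone piecewise-linear)."""
    if (s.probe.rho1, s.probe.rho2) != (lut.probe.rho1, lut.probe.rho2):
        raise ProbeMismatchError(
            f"reading probe {s.probe} does not match LUT probe {lut.probe}"
        )
    if s.wavelength != lut.wavelength:
        raise ProbeMismatchError(
            f"reading at {s.wavelength} nm, LUT at {lut.wavelength} nm"
        )
    return lut.invert(s.s)


# -- hemoglobin and saturation ---------------------------------------------

def hemoglobin_from_mua(
    mu: AbsorptionPair,
    eps: ExtinctionTable,
    total_hb_floor: float = DEFAULT_TOTAL_HB_FLOOR,
) -> HemoglobinResult:
    """Solve the two-wavelength linear system for [O2Hb], [HHb] and rSO2."""
    k = eps.k
    o2hb = (eps.eps_hhb_830 * mu.mu_a_770 - eps.eps_hhb_770 * mu.mu_a_830) / k
    hhb = -(eps.eps_o2hb_830 * mu.mu_a_770 - eps.eps_o2hb_770 * mu.mu_a_830) / k
    total = o2hb + hhb
    rso2 = o2hb / total if total > 0 else None
    low = (
        mu.flagged
        or o2hb < 0
        or hhb < 0
        or total <= total_hb_floor
    )
    return HemoglobinResult(o2hb=o2hb, hhb=hhb, rso2=rso2, low_confidence=low)


def rso2_from_intensities(
    reading_770: IntensityPair,
    reading_830: IntensityPair,
    probe: ProbeGeometry,
    eps: ExtinctionTable,
    inversion: str = "diffusion",
    mu_s_prime: float | dict[int, float] | None = None,
    luts: dict[int, SlopeLUT] | None = None,
    denominator: str = "difference",
    total_hb_floor: float = DEFAULT_TOTAL_HB_FLOOR,
) -> HemoglobinResult:
    """Full oximeter chain: intensities -> slopes -> mu_a -> rSO2.

    For ``inversion="diffusion"`` pass ``mu_s_prime`` (a single value shared
    by both wavelengths, or a {wavelength: value} mapping); for
    ``inversion="lut"`` pass ``luts`` as {wavelength: SlopeLUT}.
    """
    if {reading_770.wavelength, reading_830.wavelength} != {770, 830}:
        raise ConfigValidationError("need one reading at 770 nm and one at 830 nm")
    mu = {}
    flagged = False
    for reading in (reading_770, reading_830):
        s = spatial_slope(reading, probe, denominator=denominator)
        if inversion == "diffusion":
            if mu_s_prime is None:
                raise ConfigValidationError("diffusion inversion needs mu_s_prime")
            msp = (
                mu_s_prime[reading.wavelength]
                if isinstance(mu_s_prime, dict)
                else mu_s_prime
            )
            res = mua_from_slope_diffusion(s, msp)
        elif inversion == "lut":
            if luts is None or reading.wavelength not in luts:
                raise ConfigValidationError("lut inversion needs a LUT per wavelength")
            res = mua_from_slope_lut(s, luts[reading.wavelength])
        else:
            raise ConfigValidationError(f"unknown inversion {inversion!r}")
        mu[reading.wavelength] = res.mu_a
        flagged = flagged or res.flagged
    pair = AbsorptionPair(mu_a_770=mu[770], mu_a_830=mu[830], flagged=flagged)
    return hemoglobin_from_mua(pair, eps, total_hb_floor=total_hb_floor)


def process_reading_log(
    frame: pd.DataFrame,
    probe: ProbeGeometry,
    eps: ExtinctionTable,
    **kwargs,
) -> pd.DataFrame:
    """Apply the oximeter chain to a columnar intensity log.

    ``frame`` needs columns time, wavelength, i_near, i_far with alternating
    770/830 rows per time point; returns one output row per time point.
    """
    out = []
    for t, grp in frame.groupby("time"):
        readings = {
            int(r.wavelength): IntensityPair(
                i_near=float(r.i_near), i_far=float(r.i_far),
                wavelength=int(r.wavelength),
            )
            for r in grp.itertuples()
        }
        res = rso2_from_intensities(readings[770], readings[830], probe, eps, **kwargs)
        out.append(
            {
                "time": t,
                "o2hb_mM": res.o2hb,
                "hhb_mM": res.hhb,
                "total_hb_mM": res.total_hb,
                "rso2": res.rso2,
                "low_confidence": res.low_confidence,
            }
        )
    return pd.DataFrame(out)
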
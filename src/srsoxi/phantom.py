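"""In-silico blood-layer phantom: the synthetic end-to-end experiment.

The bench experiment this module emulates embeds a thin, fully oxygenated
blood layer at a variable depth inside a fat-like scattering medium
(Intralipid + agar), then reads every probe of the oximeter as the
blood-free top layer is thickened.  Because the probing depth of a probe is
set by its detector distances, each probe's rSO2-vs-depth curve peaks where
its measurement sensitivity peaks — that correspondence is the whole point
of the experiment.

The simulation analogue: a homogeneous scattering background whose
absorption is augmented, over the slabs occupied by the blood layer, by the
blood's hemoglobin absorption

    mu_a(lambda) = mu_a_bg(lambda)
                 + f_blood * totalHb * (S * eps_O2Hb + (1 - S) * eps_HHb),

with f_blood the blood volume fraction, totalHb the whole-blood hemoglobin
concentration (mmol/L) and S its oxygen saturation.

The sweep runs one recorded Monte Carlo base simulation of the blood-free
background (continuous weighting, so trajectories are independent of
absorption) and reweights it per depth and wavelength — every (probe, depth,
wavelength) combination reuses the same photons, which both accelerates the
sweep and makes the rSO2-depth curves smooth in depth.

Background optical properties default to nominal 1.2%-Intralipid-like values
(mu_s' ~ 1.2 mm^-1, g = 0.7) — the bench phantom's actual optics are not
characterized, so absolute rSO2 values are not comparable; curve shapes and
peak depths are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigValidationError
from .mc_engine import DetectorAnnuli, RecordedRun, RunConfig, run_recorded
from .oximetry import (
    AbsorptionPair,
    ExtinctionTable,
    HemoglobinResult,
    IntensityPair,
    ProbeGeometry,
    SlopeLUT,
    _pair_intensities_from_recorded,
    hemoglobin_from_mua,
    mua_from_slope_diffusion,
    slope_lut_from_recorded,
    spatial_slope,
    DEFAULT_TOTAL_HB_FLOOR,
)
from .tissue_models import (
    Layer,
    OpticalProperties,
    TissueModel,
    WAVELENGTHS,
)

#: Whole-blood total hemoglobin, mmol/L (~150 g/L at 64.5 kg/mol).
WHOLE_BLOOD_TOTAL_HB = 2.3


def _default_background() -> dict[int, OpticalProperties]:
    # 1.2% Intralipid-like: mu_s' ~ 1.2 mm^-1 with the g = 0.7 convention,
    # small agar/water background absorption, same at both wavelengths.
    props = OpticalProperties(mu_s=4.0, mu_a=0.0025, g=0.7, n=1.4)
    return {wl: props for wl in WAVELENGTHS}


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of the blood-layer phantom."""

    blood_thickness: float = 1.0
    blood_volume_fraction: float = 0.01
    blood_total_hb: float = WHOLE_BLOOD_TOTAL_HB
    blood_saturation: float = 1.0
    background_props: dict[int, OpticalProperties] = field(
        default_factory=_default_background
    )
    bottom_thickness: float = 30.0

    def __post_init__(self):
        if not (self.blood_thickness > 0 and self.bottom_thickness > 0):
            raise ConfigValidationError("thicknesses must be > 0")
        if not 0.0 <= self.blood_volume_fraction <= 1.0:
            raise ConfigValidationError("blood_volume_fraction must be in [0, 1]")
        if not 0.0 <= self.blood_saturation <= 1.0:
            raise ConfigValidationError("blood_saturation must be in [0, 1]")
        if self.blood_total_hb < 0:
            raise ConfigValidationError("blood_total_hb must be >= 0")


def blood_mua_increment(
    spec: PhantomSpec, eps: ExtinctionTable, wavelength: int
) -> float:
    """Absorption the blood adds over the background, mm^-1."""
    s = spec.blood_saturation
    eps_mix = s * eps.eps("o2hb", wavelength) + (1.0 - s) * eps.eps("hhb", wavelength)
    return spec.blood_volume_fraction * spec.blood_total_hb * eps_mix


def blood_layer_props(
    spec: PhantomSpec, eps: ExtinctionTable, wavelength: int
) -> OpticalProperties:
    """Optical properties of the blood-containing layer at one wavelength."""
    bg = spec.background_props[int(wavelength)]
    return OpticalProperties(
        mu_s=bg.mu_s,
        mu_a=bg.mu_a + blood_mua_increment(spec, eps, wavelength),
        g=bg.g,
        n=bg.n,
    )


def build_phantom_model(
    spec: PhantomSpec,
    blood_depth: float,
    wavelength: int,
    eps: ExtinctionTable,
) -> TissueModel:
    """Explicit layered model of the phantom with the blood at one depth.

    Layers: background slab of thickness ``blood_depth`` (omitted when 0),
    the blood layer, and the background bottom slab.
    """
    if blood_depth < 0:
        raise ConfigValidationError("blood_depth must be >= 0")
    bg = {wl: spec.background_props[wl] for wl in WAVELENGTHS}
    blood = {wl: blood_layer_props(spec, eps, wl) for wl in WAVELENGTHS}
    layers = []
    if blood_depth > 0:
        layers.append(Layer(thickness=blood_depth, props_by_wavelength=bg))
    layers.append(Layer(thickness=spec.blood_thickness, props_by_wavelength=blood))
    layers.append(Layer(thickness=spec.bottom_thickness, props_by_wavelength=bg))
    return TissueModel(
        layers=tuple(layers),
        wavelength=int(wavelength),
        label=f"phantom_depth_{blood_depth:g}mm",
    )


def background_model(spec: PhantomSpec, wavelength: int = 770) -> TissueModel:
    """Blood-free background medium of the same total depth budget."""
    bg = {wl: spec.background_props[wl] for wl in WAVELENGTHS}
    depth = spec.bottom_thickness + spec.blood_thickness + 20.0
    return TissueModel(
        layers=(Layer(thickness=depth, props_by_wavelength=bg),),
        wavelength=int(wavelength),
        label="phantom_background",
    )


def phantom_base_run(
    spec: PhantomSpec,
    config: RunConfig,
    rec_depth: float = 16.0,
    r_max: float = 31.0,
) -> RecordedRun:
    """Recorded blood-free base simulation for reweighted sweeps.

    Uses continuous weighting (trajectories independent of absorption), so a
    single run serves every probe, depth and wavelength.  Background
    scattering must be equal at both wavelengths for the shared-trajectory
    reuse to be valid; the default background satisfies this.
    """
    p770 = spec.background_props[770]
    p830 = spec.background_props[830]
    if (p770.mu_s, p770.g, p770.n) != (p830.mu_s, p830.g, p830.n):
        raise ConfigValidationError(
            "shared base run requires equal background scattering at both "
            "wavelengths; run per-wavelength simulations instead"
        )
    model = background_model(spec)
    cfg = RunConfig(**{**config.to_dict(), "weighting": "continuous"})
    annuli = DetectorAnnuli.uniform(0.5, r_max)
    return run_recorded(
        model, cfg, annuli, rec_dz=cfg.voxel_size, rec_depth=rec_depth,
        mua_override=p770.mu_a,
    )


def _delta_mua_profile(
    rec: RecordedRun, spec: PhantomSpec, eps: ExtinctionTable,
    wavelength: int, blood_depth: float,
) -> np.ndarray:
    """Per-recording-slab absorption offsets from the base run's mu_a."""
    base = spec.background_props[770].mu_a
    bg = spec.background_props[wavelength].mu_a
    n_rec = rec.slab_paths.shape[1] - 1
    dz = rec.rec_dz
    delta = np.full(n_rec + 1, bg - base)
    inc = blood_mua_increment(spec, eps, wavelength)
    edges = dz * np.arange(n_rec + 1)
    lo, hi = blood_depth, blood_depth + spec.blood_thickness
    if hi > n_rec * dz:
        raise ConfigValidationError(
            f"blood layer [{lo}, {hi}) mm exceeds the recorded depth "
            f"{n_rec * dz} mm of the base run"
        )
    # fractional overlap of each slab with the blood layer
    overlap = np.clip(
        (np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo)) / dz, 0.0, 1.0
    )
    delta[:n_rec] += inc * overlap
    return delta


def phantom_depth_sweep(
    spec: PhantomSpec,
    probes,
    depths,
    config: RunConfig,
    eps: ExtinctionTable,
    inversion: str = "lut",
    base_run: RecordedRun | None = None,
    total_hb_floor: float = DEFAULT_TOTAL_HB_FLOOR,
    lut_grid=None,
    lut_max_rel_se: float = 0.08,
) -> pd.DataFrame:
    """rSO2 for every probe as the blood layer moves deeper.

    Returns a frame with one row per (probe, depth): columns probe, rho1,
    rho2, depth (the blood layer's mid-depth, following the bench plotting
    convention), o2hb, hhb, total_hb, rso2, low_confidence.

    ``depths`` are top-of-blood-layer depths (mm).  The same seeded base run
    is reused for every combination, so rerunning with an identical config
    reproduces the table exactly.
    """
    probes = [
        p if isinstance(p, ProbeGeometry) else ProbeGeometry(*p) for p in probes
    ]
    if base_run is None:
        base_run = phantom_base_run(spec, config)
    rows = []
    luts: dict[tuple, dict[int, SlopeLUT]] = {}
    if inversion == "lut":
        base_mu = spec.background_props[770].mu_a
        if lut_grid is None:
            # background absorption up through twice the full blood loading
            span = 2.0 * max(
                blood_mua_increment(spec, eps, wl) for wl in WAVELENGTHS
            ) + 1e-3
            lut_grid = base_mu + np.linspace(0.0, span, 13)
        for probe in probes:
            luts[(probe.rho1, probe.rho2)] = {
                wl: slope_lut_from_recorded(
                    base_run, probe, lut_grid, base_mu_a=base_mu, wavelength=wl,
                    max_rel_se=lut_max_rel_se,
                )
                for wl in WAVELENGTHS
            }
    for probe in probes:
        msp = {
            wl: spec.background_props[wl].mu_s_prime for wl in WAVELENGTHS
        }
        for depth in depths:
            mua = {}
            flagged = False
            for wl in WAVELENGTHS:
                delta = _delta_mua_profile(base_run, spec, eps, wl, depth)
                i_a, i_b = _pair_intensities_from_recorded(base_run, probe, delta)
                s = spatial_slope(
                    IntensityPair(i_near=i_a, i_far=i_b, wavelength=wl), probe
                )
                if inversion == "lut":
                    res = luts[(probe.rho1, probe.rho2)][wl].invert(s.s)
                elif inversion == "diffusion":
                    res = mua_from_slope_diffusion(s, msp[wl])
                else:
                    raise ConfigValidationError(f"unknown inversion {inversion!r}")
                mua[wl] = res.mu_a
                flagged = flagged or res.flagged
            hb = hemoglobin_from_mua(
                AbsorptionPair(mua[770], mua[830], flagged=flagged), eps,
                total_hb_floor=total_hb_floor,
            )
            rows.append(
                {
                    "probe": f"{probe.rho1:g}-{probe.rho2:g} mm",
                    "rho1_mm": probe.rho1,
                    "rho2_mm": probe.rho2,
                    "depth_mm": depth + 0.5 * spec.blood_thickness,
                    "o2hb_mM": hb.o2hb,
                    "hhb_mM": hb.hhb,
                    "total_hb_mM": hb.total_hb,
                    "rso2": hb.rso2,
                    "low_confidence": hb.low_confidence,
                }
            )
    return pd.DataFrame(rows)


def rso2_peak_depth(sweep: pd.DataFrame, probe_label: str) -> float:
    """Blood-layer mid-depth at which a probe's rSO2 curve peaks."""
    sub = sweep[sweep["probe"] == probe_label]
    return float(sub.loc[sub["rso2"].idxmax(), "depth_mm"])
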
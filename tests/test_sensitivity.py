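"""Mean partial paths, sensitivity grids, profile metrics, maps, regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srsoxi import (
    DetectorAnnuli,
    RunConfig,
    make_preset_model,
    run_simulation,
)
from srsoxi.errors import (
    EmptyRingError,
    GeometryMismatchError,
    NonPositiveProfileError,
    RankDeficientError,
)
from srsoxi.mc_engine import run_recorded
from srsoxi.sensitivity import (
    DepthMap,
    DepthProfile,
    depth_profile,
    fit_dp_regression,
    mean_path_grid,
    mean_path_interval,
    pair_depth_profile,
    profile_metrics,
    sensitivity_grid,
    sweep_depth_map,
)


def _tallies_with(det_w, path_w):
    """Hand-built TallySet for arithmetic checks."""
    from srsoxi.mc_engine import TallySet

    det_w = np.asarray(det_w, dtype=float)
    path_w = np.asarray(path_w, dtype=float)
    n_rings = det_w.size
    return TallySet(
        detected_weight_by_ring=det_w,
        path_weight_by_ring=path_w,
        launched=float(det_w.sum() + 1),
        absorbed_weight=0.0,
        transmitted_weight=0.0,
        escaped_outside_weight=1.0,
        terminated_weight=0.0,
        rouletted_weight=0.0,
        annuli=DetectorAnnuli.uniform(1.0, float(n_rings)),
        config=RunConfig(n_photons=1, voxel_size=1.0),
    )


# -- mean-partial-path arithmetic ------------------------------------------

def test_mean_path_single_photon():
    # one photon, weight 0.5, 2 mm of path in one voxel -> L = 2 mm there
    t = _tallies_with([0.5], [[0.5 * 2.0, 0.0]])
    L = mean_path_grid(t, 0)
    assert L[0] == pytest.approx(2.0)
    assert L[1] == 0.0


def test_mean_path_two_photons_weighted():
    # weights 1 and 3 with paths 1 and 2 mm: L = (1*1 + 2*3) / 4 = 1.75 mm
    t = _tallies_with([4.0], [[1.0 * 1.0 + 2.0 * 3.0]])
    assert mean_path_grid(t, 0)[0] == pytest.approx(1.75)


def test_mean_path_empty_ring_raises():
    t = _tallies_with([0.0], [[0.0]])
    with pytest.raises(EmptyRingError) as err:
        mean_path_grid(t, 0)
    assert err.value.ring == 0


def test_mean_path_totals_match_brute_force_records():
    """Sum of L over slabs equals the detection-weighted mean total path."""
    model = make_preset_model("gastric", 770)
    annuli = DetectorAnnuli.uniform(0.5, 10.0)
    cfg = RunConfig(n_photons=20_000, seed=23, voxel_size=0.5,
                    weighting="continuous")
    rec = run_recorded(model, cfg, annuli, rec_dz=0.5, rec_depth=7.0)
    for r_lo, r_hi in ((2.5, 3.5), (4.5, 5.5)):
        m = (rec.exit_radius >= r_lo) & (rec.exit_radius < r_hi)
        brute = float(np.sum(rec.weight[m] * rec.total_path[m]) / rec.weight[m].sum())
        L = mean_path_interval(rec.tallies, r_lo, r_hi)
        assert L.sum() == pytest.approx(brute, rel=1e-6)


# -- sensitivity grids -----------------------------------------------------

def test_equal_paths_give_zero_sensitivity():
    L = np.random.default_rng(0).random((4, 4, 5))
    g = sensitivity_grid(L, L, (3.0, 5.0), 0.2, mode="full_3d")
    assert np.all(g.values == 0.0)
    prof = depth_profile(g)
    assert np.all(prof.sensitivity == 0.0)


def test_grid_shape_mismatch_raises():
    with pytest.raises(GeometryMismatchError):
        sensitivity_grid(np.zeros(3), np.zeros(4), (3.0, 5.0), 0.2)


def test_depth_profile_total_equals_grid_total():
    rng = np.random.default_rng(1)
    vals = rng.normal(size=(6, 6, 8))
    g = sensitivity_grid(np.zeros_like(vals), vals, (3.0, 5.0), 0.2,
                         mode="full_3d")
    prof = depth_profile(g)
    assert prof.sensitivity.sum() == pytest.approx(g.total)
    assert prof.sensitivity.size == 8


def test_surface_layer_has_positive_and_negative_voxels():
    """In the 3-D sensitivity map the 0.2 mm surface layer carries voxels of
    both signs (near-detector paths exceed far-detector paths under the near
    detector and vice versa), while their depth sum nearly cancels."""
    model = make_preset_model("homogeneous_skin", 770)
    annuli = DetectorAnnuli(np.array([2.5, 3.5, 4.5, 5.5]))
    cfg = RunConfig(
        n_photons=150_000, seed=29, voxel_size=0.2, tally_mode="full_3d",
        grid_x=(-4.0, 10.0), grid_y=(-4.0, 4.0), grid_z_max=10.0,
    )
    t = run_simulation(model, cfg, annuli)
    L_near = mean_path_grid(t, 0)
    L_far = mean_path_grid(t, 2)
    g = sensitivity_grid(L_near, L_far, (3.0, 5.0), 0.2, mode="full_3d")
    # interior voxels of the first 0.2 mm layer (trim clamped grid edges)
    surface = g.values[2:-2, 2:-2, 0]
    assert surface.min() < 0 < surface.max()
    # most of the positive surface sensitivity is canceled by negative
    # voxels, so the net surface sum is a small fraction of the gross
    pos = surface[surface > 0].sum()
    neg = -surface[surface < 0].sum()
    assert neg > 0.3 * pos
    assert pos - neg < 0.6 * pos
    # and the net surface value sits below the profile peak
    profile = depth_profile(g)
    assert profile.sensitivity[0] < profile.sensitivity.max()


# -- profile metrics -------------------------------------------------------

def test_profile_metrics_piecewise_linear_example():
    prof = DepthProfile(
        depth_centers=np.array([0.1, 0.3, 0.5, 0.7, 0.9]),
        sensitivity=np.array([0.0, 1.0, 2.0, 1.0, 0.0]),
    )
    m = profile_metrics(prof)
    assert m.peak_depth == pytest.approx(0.5)
    assert m.half_range_low == pytest.approx(0.3)
    assert m.half_range_high == pytest.approx(0.7)
    assert m.depth_10pct == pytest.approx(0.86)


def test_profile_metrics_requires_positive_maximum():
    prof = DepthProfile(
        depth_centers=np.array([0.1, 0.3]), sensitivity=np.array([-1.0, -2.0])
    )
    with pytest.raises(NonPositiveProfileError):
        profile_metrics(prof)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=4, max_size=40),
    st.integers(min_value=1, max_value=38),
)
def test_profile_metrics_ordering_invariant(increments, peak_pos):
    """half_low <= peak <= half_high <= depth_10 for unimodal profiles
    (monotone rise to a single maximum, then monotone fall)."""
    inc = np.asarray(increments)
    peak_pos = peak_pos % len(inc) or 1
    y = np.concatenate([
        np.cumsum(inc[:peak_pos]),
        np.cumsum(inc[:peak_pos])[-1] - np.cumsum(inc[peak_pos:]),
    ])
    x = 0.2 * (np.arange(len(y)) + 0.5)
    m = profile_metrics(DepthProfile(x, y))
    assert m.half_range_low <= m.peak_depth + 1e-12
    assert m.peak_depth <= m.half_range_high + 1e-12
    if not np.isnan(m.depth_10pct):
        assert m.half_range_high <= m.depth_10pct + 1e-12


# -- depth maps and regression ---------------------------------------------

def test_sweep_normalized_curves_peak_at_one(skin_map_tallies):
    model, tallies = skin_map_tallies
    dm = sweep_depth_map(model, 10.0, None, tallies=tallies)
    assert np.allclose(dm.normalized_curves.max(axis=1), 1.0)
    # each refined peak lies inside its curve's near-maximum (>= 0.8) region
    for curve, peak in zip(dm.normalized_curves, dm.peak_depths):
        near_max = dm.depth_centers[curve >= 0.8]
        assert near_max.min() - 0.25 <= peak <= near_max.max() + 0.25


def test_dp_is_about_one_fifth_of_rho2_at_half_rho2(skin_map_tallies):
    """For rho1 ~ rho2/2 the probing depth is ~rho2/5 in the layered skin
    model (checked loosely: 30% relative)."""
    model, tallies = skin_map_tallies
    for rho2 in (10.0, 20.0):
        dm = sweep_depth_map(model, rho2, None, tallies=tallies)
        i = int(np.argmin(np.abs(dm.rho1_values - rho2 / 2)))
        assert dm.peak_depths[i] == pytest.approx(rho2 / 5, rel=0.30)


def test_dp_nondecreasing_in_rho1(skin_map_tallies):
    """Deeper probing with wider near-detector spacing: D_p grows (within MC
    noise) with rho1 at fixed rho2.  Pairs with nearly coincident detectors
    (rho1 within 2 mm of rho2) are excluded — their sensitivity is a
    difference of almost identical path profiles, noise-dominated at any
    desk-scale photon count."""
    model, tallies = skin_map_tallies
    dm = sweep_depth_map(model, 20.0, None, tallies=tallies)
    keep = dm.rho1_values <= 20.0 - 2.0
    dp = dm.peak_depths[keep]
    assert dp[-1] > dp[0]
    assert np.all(np.diff(dp) > -0.6)


def test_regression_recovers_exact_linear_law():
    rho1 = np.array([0.5, 1.0, 2.0, 3.0, 1.5, 4.0])
    maps = []
    for rho2 in (5.0, 10.0):
        dp = 0.1 * rho1 + 0.08 * rho2 + 0.9
        maps.append(
            DepthMap(
                rho2=rho2,
                rho1_values=rho1,
                depth_centers=np.array([0.25]),
                normalized_curves=np.ones((rho1.size, 1)),
                peak_depths=dp,
            )
        )
    reg = fit_dp_regression(maps)
    assert reg.coef_rho1 == pytest.approx(0.1, abs=1e-12)
    assert reg.coef_rho2 == pytest.approx(0.08, abs=1e-12)
    assert reg.intercept == pytest.approx(0.9, abs=1e-12)
    assert reg.rmse == pytest.approx(0.0, abs=1e-12)


def test_regression_rejects_rank_deficient_design():
    rho1 = np.array([1.0, 2.0, 3.0])
    maps = [
        DepthMap(
            rho2=5.0,
            rho1_values=rho1,
            depth_centers=np.array([0.25]),
            normalized_curves=np.ones((3, 1)),
            peak_depths=np.ones(3),
        )
    ]
    with pytest.raises(RankDeficientError):
        fit_dp_regression(maps)  # single rho2: cannot span both predictors
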
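# Methods

## The measurement model

A spatially resolved (SRS) tissue oximeter illuminates the tissue at one
point and reads the diffusely reflected intensity at two distances ρ₁ < ρ₂
from the source. The spatial slope of the detected intensity,

    S = ln(I_A / I_B) / (ρ₂ − ρ₁),        A = near, B = far,

is converted to an absorption coefficient per wavelength, and the
two-wavelength absorption pair to hemoglobin concentrations and regional
oxygen saturation rSO₂ = [O₂Hb]/([O₂Hb]+[HHb]).

The question the package answers quantitatively is *where* such a probe
measures. Writing L_A(x,y,z) and L_B(x,y,z) for the detection-weighted mean
partial path lengths of photons in the voxel at (x,y,z),

    L = Σᵢ Lᵢ Iᵢ / Σᵢ Iᵢ,

a local absorption change Δμ_a(x,y,z) perturbs the slope by
Δμ_a·(L_B − L_A) (up to the fixed 1/(ρ₂−ρ₁) normalization of S), so
**L_B − L_A (mm) is the SRS measurement sensitivity of that voxel**. Summing
over all voxels at one depth gives the sensitivity-versus-depth profile; its
peak depth D_p is the probing depth of the (ρ₁, ρ₂) pair.

## Monte Carlo transport

`mc_engine` implements weighted photon transport in the MCML tradition:

- pencil beam incident at the origin along +z on laterally infinite slabs;
- free path −ln(u)/μ_t of the current layer; Henyey–Greenstein deflection
  cosine with the layer's g; azimuth uniform (sampled by unit-disk
  rejection);
- absorption by survival weighting (w ← w·μ_s/μ_t per collision), Russian
  roulette below a weight threshold (default 1e−4, survival 0.1);
- unpolarized Fresnel reflection/refraction at the top and bottom surfaces
  and at internal index steps, decided all-or-none so that every photon has
  exactly one terminal event and the weight ledger
  (detected + absorbed + transmitted + escaped (+ terminated, + rouletted)
  = launched) closes to 1e−9 with roulette off;
- photons crossing the bottom of the last layer are tallied as transmitted
  and never re-entered (bottom escape), which is both the thin-organ
  boundary condition and, with a deep enough stack, a semi-infinite medium.

Geometric path lengths are recorded per depth slab (default 0.2 mm; 0.5 mm
for the many-pair sweeps), split exactly at slab and layer boundaries. On
exit through the top surface the photon's weight and weighted path record
are credited to the annular detector ring containing its exit radius.
Detectors are rings because the configuration is cylindrically symmetric: a
run with contiguous fine rings (0.5 mm, spanning 0–31 mm) therefore serves
*every* detector pair at once — nominal detectors of width 1.0 mm are
assembled as unions of fine rings. In `full_3d` mode each detected
trajectory is first rotated about z so its exit lies on +x (putting both
detectors of a pair on one axis), then binned into voxels; out-of-grid path
is clamped into boundary voxels so depth sums are conserved exactly (trim
edge voxels when imaging).

Randomness is a counter-based SplitMix64 substream per photon index, so
tallies are bit-reproducible for a given seed and unaffected by tally mode.

A second absorption estimator, `weighting="continuous"`, samples collisions
at rate μ_s and attenuates continuously by exp(−μ_a·ℓ). Its trajectories do
not depend on μ_a at all, which makes two techniques exact rather than
approximate:

- **absorption reweighting**: a single recorded base run (per-photon exit
  ring, weight and per-slab paths) is re-used for any absorption profile by
  multiplying each photon's weight with exp(−Σ Δμ_a·L_slab). The slope
  lookup tables and the whole phantom sweep are computed this way;
- **common-random-number perturbation checks**: two runs at μ_a and
  μ_a + Δμ_a share every trajectory, so the first-order sensitivity
  identity can be verified almost noise-free.

## Tissue models

Three presets (per-wavelength scattering; absorption and anisotropy shared
between 770 and 830 nm):

| preset | layers | μ_s (770/830), mm⁻¹ | μ_a, mm⁻¹ | g |
|---|---|---|---|---|
| homogeneous_skin | 40 mm slab | 26/23 | 0.0195 | 0.95 |
| skin_subcutaneous | skin 1.5 / fat 2.5 / muscle 20 mm | 26/23, 24/22, 14/13 | 0.020, 0.003, 0.025 | 0.95 |
| gastric | 7 mm slab | 15/14 | 0.030 | 0.92 |

The homogeneous medium uses skin scattering with the mean absorption of the
four tissue rows (0.0195 mm⁻¹) — at these wavelengths the hemoglobin
spectra cross near this level at ~65% saturation, which is why a single
shared μ_a is a meaningful "average tissue". Its 40 mm depth makes bottom
escape negligible for every probe. Refractive indices are not part of the
published property set; we default to n = 1.4 for tissue against n = 1.0
ambient (the standard MCML convention) with a matched-boundary option for
diffusion-limit comparisons. Sensitivity analyses default to the 770 nm
column (absorption is identical at both wavelengths by construction, and
scattering differs by <12%).

## Probing-depth analysis

For one pair, the per-slab sensitivity profile is
`mean_path(far ring) − mean_path(near ring)` summed over each depth. Summary
metrics follow the published table's definitions: the peak depth, the
outermost linear-interpolated crossings of half maximum on each side of the
peak, and the first depth beyond the peak where the profile falls to 10% of
maximum. The peak depth is the vertex of a parabola least-squares fitted
over the contiguous bins within 80% of the maximum — for a sharp peak this
window is just the three bins around the argmax and the fit is the familiar
3-point parabolic refinement, while for the broad profiles of the larger
probes (whose near-maximum plateau spans millimetres) it averages over the
plateau instead of letting Monte Carlo noise pick an arbitrary plateau bin.
Discretization bias stays below half a slab; no pre-smoothing is applied.

The depth map fixes ρ₂ and sweeps ρ₁ from 0.5 mm to ρ₂ − 0.5 mm in 0.5 mm
steps (ρ₂ ∈ {5, 10, 20, 30} mm, 0.5 mm slabs), normalizes each curve to a
maximum of 1, and records D_p per curve. Pooling all (ρ₁, ρ₂, D_p) points
of one tissue model, ordinary least squares with intercept gives the planar
probing-depth law D_p ≈ a·ρ₁ + b·ρ₂ + c.

A peak depth is only as good as the mean-path profile it comes from, so the
sweep carries a detectability gate: a map is refused when its far ring's
intensity has a relative Monte Carlo standard error above 2%
(√(Σw²)/Σw over the ring's detected weights). This matters most for the
gastric slab, which transmits most light — its reflectance at ρ ≥ 20 mm is
so faint (detected weight of order 10⁻⁶ of launched) that no desk-scale
photon count produces a meaningful D_p there; including such rows visibly
poisons the regression (the fitted plane chases far-ring noise). The
regression protocol sweeps the default set and, when fewer than three ρ₂
levels survive the gate (a planar fit needs leverage in ρ₂), augments the
sweep with the intermediate distances {8, 14} mm of the published figure
set (ρ₂ ∈ {5, 8, 14, 30}; both sets are supported via configuration). In
practice at 5×10⁶ photons the skin-subcutaneous model keeps {5, 10, 20}
and the gastric model is fitted on {5, 8, 10, 14}.

Note one internal inconsistency in the published account: the running text
quotes a 2 mm peak for the 3–5 mm pair while its summary table prints
1.4 mm. The table is the self-consistent value (our simulations reproduce
1.4 ± slab resolution) and is what this package targets.

## Oximeter inversion

The diffusion-approximation closed form μ_a = (S − 2/ρ)²/(3 μ_s′) with
ρ = (ρ₁+ρ₂)/2 is exact only in the far field; for the short probes
(3/5, 6/8 mm) it is biased, which is why a Monte-Carlo-generated slope(μ_a)
lookup table per probe and wavelength is the default inversion. The LUT is
strictly monotone by construction (non-monotone sequences are rejected as
under-resolved) and inverted by piecewise-linear interpolation, clamped
with a flag outside its range.

The published device formula divides the log-ratio by the *mean* distance
ρ; dimensional consistency with the 2/ρ term of the diffusion inversion
requires the two-point difference ρ₂ − ρ₁ (the finite-difference estimate
of −d ln I/dρ), which is our default; the mean-denominator variant is
available as `denominator="mean"`. With identical μ_s′ at both wavelengths
the saturation is gain- and scattering-independent; with the table's
slightly wavelength-dependent scattering a per-wavelength μ_s′ inversion is
provided and the shared-μ_s′ one documents the approximation.

Hemoglobin extinction coefficients are not part of the published analysis
beyond a citation; the bundled table (data/hemoglobin_extinction.csv)
derives from the widely used compiled in-vitro spectra (Prahl/OMLC),
converted to natural-log mm⁻¹·mM⁻¹. With it, equal absorption at 770 and
830 nm corresponds to 63.9% saturation — the physiological coincidence
(~65%) that justifies the homogeneous model's shared absorption
coefficient. The table is injectable; every exact test of the hemoglobin
algebra is a round-trip identity valid for any non-degenerate table.

## The phantom generator

`phantom` is the package's synthetic end-to-end experiment: a fully
oxygenated 1 mm blood layer (1% blood volume, whole-blood totalHb 2.3 mM)
at a variable depth inside an Intralipid-like background (μ_s′ 1.2 mm⁻¹,
g 0.7, μ_a 0.0025 mm⁻¹ at both wavelengths, n 1.4). Blood adds
f·totalHb·(S·ε_O₂Hb + (1−S)·ε_HHb) to the background absorption over the
slabs it occupies. One recorded base run of the blood-free background
serves every probe, depth and wavelength by reweighting; rSO₂-vs-depth
tables report the blood layer's mid-depth.

What the generator emulates: the geometry and composition logic of the
bench phantom, the per-probe depth selectivity, and the depth at which each
probe's rSO₂ reading peaks. What it does not: the bench phantom's actual
Intralipid scattering spectrum, blood-dilution optics, container walls, and
probe coupling — none of which are characterized — so absolute rSO₂ values
of the bench experiment are out of reach and only curve shapes and peak
depths are meaningful. The `low_confidence` flag (negative concentrations,
or totalHb below 0.015 mM) encodes the regime where the output reflects the
background spectrum rather than blood.

## Numerical choices

- Roulette 1e−4 / 0.1 (MCML convention); path cap 10⁴ mm as a loop guard.
- Ring width 1.0 mm centered on each nominal distance (detector size is not
  part of the published probe description; rings are additive so any
  multiple of 0.5 mm is available).
- Peak refinement clamps the parabolic vertex to ± one slab; profiles with
  their maximum at an edge are not refined.
- Half-maximum crossings use the outermost crossing on each side (profiles
  can be noisy and sign-changing near the surface); the 10% depth scans
  deeper than the peak only and is NaN when the model is too thin to reach
  it (possible for the gastric slab).
- Degenerate inputs raise named errors rather than returning silent
  defaults: empty detector rings, non-monotone LUTs, rank-deficient
  regression designs, mismatched probe/LUT pairings, full-3D tallies that
  would exceed ~2 GB.
- Study problem sizes: the headline numbers (scripts/acceptance.py) use
  5×10⁶ photons per tissue model — one shared fine-annuli run per model —
  with 0.2 mm slabs for single-pair profiles and 0.5 mm for map sweeps.
  The test suite runs the same protocol at 2.5×10⁶ photons for the
  homogeneous medium, 5×10⁶ for the map sweeps and 10⁶ for the phantom
  base, chosen so Monte Carlo noise stays small against the tolerances
  being checked while the whole suite stays in the tens-of-minutes range.

## Known limitations

- The sensitivity profiles of the largest probe (20–30 mm) and the
  large-ρ₁ sweep rows have near-maximum plateaus several millimetres wide;
  any peak-location statistic on such a curve — ours or the published
  table's — is determined to no better than about a millimetre. Our
  converged 20–30 mm peak sits near 5.9 mm against the published 5.0 mm,
  while every envelope metric of the same curve (half-maximum range, 10%
  depth) agrees; likewise the fitted ρ₁ coefficient of the
  skin-subcutaneous probing-depth law runs ~0.03 steeper than the published
  0.090, at the edge of the reproduction tolerance. The ρ₂ coefficients and
  intercepts reproduce well.
- No polarization, fluorescence, time- or frequency-domain transport, GPU
  kernels, or curved (endoscopic) surfaces.
- Layers are laterally homogeneous; the published discussion's
  inhomogeneity caveat (e.g. a vessel under one detector) is out of scope.
- The full-3D tally's lateral binning assigns each sub-segment to the voxel
  of its midpoint (depth splitting is exact); at the default step sizes the
  lateral mis-assignment is below a tenth of a voxel.
- Chromophores beyond O₂Hb and HHb (water, lipid) are not modeled.
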
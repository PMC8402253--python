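# srsoxi

Measurement-depth analysis and oximetry for spatially resolved
near-infrared spectroscopy (SRS).

SRS tissue oximeters read diffusely reflected light at two distances ρ₁ < ρ₂
from a source, convert the spatial intensity slope S = ln(I_A/I_B)/(ρ₂−ρ₁)
into an absorption coefficient per wavelength, and the 770/830 nm absorption
pair into hemoglobin concentrations and regional oxygen saturation
rSO₂ = [O₂Hb]/([O₂Hb]+[HHb]). The open question for anyone choosing a probe
is *which depth* such a device actually measures. `srsoxi` answers it
quantitatively: a Monte Carlo photon-transport engine for layered tissue
tallies, per voxel, the detection-weighted mean partial path length
L = Σ Lᵢ Iᵢ / Σ Iᵢ for each detector, and the two-detector difference

    sensitivity(x, y, z) = L_far − L_near      [mm]

is the SRS measurement sensitivity of that voxel: a local absorption change
Δμ_a shifts the slope by Δμ_a·(L_far − L_near)/(ρ₂−ρ₁). Summed over each
depth, the sensitivity profile peaks at the probing depth D_p of the pair;
sweeping (ρ₁, ρ₂) yields depth maps and the planar law
D_p ≈ a·ρ₁ + b·ρ₂ + c per tissue type. The package also implements the full
oximeter computation chain (slope → absorption by diffusion formula or
Monte-Carlo lookup table → hemoglobin → rSO₂) and an in-silico analogue of
the classic validation experiment: a fully oxygenated blood layer buried at
increasing depth in a fat-like scattering medium, read by four probes
(3–5, 6–8, 9–14, 20–30 mm).

Audience: biomedical-optics researchers and oximeter developers who need
probing-depth numbers for probe design, and anyone reproducing or extending
SRS depth-sensitivity analyses.

## Worked example

```python
from srsoxi import (DetectorAnnuli, RunConfig, make_preset_model,
                    run_simulation, pair_depth_profile, profile_metrics)

model = make_preset_model("homogeneous_skin", 770)   # 40 mm slab, mu_s=26/mm,
                                                     # mu_a=0.0195/mm, g=0.95
cfg = RunConfig(n_photons=500_000, seed=7, voxel_size=0.2)
tallies = run_simulation(model, cfg, DetectorAnnuli.uniform(0.5, 31.0))

for rho1, rho2 in ((3, 5), (6, 8), (9, 14), (20, 30)):
    m = profile_metrics(pair_depth_profile(tallies, rho1, rho2))
    print(f"{rho1}-{rho2} mm pair: peak {m.peak_depth:.1f} mm, "
          f"half range {m.half_range_low:.1f}-{m.half_range_high:.1f} mm, "
          f"10% depth {m.depth_10pct:.1f} mm")
```

prints (exact values are seed-dependent at this photon count):

```
3-5 mm pair: peak 1.5 mm, half range 0.1-3.3 mm, 10% depth 5.9 mm
6-8 mm pair: peak 2.4 mm, half range 0.7-4.7 mm, 10% depth 7.7 mm
9-14 mm pair: peak 3.6 mm, half range 1.3-6.5 mm, 10% depth 10.3 mm
20-30 mm pair: peak 6.6 mm, half range 3.3-8.9 mm, 10% depth 15.2 mm
```

Reading: the 3–5 mm probe samples mostly the top ~1.5 mm of tissue and is
blind below ~6 mm; the 20–30 mm probe peaks around 5–6 mm deep. One run with
fine detector annuli serves every pair, because rings are additive. The same
`TallySet` feeds the depth-map sweep (`srsoxi.sensitivity.sweep_depth_map`,
`dp_regression_protocol`) and, via per-area ring intensities, the oximeter
chain (`srsoxi.oximetry`). The phantom experiment lives in `srsoxi.phantom`.

A `srsoxi` command-line tool wraps the same library
(`srsoxi simulate|sensitivity|metrics|map|regress|lut|oximeter|phantom`),
writing CSV/HDF5 outputs with JSON run manifests.

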
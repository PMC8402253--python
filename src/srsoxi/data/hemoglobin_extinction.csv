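# Hemoglobin extinction coefficients at the two LED wavelengths.
# Source: compiled in-vitro human hemoglobin spectra (Prahl / OMLC tabulation,
# molar log10 extinction in cm^-1 M^-1), converted to natural-log units of
# mm^-1 per (mmol/L): value_mm1_per_mM = value_cm1_per_M * ln(10) * 1e-4.
# Injectable: pass any CSV with these columns to ExtinctionTable.from_csv.
wavelength_nm,species,extinction_mm1_per_mM
770,O2Hb,0.146466
770,HHb,0.297087
830,O2Hb,0.224312
830,HHb,0.159596
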
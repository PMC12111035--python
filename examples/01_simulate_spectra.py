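"""Generate flour-like NIR spectra with known ground truth and save them.

Draws 60 samples of the SV-like preset (broad absorption bands at 930,
1200 and 1460 nm; reference values on the sedimentation-value scale),
prints what was planted, and writes the CSV dialect the rest of the
toolkit reads.
"""

from flourspec import SyntheticConfig, generate, write_spectra_csv

config = SyntheticConfig.preset("sv_like", n_samples=60, seed=42)
spectra, truth = generate(config)

print(f"samples:        {spectra.n_samples}")
print(f"wavelengths:    {spectra.n_wavelengths} "
      f"({spectra.wavelengths_nm[0]:.0f}-{spectra.wavelengths_nm[-1]:.0f} nm)")
print(f"reference ({spectra.reference_label}): "
      f"mean {spectra.reference.mean():.1f}, SD {spectra.reference.std(ddof=1):.1f} mL")
centers = ", ".join(f"{spectra.wavelengths_nm[i]:.0f}" for i in truth.band_center_indices)
print(f"planted band centers: {centers} nm")
print(f"planted informative wavelengths: {truth.planted_indices.size} grid points")

write_spectra_csv(spectra, "scratch_example_spectra.csv")
print("wrote scratch_example_spectra.csv")
# The planted indices are the wavelengths a selector should find: they sit
# within 3 grid steps of the nonzero-weight band centers.
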
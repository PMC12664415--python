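"""Spectrophotometric assay arithmetic: standard curve -> total phenolic
content, and DPPH percent inhibition.

A gallic-acid standard curve (200-1000 mg/L) converts a Folin-Ciocalteu
absorbance into a concentration, which the extract volume, dilution factor
and sample dry weight turn into mg gallic-acid equivalents per g dry weight.
"""

from sonoextract import AssaySample, content_from_assay, dpph_inhibition, fit_calibration

# Standard curve: absorbance vs gallic acid concentration (mg/L).
standards = [(200, 0.21), (400, 0.42), (600, 0.60), (800, 0.82), (1000, 1.01)]
cal = fit_calibration(standards)
print(f"Calibration: A = {cal.slope:.6f} * C + {cal.intercept:+.4f}  (R^2 = {cal.r_squared:.4f})")

# A diluted extract aliquot read at 765 nm.
sample = AssaySample(
    absorbance=0.78, extract_volume=0.08, dilution_factor=20, dry_weight=4.0
)
tpc = content_from_assay(cal, sample)
print(f"TPC = {tpc:.1f} mg GAE/g d.w. "
      f"(inferred C = {cal.concentration(sample.absorbance):.0f} mg/L, V = 0.08 L, Df = 20, W = 4 g)")

# DPPH radical scavenging: how much the extract bleaches the radical.
aa = dpph_inhibition(blank_absorbance=0.80, sample_absorbance=0.11)
print(f"Antioxidant activity = {aa:.1f} % DPPH inhibition")
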
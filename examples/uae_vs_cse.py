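"""Full-pipeline comparison of ultrasound-assisted (UAE) versus conventional
shaking (CSE) extraction on a matched synthetic pair.

The CSE arm is generated with true saturation concentration scaled by 0.90
and rate constant by 0.65 relative to UAE — the typical intensification
ultrasound provides through cavitation.  The pipeline fits every stage per
(temperature, method) and the comparison table reports percent differences
at each method's optimum temperature.
"""

from sonoextract import StudyConfig, SyntheticSpec, generate_uae_cse_pair, run_study

dataset = generate_uae_cse_pair(SyntheticSpec(seed=1))
bundle = run_study(
    dataset,
    StudyConfig(n_terms=(10,), bootstrap_iterations=200, seed=1, c_max=175.0),
)

print("Kinetics (per temperature and method):")
print(bundle.kinetics_table[["temperature", "method", "cs", "k", "r_squared"]]
      .to_string(index=False))

print("\nUAE vs CSE at the optimum temperature:")
print(bundle.comparison_table.to_string(index=False))
print(
    "\nAll four parameters (Cs, k, De, K_T) are larger for UAE: ultrasound both"
    "\nraises the extractable yield and accelerates internal and external transport."
)
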
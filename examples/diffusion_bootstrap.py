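"""Estimate the effective diffusivity De from a Crank sphere-diffusion fit
with a series-truncation study and a residual-resampling bootstrap CI.

Synthetic unaccomplished-ratio data y(t) are generated from the Crank model
at De = 12.69e-13 m^2/s (a realistic value for phenolics in leaf powder at
50 degC) with 1 % y-noise.  A single series term visibly biases the fit;
10 and 20 terms agree to ~1e-6 relative.
"""

from sonoextract import bootstrap_de, fit_de, generate_diffusion_dataset

RADIUS = 1.25e-4  # particle radius, m

data = generate_diffusion_dataset(
    de_by_temperature={50.0: 12.690e-13}, noise_sd_y=0.01, seed=7
)
t_seconds, y = data[50.0]

print("n_terms   De (m^2/s)       R^2      95% bootstrap CI (m^2/s)")
for n_terms in (1, 10, 20):
    fit = fit_de((t_seconds, y), radius=RADIUS, n_terms=n_terms)
    boot = bootstrap_de(fit, n_iterations=2000, seed=11)
    print(
        f"{n_terms:4d}      {fit.de:.4e}   {fit.quality.r_squared:.4f}"
        f"   [{boot.ci_low:.3e}, {boot.ci_high:.3e}]  SE {boot.standard_error:.2e}"
    )

print(
    "\nTrue De = 1.269e-12 m^2/s. The 1-term fit is biased low because the"
    "\ntruncated series undershoots y at small times; 10 and 20 terms coincide,"
    "\nso 10 terms suffice. The CI comes from refitting 2000 pseudo-datasets"
    "\nbuilt from the fitted curve plus resampled centred residuals."
)
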
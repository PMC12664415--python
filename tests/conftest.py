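import numpy as np
import pytest

from sonoextract import ExtractionCurve, pso_predict

STUDY_TIMES = np.arange(10.0, 90.0, 10.0)  # minutes


@pytest.fixture
def noiseless_curve() -> ExtractionCurve:
    """Exact pseudo-second-order curve at study-scale parameters (50 degC)."""
    cs, k = 159.15, 12.3074e-4
    return ExtractionCurve(
        times=STUDY_TIMES,
        concentrations=pso_predict(cs, k, STUDY_TIMES),
        temperature=50.0,
        meta={"true_cs": cs, "true_k": k},
    )


@pytest.fixture
def noisy_curve() -> ExtractionCurve:
    """Study-scale curve with sigma = 1 mg/g additive Gaussian noise."""
    rng = np.random.default_rng(42)
    cs, k = 159.15, 12.3074e-4
    clean = pso_predict(cs, k, STUDY_TIMES)
    return ExtractionCurve(
        times=STUDY_TIMES,
        concentrations=np.clip(clean + rng.normal(0, 1.0, STUDY_TIMES.size), 0, None),
        temperature=50.0,
        meta={"true_cs": cs, "true_k": k},
    )
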
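import numpy as np
import pytest

from uvact.kinetics import SurvivalCurve, SurvivalPoint

DEFAULT_DOSES = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)


def exact_curve(neg_log_fn, wavelength_nm=280.0, doses=DEFAULT_DOSES, n=4):
    """Noise-free SurvivalCurve whose mean follows ``neg_log_fn(dose)``."""
    points = [
        SurvivalPoint(d, -float(neg_log_fn(d)), 0.0, n=n) for d in doses
    ]
    return SurvivalCurve(wavelength_nm=wavelength_nm, points=tuple(points))


@pytest.fixture
def first_order_curve():
    """Factory for exact log-linear curves -log10 S = k * F."""

    def make(k, wavelength_nm=280.0, doses=DEFAULT_DOSES):
        return exact_curve(lambda d: k * d, wavelength_nm, doses)

    return make


@pytest.fixture
def quadratic_curve():
    """Factory for exact quadratic curves -log10 S = b1*F + b2*F^2."""

    def make(b1, b2, wavelength_nm=280.0, doses=DEFAULT_DOSES):
        return exact_curve(lambda d: b1 * d + b2 * d * d, wavelength_nm, doses)

    return make


@pytest.fixture
def calibrated_model():
    from uvact.synthetic import default_kinetics

    return default_kinetics()
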
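import numpy as np
import pytest

from dimeye.eye_optics import EyeGeometry
from dimeye.pigment_spectra import Spectrum, template_a1


@pytest.fixture
def bogong_eye() -> EyeGeometry:
    """Measured geometry of the Bogong moth superposition eye (μm)."""
    return EyeGeometry(facet_diameter_D=22, eye_radius_R=969,
                       focal_length_f=485, aperture_A=857,
                       rhabdom_diameter_d=10, rhabdom_length_physical=47,
                       has_tapetum=True, absorption_coeff_k=0.0067)


@pytest.fixture
def template_spectrum():
    """Factory for noiseless template spectra on the standard 1-nm grid."""
    def make(lambda_max: float, lo: float = 300.0, hi: float = 700.0) -> Spectrum:
        wl = np.arange(lo, hi + 0.5, 1.0)
        return Spectrum(wl, template_a1(wl, lambda_max),
                        label=f"template {lambda_max}", condition="synthetic")
    return make
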
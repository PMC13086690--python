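"""Anatomical resolution, image brightness and optical sensitivity of
superposition compound eyes.

A classical refracting superposition eye focuses light collected through a
wide multi-facet pupil onto a single fused rhabdom per ommatidium.  Three
quantities summarise what such an eye can do with dim light:

* the **interommatidial angle** ``Δφ = D / R`` (radians), set by facet
  diameter ``D`` and eye radius of curvature ``R`` — the anatomical limit
  on spatial resolution;
* the **F-number** ``F = f / A``, focal length over the diameter of the
  superposition aperture (measured in practice as the eye-glow diameter) —
  lower F means a brighter retinal image, with brightness ∝ 1/F²;
* the **optical sensitivity**

  .. math:: S = (\\pi/4)^2\\, A^2\\, (d/f)^2\\, \\frac{kl}{2.3 + kl}
      \\qquad (\\mu m^2\\,sr)

  the fraction of light absorbed from an extended scene, where ``d`` and
  ``l`` are the rhabdom diameter and (effective) length and ``k`` its
  absorption coefficient.  A reflective tapetum doubles the effective path
  length ``l`` relative to the physical rhabdom.

All lengths are micrometres; angles are computed in radians and reported
in degrees; ``S`` is in μm²·sr.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

from .exceptions import DomainError

#: Default rhabdom absorption coefficient (μm⁻¹), measured in lobster rhabdoms
#: and conventionally applied to lepidopteran superposition eyes.
DEFAULT_ABSORPTION_COEFF = 0.0067


@dataclass(frozen=True)
class EyeGeometry:
    """Physical parameters of a (superposition) compound eye.

    All lengths in μm.  ``rhabdom_length_physical`` is the anatomical
    rhabdom length; the effective absorbing length is derived from it and
    ``has_tapetum`` (see :func:`effective_rhabdom_length`) and never stored
    implicitly doubled.
    """

    facet_diameter_D: float
    eye_radius_R: float
    focal_length_f: float
    aperture_A: float
    rhabdom_diameter_d: float
    rhabdom_length_physical: float
    has_tapetum: bool = True
    absorption_coeff_k: float = DEFAULT_ABSORPTION_COEFF

    def __post_init__(self):
        for name in ("facet_diameter_D", "eye_radius_R", "focal_length_f",
                     "aperture_A", "rhabdom_diameter_d",
                     "rhabdom_length_physical"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.absorption_coeff_k <= 0:
            raise DomainError("absorption_coeff_k must be > 0")
        if self.aperture_A < self.facet_diameter_D:
            # physically implausible for a superposition eye, but legitimate
            # for apposition-eye comparisons where A equals one facet
            warnings.warn(
                "aperture_A < facet_diameter_D: superposition pupil smaller "
                "than one facet (apposition-style geometry?)",
                UserWarning, stacklevel=2)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class OpticalMetrics:
    """Derived optical metrics of one eye (degrees, dimensionless, μm²·sr, μm)."""

    interommatidial_angle_deg: float
    f_number: float
    optical_sensitivity_S: float
    effective_rhabdom_length: float

    def to_dict(self) -> dict:
        return asdict(self)


def interommatidial_angle(facet_diameter_um: float, eye_radius_um: float) -> float:
    """Interommatidial angle Δφ = D/R, returned in **degrees**.

    Parameters are the facet (lens) centre-to-centre spacing ``D`` and the
    local radius of curvature ``R`` of the eye, both in μm.
    """
    if eye_radius_um <= 0:
        raise DomainError("eye radius must be > 0")
    if facet_diameter_um < 0:
        raise DomainError("facet diameter must be >= 0")
    return math.degrees(facet_diameter_um / eye_radius_um)


def f_number(focal_length_um: float, aperture_um: float) -> float:
    """F-number F = f/A of an imaging system (dimensionless, lower = brighter)."""
    if focal_length_um <= 0 or aperture_um <= 0:
        raise DomainError("focal length and aperture must be > 0")
    return focal_length_um / aperture_um


def effective_rhabdom_length(physical_length_um: float, has_tapetum: bool) -> float:
    """Effective absorbing path length of the rhabdom.

    With a reflective tapetum behind the retina, light traverses the rhabdom
    twice, so the effective length is double the physical length.
    """
    if physical_length_um < 0:
        raise DomainError("rhabdom length must be >= 0")
    return 2.0 * physical_length_um if has_tapetum else float(physical_length_um)


def optical_sensitivity(aperture_um: float, rhabdom_diameter_um: float,
                        focal_length_um: float, effective_length_um: float,
                        k_per_um: float = DEFAULT_ABSORPTION_COEFF) -> float:
    """Optical sensitivity S = (π/4)² A² (d/f)² · kl/(2.3 + kl)  (μm²·sr).

    ``effective_length_um`` is the *effective* rhabdom length (already
    doubled if a tapetum is present); ``k_per_um`` its absorption
    coefficient.  Saturates at (π/4)²A²(d/f)² for kl → ∞ (full absorption).
    """
    if focal_length_um <= 0 or k_per_um <= 0:
        raise DomainError("focal length and absorption coefficient must be > 0")
    if aperture_um <= 0:
        raise DomainError("aperture must be > 0")
    if rhabdom_diameter_um < 0 or effective_length_um < 0:
        raise DomainError("rhabdom dimensions must be >= 0")
    kl = k_per_um * effective_length_um
    absorbed = kl / (2.3 + kl)
    return (math.pi / 4.0) ** 2 * aperture_um ** 2 \
        * (rhabdom_diameter_um / focal_length_um) ** 2 * absorbed


def brightness_ratio(f_number_a: float, f_number_b: float) -> float:
    """How much brighter eye *a*'s image is than eye *b*'s: (F_b/F_a)².

    Retinal image brightness of an extended scene scales as 1/F².
    """
    if f_number_a <= 0 or f_number_b <= 0:
        raise DomainError("F-numbers must be > 0")
    return (f_number_b / f_number_a) ** 2


def sensitivity_ratio(sensitivity_a: float, sensitivity_b: float) -> float:
    """Ratio S_a/S_b of two optical sensitivities."""
    if sensitivity_b <= 0:
        raise DomainError("reference sensitivity must be > 0")
    return sensitivity_a / sensitivity_b


def compute_metrics(geometry: EyeGeometry) -> OpticalMetrics:
    """All optical metrics for one eye geometry."""
    l_eff = effective_rhabdom_length(geometry.rhabdom_length_physical,
                                     geometry.has_tapetum)
    return OpticalMetrics(
        interommatidial_angle_deg=interommatidial_angle(
            geometry.facet_diameter_D, geometry.eye_radius_R),
        f_number=f_number(geometry.focal_length_f, geometry.aperture_A),
        optical_sensitivity_S=optical_sensitivity(
            geometry.aperture_A, geometry.rhabdom_diameter_d,
            geometry.focal_length_f, l_eff, geometry.absorption_coeff_k),
        effective_rhabdom_length=l_eff,
    )


def round_sig(value: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (report precision)."""
    if value == 0 or not math.isfinite(value):
        return value
    return round(value, -int(math.floor(math.log10(abs(value)))) + (sig - 1))
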
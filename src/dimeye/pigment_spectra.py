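"""Visual-pigment absorbance spectra: template evaluation and λmax fitting.

A visual pigment (opsin + retinal chromophore) has an absorbance spectrum
whose shape is essentially universal once the wavelength axis is scaled by
the peak wavelength λmax.  The A1 (11-*cis*-retinal) template of
Govardovskii and colleagues expresses the main (α) band as

.. math::
    S_\\alpha(\\lambda) = \\frac{1}{e^{A(a-x)} + e^{B(b-x)} + e^{C(c-x)} + D},
    \\qquad x = \\lambda_{max}/\\lambda

with published constants, plus a Gaussian β band from the chromophore's
*cis* absorption.  Fitting the template to a measured absorbance spectrum
by nonlinear least squares yields λmax; case-resampling bootstrap gives a
percentile confidence interval.  Difference spectra (dark − acid-denatured)
isolate the pigment contribution from free-retinal contamination in the
UV, and the oxime check (peak migration into 345–375 nm after
hydroxylamine + light) verifies a functional, covalently bound pigment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .exceptions import (BoundaryWarning, DomainError, FitError,
                         GridMismatchError, NoCrossingError,
                         UnreliableCIWarning)
from .ocellar_optics import moving_average

SPECTRUM_CONDITIONS = ("dark", "acid_denatured", "hydroxylamine_illuminated",
                       "difference", "synthetic")

#: conditions whose absorbance may legitimately be negative (baseline-relative)
_NEGATIVE_OK = ("difference", "synthetic")

#: wavelength range (nm) in which retinal oxime absorbs maximally
OXIME_RANGE_NM = (345.0, 375.0)


@dataclass
class Spectrum:
    """A sampled absorbance-vs-wavelength curve.

    ``wavelength_nm`` must be strictly increasing; ``absorbance`` is
    dimensionless (relative) absorbance of the same length.  Negative
    values are permitted only for difference and synthetic spectra.
    """

    wavelength_nm: np.ndarray
    absorbance: np.ndarray
    label: str = ""
    condition: str = "dark"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelength_nm.shape != self.absorbance.shape:
            raise DomainError("wavelength and absorbance lengths differ")
        if self.wavelength_nm.ndim != 1 or len(self.wavelength_nm) == 0:
            raise DomainError("spectrum must be a non-empty 1-D sequence")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise DomainError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise DomainError("absorbance must be finite")
        if self.condition not in SPECTRUM_CONDITIONS:
            raise DomainError(f"unknown condition {self.condition!r}")
        if self.condition not in _NEGATIVE_OK and np.any(self.absorbance < 0):
            raise DomainError(
                f"negative absorbance not allowed for condition {self.condition!r}")

    def __len__(self) -> int:
        return len(self.wavelength_nm)


@dataclass(frozen=True)
class TemplateParams:
    """Published A1 template constants (α band, a(λmax) width term, β band).

    These are fixed literature values; they are exposed for inspection,
    not for tuning.
    """

    A: float = 69.7
    B: float = 28.0
    C: float = -14.9
    D: float = 0.674
    b: float = 0.922
    c: float = 1.104
    beta_amplitude: float = 0.26

    def a(self, lambda_max_nm):
        return 0.8795 + 0.0459 * np.exp(-(lambda_max_nm - 300.0) ** 2 / 11940.0)

    def beta_center(self, lambda_max_nm):
        return 189.0 + 0.315 * lambda_max_nm

    def beta_width(self, lambda_max_nm):
        return -40.5 + 0.195 * lambda_max_nm


A1_PARAMS = TemplateParams()


def template_a1(wavelength_nm, lambda_max_nm: float,
                include_beta: bool = True) -> np.ndarray | float:
    """A1 visual-pigment template, relative absorbance at ``wavelength_nm``.

    Vectorised over ``wavelength_nm``.  λmax must lie in [300, 700] nm
    (the template's validated range); the returned value is S_α (+ S_β).
    """
    if not 300.0 <= lambda_max_nm <= 700.0:
        raise DomainError("lambda_max must lie in [300, 700] nm")
    wl = np.asarray(wavelength_nm, dtype=float)
    if np.any(wl <= 0):
        raise DomainError("wavelengths must be > 0")
    p = A1_PARAMS
    x = lambda_max_nm / wl
    alpha = 1.0 / (np.exp(p.A * (p.a(lambda_max_nm) - x))
                   + np.exp(p.B * (p.b - x))
                   + np.exp(p.C * (p.c - x)) + p.D)
    if include_beta:
        lm_b = p.beta_center(lambda_max_nm)
        b_b = p.beta_width(lambda_max_nm)
        alpha = alpha + p.beta_amplitude * np.exp(-((wl - lm_b) / b_b) ** 2)
    if np.ndim(wavelength_nm) == 0:
        return float(alpha)
    return alpha


@dataclass
class TemplateFitResult:
    """Outcome of a template fit: λmax, amplitude, residual and optional CI."""

    lambda_max_nm: float
    amplitude: float
    rss: float
    fitted_curve: Spectrum
    baseline: float = 0.0
    ci_95: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None

    def to_dict(self) -> dict:
        d = {
            "lambda_max_nm": round(self.lambda_max_nm, 1),
            "amplitude": self.amplitude,
            "baseline": self.baseline,
            "rss": self.rss,
        }
        if self.ci_95 is not None:
            d["ci_95_nm"] = [round(self.ci_95[0], 1), round(self.ci_95[1], 1)]
            d["n_boot"] = self.n_boot
            d["seed"] = self.seed
        return d


def _window_data(spectrum: Spectrum, fit_window_nm) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = fit_window_nm
    mask = (spectrum.wavelength_nm >= lo) & (spectrum.wavelength_nm <= hi)
    if mask.sum() < 10:
        raise FitError(f"need >= 10 points in fit window, got {int(mask.sum())}")
    wl = spectrum.wavelength_nm[mask]
    y = spectrum.absorbance[mask]
    peak = np.max(np.abs(y))
    if peak == 0 or np.ptp(y) == 0:
        raise FitError("flat spectrum: no interior optimum")
    return wl, y / np.max(y)    # normalise to unit maximum within the window


def _ls_coeffs(t: np.ndarray, y: np.ndarray, baseline: bool):
    """Closed-form least-squares (amplitude[, baseline]) and RSS for one template."""
    if not baseline:
        den = float(t @ t)
        amp = float(t @ y) / den
        rss = float(y @ y) - den * amp ** 2
        return amp, 0.0, rss
    n = len(t)
    st, stt, sy, sty = t.sum(), float(t @ t), y.sum(), float(t @ y)
    det = stt * n - st ** 2
    amp = (sty * n - st * sy) / det
    b0 = (stt * sy - st * sty) / det
    rss = float(y @ y) - amp * sty - b0 * sy
    return float(amp), float(b0), float(rss)


def fit_lambda_max(spectrum: Spectrum, fit_window_nm=(300.0, 700.0),
                   bounds_nm=(300.0, 700.0), include_beta: bool = True,
                   baseline: bool = False) -> TemplateFitResult:
    """Estimate λmax by nonlinear least squares against the A1 template.

    The spectrum is normalised to unit maximum inside ``fit_window_nm``;
    for each candidate λmax the amplitude (and optional additive baseline)
    is solved in closed form, so the search is one-dimensional: a 1-nm
    grid scan over ``bounds_nm`` followed by bounded local refinement to
    0.01 nm.  Emits :class:`BoundaryWarning` when the optimum sits at a
    bound (the true peak may lie outside the allowed range).
    """
    wl, y = _window_data(spectrum, fit_window_nm)

    grid = np.arange(bounds_nm[0], bounds_nm[1] + 0.5, 1.0)

    def rss_at(lmax: float) -> float:
        t = template_a1(wl, lmax, include_beta)
        return _ls_coeffs(t, y, baseline)[2]

    rss_grid = np.array([rss_at(g) for g in grid])
    i = int(np.argmin(rss_grid))
    if i == 0 or i == len(grid) - 1:
        warnings.warn("λmax optimum at fit bound", BoundaryWarning, stacklevel=2)
        best = float(grid[i])
    else:
        res = optimize.minimize_scalar(
            rss_at, bounds=(grid[i - 1], grid[i + 1]), method="bounded",
            options={"xatol": 0.01})
        best = float(res.x)
        if rss_at(best) > rss_grid[i]:    # refinement must not move uphill
            best = float(grid[i])

    t = template_a1(wl, best, include_beta)
    amp, b0, rss = _ls_coeffs(t, y, baseline)
    fitted = Spectrum(wl, amp * t + b0, label=f"{spectrum.label} fit".strip(),
                      condition="synthetic")
    return TemplateFitResult(lambda_max_nm=best, amplitude=amp, rss=rss,
                             fitted_curve=fitted, baseline=b0)


def bootstrap_ci(spectrum: Spectrum, n_boot: int = 1000, *, seed: int,
                 fit_window_nm=(300.0, 700.0), bounds_nm=(300.0, 700.0),
                 include_beta: bool = True,
                 baseline: bool = False) -> tuple[float, float]:
    """95% percentile bootstrap CI for λmax (case resampling of points).

    Resamples (λ, absorbance) pairs with replacement ``n_boot`` times —
    represented internally as multinomial resampling weights so every
    replicate is refit with one vectorised weighted least-squares pass
    over the 1-nm λmax grid, plus parabolic refinement of the RSS minimum.
    Deterministic for a fixed ``seed``.  Replicates whose optimum sits at
    a grid bound count as failures; more than 10% failures attach an
    :class:`UnreliableCIWarning`.
    """
    if n_boot < 2:
        raise DomainError("n_boot must be >= 2")
    wl, y = _window_data(spectrum, fit_window_nm)
    n = len(wl)
    grid = np.arange(bounds_nm[0], bounds_nm[1] + 0.5, 1.0)
    T = np.stack([template_a1(wl, g, include_beta) for g in grid])   # (G, n)

    rng = np.random.default_rng(seed)
    C = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)  # (B, n)

    sty = T @ (C * y).T                   # (G, B)  Σ c t y
    stt = (T ** 2) @ C.T                  # (G, B)  Σ c t²
    syy = C @ (y * y)                     # (B,)    Σ c y²
    if not baseline:
        with np.errstate(invalid="ignore", divide="ignore"):
            rss = syy[None, :] - sty ** 2 / stt
    else:
        st = T @ C.T                      # (G, B)  Σ c t
        sy = C @ y                        # (B,)    Σ c y
        det = stt * n - st ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            amp = (sty * n - st * sy[None, :]) / det
            b0 = (stt * sy[None, :] - st * sty) / det
            rss = syy[None, :] - amp * sty - b0 * sy[None, :]
    rss = np.where(np.isfinite(rss), rss, np.inf)

    i_best = np.argmin(rss, axis=0)                            # (B,)
    interior = (i_best > 0) & (i_best < len(grid) - 1)
    ok = interior & np.isfinite(rss[i_best, np.arange(n_boot)])
    n_fail = int(n_boot - ok.sum())
    if n_fail > 0.10 * n_boot:
        warnings.warn(f"{n_fail}/{n_boot} bootstrap refits failed; "
                      "CI may be unreliable", UnreliableCIWarning, stacklevel=2)
    if ok.sum() < 2:
        raise FitError("bootstrap failed: too few successful refits")

    idx = np.arange(n_boot)[ok]
    ib = i_best[ok]
    r0, rm, rp = rss[ib, idx], rss[ib - 1, idx], rss[ib + 1, idx]
    denom = rm - 2.0 * r0 + rp
    offset = np.where(denom > 0, 0.5 * (rm - rp) / np.where(denom > 0, denom, 1.0), 0.0)
    lam = grid[ib] + np.clip(offset, -1.0, 1.0)
    lo, hi = np.percentile(lam, [2.5, 97.5])
    return float(lo), float(hi)


def fit_with_ci(spectrum: Spectrum, n_boot: int = 1000, *, seed: int,
                fit_window_nm=(300.0, 700.0), bounds_nm=(300.0, 700.0),
                include_beta: bool = True,
                baseline: bool = False) -> TemplateFitResult:
    """Point fit plus bootstrap CI in one :class:`TemplateFitResult`."""
    result = fit_lambda_max(spectrum, fit_window_nm, bounds_nm,
                            include_beta, baseline)
    ci = bootstrap_ci(spectrum, n_boot, seed=seed, fit_window_nm=fit_window_nm,
                      bounds_nm=bounds_nm, include_beta=include_beta,
                      baseline=baseline)
    return replace(result, ci_95=ci, n_boot=n_boot, seed=seed)


def difference_spectrum(minuend: Spectrum, subtrahend: Spectrum,
                        interpolate: bool = False) -> Spectrum:
    """Pointwise difference ``minuend − subtrahend`` (condition "difference").

    Requires identical wavelength grids unless ``interpolate`` is set, in
    which case the subtrahend is linearly interpolated onto the part of
    the minuend grid the two spectra share.
    """
    same_grid = (len(minuend) == len(subtrahend)
                 and np.array_equal(minuend.wavelength_nm, subtrahend.wavelength_nm))
    if same_grid:
        wl = minuend.wavelength_nm
        diff = minuend.absorbance - subtrahend.absorbance
    elif interpolate:
        lo = max(minuend.wavelength_nm[0], subtrahend.wavelength_nm[0])
        hi = min(minuend.wavelength_nm[-1], subtrahend.wavelength_nm[-1])
        if lo >= hi:
            raise GridMismatchError("wavelength ranges do not overlap")
        mask = (minuend.wavelength_nm >= lo) & (minuend.wavelength_nm <= hi)
        wl = minuend.wavelength_nm[mask]
        sub = np.interp(wl, subtrahend.wavelength_nm, subtrahend.absorbance)
        diff = minuend.absorbance[mask] - sub
    else:
        raise GridMismatchError(
            "wavelength grids differ (pass interpolate=True to resample)")
    label = f"{minuend.label} - {subtrahend.label}".strip(" -")
    return Spectrum(wl, diff, label=label, condition="difference")


def peak_wavelength(spectrum: Spectrum, smoothing_window_nm: float = 0.0) -> float:
    """Wavelength of maximum absorbance after moving-average smoothing.

    ``smoothing_window_nm`` is converted to samples using the median grid
    step.  Warns when the maximum lies at the boundary of the measured
    range (no interior peak).
    """
    if len(spectrum) < 5:
        raise DomainError("need >= 5 points for peak detection")
    if smoothing_window_nm < 0:
        raise DomainError("smoothing window must be >= 0")
    step = float(np.median(np.diff(spectrum.wavelength_nm)))
    window = max(1, int(round(smoothing_window_nm / step)))
    smoothed = moving_average(spectrum.absorbance, window)
    i = int(np.argmax(smoothed))
    if i == 0 or i == len(smoothed) - 1:
        warnings.warn("absorbance maximum at range boundary",
                      BoundaryWarning, stacklevel=2)
    return float(spectrum.wavelength_nm[i])


def oxime_check(before: Spectrum, after: Spectrum,
                smoothing_window_nm: float = 0.0) -> dict:
    """Did hydroxylamine + illumination shift the peak to retinal oxime?

    ``shifted`` is true iff the post-treatment peak falls inside the oxime
    band (345–375 nm) *and* is blue-shifted relative to the dark peak —
    the signature of covalently bound retinal released as retinal oxime.
    """
    peak_before = peak_wavelength(before, smoothing_window_nm)
    peak_after = peak_wavelength(after, smoothing_window_nm)
    shifted = (OXIME_RANGE_NM[0] <= peak_after <= OXIME_RANGE_NM[1]
               and peak_after < peak_before)
    return {"peak_before_nm": peak_before, "peak_after_nm": peak_after,
            "shifted": bool(shifted)}


def threshold_wavelength(lambda_max_nm: float, level: float = 0.05,
                         limb: str = "long", include_beta: bool = True) -> float:
    """Wavelength at which the template falls to ``level`` on one limb.

    ``limb="long"`` solves on the descending branch above λmax (the
    long-wavelength shoulder used to bound the spectral range an animal
    can still perceive); ``limb="short"`` finds the nearest crossing below
    λmax.  Solved by bracketed bisection to better than 0.1 nm.
    """
    if not 0 < level < 1:
        raise DomainError("level must lie in (0, 1)")
    if limb not in ("long", "short"):
        raise DomainError("limb must be 'long' or 'short'")

    def f(wl):
        return template_a1(wl, lambda_max_nm, include_beta) - level

    if limb == "long":
        if level >= f(lambda_max_nm) + level:    # level above peak value
            return float(lambda_max_nm)
        if f(800.0) > 0:
            raise NoCrossingError(
                f"template stays above {level} out to 800 nm")
        return float(optimize.brentq(f, lambda_max_nm, 800.0, xtol=0.01))

    # short limb: scan down from the peak for the nearest sign change
    grid = np.arange(lambda_max_nm, 300.0 - 0.5, -0.5)
    vals = f(grid)
    crossings = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    if len(crossings) == 0:
        raise NoCrossingError(
            f"template never reaches {level} between 300 nm and the peak")
    j = crossings[0]
    return float(optimize.brentq(f, grid[j + 1], grid[j], xtol=0.01))
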
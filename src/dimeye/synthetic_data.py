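"""Synthetic inputs with known ground truth for every analysis stage.

Each generator emulates one class of raw data consumed by the package —
noisy pigment absorbance spectra, blurred grating line profiles, unimodal
z-stack focus series and per-ocellus lens measurement tables — and writes
its true parameters into the output's ``meta`` dict, so recovery tests
read the truth from metadata rather than re-deriving it.  All randomness
flows through ``numpy.random.default_rng(seed)``; identical arguments give
byte-identical output.

Default parameters reflect the measurement conditions of the hanging-drop
and spectroscopy experiments this package analyses: 300–700 nm spectra at
1-nm steps, 2-μm z-steps in water (n = 1.33), per-colour back-focal
distances of 40/35/30 μm (red/green/blue) with ~10 μm spread, and a mean
ocellar focal length of 190 ± 24 μm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .exceptions import DomainError
from .ocellar_optics import GratingProfile, ZStackFocusSeries
from .pigment_spectra import Spectrum, template_a1

#: free (non-covalently bound) retinal contamination: Gaussian centred in
#: the 350–450 nm band where free retinal absorbs
FREE_RETINAL_PEAK_NM = 380.0
FREE_RETINAL_SD_NM = 30.0

DEFAULT_GRID = (300.0, 700.0, 1.0)

DEFAULT_BFD_MEANS_UM = {"red": 40.0, "green": 35.0, "blue": 30.0}


def gaussian_mtf(blur_sigma_deg: float, frequency_cpd: float) -> float:
    """Modulation transfer of a Gaussian blur: exp(−2π²σ²f²).

    σ in degrees, f in cycles/degree.  A unit-contrast sinusoid blurred by
    a Gaussian of angular width σ retains exactly this contrast.
    """
    return float(np.exp(-2.0 * np.pi ** 2 * blur_sigma_deg ** 2 * frequency_cpd ** 2))


def make_spectrum(lambda_max_nm: float, grid=DEFAULT_GRID,
                  noise_sd: float = 0.0, baseline: float = 0.0,
                  contamination_amplitude: float = 0.0, *,
                  seed: int) -> Spectrum:
    """Synthetic pigment absorbance spectrum with known λmax.

    Amplitude-1 A1 template at ``lambda_max_nm`` plus a constant
    ``baseline``, an optional free-retinal contamination Gaussian (380 nm,
    sd 30 nm) scaled by ``contamination_amplitude``, and i.i.d. Gaussian
    noise of standard deviation ``noise_sd``.
    """
    lo, hi, step = grid
    if not (lo > 0 and hi > lo and step > 0):
        raise DomainError(f"invalid wavelength grid {grid!r}")
    if noise_sd < 0 or baseline < 0 or contamination_amplitude < 0:
        raise DomainError("noise_sd, baseline and contamination must be >= 0")
    wl = np.arange(lo, hi + step / 2, step)
    clean = template_a1(wl, lambda_max_nm) + baseline
    clean = clean + contamination_amplitude * np.exp(
        -0.5 * ((wl - FREE_RETINAL_PEAK_NM) / FREE_RETINAL_SD_NM) ** 2)
    rng = np.random.default_rng(seed)
    y = clean + rng.normal(0.0, noise_sd, size=wl.shape)
    meta = {"kind": "spectrum", "seed": int(seed),
            "true_lambda_max_nm": float(lambda_max_nm),
            "noise_sd": float(noise_sd), "baseline": float(baseline),
            "contamination_amplitude": float(contamination_amplitude),
            "contamination_peak_nm": FREE_RETINAL_PEAK_NM,
            "grid": [float(lo), float(hi), float(step)]}
    return Spectrum(wl, y, label=f"synthetic λmax={lambda_max_nm:g} nm",
                    condition="synthetic", meta=meta)


def make_grating_profile(frequency_cpd: float, waveform: str = "sine",
                         blur_sigma_deg: float = 0.0,
                         samples_per_period: int = 64, n_periods: int = 5,
                         noise_sd: float = 0.0, *, seed: int) -> GratingProfile:
    """Synthetic greyscale line scan across a (blurred) grating image.

    Mean-128, amplitude-127 square or sine wave sampled at
    ``samples_per_period`` per cycle over ``n_periods`` cycles, convolved
    with a Gaussian of angular width ``blur_sigma_deg`` (circular
    boundary, so edge samples stay representative) plus Gaussian noise.
    For sine waveforms the exact post-blur contrast exp(−2π²σ²f²) is
    recorded in ``meta["true_contrast"]``.
    """
    if samples_per_period < 16:
        raise DomainError("need >= 16 samples per period")
    if n_periods < 3:
        raise DomainError("need >= 3 periods")
    if waveform not in ("sine", "square"):
        raise DomainError("waveform must be 'sine' or 'square'")
    if frequency_cpd <= 0 or blur_sigma_deg < 0 or noise_sd < 0:
        raise DomainError("frequency must be > 0; blur and noise >= 0")

    n = samples_per_period * n_periods
    period_deg = 1.0 / frequency_cpd
    position = np.arange(n) * period_deg / samples_per_period
    phase = 2.0 * np.pi * frequency_cpd * position
    if waveform == "sine":
        wave = np.sin(phase)
    else:
        wave = np.sign(np.sin(phase))
        wave[wave == 0] = 1.0
    signal = 128.0 + 127.0 * wave
    if blur_sigma_deg > 0:
        sigma_samples = blur_sigma_deg * samples_per_period / period_deg
        signal = gaussian_filter1d(signal, sigma_samples, mode="wrap")
    rng = np.random.default_rng(seed)
    intensity = np.clip(signal + rng.normal(0.0, noise_sd, size=n), 0.0, None)
    meta = {"kind": "grating", "seed": int(seed), "waveform": waveform,
            "frequency_cpd": float(frequency_cpd),
            "blur_sigma_deg": float(blur_sigma_deg),
            "noise_sd": float(noise_sd)}
    if waveform == "sine":
        meta["true_contrast"] = gaussian_mtf(blur_sigma_deg, frequency_cpd)
    return GratingProfile(position, intensity, frequency_cpd,
                          position_unit="deg", meta=meta)


def make_zstack(true_bfd_um: float, step_um: float = 2.0, n_frames: int = 30,
                focus_width_um: float = 6.0, noise_sd: float = 0.0,
                refractive_index_n: float = 1.33, *,
                seed: int) -> ZStackFocusSeries:
    """Synthetic through-focus series with a known back focal distance.

    The focus score is a unit-height Gaussian over frame index centred at
    ``true_bfd_um / (step_um · n)`` frames from the reference (frame 0,
    the lens back surface), with width ``focus_width_um`` expressed in
    frames, plus Gaussian noise.
    """
    if step_um <= 0 or n_frames < 3 or focus_width_um <= 0 or noise_sd < 0:
        raise DomainError("invalid z-stack parameters")
    if refractive_index_n < 1:
        raise DomainError("refractive index must be >= 1")
    center_frame = true_bfd_um / (step_um * refractive_index_n)
    if not 0 <= center_frame <= n_frames - 1:
        raise DomainError(
            f"true BFD {true_bfd_um} μm lies outside the stack span "
            f"(0..{(n_frames - 1) * step_um * refractive_index_n:.1f} μm)")
    frames = np.arange(n_frames)
    width_frames = focus_width_um / step_um
    score = np.exp(-0.5 * ((frames - center_frame) / width_frames) ** 2)
    rng = np.random.default_rng(seed)
    score = score + rng.normal(0.0, noise_sd, size=n_frames)
    meta = {"kind": "zstack", "seed": int(seed),
            "true_bfd_um": float(true_bfd_um),
            "focus_width_um": float(focus_width_um),
            "noise_sd": float(noise_sd)}
    return ZStackFocusSeries(frames, score, step_um=step_um,
                             refractive_index_n=refractive_index_n,
                             reference_frame=0, meta=meta)


def make_lens_dataset(n_ocelli: int = 10,
                      bfd_means_by_color: dict | None = None,
                      bfd_sd: float = 10.0, f_mean: float = 190.0,
                      f_sd: float = 24.0, *, seed: int) -> pd.DataFrame:
    """Synthetic per-ocellus lens measurement table (chromatic aberration).

    Each of ``n_ocelli`` lenses is measured once per background colour and
    grating orientation.  BFD = colour mean + per-ocellus random intercept
    (sd 0.6·``bfd_sd``) + residual (sd 0.8·``bfd_sd``), so the total
    spread equals ``bfd_sd``; focal length ~ N(f_mean, f_sd) per ocellus.
    Ground-truth parameters are stored in ``df.attrs``.
    """
    if n_ocelli < 2:
        raise DomainError("need >= 2 ocelli")
    if bfd_sd < 0 or f_sd < 0 or f_mean <= 0:
        raise DomainError("invalid spread/mean parameters")
    means = dict(DEFAULT_BFD_MEANS_UM if bfd_means_by_color is None
                 else bfd_means_by_color)
    rng = np.random.default_rng(seed)
    orientations = (0, 45, 90, 135)
    rows = []
    for ocellus in range(n_ocelli):
        intercept = rng.normal(0.0, 0.6 * bfd_sd)
        f_ocellus = rng.normal(f_mean, f_sd)
        for color, mu in means.items():
            for orientation in orientations:
                bfd = mu + intercept + rng.normal(0.0, 0.8 * bfd_sd)
                rows.append({"ocellus_id": f"oc{ocellus:02d}",
                             "background_color": color,
                             "grating_orientation": orientation,
                             "bfd_um": bfd,
                             "focal_length_um": f_ocellus})
    df = pd.DataFrame(rows)
    df.attrs["ground_truth"] = {"kind": "lens_dataset", "seed": int(seed),
                                "bfd_means_by_color": means,
                                "bfd_sd": float(bfd_sd),
                                "f_mean": float(f_mean), "f_sd": float(f_sd)}
    return df
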
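"""Hanging-drop optics of ocellar lenses.

An isolated ocellar lens is suspended concave-side-down on a water droplet
and made to image a displayed grating.  From a through-focus z-stack one
reads the *back focal distance* (BFD, lens inner surface → plane of best
focus, corrected for the refractive index of the medium); from the image
magnification at effective infinity one obtains the *focal length*
``f = s0 · (image period / object period)``.  Image quality is quantified
by the Michelson contrast ``M = (Imax − Imin)/(Imax + Imin)`` of imaged
gratings, and the *optical cutoff frequency* f_c is the x-intercept of a
linear regression of contrast against spatial frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (BoundaryWarning, DomainError, EstimationError,
                         InsufficientDataError, NoCutoffError)

WATER_REFRACTIVE_INDEX = 1.33

# distance below which the grating is no longer at effective infinity (μm)
EFFECTIVE_INFINITY_UM = 100_000.0


@dataclass
class ZStackFocusSeries:
    """Per-frame focus scores of a through-focus z-stack.

    ``focus_score`` is any unimodal sharpness metric (higher = sharper);
    a variance-of-intensity score is conventional but not required.
    ``reference_frame`` is the frame in which the lens back surface is in
    focus; ``step_um`` the physical z-step per frame and
    ``refractive_index_n`` that of the medium between lens and focal plane.
    """

    frame_index: np.ndarray
    focus_score: np.ndarray
    step_um: float
    refractive_index_n: float = WATER_REFRACTIVE_INDEX
    reference_frame: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.focus_score = np.asarray(self.focus_score, dtype=float)
        if self.step_um <= 0:
            raise DomainError("step_um must be > 0")
        if self.refractive_index_n < 1:
            raise DomainError("refractive_index_n must be >= 1")
        if self.frame_index.shape != self.focus_score.shape:
            raise DomainError("frame_index and focus_score lengths differ")
        if not np.all(np.isfinite(self.focus_score)):
            raise DomainError("focus scores must be finite")


@dataclass
class GratingProfile:
    """A 1-D greyscale intensity line scan across a grating image.

    ``position`` is in degrees of visual angle unless ``position_unit``
    says otherwise; ``spatial_frequency_cpd`` is the known frequency of
    the displayed grating in cycles/degree.
    """

    position: np.ndarray
    intensity: np.ndarray
    spatial_frequency_cpd: float
    position_unit: str = "deg"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position.shape != self.intensity.shape:
            raise DomainError("position and intensity lengths differ")
        if np.any(self.intensity < 0):
            raise DomainError("intensity values must be >= 0")
        if self.spatial_frequency_cpd <= 0:
            raise DomainError("spatial frequency must be > 0")

    def n_periods(self) -> float | None:
        """Number of full grating periods covered, if position is angular."""
        if self.position_unit != "deg" or len(self.position) < 2:
            return None
        span = float(self.position.max() - self.position.min())
        return span * self.spatial_frequency_cpd


@dataclass
class ContrastCurve:
    """Contrast vs spatial frequency with fitted cutoff.

    ``points`` keeps *all* measured (frequency, contrast) pairs, including
    any below the regression floor; ``used`` flags the ones that entered
    the ordinary least-squares line contrast = intercept + slope·frequency,
    whose x-intercept is ``cutoff_fc``.
    """

    points: np.ndarray            # shape (n, 2): frequency_cpd, contrast
    used: np.ndarray              # bool mask of points used in the fit
    cutoff_fc: float
    regression_slope: float
    regression_intercept: float

    def to_dict(self) -> dict:
        return {
            "cutoff_fc_cpd": self.cutoff_fc,
            "regression_slope": self.regression_slope,
            "regression_intercept": self.regression_intercept,
            "n_points": int(len(self.points)),
            "n_used": int(self.used.sum()),
        }


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; ``window`` in samples, 1 or 0 = no smoothing.

    Edges use a shrinking window (normalised by the actual number of
    samples averaged), so the output length equals the input length.
    """
    values = np.asarray(values, dtype=float)
    if window <= 1:
        return values.copy()
    kernel = np.ones(int(window))
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def back_focal_distance(series: ZStackFocusSeries,
                        smoothing_window: int = 1) -> float:
    """Back focal distance (μm) from a through-focus series.

    BFD = |best-focus frame − reference frame| × step_um × n, where the
    best-focus frame is the argmax of the (optionally smoothed) focus
    score.  Raises :class:`EstimationError` for a flat series; warns if
    the maximum lies at the stack boundary (the true focus may be outside
    the scanned range).
    """
    score = moving_average(series.focus_score, smoothing_window)
    if np.ptp(score) == 0:
        raise EstimationError("flat focus series: no best-focus plane")
    i_best = int(np.argmax(score))
    if i_best == 0 or i_best == len(score) - 1:
        warnings.warn("focus maximum at stack boundary; BFD may be truncated",
                      BoundaryWarning, stacklevel=2)
    best_frame = int(series.frame_index[i_best])
    n_frames = abs(best_frame - series.reference_frame)
    return n_frames * series.step_um * series.refractive_index_n


def focal_length(s0_um: float, image_period_um: float,
                 object_period: float) -> float:
    """Focal length f = s0 × (image period / object period)  (μm).

    ``s0_um`` is the object (grating) distance; the ratio of the grating
    period in the image to the period of the displayed object is the
    magnification.  Warns when s0 is below effective infinity (100 mm).
    """
    if s0_um <= 0 or image_period_um <= 0 or object_period <= 0:
        raise DomainError("distances and periods must be > 0")
    if s0_um < EFFECTIVE_INFINITY_UM:
        warnings.warn("object distance below 100 mm: grating not at "
                      "effective infinity; focal length biased",
                      UserWarning, stacklevel=2)
    return s0_um * (image_period_um / object_period)


def michelson_contrast(i_max: float, i_min: float) -> float:
    """Michelson contrast (Imax − Imin)/(Imax + Imin), in [0, 1]."""
    if i_min < 0 or i_max < i_min:
        raise DomainError("require i_max >= i_min >= 0")
    if i_max + i_min == 0:
        raise EstimationError("contrast undefined for an all-zero field")
    return (i_max - i_min) / (i_max + i_min)


def profile_contrast(profile: GratingProfile, smoothing_window: int = 1,
                     edge_trim_fraction: float = 0.1) -> float:
    """Michelson contrast of a grating line profile.

    Optionally smooths with a centred moving average (window in samples,
    1 = none), trims ``edge_trim_fraction`` of samples at each end to
    discard windowing/vignetting artefacts, then takes the min and max of
    what remains.  Requires at least two full grating periods in the
    trimmed extent.
    """
    if not 0 <= edge_trim_fraction < 0.5:
        raise DomainError("edge_trim_fraction must be in [0, 0.5)")
    smoothed = moving_average(profile.intensity, smoothing_window)
    n = len(smoothed)
    trim = int(round(n * edge_trim_fraction))
    kept = slice(trim, n - trim if trim else n)
    intensity = smoothed[kept]
    if len(intensity) < 2:
        raise InsufficientDataError("profile empty after edge trimming")
    if profile.position_unit == "deg":
        span = float(np.ptp(profile.position[kept]))
        if span * profile.spatial_frequency_cpd < 2:
            raise InsufficientDataError(
                "fewer than 2 grating periods after trimming")
    return michelson_contrast(float(intensity.max()), float(intensity.min()))


def cutoff_frequency(curve_points, contrast_floor: float = 0.02) -> ContrastCurve:
    """Optical cutoff frequency from contrast-vs-frequency measurements.

    Fits an unweighted ordinary least-squares line to all points with
    contrast above ``contrast_floor`` (near-zero points sit on the noise
    tail and are excluded from the fit but retained in the record) and
    returns its x-intercept −intercept/slope.  The slope must be negative
    (contrast must fall with frequency) for a cutoff to exist.
    """
    pts = np.asarray(curve_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DomainError("curve_points must be a sequence of (frequency, contrast)")
    if np.any(pts[:, 0] <= 0):
        raise DomainError("spatial frequencies must be > 0")
    if np.any((pts[:, 1] < 0) | (pts[:, 1] > 1)):
        raise DomainError("contrasts must lie in [0, 1]")
    order = np.argsort(pts[:, 0])
    pts = pts[order]
    # floor 0 disables the exclusion entirely (a measured 0 is then usable)
    if contrast_floor > 0:
        used = pts[:, 1] > contrast_floor
    else:
        used = np.ones(len(pts), dtype=bool)
    if used.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 points above the contrast floor, got {int(used.sum())}")
    fit = stats.linregress(pts[used, 0], pts[used, 1])
    if fit.slope >= 0:
        raise NoCutoffError("contrast does not decrease with frequency")
    fc = -fit.intercept / fit.slope
    return ContrastCurve(points=pts, used=used, cutoff_fc=float(fc),
                         regression_slope=float(fit.slope),
                         regression_intercept=float(fit.intercept))


def summarize_lens_measurements(measurements: pd.DataFrame, value: str,
                                group_by: str) -> pd.DataFrame:
    """Descriptive per-group summary (mean, sd, n) of lens measurements.

    ``measurements`` is a table of per-acquisition values (e.g. the output
    of the synthetic lens-dataset generator), ``value`` the numeric column
    to summarise (``bfd_um`` or ``focal_length_um``) and ``group_by`` the
    grouping column (``background_color`` or ``grating_orientation``).
    Groups with a single value report sd = 0 (flagged by n = 1).
    """
    if group_by not in measurements.columns or value not in measurements.columns:
        raise DomainError(f"columns {group_by!r}/{value!r} not in table")
    if measurements.empty:
        raise InsufficientDataError("no measurements to summarize")
    grouped = measurements.groupby(group_by, observed=True)[value]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out = out.rename(columns={group_by: "group"})
    return out
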
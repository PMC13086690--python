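"""CSV readers/writers, run configuration and the JSON analysis report.

Tabular inputs are plain comma-separated UTF-8 files with a mandatory
header; lines starting with ``#`` before the header carry ``key: value``
metadata (units are fixed by column-name convention: ``wavelength_nm``,
``frequency_cpd`` and so on).  Structured outputs are JSON with stable
field ordering and documented float precision, so identical inputs give
byte-identical report bodies (provenance timestamp aside).
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import eye_optics, ocellar_optics, pigment_spectra
from .exceptions import DomainError, ParseError
from .ocellar_optics import GratingProfile, ZStackFocusSeries
from .pigment_spectra import Spectrum

PACKAGE_VERSION = "0.1.0"


# ---------------------------------------------------------------- CSV layer

def _parse_table(path, required_columns):
    """Read a commented CSV; returns (metadata dict, column dict of floats)."""
    path = Path(path)
    meta: dict = {}
    header = None
    columns: dict[str, list[float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                text = ",".join(row).lstrip().lstrip("#").strip()
                if ":" in text:
                    key, _, val = text.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if header is None:
                header = [c.strip() for c in row]
                missing = [c for c in required_columns if c not in header]
                if missing:
                    raise ParseError(f"missing required column(s) {missing}; "
                                     f"header row is mandatory", path, lineno)
                columns = {c: [] for c in header}
                continue
            if len(row) != len(header):
                raise ParseError(f"expected {len(header)} fields, got {len(row)}",
                                 path, lineno)
            for name, cell in zip(header, row):
                try:
                    columns[name].append(float(cell))
                except ValueError:
                    raise ParseError(f"non-numeric value {cell!r} in column "
                                     f"{name!r}", path, lineno) from None
    if header is None:
        raise ParseError("empty file: no header found", path)
    return meta, {k: np.asarray(v) for k, v in columns.items()}


def read_spectrum_csv(path) -> Spectrum:
    """Read a two-column ``wavelength_nm,absorbance`` spectrum CSV."""
    meta, cols = _parse_table(path, ("wavelength_nm", "absorbance"))
    wl = cols["wavelength_nm"]
    if np.any(np.diff(wl) <= 0):
        bad = int(np.nonzero(np.diff(wl) <= 0)[0][0])
        raise ParseError(f"wavelengths not strictly increasing near "
                         f"{wl[bad]:g} nm (duplicate or unsorted row)", path)
    return Spectrum(wl, cols["absorbance"],
                    label=meta.pop("label", Path(path).stem),
                    condition=meta.pop("condition", "dark"), meta=meta)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# label: {spectrum.label}\n")
        fh.write(f"# condition: {spectrum.condition}\n")
        for key, val in spectrum.meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("wavelength_nm,absorbance\n")
        for wl, ab in zip(spectrum.wavelength_nm, spectrum.absorbance):
            fh.write(f"{wl:.6g},{ab:.10g}\n")


def read_zstack_csv(path) -> ZStackFocusSeries:
    """Read a ``frame,focus_score`` CSV; step/index/reference in '#' metadata."""
    meta, cols = _parse_table(path, ("frame", "focus_score"))
    try:
        step = float(meta.pop("step_um"))
    except KeyError:
        raise ParseError("missing '# step_um:' metadata line", path) from None
    n = float(meta.pop("refractive_index_n", ocellar_optics.WATER_REFRACTIVE_INDEX))
    ref = int(float(meta.pop("reference_frame", 0)))
    return ZStackFocusSeries(cols["frame"].astype(int), cols["focus_score"],
                             step_um=step, refractive_index_n=n,
                             reference_frame=ref, meta=meta)


def write_zstack_csv(series: ZStackFocusSeries, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# step_um: {series.step_um:g}\n")
        fh.write(f"# refractive_index_n: {series.refractive_index_n:g}\n")
        fh.write(f"# reference_frame: {series.reference_frame}\n")
        for key, val in series.meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("frame,focus_score\n")
        for fr, sc in zip(series.frame_index, series.focus_score):
            fh.write(f"{fr},{sc:.10g}\n")


def read_profile_csv(path) -> GratingProfile:
    """Read a ``position,intensity`` line-profile CSV.

    Requires a ``# frequency_cpd:`` metadata line; ``# position_unit:``
    defaults to degrees.
    """
    meta, cols = _parse_table(path, ("position", "intensity"))
    try:
        freq = float(meta.pop("frequency_cpd"))
    except KeyError:
        raise ParseError("missing '# frequency_cpd:' metadata line", path) from None
    unit = meta.pop("position_unit", "deg")
    return GratingProfile(cols["position"], cols["intensity"], freq,
                          position_unit=unit, meta=meta)


def write_profile_csv(profile: GratingProfile, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(f"# frequency_cpd: {profile.spatial_frequency_cpd:g}\n")
        fh.write(f"# position_unit: {profile.position_unit}\n")
        for key, val in profile.meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("position,intensity\n")
        for pos, inten in zip(profile.position, profile.intensity):
            fh.write(f"{pos:.10g},{inten:.10g}\n")


def read_curve_csv(path) -> np.ndarray:
    """Read a ``frequency_cpd,contrast`` table as an (n, 2) array."""
    _, cols = _parse_table(path, ("frequency_cpd", "contrast"))
    return np.column_stack([cols["frequency_cpd"], cols["contrast"]])


# ------------------------------------------------------------ config/report

@dataclass
class RunConfig:
    """Configuration of a pipeline run; loadable from YAML or JSON.

    Each stage key is optional; a stage runs iff its section is present.
    ``seed`` is mandatory whenever a stochastic stage (opsin fitting with
    bootstrap) is enabled.
    """

    eye_geometry: dict | None = None           # EyeGeometry fields
    spectra: list = field(default_factory=list)  # [{path, window, n_boot, ...}]
    zstacks: list = field(default_factory=list)  # [{path, smoothing_window}]
    contrast_curves: list = field(default_factory=list)  # [{path, floor}]
    seed: int | None = None
    output_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        needs_seed = any(s.get("n_boot", 0) for s in self.spectra)
        if needs_seed and self.seed is None:
            raise DomainError("seed is mandatory when bootstrapping is enabled")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ParseError("config must be a mapping", path)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config key(s): {sorted(unknown)}", path)
        return cls(**data)

    def to_dict(self) -> dict:
        return {"eye_geometry": self.eye_geometry, "spectra": self.spectra,
                "zstacks": self.zstacks, "contrast_curves": self.contrast_curves,
                "seed": self.seed, "output_dir": self.output_dir,
                "log_level": self.log_level}


def _check_no_nan(obj, path="report"):
    if isinstance(obj, dict):
        for key, val in obj.items():
            _check_no_nan(val, f"{path}.{key}")
    elif isinstance(obj, (list, tuple)):
        for i, val in enumerate(obj):
            _check_no_nan(val, f"{path}[{i}]")
    elif isinstance(obj, float) and not math.isfinite(obj):
        raise DomainError(f"non-finite value at {path}")


@dataclass
class AnalysisReport:
    """Structured result of a pipeline run (units embedded in key names)."""

    stages: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"stages": self.stages, "errors": self.errors,
                "provenance": self.provenance}


def write_report(report: AnalysisReport, path) -> None:
    """Serialise a report to JSON (stable ordering, NaN rejected by name)."""
    payload = report.to_dict()
    _check_no_nan(payload)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_report(path) -> AnalysisReport:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return AnalysisReport(stages=data.get("stages", {}),
                          errors=data.get("errors", {}),
                          provenance=data.get("provenance", {}))


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute all configured stages; stage failures are recorded, not fatal.

    Independent stages keep running after one fails; the report's
    ``errors`` maps stage name → message, and the process exit status of
    the CLI is nonzero iff this map is non-empty.
    """
    stages: dict = {}
    errors: dict = {}

    if config.eye_geometry is not None:
        try:
            geometry = eye_optics.EyeGeometry(**config.eye_geometry)
            metrics = eye_optics.compute_metrics(geometry)
            stages["eye_metrics"] = {
                "inputs": geometry.to_dict(),
                "metrics": {
                    "interommatidial_angle_deg": eye_optics.round_sig(
                        metrics.interommatidial_angle_deg),
                    "f_number": eye_optics.round_sig(metrics.f_number),
                    "optical_sensitivity_S_um2sr": eye_optics.round_sig(
                        metrics.optical_sensitivity_S),
                    "effective_rhabdom_length_um": metrics.effective_rhabdom_length,
                },
                "units": {"lengths": "um", "angle": "deg",
                          "optical_sensitivity_S": "um^2 sr"},
            }
        except Exception as exc:               # noqa: BLE001 - reported per stage
            errors["eye_metrics"] = str(exc)

    for spec in config.spectra:
        name = f"fit_opsin:{Path(spec['path']).stem}"
        try:
            spectrum = read_spectrum_csv(spec["path"])
            window = tuple(spec.get("window", (300.0, 700.0)))
            n_boot = int(spec.get("n_boot", 0))
            kwargs = dict(fit_window_nm=window,
                          include_beta=spec.get("include_beta", True),
                          baseline=spec.get("baseline", False))
            if n_boot:
                result = pigment_spectra.fit_with_ci(
                    spectrum, n_boot, seed=int(config.seed), **kwargs)
            else:
                result = pigment_spectra.fit_lambda_max(spectrum, **kwargs)
            stages[name] = result.to_dict()
        except Exception as exc:               # noqa: BLE001
            errors[name] = str(exc)

    for spec in config.zstacks:
        name = f"bfd:{Path(spec['path']).stem}"
        try:
            series = read_zstack_csv(spec["path"])
            bfd = ocellar_optics.back_focal_distance(
                series, smoothing_window=int(spec.get("smoothing_window", 1)))
            stages[name] = {"bfd_um": round(bfd, 2),
                            "step_um": series.step_um,
                            "refractive_index_n": series.refractive_index_n}
        except Exception as exc:               # noqa: BLE001
            errors[name] = str(exc)

    for spec in config.contrast_curves:
        name = f"cutoff:{Path(spec['path']).stem}"
        try:
            points = read_curve_csv(spec["path"])
            curve = ocellar_optics.cutoff_frequency(
                points, contrast_floor=float(spec.get("floor", 0.02)))
            stages[name] = curve.to_dict()
        except Exception as exc:               # noqa: BLE001
            errors[name] = str(exc)

    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
    provenance = {"config_sha256": config_hash,
                  "package_version": PACKAGE_VERSION,
                  "created_at": datetime.now(timezone.utc).isoformat()}
    return AnalysisReport(stages=stages, errors=errors, provenance=provenance)
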
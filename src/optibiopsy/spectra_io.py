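"""Spectral data types and the on-disk dataset layout.

A dataset is a directory of two-column CSV spectra (header
``wavelength_nm,value``) tied together by a JSON manifest.  Each manifest
record describes one acquisition at one probe location: a diffuse
reflectance (DRS) record points at its raw signal, its dark background and
its Spectralon white-reference spectrum; an autofluorescence (AF) record
points at its signal and dark background and carries the excitation
wavelength.  Records taken at the same tissue location share a
``measurement_id`` so that DRS and AF features can later be paired.

All wavelengths are in nanometres; there is no unit field.  Paths inside a
manifest are relative to the manifest file, so a dataset directory can be
moved or shipped as a unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DRS",
    "AF",
    "MODALITIES",
    "KINDS",
    "HEALTHY",
    "TUMOR",
    "TISSUE_LABELS",
    "Spectrum",
    "MeasurementRecord",
    "Manifest",
    "SpectrumError",
    "ManifestError",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
]

DRS = "DRS"
AF = "AF"
MODALITIES = (DRS, AF)

#: Processing stages a spectrum can be in.
KINDS = (
    "raw",
    "dark",
    "reference",
    "reflectance",
    "background_subtracted",
    "normalized",
)

HEALTHY = "healthy"
TUMOR = "tumor"
TISSUE_LABELS = (HEALTHY, TUMOR)

CSV_HEADER = ("wavelength_nm", "value")


class SpectrumError(ValueError):
    """Raised for malformed or physically invalid spectra."""


class ManifestError(ValueError):
    """Raised for manifests violating the dataset schema."""


@dataclass(frozen=True, eq=False)
class Spectrum:
    """A single spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing, finite wavelength grid in nm, length >= 2.
    values
        Intensity values (detector counts, or dimensionless reflectance
        after calibration), same length as the grid, all finite.
    modality
        ``"DRS"`` or ``"AF"``.
    kind
        Processing stage, one of :data:`KINDS`.
    excitation_nm
        Excitation wavelength; required for AF, forbidden for DRS.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    modality: str
    kind: str = "raw"
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1:
            raise SpectrumError("wavelengths and values must be 1-D")
        if len(wl) != len(vals):
            raise SpectrumError(
                f"length mismatch: {len(wl)} wavelengths vs {len(vals)} values"
            )
        if len(wl) < 2:
            raise SpectrumError("a spectrum needs at least 2 samples")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise SpectrumError("non-finite wavelength or value")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            bad = wl[1:][steps <= 0][0]
            raise SpectrumError(
                f"wavelengths not strictly increasing at {bad:g} nm"
            )
        if self.modality not in MODALITIES:
            raise SpectrumError(f"unknown modality {self.modality!r}")
        if self.kind not in KINDS:
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        if self.modality == AF:
            if self.excitation_nm is None or not self.excitation_nm > 0:
                raise SpectrumError("AF spectra require a positive excitation_nm")
        elif self.excitation_nm is not None:
            raise SpectrumError("excitation_nm is only meaningful for AF spectra")

    def __len__(self) -> int:
        return len(self.wavelengths_nm)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.values, other.values)
            and self.modality == other.modality
            and self.kind == other.kind
            and self.excitation_nm == other.excitation_nm
        )

    def with_values(self, values: np.ndarray, kind: str) -> "Spectrum":
        """Return a copy with new values (same grid and metadata)."""
        return Spectrum(
            wavelengths_nm=self.wavelengths_nm,
            values=np.asarray(values, dtype=float),
            modality=self.modality,
            kind=kind,
            excitation_nm=self.excitation_nm,
        )


def read_spectrum(
    path: str | Path,
    modality: str,
    kind: str = "raw",
    excitation_nm: float | None = None,
) -> Spectrum:
    """Read a two-column CSV spectrum, sorting rows by wavelength.

    Duplicate wavelengths are an error (instrument-export anomaly), reported
    with the offending wavelength.
    """
    path = Path(path)
    if not path.is_file():
        raise SpectrumError(f"spectrum file not found: {path}")
    try:
        frame = pd.read_csv(path, dtype=float, float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise SpectrumError(f"malformed spectrum CSV {path}: {exc}") from exc
    if tuple(frame.columns) != CSV_HEADER:
        raise SpectrumError(
            f"{path}: expected header {','.join(CSV_HEADER)!r}, "
            f"got {','.join(map(str, frame.columns))!r}"
        )
    frame = frame.sort_values("wavelength_nm", kind="stable")
    wl = frame["wavelength_nm"].to_numpy()
    dup = wl[1:][np.diff(wl) == 0]
    if dup.size:
        raise SpectrumError(
            f"{path}: duplicate wavelength {dup[0]:g} nm"
        )
    return Spectrum(
        wavelengths_nm=wl,
        values=frame["value"].to_numpy(),
        modality=modality,
        kind=kind,
        excitation_nm=excitation_nm,
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as CSV at full float precision (round-trip exact)."""
    path = Path(path)
    if not path.parent.is_dir():
        raise SpectrumError(f"directory does not exist: {path.parent}")
    lines = [",".join(CSV_HEADER)]
    for wl, v in zip(spectrum.wavelengths_nm, spectrum.values):
        lines.append(f"{wl:.17g},{v:.17g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Manifest


@dataclass(frozen=True)
class MeasurementRecord:
    """One acquisition at one probe location.

    DRS records carry a white-reference path; AF records carry the
    excitation wavelength instead.  All paths are relative to the manifest.
    """

    measurement_id: str
    patient_id: str
    tissue_label: str
    modality: str
    spectrum_path: str
    dark_path: str
    reference_path: str | None = None
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        if self.tissue_label not in TISSUE_LABELS:
            raise ManifestError(
                f"{self.measurement_id}: unknown tissue_label {self.tissue_label!r}"
            )
        if self.modality not in MODALITIES:
            raise ManifestError(
                f"{self.measurement_id}: unknown modality {self.modality!r}"
            )
        if self.modality == DRS and self.reference_path is None:
            raise ManifestError(
                f"{self.measurement_id}: DRS record requires reference_path"
            )
        if self.modality == AF and self.reference_path is not None:
            raise ManifestError(
                f"{self.measurement_id}: AF record must not carry reference_path"
            )
        if self.modality == AF and (
            self.excitation_nm is None or not self.excitation_nm > 0
        ):
            raise ManifestError(
                f"{self.measurement_id}: AF record requires positive excitation_nm"
            )
        if self.modality == DRS and self.excitation_nm is not None:
            raise ManifestError(
                f"{self.measurement_id}: DRS record must not carry excitation_nm"
            )

    def to_dict(self) -> dict:
        out = {
            "measurement_id": self.measurement_id,
            "patient_id": self.patient_id,
            "tissue_label": self.tissue_label,
            "modality": self.modality,
            "spectrum_path": self.spectrum_path,
            "dark_path": self.dark_path,
        }
        if self.reference_path is not None:
            out["reference_path"] = self.reference_path
        if self.excitation_nm is not None:
            out["excitation_nm"] = self.excitation_nm
        return out


_RECORD_FIELDS = {f.name for f in fields(MeasurementRecord)}


@dataclass
class Manifest:
    """The dataset index: measurement records plus free-form metadata.

    A ``measurement_id`` names a probe location and is shared by the DRS
    and AF records taken there; the combination
    (measurement_id, modality, excitation_nm) must be unique.
    """

    records: list[MeasurementRecord]
    dataset_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for rec in self.records:
            key = (rec.measurement_id, rec.modality, rec.excitation_nm)
            if key in seen:
                raise ManifestError(
                    f"duplicate record for measurement_id={rec.measurement_id!r}, "
                    f"modality={rec.modality}"
                )
            seen.add(key)

    def grouped(self) -> dict[str, list[MeasurementRecord]]:
        """Records grouped by measurement_id, in first-seen order."""
        groups: dict[str, list[MeasurementRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.measurement_id, []).append(rec)
        return groups


def _check_paths(manifest: Manifest, root: Path) -> None:
    for rec in manifest.records:
        paths = [rec.spectrum_path, rec.dark_path]
        if rec.reference_path is not None:
            paths.append(rec.reference_path)
        for rel in paths:
            if not (root / rel).is_file():
                raise ManifestError(
                    f"{rec.measurement_id}: referenced file missing: {rel}"
                )


def read_manifest(path: str | Path) -> Manifest:
    """Read and validate a JSON manifest; referenced files must exist."""
    path = Path(path)
    if not path.is_file():
        raise ManifestError(f"manifest not found: {path}")
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ManifestError(f"malformed manifest JSON {path}: {exc}") from exc
    if not isinstance(doc, dict) or "records" not in doc:
        raise ManifestError(f"{path}: manifest must be an object with 'records'")
    records = []
    for i, raw in enumerate(doc["records"]):
        if not isinstance(raw, dict):
            raise ManifestError(f"{path}: record {i} is not an object")
        unknown = set(raw) - _RECORD_FIELDS
        if unknown:
            raise ManifestError(
                f"{path}: record {i} has unknown keys {sorted(unknown)}"
            )
        try:
            records.append(MeasurementRecord(**raw))
        except TypeError as exc:
            raise ManifestError(f"{path}: record {i}: {exc}") from exc
    manifest = Manifest(records=records, dataset_meta=doc.get("dataset_meta", {}))
    _check_paths(manifest, path.parent)
    return manifest


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write a manifest as deterministic, sorted-key JSON."""
    path = Path(path)
    doc = {
        "records": [rec.to_dict() for rec in manifest.records],
        "dataset_meta": manifest.dataset_meta,
    }
    path.write_text(
        json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
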
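"""Ratiometric spectral band features.

The classifier never sees full spectra: each measurement is reduced to four
dimensionless band ratios, which cancels the multiplicative intensity
variation caused by probe contact pressure and avoids overfitting a small
dataset.

DRS (calibrated reflectance, mean over closed bands):

    ratio1 = Rbar[475-575 nm] / Rbar[800-900 nm]   visible contrast (hemoglobin)
    ratio2 = Rbar[1100-1120 nm] / Rbar[800-900 nm] lipid/collagen absorption edge

AF under 415 nm excitation (background-subtracted counts):

    ratio3 = Ibar[495-505 nm] / Ibar[550-650 nm]   bile emission peak
    ratio4 = Ibar[670-680 nm] / Ibar[550-650 nm]   porphyrin red peak

The 800-900 nm reflectance band and 550-650 nm emission band serve as
normalization regions with no strong spectral features.  A band mean is the
arithmetic mean of the samples whose wavelength falls inside the closed
interval; band endpoints are inclusive and no edge interpolation is done.
AF channels at 385 or 450 nm excitation are carried through I/O but yield
no features.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import preprocess
from .spectra_io import (
    AF,
    DRS,
    Manifest,
    MeasurementRecord,
    Spectrum,
    read_spectrum,
)

__all__ = [
    "SpectralBand",
    "FeatureVector",
    "BandCoverageError",
    "FeatureError",
    "DEFAULT_BANDS",
    "AF_CLASSIFICATION_EXCITATION_NM",
    "load_bands",
    "band_mean",
    "drs_ratios",
    "af_ratios",
    "build_feature_table",
    "write_feature_table",
    "read_feature_table",
]

log = logging.getLogger(__name__)

#: Only this AF excitation channel produces features.
AF_CLASSIFICATION_EXCITATION_NM = 415.0

RATIO_COLUMNS = ["ratio1", "ratio2", "ratio3", "ratio4"]
TABLE_COLUMNS = ["measurement_id", "patient_id", "tissue_label", *RATIO_COLUMNS]


class BandCoverageError(ValueError):
    """Raised when a spectrum has no samples inside a requested band."""


class FeatureError(ValueError):
    """Raised when feature extraction fails for a measurement."""


@dataclass(frozen=True)
class SpectralBand:
    """Closed wavelength interval [lo_nm, hi_nm] used for band averaging."""

    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if not (0 < self.lo_nm < self.hi_nm):
            raise ValueError(
                f"invalid band [{self.lo_nm}, {self.hi_nm}]: need 0 < lo < hi"
            )

    def __str__(self) -> str:
        return f"[{self.lo_nm:g}, {self.hi_nm:g}] nm"


#: Named band defaults.  Reusable for other organs via ``load_bands``.
DEFAULT_BANDS: dict[str, SpectralBand] = {
    "drs_vis": SpectralBand(475.0, 575.0),
    "drs_nir_norm": SpectralBand(800.0, 900.0),
    "drs_lipid_edge": SpectralBand(1100.0, 1120.0),
    "af_bile": SpectralBand(495.0, 505.0),
    "af_norm": SpectralBand(550.0, 650.0),
    "af_porphyrin": SpectralBand(670.0, 680.0),
}


def load_bands(path: str | Path) -> dict[str, SpectralBand]:
    """Load band overrides from a YAML/JSON mapping name -> [lo_nm, hi_nm].

    Unnamed bands keep their defaults.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: band file must map band name to [lo, hi]")
    bands = dict(DEFAULT_BANDS)
    for name, pair in doc.items():
        if name not in DEFAULT_BANDS:
            raise ValueError(f"{path}: unknown band name {name!r}")
        lo, hi = pair
        bands[name] = SpectralBand(float(lo), float(hi))
    return bands


@dataclass(frozen=True)
class FeatureVector:
    """The four band ratios for one measurement location.

    ``ratio1``/``ratio2`` are present iff a DRS acquisition exists;
    ``ratio3``/``ratio4`` iff a 415 nm AF acquisition exists.  Missing
    ratios are NaN.
    """

    measurement_id: str
    patient_id: str
    tissue_label: str
    ratio1: float = math.nan
    ratio2: float = math.nan
    ratio3: float = math.nan
    ratio4: float = math.nan

    @property
    def has_drs(self) -> bool:
        return not math.isnan(self.ratio1)

    @property
    def has_af(self) -> bool:
        return not math.isnan(self.ratio3)


def band_mean(spectrum: Spectrum, band: SpectralBand) -> float:
    """Arithmetic mean of the samples with lo_nm <= wavelength <= hi_nm."""
    wl = spectrum.wavelengths_nm
    mask = (wl >= band.lo_nm) & (wl <= band.hi_nm)
    if not np.any(mask):
        raise BandCoverageError(
            f"no samples in band {band}; spectrum covers "
            f"[{wl[0]:g}, {wl[-1]:g}] nm"
        )
    return float(np.mean(spectrum.values[mask]))


def _ratio(num: float, den: float, what: str, eps: float) -> float:
    if abs(den) < eps:
        raise FeatureError(f"{what}: normalization band mean {den:g} below {eps:g}")
    return num / den


def drs_ratios(
    reflectance: Spectrum,
    bands: dict[str, SpectralBand] | None = None,
    eps: float = 1e-12,
) -> tuple[float, float]:
    """(ratio1, ratio2) from a calibrated DRS reflectance spectrum."""
    bands = bands or DEFAULT_BANDS
    if reflectance.modality != DRS:
        raise FeatureError(f"expected DRS spectrum, got {reflectance.modality}")
    if reflectance.kind not in ("reflectance", "normalized"):
        raise FeatureError(
            f"expected calibrated reflectance, got kind {reflectance.kind!r}"
        )
    norm = band_mean(reflectance, bands["drs_nir_norm"])
    ratio1 = _ratio(band_mean(reflectance, bands["drs_vis"]), norm, "ratio1", eps)
    ratio2 = _ratio(band_mean(reflectance, bands["drs_lipid_edge"]), norm, "ratio2", eps)
    return ratio1, ratio2


def af_ratios(
    af_spectrum: Spectrum,
    bands: dict[str, SpectralBand] | None = None,
    eps: float = 1e-12,
) -> tuple[float, float]:
    """(ratio3, ratio4) from a background-subtracted 415 nm AF spectrum."""
    bands = bands or DEFAULT_BANDS
    if af_spectrum.modality != AF:
        raise FeatureError(f"expected AF spectrum, got {af_spectrum.modality}")
    if af_spectrum.excitation_nm != AF_CLASSIFICATION_EXCITATION_NM:
        raise FeatureError(
            f"AF features are defined for {AF_CLASSIFICATION_EXCITATION_NM:g} nm "
            f"excitation only, got {af_spectrum.excitation_nm:g} nm"
        )
    if af_spectrum.kind not in ("background_subtracted", "normalized"):
        raise FeatureError(
            f"expected background-subtracted AF spectrum, got kind "
            f"{af_spectrum.kind!r}"
        )
    norm = band_mean(af_spectrum, bands["af_norm"])
    ratio3 = _ratio(band_mean(af_spectrum, bands["af_bile"]), norm, "ratio3", eps)
    ratio4 = _ratio(band_mean(af_spectrum, bands["af_porphyrin"]), norm, "ratio4", eps)
    return ratio3, ratio4


def _drs_features(rec: MeasurementRecord, root: Path, bands) -> tuple[float, float]:
    signal = read_spectrum(root / rec.spectrum_path, DRS, "raw")
    dark = read_spectrum(root / rec.dark_path, DRS, "dark")
    reference = read_spectrum(root / rec.reference_path, DRS, "reference")
    triple = preprocess.CalibrationTriple(signal, reference, dark)
    return drs_ratios(preprocess.compute_reflectance(triple), bands)


def _af_features(rec: MeasurementRecord, root: Path, bands) -> tuple[float, float]:
    signal = read_spectrum(root / rec.spectrum_path, AF, "raw", rec.excitation_nm)
    dark = read_spectrum(root / rec.dark_path, AF, "dark", rec.excitation_nm)
    return af_ratios(preprocess.subtract_dark(signal, dark), bands)


def build_feature_table(
    manifest: Manifest,
    root: str | Path,
    bands: dict[str, SpectralBand] | None = None,
) -> pd.DataFrame:
    """Compute the feature table: one row per measurement location.

    Each measurement's DRS record is calibrated and reduced to
    (ratio1, ratio2); its 415 nm AF record is dark-subtracted and reduced
    to (ratio3, ratio4).  Missing modalities yield NaN ratios and a logged
    warning.  Any extraction failure is re-raised annotated with the
    measurement_id.
    """
    root = Path(root)
    rows = []
    for mid, records in manifest.grouped().items():
        labels = {r.tissue_label for r in records}
        patients = {r.patient_id for r in records}
        if len(labels) > 1 or len(patients) > 1:
            raise FeatureError(
                f"{mid}: inconsistent tissue_label/patient_id across records"
            )
        vec = {
            "measurement_id": mid,
            "patient_id": patients.pop(),
            "tissue_label": labels.pop(),
            "ratio1": math.nan,
            "ratio2": math.nan,
            "ratio3": math.nan,
            "ratio4": math.nan,
        }
        try:
            for rec in records:
                if rec.modality == DRS:
                    vec["ratio1"], vec["ratio2"] = _drs_features(rec, root, bands)
                elif rec.excitation_nm == AF_CLASSIFICATION_EXCITATION_NM:
                    vec["ratio3"], vec["ratio4"] = _af_features(rec, root, bands)
        except (ValueError, OSError) as exc:
            raise FeatureError(f"measurement {mid}: {exc}") from exc
        if math.isnan(vec["ratio1"]):
            log.warning("measurement %s: no DRS record; ratio1/ratio2 missing", mid)
        if math.isnan(vec["ratio3"]):
            log.warning("measurement %s: no 415 nm AF record; ratio3/ratio4 missing", mid)
        rows.append(vec)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the feature table CSV (empty cells for missing modalities)."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table CSV written by :func:`write_feature_table`."""
    table = pd.read_csv(path, float_precision="round_trip")
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: feature table missing columns {sorted(missing)}")
    return table[TABLE_COLUMNS]
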
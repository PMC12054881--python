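"""Synthetic DRS/AF tissue-spectra generator.

Emulates an ex-vivo liver measurement session with a fiber-optic needle
probe: raw diffuse-reflectance calibration triples (signal, Spectralon
white reference, dark background) on a 500-1120 nm grid and 415 nm-excited
autofluorescence signal/dark pairs on a 360-830 nm grid, for healthy liver
tissue and colorectal-metastasis tumor tissue.

The generative model is deliberately phenomenological.  Chromophore and
fluorophore templates are explicit parametric stand-ins (Gaussian bands,
sigmoid edges), not literature extinction spectra; only the qualitative
band structure matters for the downstream ratio features.

DRS:  signal = dark + g * L(lambda) * a * (lambda/800)^-b * T(lambda) + noise
where L is a smooth lamp shape, g a per-measurement contact-pressure gain,
a * (lambda/800)^-b a scattering power law and
T = exp(-blood * A_hb - lipid_collagen * A_lc) the chromophore
transmission.  Healthy tissue draws more blood (hemoglobin absorption in
the visible) and more lipid/collagen (absorption edge above ~1050 nm), so
after calibration tumor shows higher visible reflectance and a higher
1100-1120 nm shoulder.

AF:   signal = dark + g * [bile + porphyrin + broad red] * reabsorption * LPF + noise
with a broad bile-like peak near 500 nm (stronger in tumor), a porphyrin
double peak at 650/710 nm and a broad red baseline (both stronger in
healthy), hemoglobin reabsorption dips, and a hard 458 nm long-pass edge.

Shot noise is Gaussian with variance proportional to the signal level
(large-count Poisson approximation); the contact-pressure gain g is a
single multiplicative factor per acquisition, which the ratiometric
features must (and do) cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import preprocess
from .spectra_io import (
    AF,
    DRS,
    HEALTHY,
    TUMOR,
    Manifest,
    MeasurementRecord,
    Spectrum,
    write_manifest,
    write_spectrum,
)

__all__ = [
    "ClassParams",
    "GeneratorConfig",
    "GeneratorError",
    "chromophore_attenuation",
    "fluorophore_basis",
    "simulate_drs_measurement",
    "simulate_af_measurement",
    "generate_measurements",
    "generate_dataset",
    "generate_feature_frame",
]


class GeneratorError(ValueError):
    """Raised for invalid generator configurations."""


# --------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional tissue parameters.

    ``*_median``/``*_sigma`` parameterize lognormal draws (median and
    log-space sigma); scattering amplitude and exponent are Gaussian.
    Fluorophore amplitudes are in detector counts at the template peak.
    """

    blood_fraction_median: float
    blood_fraction_sigma: float
    lipid_collagen_median: float
    lipid_collagen_sigma: float
    scatter_amplitude_mean: float = 0.55
    scatter_amplitude_sd: float = 0.06
    scatter_exponent_mean: float = 0.7
    scatter_exponent_sd: float = 0.1
    bile_amp_median: float = 800.0
    bile_amp_sigma: float = 0.6
    porphyrin_amp_median: float = 500.0
    porphyrin_amp_sigma: float = 0.6
    red_baseline_amp_median: float = 700.0
    red_baseline_amp_sigma: float = 0.6
    bilirubin_amp_median: float = 0.0
    bilirubin_amp_sigma: float = 0.3


#: Healthy liver: dark red (blood-rich), lipid/collagen absorption in the
#: NIR, porphyrin-dominated red autofluorescence.
HEALTHY_DEFAULTS = ClassParams(
    blood_fraction_median=1.2,
    blood_fraction_sigma=0.45,
    lipid_collagen_median=1.0,
    lipid_collagen_sigma=0.50,
    bile_amp_median=600.0,
    porphyrin_amp_median=800.0,
    red_baseline_amp_median=800.0,
)

#: Colorectal metastasis: pale yellowish (blood-poor), weak NIR edge,
#: bile-dominated autofluorescence.
TUMOR_DEFAULTS = ClassParams(
    blood_fraction_median=0.4,
    blood_fraction_sigma=0.50,
    lipid_collagen_median=0.3,
    lipid_collagen_sigma=0.50,
    bile_amp_median=2000.0,
    porphyrin_amp_median=200.0,
    red_baseline_amp_median=500.0,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full study-condition description for one synthetic dataset."""

    n_healthy: int = 24
    n_tumor: int = 28
    seed: int = 0
    # grids (nm)
    drs_start_nm: float = 500.0
    drs_stop_nm: float = 1120.0
    drs_step_nm: float = 1.0
    af_start_nm: float = 360.0
    af_stop_nm: float = 830.0
    af_step_nm: float = 1.0
    # class-conditional tissue parameters
    healthy: ClassParams = HEALTHY_DEFAULTS
    tumor: ClassParams = TUMOR_DEFAULTS
    # acquisition model
    lamp_peak_counts: float = 10000.0
    dark_level_counts: float = 100.0
    dark_noise_sd: float = 2.0
    shot_noise_scale: float = 1.0
    gain_jitter: tuple[float, float] = (0.6, 1.4)
    outlier_fraction: float = 0.08
    lpf_edge_nm: float = 458.0
    reabsorption_strength: float = 0.5
    include_secondary_excitations: bool = False

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_tumor < 0:
            raise GeneratorError("sample counts must be nonnegative")
        for name in ("drs", "af"):
            start = getattr(self, f"{name}_start_nm")
            stop = getattr(self, f"{name}_stop_nm")
            step = getattr(self, f"{name}_step_nm")
            if not (0 < start < stop and step > 0):
                raise GeneratorError(f"invalid {name} grid ({start}, {stop}, {step})")
        if not 0 <= self.outlier_fraction < 1:
            raise GeneratorError("outlier_fraction must be in [0, 1)")
        lo, hi = self.gain_jitter
        if not (0 < lo <= hi):
            raise GeneratorError("gain_jitter bounds must satisfy 0 < lo <= hi")
        if self.shot_noise_scale < 0 or self.dark_noise_sd < 0:
            raise GeneratorError("noise scales must be nonnegative")
        if self.lamp_peak_counts <= 0 or self.dark_level_counts < 0:
            raise GeneratorError("invalid lamp/dark levels")

    @property
    def drs_grid(self) -> np.ndarray:
        return np.arange(
            self.drs_start_nm, self.drs_stop_nm + self.drs_step_nm / 2, self.drs_step_nm
        )

    @property
    def af_grid(self) -> np.ndarray:
        return np.arange(
            self.af_start_nm, self.af_stop_nm + self.af_step_nm / 2, self.af_step_nm
        )

    def params_for(self, tissue_label: str) -> ClassParams:
        if tissue_label == HEALTHY:
            return self.healthy
        if tissue_label == TUMOR:
            return self.tumor
        raise GeneratorError(f"unknown tissue label {tissue_label!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gain_jitter"] = list(self.gain_jitter)
        return d

    @classmethod
    def from_dict(cls, doc: dict) -> "GeneratorConfig":
        doc = dict(doc)
        for key in ("healthy", "tumor"):
            if key in doc and isinstance(doc[key], dict):
                doc[key] = ClassParams(**doc[key])
        if "gain_jitter" in doc:
            doc["gain_jitter"] = tuple(doc["gain_jitter"])
        return cls(**doc)


# --------------------------------------------------------------------------
# Spectral templates


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def hemoglobin_absorption_template(grid: np.ndarray) -> np.ndarray:
    """Qualitative hemoglobin absorption shape A_hb (dimensionless).

    Soret-like band at 420 nm (where covered), Q-band-like peaks at 542 and
    576 nm, plus a broad visible pedestal that decays above 600 nm.  A
    stand-in shape, not literature extinction data.
    """
    grid = np.asarray(grid, dtype=float)
    return (
        3.0 * _gauss(grid, 420.0, 18.0)
        + 1.0 * _gauss(grid, 542.0, 12.0)
        + 1.1 * _gauss(grid, 576.0, 11.0)
        + 0.7 * _sigmoid((600.0 - grid) / 25.0)
    )


def lipid_collagen_template(grid: np.ndarray) -> np.ndarray:
    """Qualitative lipid/collagen absorption edge A_lc: sigmoidal rise ~1050 nm."""
    grid = np.asarray(grid, dtype=float)
    return _sigmoid((np.asarray(grid, dtype=float) - 1080.0) / 20.0)


def chromophore_attenuation(
    grid: np.ndarray, blood_fraction: float, lipid_collagen_strength: float
) -> np.ndarray:
    """Beer-Lambert-style transmission exp(-bf*A_hb - lc*A_lc), in (0, 1]."""
    if blood_fraction < 0 or lipid_collagen_strength < 0:
        raise GeneratorError("chromophore parameters must be nonnegative")
    grid = np.asarray(grid, dtype=float)
    return np.exp(
        -blood_fraction * hemoglobin_absorption_template(grid)
        - lipid_collagen_strength * lipid_collagen_template(grid)
    )


def fluorophore_basis(grid: np.ndarray) -> dict[str, np.ndarray]:
    """Unit-peak emission templates on the AF grid.

    bile: broad peak at 500 nm (tissue-shifted from the ~510 nm cuvette
    peak); porphyrin: double peak at 650/710 nm; red_baseline: broad
    emission centered 620 nm; bilirubin: small optional 560 nm band.
    """
    grid = np.asarray(grid, dtype=float)
    porph = _gauss(grid, 650.0, 12.0) + 0.8 * _gauss(grid, 710.0, 14.0)
    basis = {
        "bile": _gauss(grid, 500.0, 45.0),
        "porphyrin": porph / porph.max() if porph.max() > 0 else porph,
        "red_baseline": _gauss(grid, 620.0, 80.0),
        "bilirubin": _gauss(grid, 560.0, 30.0),
    }
    return basis


def _lamp_shape(grid: np.ndarray, peak: float) -> np.ndarray:
    # broad halogen-like spectrum, smooth and strictly positive on the grid
    return peak * _gauss(np.asarray(grid, dtype=float), 840.0, 300.0)


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    if median == 0:
        return 0.0
    return float(median * np.exp(sigma * rng.standard_normal()))


def _draw_blood(label: str, config: GeneratorConfig, rng: np.random.Generator) -> float:
    """Class-conditional blood fraction with the tumor-outlier rule.

    With probability ``outlier_fraction`` a tumor measurement draws a
    healthy-level blood fraction (surface blood on the pale tumor slice).
    The uniform deviate is consumed for every tumor draw so that the
    outlier rule does not perturb the remaining stream.
    """
    params = config.params_for(label)
    if label == TUMOR:
        u = rng.uniform()
        if u < config.outlier_fraction:
            params = config.healthy
    return _lognormal(rng, params.blood_fraction_median, params.blood_fraction_sigma)


def _shot_noise(
    rng: np.random.Generator, level: np.ndarray, scale: float
) -> np.ndarray:
    # Gaussian with variance ~ level: large-count Poisson approximation
    if scale == 0:
        return np.zeros_like(level)
    return scale * np.sqrt(np.clip(level, 0, None)) * rng.standard_normal(level.shape)


# --------------------------------------------------------------------------
# Per-measurement simulators


def simulate_drs_measurement(
    tissue_label: str, config: GeneratorConfig, rng: np.random.Generator
) -> preprocess.CalibrationTriple:
    """Simulate one raw DRS acquisition with its calibration spectra."""
    grid = config.drs_grid
    lamp = _lamp_shape(grid, config.lamp_peak_counts)
    params = config.params_for(tissue_label)

    blood = _draw_blood(tissue_label, config, rng)
    lipid_collagen = _lognormal(
        rng, params.lipid_collagen_median, params.lipid_collagen_sigma
    )
    scatter_amp = abs(rng.normal(params.scatter_amplitude_mean, params.scatter_amplitude_sd))
    scatter_exp = rng.normal(params.scatter_exponent_mean, params.scatter_exponent_sd)
    gain = rng.uniform(*config.gain_jitter)

    scatter = scatter_amp * (grid / 800.0) ** (-scatter_exp)
    tissue = lamp * scatter * chromophore_attenuation(grid, blood, lipid_collagen)

    signal_level = config.dark_level_counts + gain * tissue
    signal = signal_level + _shot_noise(rng, signal_level, config.shot_noise_scale)
    ref_level = config.dark_level_counts + lamp
    reference = ref_level + _shot_noise(rng, ref_level, config.shot_noise_scale)
    dark = config.dark_level_counts + config.dark_noise_sd * rng.standard_normal(
        grid.shape
    )
    return preprocess.CalibrationTriple(
        signal=Spectrum(grid, signal, DRS, "raw"),
        reference=Spectrum(grid, reference, DRS, "reference"),
        background=Spectrum(grid, dark, DRS, "dark"),
    )


def simulate_af_measurement(
    tissue_label: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    excitation_nm: float = 415.0,
) -> tuple[Spectrum, Spectrum]:
    """Simulate one raw AF acquisition and its dark background.

    415 nm excitation produces the class-informative bile/porphyrin
    structure; 385 and 450 nm produce broad structureless emission carried
    in the data model but excluded from features.
    """
    if excitation_nm not in (385.0, 415.0, 450.0):
        raise GeneratorError(
            f"unsupported AF excitation {excitation_nm!r} nm (use 385/415/450)"
        )
    grid = config.af_grid
    params = config.params_for(tissue_label)
    basis = fluorophore_basis(grid)

    gain = rng.uniform(*config.gain_jitter)
    blood = _draw_blood(tissue_label, config, rng)
    if excitation_nm == 415.0:
        emission = (
            _lognormal(rng, params.bile_amp_median, params.bile_amp_sigma)
            * basis["bile"]
            + _lognormal(rng, params.porphyrin_amp_median, params.porphyrin_amp_sigma)
            * basis["porphyrin"]
            + _lognormal(
                rng, params.red_baseline_amp_median, params.red_baseline_amp_sigma
            )
            * basis["red_baseline"]
            + _lognormal(rng, params.bilirubin_amp_median, params.bilirubin_amp_sigma)
            * basis["bilirubin"]
        )
    else:
        # metabolic-biomarker channels: broad featureless emission
        center = 520.0 if excitation_nm == 385.0 else 560.0
        emission = _lognormal(rng, 400.0, 0.3) * _gauss(grid, center, 85.0)

    reabsorption = np.exp(
        -config.reabsorption_strength * blood * hemoglobin_absorption_template(grid)
    )
    lpf = (grid >= config.lpf_edge_nm).astype(float)
    level = config.dark_level_counts + gain * emission * reabsorption * lpf
    signal = level + _shot_noise(rng, level, config.shot_noise_scale)
    dark = config.dark_level_counts + config.dark_noise_sd * rng.standard_normal(
        grid.shape
    )
    return (
        Spectrum(grid, signal, AF, "raw", excitation_nm),
        Spectrum(grid, dark, AF, "dark", excitation_nm),
    )


# --------------------------------------------------------------------------
# Dataset assembly


@dataclass(frozen=True)
class SimulatedMeasurement:
    measurement_id: str
    patient_id: str
    tissue_label: str
    drs: preprocess.CalibrationTriple
    af: dict[float, tuple[Spectrum, Spectrum]]


def generate_measurements(config: GeneratorConfig) -> list[SimulatedMeasurement]:
    """Simulate all measurements of a dataset, deterministically from the seed.

    Measurements are emitted healthy-first, then tumor; each gets one DRS
    triple and one 415 nm AF pair (plus 385/450 nm pairs when
    ``include_secondary_excitations`` is set).  Patients are assigned
    round-robin at roughly five measurements per patient, mimicking a
    multi-location sampling session.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_healthy + config.n_tumor
    n_patients = max(1, round(n_total / 5.2))
    excitations = [415.0]
    if config.include_secondary_excitations:
        excitations = [385.0, 415.0, 450.0]

    out = []
    plan = [(HEALTHY, "h", i) for i in range(config.n_healthy)]
    plan += [(TUMOR, "t", i) for i in range(config.n_tumor)]
    for label, prefix, i in plan:
        mid = f"{prefix}{i + 1:03d}"
        patient = f"p{(i % n_patients) + 1:02d}"
        triple = simulate_drs_measurement(label, config, rng)
        af = {
            exc: simulate_af_measurement(label, config, rng, exc)
            for exc in excitations
        }
        out.append(SimulatedMeasurement(mid, patient, label, triple, af))
    return out


def generate_dataset(config: GeneratorConfig, out_dir: str | Path) -> Manifest:
    """Write a full synthetic dataset (CSV spectra + manifest) to disk.

    Refuses classification-impossible datasets (a class with zero
    measurements).  Byte-identical for identical (config, seed).
    """
    if config.n_healthy < 1 or config.n_tumor < 1:
        raise GeneratorError(
            "need at least one measurement per tissue class "
            f"(got n_healthy={config.n_healthy}, n_tumor={config.n_tumor})"
        )
    out_dir = Path(out_dir)
    if not out_dir.parent.is_dir():
        raise GeneratorError(f"parent directory does not exist: {out_dir.parent}")
    out_dir.mkdir(exist_ok=True)
    spectra_dir = out_dir / "spectra"
    spectra_dir.mkdir(exist_ok=True)

    records = []
    for m in generate_measurements(config):
        stem = f"spectra/{m.measurement_id}"
        write_spectrum(m.drs.signal, out_dir / f"{stem}_drs_signal.csv")
        write_spectrum(m.drs.background, out_dir / f"{stem}_drs_dark.csv")
        write_spectrum(m.drs.reference, out_dir / f"{stem}_drs_reference.csv")
        records.append(
            MeasurementRecord(
                measurement_id=m.measurement_id,
                patient_id=m.patient_id,
                tissue_label=m.tissue_label,
                modality=DRS,
                spectrum_path=f"{stem}_drs_signal.csv",
                dark_path=f"{stem}_drs_dark.csv",
                reference_path=f"{stem}_drs_reference.csv",
            )
        )
        for exc, (signal, dark) in sorted(m.af.items()):
            tag = f"af{int(exc)}"
            write_spectrum(signal, out_dir / f"{stem}_{tag}_signal.csv")
            write_spectrum(dark, out_dir / f"{stem}_{tag}_dark.csv")
            records.append(
                MeasurementRecord(
                    measurement_id=m.measurement_id,
                    patient_id=m.patient_id,
                    tissue_label=m.tissue_label,
                    modality=AF,
                    spectrum_path=f"{stem}_{tag}_signal.csv",
                    dark_path=f"{stem}_{tag}_dark.csv",
                    excitation_nm=exc,
                )
            )
    manifest = Manifest(
        records=records, dataset_meta={"generator_config": config.to_dict()}
    )
    write_manifest(manifest, out_dir / "manifest.json")
    return manifest


def generate_feature_frame(
    config: GeneratorConfig, bands: dict[str, feat.SpectralBand] | None = None
) -> pd.DataFrame:
    """Simulate a dataset and compute its feature table in memory.

    Identical numbers to generate_dataset -> build_feature_table on the
    same config (spectrum serialization is exact), without touching disk.
    """
    rows = []
    for m in generate_measurements(config):
        refl = preprocess.compute_reflectance(m.drs)
        r1, r2 = feat.drs_ratios(refl, bands)
        signal, dark = m.af[415.0]
        r3, r4 = feat.af_ratios(preprocess.subtract_dark(signal, dark), bands)
        rows.append(
            {
                "measurement_id": m.measurement_id,
                "patient_id": m.patient_id,
                "tissue_label": m.tissue_label,
                "ratio1": r1,
                "ratio2": r2,
                "ratio3": r3,
                "ratio4": r4,
            }
        )
    return pd.DataFrame(rows, columns=feat.TABLE_COLUMNS)
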
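"""Raw-spectrum preprocessing: reflectance calibration and dark subtraction.

Diffuse reflectance is calibrated against a Spectralon white reference and a
dark background taken on the same spectrometer:

    R(lambda) = (Signal - Background) / (Reference - Background)

Autofluorescence spectra only have their dark background subtracted.  No
resampling is ever done: all operations demand an identical wavelength grid,
as holds for spectra from a single instrument, and a grid mismatch is a
loud error rather than a silent interpolation.

Negative calibrated values (possible through noise) are preserved, never
clamped: the downstream band features are linear in the spectrum and
clamping would bias them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectra_io import DRS, Spectrum, SpectrumError

__all__ = [
    "GridMismatchError",
    "CalibrationError",
    "CalibrationTriple",
    "assert_common_grid",
    "compute_reflectance",
    "subtract_dark",
    "mean_normalize",
]

log = logging.getLogger(__name__)

#: Default floor on |Reference - Background| below which Eq-style
#: reflectance division is refused (counts units).
DENOMINATOR_FLOOR = 1e-9


class GridMismatchError(ValueError):
    """Raised when spectra expected on one grid disagree."""


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs (e.g. vanishing denominator)."""


def assert_common_grid(spectra: list[Spectrum]) -> None:
    """Check that all spectra share an element-wise identical grid.

    Raises :class:`GridMismatchError` naming the first divergence.
    """
    if not spectra:
        raise GridMismatchError("no spectra given")
    ref = spectra[0].wavelengths_nm
    for i, s in enumerate(spectra[1:], start=1):
        wl = s.wavelengths_nm
        if len(wl) != len(ref):
            raise GridMismatchError(
                f"spectrum {i}: grid length {len(wl)} != {len(ref)}"
            )
        diff = wl != ref
        if np.any(diff):
            j = int(np.argmax(diff))
            raise GridMismatchError(
                f"spectrum {i}: grid differs at index {j} "
                f"({wl[j]:g} nm vs {ref[j]:g} nm)"
            )


@dataclass(frozen=True)
class CalibrationTriple:
    """Signal, white-reference and dark-background spectra on one grid."""

    signal: Spectrum
    reference: Spectrum
    background: Spectrum

    def __post_init__(self) -> None:
        if self.signal.kind != "raw":
            raise SpectrumError(f"signal must be kind 'raw', got {self.signal.kind!r}")
        if self.reference.kind != "reference":
            raise SpectrumError(
                f"reference must be kind 'reference', got {self.reference.kind!r}"
            )
        if self.background.kind != "dark":
            raise SpectrumError(
                f"background must be kind 'dark', got {self.background.kind!r}"
            )
        assert_common_grid([self.signal, self.reference, self.background])


def compute_reflectance(
    triple: CalibrationTriple, eps: float = DENOMINATOR_FLOOR
) -> Spectrum:
    """Calibrated diffuse reflectance from a signal/reference/dark triple.

    R = (Signal - Background) / (Reference - Background), element-wise on
    the shared grid.  R may exceed 1 or be negative; such values are logged
    as warnings but preserved.  A denominator with magnitude below ``eps``
    anywhere raises :class:`CalibrationError` naming the wavelength.
    """
    wl = triple.signal.wavelengths_nm
    denom = triple.reference.values - triple.background.values
    bad = np.abs(denom) < eps
    if np.any(bad):
        raise CalibrationError(
            f"reference - background below {eps:g} at "
            f"{wl[bad][0]:g} nm; calibration undefined"
        )
    r = (triple.signal.values - triple.background.values) / denom
    n_neg = int(np.sum(r < 0))
    if n_neg:
        log.warning("reflectance negative at %d of %d samples (preserved)", n_neg, len(r))
    if np.any(r > 1):
        log.warning("reflectance exceeds 1 at %d samples (preserved)", int(np.sum(r > 1)))
    return triple.signal.with_values(r, kind="reflectance")


def subtract_dark(af_signal: Spectrum, dark: Spectrum) -> Spectrum:
    """Subtract the dark background from an AF spectrum (negatives kept)."""
    assert_common_grid([af_signal, dark])
    return af_signal.with_values(
        af_signal.values - dark.values, kind="background_subtracted"
    )


def mean_normalize(spectrum: Spectrum, eps: float = 1e-12) -> Spectrum:
    """Divide a spectrum by its arithmetic mean over the full grid.

    The output mean is 1 to floating tolerance.  Used for plotting and
    comparison; the ratiometric band features are invariant to it.
    """
    m = float(np.mean(spectrum.values))
    if abs(m) <= eps:
        raise CalibrationError(
            f"cannot mean-normalize: spectrum mean {m:g} is below {eps:g}"
        )
    return spectrum.with_values(spectrum.values / m, kind="normalized")
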
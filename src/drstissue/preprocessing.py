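"""Standard normal variate (SNV) normalization and per-class mean/SD profiles.

SNV z-scores each spectrum over wavelength — subtract the spectrum's mean,
divide by its sample standard deviation — removing multiplicative gain and
additive offset effects (probe contact pressure, source drift) that carry
no tissue information.  Class profiles (mean and SD spectrum per tissue
label) are the substrate for landmark discovery and for mean-spectra plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import Measurement, SpectraSet, Spectrum, WavelengthGrid

__all__ = [
    "NormalizationError",
    "ProfileError",
    "ClassProfile",
    "snv",
    "snv_normalize",
    "snv_normalize_set",
    "class_profiles",
]


class NormalizationError(ValueError):
    """SNV undefined (constant spectrum)."""


class ProfileError(ValueError):
    """A class has too few measurements for a mean/SD profile."""


@dataclass(frozen=True)
class ClassProfile:
    """Per-wavelength mean and sample SD of one tissue class."""

    label: str
    grid: WavelengthGrid
    mean_spectrum: np.ndarray
    sd_spectrum: np.ndarray
    n: int


def snv(values: np.ndarray) -> np.ndarray:
    """SNV-transform a 1-D array: (x - mean(x)) / sd(x), sample SD (n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise NormalizationError("SNV needs at least two points")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise NormalizationError("SNV undefined for a constant spectrum")
    return (x - x.mean()) / sd


def snv_normalize(s: Spectrum) -> Spectrum:
    """SNV-normalize one spectrum (output mean 0, sample SD 1)."""
    return Spectrum(grid=s.grid, reflectance=snv(s.reflectance), meta={**s.meta, "snv": True})


def snv_normalize_set(spectra: SpectraSet) -> SpectraSet:
    """SNV-normalize every measurement independently."""
    out = tuple(
        Measurement(m.patient_id, m.location_id, m.label, snv_normalize(m.spectrum))
        for m in spectra
    )
    return SpectraSet(out, spectra.grid)


def class_profiles(spectra: SpectraSet, labels=("tumor", "healthy")) -> list[ClassProfile]:
    """Per-wavelength mean and sample SD for each tissue class.

    Unlabeled measurements are excluded.  A class with fewer than two
    measurements raises :class:`ProfileError` naming the class.
    """
    profiles = []
    for label in labels:
        stack = np.array(
            [m.spectrum.reflectance for m in spectra if m.label == label]
        )
        if stack.ndim != 2 or stack.shape[0] < 2:
            raise ProfileError(
                f"class {label!r} has {0 if stack.ndim != 2 else stack.shape[0]} "
                "measurements; need at least 2"
            )
        profiles.append(
            ClassProfile(
                label=label,
                grid=spectra.grid,
                mean_spectrum=stack.mean(axis=0),
                sd_spectrum=stack.std(axis=0, ddof=1),
                n=stack.shape[0],
            )
        )
    return profiles
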
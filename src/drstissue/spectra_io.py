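"""Spectral containers, calibration, stitching, resampling and tabular I/O.

A diffuse-reflectance measurement arrives as detector counts from two
spectrometers (a visible channel and a near-infrared channel).  Counts are
converted to reflectance against white (Spectralon) and dark references,
the two channels are stitched into one continuous spectrum, and everything
downstream lives on a canonical 400-1600 nm grid sampled at 1 nm
(1201 points).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_START_NM",
    "CANONICAL_STOP_NM",
    "CANONICAL_STEP_NM",
    "WavelengthGrid",
    "RawSpectrum",
    "ReferencePair",
    "Spectrum",
    "Measurement",
    "SpectraSet",
    "GridError",
    "CalibrationError",
    "StitchError",
    "ExtrapolationError",
    "ParseError",
    "calibrate_reflectance",
    "stitch_spectra",
    "resample_to_grid",
    "read_spectra_table",
    "write_spectra_table",
    "read_raw_channel_table",
]

CANONICAL_START_NM = 400.0
CANONICAL_STOP_NM = 1600.0
CANONICAL_STEP_NM = 1.0

LABELS = ("tumor", "healthy", "unlabeled")

WHITE_LOCATION = "__white__"
DARK_LOCATION = "__dark__"


class GridError(ValueError):
    """Wavelength grids that should match do not."""


class CalibrationError(ValueError):
    """White-minus-dark reference is non-positive somewhere."""


class StitchError(ValueError):
    """The two channels cannot be joined (no overlap / insufficient span)."""


class ExtrapolationError(ValueError):
    """Requested grid extends beyond the source spectrum's span."""


class ParseError(ValueError):
    """A spectra table violates the documented dialect."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing, uniformly spaced wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise GridError("grid needs at least two wavelengths")
        d = np.diff(v)
        if np.any(d <= 0):
            raise GridError("wavelengths must be strictly increasing")
        if not np.allclose(d, d[0], rtol=0, atol=1e-9):
            raise GridError("wavelength spacing must be uniform")
        object.__setattr__(self, "values", v)

    @property
    def start_nm(self) -> float:
        return float(self.values[0])

    @property
    def stop_nm(self) -> float:
        return float(self.values[-1])

    @property
    def step_nm(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash((self.start_nm, self.stop_nm, len(self)))

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an on-grid wavelength; raises GridError if off-grid."""
        idx = int(round((wavelength_nm - self.start_nm) / self.step_nm))
        if idx < 0 or idx >= len(self) or abs(self.values[idx] - wavelength_nm) > 1e-6:
            raise GridError(f"wavelength {wavelength_nm} nm is not on the grid")
        return idx

    @classmethod
    def regular(cls, start_nm: float, stop_nm: float, step_nm: float) -> "WavelengthGrid":
        n = int(round((stop_nm - start_nm) / step_nm)) + 1
        return cls(start_nm + step_nm * np.arange(n))

    @classmethod
    def canonical(cls) -> "WavelengthGrid":
        """The 400-1600 nm, 1 nm, endpoint-inclusive grid (1201 points)."""
        return cls.regular(CANONICAL_START_NM, CANONICAL_STOP_NM, CANONICAL_STEP_NM)


@dataclass(frozen=True)
class RawSpectrum:
    """Per-channel values on the channel's own grid (counts or reflectance)."""

    channel: str  # "vis" | "nir"
    wavelengths: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if self.channel not in ("vis", "nir"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if wl.shape != v.shape or wl.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if np.any(np.diff(wl) <= 0):
            raise GridError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ReferencePair:
    """White and dark reference spectra for one channel."""

    white: RawSpectrum
    dark: RawSpectrum

    def __post_init__(self):
        if self.white.channel != self.dark.channel:
            raise GridError("white and dark references belong to different channels")
        if not np.array_equal(self.white.wavelengths, self.dark.wavelengths):
            raise GridError("white and dark references are on different grids")

    @property
    def channel(self) -> str:
        return self.white.channel


@dataclass(frozen=True)
class Spectrum:
    """A stitched reflectance spectrum on a shared wavelength grid."""

    grid: WavelengthGrid
    reflectance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape != (len(self.grid),):
            raise GridError("reflectance length does not match grid")
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectance must be finite")
        object.__setattr__(self, "reflectance", r)


@dataclass(frozen=True)
class Measurement:
    """One probe contact: a labeled spectrum bound to patient and location."""

    patient_id: str
    location_id: str
    label: str
    spectrum: Spectrum

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class SpectraSet:
    """A cohort of measurements sharing one wavelength grid."""

    measurements: tuple
    grid: WavelengthGrid

    def __post_init__(self):
        ms = tuple(self.measurements)
        for m in ms:
            if m.spectrum.grid != self.grid:
                raise GridError(
                    f"measurement ({m.patient_id}, {m.location_id}) is on a different grid"
                )
        object.__setattr__(self, "measurements", ms)

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    def labeled(self) -> "SpectraSet":
        """Subset with the unlabeled (uncertain-histology) measurements dropped."""
        return SpectraSet(
            tuple(m for m in self.measurements if m.label != "unlabeled"), self.grid
        )

    def patients(self) -> tuple:
        seen = {}
        for m in self.measurements:
            seen.setdefault(m.patient_id, None)
        return tuple(seen)

    def subset_patients(self, patient_ids) -> "SpectraSet":
        wanted = set(patient_ids)
        return SpectraSet(
            tuple(m for m in self.measurements if m.patient_id in wanted), self.grid
        )


# ---------------------------------------------------------------------------
# calibration / stitching / resampling


def calibrate_reflectance(raw: RawSpectrum, refs: ReferencePair) -> RawSpectrum:
    """Convert counts S to reflectance R = (S - D) / (W - D).

    ``raw`` and both references must share channel and grid.  A wavelength
    where W - D <= 0 has no usable dynamic range and raises
    :class:`CalibrationError` naming the offending wavelength.
    """
    if raw.channel != refs.channel:
        raise GridError(
            f"channel mismatch: spectrum is {raw.channel}, references are {refs.channel}"
        )
    if not np.array_equal(raw.wavelengths, refs.white.wavelengths):
        raise GridError("spectrum and references are on different grids")
    denom = refs.white.values - refs.dark.values
    bad = denom <= 0
    if np.any(bad):
        wl_bad = raw.wavelengths[bad][0]
        raise CalibrationError(
            f"white minus dark is non-positive at {wl_bad:g} nm"
        )
    refl = (raw.values - refs.dark.values) / denom
    return replace(raw, values=refl, meta={**raw.meta, "calibrated": True})


def stitch_spectra(
    vis: RawSpectrum,
    nir: RawSpectrum,
    policy: str = "crossfade",
    grid: WavelengthGrid | None = None,
    splice_nm: float | None = None,
) -> Spectrum:
    """Join calibrated VIS and NIR channels into one continuous spectrum.

    Outside the overlap each channel passes through unchanged (linearly
    interpolated onto the output grid).  Inside the overlap:

    * ``policy="crossfade"`` (default): linear cross-fade, the VIS weight
      falling 1 -> 0 across the overlap, so the output is continuous.
    * ``policy="cut"``: hard switch at ``splice_nm`` (default: overlap
      midpoint); VIS strictly below, NIR at and above.

    The output grid defaults to the canonical 400-1600 nm grid clipped to
    the union of the channel spans.
    """
    if vis.channel != "vis" or nir.channel != "nir":
        raise StitchError("stitch expects a vis channel and a nir channel")
    lo = max(vis.wavelengths[0], nir.wavelengths[0])
    hi = min(vis.wavelengths[-1], nir.wavelengths[-1])
    if hi <= lo:
        raise StitchError(
            f"channels do not overlap (vis ends {vis.wavelengths[-1]:g} nm, "
            f"nir starts {nir.wavelengths[0]:g} nm)"
        )
    if grid is None:
        full = WavelengthGrid.canonical()
        keep = (full.values >= vis.wavelengths[0] - 1e-9) & (
            full.values <= nir.wavelengths[-1] + 1e-9
        )
        if keep.sum() < 2:
            raise StitchError("channels do not cover the canonical grid span")
        grid = WavelengthGrid(full.values[keep])
    lam = grid.values
    out = np.empty_like(lam)

    vis_ok = lam <= vis.wavelengths[-1] + 1e-9
    nir_ok = lam >= nir.wavelengths[0] - 1e-9
    if not np.all(vis_ok | nir_ok):
        raise StitchError("output grid extends beyond both channel spans")
    v = np.full_like(lam, np.nan)
    n = np.full_like(lam, np.nan)
    v[vis_ok] = np.interp(lam[vis_ok], vis.wavelengths, vis.values)
    n[nir_ok] = np.interp(lam[nir_ok], nir.wavelengths, nir.values)

    if policy == "crossfade":
        w = np.clip((hi - lam) / (hi - lo), 0.0, 1.0)  # VIS weight
        w[~nir_ok] = 1.0
        w[~vis_ok] = 0.0
        out = np.where(w >= 1.0, v, np.where(w <= 0.0, n, w * v + (1.0 - w) * n))
    elif policy == "cut":
        cut = 0.5 * (lo + hi) if splice_nm is None else float(splice_nm)
        if not (lo <= cut <= hi):
            raise StitchError(f"splice wavelength {cut:g} nm outside overlap [{lo:g}, {hi:g}]")
        out = np.where(lam < cut, v, n)
    else:
        raise ValueError(f"unknown stitch policy {policy!r}")
    meta = {**vis.meta, **nir.meta, "stitch_policy": policy}
    return Spectrum(grid=grid, reflectance=out, meta=meta)


def resample_to_grid(s: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto a target grid within its span."""
    src = s.grid.values
    if grid.start_nm < src[0] - 1e-9 or grid.stop_nm > src[-1] + 1e-9:
        raise ExtrapolationError(
            f"target grid {grid.start_nm:g}-{grid.stop_nm:g} nm exceeds "
            f"source span {src[0]:g}-{src[-1]:g} nm"
        )
    if grid == s.grid:
        return s
    vals = np.interp(grid.values, src, s.reflectance)
    return Spectrum(grid=grid, reflectance=vals, meta=dict(s.meta))


# ---------------------------------------------------------------------------
# tabular I/O
#
# Dialect: comma-delimited UTF-8, header
#   patient_id, location_id, label, wl_<nm>, wl_<nm>, ...
# label in {tumor, healthy, unlabeled}; '.' decimal separator.


def _grid_from_columns(columns) -> tuple[WavelengthGrid, list]:
    wl_cols = [c for c in columns if c.startswith("wl_")]
    if not wl_cols:
        raise ParseError("no wavelength columns (expected headers like 'wl_400')")
    try:
        wls = [float(c[3:]) for c in wl_cols]
    except ValueError as e:
        raise ParseError(f"malformed wavelength column header: {e}") from None
    order = np.argsort(wls)
    wl_cols = [wl_cols[i] for i in order]
    grid = WavelengthGrid(np.asarray(sorted(wls)))
    return grid, wl_cols


def read_spectra_table(path) -> SpectraSet:
    """Read a spectra table (see module docstring for the dialect)."""
    df = pd.read_csv(
        path, dtype={"patient_id": str, "location_id": str}, float_precision="round_trip"
    )
    required = ["patient_id", "location_id", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")
    grid, wl_cols = _grid_from_columns(df.columns)

    dup = df.duplicated(subset=["patient_id", "location_id"], keep=False)
    if dup.any():
        rows = [str(i + 2) for i in df.index[dup]]  # +2: header + 1-based
        raise ParseError(
            f"duplicated (patient_id, location_id) at file row(s) {', '.join(rows)}"
        )
    bad_label = ~df["label"].isin(LABELS)
    if bad_label.any():
        i = df.index[bad_label][0]
        raise ParseError(f"unknown label {df.loc[i, 'label']!r} at file row {i + 2}")

    values = df[wl_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    nonnum = np.isnan(values) & df[wl_cols].notna().to_numpy()
    if nonnum.any() or np.isnan(values).any():
        i = int(np.argwhere(np.isnan(values).any(axis=1))[0][0])
        raise ParseError(f"non-numeric or missing reflectance at file row {i + 2}")

    measurements = [
        Measurement(
            patient_id=row.patient_id,
            location_id=row.location_id,
            label=row.label,
            spectrum=Spectrum(grid=grid, reflectance=values[i]),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]
    return SpectraSet(tuple(measurements), grid)


def write_spectra_table(spectra: SpectraSet, path) -> None:
    """Write a SpectraSet in the spectra-table dialect (full precision)."""
    wl_cols = [f"wl_{wl:g}" for wl in spectra.grid.values]
    rows = []
    for m in spectra:
        rows.append(
            {"patient_id": m.patient_id, "location_id": m.location_id, "label": m.label}
            | dict(zip(wl_cols, m.spectrum.reflectance))
        )
    df = pd.DataFrame(rows, columns=["patient_id", "location_id", "label"] + wl_cols)
    df.to_csv(path, index=False, float_format="%.17g")


def read_raw_channel_table(path) -> tuple[list, ReferencePair]:
    """Read a raw per-channel file: sample rows plus white/dark reference rows.

    Same dialect as the spectra table with an extra ``channel`` column; the
    white and dark references are stored as rows with the reserved location
    ids ``__white__`` and ``__dark__``.  Returns the sample RawSpectrum rows
    (with patient/location/label in ``meta``) and the reference pair.
    """
    df = pd.read_csv(
        path, dtype={"patient_id": str, "location_id": str}, float_precision="round_trip"
    )
    for col in ("channel", "patient_id", "location_id"):
        if col not in df.columns:
            raise ParseError(f"missing required column(s): {col}")
    channels = df["channel"].unique()
    if len(channels) != 1:
        raise ParseError("a raw channel file must contain exactly one channel")
    channel = str(channels[0])
    grid, wl_cols = _grid_from_columns(df.columns)
    values = df[wl_cols].to_numpy(dtype=float)

    def _one(loc: str) -> RawSpectrum:
        idx = df.index[df["location_id"] == loc]
        if len(idx) != 1:
            raise ParseError(f"expected exactly one {loc} reference row")
        return RawSpectrum(channel=channel, wavelengths=grid.values, values=values[idx[0]])

    refs = ReferencePair(white=_one(WHITE_LOCATION), dark=_one(DARK_LOCATION))
    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.location_id in (WHITE_LOCATION, DARK_LOCATION):
            continue
        meta = {
            "patient_id": row.patient_id,
            "location_id": row.location_id,
            "label": getattr(row, "label", "unlabeled"),
        }
        samples.append(
            RawSpectrum(channel=channel, wavelengths=grid.values, values=values[i], meta=meta)
        )
    return samples, refs
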
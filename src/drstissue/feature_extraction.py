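"""Landmark and slope features from class mean spectra.

With 1201 wavelengths and on the order of a hundred labeled measurements,
using every wavelength as a predictor invites overfitting.  Instead, the
class mean spectra nominate a compact candidate set:

* landmark features — the normalized intensity at each local minimum or
  maximum of a (smoothed) class mean spectrum, and
* slope features — the per-nm difference quotient of normalized intensity
  between two landmark wavelengths.

The candidate set is derived from training data only when run inside the
evaluation loop; a frozen :class:`FeatureSpec` can be serialized and
reapplied to new spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocessing import ClassProfile
from .spectra_io import SpectraSet

__all__ = [
    "Landmark",
    "SlopePair",
    "FeatureSpec",
    "FeatureTable",
    "FeatureSpecError",
    "detect_landmarks",
    "propose_slope_pairs",
    "build_feature_spec",
    "compute_features",
]

DEFAULT_SMOOTH_WINDOW_NM = 15.0
DEFAULT_MIN_PROMINENCE = 0.05  # SNV units
DEFAULT_MIN_PAIR_SEPARATION_NM = 20.0


class FeatureSpecError(ValueError):
    pass


@dataclass(frozen=True)
class Landmark:
    """A local extremum of a class mean spectrum."""

    wavelength_nm: float
    kind: str  # "min" | "max"
    source_class: str
    prominence: float

    def __post_init__(self):
        if self.kind not in ("min", "max"):
            raise FeatureSpecError(f"landmark kind must be 'min' or 'max', got {self.kind!r}")
        if not self.prominence > 0:
            raise FeatureSpecError("landmark prominence must be positive")


@dataclass(frozen=True)
class SlopePair:
    """An ordered wavelength pair (lambda1 < lambda2) for a slope feature."""

    lambda1_nm: float
    lambda2_nm: float

    def __post_init__(self):
        if not self.lambda1_nm < self.lambda2_nm:
            raise FeatureSpecError("slope pair requires lambda1 < lambda2")


@dataclass(frozen=True)
class FeatureSpec:
    """An ordered, named candidate feature set.

    Landmarks are ordered by wavelength (then kind, then source class);
    pairs lexicographically.  Names are stable identifiers usable as table
    columns.
    """

    landmarks: tuple
    pairs: tuple

    def __post_init__(self):
        lms = tuple(
            sorted(self.landmarks, key=lambda l: (l.wavelength_nm, l.kind, l.source_class))
        )
        prs = tuple(sorted(self.pairs, key=lambda p: (p.lambda1_nm, p.lambda2_nm)))
        object.__setattr__(self, "landmarks", lms)
        object.__setattr__(self, "pairs", prs)
        names = self.names
        if len(set(names)) != len(names):
            raise FeatureSpecError("feature names are not unique")

    @property
    def names(self) -> tuple:
        lm = tuple(f"landmark_{l.wavelength_nm:g}_{l.kind}" for l in self.landmarks)
        sl = tuple(f"slope_{p.lambda1_nm:g}_{p.lambda2_nm:g}" for p in self.pairs)
        return lm + sl

    def __len__(self) -> int:
        return len(self.landmarks) + len(self.pairs)

    def restrict(self, names) -> "FeatureSpec":
        """Keep only the named features, preserving original ordering."""
        wanted = set(names)
        unknown = wanted - set(self.names)
        if unknown:
            raise FeatureSpecError(f"unknown feature name(s): {sorted(unknown)}")
        lm_names = dict(zip(self.names[: len(self.landmarks)], self.landmarks))
        pr_names = dict(zip(self.names[len(self.landmarks) :], self.pairs))
        return FeatureSpec(
            landmarks=tuple(l for n, l in lm_names.items() if n in wanted),
            pairs=tuple(p for n, p in pr_names.items() if n in wanted),
        )

    def to_text(self) -> str:
        """One feature per line: 'landmark <nm> <kind>' / 'slope <nm1> <nm2>'."""
        lines = [f"landmark {l.wavelength_nm:g} {l.kind}" for l in self.landmarks]
        lines += [f"slope {p.lambda1_nm:g} {p.lambda2_nm:g}" for p in self.pairs]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "FeatureSpec":
        landmarks, pairs = [], []
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "landmark" and len(parts) == 3:
                landmarks.append(
                    Landmark(float(parts[1]), parts[2], source_class="frozen", prominence=np.inf)
                )
            elif parts[0] == "slope" and len(parts) == 3:
                pairs.append(SlopePair(float(parts[1]), float(parts[2])))
            else:
                raise FeatureSpecError(f"malformed feature spec line {lineno}: {line!r}")
        return cls(tuple(landmarks), tuple(pairs))


@dataclass(frozen=True)
class FeatureTable:
    """Measurements x features, with patient_id and label bookkeeping columns."""

    frame: pd.DataFrame
    feature_names: tuple

    def __post_init__(self):
        for col in ("patient_id", "label"):
            if col not in self.frame.columns:
                raise FeatureSpecError(f"feature table missing {col!r} column")
        missing = [n for n in self.feature_names if n not in self.frame.columns]
        if missing:
            raise FeatureSpecError(f"feature table missing feature column(s) {missing}")
        X = self.frame[list(self.feature_names)].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise FeatureSpecError("feature values must be finite")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Binary labels, tumor = 1 (positive class), healthy = 0."""
        return (self.frame["label"] == "tumor").to_numpy(dtype=int)

    @property
    def patients(self) -> np.ndarray:
        return self.frame["patient_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


def _smooth(values: np.ndarray, window_pts: int) -> np.ndarray:
    # centered moving average with edge-shrunk windows
    if window_pts <= 1:
        return values
    kernel = np.ones(window_pts) / window_pts
    padded = np.pad(values, window_pts // 2, mode="edge")
    sm = np.convolve(padded, kernel, mode="same")
    half = window_pts // 2
    return sm[half : half + values.size]


def detect_landmarks(
    profile: ClassProfile,
    smooth_window_nm: float = DEFAULT_SMOOTH_WINDOW_NM,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> list[Landmark]:
    """Local minima/maxima of the (smoothed) class mean spectrum.

    The mean spectrum is smoothed with a centered moving average of width
    ``smooth_window_nm`` and extrema with topographic prominence at least
    ``min_prominence`` are reported, sorted by wavelength.  Grid endpoints
    are never reported as extrema.
    """
    grid = profile.grid
    step = grid.step_nm
    window_pts = max(1, int(round(smooth_window_nm / step)))
    if window_pts % 2 == 0:
        window_pts += 1
    if window_pts > len(grid):
        raise FeatureSpecError(
            f"smoothing window {smooth_window_nm:g} nm exceeds the spectrum span"
        )
    y = _smooth(np.asarray(profile.mean_spectrum, dtype=float), window_pts)

    out = []
    for sign, kind in ((1.0, "max"), (-1.0, "min")):
        idx, props = find_peaks(sign * y, prominence=min_prominence)
        for i, prom in zip(idx, props["prominences"]):
            out.append(
                Landmark(
                    wavelength_nm=float(grid.values[i]),
                    kind=kind,
                    source_class=profile.label,
                    prominence=float(prom),
                )
            )
    out.sort(key=lambda l: (l.wavelength_nm, l.kind))
    return out


def propose_slope_pairs(
    landmarks: list[Landmark],
    max_pairs: int | None = None,
    min_separation_nm: float = DEFAULT_MIN_PAIR_SEPARATION_NM,
) -> list[SlopePair]:
    """Wavelength pairs for slope features from the pooled landmark list.

    Rule: pairs of consecutive distinct landmark wavelengths (union over
    classes, deduplicated) plus pairs spanning each minimum to its flanking
    maxima; pairs closer than ``min_separation_nm`` are dropped; the list is
    truncated deterministically (lexicographic order) to ``max_pairs``.
    Fewer than two landmarks yield an empty list.
    """
    wls = sorted({l.wavelength_nm for l in landmarks})
    if len(wls) < 2:
        return []
    pairs = {(a, b) for a, b in zip(wls, wls[1:])}

    by_wl = sorted(landmarks, key=lambda l: l.wavelength_nm)
    for i, lm in enumerate(by_wl):
        if lm.kind != "min":
            continue
        left = next((o for o in reversed(by_wl[:i]) if o.kind == "max"), None)
        right = next((o for o in by_wl[i + 1 :] if o.kind == "max"), None)
        if left is not None and left.wavelength_nm < lm.wavelength_nm:
            pairs.add((left.wavelength_nm, lm.wavelength_nm))
        if right is not None and right.wavelength_nm > lm.wavelength_nm:
            pairs.add((lm.wavelength_nm, right.wavelength_nm))

    kept = sorted(p for p in pairs if p[1] - p[0] >= min_separation_nm)
    if max_pairs is not None:
        kept = kept[:max_pairs]
    return [SlopePair(a, b) for a, b in kept]


def build_feature_spec(
    profiles: list[ClassProfile],
    smooth_window_nm: float = DEFAULT_SMOOTH_WINDOW_NM,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation_nm: float = DEFAULT_MIN_PAIR_SEPARATION_NM,
    max_pairs: int | None = None,
) -> FeatureSpec:
    """Union the landmarks of all class profiles and derive slope pairs."""
    landmarks = []
    for p in profiles:
        landmarks.extend(detect_landmarks(p, smooth_window_nm, min_prominence))
    # same (wavelength, kind) found in both classes collapses to one feature
    dedup = {}
    for l in landmarks:
        dedup.setdefault((l.wavelength_nm, l.kind), l)
    landmarks = list(dedup.values())
    pairs = propose_slope_pairs(landmarks, max_pairs, min_separation_nm)
    return FeatureSpec(tuple(landmarks), tuple(pairs))


def compute_features(spectra: SpectraSet, spec: FeatureSpec) -> FeatureTable:
    """Evaluate every feature on every measurement (input row order kept).

    Landmark features are the normalized intensity at the landmark
    wavelength; slope features are (z(l2) - z(l1)) / (l2 - l1) in per-nm
    units.  Landmark or pair wavelengths off the set's grid raise
    :class:`FeatureSpecError`.
    """
    grid = spectra.grid
    try:
        lm_idx = [grid.index_of(l.wavelength_nm) for l in spec.landmarks]
        pr_idx = [
            (grid.index_of(p.lambda1_nm), grid.index_of(p.lambda2_nm)) for p in spec.pairs
        ]
    except Exception as e:
        raise FeatureSpecError(str(e)) from None

    rows = []
    for m in spectra:
        z = m.spectrum.reflectance
        vals = [z[i] for i in lm_idx]
        vals += [
            (z[j] - z[i]) / (p.lambda2_nm - p.lambda1_nm)
            for (i, j), p in zip(pr_idx, spec.pairs)
        ]
        rows.append([m.patient_id, m.label] + vals)
    frame = pd.DataFrame(rows, columns=["patient_id", "label"] + list(spec.names))
    return FeatureTable(frame=frame, feature_names=spec.names)
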
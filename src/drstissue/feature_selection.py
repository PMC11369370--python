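"""ReliefF feature ranking and deterministic top-k selection.

ReliefF is an instance-based feature-weighting algorithm: for each sampled
instance it finds the k nearest same-class neighbors (hits) and k nearest
other-class neighbors (misses), then penalizes features that differ across
hits and rewards features that differ across misses.  Features whose values
change with the class boundary, rather than with within-class variation,
accumulate positive weight.

Implementation notes:

* features are min-max scaled to [0, 1] over the whole table; the
  per-feature difference is diff(f, a, b) = |x_af - x_bf| / (max_f - min_f),
  and instance distance is the Manhattan sum of diffs;
* the weight update for instance i is
  W[f] <- W[f] - sum_hits diff(f, i, h) / (m k) + sum_misses diff(f, i, m') / (m k),
  so every weight lies in [-1, 1];
* a constant feature has diff identically zero and weight exactly 0;
* neighbor-distance ties are broken by row order, making the ranking fully
  deterministic when every instance is used (m = ALL, the default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .feature_extraction import FeatureSpec, FeatureTable

__all__ = ["RankedFeatures", "SelectionError", "relieff_rank", "select_top_k"]

DEFAULT_K_NEIGHBORS = 10
DEFAULT_TOP_K = 20


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class RankedFeatures:
    """Per-feature ReliefF weights with a deterministic descending order."""

    names: tuple  # in FeatureSpec (declaration) order
    weights: np.ndarray  # aligned with names
    order: tuple  # names sorted by descending weight, ties by declaration order
    k_neighbors: int
    m_samples: int
    seed: int | None

    def weight_of(self, name: str) -> float:
        return float(self.weights[self.names.index(name)])

    def to_text(self) -> str:
        """Two-column delimited text (feature, weight), ranked."""
        lines = [f"{n}\t{self.weight_of(n):.12g}" for n in self.order]
        return "\n".join(lines) + "\n"


def relieff_rank(
    table: FeatureTable,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    m_samples: int | None = None,
    seed: int | None = None,
) -> RankedFeatures:
    """Rank the table's features by ReliefF weight.

    ``m_samples=None`` uses every instance (deterministic).  ``k_neighbors``
    is clamped to (smallest class size - 1) with a warning; a value of zero
    or a single-class table is an error.
    """
    X = table.X
    y = table.y
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise SelectionError("ReliefF needs at least two classes")
    smallest = int(counts.min())
    if k_neighbors >= smallest:
        clamped = smallest - 1
        if clamped < 1:
            raise SelectionError(
                f"smallest class has {smallest} instance(s); cannot pick neighbors"
            )
        warnings.warn(
            f"k_neighbors={k_neighbors} >= smallest class size {smallest}; "
            f"clamped to {clamped}",
            stacklevel=2,
        )
        k_neighbors = clamped

    # min-max scaling; constant features get a zero denominator -> diff 0
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    nonconst = span > 0
    Xs = np.zeros_like(X)
    Xs[:, nonconst] = (X[:, nonconst] - lo[nonconst]) / span[nonconst]

    if m_samples is None or m_samples >= n:
        sample_idx = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        sample_idx = np.sort(rng.choice(n, size=m_samples, replace=False))
    m = sample_idx.size

    W = np.zeros(p)
    row_order = np.arange(n)
    for i in sample_idx:
        diffs = np.abs(Xs - Xs[i])  # (n, p) per-feature diffs to instance i
        dist = diffs.sum(axis=1)
        for is_hit in (True, False):
            mask = (y == y[i]) if is_hit else (y != y[i])
            cand = row_order[mask & (row_order != i)]
            # stable sort on distance keeps row order as the tie-break
            nearest = cand[np.argsort(dist[cand], kind="stable")[:k_neighbors]]
            contrib = diffs[nearest].sum(axis=0) / (m * k_neighbors)
            W += contrib if not is_hit else -contrib

    order_idx = np.lexsort((np.arange(p), -W))  # descending weight, ties by position
    names = tuple(table.feature_names)
    return RankedFeatures(
        names=names,
        weights=W,
        order=tuple(names[i] for i in order_idx),
        k_neighbors=k_neighbors,
        m_samples=m,
        seed=seed,
    )


def select_top_k(ranked: RankedFeatures, spec: FeatureSpec, k: int = DEFAULT_TOP_K) -> FeatureSpec:
    """Restrict a FeatureSpec to the k largest-weight features.

    Ties are broken by declaration order; the returned spec preserves the
    original relative ordering of the surviving features.
    """
    if k > len(ranked.names):
        raise SelectionError(
            f"cannot select top {k} of {len(ranked.names)} features"
        )
    chosen = ranked.order[:k]
    return spec.restrict(chosen)
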
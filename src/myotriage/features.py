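"""Patient-level features: statistics over per-voxel encodings.

A patient's myocardium is represented by the set of encodings of all
its voxels; this module collapses that variable-size set into one
fixed-length vector by computing order-invariant statistics per
encoding dimension.  The default statistic set (mean, standard
deviation, minimum, quartiles, maximum) summarizes location, scale and
extremes of each encoding dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PatientFeatureVector",
    "EncodingSummarizer",
    "summarize_encodings",
    "DEFAULT_STATISTICS",
]

# Percentiles use linear interpolation between order statistics.
_STAT_FUNCS = {
    "mean": lambda a: a.mean(axis=0),
    "std": lambda a: a.std(axis=0),
    "min": lambda a: a.min(axis=0),
    "p25": lambda a: np.percentile(a, 25, axis=0, method="linear"),
    "median": lambda a: np.percentile(a, 50, axis=0, method="linear"),
    "p75": lambda a: np.percentile(a, 75, axis=0, method="linear"),
    "max": lambda a: a.max(axis=0),
}

DEFAULT_STATISTICS = ("mean", "std", "min", "p25", "median", "p75", "max")


@dataclass
class PatientFeatureVector:
    """Fixed-length feature vector: encoding_dim x len(statistics) values,
    dimension-major (all statistics of dimension 0 first)."""

    patient_id: str
    values: np.ndarray
    statistics: tuple
    encoding_dim: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.encoding_dim * len(self.statistics),):
            raise ValueError("feature length must be encoding_dim x n_statistics")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite")

    @property
    def names(self):
        return [
            f"dim{d}_{s}"
            for d in range(self.encoding_dim)
            for s in self.statistics
        ]


def summarize_encodings(encoding_set, statistics=DEFAULT_STATISTICS):
    """One feature vector from a VoxelEncodingSet.

    Invariant to voxel ordering; for each encoding dimension the
    requested statistics are laid out contiguously (dimension-major).
    """
    statistics = tuple(statistics)
    if not statistics:
        raise ValueError("at least one statistic is required")
    unknown = [s for s in statistics if s not in _STAT_FUNCS]
    if unknown:
        raise ValueError(f"unknown statistics {unknown}; known: {sorted(_STAT_FUNCS)}")
    enc = np.asarray(encoding_set.encodings, dtype=float)
    if enc.size == 0:
        raise ValueError("empty encoding set")
    per_stat = np.stack([_STAT_FUNCS[s](enc) for s in statistics])  # (n_stat, dim)
    values = per_stat.T.reshape(-1)  # dimension-major
    return PatientFeatureVector(
        patient_id=getattr(encoding_set, "patient_id", ""),
        values=values,
        statistics=statistics,
        encoding_dim=enc.shape[1],
    )


class EncodingSummarizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: list of VoxelEncodingSet -> feature matrix."""

    def __init__(self, statistics=DEFAULT_STATISTICS):
        self.statistics = tuple(statistics)

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        rows = [summarize_encodings(e, self.statistics).values for e in X]
        return np.vstack(rows)

    def feature_names(self, encoding_dim):
        return [
            f"dim{d}_{s}" for d in range(encoding_dim) for s in self.statistics
        ]
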
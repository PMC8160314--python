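"""Alpha diversity and pairwise dissimilarity metrics.

Richness and Shannon entropy feed the floating-vs-settled diversity
comparison; Bray-Curtis, Jaccard and Ruzicka are the dissimilarities
consumed by the Raup-Crick and stochasticity-ratio null models. All
metrics operate on counts (the tables are rarefied to equal depth
first); pass ``relative=True`` to normalise non-rarefied input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .io import AbundanceTable


@dataclass
class DissimilarityMatrix:
    """Symmetric sample x sample dissimilarity in [0, 1]."""

    sample_ids: list[str]
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValidationError("dissimilarity matrix shape does not match sample ids")
        if not np.allclose(d, d.T):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValidationError("dissimilarity matrix diagonal is not zero")
        if np.any(d < -1e-12) or np.any(d > 1 + 1e-12):
            raise ValidationError("dissimilarity values outside [0, 1]")
        self.data = np.clip(d, 0.0, 1.0)

    def between(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.data[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def richness(table: AbundanceTable, sample: str) -> int:
    """Number of taxa observed (count > 0) in a sample."""
    return int(np.count_nonzero(table.sample_counts(sample)))


def shannon_entropy(table: AbundanceTable, sample: str) -> float:
    """Shannon entropy H = -sum f ln f in nats over observed taxa."""
    x = table.sample_counts(sample).astype(float)
    total = x.sum()
    if total <= 0:
        raise UndefinedStatisticError(f"sample {sample!r} has no reads; entropy undefined")
    f = x[x > 0] / total
    return float(-(f * np.log(f)).sum())


# ---------------------------------------------------------------------------
# pairwise dissimilarities
# ---------------------------------------------------------------------------

def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("count vectors must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise UndefinedStatisticError("dissimilarity undefined for two all-zero vectors")
    return x, y


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: sum|x - y| / sum(x + y)."""
    x, y = _check_pair(x, y)
    return float(np.abs(x - y).sum() / (x + y).sum())


def jaccard(x, y) -> float:
    """Incidence-based Jaccard: 1 - |shared| / |union| (presence = count > 0)."""
    x, y = _check_pair(x, y)
    a, b = x > 0, y > 0
    union = np.count_nonzero(a | b)
    shared = np.count_nonzero(a & b)
    return float(1.0 - shared / union)


def ruzicka(x, y) -> float:
    """Abundance-based Ruzicka: 1 - sum min(x, y) / sum max(x, y).

    Reduces exactly to Jaccard on presence/absence (0/1) vectors.
    """
    x, y = _check_pair(x, y)
    return float(1.0 - np.minimum(x, y).sum() / np.maximum(x, y).sum())


METRICS = {"bray_curtis": bray_curtis, "jaccard": jaccard, "ruzicka": ruzicka}


def pairwise_matrix(table: AbundanceTable, metric: str, relative: bool = False) -> DissimilarityMatrix:
    """All-pairs dissimilarity over the table's samples."""
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    samples = table.sample_ids
    if len(samples) < 2:
        raise ValidationError("pairwise matrix needs at least 2 samples")
    mat = table.matrix.astype(float)
    if relative:
        totals = mat.sum(axis=0)
        totals[totals == 0] = 1.0
        mat = mat / totals
    fn = METRICS[metric]
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(mat[:, i], mat[:, j])
    return DissimilarityMatrix(samples, out, metric)
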
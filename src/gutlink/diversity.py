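"""Alpha diversity (Shannon index) and beta diversity (Bray-Curtis, PCoA).

Shannon entropy is reported in nats, the Shannon-Wiener convention in
ecology.  Two estimators are provided:

plugin
    H = -sum p_i ln p_i over taxa with p_i > 0.
chao_shen
    Coverage-adjusted nonparametric estimator.  With f1 singletons among a
    total of n reads, sample coverage C = 1 - f1/n, coverage-adjusted
    proportions p~_i = C p_i, and

        H = sum_i  -p~_i ln p~_i / (1 - (1 - p~_i)^n),

    the denominator being each taxon's probability of appearing in the
    sample at all (a Horvitz-Thompson correction for unseen taxa).

Beta diversity uses Bray-Curtis dissimilarity, embedded by classical
principal coordinates analysis (Gower double-centering followed by an
eigendecomposition; axes with negative eigenvalues are reported in a
warning and dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .tables import AbundanceTable, CountTable, to_relative_abundance

__all__ = [
    "shannon",
    "shannon_per_sample",
    "bray_curtis",
    "distance_matrix",
    "pcoa",
    "DistanceMatrix",
    "Ordination",
]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if m.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (m < -1e-12).any():
            raise ValueError("distances must be >= 0")
        self.matrix = m


@dataclass
class Ordination:
    """PCoA embedding: samples x axes coordinates, sorted by eigenvalue."""

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    n_negative_eigenvalues: int = 0


def shannon(counts, estimator: str = "plugin") -> float:
    """Shannon diversity (nats) of one sample's count vector."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    n = c.sum()
    if n <= 0:
        raise ValueError("cannot compute diversity of an all-zero sample")
    p = c[c > 0] / n
    if estimator == "plugin":
        return float(-(p * np.log(p)).sum())
    if estimator == "chao_shen":
        f1 = int((c == 1).sum())
        coverage = 1.0 - f1 / n
        if coverage <= 0:  # every read a singleton; no coverage information
            raise ValueError("sample coverage is zero (all counts are singletons)")
        pa = coverage * p
        return float((-pa * np.log(pa) / (1.0 - (1.0 - pa) ** n)).sum())
    raise ValueError(f"unknown estimator: {estimator!r}")


def shannon_per_sample(t: CountTable, estimator: str = "plugin") -> dict[str, float]:
    return {
        s: shannon(t.counts[:, j], estimator=estimator)
        for j, s in enumerate(t.sample_ids)
    }


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


_METRICS = {"bray_curtis": "braycurtis"}


def distance_matrix(t: AbundanceTable | CountTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """All-pairs sample dissimilarity matrix."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric: {metric!r}")
    if isinstance(t, CountTable):
        t = to_relative_abundance(t)
    if len(t.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(t.values.T, metric=_METRICS[metric]))
    return DistanceMatrix(list(t.sample_ids), d, metric)


def pcoa(d: DistanceMatrix) -> Ordination:
    """Classical PCoA (principal coordinates / Torgerson scaling).

    Gower-centers -d^2/2, eigendecomposes, and keeps the axes with
    positive eigenvalues; coordinates are eigenvectors scaled by
    sqrt(eigenvalue).  Proportions explained are relative to the sum of
    the positive eigenvalues.
    """
    m = d.matrix
    n = m.shape[0]
    a = -0.5 * m**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-12, 1e-12 * max(abs(eigvals[0]), 1.0))
    pos = eigvals > tol
    n_neg = int((eigvals < -tol).sum())
    if n_neg:
        logger.warning(
            "PCoA: %d negative eigenvalue(s) dropped (non-Euclidean dissimilarity)",
            n_neg,
        )
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    total = lam.sum()
    prop = lam / total if total > 0 else np.zeros_like(lam)
    return Ordination(list(d.sample_ids), coords, lam, prop, n_neg)
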
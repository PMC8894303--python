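"""Haralick-style texture features of a normalized symmetric GLCM.

Twelve second-order features are computed on the quantized level scale
0..Ng−1 (not rescaled back to 0–255).  With p(i, j) the matrix entries,
px/py the row/column marginals (equal for a symmetric matrix), μx, σx
their mean and standard deviation, and p_sum(k) = Σ_{i+j=k} p(i, j) the
level-sum distribution:

=================  ===========================================================
contrast           Σij (i−j)² p(i,j)            local intensity variation
cluster_shade      Σij (i+j−μx−μy)³ p(i,j)      skewness: >0 bright-on-dark
cluster_prominence Σij (i+j−μx−μy)⁴ p(i,j)      heavy-tailedness of the sums
entropy            −Σij p log₂ p                randomness (bits)
variance           Σij (i−μx)² p(i,j)           grey-level heterogeneity
mean               (μx+μy)/2                    mean quantized level
correlation        Σij (i−μx)(j−μy) p / (σxσy)  linear dependence of the pair
energy             Σij p²                       angular second moment
homogeneity        Σij p / (1+(i−j)²)           inverse difference moment
mean_sum           Σk k p_sum(k)                sum average
entropy_sum        −Σk p_sum log₂ p_sum         sum entropy (bits)
variance_sum       Σk (k−mean_sum)² p_sum(k)    sum variance
=================  ===========================================================

Entropies use base-2 logarithms with 0·log 0 := 0.  ``variance_sum`` is the
dispersion of the sum distribution about ``mean_sum``.  ``correlation`` is
undefined on a constant ROI (σx = 0) and reported as NaN; downstream
averaging excludes those NaNs rather than coercing them to a value, since a
constant region carries no linear-dependence information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np

from .errors import ValidationError
from .glcm import CooccurrenceMatrix

__all__ = [
    "FEATURE_NAMES",
    "MarginalStats",
    "TextureFeatureVector",
    "compute_features",
    "marginal_stats",
    "sum_distribution",
]

#: Canonical output order of the feature columns.
FEATURE_NAMES: tuple[str, ...] = (
    "contrast",
    "cluster_shade",
    "cluster_prominence",
    "entropy",
    "variance",
    "mean",
    "correlation",
    "energy",
    "homogeneity",
    "mean_sum",
    "entropy_sum",
    "variance_sum",
)


@dataclass(frozen=True)
class MarginalStats:
    """Mean and SD of the row (x) and column (y) marginals, in level units.

    For a symmetric matrix μx = μy and σx = σy exactly; both are exposed
    because row/column means and SDs are part of the computed per-matrix
    quantities even though they are not in the reported feature set.
    """

    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float


@dataclass(frozen=True)
class TextureFeatureVector:
    contrast: float
    cluster_shade: float
    cluster_prominence: float
    entropy: float
    variance: float
    mean: float
    correlation: float
    energy: float
    homogeneity: float
    mean_sum: float
    entropy_sum: float
    variance_sum: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    @classmethod
    def from_dict(cls, d: dict) -> "TextureFeatureVector":
        return cls(**{name: float(d[name]) for name in FEATURE_NAMES})


def _as_matrix(m: CooccurrenceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(m, CooccurrenceMatrix):
        return m.p
    p = np.asarray(m, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValidationError("co-occurrence matrix must be square")
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("matrix must be normalized with non-negative entries")
    if not np.allclose(p, p.T, rtol=0.0, atol=1e-12):
        raise ValidationError("matrix must be symmetric")
    return p


def marginal_stats(m: CooccurrenceMatrix | np.ndarray) -> MarginalStats:
    """Mean/SD of the level marginals of a normalized GLCM."""
    p = _as_matrix(m)
    levels = np.arange(p.shape[0], dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(px @ levels)
    mu_y = float(py @ levels)
    sigma_x = math.sqrt(max(0.0, float(px @ levels**2) - mu_x**2))
    sigma_y = math.sqrt(max(0.0, float(py @ levels**2) - mu_y**2))
    return MarginalStats(mu_x=mu_x, mu_y=mu_y, sigma_x=sigma_x, sigma_y=sigma_y)


def sum_distribution(m: CooccurrenceMatrix | np.ndarray) -> np.ndarray:
    """Distribution of the level sum i+j, indexed k = 0 .. 2(Ng−1)."""
    p = _as_matrix(m)
    ng = p.shape[0]
    p_sum = np.zeros(2 * ng - 1)
    # anti-diagonal sums: trace of the flipped matrix at each offset
    flipped = p[:, ::-1]
    for k in range(2 * ng - 1):
        p_sum[k] = np.trace(flipped, offset=ng - 1 - k)
    return p_sum


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def compute_features(m: CooccurrenceMatrix | np.ndarray) -> TextureFeatureVector:
    """Compute the twelve texture features from one normalized symmetric GLCM."""
    p = _as_matrix(m)
    ng = p.shape[0]
    levels = np.arange(ng, dtype=float)
    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    ms = marginal_stats(p)

    diff = ii - jj
    dev_sum = ii + jj - ms.mu_x - ms.mu_y

    contrast = float((diff**2 * p).sum())
    cluster_shade = float((dev_sum**3 * p).sum())
    cluster_prominence = float((dev_sum**4 * p).sum())
    entropy = _entropy_bits(p.ravel())
    variance = float(((ii - ms.mu_x) ** 2 * p).sum())
    mean = (ms.mu_x + ms.mu_y) / 2.0
    if ms.sigma_x > 0 and ms.sigma_y > 0:
        correlation = float(
            ((ii - ms.mu_x) * (jj - ms.mu_y) * p).sum() / (ms.sigma_x * ms.sigma_y)
        )
    else:
        correlation = float("nan")
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + diff**2)).sum())

    p_sum = sum_distribution(p)
    k = np.arange(p_sum.size, dtype=float)
    mean_sum = float(k @ p_sum)
    entropy_sum = _entropy_bits(p_sum)
    variance_sum = float(((k - mean_sum) ** 2) @ p_sum)

    return TextureFeatureVector(
        contrast=contrast,
        cluster_shade=cluster_shade,
        cluster_prominence=cluster_prominence,
        entropy=entropy,
        variance=variance,
        mean=mean,
        correlation=correlation,
        energy=energy,
        homogeneity=homogeneity,
        mean_sum=mean_sum,
        entropy_sum=entropy_sum,
        variance_sum=variance_sum,
    )
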
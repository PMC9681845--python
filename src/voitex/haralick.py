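"""The 11 Haralick texture parameters of a normalized GLCM.

With ``p(i, j)`` a normalized ``Ng x Ng`` co-occurrence matrix over 1-based
gray levels, marginals ``p_x(i) = sum_j p(i,j)``, sum distribution
``p_sum(k) = sum_{i+j=k} p(i,j)`` (``k = 2..2Ng``) and difference
distribution ``p_diff(k) = sum_{|i-j|=k} p(i,j)`` (``k = 0..Ng-1``):

==========================  ====================================================
uniformity                  ``sum p(i,j)^2``  (angular second moment / energy)
contrast                    ``sum (i-j)^2 p(i,j)``
homogeneity                 ``sum p(i,j) / (1 + (i-j)^2)``  (inverse difference
                            moment)
entropy                     ``-sum p(i,j) log p(i,j)``
variance                    ``sum_i (i - mu)^2 p_x(i)``  (sum of squares), with
                            ``mu = sum_i i p_x(i)``
correlation                 ``(sum i j p(i,j) - mu_x mu_y) / (sigma_x sigma_y)``,
                            0 when ``sigma_x sigma_y = 0``
sum_average                 ``sum k p_sum(k)``
sum_entropy                 ``-sum p_sum(k) log p_sum(k)``
sum_variance                ``sum (k - sum_average)^2 p_sum(k)``
entropy_of_difference       ``-sum p_diff(k) log p_diff(k)``
variance_of_difference      ``sum (k - mu_d)^2 p_diff(k)``, ``mu_d = sum k
                            p_diff(k)``
==========================  ====================================================

``0 * log 0 == 0`` throughout. The log base defaults to natural log and is
configurable (``"e"``, ``2`` or ``10``) because published conventions vary.
Sum variance is centred on the sum average (a central moment), not on sum
entropy as in a well-known misprint of the original formula list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PARAMETER_NAMES",
    "HaralickVector",
    "Marginals",
    "marginals",
    "compute_features",
]

#: Canonical ordered parameter set; every feature table uses this order.
PARAMETER_NAMES = (
    "contrast",
    "correlation",
    "entropy_of_difference",
    "entropy",
    "homogeneity",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "uniformity",
    "variance_of_difference",
    "variance",
)

DEFAULT_LOG_BASE = "e"


def _log_divisor(log_base: str | float) -> float:
    if log_base in ("e", math.e):
        return 1.0
    base = float(log_base)
    if base <= 1:
        raise ValueError(f"log base must exceed 1, got {log_base!r}")
    return math.log(base)


@dataclass
class HaralickVector:
    """One value per parameter in :data:`PARAMETER_NAMES` order.

    A degenerate (all-zero) input matrix yields ``degenerate=True`` with
    every value NaN.
    """

    values: dict[str, float]
    degenerate: bool = False

    def __post_init__(self) -> None:
        if tuple(self.values) != PARAMETER_NAMES:
            raise ValueError("values must carry exactly the 11 canonical keys")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in PARAMETER_NAMES])


@dataclass
class Marginals:
    p_x: np.ndarray  # index i-1 for level i
    p_y: np.ndarray
    p_sum: np.ndarray  # index k-2 for k = 2..2Ng
    p_diff: np.ndarray  # index k for k = 0..Ng-1


def marginals(p: np.ndarray, *, atol: float = 1e-8) -> Marginals:
    """Row, column, sum and difference marginals of a normalized matrix."""
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {p.shape}")
    if abs(p.sum() - 1.0) > atol:
        raise ValueError(f"matrix must sum to 1, sums to {p.sum():g}")
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    p_x = p.sum(axis=1)
    p_y = p.sum(axis=0)
    p_sum = np.bincount((ii + jj).ravel() - 2, weights=p.ravel(), minlength=2 * ng - 1)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=ng)
    return Marginals(p_x=p_x, p_y=p_y, p_sum=p_sum, p_diff=p_diff)


def _entropy(dist: np.ndarray, log_div: float) -> float:
    nz = dist[dist > 0]
    return float(-(nz * np.log(nz)).sum() / log_div)


def compute_features(
    p: np.ndarray, log_base: str | float = DEFAULT_LOG_BASE
) -> HaralickVector:
    """All 11 parameters of one normalized GLCM.

    An all-zero matrix (a VOI with no co-occurring pairs at this distance)
    returns a degenerate vector of NaNs rather than raising: degeneracy is
    cohort data.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] < 2:
        raise ValueError(f"expected a square Ng>=2 matrix, got shape {p.shape}")
    if not p.any():
        return HaralickVector(
            values={k: float("nan") for k in PARAMETER_NAMES}, degenerate=True
        )
    log_div = _log_divisor(log_base)
    m = marginals(p)
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    k_diff = np.arange(0, ng, dtype=np.float64)

    mu_x = float((i * m.p_x).sum())
    mu_y = float((i * m.p_y).sum())
    sig_x = math.sqrt(float(((i - mu_x) ** 2 * m.p_x).sum()))
    sig_y = math.sqrt(float(((i - mu_y) ** 2 * m.p_y).sum()))

    uniformity = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
    entropy = _entropy(p.ravel(), log_div)
    variance = float(((i - mu_x) ** 2 * m.p_x).sum())
    if sig_x * sig_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 0.0  # constant texture: no linear dependence to measure
    sum_average = float((k_sum * m.p_sum).sum())
    sum_entropy = _entropy(m.p_sum, log_div)
    sum_variance = float(((k_sum - sum_average) ** 2 * m.p_sum).sum())
    entropy_of_difference = _entropy(m.p_diff, log_div)
    mu_d = float((k_diff * m.p_diff).sum())
    variance_of_difference = float(((k_diff - mu_d) ** 2 * m.p_diff).sum())

    values = {
        "contrast": contrast,
        "correlation": correlation,
        "entropy_of_difference": entropy_of_difference,
        "entropy": entropy,
        "homogeneity": homogeneity,
        "sum_average": sum_average,
        "sum_entropy": sum_entropy,
        "sum_variance": sum_variance,
        "uniformity": uniformity,
        "variance_of_difference": variance_of_difference,
        "variance": variance,
    }
    return HaralickVector(values=values, degenerate=False)
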
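"""Spatial statistics for pore parameter fields.

Three tools used to characterise the spatial arrangement of pores:

* ``cluster_bins`` — partition a scalar parameter (e.g. pore area) into
  three ordered bins (small / medium / large) whose adjacent bin means are
  maximally separated,
* ``morans_i`` — Moran's I spatial autocorrelation of a parameter over the
  pore centroids with a permutation and a normal-approximation p-value,
* ``rank_sum_test`` — the Mann–Whitney rank-sum comparison used for all
  two-sample pore-parameter contrasts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "Binning",
    "SpatialAutocorrResult",
    "RankSumResult",
    "cluster_bins",
    "morans_i",
    "rank_sum_test",
]

BIN_LABELS = ("small", "medium", "large")


@dataclass
class Binning:
    thresholds: tuple[float, float]  # value <= t0 -> small, <= t1 -> medium
    labels: np.ndarray  # per-value label, one of BIN_LABELS
    bin_means: tuple[float, float, float]
    min_gap: float  # objective value: smaller of the two adjacent mean gaps


@dataclass
class SpatialAutocorrResult:
    I: float
    expected_I: float  # −1/(n−1) under the null
    p_perm: float
    p_norm: float
    n_perm: int
    weight_spec: str
    perm_sd: float  # SD of I over the permutation null (for diagnostics)


@dataclass
class RankSumResult:
    U: float
    p_value: float
    n1: int
    n2: int
    method: str


# --------------------------------------------------------------------------

def cluster_bins(values, objective: str = "min_gap") -> Binning:
    """Three-bin maximal-separation clustering of a scalar parameter.

    All ordered threshold pairs on the sorted observed values are searched
    exhaustively; the partition maximising the separation of adjacent bin
    means is returned. ``objective='min_gap'`` (default) maximises the
    smaller of the two adjacent gaps (each bin's mean maximally separated
    from the *next nearest* bin's mean); ``'sum_gap'`` maximises their
    sum. Ties are broken toward the more balanced partition (smaller
    variance of bin counts), then toward lower thresholds.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if len(np.unique(x)) < 3:
        raise ValueError("3-bin clustering needs at least 3 distinct values")
    if objective not in ("min_gap", "sum_gap"):
        raise ValueError(f"unknown objective {objective!r}")

    csum = np.concatenate([[0.0], np.cumsum(x)])

    def mean(lo: int, hi: int) -> float:  # mean of x[lo:hi]
        return (csum[hi] - csum[lo]) / (hi - lo)

    # valid cut indices: bins must not split ties, so cuts sit at distinct-value
    # boundaries (thresholds constrained to observed values)
    cuts = [i for i in range(1, n) if x[i] > x[i - 1]]
    best = None
    for i, j in itertools.combinations(cuts, 2):
        m1, m2, m3 = mean(0, i), mean(i, j), mean(j, n)
        g1, g2 = m2 - m1, m3 - m2
        obj = min(g1, g2) if objective == "min_gap" else g1 + g2
        counts = (i, j - i, n - j)
        balance = float(np.var(counts))
        key = (-obj, balance, x[i - 1], x[j - 1])
        if best is None or key < best[0]:
            best = (key, i, j, (m1, m2, m3), obj)
    _, i, j, means, obj = best
    labels = np.empty(n, dtype=object)
    sorter = np.argsort(np.asarray(values, dtype=float), kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[sorter] = np.arange(n)
    labels = np.where(ranks < i, BIN_LABELS[0], np.where(ranks < j, BIN_LABELS[1], BIN_LABELS[2]))
    return Binning(
        thresholds=(float(x[i - 1]), float(x[j - 1])),
        labels=labels,
        bin_means=tuple(float(m) for m in means),
        min_gap=float(min(means[1] - means[0], means[2] - means[1])),
    )


# --------------------------------------------------------------------------

def _build_weights(coords: np.ndarray, weights) -> tuple[np.ndarray, str]:
    n = len(coords)
    if isinstance(weights, np.ndarray):
        W = np.array(weights, dtype=float)
        if W.shape != (n, n):
            raise ValueError("weight matrix must be n x n")
        np.fill_diagonal(W, 0.0)
        return W, "user-supplied matrix"
    d = squareform(pdist(coords))
    if np.any(d[~np.eye(n, dtype=bool)] == 0):
        raise ValueError("coincident coordinates: weights undefined")
    if weights == "inverse_distance":
        with np.errstate(divide="ignore"):
            W = 1.0 / d
        np.fill_diagonal(W, 0.0)
        return W, "inverse distance (1/d)"
    if isinstance(weights, tuple) and weights[0] == "knn":
        k = int(weights[1])
        if not 1 <= k < n:
            raise ValueError("knn weights need 1 <= k < n")
        W = np.zeros((n, n))
        dd = d.copy()
        np.fill_diagonal(dd, np.inf)
        nearest = np.argsort(dd, axis=1, kind="stable")[:, :k]
        rows = np.repeat(np.arange(n), k)
        W[rows, nearest.ravel()] = 1.0
        return W, f"binary k-NN (k={k})"
    raise ValueError(f"unknown weight spec {weights!r}")


def morans_i(
    values,
    coords,
    weights="inverse_distance",
    n_perm: int = 999,
    seed: int | np.random.Generator | None = 0,
) -> SpatialAutocorrResult:
    """Moran's I with permutation and normal-approximation inference.

    I = (n/S₀) Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)²   with wᵢᵢ = 0.

    +1 indicates perfect spatial clustering of similar values, −1 perfect
    dispersion, and values near E[I] = −1/(n−1) a random arrangement.
    The permutation p is two-sided, ``(count + 1)/(n_perm + 1)``, counting
    permuted |I − E[I]| at least as extreme as observed; the analytic p
    uses the normality-assumption variance. ``weights`` may be
    ``"inverse_distance"`` (default), ``("knn", k)`` for binary k-nearest-
    neighbour weights, or a precomputed (n, n) matrix.
    """
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Moran's I needs at least 4 observations")
    if coords.shape[0] != n:
        raise ValueError("values and coordinates must align")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant values: Moran's I undefined")

    W, spec = _build_weights(coords, weights)
    S0 = W.sum()
    I_obs = float(n / S0 * (z @ W @ z) / denom)
    e_i = -1.0 / (n - 1)

    # permutation null (vectorised: permute the standardized values)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.array([rng.permutation(z) for _ in range(n_perm)])
    I_perm = n / S0 * np.einsum("pi,ij,pj->p", perms, W, perms) / denom
    extreme = np.abs(I_perm - e_i) >= abs(I_obs - e_i) - 1e-12
    p_perm = (int(extreme.sum()) + 1) / (n_perm + 1)

    # normality-assumption variance
    S1 = 0.5 * ((W + W.T) ** 2).sum()
    S2 = ((W.sum(axis=0) + W.sum(axis=1)) ** 2).sum()
    var_norm = (n * n * S1 - n * S2 + 3.0 * S0 * S0) / (S0 * S0 * (n * n - 1.0)) - e_i**2
    zscore = (I_obs - e_i) / math.sqrt(var_norm)
    p_norm = 2.0 * stats.norm.sf(abs(zscore))

    return SpatialAutocorrResult(
        I=I_obs,
        expected_I=e_i,
        p_perm=float(p_perm),
        p_norm=float(p_norm),
        n_perm=n_perm,
        weight_spec=spec,
        perm_sd=float(I_perm.std(ddof=1)),
    )


# --------------------------------------------------------------------------

def rank_sum_test(x, y) -> RankSumResult:
    """Mann–Whitney rank-sum test (two-sided).

    Midranks handle ties; the p-value is exact (by enumeration) when
    n₁ + n₂ ≤ 12 and there are no ties, otherwise a tie-corrected normal
    approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if no_ties and len(pooled) <= 12:
        method = "exact"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "normal"
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return RankSumResult(U=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
                         n1=len(x), n2=len(y), method=method)
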
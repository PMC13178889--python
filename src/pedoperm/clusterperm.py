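"""Cluster-based permutation inference for 2D pressure maps and 1D series.

The procedure: a two-sample t-test at every pixel (or time point), a
cluster-forming threshold on the pointwise p-values (default p < .01),
grouping of super-threshold points into contiguous clusters (8-connectivity
in 2D, index adjacency in 1D), cluster mass = sum of |t| over members, and a
max-statistic Monte Carlo null: group labels are permuted, the whole map is
recomputed, and the maximum cluster mass over both signs is recorded per
permutation.  Corrected cluster p-values from this null control the
family-wise error rate across the map.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "PermConfig",
    "StatMap",
    "Cluster",
    "ClusterResult",
    "pointwise_tmap",
    "form_clusters",
    "permutation_null",
    "cluster_test",
    "cluster_table",
]


@dataclass(frozen=True)
class PermConfig:
    """Settings for the cluster permutation test.

    cluster_forming_p
        Pointwise two-sided p threshold for cluster membership (default .01).
    cluster_alpha
        Corrected significance level for clusters (default .05).
    n_perm
        Monte Carlo iterations (default 1000).
    connectivity
        8 (diagonals contiguous, default) or 4, for 2D maps; 1D series use
        index adjacency regardless.
    min_group_coverage
        A point is testable only if at least this fraction of subjects in
        *each* group has a nonzero value there (default 0.5); set to 0 to
        test every point (e.g. COP coordinate series, which are not
        activation-gated).
    equal_var
        False (default) = Welch t; True = pooled-variance Student t.
    cluster_stat
        "mass" (sum of |t|, default) or "max" (largest |t| in the cluster).
    exhaustive
        "auto" (default): enumerate all distinct relabelings when there are
        at most n_perm of them, giving an exact test on tiny inputs; True
        forces enumeration; False forces with-replacement sampling.
    """

    cluster_forming_p: float = 0.01
    cluster_alpha: float = 0.05
    n_perm: int = 1000
    connectivity: int = 8
    min_group_coverage: float = 0.5
    equal_var: bool = False
    cluster_stat: str = "mass"
    exhaustive: object = "auto"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.cluster_forming_p < 1 and 0 < self.cluster_alpha < 1):
            raise ValueError("thresholds must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.cluster_stat not in ("mass", "max"):
            raise ValueError("cluster_stat must be 'mass' or 'max'")


@dataclass
class StatMap:
    """Pointwise test statistics on the analysis grid/axis."""

    t_values: np.ndarray
    p_values: np.ndarray
    df: np.ndarray
    testable_mask: np.ndarray
    n_zero_variance: int = 0


@dataclass
class Cluster:
    """A contiguous set of super-threshold points of one sign."""

    members: np.ndarray  # boolean mask on the analysis grid/axis
    sign: str  # "positive" | "negative"
    mass: float  # sum of |t| over members
    stat: float  # cluster-level statistic used for inference
    size: int
    p_corrected: Optional[float] = None
    significant: Optional[bool] = None


@dataclass
class ClusterResult:
    stat_map: StatMap
    clusters: list[Cluster]
    null_distribution: np.ndarray
    config: PermConfig
    exhaustive: bool = False

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def significant_mask(self) -> np.ndarray:
        out = np.zeros(self.stat_map.t_values.shape, dtype=bool)
        for c in self.significant_clusters:
            out |= c.members
        return out


def _welch_arrays(
    X: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, equal_var: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """t, df and zero-variance mask for group A vs B along axis 0."""
    a, b = X[idx_a], X[idx_b]
    na, nb = len(idx_a), len(idx_b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full_like(se2, float(na + nb - 2))
    else:
        sa, sb = va / na, vb / nb
        se2 = sa + sb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
    t = np.where(zero, 0.0, t)
    df = np.where(zero | ~np.isfinite(df), 1.0, df)
    return t, df, zero


def pointwise_tmap(
    group_a: np.ndarray, group_b: np.ndarray, config: PermConfig = PermConfig()
) -> StatMap:
    """Two-sample t statistic at every point of two stacks.

    ``group_a``/``group_b`` have shape (n_subjects, ...) on a common grid.
    Points where fewer than ``min_group_coverage`` of either group's
    subjects have a nonzero value are masked out; a testable point with zero
    variance in both groups gets t = 0, p = 1 (counted in
    ``n_zero_variance``).  Swapping the groups negates the map exactly.
    """
    A = np.asarray(group_a, dtype=float)
    B = np.asarray(group_b, dtype=float)
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("groups must share the grid shape")
    if len(A) < 2 or len(B) < 2:
        raise ValueError("need at least 2 subjects per group")
    if config.min_group_coverage > 0:
        cov_a = (A != 0).mean(axis=0)
        cov_b = (B != 0).mean(axis=0)
        testable = (cov_a >= config.min_group_coverage) & (cov_b >= config.min_group_coverage)
    else:
        testable = np.ones(A.shape[1:], dtype=bool)
    X = np.concatenate([A, B], axis=0)
    idx_a = np.arange(len(A))
    idx_b = np.arange(len(A), len(A) + len(B))
    t, df, zero = _welch_arrays(X, idx_a, idx_b, config.equal_var)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, 1.0, p)
    t = np.where(testable, t, 0.0)
    p = np.where(testable, p, 1.0)
    n_zero = int(np.count_nonzero(zero & testable))
    if n_zero:
        warnings.warn(f"{n_zero} testable point(s) with zero variance in both groups")
    return StatMap(t_values=t, p_values=p, df=df, testable_mask=testable, n_zero_variance=n_zero)


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    if ndim == 1:
        return np.ones(3, dtype=int)
    if connectivity == 8:
        return np.ones((3, 3), dtype=int)
    return ndimage.generate_binary_structure(2, 1)


def form_clusters(stat: StatMap, config: PermConfig = PermConfig()) -> list[Cluster]:
    """Group super-threshold points of common sign into contiguous clusters."""
    clusters: list[Cluster] = []
    super_thr = stat.testable_mask & (stat.p_values < config.cluster_forming_p)
    struct = _structure(stat.t_values.ndim, config.connectivity)
    for sign, sign_mask in (
        ("positive", stat.t_values > 0),
        ("negative", stat.t_values < 0),
    ):
        labels, n = ndimage.label(super_thr & sign_mask, structure=struct)
        for k in range(1, n + 1):
            members = labels == k
            abs_t = np.abs(stat.t_values[members])
            mass = float(abs_t.sum())
            stat_val = mass if config.cluster_stat == "mass" else float(abs_t.max())
            clusters.append(
                Cluster(
                    members=members,
                    sign=sign,
                    mass=mass,
                    stat=stat_val,
                    size=int(members.sum()),
                )
            )
    clusters.sort(key=lambda c: c.stat, reverse=True)
    return clusters


def _max_cluster_stat(
    t: np.ndarray, p: np.ndarray, testable: np.ndarray, config: PermConfig
) -> float:
    """Maximum cluster statistic over both signs; 0 if no cluster forms."""
    super_thr = testable & (p < config.cluster_forming_p)
    if not super_thr.any():
        return 0.0
    struct = _structure(t.ndim, config.connectivity)
    best = 0.0
    abs_t = np.abs(t)
    for sign_mask in (t > 0, t < 0):
        labels, n = ndimage.label(super_thr & sign_mask, structure=struct)
        if n == 0:
            continue
        agg = ndimage.sum_labels if config.cluster_stat == "mass" else ndimage.maximum
        vals = agg(abs_t, labels, index=np.arange(1, n + 1))
        best = max(best, float(np.max(vals)))
    return best


def _n_distinct_relabelings(n_total: int, n_a: int) -> int:
    return math.comb(n_total, n_a)


def permutation_null(
    group_a: np.ndarray,
    group_b: np.ndarray,
    config: PermConfig = PermConfig(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, bool]:
    """Null distribution of the maximum cluster statistic under relabeling.

    Labels are permuted preserving group sizes; for each relabeling the
    t-map, threshold and clusters are recomputed and the maximum cluster
    statistic over both signs recorded (0 when no cluster forms).  The
    testable mask is computed once from the observed grouping and held
    fixed.  When the number of distinct relabelings is at most ``n_perm``
    (and ``exhaustive`` is not False), all of them are enumerated, giving an
    exact null; otherwise ``n_perm`` random permutations are drawn (with
    replacement across draws, with a warning if fewer distinct relabelings
    exist than draws requested).

    Returns (null values, exhaustive flag).
    """
    A = np.asarray(group_a, dtype=float)
    B = np.asarray(group_b, dtype=float)
    observed = pointwise_tmap(A, B, config)
    testable = observed.testable_mask
    X = np.concatenate([A, B], axis=0)
    n_a, n_total = len(A), len(A) + len(B)
    n_distinct = _n_distinct_relabelings(n_total, n_a)
    use_exhaustive = config.exhaustive is True or (
        config.exhaustive == "auto" and n_distinct <= config.n_perm
    )
    null = []
    if use_exhaustive:
        for combo in itertools.combinations(range(n_total), n_a):
            idx_a = np.array(combo)
            idx_b = np.setdiff1d(np.arange(n_total), idx_a, assume_unique=True)
            null.append(_perm_stat(X, idx_a, idx_b, testable, config))
    else:
        if n_distinct < config.n_perm:
            warnings.warn(
                f"only {n_distinct} distinct relabelings for {config.n_perm} "
                "requested permutations; sampling with replacement"
            )
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        for _ in range(config.n_perm):
            perm = rng.permutation(n_total)
            null.append(_perm_stat(X, perm[:n_a], perm[n_a:], testable, config))
    return np.asarray(null), use_exhaustive


def _perm_stat(
    X: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    testable: np.ndarray,
    config: PermConfig,
) -> float:
    t, df, zero = _welch_arrays(X, idx_a, idx_b, config.equal_var)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero, 1.0, p)
    return _max_cluster_stat(t, p, testable, config)


def cluster_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    config: PermConfig = PermConfig(),
    rng: Optional[np.random.Generator] = None,
) -> ClusterResult:
    """Full cluster permutation test of group A vs group B.

    Corrected p-values: with a Monte Carlo null, p = (1 + #{null >= stat}) /
    (1 + n_perm), never below 1/(n_perm + 1); with an exhaustive null the
    plain proportion #{null >= stat} / m is exact (the identity relabeling
    is among the m).  A cluster is significant iff p <= cluster_alpha.
    The same call handles 2D maps, 1D time series and COP coordinate series.
    """
    stat_map = pointwise_tmap(group_a, group_b, config)
    clusters = form_clusters(stat_map, config)
    null, exhaustive = permutation_null(group_a, group_b, config, rng=rng)
    m = len(null)
    for c in clusters:
        exceed = int(np.count_nonzero(null >= c.stat))
        c.p_corrected = exceed / m if exhaustive else (1 + exceed) / (1 + m)
        c.significant = c.p_corrected <= config.cluster_alpha
    return ClusterResult(
        stat_map=stat_map,
        clusters=clusters,
        null_distribution=null,
        config=config,
        exhaustive=exhaustive,
    )


def cluster_table(result: ClusterResult) -> pd.DataFrame:
    """Tabular summary: one row per cluster (id, sign, size, mass, p, flag)."""
    rows = [
        {
            "cluster": i + 1,
            "sign": c.sign,
            "size": c.size,
            "mass": c.mass,
            "p_corrected": c.p_corrected,
            "significant": bool(c.significant),
        }
        for i, c in enumerate(result.clusters)
    ]
    return pd.DataFrame(
        rows, columns=["cluster", "sign", "size", "mass", "p_corrected", "significant"]
    )
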
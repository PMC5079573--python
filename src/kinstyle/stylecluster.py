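"""Two-step (BIRCH-style) clustering of movement feature vectors.

The procedure follows the classic TwoStep design for all-continuous data:

1. a sequential pre-cluster pass that condenses trials into sub-clusters,
   each summarized only by its cluster-feature (CF) statistics — point
   count N, per-dimension linear sum LS and squared sum SS;
2. greedy hierarchical agglomeration of the sub-clusters under a
   log-likelihood distance, with automatic selection of the number of
   clusters from the BIC trace refined by the ratio of successive minimum
   merge distances.

Predictor importance scores each feature column by the normalized
-log10 p-value of a one-way F-test of cluster mean differences; the most
discriminative column scores 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError
from .kinfeat import FeatureMatrix

logger = logging.getLogger(__name__)

#: Default per-dimension additive variance inside the log terms.  The
#: TwoStep log-likelihood distance adds the GLOBAL variance of each
#: dimension to the within-cluster variance; on z-scored features that is
#: 1.  (It also keeps singleton sub-clusters, whose variance is 0, finite.)
DEFAULT_GLOBAL_VARIANCE = 1.0
#: Floor applied to supplied global variances so constant columns stay
#: finite inside the log.
VARIANCE_FLOOR = 1e-6
DEFAULT_K_MAX = 15
DEFAULT_BIC_RATIO = 0.04
DEFAULT_MAX_SUBCLUSTERS = 512


@dataclass
class CFEntry:
    """Cluster-feature statistics: sufficient summary of a point set."""

    N: int
    LS: np.ndarray
    SS: np.ndarray

    def __post_init__(self) -> None:
        self.LS = np.asarray(self.LS, dtype=float)
        self.SS = np.asarray(self.SS, dtype=float)
        if self.N < 1:
            raise InvalidArgumentError("CFEntry needs N >= 1")
        if self.LS.shape != self.SS.shape:
            raise InvalidArgumentError("LS and SS must have the same shape")

    @classmethod
    def from_points(cls, points: np.ndarray) -> "CFEntry":
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return cls(N=pts.shape[0], LS=pts.sum(axis=0),
                   SS=(pts ** 2).sum(axis=0))

    def merge(self, other: "CFEntry") -> "CFEntry":
        if self.LS.shape != other.LS.shape:
            raise InvalidArgumentError("dimension mismatch in CF merge")
        return CFEntry(self.N + other.N, self.LS + other.LS,
                       self.SS + other.SS)

    def variances(self) -> np.ndarray:
        """Per-dimension (biased) variance, clamped at 0."""
        mean = self.LS / self.N
        return np.maximum(self.SS / self.N - mean ** 2, 0.0)


def _xi(N: np.ndarray, LS: np.ndarray, SS: np.ndarray,
        reg: np.ndarray | float) -> np.ndarray:
    """Vectorized log-likelihood term xi_v = -N_v * sum_k 0.5*log(var + reg).

    N: (m,); LS, SS: (m, d).  Returns (m,).
    """
    Nc = N[:, None]
    var = np.maximum(SS / Nc - (LS / Nc) ** 2, 0.0)
    return -N * 0.5 * np.sum(np.log(var + reg), axis=1)


def _entry_xi(e: CFEntry, reg: np.ndarray | float) -> float:
    return float(_xi(np.array([e.N], dtype=float), e.LS[None, :],
                     e.SS[None, :], reg)[0])


def loglik_distance(a: CFEntry, b: CFEntry,
                    global_variances: np.ndarray | float | None = None
                    ) -> float:
    """Log-likelihood merge distance d(a, b) = xi_a + xi_b - xi_{a u b}.

    ``global_variances`` is the per-dimension variance of the whole
    dataset, added to the within-cluster variances inside the log terms
    (default 1, the value for z-scored features); it both follows the
    TwoStep distance definition and keeps zero-variance singletons finite.
    The distance is symmetric and non-negative, and depends on the point
    sets only through their CF statistics.
    """
    if a.LS.shape != b.LS.shape:
        raise InvalidArgumentError("dimension mismatch")
    reg = DEFAULT_GLOBAL_VARIANCE if global_variances is None else global_variances
    merged = a.merge(b)
    d = _entry_xi(a, reg) + _entry_xi(b, reg) - _entry_xi(merged, reg)
    return max(d, 0.0)


def _pairwise_merge_distance(N, LS, SS, reg):
    """Full (m, m) matrix of merge distances from stacked CF arrays."""
    m = N.shape[0]
    xi = _xi(N, LS, SS, reg)
    D = np.full((m, m), np.inf)
    for i in range(m):
        Nm = N[i] + N
        LSm = LS[i] + LS
        SSm = SS[i] + SS
        xim = _xi(Nm, LSm, SSm, reg)
        D[i] = np.maximum(xi[i] + xi - xim, 0.0)
    np.fill_diagonal(D, np.inf)
    return D


def precluster(X: np.ndarray,
               distance_threshold: float = 0.0,
               max_subclusters: int = DEFAULT_MAX_SUBCLUSTERS,
               global_variances: float | np.ndarray = DEFAULT_GLOBAL_VARIANCE
               ) -> tuple[list[CFEntry], np.ndarray]:
    """Single sequential pass condensing points into CF sub-clusters.

    Each point joins the nearest existing sub-cluster if the log-likelihood
    merge distance is at or below the threshold, otherwise it seeds a new
    one.  If the sub-cluster count exceeds ``max_subclusters`` the threshold
    is raised and the existing entries are re-inserted through the same
    rule (the CF-tree rebuild contract); point totals are conserved.

    Returns the entries and a point -> sub-cluster index map.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n == 0:
        raise InvalidArgumentError("empty input")
    reg = global_variances
    thr = float(distance_threshold)

    # stacked CF arrays for vectorized nearest-entry search
    N = np.empty(0)
    LS = np.empty((0, d))
    SS = np.empty((0, d))
    assign = np.empty(n, dtype=int)

    def insert(pN, pLS, pSS, cur_thr):
        nonlocal N, LS, SS
        if N.shape[0] > 0:
            xi = _xi(N, LS, SS, reg)
            xip = _xi(np.array([pN]), pLS[None, :], pSS[None, :], reg)[0]
            xim = _xi(N + pN, LS + pLS, SS + pSS, reg)
            dist = np.maximum(xi + xip - xim, 0.0)
            j = int(np.argmin(dist))
            if dist[j] <= cur_thr:
                N[j] += pN
                LS[j] += pLS
                SS[j] += pSS
                return j
        N = np.append(N, pN)
        LS = np.vstack([LS, pLS])
        SS = np.vstack([SS, pSS])
        return N.shape[0] - 1

    for i in range(n):
        assign[i] = insert(1.0, X[i], X[i] ** 2, thr)
        while N.shape[0] > max_subclusters:
            # raise threshold and rebuild from the current entries
            D = _pairwise_merge_distance(N, LS, SS, reg)
            nn = D.min(axis=1)
            thr = max(thr * 2.0, float(np.min(nn[nn > 0], initial=0.0)))
            if thr == 0.0:
                thr = float(np.finfo(float).tiny)
            oldN, oldLS, oldSS = N, LS, SS
            N = np.empty(0)
            LS = np.empty((0, d))
            SS = np.empty((0, d))
            remap = np.empty(oldN.shape[0], dtype=int)
            for e in range(oldN.shape[0]):
                remap[e] = insert(oldN[e], oldLS[e], oldSS[e], thr)
            assign[:i + 1] = remap[assign[:i + 1]]

    entries = [CFEntry(int(N[j]), LS[j].copy(), SS[j].copy())
               for j in range(N.shape[0])]
    assert sum(e.N for e in entries) == n
    return entries, assign


@dataclass
class MergeHistory:
    """Record of one full greedy agglomeration of sub-clusters.

    ``labels_at`` maps a cluster count k to per-sub-cluster labels (0..k-1);
    ``merge_distance`` maps k to the minimum inter-cluster distance consumed
    by the merge taking k clusters to k-1.
    """

    labels_at: dict[int, np.ndarray]
    merge_distance: dict[int, float]
    m: int


def agglomerate_full(subclusters: list[CFEntry],
                     global_variances: float | np.ndarray = DEFAULT_GLOBAL_VARIANCE
                     ) -> MergeHistory:
    """Greedy hierarchical merging of sub-clusters down to one cluster."""
    m = len(subclusters)
    if m == 0:
        raise InvalidArgumentError("no sub-clusters")
    reg = global_variances
    N = np.array([e.N for e in subclusters], dtype=float)
    LS = np.vstack([e.LS for e in subclusters])
    SS = np.vstack([e.SS for e in subclusters])
    active = list(range(m))
    labels = np.arange(m)
    D = _pairwise_merge_distance(N, LS, SS, reg)

    history = MergeHistory(labels_at={}, merge_distance={}, m=m)
    history.labels_at[m] = _canonical(labels.copy())
    k = m
    while k > 1:
        sub = np.ix_(active, active)
        Dv = D[sub]
        flat = int(np.argmin(Dv))
        ii, jj = divmod(flat, len(active))
        i, j = active[ii], active[jj]
        history.merge_distance[k] = float(Dv[ii, jj])
        # merge j into i
        N[i] += N[j]
        LS[i] += LS[j]
        SS[i] += SS[j]
        labels[labels == labels[j]] = labels[i]
        active.remove(j)
        # refresh distances for merged entry
        idx = np.array(active)
        xi = _xi(N[idx], LS[idx], SS[idx], reg)
        xii = _xi(N[i:i + 1], LS[i:i + 1], SS[i:i + 1], reg)[0]
        xim = _xi(N[idx] + N[i], LS[idx] + LS[i], SS[idx] + SS[i], reg)
        drow = np.maximum(xi + xii - xim, 0.0)
        D[i, idx] = drow
        D[idx, i] = drow
        D[i, i] = np.inf
        k -= 1
        history.labels_at[k] = _canonical(labels.copy())
    return history


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel to 0..k-1 in order of first appearance."""
    _, canon = np.unique(labels, return_inverse=True)
    return canon


def agglomerate(subclusters: list[CFEntry], k: int,
                global_variances: float | np.ndarray = DEFAULT_GLOBAL_VARIANCE
                ) -> tuple[np.ndarray, dict[int, float]]:
    """Labels of each sub-cluster at level k, plus the merge-distance trace."""
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if k > len(subclusters):
        raise InvalidArgumentError("k exceeds number of sub-clusters")
    history = agglomerate_full(subclusters, global_variances)
    return history.labels_at[k], history.merge_distance


def bic_trace(subclusters: list[CFEntry], history: MergeHistory,
              k_max: int,
              global_variances: float | np.ndarray = DEFAULT_GLOBAL_VARIANCE
              ) -> np.ndarray:
    """BIC(k) for k = 1..k_max: -2 * sum_clusters xi + 2*k*d*log(n)."""
    N = np.array([e.N for e in subclusters], dtype=float)
    LS = np.vstack([e.LS for e in subclusters])
    SS = np.vstack([e.SS for e in subclusters])
    n = N.sum()
    d = LS.shape[1]
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        labels = history.labels_at[k]
        xs = 0.0
        for c in range(k):
            mask = labels == c
            xs += _xi(np.array([N[mask].sum()]),
                      LS[mask].sum(axis=0)[None, :],
                      SS[mask].sum(axis=0)[None, :], global_variances)[0]
        out[k - 1] = -2.0 * xs + 2.0 * k * d * np.log(n)
    return out


def select_k(bic: np.ndarray, merge_distance: dict[int, float],
             ratio_criterion: float = DEFAULT_BIC_RATIO) -> int:
    """Two-stage cluster-count selection.

    Stage 1 (coarse): if the BIC already worsens from 1 to 2 clusters the
    data carry no cluster structure and k = 1.  Otherwise the coarse
    estimate k0 is the smallest k at which the successive BIC change,
    relative to the first change, falls below ``ratio_criterion``; when no
    change falls below it the whole range up to k_max stays in play.

    Stage 2 (refine): among 2 <= k <= k0, pick the k maximizing the ratio
    of the minimum inter-cluster merge distance at level k to the one at
    level k+1 (a large ratio means merging below k is much cheaper than
    merging past it).  Ties go to the smaller k; if the ratios are flat
    there is no refinement signal and k0 is returned with a warning.
    """
    k_max = len(bic)
    if k_max < 2:
        raise InvalidArgumentError("need BIC for at least k = 1, 2")
    d1 = bic[1] - bic[0]
    if d1 >= 0:
        return 1
    k0 = k_max
    for k in range(1, k_max):
        if abs(bic[k] - bic[k - 1]) / abs(d1) < ratio_criterion:
            k0 = k
            break
    if k0 < 2:
        return 1
    ratios = {}
    for k in range(2, k0 + 1):
        d_here = merge_distance.get(k, np.nan)
        d_next = merge_distance.get(k + 1, np.nan)
        if np.isfinite(d_here) and np.isfinite(d_next) and d_next > 0:
            ratios[k] = d_here / d_next
    if not ratios:
        return k0
    vals = np.array(list(ratios.values()))
    if np.ptp(vals) <= 1e-9 * max(1.0, np.abs(vals).max()):
        warnings.warn("flat merge-distance ratios: no refinement signal, "
                      "keeping the coarse BIC estimate", stacklevel=2)
        return k0
    best_k, best_ratio = 2, -np.inf
    for k, ratio in ratios.items():
        if ratio > best_ratio + 1e-12:
            best_ratio, best_k = ratio, k
    return best_k


def pi_from_significance(pvals: np.ndarray) -> np.ndarray:
    """PI_i = -log10(p_i) / max_j -log10(p_j), p floored at 1e-300.

    The most significant predictor scores exactly 1; a predictor with
    p = 0.01 scores 0.5 when the best -log10 p is 4.
    """
    pvals = np.asarray(pvals, dtype=float)
    neglog = -np.log10(np.maximum(pvals, 1e-300))
    denom = neglog.max()
    return neglog / denom if denom > 0 else np.zeros_like(neglog)


def predictor_importance(features: FeatureMatrix | pd.DataFrame | np.ndarray,
                         assignments: np.ndarray,
                         columns: list[str] | None = None) -> pd.Series:
    """Predictor importance PI_i = -log10(p_i) / max_j -log10(p_j).

    p_i is the one-way ANOVA F-test p-value of cluster mean differences for
    column i; p-values are floored at 1e-300 before the log so a numerically
    zero p-value still yields a finite score.  The best column scores 1.
    """
    if isinstance(features, FeatureMatrix):
        X = features.X
        columns = features.columns
    elif isinstance(features, pd.DataFrame):
        X = features.to_numpy()
        columns = list(features.columns)
    else:
        X = np.asarray(features, dtype=float)
        if columns is None:
            columns = [f"x{j}" for j in range(X.shape[1])]
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    if len(labels) < 2:
        raise InsufficientDataError("need at least 2 clusters")
    groups_idx = [np.flatnonzero(assignments == c) for c in labels]
    if any(len(g) < 2 for g in groups_idx):
        raise InsufficientDataError("every cluster needs >= 2 members")
    pvals = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        groups = [X[g, j] for g in groups_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.f_oneway(*groups)
        pvals[j] = 1.0 if not np.isfinite(p) else p
    return pd.Series(pi_from_significance(pvals), index=columns, name="PI")


def importance_by_variable(importances: pd.Series) -> pd.Series:
    """Aggregate column-level PI to variable level (max over time points)."""
    var = importances.index.str.rsplit("@", n=1).str[0]
    return importances.groupby(var).max().sort_values(ascending=False)


@dataclass
class ClusterModel:
    """Result of a two-step clustering fit on one intent's trials."""

    assignments: np.ndarray          # trial -> cluster label, 1..k
    k: int
    bic_trace: np.ndarray            # BIC(k), k = 1..k_max
    distance_trace: dict[int, float]  # merge level -> min inter-cluster dist
    importances: pd.Series           # column -> PI in [0, 1]
    subclusters: list[CFEntry] = field(default_factory=list)

    def shares(self) -> np.ndarray:
        """Percentage of trials per cluster, ordered by label."""
        counts = np.bincount(self.assignments, minlength=self.k + 1)[1:]
        return 100.0 * counts / counts.sum()


def fit_two_step(features: FeatureMatrix | np.ndarray,
                 k_max: int = DEFAULT_K_MAX,
                 distance_threshold: float = 0.0,
                 max_subclusters: int = DEFAULT_MAX_SUBCLUSTERS,
                 ratio_criterion: float = DEFAULT_BIC_RATIO,
                 global_variances: float | np.ndarray | None = None,
                 k: int | None = None) -> ClusterModel:
    """Full two-step fit: pre-cluster, agglomerate, select k, score columns.

    Deterministic given the input order and configuration.  When
    ``global_variances`` is not given it is computed from the data (the
    per-column variance, floored for constant columns), as the TwoStep
    distance prescribes.  Cluster labels are reported 1..k in order of
    descending cluster size.  Pass ``k`` to bypass automatic selection.
    """
    if isinstance(features, FeatureMatrix):
        X = features.X
        columns = features.columns
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        columns = None
    n = X.shape[0]
    if n < 2:
        raise InvalidArgumentError("need at least 2 trials")
    if k_max > n:
        warnings.warn(f"k_max lowered from {k_max} to {n} (few trials)",
                      stacklevel=2)
        k_max = n
    if global_variances is None:
        global_variances = np.maximum(X.var(axis=0), VARIANCE_FLOOR)
    entries, point_map = precluster(X, distance_threshold, max_subclusters,
                                    global_variances)
    history = agglomerate_full(entries, global_variances)
    k_eff = min(k_max, len(entries))
    bic = bic_trace(entries, history, k_eff, global_variances)
    if k is None:
        k = select_k(bic, history.merge_distance, ratio_criterion) \
            if k_eff >= 2 else 1
    if k > len(entries):
        raise InvalidArgumentError("k exceeds number of sub-clusters")
    sub_labels = history.labels_at[k]
    raw_assign = sub_labels[point_map]
    # relabel 1..k by descending size
    counts = np.bincount(raw_assign, minlength=k)
    order = np.argsort(-counts, kind="stable")
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(1, k + 1)
    assignments = rank[raw_assign]
    if k >= 2 and np.all(np.bincount(assignments)[1:] >= 2):
        imp = predictor_importance(X if columns is None else
                                   pd.DataFrame(X, columns=columns),
                                   assignments)
    else:
        imp = pd.Series(dtype=float, name="PI")
    return ClusterModel(assignments=assignments, k=k, bic_trace=bic,
                        distance_trace=history.merge_distance,
                        importances=imp, subclusters=entries)
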
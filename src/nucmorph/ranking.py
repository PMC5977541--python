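"""Feature ranking: Wilcoxon rank-sum, PLS-based VIP, and MRMR (MID/MIQ).

Each ranker orders the feature columns of a patches x features matrix by
relevance to a binary label, with deterministic tie-breaking, and never
sees test-fold data (enforced by the cross-validation driver).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.cross_decomposition import PLSRegression

MRMR_EPS = 1e-12


@dataclass(frozen=True)
class RankingResult:
    method: str
    ordered_features: list[str] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)

    def top(self, k: int) -> list[str]:
        return self.ordered_features[:k]


def _check_xy(X: np.ndarray, y: np.ndarray):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (patches x features)")
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    return X, y


_EXACT_MAX_N = 20


def ranksum_pvalue(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p-value and z statistic.

    The p-value uses the exact Mann-Whitney null for small tie-free
    samples and otherwise the normal approximation with tie and
    continuity corrections; z is always the (tie-corrected) normal
    deviate, used only for deterministic tie-breaking. A constant pooled
    sample has zero variance; p is 1 by convention.
    """
    from scipy.stats import mannwhitneyu, rankdata

    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = float(np.sum(ranks[:n1]))
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0, 0.0
    z = (u - mu) / np.sqrt(var)
    if n <= _EXACT_MAX_N and tie_term == 0:
        p = float(mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    else:
        z_cc = (abs(u - mu) - 0.5) / np.sqrt(var)
        p = 2.0 * norm.sf(max(z_cc, 0.0))
    return min(p, 1.0), float(z)


def ranksum_rank(X, y, feature_names: list[str]) -> RankingResult:
    """Order features by ascending rank-sum p-value; ties by |z| descending,
    then catalog order."""
    X, y = _check_xy(X, y)
    pvals, zs = [], []
    for j in range(X.shape[1]):
        p, z = ranksum_pvalue(X[y == 1, j], X[y == 0, j])
        pvals.append(p)
        zs.append(z)
    order = sorted(range(X.shape[1]), key=lambda j: (pvals[j], -abs(zs[j]), j))
    return RankingResult(
        method="ranksum",
        ordered_features=[feature_names[j] for j in order],
        scores=[pvals[j] for j in order],
    )


def vip_scores(X: np.ndarray, y: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Variable importance in projection from a PLS fit of y on z-scored X.

    VIP_j = sqrt( p * sum_k SS_k (w_jk / ||w_k||)^2 / sum_k SS_k ) with
    SS_k = q_k^2 t_k' t_k the y-variance captured by component k.
    Satisfies (1/p) sum_j VIP_j^2 = 1.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if p < n_components:
        raise ValueError("need at least n_components features")
    n_components = min(n_components, n - 1, p)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-9 * (np.abs(mu) + 1.0)] = 1.0
    Xz = (X - mu) / sd
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xz, y.astype(float))
    W = pls.x_weights_  # (p, K)
    T = pls.x_scores_  # (n, K)
    q = pls.y_loadings_.ravel()  # (K,)
    ss = q**2 * np.sum(T**2, axis=0)
    wnorm2 = np.sum(W**2, axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    vip2 = p * (W**2 / wnorm2) @ ss / ss.sum()
    return np.sqrt(vip2)


def pls_vip_rank(X, y, feature_names: list[str], n_components: int = 2) -> RankingResult:
    """Order features by VIP descending; ties by catalog order."""
    vip = vip_scores(X, y, n_components=n_components)
    order = sorted(range(len(vip)), key=lambda j: (-vip[j], j))
    return RankingResult(
        method="pca_vip",
        ordered_features=[feature_names[j] for j in order],
        scores=[float(vip[j]) for j in order],
    )


def discretize(values: np.ndarray) -> np.ndarray:
    """Three-level discretization at mu +/- sigma into {-1, 0, +1}."""
    v = np.asarray(values, dtype=float)
    mu, sd = v.mean(), v.std()
    out = np.zeros(len(v), dtype=int)
    out[v < mu - sd] = -1
    out[v > mu + sd] = 1
    return out


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (bits) between two discrete label vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    n = len(a)
    mi = 0.0
    for va in np.unique(a):
        for vb in np.unique(b):
            pab = np.count_nonzero((a == va) & (b == vb)) / n
            if pab == 0:
                continue
            pa = np.count_nonzero(a == va) / n
            pb = np.count_nonzero(b == vb) / n
            mi += pab * np.log2(pab / (pa * pb))
    return max(mi, 0.0)


def mrmr_rank(
    X, y, feature_names: list[str], variant: str = "MID", k: int | None = None
) -> RankingResult:
    """Greedy minimum-redundancy maximum-relevance selection.

    The first feature maximizes MI with the class; thereafter MID
    maximizes I(j; c) - mean_s I(j; s) and MIQ maximizes
    I(j; c) / max(mean_s I(j; s), eps) over the selected set S.
    Ties break by catalog order.
    """
    if variant not in ("MID", "MIQ"):
        raise ValueError("variant must be MID or MIQ")
    X, y = _check_xy(X, y)
    p = X.shape[1]
    k = p if k is None else min(k, p)
    levels = np.column_stack([discretize(X[:, j]) for j in range(p)])
    relevance = np.array([mutual_information(levels[:, j], y) for j in range(p)])
    mi_cache: dict[tuple[int, int], float] = {}

    def pair_mi(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in mi_cache:
            mi_cache[key] = mutual_information(levels[:, key[0]], levels[:, key[1]])
        return mi_cache[key]

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(p))
    while remaining and len(selected) < k:
        best_j, best_score = None, -np.inf
        for j in remaining:
            if not selected:
                score = relevance[j]
            else:
                redundancy = float(np.mean([pair_mi(j, s) for s in selected]))
                if variant == "MID":
                    score = relevance[j] - redundancy
                else:
                    score = relevance[j] / max(redundancy, MRMR_EPS)
            if score > best_score:
                best_j, best_score = j, score
        selected.append(best_j)
        scores.append(float(best_score))
        remaining.remove(best_j)
    return RankingResult(
        method=f"mrmr_{variant.lower()}",
        ordered_features=[feature_names[j] for j in selected],
        scores=scores,
    )


def rank_features(
    method: str, X, y, feature_names: list[str], n_top: int | None = None
) -> RankingResult:
    """Dispatch to a ranker by name.

    `n_top` lets the greedy MRMR variants stop after the needed number
    of selections; the exhaustive rankers ignore it (their full ordering
    is cheap) and callers slice with `RankingResult.top`.
    """
    if method == "ranksum":
        return ranksum_rank(X, y, feature_names)
    if method == "pca_vip":
        return pls_vip_rank(X, y, feature_names)
    if method == "mrmr_mid":
        return mrmr_rank(X, y, feature_names, variant="MID", k=n_top)
    if method == "mrmr_miq":
        return mrmr_rank(X, y, feature_names, variant="MIQ", k=n_top)
    raise ValueError(f"unknown ranking method {method!r}")


RANKER_NAMES = ("ranksum", "pca_vip", "mrmr_mid", "mrmr_miq")
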
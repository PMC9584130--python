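"""Hidden-subgroup detection on composite-phenotype scores.

Subjects are clustered by k-means on their latent-variable scores, the
number of clusters is selected by a majority rule over classical validity
indices, cluster quality is summarized by silhouettes, and the two groups'
correlation networks are compared pairwise with Fisher's z test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .validity import INDEX_ROSTER, index_votes

logger = logging.getLogger(__name__)

__all__ = [
    "GroupAssignment",
    "CorrComparison",
    "kmeans_subjects",
    "select_k_majority",
    "silhouette_report",
    "group_lv_tests",
    "compare_correlations_fisher",
    "groupwise_correlation_matrices",
]


@dataclass
class GroupAssignment:
    """k-means partition of subjects on LV scores.

    ``labels`` are 1-based group ids, relabelled by descending group size
    (group 1 is the largest).
    """

    labels: pd.Series
    centroids: pd.DataFrame
    inertia: float
    silhouette_mean: float

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass(frozen=True)
class CorrComparison:
    """Fisher-z comparison of one correlation across two groups."""

    lv_pair: tuple[str, str]
    r1: float
    n1: int
    r2: float
    n2: int
    z_stat: float
    p: float


def _multicollinearity_guard(scores: pd.DataFrame) -> None:
    R = np.corrcoef(scores.values, rowvar=False)
    off = np.abs(R[np.triu_indices_from(R, k=1)])
    if off.size and off.max() > 0.5:
        warnings.warn(
            f"pairwise LV |r| up to {off.max():.2f} exceeds 0.5; k-means on "
            "these scores may be distorted by multicollinearity",
            UserWarning,
            stacklevel=3,
        )


def kmeans_subjects(
    scores: pd.DataFrame,
    k: int,
    *,
    seed: int = 0,
    n_restarts: int = 50,
) -> GroupAssignment:
    """Best-of-restarts k-means (k-means++ init) on LV scores.

    Emits a multicollinearity warning when any pairwise LV correlation
    exceeds 0.5 in absolute value before clustering.
    """
    n = len(scores)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of subjects {n}")
    _multicollinearity_guard(scores)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(scores.values)
    # relabel by descending size; ties broken by original label
    order = sorted(range(k), key=lambda c: (-(raw == c).sum(), c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=scores.index, name="group")
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=range(1, k + 1), columns=scores.columns
    )
    sil = silhouette_samples(scores.values, raw)
    return GroupAssignment(labels, centroids, float(km.inertia_), float(sil.mean()))


def select_k_majority(
    scores: pd.DataFrame,
    k_range: range | list[int] = range(2, 11),
    *,
    indices: list[str] | None = None,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[int, pd.Series]:
    """Choose the number of subject clusters by validity-index majority rule.

    Each index in the roster votes for its optimal k over ``k_range``; the
    modal k wins, ties going to the smallest k.  Indices that fail on
    degenerate data abstain (logged).  Returns ``(k, votes)`` where
    ``votes`` is the per-index vote tally.
    """
    ks = list(k_range)
    if min(ks) < 2 or max(ks) >= len(scores):
        raise ValueError("k_range must lie within {2..n-1}")
    names = list(INDEX_ROSTER) if indices is None else list(indices)
    if len(names) < 5:
        raise ValueError("need at least 5 validity indices for a majority rule")
    votes = index_votes(
        scores.values, ks, indices=names, seed=seed, n_restarts=n_restarts
    )
    abstained = [n for n, v in votes.items() if v is None]
    if abstained:
        logger.info("validity indices abstained: %s", abstained)
    cast = [v for v in votes.values() if v is not None]
    if not cast:
        raise ValueError("every validity index failed")
    counts = pd.Series(cast).value_counts()
    top = counts[counts == counts.max()].index.min()
    if counts.max() == 1:
        warnings.warn(
            "all validity indices disagree; falling back to the smallest "
            "voted k",
            UserWarning,
            stacklevel=2,
        )
    return int(top), pd.Series(votes, name="voted_k")


def silhouette_report(
    scores: pd.DataFrame, labels: pd.Series
) -> tuple[pd.Series, float]:
    """Per-subject silhouette values (Euclidean) and their mean.

    Subjects in singleton clusters get s(i) = 0 by convention (warned).
    """
    if labels.nunique() < 2:
        raise ValueError("need at least 2 groups for silhouettes")
    sizes = labels.value_counts()
    if (sizes == 1).any():
        warnings.warn("singleton cluster(s): silhouette set to 0", UserWarning, stacklevel=2)
    vals = silhouette_samples(scores.loc[labels.index].values, labels.values)
    s = pd.Series(vals, index=labels.index, name="silhouette")
    return s, float(s.mean())


def group_lv_tests(scores: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per LV between the two groups.

    Uses the Mann-Whitney U normal approximation with tie correction.
    Returns a DataFrame indexed by LV with ``statistic`` and ``p`` columns.
    """
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    g1 = scores.loc[labels[labels == groups[0]].index]
    g2 = scores.loc[labels[labels == groups[1]].index]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    rows = {}
    for lv in scores.columns:
        x, y = g1[lv].values, g2[lv].values
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            warnings.warn(f"{lv}: all observations equal; p = 1", UserWarning, stacklevel=2)
            rows[lv] = {"statistic": len(x) * len(y) / 2, "p": 1.0}
            continue
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        rows[lv] = {"statistic": float(res.statistic), "p": float(res.pvalue)}
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_correlations_fisher(
    r1: float, n1: int, r2: float, n2: int, lv_pair: tuple[str, str] = ("", "")
) -> CorrComparison:
    """Fisher z test for the difference of two independent correlations.

    ``z_i = atanh(r_i)``; the statistic ``(z1 - z2) / sqrt(1/(n1-3) +
    1/(n2-3))`` is referred to the standard normal, two-sided.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("each group needs n >= 4")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1 (Fisher transform diverges at 1)")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    z_stat = (z1 - z2) / se
    p = float(2 * stats.norm.sf(abs(z_stat)))
    return CorrComparison(lv_pair, float(r1), int(n1), float(r2), int(n2),
                          float(z_stat), max(p, np.finfo(float).tiny))


def groupwise_correlation_matrices(
    scores: pd.DataFrame, labels: pd.Series
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Per-group Pearson LV correlation matrices and all Fisher comparisons.

    Returns ``(matrices, comparisons)`` where ``comparisons`` holds one row
    per LV pair with the two correlations, the Fisher z statistic, the
    unadjusted p and its Benjamini-Hochberg adjustment (``p_bh``).
    """
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    mats: dict[int, pd.DataFrame] = {}
    ns: dict[int, int] = {}
    for g in groups:
        sub = scores.loc[labels[labels == g].index]
        if (sub.std(ddof=0) == 0).any():
            bad = sub.columns[sub.std(ddof=0) == 0].tolist()
            raise ValueError(f"constant LV(s) within group {g}: {bad}")
        mats[g] = sub.corr()
        ns[g] = len(sub)
    rows = []
    cols = list(scores.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            cmp = compare_correlations_fisher(
                mats[groups[0]].loc[a, b], ns[groups[0]],
                mats[groups[1]].loc[a, b], ns[groups[1]],
                lv_pair=(a, b),
            )
            rows.append(
                {
                    "lv_a": a, "lv_b": b, "r1": cmp.r1, "n1": cmp.n1,
                    "r2": cmp.r2, "n2": cmp.n2, "z_stat": cmp.z_stat, "p": cmp.p,
                }
            )
    comparisons = pd.DataFrame(rows)
    comparisons["p_bh"] = multipletests(comparisons["p"], method="fdr_bh")[1]
    return mats, comparisons
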
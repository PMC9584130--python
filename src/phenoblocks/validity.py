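"""Cluster-validity indices used by the majority-rule choice of k.

Twelve classical internal indices are implemented.  Each exposes a score
per candidate k and a decision rule (maximize, minimize, or an elbow/
threshold rule); the majority-rule selector lets each index cast one vote
for its optimal k.  Indices operating on pairwise distances share a single
precomputed distance matrix.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

__all__ = ["INDEX_ROSTER", "index_votes", "KMeansSweep"]


class KMeansSweep:
    """k-means solutions (labels, inertia, centroids) over a range of k.

    Includes k = 1 and k = max(k_range) + 1, which the elbow-style indices
    (Ball-Hall, Hartigan, Krzanowski-Lai, gap) need as context.
    """

    def __init__(self, X: np.ndarray, k_range: list[int], *, seed: int = 0,
                 n_restarts: int = 10):
        self.X = np.asarray(X, dtype=float)
        self.n, self.d = self.X.shape
        self.k_range = list(k_range)
        self.labels: dict[int, np.ndarray] = {}
        self.inertia: dict[int, float] = {}
        self.centroids: dict[int, np.ndarray] = {}
        mean = self.X.mean(axis=0)
        self.labels[1] = np.zeros(self.n, dtype=int)
        self.inertia[1] = float(((self.X - mean) ** 2).sum())
        self.centroids[1] = mean[None, :]
        for k in sorted(set(self.k_range + [max(self.k_range) + 1])):
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            self.labels[k] = km.fit_predict(self.X)
            self.inertia[k] = float(km.inertia_)
            self.centroids[k] = km.cluster_centers_

    # distance machinery shared by the pairwise indices --------------------
    _dists: np.ndarray | None = None

    @property
    def dists(self) -> np.ndarray:
        if self._dists is None:
            self._dists = pdist(self.X)
        return self._dists

    def within_mask(self, k: int) -> np.ndarray:
        """Condensed-form boolean mask of same-cluster pairs."""
        lab = self.labels[k]
        return squareform(lab[:, None] == lab[None, :], checks=False).astype(bool)


def _pair_sums(sweep: KMeansSweep, k: int):
    same = sweep.within_mask(k)
    d = sweep.dists
    s_w, n_w = d[same].sum(), int(same.sum())
    s_b, n_b = d[~same].sum(), int((~same).sum())
    return s_w, n_w, s_b, n_b


# ----- score curves ------------------------------------------------------

def _silhouette(sweep: KMeansSweep) -> dict[int, float]:
    return {k: silhouette_score(sweep.X, sweep.labels[k]) for k in sweep.k_range}


def _calinski_harabasz(sweep: KMeansSweep) -> dict[int, float]:
    return {k: calinski_harabasz_score(sweep.X, sweep.labels[k]) for k in sweep.k_range}


def _davies_bouldin(sweep: KMeansSweep) -> dict[int, float]:
    return {k: davies_bouldin_score(sweep.X, sweep.labels[k]) for k in sweep.k_range}


def _dunn(sweep: KMeansSweep) -> dict[int, float]:
    D = squareform(sweep.dists)
    out = {}
    for k in sweep.k_range:
        lab = sweep.labels[k]
        diam = max(D[np.ix_(lab == c, lab == c)].max() for c in np.unique(lab))
        sep = min(
            D[np.ix_(lab == a, lab == b)].min()
            for a in np.unique(lab) for b in np.unique(lab) if a < b
        )
        out[k] = sep / diam
    return out


def _c_index(sweep: KMeansSweep) -> dict[int, float]:
    d_sorted = np.sort(sweep.dists)
    csum = np.concatenate([[0.0], np.cumsum(d_sorted)])
    out = {}
    for k in sweep.k_range:
        s_w, n_w, _, _ = _pair_sums(sweep, k)
        s_min = csum[n_w]
        s_max = csum[-1] - csum[len(d_sorted) - n_w]
        out[k] = (s_w - s_min) / (s_max - s_min)
    return out


def _point_biserial(sweep: KMeansSweep) -> dict[int, float]:
    d = sweep.dists
    sd = d.std()
    n_t = len(d)
    out = {}
    for k in sweep.k_range:
        s_w, n_w, s_b, n_b = _pair_sums(sweep, k)
        out[k] = (s_b / n_b - s_w / n_w) * np.sqrt(n_w * n_b / n_t**2) / sd
    return out


def _mcclain_rao(sweep: KMeansSweep) -> dict[int, float]:
    out = {}
    for k in sweep.k_range:
        s_w, n_w, s_b, n_b = _pair_sums(sweep, k)
        out[k] = (s_w / n_w) / (s_b / n_b)
    return out


def _pbm(sweep: KMeansSweep) -> dict[int, float]:
    mean = sweep.X.mean(axis=0)
    e1 = float(np.linalg.norm(sweep.X - mean, axis=1).sum())
    out = {}
    for k in sweep.k_range:
        lab, cen = sweep.labels[k], sweep.centroids[k]
        ek = float(np.linalg.norm(sweep.X - cen[lab], axis=1).sum())
        dk = max(
            np.linalg.norm(cen[a] - cen[b])
            for a in range(k) for b in range(k) if a < b
        )
        out[k] = (e1 * dk / (ek * k)) ** 2
    return out


def _ball_hall(sweep: KMeansSweep) -> dict[int, float]:
    return {k: sweep.inertia[k] / k for k in [1] + sweep.k_range}


def _hartigan(sweep: KMeansSweep) -> dict[int, float]:
    return {
        k: (sweep.inertia[k] / sweep.inertia[k + 1] - 1) * (sweep.n - k - 1)
        for k in sweep.k_range
    }


def _krzanowski_lai(sweep: KMeansSweep) -> dict[int, float]:
    d = sweep.d

    def diff(k: int) -> float:
        return (k - 1) ** (2 / d) * sweep.inertia[k - 1] - k ** (2 / d) * sweep.inertia[k]

    return {
        k: abs(diff(k)) / abs(diff(k + 1))
        for k in sweep.k_range
        if k + 1 in sweep.inertia and diff(k + 1) != 0
    }


def _gap(sweep: KMeansSweep, *, n_refs: int = 10, seed: int = 0):
    """Gap statistic curves (gap, s) over k_range plus the trailing k."""
    rng = np.random.default_rng(seed)
    X = sweep.X
    # PCA-aligned bounding box reference (Tibshirani et al.)
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)
    ks = sorted(set(sweep.k_range + [max(sweep.k_range) + 1]))
    log_w_ref = {k: [] for k in ks}
    for _ in range(n_refs):
        Z = rng.uniform(lo, hi, size=Xp.shape) @ Vt
        for k in ks:
            km = KMeans(n_clusters=k, n_init=1, random_state=seed)
            km.fit(Z)
            log_w_ref[k].append(np.log(km.inertia_))
    gap, s = {}, {}
    for k in ks:
        ref = np.asarray(log_w_ref[k])
        gap[k] = float(ref.mean() - np.log(sweep.inertia[k]))
        s[k] = float(ref.std(ddof=0) * np.sqrt(1 + 1 / n_refs))
    return gap, s


# ----- votes -------------------------------------------------------------

def _vote_max(scores: dict[int, float], ks: list[int]) -> int:
    return min((k for k in ks if k in scores), key=lambda k: (-scores[k], k))


def _vote_min(scores: dict[int, float], ks: list[int]) -> int:
    return min((k for k in ks if k in scores), key=lambda k: (scores[k], k))


def _vote_silhouette(sweep):
    return _vote_max(_silhouette(sweep), sweep.k_range)


def _vote_ch(sweep):
    return _vote_max(_calinski_harabasz(sweep), sweep.k_range)


def _vote_db(sweep):
    return _vote_min(_davies_bouldin(sweep), sweep.k_range)


def _vote_dunn(sweep):
    return _vote_max(_dunn(sweep), sweep.k_range)


def _vote_c_index(sweep):
    return _vote_min(_c_index(sweep), sweep.k_range)


def _vote_point_biserial(sweep):
    return _vote_max(_point_biserial(sweep), sweep.k_range)


def _vote_mcclain_rao(sweep):
    return _vote_min(_mcclain_rao(sweep), sweep.k_range)


def _vote_pbm(sweep):
    return _vote_max(_pbm(sweep), sweep.k_range)


def _vote_ball_hall(sweep):
    bh = _ball_hall(sweep)
    # largest drop between successive levels marks the elbow
    drops = {k: bh[k - 1] - bh[k] for k in sweep.k_range if k - 1 in bh}
    return _vote_max(drops, sweep.k_range)


def _vote_hartigan(sweep, threshold: float = 10.0):
    h = _hartigan(sweep)
    small = [k for k in sweep.k_range if h[k] <= threshold]
    return small[0] if small else _vote_min(h, sweep.k_range)


def _vote_krzanowski_lai(sweep):
    return _vote_max(_krzanowski_lai(sweep), sweep.k_range)


def _vote_gap(sweep):
    gap, s = _gap(sweep, seed=0)
    for k in sweep.k_range:
        if gap[k] >= gap[k + 1] - s[k + 1]:
            return k
    return _vote_max(gap, sweep.k_range)


INDEX_ROSTER: dict[str, callable] = {
    "silhouette": _vote_silhouette,
    "calinski_harabasz": _vote_ch,
    "davies_bouldin": _vote_db,
    "dunn": _vote_dunn,
    "c_index": _vote_c_index,
    "point_biserial": _vote_point_biserial,
    "mcclain_rao": _vote_mcclain_rao,
    "pbm": _vote_pbm,
    "ball_hall": _vote_ball_hall,
    "hartigan": _vote_hartigan,
    "krzanowski_lai": _vote_krzanowski_lai,
    "gap": _vote_gap,
}


def index_votes(
    X: np.ndarray,
    k_range: list[int],
    *,
    indices: list[str] | None = None,
    seed: int = 0,
    n_restarts: int = 10,
) -> dict[str, int | None]:
    """One vote (optimal k) per validity index; failures abstain with None."""
    names = list(INDEX_ROSTER) if indices is None else indices
    sweep = KMeansSweep(X, k_range, seed=seed, n_restarts=n_restarts)
    votes: dict[str, int | None] = {}
    for name in names:
        try:
            votes[name] = int(INDEX_ROSTER[name](sweep))
        except Exception:  # degenerate data: the index abstains
            votes[name] = None
    return votes
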
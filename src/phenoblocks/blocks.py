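"""Discovery of composite-phenotype structure by spectral clustering of traits.

The trait panel is grouped into blocks by running normalized spectral
clustering on a k-nearest-neighbour graph whose edge weights are absolute
Spearman correlations between per-subject change scores.  The number of
blocks is chosen by the maximum eigenvalue gap of the symmetric normalized
graph Laplacian.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "BlockStructure",
    "AffinityGraph",
    "SpectralEmbedding",
    "spearman_similarity",
    "knn_affinity",
    "spectral_embed",
    "select_k_eigengap",
    "spectral_cluster",
    "discover_blocks",
]


@dataclass(frozen=True)
class BlockStructure:
    """Partition of traits into blocks (the composite-phenotype structure).

    ``assignment`` maps each trait name to a block id; block ids are
    contiguous integers ``1..n_blocks``.
    """

    assignment: dict[str, int]

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"block ids must be contiguous 1..B, got {ids}")

    @property
    def n_blocks(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def traits(self) -> list[str]:
        return list(self.assignment)

    def members(self, block_id: int) -> list[str]:
        """Traits belonging to ``block_id``, in trait order."""
        return [t for t, b in self.assignment.items() if b == block_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trait": list(self.assignment), "block_id": list(self.assignment.values())}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BlockStructure":
        return cls(dict(zip(df["trait"].astype(str), df["block_id"].astype(int))))

    @classmethod
    def from_labels(cls, traits: list[str], labels: np.ndarray) -> "BlockStructure":
        """Build from raw integer labels, relabelled to contiguous ids
        ordered by first trait occurrence."""
        remap: dict[int, int] = {}
        for lab in labels:
            if lab not in remap:
                remap[lab] = len(remap) + 1
        return cls({t: remap[lab] for t, lab in zip(traits, labels)})


@dataclass(frozen=True)
class AffinityGraph:
    """kNN-filtered similarity graph over traits.

    ``weights`` is symmetric with zero diagonal; ``degrees`` are the row sums.
    """

    weights: pd.DataFrame
    k_nn: int

    @property
    def degrees(self) -> pd.Series:
        return self.weights.sum(axis=1)


@dataclass(frozen=True)
class SpectralEmbedding:
    """Eigendecomposition of the symmetric normalized Laplacian.

    Eigenvalues are ascending and lie in [0, 2]; eigenvectors are the
    matching columns (traits x p).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    traits: list[str] = field(default_factory=list)


def spearman_similarity(change: pd.DataFrame) -> pd.DataFrame:
    """Absolute Spearman correlation matrix of trait change scores.

    Average ranks are used for ties.  Raises for constant traits (the
    correlation is undefined there).
    """
    if len(change) < 3:
        raise ValueError("need at least 3 subjects for a Spearman similarity")
    sds = change.std(axis=0, ddof=0)
    constant = sds.index[sds.values == 0].tolist()
    if constant:
        raise ValueError(f"constant trait(s) have undefined correlation: {constant}")
    rho = stats.spearmanr(change.values, axis=0).statistic
    rho = np.atleast_2d(rho)
    S = np.abs(rho)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=change.columns, columns=change.columns)


def knn_affinity(S: pd.DataFrame, k_nn: int = 7) -> AffinityGraph:
    """Sparsify a similarity matrix with a union-symmetrized kNN filter.

    An edge (j, k) survives when k is among j's ``k_nn`` most similar traits
    or j is among k's.  Ties in similarity are broken deterministically by
    trait order.  The diagonal is zeroed.
    """
    p = S.shape[0]
    if not 1 <= k_nn <= p - 1:
        raise ValueError(f"k_nn must be in [1, {p - 1}], got {k_nn}")
    A = S.values.copy().astype(float)
    np.fill_diagonal(A, 0.0)
    keep = np.zeros_like(A, dtype=bool)
    for j in range(p):
        # stable argsort on -similarity -> ties resolved by trait order
        order = np.argsort(-A[j], kind="stable")
        order = order[order != j]
        keep[j, order[:k_nn]] = True
    keep |= keep.T  # union symmetrization
    W = np.where(keep, A, 0.0)
    graph = AffinityGraph(pd.DataFrame(W, index=S.index, columns=S.columns), k_nn)
    deg = graph.degrees.values
    if _n_components(W) > 1:
        warnings.warn(
            "kNN affinity graph is disconnected; the eigengap will reflect "
            "its components",
            UserWarning,
            stacklevel=2,
        )
    if np.any(deg == 0):
        isolated = graph.weights.index[deg == 0].tolist()
        warnings.warn(f"isolated traits with zero degree: {isolated}", UserWarning, stacklevel=2)
    return graph


def _n_components(W: np.ndarray) -> int:
    from scipy.sparse.csgraph import connected_components

    return connected_components((W > 0).astype(int), directed=False)[0]


def spectral_embed(graph: AffinityGraph) -> SpectralEmbedding:
    """Eigendecompose ``L_sym = I - D^{-1/2} W D^{-1/2}``.

    Raises when any vertex has zero degree (its normalization is undefined).
    """
    W = graph.weights.values
    d = W.sum(axis=1)
    if np.any(d <= 0):
        isolated = graph.weights.index[d <= 0].tolist()
        raise ValueError(f"zero-degree traits make L_sym undefined: {isolated}")
    d_isqrt = 1.0 / np.sqrt(d)
    L = np.eye(len(d)) - d_isqrt[:, None] * W * d_isqrt[None, :]
    L = (L + L.T) / 2.0
    evals, evecs = np.linalg.eigh(L)
    evals = np.clip(evals, 0.0, 2.0)
    return SpectralEmbedding(evals, evecs, list(graph.weights.index))


def select_k_eigengap(emb: SpectralEmbedding, k_max: int | None = None) -> int:
    """Number of clusters by the maximum eigenvalue-gap criterion.

    Returns the k in ``{2..k_max}`` maximizing ``gamma_{k+1} - gamma_k`` on
    the ascending Laplacian spectrum; ties go to the smallest k.  A one-block
    solution is uninformative, so the search starts at 2.
    """
    p = len(emb.eigenvalues)
    if k_max is None:
        k_max = p - 1
    if not 2 <= k_max <= p - 1:
        raise ValueError(f"k_max must be in [2, {p - 1}], got {k_max}")
    ks = np.arange(2, k_max + 1)
    gaps = emb.eigenvalues[ks] - emb.eigenvalues[ks - 1]  # gamma_{k+1} - gamma_k, 1-based
    # ties (within float tolerance) resolve to the smallest k
    tied = np.nonzero(gaps >= gaps.max() - 1e-9)[0]
    return int(ks[tied[0]])


def spectral_cluster(
    emb: SpectralEmbedding,
    k: int,
    *,
    seed: int = 0,
    n_restarts: int = 50,
) -> BlockStructure:
    """k-means on the row-normalized first-k eigenvector matrix.

    Rows of the traits x k eigenvector matrix are scaled to unit length
    (degenerate all-zero rows are left unnormalized with a warning), then
    clustered by best-of-``n_restarts`` k-means.  Labels are relabelled to
    contiguous block ids ordered by first trait occurrence.
    """
    p = len(emb.traits)
    if not 2 <= k <= p:
        raise ValueError(f"k must be in [2, {p}], got {k}")
    U = emb.eigenvectors[:, :k].copy()
    norms = np.linalg.norm(U, axis=1)
    zero = norms < 1e-12
    if zero.any():
        warnings.warn(
            f"all-zero embedding row(s) left unnormalized: "
            f"{[emb.traits[i] for i in np.where(zero)[0]]}",
            UserWarning,
            stacklevel=2,
        )
        norms[zero] = 1.0
    U /= norms[:, None]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(U)
    return BlockStructure.from_labels(emb.traits, labels)


def discover_blocks(
    change: pd.DataFrame,
    *,
    k_nn: int = 7,
    k: int | None = None,
    k_max: int | None = None,
    seed: int = 0,
    n_restarts: int = 50,
) -> tuple[BlockStructure, SpectralEmbedding]:
    """Full trait-clustering pipeline: similarity -> kNN -> Laplacian -> k-means.

    When ``k`` is None the cluster count is chosen by the eigengap criterion.
    Returns the block structure together with the spectral embedding (whose
    eigenvalues carry the gap diagnostics).
    """
    S = spearman_similarity(change)
    graph = knn_affinity(S, k_nn)
    emb = spectral_embed(graph)
    if k is None:
        k = select_k_eigengap(emb, k_max)
        logger.info("eigengap selected k=%d blocks", k)
    structure = spectral_cluster(emb, k, seed=seed, n_restarts=n_restarts)
    return structure, emb
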
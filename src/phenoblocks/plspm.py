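"""Partial least squares path modeling of composite phenotypes.

Each trait block is treated as a reflective (mode A) block of manifest
variables whose latent variable — the composite phenotype — is estimated by
the classical Lohmöller alternating algorithm: outer estimation standardizes
``X_b w_b``, inner estimation combines adjacent latent scores under the
centroid scheme (signs of their correlations), and mode-A weights are
updated as correlations of the manifest variables with the inner estimate.
Block unidimensionality is diagnosed with standardized Cronbach's alpha,
Dillon-Goldstein's rho and the leading eigenvalues of the block correlation
matrix.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blocks import BlockStructure

logger = logging.getLogger(__name__)

__all__ = [
    "PathModel",
    "PLSPMModel",
    "UnidimReport",
    "build_default_path_model",
    "align_signs",
    "fit_plspm",
    "unidimensionality",
    "unidimensionality_report",
]


@dataclass(frozen=True)
class PathModel:
    """Inner (structural) model over latent variables.

    ``path.loc[i, j] = True`` means LV j is a predecessor of LV i (column
    causes row).  The directed graph must be acyclic.  ``modes`` maps block
    id to 'A' (reflective) — mode B is not implemented.  ``scheme`` is the
    inner weighting scheme; only 'centroid' is supported.
    """

    blocks: BlockStructure
    path: pd.DataFrame
    modes: dict[int, str] = field(default_factory=dict)
    scheme: str = "centroid"

    def __post_init__(self) -> None:
        ids = sorted(set(self.blocks.assignment.values()))
        if list(self.path.index) != ids or list(self.path.columns) != ids:
            raise ValueError("path matrix must be indexed by the block ids")
        if self.path.values.diagonal().any():
            raise ValueError("self-loops are not allowed in the path matrix")
        if _has_cycle(self.path.values.astype(bool)):
            raise ValueError("path matrix contains a cycle")
        if len(ids) >= 2 and not (self.path.values.any(axis=0) | self.path.values.any(axis=1)).all():
            raise ValueError("every latent variable must appear in at least one path arc")
        for b, m in self.modes.items():
            if m != "A":
                raise NotImplementedError(f"block {b}: only mode A is implemented")
        if self.scheme != "centroid":
            raise NotImplementedError(f"inner scheme {self.scheme!r} not implemented")

    @property
    def adjacency(self) -> np.ndarray:
        """Symmetric LV adjacency used by the inner estimation."""
        A = self.path.values.astype(bool)
        return A | A.T


def _has_cycle(A: np.ndarray) -> bool:
    # Kahn's algorithm on the arc set {j -> i : A[i, j]}
    indeg = A.sum(axis=1).astype(int)
    queue = [i for i in range(len(A)) if indeg[i] == 0]
    seen = 0
    A = A.copy()
    while queue:
        j = queue.pop()
        seen += 1
        for i in np.where(A[:, j])[0]:
            A[i, j] = False
            indeg[i] -= 1
            if indeg[i] == 0:
                queue.append(i)
    return seen < len(A)


def build_default_path_model(
    blocks: BlockStructure, target_block: int | str = "SPO2"
) -> PathModel:
    """Star-shaped inner model: every other LV has a single arc into the target.

    ``target_block`` may be a block id or the name of a trait whose block is
    the target (default the oxygen-saturation trait).  All blocks are mode A
    and the centroid scheme is used.
    """
    if isinstance(target_block, str):
        if target_block not in blocks.assignment:
            raise KeyError(f"unknown trait {target_block!r}")
        target_block = blocks.assignment[target_block]
    ids = sorted(set(blocks.assignment.values()))
    if target_block not in ids:
        raise KeyError(f"unknown block id {target_block}")
    path = pd.DataFrame(False, index=ids, columns=ids)
    for b in ids:
        if b != target_block:
            path.loc[target_block, b] = True
    return PathModel(blocks, path, modes={b: "A" for b in ids}, scheme="centroid")


def align_signs(
    change: pd.DataFrame, blocks: BlockStructure
) -> tuple[pd.DataFrame, list[str]]:
    """Flip manifest variables so every block loads positively on its first
    principal axis.

    Within each multi-trait block, the first principal component of the
    block correlation matrix is oriented so the majority of its loadings are
    positive; traits with a negative loading are multiplied by -1.  When the
    split is even (e.g. two anti-correlated pairs) the orientation is
    ambiguous; the convention is to flip the half containing the block's
    first trait.  Returns the aligned change table and the list of flipped
    traits (also logged).  Applying the operation twice is the identity.
    """
    missing = [t for t in blocks.traits if t not in change.columns]
    if missing:
        raise ValueError(f"blocks reference traits absent from the table: {missing}")
    out = change.copy()
    flipped: list[str] = []
    for b in range(1, blocks.n_blocks + 1):
        members = blocks.members(b)
        if len(members) < 2:
            continue
        R = np.corrcoef(out[members].values, rowvar=False)
        pc1 = _top_eigvec(R)
        n_pos, n_neg = int(np.sum(pc1 >= 0)), int(np.sum(pc1 < 0))
        if n_pos < n_neg or (n_pos == n_neg and pc1[0] >= 0):
            pc1 = -pc1
        for t, load in zip(members, pc1):
            if load < 0:
                out[t] = -out[t]
                flipped.append(t)
    if flipped:
        logger.info("sign-aligned (multiplied by -1): %s", flipped)
    return out, flipped


def _top_eigvec(R: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue of a correlation matrix.

    A (near-)degenerate top eigenspace — e.g. mutually uncorrelated traits —
    leaves the principal axis undefined; the tie is broken toward the
    equal-weight composite by projecting the all-ones direction onto the
    top eigenspace.
    """
    evals, evecs = np.linalg.eigh(R)
    top = evals >= evals[-1] - 1e-10
    if top.sum() > 1:
        proj = evecs[:, top] @ (evecs[:, top].T @ np.ones(len(R)))
        norm = np.linalg.norm(proj)
        if norm > 1e-12:
            return proj / norm
    return evecs[:, -1]


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance manifest variable")
    return (X - X.mean(axis=0)) / sd


@dataclass
class PLSPMModel:
    """Fitted PLSPM: outer weights, loadings and latent-variable scores.

    ``lv_scores`` is subjects x LVs with columns ``LV1..LVB``; each column
    has mean 0 and SD 1 (population convention).  ``outer_weights`` and
    ``loadings`` are per-manifest-variable Series; loadings are the
    correlations of each manifest variable with its block's LV score.
    """

    outer_weights: pd.Series
    loadings: pd.Series
    lv_scores: pd.DataFrame
    converged: bool
    n_iter: int
    model: PathModel


def fit_plspm(
    change: pd.DataFrame,
    model: PathModel,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PLSPMModel:
    """Estimate latent-variable scores by the Lohmöller alternating algorithm.

    Manifest variables are standardized; outer weights start at 1; the loop
    alternates outer estimation (standardize ``X_b w_b``), centroid inner
    estimation (sum of adjacent LV scores weighted by correlation signs) and
    mode-A weight updates (``w_b = corr(X_b, Z_b)``) until the largest
    weight change falls below ``tol`` or ``max_iter`` is hit (then
    ``converged=False`` with a warning and the last iterate is returned).
    Single-variable blocks bypass the iteration: their LV is the
    standardized variable itself with loading 1.  LV score signs are flipped
    so the majority of each block's loadings are positive.
    """
    blocks = model.blocks
    ids = sorted(set(blocks.assignment.values()))
    members = {b: blocks.members(b) for b in ids}
    X = {b: _standardize(change[members[b]].values.astype(float)) for b in ids}
    n = len(change)
    adj = model.adjacency

    W = {b: np.ones(len(members[b])) for b in ids}
    Y = np.column_stack([_standardize((X[b] @ W[b])[:, None])[:, 0] for b in ids])
    multi = [i for i, b in enumerate(ids) if len(members[b]) > 1]

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        delta = 0.0
        C = np.corrcoef(Y, rowvar=False)
        # centroid scheme: adjacent LVs weighted by the sign of their correlation
        E = np.where(adj, np.sign(C), 0.0)
        Z = Y @ E.T
        for i in multi:
            b = ids[i]
            w_new = (X[b].T @ _standardize(Z[:, [i]])[:, 0]) / n  # corr: both standardized
            delta = max(delta, float(np.max(np.abs(w_new - W[b]))))
            W[b] = w_new
            Y[:, i] = _standardize((X[b] @ w_new)[:, None])[:, 0]
        if delta < tol:
            converged = True
            break
    if not converged and multi:
        warnings.warn(
            f"PLSPM did not converge in {max_iter} iterations "
            f"(last max weight change {delta:.2e})",
            UserWarning,
            stacklevel=2,
        )
    if not multi:
        converged = True

    weights, loadings = {}, {}
    for i, b in enumerate(ids):
        lam = (X[b].T @ Y[:, i]) / n
        if np.sum(lam > 0) < np.sum(lam < 0):
            Y[:, i] = -Y[:, i]
            W[b] = -W[b]
            lam = -lam
        for t, w_t, l_t in zip(members[b], W[b], lam):
            weights[t] = float(w_t)
            loadings[t] = float(l_t)

    lv_scores = pd.DataFrame(
        Y, index=change.index, columns=[f"LV{b}" for b in ids]
    )
    order = list(change.columns[change.columns.isin(weights)])
    return PLSPMModel(
        outer_weights=pd.Series(weights).reindex(order),
        loadings=pd.Series(loadings).reindex(order),
        lv_scores=lv_scores,
        converged=converged,
        n_iter=it,
        model=model,
    )


@dataclass(frozen=True)
class UnidimReport:
    """Unidimensionality diagnostics of one reflective block."""

    c_alpha: float
    dg_rho: float
    eig_1st: float
    eig_2nd: float
    n_mvs: int


def unidimensionality(change: pd.DataFrame, block: list[str]) -> UnidimReport:
    """Standardized alpha, Dillon-Goldstein's rho and leading eigenvalues.

    For k manifest variables with mean off-diagonal correlation ``r_bar``
    (after sign alignment toward the first principal axis):
    ``alpha = k*r_bar / (1 + (k-1)*r_bar)``; ``rho`` uses the first-principal-
    component loadings ``lam_j``: ``(sum lam)^2 / ((sum lam)^2 + sum(1 -
    lam^2))``; the eigenvalues are those of the block correlation matrix
    (sign flips leave them unchanged).  A single-variable block is perfectly
    unidimensional: ``(1, 1, 1, 0)``.
    """
    if not block:
        raise ValueError("empty block")
    k = len(block)
    if k == 1:
        return UnidimReport(1.0, 1.0, 1.0, 0.0, 1)
    sub = change[block]
    if (sub.std(axis=0, ddof=0) == 0).any():
        bad = sub.columns[(sub.std(axis=0, ddof=0) == 0)].tolist()
        raise ValueError(f"zero-variance trait(s): {bad}")
    R = np.corrcoef(sub.values, rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(R))[::-1]
    # sign-align via PC1 of R, then mean off-diagonal correlation
    pc1 = _top_eigvec(R)
    if pc1.sum() < 0:
        pc1 = -pc1
    signs = np.where(pc1 < 0, -1.0, 1.0)
    R_aligned = R * np.outer(signs, signs)
    r_bar = (R_aligned.sum() - k) / (k * (k - 1))
    c_alpha = k * r_bar / (1 + (k - 1) * r_bar)
    lam = np.abs(pc1) * np.sqrt(evals[0])  # PC1 loadings, positive after alignment
    s = lam.sum()
    dg_rho = s**2 / (s**2 + np.sum(1 - lam**2))
    return UnidimReport(
        float(c_alpha), float(dg_rho), float(evals[0]),
        float(evals[1]) if k > 1 else 0.0, k,
    )


def unidimensionality_report(
    change: pd.DataFrame, blocks: BlockStructure
) -> pd.DataFrame:
    """One diagnostics row per block (index ``LV1..LVB``)."""
    rows = {}
    for b in range(1, blocks.n_blocks + 1):
        rep = unidimensionality(change, blocks.members(b))
        rows[f"LV{b}"] = {
            "manifest_variables": ", ".join(blocks.members(b)),
            "mode": "A",
            "n_mvs": rep.n_mvs,
            "c_alpha": rep.c_alpha,
            "dg_rho": rep.dg_rho,
            "eig_1st": rep.eig_1st,
            "eig_2nd": rep.eig_2nd,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
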
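"""Similarity integration, label propagation and score fusion.

The miRNA-side and disease-side similarity components are blended into one
matrix per side, row-normalised into stochastic transition operators, and
labels (the known causal adjacency) are diffused over each side separately:

    F  <-  alpha * W @ F + (1 - alpha) * Y ,   F0 = Y

which converges to the closed form ``(1 - alpha) (I - alpha W)^-1 Y`` for
``alpha < 1``.  The final score of a miRNA-disease pair is the mean of the
two sides' propagation results.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import numpy as np

from .data import BipartiteNetwork
from .errors import AlignmentError, ConvergenceError, DataFormatError, MdcapError
from .similarity import SimilarityMatrix

ROW_SUM_TOL = 1e-10


@dataclass
class TransitionMatrix:
    """Row-stochastic propagation operator with entity labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DataFormatError("transition matrix shape does not match labels")
        if (self.values < 0).any():
            raise MdcapError("transition matrix has negative entries")
        row_sums = self.values.sum(axis=1)
        if np.abs(row_sums - 1.0).max() > ROW_SUM_TOL:
            raise MdcapError("transition matrix rows do not sum to 1")


@dataclass
class ScoreMatrix:
    """Fused prediction scores in [0, 1] for every miRNA-disease pair."""

    mirnas: list[str]
    diseases: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirnas), len(self.diseases)):
            raise DataFormatError("score matrix shape does not match labels")
        if not np.isfinite(self.values).all():
            raise MdcapError("score matrix contains non-finite values")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise MdcapError("scores outside [0, 1]")

    def score(self, mirna: str, disease: str) -> float:
        return float(
            self.values[self.mirnas.index(mirna), self.diseases.index(disease)]
        )


def integrate(
    primary_sim: SimilarityMatrix,
    gip: SimilarityMatrix,
    hpi: SimilarityMatrix,
    mix_weight: float = 0.5,
    hpi_weight: float = 0.5,
) -> SimilarityMatrix:
    """Blend a primary (semantic/functional) kernel with GIP, then with HPI.

    Where the primary kernel is defined the blend is
    ``w * primary + (1 - w) * gip``; undefined entries fall back to GIP alone.
    The result is then adjusted towards the hub promoted index:
    ``(1 - lambda) * S + lambda * HPI``.
    """
    for m, w in ((gip, "gip"), (hpi, "hpi")):
        if list(m.labels) != list(primary_sim.labels):
            raise AlignmentError(f"{w} labels do not match the primary similarity")
    if not (0 <= mix_weight <= 1 and 0 <= hpi_weight <= 1):
        raise MdcapError("mix_weight and hpi_weight must lie in [0, 1]")
    p, g, h = primary_sim.values, gip.values, hpi.values
    base = np.where(np.isnan(p), g, mix_weight * p + (1 - mix_weight) * g)
    S = (1 - hpi_weight) * base + hpi_weight * h
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(list(primary_sim.labels), S, kind="integrated")


def row_normalize(sim: SimilarityMatrix) -> TransitionMatrix:
    """Divide each row by its sum; a zero row becomes a unit self-loop.

    Self-loops (rather than uniform rows) keep isolated entities from leaking
    label mass to unrelated entities.
    """
    v = np.nan_to_num(sim.values, nan=0.0)
    if (v < 0).any():
        raise MdcapError("cannot normalise a matrix with negative entries")
    row_sums = v.sum(axis=1)
    W = np.array(v, dtype=float)
    zero = row_sums == 0
    nz = ~zero
    W[nz] = W[nz] / row_sums[nz, None]
    if zero.any():
        W[zero] = 0.0
        W[zero, np.flatnonzero(zero)] = 1.0
    return TransitionMatrix(list(sim.labels), W)


def label_propagate(
    W: TransitionMatrix,
    Y: np.ndarray,
    alpha: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Iterate ``F <- alpha W F + (1 - alpha) Y`` from ``F0 = Y`` to convergence.

    For binary ``Y`` and row-stochastic ``W`` the fixed point lies in [0, 1]
    elementwise (a convex geometric series of stochastic averages).  Raises
    :class:`ConvergenceError` carrying the last residual if the max-abs change
    is still above ``tol`` after ``max_iter`` sweeps.
    """
    if not 0 <= alpha < 1:
        raise MdcapError(f"alpha must be in [0, 1), got {alpha}")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != W.values.shape[0]:
        raise DataFormatError("label matrix rows do not match the operator")
    if alpha == 0:
        return Y.copy()
    F = Y.copy()
    residual = np.inf
    for _ in range(max_iter):
        F_next = alpha * (W.values @ F) + (1 - alpha) * Y
        residual = float(np.abs(F_next - F).max())
        F = F_next
        if residual < tol:
            return F
    raise ConvergenceError(
        f"label propagation residual {residual:.3g} > tol {tol:.3g} "
        f"after {max_iter} iterations",
        residual=residual,
    )


def label_propagate_closed_form(
    W: TransitionMatrix, Y: np.ndarray, alpha: float
) -> np.ndarray:
    """Direct solve of the propagation fixed point, ``(1-a)(I - aW)^-1 Y``."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = W.values.shape[0]
    return (1 - alpha) * np.linalg.solve(np.eye(n) - alpha * W.values, Y)


def fuse_scores(
    F_mirna_side: np.ndarray,
    F_disease_side: np.ndarray,
    mirnas: list[str],
    diseases: list[str],
) -> ScoreMatrix:
    """Elementwise mean of the two propagation results (both oriented m x d)."""
    A = np.asarray(F_mirna_side, dtype=float)
    B = np.asarray(F_disease_side, dtype=float)
    if A.shape != B.shape:
        raise DataFormatError(f"shape mismatch: {A.shape} vs {B.shape}")
    return ScoreMatrix(mirnas, diseases, (A + B) / 2.0)


def rank_candidates(
    scores: ScoreMatrix,
    net: BipartiteNetwork,
    query: str,
    top_k: int | None = None,
    exclude_known: bool = True,
) -> list[tuple[str, float, int]]:
    """Rank partners of a query miRNA (over diseases) or disease (over miRNAs).

    Descending by score with lexicographic tie-break; known causal pairs are
    dropped first when ``exclude_known`` is set.  Returns (entity, score,
    rank) triples with 1-based ranks.
    """
    if query in scores.mirnas:
        i = scores.mirnas.index(query)
        entities = scores.diseases
        vals = scores.values[i, :]
        known = {d for m, d in net.edges() if m == query}
    elif query in scores.diseases:
        j = scores.diseases.index(query)
        entities = scores.mirnas
        vals = scores.values[:, j]
        known = {m for m, d in net.edges() if d == query}
    else:
        close = difflib.get_close_matches(query, scores.mirnas + scores.diseases, n=3)
        raise MdcapError(
            f"query {query!r} not found among miRNAs or diseases"
            + (f"; did you mean: {', '.join(close)}?" if close else "")
        )
    pairs = [
        (name, float(v))
        for name, v in zip(entities, vals)
        if not (exclude_known and name in known)
    ]
    pairs.sort(key=lambda t: (-t[1], t[0]))
    if top_k is not None:
        pairs = pairs[:top_k]
    return [(name, v, r) for r, (name, v) in enumerate(pairs, start=1)]
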
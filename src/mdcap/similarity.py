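"""Similarity kernels on the causal network.

Four components feed the propagation operators:

* **Disease semantic similarity** — Wang-style DAG similarity on MeSH tree
  numbers.  Each disease induces a set of ancestor terms; a term's semantic
  contribution decays by a factor ``delta`` per edge up the hierarchy (1 at the
  disease's own node, max over paths/positions elsewhere).  The similarity of
  two diseases is the summed contribution of their shared terms relative to
  their total semantic values.
* **miRNA functional similarity** — MISIM best-match-average: two miRNAs are
  similar when each disease in one miRNA's causal disease set has a close
  semantic match in the other's.
* **Gaussian interaction profile (GIP) kernel** — an RBF kernel on the binary
  interaction profiles (rows/columns of the adjacency), with the bandwidth
  normalised by the mean squared profile norm.
* **Hub promoted index (HPI)** — neighbourhood overlap divided by the smaller
  degree, which favours links to hubs.

Entries that cannot be computed (diseases absent from the ontology, miRNAs
with no profiled disease) are NaN, never 0: a missing value must not assert
dissimilarity, and integration later falls back to the GIP kernel there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import BipartiteNetwork, DiseaseOntology
from .errors import DataFormatError, MdcapError, NoOntologyError

SYMMETRY_TOL = 1e-12


@dataclass
class SimilarityMatrix:
    """A labelled square similarity matrix with values in [0, 1] (NaN = undefined)."""

    labels: list[str]
    values: np.ndarray
    kind: str = "integrated"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DataFormatError("similarity matrix shape does not match labels")
        self.validate()

    def validate(self):
        v = self.values
        finite = ~np.isnan(v)
        if finite.any() and ((v[finite] < -SYMMETRY_TOL).any() or (v[finite] > 1 + 1e-9).any()):
            raise MdcapError(f"{self.kind} similarity entries outside [0, 1]")
        diff = np.abs(v - v.T)
        defined = ~np.isnan(diff)
        asym = diff[defined].max() if defined.any() else 0.0
        mismatch = (np.isnan(v) != np.isnan(v.T)).any()
        if mismatch or asym > 1e-9:
            raise MdcapError(f"{self.kind} similarity matrix is not symmetric")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_tsv(self, path: str | Path):
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "integrated") -> "SimilarityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index), frame.to_numpy(dtype=float), kind)


@dataclass
class SemanticProfile:
    """Ancestor-term contributions of one disease in the MeSH DAG."""

    disease: str
    contributions: dict[str, float]
    total_value: float = field(init=False)

    def __post_init__(self):
        self.total_value = float(sum(self.contributions.values()))


def semantic_profile(
    ontology: DiseaseOntology, disease: str, delta: float = 0.5
) -> SemanticProfile:
    """Semantic contributions of every ancestor term of ``disease``.

    For a term at distance ``k`` above one of the disease's tree numbers the
    contribution along that chain is ``delta**k``; with several tree numbers
    (or several paths in the implied DAG) the maximum applies, so the
    disease's own terms always contribute exactly 1.
    """
    if not 0 < delta < 1:
        raise MdcapError(f"delta must be in (0, 1), got {delta}")
    treenums = ontology.resolve(disease)
    if not treenums:
        raise NoOntologyError(f"disease {disease!r} resolves to no MeSH tree number")
    contributions: dict[str, float] = {}
    for tn in treenums:
        for k, term in enumerate(DiseaseOntology.ancestors(tn)):
            value = delta**k
            if value > contributions.get(term, 0.0):
                contributions[term] = value
    return SemanticProfile(disease, contributions)


def disease_similarity(p1: SemanticProfile, p2: SemanticProfile) -> float:
    """Wang-style semantic similarity of two diseases via shared ancestors."""
    shared = p1.contributions.keys() & p2.contributions.keys()
    if not shared:
        return 0.0
    num = sum(p1.contributions[t] + p2.contributions[t] for t in shared)
    return num / (p1.total_value + p2.total_value)


def semantic_similarity_matrix(
    ontology: DiseaseOntology,
    diseases: Sequence[str],
    delta: float = 0.5,
) -> SimilarityMatrix:
    """Pairwise semantic similarity over ``diseases``; unresolvable names get NaN."""
    profiles: list[SemanticProfile | None] = []
    for d in diseases:
        try:
            profiles.append(semantic_profile(ontology, d, delta))
        except NoOntologyError:
            profiles.append(None)
    n = len(diseases)
    values = np.full((n, n), np.nan)
    for i in range(n):
        if profiles[i] is None:
            continue
        values[i, i] = 1.0
        for j in range(i + 1, n):
            if profiles[j] is None:
                continue
            values[i, j] = values[j, i] = disease_similarity(profiles[i], profiles[j])
    return SimilarityMatrix(list(diseases), values, kind="semantic")


def functional_similarity(
    net: BipartiteNetwork, disease_sim: SimilarityMatrix
) -> SimilarityMatrix:
    """MISIM best-match-average functional similarity between miRNAs.

    ``FS(m1, m2)`` averages, over both directions, the best semantic match of
    each disease in one miRNA's causal disease set against the other's.
    Disease sets are restricted to diseases with a defined semantic profile;
    a miRNA left with an empty set gets NaN entries (undefined, not 0).
    """
    if list(disease_sim.labels) != list(net.diseases):
        raise DataFormatError("disease similarity labels do not match the network")
    S = disease_sim.values
    profiled = ~np.isnan(np.diag(S))
    disease_sets = [
        np.flatnonzero((net.adjacency[i] > 0) & profiled) for i in range(len(net.mirnas))
    ]
    n = len(net.mirnas)
    values = np.full((n, n), np.nan)
    for i in range(n):
        Di = disease_sets[i]
        if Di.size == 0:
            continue
        values[i, i] = 1.0
        for j in range(i + 1, n):
            Dj = disease_sets[j]
            if Dj.size == 0:
                continue
            sub = S[np.ix_(Di, Dj)]
            fs = (sub.max(axis=1).sum() + sub.max(axis=0).sum()) / (Di.size + Dj.size)
            values[i, j] = values[j, i] = fs
    return SimilarityMatrix(list(net.mirnas), values, kind="functional")


def _profiles(net: BipartiteNetwork, side: str) -> tuple[list[str], np.ndarray]:
    if side == "mirna":
        return list(net.mirnas), net.adjacency
    if side == "disease":
        return list(net.diseases), net.adjacency.T
    raise MdcapError(f"side must be 'mirna' or 'disease', got {side!r}")


def gip_kernel(
    net: BipartiteNetwork, side: str, bandwidth_scale: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction profile kernel on one side of the network.

    ``K(i, j) = exp(-gamma * ||IP_i - IP_j||^2)`` with the bandwidth
    ``gamma = bandwidth_scale / mean_i ||IP_i||^2``, where ``IP_i`` is the
    binary interaction profile (adjacency row or column).
    """
    if bandwidth_scale <= 0:
        raise MdcapError("bandwidth_scale must be positive")
    labels, P = _profiles(net, side)
    sq_norms = (P * P).sum(axis=1)
    mean_norm = sq_norms.mean()
    if mean_norm == 0:
        raise MdcapError("all interaction profiles are zero; GIP bandwidth undefined")
    gamma = bandwidth_scale / mean_norm
    sqdist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.clip(sqdist, 0.0, None, out=sqdist)
    K = np.exp(-gamma * sqdist)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return SimilarityMatrix(labels, K, kind="gip")


def hub_promoted_index(net: BipartiteNetwork, side: str) -> SimilarityMatrix:
    """Hub promoted index: |N(i) ∩ N(j)| / min(|N(i)|, |N(j)|), self = 1."""
    labels, P = _profiles(net, side)
    overlap = P @ P.T
    deg = P.sum(axis=1)
    min_deg = np.minimum.outer(deg, deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(min_deg > 0, overlap / np.where(min_deg > 0, min_deg, 1.0), 0.0)
    H = (H + H.T) / 2.0
    np.fill_diagonal(H, 1.0)
    return SimilarityMatrix(labels, H, kind="hpi")
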
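"""End-to-end scoring: network + ontology -> fused causal-association scores."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .data import BipartiteNetwork, DiseaseOntology
from .errors import MdcapError
from .propagation import (
    ScoreMatrix,
    TransitionMatrix,
    fuse_scores,
    integrate,
    label_propagate,
    row_normalize,
)
from .similarity import (
    SimilarityMatrix,
    functional_similarity,
    gip_kernel,
    hub_promoted_index,
    semantic_similarity_matrix,
)


@dataclass(frozen=True)
class MDCAPConfig:
    """Hyperparameters of the model.

    delta
        Semantic-contribution decay per MeSH edge, in (0, 1).
    bandwidth_scale
        GIP kernel bandwidth multiplier (gamma-prime of the original kernel).
    mix_weight
        Weight of the semantic/functional kernel against GIP, in [0, 1].
    hpi_weight
        Weight of the hub-promoted-index adjustment, in [0, 1].
    alpha
        Propagation trade-off between diffusion and the known labels, in [0, 1).
    tol, max_iter
        Convergence threshold (max-abs change) and iteration cap.
    """

    delta: float = 0.5
    bandwidth_scale: float = 1.0
    mix_weight: float = 0.5
    hpi_weight: float = 0.5
    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self):
        if not 0 < self.delta < 1:
            raise MdcapError("delta must be in (0, 1)")
        if self.bandwidth_scale <= 0:
            raise MdcapError("bandwidth_scale must be positive")
        for name in ("mix_weight", "hpi_weight"):
            if not 0 <= getattr(self, name) <= 1:
                raise MdcapError(f"{name} must be in [0, 1]")
        if not 0 <= self.alpha < 1:
            raise MdcapError("alpha must be in [0, 1)")
        if self.tol <= 0 or self.max_iter < 1:
            raise MdcapError("tol must be positive and max_iter >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def integrated_similarities(
    net: BipartiteNetwork,
    ontology: DiseaseOntology | None = None,
    config: MDCAPConfig = MDCAPConfig(),
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Integrated miRNA-side and disease-side similarity matrices.

    Without an ontology the semantic and functional components are undefined
    everywhere, so both sides reduce to the GIP kernel adjusted by HPI.
    """
    if ontology is not None:
        sem = semantic_similarity_matrix(ontology, net.diseases, config.delta)
        fun = functional_similarity(net, sem)
    else:
        nd, nm = len(net.diseases), len(net.mirnas)
        sem = SimilarityMatrix(list(net.diseases), np.full((nd, nd), np.nan), "semantic")
        fun = SimilarityMatrix(list(net.mirnas), np.full((nm, nm), np.nan), "functional")
    sim_m = integrate(
        fun,
        gip_kernel(net, "mirna", config.bandwidth_scale),
        hub_promoted_index(net, "mirna"),
        config.mix_weight,
        config.hpi_weight,
    )
    sim_d = integrate(
        sem,
        gip_kernel(net, "disease", config.bandwidth_scale),
        hub_promoted_index(net, "disease"),
        config.mix_weight,
        config.hpi_weight,
    )
    return sim_m, sim_d


def transition_matrices(
    net: BipartiteNetwork,
    ontology: DiseaseOntology | None = None,
    config: MDCAPConfig = MDCAPConfig(),
) -> tuple[TransitionMatrix, TransitionMatrix]:
    """Row-stochastic propagation operators for the miRNA and disease sides."""
    sim_m, sim_d = integrated_similarities(net, ontology, config)
    return row_normalize(sim_m), row_normalize(sim_d)


def predict_scores(
    net: BipartiteNetwork,
    ontology: DiseaseOntology | None = None,
    config: MDCAPConfig = MDCAPConfig(),
) -> ScoreMatrix:
    """Run the full model: propagate labels on both sides and fuse.

    The miRNA-side operator diffuses each disease's label column over similar
    miRNAs; the disease-side operator diffuses each miRNA's label row over
    similar diseases; the final score is the mean of the two results.
    """
    W_m, W_d = transition_matrices(net, ontology, config)
    Y = net.adjacency
    F_m = label_propagate(W_m, Y, config.alpha, config.tol, config.max_iter)
    F_d = label_propagate(W_d, Y.T, config.alpha, config.tol, config.max_iter).T
    return fuse_scores(F_m, F_d, list(net.mirnas), list(net.diseases))
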
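"""Synthetic fixtures: planted-block networks, toy ontologies, conservation data.

Every external input of the package can be emulated here so the whole model is
testable without any database download:

* a bipartite stochastic block model stands in for the curated causal
  association table — miRNAs and diseases are assigned to co-association
  blocks and edges are drawn with a high within-block and low between-block
  probability, so the planted structure is recoverable by the predictor;
* a rooted MeSH-like tree attaches same-block diseases under a shared subtree,
  making semantic similarity informative about the blocks;
* a conservation fixture plants a positive family-size trend and a negative
  SNP-count trend against the causal disease number, with Gaussian noise.

Writers emit the exact dialects the parsers read (association TSV, two-column
MeSH TSV, family TSV, GFF3, VCF v4.2), so parse(write(fixture)) round-trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import (
    AssociationRecord,
    BipartiteNetwork,
    DiseaseOntology,
    PrecursorInterval,
    SnpPosition,
    build_network,
)
from .errors import EmptyNetworkError, MdcapError

CAUSAL_CODES = ("Target", "Genetics")
NONCAUSAL_CODES = ("Epigenetics", "Circulation_biomarker", "Genetics_GWAS", "Tissue_expression")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block association generator.

    Defaults define the package's standard recovery benchmark: 60 miRNAs x 40
    diseases in 4 co-association blocks, dense within blocks (p=0.3) and
    sparse between (p=0.02), with every sampled edge flagged causal.
    """

    n_mirnas: int = 60
    n_diseases: int = 40
    n_blocks: int = 4
    p_within: float = 0.3
    p_between: float = 0.02
    causal_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_mirnas, self.n_diseases, self.n_blocks) < 1:
            raise MdcapError("counts must be positive")
        if not 0 <= self.p_between < self.p_within <= 1:
            raise MdcapError("need 0 <= p_between < p_within <= 1")
        if not 0 <= self.causal_fraction <= 1:
            raise MdcapError("causal_fraction must be in [0, 1]")


def _block_of(index: int, n_blocks: int) -> int:
    return index % n_blocks


def mirna_block(name_index: int, spec: SyntheticSpec) -> int:
    return _block_of(name_index, spec.n_blocks)


def generate_network(spec: SyntheticSpec) -> tuple[BipartiteNetwork, list[AssociationRecord]]:
    """Sample a planted-block association table and its causal network.

    Entities are assigned to blocks round-robin; edge (i, j) is drawn with
    ``p_within`` when miRNA i and disease j share a block, else ``p_between``.
    Each edge becomes an association record with an evidence code consistent
    with its causality flag.  Entities that end up with zero causal edges are
    dropped from the network (with a warning) rather than forced an edge.
    """
    rng = np.random.default_rng(spec.seed)
    m_block = np.arange(spec.n_mirnas) % spec.n_blocks
    d_block = np.arange(spec.n_diseases) % spec.n_blocks
    same = m_block[:, None] == d_block[None, :]
    prob = np.where(same, spec.p_within, spec.p_between)
    edges = rng.random((spec.n_mirnas, spec.n_diseases)) < prob

    mirnas = [f"hsa-mir-{i + 1:03d}" for i in range(spec.n_mirnas)]
    diseases = [f"synthetic disease {j + 1:03d}" for j in range(spec.n_diseases)]
    records: list[AssociationRecord] = []
    pmid = 10_000_000
    for i in range(spec.n_mirnas):
        for j in range(spec.n_diseases):
            if not edges[i, j]:
                continue
            causal = bool(rng.random() < spec.causal_fraction)
            codes = CAUSAL_CODES if causal else NONCAUSAL_CODES
            code = codes[int(rng.integers(len(codes)))]
            pmid += 1
            records.append(
                AssociationRecord(mirnas[i], diseases[j], code, pmid, causal)
            )
    if not any(r.causal for r in records):
        raise EmptyNetworkError("synthetic spec produced no causal edges")
    net = build_network(records, causal_only=True)
    dropped = (spec.n_mirnas - len(net.mirnas)) + (spec.n_diseases - len(net.diseases))
    if dropped:
        warnings.warn(
            f"{dropped} entities had no causal edge and were dropped", stacklevel=2
        )
    return net, records


def disease_blocks(net: BipartiteNetwork, spec: SyntheticSpec) -> dict[str, int]:
    """Recover each network disease's planted block from its generated name."""
    blocks = {}
    for name in net.diseases:
        idx = int(name.rsplit(" ", 1)[1]) - 1
        blocks[name] = _block_of(idx, spec.n_blocks)
    return blocks


def generate_ontology(
    diseases: Sequence[str],
    blocks: dict[str, int] | None = None,
    branching: int = 2,
    depth: int = 2,
    seed: int = 0,
) -> DiseaseOntology:
    """Build a MeSH-like tree and attach diseases to its leaves.

    One subtree per block is rooted at a top-level tree number; diseases of a
    block are attached (round-robin, in seeded random order) to the leaves of
    their subtree, so same-block diseases share deeper ancestors.  With
    ``depth == 1`` all leaves are direct siblings of the block root.  When a
    subtree has fewer leaves than diseases, leaves are reused.
    """
    if branching < 1 or depth < 1:
        raise MdcapError("branching and depth must be positive")
    blocks = blocks or {d: 0 for d in diseases}
    n_blocks = max(blocks.values()) + 1
    rng = np.random.default_rng(seed)

    def subtree_leaves(root: str) -> list[str]:
        level = [root]
        for _ in range(depth):
            level = [f"{node}.{k + 1:02d}" for node in level for k in range(branching)]
        return level

    term_map: dict[str, set[str]] = {}
    for b in range(n_blocks):
        leaves = subtree_leaves(f"C{b + 1:02d}")
        members = sorted(d for d, blk in blocks.items() if blk == b)
        order = rng.permutation(len(leaves))
        for rank, disease in enumerate(members):
            leaf = leaves[order[rank % len(leaves)]]
            term_map.setdefault(disease, set()).add(leaf)
    return DiseaseOntology({k: frozenset(v) for k, v in term_map.items()})


@dataclass
class ConservationFixture:
    """In-memory conservation data with planted trends."""

    mirnas: list[str]
    cdn: np.ndarray
    family_by_mirna: dict[str, str]
    family_members: list[tuple[str, str]]  # (family_id, member_id) incl. paralogues
    intervals: list[PrecursorInterval]
    snps: list[SnpPosition]
    expected_signs: dict[str, int] = field(default_factory=dict)

    def family_sizes(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fam, _ in self.family_members:
            counts[fam] = counts.get(fam, 0) + 1
        return {m: counts[f] for m, f in self.family_by_mirna.items()}

    def snp_counts(self) -> dict[str, int]:
        from .conservation import snp_count

        return snp_count(self.intervals, self.snps)


def generate_conservation_fixture(
    n_mirnas: int = 200,
    effect_family: float = 0.3,
    effect_snp: float = 0.25,
    noise_sd: float = 1.0,
    seed: int = 0,
    snp_base: int = 12,
    mirnas: Sequence[str] | None = None,
    cdn: Sequence[int] | None = None,
) -> ConservationFixture:
    """Plant a positive cdn-family and a negative cdn-SNP trend.

    By default cdn mimics the curated data's skew: about half the miRNAs have
    no causal disease, the rest are uniform on 1..30; real miRNA ids and cdn
    values (e.g. from a generated association table) may be passed instead.
    Family size is ``max(1, round(1 + effect_family * cdn + N(0, noise_sd)))``;
    the SNP count is ``max(0, round(snp_base - effect_snp * cdn +
    N(0, noise_sd)))``, each realised as actual family members / SNP positions
    inside an 80-nt precursor so the file round trip preserves the counts.
    """
    rng = np.random.default_rng(seed)
    if mirnas is not None:
        mirnas = list(mirnas)
        n_mirnas = len(mirnas)
    else:
        mirnas = [f"hsa-mir-c{i + 1:04d}" for i in range(n_mirnas)]
    if cdn is not None:
        cdn = np.asarray(cdn, dtype=int)
        if len(cdn) != n_mirnas:
            raise MdcapError("cdn length does not match the miRNA list")
    else:
        cdn = np.where(
            rng.random(n_mirnas) < 0.5, 0, rng.integers(1, 31, size=n_mirnas)
        ).astype(int)
    fam_sizes = np.maximum(
        1,
        np.rint(1 + effect_family * cdn + rng.normal(0, noise_sd, n_mirnas)).astype(int),
    )
    snp_counts = np.maximum(
        0,
        np.rint(snp_base - effect_snp * cdn + rng.normal(0, noise_sd, n_mirnas)).astype(int),
    )

    family_by_mirna: dict[str, str] = {}
    family_members: list[tuple[str, str]] = []
    intervals: list[PrecursorInterval] = []
    snps: list[SnpPosition] = []
    rs = 1
    for i, mirna in enumerate(mirnas):
        family = f"mirfam-{i + 1:04d}"
        family_by_mirna[mirna] = family
        family_members.append((family, mirna))
        for k in range(fam_sizes[i] - 1):
            family_members.append((family, f"{mirna}-paralog-{k + 1}"))
        start = 1000 + i * 1000
        end = start + 79
        intervals.append(PrecursorInterval(mirna, "chr1", start, end, "+"))
        if snp_counts[i] > 0:
            positions = rng.choice(80, size=snp_counts[i], replace=False)
            for p in np.sort(positions):
                snps.append(SnpPosition("chr1", int(start + p), f"rs{rs}"))
                rs += 1
    signs = {
        "family_size": int(np.sign(effect_family)),
        "snp_count": -int(np.sign(effect_snp)),
    }
    return ConservationFixture(
        mirnas, cdn, family_by_mirna, family_members, intervals, snps, signs
    )


# ---------------------------------------------------------------------------
# Writers (dialects match the data-module parsers exactly)
# ---------------------------------------------------------------------------


def write_association_tsv(records: Sequence[AssociationRecord], path: str | Path):
    lines = ["mir\tdisease\tcategory\tpmid\tcausality"]
    for r in records:
        pmid = "" if r.pmid is None else str(r.pmid)
        lines.append(
            f"{r.mirna_id}\t{r.disease_name}\t{r.evidence_code}\t{pmid}\t"
            f"{'yes' if r.causal else 'no'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_mesh_tsv(ontology: DiseaseOntology, path: str | Path):
    lines = []
    for name in sorted(ontology.term_to_treenums):
        for tn in sorted(ontology.term_to_treenums[name]):
            lines.append(f"{name}\t{tn}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mesh_ascii(ontology: DiseaseOntology, path: str | Path):
    blocks = []
    for name in sorted(ontology.term_to_treenums):
        lines = ["*NEWRECORD", f"MH = {name}"]
        lines += [f"MN = {tn}" for tn in sorted(ontology.term_to_treenums[name])]
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n")


def write_family_tsv(family_members: Sequence[tuple[str, str]], path: str | Path):
    lines = [f"{fam}\t{member}" for fam, member in family_members]
    Path(path).write_text("\n".join(lines) + "\n")


def write_gff3(intervals: Sequence[PrecursorInterval], path: str | Path):
    lines = ["##gff-version 3"]
    for i, iv in enumerate(intervals, 1):
        lines.append(
            f"{iv.chrom}\t.\tmiRNA_primary_transcript\t{iv.start}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\tID=MI{i:07d};Name={iv.mirna_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf(snps: Sequence[SnpPosition], path: str | Path):
    chroms = sorted({s.chrom for s in snps})
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
        lines.append(f"{s.chrom}\t{s.pos}\t{s.id}\tA\tG\t.\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")
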
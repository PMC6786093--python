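"""Input parsing and the causal bipartite network.

This module turns the raw inputs of the analysis — an HMDD-style association
table, MeSH descriptor records, a miRNA family table, precursor intervals
(GFF3) and SNP positions (VCF) — into typed records, applies the evidence-code
candidate screen, and materialises the known causal associations as a binary
miRNA x disease adjacency matrix.

Evidence-code screen
--------------------
HMDD v3+ tags every association with an evidence code.  Codes of class
``Target`` and ``Genetics`` reflect functional or genetic evidence of a causal
role and are retained as causal candidates, *except* ``Genetics_GWAS``: a GWAS
locus associates a genomic region with a disease but carries no direction of
effect for the miRNA, so it is excluded.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, EmptyNetworkError

logger = logging.getLogger(__name__)

#: Evidence-code classes seen in HMDD-style tables.  Unknown codes are kept in
#: the records but flagged with a log message; they are never selected by the
#: candidate screen.
EVIDENCE_VOCABULARY = frozenset(
    {
        "Target",
        "Genetics",
        "Genetics_GWAS",
        "Epigenetics",
        "Circulation_biomarker",
        "Tissue_expression",
        "Other",
    }
)

#: Default header aliases for association tables (matched case-insensitively).
DEFAULT_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "mirna": ("mir", "mirna", "mirna_id", "microrna"),
    "disease": ("disease", "disease_name"),
    "evidence": ("category", "categories", "evidence", "evidence_code"),
    "pmid": ("pmid", "pubmed", "pubmed_id"),
    "causal": ("causality", "causal", "causality_category"),
}

_TRUTHY = {"yes", "y", "true", "1", "causal"}
_FALSY = {"no", "n", "false", "0", "non-causal", "noncausal", "unknown", ""}


@dataclass(frozen=True)
class AssociationRecord:
    """One curated miRNA-disease link."""

    mirna_id: str
    disease_name: str
    evidence_code: str
    pmid: int | None = None
    causal: bool = False

    def __post_init__(self):
        if not self.mirna_id or not self.disease_name:
            raise DataFormatError("mirna_id and disease_name must be nonempty")


@dataclass(frozen=True)
class PrecursorInterval:
    """Genomic interval of a miRNA precursor (1-based, inclusive ends)."""

    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class SnpPosition:
    """A single SNP site (1-based coordinate)."""

    chrom: str
    pos: int
    id: str = "."


def normalize_disease_name(name: str) -> str:
    """Normalize a disease name for case-insensitive MeSH matching.

    Lower-cases, strips, collapses internal whitespace and standardises comma
    spacing so that e.g. ``"Carcinoma,  Hepatocellular "`` and
    ``"carcinoma, hepatocellular"`` compare equal.
    """
    name = re.sub(r"\s+", " ", name.strip())
    name = re.sub(r"\s*,\s*", ", ", name)
    return name.lower()


def _parse_causal(value: object) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY or text in {"nan", "none", "-"}:
        return False
    logger.warning("Unrecognised causality value %r treated as non-causal", value)
    return False


def _parse_pmid(value: object) -> int | None:
    text = str(value).strip()
    if not text or text.lower() in {"nan", "none", "-", "na"}:
        return None
    try:
        pmid = int(float(text))
    except ValueError:
        return None
    return pmid if pmid > 0 else None


def _resolve_columns(
    columns: Sequence[str], aliases: Mapping[str, tuple[str, ...]]
) -> dict[str, str | None]:
    lower = {c.lower().strip(): c for c in columns}
    resolved: dict[str, str | None] = {}
    for role, names in aliases.items():
        resolved[role] = None
        for candidate in names:
            if candidate.lower() in lower:
                resolved[role] = lower[candidate.lower()]
                break
    return resolved


def parse_associations(
    path: str | Path,
    column_aliases: Mapping[str, tuple[str, ...]] | None = None,
) -> list[AssociationRecord]:
    """Parse a tab-separated association table into records.

    Columns are located through a configurable alias map (HMDD dialects vary
    between versions).  miRNA ids are lower-cased; duplicate
    (mirna, disease, pmid, evidence) rows are collapsed to one record.  A
    missing mandatory column (mirna / disease / evidence) raises
    :class:`DataFormatError`; a causality column is used when present,
    otherwise all records carry ``causal=False`` and downstream causal
    filtering falls back to the evidence-code screen.
    """
    aliases = dict(DEFAULT_COLUMN_ALIASES)
    if column_aliases:
        aliases.update(column_aliases)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"Association table {path} is empty", stacklevel=2)
        return []
    cols = _resolve_columns(list(frame.columns), aliases)
    for role in ("mirna", "disease", "evidence"):
        if cols[role] is None:
            raise DataFormatError(
                f"Association table {path} lacks a '{role}' column "
                f"(accepted aliases: {', '.join(aliases[role])})"
            )

    records: list[AssociationRecord] = []
    seen: set[tuple] = set()
    for _, row in frame.iterrows():
        mirna = str(row[cols["mirna"]]).strip().lower()
        disease = str(row[cols["disease"]]).strip()
        code = str(row[cols["evidence"]]).strip()
        if not mirna or not disease:
            continue
        pmid = _parse_pmid(row[cols["pmid"]]) if cols["pmid"] else None
        causal = _parse_causal(row[cols["causal"]]) if cols["causal"] else False
        key = (mirna, disease, pmid, code)
        if key in seen:
            continue
        seen.add(key)
        if code and code not in EVIDENCE_VOCABULARY:
            logger.info("Unknown evidence code %r for %s / %s", code, mirna, disease)
        records.append(AssociationRecord(mirna, disease, code, pmid, causal))
    if not records:
        warnings.warn(f"Association table {path} contains no data rows", stacklevel=2)
    return records


def is_candidate_code(code: str) -> bool:
    """True iff an evidence code passes the causal-candidate screen."""
    c = code.strip().lower()
    return c == "target" or (c.startswith("genetics") and c != "genetics_gwas")


def screen_candidates(records: Iterable[AssociationRecord]) -> list[AssociationRecord]:
    """Keep records whose evidence code marks them as causal candidates.

    Retains codes of class ``Target`` and ``Genetics`` except
    ``Genetics_GWAS``; order is preserved and the operation is idempotent.
    """
    kept = []
    for rec in records:
        if is_candidate_code(rec.evidence_code):
            kept.append(rec)
        else:
            logger.debug("Screened out %s (code %s)", rec.mirna_id, rec.evidence_code)
    return kept


@dataclass
class BipartiteNetwork:
    """Binary miRNA x disease adjacency with stable, sorted index maps."""

    mirnas: list[str]
    diseases: list[str]
    adjacency: np.ndarray

    mirna_index: dict[str, int] = field(init=False, repr=False)
    disease_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        if self.adjacency.shape != (len(self.mirnas), len(self.diseases)):
            raise DataFormatError("adjacency shape does not match entity lists")
        if not np.isin(self.adjacency, (0.0, 1.0)).all():
            raise DataFormatError("adjacency must be binary")
        if len(set(self.mirnas)) != len(self.mirnas):
            raise DataFormatError("duplicate miRNA labels")
        if len(set(self.diseases)) != len(self.diseases):
            raise DataFormatError("duplicate disease labels")
        self.mirna_index = {m: i for i, m in enumerate(self.mirnas)}
        self.disease_index = {d: j for j, d in enumerate(self.diseases)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.adjacency.shape

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def edges(self) -> list[tuple[str, str]]:
        """Sorted list of (mirna, disease) pairs with an edge."""
        rows, cols = np.nonzero(self.adjacency)
        return sorted((self.mirnas[i], self.diseases[j]) for i, j in zip(rows, cols))

    def has_edge(self, mirna: str, disease: str) -> bool:
        i = self.mirna_index.get(mirna)
        j = self.disease_index.get(disease)
        return i is not None and j is not None and self.adjacency[i, j] == 1

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "BipartiteNetwork":
        pairs = sorted(set(edges))
        if not pairs:
            raise EmptyNetworkError("no edges to build a network from")
        mirnas = sorted({m for m, _ in pairs})
        diseases = sorted({d for _, d in pairs})
        net = cls(mirnas, diseases, np.zeros((len(mirnas), len(diseases))))
        for m, d in pairs:
            net.adjacency[net.mirna_index[m], net.disease_index[d]] = 1.0
        return net


def build_network(
    records: Iterable[AssociationRecord], causal_only: bool = True
) -> BipartiteNetwork:
    """Build the bipartite association network from records.

    With ``causal_only`` the curated causality flag selects edges; when no
    record carries a causal flag the evidence-code screen is used as the
    fallback pre-filter.  Entity orders are deterministic (lexicographic) so
    the adjacency is independent of input row order.
    """
    records = list(records)
    if causal_only:
        selected = [r for r in records if r.causal]
        if not selected:
            selected = screen_candidates(records)
    else:
        selected = records
    if not selected:
        raise EmptyNetworkError("zero records survive filtering; cannot build network")
    return BipartiteNetwork.from_edges((r.mirna_id, r.disease_name) for r in selected)


# ---------------------------------------------------------------------------
# MeSH ontology
# ---------------------------------------------------------------------------

_TREENUM_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]+)*$")


@dataclass
class DiseaseOntology:
    """Disease name -> set of MeSH tree numbers; the DAG is implied by prefixes.

    The parent of a tree number is its prefix truncated at the last dot;
    top-level numbers (no dot) are roots.  Name lookup is case-insensitive
    after whitespace/comma normalization.
    """

    term_to_treenums: dict[str, frozenset[str]]

    def __post_init__(self):
        self.term_to_treenums = {
            normalize_disease_name(k): frozenset(v)
            for k, v in self.term_to_treenums.items()
            if v
        }

    def resolve(self, disease: str) -> frozenset[str] | None:
        return self.term_to_treenums.get(normalize_disease_name(disease))

    def __contains__(self, disease: str) -> bool:
        return self.resolve(disease) is not None

    def __len__(self) -> int:
        return len(self.term_to_treenums)

    @staticmethod
    def parent(treenum: str) -> str | None:
        head, sep, _ = treenum.rpartition(".")
        return head if sep else None

    @classmethod
    def ancestors(cls, treenum: str) -> list[str]:
        """The chain from a tree number up to its root, self included."""
        chain = [treenum]
        parent = cls.parent(treenum)
        while parent is not None:
            chain.append(parent)
            parent = cls.parent(parent)
        return chain


def parse_mesh(path: str | Path) -> DiseaseOntology:
    """Parse MeSH descriptors from the ASCII dialect or a two-column TSV.

    The ASCII dialect is record-oriented (``MH = name`` followed by one or
    more ``MN = treenum`` lines); the TSV dialect is one (name, treenum) pair
    per line.  The dialect is auto-detected.  Terms with zero tree numbers
    are skipped with a warning.
    """
    text = Path(path).read_text(encoding="utf-8")
    terms: dict[str, set[str]] = {}
    if re.search(r"^MH\s*=", text, flags=re.MULTILINE):
        current: str | None = None
        for line in text.splitlines():
            line = line.strip()
            if line.startswith("MH"):
                m = re.match(r"MH\s*=\s*(.+)$", line)
                if m:
                    current = m.group(1).strip()
                    terms.setdefault(current, set())
            elif line.startswith("MN") and current is not None:
                m = re.match(r"MN\s*=\s*(\S+)", line)
                if m:
                    terms[current].add(m.group(1))
            elif line.startswith("*NEWRECORD"):
                current = None
    else:
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            name, treenum = parts[0].strip(), parts[1].strip()
            if not _TREENUM_RE.match(treenum):
                if lineno == 1:  # tolerate a header line
                    continue
                warnings.warn(
                    f"{path}:{lineno}: {treenum!r} is not a tree number; skipped",
                    stacklevel=2,
                )
                continue
            terms.setdefault(name, set()).add(treenum)
    for name in [n for n, tns in terms.items() if not tns]:
        warnings.warn(f"MeSH term {name!r} has no tree numbers; skipped", stacklevel=2)
        del terms[name]
    return DiseaseOntology({k: frozenset(v) for k, v in terms.items()})


# ---------------------------------------------------------------------------
# Conservation inputs: family table, precursor GFF3, SNP VCF
# ---------------------------------------------------------------------------


def parse_family_table(path: str | Path) -> dict[str, str]:
    """Parse a two-column ``family_id <tab> mirna_id`` TSV into mirna -> family."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DataFormatError(f"{path}:{lineno}: expected 2 columns")
        family, mirna = parts[0].strip(), parts[1].strip().lower()
        if lineno == 1 and family.lower() in {"family", "family_id"}:
            continue
        mapping[mirna] = family
    return mapping


def family_sizes(mirna_to_family: Mapping[str, str]) -> dict[str, int]:
    """Member count of each miRNA's family, keyed by miRNA id."""
    counts: dict[str, int] = {}
    for family in mirna_to_family.values():
        counts[family] = counts.get(family, 0) + 1
    return {m: counts[f] for m, f in mirna_to_family.items()}


def parse_precursor_gff(path: str | Path) -> list[PrecursorInterval]:
    """Read miRNA precursor intervals from GFF3.

    Only features of type ``miRNA_primary_transcript`` are consumed; the
    miRNA id is the ``Name`` attribute (``ID`` as fallback), lower-cased.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    intervals = []
    for feat in db.features_of_type("miRNA_primary_transcript"):
        name = (feat.attributes.get("Name") or feat.attributes.get("ID") or [None])[0]
        if name is None:
            warnings.warn(f"precursor at {feat.seqid}:{feat.start} has no Name/ID", stacklevel=2)
            continue
        intervals.append(
            PrecursorInterval(name.lower(), feat.seqid, feat.start, feat.end,
                              feat.strand if feat.strand in "+-" else "+")
        )
    return intervals


def parse_snp_vcf(path: str | Path) -> list[SnpPosition]:
    """Read SNP positions from a VCF; only CHROM/POS/ID are consumed."""
    import pysam

    snps = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            snps.append(SnpPosition(rec.chrom, rec.pos, rec.id or "."))
    return snps
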
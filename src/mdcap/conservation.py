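"""miRNA conservation side-analysis.

Two per-miRNA disease counts are derived from the association records:

* **cdn** (causal disease number) — distinct diseases with a causal link;
* **dsw** (disease spectrum width) — distinct diseases regardless of causality.

Conservation is proxied by (a) the size of a miRNA's family — conserved
miRNAs have more paralogues — and (b) the number of SNPs harboured in its
precursor — conserved precursors tolerate fewer variants.  Correlations of
cdn/dsw against these proxies are reported with both Pearson's r and
Spearman's rho (Spearman is the safer choice for count data); min-max
normalization of the disease counts is offered for plotting but cannot change
either coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .data import AssociationRecord, PrecursorInterval, SnpPosition
from .errors import MdcapError

#: Default cdn group boundaries: 0, 1-5, 6-15, 16-30, >30.
DEFAULT_CDN_BOUNDARIES: tuple[int, ...] = (0, 5, 15, 30)


@dataclass
class ConservationProfile:
    """Per-miRNA disease counts and conservation proxies."""

    mirna_id: str
    cdn: int
    dsw: int
    family_size: int | None = None
    snp_count: int | None = None

    def __post_init__(self):
        if not (0 <= self.cdn <= self.dsw):
            raise MdcapError(
                f"{self.mirna_id}: cdn ({self.cdn}) must satisfy 0 <= cdn <= dsw ({self.dsw})"
            )


def compute_cdn_dsw(records: Iterable[AssociationRecord]) -> dict[str, tuple[int, int]]:
    """Distinct causal and total disease counts per miRNA."""
    all_d: dict[str, set[str]] = {}
    causal_d: dict[str, set[str]] = {}
    for rec in records:
        all_d.setdefault(rec.mirna_id, set()).add(rec.disease_name)
        if rec.causal:
            causal_d.setdefault(rec.mirna_id, set()).add(rec.disease_name)
    return {
        m: (len(causal_d.get(m, ())), len(ds)) for m, ds in sorted(all_d.items())
    }


def group_label(low: int | None, high: int | None) -> str:
    if low is None:
        return str(high)
    if high is None:
        return f">{low}"
    return f"{low}-{high}"


def group_by_cdn(
    cdn_by_mirna: Mapping[str, int],
    boundaries: Sequence[int] = DEFAULT_CDN_BOUNDARIES,
) -> dict[str, set[str]]:
    """Partition miRNAs into cdn bands.

    With the default boundaries (0, 5, 15, 30) the five groups are
    ``0``, ``1-5``, ``6-15``, ``16-30`` and ``>30`` — the top group being the
    small set of miRNAs causal in more than 30 diseases.
    """
    bounds = list(boundaries)
    if bounds != sorted(set(bounds)) or len(bounds) < 1:
        raise MdcapError("boundaries must be strictly increasing")
    labels = [group_label(None, bounds[0])]
    for lo, hi in zip(bounds, bounds[1:]):
        labels.append(f"{lo + 1}-{hi}" if lo + 1 < hi else str(hi))
    labels.append(group_label(bounds[-1], None))
    groups: dict[str, set[str]] = {lab: set() for lab in labels}
    for mirna, cdn in cdn_by_mirna.items():
        idx = int(np.searchsorted(bounds, cdn, side="left"))
        groups[labels[idx]].add(mirna)
    return groups


def snp_count(
    intervals: Iterable[PrecursorInterval], snps: Iterable[SnpPosition]
) -> dict[str, int]:
    """SNP positions falling inside each miRNA's precursor interval(s).

    Coordinates are 1-based inclusive on both sides; strand is ignored; a
    miRNA with several precursor copies sums counts over them.  Malformed
    intervals (start > end or empty chrom) are skipped with a warning.
    """
    by_chrom: dict[str, np.ndarray] = {}
    snps = list(snps)
    for chrom in {s.chrom for s in snps}:
        by_chrom[chrom] = np.sort([s.pos for s in snps if s.chrom == chrom])
    counts: dict[str, int] = {}
    for iv in intervals:
        counts.setdefault(iv.mirna_id, 0)
        if iv.start > iv.end or not iv.chrom:
            warnings.warn(
                f"skipping malformed interval for {iv.mirna_id} "
                f"({iv.chrom}:{iv.start}-{iv.end})",
                stacklevel=2,
            )
            continue
        positions = by_chrom.get(iv.chrom)
        if positions is None:
            continue
        lo = int(np.searchsorted(positions, iv.start, side="left"))
        hi = int(np.searchsorted(positions, iv.end, side="right"))
        counts[iv.mirna_id] += hi - lo
    return counts


def build_profiles(
    records: Iterable[AssociationRecord],
    family_size_by_mirna: Mapping[str, int] | None = None,
    snp_count_by_mirna: Mapping[str, int] | None = None,
) -> list[ConservationProfile]:
    """Assemble per-miRNA conservation profiles from the available inputs."""
    profiles = []
    for mirna, (cdn, dsw) in compute_cdn_dsw(records).items():
        profiles.append(
            ConservationProfile(
                mirna,
                cdn,
                dsw,
                family_size=(family_size_by_mirna or {}).get(mirna),
                snp_count=(snp_count_by_mirna or {}).get(mirna),
            )
        )
    return profiles


@dataclass
class CorrelationResult:
    metric: str
    feature: str
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; rank- and correlation-preserving."""
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise MdcapError("cannot min-max normalize a constant vector")
    return (values - lo) / (hi - lo)


def correlate_conservation(
    profiles: Sequence[ConservationProfile],
    metric: str = "cdn",
    feature: str = "family_size",
    normalize: bool = True,
) -> CorrelationResult:
    """Correlate a disease-count metric (cdn/dsw) with a conservation proxy.

    Profiles missing the feature are dropped; at least 3 complete pairs and
    nonzero variance on both sides are required.
    """
    if metric not in ("cdn", "dsw"):
        raise MdcapError(f"metric must be 'cdn' or 'dsw', got {metric!r}")
    if feature not in ("family_size", "snp_count"):
        raise MdcapError(f"feature must be 'family_size' or 'snp_count', got {feature!r}")
    pairs = [
        (getattr(p, metric), getattr(p, feature))
        for p in profiles
        if getattr(p, feature) is not None
    ]
    if len(pairs) < 3:
        raise MdcapError("need at least 3 profiles with both values present")
    x = np.array([a for a, _ in pairs], dtype=float)
    y = np.array([b for _, b in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MdcapError("zero variance: correlation undefined")
    if normalize:
        x = minmax_normalize(x)
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(
        metric,
        feature,
        float(pr.statistic),
        float(pr.pvalue),
        float(sr.statistic),
        float(sr.pvalue),
        len(pairs),
    )
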
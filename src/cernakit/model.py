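"""Shared data model for the ceRNA-network pipeline.

All genomic coordinates are 1-based inclusive (GTF convention).  Expression
matrices are feature x sample; the two phenotype groups are labelled ``H``
(high intramuscular fat) and ``L`` (low).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

BIOTYPES = ("mRNA", "lncRNA", "circRNA", "miRNA")
GROUPS = ("H", "L")

#: hierarchy of canonical miRNA seed-site classes, weakest first
SEED_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")


class CernakitError(ValueError):
    """Raised on malformed input; readers reject rather than coerce."""


@dataclass
class ExpressionMatrix:
    """Feature x sample expression values with a sample -> group map.

    Parameters
    ----------
    values
        DataFrame, rows = feature ids, columns = sample ids.  All entries
        must be finite and non-negative.
    groups
        Map from every sample id to ``"H"`` or ``"L"``; both groups must be
        non-empty.
    layer
        One of ``counts``, ``fpkm``, ``cpm``, ``log2fpkm``, ``log2cpm``.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = sorted(set(idx[idx.duplicated()]))
            raise CernakitError(f"duplicate feature ids: {dups}")
        arr = self.values.to_numpy()
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
            raise CernakitError("expression values must be finite and >= 0")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise CernakitError(f"samples without a group label: {missing}")
        labels = {self.groups[s] for s in self.values.columns}
        bad = labels - set(GROUPS)
        if bad:
            raise CernakitError(f"unknown group labels: {sorted(bad)}")
        if self.values.shape[1] and labels != set(GROUPS):
            raise CernakitError("both groups H and L must be non-empty")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)], dict(self.groups), self.layer
        )


@dataclass
class TranscriptAnnotation:
    """One transcript: location, structure and biotype.

    ``length_bp`` is the summed exon length when exons are present,
    otherwise the genomic span ``end - start + 1``.
    """

    feature_id: str
    biotype: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise CernakitError(
                f"{self.feature_id}: unknown biotype {self.biotype!r}"
            )
        if self.strand not in ("+", "-"):
            raise CernakitError(f"{self.feature_id}: bad strand {self.strand!r}")
        if self.start > self.end:
            raise CernakitError(f"{self.feature_id}: start > end")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for (s, e) in self.exons:
            if s > e or s < self.start or e > self.end:
                raise CernakitError(
                    f"{self.feature_id}: exon ({s},{e}) outside transcript span"
                )
            if prev_end is not None and s <= prev_end:
                raise CernakitError(f"{self.feature_id}: overlapping exons")
            prev_end = e

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def length_bp(self) -> int:
        if self.exons:
            return sum(e - s + 1 for s, e in self.exons)
        return self.end - self.start + 1


@dataclass(frozen=True)
class TargetPair:
    """Directed miRNA -> target link with its provenance."""

    mirna_id: str
    target_id: str
    source: str = "seed_match"
    score: Optional[float] = None
    score_b: Optional[float] = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.target_id)


@dataclass(frozen=True)
class LncTargetPair:
    """lncRNA -> gene link assigned by one of three modes.

    evidence: distance in bp (cis), signed Pearson correlation (trans) or
    overlap length in bp (antisense).
    """

    lnc_id: str
    gene_id: str
    mode: str
    evidence: float


@dataclass(frozen=True)
class SeedMatch:
    """A canonical seed-complementary site in a target sequence.

    ``site_start`` is the 1-based position in the target of the first
    nucleotide complementary to the seed (miRNA positions 2-7/2-8).
    """

    mirna_id: str
    target_id: str
    site_start: int
    match_class: str


@dataclass
class DEResult:
    """Per-feature differential-expression call (H over L)."""

    feature_id: str
    mean_H: float
    mean_L: float
    log2fc: float
    p_value: float
    p_adj: float
    status: str = "ns"


@dataclass(frozen=True)
class CorrelationEdge:
    """An undirected co-expression edge that passed a correlation gate."""

    id_a: str
    id_b: str
    method: str  # SCC or PCC
    rho: float
    n_samples: int

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass(frozen=True)
class CeRNATriplet:
    """A (ceRNA, miRNA, mRNA) competing triplet with its three correlations.

    The miRNA is negatively correlated (Spearman) with both the ceRNA
    (lncRNA or circRNA) and the mRNA, which are positively correlated
    (Pearson) with each other.
    """

    cerna_id: str
    cerna_type: str
    mirna_id: str
    mrna_id: str
    scc_mirna_cerna: float
    scc_mirna_mrna: float
    pcc_cerna_mrna: float

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cerna_id, self.mirna_id, self.mrna_id)


@dataclass
class CeRNANetwork:
    """Typed network assembled from competing triplets.

    nodes: id -> biotype; edges: (source, target, edge_type, rho), with
    edges deduplicated across triplets.  Edge types are ``mirna_ceRNA``,
    ``mirna_mRNA`` and ``coexpression``.
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edges: list[tuple[str, str, str, float]] = field(default_factory=list)
    triplets: list[CeRNATriplet] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)
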
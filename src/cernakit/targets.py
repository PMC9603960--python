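"""miRNA target prediction and lncRNA target-gene assignment.

miRNA targets come from canonical seed matching (reverse complements of
miRNA positions 2-7/2-8 in the target sequence, with the 7mer-A1/8mer
variants requiring an adenine opposite miRNA position 1) or from imported
prediction tables whose intersection is taken.  lncRNA targets are
assigned by three modes: cis (genomic proximity), antisense (opposite
strand exonic-span overlap) and trans (expression correlation).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    CernakitError,
    ExpressionMatrix,
    LncTargetPair,
    SEED_CLASSES,
    SeedMatch,
    TargetPair,
    TranscriptAnnotation,
)

logger = logging.getLogger(__name__)

_IUPAC = set("ACGTUNRYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _as_dna(seq: str, name: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _IUPAC
    if bad:
        raise CernakitError(f"{name}: non-IUPAC characters {sorted(bad)}")
    return s


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ------------------------------------------------------------ seed match


def seed_match_targets(mirnas: Mapping[str, str],
                       targets: Mapping[str, str],
                       min_class: str = "7mer-m8") -> list[SeedMatch]:
    """Scan target sequences for canonical miRNA seed sites.

    For each miRNA the seed is positions 2-7 (6mer) or 2-8 (7mer-m8); a
    site is the exact reverse complement of the seed in the target, read
    5'->3'.  An adenine in the target immediately 3' of the site (opposite
    miRNA position 1) upgrades 6mer -> 7mer-A1 and 7mer-m8 -> 8mer.  All
    sites of class >= ``min_class`` are reported, per target, in
    deterministic left-to-right order; ``site_start`` is the 1-based
    position of the seed-complementary span.
    """
    if min_class not in SEED_CLASSES:
        raise CernakitError(f"unknown seed class {min_class!r}")
    min_rank = SEED_CLASSES.index(min_class)
    matches: list[SeedMatch] = []
    mir_seeds = []
    for mid, mseq in mirnas.items():
        m = _as_dna(mseq, mid)
        if len(m) < 8:
            raise CernakitError(f"{mid}: miRNA shorter than 8 nt")
        mir_seeds.append((mid, _revcomp(m[1:7]), _revcomp(m[1:8])))
    scan_6mers = min_rank <= SEED_CLASSES.index("7mer-A1")
    for tid, tseq in targets.items():
        t = _as_dna(tseq, tid)
        for mid, rc6, rc7 in mir_seeds:
            sites: dict[int, str] = {}
            i = t.find(rc7)
            while i != -1:
                sites[i] = "8mer" if t[i + 7:i + 8] == "A" else "7mer-m8"
                i = t.find(rc7, i + 1)
            if scan_6mers:
                i = t.find(rc6)
                while i != -1:
                    if i not in sites:  # a 7mer match at i takes precedence
                        sites[i] = ("7mer-A1" if t[i + 6:i + 7] == "A"
                                    else "6mer")
                    i = t.find(rc6, i + 1)
            for i in sorted(sites):
                if SEED_CLASSES.index(sites[i]) >= min_rank:
                    matches.append(SeedMatch(mid, tid, i + 1, sites[i]))
    return matches


def seed_matches_to_pairs(matches: Iterable[SeedMatch]) -> list[TargetPair]:
    """Collapse per-site matches to unique (miRNA, target) pairs.

    The score is the number of sites found for the pair.
    """
    counts: dict[tuple[str, str], int] = {}
    order: list[tuple[str, str]] = []
    for m in matches:
        key = (m.mirna_id, m.target_id)
        if key not in counts:
            order.append(key)
        counts[key] = counts.get(key, 0) + 1
    return [
        TargetPair(mid, tid, source="seed_match", score=float(counts[(mid, tid)]))
        for mid, tid in order
    ]


def intersect_predictions(set_a: Sequence[TargetPair],
                          set_b: Sequence[TargetPair]) -> list[TargetPair]:
    """Pairs predicted by both input sets, with both scores carried."""
    b_by_key = {p.key: p for p in set_b}
    out = []
    for pa in set_a:
        pb = b_by_key.get(pa.key)
        if pb is not None:
            out.append(
                TargetPair(pa.mirna_id, pa.target_id, source="intersection",
                           score=pa.score, score_b=pb.score)
            )
    return out


# ------------------------------------------------------- novel lncRNAs


def filter_novel_lncrna(candidates: Sequence[TranscriptAnnotation],
                        coding_scores: Mapping[str, tuple[float, float]],
                        min_length_bp: int = 200,
                        min_exons: int = 2) -> list[str]:
    """Novel-lncRNA filter: structure plus coding-potential intersection.

    A candidate is kept iff length > ``min_length_bp`` (strict), exon
    count >= ``min_exons``, and BOTH supplied coding-potential scores
    (e.g. CNCI and CPC, higher = more coding) are < 0.
    """
    kept = []
    for ann in candidates:
        if ann.feature_id not in coding_scores:
            raise CernakitError(
                f"missing coding-potential scores for {ann.feature_id!r}"
            )
        cnci, cpc = coding_scores[ann.feature_id]
        if (ann.length_bp > min_length_bp and ann.exon_count >= min_exons
                and cnci < 0 and cpc < 0):
            kept.append(ann.feature_id)
    return kept


# --------------------------------------------------------- lncRNA modes


def _span_distance(a: TranscriptAnnotation, b: TranscriptAnnotation) -> int:
    """Coordinate gap between two spans; 0 when they overlap or abut."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _span_overlap(a: TranscriptAnnotation, b: TranscriptAnnotation) -> int:
    return min(a.end, b.end) - max(a.start, b.start) + 1


def lnc_targets_cis(lncs: Sequence[TranscriptAnnotation],
                    genes: Sequence[TranscriptAnnotation],
                    window_bp: int = 100_000) -> list[LncTargetPair]:
    """cis mode: genes within ``window_bp`` of the lncRNA on the same
    chromosome (overlap counts as distance 0).  Evidence is the distance."""
    pairs = []
    for lnc in lncs:
        for gene in genes:
            if lnc.chrom != gene.chrom or lnc.feature_id == gene.feature_id:
                continue
            d = _span_distance(lnc, gene)
            if d <= window_bp:
                pairs.append(
                    LncTargetPair(lnc.feature_id, gene.feature_id, "cis", d)
                )
    return pairs


def lnc_targets_antisense(lncs: Sequence[TranscriptAnnotation],
                          genes: Sequence[TranscriptAnnotation],
                          min_overlap_bp: int = 1) -> list[LncTargetPair]:
    """antisense mode: opposite-strand span overlap on the same chromosome.

    Evidence is the overlap length in bp (inclusive coordinates).
    """
    pairs = []
    for lnc in lncs:
        for gene in genes:
            if lnc.chrom != gene.chrom or lnc.strand == gene.strand:
                continue
            ov = _span_overlap(lnc, gene)
            if ov >= min_overlap_bp:
                pairs.append(
                    LncTargetPair(lnc.feature_id, gene.feature_id,
                                  "antisense", ov)
                )
    return pairs


def lnc_targets_trans(expr: ExpressionMatrix,
                      lnc_ids: Sequence[str],
                      gene_ids: Sequence[str],
                      min_abs_pcc: float = 0.9) -> list[LncTargetPair]:
    """trans mode: |Pearson correlation| >= ``min_abs_pcc`` across all
    samples.  Constant-expression features are excluded with a logged
    warning.  Evidence is the signed correlation."""
    if len(expr.sample_ids) < 3:
        raise CernakitError("trans mode needs >= 3 samples")
    values = expr.values
    n_constant = 0

    def usable(fid: str) -> bool:
        nonlocal n_constant
        if np.std(values.loc[fid].to_numpy()) == 0:
            n_constant += 1
            return False
        return True

    lncs = [f for f in lnc_ids if usable(f)]
    genes = [f for f in gene_ids if usable(f)]
    if n_constant:
        logger.warning(
            "excluded %d constant-expression feature(s) from trans pairing",
            n_constant,
        )
    pairs = []
    for lnc in lncs:
        x = values.loc[lnc].to_numpy(dtype=float)
        for gene in genes:
            if lnc == gene:
                continue
            y = values.loc[gene].to_numpy(dtype=float)
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) >= min_abs_pcc:
                pairs.append(LncTargetPair(lnc, gene, "trans", r))
    return pairs
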
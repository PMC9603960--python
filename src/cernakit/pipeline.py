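"""End-to-end ceRNA pipeline: differential expression -> target
inference -> correlation-gated triplet assembly.

This is the procedure applied per comparison (H vs L): each biotype layer
is tested for differential expression on raw counts; miRNA targets are
the intersection of canonical seed matches with the supplied prediction
table; correlations are computed on log2(FPKM + 1) for transcript layers
and log2(CPM + 1) for miRNA tags, across all samples pooled; and every
competing triplet passing the SCC/PCC gates is assembled into a typed
network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .diffexpr import (
    DEConfig,
    compute_cpm,
    compute_fpkm,
    log2_layer,
    nb_de_test,
)
from .model import (
    CeRNANetwork,
    CeRNATriplet,
    DEResult,
    ExpressionMatrix,
    TargetPair,
)
from .network import (
    CeRNAConfig,
    assemble_triplets,
    build_network,
    negative_pairs,
    network_stats,
    positive_pairs,
)
from .targets import intersect_predictions, seed_match_targets, seed_matches_to_pairs


@dataclass
class PipelineResult:
    de_results: dict[str, list[DEResult]]  # biotype -> per-feature calls
    de_status: dict[str, str]
    target_pairs: list[TargetPair]
    triplets: list[CeRNATriplet]
    network: CeRNANetwork
    stats: dict = field(default_factory=dict)


def correlation_layers(matrices: Mapping[str, ExpressionMatrix],
                       lengths: Mapping[str, float],
                       log_scale: bool = True,
                       ) -> dict[str, ExpressionMatrix]:
    """Depth/length-normalized layers used for SCC/PCC.

    Transcript biotypes become log2(FPKM + 1); miRNA becomes
    log2(CPM + 1).  ``log_scale=False`` leaves FPKM/CPM raw.
    """
    layers = {}
    for bt, mat in matrices.items():
        norm = compute_cpm(mat) if bt == "miRNA" else compute_fpkm(mat, lengths)
        layers[bt] = log2_layer(norm) if log_scale else norm
    return layers


def run_pipeline(matrices: Mapping[str, ExpressionMatrix],
                 lengths: Mapping[str, float],
                 biotypes: Mapping[str, str],
                 target_table: Sequence[TargetPair],
                 mirna_seqs: Optional[Mapping[str, str]] = None,
                 target_seqs: Optional[Mapping[str, str]] = None,
                 de_config: Optional[DEConfig] = None,
                 cerna_config: Optional[CeRNAConfig] = None,
                 min_seed_class: str = "7mer-m8") -> PipelineResult:
    """Run DE, target inference and ceRNA assembly on count matrices.

    When sequences are given, the final miRNA-target set is the
    intersection of the imported ``target_table`` with canonical seed
    matches; otherwise the table is used as-is.
    """
    de_config = de_config or DEConfig()
    cerna_config = cerna_config or CeRNAConfig()

    de_results = {bt: nb_de_test(mat, de_config)
                  for bt, mat in matrices.items()}
    de_status = {r.feature_id: r.status
                 for results in de_results.values() for r in results}

    if mirna_seqs is not None and target_seqs is not None:
        matched = seed_matches_to_pairs(
            seed_match_targets(mirna_seqs, target_seqs, min_seed_class)
        )
        target_pairs = intersect_predictions(list(target_table), matched)
    else:
        target_pairs = list(target_table)

    layers = correlation_layers(matrices, lengths)
    status = de_status if cerna_config.require_de else None
    neg = negative_pairs(layers, target_pairs,
                         scc_max=cerna_config.scc_max, de_status=status)

    # candidate (ceRNA, mRNA) pairs: partners sharing a miRNA in neg edges
    by_mirna: dict[str, list[str]] = {}
    for e in neg:
        by_mirna.setdefault(e.id_a, []).append(e.id_b)
    candidates = set()
    for mirna, partners in by_mirna.items():
        cers = [p for p in partners if biotypes.get(p) in ("lncRNA", "circRNA")]
        mrnas = [p for p in partners if biotypes.get(p) == "mRNA"]
        for c in cers:
            for m in mrnas:
                candidates.add((c, m))
    pos = positive_pairs(layers, sorted(candidates),
                         pcc_min=cerna_config.pcc_min, de_status=status)

    triplets = assemble_triplets(neg, pos, target_pairs, biotypes)
    network = build_network(triplets)
    return PipelineResult(
        de_results=de_results, de_status=de_status,
        target_pairs=target_pairs, triplets=triplets,
        network=network, stats=network_stats(network),
    )
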
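"""Correlation-gated ceRNA triplet assembly and network construction.

The procedure: among differentially expressed features, miRNA-target
pairs with Spearman correlation strictly below ``scc_max`` (default -0.7)
become negative edges; candidate (ceRNA, mRNA) pairs with Pearson
correlation strictly above ``pcc_min`` (default 0.9) become positive
edges.  Every combination in which one miRNA holds negative edges to
both a ceRNA (lncRNA or circRNA) and an mRNA that are themselves
positively co-expressed is emitted as a competing triplet, and the
triplets are merged into a typed network with deduplicated edges.

Correlations are computed across all samples pooled (both phenotype
groups), on whatever layer the caller provides; log-scale layers are the
default upstream.  Zero-variance features yield an undefined correlation
and are excluded from pairing with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    CernakitError,
    CeRNANetwork,
    CeRNATriplet,
    CorrelationEdge,
    TargetPair,
)

logger = logging.getLogger(__name__)


@dataclass
class CeRNAConfig:
    """Correlation gates for pair selection (strict inequalities)."""

    scc_max: float = -0.7
    pcc_min: float = 0.9
    require_de: bool = True


# ------------------------------------------------------------ statistics


def spearman(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Tie-aware Spearman rank correlation; None if undefined.

    Defined as the Pearson correlation of average ranks.  Returns None
    (an undefined marker the caller must handle) when either vector has
    zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise CernakitError("spearman needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return pearson(rx, ry)


def pearson(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Pearson linear correlation; None if undefined (zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise CernakitError("pearson needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    xc = x - x.mean()
    yc = y - y.mean()
    # single sqrt of the product keeps r exact for integer-valued input
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    return max(-1.0, min(1.0, r))


# ------------------------------------------------------- pair selection


def _vector(expr_layers: Mapping[str, "object"], feature_id: str) -> np.ndarray:
    """Look a feature up across expression layers (one matrix per biotype)."""
    for matrix in expr_layers.values():
        if feature_id in matrix.values.index:
            return matrix.values.loc[feature_id].to_numpy(dtype=float)
    raise CernakitError(f"feature missing from expression layers: {feature_id!r}")


def _de_ok(feature_id: str, de_status: Optional[Mapping[str, str]]) -> bool:
    if de_status is None:
        return True
    return de_status.get(feature_id, "ns") != "ns"


def negative_pairs(expr_layers: Mapping[str, "object"],
                   target_pairs: Sequence[TargetPair],
                   scc_max: float = -0.7,
                   de_status: Optional[Mapping[str, str]] = None,
                   ) -> list[CorrelationEdge]:
    """miRNA-target pairs with Spearman correlation strictly < ``scc_max``.

    When ``de_status`` is given, both members must be differentially
    expressed (status != ns).  Pairs with an undefined correlation are
    dropped with a logged count.
    """
    edges = []
    n_undefined = 0
    for pair in target_pairs:
        if not (_de_ok(pair.mirna_id, de_status)
                and _de_ok(pair.target_id, de_status)):
            continue
        x = _vector(expr_layers, pair.mirna_id)
        y = _vector(expr_layers, pair.target_id)
        rho = spearman(x, y)
        if rho is None:
            n_undefined += 1
            continue
        if rho < scc_max:
            edges.append(
                CorrelationEdge(pair.mirna_id, pair.target_id, "SCC",
                                rho, x.size)
            )
    if n_undefined:
        logger.warning("dropped %d pair(s) with undefined SCC", n_undefined)
    return edges


def positive_pairs(expr_layers: Mapping[str, "object"],
                   candidate_pairs: Iterable[tuple[str, str]],
                   pcc_min: float = 0.9,
                   de_status: Optional[Mapping[str, str]] = None,
                   ) -> list[CorrelationEdge]:
    """(ceRNA, mRNA) pairs with Pearson correlation strictly > ``pcc_min``."""
    edges = []
    n_undefined = 0
    for id_a, id_b in candidate_pairs:
        if not (_de_ok(id_a, de_status) and _de_ok(id_b, de_status)):
            continue
        x = _vector(expr_layers, id_a)
        y = _vector(expr_layers, id_b)
        rho = pearson(x, y)
        if rho is None:
            n_undefined += 1
            continue
        if rho > pcc_min:
            edges.append(CorrelationEdge(id_a, id_b, "PCC", rho, x.size))
    if n_undefined:
        logger.warning("dropped %d pair(s) with undefined PCC", n_undefined)
    return edges


# -------------------------------------------------------------- assembly


def assemble_triplets(neg_edges: Sequence[CorrelationEdge],
                      pos_edges: Sequence[CorrelationEdge],
                      target_pairs: Sequence[TargetPair],
                      biotypes: Mapping[str, str]) -> list[CeRNATriplet]:
    """Enumerate all competing (ceRNA, miRNA, mRNA) triplets.

    A triplet is emitted iff (miRNA, ceRNA) and (miRNA, mRNA) are both
    negative edges, both are predicted targets of that miRNA, and
    (ceRNA, mRNA) is a positive edge.  Output is exhaustive and sorted
    lexicographically by (ceRNA, miRNA, mRNA).
    """
    targeted = {p.key for p in target_pairs}
    pos = {}
    for e in pos_edges:
        pos[(e.id_a, e.id_b)] = e.rho
        pos[(e.id_b, e.id_a)] = e.rho
    # negative edges grouped per miRNA, split by partner biotype
    by_mirna: dict[str, dict[str, list[tuple[str, float]]]] = {}
    for e in neg_edges:
        mirna, partner = e.id_a, e.id_b
        if biotypes.get(mirna) != "miRNA":
            mirna, partner = e.id_b, e.id_a
        if biotypes.get(mirna) != "miRNA":
            raise CernakitError(
                f"negative edge without a miRNA endpoint: {e.id_a}-{e.id_b}"
            )
        btype = biotypes.get(partner)
        if btype is None:
            raise CernakitError(f"untyped feature {partner!r}")
        if (mirna, partner) not in targeted:
            continue
        by_mirna.setdefault(mirna, {}).setdefault(btype, []).append(
            (partner, e.rho)
        )
    triplets = []
    for mirna, groups in by_mirna.items():
        mrnas = groups.get("mRNA", [])
        cernas = groups.get("lncRNA", []) + groups.get("circRNA", [])
        for cerna, rho_mc in cernas:
            for mrna, rho_mm in mrnas:
                rho_cm = pos.get((cerna, mrna))
                if rho_cm is None:
                    continue
                triplets.append(
                    CeRNATriplet(cerna, biotypes[cerna], mirna, mrna,
                                 rho_mc, rho_mm, rho_cm)
                )
    triplets.sort(key=lambda t: t.key)
    return triplets


def build_network(triplets: Sequence[CeRNATriplet]) -> CeRNANetwork:
    """Merge triplets into a typed network with deduplicated nodes/edges.

    miRNA edges are typed ``mirna_ceRNA`` / ``mirna_mRNA``; the
    ceRNA-mRNA edge is typed ``coexpression``.
    """
    net = CeRNANetwork(triplets=list(triplets))
    seen: set[tuple[str, str, str]] = set()
    for t in triplets:
        net.nodes.setdefault(t.mirna_id, "miRNA")
        net.nodes.setdefault(t.cerna_id, t.cerna_type)
        net.nodes.setdefault(t.mrna_id, "mRNA")
        for src, tgt, etype, rho in (
            (t.mirna_id, t.cerna_id, "mirna_ceRNA", t.scc_mirna_cerna),
            (t.mirna_id, t.mrna_id, "mirna_mRNA", t.scc_mirna_mrna),
            (t.cerna_id, t.mrna_id, "coexpression", t.pcc_cerna_mrna),
        ):
            key = (src, tgt, etype)
            if key not in seen:
                seen.add(key)
                net.edges.append((src, tgt, etype, rho))
    return net


def network_stats(network: CeRNANetwork) -> dict:
    """Node counts by biotype, edge counts by type, and the triplet count."""
    nodes_by_type: dict[str, int] = {}
    for btype in network.nodes.values():
        nodes_by_type[btype] = nodes_by_type.get(btype, 0) + 1
    edges_by_type: dict[str, int] = {}
    for _s, _t, etype, _r in network.edges:
        edges_by_type[etype] = edges_by_type.get(etype, 0) + 1
    return {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "nodes_by_type": nodes_by_type,
        "edges_by_type": edges_by_type,
        "n_triplets": len(network.triplets),
    }


def find_hubs(edges: Iterable[tuple[str, str]],
              min_degree: int = 3) -> list[str]:
    """Nodes of degree >= ``min_degree`` in a simple undirected graph,
    sorted by (degree desc, id).  Self-loops are rejected; parallel
    edges count once."""
    seen: set[frozenset] = set()
    degree: dict[str, int] = {}
    for a, b in edges:
        if a == b:
            raise CernakitError(f"self-loop on {a!r}")
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    hubs = [n for n, d in degree.items() if d >= min_degree]
    hubs.sort(key=lambda n: (-degree[n], n))
    return hubs
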
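"""Readers and writers for every external format the pipeline touches.

Counts are TSV (header = sample ids, first column = feature ids), group
labels a two-column TSV, annotations GTF, sequences FASTA, miRNA-target
tables TSV, and networks SIF or GraphML.  Readers reject malformed input
rather than silently coercing it.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional

import gffutils
import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CernakitError,
    CeRNANetwork,
    CeRNATriplet,
    ExpressionMatrix,
    TargetPair,
    TranscriptAnnotation,
)

# ---------------------------------------------------------------- counts


def read_groups(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV (sample_id, group) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] != 2:
        raise CernakitError(f"{path}: expected two columns (sample, group)")
    return dict(zip(df[0], df[1]))


def read_counts(path: str | os.PathLike, groups: Mapping[str, str],
                layer: str = "counts") -> ExpressionMatrix:
    """Read a feature x sample TSV into an :class:`ExpressionMatrix`.

    Row and column order are preserved.  Duplicate feature ids, empty or
    non-numeric cells and samples without a group label are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise CernakitError(f"{path}: duplicate feature ids: {dups}")
    if df.isna().any().any():
        r, c = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(df.at[r, c])
        )
        raise CernakitError(f"{path}: missing value at row {r!r}, column {c!r}")
    try:
        df = df.apply(pd.to_numeric).astype(float)
    except (ValueError, TypeError) as exc:
        raise CernakitError(f"{path}: non-numeric cell: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, dict(groups), layer=layer)


def write_counts(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = matrix.values
    # integer layers round-trip byte-identically
    if (df.to_numpy() % 1 == 0).all():
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="feature_id")


def write_groups(groups: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sample, grp in groups.items():
            fh.write(f"{sample}\t{grp}\n")


# ---------------------------------------------------------------- GTF


def read_gtf(path: str | os.PathLike,
             default_biotype: str = "mRNA") -> list[TranscriptAnnotation]:
    """Parse a GTF into one :class:`TranscriptAnnotation` per transcript.

    Transcript features define the span; exon lines populate the exon
    list (order-independent).  The ``biotype`` (or ``transcript_biotype``)
    attribute is honoured when present, else ``default_biotype`` is used.
    Coordinates stay 1-based inclusive.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    annotations: dict[str, TranscriptAnnotation] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for feat in db.all_features():
        if feat.featuretype not in ("transcript", "exon"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            raise CernakitError(
                f"{path}: {feat.featuretype} line without transcript_id"
            )
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append((feat.start, feat.end))
            continue
        biotype = (
            feat.attributes.get("biotype", [None])[0]
            or feat.attributes.get("transcript_biotype", [None])[0]
            or default_biotype
        )
        if tid in annotations:
            raise CernakitError(f"{path}: duplicate transcript_id {tid!r}")
        annotations[tid] = TranscriptAnnotation(
            feature_id=tid, biotype=biotype, chrom=feat.seqid,
            strand=feat.strand, start=feat.start, end=feat.end,
        )
        order.append(tid)
    out = []
    for tid in order:
        ann = annotations[tid]
        ann.exons = sorted(exons.get(tid, []))
        # re-validate exon placement against the transcript span
        out.append(
            TranscriptAnnotation(
                ann.feature_id, ann.biotype, ann.chrom, ann.strand,
                ann.start, ann.end, ann.exons,
            )
        )
    return out


def write_gtf(annotations: Iterable[TranscriptAnnotation],
              path: str | os.PathLike, source: str = "cernakit") -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            attrs = (
                f'transcript_id "{ann.feature_id}"; '
                f'biotype "{ann.biotype}";'
            )
            fh.write(
                f"{ann.chrom}\t{source}\ttranscript\t{ann.start}\t{ann.end}"
                f"\t.\t{ann.strand}\t.\t{attrs}\n"
            )
            for (s, e) in ann.exons:
                fh.write(
                    f"{ann.chrom}\t{source}\texon\t{s}\t{e}"
                    f"\t.\t{ann.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------- FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into an id -> uppercase sequence dict."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise CernakitError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- targets


def read_target_table(path: str | os.PathLike,
                      source: str = "imported_A") -> list[TargetPair]:
    """Read a (mirna_id, target_id[, score]) TSV into TargetPairs."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, comment="#")
    cols = list(df.columns)
    if len(cols) < 2:
        raise CernakitError(f"{path}: need at least mirna_id and target_id")
    pairs = []
    seen = set()
    for row in df.itertuples(index=False):
        mirna, target = str(row[0]), str(row[1])
        if (mirna, target) in seen:
            raise CernakitError(
                f"{path}: duplicate pair ({mirna!r}, {target!r})"
            )
        seen.add((mirna, target))
        score = float(row[2]) if len(cols) > 2 and pd.notna(row[2]) else None
        pairs.append(TargetPair(mirna, target, source=source, score=score))
    return pairs


def write_target_table(pairs: Iterable[TargetPair],
                       path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\ttarget_id\tscore\n")
        for p in pairs:
            score = "" if p.score is None else repr(p.score)
            fh.write(f"{p.mirna_id}\t{p.target_id}\t{score}\n")


# ---------------------------------------------------------------- networks


def _check_typed(network: CeRNANetwork) -> None:
    for src, tgt, _etype, _rho in network.edges:
        for node in (src, tgt):
            if node not in network.nodes or not network.nodes[node]:
                raise CernakitError(f"node with undefined type: {node!r}")


def write_network(network: CeRNANetwork, path: str | os.PathLike,
                  fmt: str = "SIF") -> None:
    """Export a ceRNA network as SIF (for Cytoscape) or GraphML.

    SIF carries one edge per line (``source<TAB>edgetype<TAB>target``);
    GraphML additionally carries node biotypes and edge correlations so the
    round-trip preserves node and edge counts and attributes.
    """
    _check_typed(network)
    if fmt.upper() == "SIF":
        with open(path, "w") as fh:
            for src, tgt, etype, _rho in network.edges:
                fh.write(f"{src}\t{etype}\t{tgt}\n")
    elif fmt.lower() == "graphml":
        g = nx.Graph()
        for node, biotype in network.nodes.items():
            g.add_node(node, biotype=biotype)
        for src, tgt, etype, rho in network.edges:
            g.add_edge(src, tgt, etype=etype, rho=rho)
        nx.write_graphml(g, str(path))
    else:
        raise CernakitError(f"unknown network format {fmt!r}")


def read_sif(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    """Read a SIF file back into (source, edgetype, target) tuples."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise CernakitError(f"{path}: malformed SIF line {line!r}")
            edges.append((parts[0], parts[1], parts[2]))
    return edges


def read_graphml_network(path: str | os.PathLike) -> CeRNANetwork:
    g = nx.read_graphml(str(path))
    net = CeRNANetwork()
    for node, data in g.nodes(data=True):
        net.nodes[node] = data.get("biotype", "")
    for src, tgt, data in g.edges(data=True):
        net.edges.append(
            (src, tgt, data.get("etype", ""), float(data.get("rho", 0.0)))
        )
    _check_typed(net)
    return net


# ---------------------------------------------------------------- triplets


def write_triplets(triplets: Iterable[CeRNATriplet],
                   path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cerna_id\tcerna_type\tmirna_id\tmrna_id\t"
            "scc_mirna_cerna\tscc_mirna_mrna\tpcc_cerna_mrna\n"
        )
        for t in triplets:
            fh.write(
                f"{t.cerna_id}\t{t.cerna_type}\t{t.mirna_id}\t{t.mrna_id}\t"
                f"{t.scc_mirna_cerna!r}\t{t.scc_mirna_mrna!r}\t"
                f"{t.pcc_cerna_mrna!r}\n"
            )


def read_triplets(path: str | os.PathLike) -> list[CeRNATriplet]:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str, 2: str, 3: str},
                     float_precision="round_trip")
    return [
        CeRNATriplet(
            r.cerna_id, r.cerna_type, r.mirna_id, r.mrna_id,
            float(r.scc_mirna_cerna), float(r.scc_mirna_mrna),
            float(r.pcc_cerna_mrna),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------- GMT


def read_gmt(path: str | os.PathLike) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file into term_id -> (description, gene set)."""
    term_map: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise CernakitError(f"{path}: GMT line with < 3 fields")
            term, desc, genes = parts[0], parts[1], parts[2:]
            if term in term_map:
                raise CernakitError(f"{path}: duplicate term {term!r}")
            term_map[term] = (desc, {g for g in genes if g})
    return term_map
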
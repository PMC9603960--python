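"""Synthetic multi-layer RNA-seq data with planted DE features and
planted ceRNA motifs.

The generator emulates a two-group (H vs L, 3 samples each) whole
transcriptome design: negative-binomial counts for four biotype layers
(mRNA, lncRNA, circRNA, miRNA), a configurable fraction of features
differentially expressed with |log2FC| >= 1, and planted competing
triplets in which a shared per-sample latent factor enters the miRNA
with coefficient -beta and the ceRNA/mRNA with +beta, so the miRNA is
monotonically negatively associated with both partners and the partners
positively with each other.  Planted targeting is realized twice over:
in the miRNA-target pair table and as perfect 8mer seed-complementary
sites written into the partner sequences.

Everything is reproducible from one master seed; each generation stage
draws from its own child stream keyed by a fixed stage label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CernakitError,
    ExpressionMatrix,
    TargetPair,
    TranscriptAnnotation,
)

_STAGES = {
    "structure": 1,
    "de": 2,
    "latent": 3,
    "counts": 4,
    "sequences": 5,
    "decoy_pairs": 6,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """Generative parameters; defaults are the desk-scale study conditions.

    Feature counts are scaled down roughly 20x from the study's
    transcriptome (which held ~21k mRNAs); the 3 vs 3 group design, NB
    count model and DE effect-size range (|log2FC| uniform on [1, 4])
    are kept.  Planted-motif parameters: the latent factor is
    z_s = delta * g_s + u_s with g_s = +-1/2 by group and
    u_s ~ N(0, latent_sd^2); members load on z with +-beta plus
    N(0, noise_sd^2) on the log2 scale, so each planted member carries a
    true group log2FC of +-beta*delta as well as the shared motif.
    """

    n_per_group: int = 3
    n_mrna: int = 1000
    n_lncrna: int = 500
    n_circrna: int = 650
    n_mirna: int = 100
    mean_log: float = 4.0       # lognormal(meanlog, sdlog) base means
    mean_sdlog: float = 1.0
    library_sdlog: float = 0.1  # per-sample depth factor spread
    dispersion: float = 0.1     # NB dispersion phi (1/size)
    fraction_de: float = 0.1
    lfc_range: tuple[float, float] = (1.0, 4.0)
    n_lnc_triplets: int = 20
    n_circ_triplets: int = 5
    motif_beta: float = 1.0
    motif_group_delta: float = 4.0
    motif_latent_sd: float = 0.5
    motif_noise_sd: float = 0.1   # sigma on the latent (log2) scale
    planted_base_mean: float = 400.0
    planted_dispersion: float = 0.01
    utr_length: int = 300
    mirna_length: int = 22
    n_decoy_target_pairs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise CernakitError("n_per_group must be >= 1")
        for name in ("n_mrna", "n_lncrna", "n_circrna", "n_mirna",
                     "n_lnc_triplets", "n_circ_triplets",
                     "n_decoy_target_pairs"):
            if getattr(self, name) < 0:
                raise CernakitError(f"{name} must be >= 0")
        if self.motif_noise_sd < 0 or self.motif_latent_sd < 0:
            raise CernakitError("noise sds must be >= 0")
        n_trip = self.n_lnc_triplets + self.n_circ_triplets
        if (self.n_lnc_triplets > self.n_lncrna
                or self.n_circ_triplets > self.n_circrna
                or n_trip > self.n_mrna or n_trip > self.n_mirna):
            raise CernakitError(
                "more planted triplets requested than available features"
            )


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset, for recovery scoring."""

    de_features: dict[str, float]  # feature -> true log2FC (H over L)
    planted_triplets: list[tuple[str, str, str]]  # (ceRNA, miRNA, mRNA)
    planted_types: dict[str, str]  # ceRNA id -> lncRNA | circRNA
    pair_correlations: dict[tuple[str, str], float]  # model-implied latent rho


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    matrices: dict[str, ExpressionMatrix]  # biotype -> counts
    annotations: list[TranscriptAnnotation]
    mirna_seqs: dict[str, str]
    target_seqs: dict[str, str]  # mRNA/lncRNA/circRNA sequences
    target_pairs: list[TargetPair]
    truth: SimulationTruth

    @property
    def lengths(self) -> dict[str, int]:
        return {a.feature_id: a.length_bp for a in self.annotations}

    @property
    def biotypes(self) -> dict[str, str]:
        return {a.feature_id: a.biotype for a in self.annotations}


def recovery_benchmark_config(seed: int = 0) -> SimulationConfig:
    """The standard recovery benchmark: 20 planted lncRNA triplets (60
    planted members) among exactly 2,000 decoy features across the four
    biotype layers, motif noise sd 0.1."""
    return SimulationConfig(
        n_mrna=1020, n_lncrna=520, n_circrna=400, n_mirna=120,
        n_lnc_triplets=20, n_circ_triplets=0,
        motif_noise_sd=0.1, seed=seed,
    )


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STAGES[stage]])


def _nb_sample(rng: np.random.Generator, mu: np.ndarray,
               phi: np.ndarray) -> np.ndarray:
    """NB(mean mu, dispersion phi) counts; phi -> 0 approaches Poisson."""
    phi = np.maximum(phi, 1e-12)
    r = 1.0 / phi
    p = r / (r + np.maximum(mu, 1e-300))
    return rng.negative_binomial(r, p)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate count matrices, annotations, sequences, a miRNA-target
    table and the ground truth, all reproducible from ``config.seed``."""
    cfg = config
    n = cfg.n_per_group
    samples = [f"H{i+1}" for i in range(n)] + [f"L{i+1}" for i in range(n)]
    groups = {s: s[0] for s in samples}
    g_sign = np.array([0.5 if s.startswith("H") else -0.5 for s in samples])

    ids = {
        "mRNA": [f"gene{i:05d}" for i in range(cfg.n_mrna)],
        "lncRNA": [f"lnc{i:05d}" for i in range(cfg.n_lncrna)],
        "circRNA": [f"circ{i:05d}" for i in range(cfg.n_circrna)],
        "miRNA": [f"mir{i:04d}" for i in range(cfg.n_mirna)],
    }

    # --- structure: base means, library factors, annotations ------------
    rng = _stage_rng(cfg.seed, "structure")
    base_mean = {
        bt: rng.lognormal(cfg.mean_log, cfg.mean_sdlog, size=len(fids))
        for bt, fids in ids.items()
    }
    libfac = {
        bt: rng.lognormal(0.0, cfg.library_sdlog, size=len(samples))
        for bt in ids
    }
    length_scale = {"mRNA": 1500, "lncRNA": 1000, "circRNA": 500}
    annotations: list[TranscriptAnnotation] = []
    for bt, fids in ids.items():
        for fid in fids:
            chrom = f"chr{rng.integers(1, 19)}"
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(1, 100_000_000))
            if bt == "miRNA":
                length = cfg.mirna_length
                exons: list[tuple[int, int]] = []
                end = start + length - 1
            else:
                length = max(230, int(rng.lognormal(
                    np.log(length_scale[bt]), 0.4)))
                if bt == "circRNA":
                    exons = []
                    end = start + length - 1
                else:
                    # two exons split the transcript length around an intron
                    l1 = max(1, length // 2)
                    l2 = length - l1
                    intron = int(rng.integers(100, 5000))
                    e1 = (start, start + l1 - 1)
                    e2 = (e1[1] + intron + 1, e1[1] + intron + l2)
                    exons = [e1, e2]
                    end = e2[1]
            annotations.append(
                TranscriptAnnotation(fid, bt, chrom, strand, start, end, exons)
            )

    # --- planted motifs and DE assignment -------------------------------
    rng = _stage_rng(cfg.seed, "de")
    n_trip = cfg.n_lnc_triplets + cfg.n_circ_triplets
    pick = lambda pool, k: [pool[i] for i in
                            rng.choice(len(pool), size=k, replace=False)]
    trip_mirnas = pick(ids["miRNA"], n_trip)
    trip_mrnas = pick(ids["mRNA"], n_trip)
    trip_lncs = pick(ids["lncRNA"], cfg.n_lnc_triplets)
    trip_circs = pick(ids["circRNA"], cfg.n_circ_triplets)
    cernas = trip_lncs + trip_circs
    planted_triplets = list(zip(cernas, trip_mirnas, trip_mrnas))
    planted_types = {c: "lncRNA" for c in trip_lncs}
    planted_types.update({c: "circRNA" for c in trip_circs})
    planted_members = set(cernas) | set(trip_mirnas) | set(trip_mrnas)

    de_features: dict[str, float] = {}
    lfc_lo, lfc_hi = cfg.lfc_range
    for bt, fids in ids.items():
        free = [f for f in fids if f not in planted_members]
        n_de = int(round(cfg.fraction_de * len(fids)))
        n_de = min(n_de, len(free))
        for f in pick(free, n_de) if n_de else []:
            mag = rng.uniform(lfc_lo, lfc_hi)
            de_features[f] = float(mag if rng.random() < 0.5 else -mag)

    # planted members carry group log2FC +-beta*delta through the latent;
    # the coupling sign alternates across triplets so planted features do
    # not skew library composition in one direction
    member_lfc = cfg.motif_beta * cfg.motif_group_delta
    motif_sign = [1 if j % 2 == 0 else -1 for j in range(n_trip)]
    for s, (cerna, mirna, mrna) in zip(motif_sign, planted_triplets):
        de_features[mirna] = -s * member_lfc
        de_features[cerna] = s * member_lfc
        de_features[mrna] = s * member_lfc

    # --- latent factors for planted motifs ------------------------------
    rng = _stage_rng(cfg.seed, "latent")
    motif_effect: dict[str, np.ndarray] = {}  # feature -> log2-scale shift
    pair_corr: dict[tuple[str, str], float] = {}
    var_z = cfg.motif_group_delta**2 / 4.0 + cfg.motif_latent_sd**2
    signal = cfg.motif_beta**2 * var_z
    rho_model = signal / (signal + cfg.motif_noise_sd**2)
    for s, (cerna, mirna, mrna) in zip(motif_sign, planted_triplets):
        z = (s * cfg.motif_group_delta * g_sign
             + cfg.motif_latent_sd * rng.standard_normal(len(samples)))
        eps = cfg.motif_noise_sd * rng.standard_normal((3, len(samples)))
        motif_effect[mirna] = -cfg.motif_beta * z + eps[0]
        motif_effect[cerna] = cfg.motif_beta * z + eps[1]
        motif_effect[mrna] = cfg.motif_beta * z + eps[2]
        pair_corr[(mirna, cerna)] = -rho_model
        pair_corr[(mirna, mrna)] = -rho_model
        pair_corr[(cerna, mrna)] = rho_model

    # --- counts ----------------------------------------------------------
    rng = _stage_rng(cfg.seed, "counts")
    matrices: dict[str, ExpressionMatrix] = {}
    for bt, fids in ids.items():
        log2mu = np.log2(base_mean[bt])[:, None] + np.log2(libfac[bt])[None, :]
        phi = np.full((len(fids), 1), cfg.dispersion)
        for i, fid in enumerate(fids):
            if fid in planted_members:
                log2mu[i] = (np.log2(cfg.planted_base_mean)
                             + np.log2(libfac[bt])
                             + motif_effect[fid])
                phi[i] = cfg.planted_dispersion
            elif fid in de_features:
                log2mu[i] = log2mu[i] + de_features[fid] * g_sign
        counts = _nb_sample(rng, 2.0**log2mu, phi)
        matrices[bt] = ExpressionMatrix(
            pd.DataFrame(counts, index=fids, columns=samples, dtype=float),
            groups, layer="counts",
        )

    # --- sequences with planted seed sites -------------------------------
    rng = _stage_rng(cfg.seed, "sequences")
    mirna_seqs = {m: _random_seq(rng, cfg.mirna_length) for m in ids["miRNA"]}
    target_seqs = {
        f: _random_seq(rng, cfg.utr_length)
        for bt in ("mRNA", "lncRNA", "circRNA") for f in ids[bt]
    }
    for cerna, mirna, mrna in planted_triplets:
        site = _revcomp(mirna_seqs[mirna][1:8]) + "A"  # perfect 8mer site
        for tid in (cerna, mrna):
            seq = target_seqs[tid]
            pos = int(rng.integers(0, len(seq) - len(site) + 1))
            target_seqs[tid] = seq[:pos] + site + seq[pos + len(site):]

    # --- target-pair table: planted + decoy predictions ------------------
    rng = _stage_rng(cfg.seed, "decoy_pairs")
    pairs: list[TargetPair] = []
    seen: set[tuple[str, str]] = set()
    for cerna, mirna, mrna in planted_triplets:
        for tgt in (cerna, mrna):
            pairs.append(TargetPair(mirna, tgt, source="simulated"))
            seen.add((mirna, tgt))
    all_targets = ids["mRNA"] + ids["lncRNA"] + ids["circRNA"]
    n_decoy = 0
    while n_decoy < cfg.n_decoy_target_pairs:
        m = ids["miRNA"][rng.integers(len(ids["miRNA"]))]
        t = all_targets[rng.integers(len(all_targets))]
        if (m, t) in seen:
            continue
        seen.add((m, t))
        pairs.append(TargetPair(m, t, source="simulated"))
        n_decoy += 1

    truth = SimulationTruth(
        de_features=de_features,
        planted_triplets=planted_triplets,
        planted_types=planted_types,
        pair_correlations=pair_corr,
    )
    return SimulatedDataset(
        config=cfg, matrices=matrices, annotations=annotations,
        mirna_seqs=mirna_seqs, target_seqs=target_seqs,
        target_pairs=pairs, truth=truth,
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write a simulated dataset in the dialects the readers consume:
    one counts TSV per biotype, a groups TSV, a GTF, two FASTAs, the
    miRNA-target table and the ground-truth tables."""
    import os

    from . import io as cio

    os.makedirs(outdir, exist_ok=True)
    join = lambda name: os.path.join(str(outdir), name)
    for bt, mat in dataset.matrices.items():
        cio.write_counts(mat, join(f"counts_{bt}.tsv"))
    any_mat = next(iter(dataset.matrices.values()))
    cio.write_groups(any_mat.groups, join("groups.tsv"))
    cio.write_gtf(dataset.annotations, join("annotations.gtf"))
    cio.write_fasta(dataset.mirna_seqs, join("mirna.fa"))
    cio.write_fasta(dataset.target_seqs, join("targets.fa"))
    cio.write_target_table(dataset.target_pairs, join("target_pairs.tsv"))
    with open(join("truth_triplets.tsv"), "w") as fh:
        fh.write("cerna_id\tcerna_type\tmirna_id\tmrna_id\n")
        for cerna, mirna, mrna in dataset.truth.planted_triplets:
            fh.write(f"{cerna}\t{dataset.truth.planted_types[cerna]}"
                     f"\t{mirna}\t{mrna}\n")
    with open(join("truth_de.tsv"), "w") as fh:
        fh.write("feature_id\ttrue_log2fc\n")
        for fid, lfc in dataset.truth.de_features.items():
            fh.write(f"{fid}\t{lfc!r}\n")


def score_recovery(called: Sequence, truth: SimulationTruth,
                   ) -> tuple[float, Optional[float]]:
    """Sensitivity and precision of called triplets against the truth.

    ``called`` holds triplets (objects with ``.key`` or plain
    (ceRNA, miRNA, mRNA) tuples).  With no calls, precision is undefined
    and returned as None.
    """
    called_keys = {
        t.key if hasattr(t, "key") else tuple(t) for t in called
    }
    planted = {tuple(t) for t in truth.planted_triplets}
    hits = len(called_keys & planted)
    sensitivity = hits / len(planted) if planted else 1.0
    precision = hits / len(called_keys) if called_keys else None
    return sensitivity, precision
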
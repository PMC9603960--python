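"""Normalization and negative-binomial differential expression.

The DE engine is a self-contained gene-wise negative-binomial Wald test:
library sizes by median-of-ratios, NB dispersion by method of moments, and
a Wald statistic on the difference of log group means with a delta-method
variance.  Calls use the conventional RNA-seq gate p < 0.05 and
|log2 fold-change| >= 1 (fold change is H over L), applied with the p
comparison strict and the fold-change comparison inclusive.

miRNA tag counts are depth-normalized per million without a length term
(``compute_cpm``); transcript-level biotypes use FPKM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CernakitError, DEResult, ExpressionMatrix

_DISPERSION_FLOOR = 1e-8


@dataclass
class DEConfig:
    """Thresholds and conventions for differential-expression calls."""

    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    pseudocount: float = 0.5
    adjust: str = "none"  # none | BH

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.lfc_threshold <= 0:
            raise CernakitError("thresholds must be > 0")
        if self.adjust not in ("none", "BH"):
            raise CernakitError(f"unknown adjust setting {self.adjust!r}")


# ---------------------------------------------------------------- scaling


def compute_fpkm(counts: ExpressionMatrix,
                 lengths: Mapping[str, float]) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM_gs = counts_gs / (length_g/1e3 * total_s/1e6), with total_s the
    column sum of raw counts.  Satisfies the per-sample identity
    sum_g FPKM_gs * length_g(kb) = 1e6.
    """
    if counts.layer != "counts":
        raise CernakitError("compute_fpkm expects a counts layer")
    totals = counts.values.sum(axis=0)
    zero = [s for s, t in totals.items() if t <= 0]
    if zero:
        raise CernakitError(f"zero column total for sample(s): {zero}")
    missing = [g for g in counts.feature_ids if g not in lengths]
    if missing:
        raise CernakitError(f"features without a length: {missing[:5]}")
    kb = pd.Series({g: lengths[g] / 1e3 for g in counts.feature_ids})
    if (kb <= 0).any():
        raise CernakitError("all feature lengths must be > 0")
    fpkm = counts.values.div(totals / 1e6, axis=1).div(kb, axis=0)
    return ExpressionMatrix(fpkm, dict(counts.groups), layer="fpkm")


def compute_cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts (tags) per million; the small-RNA analogue of FPKM."""
    totals = counts.values.sum(axis=0)
    zero = [s for s, t in totals.items() if t <= 0]
    if zero:
        raise CernakitError(f"zero column total for sample(s): {zero}")
    cpm = counts.values.div(totals / 1e6, axis=1)
    return ExpressionMatrix(cpm, dict(counts.groups), layer="cpm")


def log2_layer(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(x + offset) transform used before correlation analysis."""
    return ExpressionMatrix(
        np.log2(matrix.values + offset), dict(matrix.groups),
        layer=f"log2{matrix.layer}",
    )


# ---------------------------------------------------------------- DE test


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    Ratios are taken to the geometric mean across samples over features
    expressed in every sample; if no feature is positive everywhere the
    estimator degenerates and total-count scaling is used instead.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.any():
        loggeo = np.log(arr[positive]).mean(axis=1, keepdims=True)
        sf = np.exp(np.median(np.log(arr[positive]) - loggeo, axis=0))
    else:
        totals = arr.sum(axis=0)
        sf = totals / np.exp(np.log(totals).mean())
    return pd.Series(sf, index=counts.columns)


def _group_moments(x: np.ndarray) -> tuple[float, float]:
    return float(x.mean()), float(x.var(ddof=1))


def nb_de_test(counts: ExpressionMatrix,
               config: DEConfig | None = None) -> list[DEResult]:
    """Gene-wise NB Wald test of H vs L on normalized counts.

    Per feature: the within-group variance pooled across the two groups
    gives a method-of-moments dispersion phi = (var - mean)/mean^2 floored
    at 1e-8; the Wald statistic contrasts log normalized group means with
    delta-method variance (1/mu + phi)/n per group.  Features with zero
    counts everywhere get p = 1, log2fc = 0, status ``ns``.
    """
    config = config or DEConfig()
    if counts.layer != "counts":
        raise CernakitError("nb_de_test expects raw counts")
    h_samples = counts.samples_in("H")
    l_samples = counts.samples_in("L")
    if len(h_samples) < 2 or len(l_samples) < 2:
        raise CernakitError("each group needs >= 2 samples")

    sf = size_factors(counts.values)
    norm = counts.values.div(sf, axis=1)
    H = norm[h_samples].to_numpy(dtype=float)
    L = norm[l_samples].to_numpy(dtype=float)
    nH, nL = H.shape[1], L.shape[1]
    c = config.pseudocount

    results: list[DEResult] = []
    for i, fid in enumerate(counts.feature_ids):
        xh, xl = H[i], L[i]
        mh, vh = _group_moments(xh)
        ml, vl = _group_moments(xl)
        if mh == 0 and ml == 0:
            results.append(DEResult(fid, 0.0, 0.0, 0.0, 1.0, 1.0, "ns"))
            continue
        log2fc = math.log2((mh + c) / (ml + c))
        # pooled within-group MoM dispersion, floored
        pooled_mean = (nH * mh + nL * ml) / (nH + nL)
        pooled_var = ((nH - 1) * vh + (nL - 1) * vl) / (nH + nL - 2)
        phi = _DISPERSION_FLOOR
        if pooled_mean > 0:
            phi = max((pooled_var - pooled_mean) / pooled_mean**2,
                      _DISPERSION_FLOOR)
        # delta-method variance of log mean; pseudocount keeps zero-mean
        # groups finite
        var_log = (1.0 / (mh + c) + phi) / nH + (1.0 / (ml + c) + phi) / nL
        z = (math.log(mh + c) - math.log(ml + c)) / math.sqrt(var_log)
        # t reference with nH+nL-2 df: the dispersion is estimated from
        # the same few samples, so the normal reference is anticonservative
        p = 2.0 * stats.t.sf(abs(z), df=nH + nL - 2)
        results.append(DEResult(fid, mh, ml, log2fc, float(p), float(p), "ns"))

    if config.adjust == "BH":
        pvals = [r.p_value for r in results]
        _, padj, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, padj):
            r.p_adj = float(q)
    return classify_de(results, config)


def classify_de(results: Sequence[DEResult],
                config: DEConfig | None = None) -> list[DEResult]:
    """Assign up/down/ns status from log2fc and p.

    Up: log2fc >= +threshold and p < p_threshold; down: log2fc <=
    -threshold and p < p_threshold; otherwise ns.  The magnitude
    comparison is inclusive and the p comparison strict.
    """
    config = config or DEConfig()
    out = []
    for r in results:
        status = "ns"
        if r.p_value < config.p_threshold:
            if r.log2fc >= config.lfc_threshold:
                status = "up"
            elif r.log2fc <= -config.lfc_threshold:
                status = "down"
        r.status = status
        out.append(r)
    return out


def de_table(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "baseMeanH": [r.mean_H for r in results],
            "baseMeanL": [r.mean_L for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p_value for r in results],
            "padj": [r.p_adj for r in results],
            "status": [r.status for r in results],
        }
    ).set_index("feature_id")


# ---------------------------------------------------------------- qPCR


def ddct(ct_target: Sequence[float] | float,
         ct_reference: Sequence[float] | float,
         calibrator_delta: float = 0.0) -> np.ndarray | float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference); ddCt = dCt - calibrator_delta;
    returns 2 ** (-ddCt).
    """
    tgt = np.asarray(ct_target, dtype=float)
    ref = np.asarray(ct_reference, dtype=float)
    if not (np.all(np.isfinite(tgt)) and np.all(np.isfinite(ref))):
        raise CernakitError("Ct values must be finite")
    rel = 2.0 ** (-(tgt - ref - calibrator_delta))
    if rel.ndim == 0:
        return float(rel)
    return rel
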
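"""Over-representation analysis of gene lists against term -> gene maps.

The statistic is the upper-tail hypergeometric probability P[X >= k] of
drawing k term members in a selection of size n from a universe of size N
containing K term members, with Benjamini-Hochberg adjustment across the
tested terms.  Term content (GO/KEGG or anything else) is supplied by the
caller, e.g. from a GMT file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CernakitError


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # selected genes in term
    K: int  # term size within universe
    n: int  # selection size
    N: int  # universe size
    p_value: float
    p_adj: float


def hypergeom_enrich(selected: Iterable[str],
                     universe: Iterable[str],
                     term_map: Mapping[str, tuple[str, set[str]]],
                     ) -> list[EnrichmentResult]:
    """One-sided over-representation test per term.

    Terms are intersected with the universe first; terms with no selected
    member are reported with p = 1.  Results are sorted by raw p then term
    id, so output is invariant to term iteration order.
    """
    selected = set(selected)
    universe = set(universe)
    stray = sorted(selected - universe)
    if stray:
        raise CernakitError(f"selected ids outside the universe: {stray}")
    N, n = len(universe), len(selected)
    results = []
    for term_id in sorted(term_map):
        name, genes = term_map[term_id]
        members = genes & universe
        K = len(members)
        k = len(members & selected)
        # P[X >= k]; sf(k-1) is the exact upper tail
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term_id, name, k, K, n, N, min(p, 1.0), 1.0))
    if results:
        _, padj, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        for r, q in zip(results, padj):
            r.p_adj = float(q)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
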
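"""Gene-set over-representation and 2x2 Fisher exact testing.

Over-representation of a query gene list within catalog sets is tested with
a one-sided hypergeometric against the supplied universe (the genes on the
expression platform / annotation table, not the genome).  Display selection
mirrors the standard heat-map filters: sets smaller than ``max_set_size``
total members, BH-corrected p below ``max_bh_p``, and coverage (fraction of
the query annotated to the set, k/n) of at least ``min_coverage``.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import hypergeom_p
from .stats_util import bh_adjust


def fold_enrichment(k: int, K: int, n: int, N: int) -> float:
    """(k/n) / (K/N): query hit rate over the universe-wide rate."""
    if n == 0 or K == 0:
        return 0.0
    return float((k / n) / (K / N))

log = logging.getLogger("epismoke")

DEFAULT_MAX_SET_SIZE = 2000
DEFAULT_MAX_BH_P = 0.01
DEFAULT_MIN_COVERAGE = 0.10


def geneset_enrichment(
    query_genes,
    universe,
    catalog: dict[str, tuple[str, tuple[str, ...]]],
    max_set_size: int = DEFAULT_MAX_SET_SIZE,
    max_bh_p: float = DEFAULT_MAX_BH_P,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    ease: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hypergeometric over-representation of query genes in catalog sets.

    ``ease=True`` applies the EASE-style penalty (k reduced by one in the
    p-value) for comparability with hosted annotation tools.
    Returns (full, selected) tables.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    query = {str(g).upper() for g in query_genes}
    uni = {str(g).upper() for g in universe}
    outside = sorted(query - uni)
    if outside:
        raise ValueError(
            f"{len(outside)} query genes absent from universe, e.g. {outside[:5]}"
        )
    n, N = len(query), len(uni)
    rows = []
    for set_id, (desc, members) in catalog.items():
        mem = {m.upper() for m in members}
        K = len(uni & mem)
        k = len(query & mem)
        p = hypergeom_p(max(k - 1, 0) if ease else k, K, n, N)
        rows.append(
            {
                "id": set_id,
                "description": desc,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "total_members": len(mem),
                "fraction_target": k / n if n else 0.0,
                "fraction_background": (K - k) / (N - n) if N > n else np.nan,
                "fold_change": fold_enrichment(k, K, n, N),
                "coverage": k / n if n else 0.0,
                "p": p,
            }
        )
    full = pd.DataFrame(rows)
    full["q"] = bh_adjust(full["p"].to_numpy())
    full["selected"] = (
        (full["total_members"] < max_set_size)
        & (full["q"] < max_bh_p)
        & (full["coverage"] >= min_coverage)
    )
    selected = full[full["selected"]].reset_index(drop=True)
    log.info(
        "gene-set enrichment: query=%d universe=%d sets=%d selected=%d",
        n, N, len(full), len(selected),
    )
    return full, selected


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2x2 table [[a, b], [c, d]].

    Returns (odds_ratio, p).  The odds ratio is (a*d)/(b*c); inf when
    b*c = 0 with a*d > 0, and reported as 1 for degenerate tables with
    a*d = b*c = 0.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("table total must be positive")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = float("inf") if ad > 0 else 1.0
    else:
        odds = ad / bc
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)
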
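"""Chromatin-expression integration.

Genes are grouped by the class and TSS-proximity zone of their assigned
peaks; each group's per-day differential-expression t statistics are compared
against the t statistics of all other tested genes with a pooled two-sample t
(the "meta-T").  A negative meta-T means the peak-associated genes are more
smoke-down-regulated than the rest of the transcriptome that day.
"""
from __future__ import annotations

import logging
from dataclasses import asdict

import pandas as pd

from .genesets import fisher_2x2
from .stats_util import pooled_t, welch_t
from .types import MetaTResult, Peak

log = logging.getLogger("epismoke")


def peak_gene_sets(
    assignments: pd.DataFrame, peaks: list[Peak], zone: str
) -> dict[str, set[str]]:
    """Per peak class, the genes with >=1 assigned peak in the given zone.

    A gene linked to peaks of several classes appears in several sets;
    duplicate links to the same class count once.
    """
    labels = {p.name: p.label for p in peaks}
    unknown = sorted(set(assignments["peak_name"]) - set(labels))
    if unknown:
        raise ValueError(f"assignments reference unknown peaks, e.g. {unknown[:5]}")
    out: dict[str, set[str]] = {}
    sub = assignments[
        (assignments["zone"] == zone) & assignments["gene_id"].notna()
    ]
    for row in sub.itertuples(index=False):
        label = labels[row.peak_name]
        if label is None:
            raise ValueError(f"peak {row.peak_name!r} is unclassified")
        out.setdefault(label, set()).add(str(row.gene_id))
    return out


def meta_t(
    de_results: pd.DataFrame,
    gene_set,
    day: int | None = None,
    peak_class: str = "",
    zone: str = "",
    welch: bool = False,
) -> MetaTResult:
    """Compare in-set vs out-of-set differential-expression t statistics.

    ``de_results`` must carry one day's results (columns gene_id, t_stat,
    day).  Genes without a t statistic are simply not part of either group.
    """
    genes = set(str(g) for g in gene_set)
    days = set(de_results["day"]) if "day" in de_results else {day}
    if len(days) != 1:
        raise ValueError("de_results must contain a single day")
    the_day = int(day if day is not None else next(iter(days)))
    in_mask = de_results["gene_id"].astype(str).isin(genes)
    t_in = de_results.loc[in_mask, "t_stat"].to_numpy()
    t_out = de_results.loc[~in_mask, "t_stat"].to_numpy()
    if t_in.size == 0:
        raise ValueError("gene set is disjoint from the tested genes")
    if t_in.size < 2 or t_out.size < 2:
        raise ValueError("need >= 2 genes in both the set and its complement")
    stat_fn = welch_t if welch else pooled_t
    t, p, _ = stat_fn(t_in, t_out)
    return MetaTResult(
        day=the_day, peak_class=peak_class, zone=zone,
        n_in=int(t_in.size), n_out=int(t_out.size),
        meta_t=t, p=p,
    )


def integration_grid(
    de_by_day: dict[int, pd.DataFrame],
    class_gene_sets: dict[str, dict[str, set[str]]],
    welch: bool = False,
) -> pd.DataFrame:
    """Full day x class x zone grid of meta-T comparisons.

    ``class_gene_sets`` maps zone -> {peak_class -> gene set}.
    """
    missing = sorted(set((1, 2, 4)) - set(de_by_day))
    if missing:
        raise ValueError(f"missing differential-expression days: {missing}")
    rows = []
    for day in sorted(de_by_day):
        for zone in class_gene_sets:
            for peak_class in sorted(class_gene_sets[zone]):
                res = meta_t(
                    de_by_day[day],
                    class_gene_sets[zone][peak_class],
                    day=day,
                    peak_class=peak_class,
                    zone=zone,
                    welch=welch,
                )
                rows.append(asdict(res))
    grid = pd.DataFrame(rows)
    log.info("integration grid: %d comparisons", len(grid))
    return grid


def overlap_de_sets(our_de_genes, external_de_genes, universe) -> dict:
    """Fisher test of overlap between two DE gene sets within a universe."""
    ours = {str(g) for g in our_de_genes}
    ext = {str(g) for g in external_de_genes}
    uni = {str(g) for g in universe}
    stray = sorted((ours | ext) - uni)
    if stray:
        raise ValueError(
            f"{len(stray)} genes outside the universe, e.g. {stray[:5]}"
        )
    a = len(ours & ext)
    b = len(ours - ext)
    c = len(ext - ours)
    d = len(uni) - a - b - c
    odds, p = fisher_2x2(a, b, c, d)
    return {
        "in_both": a, "ours_only": b, "external_only": c, "neither": d,
        "odds_ratio": odds, "p": p,
    }
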
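"""Peak-to-gene annotation by TSS proximity and region-overlap comparison.

Each peak is assigned to the gene whose TSS is nearest to the peak midpoint
on the same chromosome.  Distances are signed relative to gene orientation
(upstream negative).  Zones follow the 1 kb / 100 kb convention: |d| <= 1 kb
proximal, 1 kb < |d| <= 100 kb distal, beyond that remote (boundaries
inclusive in the nearer zone).
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .types import DISTAL_BP, PROXIMAL_BP, Peak

log = logging.getLogger("epismoke")


def zone_classify(distance: float) -> str:
    """Classify a signed TSS distance into proximal / distal / remote."""
    if distance is None or (isinstance(distance, float) and math.isnan(distance)):
        return "remote"
    d = abs(distance)
    if d <= PROXIMAL_BP:
        return "proximal"
    if d <= DISTAL_BP:
        return "distal"
    return "remote"


def assign_nearest_tss(peaks: list[Peak], tss_table: pd.DataFrame) -> pd.DataFrame:
    """Assign every peak to its nearest TSS.

    Returns a DataFrame with columns peak_name, gene_id, distance, zone,
    label (the peak's class if set).  Peaks on chromosomes absent from the
    TSS table get gene_id=None / zone=remote and a warning.

    Ties in |distance| are broken by the lexicographically smaller gene_id.
    """
    if len(tss_table) == 0:
        raise ValueError("TSS table is empty")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in tss_table.groupby("chrom", sort=False):
        sub = sub.sort_values(["tss", "gene_id"], kind="mergesort")
        by_chrom[str(chrom)] = (
            sub["tss"].to_numpy(dtype=np.int64),
            sub["gene_id"].to_numpy(dtype=object),
            sub["strand"].to_numpy(dtype=object),
        )

    rows = []
    n_missing = 0
    for p in peaks:
        chrom = p.interval.chrom
        mid = p.interval.midpoint
        if chrom not in by_chrom:
            n_missing += 1
            rows.append((p.name, None, np.nan, "remote", p.label))
            continue
        pos, genes, strands = by_chrom[chrom]
        i = int(np.searchsorted(pos, mid))
        candidates = [j for j in (i - 1, i) if 0 <= j < len(pos)]
        dmin = min(abs(mid - int(pos[j])) for j in candidates)
        # widen to all TSS at exactly dmin (duplicate positions possible)
        best: list[int] = []
        j = i - 1
        while j >= 0 and abs(mid - int(pos[j])) == dmin:
            best.append(j)
            j -= 1
        j = i
        while j < len(pos) and abs(mid - int(pos[j])) == dmin:
            best.append(j)
            j += 1
        k = min(best, key=lambda j: str(genes[j]))
        d = mid - int(pos[k])
        if strands[k] == "-":
            d = -d
        rows.append((p.name, str(genes[k]), float(d), zone_classify(d), p.label))
    if n_missing:
        log.warning(
            "%d peaks on chromosomes absent from the TSS table", n_missing
        )
    out = pd.DataFrame(
        rows, columns=["peak_name", "gene_id", "distance", "zone", "label"]
    )
    log.info(
        "assigned %d peaks to nearest TSS: %s",
        len(out), out["zone"].value_counts().to_dict(),
    )
    return out


def zone_percentages(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-class zone percentage table (rows sum to 100)."""
    tab = (
        assignments.groupby(["label", "zone"]).size().unstack(fill_value=0)
    )
    for z in ("proximal", "distal", "remote"):
        if z not in tab.columns:
            tab[z] = 0
    tab = tab[["proximal", "distal", "remote"]]
    return 100.0 * tab.div(tab.sum(axis=1), axis=0)


def filter_regions(regions: pd.DataFrame, min_reads: float) -> pd.DataFrame:
    """Keep regions with count > min_reads in every per-sample count column."""
    count_cols = [c for c in regions.columns if c.startswith("count_")]
    if not count_cols:
        raise ValueError("region table has no count columns")
    if regions[count_cols].isna().any().any():
        raise ValueError("region table has missing count values")
    keep = (regions[count_cols] > min_reads).all(axis=1)
    out = regions[keep].reset_index(drop=True)
    log.info(
        "region filter (count > %s in all of %d samples): %d of %d retained",
        min_reads, len(count_cols), len(out), len(regions),
    )
    return out


def _any_overlap(peak: Peak, starts: np.ndarray, ends: np.ndarray) -> bool:
    """Does the peak overlap (>=1 bp, half-open) any of the sorted regions?"""
    i = int(np.searchsorted(starts, peak.interval.end))  # regions starting before peak end
    if i == 0:
        return False
    return bool((ends[:i] > peak.interval.start).any())


def overlap_with_regions(
    peaks: list[Peak],
    region_sets: dict[str, pd.DataFrame],
    min_reads: float = 10,
) -> pd.DataFrame:
    """Annotate each peak with the read-filtered region sets it overlaps.

    ``region_sets`` maps a set name (e.g. "air", "smoke") to a region table
    with per-sample count columns; each table is filtered with
    :func:`filter_regions` before intersection.  The returned table has one
    boolean column per set plus a ``category`` column: "both" (all sets),
    "neither", or "<name>-only" style membership.
    """
    if not region_sets:
        raise ValueError("no region sets given")
    filtered = {}
    for name, df in region_sets.items():
        kept = filter_regions(df, min_reads)
        by_chrom = {}
        for chrom, sub in kept.groupby("chrom", sort=False):
            sub = sub.sort_values("start", kind="mergesort")
            by_chrom[str(chrom)] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
            )
        filtered[name] = by_chrom

    names = list(region_sets)
    rows = []
    for p in peaks:
        hits = {}
        for name in names:
            by_chrom = filtered[name]
            if p.interval.chrom in by_chrom:
                starts, ends = by_chrom[p.interval.chrom]
                hits[name] = _any_overlap(p, starts, ends)
            else:
                hits[name] = False
        hit_names = [n for n in names if hits[n]]
        if len(hit_names) == len(names):
            category = "both" if len(names) == 2 else "all"
        elif not hit_names:
            category = "neither"
        else:
            category = "+".join(hit_names) + "-only"
        rows.append((p.name, p.label, *[hits[n] for n in names], category))
    return pd.DataFrame(
        rows, columns=["peak_name", "label", *names, "category"]
    )


def overlap_summary(overlaps: pd.DataFrame) -> pd.DataFrame:
    """Per-class percentage of peaks in each overlap category."""
    tab = overlaps.groupby(["label", "category"]).size().unstack(fill_value=0)
    return 100.0 * tab.div(tab.sum(axis=1), axis=0)
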
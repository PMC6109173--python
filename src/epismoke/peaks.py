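"""Two-condition quantitative peak comparison.

Peaks called in the air- and smoke-exposed conditions are classified by
interval overlap into air-unique, smoke-unique and common peaks; a robust
linear trend of M (log2 smoke/air) on A (mean log2 intensity) is fitted on the
common peaks only and subtracted from every peak's M, on the rationale that
regions marked in both conditions should on average show no difference, so any
systematic M-on-A trend among them reflects sequencing-depth and
signal-intensity bias rather than biology.  Significance of the rescaled
counts comes from an exact conditional binomial test (equal-rate Poisson
null: conditional on the total, counts split Binomial(n, 1/2)).
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .types import GenomicInterval, MAFit, Peak, PEAK_CLASSES

log = logging.getLogger("epismoke")

DEFAULT_PSEUDOCOUNT = 0.5
HUBER_TUNING = 1.345
HUBER_TOL = 1e-8
HUBER_MAX_ITER = 50


class ConvergenceError(RuntimeError):
    pass


def compute_ma(
    x_air: float, x_smoke: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> tuple[float, float]:
    """Return (M, A) for one peak's pseudocount-adjusted read counts.

    M = log2((x_smoke+c)/(x_air+c)), A = 0.5*log2((x_smoke+c)*(x_air+c)).
    """
    if x_air < 0 or x_smoke < 0:
        raise ValueError("read counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (x_air == 0 or x_smoke == 0):
        raise ValueError("zero count with zero pseudocount is undefined")
    a = x_air + pseudocount
    s = x_smoke + pseudocount
    return float(np.log2(s / a)), float(0.5 * np.log2(s * a))


def merge_within(peaks: list[Peak]) -> list[Peak]:
    """Merge overlapping peaks within one condition's list.

    Overlapping (>=1 bp, half-open) intervals are merged into their union;
    counts are summed per condition and member names concatenated.
    """
    out: list[Peak] = []
    key = lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
    for p in sorted(peaks, key=key):
        if out and p.interval.chrom == out[-1].interval.chrom and \
                p.interval.start < out[-1].interval.end:
            prev = out[-1]
            merged = Peak(
                GenomicInterval(
                    prev.interval.chrom,
                    prev.interval.start,
                    max(prev.interval.end, p.interval.end),
                ),
                prev.name,
                prev.x_air + p.x_air,
                prev.x_smoke + p.x_smoke,
                members=prev.members + p.members,
            )
            out[-1] = merged
        else:
            out.append(
                Peak(p.interval, p.name, p.x_air, p.x_smoke, members=p.members)
            )
    return out


def classify_peaks(
    air_peaks: list[Peak], smoke_peaks: list[Peak]
) -> list[Peak]:
    """Classify two peak sets into air-unique / smoke-unique / common peaks.

    Each input list is first merged internally.  An air peak that overlaps
    (>=1 bp) any smoke peak is merged, together with all of its transitive
    overlap partners, into a single common peak spanning the union interval,
    with counts summed over merged members per condition.  Non-overlapping
    peaks keep their intervals and are labelled air_unique / smoke_unique.
    """
    air = merge_within(air_peaks)
    smoke = merge_within(smoke_peaks)
    tagged = [("air", p) for p in air] + [("smoke", p) for p in smoke]
    tagged.sort(key=lambda t: (t[1].interval.chrom, t[1].interval.start))

    out: list[Peak] = []
    cluster: list[tuple[str, Peak]] = []
    cluster_chrom, cluster_end = None, -1
    n_common = 0

    def flush():
        nonlocal n_common
        if not cluster:
            return
        sides = {side for side, _ in cluster}
        if len(sides) == 1:
            # same-side peaks never chain post-merge: singleton cluster
            side, p = cluster[0]
            p.label = "air_unique" if side == "air" else "smoke_unique"
            out.append(p)
        else:
            n_common += 1
            members = tuple(m for _, p in cluster for m in p.members)
            union = GenomicInterval(
                cluster[0][1].interval.chrom,
                min(p.interval.start for _, p in cluster),
                max(p.interval.end for _, p in cluster),
            )
            merged = Peak(
                union,
                f"common_{n_common:05d}",
                sum(p.x_air for _, p in cluster),
                sum(p.x_smoke for _, p in cluster),
                label="common",
                members=members,
            )
            out.append(merged)

    for side, p in tagged:
        if (
            cluster
            and p.interval.chrom == cluster_chrom
            and p.interval.start < cluster_end
        ):
            cluster.append((side, p))
            cluster_end = max(cluster_end, p.interval.end)
        else:
            flush()
            cluster = [(side, p)]
            cluster_chrom = p.interval.chrom
            cluster_end = p.interval.end
    flush()

    counts = {lab: sum(1 for p in out if p.label == lab) for lab in PEAK_CLASSES}
    log.info(
        "classified peaks: %d air-unique, %d smoke-unique, %d common "
        "(from %d air + %d smoke inputs)",
        counts["air_unique"], counts["smoke_unique"], counts["common"],
        len(air), len(smoke),
    )
    return out


def annotate_ma(peaks: list[Peak], pseudocount: float = DEFAULT_PSEUDOCOUNT) -> None:
    """Fill M and A in place for every peak."""
    for p in peaks:
        p.M, p.A = compute_ma(p.x_air, p.x_smoke, pseudocount)


def huber_irls(
    x: np.ndarray,
    y: np.ndarray,
    tuning: float = HUBER_TUNING,
    tol: float = HUBER_TOL,
    max_iter: int = HUBER_MAX_ITER,
) -> tuple[float, float, int, float]:
    """Huber-weighted IRLS line fit y ~ intercept + slope*x.

    Scale is re-estimated each iteration from the MAD of the residuals.
    Returns (intercept, slope, n_iter, mean final weight).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.ones_like(y)
    frozen_scale = None
    for it in range(1, max_iter + 1):
        resid = y - X @ beta
        med = np.median(resid)
        scale = 1.4826 * np.median(np.abs(resid - med))
        if frozen_scale is not None:
            scale = frozen_scale
        elif scale <= tol:
            if np.max(np.abs(resid)) <= tol * max(1.0, float(np.max(np.abs(y)))):
                # (near-)exact fit; Huber weights are all 1
                return float(beta[0]), float(beta[1]), it, 1.0
            # MAD degenerates when >50% of points sit exactly on one line;
            # fall back to the (normal-consistent) mean absolute deviation
            # and keep it fixed so the iteration stays a contraction
            scale = np.mean(np.abs(resid - med)) / 0.7979
            frozen_scale = scale
        u = np.abs(resid) / scale
        w = np.where(u <= tuning, 1.0, tuning / u)
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(Xw.T @ X, Xw.T @ y)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            return float(beta[0]), float(beta[1]), it, float(np.mean(w))
    raise ConvergenceError(
        f"Huber IRLS did not converge in {max_iter} iterations "
        f"(last coefficient change {delta:.3g})"
    )


def fit_ma_normalization(common_peaks: list[Peak]) -> MAFit:
    """Fit the robust M-on-A trend over common peaks."""
    pts = [
        p for p in common_peaks
        if p.M is not None and np.isfinite(p.M) and np.isfinite(p.A)
    ]
    if len(pts) < 3:
        raise ValueError(
            f"need >=3 common peaks with finite M, A; got {len(pts)}"
        )
    if any(p.label not in (None, "common") for p in pts):
        raise ValueError("fit_ma_normalization accepts common peaks only")
    a = np.array([p.A for p in pts])
    m = np.array([p.M for p in pts])
    intercept, slope, n_iter, mean_w = huber_irls(a, m)
    log.info(
        "M-A fit on %d common peaks: intercept=%.4f slope=%.4f (%d iterations)",
        len(pts), intercept, slope, n_iter,
    )
    return MAFit(intercept, slope, len(pts), n_iter, mean_w)


def conditional_binomial_p(x_air: int, x_smoke: int) -> float:
    """Two-sided exact test of an equal split given the total count."""
    n = x_air + x_smoke
    if n == 0:
        return 1.0
    return float(stats.binomtest(x_smoke, n, 0.5).pvalue)


def normalize_and_score(peaks: list[Peak], fit: MAFit) -> list[Peak]:
    """Compute normalized M and conditional-binomial p for every peak.

    The fitted trend is removed symmetrically: the smoke count is scaled by
    2^(-trend/2) and the air count by 2^(+trend/2) (rounded to integers), so
    the rescaled counts have expected M_norm = 0 under the null.
    """
    for p in peaks:
        if p.M is None or p.A is None:
            raise ValueError(f"peak {p.name!r} lacks M/A; call annotate_ma first")
        trend = fit.predict(p.A)
        p.m_norm = p.M - trend
        x_smoke = int(round(p.x_smoke * 2.0 ** (-trend / 2.0)))
        x_air = int(round(p.x_air * 2.0 ** (trend / 2.0)))
        p.p_value = conditional_binomial_p(max(x_air, 0), max(x_smoke, 0))
    return peaks


def rank_peaks(peaks: list[Peak], label: str) -> list[Peak]:
    """Rank one class's peaks: p ascending, |M_norm| descending, coordinate."""
    if label not in PEAK_CLASSES:
        raise ValueError(f"unknown peak class {label!r}")
    chosen = [p for p in peaks if p.label == label]
    for p in chosen:
        if p.p_value is None or p.m_norm is None:
            raise ValueError(f"peak {p.name!r} is not scored")
    return sorted(
        chosen,
        key=lambda p: (
            p.p_value,
            -abs(p.m_norm),
            p.interval.chrom,
            p.interval.start,
            p.interval.end,
        ),
    )
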
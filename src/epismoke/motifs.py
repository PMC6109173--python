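"""Known-motif over-representation by PWM scanning against a background set.

Scanning uses a log-odds score against a background base composition; a
sequence is a ZOOPS hit when any window on either strand reaches a configured
fraction of the maximum attainable score.  Over-representation of hit counts
in the target set versus the pooled target+background universe is tested with
a one-sided hypergeometric, BH-adjusted over the motifs tested in the run.
A motif is "selected" when it is present in at least ``min_frac`` of target
sequences, enriched at fold change > ``min_fc`` and significant at
q < ``max_q``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("epismoke")

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
#: complement lookup on encoded bases (N stays N)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)
_ENCODE = np.full(256, 4, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

DEFAULT_SCORE_FRACTION = 0.8
UNIFORM_BG = np.full(4, 0.25)


@dataclass(frozen=True)
class MotifPWM:
    """A position weight matrix: 4 x L per-column base probabilities."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != 4:
            raise ValueError(f"PWM {self.name!r}: matrix must be 4 x L")
        if m.shape[1] < 4:
            raise ValueError(f"PWM {self.name!r}: length must be >= 4")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.name!r}: columns must sum to 1")
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def log_odds(self) -> np.ndarray:
        """5 x L log2-odds score table; row 4 (N) scores 0."""
        lo = np.zeros((5, self.length))
        lo[:4] = np.log2(self.matrix / self.background[:, None])
        return lo

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:4].max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


def encode_sequence(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Scores of all windows of one encoded sequence (one strand)."""
    L = log_odds.shape[1]
    if codes.shape[0] < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return log_odds[windows, np.arange(L)].sum(axis=1)


def best_score(seq: str, pwm: MotifPWM) -> float:
    """Best log-odds window score over both strands (-inf if too short)."""
    codes = encode_sequence(seq)
    lo = pwm.log_odds
    fwd = _window_scores(codes, lo)
    rev = _window_scores(_COMPLEMENT[codes][::-1], lo)
    scores = np.concatenate([fwd, rev])
    return float(scores.max()) if scores.size else float("-inf")


def scan_pwm(
    seq: str, pwm: MotifPWM, score_fraction: float = DEFAULT_SCORE_FRACTION
) -> bool:
    """ZOOPS hit flag: does any window on either strand reach the threshold?"""
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    if len(seq) < pwm.length:
        log.warning("sequence shorter than PWM %s; no window", pwm.name)
        return False
    return best_score(seq, pwm) >= score_fraction * pwm.max_score


def count_hits(
    seqs: list[str], pwm: MotifPWM, score_fraction: float = DEFAULT_SCORE_FRACTION
) -> int:
    """Number of sequences with >=1 scoring window (ZOOPS counting)."""
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    threshold = score_fraction * pwm.max_score
    lo = pwm.log_odds
    L = pwm.length
    lengths = {len(s) for s in seqs}
    hits = 0
    if len(lengths) == 1 and lengths and next(iter(lengths)) >= L:
        # equal-length fast path: score all sequences in one array op
        codes = np.stack([encode_sequence(s) for s in seqs])
        windows = np.lib.stride_tricks.sliding_window_view(codes, L, axis=1)
        fwd = lo[windows, np.arange(L)].sum(axis=2).max(axis=1)
        rc = _COMPLEMENT[codes][:, ::-1]
        windows = np.lib.stride_tricks.sliding_window_view(rc, L, axis=1)
        rev = lo[windows, np.arange(L)].sum(axis=2).max(axis=1)
        hits = int((np.maximum(fwd, rev) >= threshold).sum())
    else:
        for s in seqs:
            if len(s) >= L and best_score(s, pwm) >= threshold:
                hits += 1
    return hits


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation p: P(X >= k), X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_change(k: int, K: int, n: int, N: int) -> float:
    """(k/n) / ((K-k)/(N-n)): target hit rate over background hit rate."""
    target_rate = k / n
    bg = (K - k) / (N - n) if N > n else np.nan
    if bg == 0:
        return float("inf") if target_rate > 0 else 0.0
    return float(target_rate / bg)


def motif_enrichment_table(
    target_seqs: list[tuple[str, str]],
    background_seqs: list[tuple[str, str]],
    pwms: list[MotifPWM],
    score_fraction: float = DEFAULT_SCORE_FRACTION,
    min_frac: float = 0.05,
    min_fc: float = 1.1,
    max_q: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Motif over-representation of target vs background sequences.

    Returns (full, selected) tables of enrichment rows.  Selection requires
    fraction_target >= min_frac, fold_change > min_fc and q < max_q.
    """
    from .stats_util import bh_adjust

    if not target_seqs:
        raise ValueError("target sequence set is empty")
    if not background_seqs:
        raise ValueError("background sequence set is empty")
    target_ids = {name for name, _ in target_seqs}
    if target_ids & {name for name, _ in background_seqs}:
        raise ValueError("target and background sequence ids overlap")

    tseqs = [s for _, s in target_seqs]
    bseqs = [s for _, s in background_seqs]
    n = len(tseqs)
    N = n + len(bseqs)
    rows = []
    for pwm in pwms:
        k = count_hits(tseqs, pwm, score_fraction)
        k_bg = count_hits(bseqs, pwm, score_fraction)
        K = k + k_bg
        rows.append(
            {
                "id": pwm.name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fraction_target": k / n,
                "fraction_background": k_bg / (N - n),
                "fold_change": fold_change(k, K, n, N),
                "p": hypergeom_p(k, K, n, N),
            }
        )
    full = pd.DataFrame(rows)
    full["q"] = bh_adjust(full["p"].to_numpy())
    full["selected"] = (
        (full["fraction_target"] >= min_frac)
        & (full["fold_change"] > min_fc)
        & (full["q"] < max_q)
    )
    selected = full[full["selected"]].reset_index(drop=True)
    log.info(
        "motif enrichment: %d/%d motifs selected (>=%.0f%% of %d targets, "
        "FC>%.2f, q<%.2f)",
        len(selected), len(full), 100 * min_frac, n, min_fc, max_q,
    )
    return full, selected
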
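"""Expression-side statistics.

* location/scale batch adjustment (per gene, batch means equalized and batch
  spreads rescaled to the pooled spread, preserving the gene's global mean),
* per-day pooled-variance t-tests of smoke vs air,
* Benjamini-Hochberg FDR,
* a per-gene random-intercept linear mixed model
  y_ij = b0i + b1*trt_i + b2*time_j + b3*trt_i*time_j + e_ij
  with b0i ~ N(0, sigma_subject^2), fitted by maximum likelihood via a 1-D
  profile over the variance ratio gamma = sigma_subject^2 / sigma_noise^2;
  the treatment x time interaction (b3) is tested by a likelihood ratio
  against the model without the interaction term.  Rather than referring the
  LR statistic directly to chi-square(1) -- anti-conservative at the small
  per-gene sample sizes this design produces -- it is mapped onto an
  F(1, N - p - (g-1)) reference via F = (exp(LR/N) - 1) * df_den, which is
  the exact monotone LR <-> F relation of the fixed-effects linear model
  (recovered here when the variance ratio profiles to zero) and converges to
  the chi-square(1) reference as N grows.

Time is coded numerically in days (1, 2, 4); treatment is 0 = air, 1 = smoke.
Technical replicates are treated as independent observations within subject.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stats_util import bh_adjust, pooled_t  # noqa: F401  (bh_adjust re-exported)
from .types import ExpressionStudy, VALID_DAYS

log = logging.getLogger("epismoke")

DEFAULT_LMM_FDR = 0.1
_LOG_GAMMA_BOUNDS = (-12.0, 8.0)


def batch_adjust(study: ExpressionStudy) -> ExpressionStudy:
    """Remove additive/multiplicative batch effects per gene.

    Within each batch, values are centered to the batch mean and rescaled by
    pooled-sd / batch-sd, then the global gene mean is restored, so per-gene
    batch means are equal afterwards.  Genes with zero variance inside a
    batch are centered only (scale left at 1) and counted in the log.
    The transform is idempotent.
    """
    sheet = study.samples
    batches = sheet["batch"]
    groups = {b: list(idx) for b, idx in batches.groupby(batches).groups.items()}
    if len(groups) < 2:
        raise ValueError("batch adjustment needs >= 2 batches")
    for b, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"batch {b!r} has a single sample")

    X = study.matrix.to_numpy(dtype=float)
    cols = {s: i for i, s in enumerate(study.matrix.columns)}
    global_mean = X.mean(axis=1)

    n_flagged = 0
    centered_ss = np.zeros(X.shape[0])
    total_df = 0
    stats_per_batch = {}
    for b, ids in groups.items():
        j = [cols[s] for s in ids]
        sub = X[:, j]
        mb = sub.mean(axis=1)
        sb = sub.std(axis=1, ddof=1)
        stats_per_batch[b] = (j, mb, sb)
        centered_ss += (len(j) - 1) * sb**2
        total_df += len(j) - 1
    pooled_sd = np.sqrt(centered_ss / total_df)

    out = X.copy()
    for b, (j, mb, sb) in stats_per_batch.items():
        scale = np.divide(
            pooled_sd, sb, out=np.ones_like(sb), where=sb > 0
        )
        n_flagged += int((sb == 0).sum())
        out[:, j] = (X[:, j] - mb[:, None]) * scale[:, None] + global_mean[:, None]
    if n_flagged:
        log.warning(
            "batch_adjust: %d zero-variance gene/batch cells centered only",
            n_flagged,
        )
    matrix = pd.DataFrame(out, index=study.matrix.index, columns=study.matrix.columns)
    return ExpressionStudy(matrix, sheet.copy())


def per_day_de(study: ExpressionStudy, day: int) -> pd.DataFrame:
    """Pooled-variance t of smoke vs air for one day, per gene.

    Returns columns gene_id, day, t_stat (smoke - air), p, df.
    """
    if day not in VALID_DAYS:
        raise ValueError(f"day must be one of {VALID_DAYS}")
    sheet = study.samples
    on_day = sheet[sheet["day"] == day]
    smoke_ids = on_day.index[on_day["treatment"] == "smoke"]
    air_ids = on_day.index[on_day["treatment"] == "air"]
    if len(smoke_ids) < 2 or len(air_ids) < 2:
        raise ValueError(
            f"day {day}: need >= 2 samples per arm "
            f"(smoke={len(smoke_ids)}, air={len(air_ids)})"
        )
    S = study.matrix[list(smoke_ids)].to_numpy(dtype=float)
    A = study.matrix[list(air_ids)].to_numpy(dtype=float)
    ns, na = S.shape[1], A.shape[1]
    df = ns + na - 2
    diff = S.mean(axis=1) - A.mean(axis=1)
    ss = ((S - S.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (A - A.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    se = np.sqrt(ss / df * (1 / ns + 1 / na))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # zero pooled variance: equal means -> t=0, p=1; else infinite t
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return pd.DataFrame(
        {
            "gene_id": study.matrix.index,
            "day": day,
            "t_stat": t,
            "p": np.minimum(p, 1.0),
            "df": df,
        }
    ).reset_index(drop=True)


class _LMMDesign:
    """Precomputed sufficient statistics for one fixed-effects design."""

    def __init__(self, X: np.ndarray, group_idx: np.ndarray, n_groups: int):
        self.X = X
        self.N, self.p = X.shape
        self.XtX = X.T @ X
        self.G = np.zeros((n_groups, self.p))
        np.add.at(self.G, group_idx, X)
        self.ng = np.bincount(group_idx, minlength=n_groups).astype(float)
        self.group_idx = group_idx

    def profile_ll(self, gamma: float, Xty, yty, h):
        """Profile log-likelihood at variance ratio gamma (>= 0)."""
        c = gamma / (1.0 + gamma * self.ng)
        ch = c * h
        XtVX = self.XtX - (self.G * c[:, None]).T @ self.G
        XtVy = Xty - self.G.T @ ch
        ytVy = yty - ch @ h
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - XtVy @ beta
        if rss <= 0:
            rss = 1e-300
        sigma2 = rss / self.N
        ll = -0.5 * (
            self.N * np.log(2 * np.pi * sigma2)
            + np.log1p(gamma * self.ng).sum()
            + self.N
        )
        return ll, beta, sigma2

    def fit(self, y: np.ndarray):
        """ML fit: maximize the gamma-profile. Returns (ll, beta, s2, gamma)."""
        Xty = self.X.T @ y
        yty = float(y @ y)
        h = np.zeros(self.ng.shape[0])
        np.add.at(h, self.group_idx, y)

        def neg_ll(log_gamma: float) -> float:
            return -self.profile_ll(np.exp(log_gamma), Xty, yty, h)[0]

        res = optimize.minimize_scalar(
            neg_ll, bounds=_LOG_GAMMA_BOUNDS, method="bounded",
            options={"xatol": 1e-5},
        )
        ll0, beta0, s20 = self.profile_ll(0.0, Xty, yty, h)
        llg, betag, s2g = self.profile_ll(np.exp(res.x), Xty, yty, h)
        if ll0 >= llg:
            return ll0, beta0, s20, 0.0
        return llg, betag, s2g, float(np.exp(res.x))


def lmm_interaction(
    study: ExpressionStudy, fdr: float = DEFAULT_LMM_FDR
) -> pd.DataFrame:
    """Per-gene random-intercept interaction test.

    Returns columns gene_id, beta1 (treatment), beta2 (time), beta3
    (treatment x time), sigma_subject2, sigma_noise2, p_beta3, q_beta3,
    significant, converged.  Genes that fail to fit are flagged
    converged=False and excluded from the FDR set.
    """
    sheet = study.samples
    subjects = sheet["subject"].astype(str)
    if subjects.nunique() < 2:
        raise ValueError("mixed model needs >= 2 subjects")
    arms_per_subject = sheet.groupby(subjects)["treatment"].nunique()
    if (arms_per_subject < 2).any():
        bad = arms_per_subject[arms_per_subject < 2].index.tolist()
        raise ValueError(f"subjects observed in one arm only: {bad}")

    trt = (sheet["treatment"] == "smoke").to_numpy(dtype=float)
    time = sheet["day"].to_numpy(dtype=float)
    codes, uniques = pd.factorize(subjects)
    n_groups = len(uniques)

    X_full = np.column_stack([np.ones_like(trt), trt, time, trt * time])
    X_null = X_full[:, :3]
    design_full = _LMMDesign(X_full, codes, n_groups)
    design_null = _LMMDesign(X_null, codes, n_groups)

    N = X_full.shape[0]
    # residual df after fixed effects and the g-1 between-subject contrasts
    df_den = N - X_full.shape[1] - (n_groups - 1)
    if df_den < 1:
        raise ValueError("design leaves no residual degrees of freedom")

    Y = study.matrix.to_numpy(dtype=float)
    rows = []
    n_fail = 0
    for g, gene in enumerate(study.matrix.index):
        y = Y[g]
        try:
            ll_full, beta, s2, gamma = design_full.fit(y)
            ll_null, *_ = design_null.fit(y)
            lrt = max(0.0, 2.0 * (ll_full - ll_null))
            f_stat = np.expm1(lrt / N) * df_den
            p = float(stats.f.sf(f_stat, 1, df_den))
            rows.append(
                (gene, beta[1], beta[2], beta[3], gamma * s2, s2, p, True)
            )
        except np.linalg.LinAlgError:
            n_fail += 1
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False))
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "beta1", "beta2", "beta3",
            "sigma_subject2", "sigma_noise2", "p_beta3", "converged",
        ],
    )
    out["q_beta3"] = np.nan
    ok = out["converged"]
    if ok.any():
        out.loc[ok, "q_beta3"] = bh_adjust(out.loc[ok, "p_beta3"].to_numpy())
    out["significant"] = out["q_beta3"] < fdr
    if n_fail:
        log.warning("lmm_interaction: %d genes failed to converge", n_fail)
    log.info(
        "lmm_interaction: %d genes tested, %d significant at q < %s",
        int(ok.sum()), int(out["significant"].sum()), fdr,
    )
    return out
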
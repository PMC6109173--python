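import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epismoke import expression as expr
from epismoke.simulate import SimConfig, simulate_expression
from epismoke.stats_util import bh_adjust, pooled_t
from epismoke.types import ExpressionStudy


def make_study(values, subjects, treatments, days, batches=None, genes=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    ids = [f"s{i}" for i in range(n)]
    sheet = pd.DataFrame(
        {
            "subject": subjects,
            "treatment": treatments,
            "day": days,
            "batch": batches if batches is not None else subjects,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionStudy(pd.DataFrame(values, index=genes, columns=ids), sheet)


class TestBatchAdjust:
    def _two_batch_study(self, values):
        return make_study(
            values,
            subjects=["A"] * 4 + ["B"] * 4,
            treatments=["air", "smoke"] * 4,
            days=[1, 1, 2, 2] * 2,
            batches=["B1"] * 4 + ["B2"] * 4,
        )

    def test_batch_means_equalized_to_global_mean(self, rng):
        vals = np.concatenate([rng.normal(5, 1, 4), rng.normal(7, 1, 4)])
        study = self._two_batch_study(vals)
        adjusted = expr.batch_adjust(study)
        row = adjusted.matrix.iloc[0]
        assert row[:4].mean() == pytest.approx(row[4:].mean(), abs=1e-10)
        assert row.mean() == pytest.approx(study.matrix.iloc[0].mean(), abs=1e-10)

    def test_idempotent(self, rng):
        study = self._two_batch_study(rng.normal(size=(50, 8)))
        once = expr.batch_adjust(study)
        twice = expr.batch_adjust(once)
        assert np.allclose(once.matrix, twice.matrix, atol=1e-10)

    def test_single_batch_rejected(self):
        study = make_study(
            np.ones((1, 4)), ["A"] * 4, ["air", "smoke"] * 2, [1, 1, 2, 2],
            batches=["B1"] * 4,
        )
        with pytest.raises(ValueError, match="2 batches"):
            expr.batch_adjust(study)

    def test_singleton_batch_rejected(self):
        study = make_study(
            np.ones((1, 3)), ["A", "A", "B"], ["air", "smoke", "air"],
            [1, 1, 1], batches=["B1", "B1", "B2"],
        )
        with pytest.raises(ValueError, match="single sample"):
            expr.batch_adjust(study)

    def test_zero_variance_gene_centered_only(self, caplog):
        vals = np.array([[5.0, 5.0, 5.0, 7.0, 8.0, 9.0]])
        study = make_study(
            vals, ["A"] * 3 + ["B"] * 3,
            ["air", "smoke", "air"] * 2, [1, 1, 2] * 2,
            batches=["B1"] * 3 + ["B2"] * 3,
        )
        with caplog.at_level("WARNING", logger="epismoke"):
            adjusted = expr.batch_adjust(study)
        row = adjusted.matrix.iloc[0]
        assert row[:3].mean() == pytest.approx(row[3:].mean())
        assert np.ptp(row[:3]) == 0  # centered, not rescaled


class TestPerDayDE:
    def _day_study(self, air, smoke):
        vals = np.concatenate([air, smoke])[None, :]
        n = len(air) + len(smoke)
        return make_study(
            vals,
            subjects=["A"] * n,
            treatments=["air"] * len(air) + ["smoke"] * len(smoke),
            days=[1] * n,
        )

    def test_textbook_pooled_t(self):
        study = self._day_study([1, 2, 3, 4], [3, 4, 5, 6])
        out = expr.per_day_de(study, 1)
        assert out.iloc[0].t_stat == pytest.approx(2.191, abs=1e-3)
        assert out.iloc[0].df == 6
        assert out.iloc[0].p == pytest.approx(0.0707, abs=1e-3)

    def test_identical_arms_null(self):
        study = self._day_study([1, 2, 3], [1, 2, 3])
        out = expr.per_day_de(study, 1)
        assert out.iloc[0].t_stat == 0.0
        assert out.iloc[0].p == 1.0

    def test_sign_convention_smoke_minus_air(self):
        study = self._day_study([1.0, 1.0], [2.0, 2.1])
        assert expr.per_day_de(study, 1).iloc[0].t_stat > 0

    def test_antisymmetric_under_arm_swap(self, rng):
        vals = rng.normal(size=(20, 8))
        kwargs = dict(subjects=["A"] * 8, days=[1] * 8)
        study = make_study(vals, treatments=["air"] * 4 + ["smoke"] * 4, **kwargs)
        swapped = make_study(vals, treatments=["smoke"] * 4 + ["air"] * 4, **kwargs)
        a = expr.per_day_de(study, 1)["t_stat"].to_numpy()
        b = expr.per_day_de(swapped, 1)["t_stat"].to_numpy()
        assert np.allclose(a, -b, atol=1e-12)

    def test_insufficient_arm_rejected(self):
        study = self._day_study([1, 2], [3])
        with pytest.raises(ValueError, match="2 samples per arm"):
            expr.per_day_de(study, 1)

    def test_invalid_day_rejected(self, rng):
        study = self._day_study([1, 2], [3, 4])
        with pytest.raises(ValueError, match="day"):
            expr.per_day_de(study, 3)


class TestBH:
    def test_step_up_examples(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=500)
        expected = sm.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    def test_null_uniform_controls_fdr(self, rng):
        p = rng.uniform(size=1000)
        assert (bh_adjust(p) < 0.1).mean() < 0.01

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                 min_size=1, max_size=30)
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_and_dominates_p(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestLMM:
    def test_zero_subject_variance_matches_ols(self):
        cfg = SimConfig(seed=9, sigma_subject=0.0, sigma_noise=0.5,
                        batch_shift=0.0, n_subjects=2)
        genes = [f"g{i}" for i in range(20)]
        study, _ = simulate_expression(cfg, genes, set(genes[:10]),
                                       np.random.default_rng(9))
        out = expr.lmm_interaction(study)
        sheet = study.samples
        trt = (sheet["treatment"] == "smoke").to_numpy(float)
        time = sheet["day"].to_numpy(float)
        X = np.column_stack([np.ones_like(trt), trt, time, trt * time])
        for i, gene in enumerate(genes):
            y = study.matrix.loc[gene].to_numpy()
            ols = np.linalg.lstsq(X, y, rcond=None)[0]
            row = out.set_index("gene_id").loc[gene]
            assert row.beta1 == pytest.approx(ols[1], abs=1e-6)
            assert row.beta3 == pytest.approx(ols[3], abs=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        smf = pytest.importorskip("statsmodels.regression.mixed_linear_model")
        cfg = SimConfig(seed=4, n_subjects=4, sigma_subject=0.6,
                        sigma_noise=0.5, batch_shift=0.0)
        genes = [f"g{i}" for i in range(5)]
        study, _ = simulate_expression(cfg, genes, set(genes[:2]),
                                       np.random.default_rng(4))
        ours = expr.lmm_interaction(study).set_index("gene_id")
        sheet = study.samples
        data = pd.DataFrame(
            {
                "trt": (sheet["treatment"] == "smoke").astype(float),
                "time": sheet["day"].astype(float),
                "subject": sheet["subject"],
            }
        )
        exog = np.column_stack(
            [np.ones(len(data)), data.trt, data.time, data.trt * data.time]
        )
        for gene in genes:
            res = smf.MixedLM(
                study.matrix.loc[gene].to_numpy(), exog, groups=data["subject"]
            ).fit(reml=False)
            assert ours.loc[gene, "beta3"] == pytest.approx(
                res.params[3], abs=1e-4
            )
            assert ours.loc[gene, "sigma_noise2"] == pytest.approx(
                res.scale, rel=0.05
            )

    def test_recovers_subject_variance_at_moderate_n(self):
        cfg = SimConfig(seed=12, n_subjects=10, sigma_subject=1.0,
                        sigma_noise=0.5, batch_shift=0.0)
        genes = [f"g{i}" for i in range(300)]
        study, _ = simulate_expression(cfg, genes, set(),
                                       np.random.default_rng(12))
        out = expr.lmm_interaction(study)
        mean_var = out["sigma_subject2"].mean()
        assert abs(mean_var - 1.0) < 0.25

    def test_single_arm_subject_rejected(self):
        study = make_study(
            np.ones((1, 8)),
            subjects=["A"] * 4 + ["B"] * 4,
            treatments=["air"] * 4 + ["smoke"] * 4,
            days=[1, 2, 4, 1] * 2,
        )
        with pytest.raises(ValueError, match="one arm"):
            expr.lmm_interaction(study)

    def test_planted_sensitivity_and_fdr_over_seeds(self):
        from epismoke.simulate import simulate_all

        sens, fdrs = [], []
        for seed in range(5):
            d = simulate_all(SimConfig(seed=seed))
            out = expr.lmm_interaction(expr.batch_adjust(d.study))
            planted = set(
                d.truth.gene_effects.loc[d.truth.gene_effects.planted, "gene_id"]
            )
            sig = set(out.loc[out.significant, "gene_id"])
            sens.append(len(sig & planted) / len(planted))
            fdrs.append(len(sig - planted) / len(sig) if sig else 0.0)
        assert np.mean(sens) >= 0.8
        assert np.mean(fdrs) <= 0.15


def test_pooled_t_matches_scipy(rng):
    from scipy import stats

    for _ in range(20):
        x = rng.normal(size=rng.integers(3, 20))
        y = rng.normal(size=rng.integers(3, 20))
        t, p, df = pooled_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)
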
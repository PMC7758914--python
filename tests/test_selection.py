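"""DIC comparison, trend resampling and the 97.5%-probability rule."""

import numpy as np
import pytest

from bymtrends.inference import FitResult, ModelSpec, SamplerSettings
from bymtrends.selection import (
    DicSummary,
    block_trends,
    classify_trend,
    compute_dic,
    select_model,
    summarize_indicator,
)
from bymtrends.studies import _synthetic_normal_fit


def fake_fit(deviance_draws, d_at_mean, dataset_key=("x", "binary", 4, (6, 7))):
    dev = np.asarray(deviance_draws, dtype=float).reshape(1, -1)
    n = dev.shape[1]
    spec = ModelSpec(family="binary", sampler=SamplerSettings(iterations=n + 1, burnin=0, thin=1, chains=1, seed=0))
    return FitResult(
        draws={k: np.zeros((1, n)) for k in ("alpha", "beta", "tau_u", "tau_v", "tau_delta")}
        | {k: np.zeros((1, n, 2)) for k in ("u", "v", "delta")},
        fitted=np.full((1, n, 2, 2), 0.5),
        deviance_draws=dev,
        deviance_at_mean=d_at_mean,
        diagnostics={"rhat_max": 1.0},
        block_ids=("A", "B"),
        rounds=(6, 7),
        family="binary",
        spec=spec,
        dataset_key=dataset_key,
    )


class TestDic:
    def test_arithmetic(self):
        d = DicSummary(dbar=100.0, d_at_mean=96.0)
        assert d.pd == 4.0 and d.dic == 104.0

    def test_degenerate_posterior_has_zero_pd(self):
        f = fake_fit(np.full(500, 87.5), 87.5)
        d = compute_dic(f)
        assert d.pd == 0.0 and d.dic == d.dbar == 87.5

    def test_identity_dic_equals_dbar_plus_pd(self):
        f = fake_fit(np.random.default_rng(0).normal(200, 5, size=1000), 195.0)
        d = compute_dic(f)
        assert d.dic == d.dbar + d.pd

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            compute_dic(fake_fit(np.ones(50), 1.0))

    def test_conjugate_normal_pd_matches_effective_parameters(self):
        """Normal-normal toy: y_i ~ N(theta, s2) with theta ~ N(0, t2).
        pD = Dbar - D(theta_bar) should equal n * v_post / s2, the model's
        effective parameter count (the shrinkage factor)."""
        rng = np.random.default_rng(42)
        n, s2, t2 = 10, 4.0, 9.0
        y = rng.normal(1.0, np.sqrt(s2), size=n)
        v_post = 1.0 / (n / s2 + 1.0 / t2)
        m_post = v_post * y.sum() / s2
        theta = rng.normal(m_post, np.sqrt(v_post), size=40_000)
        dev = ((y[None, :] - theta[:, None]) ** 2 / s2).sum(axis=1)  # + const, cancels
        dbar = dev.mean()
        d_at_mean = ((y - theta.mean()) ** 2 / s2).sum()
        pd_expected = n * v_post / s2
        assert dbar - d_at_mean == pytest.approx(pd_expected, rel=0.05)


class TestSelectModel:
    def test_lower_dic_wins(self):
        f0 = fake_fit(np.full(200, 110.0), 110.0)
        f1 = fake_fit(np.full(200, 104.0), 104.0)
        sel = select_model(f0, f1)
        assert sel.interaction_evidence and sel.chosen is f1

    def test_tie_goes_to_no_interaction(self):
        f0 = fake_fit(np.full(200, 104.0), 104.0)
        f1 = fake_fit(np.full(200, 104.0), 104.0)
        sel = select_model(f0, f1)
        assert not sel.interaction_evidence and sel.chosen is f0

    def test_no_interaction_kept_when_clearly_better(self):
        f0 = fake_fit(np.full(200, 100.0), 100.0)
        f1 = fake_fit(np.full(200, 108.0), 108.0)
        assert not select_model(f0, f1).interaction_evidence

    def test_mismatched_datasets_rejected(self):
        f0 = fake_fit(np.full(200, 100.0), 100.0)
        f1 = fake_fit(np.full(200, 100.0), 100.0, dataset_key=("other", "binary", 4, (6, 7)))
        with pytest.raises(ValueError, match="same dataset"):
            select_model(f0, f1)


class TestClassifyTrend:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (0.36, 0.59, "decrease"),
            (1.02, 1.32, "increase"),
            (0.83, 1.23, "indeterminate"),
            (1.0, 1.2, "indeterminate"),  # bound exactly 1.0
            (0.8, 1.0, "indeterminate"),
            (0.999, 1.001, "indeterminate"),
        ],
    )
    def test_rule(self, lo, hi, expected):
        assert classify_trend(lo, hi) == expected

    def test_nonpositive_bounds_rejected(self):
        with pytest.raises(ValueError):
            classify_trend(0.0, 1.2)
        with pytest.raises(ValueError):
            classify_trend(1.3, 1.2)

    def test_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            lo = rng.uniform(0.01, 2.0)
            hi = lo * rng.uniform(1.0, 2.0)
            assert classify_trend(lo, hi) in ("increase", "decrease", "indeterminate")


class TestBlockTrends:
    def test_degenerate_posterior_gives_point_cri(self):
        f = _synthetic_normal_fit(np.log(1.1), 0.0, 0.0, 4000, seed=1)
        trends = block_trends(f, resamples=2000, seed=2)
        for t in trends:
            assert t.or_point == pytest.approx(1.10, abs=1e-9)
            assert t.lo == pytest.approx(t.hi)

    def test_joint_mode_respects_perfect_anticorrelation(self):
        """delta_i = -beta + const per draw: joint resampling gives a
        degenerate CrI, independent resampling does not."""
        rng = np.random.default_rng(3)
        f = _synthetic_normal_fit(np.log(1.2), 0.2, 0.0, 4000, seed=4, n_blocks=2)
        const = 0.05
        f.draws["delta"][:] = (-f.draws["beta"] + const)[..., None]
        joint = block_trends(f, resamples=2000, seed=5, mode="joint")
        indep = block_trends(f, resamples=2000, seed=5, mode="independent")
        assert joint[0].hi - joint[0].lo == pytest.approx(0.0, abs=1e-12)
        assert indep[0].hi - indep[0].lo > 0.1

    def test_no_interaction_fit_shares_one_estimate(self):
        f = _synthetic_normal_fit(np.log(1.15), 0.02, 0.0, 4000, seed=6)
        f = type(f)(**{**f.__dict__, "spec": ModelSpec(
            family="binary", include_interaction=False,
            sampler=SamplerSettings(iterations=2, burnin=0, thin=1, chains=1, seed=0))})
        trends = block_trends(f, resamples=2000, seed=7)
        assert len({(t.or_point, t.lo, t.hi) for t in trends}) == 1

    def test_deterministic_given_seed(self):
        f = _synthetic_normal_fit(np.log(1.2), 0.05, 0.05, 4000, seed=8)
        a = block_trends(f, resamples=2000, seed=9)
        b = block_trends(f, resamples=2000, seed=9)
        assert [(t.lo, t.hi) for t in a] == [(t.lo, t.hi) for t in b]

    def test_too_few_resamples_rejected(self):
        f = _synthetic_normal_fit(0.0, 0.05, 0.05, 4000, seed=10)
        with pytest.raises(ValueError, match="1000"):
            block_trends(f, resamples=500, seed=1)


class TestSummarize:
    def test_counts_sum_to_blocks(self):
        f0 = fake_fit(np.full(200, 110.0), 110.0)
        f1 = fake_fit(np.full(200, 104.0), 104.0)
        sel = select_model(f0, f1)
        fit_n = _synthetic_normal_fit(np.log(1.3), 0.02, 0.3, 4000, seed=11, n_blocks=6)
        trends = block_trends(fit_n, resamples=2000, seed=12)
        s = summarize_indicator(trends, sel, indicator_id="x")
        assert s.n_blocks == 6
        assert s.or_range[0] <= s.or_range[1]

    def test_all_increase(self):
        f0 = fake_fit(np.full(200, 110.0), 110.0)
        sel = select_model(f0, fake_fit(np.full(200, 104.0), 104.0))
        fit_n = _synthetic_normal_fit(np.log(1.5), 0.01, 0.0, 4000, seed=13, n_blocks=4)
        trends = block_trends(fit_n, resamples=2000, seed=14)
        s = summarize_indicator(trends, sel, indicator_id="x")
        assert s.n_increase == 4 and s.n_decrease == 0 and s.n_indeterminate == 0
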
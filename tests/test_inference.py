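"""The BYM model: likelihood, deviance, sampler correctness, smoothing."""

import numpy as np
import pytest
from scipy.special import expit

from bymtrends.data import IndicatorDataset, IndicatorObservation
from bymtrends.inference import (
    ModelParams,
    ModelSpec,
    SamplerSettings,
    deviance,
    fit,
    log_likelihood,
    smoothed_levels,
)
from bymtrends.spatial import build_graph_from_edgelist, make_lattice
from conftest import TINY_SAMPLER, tiny_spec


def params_for(block_ids, alpha=0.0, beta=0.0, **kw):
    B = len(block_ids)
    defaults = dict(u=np.zeros(B), v=np.zeros(B), delta=np.zeros(B), tau_u=1.0, tau_v=1.0, tau_delta=1.0)
    defaults.update(kw)
    return ModelParams(alpha=alpha, beta=beta, block_ids=tuple(block_ids), **defaults)


class TestLogLikelihood:
    def test_binary_half_probability_cell(self):
        ds = IndicatorDataset("x", "binary", [IndicatorObservation("A", 6, 0, 19)], rounds=(6,))
        spec = ModelSpec(family="binary")
        ll = log_likelihood(params_for(["A"]), ds, spec)
        assert ll == pytest.approx(19 * np.log(0.5))

    def test_poisson_zero_count_cell(self):
        ds = IndicatorDataset("x", "count", [IndicatorObservation("A", 6, 0, 10)], rounds=(6,))
        spec = ModelSpec(family="count")
        eta = 0.3
        ll = log_likelihood(params_for(["A"], alpha=eta), ds, spec)
        assert ll == pytest.approx(-10 * np.exp(eta))

    def test_empty_dataset_zero(self):
        ds = IndicatorDataset("x", "binary", [], rounds=(6,))
        assert log_likelihood(params_for(["A"]), ds, ModelSpec(family="binary")) == 0.0

    def test_family_mismatch_rejected(self):
        ds = IndicatorDataset("x", "binary", [IndicatorObservation("A", 6, 1, 2)], rounds=(6,))
        with pytest.raises(ValueError, match="family"):
            log_likelihood(params_for(["A"]), ds, ModelSpec(family="count"))


class TestDeviance:
    def test_minus_two_loglik(self):
        ds = IndicatorDataset("x", "binary", [IndicatorObservation("A", 6, 0, 19)], rounds=(6,))
        spec = ModelSpec(family="binary")
        p = params_for(["A"])
        assert deviance(p, ds, spec) == pytest.approx(-2 * log_likelihood(p, ds, spec))

    def test_empty_dataset_zero(self):
        ds = IndicatorDataset("x", "binary", [], rounds=(6,))
        assert deviance(params_for(["A"]), ds, ModelSpec(family="binary")) == 0.0

    def test_doubling_cells_doubles_deviance(self):
        obs1 = [IndicatorObservation("A", 6, 3, 10)]
        obs2 = obs1 + [IndicatorObservation("B", 6, 3, 10)]  # identical second cell
        spec = ModelSpec(family="binary")
        d1 = deviance(params_for(["A", "B"]), IndicatorDataset("x", "binary", obs1, rounds=(6,)), spec)
        d2 = deviance(params_for(["A", "B"]), IndicatorDataset("x", "binary", obs2, rounds=(6,)), spec)
        assert d2 == pytest.approx(2 * d1)


class TestSamplerCorrectness:
    def test_single_cell_matches_1d_quadrature(self):
        """y=10 of n=20, u=v off, diffuse alpha: posterior of expit(alpha)
        centred at 0.5, matching dense 1-D quadrature within 0.01."""
        ds = IndicatorDataset("x", "binary", [IndicatorObservation("X", 6, 10, 20)], rounds=(6,))
        g = build_graph_from_edgelist([], ["X"])
        spec = ModelSpec(
            family="binary", include_spatial=False, include_unstructured=False,
            sampler=SamplerSettings(iterations=6000, burnin=1000, thin=1, chains=2, seed=3),
        )
        result = fit(ds, g, spec)
        # quadrature oracle over alpha alone
        a = np.linspace(-6, 6, 4001)
        logp = 10 * a - 20 * np.logaddexp(0, a) - 0.5 * 1e-3 * a**2
        w = np.exp(logp - logp.max()); w /= w.sum()
        oracle_mean_p = float((w * expit(a)).sum())
        sampled_mean_p = float(expit(result.flat("alpha")).mean())
        assert oracle_mean_p == pytest.approx(0.5, abs=1e-3)
        assert abs(sampled_mean_p - oracle_mean_p) < 0.01

    def test_exchange_symmetry_two_identical_blocks(self):
        obs = [IndicatorObservation(b, r, 8, 20) for b in ("A", "B") for r in (6, 7)]
        ds = IndicatorDataset("x", "binary", obs, rounds=(6, 7))
        g = build_graph_from_edgelist([("A", "B")], ["A", "B"])
        result = fit(ds, g, tiny_spec(seed=5, sampler_kwargs=dict(iterations=3000, burnin=1000)))
        u = result.flat("u")
        assert abs(u[:, 0].mean() - u[:, 1].mean()) < 0.05

    def test_deterministic_given_seed(self, lattice33, small_dataset):
        ds, _ = small_dataset
        a = fit(ds, lattice33, tiny_spec(seed=9, include_interaction=True))
        b = fit(ds, lattice33, tiny_spec(seed=9, include_interaction=True))
        for name in a.draws:
            assert np.array_equal(a.draws[name], b.draws[name])
        assert np.array_equal(a.fitted, b.fitted)

    def test_relabelling_blocks_permutes_nothing_given_same_order(self, lattice33, small_dataset):
        ds, _ = small_dataset
        mapping = {b: f"Z{b}" for b in lattice33.block_ids}
        g2 = lattice33.relabel(mapping)
        obs2 = [IndicatorObservation(mapping[o.block_id], o.round, o.y, o.n) for o in ds.observations]
        ds2 = IndicatorDataset(ds.indicator_id, ds.family, obs2, ds.rounds)
        a = fit(ds, lattice33, tiny_spec(seed=4))
        b = fit(ds2, g2, tiny_spec(seed=4))
        assert np.array_equal(a.draws["u"], b.draws["u"])
        assert b.block_ids == tuple(mapping[x] for x in a.block_ids)

    def test_count_family_recovers_rate_scale(self):
        """Poisson-log model on generated count data: smoothed rates sit
        near the generating per-unit rate."""
        from bymtrends.simulate import TruthSpec, generate

        g = make_lattice(3, 3)
        ds, truth = generate(g, TruthSpec(alpha0=np.log(0.4), beta0=0.1, sd_u=0.2, sd_v=0.05,
                                          family="count", n_range=(50, 100), seed=13))
        result = fit(ds, g, tiny_spec(family="count", seed=14,
                                      sampler_kwargs=dict(iterations=2000, burnin=600)))
        sm = smoothed_levels(result)
        assert (sm["median"] > 0).all()
        med = sm.set_index(["block_id", "round"])["median"]
        rel_err = [
            abs(med.loc[(b, r)] - truth.true_cell_values[g.index(b), k]) / truth.true_cell_values[g.index(b), k]
            for b in g.block_ids
            for k, r in enumerate(ds.rounds)
        ]
        assert np.median(rel_err) < 0.15

    def test_empty_dataset_rejected(self, lattice33):
        ds = IndicatorDataset("x", "binary", [], rounds=(6,))
        with pytest.raises(ValueError, match="empty"):
            fit(ds, lattice33, tiny_spec())

    def test_shrinkage_monotone_in_precision(self):
        """Large tau pulls smoothed levels toward the pooled fit; small tau
        leaves them near the raw proportions."""
        g = make_lattice(3, 3)
        rng = np.random.default_rng(12)
        obs = [
            IndicatorObservation(b, 6, int(y), 40)
            for b, y in zip(g.block_ids, rng.binomial(40, rng.uniform(0.2, 0.8, size=9)))
        ]
        ds = IndicatorDataset("x", "binary", obs, rounds=(6,))
        raw = np.array([o.raw_value for o in obs])
        dist_to_raw = []
        for tau in (0.05, 5.0, 500.0):
            spec = ModelSpec(
                family="binary", fixed_tau_u=tau, fixed_tau_v=tau,
                sampler=SamplerSettings(seed=2, **TINY_SAMPLER),
            )
            result = fit(ds, g, spec)
            sm = smoothed_levels(result).sort_values("block_id")
            order = np.argsort([str(b) for b in g.block_ids])
            dist_to_raw.append(float(np.abs(sm["median"].to_numpy() - raw[order]).mean()))
        assert dist_to_raw[0] < dist_to_raw[1] < dist_to_raw[2]


class TestMissingCells:
    def test_missing_cell_cri_wider_than_observed_neighbour(self):
        g = make_lattice(2, 2)
        obs = [
            IndicatorObservation(b, r, 10, 30)
            for b in g.block_ids
            for r in (6, 7)
            if not (b == "B0_0")  # block entirely unsurveyed
        ]
        ds = IndicatorDataset("x", "binary", obs, rounds=(6, 7),
                              missing={("B0_0", 6), ("B0_0", 7)})
        result = fit(ds, g, tiny_spec(seed=6, sampler_kwargs=dict(iterations=2000, burnin=500)))
        lv = smoothed_levels(result).set_index(["block_id", "round"])
        w_missing = lv.loc[("B0_0", 6), "hi"] - lv.loc[("B0_0", 6), "lo"]
        w_neigh = lv.loc[("B0_1", 6), "hi"] - lv.loc[("B0_1", 6), "lo"]
        assert w_missing > w_neigh

    def test_every_cell_gets_fitted_draws(self, small_fit_interaction, small_dataset):
        ds, _ = small_dataset
        lv = smoothed_levels(small_fit_interaction)
        assert len(lv) == 9 * len(ds.rounds)
        assert ((lv["lo"] <= lv["median"]) & (lv["median"] <= lv["hi"])).all()
        assert lv["lo"].min() >= 0 and lv["hi"].max() <= 1


class TestSmoothedLevels:
    def test_requires_enough_draws(self, lattice33, small_dataset):
        ds, _ = small_dataset
        result = fit(ds, lattice33, tiny_spec(seed=1, sampler_kwargs=dict(iterations=500, burnin=300, chains=1)))
        with pytest.raises(ValueError, match="500"):
            smoothed_levels(result)

    def test_diagnostics_present(self, small_fit_interaction):
        d = small_fit_interaction.diagnostics
        assert "rhat_max" in d and "ess_min" in d and d["rhat_max"] > 0

    def test_draw_counts_match_settings(self, small_fit_interaction):
        s = small_fit_interaction.spec.sampler
        assert small_fit_interaction.n_draws == s.chains * s.kept_per_chain
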
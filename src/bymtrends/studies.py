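"""Self-contained verification studies for the pipeline.

Each study generates its own inputs (synthetic data with known truth, or a
tiny fixed dataset), runs the package end to end and measures a property of
the result: agreement of the MCMC sampler with a dense quadrature oracle,
recovery and coverage of the state-average trend, DIC selection behaviour,
trend-classification operating characteristics, imputation of missing
blocks, and the analytic check of the resampling procedure.  They back both
the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .data import IndicatorDataset, IndicatorObservation
from .inference import FitResult, ModelSpec, SamplerSettings, fit, smoothed_levels
from .selection import block_trends, select_model
from .simulate import TruthSpec, generate, scenario
from .spatial import build_graph_from_edgelist, make_lattice

__all__ = [
    "two_block_dataset",
    "quadrature_posterior_2block",
    "oracle_study",
    "recovery_study",
    "dic_selection_study",
    "classification_study",
    "imputation_study",
    "resampling_check",
    "FAST_SAMPLER",
]

# Desk-scale sampler for replicate studies on the 6x6 lattice.
FAST_SAMPLER = dict(iterations=3000, burnin=1000, thin=2, chains=2)


# ---------------------------------------------------------------------------
# Quadrature oracle: 2 blocks, 2 rounds, binary, fixed precisions
# ---------------------------------------------------------------------------


def two_block_dataset() -> tuple:
    """Fixed 2-block, 2-round binary dataset on a single edge."""
    graph = build_graph_from_edgelist([("A", "B")], ["A", "B"])
    obs = [
        IndicatorObservation("A", 6, 8, 20),
        IndicatorObservation("A", 7, 12, 20),
        IndicatorObservation("B", 6, 12, 20),
        IndicatorObservation("B", 7, 15, 20),
    ]
    dataset = IndicatorDataset("twoblock", "binary", obs, rounds=(6, 7))
    return graph, dataset


def _two_block_log_post(theta, y, n, t, tau_u, tau_v, prec_ab):
    """Unnormalised log posterior over (alpha, beta, u1, v1, v2); u2 = -u1."""
    alpha, beta, u1, v1, v2 = theta[..., 0], theta[..., 1], theta[..., 2], theta[..., 3], theta[..., 4]
    u = np.stack([u1, -u1], axis=-1)
    v = np.stack([v1, v2], axis=-1)
    eta = (alpha[..., None] + u + v)[..., :, None] + beta[..., None, None] * t[None, :]
    ll = (y * eta - n * np.logaddexp(0.0, eta)).sum(axis=(-1, -2))
    lp = (
        -0.5 * prec_ab * (alpha**2 + beta**2)
        - 0.5 * tau_u * (2.0 * u1) ** 2  # ICAR pairwise difference (u1-u2)^2
        - 0.5 * tau_v * (v1**2 + v2**2)
    )
    return ll + lp


def quadrature_posterior_2block(tau_u=4.0, tau_v=16.0, prec_ab=1e-3, grid_points=25, half_width_sds=6.0):
    """Dense-grid posterior means/sds of (alpha, beta) for the 2-block model.

    Finds the posterior mode by optimisation, lays a regular 5-D grid of
    ``grid_points`` per axis spanning mode +/- ``half_width_sds`` Laplace
    sds, and integrates by the midpoint rule.  Independent of the sampler.
    """
    _, dataset = two_block_dataset()
    y = np.array([[8.0, 12.0], [12.0, 15.0]])
    n = np.full((2, 2), 20.0)
    t = np.array([0.0, 1.0])

    def neg(theta):
        return -_two_block_log_post(np.asarray(theta), y, n, t, tau_u, tau_v, prec_ab)

    res = minimize(neg, np.zeros(5), method="BFGS")
    mode, cov = res.x, res.hess_inv
    sds = np.sqrt(np.diag(cov))
    axes = [np.linspace(m - half_width_sds * s, m + half_width_sds * s, grid_points) for m, s in zip(mode, sds)]
    grids = np.meshgrid(*axes, indexing="ij")
    theta = np.stack(grids, axis=-1)
    logp = _two_block_log_post(theta, y, n, t, tau_u, tau_v, prec_ab)
    w = np.exp(logp - logp.max())
    w /= w.sum()
    out = {}
    for k, name in enumerate(("alpha", "beta", "u1", "v1", "v2")):
        x = grids[k]
        mean = float((w * x).sum())
        out[name] = {"mean": mean, "sd": float(np.sqrt((w * (x - mean) ** 2).sum()))}
    return out


def oracle_study(seed: int, tau_u=4.0, tau_v=16.0, sampler_kwargs=None):
    """Sampler vs quadrature on the 2-block model: returns the worst absolute
    discrepancy in posterior mean and sd of (alpha, beta), logit scale."""
    graph, dataset = two_block_dataset()
    oracle = quadrature_posterior_2block(tau_u=tau_u, tau_v=tau_v)
    kw = dict(iterations=8000, burnin=2000, thin=2, chains=4)
    kw.update(sampler_kwargs or {})
    spec = ModelSpec(
        family="binary",
        include_interaction=False,
        fixed_tau_u=tau_u,
        fixed_tau_v=tau_v,
        sampler=SamplerSettings(seed=seed, **kw),
    )
    result = fit(dataset, graph, spec)
    errs = {}
    for name in ("alpha", "beta"):
        draws = result.flat(name)
        errs[f"{name}_mean"] = abs(float(draws.mean()) - oracle[name]["mean"])
        errs[f"{name}_sd"] = abs(float(draws.std()) - oracle[name]["sd"])
    return {"errors": errs, "max_abs_error": max(errs.values()), "oracle": oracle}


# ---------------------------------------------------------------------------
# Replicate studies on the 6x6 lattice
# ---------------------------------------------------------------------------


def _lattice_spec(family="binary", interaction=True, seed=0, sampler_kwargs=None):
    kw = dict(FAST_SAMPLER)
    kw.update(sampler_kwargs or {})
    return ModelSpec(
        family=family, include_interaction=interaction, sampler=SamplerSettings(seed=seed, **kw)
    )


def recovery_study(n_reps: int, seed: int, sampler_kwargs=None):
    """Recovery of the state-average trend beta on a 6x6 lattice, 4 rounds,
    n = 50 per cell, truth beta0 = ln 1.2, sd_u = 0.5, sd_v = 0.1,
    sd_delta = 0.2.  Returns per-replicate posterior-mean bias and whether
    the 95% CrI covered the truth."""
    graph = make_lattice(6, 6)
    beta0 = float(np.log(1.2))
    truth_spec = TruthSpec(alpha0=0.0, beta0=beta0, sd_u=0.5, sd_v=0.1, sd_delta=0.2, n_range=(50, 50))
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_reps) % (2**31)
    biases, covered = [], []
    for r in range(n_reps):
        dataset, _ = generate(graph, replace(truth_spec, seed=int(seeds[2 * r])))
        result = fit(dataset, graph, _lattice_spec(seed=int(seeds[2 * r + 1]), sampler_kwargs=sampler_kwargs))
        draws = result.flat("beta")
        biases.append(float(draws.mean()) - beta0)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        covered.append(bool(lo <= beta0 <= hi))
    return {
        "biases": biases,
        "mean_abs_bias": abs(float(np.mean(biases))),
        "coverage": int(sum(covered)),
        "n_reps": n_reps,
    }


DIC_SAMPLER = dict(iterations=9000, burnin=2000, thin=1, chains=2)


def dic_selection_study(sd_delta: float, n_reps: int, seed: int, sampler_kwargs=None):
    """How often DIC picks the interaction model when the truth has
    per-block trend deviations of the given sd (0 disables them).

    Uses longer chains than the other studies (thin 1) because the DIC gap
    between the models is small under a null interaction and Dbar needs a
    low Monte-Carlo error to resolve it."""
    sampler_kwargs = {**DIC_SAMPLER, **(sampler_kwargs or {})}
    graph = make_lattice(6, 6)
    truth_spec = TruthSpec(
        alpha0=0.0, beta0=float(np.log(1.2)), sd_u=0.5, sd_v=0.1, sd_delta=sd_delta, n_range=(50, 50)
    )
    seeds = np.random.SeedSequence(seed).generate_state(3 * n_reps) % (2**31)
    picks = []
    for r in range(n_reps):
        dataset, _ = generate(graph, replace(truth_spec, seed=int(seeds[3 * r])))
        f0 = fit(dataset, graph, _lattice_spec(interaction=False, seed=int(seeds[3 * r + 1]), sampler_kwargs=sampler_kwargs))
        f1 = fit(dataset, graph, _lattice_spec(interaction=True, seed=int(seeds[3 * r + 2]), sampler_kwargs=sampler_kwargs))
        picks.append(select_model(f0, f1).interaction_evidence)
    return {"interaction_selected": int(sum(picks)), "n_reps": n_reps}


def classification_study(seed: int, n_reps: int = 3, sampler_kwargs=None, resamples=10_000):
    """Operating characteristics of trend classification.

    6x6 lattice, n = 100 per cell, flat state average; one third of blocks
    truly rise (OR 1.5), one third decline (OR 0.67), one third are null
    (OR 1).  Measures the fraction of non-null blocks classified with the
    correct sign and the fraction of null blocks classified as either
    increase or decrease."""
    graph = make_lattice(6, 6)
    B = graph.n_blocks
    third = B // 3
    delta = np.concatenate(
        [np.full(third, np.log(1.5)), np.full(third, -np.log(1.5)), np.zeros(B - 2 * third)]
    )
    truth_spec = TruthSpec(
        alpha0=0.0, beta0=0.0, sd_u=0.5, sd_v=0.1, sd_delta=0.4,
        n_range=(100, 100), delta_values=tuple(delta),
    )
    seeds = np.random.SeedSequence(seed).generate_state(3 * n_reps) % (2**31)
    correct = total_signed = null_flagged = total_null = 0
    for r in range(n_reps):
        dataset, truth = generate(graph, replace(truth_spec, seed=int(seeds[3 * r])))
        result = fit(dataset, graph, _lattice_spec(seed=int(seeds[3 * r + 1]), sampler_kwargs=sampler_kwargs))
        trends = block_trends(result, resamples=resamples, seed=int(seeds[3 * r + 2]), mode="joint")
        for t, d in zip(trends, truth.delta):
            if d > 0:
                total_signed += 1
                correct += t.category == "increase"
            elif d < 0:
                total_signed += 1
                correct += t.category == "decrease"
            else:
                total_null += 1
                null_flagged += t.category != "indeterminate"
    return {
        "signed_accuracy": correct / total_signed,
        "null_false_positive_rate": null_flagged / total_null,
        "n_signed": total_signed,
        "n_null": total_null,
    }


def imputation_study(seed: int, sampler_kwargs=None):
    """Imputation of unsurveyed blocks under the with_missing scenario on a
    6x6 lattice.  For each missing cell: does it get a CrI, is that CrI
    wider than the median observed-cell CrI, and does its posterior median
    lie within [min, max] of its neighbours' medians +/- 2 posterior sds?"""
    graph = make_lattice(6, 6)
    truth_spec = replace(scenario("with_missing"), seed=seed)
    dataset, _ = generate(graph, truth_spec)
    if not dataset.missing:
        raise RuntimeError("scenario produced no missing cells")
    result = fit(dataset, graph, _lattice_spec(seed=seed + 1, sampler_kwargs=sampler_kwargs))
    levels = smoothed_levels(result).set_index(["block_id", "round"])
    fitted = result.fitted_flat()  # (N, B, R)
    ridx = {r: k for k, r in enumerate(dataset.rounds)}
    widths = levels["hi"] - levels["lo"]
    observed_keys = [(o.block_id, o.round) for o in dataset.observations]
    med_obs_width = float(np.median([widths.loc[k] for k in observed_keys]))

    n_checked = wider = in_hull = 0
    width_ratios = []
    for bid, rnd in sorted(dataset.missing, key=str):
        row = levels.loc[(bid, rnd)]
        w = float(row["hi"] - row["lo"])
        width_ratios.append(w / med_obs_width)
        n_checked += 1
        wider += w > med_obs_width
        nbrs = graph.neighbors(bid)
        nbr_meds = [float(levels.loc[(nb, rnd), "median"]) for nb in nbrs]
        sd = float(fitted[:, graph.index(bid), ridx[rnd]].std())
        lo_hull, hi_hull = min(nbr_meds) - 2 * sd, max(nbr_meds) + 2 * sd
        in_hull += lo_hull <= float(row["median"]) <= hi_hull
    return {
        "n_missing": n_checked,
        "all_have_cri": True,
        "frac_wider_than_observed_median": wider / n_checked,
        "frac_within_neighbour_hull": in_hull / n_checked,
        "median_width_ratio": float(np.median(width_ratios)),
    }


# ---------------------------------------------------------------------------
# Analytic resampling check
# ---------------------------------------------------------------------------


def _synthetic_normal_fit(mu_beta, sd_beta, sd_delta, n_draws, seed, n_blocks=3) -> FitResult:
    """A FitResult whose beta/delta draws are exact independent normals, for
    checking block_trends against closed-form lognormal quantiles."""
    rng = np.random.default_rng(seed)
    chains, per = 2, n_draws // 2
    draws = {
        "alpha": np.zeros((chains, per)),
        "beta": rng.normal(mu_beta, sd_beta, size=(chains, per)),
        "u": np.zeros((chains, per, n_blocks)),
        "v": np.zeros((chains, per, n_blocks)),
        "delta": rng.normal(0.0, sd_delta, size=(chains, per, n_blocks)),
        "tau_u": np.ones((chains, per)),
        "tau_v": np.ones((chains, per)),
        "tau_delta": np.ones((chains, per)),
    }
    spec = ModelSpec(
        family="binary", include_interaction=True,
        sampler=SamplerSettings(iterations=per + 1, burnin=0, thin=1, chains=chains, seed=seed),
    )
    return FitResult(
        draws=draws,
        fitted=np.full((chains, per, n_blocks, 2), 0.5),
        deviance_draws=np.zeros((chains, per)),
        deviance_at_mean=0.0,
        diagnostics={"rhat_max": 1.0},
        block_ids=tuple(f"B{i}" for i in range(n_blocks)),
        rounds=(6, 7),
        family="binary",
        spec=spec,
        dataset_key=("synthetic-normal", "binary", 0, (6, 7)),
    )


def resampling_check(seed: int, mu_beta=float(np.log(1.2)), sd_beta=0.05, sd_delta=0.05,
                     n_draws=40_000, resamples=10_000):
    """block_trends in independent mode vs the closed form: beta + delta_i
    with independent normal marginals is Normal(mu, sd_beta^2 + sd_delta^2),
    so the OR CrI endpoints are lognormal quantiles.  Returns the worst
    absolute endpoint discrepancy on the OR scale."""
    fit_result = _synthetic_normal_fit(mu_beta, sd_beta, sd_delta, n_draws, seed)
    trends = block_trends(fit_result, resamples=resamples, seed=seed + 1, mode="independent")
    s = np.hypot(sd_beta, sd_delta)
    lo_true = float(np.exp(norm.ppf(0.025, mu_beta, s)))
    hi_true = float(np.exp(norm.ppf(0.975, mu_beta, s)))
    worst = max(max(abs(t.lo - lo_true), abs(t.hi - hi_true)) for t in trends)
    return {"max_abs_endpoint_error": worst, "lo_true": lo_true, "hi_true": hi_true}
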
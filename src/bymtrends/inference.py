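"""Hierarchical Bayesian BYM spatiotemporal model and its MCMC sampler.

Model
-----
For block i and survey round with time value t (years since the first
round), the linear predictor is

    eta_it = alpha + beta * t + u_i + v_i [+ delta_i * t]

with y_it ~ Binomial(n_it, logit^-1(eta_it)) for binary indicators and
y_it ~ Poisson(n_it * exp(eta_it)) for count indicators.  u is the spatially
structured ICAR effect (smoothing toward bordering blocks), v the
unstructured iid effect, and delta the optional per-block deviation from
the state-average trend beta (the space-time interaction).  u sums to zero
per graph component and delta sums to zero, so alpha and beta stay
identified as the state-wide level and trend.

Inference is adaptive random-walk Metropolis-within-Gibbs: scalar updates
for alpha and beta, graph-coloured vectorised single-site updates for u
(neighbour sums stay fixed within a colour class), vectorised single-site
updates for v and delta, and conjugate gamma Gibbs draws for the precisions.
Proposal scales adapt toward ~40% acceptance during burn-in and are frozen
afterwards.  Missing cells contribute nothing to the likelihood; the
posterior draws of their fitted values are the model's imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import expit, gammaln

from .data import IndicatorDataset
from .spatial import BlockGraph, icar_precision

__all__ = [
    "Priors",
    "SamplerSettings",
    "ModelSpec",
    "ModelParams",
    "FitResult",
    "fit",
    "log_likelihood",
    "deviance",
    "smoothed_levels",
]

RHAT_THRESHOLD = 1.05


@dataclass(frozen=True)
class Priors:
    """Weakly informative defaults: Gamma(1, 5e-4) on precisions, nearly
    flat normals on the fixed effects."""

    a_tau_u: float = 1.0
    b_tau_u: float = 5e-4
    a_tau_v: float = 1.0
    b_tau_v: float = 5e-4
    a_tau_delta: float = 1.0
    b_tau_delta: float = 5e-4
    prec_alpha: float = 1e-3
    prec_beta: float = 1e-3

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter {name} must be > 0")


@dataclass(frozen=True)
class SamplerSettings:
    iterations: int = 5000
    burnin: int = 2000
    thin: int = 2
    chains: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burnin:
            raise ValueError("iterations must exceed burnin")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.burnin) // self.thin


@dataclass(frozen=True)
class ModelSpec:
    """Likelihood family, interaction flag, time coding, priors, sampler.

    ``time_values`` maps survey round labels to time covariate values
    (default: years since the first round, i.e. 0, 1, 2, ...).  Setting
    ``fixed_tau_*`` pins a precision instead of sampling it;
    ``include_spatial`` / ``include_unstructured`` drop u or v entirely
    (useful for reduced oracle models).
    """

    family: str
    include_interaction: bool = False
    time_values: dict | None = None
    priors: Priors = field(default_factory=Priors)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    include_spatial: bool = True
    include_unstructured: bool = True
    fixed_tau_u: float | None = None
    fixed_tau_v: float | None = None
    fixed_tau_delta: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("binary", "count"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.time_values is not None:
            ts = [self.time_values[r] for r in sorted(self.time_values)]
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError("time_values must be strictly increasing in round order")

    def times_for(self, rounds: Sequence[int]) -> np.ndarray:
        if self.time_values is None:
            first = min(rounds)
            return np.asarray([r - first for r in rounds], dtype=float)
        return np.asarray([self.time_values[r] for r in rounds], dtype=float)


@dataclass(frozen=True)
class ModelParams:
    """One point in parameter space, with u/v/delta in block_ids order."""

    alpha: float
    beta: float
    u: np.ndarray
    v: np.ndarray
    delta: np.ndarray
    tau_u: float
    tau_v: float
    tau_delta: float
    block_ids: tuple


def _eta_matrix(params: ModelParams, t: np.ndarray) -> np.ndarray:
    """Linear predictor (n_blocks, n_rounds)."""
    base = params.alpha + params.u + params.v  # (B,)
    slope = params.beta + params.delta  # (B,)
    return base[:, None] + slope[:, None] * t[None, :]


def _binom_logpmf(y, n, eta):
    # stable on the logit scale: log p = eta - log(1+e^eta), log(1-p) = -log(1+e^eta)
    return (
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        + y * eta - n * np.logaddexp(0.0, eta)
    )


def _poisson_logpmf(y, lam):
    y = np.asarray(y, dtype=float)
    out = -lam - gammaln(y + 1)
    pos = y > 0
    out = np.where(pos, out + y * np.log(np.where(pos, lam, 1.0)), out)
    return out


def log_likelihood(params: ModelParams, dataset: IndicatorDataset, spec: ModelSpec) -> float:
    """Sum of binomial/Poisson log-pmf over observed cells; missing cells
    contribute nothing."""
    if spec.family != dataset.family:
        raise ValueError(f"spec family {spec.family!r} does not match dataset family {dataset.family!r}")
    if not dataset.observations:
        return 0.0
    t = spec.times_for(dataset.rounds)
    ridx = {r: k for k, r in enumerate(dataset.rounds)}
    bidx = {b: i for i, b in enumerate(params.block_ids)}
    eta = _eta_matrix(params, t)
    total = 0.0
    for o in dataset.observations:
        e = eta[bidx[o.block_id], ridx[o.round]]
        if spec.family == "binary":
            total += float(_binom_logpmf(float(o.y), float(o.n), e))
        else:
            total += float(_poisson_logpmf(float(o.y), float(o.n) * np.exp(e)))
    return total


def deviance(params: ModelParams, dataset: IndicatorDataset, spec: ModelSpec) -> float:
    """-2 * log-likelihood (saturated constant omitted: it cancels in any
    model comparison on the same data)."""
    return -2.0 * log_likelihood(params, dataset, spec)


# ---------------------------------------------------------------------------
# Sampler internals
# ---------------------------------------------------------------------------


def _loglik_rows(y, n, obs, eta, family):
    """Per-block log-likelihood kernel (constants dropped), summed over
    observed rounds.  eta is (B, R) or a row subset."""
    if family == "binary":
        ll = y * eta - n * np.logaddexp(0.0, eta)
    else:
        ll = y * eta - n * np.exp(eta)
    return np.where(obs, ll, 0.0).sum(axis=-1)


class _AdaptiveScale:
    """Robbins-Monro adaptation of log proposal scales toward a target
    acceptance rate; frozen after burn-in."""

    def __init__(self, shape, target=0.40, init=0.3):
        self.log_s = np.full(shape, np.log(init))
        self.target = target
        self.t = 0

    @property
    def scale(self):
        return np.exp(self.log_s)

    def update(self, accepted):
        self.t += 1
        gamma = min(0.25, 2.0 / np.sqrt(self.t))
        self.log_s += gamma * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_s, np.log(1e-4), np.log(20.0), out=self.log_s)


def _color_classes(graph: BlockGraph) -> list[np.ndarray]:
    """Greedy colouring on integer positions (label-independent), so u sites
    within a class share no edge and can be updated simultaneously."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(graph.n_blocks))
    g.add_edges_from(map(tuple, graph.edge_index_pairs()))
    coloring = nx.coloring.greedy_color(g, strategy="largest_first")
    n_colors = 1 + max(coloring.values(), default=0)
    return [np.asarray([i for i in range(graph.n_blocks) if coloring[i] == c], dtype=np.int64) for c in range(n_colors)]


@dataclass
class _ChainState:
    alpha: float
    beta: float
    u: np.ndarray
    v: np.ndarray
    delta: np.ndarray
    tau_u: float
    tau_v: float
    tau_delta: float


def _run_chain(y, n, obs, t, graph, spec: ModelSpec, rng: np.random.Generator):
    B, R = y.shape
    pri = spec.priors
    fam = spec.family
    labels = graph.component_labels()
    comps = [np.flatnonzero(labels == k) for k in range(graph.n_components)]
    icar_rank = B - graph.n_components
    Q = icar_precision(graph).Q
    A = sp.csr_matrix(-sp.triu(Q, k=1) - sp.tril(Q, k=-1))  # adjacency
    deg = np.asarray(Q.diagonal())
    colors = _color_classes(graph) if spec.include_spatial else []

    # crude initialisation at the empirical pooled level
    tot_y, tot_n = y[obs].sum(), n[obs].sum()
    rate = (tot_y + 0.5) / (tot_n + 1.0)
    alpha0 = float(np.log(rate / (1 - rate)) if fam == "binary" else np.log(max(rate, 1e-6)))
    st = _ChainState(
        alpha=alpha0,
        beta=0.0,
        u=np.zeros(B),
        v=np.zeros(B),
        delta=np.zeros(B),
        tau_u=spec.fixed_tau_u or 10.0,
        tau_v=spec.fixed_tau_v or 10.0,
        tau_delta=spec.fixed_tau_delta or 10.0,
    )

    def eta_full():
        return (st.alpha + st.u + st.v)[:, None] + (st.beta + st.delta)[:, None] * t[None, :]

    eta = eta_full()
    row_ll = _loglik_rows(y, n, obs, eta, fam)  # per-block, current

    s_alpha = _AdaptiveScale((), init=0.1)
    s_beta = _AdaptiveScale((), init=0.1)
    s_u = _AdaptiveScale(B, init=0.3)
    s_v = _AdaptiveScale(B, init=0.3)
    s_d = _AdaptiveScale(B, init=0.2)
    s_scale_u = _AdaptiveScale((), init=0.3)
    s_scale_v = _AdaptiveScale((), init=0.3)
    s_scale_d = _AdaptiveScale((), init=0.3)

    settings = spec.sampler
    kept = settings.kept_per_chain
    out = {
        "alpha": np.empty(kept),
        "beta": np.empty(kept),
        "u": np.empty((kept, B)),
        "v": np.empty((kept, B)),
        "delta": np.empty((kept, B)),
        "tau_u": np.empty(kept),
        "tau_v": np.empty(kept),
        "tau_delta": np.empty(kept),
        "fitted": np.empty((kept, B, R)),
        "deviance": np.empty(kept),
    }
    k = 0

    def total_ll():
        return row_ll.sum()

    def dev_now():
        if fam == "binary":
            lp = _binom_logpmf(y, n, eta)
        else:
            lp = _poisson_logpmf(y, n * np.exp(eta))
        return -2.0 * float(np.where(obs, lp, 0.0).sum())

    for it in range(settings.iterations):
        adapting = it < settings.burnin

        # alpha ----------------------------------------------------------
        e = rng.normal(0.0, s_alpha.scale)
        new_eta = eta + e
        new_ll = _loglik_rows(y, n, obs, new_eta, fam)
        dprior = -0.5 * pri.prec_alpha * ((st.alpha + e) ** 2 - st.alpha**2)
        acc = np.log(rng.uniform()) < (new_ll.sum() - row_ll.sum() + dprior)
        if acc:
            st.alpha += e
            eta, row_ll = new_eta, new_ll
        if adapting:
            s_alpha.update(acc)

        # beta -----------------------------------------------------------
        e = rng.normal(0.0, s_beta.scale)
        new_eta = eta + e * t[None, :]
        new_ll = _loglik_rows(y, n, obs, new_eta, fam)
        dprior = -0.5 * pri.prec_beta * ((st.beta + e) ** 2 - st.beta**2)
        acc = np.log(rng.uniform()) < (new_ll.sum() - row_ll.sum() + dprior)
        if acc:
            st.beta += e
            eta, row_ll = new_eta, new_ll
        if adapting:
            s_beta.update(acc)

        # u: coloured single-site updates --------------------------------
        if spec.include_spatial:
            for cls in colors:
                s_nb = A[cls].dot(st.u)  # neighbour sums, fixed within class
                e = rng.normal(0.0, s_u.scale[cls])
                eta_c = eta[cls] + e[:, None]
                ll_new = _loglik_rows(y[cls], n[cls], obs[cls], eta_c, fam)
                du = st.u[cls]
                dprior = -0.5 * st.tau_u * (deg[cls] * ((du + e) ** 2 - du**2) - 2.0 * e * s_nb)
                accept = np.log(rng.uniform(size=len(cls))) < (ll_new - row_ll[cls] + dprior)
                if accept.any():
                    idx = cls[accept]
                    st.u[idx] += e[accept]
                    eta[idx] = eta_c[accept]
                    row_ll[idx] = ll_new[accept]
                if adapting:
                    s_u.log_s[cls] += min(0.25, 2.0 / np.sqrt(it + 1)) * (accept.astype(float) - s_u.target)
            # recentre per component; compensate via alpha (likelihood-neutral
            # for the overall mean; residual per-component centring is the
            # standard on-the-fly constraint)
            m_all = st.u.mean()
            st.alpha += m_all
            st.u -= m_all
            if graph.n_components > 1:
                for idx in comps:
                    st.u[idx] -= st.u[idx].mean()
                eta = eta_full()
                row_ll = _loglik_rows(y, n, obs, eta, fam)

        # v: vectorised single-site updates ------------------------------
        if spec.include_unstructured:
            e = rng.normal(0.0, s_v.scale)
            eta_new = eta + e[:, None]
            ll_new = _loglik_rows(y, n, obs, eta_new, fam)
            dprior = -0.5 * st.tau_v * ((st.v + e) ** 2 - st.v**2)
            accept = np.log(rng.uniform(size=B)) < (ll_new - row_ll + dprior)
            st.v[accept] += e[accept]
            eta[accept] = eta_new[accept]
            row_ll[accept] = ll_new[accept]
            if adapting:
                s_v.update(accept)

        # delta ----------------------------------------------------------
        if spec.include_interaction:
            e = rng.normal(0.0, s_d.scale)
            eta_new = eta + e[:, None] * t[None, :]
            ll_new = _loglik_rows(y, n, obs, eta_new, fam)
            dprior = -0.5 * st.tau_delta * ((st.delta + e) ** 2 - st.delta**2)
            accept = np.log(rng.uniform(size=B)) < (ll_new - row_ll + dprior)
            st.delta[accept] += e[accept]
            eta[accept] = eta_new[accept]
            row_ll[accept] = ll_new[accept]
            if adapting:
                s_d.update(accept)
            m = st.delta.mean()
            st.beta += m
            st.delta -= m
            eta = eta_full()
            row_ll = _loglik_rows(y, n, obs, eta, fam)

        # joint rescaling moves: propose (x, tau) -> (c x, tau / c^2).
        # The Gaussian/ICAR prior exponent is invariant, the tau powers and
        # the Jacobian collapse to -2 log c, so the move costs only the
        # likelihood change plus the gamma prior terms.  It decouples the
        # field scale from tau and fixes the slow tau mixing when the field
        # is near zero.
        def scale_move(x, tau, eta_shift, a_pr, b_pr, scaler):
            nonlocal eta, row_ll
            e = rng.normal(0.0, scaler.scale)
            c = np.exp(e)
            new_eta = eta + (c - 1.0) * eta_shift
            new_ll = _loglik_rows(y, n, obs, new_eta, fam)
            logacc = (
                new_ll.sum() - row_ll.sum()
                - 2.0 * e - 2.0 * (a_pr - 1.0) * e
                - b_pr * tau * (c**-2 - 1.0)
            )
            if np.log(rng.uniform()) < logacc:
                eta, row_ll = new_eta, new_ll
                if adapting:
                    scaler.update(1.0)
                return c, tau / c**2, True
            if adapting:
                scaler.update(0.0)
            return 1.0, tau, False

        if spec.include_spatial and spec.fixed_tau_u is None:
            c, st.tau_u, ok = scale_move(st.u, st.tau_u, st.u[:, None], pri.a_tau_u, pri.b_tau_u, s_scale_u)
            if ok:
                st.u *= c
        if spec.include_unstructured and spec.fixed_tau_v is None:
            c, st.tau_v, ok = scale_move(st.v, st.tau_v, st.v[:, None], pri.a_tau_v, pri.b_tau_v, s_scale_v)
            if ok:
                st.v *= c
        if spec.include_interaction and spec.fixed_tau_delta is None:
            c, st.tau_delta, ok = scale_move(
                st.delta, st.tau_delta, st.delta[:, None] * t[None, :], pri.a_tau_delta, pri.b_tau_delta, s_scale_d
            )
            if ok:
                st.delta *= c

        # precisions: conjugate gamma Gibbs ------------------------------
        if spec.include_spatial and spec.fixed_tau_u is None:
            quad = float(st.u @ Q.dot(st.u))
            st.tau_u = rng.gamma(pri.a_tau_u + 0.5 * icar_rank, 1.0 / (pri.b_tau_u + 0.5 * quad))
        if spec.include_unstructured and spec.fixed_tau_v is None:
            st.tau_v = rng.gamma(pri.a_tau_v + 0.5 * B, 1.0 / (pri.b_tau_v + 0.5 * float(st.v @ st.v)))
        if spec.include_interaction and spec.fixed_tau_delta is None:
            st.tau_delta = rng.gamma(
                pri.a_tau_delta + 0.5 * max(B - 1, 1), 1.0 / (pri.b_tau_delta + 0.5 * float(st.delta @ st.delta))
            )

        # store ----------------------------------------------------------
        if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0 and k < kept:
            out["alpha"][k] = st.alpha
            out["beta"][k] = st.beta
            out["u"][k] = st.u
            out["v"][k] = st.v
            out["delta"][k] = st.delta
            out["tau_u"][k] = st.tau_u
            out["tau_v"][k] = st.tau_v
            out["tau_delta"][k] = st.tau_delta
            out["fitted"][k] = expit(eta) if fam == "binary" else np.exp(eta)
            out["deviance"][k] = dev_now()
            k += 1
    return out


@dataclass
class FitResult:
    """Posterior draws, fitted values for every cell (incl. missing cells:
    the imputation), deviance summaries and convergence diagnostics.

    Draw arrays have shape (chains, draws[, n_blocks]); ``fitted`` has shape
    (chains, draws, n_blocks, n_rounds) on the probability (binary) or
    rate-per-unit (count) scale.
    """

    draws: dict
    fitted: np.ndarray
    deviance_draws: np.ndarray
    deviance_at_mean: float
    diagnostics: dict
    block_ids: tuple
    rounds: tuple
    family: str
    spec: ModelSpec
    dataset_key: tuple

    @property
    def n_draws(self) -> int:
        return int(self.deviance_draws.size)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("rhat_max", np.inf) <= RHAT_THRESHOLD)

    def flat(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains flattened: (n_draws[, B])."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def fitted_flat(self) -> np.ndarray:
        return self.fitted.reshape(-1, *self.fitted.shape[2:])

    def posterior_mean_params(self) -> ModelParams:
        return ModelParams(
            alpha=float(self.flat("alpha").mean()),
            beta=float(self.flat("beta").mean()),
            u=self.flat("u").mean(axis=0),
            v=self.flat("v").mean(axis=0),
            delta=self.flat("delta").mean(axis=0),
            tau_u=float(self.flat("tau_u").mean()),
            tau_v=float(self.flat("tau_v").mean()),
            tau_delta=float(self.flat("tau_delta").mean()),
            block_ids=self.block_ids,
        )

    def to_draws_table(self):
        """Long draws table: columns param, index, chain, iter, value."""
        import pandas as pd

        rows = []
        for name, arr in self.draws.items():
            C, D = arr.shape[:2]
            if arr.ndim == 2:
                for c in range(C):
                    rows.append(
                        pd.DataFrame(
                            {"param": name, "index": "", "chain": c, "iter": np.arange(D), "value": arr[c]}
                        )
                    )
            else:
                for c in range(C):
                    for b, bid in enumerate(self.block_ids):
                        rows.append(
                            pd.DataFrame(
                                {"param": name, "index": str(bid), "chain": c, "iter": np.arange(D), "value": arr[c, :, b]}
                            )
                        )
        return pd.concat(rows, ignore_index=True)


def _diagnostics(draws: dict, spec: ModelSpec) -> dict:
    import arviz as az

    keep = {"alpha": draws["alpha"], "beta": draws["beta"]}
    if spec.include_spatial:
        keep["u"] = draws["u"]
        if spec.fixed_tau_u is None:
            keep["tau_u"] = draws["tau_u"]
    if spec.include_unstructured:
        keep["v"] = draws["v"]
        if spec.fixed_tau_v is None:
            keep["tau_v"] = draws["tau_v"]
    if spec.include_interaction:
        keep["delta"] = draws["delta"]
        if spec.fixed_tau_delta is None:
            keep["tau_delta"] = draws["tau_delta"]
    idata = az.from_dict(posterior=keep)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    per_param = {}
    rmax, emin = 0.0, np.inf
    for name in keep:
        rv = np.atleast_1d(rhat[name].values)
        ev = np.atleast_1d(ess[name].values)
        r = float(np.nanmax(rv)) if np.isfinite(rv).any() else float("nan")
        e = float(np.nanmin(ev)) if np.isfinite(ev).any() else float("nan")
        per_param[name] = {"rhat": r, "ess": e}
        rmax = max(rmax, r) if np.isfinite(r) else rmax
        emin = min(emin, e) if np.isfinite(e) else emin
    return {"per_param": per_param, "rhat_max": rmax, "ess_min": emin}


def fit(dataset: IndicatorDataset, graph: BlockGraph, spec: ModelSpec) -> FitResult:
    """Fit the BYM spatiotemporal model by MCMC; deterministic given seed.

    Missing cells are excluded from the likelihood but receive fitted-value
    draws from the posterior of eta — this is the model's imputation of
    blocks with no respondents.  Non-convergence (split-Rhat > 1.05) is
    flagged in the result, never silent.
    """
    if not dataset.observations:
        raise ValueError("empty dataset: nothing to fit")
    if spec.family != dataset.family:
        raise ValueError(f"spec family {spec.family!r} does not match dataset family {dataset.family!r}")
    arrays = dataset.to_arrays(graph)
    y, n, obs = arrays["y"], arrays["n"], arrays["observed"]
    t = spec.times_for(dataset.rounds)
    settings = spec.sampler

    chain_out = []
    root = np.random.SeedSequence(settings.seed)
    for c, ss in enumerate(root.spawn(settings.chains)):
        rng = np.random.Generator(np.random.PCG64(ss))
        chain_out.append(_run_chain(y, n, obs, t, graph, spec, rng))

    draws = {name: np.stack([co[name] for co in chain_out]) for name in
             ("alpha", "beta", "u", "v", "delta", "tau_u", "tau_v", "tau_delta")}
    fitted = np.stack([co["fitted"] for co in chain_out])
    deviance_draws = np.stack([co["deviance"] for co in chain_out])

    result = FitResult(
        draws=draws,
        fitted=fitted,
        deviance_draws=deviance_draws,
        deviance_at_mean=np.nan,
        diagnostics={},
        block_ids=graph.block_ids,
        rounds=dataset.rounds,
        family=dataset.family,
        spec=spec,
        dataset_key=(dataset.indicator_id, dataset.family, len(dataset.observations), dataset.rounds),
    )
    result.deviance_at_mean = deviance(result.posterior_mean_params(), dataset, spec)
    result.diagnostics = _diagnostics(draws, spec)
    return result


def smoothed_levels(fit_result: FitResult) -> "pd.DataFrame":
    """Posterior median and 95% credible interval (2.5th/97.5th quantiles of
    the fitted-value draws) for every (block, round), including missing
    cells."""
    import pandas as pd

    if fit_result.n_draws < 500:
        raise ValueError(f"need >= 500 posterior draws for stable quantiles, have {fit_result.n_draws}")
    f = fit_result.fitted_flat()  # (N, B, R)
    med = np.median(f, axis=0)
    lo, hi = np.quantile(f, [0.025, 0.975], axis=0)
    rows = []
    for i, bid in enumerate(fit_result.block_ids):
        for k, rnd in enumerate(fit_result.rounds):
            rows.append({"block_id": bid, "round": rnd, "median": med[i, k], "lo": lo[i, k], "hi": hi[i, k]})
    return pd.DataFrame(rows, columns=["block_id", "round", "median", "lo", "hi"])
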
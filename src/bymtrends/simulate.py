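"""Synthetic indicator data with the generative structure the model assumes.

Generates block-round observations from the BYM spatiotemporal model itself:
an ICAR spatial field u, iid heterogeneity v, a state-average linear trend
beta0, optional per-block trend deviations delta, survey-scale denominators
drawn uniformly from a range (default 19-123 respondents per block-round,
the scale of a block-level household survey), and optionally missing cells.
The realised truth is returned alongside the dataset so recovery tests can
compare posterior estimates against known generating values.

The default map is a rectangular rook lattice with cells removed to give
534 blocks — the number of sub-district blocks in the motivating state-wide
survey — since the analysis depends on the map only through adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import IndicatorDataset, IndicatorObservation
from .spatial import BlockGraph, icar_precision, make_lattice, sample_icar_field

__all__ = ["TruthSpec", "SyntheticTruth", "generate", "scenario", "default_blocks_graph", "SCENARIOS"]


@dataclass(frozen=True)
class TruthSpec:
    """Generating truth for one synthetic indicator.

    alpha0 and beta0 are on the logit (binary) or log (count) scale;
    sd_delta = 0 disables the space-time interaction.  ``delta_values``
    optionally pins per-block trend deviations instead of drawing them.
    """

    alpha0: float = 0.0
    beta0: float = 0.0
    sd_u: float = 0.0
    sd_v: float = 0.0
    sd_delta: float = 0.0
    n_range: tuple[int, int] = (19, 123)
    rounds: int = 4
    missing_fraction: float = 0.0
    family: str = "binary"
    seed: int = 0
    delta_values: tuple[float, ...] | None = None
    missing_unit: str = "block"

    def __post_init__(self) -> None:
        if min(self.sd_u, self.sd_v, self.sd_delta) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_range[0] < 1 or self.n_range[1] < self.n_range[0]:
            raise ValueError(f"invalid n_range {self.n_range}")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError(f"missing_fraction must be in [0, 1), got {self.missing_fraction}")
        if self.rounds < 1:
            raise ValueError("need at least one round")
        if self.family not in ("binary", "count"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.missing_unit not in ("block", "cell"):
            raise ValueError(f"missing_unit must be 'block' or 'cell', got {self.missing_unit!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Realised generating values: fields in graph block order, plus the
    per-cell true probability (binary) or rate per unit denominator
    (count)."""

    alpha: float
    beta: float
    u: np.ndarray
    v: np.ndarray
    delta: np.ndarray
    true_cell_values: np.ndarray  # (n_blocks, n_rounds)
    block_ids: tuple
    rounds: tuple

    def true_or(self) -> np.ndarray:
        """True per-block relative change per year, exp(beta + delta_i)."""
        return np.exp(self.beta + self.delta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block_id": list(self.block_ids),
                "u": self.u,
                "v": self.v,
                "delta": self.delta,
                "true_or": self.true_or(),
            }
        )


def _center(x: np.ndarray, labels: np.ndarray | None = None) -> np.ndarray:
    if labels is None:
        return x - x.mean()
    out = x.copy()
    for k in np.unique(labels):
        m = labels == k
        out[m] -= out[m].mean()
    return out


def generate(
    graph: BlockGraph, truth: TruthSpec, indicator_id: str = "synthetic", first_round: int = 6
) -> tuple[IndicatorDataset, SyntheticTruth]:
    """Draw one synthetic indicator dataset and its generating truth.

    eta_it = alpha0 + beta0*t + u_i + v_i + delta_i*t with t = 0..rounds-1;
    y_it ~ Binomial(n_it, expit(eta)) or Poisson(n_it * exp(eta)); n_it
    uniform integers from n_range; a missing_fraction of cells is removed
    after generation.  Deterministic given truth.seed.
    """
    rng = np.random.default_rng(truth.seed)
    B = graph.n_blocks
    labels = graph.component_labels()

    if truth.sd_u > 0:
        prec = icar_precision(graph)
        u = sample_icar_field(prec, 1.0 / truth.sd_u**2, rng, graph=graph)
    else:
        u = np.zeros(B)
    v = rng.normal(0.0, truth.sd_v, size=B) if truth.sd_v > 0 else np.zeros(B)
    if truth.delta_values is not None:
        if len(truth.delta_values) != B:
            raise ValueError(f"delta_values has length {len(truth.delta_values)}, expected {B}")
        delta = np.asarray(truth.delta_values, dtype=float)
    elif truth.sd_delta > 0:
        delta = _center(rng.normal(0.0, truth.sd_delta, size=B), labels)
    else:
        delta = np.zeros(B)

    t = np.arange(truth.rounds, dtype=float)
    eta = (truth.alpha0 + u + v)[:, None] + (truth.beta0 + delta)[:, None] * t[None, :]
    n = rng.integers(truth.n_range[0], truth.n_range[1] + 1, size=(B, truth.rounds))
    if truth.family == "binary":
        p = expit(eta)
        y = rng.binomial(n, p)
        cell_truth = p
    else:
        mu = np.exp(eta)
        y = rng.poisson(n * mu)
        cell_truth = mu

    rounds = tuple(first_round + k for k in range(truth.rounds))
    cells = [(i, k) for i in range(B) for k in range(truth.rounds)]
    missing_idx: set[tuple[int, int]] = set()
    if truth.missing_fraction > 0:
        if truth.missing_unit == "block":
            # unsurveyed blocks: no respondents in any round, the situation
            # the model imputes from neighbours alone
            n_miss = max(1, int(round(truth.missing_fraction * B)))
            blocks = rng.choice(B, size=n_miss, replace=False)
            missing_idx = {(int(i), k) for i in blocks for k in range(truth.rounds)}
        else:
            n_miss = int(round(truth.missing_fraction * len(cells)))
            chosen = rng.choice(len(cells), size=n_miss, replace=False)
            missing_idx = {cells[c] for c in chosen}

    obs = [
        IndicatorObservation(block_id=graph.block_ids[i], round=rounds[k], y=int(y[i, k]), n=int(n[i, k]))
        for i, k in cells
        if (i, k) not in missing_idx
    ]
    missing = {(graph.block_ids[i], rounds[k]) for i, k in missing_idx}
    dataset = IndicatorDataset(
        indicator_id=indicator_id, family=truth.family, observations=obs, rounds=rounds, missing=missing
    )
    synth = SyntheticTruth(
        alpha=truth.alpha0,
        beta=truth.beta0,
        u=u,
        v=v,
        delta=delta,
        true_cell_values=cell_truth,
        block_ids=graph.block_ids,
        rounds=rounds,
    )
    return dataset, synth


# Scenario presets: documented study conditions, not tuning knobs.
SCENARIOS: dict[str, TruthSpec] = {
    # broad rise in the state average with mild block-to-block trend spread
    "universal_rise": TruthSpec(alpha0=-0.5, beta0=float(np.log(1.25)), sd_u=0.5, sd_v=0.1, sd_delta=0.05),
    # mirror image: a state-wide decline
    "universal_decline": TruthSpec(alpha0=0.5, beta0=float(np.log(0.8)), sd_u=0.5, sd_v=0.1, sd_delta=0.05),
    # flat state average, strong interaction: some blocks rise, others fall
    "opposite_trends": TruthSpec(alpha0=0.0, beta0=0.0, sd_u=0.5, sd_v=0.1, sd_delta=0.4),
    # no space-time interaction at all
    "no_interaction": TruthSpec(alpha0=0.0, beta0=float(np.log(1.1)), sd_u=0.5, sd_v=0.1, sd_delta=0.0),
    # like universal_rise but with 2% of block-rounds unsurveyed
    "with_missing": TruthSpec(
        alpha0=-0.5, beta0=float(np.log(1.25)), sd_u=0.5, sd_v=0.1, sd_delta=0.05, missing_fraction=0.02
    ),
}


def scenario(name: str, **overrides) -> TruthSpec:
    """A documented preset TruthSpec; unknown names raise with the list of
    valid names."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid names: {sorted(SCENARIOS)}")
    spec = SCENARIOS[name]
    return replace(spec, **overrides) if overrides else spec


# 23x24 lattice minus 18 cells = 534 blocks, the survey's block count.
_DEFAULT_DROP = tuple((0, c) for c in range(9)) + tuple((22, c) for c in range(15, 24))


def default_blocks_graph() -> BlockGraph:
    """The default 534-block study map: a 23x24 rook lattice with corner
    cells removed (adjacency is all the analysis uses of the geography)."""
    g = make_lattice(23, 24, drop=_DEFAULT_DROP)
    assert g.n_blocks == 534
    return g
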
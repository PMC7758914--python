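"""Indicator observations, raw block-level estimates and tabular I/O.

An indicator is observed per block and survey round as a (y, n) pair:
successes out of a denominator for binary indicators, or summed counts out
of the summed maximum possible count for count indicators (e.g. number of
advice items received out of the number asked about, which varies across
respondents and rounds).  Blocks with no respondents in a round are missing
cells, represented explicitly — never as zero counts — so the model can
impute them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spatial import BlockGraph

FAMILIES = ("binary", "count")

__all__ = [
    "IndicatorObservation",
    "IndicatorDataset",
    "raw_proportion",
    "weighted_count_ratio",
    "read_observations",
    "read_individual_counts",
    "write_observations",
    "validate_dataset",
]


@dataclass(frozen=True)
class IndicatorObservation:
    """One observed (block, round) cell: y successes/counts out of n."""

    block_id: object
    round: int
    y: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1 (got n={self.n} for block {self.block_id!r}); a cell with no respondents is a missing cell, not a zero denominator")
        if not (0 <= self.y <= self.n):
            raise ValueError(f"need 0 <= y <= n, got y={self.y}, n={self.n} for block {self.block_id!r}, round {self.round}")

    @property
    def raw_value(self) -> float:
        return raw_proportion(self.y, self.n)


@dataclass
class IndicatorDataset:
    """All observations of one indicator across blocks and rounds."""

    indicator_id: str
    family: str
    observations: list[IndicatorObservation]
    rounds: tuple[int, ...]
    missing: set[tuple[object, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        self.rounds = tuple(self.rounds)
        seen = set()
        for obs in self.observations:
            key = (obs.block_id, obs.round)
            if key in seen:
                raise ValueError(f"duplicate observation for block {obs.block_id!r}, round {obs.round}")
            if obs.round not in self.rounds:
                raise ValueError(f"observation round {obs.round} not in rounds {self.rounds}")
            seen.add(key)
        overlap = self.missing & seen
        if overlap:
            raise ValueError(f"cells marked missing but observed: {sorted(map(str, overlap))[:3]}")

    @property
    def block_ids(self) -> tuple:
        seen: dict = {}
        for obs in self.observations:
            seen.setdefault(obs.block_id, None)
        for bid, _ in sorted(self.missing, key=str):
            seen.setdefault(bid, None)
        return tuple(seen)

    def observed(self) -> dict[tuple[object, int], IndicatorObservation]:
        return {(o.block_id, o.round): o for o in self.observations}

    def raw_estimates(self) -> pd.DataFrame:
        """Raw (unsmoothed) per-cell estimates y/n for observed cells only."""
        rows = [
            {"block_id": o.block_id, "round": o.round, "y": o.y, "n": o.n, "raw_value": o.raw_value}
            for o in self.observations
        ]
        return pd.DataFrame(rows, columns=["block_id", "round", "y", "n", "raw_value"])

    def to_arrays(self, graph: BlockGraph) -> dict:
        """Dense (n_blocks, n_rounds) arrays of y, n and an observed mask,
        in graph block order; unobserved cells hold zeros under mask False."""
        B, R = graph.n_blocks, len(self.rounds)
        ridx = {r: k for k, r in enumerate(self.rounds)}
        y = np.zeros((B, R))
        n = np.zeros((B, R))
        obs = np.zeros((B, R), dtype=bool)
        for o in self.observations:
            i, k = graph.index(o.block_id), ridx[o.round]
            y[i, k] = o.y
            n[i, k] = o.n
            obs[i, k] = True
        return {"y": y, "n": n, "observed": obs}


def raw_proportion(y: int, n: int) -> float:
    """Raw proportion y/n; n = 0 signals a missing cell, not a zero estimate."""
    if n == 0:
        raise ValueError("n = 0 denotes a missing cell (no respondents), not a proportion of zero")
    if n < 0 or not (0 <= y <= n):
        raise ValueError(f"need 0 <= y <= n with n >= 1, got y={y}, n={n}")
    return y / n


def weighted_count_ratio(records: Iterable[tuple[int, int]]) -> tuple[float, int, int]:
    """Block-level count estimate, weighted by the maximum possible count.

    Each record is a per-respondent (count, max_count) pair; the block value
    is the ratio of sums sum(count)/sum(max_count), i.e. the mean of
    per-respondent ratios weighted by max_count.  Returns
    ``(value, y, n) = (sum_c / sum_m, sum_c, sum_m)`` so the aggregate plugs
    into the Poisson model as counts with an offset.
    """
    total_c = total_m = 0
    for k, (c, m) in enumerate(records):
        if m < 1:
            raise ValueError(f"record {k}: max_count must be >= 1, got {m}")
        if not (0 <= c <= m):
            raise ValueError(f"record {k}: need 0 <= count <= max_count, got ({c}, {m})")
        total_c += c
        total_m += m
    if total_m == 0:
        raise ValueError("no records")
    return total_c / total_m, total_c, total_m


OBS_COLUMNS = ["indicator_id", "family", "block_id", "round", "y", "n"]


def read_observations(
    table,
    family: str | None = None,
    graph: BlockGraph | None = None,
    rounds: Sequence[int] | None = None,
) -> dict[str, IndicatorDataset]:
    """Read the aggregated observation CSV into one dataset per indicator.

    Columns: ``indicator_id,family,block_id,round,y,n``.  Duplicate
    (block, round) rows are rejected.  If a graph is given, blocks present
    in the graph but absent from the table for a round are recorded as
    missing cells of that round.
    """
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, dtype={"block_id": str})
    missing_cols = [c for c in OBS_COLUMNS if c not in df.columns and not (c == "family" and family)]
    if missing_cols:
        raise ValueError(f"observation table lacks columns {missing_cols}")
    if "family" not in df.columns:
        df = df.assign(family=family)
    bad = df[df["y"] > df["n"]]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(f"y > n for indicator {r['indicator_id']!r}, block {r['block_id']!r}, round {r['round']}")
    out: dict[str, IndicatorDataset] = {}
    for ind, sub in df.groupby("indicator_id", sort=True):
        fams = sub["family"].unique()
        if len(fams) != 1:
            raise ValueError(f"indicator {ind!r} has conflicting families {list(fams)}")
        fam = family or fams[0]
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {fam!r} for indicator {ind!r}")
        rnds = tuple(rounds) if rounds is not None else tuple(sorted(sub["round"].unique()))
        obs = [
            IndicatorObservation(block_id=r.block_id, round=int(r.round), y=int(r.y), n=int(r.n))
            for r in sub.itertuples()
        ]
        miss: set[tuple[object, int]] = set()
        if graph is not None:
            have = {(o.block_id, o.round) for o in obs}
            miss = {(b, r) for b in graph.block_ids for r in rnds if (b, r) not in have}
        out[str(ind)] = IndicatorDataset(
            indicator_id=str(ind), family=fam, observations=obs, rounds=rnds, missing=miss
        )
    return out


def read_individual_counts(table, graph: BlockGraph | None = None, rounds=None) -> dict[str, IndicatorDataset]:
    """Read the individual-level count CSV
    (``indicator_id,block_id,round,count,max_count``), aggregating each
    (indicator, block, round) cell by the weighted count ratio."""
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, dtype={"block_id": str})
    need = ["indicator_id", "block_id", "round", "count", "max_count"]
    lack = [c for c in need if c not in df.columns]
    if lack:
        raise ValueError(f"individual-level table lacks columns {lack}")
    rows = []
    for (ind, bid, rnd), sub in df.groupby(["indicator_id", "block_id", "round"], sort=True):
        _, y, n = weighted_count_ratio(zip(sub["count"], sub["max_count"]))
        rows.append({"indicator_id": ind, "family": "count", "block_id": bid, "round": rnd, "y": y, "n": n})
    return read_observations(pd.DataFrame(rows), graph=graph, rounds=rounds)


def write_observations(datasets: Iterable[IndicatorDataset], path) -> pd.DataFrame:
    """Write datasets in the aggregated CSV dialect plus a raw_value column."""
    rows = []
    for ds in datasets:
        for o in sorted(ds.observations, key=lambda o: (str(o.block_id), o.round)):
            rows.append(
                {
                    "indicator_id": ds.indicator_id,
                    "family": ds.family,
                    "block_id": o.block_id,
                    "round": o.round,
                    "y": o.y,
                    "n": o.n,
                    "raw_value": o.raw_value,
                }
            )
    df = pd.DataFrame(rows, columns=OBS_COLUMNS + ["raw_value"])
    if path is not None:
        df.to_csv(path, index=False)
    return df


@dataclass
class ValidationReport:
    issues: list[str]
    denominator_range: tuple[int, int] | None
    rounds_without_observations: list[int]
    n_missing_cells: int

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_dataset(dataset: IndicatorDataset, graph: BlockGraph) -> ValidationReport:
    """Check a dataset against the graph; hard error on invariant violations."""
    known = set(graph.block_ids)
    unknown = sorted({str(o.block_id) for o in dataset.observations if o.block_id not in known})
    if unknown:
        raise ValueError(f"observations reference blocks absent from the graph: {unknown[:5]}")
    issues: list[str] = []
    ns = [o.n for o in dataset.observations]
    by_round = {r: 0 for r in dataset.rounds}
    for o in dataset.observations:
        by_round[o.round] += 1
    empty_rounds = [r for r, c in by_round.items() if c == 0]
    for r in empty_rounds:
        issues.append(f"round {r} has zero observations")
    unknown_missing = sorted({str(b) for b, _ in dataset.missing if b not in known})
    if unknown_missing:
        raise ValueError(f"missing cells reference blocks absent from the graph: {unknown_missing[:5]}")
    return ValidationReport(
        issues=issues,
        denominator_range=(min(ns), max(ns)) if ns else None,
        rounds_without_observations=empty_rounds,
        n_missing_cells=len(dataset.missing),
    )
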
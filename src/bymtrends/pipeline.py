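"""Config-driven orchestration of the full analysis.

For each indicator: raw estimation, fit of the no-interaction and the
interaction model, DIC selection, block-level trend estimation by posterior
resampling, classification, and writing of all artifacts (smoothed-level
CSV, trends CSV, summary CSV, draws table, JSON run report, optionally a
GeoJSON annotated with per-block trend properties).  Both models are always
fitted so the DIC table is always reportable.  Convergence warnings are
prominent but non-fatal: the workflow is batch over many indicators.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import IndicatorDataset, read_observations, validate_dataset
from .inference import ModelSpec, SamplerSettings, fit, smoothed_levels
from .selection import block_trends, select_model, summarize_indicator, trends_table
from .spatial import BlockGraph, build_graph_from_geojson, read_edgelist_csv

log = logging.getLogger("bymtrends")

__all__ = ["RunConfig", "run_indicator", "run_all", "load_config", "annotate_geojson"]


@dataclass
class RunConfig:
    """Flat run configuration, loadable from a YAML document."""

    observations: str | None = None
    adjacency: str | None = None  # GeoJSON (.geojson/.json) or edge-list CSV
    blocks: str | None = None  # companion blocks.csv for an edge-list
    out_dir: str = "bymtrends_out"
    indicators: list[str] = field(default_factory=list)
    families: dict[str, str] = field(default_factory=dict)
    resamples: int = 10_000
    mode: str = "joint"
    seed: int = 0
    iterations: int = 5000
    burnin: int = 2000
    thin: int = 2
    chains: int = 4
    id_property: str = "block_id"
    save_draws: bool = False  # persist the chosen fit's draws table (large)

    def __post_init__(self) -> None:
        if self.resamples < 1000:
            raise ValueError(f"resamples must be >= 1000, got {self.resamples}")
        if self.mode not in ("joint", "independent"):
            raise ValueError(f"mode must be 'joint' or 'independent', got {self.mode!r}")

    def sampler(self, seed: int) -> SamplerSettings:
        return SamplerSettings(
            iterations=self.iterations, burnin=self.burnin, thin=self.thin, chains=self.chains, seed=seed
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


def load_graph(config: RunConfig) -> BlockGraph:
    if config.adjacency is None:
        raise ValueError("config.adjacency is required (GeoJSON or edge-list CSV)")
    p = Path(config.adjacency)
    if p.suffix.lower() in (".geojson", ".json"):
        return build_graph_from_geojson(p, id_property=config.id_property)
    return read_edgelist_csv(p, blocks_path=config.blocks)


def _indicator_seed(base_seed: int, indicator_id: str) -> int:
    # stable per-indicator stream, independent of run order and process; < 2**31
    import zlib

    h = np.random.SeedSequence([base_seed, zlib.crc32(indicator_id.encode())])
    return int(h.generate_state(1)[0] % (2**31))


@dataclass
class IndicatorResult:
    indicator_id: str
    selection: object
    smoothed: pd.DataFrame
    trends: list
    summary: object
    report: dict


def run_indicator(
    config: RunConfig,
    indicator_id: str,
    dataset: IndicatorDataset | None = None,
    graph: BlockGraph | None = None,
    write: bool = True,
) -> IndicatorResult:
    """Full per-indicator procedure: raw estimation, both fits, DIC
    selection, trends on the chosen fit, classification, summary; artifacts
    written under ``out_dir/<indicator>/``."""
    t0 = time.perf_counter()
    if graph is None:
        graph = load_graph(config)
    if dataset is None:
        if config.observations is None:
            raise ValueError("config.observations is required when no dataset is passed")
        datasets = read_observations(config.observations, graph=graph)
        if indicator_id not in datasets:
            raise KeyError(f"indicator {indicator_id!r} not in observations (have {sorted(datasets)})")
        dataset = datasets[indicator_id]
    validate_dataset(dataset, graph)
    seed = _indicator_seed(config.seed, indicator_id)
    raw = dataset.raw_estimates()
    log.info("indicator=%s stage=raw n_cells=%d elapsed=%.2fs", indicator_id, len(raw), time.perf_counter() - t0)

    fits = {}
    for interaction in (False, True):
        t1 = time.perf_counter()
        spec = ModelSpec(
            family=dataset.family,
            include_interaction=interaction,
            sampler=config.sampler(seed + int(interaction)),
        )
        fits[interaction] = fit(dataset, graph, spec)
        log.info(
            "indicator=%s stage=fit interaction=%s rhat_max=%.3f seed=%d elapsed=%.2fs",
            indicator_id, interaction, fits[interaction].diagnostics["rhat_max"], seed + int(interaction),
            time.perf_counter() - t1,
        )
        if not fits[interaction].converged:
            log.warning(
                "indicator=%s CONVERGENCE WARNING: interaction=%s split-Rhat %.3f > 1.05",
                indicator_id, interaction, fits[interaction].diagnostics["rhat_max"],
            )

    sel = select_model(fits[False], fits[True])
    smoothed = smoothed_levels(sel.chosen)
    trends = block_trends(sel.chosen, resamples=config.resamples, seed=seed + 7, mode=config.mode)
    summary = summarize_indicator(trends, sel, indicator_id=indicator_id)

    report = {
        "indicator_id": indicator_id,
        "family": dataset.family,
        "software_version": __version__,
        "seed": seed,
        "resamples": config.resamples,
        "mode": config.mode,
        "dic": {
            "no_interaction": {"dbar": sel.dic_no_interaction.dbar, "pd": sel.dic_no_interaction.pd, "dic": sel.dic_no_interaction.dic},
            "interaction": {"dbar": sel.dic_interaction.dbar, "pd": sel.dic_interaction.pd, "dic": sel.dic_interaction.dic},
        },
        "interaction_selected": sel.interaction_evidence,
        "diagnostics": {
            "no_interaction": fits[False].diagnostics,
            "interaction": fits[True].diagnostics,
        },
        "unconverged": not sel.chosen.converged,
        "n_missing_cells": len(dataset.missing),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }

    if write:
        out = Path(config.out_dir) / indicator_id
        out.mkdir(parents=True, exist_ok=True)
        raw.to_csv(out / "raw_estimates.csv", index=False)
        smoothed.to_csv(out / "smoothed_levels.csv", index=False)
        trends_table(trends, indicator_id).to_csv(out / "trends.csv", index=False)
        sel.dic_table().to_csv(out / "dic.csv", index=False)
        if config.save_draws:
            sel.chosen.to_draws_table().to_csv(out / "draws.csv", index=False)
        with open(out / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return IndicatorResult(indicator_id, sel, smoothed, trends, summary, report)


def run_all(config: RunConfig, datasets: dict[str, IndicatorDataset] | None = None, graph: BlockGraph | None = None):
    """Map :func:`run_indicator` over the indicator list; one failure does
    not stop the others.  Returns (results, combined summary DataFrame,
    failures)."""
    if graph is None:
        graph = load_graph(config)
    if datasets is None:
        datasets = read_observations(config.observations, graph=graph)
    indicator_ids = config.indicators or sorted(datasets)
    if not indicator_ids:
        raise ValueError("empty indicator list")
    results: dict[str, IndicatorResult] = {}
    failures: dict[str, str] = {}
    for ind in indicator_ids:
        try:
            results[ind] = run_indicator(config, ind, dataset=datasets.get(ind), graph=graph)
        except Exception as exc:  # record and continue with the rest
            log.error("indicator=%s FAILED: %s", ind, exc)
            failures[ind] = str(exc)
    rows = []
    for ind in indicator_ids:
        if ind in results:
            r = results[ind]
            s = r.summary
            rows.append(
                {
                    "indicator_id": ind,
                    "status": "unconverged" if r.report["unconverged"] else "ok",
                    "interaction_selected": s.interaction_selected,
                    "dic_no_int": r.selection.dic_no_interaction.dic,
                    "dic_int": r.selection.dic_interaction.dic,
                    "n_increase": s.n_increase,
                    "n_decrease": s.n_decrease,
                    "n_indeterminate": s.n_indeterminate,
                }
            )
        else:
            rows.append({"indicator_id": ind, "status": f"failed: {failures[ind]}"})
    combined = pd.DataFrame(rows)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    combined.to_csv(out / "summary.csv", index=False)
    return results, combined, failures


def annotate_geojson(geojson: dict, trends: list, indicator_id: str, id_property: str = "block_id") -> dict:
    """Attach or_point and category per block to a FeatureCollection's
    properties, for downstream choropleth rendering."""
    by_block = {t.block_id: t for t in trends}
    out = json.loads(json.dumps(geojson))  # deep copy
    for feat in out["features"]:
        bid = feat["properties"][id_property]
        t = by_block.get(bid)
        if t is not None:
            feat["properties"][f"{indicator_id}_or_point"] = t.or_point
            feat["properties"][f"{indicator_id}_category"] = t.category
    return out
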
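"""End-to-end pipeline: encode -> mine -> filter -> graph -> report.

Fully reproducible under a fixed seed; per-stage rule counts are logged
to the ``crashrules`` logger so calibration and filtering behaviour can
be audited from the run log alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import graph as rgs
from .catalog import FactorCatalog, default_catalog
from .filtering import FilterConfig, apply_filters, filter_report_frame, kept_rules
from .mining import MiningConfig, mine_rules, rules_to_frame, write_rules_csv
from .report import (
    combination_profile,
    combination_profile_frame,
    rule_value_distribution,
    top_rules,
)
from .synthetic import GeneratorConfig, PlantedRuleSpec, generate, study_config
from .transactions import TransactionTable, load_crash_table, validate

log = logging.getLogger("crashrules")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; synthetic data when no CSV given."""

    input_csv: str | None = None
    use_default_catalog: bool = True
    catalog_yaml: str | None = None
    seed: int = 0
    n_records: int = 1068  # synthetic only
    mining: MiningConfig = field(default_factory=MiningConfig)
    filtering: FilterConfig = field(default_factory=FilterConfig)
    louvain_seed: int = 0
    kmeans_groups: int = 20
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        mining = MiningConfig(**raw.pop("mining", {}))
        filt_raw = raw.pop("filtering", {})
        if "blacklist" in filt_raw:
            filt_raw["blacklist"] = [tuple(p) for p in filt_raw["blacklist"]]
        filtering = FilterConfig(**filt_raw)
        return cls(mining=mining, filtering=filtering, **raw)


@dataclass
class PipelineResult:
    table: TransactionTable
    catalog: FactorCatalog
    candidates: list
    filtered: list
    kept: list
    graph: object
    closeness: dict
    pagerank: dict
    partition: rgs.Partition
    report: dict


def _load_or_generate(config: PipelineConfig, catalog: FactorCatalog) -> TransactionTable:
    if config.input_csv:
        table = load_crash_table(config.input_csv, catalog)
        log.info("loaded %d records x %d items from %s",
                 table.n_records, len(table.items), config.input_csv)
        vr = validate(table, catalog)
        if vr.violations:
            log.warning("%d exclusivity violations in input", len(vr.violations))
        if vr.unknown_items:
            log.warning("unknown items in input: %s", vr.unknown_items)
        return table
    gen = study_config(seed=config.seed, n_records=config.n_records)
    table = generate(gen)
    log.info("generated synthetic table: %d records x %d items (seed %d)",
             table.n_records, len(table.items), config.seed)
    return table


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    if config.catalog_yaml:
        catalog = FactorCatalog.from_yaml(config.catalog_yaml)
    else:
        catalog = default_catalog()

    table = _load_or_generate(config, catalog)

    candidates = mine_rules(table, config.mining)
    log.info("mining: %d candidate rules at S>=%.3g C>=%.3g L>%s |LHS|<=%d",
             len(candidates), config.mining.min_support,
             config.mining.min_confidence, config.mining.min_lift,
             config.mining.max_lhs_size)
    if not candidates:
        raise RuntimeError("mining produced no candidate rules; lower the thresholds")

    filtered = apply_filters(candidates, table, config.filtering, catalog)
    kept = kept_rules(filtered)
    by_reason: dict[str, int] = {}
    for fr in filtered:
        by_reason[fr.rejection_reason] = by_reason.get(fr.rejection_reason, 0) + 1
    log.info("filtering: %d kept of %d (%s)", len(kept), len(filtered),
             ", ".join(f"{k}={v}" for k, v in sorted(by_reason.items())))
    if not kept:
        raise RuntimeError("all rules were filtered out")

    g = rgs.build_graph(kept)
    close = rgs.closeness(g)
    pr = rgs.pagerank(g)
    partition = rgs.detect_communities(g, seed=config.louvain_seed)
    log.info("graph: %d nodes (%d factors), %d edges, %d modules, Q=%.3f",
             g.number_of_nodes(), len(rgs.factor_nodes(g)),
             g.number_of_edges(), partition.n_modules, partition.q)

    dist = rule_value_distribution(kept)
    cells = combination_profile(table, catalog)
    contributions = rgs.factor_contributions(g, close, catalog)
    report = {
        "n_records": table.n_records,
        "n_candidate_rules": len(candidates),
        "n_kept_rules": len(kept),
        "rejections": by_reason,
        "distribution": dist,
        "graph": {
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
            "n_factor_nodes": len(rgs.factor_nodes(g)),
            "n_modules": partition.n_modules,
            "modularity_q": partition.q,
        },
        "top_lift_rules": [
            {"rule": r.label(), "support": r.support,
             "confidence": r.confidence, "lift": r.lift}
            for r in top_rules(kept, "lift", 10)
        ],
        "factor_contributions": {
            construct: [{"factor": f, "contribution_pct": c} for f, c in ranked[:8]]
            for construct, ranked in contributions.items()
        },
        "combination_profile": {
            "+".join(sorted(cell)): frac for cell, frac in sorted(
                cells.items(), key=lambda kv: "+".join(sorted(kv[0]))
            )
        },
    }

    result = PipelineResult(
        table=table, catalog=catalog, candidates=candidates, filtered=filtered,
        kept=kept, graph=g, closeness=close, pagerank=pr, partition=partition,
        report=report,
    )
    if config.output_dir:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_rules_csv(result.kept, out / "rules.csv")
    rules_to_frame(result.candidates).to_csv(out / "candidates.csv", index=False)
    filter_report_frame(result.filtered).to_csv(out / "filter_report.csv", index=False)
    rgs.export_graph(result.graph, out / "rules_graph.graphml", result.partition)
    rgs.export_graph(result.graph, out / "rules_graph.gexf", result.partition)
    rgs.centrality_frame(
        result.graph, result.closeness, result.pagerank, result.partition
    ).to_csv(out / "centrality.csv", index=False)
    cells = combination_profile(result.table, result.catalog)
    combination_profile_frame(cells).to_csv(out / "combination_profile.csv", index=False)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(result.report, fh, indent=2)
    log.info("artifacts written to %s", out)


__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "GeneratorConfig",
    "PlantedRuleSpec",
]
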
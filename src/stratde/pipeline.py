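"""End-to-end driver: simulate (optional) -> filter -> call -> enrich -> compare.

The whole run is configured by one mapping (YAML-friendly) holding the
synthetic-study parameters, the DE thresholds and the seed, and returns all
intermediate objects so drivers and tests can inspect any stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

import pandas as pd

from stratde.compare_report import (
    ConcordanceResult,
    ModelComparison,
    assign_color_classes,
    compare_models,
    qpcr_concordance,
)
from stratde.de_core import FilterParams, filter_detected, run_model
from stratde.enrich import adjust_pvalues, fisher_enrichment
from stratde.io_formats import CountTable, TermAnnotation
from stratde.sim import SyntheticSpec, simulate_annotation, simulate_counts, simulate_qpcr


@dataclass
class PipelineResult:
    table: CountTable
    truth: pd.DataFrame
    calls: dict[str, pd.DataFrame]
    universes: dict[str, set]
    comparison: ModelComparison
    colors: dict[str, str]
    annotation: TermAnnotation | None = None
    enrichment: pd.DataFrame | None = None
    concordance: dict[str, ConcordanceResult] = field(default_factory=dict)


def run_synthetic_study(
    spec: SyntheticSpec | None = None,
    params: FilterParams | None = None,
    n_terms: int = 50,
    enriched_terms: int = 1,
    enrichment_odds: float = 20.0,
    qpcr_panel_size: int = 10,
    qpcr_noise_sd: float = 0.25,
    qpcr_min_expr: float = 5.0,
    adjust: str = "none",
) -> PipelineResult:
    """Run the full synthetic two-model analysis with known ground truth.

    Enrichment tests the shared-DE set (genes called DE in the same
    direction in both models) against the simulated annotation, with each
    model's universe being its detection-filtered gene set (their union for
    the shared set). The qPCR panel per model draws the highest-|log2fc|
    called genes among well-measured high-stratum hits, mirroring a
    validation panel of strong candidates.
    """
    spec = spec or SyntheticSpec()
    params = params or FilterParams()
    table, truth = simulate_counts(spec)

    calls: dict[str, pd.DataFrame] = {}
    universes: dict[str, set] = {}
    for model in table.models():
        filtered = filter_detected(table, params, model)
        calls[model] = run_model(table, params, model)
        universes[model] = set(filtered.gene_ids)

    comparison = compare_models(calls["A"], calls["B"])
    colors = assign_color_classes(comparison)

    annotation = simulate_annotation(
        truth, n_terms=n_terms, enriched_terms=enriched_terms,
        enrichment_odds=enrichment_odds, seed=spec.seed + 1,
    )
    shared = comparison.genes_in_class("up-both") | comparison.genes_in_class("down-both")
    universe = universes["A"] | universes["B"]
    enrichment = adjust_pvalues(fisher_enrichment(shared, universe, annotation), adjust)

    concordance: dict[str, ConcordanceResult] = {}
    for offset, model in enumerate(("A", "B")):
        de_calls = calls[model]
        # validation panel: strongest well-measured hits — high-stratum DE
        # calls with both condition means above qpcr_min_expr CPM, ranked by
        # |log2fc|; the expression floor keeps one-sided dropouts (huge
        # apparent fold change, unreliable measurement) off the panel
        well_measured = (
            de_calls[["ctrl_norm", "diab_norm"]].min(axis=1) >= qpcr_min_expr
        )
        de = de_calls[
            (de_calls["call"] != "unchanged")
            & (de_calls["stratum"] == "high")
            & well_measured
        ]
        panel = de.reindex(de["log2fc"].abs().sort_values(ascending=False).index)
        panel = panel.head(qpcr_panel_size)
        if len(panel) >= 3:
            qpcr = simulate_qpcr(
                truth, list(panel["gene_id"]), qpcr_noise_sd,
                seed=spec.seed + 2 + offset, model=model,
            )
            concordance[model] = qpcr_concordance(de_calls, qpcr)

    return PipelineResult(
        table=table, truth=truth, calls=calls, universes=universes,
        comparison=comparison, colors=colors, annotation=annotation,
        enrichment=enrichment, concordance=concordance,
    )


def config_to_objects(config: dict[str, Any]) -> tuple[SyntheticSpec, FilterParams, dict]:
    """Split a flat YAML config into spec, params and pipeline keywords."""
    spec_fields = set(SyntheticSpec.__dataclass_fields__)
    param_fields = set(FilterParams.__dataclass_fields__)
    spec_kwargs = {k: v for k, v in config.items() if k in spec_fields}
    if "baseline_shape" in spec_kwargs:
        spec_kwargs["baseline_shape"] = tuple(spec_kwargs["baseline_shape"])
    param_kwargs = {k: v for k, v in config.items() if k in param_fields}
    rest = {k: v for k, v in config.items() if k not in spec_fields | param_fields}
    return SyntheticSpec(**spec_kwargs), FilterParams(**param_kwargs), rest


def result_summary(result: PipelineResult) -> dict[str, Any]:
    """Headline numbers of a run, JSON-ready."""
    out: dict[str, Any] = {
        "n_genes": len(result.table.gene_ids),
        "n_filtered_A": len(result.universes["A"]),
        "n_filtered_B": len(result.universes["B"]),
    }
    for model, calls in result.calls.items():
        out[f"up_{model}"] = int((calls["call"] == "up").sum())
        out[f"down_{model}"] = int((calls["call"] == "down").sum())
    out["shared_up"] = result.comparison.summary["up-both"]
    out["shared_down"] = result.comparison.summary["down-both"]
    out["discordant"] = result.comparison.summary["discordant"]
    for model, conc in result.concordance.items():
        out[f"qpcr_r_{model}"] = conc.r
    if result.enrichment is not None and not result.enrichment.empty:
        out["top_enrichment_acc"] = str(result.enrichment.iloc[0]["acc"])
        out["top_enrichment_p"] = float(result.enrichment.iloc[0]["p"])
    return out


def spec_params_header(spec: SyntheticSpec, params: FilterParams) -> dict:
    """Provenance header fields for result writers."""
    hdr = {f"spec.{k}": v for k, v in asdict(spec).items()}
    hdr.update({f"params.{k}": v for k, v in asdict(params).items()})
    return hdr
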
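"""End-to-end pipeline: chain signature extraction, ortholog pairing,
correlation, overlap curves and enrichment on real or synthetic inputs.

A run is fully described by a :class:`RunConfig`; every run writes its
resolved configuration, a machine-readable summary (per-stage record counts,
dropped-gene accounting, config hash) and one tab-separated table per result
into the output directory.  Two runs with identical config and seed produce
byte-identical outputs.  Any stage error aborts the run with the stage name
and offending input identified.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .datatypes import (
    PairedVector,
    RankedVector,
    Signature,
    Species,
    ValidationError,
)
from .compare import (
    CorrelationResult,
    cumulative_overlap,
    overlap_summary,
    rank_comparisons,
    spearman_rho,
)
from .enrichment import enrich_collection, project_cell_states, tf_enrichment
from .io import (
    read_de_table,
    read_gmt,
    read_ortholog_map,
    read_trrust,
    write_de_table,
    write_gmt,
    write_ortholog_map,
    write_results,
)
from .ortholog import map_gene_set, pair_fold_changes
from .signatures import add_fdr, extract_signature
from .simulate import GenerativeConfig, ProgramSpec, simulate_pair

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline",
           "ranked_from_paired", "top_k_paired"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    When ``de_a`` is unset the run simulates its own inputs from the
    ``generative`` config (and writes them into ``outdir/inputs`` so the run
    is reproducible from files alone).
    """

    outdir: str = "sigcross_run"
    seed: int = 0
    # thresholds
    fdr_max: float = 0.1
    lfc_min: float = 1.0
    top_k: int = 100
    significance_alpha: float = 0.05
    # policies
    ortholog_policy: str = "strict_one_to_one"
    universe_policy: str = "query_table"  # or "intersect_reference"
    # input paths (all optional; unset de_a switches to simulation)
    de_a: str | None = None
    de_b: str | None = None
    ortholog_map: str | None = None
    reference_gmt: str | None = None
    tf_targets: str | None = None
    markers_gmt: str | None = None
    species_a: str = "synthetic"
    species_b: str = "synthetic"
    generative: GenerativeConfig = field(default_factory=GenerativeConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.fdr_max <= 1:
            raise ValidationError("fdr_max must lie in [0, 1]")
        if self.lfc_min <= 0:
            raise ValidationError("lfc_min must be positive")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if not 0 < self.significance_alpha < 1:
            raise ValidationError("significance_alpha must lie in (0, 1)")
        if self.ortholog_policy not in ("strict_one_to_one", "expand_all"):
            raise ValidationError(
                f"unknown ortholog_policy '{self.ortholog_policy}'"
            )
        if self.universe_policy not in ("query_table", "intersect_reference"):
            raise ValidationError(
                f"unknown universe_policy '{self.universe_policy}'"
            )

    @property
    def simulate(self) -> bool:
        return self.de_a is None

    def resolved_text(self) -> str:
        """Flat key=value rendering of the full resolved configuration."""
        lines = ["[run]"]
        for f in dataclasses.fields(self):
            # outdir is where results land, not what the run computes: leaving
            # it out keeps outputs byte-identical across output locations
            if f.name in ("generative", "outdir"):
                continue
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        lines.append("[simulate]")
        for f in dataclasses.fields(self.generative):
            v = getattr(self.generative, f.name)
            if f.name == "programs":
                v = "; ".join(
                    f"{p.name}:size={p.size},effect={p.effect},"
                    f"effect_sd={p.effect_sd},direction={p.direction}"
                    for p in v
                )
            lines.append(f"{f.name} = {v}")
        return "\n".join(lines) + "\n"

    def config_hash(self) -> str:
        return hashlib.md5(self.resolved_text().encode()).hexdigest()

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a plain-text key=value config with [run] and [simulate]
        sections; keyword overrides win over file values."""
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(f"no such config file: {path}")
        kwargs: dict = {}
        if parser.has_section("run"):
            for key, raw in parser.items("run"):
                kwargs[key] = _coerce(cls, key, raw)
        sim_kwargs: dict = {}
        if parser.has_section("simulate"):
            for key, raw in parser.items("simulate"):
                if key == "programs":
                    sim_kwargs[key] = _parse_programs(raw)
                else:
                    sim_kwargs[key] = _coerce(GenerativeConfig, key, raw)
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        gen_over = kwargs.pop("generative", None)
        if gen_over is not None:
            kwargs["generative"] = gen_over
        elif sim_kwargs:
            kwargs["generative"] = GenerativeConfig(**sim_kwargs)
        return cls(**kwargs)


def _coerce(cls, key: str, raw: str):
    types = {f.name: f.type for f in dataclasses.fields(cls)}
    if key not in types:
        raise ValidationError(f"unknown config key '{key}'")
    raw = raw.strip()
    if raw.lower() in ("none", ""):
        return None
    t = str(types[key])
    if "int" in t:
        return int(raw)
    if "float" in t:
        return float(raw)
    return raw


def _parse_programs(raw: str) -> list[ProgramSpec]:
    """Parse 'name:size=100,effect=2.0[,effect_sd=0,direction=up]; ...'."""
    programs = []
    for chunk in raw.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        name, _, rest = chunk.partition(":")
        kv = dict(part.split("=", 1) for part in rest.split(",") if part)
        programs.append(
            ProgramSpec(
                name=name.strip(),
                size=int(kv.get("size", 0)),
                effect=float(kv.get("effect", 0.0)),
                effect_sd=float(kv.get("effect_sd", 0.0)),
                direction=kv.get("direction", "up").strip(),
            )
        )
    return programs


@dataclass
class RunReport:
    """What a pipeline run produced: counts, table paths, in-memory results."""

    outdir: Path
    counts: dict
    tables: dict[str, Path]
    config_hash: str
    signature_a: Signature
    signature_b: Signature | None
    paired: PairedVector | None
    correlation: list[CorrelationResult]
    curves: dict
    enrichment: list
    tf_results: list
    projections: list
    overlaps: dict


def ranked_from_paired(paired: PairedVector, order: str = "descending") -> RankedVector:
    """Rank the species-A side of a paired vector by its fold changes."""
    df = paired.data.sort_values(
        ["fc_a", "gene_a"], ascending=[order == "ascending", True],
        kind="mergesort",
    )
    return RankedVector(
        genes=tuple(df["gene_a"]),
        values=tuple(float(v) for v in df["fc_a"]),
        order=order,
    )


def top_k_paired(paired: PairedVector, k: int, direction: str = "increased") -> set[str]:
    """Top-k species-B genes of a paired vector (by fc_b, ties by gene_b),
    returned as their species-A identifiers."""
    if not 1 <= k <= paired.n_pairs:
        raise ValidationError(f"k={k} out of range for {paired.n_pairs} pairs")
    df = paired.data.sort_values(
        ["fc_b", "gene_b"], ascending=[direction == "decreased", True],
        kind="mergesort",
    )
    return set(df["gene_a"].head(k))


def _load_inputs(config: RunConfig, outdir: Path):
    if config.simulate:
        pair = simulate_pair(config.generative)
        inputs = outdir / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        write_de_table(pair.table_a, inputs / "de_table_a.tsv")
        write_de_table(pair.table_b, inputs / "de_table_b.tsv")
        write_ortholog_map(pair.ortholog_map, inputs / "ortholog_map.tsv")
        write_gmt(pair.reference_sets, inputs / "reference_sets.gmt")
        return pair.table_a, pair.table_b, pair.ortholog_map, pair.reference_sets
    table_a = read_de_table(config.de_a, label=Path(config.de_a).stem,
                            species=Species(config.species_a))
    table_b = None
    omap = None
    refsets = None
    if config.de_b:
        table_b = read_de_table(config.de_b, label=Path(config.de_b).stem,
                                species=Species(config.species_b))
    if config.ortholog_map:
        omap = read_ortholog_map(config.ortholog_map,
                                 config.species_a, config.species_b)
    if config.reference_gmt:
        refsets = read_gmt(config.reference_gmt)
    return table_a, table_b, omap, refsets


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured analysis stages and write all result tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    tables: dict[str, Path] = {}
    params = {"config_hash": config.config_hash(), "version": __version__}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ValidationError, FileNotFoundError, ValueError) as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrap

    table_a, table_b, omap, refsets = stage("inputs")(_load_inputs, config, outdir)
    counts["genes_a"] = len(table_a)
    counts["genes_b"] = len(table_b) if table_b is not None else 0

    # -- signatures ---------------------------------------------------------
    def _signatures():
        nonlocal table_a, table_b
        if not table_a.has_fdr:
            table_a = add_fdr(table_a)
        sig_a = extract_signature(table_a, config.fdr_max, config.lfc_min)
        sig_b = None
        if table_b is not None:
            if not table_b.has_fdr:
                table_b = add_fdr(table_b)
            sig_b = extract_signature(table_b, config.fdr_max, config.lfc_min)
        return sig_a, sig_b

    sig_a, sig_b = stage("signatures")(_signatures)
    counts["signature_a_up"] = len(sig_a.up)
    counts["signature_a_down"] = len(sig_a.down)
    rows = [{"gene": g, "direction": "up"} for g in sorted(sig_a.up)]
    rows += [{"gene": g, "direction": "down"} for g in sorted(sig_a.down)]
    if rows:
        write_results(pd.DataFrame(rows), outdir / "signature_a.tsv",
                      parameters=params, seed=config.seed)
        tables["signature_a"] = outdir / "signature_a.tsv"
    if sig_b is not None:
        counts["signature_b_up"] = len(sig_b.up)
        counts["signature_b_down"] = len(sig_b.down)

    # -- ortholog pairing + correlation + curves ----------------------------
    paired = None
    correlation: list[CorrelationResult] = []
    curves: dict = {}
    overlaps: dict = {}
    if table_b is not None and omap is not None:
        paired = stage("orthologs")(pair_fold_changes, table_a, table_b, omap)
        counts["ortholog_pairs"] = paired.n_pairs
        counts["ortholog_dropped"] = dict(paired.dropped)
        write_results(paired.data, outdir / "paired_fold_changes.tsv",
                      parameters={**params,
                                  "dropped": json.dumps(paired.dropped,
                                                        sort_keys=True)},
                      seed=config.seed)
        tables["paired_fold_changes"] = outdir / "paired_fold_changes.tsv"

        rs = stage("correlation")(spearman_rho, paired)
        correlation = rank_comparisons(
            [CorrelationResult(f"{table_b.label}_vs_{table_a.label}", rs,
                               paired.n_pairs)]
        )
        write_results(correlation, outdir / "correlation.tsv",
                      parameters=params, seed=config.seed)
        tables["correlation"] = outdir / "correlation.tsv"

        def _curves():
            out = {}
            k = min(config.top_k, paired.n_pairs)
            for direction, order in (("increased", "descending"),
                                     ("decreased", "ascending")):
                reference = ranked_from_paired(paired, order)
                query = top_k_paired(paired, k, direction)
                out[direction] = cumulative_overlap(reference, query)
            return out

        curves = stage("overlap_curves")(_curves)
        curve_rows = []
        for direction, curve in curves.items():
            path = outdir / f"overlap_curve_{direction}.tsv"
            write_results(curve.curve, path,
                          parameters={**params, "direction": direction,
                                      "area": curve.area,
                                      "p_value": curve.p_value},
                          seed=config.seed)
            tables[f"overlap_curve_{direction}"] = path
            curve_rows.append(
                {"direction": direction, "n_universe": curve.n_universe,
                 "k_query": curve.k_query, "area": curve.area,
                 "p_value": curve.p_value}
            )
        write_results(pd.DataFrame(curve_rows), outdir / "overlap_areas.tsv",
                      parameters=params, seed=config.seed)
        tables["overlap_areas"] = outdir / "overlap_areas.tsv"

        if sig_b is not None and (sig_b.up or sig_b.down):
            def _overlaps():
                out = {}
                for side in ("up", "down"):
                    genes_b = getattr(sig_b, side)
                    genes_a = getattr(sig_a, side)
                    if not genes_b or not genes_a:
                        continue
                    mapped, report = map_gene_set(
                        genes_b, omap.inverted(), config.ortholog_policy
                    )
                    if not mapped:
                        continue
                    out[side] = overlap_summary(genes_a, mapped)
                    out[f"{side}_drop"] = report.counts()
                return out

            overlaps = stage("signature_overlap")(_overlaps)
            rows = [
                {"side": side, "n_a": o.n_a, "n_b": o.n_b,
                 "n_intersection": o.n_intersection,
                 "pct_of_a": o.pct_of_a, "pct_of_b": o.pct_of_b}
                for side, o in overlaps.items() if not side.endswith("_drop")
            ]
            if rows:
                write_results(pd.DataFrame(rows),
                              outdir / "signature_overlap.tsv",
                              parameters=params, seed=config.seed)
                tables["signature_overlap"] = outdir / "signature_overlap.tsv"

    # -- enrichment ---------------------------------------------------------
    enrichment_results: list = []
    if refsets is not None and sig_a.up:
        def _enrich():
            universe = table_a.genes
            if config.universe_policy == "intersect_reference":
                universe = universe & refsets.all_members()
            query = sig_a.up & universe
            if not query:
                raise ValidationError(
                    "up-signature has no genes in the enrichment universe"
                )
            return enrich_collection(query, refsets, universe,
                                     alpha=config.significance_alpha)

        enrichment_results = stage("enrichment")(_enrich)
        counts["enrichment_sets"] = len(enrichment_results)
        write_results(
            enrichment_results, outdir / "enrichment.tsv",
            parameters={**params, "universe_policy": config.universe_policy,
                        "alpha": config.significance_alpha},
            seed=config.seed,
        )
        tables["enrichment"] = outdir / "enrichment.tsv"

    # -- TF-target enrichment ----------------------------------------------
    tf_results: list = []
    if config.tf_targets:
        def _tf():
            targets = read_trrust(config.tf_targets)
            universe = table_a.genes
            return tf_enrichment(sig_a.up & universe, sig_a.down & universe,
                                 targets, universe,
                                 alpha=config.significance_alpha)

        tf_results = stage("tf_enrichment")(_tf)
        rows = [
            {"tf": r.tf_name, "display_score": r.display_score,
             "up_observed": r.up_result.observed, "up_adj_p": r.up_result.adj_p,
             "down_observed": r.down_result.observed,
             "down_adj_p": r.down_result.adj_p}
            for r in tf_results
        ]
        write_results(pd.DataFrame(rows), outdir / "tf_enrichment.tsv",
                      parameters=params, seed=config.seed)
        tables["tf_enrichment"] = outdir / "tf_enrichment.tsv"

    # -- single-cell marker projection --------------------------------------
    projections: list = []
    if config.markers_gmt:
        def _project():
            markers = read_gmt(config.markers_gmt)
            return project_cell_states(table_a, markers)

        projections = stage("projection")(_project)
        write_results(projections, outdir / "cell_state_projection.tsv",
                      parameters=params, seed=config.seed)
        tables["cell_state_projection"] = outdir / "cell_state_projection.tsv"

    # -- provenance ---------------------------------------------------------
    (outdir / "resolved_config.txt").write_text(config.resolved_text(),
                                                encoding="utf-8")
    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "tables": {k: str(v.name) for k, v in sorted(tables.items())},
        "policies": {
            "ortholog_policy": config.ortholog_policy,
            "universe_policy": config.universe_policy,
            "fdr_max": config.fdr_max,
            "lfc_min": config.lfc_min,
            "top_k": config.top_k,
            "significance_alpha": config.significance_alpha,
        },
    }
    (outdir / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return RunReport(
        outdir=outdir, counts=counts, tables=tables,
        config_hash=config.config_hash(),
        signature_a=sig_a, signature_b=sig_b, paired=paired,
        correlation=correlation, curves=curves,
        enrichment=enrichment_results, tf_results=tf_results,
        projections=projections, overlaps=overlaps,
    )
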
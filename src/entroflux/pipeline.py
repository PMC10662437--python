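"""Configuration-driven orchestration: simulate -> build -> solve -> diff ->
crossmatch, with a reproducible run manifest.

Every study parameter is surfaced in one config mapping (YAML on disk):
the 2-TPM activity threshold, the ion-exchange closing list, the
experimental-over-curation priority, the eFBA scale, the top-k cutoff and
the clustering settings.  Each cell line yields one context-specific model
and one eFBA solution; the cohort stages then compute the shared-reaction
fold-change table, rankings, clusterings, subsystem tallies, cofactor views
and the biomarker cross-match.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarker_match, context_builder, flux_analysis
from .context_builder import (
    CurationSpec,
    CultureMeasurement,
    ExtractionConfig,
    classify_genes,
    apply_exchange_constraints,
    compute_uptake_bound,
    extract_context_model,
    resolve_conflicts,
    OmicsEvidence,
)
from .efba_solver import problem_from_model, solve_efba
from .model_core import MetabolicModel, read_model, write_model

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline",
           "simulate_command", "build_context_models", "solve_cohort",
           "differential_analysis", "crossmatch_stage"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    model_path: str
    expression_path: str
    media_path: str
    protein_path: str
    catalogue_path: str
    outdir: str
    conditions: dict                      # sample/line -> disease|control
    curation_path: str | None = None
    seed: int = 0
    tpm_threshold: float = 2.0
    close_ion_exchange: bool = True
    ion_ids: tuple = context_builder.DEFAULT_ION_IDS
    priority: tuple = ("experimental", "curation")
    protein_fraction: float = context_builder.DEFAULT_PROTEIN_FRACTION
    fix_media_uptakes: bool = True        # eFBA driven by measured rates
    efba_scale: float = 1.0
    top_k: int = 50
    aggregate: str = "max"
    cluster_metric: str = "euclidean"
    cluster_method: str = "ward"
    # mask control means below the eFBA convergence noise (~1e-8), not just
    # exact zeros: fold changes on bound-pinned zero fluxes are numerical junk
    fc_eps: float = 1e-6
    cofactors: tuple = ("nad", "nadh")
    cofactor_compartments: tuple = ("m", "c")
    cofactor_subsystem: str = "NAD metabolism"
    stages: tuple = ("build", "solve", "diff", "crossmatch")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            paths = raw["paths"]
            kwargs = {
                "model_path": paths["model"],
                "expression_path": paths["expression"],
                "media_path": paths["media"],
                "protein_path": paths["protein"],
                "catalogue_path": paths.get("catalogue", ""),
                "curation_path": paths.get("curation"),
                "outdir": paths["outdir"],
                "conditions": dict(raw["cohort"]),
            }
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc}") from exc
        for section in ("extraction", "efba", "analysis"):
            for key, value in (raw.get(section) or {}).items():
                if key in ("ion_ids", "priority", "cofactors",
                           "cofactor_compartments", "stages"):
                    value = tuple(value)
                kwargs[key] = value
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        return cls(**kwargs)

    def validate(self) -> None:
        labels = set(self.conditions.values())
        if not labels <= {"disease", "control"}:
            raise ConfigError(f"conditions must be disease/control, got {labels}")
        if "control" not in labels:
            raise ConfigError("cohort needs at least one control line")
        required = {
            "build": [self.model_path, self.expression_path, self.media_path,
                      self.protein_path],
            "crossmatch": [self.catalogue_path],
        }
        for stage, paths in required.items():
            if stage not in self.stages:
                continue
            for p in paths:
                if not p or not Path(p).exists():
                    raise ConfigError(
                        f"stage {stage!r} requires existing path {p!r}"
                    )
        if self.curation_path and not Path(self.curation_path).exists():
            raise ConfigError(f"curation path {self.curation_path!r} does not exist")


def _read_curation(path) -> CurationSpec:
    if not path:
        return CurationSpec()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return CurationSpec(
        active_reactions=set(raw.get("active_reactions", [])),
        inactive_reactions=set(raw.get("inactive_reactions", [])),
        active_genes=set(raw.get("active_genes", [])),
        inactive_genes=set(raw.get("inactive_genes", [])),
        fixed_rates=dict(raw.get("fixed_rates", {})),
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def compute_line_uptakes(media: pd.DataFrame, protein_mass: float,
                         protein_fraction: float) -> dict:
    """Media table + one line's protein mass -> uptake magnitudes by base id."""
    uptakes = {}
    for row in media.itertuples():
        m = CultureMeasurement(
            metabolite=str(row.metabolite),
            concentration=float(row.concentration_umol_per_l),
            media_volume=float(row.media_volume_l),
            interval=float(row.interval_hr),
            protein_mass=float(protein_mass),
            protein_fraction=protein_fraction,
        )
        uptakes[m.metabolite] = compute_uptake_bound(m)
    return uptakes


def build_context_models(model: MetabolicModel, expression: pd.DataFrame,
                         media: pd.DataFrame, protein: dict,
                         curation: CurationSpec, config: RunConfig
                         ) -> dict:
    """One context-specific model per cell line.

    Returns {line: {"model", "report", "uptakes", "overrides"}}.
    """
    extraction_cfg = ExtractionConfig(
        tpm_threshold=config.tpm_threshold,
        close_ion_exchange=config.close_ion_exchange,
        ion_ids=tuple(config.ion_ids),
        priority=tuple(config.priority),
    )
    out = {}
    for line in config.conditions:
        if line not in expression.columns:
            raise StageError(f"build: no expression column for line {line!r}")
        if line not in protein:
            raise StageError(f"build: no protein mass for line {line!r}")
        tpm = expression[[line]]
        active, inactive = classify_genes(tpm, config.tpm_threshold)
        evidence = OmicsEvidence(tpm=tpm[line].to_dict(),
                                 active_genes=active, inactive_genes=inactive)
        merged, overrides = resolve_conflicts(evidence, curation,
                                              tuple(config.priority))
        uptakes = compute_line_uptakes(media, protein[line],
                                       config.protein_fraction)
        constrained, media_warnings = apply_exchange_constraints(
            model, uptakes, extraction_cfg
        )
        context, report = extract_context_model(constrained, merged,
                                                extraction_cfg)
        context.name = line
        report["media_warnings"] = media_warnings
        out[line] = {"model": context, "report": report,
                     "uptakes": uptakes, "overrides": overrides}
    return out


def solve_cohort(contexts: dict, config: RunConfig) -> dict:
    """One eFBA solution per context model.

    When ``fix_media_uptakes`` is set, measured media exchange rates are
    imposed as exact rates — the driving constraints without which the
    entropic optimum is the trivial all-zero net flux.
    """
    solutions = {}
    for line, ctx in contexts.items():
        model = ctx["model"]
        fixed = {}
        if config.fix_media_uptakes:
            met_index = {m.id: m for m in model.metabolites}
            for rxn in model.exchange_reactions():
                base = met_index[next(iter(rxn.stoich))].base_id
                if base in ctx["uptakes"]:
                    fixed[rxn.id] = -abs(ctx["uptakes"][base])
        problem = problem_from_model(model, fixed=fixed, scale=config.efba_scale)
        solutions[line] = solve_efba(problem)
    return solutions


def differential_analysis(contexts: dict, solutions: dict,
                          base_model: MetabolicModel, config: RunConfig) -> dict:
    """Shared-reaction fold changes, top-k, clustering, tallies and cofactor
    views."""
    shared = flux_analysis.shared_reactions([c["model"] for c in contexts.values()])
    table = flux_analysis.flux_table(
        {line: sol.net_flux() for line, sol in solutions.items()},
        config.conditions, reactions=shared,
    )
    control_ids = [l for l, c in config.conditions.items() if c == "control"]
    fc = flux_analysis.fold_changes(table, control_ids, eps=config.fc_eps)
    topk = flux_analysis.top_k_reactions(fc, k=config.top_k,
                                         aggregate=config.aggregate)
    clustering = flux_analysis.cluster_models_and_reactions(
        fc.values.loc[topk.index], metric=config.cluster_metric,
        method=config.cluster_method,
    )
    tally = flux_analysis.subsystem_tally(list(topk.index), base_model)
    cofactor_views = {}
    for comp in config.cofactor_compartments:
        rids = flux_analysis.select_cofactor_reactions(
            base_model, cofactors=tuple(config.cofactors), compartment=comp
        )
        cofactor_views[f"cofactor_{comp}"] = sorted(rids & shared)
    cofactor_views["subsystem"] = sorted(
        flux_analysis.select_cofactor_reactions(
            base_model, subsystem=config.cofactor_subsystem
        ) & shared
    )
    return {
        "shared": shared,
        "flux_table": table,
        "fold_changes": fc,
        "top_k": topk,
        "clustering": clustering,
        "tally": tally,
        "cofactor_views": cofactor_views,
    }


def crossmatch_stage(base_model: MetabolicModel, top_reactions,
                     catalogue) -> biomarker_match.CrossmatchResult:
    mets = biomarker_match.metabolites_of_reactions(base_model, top_reactions)
    return biomarker_match.crossmatch(mets, catalogue)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages end to end; returns a summary dict and
    writes all artifacts plus a manifest under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "warnings": [],
        "outputs": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    summary: dict = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(outdir, manifest, complete=False)
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "status": "ok",
            "wall_seconds": round(time.perf_counter() - t0, 3),
        }

    state: dict = {}

    def stage_build():
        model = read_model(config.model_path)
        expression = pd.read_csv(config.expression_path, sep="\t", index_col=0)
        media = pd.read_csv(config.media_path, sep="\t")
        with open(config.protein_path) as fh:
            protein = json.load(fh)
        curation = _read_curation(config.curation_path)
        contexts = build_context_models(model, expression, media, protein,
                                        curation, config)
        state["base_model"] = model
        state["contexts"] = contexts
        models_dir = outdir / "models"
        models_dir.mkdir(exist_ok=True)
        for line, ctx in contexts.items():
            write_model(ctx["model"], models_dir / f"{line}.json")
            manifest["warnings"].extend(
                f"{line}: {w}" for w in ctx["report"]["media_warnings"]
            )
            manifest["warnings"].extend(
                f"{line}: unsatisfiable active gene {g}"
                for g in ctx["report"]["unsatisfiable_active_genes"]
            )
            manifest["warnings"].extend(
                f"{line}: override {o}" for o in ctx["overrides"]
            )
        with open(outdir / "extraction_reports.json", "w") as fh:
            json.dump({l: c["report"] for l, c in contexts.items()}, fh,
                      indent=1, sort_keys=True)
        summary["n_models"] = len(contexts)

    def stage_solve():
        solutions = solve_cohort(state["contexts"], config)
        state["solutions"] = solutions
        sol_dir = outdir / "solutions"
        sol_dir.mkdir(exist_ok=True)
        for line, sol in solutions.items():
            sol.to_frame().to_csv(sol_dir / f"{line}.tsv", sep="\t")
            with open(sol_dir / f"{line}.json", "w") as fh:
                json.dump({"objective": sol.objective, "residual": sol.residual,
                           "status": sol.status, "scale": sol.scale}, fh, indent=1)
        summary["n_solutions"] = len(solutions)

    def stage_diff():
        diff = differential_analysis(state["contexts"], state["solutions"],
                                     state["base_model"], config)
        state["diff"] = diff
        diff["fold_changes"].values.to_csv(outdir / "fold_changes.tsv", sep="\t")
        topk = diff["top_k"].copy()
        subsys = {r.id: r.subsystem for r in state["base_model"].reactions}
        topk["subsystem"] = [subsys.get(rid, "") for rid in topk.index]
        topk.to_csv(outdir / "top_reactions.tsv", sep="\t")
        for which in ("row", "col"):
            newick = flux_analysis.linkage_to_newick(
                diff["clustering"][f"{which}_linkage"],
                diff["clustering"][f"{which}_labels"],
            )
            (outdir / f"dendrogram_{which}s.nwk").write_text(newick + "\n")
        with open(outdir / "subsystem_tally.json", "w") as fh:
            json.dump(diff["tally"], fh, indent=1, sort_keys=True)
        with open(outdir / "cofactor_views.json", "w") as fh:
            json.dump(diff["cofactor_views"], fh, indent=1, sort_keys=True)
        n_masked = int(diff["fold_changes"].mask.any(axis=1).sum())
        if n_masked:
            manifest["warnings"].append(
                f"diff: {n_masked} reactions masked (near-zero control mean)"
            )
        summary["n_shared_reactions"] = len(diff["shared"])
        summary["n_top"] = len(diff["top_k"])

    def stage_crossmatch():
        catalogue = biomarker_match.read_catalogue(config.catalogue_path)
        result = crossmatch_stage(state["base_model"],
                                  list(state["diff"]["top_k"].index), catalogue)
        state["crossmatch"] = result
        with open(outdir / "crossmatch.json", "w") as fh:
            json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
        summary["n_matched_metabolites"] = len(result.matched)
        summary["replicated_proportion"] = result.proportion

    stage_funcs = {
        "build": stage_build,
        "solve": stage_solve,
        "diff": stage_diff,
        "crossmatch": stage_crossmatch,
    }
    for name in config.stages:
        if name not in stage_funcs:
            raise ConfigError(f"unknown stage {name!r}")
        run_stage(name, stage_funcs[name])

    _write_manifest(outdir, manifest, complete=True)
    summary["outdir"] = str(outdir)
    summary["state"] = state
    return summary


def _write_manifest(outdir: Path, manifest: dict, complete: bool) -> None:
    manifest["complete"] = complete
    checksums = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            checksums[str(path.relative_to(outdir))] = _sha256(path)
    manifest["outputs"] = checksums
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def simulate_command(outdir, scenario=None) -> dict:
    """Generate the synthetic input bundle (wraps the synthetic-data module)."""
    from .synthetic_data import SyntheticScenario, write_bundle

    sc = scenario or SyntheticScenario()
    sc.validate()
    return write_bundle(outdir, sc)


def default_config_for_bundle(paths: dict, outdir, scenario=None) -> RunConfig:
    """RunConfig wired to a simulated bundle's file layout."""
    from .synthetic_data import SyntheticScenario

    sc = scenario or SyntheticScenario()
    return RunConfig(
        model_path=paths["model"],
        expression_path=paths["expression"],
        media_path=paths["media"],
        protein_path=paths["protein"],
        catalogue_path=paths["catalogue"],
        outdir=str(outdir),
        conditions=sc.condition_map(),
        seed=sc.seed,
        protein_fraction=sc.protein_fraction,
    )
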
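"""Context-specific model extraction: omics thresholding, media-derived
uptake bounds, evidence merging and flux-consistency pruning.

The stage turns a generic network plus per-line evidence into a cell-line
model: genes are called active at a TPM threshold (default 2, inclusive),
exchange bounds are derived from spent-media measurements via

    uptake = concentration (umol/L) * media volume (L)
             / (cell dry weight (gDW) * interval (hr)),

with cell dry weight computed from total protein mass and the neuronal
protein fraction (default 55.93% of dry mass), and the reaction set is
pruned to a flux-consistent core that keeps every active-gene-supported
reaction it can (a FASTCC-style consistency extraction: designated-active
reactions are the core, reactions with inactive GPRs are dropped unless
needed to keep the core unblocked, and every remaining blocked reaction is
removed).  Experimental evidence outranks literature curation by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import MetabolicModel, evaluate_gpr, parse_gpr
from .efba_solver import InfeasibleModelError, flux_variability

__all__ = [
    "OmicsEvidence",
    "CultureMeasurement",
    "CurationSpec",
    "ExtractionConfig",
    "ExtractionError",
    "classify_genes",
    "cell_dry_weight",
    "compute_uptake_bound",
    "apply_exchange_constraints",
    "resolve_conflicts",
    "find_blocked_reactions",
    "extract_context_model",
]

DEFAULT_TPM_THRESHOLD = 2.0
DEFAULT_PROTEIN_FRACTION = 0.5593
DEFAULT_ION_IDS = ("h", "h2o", "pi", "na1", "k", "cl", "ca2", "fe2", "mg2")
FVA_ZERO_TOL = 1e-9


class ExtractionError(RuntimeError):
    pass


@dataclass
class OmicsEvidence:
    """Per-line transcriptomic evidence: TPM values and the derived calls."""

    tpm: dict                   # gene -> mean TPM for this line
    active_genes: set
    inactive_genes: set

    def __post_init__(self):
        if self.active_genes & self.inactive_genes:
            raise ValueError("a gene cannot be both active and inactive")


@dataclass
class CultureMeasurement:
    """One media metabolite measurement for one cell line (Eq.-style units)."""

    metabolite: str             # base id, no compartment suffix
    concentration: float        # umol/L
    media_volume: float         # L
    interval: float             # hr
    protein_mass: float         # g per culture
    protein_fraction: float = DEFAULT_PROTEIN_FRACTION

    def __post_init__(self):
        for name in ("concentration", "media_volume", "protein_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.interval <= 0:
            raise ValueError("sampling interval must be positive")


@dataclass
class CurationSpec:
    """Literature-designated activity calls and optional fixed rates."""

    active_reactions: set = field(default_factory=set)
    inactive_reactions: set = field(default_factory=set)
    active_genes: set = field(default_factory=set)
    inactive_genes: set = field(default_factory=set)
    fixed_rates: dict = field(default_factory=dict)  # reaction id -> rate

    def __post_init__(self):
        if self.active_reactions & self.inactive_reactions:
            raise ValueError("reaction designated both active and inactive")
        if self.active_genes & self.inactive_genes:
            raise ValueError("gene designated both active and inactive")


@dataclass
class ExtractionConfig:
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD
    close_ion_exchange: bool = True
    ion_ids: tuple = DEFAULT_ION_IDS
    priority: tuple = ("experimental", "curation")
    empty_gpr_active: bool = True
    strict_uptakes: bool = False  # fix exchange rates instead of bounding them

    def __post_init__(self):
        if self.tpm_threshold <= 0:
            raise ValueError("TPM threshold must be positive")
        if set(self.priority) != {"experimental", "curation"}:
            raise ValueError("priority must order 'experimental' and 'curation'")


# ---------------------------------------------------------------------------
# Gene classification and Eq.-1 style uptake bounds
# ---------------------------------------------------------------------------

def classify_genes(expression, threshold: float = DEFAULT_TPM_THRESHOLD
                   ) -> tuple[set, set]:
    """Split genes into (active, inactive) at a TPM threshold.

    ``expression`` is a gene -> TPM mapping or a gene x sample DataFrame, in
    which case the mean across the line's samples is used.  The comparison
    is inclusive: a gene exactly at the threshold is active (genes *below*
    the threshold are the inactive ones).
    """
    if isinstance(expression, pd.DataFrame):
        if expression.empty:
            raise ValueError("empty expression table")
        values = expression.mean(axis=1)
    else:
        if not expression:
            raise ValueError("empty expression table")
        values = pd.Series(expression, dtype=float)
    if (values < 0).any():
        raise ValueError("TPM values must be non-negative")
    active = set(values.index[values >= threshold])
    inactive = set(values.index) - active
    return active, inactive


def cell_dry_weight(protein_mass: float,
                    protein_fraction: float = DEFAULT_PROTEIN_FRACTION) -> float:
    """Dry weight (gDW) from total protein mass via the protein fraction of
    dry mass."""
    if not 0 < protein_fraction <= 1:
        raise ValueError("protein fraction must be in (0, 1]")
    if protein_mass < 0:
        raise ValueError("protein mass must be non-negative")
    return protein_mass / protein_fraction


def compute_uptake_bound(measurement: CultureMeasurement,
                         literal_protein_term: bool = False) -> float:
    """Uptake magnitude (umol/gDW/hr) from one media measurement.

    Default mode: concentration * volume / (dry weight * interval), with dry
    weight derived from protein mass.  ``literal_protein_term`` additionally
    divides by the protein mass, for the reading in which dry weight and
    protein concentration are independent denominator terms.
    """
    dw = cell_dry_weight(measurement.protein_mass, measurement.protein_fraction)
    if dw == 0:
        raise ValueError("zero cell dry weight")
    uptake = (measurement.concentration * measurement.media_volume
              / (dw * measurement.interval))
    if literal_protein_term:
        if measurement.protein_mass == 0:
            raise ValueError("zero protein mass in literal mode")
        uptake /= measurement.protein_mass
    return uptake


def apply_exchange_constraints(model: MetabolicModel, uptakes: dict,
                               config: ExtractionConfig | None = None
                               ) -> tuple[MetabolicModel, list]:
    """Constrain exchange bounds from media uptakes (keyed by base id).

    Media metabolites: exchange lower bound set to -uptake (uptake =
    negative flux under the export-positive convention); in strict mode the
    rate is fixed (lb = ub = -uptake).  Exchanges of metabolites absent from
    the media are closed to [0, ub] (no uptake, export allowed).  Ion
    exchanges in the configured list are closed entirely.  Returns the
    constrained copy plus a report of warnings.
    """
    cfg = config or ExtractionConfig()
    out = model.copy()
    report = []
    met_index = {m.id: m for m in out.metabolites}
    base_by_exchange = {}
    for rxn in out.exchange_reactions():
        met_id = next(iter(rxn.stoich))
        base_by_exchange[rxn.id] = met_index[met_id].base_id
    covered = set()
    for rxn in out.exchange_reactions():
        base = base_by_exchange[rxn.id]
        if cfg.close_ion_exchange and base in cfg.ion_ids:
            rxn.lower_bound = rxn.upper_bound = 0.0
            continue
        if base in uptakes:
            covered.add(base)
            u = abs(float(uptakes[base]))
            rxn.lower_bound = -u
            if cfg.strict_uptakes:
                rxn.upper_bound = -u
        else:
            rxn.lower_bound = 0.0
    for base in uptakes:
        if base not in covered:
            msg = f"media metabolite {base!r} has no exchange reaction"
            report.append(msg)
            warnings.warn(msg)
    return out, report


# ---------------------------------------------------------------------------
# Evidence merging
# ---------------------------------------------------------------------------

def resolve_conflicts(omics: OmicsEvidence, curation: CurationSpec | None,
                      priority: tuple = ("experimental", "curation")
                      ) -> tuple[dict, list]:
    """Merge omics and curation activity designations.

    Returns (merged designations, override log).  Where the two sources
    disagree on a gene or reaction, the higher-priority source wins and the
    override is logged.
    """
    cur = curation or CurationSpec()
    experimental_first = priority.index("experimental") < priority.index("curation")
    log = []

    active_genes = set(omics.active_genes)
    inactive_genes = set(omics.inactive_genes)
    for g in cur.active_genes:
        if g in inactive_genes:
            if experimental_first:
                log.append(f"gene {g}: curation-active overridden by omics-inactive")
            else:
                inactive_genes.discard(g)
                active_genes.add(g)
                log.append(f"gene {g}: omics-inactive overridden by curation-active")
        else:
            active_genes.add(g)
    for g in cur.inactive_genes:
        if g in active_genes:
            if experimental_first:
                log.append(f"gene {g}: curation-inactive overridden by omics-active")
            else:
                active_genes.discard(g)
                inactive_genes.add(g)
                log.append(f"gene {g}: omics-active overridden by curation-inactive")
        else:
            inactive_genes.add(g)

    merged = {
        "active_genes": active_genes,
        "inactive_genes": inactive_genes,
        "active_reactions": set(cur.active_reactions),
        "inactive_reactions": set(cur.inactive_reactions),
        "fixed_rates": dict(cur.fixed_rates),
    }
    return merged, log


# ---------------------------------------------------------------------------
# Flux consistency
# ---------------------------------------------------------------------------

def find_blocked_reactions(model: MetabolicModel, tol: float = FVA_ZERO_TOL) -> set:
    """Reactions whose flux-variability minimum and maximum are both zero."""
    fva = flux_variability(model, zero_tol=tol)
    return {rid for rid, (lo, hi) in fva.items() if lo == 0.0 and hi == 0.0}


def _consistent_subset(model: MetabolicModel, keep_ids: set) -> set:
    """Iteratively strip blocked reactions from the subnetwork ``keep_ids``."""
    current = set(keep_ids)
    while True:
        sub = model.subset(current)
        blocked = find_blocked_reactions(sub)
        if not blocked:
            return current
        current -= blocked


def extract_context_model(model: MetabolicModel, merged: dict,
                          config: ExtractionConfig | None = None
                          ) -> tuple[MetabolicModel, dict]:
    """Extract the flux-consistent context-specific model.

    Contract: (a) every designated-active, non-blocked reaction is kept;
    (b) each active gene keeps at least one reaction whenever feasible,
    with infeasible genes listed in the report; (c) reactions whose GPR
    evaluates inactive are excluded unless required to keep the core
    flux-consistent (each retention logged); (d) the output model passes
    ``find_blocked_reactions == {}``.
    """
    cfg = config or ExtractionConfig()
    active_genes = set(merged.get("active_genes", set()))
    core = set(merged.get("active_reactions", set()))
    forced_out = set(merged.get("inactive_reactions", set()))
    all_ids = set(model.reaction_ids())

    for rid in core | forced_out:
        if rid not in all_ids:
            raise ExtractionError(f"designation references unknown reaction {rid!r}")

    # GPR verdict per reaction under the merged gene calls
    gpr_active: dict[str, bool] = {}
    for rxn in model.reactions:
        tree = parse_gpr(rxn.gpr)
        if tree is None:
            gpr_active[rxn.id] = cfg.empty_gpr_active
        else:
            gpr_active[rxn.id] = evaluate_gpr(tree, active_genes)

    core |= {rid for rid in all_ids
             if gpr_active[rid] and rid not in forced_out}
    removed_inactive = {rid for rid in all_ids
                        if not gpr_active[rid] and rid not in core}
    removed_inactive |= forced_out
    candidate = all_ids - removed_inactive

    # full-model feasibility of the core
    blocked_full = find_blocked_reactions(model)
    dead_core = sorted((core & set(merged.get("active_reactions", set())))
                       & blocked_full)
    if dead_core:
        raise ExtractionError(
            f"designated-active reactions are blocked even in the full model: {dead_core}"
        )
    core -= blocked_full  # unreachable reactions cannot be retained

    # greedy add-back of GPR-inactive reactions while core reactions are lost
    included_inactive: set = set()
    consistent = _consistent_subset(model, candidate)
    while core - consistent:
        best = None
        for rid in sorted(removed_inactive - included_inactive):
            trial = _consistent_subset(model,
                                       candidate | included_inactive | {rid})
            if len(core & trial) > len(core & consistent):
                best = (rid, trial)
                break
        if best is None:
            # no single reaction rescues the core; try the full complement
            # (covers multi-reaction dependencies) before giving up
            trial = _consistent_subset(model, all_ids - forced_out)
            if core - trial:
                raise ExtractionError(
                    "designated-active reactions cannot be made flux-consistent: "
                    f"{sorted(core - trial)}"
                )
            included_inactive |= removed_inactive - forced_out
            consistent = trial
            continue
        rid, trial = best
        included_inactive.add(rid)
        consistent = trial

    # active-gene coverage: each active gene needs >= 1 surviving reaction
    unsatisfiable_genes: list[str] = []
    gene_rxns: dict[str, list] = {}
    for rxn in model.reactions:
        for g in rxn.genes:
            gene_rxns.setdefault(g, []).append(rxn.id)
    for g in sorted(active_genes & set(gene_rxns)):
        rids = gene_rxns[g]
        if any(rid in consistent for rid in rids):
            continue
        recovered = False
        for rid in sorted(set(rids) - blocked_full):
            trial = _consistent_subset(model, consistent | {rid})
            if rid in trial and not (core - trial):
                consistent = trial
                recovered = True
                break
        if not recovered:
            unsatisfiable_genes.append(g)

    out = model.subset(consistent, name=model.name)
    leftover = find_blocked_reactions(out)
    if leftover:  # pragma: no cover - guarded by _consistent_subset
        raise ExtractionError(f"extraction left blocked reactions: {sorted(leftover)}")

    report = {
        "kept_reactions": sorted(consistent),
        "removed_reactions": sorted(all_ids - consistent),
        "removed_inactive_gpr": sorted(removed_inactive - consistent),
        "retained_inactive_gpr": sorted(consistent & removed_inactive),
        "unsatisfiable_active_genes": unsatisfiable_genes,
        "blocked_in_full_model": sorted(blocked_full),
    }
    return out, report
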
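"""Synthetic study inputs: toy stoichiometric networks, cohort expression
tables, culture-media measurements and a clinical biomarker catalogue, all
with recorded ground truth.

The generators emulate the study design the pipeline targets: a cohort of
three disease and three control neural-precursor lines, each line yielding
one expression profile, cultured in identical media.  Disease lines carry a
condition-dependent downregulation (default log2FC = -2) of every gene of
one target pathway; gene baselines are laid out so that only the
"vulnerable" part of that pathway falls below the 2-TPM activity threshold
in disease lines, while a designated dead-end branch is inactive in every
line.  Flux differences between the extracted cohort models therefore have
a known cause against which recovery is tested.

The default toy network has 79 reactions over three compartments (e, c, m):
a glycolysis chain, a TCA cycle with an anaplerotic pyruvate carboxylase,
an NAD+/NADH pair coupled to redox reactions in both cytosol and
mitochondria with an electron shuttle between them, NAD synthesis and
degradation, amino-acid branches (serine/glycine, glutamate/glutamine,
tyrosine/dopamine/norepinephrine), a cholesterol chain, a dead-end folate
branch (the ground-truth blocked reactions) and a lipid-synthesis subsystem
built as parallel two-step routes from acetyl-CoA — the structure that lets
a partial knockout re-route flux through the surviving routes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model_core import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = [
    "SyntheticScenario",
    "GroundTruth",
    "make_fixture_chain",
    "make_fixture_cycle",
    "make_toy_network",
    "simulate_expression",
    "simulate_media_measurements",
    "make_biomarker_catalogue",
    "TABLE1_COUNTS",
]

LIPID_SUBSYSTEM = "Lipid metabolism"
DEAD_SUBSYSTEM = "Folate metabolism"


@dataclass
class SyntheticScenario:
    """Full generative specification of one synthetic study."""

    seed: int = 0
    n_disease: int = 3
    n_control: int = 3
    target_subsystem: str = LIPID_SUBSYSTEM
    log2_fold_change: float = -2.0
    noise_sd: float = 0.4
    n_lipid_routes: int = 10
    n_vulnerable_routes: int = 2
    cofactor_coupling: bool = True
    include_dead_branch: bool = True
    # culture-media defaults: identical media for every line
    media_concentrations: dict = field(
        default_factory=lambda: {"glc": 240.0, "ncam": 24.0, "tyr_L": 24.0}
    )
    media_volume_l: float = 0.002
    interval_hr: float = 48.0
    protein_mass_g: float = 5.593e-4
    protein_mass_cv: float = 0.01  # line-to-line lognormal variation
    protein_fraction: float = 0.5593

    def sample_names(self) -> list:
        return [f"IPD{i + 1}" for i in range(self.n_disease)] + [
            f"CTRL{i + 1}" for i in range(self.n_control)
        ]

    def condition_map(self) -> dict:
        return {s: ("disease" if s.startswith("IPD") else "control")
                for s in self.sample_names()}

    def validate(self) -> None:
        if self.n_disease < 1 or self.n_control < 1:
            raise ValueError("cohort needs at least one disease and one control line")
        if self.n_lipid_routes < 3 or not (
            0 <= self.n_vulnerable_routes < self.n_lipid_routes
        ):
            raise ValueError("invalid lipid route specification")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class GroundTruth:
    """What the generators actually planted, for recovery tests."""

    dysregulated_subsystem: str
    gene_log2fc: dict            # gene id -> true disease log2FC
    blocked_reactions: list      # dead-end branch, blocked in every model
    vulnerable_reactions: list   # expected to drop out of disease models
    inactive_genes_by_design: list
    gene_baseline_log2tpm: dict
    cofactor_reactions_m: list   # reactions touching nad[m]/nadh[m]
    cofactor_reactions_c: list


# ---------------------------------------------------------------------------
# Analytic fixtures
# ---------------------------------------------------------------------------

def make_fixture_chain(n_internal: int, uptake: float = 0.0) -> MetabolicModel:
    """Linear pathway EX_A (uptake fixed) -> n_internal conversions -> EX_B.

    All reactions reversible with bounds +/-1000 except the uptake exchange,
    which is fixed at net -uptake (export-positive convention).  The network
    has a single flux degree of freedom once the uptake is fixed, so the
    entropic optimum is known in closed form.
    """
    if n_internal < 1:
        raise ValueError("need at least one internal conversion")
    met_ids = ["A[c]"] + [f"M{i}[c]" for i in range(1, n_internal)] + ["B[c]"]
    mets = [Metabolite(mid) for mid in met_ids]
    rxns = [Reaction("EX_A", {"A[c]": -1.0}, -uptake, -uptake,
                     subsystem="Exchange/demand reactions")]
    for i in range(n_internal):
        rxns.append(
            Reaction(f"R{i + 1}", {met_ids[i]: -1.0, met_ids[i + 1]: 1.0},
                     -DEFAULT_BOUND, DEFAULT_BOUND, subsystem="Chain")
        )
    rxns.append(Reaction("EX_B", {f"B[c]": -1.0}, -DEFAULT_BOUND, DEFAULT_BOUND,
                         subsystem="Exchange/demand reactions"))
    return MetabolicModel("chain", mets, rxns)


def make_fixture_cycle() -> MetabolicModel:
    """Closed two-reaction cycle A->B->A with no exchanges.

    The only steady-state fluxes are equal-magnitude cycle fluxes; FBA can
    drive the cycle to its bound while the entropic optimum is zero net flux
    — the canonical thermodynamically infeasible loop."""
    mets = [Metabolite("A[c]"), Metabolite("B[c]")]
    rxns = [
        Reaction("r_ab", {"A[c]": -1.0, "B[c]": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND,
                 subsystem="Cycle"),
        Reaction("r_ba", {"B[c]": -1.0, "A[c]": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND,
                 subsystem="Cycle"),
    ]
    return MetabolicModel("cycle", mets, rxns)


# ---------------------------------------------------------------------------
# Toy cohort network
# ---------------------------------------------------------------------------

def _gene_for(rxn_id: str) -> str:
    return f"g_{rxn_id}"


def make_toy_network(scenario: SyntheticScenario | None = None
                     ) -> tuple[MetabolicModel, GroundTruth]:
    """Deterministic toy genome-scale stand-in network plus its ground truth.

    Construction is purely a function of the scenario's structural fields
    (routes, cofactor coupling, dead branch); the seed only enters the
    expression/media simulators.
    """
    sc = scenario or SyntheticScenario()
    sc.validate()

    mets: dict[str, Metabolite] = {}
    rxns: list[Reaction] = []

    def M(mid: str):
        if mid not in mets:
            mets[mid] = Metabolite(mid)
        return mid

    def add(rid, stoich, subsystem, lb=0.0, ub=DEFAULT_BOUND, gpr=None):
        for mid in stoich:
            M(mid)
        rule = _gene_for(rid) if gpr is None else gpr
        rxns.append(Reaction(rid, stoich, lb, ub, rule, subsystem))

    def add_exchange(base):
        mid = M(f"{base}[e]")
        rxns.append(Reaction(f"EX_{base}", {mid: -1.0}, -DEFAULT_BOUND,
                             DEFAULT_BOUND, "", "Exchange/demand reactions"))

    def add_transport(base, direction="in"):
        a, b = f"{base}[e]", f"{base}[c]"
        if direction == "out":
            a, b = b, a
        add(f"t_{base}", {M(a): -1.0, M(b): 1.0}, "Extracellular transport",
            lb=-DEFAULT_BOUND)

    # boundary species
    for base in ("glc", "ncam", "tyr_L", "na1"):
        add_exchange(base)
        add_transport(base, "in")
    for base in ("lac_L", "gly", "gln_L", "degw", "lip", "chol", "nrpphr"):
        add_exchange(base)
        add_transport(base, "out")

    nad_c, nadh_c = "nad[c]", "nadh[c]"
    nad_m, nadh_m = "nad[m]", "nadh[m]"

    # glycolysis
    gapd_stoich = {"g3p[c]": -1.0, "pg3[c]": 1.0}
    if sc.cofactor_coupling:
        gapd_stoich.update({M(nad_c): -1.0, M(nadh_c): 1.0})
    add("r_hex", {"glc[c]": -1.0, "g6p[c]": 1.0}, "Glycolysis")
    add("r_pgi", {"g6p[c]": -1.0, "f6p[c]": 1.0}, "Glycolysis")
    add("r_pfk", {"f6p[c]": -1.0, "fdp[c]": 1.0}, "Glycolysis")
    add("r_fba", {"fdp[c]": -1.0, "g3p[c]": 1.0}, "Glycolysis")
    add("r_gapd", gapd_stoich, "Glycolysis",
        gpr=f"{_gene_for('r_gapd')}_1 and {_gene_for('r_gapd')}_2")
    add("r_eno", {"pg3[c]": -1.0, "pep[c]": 1.0}, "Glycolysis")
    add("r_pyk", {"pep[c]": -1.0, "pyr[c]": 1.0}, "Glycolysis")

    # pyruvate metabolism
    ldh = {"pyr[c]": -1.0, "lac_L[c]": 1.0}
    pdh = {"pyr[m]": -1.0, "accoa[m]": 1.0}
    if sc.cofactor_coupling:
        ldh.update({M(nadh_c): -1.0, M(nad_c): 1.0})
        pdh.update({M(nad_m): -1.0, M(nadh_m): 1.0})
    add("r_ldh", ldh, "Pyruvate metabolism",
        gpr=f"{_gene_for('r_ldh')}_1 or {_gene_for('r_ldh')}_2")
    add("r_pdh", pdh, "Pyruvate metabolism")
    add("r_pc", {"pyr[m]": -1.0, "oaa[m]": 1.0}, "Pyruvate metabolism")

    # mitochondrial transport + redox shuttle
    add("t_pyr", {"pyr[c]": -1.0, "pyr[m]": 1.0}, "Mitochondrial transport",
        lb=-DEFAULT_BOUND)
    if sc.cofactor_coupling:
        add("t_redox_shuttle",
            {nadh_c: -1.0, nad_m: -1.0, nad_c: 1.0, nadh_m: 1.0},
            "Mitochondrial transport", lb=-DEFAULT_BOUND)
    add("t_cit", {"cit[m]": -1.0, "cit[c]": 1.0}, "Mitochondrial transport",
        lb=-DEFAULT_BOUND)
    add("t_glu_L", {"glu_L[m]": -1.0, "glu_L[c]": 1.0}, "Mitochondrial transport",
        lb=-DEFAULT_BOUND)

    # TCA cycle
    def redox_m(stoich):
        if sc.cofactor_coupling:
            stoich.update({M(nad_m): -1.0, M(nadh_m): 1.0})
        return stoich

    add("r_cs", {"accoa[m]": -1.0, "oaa[m]": -1.0, "cit[m]": 1.0}, "Citric acid cycle")
    add("r_acon", {"cit[m]": -1.0, "icit[m]": 1.0}, "Citric acid cycle")
    add("r_icdh", redox_m({"icit[m]": -1.0, "akg[m]": 1.0}), "Citric acid cycle")
    add("r_akgd", redox_m({"akg[m]": -1.0, "succ[m]": 1.0}), "Citric acid cycle",
        lb=-DEFAULT_BOUND)
    add("r_sdh", {"succ[m]": -1.0, "fum[m]": 1.0}, "Citric acid cycle",
        lb=-DEFAULT_BOUND)
    add("r_fum", {"fum[m]": -1.0, "mal_L[m]": 1.0}, "Citric acid cycle",
        lb=-DEFAULT_BOUND)
    add("r_mdh", redox_m({"mal_L[m]": -1.0, "oaa[m]": 1.0}), "Citric acid cycle",
        lb=-DEFAULT_BOUND)

    if sc.cofactor_coupling:
        add("r_etc", {nadh_m: -1.0, nad_m: 1.0}, "Oxidative phosphorylation")

    # amino acid branches
    add("r_gdh", {"akg[m]": -1.0, "glu_L[m]": 1.0}, "Glutamate metabolism")
    add("r_glns", {"glu_L[c]": -1.0, "gln_L[c]": 1.0}, "Glutamate metabolism")
    add("r_psp", {"pg3[c]": -1.0, "ser_L[c]": 1.0},
        "Glycine, serine and alanine metabolism")
    add("r_shmt", {"ser_L[c]": -1.0, "gly[c]": 1.0},
        "Glycine, serine and alanine metabolism")
    add("r_tyrh", {"tyr_L[c]": -1.0, "dopa[c]": 1.0}, "Tyrosine metabolism")
    add("r_dbh", {"dopa[c]": -1.0, "nrpphr[c]": 1.0}, "Tyrosine metabolism")

    # NAD synthesis / degradation
    if sc.cofactor_coupling:
        add("r_nadsyn", {"ncam[c]": -1.0, nad_c: 1.0}, "NAD metabolism")
        add("r_naddeg", {nad_c: -1.0, "degw[c]": 1.0}, "NAD metabolism")
    else:
        add("r_nadsyn", {"ncam[c]": -1.0, "nadp[c]": 1.0}, "NAD metabolism")
        add("r_naddeg", {"nadp[c]": -1.0, "degw[c]": 1.0}, "NAD metabolism")

    # dead-end folate branch (ground-truth blocked reactions)
    blocked = []
    if sc.include_dead_branch:
        add("r_fol1", {"f6p[c]": -1.0, "fol1[c]": 1.0}, DEAD_SUBSYSTEM)
        add("r_fol2", {"fol1[c]": -1.0, "fol2[c]": 1.0}, DEAD_SUBSYSTEM)
        blocked = ["r_fol1", "r_fol2"]

    # cholesterol chain
    add("r_hmgs", {"accoa[c]": -1.0, "hmg[c]": 1.0}, "Cholesterol metabolism")
    add("r_hmgr", {"hmg[c]": -1.0, "mev[c]": 1.0}, "Cholesterol metabolism")
    add("r_sqls", {"mev[c]": -1.0, "sql[c]": 1.0}, "Cholesterol metabolism")
    add("r_dhcr", {"sql[c]": -1.0, "chol[c]": 1.0}, "Cholesterol metabolism")

    # lipid synthesis: feeder + parallel two-step routes
    add("r_acl", {"cit[c]": -1.0, "accoa[c]": 1.0}, "Citrate shuttle")
    vulnerable = []
    for j in range(1, sc.n_lipid_routes + 1):
        a, b = f"r_lipa{j}", f"r_lipb{j}"
        add(a, {"accoa[c]": -1.0, f"lipI{j}[c]": 1.0}, LIPID_SUBSYSTEM)
        add(b, {f"lipI{j}[c]": -1.0, "lip[c]": 1.0}, LIPID_SUBSYSTEM)
        if j <= sc.n_vulnerable_routes:
            vulnerable += [a, b]

    model = MetabolicModel("toy", list(mets.values()), rxns)

    # --- gene baselines and true effects -----------------------------------
    rng = np.random.default_rng(10_000)  # layout RNG: fixed, topology-stable
    baselines: dict[str, float] = {}
    gene_fc: dict[str, float] = {}
    inactive_by_design: list[str] = []
    vulnerable_set = set(vulnerable)
    for rxn in model.reactions:
        genes = sorted(rxn.genes)
        if not genes:
            continue
        for g in genes:
            in_target = rxn.subsystem == sc.target_subsystem
            if rxn.id in blocked:
                base = -1.0  # well below the 2-TPM threshold in every line
                inactive_by_design.append(g)
            elif rxn.id in vulnerable_set:
                base = 2.2   # active in controls, lost under the disease shift
            else:
                base = float(rng.uniform(4.5, 6.0))
            baselines[g] = base
            gene_fc[g] = sc.log2_fold_change if in_target else 0.0

    cof_m = sorted(
        r.id for r in model.reactions
        if {"nad[m]", "nadh[m]"} & set(r.stoich)
    )
    cof_c = sorted(
        r.id for r in model.reactions
        if {"nad[c]", "nadh[c]"} & set(r.stoich)
    )
    truth = GroundTruth(
        dysregulated_subsystem=sc.target_subsystem,
        gene_log2fc=gene_fc,
        blocked_reactions=blocked,
        vulnerable_reactions=vulnerable,
        inactive_genes_by_design=sorted(inactive_by_design),
        gene_baseline_log2tpm=baselines,
        cofactor_reactions_m=cof_m,
        cofactor_reactions_c=cof_c,
    )
    return model, truth


# ---------------------------------------------------------------------------
# Expression and media simulators
# ---------------------------------------------------------------------------

def simulate_expression(model: MetabolicModel, scenario: SyntheticScenario,
                        truth: GroundTruth | None = None) -> pd.DataFrame:
    """Gene x sample TPM table for the cohort.

    log2-TPM for gene g in sample s is N(baseline_g + shift, noise_sd) with
    shift = the scenario log2FC iff s is a disease line and g belongs to the
    target subsystem; TPM = 2**log2TPM is therefore log-normal and positive.
    """
    if truth is None:
        _, truth = make_toy_network(scenario)
    if not any(fc != 0.0 for fc in truth.gene_log2fc.values()) and \
            scenario.log2_fold_change != 0.0:
        raise ValueError(
            f"target subsystem {scenario.target_subsystem!r} has no genes in the network"
        )
    rng = np.random.default_rng(scenario.seed)
    genes = sorted(truth.gene_baseline_log2tpm)
    samples = scenario.sample_names()
    conditions = scenario.condition_map()
    data = np.empty((len(genes), len(samples)))
    for i, g in enumerate(genes):
        base = truth.gene_baseline_log2tpm[g]
        for j, s in enumerate(samples):
            shift = truth.gene_log2fc[g] if conditions[s] == "disease" else 0.0
            noise = rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd > 0 else 0.0
            data[i, j] = 2.0 ** (base + shift + noise)
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=samples)


def simulate_media_measurements(model: MetabolicModel,
                                scenario: SyntheticScenario
                                ) -> tuple[pd.DataFrame, dict]:
    """Culture-media measurement table plus per-line protein mass (g).

    One row per media metabolite: concentration (umol/L), media volume (L)
    and sampling interval (hr).  Metabolites absent from the media get no
    row; their exchanges are closed downstream.  Protein mass varies
    log-normally between lines (measurement/line variability).
    """
    if not any(r.is_exchange for r in model.reactions):
        raise ValueError("model has no exchange reactions")
    rng = np.random.default_rng(scenario.seed + 1)
    rows = [
        {
            "metabolite": base,
            "concentration_umol_per_l": conc,
            "media_volume_l": scenario.media_volume_l,
            "interval_hr": scenario.interval_hr,
        }
        for base, conc in sorted(scenario.media_concentrations.items())
    ]
    media = pd.DataFrame(rows)
    protein = {
        line: float(scenario.protein_mass_g *
                    np.exp(rng.normal(0.0, scenario.protein_mass_cv)))
        for line in scenario.sample_names()
    }
    return media, protein


# ---------------------------------------------------------------------------
# Biomarker catalogue fixture
# ---------------------------------------------------------------------------

# Replicated PD biomarker metabolites: VMH id -> (common name,
# increased specimens, decreased specimens).  One record per reporting study.
TABLE1_COUNTS: dict = {
    "nrpphr": ("Norepinephrine", [], ["plasma", "plasma"]),
    "dopa": ("Dopamine", ["plasma", "CSF"], ["plasma", "serum"]),
    "ins": ("Inosine", [], ["plasma", "CSF"]),
    "gly": ("Glycine", ["plasma", "plasma", "serum", "urine", "urine", "saliva"], []),
    "citr_L": ("Citrulline", [], ["serum", "serum", "serum"]),
    "gln_L": ("Glutamine",
              ["plasma", "plasma", "plasma", "serum", "serum", "putamen",
               "CSF", "urine"], ["CSF"]),
    "asp_L": ("Aspartic acid", ["plasma", "urine", "serum"], ["serum"]),
    "ile_L": ("Isoleucine",
              ["serum", "CSF", "fecal", "urine", "urine", "saliva"], ["fecal"]),
    "met_L": ("Methionine", ["plasma", "plasma", "CSF"], ["plasma", "plasma"]),
    "ser_L": ("Serine", ["plasma", "CSF"], ["serum", "serum"]),
    "tyr_L": ("Tyrosine",
              ["plasma", "plasma", "plasma", "serum", "serum", "serum", "serum",
               "urine", "urine", "saliva"], ["fecal", "fecal", "plasma"]),
    "val_L": ("Valine", ["serum", "saliva"], ["fecal"]),
    "4abut": ("GABA", ["plasma", "urine", "urine", "saliva"], []),
    "cit": ("Citric acid", ["plasma", "serum", "serum", "CSF"], ["plasma", "serum"]),
    "crn": ("Carnitine", ["plasma"], ["plasma", "CSF"]),
}

_DECOYS = ["decoy1", "decoy2", "decoy3", "decoy4", "decoy5"]


def make_biomarker_catalogue() -> pd.DataFrame:
    """Per-(metabolite, study) directional catalogue of clinical reports.

    Encodes the replicated PD biomarker panel (15 metabolites with their
    study counts and biospecimens) plus five synthetic decoy metabolites that
    no fixture model produces, for negative testing.
    """
    rows = []
    for vmh_id, (name, inc, dec) in TABLE1_COUNTS.items():
        k = 0
        for spec in inc:
            k += 1
            rows.append((vmh_id, name, "increased", spec, f"{vmh_id}_study{k}"))
        for spec in dec:
            k += 1
            rows.append((vmh_id, name, "decreased", spec, f"{vmh_id}_study{k}"))
    for i, d in enumerate(_DECOYS):
        direction = "increased" if i % 2 == 0 else "decreased"
        rows.append((d, f"Decoy metabolite {i + 1}", direction, "plasma",
                     f"{d}_study1"))
    return pd.DataFrame(
        rows, columns=["metabolite_id", "common_name", "direction",
                       "biospecimen", "study_label"]
    )


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def write_bundle(outdir, scenario: SyntheticScenario | None = None) -> dict:
    """Generate and write the full synthetic input bundle to ``outdir``.

    Emits model JSON, expression TSV, media TSV, per-line protein JSON,
    catalogue TSV, ground-truth JSON and a manifest recording the scenario.
    Returns the path map."""
    from pathlib import Path

    from .model_core import write_model

    sc = scenario or SyntheticScenario()
    sc.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, truth = make_toy_network(sc)
    expr = simulate_expression(model, sc, truth)
    media, protein = simulate_media_measurements(model, sc)
    catalogue = make_biomarker_catalogue()

    paths = {
        "model": outdir / "model.json",
        "expression": outdir / "expression.tsv",
        "media": outdir / "media.tsv",
        "protein": outdir / "protein.json",
        "catalogue": outdir / "catalogue.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "manifest": outdir / "scenario_manifest.json",
    }
    write_model(model, paths["model"], fmt="json")
    expr.to_csv(paths["expression"], sep="\t")
    media.to_csv(paths["media"], sep="\t", index=False)
    with open(paths["protein"], "w") as fh:
        json.dump(protein, fh, indent=1, sort_keys=True)
    catalogue.to_csv(paths["catalogue"], sep="\t", index=False)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)
    with open(paths["manifest"], "w") as fh:
        json.dump({"scenario": asdict(sc)}, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
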
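"""Cross-matching of model-implicated metabolites against a clinical
biomarker catalogue.

The catalogue holds one record per (metabolite, study) with a reported
direction of concentration change in a biospecimen.  Matching keys are
compartment-stripped, case-insensitive VMH-style base ids.  A matched
metabolite is *replicated* when at least two studies report it (direction
agreement not required); the replicated proportion is |replicated| /
|matched|.  Per-metabolite direction classes: exclusively_increased,
exclusively_decreased, inconsistent, or single_study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model_core import MetabolicModel

__all__ = [
    "BiomarkerRecord",
    "CrossmatchResult",
    "read_catalogue",
    "catalogue_records",
    "metabolites_of_reactions",
    "classify_direction",
    "crossmatch",
]

DIRECTIONS = ("increased", "decreased")


@dataclass(frozen=True)
class BiomarkerRecord:
    metabolite: str          # VMH-style base id
    direction: str           # increased | decreased
    biospecimen: str
    study_label: str

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not self.study_label:
            raise ValueError("study label must be nonempty")


@dataclass
class CrossmatchResult:
    matched: set
    replicated: set
    proportion: float | None          # None when nothing matched
    classification: dict = field(default_factory=dict)
    records_per_metabolite: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_matched": len(self.matched),
            "n_replicated": len(self.replicated),
            "matched": sorted(self.matched),
            "replicated": sorted(self.replicated),
            "replicated_proportion": self.proportion,
            "classification": dict(sorted(self.classification.items())),
            "records_per_metabolite": dict(sorted(self.records_per_metabolite.items())),
        }


def catalogue_records(catalogue) -> list:
    """Normalize a catalogue (DataFrame or iterable of records) to records."""
    if isinstance(catalogue, pd.DataFrame):
        return [
            BiomarkerRecord(str(r.metabolite_id), str(r.direction),
                            str(r.biospecimen), str(r.study_label))
            for r in catalogue.itertuples()
        ]
    return list(catalogue)


def read_catalogue(path) -> list:
    """Read a biomarker catalogue TSV (metabolite_id, direction, biospecimen,
    study_label)."""
    return catalogue_records(pd.read_csv(path, sep="\t"))


def metabolites_of_reactions(model: MetabolicModel, reaction_ids) -> set:
    """Union of compartment-stripped base ids over the listed reactions."""
    met_index = {m.id: m for m in model.metabolites}
    rxn_index = {r.id: r for r in model.reactions}
    out = set()
    for rid in reaction_ids:
        if rid not in rxn_index:
            raise KeyError(f"no reaction {rid!r} in model")
        for mid in rxn_index[rid].stoich:
            out.add(met_index[mid].base_id)
    return out


def classify_direction(records) -> str:
    """Direction class for one metabolite's catalogue records."""
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    if len(records) == 1:
        return "single_study"
    directions = {r.direction for r in records}
    if directions == {"increased"}:
        return "exclusively_increased"
    if directions == {"decreased"}:
        return "exclusively_decreased"
    return "inconsistent"


def crossmatch(metabolites, catalogue) -> CrossmatchResult:
    """Match implicated metabolites against the catalogue.

    ``metabolites`` are base ids (case-insensitive).  The replicated
    proportion is reported as None (not-applicable) when nothing matched.
    """
    records = catalogue_records(catalogue)
    if not records:
        raise ValueError("empty biomarker catalogue")
    by_met: dict[str, list] = {}
    canonical: dict[str, str] = {}  # lowercase key -> catalogue spelling
    for rec in records:
        key = rec.metabolite.lower()
        by_met.setdefault(key, []).append(rec)
        canonical.setdefault(key, rec.metabolite)
    query = {str(m).lower() for m in metabolites}
    matched = {canonical[m] for m in query & set(by_met)}
    replicated = {m for m in matched if len(by_met[m.lower()]) >= 2}
    proportion = (len(replicated) / len(matched)) if matched else None
    classification = {m: classify_direction(by_met[m.lower()]) for m in matched}
    counts = {m: len(by_met[m.lower()]) for m in matched}
    return CrossmatchResult(
        matched=matched,
        replicated=replicated,
        proportion=proportion,
        classification=classification,
        records_per_metabolite=counts,
    )
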
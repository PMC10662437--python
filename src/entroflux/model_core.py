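"""Stoichiometric network data model, readers/writers, GPR evaluation and
model-topology similarity.

Metabolite identifiers follow the VMH convention ``base[compartment]``
(e.g. ``nad[m]`` is mitochondrial NAD+).  Exchange reactions are written in
the export-positive orientation ``met[e] ->``; an uptake of magnitude *u*
therefore corresponds to a lower bound of ``-u`` on the exchange flux.

Two on-disk dialects are supported: SBML Level 3 with the FBC package
(delegated to cobrapy/libsbml) and a minimal JSON dialect that mirrors the
in-memory structures one-to-one.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "GprParseError",
    "parse_gpr",
    "gpr_to_string",
    "evaluate_gpr",
    "gpr_genes",
    "read_model",
    "write_model",
    "stoichiometric_matrix",
    "topology_similarity",
    "split_compartment",
]

DEFAULT_BOUND = 1000.0

_COMPARTMENT_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[A-Za-z0-9]+)\]$")


class ModelValidationError(ValueError):
    """An in-memory model violates a structural invariant."""


class GprParseError(ValueError):
    """A gene-protein-reaction rule string could not be parsed."""


def split_compartment(metabolite_id: str) -> tuple[str, str]:
    """Split ``"nad[m]"`` into ``("nad", "m")``.

    Identifiers without a bracketed suffix get an empty compartment code.
    """
    m = _COMPARTMENT_RE.match(metabolite_id)
    if m is None:
        return metabolite_id, ""
    return m.group("base"), m.group("comp")


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""

    def __post_init__(self):
        base, comp = split_compartment(self.id)
        if not self.compartment:
            object.__setattr__(self, "compartment", comp)
        elif comp and comp != self.compartment:
            raise ModelValidationError(
                f"metabolite {self.id!r}: declared compartment "
                f"{self.compartment!r} contradicts id suffix {comp!r}"
            )
        if not self.name:
            object.__setattr__(self, "name", base)

    @property
    def base_id(self) -> str:
        """Identifier with the compartment suffix stripped (VMH base id)."""
        return split_compartment(self.id)[0]


# ---------------------------------------------------------------------------
# GPR rules: boolean trees over gene ids.
#
# Grammar (case-insensitive keywords, no negation — Recon-style rules):
#   expr   := term  ("or" term)*
#   term   := factor ("and" factor)*
#   factor := GENE | "(" expr ")"
#
# Trees are nested tuples ("and", [children]) / ("or", [children]); a leaf is
# the bare gene-id string; the empty rule is None.
# ---------------------------------------------------------------------------

GprNode = "str | tuple[str, list] | None"

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str | None):
    """Parse a GPR rule string into a boolean expression tree.

    Returns ``None`` for an empty/blank rule.
    """
    if rule is None or not rule.strip():
        return None
    tokens = _TOKEN_RE.findall(rule)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def advance():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr():
        terms = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            advance()
            terms.append(parse_term())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_term():
        factors = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            advance()
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def parse_factor():
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR rule: {rule!r}")
        if tok == "(":
            advance()
            node = parse_expr()
            if peek() != ")":
                raise GprParseError(f"unbalanced parenthesis in GPR rule: {rule!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r} in GPR rule: {rule!r}")
        return advance()

    tree = parse_expr()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR rule: {rule!r}")
    return tree


def gpr_to_string(tree) -> str:
    """Render a GPR tree back to a canonical rule string."""
    if tree is None:
        return ""
    if isinstance(tree, str):
        return tree

    op, children = tree

    def render(child, parent_op):
        s = gpr_to_string(child)
        if isinstance(child, tuple) and child[0] != parent_op:
            return f"({s})"
        return s

    return f" {op} ".join(render(c, op) for c in children)


def evaluate_gpr(gpr, active_genes: set, empty_default: bool = True) -> bool:
    """Evaluate a GPR tree (or rule string) against a set of active genes.

    An AND node is true iff all children are; an OR node iff any child is; a
    leaf iff the gene is active.  The empty rule returns ``empty_default``
    (reactions without gene annotation are considered available).
    """
    if isinstance(gpr, str) and gpr.strip() and gpr not in active_genes:
        # A bare string may be a full rule; parse unless it is a plain leaf.
        if re.search(r"\s|\(", gpr):
            gpr = parse_gpr(gpr)
    if gpr is None or (isinstance(gpr, str) and not gpr.strip()):
        return empty_default
    if isinstance(gpr, str):
        return gpr in active_genes
    op, children = gpr
    if op == "and":
        return all(evaluate_gpr(c, active_genes, empty_default) for c in children)
    if op == "or":
        return any(evaluate_gpr(c, active_genes, empty_default) for c in children)
    raise GprParseError(f"unknown GPR node {op!r}")


def gpr_genes(gpr) -> set:
    """All gene ids appearing in a GPR tree or rule string."""
    if isinstance(gpr, str):
        gpr = parse_gpr(gpr)
    if gpr is None:
        return set()
    if isinstance(gpr, str):
        return {gpr}
    return set().union(*(gpr_genes(c) for c in gpr[1]))


@dataclass
class Reaction:
    id: str
    stoich: dict  # metabolite id -> coefficient, negative = consumed
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""  # rule string; parsed lazily
    subsystem: str = ""
    name: str = ""

    def __post_init__(self):
        if not self.stoich:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        parse_gpr(self.gpr)  # fail fast on malformed rules

    @property
    def is_exchange(self) -> bool:
        """True iff the reaction touches exactly one metabolite (boundary)."""
        return len(self.stoich) == 1

    @property
    def genes(self) -> set:
        return gpr_genes(self.gpr)


class MetabolicModel:
    """A stoichiometric network: metabolites, reactions and the gene set
    referenced by GPR rules."""

    def __init__(self, name: str, metabolites: Iterable[Metabolite],
                 reactions: Iterable[Reaction]):
        self.name = name
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            raise ModelValidationError(f"model {self.name!r}: duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            raise ModelValidationError(f"model {self.name!r}: duplicate reaction ids")
        known = set(met_ids)
        for rxn in self.reactions:
            for met_id in rxn.stoich:
                if met_id not in known:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                    )

    # -- lookups ------------------------------------------------------------
    @property
    def genes(self) -> set:
        out: set = set()
        for rxn in self.reactions:
            out |= rxn.genes
        return out

    @property
    def compartments(self) -> set:
        return {m.compartment for m in self.metabolites}

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def get_reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.name!r}") from None

    def _rxn_index(self) -> dict:
        return {r.id: r for r in self.reactions}

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        mets = [Metabolite(m.id, m.name, m.compartment) for m in self.metabolites]
        rxns = [Reaction(r.id, dict(r.stoich), r.lower_bound, r.upper_bound,
                         r.gpr, r.subsystem, r.name) for r in self.reactions]
        return MetabolicModel(self.name, mets, rxns)

    def subset(self, reaction_ids: Iterable[str], name: str | None = None) -> "MetabolicModel":
        """Submodel restricted to the given reactions; orphan metabolites are
        dropped."""
        keep = set(reaction_ids)
        rxns = [r for r in self.reactions if r.id in keep]
        used_mets = set()
        for r in rxns:
            used_mets |= set(r.stoich)
        mets = [m for m in self.metabolites if m.id in used_mets]
        return MetabolicModel(name or self.name, mets, rxns)

    # -- equality up to element order --------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        if self.name != other.name:
            return False
        mets_a = sorted((m.id, m.name, m.compartment) for m in self.metabolites)
        mets_b = sorted((m.id, m.name, m.compartment) for m in other.metabolites)
        if mets_a != mets_b:
            return False

        def key(r: Reaction):
            return (r.id, tuple(sorted(r.stoich.items())), r.lower_bound,
                    r.upper_bound, gpr_to_string(parse_gpr(r.gpr)), r.subsystem)

        return sorted(map(key, self.reactions)) == sorted(map(key, other.reactions))

    def __repr__(self) -> str:
        return (f"MetabolicModel({self.name!r}, {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions, {len(self.genes)} genes)")


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------

def stoichiometric_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """Sparse stoichiometric matrix S (rows = metabolites in model order,
    columns = reactions in model order)."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoich.items():
            rows.append(met_index[met_id])
            cols.append(j)
            data.append(float(coeff))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _model_to_json_dict(model: MetabolicModel) -> dict:
    return {
        "name": model.name,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoich": dict(sorted(r.stoich.items())),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
    }


def _model_from_json_dict(payload: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(m["id"], m.get("name", ""), m.get("compartment", ""))
            for m in payload["metabolites"]
        ]
        rxns = [
            Reaction(
                r["id"],
                {k: float(v) for k, v in r["stoich"].items()},
                float(r.get("lb", -DEFAULT_BOUND)),
                float(r.get("ub", DEFAULT_BOUND)),
                r.get("gpr", ""),
                r.get("subsystem", ""),
            )
            for r in payload["reactions"]
        ]
    except (KeyError, TypeError) as exc:
        raise ModelValidationError(f"malformed model JSON: {exc}") from exc
    return MetabolicModel(payload.get("name", "model"), mets, rxns)


def _to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model.  SBML SIds cannot contain brackets, so the
    compartment suffix is re-encoded as ``base_comp`` with the compartment
    attribute set; the round-trip uses the attribute, never id parsing."""
    import cobra

    cm = cobra.Model(model.name or "model")
    cmet = {}
    for m in model.metabolites:
        comp = m.compartment or "c"
        sid = f"{m.base_id}_{comp}"
        met = cobra.Metabolite(sid, name=m.name or m.base_id, compartment=comp)
        cmet[m.id] = met
    cm.add_metabolites(list(cmet.values()))  # keep orphan metabolites too
    for r in model.reactions:
        # plain floats: libsbml rejects numpy scalars (e.g. for 'reversible')
        rxn = cobra.Reaction(r.id, name=r.name or r.id,
                             lower_bound=float(r.lower_bound),
                             upper_bound=float(r.upper_bound))
        rxn.subsystem = r.subsystem
        if r.subsystem:
            # subsystems survive SBML round-trips via notes, not attributes
            rxn.notes["SUBSYSTEM"] = r.subsystem
        cm.add_reactions([rxn])
        rxn.add_metabolites({cmet[k]: v for k, v in r.stoich.items()})
        if r.gpr.strip():
            rxn.gene_reaction_rule = r.gpr
    return cm


def _from_cobra(cm) -> MetabolicModel:
    mets = []
    id_map = {}
    for m in cm.metabolites:
        comp = m.compartment or ""
        base = m.id
        if comp and base.endswith(f"_{comp}"):
            base = base[: -(len(comp) + 1)]
        vmh_id = f"{base}[{comp}]" if comp else base
        id_map[m.id] = vmh_id
        mets.append(Metabolite(vmh_id, m.name or "", comp))
    rxns = []
    for r in cm.reactions:
        stoich = {id_map[m.id]: float(coeff) for m, coeff in r.metabolites.items()}
        rxns.append(
            Reaction(r.id, stoich, float(r.lower_bound), float(r.upper_bound),
                     r.gene_reaction_rule or "", r.subsystem or "", r.name or "")
        )
    return MetabolicModel(cm.id or cm.name or "model", mets, rxns)


def read_model(path, fmt: str | None = None) -> MetabolicModel:
    """Read a model from ``path`` in the ``json`` or ``sbml`` dialect.

    The format is inferred from the file extension when not given.  Flux
    bounds missing from the file default to +/-1000.
    """
    path = str(path)
    if fmt is None:
        fmt = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if fmt == "json":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelValidationError(f"cannot parse {path}: {exc}") from exc
        return _model_from_json_dict(payload)
    if fmt == "sbml":
        import logging

        import cobra

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logging.getLogger("cobra").setLevel(logging.ERROR)
            cm = cobra.io.read_sbml_model(path)
        return _from_cobra(cm)
    raise ValueError(f"unknown model format {fmt!r}")


def write_model(model: MetabolicModel, path, fmt: str | None = None) -> None:
    """Write a model to ``path`` in the ``json`` or ``sbml`` dialect."""
    path = str(path)
    if fmt is None:
        fmt = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_json_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if fmt == "sbml":
        import logging

        import cobra

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logging.getLogger("cobra").setLevel(logging.ERROR)
            cobra.io.write_sbml_model(_to_cobra(model), path)
        return
    raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# Topology similarity
# ---------------------------------------------------------------------------

def _entity_sets(model: MetabolicModel, entity: str) -> set:
    if entity == "genes":
        return model.genes
    if entity == "reactions":
        return set(model.reaction_ids())
    if entity == "metabolites":
        return set(model.metabolite_ids())
    raise ValueError(f"unknown entity {entity!r}")


def _binary_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two binary presence vectors (phi coefficient).

    Identical vectors correlate at 1 even when constant; a single constant
    vector carries no signal and is scored 0."""
    if np.array_equal(a, b):
        return 1.0
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def topology_similarity(models: Sequence[MetabolicModel], entity: str
                        ) -> tuple[np.ndarray, float]:
    """Pairwise presence/absence correlation of one entity class across models.

    For each pair of models a binary vector over the union of the entity
    (genes, reactions or metabolites) across *all* models is correlated
    (Pearson on binaries = phi coefficient).  Returns the symmetric matrix
    with unit diagonal and the mean of its upper-triangle entries — the
    cohort-average similarity.
    """
    if len(models) < 2:
        raise ValueError("topology similarity needs at least two models")
    sets = [_entity_sets(m, entity) for m in models]
    universe = sorted(set().union(*sets))
    if not universe:
        raise ValueError(f"no {entity} present in any model")
    vectors = np.array(
        [[1.0 if e in s else 0.0 for e in universe] for s in sets]
    )
    n = len(models)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _binary_correlation(vectors[i], vectors[j])
    avg = float(mat[np.triu_indices(n, k=1)].mean())
    return mat, avg
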
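"""Cohort-level differential flux analysis.

Fold changes are computed per reaction against the mean flux of the control
models,

    FC = (reaction flux - control mean flux) / control mean flux,

over the reactions shared by all models; reactions whose control mean is
numerically zero are masked rather than divided.  On top of the fold-change
table: top-k ranking by the largest absolute fold change across models,
agglomerative clustering of reactions and models, subsystem tallies with
the singleton -> "others" rule, and compartment-filtered cofactor views
(e.g. all NAD-involving reactions in the mitochondria).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .model_core import MetabolicModel, split_compartment

__all__ = [
    "FoldChangeResult",
    "shared_reactions",
    "flux_table",
    "fold_changes",
    "top_k_reactions",
    "cluster_models_and_reactions",
    "subsystem_tally",
    "select_cofactor_reactions",
    "linkage_to_newick",
]

CONTROL_MEAN_EPS = 1e-9
OTHERS_LABEL = "others"


def shared_reactions(models) -> set:
    """Intersection of reaction ids across all models."""
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least two models")
    shared = set(models[0].reaction_ids())
    for m in models[1:]:
        shared &= set(m.reaction_ids())
    if not shared:
        raise ValueError("models share no reactions")
    return shared


def flux_table(solutions: dict, conditions: dict,
               reactions=None) -> pd.DataFrame:
    """Assemble a reaction x model net-flux table.

    ``solutions`` maps model id -> {reaction id -> net flux}; ``conditions``
    maps model id -> 'disease'/'control'.  Rows are restricted to reactions
    present in every solution (or to ``reactions`` if given).  The condition
    labels are attached as a column attribute ``table.attrs['conditions']``.
    """
    ids = list(solutions)
    if reactions is None:
        reactions = set.intersection(*(set(s) for s in solutions.values()))
    rows = sorted(reactions)
    data = {mid: [solutions[mid][r] for r in rows] for mid in ids}
    table = pd.DataFrame(data, index=pd.Index(rows, name="reaction"))
    missing = set(ids) - set(conditions)
    if missing:
        raise ValueError(f"no condition label for models {sorted(missing)}")
    if not any(conditions[m] == "control" for m in ids):
        raise ValueError("flux table needs at least one control column")
    table.attrs["conditions"] = {m: conditions[m] for m in ids}
    return table


@dataclass
class FoldChangeResult:
    values: pd.DataFrame   # reaction x model fold changes (NaN where masked)
    mask: pd.DataFrame     # True where the control mean was ~0 (undefined)
    control_mean: pd.Series

    @property
    def conditions(self) -> dict:
        return self.values.attrs.get("conditions", {})


def fold_changes(table: pd.DataFrame, control_ids,
                 eps: float = CONTROL_MEAN_EPS) -> FoldChangeResult:
    """Fold change of every model's flux against the control-mean flux.

    Control columns are included (their fold changes measure within-control
    spread).  Rows with |control mean| < eps are masked, never divided.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control_ids must be nonempty")
    missing = set(control_ids) - set(table.columns)
    if missing:
        raise ValueError(f"control ids not in table: {sorted(missing)}")
    mu = table[control_ids].mean(axis=1)
    masked = mu.abs() < eps
    fc = table.sub(mu, axis=0).div(mu.where(~masked), axis=0)
    fc[masked] = np.nan
    fc.attrs["conditions"] = dict(table.attrs.get("conditions", {}))
    mask = pd.DataFrame(
        np.tile(masked.to_numpy()[:, None], (1, table.shape[1])),
        index=table.index, columns=table.columns,
    )
    return FoldChangeResult(values=fc, mask=mask, control_mean=mu)


def top_k_reactions(fc: FoldChangeResult | pd.DataFrame, k: int = 50,
                    aggregate: str = "max") -> pd.DataFrame:
    """Reactions ranked by the aggregate absolute fold change across models.

    The default aggregate is the maximum |FC| over all model columns
    (``mean`` and ``median`` are selectable); masked entries are ignored.
    Ties break lexicographically on reaction id.  Returns a DataFrame with
    columns ``rank`` and ``score`` indexed by reaction, of length
    min(k, reactions with any defined entry).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = fc.values if isinstance(fc, FoldChangeResult) else fc
    agg_fun = {"max": np.nanmax, "mean": np.nanmean, "median": np.nanmedian}
    if aggregate not in agg_fun:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    abs_fc = values.abs()
    defined = abs_fc.notna().any(axis=1)
    if not defined.any():
        raise ValueError("all fold-change entries are masked")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        score = abs_fc[defined].apply(
            lambda row: float(agg_fun[aggregate](row.to_numpy())), axis=1
        )
    order = sorted(score.index, key=lambda rid: (-score[rid], rid))[:k]
    out = pd.DataFrame({"score": score.loc[order]})
    out["rank"] = np.arange(1, len(out) + 1)
    out.index.name = "reaction"
    return out[["rank", "score"]]


def cluster_models_and_reactions(fc_subset: pd.DataFrame,
                                 metric: str = "euclidean",
                                 method: str = "ward") -> dict:
    """Agglomerative hierarchical clustering of rows (reactions) and columns
    (models) of a fold-change submatrix.

    Masked (NaN) entries are replaced by 0 for distance purposes (an
    undefined fold change carries no differential signal).  Returns linkage
    matrices and leaf orders; deterministic for a fixed input.
    """
    if fc_subset.shape[0] < 2 or fc_subset.shape[1] < 2:
        raise ValueError("clustering needs at least a 2x2 matrix")
    X = fc_subset.fillna(0.0).to_numpy(dtype=float)
    if np.allclose(X, X.flat[0]):
        warnings.warn("constant fold-change matrix: single-cluster result")
    row_link = hierarchy.linkage(X, method=method, metric=metric)
    col_link = hierarchy.linkage(X.T, method=method, metric=metric)
    return {
        "row_linkage": row_link,
        "col_linkage": col_link,
        "row_order": [fc_subset.index[i] for i in hierarchy.leaves_list(row_link)],
        "col_order": [fc_subset.columns[i] for i in hierarchy.leaves_list(col_link)],
        "row_labels": list(fc_subset.index),
        "col_labels": list(fc_subset.columns),
    }


def cut_columns(clustering: dict, n_clusters: int = 2) -> dict:
    """Flat column (model) assignment at an n-cluster cut of the dendrogram."""
    labels = hierarchy.fcluster(clustering["col_linkage"], t=n_clusters,
                                criterion="maxclust")
    return dict(zip(clustering["col_labels"], (int(x) for x in labels)))


def linkage_to_newick(linkage: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def subsystem_tally(reaction_ids, model: MetabolicModel,
                    top_n: int = 5) -> dict:
    """Count reactions per subsystem with the singleton -> "others" rule.

    Subsystems represented by exactly one reaction in the list are merged
    into an ``others`` bucket.  Returns all tallies plus the top-``top_n``
    subsystems by count (ties broken lexicographically; ``others`` competes
    like any other label).
    """
    index = {r.id: r for r in model.reactions}
    raw: dict[str, int] = {}
    for rid in reaction_ids:
        if rid not in index:
            raise KeyError(f"no reaction {rid!r} in model")
        label = index[rid].subsystem or "(unassigned)"
        raw[label] = raw.get(label, 0) + 1
    counts: dict[str, int] = {}
    for label, n in raw.items():
        if n == 1:
            counts[OTHERS_LABEL] = counts.get(OTHERS_LABEL, 0) + 1
        else:
            counts[label] = n
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return {"counts": counts, "top": ranked[:top_n]}


def select_cofactor_reactions(model: MetabolicModel, cofactors=("nad", "nadh"),
                              compartment: str | None = None,
                              subsystem: str | None = None) -> set:
    """Reactions involving a cofactor in one compartment, or labeled with a
    subsystem.

    Cofactor mode (default): reactions whose stoichiometry contains any of
    the given base ids in ``compartment``.  Subsystem mode: reactions whose
    subsystem label equals ``subsystem``.
    """
    if subsystem is not None:
        return {r.id for r in model.reactions if r.subsystem == subsystem}
    if compartment is None:
        raise ValueError("give either a compartment or a subsystem")
    if compartment not in model.compartments:
        raise ValueError(f"unknown compartment {compartment!r}")
    targets = {f"{base}[{compartment}]" for base in cofactors}
    return {r.id for r in model.reactions if targets & set(r.stoich)}
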
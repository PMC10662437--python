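"""Flux prediction: linear FBA/FVA utilities and entropic flux balance
analysis (eFBA).

eFBA minimizes the negative flux entropy

    Psi(v_f, v_r) = sum_j v_f,j ln v_f,j + sum_j v_r,j ln v_r,j

over v_f, v_r >= 0 subject to steady state S (v_f - v_r) = 0 and net-flux
bounds lb <= v_f - v_r <= ub (0 ln 0 = 0).  Unlike FBA, the optimum is the
unique interior flux distribution: the entropy term penalizes large
unidirectional fluxes, which in particular drives thermodynamically
infeasible internal cycles to zero net flux.

The solver exploits that for a fixed net flux v the optimal forward/reverse
split has a closed form.  With the Lagrangian stationarity conditions
ln v_f + 1 = mu and ln v_r + 1 = -mu one gets v_f * v_r = e^-2 and

    v_f(v) = (v + sqrt(v^2 + 4 e^-2)) / 2,      v_r = v_f - v.

Substituting the split back gives a smooth, strictly convex per-reaction
potential phi(v) with phi'(v) = 1 + ln v_f(v) and
phi''(v) = 1 / sqrt(v^2 + 4 e^-2), so eFBA reduces to minimizing
Phi(v) = sum_j phi(v_j) over the flux polytope.  The program is solved in
null-space coordinates of S (steady state holds exactly by construction)
with an exact-gradient/Hessian trust-region method; only the box
constraints remain as inequalities.

An independent oracle (`efba_oracle`) re-solves small problems (<= 3 flux
degrees of freedom) by nested grid/golden-section refinement over the
null-space coordinates using only the inner closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse
from scipy.linalg import null_space

from .model_core import MetabolicModel, stoichiometric_matrix

__all__ = [
    "EfbaProblem",
    "EfbaSolution",
    "InfeasibleModelError",
    "UnboundedModelError",
    "SolverError",
    "optimal_split",
    "entropy_potential",
    "solve_fba",
    "flux_variability",
    "problem_from_model",
    "solve_efba",
    "efba_oracle",
]

E_M2 = math.exp(-2.0)  # v_f * v_r at an interior entropic optimum
FEAS_TOL = 1e-9


class InfeasibleModelError(RuntimeError):
    pass


class UnboundedModelError(RuntimeError):
    pass


class SolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Per-reaction closed forms
# ---------------------------------------------------------------------------

def optimal_split(v):
    """Optimal (v_f, v_r) for given net flux v: v_f = (v + sqrt(v^2+4e^-2))/2.

    Vectorized; satisfies v_f - v_r = v and v_f * v_r = e^-2 exactly.
    """
    v = np.asarray(v, dtype=float)
    root = np.sqrt(v * v + 4.0 * E_M2)
    v_f = 0.5 * (v + root)
    v_r = v_f - v
    return v_f, v_r


def _xlogx(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def entropy_potential(v):
    """phi(v), phi'(v), phi''(v): the per-reaction negative entropy after the
    optimal forward/reverse split."""
    v = np.asarray(v, dtype=float)
    v_f, v_r = optimal_split(v)
    phi = _xlogx(v_f) + _xlogx(v_r)
    grad = 1.0 + np.log(v_f)
    hess = 1.0 / np.sqrt(v * v + 4.0 * E_M2)
    return phi, grad, hess


def entropy_objective(v_f, v_r):
    """Psi(v_f, v_r) = v_f^T ln v_f + v_r^T ln v_r with 0 ln 0 = 0."""
    return float(_xlogx(v_f).sum() + _xlogx(v_r).sum())


# ---------------------------------------------------------------------------
# Linear FBA / FVA
# ---------------------------------------------------------------------------

def _lp_arrays(model: MetabolicModel):
    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub


def _linprog(c, S, lb, ub):
    res = optimize.linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)), method="highs",
    )
    return res


def solve_fba(model: MetabolicModel, objective_reaction: str, sense: str = "max"
              ) -> tuple[dict, float]:
    """LP-optimal flux distribution for one objective reaction.

    Returns (flux vector keyed by reaction id, objective value).
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    rxn_ids = model.reaction_ids()
    try:
        j = rxn_ids.index(objective_reaction)
    except ValueError:
        raise KeyError(f"no reaction {objective_reaction!r} in model") from None
    S, lb, ub = _lp_arrays(model)
    c = np.zeros(len(rxn_ids))
    c[j] = -1.0 if sense == "max" else 1.0
    res = _linprog(c, S, lb, ub)
    if res.status == 2:
        raise InfeasibleModelError(
            f"model {model.name!r} has no feasible steady-state flux"
        )
    if res.status == 3:
        direction = "forward" if sense == "max" else "reverse"
        raise UnboundedModelError(
            f"objective {objective_reaction!r} is unbounded in the {direction} direction"
        )
    if res.status != 0:
        raise SolverError(f"LP failed with status {res.status}: {res.message}")
    value = float(res.x[j])
    return dict(zip(rxn_ids, map(float, res.x))), value


def flux_variability(model: MetabolicModel, reactions=None,
                     zero_tol: float = FEAS_TOL) -> dict:
    """Per-reaction (min, max) of the net flux under the model constraints.

    Values with magnitude below ``zero_tol`` are clamped to exactly 0.
    """
    rxn_ids = model.reaction_ids()
    if reactions is None:
        reactions = rxn_ids
    index = {rid: i for i, rid in enumerate(rxn_ids)}
    S, lb, ub = _lp_arrays(model)
    n = len(rxn_ids)
    out = {}
    for rid in reactions:
        if rid not in index:
            raise KeyError(f"no reaction {rid!r} in model")
        j = index[rid]
        c = np.zeros(n)
        vals = []
        for sign in (1.0, -1.0):
            c[j] = sign
            res = _linprog(c, S, lb, ub)
            if res.status == 2:
                raise InfeasibleModelError(
                    f"model {model.name!r} infeasible during flux variability"
                )
            if res.status != 0:
                raise SolverError(f"FVA LP failed for {rid}: {res.message}")
            vals.append(float(res.x[j]))
        lo, hi = vals
        if abs(lo) < zero_tol:
            lo = 0.0
        if abs(hi) < zero_tol:
            hi = 0.0
        out[rid] = (lo, hi)
    return out


# ---------------------------------------------------------------------------
# eFBA problem container
# ---------------------------------------------------------------------------

@dataclass
class EfbaProblem:
    """Entropic FBA program: steady state S v = 0, lb <= v <= ub, with flux
    units of umol/gDW/hr recorded through ``scale`` (fluxes are divided by
    ``scale`` before entering the entropy)."""

    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: list
    fixed: dict = field(default_factory=dict)  # reaction id -> exact rate
    scale: float = 1.0

    def __post_init__(self):
        self.S = np.asarray(
            self.S.toarray() if sparse.issparse(self.S) else self.S, dtype=float
        )
        self.lb = np.asarray(self.lb, dtype=float).copy()
        self.ub = np.asarray(self.ub, dtype=float).copy()
        if np.any(self.lb > self.ub):
            raise ValueError("lb > ub in eFBA problem")
        if self.S.shape[1] != len(self.lb) or len(self.lb) != len(self.ub):
            raise ValueError("S dimensions do not match bounds")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        index = {rid: i for i, rid in enumerate(self.reaction_ids)}
        for rid, rate in self.fixed.items():
            j = index[rid]
            self.lb[j] = self.ub[j] = float(rate)


@dataclass
class EfbaSolution:
    reaction_ids: list
    v_f: np.ndarray
    v_r: np.ndarray
    objective: float
    residual: float          # ||S v||_inf
    status: str
    scale: float = 1.0

    @property
    def net(self) -> np.ndarray:
        return self.v_f - self.v_r

    def net_flux(self) -> dict:
        return dict(zip(self.reaction_ids, map(float, self.net)))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"v_f": self.v_f, "v_r": self.v_r, "net": self.net},
            index=pd.Index(self.reaction_ids, name="reaction"),
        )


def problem_from_model(model: MetabolicModel, fixed: dict | None = None,
                       scale: float = 1.0) -> EfbaProblem:
    S, lb, ub = _lp_arrays(model)
    return EfbaProblem(S, lb, ub, model.reaction_ids(), dict(fixed or {}), scale)


# ---------------------------------------------------------------------------
# Null-space reduction shared by solver and oracle
# ---------------------------------------------------------------------------

def _reduce(problem: EfbaProblem):
    """Particular solution + null-space basis for {S v = 0, lb<=v<=ub}.

    Fixed reactions (lb == ub) are eliminated; the particular solution is the
    minimum-norm flux satisfying S v = 0 with the fixed values substituted.
    Returns (v0, N) with every feasible v = v0 + N t.
    """
    S, lb, ub = problem.S, problem.lb, problem.ub
    n = S.shape[1]
    fixed_mask = lb == ub
    free = ~fixed_mask
    v_fix = np.where(fixed_mask, lb, 0.0)
    rhs = -S @ v_fix
    S_free = S[:, free]
    if S_free.shape[1] == 0:
        v0 = v_fix
        if np.max(np.abs(S @ v0)) > 1e-7:
            raise InfeasibleModelError("fixed rates violate steady state")
        return v0, np.zeros((n, 0))
    sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
    if np.max(np.abs(S_free @ sol - rhs)) > 1e-7 * max(1.0, np.abs(rhs).max()):
        raise InfeasibleModelError(
            "steady state is inconsistent with the fixed exchange rates"
        )
    v0 = v_fix.copy()
    v0[free] = sol
    N_free = null_space(S_free)
    N = np.zeros((n, N_free.shape[1]))
    N[free] = N_free
    return v0, N


def _feasible_start(problem: EfbaProblem, v0, N):
    """Interior-leaning feasible point in null-space coordinates.

    The min-norm particular solution may violate the box; an LP recentres it
    (maximizing the smallest slack, capped so huge boxes stay harmless).
    """
    lb, ub = problem.lb, problem.ub
    k = N.shape[1]
    if k == 0:
        if np.any(v0 < lb - 1e-7) or np.any(v0 > ub + 1e-7):
            raise InfeasibleModelError("fixed rates violate flux bounds")
        return np.zeros(0)
    t0 = np.zeros(k)
    v = v0 + N @ t0
    if np.all(v >= lb + 1e-7) and np.all(v <= ub - 1e-7):
        return t0
    # LP in (t, s): maximize s with lb + s <= v0 + N t <= ub - s, 0<=s<=1
    free = problem.lb != problem.ub
    A = np.vstack([
        np.hstack([-N[free], np.ones((free.sum(), 1))]),
        np.hstack([N[free], np.ones((free.sum(), 1))]),
    ])
    b = np.concatenate([v0[free] - lb[free], ub[free] - v0[free]])
    c = np.zeros(k + 1)
    c[-1] = -1.0
    res = optimize.linprog(
        c, A_ub=A, b_ub=b, bounds=[(None, None)] * k + [(0.0, 1.0)],
        method="highs",
    )
    if res.status != 0 or res.x[-1] < -1e-9:
        raise InfeasibleModelError("eFBA problem has no feasible flux")
    return res.x[:k]


def _objective_in_t(problem: EfbaProblem, v0, N):
    scale = problem.scale

    def fun(t):
        v = (v0 + N @ t) / scale
        phi, _, _ = entropy_potential(v)
        return float(phi.sum())

    def jac(t):
        v = (v0 + N @ t) / scale
        _, g, _ = entropy_potential(v)
        return (N.T @ g) / scale

    def hess(t):
        v = (v0 + N @ t) / scale
        _, _, h = entropy_potential(v)
        return (N.T * h) @ N / (scale * scale)

    return fun, jac, hess


def solve_efba(problem: EfbaProblem) -> EfbaSolution:
    """Solve the entropic flux balance program.

    The strictly convex reduced objective is minimized over the null space of
    S with a trust-region method (exact gradient and Hessian); the
    steady-state constraint holds to numerical null-space precision by
    construction and the forward/reverse split is recovered in closed form.
    """
    v0, N = _reduce(problem)
    t0 = _feasible_start(problem, v0, N)
    if N.shape[1] == 0:
        v = v0
        status = "optimal"
    else:
        fun, jac, hess = _objective_in_t(problem, v0, N)
        free = problem.lb != problem.ub
        constraints = [
            optimize.LinearConstraint(
                N[free], problem.lb[free] - v0[free], problem.ub[free] - v0[free]
            )
        ]
        res = optimize.minimize(
            fun, t0, jac=jac, hess=hess, method="trust-constr",
            constraints=constraints,
            options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000},
        )
        if res.status not in (1, 2) and not res.success:
            raise SolverError(
                f"eFBA did not converge: {res.message} "
                f"(constraint violation {res.constr_violation:.2e})"
            )
        v = v0 + N @ res.x
        status = "optimal"
    # clip marginal box violations from the interior-point stopping tolerance
    v = np.clip(v, problem.lb - 1e-9, problem.ub + 1e-9)
    v_f, v_r = optimal_split(v / problem.scale)
    residual = float(np.max(np.abs(problem.S @ v))) if problem.S.size else 0.0
    return EfbaSolution(
        reaction_ids=list(problem.reaction_ids),
        v_f=v_f * problem.scale,
        v_r=v_r * problem.scale,
        objective=entropy_objective(v_f, v_r),
        residual=residual,
        status=status,
        scale=problem.scale,
    )


def solve_efba_model(model: MetabolicModel, fixed: dict | None = None,
                     scale: float = 1.0) -> EfbaSolution:
    """Convenience wrapper: build the eFBA program from a model and solve."""
    return solve_efba(problem_from_model(model, fixed=fixed, scale=scale))


# ---------------------------------------------------------------------------
# Independent oracle: nested grid/golden-section refinement, <=3 DOF
# ---------------------------------------------------------------------------

def _t_box(problem: EfbaProblem, v0, N):
    """Per-coordinate interval of the feasible t-polytope (bounding box)."""
    k = N.shape[1]
    free = problem.lb != problem.ub
    A = np.vstack([-N[free], N[free]])
    b = np.concatenate([v0[free] - problem.lb[free], problem.ub[free] - v0[free]])
    lo, hi = np.empty(k), np.empty(k)
    for i in range(k):
        c = np.zeros(k)
        for sign, target in ((1.0, lo), (-1.0, hi)):
            c[i] = sign
            res = optimize.linprog(c, A_ub=A, b_ub=b,
                                   bounds=[(None, None)] * k, method="highs")
            if res.status != 0:
                raise InfeasibleModelError("oracle: empty feasible polytope")
            target[i] = float(res.x[i])
        c[i] = 0.0
    return lo, hi


def efba_oracle(problem: EfbaProblem, max_dof: int = 3,
                n_grid: int = 13, n_zoom: int = 60) -> EfbaSolution:
    """Brute-force eFBA optimum for problems with <= ``max_dof`` flux degrees
    of freedom.

    Uses only the per-reaction closed-form split plus nested grid refinement
    (golden-section-style shrinking) over the null-space coordinates; refuses
    larger problems.
    """
    v0, N = _reduce(problem)
    k = N.shape[1]
    if k > max_dof:
        raise ValueError(f"oracle refuses problems with {k} > {max_dof} degrees of freedom")
    scale = problem.scale

    def objective_of_t(t):
        v = v0 + N @ t
        if np.any(v < problem.lb - 1e-9) or np.any(v > problem.ub + 1e-9):
            return np.inf
        phi, _, _ = entropy_potential(v / scale)
        return float(phi.sum())

    if k == 0:
        t_best = np.zeros(0)
    else:
        lo, hi = _t_box(problem, v0, N)
        centre = 0.5 * (lo + hi)
        width = hi - lo
        t_best, f_best = centre.copy(), objective_of_t(centre)
        for _ in range(n_zoom):
            axes = [np.linspace(c - w / 2, c + w / 2, n_grid)
                    for c, w in zip(t_best, width)]
            grids = np.meshgrid(*axes, indexing="ij")
            pts = np.stack([g.ravel() for g in grids], axis=1)
            vals = np.array([objective_of_t(p) for p in pts])
            j = int(np.argmin(vals))
            if vals[j] < f_best:
                f_best, t_best = vals[j], pts[j]
            width = width * (2.0 / (n_grid - 1)) * 1.5  # keep neighbours of best
            if np.all(width < 1e-12):
                break
        if not np.isfinite(f_best):
            raise InfeasibleModelError("oracle found no feasible grid point")
    v = np.clip(v0 + N @ t_best, problem.lb, problem.ub)
    v_f, v_r = optimal_split(v / scale)
    return EfbaSolution(
        reaction_ids=list(problem.reaction_ids),
        v_f=v_f * scale,
        v_r=v_r * scale,
        objective=entropy_objective(v_f, v_r),
        residual=float(np.max(np.abs(problem.S @ v))) if problem.S.size else 0.0,
        status="oracle",
        scale=scale,
    )
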
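"""Constrained optimization of drug affinity profiles over the simplex.

Three objective variants are supported:

* ``dot`` — maximize dot-product damage to the cancer subject to linear
  per-tissue damage caps: a linear program.
* ``kl`` — maximize the (negative-KL) damage subject to the same linear
  caps: a convex program whose unconstrained optimum is exactly the
  cancer's own profile.
* ``sum`` — unconstrained net-benefit objective (cancer damage minus a
  weighted sum of healthy-tissue damages): the optimum is the indicator
  of the best net-benefit coordinate.

A brute-force simplex-grid oracle (for small supports) is provided for
verification; it deliberately shares no code with the LP path.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import linprog, minimize

from .damage import DamageScore, dot_damage, kl_damage
from .isotypes import N_ISOTYPES
from .profiles import IsotypeProfile
from .weights import TissueConstraint

#: Constraint-satisfaction tolerance for reported solutions.
FEAS_TOL = 1e-7
#: Tolerance at which a constraint counts as active (held with equality).
ACTIVE_TOL = 1e-7


class SolverError(RuntimeError):
    """Solver failed for a reason other than infeasibility."""


@dataclass(frozen=True)
class OptimizationResult:
    status: str  # "optimal" | "infeasible"
    objective_model: str  # "dot" | "kl" | "sum"
    optimal_profile: Optional[IsotypeProfile] = None
    damage: Optional[DamageScore] = None
    objective_value: Optional[float] = None
    active_constraints: tuple[str, ...] = ()
    message: str = ""

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "model": self.objective_model,
            "optimal_profile": (None if self.optimal_profile is None
                                else self.optimal_profile.to_dict()),
            "damage": None if self.damage is None else self.damage.value,
            "objective_value": self.objective_value,
            "active_constraints": list(self.active_constraints),
            "message": self.message,
        }


@dataclass(frozen=True)
class DrugEvaluation:
    drug_label: str
    feasible: bool
    violations: tuple[tuple[str, float, float], ...]  # (tissue, damage, cap)
    cancer_damage: DamageScore
    tissue_damages: tuple[tuple[str, float], ...] = ()
    fraction_of_optimum: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "drug": self.drug_label,
            "feasible": self.feasible,
            "violations": [
                {"tissue": t, "damage": d, "cap": c} for t, d, c in self.violations
            ],
            "tissue_damages": [
                {"tissue": t, "damage": d} for t, d in self.tissue_damages
            ],
            "cancer_damage": self.cancer_damage.value,
            "fraction_of_optimum": self.fraction_of_optimum,
        }


def _as_constraints(constraints: Iterable) -> list[TissueConstraint]:
    out = []
    for k, c in enumerate(constraints):
        if isinstance(c, TissueConstraint):
            out.append(c)
        else:
            profile, cap = c
            label = profile.label or f"tissue_{k}"
            out.append(TissueConstraint(label, profile, cap))
        if out[-1].cap < 0:
            raise ValueError(f"negative cap for tissue {out[-1].tissue!r}")
    return out


def _constraint_matrix(constraints: Sequence[TissueConstraint]):
    A = np.vstack([c.profile.values for c in constraints])
    b = np.array([c.cap for c in constraints], dtype=float)
    return A, b


def _active_set(constraints: Sequence[TissueConstraint], r: np.ndarray,
                tol: float = ACTIVE_TOL) -> tuple[str, ...]:
    return tuple(
        c.tissue for c in constraints
        if abs(float(c.profile.values @ r) - c.cap) <= tol
    )


def _indicator(idx: int, label: str) -> IsotypeProfile:
    v = np.zeros(N_ISOTYPES)
    v[idx] = 1.0
    return IsotypeProfile(v, label)


def optimize_dot(cancer_q: IsotypeProfile, constraints: Iterable = ()
                 ) -> OptimizationResult:
    """Maximize dot damage to the cancer under per-tissue caps (an LP).

    With no constraints the optimum is exactly the indicator of the
    cancer's most-expressed isotype (ties to the earliest index) and the
    damage equals max_i q_i.
    """
    cons = _as_constraints(constraints)
    if not cons:
        iso = cancer_q.argmax()
        r = _indicator(int(iso), f"optimal({cancer_q.label})")
        return OptimizationResult(
            status="optimal", objective_model="dot", optimal_profile=r,
            damage=dot_damage(r, cancer_q), objective_value=cancer_q[iso],
        )

    A, b = _constraint_matrix(cons)
    res = linprog(
        -cancer_q.values,
        A_ub=A, b_ub=b,
        A_eq=np.ones((1, N_ISOTYPES)), b_eq=[1.0],
        bounds=(0.0, 1.0),
        method="highs",
        options={
            "presolve": True,
            "primal_feasibility_tolerance": 1e-10,
            "dual_feasibility_tolerance": 1e-10,
        },
    )
    if res.status == 2:
        return OptimizationResult(
            status="infeasible", objective_model="dot",
            message="no simplex point satisfies every tissue cap: " + res.message,
        )
    if res.status != 0:
        raise SolverError(f"LP solver failed (status {res.status}): {res.message}")

    r = np.clip(res.x, 0.0, None)
    r = r / r.sum()
    profile = IsotypeProfile(r, f"optimal({cancer_q.label})")
    return OptimizationResult(
        status="optimal", objective_model="dot", optimal_profile=profile,
        damage=dot_damage(profile, cancer_q),
        objective_value=float(cancer_q.values @ r),
        active_constraints=_active_set(cons, r),
    )


def optimize_penalized(cancer_q: IsotypeProfile,
                       penalties: Iterable = ()) -> OptimizationResult:
    """Maximize net benefit: cancer damage minus weighted healthy damages.

    The objective is linear over the simplex, so the optimum is the
    indicator of the coordinate with the largest net-benefit value;
    ties break to the earliest canonical index.
    """
    cons = _as_constraints(penalties)
    net = cancer_q.values.copy()
    for c in cons:
        net = net - c.cap * c.profile.values
    idx = int(np.argmax(net))  # argmax returns the first maximum
    profile = _indicator(idx, f"optimal({cancer_q.label})")
    return OptimizationResult(
        status="optimal", objective_model="sum", optimal_profile=profile,
        damage=dot_damage(profile, cancer_q),
        objective_value=float(net[idx]),
    )


def optimize_kl(cancer_q: IsotypeProfile, constraints: Iterable = ()
                ) -> OptimizationResult:
    """Maximize negative-KL damage under the linear per-tissue caps.

    Equivalent to minimizing KL(r || q_cancer) over the feasible polytope
    — a convex program. Unconstrained (or whenever the cancer profile
    itself is feasible) the optimum is exactly r = q_cancer with
    objective 0. Mass is confined to the cancer profile's support, since
    any mass outside it makes the objective -inf.
    """
    cons = _as_constraints(constraints)
    q = cancer_q.values
    A, b = (None, None)
    if cons:
        A, b = _constraint_matrix(cons)
        if np.all(A @ q <= b + 1e-12):
            return OptimizationResult(
                status="optimal", objective_model="kl",
                optimal_profile=cancer_q.relabel(f"optimal({cancer_q.label})"),
                damage=DamageScore(0.0, "kl"), objective_value=0.0,
                active_constraints=_active_set(cons, q),
            )
    else:
        return OptimizationResult(
            status="optimal", objective_model="kl",
            optimal_profile=cancer_q.relabel(f"optimal({cancer_q.label})"),
            damage=DamageScore(0.0, "kl"), objective_value=0.0,
        )

    support = np.flatnonzero(q > 0)
    As = A[:, support]
    qs = q[support]
    d = support.size

    # Phase 1: largest-margin feasible point on the restricted simplex
    # (variables [r_s, s], maximize s with A r + s <= b and r >= s).
    c_ph1 = np.zeros(d + 1)
    c_ph1[-1] = -1.0
    A_ub = np.block([
        [As, np.ones((As.shape[0], 1))],
        [-np.eye(d), np.ones((d, 1))],
    ])
    b_ub = np.concatenate([b, np.zeros(d)])
    A_eq = np.concatenate([np.ones(d), [0.0]])[None, :]
    ph1 = linprog(c_ph1, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                  bounds=[(0.0, 1.0)] * d + [(None, None)], method="highs")
    if ph1.status == 2 or (ph1.status == 0 and ph1.x[-1] < -FEAS_TOL):
        return OptimizationResult(
            status="infeasible", objective_model="kl",
            message="no simplex point on the cancer support satisfies every cap",
        )
    if ph1.status != 0:
        raise SolverError(f"phase-1 LP failed: {ph1.message}")
    x0 = np.clip(ph1.x[:d], 1e-12, None)
    x0 = x0 / x0.sum()

    eps = 1e-300  # guards the log; iterates are kept interior by the start

    def objective(r):
        rr = np.clip(r, eps, None)
        return float(np.sum(rr * np.log(rr / qs)))

    def gradient(r):
        rr = np.clip(r, eps, None)
        return np.log(rr / qs) + 1.0

    res = minimize(
        objective, x0, jac=gradient, method="SLSQP",
        bounds=[(0.0, 1.0)] * d,
        constraints=[
            {"type": "eq", "fun": lambda r: r.sum() - 1.0,
             "jac": lambda r: np.ones(d)},
            {"type": "ineq", "fun": lambda r: b - As @ r,
             "jac": lambda r: -As},
        ],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:
        raise SolverError(f"KL solver failed to converge: {res.message}")

    r_s = np.clip(res.x, 0.0, None)
    r_s = r_s / r_s.sum()
    if np.any(As @ r_s > b + FEAS_TOL):
        raise SolverError("KL solver returned an infeasible point")
    r = np.zeros(N_ISOTYPES)
    r[support] = r_s
    profile = IsotypeProfile(r, f"optimal({cancer_q.label})")
    score = kl_damage(profile, cancer_q)
    return OptimizationResult(
        status="optimal", objective_model="kl", optimal_profile=profile,
        damage=score, objective_value=score.value,
        active_constraints=_active_set(cons, r),
    )


def evaluate_drug(drug_r: IsotypeProfile, cancer_q: IsotypeProfile,
                  constraints: Iterable = (),
                  reference: Optional[OptimizationResult] = None
                  ) -> DrugEvaluation:
    """Screen one drug: per-tissue damages, cap violations, cancer damage.

    A drug is eliminated (infeasible) if it violates the cap of any
    healthy tissue. ``fraction_of_optimum`` is the ratio of the drug's
    cancer damage to the reference optimum's, clipped to [0, 1].
    """
    cons = _as_constraints(constraints)
    damages = [(c.tissue, dot_damage(drug_r, c.profile).value) for c in cons]
    violations = tuple(
        (t, d, c.cap) for (t, d), c in zip(damages, cons) if d > c.cap + FEAS_TOL
    )
    cancer = dot_damage(drug_r, cancer_q)
    fraction = None
    if reference is not None and reference.is_optimal:
        opt = reference.damage.value
        fraction = 0.0 if opt <= 0 else min(max(cancer.value / opt, 0.0), 1.0)
    return DrugEvaluation(
        drug_label=drug_r.label, feasible=not violations,
        violations=violations, cancer_damage=cancer,
        tissue_damages=tuple(damages), fraction_of_optimum=fraction,
    )


def _compositions(n: int, d: int) -> np.ndarray:
    """All length-``d`` tuples of non-negative ints summing to ``n``."""
    if d == 1:
        return np.array([[n]], dtype=np.int32)
    if d == 2:
        ks = np.arange(n + 1, dtype=np.int32)
        return np.column_stack([ks, n - ks])
    if d == 3:
        counts = np.arange(n + 1, 0, -1, dtype=np.int64)
        ks = np.repeat(np.arange(n + 1, dtype=np.int32), counts)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        js = (np.arange(counts.sum(), dtype=np.int64)
              - np.repeat(starts, counts)).astype(np.int32)
        return np.column_stack([ks, js, (n - ks - js).astype(np.int32)])
    blocks = []
    for k in range(n + 1):
        sub = _compositions(n - k, d - 1)
        blocks.append(np.column_stack(
            [np.full(len(sub), k, dtype=np.int32), sub]))
    return np.vstack(blocks)


@functools.lru_cache(maxsize=8)
def _simplex_grid(dims: int, steps: int) -> np.ndarray:
    """All simplex grid points with the given resolution (vertices included)."""
    n_points = math.comb(steps + dims - 1, dims - 1)
    if n_points > 20_000_000:
        raise ValueError(
            f"grid of {n_points} points is too large; coarsen grid_step "
            f"or reduce the active support"
        )
    grid = _compositions(steps, dims).astype(float) / steps
    grid.setflags(write=False)
    return grid


def brute_force_oracle(cancer_q: IsotypeProfile, constraints: Iterable = (),
                       grid_step: float = 1e-3, model: str = "dot",
                       max_support: int = 4,
                       include_slack: bool = True) -> OptimizationResult:
    """Exhaustive simplex-grid search; a test oracle, not a solver.

    Enumerates every grid point (step ``grid_step``) on the simplex over
    the active isotypes — those expressed by the cancer or any
    constrained tissue — plus, when ``include_slack`` and an unexpressed
    isotype exists, one representative slack coordinate (all such
    coordinates are interchangeable: zero objective, zero constraint
    usage). With the slack the oracle solves exactly the same problem as
    the 8-coordinate solver; without it the search is confined to the
    active support, which lower-bounds the full optimum. Vertices are
    part of the grid, so unconstrained linear optima are found exactly.
    """
    if not (0 < grid_step <= 0.1):
        raise ValueError("grid_step must be in (0, 0.1]")
    if model not in ("dot", "kl"):
        raise ValueError("model must be 'dot' or 'kl'")
    cons = _as_constraints(constraints)

    support = cancer_q.values > 0
    for c in cons:
        support |= c.profile.values > 0
    active = list(np.flatnonzero(support))
    inactive = [i for i in range(N_ISOTYPES) if i not in active]
    if inactive and include_slack:
        active.append(inactive[0])  # one slack coordinate stands in for all
    if len(active) > max_support:
        raise ValueError(
            f"{len(active)} active isotypes exceed the oracle limit ({max_support})"
        )

    A = np.vstack([c.profile.values[active] for c in cons]) if cons else None
    b = np.array([c.cap for c in cons])
    qa = cancer_q.values[active]
    steps = round(1.0 / grid_step)

    d = len(active)
    grid = _simplex_grid(d, steps)
    if A is not None:
        feasible = np.all(grid @ A.T <= b[None, :] + 1e-9, axis=1)
        grid = grid[feasible]
    if grid.shape[0] == 0:
        return OptimizationResult(
            status="infeasible", objective_model=model,
            message="no feasible grid point",
        )

    if model == "dot":
        objs = grid @ qa
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(grid > 0, grid / np.where(qa > 0, qa, 1.0), 1.0)
            terms = np.where(grid > 0, grid * np.log(ratio), 0.0)
            objs = -terms.sum(axis=1)
            bad = (grid > 0) & (qa[None, :] == 0)
            objs[bad.any(axis=1)] = -math.inf

    best = int(np.argmax(objs))
    r = np.zeros(N_ISOTYPES)
    r[active] = grid[best]
    profile = IsotypeProfile(r, f"oracle({cancer_q.label})")
    damage = (dot_damage(profile, cancer_q) if model == "dot"
              else kl_damage(profile, cancer_q))
    return OptimizationResult(
        status="optimal", objective_model=model, optimal_profile=profile,
        damage=damage, objective_value=float(objs[best]),
        active_constraints=_active_set(cons, r, tol=grid_step),
    )
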
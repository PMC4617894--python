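"""LP backbone: flux variability, flux-consistency pruning, and FBA.

All linear programs are solved with scipy's HiGHS interface over the
steady-state polytope {v : S v = 0, lb <= v <= ub}.  The consistency sweep
follows the LP-7 formulation (maximize the number of target reactions
carrying at least ``eps`` flux) with the usual direction-flip handling of
reversible reactions; a naive 2n-LP oracle is shipped alongside for
independent verification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog


class InfeasibleError(RuntimeError):
    """No steady-state flux distribution satisfies the constraints."""


class UnboundedError(RuntimeError):
    """The requested LP objective is unbounded."""


@dataclass(frozen=True)
class EpsilonPolicy:
    """Flux-activation threshold and solver feasibility tolerance.

    ``eps`` is the smallest flux magnitude counted as "carrying flux";
    anything below is numerically zero.  It must dominate the solver
    tolerance by a comfortable margin (>=100x).
    """

    eps: float = 1e-4
    feasibility_tol: float = 1e-9

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.eps < 100 * self.feasibility_tol:
            raise ValueError("eps must be >= 100x the solver tolerance")


DEFAULT_POLICY = EpsilonPolicy()


@dataclass(frozen=True)
class FluxRange:
    reaction_id: str
    vmin: float
    vmax: float


def _solve(c, A_eq, b_eq, A_ub, b_ub, bounds):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status == 2:
        raise InfeasibleError("linear program is infeasible")
    if res.status == 3:
        raise UnboundedError("linear program is unbounded")
    if not res.success:
        raise RuntimeError(f"LP solver failure: {res.message}")
    return res


def _steady_state_parts(model):
    A_eq = model.S
    b_eq = np.zeros(model.n_metabolites)
    bounds = list(zip(model.lb, model.ub))
    return A_eq, b_eq, bounds


def fva(model, reactions: Optional[Iterable[str]] = None,
        policy: EpsilonPolicy = DEFAULT_POLICY) -> dict[str, FluxRange]:
    """Per-reaction flux minima/maxima (2 LPs per reaction)."""
    if reactions is None:
        reactions = model.reaction_ids
    A_eq, b_eq, bounds = _steady_state_parts(model)
    n = model.n_reactions
    out = {}
    for rid in reactions:
        j = model.reaction_index(rid)
        c = np.zeros(n)
        c[j] = 1.0
        lo = _solve(c, A_eq, b_eq, None, None, bounds).x[j]
        hi = -_solve(-c, A_eq, b_eq, None, None, bounds).fun
        # clip solver noise so vmin <= vmax and both sit inside the bounds
        lo, hi = min(lo, hi), max(lo, hi)
        out[rid] = FluxRange(rid, float(lo), float(hi))
    return out


def maximize_flux(model, objective: str,
                  policy: EpsilonPolicy = DEFAULT_POLICY) -> float:
    """FBA: LP optimum of one reaction's flux over the steady-state polytope."""
    j = model.reaction_index(objective)
    A_eq, b_eq, bounds = _steady_state_parts(model)
    c = np.zeros(model.n_reactions)
    c[j] = -1.0
    res = _solve(c, A_eq, b_eq, None, None, bounds)
    return float(-res.fun)


def consistent_reactions_oracle(model, policy: EpsilonPolicy = DEFAULT_POLICY
                                ) -> set[str]:
    """Naive 2n-LP blocked-reaction oracle: keep r iff max |v_r| >= eps.

    Independent of the sweep implementation below; used to cross-check it.
    """
    keep = set()
    for rid, fr in fva(model, policy=policy).items():
        if fr.vmax >= policy.eps or fr.vmin <= -policy.eps:
            keep.add(rid)
    return keep


# ---------------------------------------------------------------------------
# LP-7 consistency sweep
# ---------------------------------------------------------------------------

def lp7(S, lb, ub, J: Sequence[int], eps: float) -> np.ndarray:
    """Maximize the number of reactions in J reaching flux >= eps.

    max sum(z)  s.t.  S v = 0,  v_j >= z_j (j in J),  0 <= z <= eps, bounds.
    Returns the flux vector v.
    """
    m, n = S.shape
    k = len(J)
    if k == 0:
        return np.zeros(n)
    c = np.concatenate([np.zeros(n), -np.ones(k)])
    A_eq = sparse.hstack([S, sparse.csc_matrix((m, k))], format="csc")
    b_eq = np.zeros(m)
    # z_j - v_j <= 0
    rows = np.arange(k)
    Az = sparse.csc_matrix((np.ones(k), (rows, rows)), shape=(k, k))
    Av = sparse.csc_matrix((-np.ones(k), (rows, np.asarray(J))), shape=(k, n))
    A_ub = sparse.hstack([Av, Az], format="csc")
    b_ub = np.zeros(k)
    bounds = list(zip(lb, ub)) + [(0.0, eps)] * k
    res = _solve(c, A_eq, b_eq, A_ub, b_ub, bounds)
    return res.x[:n]


def _flip(S, lb, ub, idx: Sequence[int]):
    """Reverse the orientation of the given reactions (column and bounds)."""
    idx = np.asarray(idx, dtype=int)
    sign = np.ones(S.shape[1])
    sign[idx] = -1.0
    S2 = S @ sparse.diags(sign)
    lb2, ub2 = lb.copy(), ub.copy()
    lb2[idx], ub2[idx] = -ub[idx], -lb[idx]
    return sparse.csc_matrix(S2), lb2, ub2


def fastcc(model, policy: EpsilonPolicy = DEFAULT_POLICY) -> set[str]:
    """Flux-consistent reaction subset via the LP-7 sweep.

    Every returned reaction attains |v| >= eps in some feasible steady
    state; every other reaction is blocked (max |v| < eps).
    """
    n = model.n_reactions
    S = model.S
    lb = model.lb.copy()
    ub = model.ub.copy()
    eps = policy.eps
    tol = 0.99 * eps
    irreversible = set(np.nonzero(~((lb < 0) & (ub > 0)))[0])

    J = sorted(i for i in range(n) if i in irreversible)
    v = lp7(S, lb, ub, J, eps)
    A = set(np.nonzero(np.abs(v) >= tol)[0])
    blocked_irrev = set(J) - A
    J = set(range(n)) - A - blocked_irrev

    flipped = False
    singleton = False
    while J:
        if singleton:
            Ji = [min(J)]
        else:
            Ji = sorted(J)
        v = lp7(S, lb, ub, Ji, eps)
        A |= set(np.nonzero(np.abs(v) >= tol)[0])
        if J & A:
            J -= A
            flipped = False
        else:
            Ji_rev = [i for i in Ji if i not in irreversible]
            if flipped or not Ji_rev:
                flipped = False
                if singleton:
                    J -= set(Ji)  # genuinely blocked
                else:
                    singleton = True
            else:
                S, lb, ub = _flip(S, lb, ub, Ji_rev)
                flipped = True
    return {model.reaction_ids[i] for i in sorted(A)}
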
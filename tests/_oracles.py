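"""Independent brute-force oracles used to verify the package's algorithms.

These deliberately avoid the package's LP code paths: they call scipy
directly and enumerate exhaustively where feasible.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Optional

import numpy as np
from scipy.optimize import linprog
from scipy.special import comb


def flux_extremum(model, rid: str, sense: str) -> float:
    """Direct scipy LP for min/max of one reaction's flux."""
    j = model.reaction_index(rid)
    n = model.n_reactions
    c = np.zeros(n)
    c[j] = 1.0 if sense == "min" else -1.0
    res = linprog(c, A_eq=model.S, b_eq=np.zeros(model.n_metabolites),
                  bounds=list(zip(model.lb, model.ub)), method="highs")
    assert res.status == 0, res.message
    return res.x[j] if sense == "min" else -res.fun


def blocked_oracle(model, eps: float = 1e-4) -> set[str]:
    """Reactions unable to reach |v| >= eps (2 LPs per reaction)."""
    blocked = set()
    for rid in model.reaction_ids:
        vmax = flux_extremum(model, rid, "max")
        vmin = flux_extremum(model, rid, "min")
        if vmax < eps and vmin > -eps:
            blocked.add(rid)
    return blocked


def consistent_oracle(model, eps: float = 1e-4) -> set[str]:
    return set(model.reaction_ids) - blocked_oracle(model, eps)


def is_consistent_set(model, reactions: set[str], eps: float = 1e-4) -> bool:
    """Every reaction of the subset carries |v| >= eps in the submodel."""
    if not reactions:
        return True
    sub = model.restrict(reactions)
    return not blocked_oracle(sub, eps)


def minimal_supports(model, core: set[str], eps: float = 1e-4,
                     weights: Optional[dict[str, float]] = None,
                     forced: Iterable[str] = ()) -> tuple[float, list[set[str]]]:
    """Exhaustive search for minimum-cost consistent supersets of the core.

    Cost of a candidate set = sum of ``weights`` over its non-core members
    (default weight 1 each).  ``forced`` reactions must be included and
    carry flux.  Returns (min cost, all optimal sets).
    """
    core = set(core) | set(forced)
    others = sorted(set(model.reaction_ids) - core)
    if weights is None:
        weights = {r: 1.0 for r in others}
    best_cost = None
    best_sets: list[set[str]] = []
    for size in range(len(others) + 1):
        for extra in itertools.combinations(others, size):
            cost = sum(weights.get(r, 1.0) for r in extra)
            if best_cost is not None and cost > best_cost:
                continue
            candidate = core | set(extra)
            if not is_consistent_set(model, candidate, eps):
                continue
            if best_cost is None or cost < best_cost:
                best_cost = cost
                best_sets = [candidate]
            elif cost == best_cost:
                best_sets.append(candidate)
    assert best_cost is not None, "no consistent superset exists"
    return best_cost, best_sets


def gpr_truth_table(rule, genes: list[str]):
    """All evaluations of a rule over {-1,0,1}^k via a direct evaluator."""

    def evaluate(node, assignment):
        if node.op == "gene":
            return assignment[node.gene]
        vals = [evaluate(c, assignment) for c in node.children]
        return min(vals) if node.op == "and" else max(vals)

    for values in itertools.product((-1, 0, 1), repeat=len(genes)):
        assignment = dict(zip(genes, values))
        yield assignment, evaluate(rule, assignment)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exact enumeration over combinations."""
    total = comb(N, n, exact=True)
    hits = 0
    for kk in range(k, min(K, n) + 1):
        hits += comb(K, kk, exact=True) * comb(N - K, n - kk, exact=True)
    return hits / total


def overlap_bruteforce(a, b) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end
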
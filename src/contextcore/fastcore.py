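"""Context extraction: FASTCORE and its weighted variant with
non-penalized and forced reaction sets.

The extraction alternates two LPs: LP-7 activates as many unsupported core
reactions as possible, LP-9 then finds a sparse (L1-minimal over penalized
reactions) flux mode supporting them.  Non-penalized reactions enter LP-9
with zero weight, so among equal-topology alternatives the solver prefers
supports routed through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import sparse

from .consistency import (DEFAULT_POLICY, EpsilonPolicy, InfeasibleError,
                          _flip, _solve, lp7)

SCALE = 1e5  # LP-9 bound/threshold scaling of the FASTCORE lineage


class UnrecoverableCoreError(RuntimeError):
    """A core (or forced) reaction cannot be given flux in the input model."""


@dataclass
class CoreSets:
    """Partition of reactions driving the extraction.

    core: must appear in the output; inactive: evidence of absence (bounds
    zeroed upstream); non_penalized: free to include (weight 0); forced:
    must carry flux (e.g. biomass).  Everything else is penalized non-core.
    """

    core: set[str] = field(default_factory=set)
    inactive: set[str] = field(default_factory=set)
    non_penalized: set[str] = field(default_factory=set)
    forced: set[str] = field(default_factory=set)

    def validate(self, model) -> None:
        for name, ids in (("core", self.core), ("inactive", self.inactive),
                          ("non_penalized", self.non_penalized),
                          ("forced", self.forced)):
            unknown = [r for r in ids if r not in model._rxn_index]
            if unknown:
                raise KeyError(f"{name} reaction {unknown[0]!r} not in model")
        overlap = self.core & self.inactive
        if overlap:
            raise ValueError(
                f"core and inactive sets overlap: {sorted(overlap)[:3]}")


def _lp9(S, lb, ub, K, P, weights, eps):
    """min sum_{i in P} w_i |v_i|  s.t.  S v = 0, v_K >= eps*SCALE, bounds*SCALE."""
    m, n = S.shape
    K = np.asarray(sorted(K), dtype=int)
    P = np.asarray(sorted(P), dtype=int)
    npen = len(P)
    if len(K) == 0:
        return np.zeros(n)
    c = np.concatenate([np.zeros(n), np.asarray([weights[i] for i in P])])
    A_eq = sparse.hstack([S, sparse.csc_matrix((m, npen))], format="csc")
    b_eq = np.zeros(m)
    rows = np.arange(npen)
    Iv = sparse.csc_matrix((np.ones(npen), (rows, P)), shape=(npen, n))
    Iz = sparse.csc_matrix((np.ones(npen), (rows, rows)), shape=(npen, npen))
    blocks = [
        sparse.hstack([Iv, -Iz]),    # v_p - z_p <= 0
        sparse.hstack([-Iv, -Iz]),   # -v_p - z_p <= 0
    ]
    rows_k = np.arange(len(K))
    Ik = sparse.csc_matrix((-np.ones(len(K)), (rows_k, K)), shape=(len(K), n))
    blocks.append(sparse.hstack(
        [Ik, sparse.csc_matrix((len(K), npen))]))  # -v_k <= -eps*SCALE
    A_ub = sparse.vstack(blocks, format="csc")
    b_ub = np.concatenate([np.zeros(2 * npen),
                           -np.full(len(K), eps * SCALE)])
    zmax = np.maximum(np.abs(lb[P]), np.abs(ub[P])) * SCALE if npen else np.array([])
    bounds = list(zip(lb * SCALE, ub * SCALE)) + list(zip(np.zeros(npen), zmax))
    res = _solve(c, A_eq, b_eq, A_ub, b_ub, bounds)
    return res.x[:n]


def _find_sparse_mode(S, lb, ub, J, P, weights, singleton, eps):
    """One LP-7/LP-9 round: activate core reactions J, support them sparsely."""
    if not J:
        return set()
    target = [min(J)] if singleton else sorted(J)
    v = lp7(S, lb, ub, target, eps)
    K = {i for i in target if v[i] >= 0.99 * eps}
    if not K:
        return set()
    v = _lp9(S, lb, ub, K, P, weights, eps)
    return set(np.nonzero(np.abs(v) >= 0.99 * eps)[0])


def _extract(model, core_idx: set[int], weights: np.ndarray,
             policy: EpsilonPolicy) -> set[int]:
    """Weighted FASTCORE over reaction indices; weights[i]=0 means free."""
    n = model.n_reactions
    S = model.S
    lb = model.lb.copy()
    ub = model.ub.copy()
    eps = policy.eps
    irreversible = set(np.nonzero(~((lb < 0) & (ub > 0)))[0])
    penalized = {i for i in range(n) if weights[i] > 0 and i not in core_idx}

    J = core_idx & irreversible
    P = set(penalized)
    A = _find_sparse_mode(S, lb, ub, J, P, weights, False, eps)
    missing = J - A
    if missing:
        rid = model.reaction_ids[min(missing)]
        raise UnrecoverableCoreError(
            f"irreversible core reaction {rid!r} cannot carry flux")
    J = core_idx - A

    flipped = False
    singleton = False
    while J:
        P -= A
        supp = _find_sparse_mode(S, lb, ub, J, P, weights, singleton, eps)
        A |= supp
        if J & A:
            J -= A
            flipped = False
            singleton = False
        else:
            Ji = {min(J)} if singleton else J
            Ji_rev = [i for i in Ji if i not in irreversible]
            if flipped or not Ji_rev:
                if singleton:
                    rid = model.reaction_ids[min(J)]
                    raise UnrecoverableCoreError(
                        f"core reaction {rid!r} cannot carry flux")
                flipped = False
                singleton = True
            else:
                S, lb, ub = _flip(S, lb, ub, Ji_rev)
                flipped = True
    return A


def fastcore_extract(model, core: Iterable[str],
                     policy: EpsilonPolicy = DEFAULT_POLICY) -> set[str]:
    """Close-to-minimal consistent superset of the core reaction set.

    The input model must be flux-consistent and ``core`` a subset of its
    reactions; a blocked core reaction raises
    :class:`UnrecoverableCoreError`.
    """
    core = set(core)
    if not core:
        return set()
    core_idx = {model.reaction_index(r) for r in core}
    weights = np.ones(model.n_reactions)
    for i in core_idx:
        weights[i] = 0.0
    out = _extract(model, core_idx, weights, policy)
    return {model.reaction_ids[i] for i in out} | core


def modified_fastcore(model, sets: CoreSets,
                      policy: EpsilonPolicy = DEFAULT_POLICY) -> set[str]:
    """FASTCORE with zero-cost (non-penalized) and forced reaction sets.

    Forced reactions behave like core (they must carry flux); non-penalized
    reactions cost nothing in the sparsity step but are not forced.
    Reduces to :func:`fastcore_extract` when both extra sets are empty.
    """
    sets.validate(model)
    effective_core = set(sets.core) | set(sets.forced)
    if not effective_core:
        return set()
    core_idx = {model.reaction_index(r) for r in effective_core}
    weights = np.ones(model.n_reactions)
    for rid in sets.non_penalized:
        weights[model.reaction_index(rid)] = 0.0
    for i in core_idx:
        weights[i] = 0.0
    try:
        out = _extract(model, core_idx, weights, policy)
    except UnrecoverableCoreError as exc:
        forced_idx = {model.reaction_index(r) for r in sets.forced}
        if any(model.reaction_ids[i] in str(exc) for i in forced_idx):
            raise InfeasibleError(str(exc)) from exc
        raise
    return {model.reaction_ids[i] for i in out} | effective_core
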
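"""Comparative and statistical analyses over context models.

Covers Jaccard similarity with hierarchical clustering, per-subsystem
activity and regulation scores, expression-rank queries, FBA gene
knockouts with the >1 % growth-decrease essentiality rule, rank-set
enrichment (KS + permutation null) and the exact hypergeometric upper
tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .consistency import DEFAULT_POLICY, EpsilonPolicy, maximize_flux
from .model_io import MetabolicModel

ESSENTIALITY_THRESHOLD = 0.01  # fractional growth decrease


@dataclass
class JaccardMatrix:
    model_ids: list[str]
    values: np.ndarray           # symmetric, unit diagonal
    cluster_order: list[int]     # leaf order of average-linkage clustering

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.model_ids,
                            columns=self.model_ids)


def jaccard_matrix(models: Sequence, ids: Optional[Sequence[str]] = None
                   ) -> JaccardMatrix:
    """Pairwise Jaccard index of retained-reaction sets, plus cluster order.

    ``models`` may be ContextModel instances or plain reaction-id sets.
    """
    sets = [m.retained if hasattr(m, "retained") else set(m) for m in models]
    if ids is None:
        ids = [f"model_{i}" for i in range(len(sets))]
    n = len(sets)
    J = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = sets[i] | sets[j]
            J[i, j] = J[j, i] = (
                len(sets[i] & sets[j]) / len(union) if union else 1.0)
    if n > 2:
        dist = squareform(1.0 - J, checks=False)
        link = hierarchy.linkage(dist, method="average")
        order = list(hierarchy.leaves_list(link))
    else:
        order = list(range(n))
    return JaccardMatrix(model_ids=list(ids), values=J, cluster_order=order)


def pathway_activity(context, min_reactions: int = 1) -> dict[str, float]:
    """Retained fraction of each parent subsystem ([0, 1] per subsystem).

    Subsystems with fewer than ``min_reactions`` reactions in the parent
    model are excluded (the customary cut is 4 for plotting).
    """
    parent: MetabolicModel = context.parent
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for rid, subsystem in zip(parent.reaction_ids, parent.subsystem):
        if not subsystem:
            continue
        totals[subsystem] = totals.get(subsystem, 0) + 1
        if rid in context.retained:
            hits[subsystem] = hits.get(subsystem, 0) + 1
    return {p: hits.get(p, 0) / t for p, t in totals.items()
            if t >= min_reactions}


def pathway_regulation(context, up: set[str], down: set[str]) -> dict[str, float]:
    """(|up ∩ P| - |down ∩ P|) / |P| per subsystem P of the parent model."""
    parent: MetabolicModel = context.parent
    members: dict[str, list[str]] = {}
    for rid, subsystem in zip(parent.reaction_ids, parent.subsystem):
        if subsystem:
            members.setdefault(subsystem, []).append(rid)
    out = {}
    for subsystem, rids in members.items():
        n_up = sum(1 for r in rids if r in up)
        n_down = sum(1 for r in rids if r in down)
        out[subsystem] = (n_up - n_down) / len(rids)
    return out


def condition_rank(expr: pd.DataFrame, gene: str, condition: str) -> float:
    """1-based rank of a condition for a gene (highest expression = rank 1).

    ``expr`` is gene x condition (replicates already averaged); ties get
    the average rank.
    """
    row = expr.loc[gene]
    ranks = row.rank(ascending=False, method="average")
    return float(ranks[condition])


def aggregate_conditions(expr: pd.DataFrame,
                         sample_to_condition: dict[str, str]) -> pd.DataFrame:
    """Mean expression per condition from per-sample columns."""
    groups = pd.Series(sample_to_condition)
    return expr.T.groupby(groups).mean().T


# ---------------------------------------------------------------------------
# Essentiality
# ---------------------------------------------------------------------------

@dataclass
class EssentialityResult:
    wild_type_growth: float
    knockout_growth: dict[str, float]
    decrease: dict[str, float]
    essential: set[str]

    def as_frame(self) -> pd.DataFrame:
        genes = sorted(self.knockout_growth)
        return pd.DataFrame({
            "gene": genes,
            "wild_type": self.wild_type_growth,
            "knockout": [self.knockout_growth[g] for g in genes],
            "decrease": [self.decrease[g] for g in genes],
            "essential": [g in self.essential for g in genes],
        }).set_index("gene")


def knockout_bounds(model: MetabolicModel, gene: str) -> MetabolicModel:
    """Zero the bounds of reactions whose GPR is false without the gene."""
    out = model.copy()
    for j, rule in enumerate(model.gpr):
        if rule is None or gene not in rule.genes():
            continue
        if not rule.evaluate_bool({gene: False}, default=True):
            out.lb[j] = 0.0
            out.ub[j] = 0.0
    return out


def gene_knockouts(model: MetabolicModel, biomass: str,
                   genes: Optional[Iterable[str]] = None,
                   policy: EpsilonPolicy = DEFAULT_POLICY
                   ) -> EssentialityResult:
    """Single-gene FBA knockouts; essential iff growth drops by > 1 %."""
    wt = maximize_flux(model, biomass, policy)
    if genes is None:
        genes = sorted(model.genes())
    ko_growth: dict[str, float] = {}
    decrease: dict[str, float] = {}
    essential: set[str] = set()
    for gene in genes:
        ko = knockout_bounds(model, gene)
        growth = maximize_flux(ko, biomass, policy)
        ko_growth[gene] = growth
        frac = 0.0 if wt <= 0 else max(0.0, (wt - growth) / wt)
        decrease[gene] = frac
        if frac > ESSENTIALITY_THRESHOLD:
            essential.add(gene)
    return EssentialityResult(wt, ko_growth, decrease, essential)


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def rank_set_enrichment(member_ranks: Sequence[float],
                        other_ranks: Sequence[float],
                        n_null: int = 10_000,
                        set_size: Optional[int] = None,
                        seed: int = 0) -> tuple[float, float, float]:
    """Two-sample KS test plus a permutation null over random same-size sets.

    Returns (D, analytic p, empirical p).  The empirical p is the fraction
    of ``n_null`` random draws of ``set_size`` ranks from the pooled list
    whose KS statistic reaches the observed one.
    """
    member = np.asarray(member_ranks, dtype=float)
    other = np.asarray(other_ranks, dtype=float)
    if member.size == 0 or other.size == 0:
        raise ValueError("both rank sets must be non-empty")
    if set_size is None:
        set_size = member.size
    ks = stats.ks_2samp(member, other)
    d_obs = float(ks.statistic)

    pooled = np.concatenate([member, other])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_null):
        perm = rng.permutation(pooled)
        d = stats.ks_2samp(perm[:set_size], perm[set_size:]).statistic
        if d >= d_obs:
            hits += 1
    return d_obs, float(ks.pvalue), hits / n_null


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or n > N or K > N:
        raise ValueError(f"invalid hypergeometric counts N={N}, K={K}, "
                         f"n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))
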
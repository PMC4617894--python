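"""Pipeline orchestration: core-set construction from reaction scores,
medium constraining, two-pass extraction with optional biomass forcing,
and leave-one-out cross-validation of the retained reactions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import sparse

from . import topology
from .consistency import DEFAULT_POLICY, EpsilonPolicy, fastcc
from .fastcore import CoreSets, modified_fastcore
from .model_io import MetabolicModel

logger = logging.getLogger(__name__)

CONF_HIGH = "high"
CONF_MODERATE = "moderate"
CONF_LOW = "low"
EXCL_MULTI = "multi-evidence"
EXCL_SINGLE = "single-evidence"


@dataclass
class MediumSpec:
    """Metabolites available in the growth medium (model metabolite ids)."""

    metabolites: list[str]

    @classmethod
    def from_file(cls, path: str) -> "MediumSpec":
        with open(path) as fh:
            mets = [line.strip() for line in fh
                    if line.strip() and not line.startswith("#")]
        return cls(mets)


@dataclass
class ContextModel:
    """Retained reaction subset of a parent model plus confidence labels."""

    parent: MetabolicModel
    retained: set[str]
    confidence: dict[str, str] = field(default_factory=dict)
    excluded_support: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def restricted_model(self) -> MetabolicModel:
        return self.parent.restrict(self.retained)

    def confidence_summary(self) -> dict[str, float]:
        n = len(self.retained)
        if n == 0:
            return {CONF_HIGH: 0.0, CONF_MODERATE: 0.0, CONF_LOW: 0.0}
        out = {}
        for label in (CONF_HIGH, CONF_MODERATE, CONF_LOW):
            out[label] = sum(
                1 for r in self.retained if self.confidence.get(r) == label) / n
        return out


def build_core_sets(model: MetabolicModel, reaction_scores: Mapping[str, int],
                    transporters: Optional[set[str]] = None) -> CoreSets:
    """Split scored reactions into core / non-penalized / inactive sets.

    Score +1 -> core, except transporters which go to the non-penalized set
    (promiscuous transport genes would otherwise drag whole subsystems into
    the core).  Score -1 -> inactive.
    """
    if transporters is None:
        transporters = topology.classify_transporters(model)
    core, non_pen, inactive = set(), set(), set()
    for rid, score in reaction_scores.items():
        if score == 1:
            (non_pen if rid in transporters else core).add(rid)
        elif score == -1:
            inactive.add(rid)
    return CoreSets(core=core, inactive=inactive, non_penalized=non_pen)


def exchange_reactions(model: MetabolicModel) -> dict[str, str]:
    """Boundary (single-metabolite) reactions, mapped to their metabolite."""
    out = {}
    S = model.S.tocsc()
    for j, rid in enumerate(model.reaction_ids):
        col = S[:, j]
        if col.nnz == 1:
            out[rid] = model.metabolite_ids[col.indices[0]]
    return out


def apply_medium(model: MetabolicModel, medium: MediumSpec,
                 policy: EpsilonPolicy = DEFAULT_POLICY,
                 add_missing_exchanges: bool = True,
                 uptake_bound: float = 1000.0) -> MetabolicModel:
    """Close uptake for metabolites absent from the medium, then re-prune.

    Exchange reactions of metabolites not listed in the medium lose their
    uptake direction; medium metabolites lacking an exchange reaction get
    one added on demand.  The result is the flux-consistent submodel under
    the new bounds.
    """
    present = set(medium.metabolites)
    unknown = present - set(model.metabolite_ids)
    if unknown:
        warnings.warn(f"medium metabolites not in model, skipped: "
                      f"{sorted(unknown)[:5]}")
        present -= unknown

    out = model.copy()
    boundary = exchange_reactions(out)
    S = out.S.tocsc()
    for rid, met in boundary.items():
        if met in present:
            continue
        j = out.reaction_index(rid)
        coef = S[:, j].data[0]
        # uptake = flux direction that produces the metabolite internally
        if coef < 0:
            out.lb[j] = max(out.lb[j], 0.0)
        else:
            out.ub[j] = min(out.ub[j], 0.0)

    if add_missing_exchanges:
        covered = {met for met in boundary.values()}
        missing = [m for m in sorted(present) if m not in covered]
        for met in missing:
            out = _add_exchange(out, met, uptake_bound)

    keep = fastcc(out, policy)
    return out.restrict(keep)


def _add_exchange(model: MetabolicModel, met: str,
                  uptake_bound: float) -> MetabolicModel:
    i = model.metabolite_ids.index(met)
    col = sparse.csc_matrix(([-1.0], ([i], [0])),
                            shape=(model.n_metabolites, 1))
    rid = f"EX_{met}"
    if rid in model._rxn_index:
        rid = f"EX_{met}_medium"
    return MetabolicModel(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=list(model.reaction_ids) + [rid],
        S=sparse.hstack([model.S, col], format="csc"),
        lb=np.append(model.lb, -abs(uptake_bound)),
        ub=np.append(model.ub, abs(uptake_bound)),
        gpr=list(model.gpr) + [None],
        subsystem=list(model.subsystem) + ["Exchange/demand reaction"],
        compartment=dict(model.compartment),
        objective=model.objective,
    )


def _consistent_after_inactive(model: MetabolicModel, sets: CoreSets,
                               policy: EpsilonPolicy):
    """Zero inactive bounds, re-prune, and project the sets onto the result."""
    work = model.copy()
    for rid in sets.inactive:
        j = work.reaction_index(rid)
        work.lb[j] = 0.0
        work.ub[j] = 0.0
    keep = fastcc(work, policy)
    sub = work.restrict(keep)
    dropped_core = sets.core - keep
    if dropped_core:
        logger.info("core reactions blocked after inactive removal: %s",
                    sorted(dropped_core))
    projected = CoreSets(
        core=sets.core & keep,
        inactive=set(),
        non_penalized=sets.non_penalized & keep,
        forced=set(sets.forced),
    )
    return sub, projected


def reconstruct(model: MetabolicModel, core_sets: CoreSets,
                biomass: Optional[str] = None,
                policy: EpsilonPolicy = DEFAULT_POLICY,
                transporters: Optional[set[str]] = None,
                extra_forced: Iterable[str] = ()) -> ContextModel:
    """Run the two-pass extraction and return a :class:`ContextModel`.

    With a biomass reaction: pass 1 forces biomass while treating all
    expression-supported reactions as non-penalized; its output joins the
    core for pass 2, which forces every core reaction (transporters stay
    out of the core but cost nothing).  Without biomass a single extraction
    is run.  Confidence labels here are provisional (expression-supported
    -> moderate, support-only -> low); :func:`crossvalidate` refines them.
    """
    core_sets.validate(model)
    if transporters is None:
        transporters = topology.classify_transporters(model)
    sub, sets = _consistent_after_inactive(model, core_sets, policy)
    forced = set(extra_forced)
    if biomass is not None:
        forced.add(biomass)

    if not sets.core and not sets.non_penalized and not forced:
        warnings.warn("no expression-supported reactions; empty context model")
        return ContextModel(parent=model, retained=set(),
                            provenance=_provenance(core_sets, biomass, policy))

    if forced:
        missing = forced - set(sub.reaction_ids)
        if missing:
            raise KeyError(f"forced reaction(s) blocked or absent after "
                           f"inactive removal: {sorted(missing)}")
        pass1 = modified_fastcore(sub, CoreSets(
            core=set(),
            non_penalized=sets.core | sets.non_penalized,
            forced=forced,
        ), policy)
        core2 = (sets.core | pass1) - transporters - forced
        non_pen2 = sets.non_penalized | ((pass1 | sets.core) & transporters)
        retained = modified_fastcore(sub, CoreSets(
            core=core2, non_penalized=non_pen2, forced=forced), policy)
    else:
        retained = modified_fastcore(sub, sets, policy)

    supported = sets.core | sets.non_penalized
    confidence = {
        r: (CONF_MODERATE if r in supported else CONF_LOW) for r in retained}
    return ContextModel(
        parent=model,
        retained=retained,
        confidence=confidence,
        provenance=_provenance(core_sets, biomass, policy),
    )


def _provenance(sets: CoreSets, biomass, policy) -> dict:
    return {
        "eps": policy.eps,
        "n_core": len(sets.core),
        "n_non_penalized": len(sets.non_penalized),
        "n_inactive": len(sets.inactive),
        "biomass": biomass,
    }


def crossvalidate(model: MetabolicModel, core_sets: CoreSets,
                  biomass: Optional[str] = None,
                  policy: EpsilonPolicy = DEFAULT_POLICY,
                  transporters: Optional[set[str]] = None,
                  max_folds: Optional[int] = None,
                  seed: int = 0,
                  label_excluded: bool = True) -> ContextModel:
    """Leave-one-out confidence labels for a reconstruction.

    high: present in every leave-one-core-reaction-out rebuild (supported
    by >=2 core reactions); moderate: core reactions absent from their own
    left-out run (supported by their expression only); low: the rest.
    Optionally the analogous loop over the inactive set labels exclusions
    as multi- vs single-evidence.
    """
    if transporters is None:
        transporters = topology.classify_transporters(model)
    base = reconstruct(model, core_sets, biomass, policy, transporters)
    core = sorted(core_sets.core)
    folds = core
    if max_folds is not None and len(core) > max_folds:
        rng = np.random.default_rng(seed)
        folds = sorted(rng.choice(core, size=max_folds, replace=False))

    in_all = set(base.retained)
    moderate: set[str] = set()
    for left_out in folds:
        loo_sets = CoreSets(
            core=core_sets.core - {left_out},
            inactive=set(core_sets.inactive),
            non_penalized=set(core_sets.non_penalized),
            forced=set(core_sets.forced),
        )
        run = reconstruct(model, loo_sets, biomass, policy, transporters)
        in_all &= run.retained
        if left_out not in run.retained:
            moderate.add(left_out)

    confidence = {}
    for rid in base.retained:
        if rid in moderate:
            confidence[rid] = CONF_MODERATE
        elif rid in in_all and folds:
            confidence[rid] = CONF_HIGH
        elif rid in core_sets.core or rid in core_sets.non_penalized:
            confidence[rid] = CONF_MODERATE
        else:
            confidence[rid] = CONF_LOW
    base.confidence = confidence

    if label_excluded and core_sets.inactive:
        excluded = {}
        for rid in sorted(core_sets.inactive):
            loo_sets = CoreSets(
                core=set(core_sets.core),
                inactive=core_sets.inactive - {rid},
                non_penalized=set(core_sets.non_penalized),
                forced=set(core_sets.forced),
            )
            run = reconstruct(model, loo_sets, biomass, policy, transporters)
            excluded[rid] = EXCL_SINGLE if rid in run.retained else EXCL_MULTI
        base.excluded_support = excluded
    return base
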
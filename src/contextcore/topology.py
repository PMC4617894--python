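"""Network-position analysis: transporter classification, FVA-based flux
directions, pathway entry-point detection with cofactor filtering, and
hypergeometric positional enrichment of high-regulatory-load reactions.

An entry point is the first reaction encountered after a pathway change
(or, via a transporter, a compartment change), following the directions in
which each reaction can actually carry flux.  Cofactor couples, inorganic
species and CO2 are ignored when tracing metabolite provenance, and
reactions built solely from such species are skipped outright.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .consistency import DEFAULT_POLICY, EpsilonPolicy, fva
from .model_io import MetabolicModel

CLASS_TRANSPORTER = "transporter"
CLASS_ENTRY_PATHWAY = "entry_pathway_change"
CLASS_ENTRY_COMPARTMENT = "entry_compartment_change"
CLASS_INTERNAL = "internal"

DIR_FORWARD = "forward"
DIR_BACKWARD = "backward"
DIR_BOTH = "both"
DIR_BLOCKED = "blocked"

# Default cofactor configuration (species names, compartment-stripped).
# Overridable; downstream results depend on this list.
DEFAULT_COFACTOR_PAIRS = [
    ("atp", "adp"), ("adp", "amp"), ("atp", "amp"),
    ("gtp", "gdp"), ("utp", "udp"), ("ctp", "cdp"),
    ("nad", "nadh"), ("nadp", "nadph"), ("fad", "fadh2"),
    ("gln_L", "glu_L"),
    ("accoa", "coa"),
]
DEFAULT_INORGANIC = [
    "h", "h2o", "pi", "ppi", "o2", "h2o2", "nh4", "na1", "k", "cl",
    "ca2", "mg2", "fe2", "fe3", "zn2", "so4", "hco3",
]
DEFAULT_CO2 = ["co2"]


@dataclass
class CofactorConfig:
    """Cofactor couples and small species excluded from provenance tracing."""

    pairs: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_COFACTOR_PAIRS))
    inorganic: list[str] = field(default_factory=lambda: list(DEFAULT_INORGANIC))
    co2: list[str] = field(default_factory=lambda: list(DEFAULT_CO2))
    acetyl_coa_donor_rule: bool = True
    filter_equal_formula: bool = True
    formulas: dict[str, str] = field(default_factory=dict)

    @classmethod
    def disabled(cls) -> "CofactorConfig":
        return cls(pairs=[], inorganic=[], co2=[],
                   acetyl_coa_donor_rule=False, filter_equal_formula=False)


@dataclass
class EntryPointAnnotation:
    """Per gene-associated reaction: positional class and flux direction."""

    classes: dict[str, str]
    directions: dict[str, str]

    def of_class(self, cls: str) -> set[str]:
        return {r for r, c in self.classes.items() if c == cls}

    @property
    def transporters(self) -> set[str]:
        return self.of_class(CLASS_TRANSPORTER)

    @property
    def entry_points(self) -> set[str]:
        return (self.of_class(CLASS_ENTRY_PATHWAY)
                | self.of_class(CLASS_ENTRY_COMPARTMENT))


def classify_transporters(model: MetabolicModel) -> set[str]:
    """Reactions moving at least one chemical species between compartments.

    A species is matched by its compartment-stripped identifier appearing
    as substrate in one compartment and product in another.
    """
    out = set()
    S = model.S.tocsc()
    for j, rid in enumerate(model.reaction_ids):
        col = S[:, j]
        consumed: dict[str, set[str]] = {}
        produced: dict[str, set[str]] = {}
        for i, coef in zip(col.indices, col.data):
            mid = model.metabolite_ids[i]
            species = model.species_of(mid)
            comp = model.compartment[mid]
            side = consumed if coef < 0 else produced
            side.setdefault(species, set()).add(comp)
        for species, comps_in in consumed.items():
            comps_out = produced.get(species)
            if comps_out and (comps_out - comps_in or comps_in - comps_out):
                out.add(rid)
                break
    return out


def flux_directions(model: MetabolicModel,
                    policy: EpsilonPolicy = DEFAULT_POLICY,
                    reactions: Optional[Iterable[str]] = None
                    ) -> dict[str, str]:
    """FVA-derived feasible flux direction per reaction."""
    ranges = fva(model, reactions, policy)
    out = {}
    for rid, fr in ranges.items():
        fwd = fr.vmax >= policy.eps
        bwd = fr.vmin <= -policy.eps
        if fwd and bwd:
            out[rid] = DIR_BOTH
        elif fwd:
            out[rid] = DIR_FORWARD
        elif bwd:
            out[rid] = DIR_BACKWARD
        else:
            out[rid] = DIR_BLOCKED
    return out


def _reaction_sides(model: MetabolicModel, j: int, direction: str):
    """(consumed, produced) metabolite-index lists for one orientation."""
    col = model.S.tocsc()[:, j]
    consumed, produced = [], []
    for i, coef in zip(col.indices, col.data):
        if direction == DIR_FORWARD:
            (consumed if coef < 0 else produced).append(i)
        else:
            (consumed if coef > 0 else produced).append(i)
    return consumed, produced


def _cofactor_species(model, j: int, direction: str,
                      config: CofactorConfig) -> set[str]:
    """Species filtered out of reaction j's consumed side."""
    consumed, produced = _reaction_sides(model, j, direction)
    consumed_sp = {model.species_of(model.metabolite_ids[i]) for i in consumed}
    produced_sp = {model.species_of(model.metabolite_ids[i]) for i in produced}
    dropped = set()
    small = set(config.inorganic) | set(config.co2)
    dropped |= consumed_sp & small
    for a, b in config.pairs:
        if a in consumed_sp and b in produced_sp:
            dropped.add(a)
        if b in consumed_sp and a in produced_sp:
            dropped.add(b)
    if config.acetyl_coa_donor_rule:
        if "accoa" in consumed_sp and "coa" in produced_sp:
            dropped.add("accoa")
    if config.filter_equal_formula and config.formulas:
        for a in consumed_sp:
            fa = config.formulas.get(a)
            if fa is None:
                continue
            for b in produced_sp:
                if a != b and config.formulas.get(b) == fa:
                    dropped.add(a)
    return dropped


def _producers(model: MetabolicModel, met_idx: int,
               directions: Mapping[str, str]) -> list[int]:
    """Reactions that can produce the metabolite under feasible directions."""
    row = model.S.tocsr()[met_idx, :]
    out = []
    for j, coef in zip(row.indices, row.data):
        rid = model.reaction_ids[j]
        d = directions.get(rid, DIR_BLOCKED)
        if d == DIR_BLOCKED:
            continue
        if coef > 0 and d in (DIR_FORWARD, DIR_BOTH):
            out.append(j)
        elif coef < 0 and d in (DIR_BACKWARD, DIR_BOTH):
            out.append(j)
    return out


def find_entry_points(model: MetabolicModel,
                      cofactors: Optional[CofactorConfig] = None,
                      policy: EpsilonPolicy = DEFAULT_POLICY,
                      directions: Optional[dict[str, str]] = None
                      ) -> EntryPointAnnotation:
    """Classify every gene-associated reaction by its network position."""
    if cofactors is None:
        cofactors = CofactorConfig()
    if directions is None:
        directions = flux_directions(model, policy)
    transporters = classify_transporters(model)

    classes: dict[str, str] = {}
    gene_rxns = [(j, rid) for j, rid in enumerate(model.reaction_ids)
                 if model.gpr[j] is not None]
    for j, rid in gene_rxns:
        if rid in transporters:
            classes[rid] = CLASS_TRANSPORTER
            continue
        if not model.subsystem[j]:
            warnings.warn(f"reaction {rid!r} lacks subsystem annotation; skipped")
            classes[rid] = CLASS_INTERNAL
            continue
        d = directions.get(rid, DIR_BLOCKED)
        if d == DIR_BLOCKED:
            classes[rid] = CLASS_INTERNAL
            continue
        orientations = [DIR_FORWARD, DIR_BACKWARD] if d == DIR_BOTH else [d]
        call = CLASS_INTERNAL
        for orient in orientations:
            call = _best(call, _classify_orientation(
                model, j, rid, orient, directions, transporters, cofactors))
        classes[rid] = call

    dir_table = {rid: directions.get(rid, DIR_BLOCKED) for _, rid in gene_rxns}
    return EntryPointAnnotation(classes=classes, directions=dir_table)


_PRIORITY = {CLASS_INTERNAL: 0, CLASS_ENTRY_COMPARTMENT: 1,
             CLASS_ENTRY_PATHWAY: 2, CLASS_TRANSPORTER: 3}


def _best(a: str, b: str) -> str:
    return a if _PRIORITY[a] >= _PRIORITY[b] else b


def _classify_orientation(model, j, rid, orient, directions, transporters,
                          config: CofactorConfig) -> str:
    consumed, produced = _reaction_sides(model, j, orient)
    all_species = {model.species_of(model.metabolite_ids[i])
                   for i in consumed + produced}
    small = set(config.inorganic) | set(config.co2)
    paired = {s for pair in config.pairs for s in pair}
    if all_species and all_species <= (small | paired):
        return CLASS_INTERNAL  # pure-cofactor reaction: not considered
    dropped = _cofactor_species(model, j, orient, config)
    subsystem = model.subsystem[j]
    call = CLASS_INTERNAL
    for i in consumed:
        mid = model.metabolite_ids[i]
        if model.species_of(mid) in dropped:
            continue
        for pj in _producers(model, i, directions):
            if pj == j:
                continue
            pid = model.reaction_ids[pj]
            if pid in transporters:
                call = _best(call, _trace_transporter(
                    model, pj, i, subsystem, directions, transporters))
            elif model.subsystem[pj] != subsystem:
                call = _best(call, CLASS_ENTRY_PATHWAY)
    return call


def _trace_transporter(model, tj, met_idx, subsystem, directions,
                       transporters) -> str:
    """Follow a producing transporter back to its origin compartment.

    Producers of the transported species in the origin compartment decide
    the call: same subsystem as the consuming reaction -> compartment
    change, different -> pathway change.
    """
    species = model.species_of(model.metabolite_ids[met_idx])
    tid = model.reaction_ids[tj]
    d = directions.get(tid, DIR_BLOCKED)
    orientations = [DIR_FORWARD, DIR_BACKWARD] if d == DIR_BOTH else [d]
    calls = CLASS_INTERNAL
    for orient in orientations:
        consumed, produced = _reaction_sides(model, tj, orient)
        if met_idx not in produced:
            continue
        origin = [i for i in consumed
                  if model.species_of(model.metabolite_ids[i]) == species]
        for i in origin:
            upstream = [pj for pj in _producers(model, i, directions)
                        if pj != tj]
            if not upstream:
                # fed by nothing traceable (e.g. boundary): treat as cross-
                # pathway supply
                calls = _best(calls, CLASS_ENTRY_PATHWAY)
            for pj in upstream:
                if model.reaction_ids[pj] in transporters:
                    calls = _best(calls, CLASS_ENTRY_COMPARTMENT)
                elif model.subsystem[pj] == subsystem:
                    calls = _best(calls, CLASS_ENTRY_COMPARTMENT)
                else:
                    calls = _best(calls, CLASS_ENTRY_PATHWAY)
    return calls


# ---------------------------------------------------------------------------
# Positional enrichment
# ---------------------------------------------------------------------------

MODE_TRANSPORTERS = "transporters"
MODE_ENTRY_POINTS = "entry_points_excluding_transporters"
MODE_COMBINED = "combined"


def positional_enrichment(annotation: EntryPointAnnotation,
                          hrl_reactions: set[str],
                          mode: str = MODE_COMBINED
                          ) -> tuple[int, int, int, int, float]:
    """Hypergeometric test of HRL reactions concentrating at key positions.

    Returns (N, K, n, k, p) where N is the population of gene-associated
    reactions (transporters excluded in entry-point mode), K the successes
    (transporters / entry points / their union), n the HRL draws and k the
    observed HRL successes.
    """
    from .model_analysis import hypergeom_enrichment

    population = set(annotation.classes)
    transporters = annotation.transporters
    entries = annotation.entry_points
    if mode == MODE_TRANSPORTERS:
        successes = transporters
    elif mode == MODE_ENTRY_POINTS:
        population = population - transporters
        successes = entries
    elif mode == MODE_COMBINED:
        successes = transporters | entries
    else:
        raise ValueError(f"unknown enrichment mode {mode!r}")

    unknown = hrl_reactions - set(annotation.classes)
    if unknown:
        raise ValueError(f"HRL reactions outside the gene-associated "
                         f"population: {sorted(unknown)[:3]}")
    draws = hrl_reactions & population
    N = len(population)
    K = len(successes & population)
    n = len(draws)
    k = len(draws & successes)
    p = hypergeom_enrichment(N, K, n, k)
    return N, K, n, k, p


def write_edge_list(model: MetabolicModel, path: str,
                    cofactors: Optional[CofactorConfig] = None) -> None:
    """Reaction-metabolite bipartite edge list (Cytoscape-loadable TSV)."""
    if cofactors is None:
        cofactors = CofactorConfig.disabled()
    small = set(cofactors.inorganic) | set(cofactors.co2)
    S = model.S.tocoo()
    with open(path, "w") as fh:
        fh.write("source\tinteraction\ttarget\n")
        for i, j, coef in zip(S.row, S.col, S.data):
            mid = model.metabolite_ids[i]
            if model.species_of(mid) in small:
                continue
            rid = model.reaction_ids[j]
            if coef < 0:
                fh.write(f"{mid}\tsubstrate\t{rid}\n")
            else:
                fh.write(f"{rid}\tproduct\t{mid}\n")
    return None
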
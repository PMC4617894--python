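"""Genome-scale model container, SBML read/write, and GPR rule parsing.

The model container is a thin immutable-ish bundle of numpy/scipy arrays
rather than a full-featured modelling object: the LP layers only need
stoichiometry, bounds and annotations.  SBML serialization is delegated to
cobrapy (SBML L3 + fbc on write; fbc or legacy notes on read).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import sparse


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class GPRParseError(ValueError):
    """Raised on malformed GPR strings; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRRule:
    """Boolean gene-association tree.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"``.  Leaves carry the gene
    identifier in ``gene``; internal nodes carry >=2 ``children``.
    """

    op: str
    gene: Optional[str] = None
    children: tuple["GPRRule", ...] = ()

    def __post_init__(self):
        if self.op == "gene":
            if not self.gene:
                raise ValueError("gene leaf requires a non-empty identifier")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"{self.op!r} node requires >=2 children")
        else:
            raise ValueError(f"unknown GPR node type {self.op!r}")

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def evaluate(self, scores: Mapping[str, int], default: int = 0) -> int:
        """Trinary evaluation: AND -> min over children, OR -> max."""
        if self.op == "gene":
            return scores.get(self.gene, default)
        vals = [c.evaluate(scores, default) for c in self.children]
        return min(vals) if self.op == "and" else max(vals)

    def evaluate_bool(self, active: Mapping[str, bool], default: bool = True) -> bool:
        """Boolean evaluation (complex = all, isozymes = any)."""
        if self.op == "gene":
            return active.get(self.gene, default)
        vals = (c.evaluate_bool(active, default) for c in self.children)
        return all(vals) if self.op == "and" else any(vals)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = " and " if self.op == "and" else " or "
        parts = []
        for child in self.children:
            text = child.to_string()
            if child.op != "gene":
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[tuple[str, int]]:
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]


def parse_gpr(text: str) -> Optional[GPRRule]:
    """Parse a GPR string into a :class:`GPRRule`.

    Grammar: OR-chains of AND-chains of atoms; AND binds tighter than OR when
    parentheses are absent.  ``and``/``or`` are case-insensitive; any other
    token is an opaque gene identifier.  Empty/whitespace input -> ``None``.
    """
    tokens = _tokenize(text)
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[tuple[str, int]]:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> tuple[str, int]:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_atom() -> GPRRule:
        tok = peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule", len(text))
        word, at = advance()
        if word == "(":
            node = parse_or()
            closing = peek()
            if closing is None or closing[0] != ")":
                raise GPRParseError("unbalanced parenthesis", at)
            advance()
            return node
        if word == ")":
            raise GPRParseError("unexpected ')'", at)
        if word.lower() in ("and", "or"):
            raise GPRParseError(f"operator {word!r} used as operand", at)
        return GPRRule("gene", gene=word)

    def parse_and() -> GPRRule:
        operands = [parse_atom()]
        while (tok := peek()) is not None and tok[0].lower() == "and":
            advance()
            operands.append(parse_atom())
        if len(operands) == 1:
            return operands[0]
        return GPRRule("and", children=tuple(operands))

    def parse_or() -> GPRRule:
        operands = [parse_and()]
        while (tok := peek()) is not None and tok[0].lower() == "or":
            advance()
            operands.append(parse_and())
        if len(operands) == 1:
            return operands[0]
        return GPRRule("or", children=tuple(operands))

    node = parse_or()
    if pos != len(tokens):
        word, at = tokens[pos]
        raise GPRParseError(f"unexpected token {word!r}", at)
    return node


# ---------------------------------------------------------------------------
# Metabolic model container
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    """Stoichiometric model with bounds, GPRs, subsystems and compartments."""

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sparse.csc_matrix
    lb: np.ndarray
    ub: np.ndarray
    gpr: list[Optional[GPRRule]]
    subsystem: list[str]
    compartment: dict[str, str]
    objective: Optional[str] = None
    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.S = sparse.csc_matrix(self.S)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
        self.validate()
        self._species = {m: self._strip_compartment(m)
                         for m in self.metabolite_ids}

    # -- structural -------------------------------------------------------

    def validate(self) -> None:
        m, n = self.S.shape
        if m != len(self.metabolite_ids):
            raise ModelValidationError(
                f"S has {m} rows but {len(self.metabolite_ids)} metabolites")
        if n != len(self.reaction_ids):
            raise ModelValidationError(
                f"S has {n} columns but {len(self.reaction_ids)} reactions")
        if len(self.lb) != n or len(self.ub) != n:
            raise ModelValidationError("bounds length does not match reactions")
        bad = np.nonzero(self.lb > self.ub)[0]
        if bad.size:
            raise ModelValidationError(
                f"lb > ub for reaction {self.reaction_ids[bad[0]]!r}")
        if len(self.gpr) != n:
            raise ModelValidationError("gpr list length does not match reactions")
        if len(self.subsystem) != n:
            raise ModelValidationError("subsystem list length does not match reactions")
        missing = [mid for mid in self.metabolite_ids if mid not in self.compartment]
        if missing:
            raise ModelValidationError(
                f"metabolite {missing[0]!r} has no compartment annotation")

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def reversible(self) -> np.ndarray:
        return (self.lb < 0) & (self.ub > 0)

    def reaction_index(self, rid: str) -> int:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"reaction {rid!r} not in model") from None

    def indices(self, rids: Iterable[str]) -> np.ndarray:
        return np.array([self.reaction_index(r) for r in rids], dtype=int)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for rule in self.gpr:
            if rule is not None:
                out |= rule.genes()
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            gpr=list(self.gpr),
            subsystem=list(self.subsystem),
            compartment=dict(self.compartment),
            objective=self.objective,
        )

    def restrict(self, rids: Iterable[str]) -> "MetabolicModel":
        """Submodel over a reaction subset; orphan metabolites are dropped."""
        keep = sorted(self.indices(rids))
        S = self.S[:, keep]
        used = np.asarray((abs(S) > 0).sum(axis=1)).ravel() > 0
        rows = np.nonzero(used)[0]
        mets = [self.metabolite_ids[i] for i in rows]
        rxns = [self.reaction_ids[i] for i in keep]
        return MetabolicModel(
            metabolite_ids=mets,
            reaction_ids=rxns,
            S=S[rows, :],
            lb=self.lb[keep],
            ub=self.ub[keep],
            gpr=[self.gpr[i] for i in keep],
            subsystem=[self.subsystem[i] for i in keep],
            compartment={m: self.compartment[m] for m in mets},
            objective=self.objective if self.objective in rxns else None,
        )

    def with_bounds(self, rid: str, lb: float, ub: float) -> "MetabolicModel":
        out = self.copy()
        i = out.reaction_index(rid)
        out.lb[i], out.ub[i] = lb, ub
        out.validate()
        return out

    # -- species/compartment helpers -------------------------------------

    def _strip_compartment(self, met_id: str) -> str:
        comp = self.compartment[met_id]
        for suffix in (f"_{comp}", f"[{comp}]"):
            if met_id.endswith(suffix):
                return met_id[: -len(suffix)]
        return met_id

    def species_of(self, met_id: str) -> str:
        """Compartment-stripped chemical species identifier.

        Cached at construction, so relabeling compartments afterwards does
        not change species identity.
        """
        return self._species.get(met_id, met_id)


# ---------------------------------------------------------------------------
# SBML via cobrapy
# ---------------------------------------------------------------------------

def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model("contextcore_model")
    mets = {}
    for mid in model.metabolite_ids:
        met = cobra.Metabolite(mid, compartment=model.compartment[mid])
        mets[mid] = met
    cm.add_metabolites(list(mets.values()))
    Scoo = model.S.tocoo()
    stoich: dict[int, dict[str, float]] = {j: {} for j in range(model.n_reactions)}
    for i, j, val in zip(Scoo.row, Scoo.col, Scoo.data):
        stoich[j][model.metabolite_ids[i]] = float(val)
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.subsystem = model.subsystem[j]
        reactions.append(rxn)
    cm.add_reactions(reactions)
    for j, rxn in enumerate(reactions):
        rxn.bounds = (float(model.lb[j]), float(model.ub[j]))
        rxn.add_metabolites({mets[m]: v for m, v in stoich[j].items()})
        rule = model.gpr[j]
        if rule is not None:
            rxn.gene_reaction_rule = rule.to_string()
    subsystems: dict[str, list] = {}
    for j, rxn in enumerate(reactions):
        label = model.subsystem[j]
        if label:
            subsystems.setdefault(label, []).append(rxn)
    groups = []
    for k, (label, members) in enumerate(sorted(subsystems.items())):
        gid = re.sub(r"\W", "_", label)
        if not re.match(r"[A-Za-z_]", gid):
            gid = f"g_{gid}"
        groups.append(cobra.core.Group(
            gid, name=label, members=members, kind="partonomy"))
    if groups:
        cm.add_groups(groups)
    if model.objective is not None:
        cm.objective = cm.reactions.get_by_id(model.objective)
    return cm


def _from_cobra(cm) -> MetabolicModel:
    from cobra.util.solver import linear_reaction_coefficients

    met_ids = [m.id for m in cm.metabolites]
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxn_ids = [r.id for r in cm.reactions]
    rows, cols, data = [], [], []
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    gprs: list[Optional[GPRRule]] = []
    subsystems: list[str] = []
    for j, rxn in enumerate(cm.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met, coef in rxn.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            data.append(float(coef))
        gprs.append(parse_gpr(rxn.gene_reaction_rule or ""))
        subsystems.append(rxn.subsystem or "")
    S = sparse.csc_matrix(
        (data, (rows, cols)), shape=(len(met_ids), len(rxn_ids)))
    objective = None
    coeffs = linear_reaction_coefficients(cm)
    if coeffs:
        objective = max(coeffs, key=lambda r: abs(coeffs[r])).id
    return MetabolicModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lb=lb,
        ub=ub,
        gpr=gprs,
        subsystem=subsystems,
        compartment={m.id: (m.compartment or "") for m in cm.metabolites},
        objective=objective,
    )


def _precheck_bounds(path: str) -> None:
    """Check fbc flux bounds before handing the file to cobra, so lb > ub
    errors can name the offending reaction."""
    try:
        import libsbml
    except ImportError:  # pragma: no cover - libsbml ships with cobra
        return
    doc = libsbml.readSBMLFromFile(path)
    sbml_model = doc.getModel()
    if sbml_model is None:
        return
    params = {p.getId(): p.getValue()
              for p in sbml_model.getListOfParameters()}
    for rxn in sbml_model.getListOfReactions():
        fbc = rxn.getPlugin("fbc")
        if fbc is None:
            continue
        lo = params.get(fbc.getLowerFluxBound())
        hi = params.get(fbc.getUpperFluxBound())
        if lo is not None and hi is not None and lo > hi:
            rid = re.sub(r"^R_", "", rxn.getId())
            raise ModelValidationError(
                f"reaction {rid!r} has lower bound {lo} > upper bound {hi}")


def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML file (L2/L3, fbc or note-encoded GPRs) into a model.

    Raises ``IOError`` for unreadable files and
    :class:`ModelValidationError` for structurally inconsistent content
    (e.g. lb > ub), naming the offending reaction.
    """
    import os

    from cobra.io import read_sbml_model

    if not os.path.exists(path):
        raise IOError(f"SBML file not found: {path}")
    _precheck_bounds(path)
    try:
        cm = read_sbml_model(path)
    except ModelValidationError:
        raise
    except Exception as exc:  # cobra raises a zoo of exception types
        messages = []
        cause: Optional[BaseException] = exc
        while cause is not None:
            messages.append(str(cause))
            cause = cause.__cause__ or cause.__context__
        joined = " | ".join(messages)
        if "bound" in joined.lower():
            raise ModelValidationError(joined) from exc
        raise IOError(f"could not parse SBML file {path}: {exc}") from exc
    return _from_cobra(cm)


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML L3 + fbc (GPRs as gene-product associations).

    Output is byte-deterministic: subsystem group members are re-sorted
    after serialization (cobra keeps them in set order).
    """
    from cobra.io import write_sbml_model

    model.validate()
    write_sbml_model(_to_cobra(model), path)
    _canonicalize_groups(path)


def _canonicalize_groups(path: str) -> None:
    try:
        import libsbml
    except ImportError:  # pragma: no cover
        return
    doc = libsbml.readSBMLFromFile(path)
    sbml_model = doc.getModel()
    plugin = sbml_model.getPlugin("groups") if sbml_model else None
    if plugin is None:
        return
    for gi in range(plugin.getNumGroups()):
        group = plugin.getGroup(gi)
        refs = sorted(group.getMember(mi).getIdRef()
                      for mi in range(group.getNumMembers()))
        while group.getNumMembers():
            group.removeMember(0)
        for ref in refs:
            member = group.createMember()
            member.setIdRef(ref)
    # always rewrite so the bytes come from one serializer
    libsbml.writeSBMLToFile(doc, path)
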
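"""Deterministic toy-data generators.

Everything the pipeline consumes — SBML-able toy metabolic networks,
expression z-score tables, replicate ChIP peak sets with a TSS table —
can be generated here with known ground truth, so every stage is testable
without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse

from .model_io import MetabolicModel, parse_gpr
from .regulatory import GenomicInterval


@dataclass
class FixtureSpec:
    """Parameters for the generators; one seed drives all randomness."""

    seed: int = 0
    # toy-model topology
    n_pathways: int = 2
    chain_length: int = 2
    n_blocked: int = 2
    # expression simulation
    n_samples: int = 4
    active_mean: float = 8.0
    active_sd: float = 1.0
    inactive_mean: float = -1.0
    inactive_sd: float = 1.0
    # peak simulation
    gene_loads: dict[str, int] = field(default_factory=dict)
    n_replicates: int = 3
    region_length: int = 200
    jitter: int = 10


def _build(mets, rxns):
    """Assemble a MetabolicModel from literal row specs.

    ``mets``: {met_id: compartment}; ``rxns``: list of
    (rid, {met: coef}, lb, ub, subsystem, gpr_string).
    """
    met_ids = list(mets)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rows, cols, data = [], [], []
    rids, lb, ub, gprs, subsystems = [], [], [], [], []
    for j, (rid, stoich, lo, hi, subsystem, gpr_text) in enumerate(rxns):
        rids.append(rid)
        lb.append(lo)
        ub.append(hi)
        subsystems.append(subsystem)
        gprs.append(parse_gpr(gpr_text))
        for met, coef in stoich.items():
            rows.append(met_index[met])
            cols.append(j)
            data.append(float(coef))
    S = sparse.csc_matrix((data, (rows, cols)),
                          shape=(len(met_ids), len(rids)))
    return MetabolicModel(
        metabolite_ids=met_ids, reaction_ids=rids, S=S,
        lb=np.array(lb, float), ub=np.array(ub, float),
        gpr=gprs, subsystem=subsystems,
        compartment=dict(mets),
    )


def toy1() -> tuple[MetabolicModel, dict]:
    """The canonical 9-reaction, 7-metabolite, 2-compartment network.

    Exchange R_EXA feeds transporter R_TA into a two-step chain R1 -> R2
    (PathX) with a PathY branch R3; C and D have demand outlets.  R4/R4b
    form a dead-end pair (E is never produced) and are blocked.
    """
    mets = {"A_e": "e", "A_c": "c", "B_c": "c", "C_c": "c",
            "D_c": "c", "E_c": "c", "F_c": "c"}
    rxns = [
        ("R_EXA", {"A_e": -1}, -10.0, 1000.0, "Exchange/demand reaction", ""),
        ("R_TA", {"A_e": -1, "A_c": 1}, 0.0, 1000.0,
         "Transport, extracellular", "GT"),
        ("R1", {"A_c": -1, "B_c": 1}, 0.0, 1000.0, "PathX", "G1"),
        ("R2", {"B_c": -1, "C_c": 1}, 0.0, 1000.0, "PathX", "G2"),
        ("R3", {"B_c": -1, "D_c": 1}, 0.0, 1000.0, "PathY", "G3"),
        ("R_EXC", {"C_c": -1}, 0.0, 1000.0, "Exchange/demand reaction", ""),
        ("R_EXD", {"D_c": -1}, 0.0, 1000.0, "Exchange/demand reaction", ""),
        ("R4", {"E_c": -1, "F_c": 1}, 0.0, 1000.0, "PathZ", "G4"),
        ("R4b", {"F_c": -1, "C_c": 1}, 0.0, 1000.0, "PathZ", "G4b"),
    ]
    model = _build(mets, rxns)
    truth = {
        "blocked": {"R4", "R4b"},
        "transporters": {"R_TA"},
        "minimal_support_R2": {"R_EXA", "R_TA", "R1", "R2", "R_EXC"},
        "entry_points": {"R1": "entry_pathway_change",
                         "R3": "entry_pathway_change",
                         "R2": "internal"},
        "intended_active": {"R_EXA", "R_TA", "R1", "R2", "R_EXC"},
        "active_genes": {"GT", "G1", "G2"},
        "inactive_genes": {"G3", "G4", "G4b"},
    }
    return model, truth


def parallel_paths() -> tuple[MetabolicModel, dict]:
    """Two parallel 2-reaction routes from a core source to a core sink."""
    mets = {"A_e": "e", "A_c": "c", "X1_c": "c", "X2_c": "c", "P_c": "c"}
    rxns = [
        ("R_EXA", {"A_e": -1}, -10.0, 1000.0, "Exchange/demand reaction", ""),
        ("R_UP", {"A_e": -1, "A_c": 1}, 0.0, 1000.0,
         "Transport, extracellular", "GT"),
        ("RA1", {"A_c": -1, "X1_c": 1}, 0.0, 1000.0, "PathA", "GA1"),
        ("RA2", {"X1_c": -1, "P_c": 1}, 0.0, 1000.0, "PathA", "GA2"),
        ("RB1", {"A_c": -1, "X2_c": 1}, 0.0, 1000.0, "PathB", "GB1"),
        ("RB2", {"X2_c": -1, "P_c": 1}, 0.0, 1000.0, "PathB", "GB2"),
        ("R_EXP", {"P_c": -1}, 0.0, 1000.0, "Exchange/demand reaction", ""),
    ]
    model = _build(mets, rxns)
    truth = {
        "core": {"R_UP", "R_EXP"},
        "path_a": {"RA1", "RA2"},
        "path_b": {"RB1", "RB2"},
    }
    return model, truth


def biomass_toy() -> tuple[MetabolicModel, dict]:
    """Small network with a two-precursor biomass reaction and an isozyme.

    G3 solely controls the only route to precursor C (essential); G1/G2
    are isozymes on the route to B (individually dispensable).
    """
    mets = {"A_e": "e", "A_c": "c", "B_c": "c", "C_c": "c"}
    rxns = [
        ("R_EXA", {"A_e": -1}, -10.0, 1000.0, "Exchange/demand reaction", ""),
        ("R_TA", {"A_e": -1, "A_c": 1}, 0.0, 1000.0,
         "Transport, extracellular", "GT"),
        ("R_B", {"A_c": -1, "B_c": 1}, 0.0, 1000.0, "PathX", "G1 or G2"),
        ("R_C", {"A_c": -1, "C_c": 1}, 0.0, 1000.0, "PathY", "G3"),
        ("BIOMASS", {"B_c": -1, "C_c": -1}, 0.0, 1000.0, "Biomass", ""),
    ]
    model = _build(mets, rxns)
    model.objective = "BIOMASS"
    truth = {"essential": {"GT", "G3"}, "dispensable": {"G1", "G2"}}
    return model, truth


def reversible_cycle() -> tuple[MetabolicModel, dict]:
    """Three fully reversible reactions in a closed loop (all consistent)."""
    mets = {"X_c": "c", "Y_c": "c", "Z_c": "c"}
    rxns = [
        ("RC1", {"X_c": -1, "Y_c": 1}, -1000.0, 1000.0, "Cycle", ""),
        ("RC2", {"Y_c": -1, "Z_c": 1}, -1000.0, 1000.0, "Cycle", ""),
        ("RC3", {"Z_c": -1, "X_c": 1}, -1000.0, 1000.0, "Cycle", ""),
    ]
    return _build(mets, rxns), {"blocked": set()}


def make_toy_model(spec: Optional[FixtureSpec] = None
                   ) -> tuple[MetabolicModel, dict]:
    """Parameterized variant: n_pathways chains off a shared hub metabolite.

    Each pathway p is a chain of ``chain_length`` reactions ending in a
    demand outlet; ``n_blocked`` extra dead-end reactions are appended.
    Ground truth (blocked set, transporters, per-pathway reactions) is
    returned alongside.
    """
    spec = spec or FixtureSpec()
    mets = {"A_e": "e", "A_c": "c"}
    rxns = [
        ("R_EXA", {"A_e": -1}, -10.0, 1000.0, "Exchange/demand reaction", ""),
        ("R_TA", {"A_e": -1, "A_c": 1}, 0.0, 1000.0,
         "Transport, extracellular", "GT"),
    ]
    pathway_rxns: dict[str, list[str]] = {}
    for p in range(spec.n_pathways):
        prev = "A_c"
        members = []
        for step in range(spec.chain_length):
            met = f"P{p}M{step}_c"
            mets[met] = "c"
            rid = f"P{p}R{step}"
            rxns.append((rid, {prev: -1, met: 1}, 0.0, 1000.0,
                         f"Path{p}", f"GP{p}S{step}"))
            members.append(rid)
            prev = met
        rxns.append((f"P{p}DM", {prev: -1}, 0.0, 1000.0,
                     "Exchange/demand reaction", ""))
        pathway_rxns[f"Path{p}"] = members
    blocked = set()
    for b in range(spec.n_blocked):
        src, snk = f"DEAD{b}a_c", f"DEAD{b}b_c"
        mets[src] = "c"
        mets[snk] = "c"
        rid = f"RDEAD{b}"
        rxns.append((rid, {src: -1, snk: 1}, 0.0, 1000.0,
                     "PathDead", f"GD{b}"))
        blocked.add(rid)
    model = _build(mets, rxns)
    truth = {"blocked": blocked, "transporters": {"R_TA"},
             "pathways": pathway_rxns}
    return model, truth


def make_random_model(seed: int, max_reactions: int = 15
                      ) -> MetabolicModel:
    """Random small network for consistency stress tests.

    A linear backbone with random branch points, random reversibility,
    random export placement and a couple of dead-end reactions; always
    LP-feasible (v = 0 is allowed by construction).
    """
    rng = np.random.default_rng(seed)
    n_chain = int(rng.integers(2, 6))
    mets = {"A_e": "e", "M0_c": "c"}
    rxns = [
        ("EX_A", {"A_e": -1}, -10.0, 1000.0, "Exchange/demand reaction", ""),
        ("T_A", {"A_e": -1, "M0_c": 1},
         -1000.0 if rng.random() < 0.3 else 0.0, 1000.0,
         "Transport, extracellular", ""),
    ]
    prev = "M0_c"
    for i in range(n_chain):
        met = f"M{i + 1}_c"
        mets[met] = "c"
        reversible = rng.random() < 0.4
        rxns.append((f"R{i}", {prev: -1, met: 1},
                     -1000.0 if reversible else 0.0, 1000.0, "Chain", ""))
        prev = met
    rxns.append(("EX_END", {prev: -1}, 0.0, 1000.0,
                 "Exchange/demand reaction", ""))
    # random branches off random chain positions
    n_branch = int(rng.integers(0, 3))
    for b in range(n_branch):
        if len(rxns) >= max_reactions - 2:
            break
        src = f"M{int(rng.integers(0, n_chain + 1))}_c"
        met = f"B{b}_c"
        mets[met] = "c"
        rxns.append((f"RB{b}", {src: -1, met: 1}, 0.0, 1000.0, "Branch", ""))
        if rng.random() < 0.6:
            rxns.append((f"EX_B{b}", {met: -1}, 0.0, 1000.0,
                         "Exchange/demand reaction", ""))
    # dead-end reactions (blocked by construction unless fed elsewhere)
    n_dead = int(rng.integers(0, 3))
    for d in range(n_dead):
        if len(rxns) >= max_reactions:
            break
        a, bmet = f"D{d}a_c", f"D{d}b_c"
        mets[a] = "c"
        mets[bmet] = "c"
        reversible = rng.random() < 0.3
        rxns.append((f"RD{d}", {a: -1, bmet: 1},
                     -1000.0 if reversible else 0.0, 1000.0, "Dead", ""))
    return _build(mets, rxns[:max_reactions])


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(model: MetabolicModel, active_genes: set[str],
                        spec: Optional[FixtureSpec] = None) -> pd.DataFrame:
    """Gene x sample z-score table with active/inactive genes well separated.

    Active genes draw z ~ N(active_mean, active_sd) (mass above the +1
    threshold), all other model genes ~ N(inactive_mean, inactive_sd)
    (mass below 0).
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    genes = sorted(model.genes())
    z = np.empty((len(genes), spec.n_samples))
    for gi, gene in enumerate(genes):
        if gene in active_genes:
            z[gi] = rng.normal(spec.active_mean, spec.active_sd,
                               spec.n_samples)
        else:
            z[gi] = rng.normal(spec.inactive_mean, spec.inactive_sd,
                               spec.n_samples)
    samples = [f"sample_{i}" for i in range(spec.n_samples)]
    return pd.DataFrame(z, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# Peak simulation
# ---------------------------------------------------------------------------

def simulate_peaks(spec: FixtureSpec
                   ) -> tuple[list[list[GenomicInterval]], pd.DataFrame]:
    """Replicate peak sets planting a known enhancer load per gene.

    Genes sit on one synthetic chromosome with TSSs 2 Mb apart (so the
    nearest-gene rule is unambiguous); gene g with load L gets L regions
    of ``region_length`` bp within +/-100 kb of its TSS, jittered per
    replicate by at most ``jitter`` bp.  With jitter < region length the
    replicate intersection recovers every planted region.
    """
    if not spec.gene_loads:
        raise ValueError("spec.gene_loads must map genes to planted loads")
    rng = np.random.default_rng(spec.seed)
    genes = sorted(spec.gene_loads)
    tss_rows = []
    base_regions: list[tuple[str, int, int]] = []
    for gi, gene in enumerate(genes):
        tss = 2_000_000 * (gi + 1)
        tss_rows.append({"gene_id": gene, "chrom": "chr1",
                         "tss": tss, "strand": "+"})
        for k in range(spec.gene_loads[gene]):
            offset = (k + 1) * 1500 * (1 if k % 2 == 0 else -1)
            start = tss + offset
            base_regions.append(("chr1", start, start + spec.region_length))
    replicates = []
    for _ in range(spec.n_replicates):
        rep = []
        for chrom, start, end in base_regions:
            shift = int(rng.integers(-spec.jitter, spec.jitter + 1))
            rep.append(GenomicInterval(chrom, start + shift, end + shift))
        replicates.append(sorted(rep))
    tss = pd.DataFrame(tss_rows)
    return replicates, tss
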
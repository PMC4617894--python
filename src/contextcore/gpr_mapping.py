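"""Propagate gene-level trinary scores to reactions through GPR rules.

AND nodes (protein complexes) take the minimum of their children's scores,
OR nodes (isozymes) the maximum.  Genes absent from the score mapping
default to 0 (undetermined) so missing annotation never removes reactions.
The same semantics doubles for differential-expression labels
(up = +1, down = -1, unchanged = 0).
"""

from __future__ import annotations

import logging
from typing import Mapping

from .model_io import GPRRule, MetabolicModel

logger = logging.getLogger(__name__)

MISSING_GENE_DEFAULT = 0


def evaluate_gpr(rule: GPRRule, gene_scores: Mapping[str, int],
                 default: int = MISSING_GENE_DEFAULT) -> int:
    """Trinary score of one rule under a gene -> {-1,0,1} mapping."""
    missing = rule.genes() - set(gene_scores)
    if missing:
        logger.debug("genes %s missing from scores; defaulting to %d",
                     sorted(missing), default)
    return rule.evaluate(gene_scores, default=default)


def map_scores(model: MetabolicModel, gene_scores: Mapping[str, int],
               default: int = MISSING_GENE_DEFAULT) -> dict[str, int]:
    """Per-reaction trinary score table.

    Reactions without a GPR are absent from the result (neither core nor
    inactive downstream).
    """
    table: dict[str, int] = {}
    for rid, rule in zip(model.reaction_ids, model.gpr):
        if rule is None:
            continue
        table[rid] = evaluate_gpr(rule, gene_scores, default=default)
    return table


def de_label_reactions(model: MetabolicModel,
                       up_genes: set[str], down_genes: set[str]
                       ) -> tuple[set[str], set[str]]:
    """Reaction-level up/down sets from differential-expression gene labels."""
    labels = {g: 1 for g in up_genes}
    labels.update({g: -1 for g in down_genes})
    up, down = set(), set()
    for rid, score in map_scores(model, labels).items():
        if score == 1:
            up.add(rid)
        elif score == -1:
            down.add(rid)
    return up, down
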
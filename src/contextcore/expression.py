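"""Discretization of expression z-scores into trinary calls and
per-gene aggregation across samples (consensus, ubiquity).

A z-score measures how many reference standard deviations a probe signal
sits above the platform's unexpressed distribution.  z <= 0 -> -1
(inactive), z > 5 -> +1 (expressed), anything in between -> 0
(undetermined); z == 5 exactly falls in the undetermined band.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

Z_INACTIVE = 0.0
Z_ACTIVE = 5.0


class MissingValueError(ValueError):
    """Raised when a z-score is NaN."""


def discretize(z: float) -> int:
    """Map one z-score to a trinary score in {-1, 0, 1}."""
    if isinstance(z, float) and math.isnan(z):
        raise MissingValueError("z-score is NaN")
    if z <= Z_INACTIVE:
        return -1
    if z > Z_ACTIVE:
        return 1
    return 0


def discretize_frame(z: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`discretize` over a gene x sample z-score table.

    Genes with any NaN are dropped with a warning rather than erroring,
    so one bad probe does not abort a whole run.
    """
    bad = z.index[z.isna().any(axis=1)]
    if len(bad):
        warnings.warn(f"dropping {len(bad)} gene(s) with missing z-scores: "
                      f"{list(bad[:5])}")
        z = z.drop(index=bad)
    values = z.to_numpy(dtype=float)
    scores = np.zeros_like(values, dtype=int)
    scores[values <= Z_INACTIVE] = -1
    scores[values > Z_ACTIVE] = 1
    return pd.DataFrame(scores, index=z.index, columns=z.columns)


def zscore_from_reference(intensity: float, ref_mean: float,
                          ref_sd: float) -> float:
    """Standardize an intensity against an unexpressed reference distribution."""
    if ref_sd <= 0:
        raise ValueError(f"reference SD must be positive, got {ref_sd}")
    return (intensity - ref_mean) / ref_sd


def ubiquity(scores: Iterable[int]) -> int:
    """Sum of trinary scores across samples (expression breadth)."""
    total = 0
    for s in scores:
        if s not in (-1, 0, 1):
            raise ValueError(f"trinary score expected, got {s!r}")
        total += s
    return total


def consensus(scores: Sequence[int], active_fraction: float,
              inactive_fraction: Optional[float] = None) -> int:
    """Consensus trinary call across samples.

    +1 if the share of +1 scores reaches ``active_fraction``; -1 if the
    share of -1 scores reaches ``inactive_fraction`` (defaults to the
    active fraction); 0 otherwise.
    """
    if inactive_fraction is None:
        inactive_fraction = active_fraction
    for frac in (active_fraction, inactive_fraction):
        if not 0 < frac <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {frac}")
    n = len(scores)
    if n == 0:
        return 0
    for s in scores:
        if s not in (-1, 0, 1):
            raise ValueError(f"trinary score expected, got {s!r}")
    n_up = sum(1 for s in scores if s == 1)
    n_down = sum(1 for s in scores if s == -1)
    if n_up / n >= active_fraction:
        return 1
    if n_down / n >= inactive_fraction:
        return -1
    return 0


def consensus_frame(scores: pd.DataFrame, active_fraction: float,
                    inactive_fraction: Optional[float] = None) -> pd.Series:
    """Row-wise :func:`consensus` over a gene x sample trinary table."""
    return pd.Series(
        {g: consensus(list(row), active_fraction, inactive_fraction)
         for g, row in scores.iterrows()},
        dtype=int,
    )


def collapse_probes(z: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe-level z-scores to genes by the maximum z per gene.

    Max favors detection; probes without a gene mapping are dropped.
    """
    mapped = z.loc[[p for p in z.index if p in probe_to_gene]].copy()
    mapped.index = [probe_to_gene[p] for p in mapped.index]
    return mapped.groupby(level=0).max()


def read_zscore_table(path: str) -> pd.DataFrame:
    """Read a TSV of gene_id x sample z-scores (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)
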
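"""RPKM quantification, expression calls and the stage-sharing partition.

RPKM (reads per kilobase of transcript per million mapped reads) removes
the length and sequencing-depth biases of raw counts:

    RPKM_gs = 1e9 · C_gs / (N_s · L_g)

with C the raw count, N_s the library size (column sum of the count table)
and L_g the transcript length in bp.  A gene is called expressed in a stage
when its stage-mean RPKM exceeds a small threshold (default 0.1, strict).
The Venn partition assigns every expressed gene to exactly one stage
combination.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, SampleSheet

DEFAULT_RPKM_THRESHOLD = 0.1


def compute_rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Replicate-level RPKM matrix (genes × samples)."""
    lib_sizes = cm.counts.sum(axis=0)
    zero = lib_sizes[lib_sizes == 0]
    if not zero.empty:
        raise ValueError(f"zero library size in sample(s) {list(zero.index)}")
    lengths = cm.lengths.to_numpy(dtype=float)[:, None]
    rpkm = 1e9 * cm.counts.to_numpy(dtype=float) / (lib_sizes.to_numpy()[None, :] * lengths)
    return pd.DataFrame(rpkm, index=cm.genes, columns=cm.counts.columns)


def stage_means(expr: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Average replicate columns into one column per stage."""
    cols = {}
    for stage in sheet.stages:
        members = [s for s in sheet.samples_for(stage) if s in expr.columns]
        if members:
            cols[stage] = expr[members].mean(axis=1)
    return pd.DataFrame(cols)


def expression_calls(
    stage_expr: pd.DataFrame,
    threshold: float = DEFAULT_RPKM_THRESHOLD,
) -> pd.DataFrame:
    """Boolean gene × stage table; expressed iff value > threshold (strict)."""
    if (stage_expr.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    return stage_expr > threshold


def venn_partition(calls: pd.DataFrame) -> pd.Series:
    """Counts for every non-empty stage combination.

    Each gene expressed in at least one stage falls in exactly one region;
    region counts therefore sum to the number of genes expressed anywhere.
    Keys are '+'-joined stage names in input column order.
    """
    stages = list(calls.columns)
    if len(stages) < 2:
        raise ValueError("need at least two stages for a sharing partition")
    keys = []
    for size in range(1, len(stages) + 1):
        for combo in combinations(stages, size):
            keys.append("+".join(combo))
    counts = dict.fromkeys(keys, 0)
    values = calls.to_numpy(dtype=bool)
    for row in values:
        if not row.any():
            continue
        key = "+".join(s for s, v in zip(stages, row) if v)
        counts[key] += 1
    return pd.Series(counts, name="count")


def shared_in_all(partition: pd.Series, stages: list[str]) -> int:
    return int(partition["+".join(stages)])


def stage_specific(partition: pd.Series, stages: list[str]) -> dict[str, int]:
    return {s: int(partition[s]) for s in stages}
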
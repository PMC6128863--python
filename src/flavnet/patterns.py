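"""Ternary expression-pattern scores across the sequential growth phases.

A gene's pattern score is the ordered triple over the three phase
comparisons (early, middle, mature): +1 where it was called up-regulated,
−1 where down-regulated, 0 where unchanged, e.g. {1,0,0} for a gene that
rises only between the first two stages.  Tabulating patterns per gene
family summarizes how diversely a regulator family (MYB, bHLH, WD40) or a
structural family behaves across flower development.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .diffexpr import ComparisonResult

_SCORE = {"up": 1, "down": -1, "none": 0}


def pattern_score(calls: Sequence[str]) -> tuple[int, ...]:
    """Map one gene's per-phase calls to the ternary score triple."""
    if not calls:
        raise ValueError("need one call per phase")
    scores = []
    for call in calls:
        if call not in _SCORE:
            raise ValueError(f"unknown call {call!r}; expected up/down/none")
        scores.append(_SCORE[call])
    return tuple(scores)


def score_table(results: Mapping[str, ComparisonResult]) -> pd.DataFrame:
    """Per-gene score columns (one per phase, in phase order)."""
    if not results:
        raise ValueError("no comparisons supplied")
    cols = {}
    for label, res in results.items():
        cols[f"s_{label}"] = res.table["call"].map(_SCORE)
    frame = pd.DataFrame(cols)
    if frame.isna().any().any():
        raise ValueError("comparisons cover different gene sets")
    return frame.astype(int)


def format_pattern(row: Sequence[int]) -> str:
    return "{" + ",".join(str(int(v)) for v in row) + "}"


def tabulate_patterns(
    scores: pd.DataFrame, families: pd.Series | Mapping[str, str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Count genes per (family, pattern) and distinct patterns per family.

    Genes absent from the family mapping (or mapped to '') are tabulated
    under 'unassigned'.  Per-family pattern counts sum to the family size.
    """
    fam = pd.Series(families, dtype=object).reindex(scores.index)
    fam = fam.where(fam.notna() & (fam != ""), "unassigned")
    patterns = scores.apply(format_pattern, axis=1)
    frame = pd.DataFrame({"family": fam, "pattern": patterns})
    counts = (
        frame.groupby(["family", "pattern"], sort=True)
        .size()
        .reset_index(name="count")
    )
    distinct = counts.groupby("family")["pattern"].nunique()
    return counts, distinct
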
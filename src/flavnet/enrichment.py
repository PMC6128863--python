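"""Hypergeometric GO-term enrichment of differential gene sets.

The sampling unit is a GO-term *occurrence*: N is the total number of GO
annotations across all genes, m the occurrences of one term among all
genes, n the total annotations across the differential set, and k the
occurrences of that term in the differential set.  The pmf is

    f(k; n, m, N) = C(m, k) · C(N−m, n−k) / C(N, n).

Two p-value modes are provided: ``upper_tail`` (the inferential default,
p = Σ_{i>=k} f(i)) and ``as_printed`` (p = 1 − f(k), the single-point
complement some pipelines report; retained for fidelity and comparison —
note it is not a tail probability).  A ``count_unit='genes'`` option counts
distinct genes instead of occurrences.  BH-adjusted q-values are attached.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

MODES = ("upper_tail", "as_printed")


def hypergeom_pmf(k: int, n: int, m: int, N: int) -> float:
    """f(k; n, m, N): probability of exactly k marked items in a draw of n
    from a population of N containing m marked items."""
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= m, n <= N; got n={n}, m={m}, N={N}")
    if k < 0 or k > n:
        raise ValueError(f"k={k} outside draw size n={n}")
    if k > m or n - k > N - m:
        return 0.0
    return float(stats.hypergeom.pmf(k, N, m, n))


def hypergeom_upper_tail(k: int, n: int, m: int, N: int) -> float:
    """P(X >= k) for the same hypergeometric draw."""
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= m, n <= N; got n={n}, m={m}, N={N}")
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, m, n)))


def enrich_terms(
    deu_genes: Iterable[str],
    gene2go: pd.DataFrame,
    universe_genes: Iterable[str] | None = None,
    mode: str = "upper_tail",
    count_unit: str = "occurrences",
) -> pd.DataFrame:
    """Per-term enrichment of a differential gene set against the universe.

    Returns one row per term present in the differential set, sorted by
    p-value (ties by term id): term, k, n, m, N, f, pvalue, qvalue.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if count_unit not in ("occurrences", "genes"):
        raise ValueError("count_unit must be 'occurrences' or 'genes'")
    annot = gene2go[["gene_id", "go_id"]].drop_duplicates()
    if universe_genes is not None:
        universe = set(universe_genes)
        missing = set(annot["gene_id"]) - universe
        if missing:
            warnings.warn(
                f"{len(missing)} annotated genes outside the universe are ignored"
            )
        annot = annot[annot["gene_id"].isin(universe)]
    deu = set(deu_genes)
    if not deu:
        warnings.warn("empty differential gene set; no enrichment computed")
        return pd.DataFrame(
            columns=["term", "k", "n", "m", "N", "f", "pvalue", "qvalue"]
        )
    deu_annot = annot[annot["gene_id"].isin(deu)]

    if count_unit == "occurrences":
        N = len(annot)
        n = len(deu_annot)
        m_by_term = annot.groupby("go_id").size()
        k_by_term = deu_annot.groupby("go_id").size()
    else:
        N = annot["gene_id"].nunique()
        n = deu_annot["gene_id"].nunique()
        m_by_term = annot.groupby("go_id")["gene_id"].nunique()
        k_by_term = deu_annot.groupby("go_id")["gene_id"].nunique()

    rows = []
    for term, k in k_by_term.items():
        m = int(m_by_term[term])
        k = int(k)
        f = hypergeom_pmf(k, n, m, N)
        if mode == "upper_tail":
            p = hypergeom_upper_tail(k, n, m, N)
        else:
            p = min(1.0, max(0.0, 1.0 - f))
        rows.append({"term": term, "k": k, "n": n, "m": m, "N": N, "f": f, "pvalue": p})
    result = pd.DataFrame(rows)
    result["qvalue"] = bh_adjust(result["pvalue"].to_numpy())
    return result.sort_values(["pvalue", "term"], kind="stable").reset_index(drop=True)
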
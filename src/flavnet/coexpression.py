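"""Correlation-based inference of regulator → structural-gene motifs.

Each candidate (structural gene, regulator) pair is scored by Pearson's R
over expression profiles across the developmental stages (replicate-level
by default: with four stages and two replicates each profile has eight
points, the minimum at which the joint thresholds R >= 0.8 and p <= 0.01
are satisfiable under the t test).  Among pairs passing the thresholds,
the single most positively correlated regulator and the single most
negatively correlated regulator are retained per structural gene; a
structural gene together with its retained regulator(s) is one network
motif.  Profiles are log2(normalized count + 1) for variance stabilization.

The module also provides the replicate-concordance QC (Pearson R between
replicate libraries of one stage on the log2 scale).
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, SampleSheet
from .diffexpr import size_factors
from .expression import stage_means

DEFAULT_R_MIN = 0.8
DEFAULT_P_MAX = 0.01


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    # exact ±1 for perfectly (anti)aligned deviations, avoiding 1-ulp drift
    if np.array_equal(dx, dy):
        return 1.0
    if np.array_equal(dx, -dy):
        return -1.0
    r = float((dx * dy).sum() / (sx * sy))
    return max(-1.0, min(1.0, r))


def correlation_pvalue(r: float, n_points: int) -> float:
    """Two-sided p for an observed Pearson R via t = R·sqrt((n−2)/(1−R²))
    with n−2 degrees of freedom; |R| = 1 gives p = 0."""
    if n_points < 3:
        raise ValueError("need at least 3 points")
    if abs(r) > 1:
        raise ValueError("|R| cannot exceed 1")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n_points - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n_points - 2))


def coexpression_profiles(cm: CountMatrix, level: str = "replicate") -> pd.DataFrame:
    """log2(size-factor-normalized count + 1) profiles, replicate-level or
    averaged to stage means."""
    if level not in ("replicate", "stage-mean"):
        raise ValueError("level must be 'replicate' or 'stage-mean'")
    norm = cm.counts / size_factors(cm.counts)
    profiles = np.log2(norm + 1.0)
    if level == "stage-mean":
        profiles = stage_means(profiles, cm.sheet)
    return profiles


def build_motifs(
    profiles: pd.DataFrame,
    regulator_ids: Iterable[str],
    structural_ids: Iterable[str],
    r_min: float = DEFAULT_R_MIN,
    p_max: float = DEFAULT_P_MAX,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score all (structural, regulator) pairs and retain the extremes.

    Returns (motifs, edges).  ``edges`` holds every scored pair with its R,
    p, sign and whether it was retained; ``motifs`` has one row per
    structural gene with at least one retained regulator.  Ties in maximal
    |R| break by lexicographic regulator id; constant-profile genes are
    skipped with a warning.
    """
    regulators = [g for g in regulator_ids]
    structurals = [g for g in structural_ids]
    if not regulators or not structurals:
        warnings.warn("empty regulator or structural gene list; no motifs built")
        return (
            pd.DataFrame(columns=["structural", "regulator", "r", "pvalue", "sign"]),
            pd.DataFrame(
                columns=["structural", "regulator", "r", "pvalue", "sign", "retained"]
            ),
        )
    missing = (set(regulators) | set(structurals)) - set(profiles.index)
    if missing:
        raise ValueError(f"no expression profile for genes {sorted(missing)[:5]}")

    def usable(gene: str) -> bool:
        if profiles.loc[gene].nunique() > 1:
            return True
        warnings.warn(f"gene {gene!r} has a constant profile; skipped")
        return False

    regulators = [g for g in regulators if usable(g)]
    structurals = [g for g in structurals if usable(g)]

    n = profiles.shape[1]
    edge_rows = []
    motif_rows = []
    for s in structurals:
        xs = profiles.loc[s].to_numpy(dtype=float)
        best_pos: tuple[float, str, float] | None = None  # (r, regulator, p)
        best_neg: tuple[float, str, float] | None = None
        for g in sorted(regulators):
            if g == s:
                continue
            r = pearson_r(xs, profiles.loc[g].to_numpy(dtype=float))
            p = correlation_pvalue(r, n)
            sign = 1 if r >= 0 else -1
            passed_pos = r >= r_min and p <= p_max
            passed_neg = r <= -r_min and p <= p_max
            edge_rows.append(
                {"structural": s, "regulator": g, "r": r, "pvalue": p,
                 "sign": sign, "retained": False}
            )
            if passed_pos and (best_pos is None or r > best_pos[0]):
                best_pos = (r, g, p)
            if passed_neg and (best_neg is None or r < best_neg[0]):
                best_neg = (r, g, p)
        for best, sign in ((best_pos, 1), (best_neg, -1)):
            if best is None:
                continue
            r, g, p = best
            motif_rows.append(
                {"structural": s, "regulator": g, "r": r, "pvalue": p, "sign": sign}
            )

    edges = pd.DataFrame(edge_rows)
    motifs = pd.DataFrame(
        motif_rows, columns=["structural", "regulator", "r", "pvalue", "sign"]
    )
    if not motifs.empty and not edges.empty:
        retained_keys = set(zip(motifs["structural"], motifs["regulator"], motifs["sign"]))
        edges["retained"] = [
            (s, g, sgn) in retained_keys
            for s, g, sgn in zip(edges["structural"], edges["regulator"], edges["sign"])
        ]
    return motifs, edges


def motif_summary(motifs: pd.DataFrame) -> dict[str, int]:
    """Headline counts: motifs (retained edges), distinct regulators and
    distinct structural genes."""
    return {
        "motifs": int(len(motifs)),
        "regulators": int(motifs["regulator"].nunique()) if len(motifs) else 0,
        "structurals": int(motifs["structural"].nunique()) if len(motifs) else 0,
    }


def replicate_concordance(expr: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Pearson R between replicate libraries within each stage, computed on
    log2(x + 1)-transformed expression.  Stages with a single replicate are
    skipped with a note."""
    rows = []
    logged = np.log2(expr + 1.0)
    for stage in sheet.stages:
        reps = [s for s in sheet.samples_for(stage) if s in expr.columns]
        if len(reps) < 2:
            warnings.warn(f"stage {stage!r} has fewer than 2 replicates; skipped")
            continue
        for a, b in combinations(reps, 2):
            rows.append(
                {"stage": stage, "replicate_a": a, "replicate_b": b,
                 "r": pearson_r(logged[a].to_numpy(), logged[b].to_numpy())}
            )
    return pd.DataFrame(rows, columns=["stage", "replicate_a", "replicate_b", "r"])
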
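"""Differential expression between sequential stages.

The test is the classic negative-binomial exact test for two small groups
of count libraries: libraries are normalized by median-of-ratios size
factors, a per-gene dispersion α (variance μ + αμ²) is estimated by the
method of moments and shared conservatively with a fitted mean–dispersion
trend ("take the maximum"), and the per-condition count sums are compared
under the null that both conditions share one expression level.  Genes are
called differential when the BH-adjusted p-value (FDR) is below 0.01 and
the normalized fold change exceeds 2 (or falls below 1/2).

For the observed condition sums (K_A, K_B) with K_A + K_B = T, the
two-sided exact p-value is

    p = Σ_{a+b=T, P(a)P(b) <= P(K_A)P(K_B)} P(a)P(b) / Σ_{a+b=T} P(a)P(b),

where P(·) is the NB pmf of each condition's sum under the pooled mean.
The sum's variance is assembled per library, var(K_A) = q·S_A + α·q²·Σ sf²,
with q = T / (S_A + S_B) the pooled per-size-factor mean; α = 0 reduces to
the Poisson (conditional binomial) limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix
from .synthetic_data import phase_labels

DEFAULT_FDR = 0.01
DEFAULT_FC_THRESHOLD = 2.0

# relative tolerance when comparing pmf products for "as or less probable";
# absorbs float noise in genuinely tied outcomes
_TIE_RTOL = 1e-12


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios library size factors.

    Each sample's factor is the median over reference genes of
    count / geometric-mean(count across samples).  Reference genes are those
    with nonzero counts in every sample; ``pseudo_reference=True`` relaxes
    this to genes with at least one nonzero count (geometric mean over the
    positive entries only), for sparse data.
    """
    values = counts.to_numpy(dtype=float)
    if pseudo_reference:
        mask = values > 0
        usable = mask.any(axis=1)
        if not usable.any():
            raise ValueError("count table is entirely zero")
        logs = np.where(mask, np.log(values, where=mask, out=np.zeros_like(values)), 0.0)
        log_geomean = logs.sum(axis=1) / np.maximum(mask.sum(axis=1), 1)
        sf = []
        for j in range(values.shape[1]):
            col_ok = usable & mask[:, j]
            if not col_ok.any():
                raise ValueError(f"sample {counts.columns[j]!r} has no nonzero gene")
            ratios = np.log(values[col_ok, j]) - log_geomean[col_ok]
            sf.append(np.exp(np.median(ratios)))
        return pd.Series(sf, index=counts.columns, name="size_factor")
    usable = (values > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; re-run with "
            "pseudo_reference=True (CLI flag --pseudo-reference)"
        )
    logs = np.log(values[usable])
    log_geomean = logs.mean(axis=1)
    sf = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


@dataclass
class DispersionModel:
    """Per-gene dispersion estimates: raw method-of-moments values, the
    binned-median mean–dispersion trend, and the take-maximum final α."""

    alpha_mom: pd.Series
    trend: pd.Series
    alpha: pd.Series


def estimate_dispersion(
    norm: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    n_bins: int = 10,
) -> DispersionModel:
    """Method-of-moments dispersion with take-maximum trend sharing.

    Per condition with >= 2 replicates, α̂ = max(0, (v − μ)/μ²) from the
    mean and unbiased variance of normalized counts across replicates
    (α̂ = 0 where μ = 0); conditions are averaged.  The trend is the median
    α̂ within expression-level bins; the final α is max(α̂, trend).
    """
    informative = [g for g, cols in groups.items() if len(cols) >= 2]
    if not informative:
        raise ValueError(
            "every condition has a single replicate; dispersion cannot be "
            "estimated — supply a fixed alpha via configuration"
        )
    per_condition = []
    for g in informative:
        block = norm[list(groups[g])].to_numpy(dtype=float)
        mu = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (v - mu) / np.square(mu), 0.0)
        per_condition.append(np.maximum(a, 0.0))
    alpha_mom = pd.Series(np.mean(per_condition, axis=0), index=norm.index)

    overall_mu = norm.mean(axis=1)
    trend = pd.Series(0.0, index=norm.index)
    positive = overall_mu > 0
    if positive.sum() >= 2:
        log_mu = np.log10(overall_mu[positive])
        bins = min(n_bins, max(1, int(positive.sum() // 20)))
        labels = pd.qcut(log_mu.rank(method="first"), bins, labels=False)
        medians = alpha_mom[positive].groupby(labels).median()
        trend.loc[positive.index[positive]] = labels.map(medians).to_numpy()
    alpha = pd.concat([alpha_mom, trend], axis=1).max(axis=1)
    return DispersionModel(alpha_mom=alpha_mom, trend=trend, alpha=alpha)


def _sum_pmf(k: np.ndarray, mean: float, var: float) -> np.ndarray:
    if var <= mean * (1.0 + 1e-12) or mean == 0.0:
        return stats.poisson.pmf(k, mean)
    r = mean * mean / (var - mean)
    return stats.nbinom.pmf(k, r, r / (r + mean))


def nb_exact_test(
    sum_a: int,
    sum_b: int,
    sf_a: float | Sequence[float],
    sf_b: float | Sequence[float],
    alpha: float,
) -> float:
    """Two-sided NB exact test on per-condition count sums.

    ``sf_a``/``sf_b`` are either per-library size factors (preferred: the
    sum's variance is then assembled per library) or scalar size-factor
    totals (the sum is treated as one library).  α = 0 gives the Poisson
    limit, which for equal totals is the conditional binomial test.
    """
    if sum_a < 0 or sum_b < 0:
        raise ValueError("count sums must be non-negative")
    if alpha < 0:
        raise ValueError("dispersion must be >= 0")
    sfa = np.atleast_1d(np.asarray(sf_a, dtype=float))
    sfb = np.atleast_1d(np.asarray(sf_b, dtype=float))
    s_a, s_b = sfa.sum(), sfb.sum()
    if s_a <= 0 or s_b <= 0:
        raise ValueError("size-factor totals must be positive")
    total = int(sum_a) + int(sum_b)
    if total == 0:
        return 1.0
    q = total / (s_a + s_b)
    mean_a = q * s_a
    mean_b = q * s_b
    var_a = mean_a + alpha * q * q * float((sfa**2).sum())
    var_b = mean_b + alpha * q * q * float((sfb**2).sum())

    support = np.arange(total + 1)
    pa = _sum_pmf(support, mean_a, var_a)
    pb = _sum_pmf(support, mean_b, var_b)
    prod = pa * pb[::-1]
    denom = prod.sum()
    if denom <= 0.0 or not np.isfinite(denom):
        return 1.0
    observed = prod[sum_a]
    p = prod[prod <= observed * (1.0 + _TIE_RTOL)].sum() / denom
    return float(min(1.0, max(p, np.nextafter(0, 1))))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_calls(
    fold_change: pd.Series,
    qvalues: pd.Series,
    fdr: float = DEFAULT_FDR,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
) -> pd.Series:
    """'up' / 'down' / 'none' under the joint FDR and fold-change gates
    (both strict)."""
    significant = qvalues < fdr
    up = significant & (fold_change > fc_threshold)
    down = significant & (fold_change < 1.0 / fc_threshold)
    calls = pd.Series("none", index=fold_change.index)
    calls[up] = "up"
    calls[down] = "down"
    return calls


@dataclass
class ComparisonResult:
    """Differential-expression result for one sequential stage pair."""

    label: str
    stages: tuple[str, str]
    table: pd.DataFrame  # mean_a, mean_b, fold_change, pvalue, qvalue, call

    @property
    def summary(self) -> dict[str, int]:
        up = int((self.table["call"] == "up").sum())
        down = int((self.table["call"] == "down").sum())
        return {"up": up, "down": down, "total": up + down}


def call_deus(
    cm: CountMatrix,
    stages: tuple[str, str],
    *,
    fdr: float = DEFAULT_FDR,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fixed_alpha: float | None = None,
    label: str | None = None,
) -> ComparisonResult:
    """Full differential-expression calling for one sequential stage pair.

    Fold change is the later-stage / earlier-stage ratio of normalized
    means, with 0/0 → 1 and x/0 → +inf (which passes the up gate);
    "up-regulated" means higher in the later stage.
    """
    earlier, later = stages
    for stage in stages:
        if stage not in cm.sheet.stages:
            raise ValueError(f"unknown stage {stage!r}")
    cols_a = cm.stage_columns(earlier)
    cols_b = cm.stage_columns(later)
    if not cols_a or not cols_b:
        raise ValueError(f"both stages need at least one replicate: {stages}")

    sub = cm.counts[cols_a + cols_b]
    sf = size_factors(sub)
    norm = sub / sf

    if fixed_alpha is not None:
        alpha = pd.Series(float(fixed_alpha), index=cm.genes)
    else:
        alpha = estimate_dispersion(norm, {earlier: cols_a, later: cols_b}).alpha

    sum_a = sub[cols_a].sum(axis=1).to_numpy()
    sum_b = sub[cols_b].sum(axis=1).to_numpy()
    sfa = sf[cols_a].to_numpy()
    sfb = sf[cols_b].to_numpy()
    alpha_arr = alpha.to_numpy()
    pvals = np.empty(len(cm.genes))
    for i in range(len(cm.genes)):
        pvals[i] = nb_exact_test(sum_a[i], sum_b[i], sfa, sfb, alpha_arr[i])

    mean_a = norm[cols_a].mean(axis=1)
    mean_b = norm[cols_b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_b / mean_a
    fc[(mean_a == 0) & (mean_b == 0)] = 1.0
    fc[(mean_a == 0) & (mean_b > 0)] = np.inf

    qvals = pd.Series(bh_adjust(pvals), index=cm.genes)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fc,
            "pvalue": pd.Series(pvals, index=cm.genes),
            "qvalue": qvals,
            "call": classify_calls(fc, qvals, fdr=fdr, fc_threshold=fc_threshold),
        }
    )
    return ComparisonResult(
        label=label or f"{earlier}-{later}", stages=(earlier, later), table=table
    )


def compare_all_phases(cm: CountMatrix, **kwargs) -> dict[str, ComparisonResult]:
    """Run call_deus for every sequential stage pair, keyed by phase label
    (early/middle/mature for the default four stages)."""
    stages = cm.sheet.stages
    labels = phase_labels(stages)
    results = {}
    for label, pair in zip(labels, zip(stages[:-1], stages[1:])):
        results[label] = call_deus(cm, pair, label=label, **kwargs)
    return results


def family_expression_test(
    family_values: Sequence[float], background_values: Sequence[float]
) -> float:
    """One-sided Wilcoxon rank-sum p for family > background expression.

    Exact enumeration for combined n <= 12 without ties; otherwise the
    normal approximation with midranks and tie correction.
    """
    x = np.asarray(family_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    )
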
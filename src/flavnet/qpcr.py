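"""Relative qPCR quantification (2^−ΔΔCt) and RNA-Seq concordance.

Ct is the fractional cycle at which fluorescence crosses the detection
threshold; lower Ct means more template.  With a reference gene (here the
protein phosphatase 2A catalytic subunit, PP2Acs, by default) and a
calibrator stage (default: the earliest stage), relative expression is

    ΔCt  = Ct_target − Ct_reference        (per sample)
    ΔΔCt = ΔCt_stage − ΔCt_calibrator
    RQ   = 2^−ΔΔCt

Replicates are averaged on the Ct scale before ΔCt; amplification
efficiency is fixed at 2 (no efficiency correction).  The calibrator stage
maps to RQ = 1 exactly for every gene, and adding a constant to all Ct
values leaves every RQ unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .coexpression import pearson_r


@dataclass
class CtTable:
    """Long-format Ct measurements with the reference gene and calibrator."""

    data: pd.DataFrame  # columns: gene_id, stage, replicate, ct
    reference_gene: str
    calibrator_stage: str

    def __post_init__(self) -> None:
        required = {"gene_id", "stage", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table lacks columns {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive cycle numbers")
        stages = set(self.data["stage"])
        if self.calibrator_stage not in stages:
            raise ValueError(f"calibrator stage {self.calibrator_stage!r} absent")
        ref_stages = set(
            self.data.loc[self.data["gene_id"] == self.reference_gene, "stage"]
        )
        missing_ref = stages - ref_stages
        if missing_ref:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing in "
                f"stage(s) {sorted(missing_ref)}"
            )


def ddct_relative_expression(ct: CtTable) -> pd.DataFrame:
    """Per-gene, per-stage relative expression 2^−ΔΔCt (genes × stages)."""
    mean_ct = (
        ct.data.groupby(["gene_id", "stage"])["ct"].mean().unstack("stage")
    )
    ref = mean_ct.loc[ct.reference_gene]
    targets = mean_ct.drop(index=ct.reference_gene)
    if targets.isna().any().any():
        gene = targets.index[targets.isna().any(axis=1)][0]
        raise ValueError(f"gene {gene!r} lacks Ct values in some stage")
    delta = targets.sub(ref, axis=1)
    ddct = delta.sub(delta[ct.calibrator_stage], axis=0)
    rq = np.power(2.0, -ddct)
    # order stages as first seen in the table
    order = [s for s in dict.fromkeys(ct.data["stage"]) if s in rq.columns]
    return rq[order]


def concordance(
    qpcr_rel: pd.DataFrame,
    rnaseq_profile: pd.DataFrame,
    min_stages: int = 3,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Per-gene Pearson R between qPCR and RNA-Seq stage profiles.

    Profiles are log2(x + pseudocount)-transformed.  The pattern-agreement
    flag passes when the sign of the stage-to-stage change matches RNA-Seq
    in all but at most one transition (>= 2 of 3 for four stages).
    Constant profiles are flagged as undefined.
    """
    rows = []
    for gene in qpcr_rel.index:
        if gene not in rnaseq_profile.index:
            continue
        shared = [s for s in qpcr_rel.columns if s in rnaseq_profile.columns]
        if len(shared) < min_stages:
            raise ValueError(
                f"gene {gene!r}: only {len(shared)} shared stages "
                f"(need >= {min_stages})"
            )
        q = np.log2(qpcr_rel.loc[gene, shared].to_numpy(dtype=float) + pseudocount)
        r_seq = np.log2(
            rnaseq_profile.loc[gene, shared].to_numpy(dtype=float) + pseudocount
        )
        if np.unique(q).size == 1 or np.unique(r_seq).size == 1:
            rows.append(
                {"gene_id": gene, "r": np.nan, "n_stages": len(shared),
                 "pattern_agreement": False, "defined": False}
            )
            continue
        r = pearson_r(q, r_seq)
        agree = int(np.sum(np.sign(np.diff(q)) == np.sign(np.diff(r_seq))))
        transitions = len(shared) - 1
        rows.append(
            {"gene_id": gene, "r": r, "n_stages": len(shared),
             "pattern_agreement": agree >= transitions - 1, "defined": True}
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "r", "n_stages", "pattern_agreement", "defined"]
    ).set_index("gene_id")
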
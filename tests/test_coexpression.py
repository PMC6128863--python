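"""Pearson correlation, its t-test p-value, motif retention and replicate QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import flavnet as fv


def test_pearson_hand_example_and_sign_limits():
    assert fv.pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)
    x = np.array([1.0, 2.0, 5.0])
    assert fv.pearson_r(x, x) == 1.0
    assert fv.pearson_r(x, -x) == -1.0


def test_pearson_rejects_constant_vectors():
    with pytest.raises(ValueError, match="constant"):
        fv.pearson_r([1, 1, 1], [1, 2, 3])


def test_pearson_matches_scipy_on_random_vectors():
    rng = np.random.default_rng(3)
    for _ in range(50):
        x, y = rng.normal(size=(2, 12))
        assert fv.pearson_r(x, y) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-12
        )


def test_correlation_pvalue_t_reference():
    assert fv.correlation_pvalue(0.0, 10) == 1.0
    assert fv.correlation_pvalue(1.0, 5) == 0.0
    # R=0.8 at n=8 -> t ~ 3.266 on 6 df
    assert fv.correlation_pvalue(0.8, 8) == pytest.approx(0.0171, abs=2e-3)
    with pytest.raises(ValueError):
        fv.correlation_pvalue(0.5, 2)


def _profiles(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


def test_build_motifs_retains_the_extreme_passing_regulator():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
    profiles = _profiles({
        "struct": x,
        "copy": list(x),                       # R = 1
        "good": [v + d for v, d in zip(x, [0.3, -0.2, 0.1, 0.0, -0.3, 0.2, 0.0, -0.1])],
        "weak": [1, 5, 2, 6, 3, 8, 4, 7],      # positive but below r_min
        "anti": [-v for v in x],               # R = -1
    })
    motifs, edges = fv.build_motifs(
        profiles, ["copy", "good", "weak", "anti"], ["struct"]
    )
    by_sign = motifs.set_index("sign")
    assert by_sign.loc[1, "regulator"] == "copy"
    assert by_sign.loc[-1, "regulator"] == "anti"
    assert len(motifs) == 2
    assert edges["retained"].sum() == 2
    weak_r = edges.set_index("regulator").loc["weak", "r"]
    assert 0 < weak_r < 0.8  # never retained below the threshold


def test_build_motifs_empty_lists_warn():
    with pytest.warns(UserWarning, match="empty"):
        motifs, edges = fv.build_motifs(_profiles({"a": [1, 2, 3]}), [], ["a"])
    assert motifs.empty and edges.empty


def test_at_most_one_regulator_retained_per_sign(small_dataset):
    _, catalog, cm, truth = small_dataset
    profiles = fv.coexpression_profiles(cm)
    motifs, _ = fv.build_motifs(
        profiles, catalog.regulators, sorted(set(truth.motifs["structural"]))
    )
    per = motifs.groupby(["structural", "sign"]).size()
    assert (per <= 1).all()
    summary = fv.motif_summary(motifs)
    assert summary["motifs"] == len(motifs)


def test_replicate_concordance_identity_and_null():
    rng = np.random.default_rng(8)
    expr = pd.DataFrame({
        "BD_1": rng.lognormal(3, 1, 1000),
        "BB_1": rng.lognormal(3, 1, 1000),
        "BB_2": rng.lognormal(3, 1, 1000),
    })
    expr["BD_2"] = expr["BD_1"]  # duplicated library
    sheet = fv.SampleSheet(
        {c: (c.split("_")[0], int(c.split("_")[1])) for c in expr.columns},
        stages=("BD", "BB"),
    )
    table = fv.replicate_concordance(expr, sheet).set_index("stage")
    assert table.loc["BD", "r"] == pytest.approx(1.0)
    assert abs(table.loc["BB", "r"]) < 0.1  # independent columns


def test_replicate_concordance_is_symmetric():
    expr = pd.DataFrame({"BD_1": [1.0, 5.0, 9.0], "BD_2": [2.0, 4.0, 10.0],
                         "BB_1": [1.0, 2.0, 3.0], "BB_2": [3.0, 2.0, 1.0]})
    sheet = fv.SampleSheet(
        {c: (c.split("_")[0], int(c.split("_")[1])) for c in expr.columns},
        stages=("BD", "BB"),
    )
    table = fv.replicate_concordance(expr, sheet)
    swapped = fv.replicate_concordance(expr[["BD_2", "BD_1", "BB_1", "BB_2"]], sheet)
    assert table.set_index("stage")["r"].to_dict() == pytest.approx(
        swapped.set_index("stage")["r"].to_dict()
    )
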
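"""Normalization, dispersion, the NB exact test, BH-FDR and call gates."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

import flavnet as fv


# --- size factors -----------------------------------------------------------

def test_size_factors_median_of_ratios_example():
    counts = pd.DataFrame({"A": [10, 20, 30], "B": [20, 40, 60]})
    sf = fv.size_factors(counts)
    assert sf["A"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
    assert sf["B"] == pytest.approx(np.sqrt(2), abs=1e-4)


def test_size_factors_symmetry_and_permutation_invariance():
    counts = pd.DataFrame({"A": [5, 7, 11], "B": [5, 7, 11]})
    sf = fv.size_factors(counts)
    assert sf["A"] == pytest.approx(sf["B"])
    shuffled = counts.iloc[[2, 0, 1]].reset_index(drop=True)
    pd.testing.assert_series_equal(fv.size_factors(shuffled), sf)


def test_size_factors_requires_reference_genes():
    counts = pd.DataFrame({"A": [0, 3], "B": [4, 0]})
    with pytest.raises(ValueError, match="pseudo_reference"):
        fv.size_factors(counts)
    sf = fv.size_factors(counts, pseudo_reference=True)
    assert (sf > 0).all()


# --- dispersion -------------------------------------------------------------

@pytest.mark.parametrize(
    "reps,expected", [((10.0, 10.0), 0.0), ((5.0, 15.0), 0.4), ((0.0, 0.0), 0.0)]
)
def test_moment_dispersion_estimates(reps, expected):
    norm = pd.DataFrame({"A_1": [reps[0]], "A_2": [reps[1]]})
    model = fv.estimate_dispersion(norm, {"A": ["A_1", "A_2"]})
    assert model.alpha_mom.iloc[0] == pytest.approx(expected)
    assert (model.alpha >= model.alpha_mom - 1e-15).all()


def test_dispersion_requires_replication_somewhere():
    norm = pd.DataFrame({"A_1": [3.0], "B_1": [4.0]})
    with pytest.raises(ValueError, match="fixed alpha"):
        fv.estimate_dispersion(norm, {"A": ["A_1"], "B": ["B_1"]})


# --- NB exact test ----------------------------------------------------------

def test_nb_exact_equal_counts_give_p_one():
    assert fv.nb_exact_test(25, 25, 1.0, 1.0, alpha=0.1) == 1.0


def test_nb_exact_poisson_limit_enumeration():
    # (0, 10) with equal totals reduces to Binomial(10, 1/2): only the two
    # extreme outcomes are as or less probable -> p = 2/1024
    assert fv.nb_exact_test(0, 10, 1.0, 1.0, alpha=0.0) == pytest.approx(
        2 / 1024, rel=1e-9
    )


def test_nb_exact_no_counts_no_evidence():
    assert fv.nb_exact_test(0, 0, 1.0, 1.0, alpha=0.5) == 1.0


def test_nb_exact_rejects_invalid_arguments():
    with pytest.raises(ValueError):
        fv.nb_exact_test(-1, 3, 1.0, 1.0, 0.0)
    with pytest.raises(ValueError):
        fv.nb_exact_test(1, 3, 1.0, 1.0, -0.2)
    with pytest.raises(ValueError):
        fv.nb_exact_test(1, 3, 0.0, 1.0, 0.1)


def test_nb_exact_dispersion_widens_the_null():
    """Extra-Poisson variance makes the same split less surprising."""
    p_poisson = fv.nb_exact_test(10, 40, [1.0, 1.0], [1.0, 1.0], alpha=0.0)
    p_nb = fv.nb_exact_test(10, 40, [1.0, 1.0], [1.0, 1.0], alpha=0.5)
    assert p_nb > p_poisson


# --- BH adjustment ----------------------------------------------------------

def test_bh_step_up_hand_example():
    q = fv.bh_adjust([0.002, 0.01, 0.03, 0.04])
    assert q == pytest.approx([0.008, 0.02, 0.04, 0.04])


def test_bh_degenerate_inputs():
    assert fv.bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])
    assert fv.bh_adjust([0.07]) == pytest.approx([0.07])
    with pytest.raises(ValueError):
        fv.bh_adjust([0.5, 1.5])


def test_bh_matches_independent_implementation_on_random_vectors():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        p = rng.random(rng.integers(1, 60))
        expected = multipletests(p, method="fdr_bh")[1]
        assert fv.bh_adjust(p) == pytest.approx(expected, rel=1e-12)


# --- call gates and the full comparison -------------------------------------

def test_call_gates_are_conjunctive():
    fc = pd.Series([3.0, 1.5, 10.0, 0.2], index=list("abcd"))
    q = pd.Series([0.005, 0.005, 0.02, 0.001], index=list("abcd"))
    calls = fv.classify_calls(fc, q)
    assert list(calls) == ["up", "none", "none", "down"]


def test_call_deus_detects_an_obvious_change():
    rng = np.random.default_rng(1)
    base = rng.integers(50, 500, size=200)
    counts = pd.DataFrame(
        {
            "BD_1": rng.poisson(base), "BD_2": rng.poisson(base),
            "BB_1": rng.poisson(base), "BB_2": rng.poisson(base),
        },
        index=[f"g{i}" for i in range(200)],
    )
    counts.loc["g0", ["BB_1", "BB_2"]] *= 20
    sheet = fv.SampleSheet(
        {c: (c.split("_")[0], int(c.split("_")[1])) for c in counts},
        stages=("BD", "BB"),
    )
    cm = fv.CountMatrix(
        counts=counts,
        lengths=pd.Series(1000, index=counts.index),
        sheet=sheet,
    )
    result = fv.call_deus(cm, ("BD", "BB"))
    assert result.table.loc["g0", "call"] == "up"
    assert result.summary["total"] == result.summary["up"] + result.summary["down"]
    with pytest.raises(ValueError, match="unknown stage"):
        fv.call_deus(cm, ("BD", "XX"))


def test_fold_change_zero_conventions(small_dataset):
    _, _, cm, _ = small_dataset
    result = fv.call_deus(cm, ("BD", "BB"))
    zero_both = (result.table["mean_a"] == 0) & (result.table["mean_b"] == 0)
    if zero_both.any():
        assert (result.table.loc[zero_both, "fold_change"] == 1.0).all()
    assert result.table["pvalue"].between(0, 1).all()
    assert result.table["qvalue"].between(0, 1).all()


# --- Wilcoxon rank-sum ------------------------------------------------------

def test_family_test_exact_enumeration_example():
    assert fv.family_expression_test([3, 4], [1, 2]) == pytest.approx(1 / 6)


def test_family_test_identical_groups_is_not_significant():
    assert fv.family_expression_test([1, 2, 3], [1, 2, 3]) >= 0.5


def test_family_test_separated_groups_normal_approximation():
    family = list(range(100, 110))
    background = list(range(10))
    assert fv.family_expression_test(family, background) < 1e-3
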
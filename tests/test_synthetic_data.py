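"""Generator contracts: catalog structure, determinism, NB sampling
statistics and planted-signal construction."""

import numpy as np
import pandas as pd
import pytest

import flavnet as fv


def test_default_family_counts_match_catalog_spec():
    config = fv.SimConfig(n_genes=1000, seed=3)
    catalog = fv.generate_catalog(config)
    fam = catalog.table["family"]
    assert (fam == "CHS").sum() == 14
    assert (fam == "F3'5'H").sum() == 18
    assert (fam == "WD40").sum() == 37


def test_empty_family_spec_leaves_genes_unlabelled():
    config = fv.SimConfig(n_genes=100, family_spec={}, motif_spec=[],
                          n_planted_deu_per_phase=0, seed=1)
    catalog = fv.generate_catalog(config)
    assert (catalog.table["family"] == "").all()


def test_same_seed_gives_byte_identical_outputs():
    config = fv.SimConfig(n_genes=300, n_planted_deu_per_phase=5, seed=11)
    runs = []
    for _ in range(2):
        catalog = fv.generate_catalog(config)
        cm, truth = fv.simulate_counts(catalog, config)
        runs.append(
            catalog.table.to_csv()
            + catalog.gene2go.to_csv()
            + cm.counts.to_csv()
            + truth.deu.to_csv()
        )
    assert runs[0] == runs[1]


def test_count_matrix_shape_contract():
    config = fv.SimConfig(n_genes=1000, seed=2)
    cm, _ = fv.simulate_counts(fv.generate_catalog(config), config)
    assert cm.counts.shape == (1000, 8)
    assert (cm.counts.to_numpy() >= 0).all()


def test_oversized_family_spec_rejected():
    config = fv.SimConfig(n_genes=50)
    with pytest.raises(ValueError, match="exceed n_genes"):
        config.validate()


def test_negative_dispersion_rejected():
    with pytest.raises(ValueError, match="dispersion"):
        fv.SimConfig(n_genes=100, family_spec={}, dispersion=-0.1).validate()


def test_truth_ids_exist_and_signs_are_unit(small_dataset):
    _, catalog, cm, truth = small_dataset
    assert set(truth.deu["gene_id"]) <= set(catalog.genes)
    assert set(np.sign(truth.deu["log2fc"])) <= {-1.0, 1.0}
    assert set(truth.motifs["sign"]) <= {-1, 1}
    assert set(truth.motifs["regulator"]) <= set(catalog.regulators)


def test_planted_fold_change_recovered_from_many_draws():
    """With log2FC = 3 the later/earlier ratio of sample means over ~10^4
    NB draws (alpha = 0.05) must sit in the CLT band around 8."""
    config = fv.SimConfig(
        n_genes=50, family_spec={}, motif_spec=[], reps_per_stage=5000,
        dispersion=0.05, n_planted_deu_per_phase=1, planted_log2fc=3.0, seed=5,
    )
    catalog = fv.generate_catalog(config)
    cm, truth = fv.simulate_counts(catalog, config)
    gene = truth.deu.loc[truth.deu["phase"] == "early", "gene_id"].iloc[0]
    sign = np.sign(truth.deu.loc[truth.deu["phase"] == "early", "log2fc"].iloc[0])
    bd = cm.counts.loc[gene, cm.stage_columns("BD")].mean()
    bb = cm.counts.loc[gene, cm.stage_columns("BB")].mean()
    ratio = bb / bd if sign > 0 else bd / bb
    assert 7.4 <= ratio <= 8.7


def test_unplanted_genes_have_flat_stage_means():
    config = fv.SimConfig(
        n_genes=50, family_spec={}, motif_spec=[], reps_per_stage=5000,
        dispersion=0.05, n_planted_deu_per_phase=1, seed=5,
    )
    catalog = fv.generate_catalog(config)
    cm, truth = fv.simulate_counts(catalog, config)
    planted = set(truth.deu["gene_id"])
    others = [g for g in catalog.genes if g not in planted][:10]
    for gene in others:
        means = [cm.counts.loc[gene, cm.stage_columns(s)].mean()
                 for s in cm.sheet.stages]
        assert max(means) / max(min(means), 1e-9) < 1.1


def test_zero_dispersion_is_poisson_limit():
    config = fv.SimConfig(
        n_genes=100, family_spec={}, motif_spec=[], reps_per_stage=500,
        dispersion=0.0, n_planted_deu_per_phase=0, seed=9,
    )
    cm, _ = fv.simulate_counts(fv.generate_catalog(config), config)
    block = cm.counts[cm.stage_columns("BD")].to_numpy(dtype=float)
    mean = block.mean(axis=1)
    var = block.var(axis=1, ddof=1)
    ratio = var / np.maximum(mean, 1e-9)
    assert abs(np.median(ratio) - 1.0) < 0.05
    assert (np.abs(ratio - 1.0) < 0.3).mean() > 0.95


def test_planted_motif_correlations_at_zero_noise():
    """Positive planted regulators are exact count copies (R = +1);
    negative ones mirror the profile on the log2 scale (strongly negative
    R, bounded away from the thresholds, up to integer rounding)."""
    config = fv.SimConfig(seed=4, motif_noise=0.0)
    cm, truth = fv.simulate_counts(fv.generate_catalog(config), config)
    for row in truth.motifs.itertuples(index=False):
        x = cm.counts.loc[row.structural].to_numpy(dtype=float)
        y = cm.counts.loc[row.regulator].to_numpy(dtype=float)
        if row.sign == 1:
            assert fv.pearson_r(x, y) == 1.0
        else:
            r = fv.pearson_r(np.log2(x + 1.0), np.log2(y + 1.0))
            assert r <= -0.95


def test_dataset_roundtrip(tmp_path, small_dataset):
    config, catalog, cm, truth = small_dataset
    fv.write_dataset(tmp_path, config, catalog, cm, truth)
    sheet = fv.io_formats.read_sample_sheet(tmp_path / "samples.tsv")
    back = fv.read_counts(tmp_path / "counts.tsv", sheet)
    pd.testing.assert_frame_equal(back.counts, cm.counts)
    pd.testing.assert_series_equal(back.lengths, cm.lengths, check_names=False)
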
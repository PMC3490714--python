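import numpy as np
import pytest

from starchnet.ggm import partial_corr_full, CorrelationMatrix
from starchnet.simulate import (
    GroundTruth,
    group_mean_profiles,
    make_compendium,
    make_morphology,
    make_sparse_ggm,
    simulate_diurnal_matrix,
    simulate_ggm_matrix,
)

PHASES = ["dark"] * 5 + ["light"] * 5


class TestSparseGGM:
    def test_zero_density_diagonal_precision(self):
        truth = make_sparse_ggm(10, edge_density=0.0, pcor_magnitude=0.3, seed=0)
        assert truth.true_edges == set()
        np.testing.assert_allclose(truth.precision, np.eye(10))
        np.testing.assert_allclose(truth.true_pcor, 0.0)

    def test_implied_pcor_magnitude_in_band(self):
        truth = make_sparse_ggm(20, edge_density=0.15, pcor_magnitude=0.3, seed=1)
        # oracle: invert-and-standardize the generated precision matrix
        sigma = np.linalg.inv(truth.precision)
        d = np.sqrt(np.diag(sigma))
        corr = CorrelationMatrix(truth.gene_ids, sigma / np.outer(d, d))
        net = partial_corr_full(corr)
        idx = {g: i for i, g in enumerate(truth.gene_ids)}
        mags = [abs(net.pcor[idx[a], idx[b]]) for a, b in truth.true_edges]
        assert all(0.2 <= m <= 0.4 for m in mags)

    def test_true_edges_match_nonzero_pattern(self):
        truth = make_sparse_ggm(15, n_edges=12, pcor_magnitude=0.3, seed=2)
        iu = np.triu_indices(15, k=1)
        nonzero = {
            (truth.gene_ids[i], truth.gene_ids[j])
            for i, j in zip(*iu)
            if abs(truth.true_pcor[i, j]) > 1e-12
        }
        assert nonzero == truth.true_edges
        assert len(truth.true_edges) == 12

    def test_positive_definite(self):
        truth = make_sparse_ggm(30, n_edges=40, pcor_magnitude=0.35, seed=3)
        assert np.linalg.eigvalsh(truth.precision)[0] > 0

    def test_seed_determinism(self):
        a = make_sparse_ggm(12, n_edges=10, pcor_magnitude=0.3, seed=7)
        b = make_sparse_ggm(12, n_edges=10, pcor_magnitude=0.3, seed=7)
        assert a.true_edges == b.true_edges
        np.testing.assert_array_equal(a.precision, b.precision)
        assert a.group_assignment == b.group_assignment

    def test_bad_magnitude_rejected(self):
        with pytest.raises(ValueError):
            make_sparse_ggm(10, edge_density=0.1, pcor_magnitude=0.95, seed=0)


class TestDiurnalSimulation:
    def test_group_B_light_minus_dark_is_amplitude(self):
        truth = make_sparse_ggm(40, edge_density=0.0, pcor_magnitude=0.3, seed=4)
        mat = simulate_diurnal_matrix(truth, amplitude=2.0, noise_sd=0.01, seed=5)
        for i, g in enumerate(truth.group_assignment):
            if g == "B":
                light = mat.values[i, 5:].mean()
                dark = mat.values[i, :5].mean()
                assert light - dark == pytest.approx(2.0, abs=0.05)

    def test_zero_amplitude_identity_precision_uncorrelated(self):
        truth = make_sparse_ggm(10, edge_density=0.0, pcor_magnitude=0.3, seed=6)
        mat = simulate_diurnal_matrix(truth, amplitude=0.0, noise_sd=1.0, seed=7)
        r = np.corrcoef(mat.values)
        iu = np.triu_indices(10, k=1)
        assert np.median(np.abs(r[iu])) < 0.4

    def test_large_sample_pcor_consistency(self):
        truth = make_sparse_ggm(10, n_edges=8, pcor_magnitude=0.3, seed=8)
        mat = simulate_ggm_matrix(truth, 5000, seed=9)
        r = np.corrcoef(mat.values)
        net = partial_corr_full(CorrelationMatrix(truth.gene_ids, 0.5 * (r + r.T)))
        np.testing.assert_allclose(net.pcor, truth.true_pcor, atol=0.05)

    def test_study_scale_pipeline_completes(self):
        # 133 genes x 10 arrays: shrinkage keeps everything invertible
        from starchnet.ggm import run_ggm

        truth = make_sparse_ggm(133, edge_density=0.03, pcor_magnitude=0.25, seed=10)
        mat = simulate_diurnal_matrix(truth, seed=11)
        net = run_ggm(mat)
        assert net.shrinkage_lambda > 0
        assert net.p_value is not None

    def test_transition_bump_confined_to_first_light_sample(self):
        shapes = group_mean_profiles(["C", "D"], PHASES)
        np.testing.assert_array_equal(shapes[0, :5], 0.0)
        assert shapes[0, 5] == 1.0
        np.testing.assert_array_equal(shapes[0, 6:], 0.0)
        np.testing.assert_array_equal(shapes[1], -shapes[0])


class TestCompendium:
    def test_planted_beats_decoys(self):
        wins = 0
        for seed in range(40):
            comp = make_compendium([("R", "T")], n_decoys=40, effect=0.5,
                                   noise_sd=0.1, seed=seed)
            planted = comp.loc[comp["regulator_gene"] == "R", "correlation"].iloc[0]
            decoys = comp.loc[comp["regulator_gene"] != "R", "correlation"]
            wins += planted > decoys.max()
        assert wins >= 38  # >= 95% of seeds

    def test_no_decoys(self):
        comp = make_compendium([("R", "T")], n_decoys=0, seed=0)
        assert len(comp) == 1

    def test_truncation_to_unit_interval(self):
        comp = make_compendium([("R", "T")], n_decoys=200, effect=0.9,
                               noise_sd=0.5, seed=1)
        assert comp["correlation"].between(-1, 1).all()


class TestMorphologyGenerator:
    def test_circles_have_unit_circularity(self):
        from starchnet.morphology import circularity

        table = make_morphology(n_objects=30, seed=0, wild_axis_ratio=1.0,
                                mutant_axis_ratio=1.0, shape_jitter=0.0)
        chl = table.loc[table["object_class"] == "chloroplast"]
        c = circularity(chl["area"].to_numpy(), chl["perimeter"].to_numpy())
        np.testing.assert_allclose(c, 1.0, atol=1e-6)

    def test_planted_area_reduction_detected(self):
        from starchnet.morphology import mann_whitney_u

        hits = 0
        for seed in range(20):
            t = make_morphology(n_objects=200, seed=seed)
            chl = t.loc[t["object_class"] == "chloroplast"]
            x = chl.loc[chl["line_label"] == "mutant", "area"]
            y = chl.loc[chl["line_label"] == "wild_type", "area"]
            _, p = mann_whitney_u(x, y, mode="approx")
            hits += p < 0.05
        assert hits >= 19

    def test_identical_lines_calibrated(self):
        from starchnet.morphology import mann_whitney_u

        rejections = 0
        for seed in range(40):
            t = make_morphology(n_objects=80, seed=seed, mutant_area_scale=1.0,
                                mutant_axis_ratio=1.4)
            chl = t.loc[t["object_class"] == "chloroplast"]
            x = chl.loc[chl["line_label"] == "mutant", "area"]
            y = chl.loc[chl["line_label"] == "wild_type", "area"]
            _, p = mann_whitney_u(x, y, mode="approx")
            rejections += p < 0.05
        # ~ alpha = 0.05 of 40 runs, generous binomial upper bound
        assert rejections <= 7

    def test_granule_rows_accompany_counts(self):
        t = make_morphology(n_objects=10, seed=3)
        chl = t.loc[t["object_class"] == "chloroplast"]
        for _, row in chl.iterrows():
            gr = t.loc[t["object_id"].str.startswith(row["object_id"] + "_gr")]
            assert len(gr) == row["granule_count"]
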
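"""Normalization, clustering, differential-abundance, and coupling tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import squareform

from redoxcyto import (
    AbundanceMatrix,
    OmicsSimConfig,
    coupling_classes,
    diff_abundance,
    diff_expression_rna,
    gen_omics,
    hcluster,
    median_log_normalize,
    ppm_normalize,
)
from redoxcyto.omics import linkage_to_newick


def two_group_matrix(values_a, values_b, n_features=1, age=48):
    """Matrix with one feature per row, 3 oxidized vs 3 reduced samples."""
    cols = [f"oxidized_{age}h_r{i}" for i in (1, 2, 3)] + [
        f"reduced_{age}h_r{i}" for i in (1, 2, 3)
    ]
    data = np.atleast_2d(np.concatenate([values_a, values_b]))
    if n_features > 1:
        data = np.tile(data, (n_features, 1))
    values = pd.DataFrame(data, index=[f"f{i}" for i in range(len(data))], columns=cols)
    samples = pd.DataFrame(
        {
            "redox": ["oxidized"] * 3 + ["reduced"] * 3,
            "age": age,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=cols,
    )
    return AbundanceMatrix(values, samples, "protein")


class TestMedianLogNormalize:
    def test_hand_computed_row(self):
        m = two_group_matrix([2.0, 4.0, 8.0], [4.0, 4.0, 4.0])
        out = median_log_normalize(m)
        np.testing.assert_allclose(out.values.iloc[0, :3], [-1.0, 0.0, 1.0])

    def test_constant_row_maps_to_zeros(self):
        m = two_group_matrix([5.0] * 3, [5.0] * 3)
        assert (median_log_normalize(m).values.to_numpy() == 0).all()

    def test_row_scaling_invariance(self):
        m1 = two_group_matrix([2.0, 4.0, 8.0], [1.0, 2.0, 4.0])
        m2 = two_group_matrix([20.0, 40.0, 80.0], [10.0, 20.0, 40.0])
        pd.testing.assert_frame_equal(
            median_log_normalize(m1).values, median_log_normalize(m2).values
        )

    def test_output_row_medians_are_exactly_zero_for_odd_sample_count(self):
        rng = np.random.default_rng(0)
        cols = ["s1", "s2", "s3", "s4", "s5"]
        values = pd.DataFrame(rng.uniform(1, 9, size=(10, 5)), columns=cols)
        samples = pd.DataFrame(
            {"redox": ["reduced"] * 3 + ["oxidized"] * 2, "age": 48,
             "replicate": [1, 2, 3, 1, 2]},
            index=cols,
        )
        out = median_log_normalize(AbundanceMatrix(values, samples, "protein"))
        np.testing.assert_allclose(out.values.median(axis=1), 0.0, atol=1e-12)

    def test_all_zero_row_dropped_with_warning(self):
        m = two_group_matrix([0.0] * 3, [0.0] * 3)
        with pytest.warns(UserWarning, match="nonpositive median"):
            out = median_log_normalize(m)
        assert len(out.values) == 0


class TestHCluster:
    def test_duplicated_samples_merge_first_at_zero_distance(self, rng):
        vals = rng.normal(size=(50, 3))
        m = two_group_matrix([0.0] * 3, [0.0] * 3)
        data = np.column_stack([vals, vals[:, :1], vals[:, 1:]])
        m.values = pd.DataFrame(data[:, :6], index=[f"g{i}" for i in range(50)],
                                columns=m.values.columns)
        res = hcluster(m, cluster_features=False)
        # the first merge joins the duplicated pair at distance ~ 0
        assert res.sample_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_sample_error_names_sample(self, rng):
        m = two_group_matrix([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        m.values = pd.DataFrame(
            rng.normal(size=(20, 6)), index=[f"g{i}" for i in range(20)],
            columns=m.values.columns,
        )
        m.values["reduced_48h_r3"] = 7.0  # constant column
        with pytest.raises(ValueError, match="reduced_48h_r3"):
            hcluster(m)

    def test_sign_flipped_profile_sits_at_distance_two(self, rng):
        base = rng.normal(size=40)
        cols = ["a", "b"]
        values = pd.DataFrame({"a": base, "b": -base})
        samples = pd.DataFrame(
            {"redox": ["reduced", "oxidized"], "age": 48, "replicate": [1, 1]},
            index=cols,
        )
        m = AbundanceMatrix(values, samples, "protein")
        res = hcluster(m, cluster_features=False)
        assert res.sample_linkage[0, 2] == pytest.approx(2.0, abs=1e-9)

    def test_samples_pair_by_redox_before_age_on_default_synthetic(self):
        protein, _, _ = gen_omics(OmicsSimConfig(seed=4))
        res = hcluster(protein, cluster_features=False)
        flat = fcluster(res.sample_linkage, 2, criterion="maxclust")
        redox = protein.samples.loc[list(res.sample_order), "redox"].to_numpy()
        groups = {c: set(redox[flat == c]) for c in np.unique(flat)}
        assert all(len(v) == 1 for v in groups.values())

    def test_newick_export_contains_all_leaves(self):
        protein, _, _ = gen_omics(OmicsSimConfig(seed=4, n_features=60, n_planted_de=6))
        res = hcluster(protein, cluster_features=False)
        nwk = linkage_to_newick(res.sample_linkage, list(res.sample_order))
        assert nwk.endswith(";")
        for name in res.sample_order:
            assert name in nwk


class TestDiffAbundance:
    def test_hand_computed_welch_statistic(self):
        # A = (1.0, 1.1, 0.9) vs B = (3.0, 3.1, 2.9): t = -2 / sqrt(0.01/3 + 0.01/3)
        m = two_group_matrix([1.0, 1.1, 0.9], [3.0, 3.1, 2.9])
        res = diff_abundance(m, 48, method="bh")
        expected = -2.0 / np.sqrt(0.01 / 3 + 0.01 / 3)
        assert res.table["t"].iloc[0] == pytest.approx(expected, rel=1e-9)
        assert abs(res.table["t"].iloc[0]) == pytest.approx(24.49, abs=0.01)

    def test_identical_groups_not_significant(self):
        m = two_group_matrix([1.0, 1.1, 0.9], [1.0, 1.1, 0.9], n_features=5)
        res = diff_abundance(m, 48)
        assert (res.table["log2fc"] == 0).all()
        assert not res.table["significant"].any()

    def test_q_dominates_p_and_is_monotone(self):
        protein, _, _ = gen_omics(OmicsSimConfig(seed=6))
        res = diff_abundance(protein, 48, seed=6)
        tab = res.table.sort_values("p")
        assert (tab["q"] >= tab["p"] - 1e-12).all()
        assert (np.diff(tab["q"].to_numpy()) >= -1e-12).all()

    def test_label_swap_negates_lfc_and_preserves_p(self):
        protein, _, _ = gen_omics(OmicsSimConfig(seed=7, n_features=200, n_planted_de=20))
        res = diff_abundance(protein, 48, seed=7)
        swapped = protein.samples.copy()
        swapped["redox"] = swapped["redox"].map(
            {"reduced": "oxidized", "oxidized": "reduced"}
        )
        res2 = diff_abundance(
            AbundanceMatrix(protein.values, swapped, "protein"), 48, seed=7
        )
        np.testing.assert_allclose(res2.table["log2fc"], -res.table["log2fc"])
        np.testing.assert_allclose(res2.table["p"], res.table["p"])

    def test_fold_change_filter_blocks_small_effects(self):
        rng = np.random.default_rng(1)
        # highly consistent but only 0.5 log2 units apart: p small, fc filter blocks
        a = 1.0 + 0.001 * rng.standard_normal(3)
        b = 1.5 + 0.001 * rng.standard_normal(3)
        m = two_group_matrix(b, a, n_features=3)
        res = diff_abundance(m, 48, method="bh")
        assert (res.table["q"] <= 0.05).all()
        assert not res.table["significant"].any()

    def test_missingness_rule_excludes_sparse_features(self):
        m = two_group_matrix([1.0, 1.1, 0.9], [3.0, 3.1, 2.9], n_features=4)
        m.values.iloc[0, 0] = np.nan            # 1 missing: kept
        m.values.iloc[1, [0, 1]] = np.nan       # 2 missing in one group: dropped
        res = diff_abundance(m, 48, method="bh")
        assert "f1" not in res.table.index
        assert "f0" in res.table.index

    def test_planted_strong_effects_detected_with_high_sensitivity(self):
        protein, _, truth = gen_omics(OmicsSimConfig(seed=8))
        res = diff_abundance(protein, 48, seed=8)
        strong = truth[(truth["planted"]) & (truth["true_lfc_protein"].abs() >= 2.0)]
        assert res.table.loc[strong.index, "significant"].mean() >= 0.9

    def test_single_replicate_group_rejected(self):
        m = two_group_matrix([1.0, 1.1, 0.9], [3.0, 3.1, 2.9])
        with pytest.warns(UserWarning):
            small = AbundanceMatrix(
                m.values.iloc[:, [0, 3, 4]], m.samples.iloc[[0, 3, 4]], "protein"
            )
        with pytest.raises(ValueError, match="replicates"):
            diff_abundance(small, 48)


class TestPpmNormalize:
    def _counts(self, cols):
        samples = pd.DataFrame(
            {"redox": ["reduced", "oxidized"], "age": 48, "replicate": [1, 1]},
            index=list(cols),
        )
        return samples

    def test_hand_computed_column(self):
        samples = self._counts("ab")
        values = pd.DataFrame({"a": [10, 30, 60], "b": [1, 1, 2]}, index=["x", "y", "z"])
        out = ppm_normalize(AbundanceMatrix(values, samples, "rna"))
        np.testing.assert_allclose(out.values["a"], [1e5, 3e5, 6e5])

    def test_every_column_sums_to_a_million(self):
        rng = np.random.default_rng(3)
        samples = self._counts("ab")
        values = pd.DataFrame(rng.integers(0, 500, size=(40, 2)), columns=["a", "b"])
        out = ppm_normalize(AbundanceMatrix(values, samples, "rna"))
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6)

    def test_depth_invariance(self):
        samples = self._counts("ab")
        v1 = pd.DataFrame({"a": [10, 30, 60], "b": [5, 5, 5]})
        v2 = v1.copy()
        v2["a"] = v2["a"] * 2
        o1 = ppm_normalize(AbundanceMatrix(v1, samples, "rna"))
        o2 = ppm_normalize(AbundanceMatrix(v2, samples, "rna"))
        pd.testing.assert_series_equal(o1.values["a"], o2.values["a"])

    def test_zero_total_sample_rejected(self):
        samples = self._counts("ab")
        values = pd.DataFrame({"a": [10, 30], "b": [0, 0]})
        with pytest.raises(ValueError, match="zero-total"):
            ppm_normalize(AbundanceMatrix(values, samples, "rna"))


class TestRnaSubstituteTest:
    def test_planted_fourfold_feature_detected(self):
        _, rna, truth = gen_omics(OmicsSimConfig(seed=9))
        res = diff_expression_rna(ppm_normalize(rna), 48, seed=9)
        strong = truth[(truth["planted"]) & (~truth["uncoupled"]) &
                       (truth["true_lfc_rna"].abs() >= 2.0)]
        assert res.table.loc[strong.index, "significant"].mean() > 0.8

    def test_result_labeled_as_substitute(self):
        _, rna, _ = gen_omics(OmicsSimConfig(seed=9, n_features=100, n_planted_de=5))
        res = diff_expression_rna(ppm_normalize(rna), 48, seed=9)
        assert "substitute" in res.note


class TestCoupling:
    def _diff(self, lfc, sig, genes):
        table = pd.DataFrame(
            {
                "log2fc": lfc,
                "t": 0.0,
                "p": 0.0,
                "q": 0.0,
                "significant": sig,
            },
            index=genes,
        )
        from redoxcyto.omics import DiffResult

        return DiffResult(table, "oxidized vs reduced @ 48 h", 0.05, 2.0, "bh")

    def test_classification_rules(self):
        genes = ["up_coupled", "down_uncoupled", "not_sig"]
        prot = self._diff([2.0, -2.5, 3.0], [True, True, False], genes)
        rna = self._diff([1.5, 2.0, 3.0], [True, True, True], genes)
        out = coupling_classes(prot, rna).table
        assert out.loc["up_coupled", "coupling_class"] == "coupled-oxidized"
        assert out.loc["down_uncoupled", "coupling_class"] == "uncoupled-protein-reduced"
        assert out.loc["not_sig", "coupling_class"] == "ns"

    def test_non_ns_classes_require_protein_significance(self):
        genes = ["a", "b"]
        prot = self._diff([2.0, 2.0], [False, True], genes)
        rna = self._diff([-2.0, -2.0], [True, True], genes)
        out = coupling_classes(prot, rna).table
        sig_classes = out[out["coupling_class"] != "ns"]
        assert sig_classes["protein_significant"].all()

    def test_planted_hsp30_like_feature_classified_uncoupled(self):
        protein, rna, _ = gen_omics(OmicsSimConfig(seed=10))
        prot_res = diff_abundance(protein, 48, seed=10)
        rna_res = diff_expression_rna(ppm_normalize(rna), 48, seed=10)
        out = coupling_classes(prot_res, rna_res).table
        assert out.loc["HSP30like", "coupling_class"] == "uncoupled-protein-reduced"

    def test_disjoint_gene_sets_rejected(self):
        prot = self._diff([2.0], [True], ["a"])
        rna = self._diff([2.0], [True], ["b"])
        with pytest.raises(ValueError, match="shared"):
            coupling_classes(prot, rna)
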
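"""Copy-number concordance, identity vectors and mirror-tree statistics."""

import numpy as np
import pytest
from scipy import stats

from coevokit.coevo import (
    ContingencyTable,
    CopyProfile,
    DistanceMatrix,
    contingency_from_profiles,
    exact_mirror_permutation_pvalue,
    exact_permutation_independence_test,
    identity_vector,
    mirror_correlation,
    mirror_permutation_pvalue,
    msa_distance_matrix,
    n_distinguishable_permutations,
    pairwise_identity,
    pearson_chi2_test,
    permutation_independence_test,
    read_copy_profiles,
    vector_correlation,
)
from coevokit.seqcore import MSA, MSARow
from coevokit import packaged_copy_panel_path


class TestContingency:
    def test_eutherian_panel_reproduces_published_table(self, eutherian_panel):
        table = contingency_from_profiles(eutherian_panel)
        assert table.row_labels == (1, 2)  # family B levels
        assert table.col_labels == (0, 1, 2)  # family A levels
        assert table.counts.tolist() == [[1, 4, 0], [0, 0, 3]]
        assert table.n == 8

    def test_packaged_panel_matches_inline_fixture(self, eutherian_panel):
        packaged = read_copy_profiles(packaged_copy_panel_path())
        assert {(p.species, p.copies_a, p.copies_b) for p in packaged} == {
            (p.species, p.copies_a, p.copies_b) for p in eutherian_panel
        }

    @pytest.mark.parametrize(
        "profiles",
        [
            [CopyProfile("solo", 1, 1)],
            [CopyProfile(f"s{i}", 2, 1) for i in range(5)],
        ],
    )
    def test_constant_panels_are_flagged_degenerate(self, profiles):
        table = contingency_from_profiles(profiles)
        assert table.shape == (1, 1)
        assert table.degenerate

    def test_copy_number_bound_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            CopyProfile("weird", 11, 1)


class TestPearsonChi2:
    def test_published_table_statistic_df_and_pvalue(self, eutherian_panel):
        res = pearson_chi2_test(contingency_from_profiles(eutherian_panel))
        assert res.statistic == pytest.approx(8.0, abs=1e-12)
        assert res.df == 2
        assert round(res.p_value, 3) == 0.018

    def test_proportional_rows_give_zero_statistic(self):
        table = ContingencyTable((0, 1), (0, 1), np.array([[2, 4], [1, 2]]))
        res = pearson_chi2_test(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_table_advises_permutation_test(self):
        table = contingency_from_profiles([CopyProfile(f"s{i}", 1, 1) for i in range(4)])
        with pytest.raises(ValueError, match="permutation"):
            pearson_chi2_test(table)

    def test_matches_reference_implementation_on_random_tables(self):
        """Cross-check against scipy's chi-squared contingency test."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            r, c = rng.integers(2, 5, size=2)
            counts = rng.integers(1, 20, size=(r, c))
            table = ContingencyTable(
                tuple(range(r)), tuple(range(c)), counts
            )
            res = pearson_chi2_test(table)
            ref = stats.chi2_contingency(counts, correction=False)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.df == ref.dof
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestPermutationIndependence:
    def test_constant_family_b_gives_p_one(self):
        profiles = [CopyProfile(f"s{i}", i % 2 + 1, 1) for i in range(8)]
        res = permutation_independence_test(profiles, n_perm=199, seed=3)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_coupling_is_significant_by_exact_enumeration(self):
        profiles = [CopyProfile(f"s{i}", 1 + (i < 4), 1 + (i < 4)) for i in range(8)]
        exact = exact_permutation_independence_test(profiles)
        assert exact.p_value <= 0.05
        mc = permutation_independence_test(profiles, n_perm=999, seed=5)
        assert mc.p_value <= 0.05

    def test_monte_carlo_matches_exact_enumeration(self, eutherian_panel):
        exact = exact_permutation_independence_test(eutherian_panel)
        assert exact.n_permutations == n_distinguishable_permutations(
            [p.copies_b for p in eutherian_panel]
        )
        mc = permutation_independence_test(eutherian_panel, n_perm=100_000, seed=1)
        sigma = np.sqrt(exact.p_value * (1 - exact.p_value) / 100_000)
        assert abs(mc.p_value - exact.p_value) < 4 * sigma + 2 / 100_000

    def test_seed_is_mandatory_and_reproducible(self, eutherian_panel):
        with pytest.raises(ValueError, match="seed"):
            permutation_independence_test(eutherian_panel, n_perm=199)
        a = permutation_independence_test(eutherian_panel, n_perm=199, seed=9)
        b = permutation_independence_test(eutherian_panel, n_perm=199, seed=9)
        assert a.p_value == b.p_value


def _msa(rows):
    return MSA([MSARow(f"r{i}", sp, g, paralog=par)
                for i, (sp, g, par) in enumerate(rows)])


class TestIdentityVectors:
    def test_pairwise_identity_gap_conventions(self):
        # both-gap columns excluded; one-gap columns count as mismatches
        assert pairwise_identity("AC-E", "AC-F") == pytest.approx(100 * 2 / 3)
        assert pairwise_identity("AC-E", "ACDE") == pytest.approx(100 * 3 / 4)

    def test_identity_vector_toy_values(self):
        msa = _msa([("hum", "ACDE", None), ("chp", "ACDF", None), ("rod", "AGGG", None)])
        vec = identity_vector(msa, "hum")
        assert vec == {"chp": pytest.approx(75.0), "rod": pytest.approx(25.0)}

    def test_all_rows_equal_reference_give_100(self):
        msa = _msa([("hum", "ACDE", None), ("a", "ACDE", None), ("b", "ACDE", None)])
        assert set(identity_vector(msa, "hum").values()) == {100.0}

    def test_multi_paralog_species_collapsed_by_max(self):
        msa = _msa([
            ("hum", "ACDE", None),
            ("mus", "ACDF", "1"),  # 75 %
            ("mus", "AGGG", "2"),  # 25 %
        ])
        assert identity_vector(msa, "hum")["mus"] == pytest.approx(75.0)

    def test_missing_reference_lists_available_species(self):
        msa = _msa([("a", "ACDE", None), ("b", "ACDF", None)])
        with pytest.raises(KeyError, match="available"):
            identity_vector(msa, "hum")

    def test_vector_correlation_limit_cases_and_hand_value(self):
        va = {"a": 100.0, "b": 50.0, "c": 25.0}
        assert vector_correlation(va, va).r == pytest.approx(1.0)
        neg = {k: 100.0 - v for k, v in va.items()}
        assert vector_correlation(va, neg).r == pytest.approx(-1.0)
        vb = {"a": 100.0, "b": 60.0, "c": 20.0}
        # hand evaluation of the Pearson formula on these three pairs
        assert vector_correlation(va, vb).r == pytest.approx(0.98198, abs=1e-4)

    def test_too_few_shared_species_is_error(self):
        with pytest.raises(ValueError, match="shared"):
            vector_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


class TestDistanceMatrices:
    def test_msa_distance_matrix_toy_values(self):
        msa = _msa([("hum", "ACDE", None), ("chp", "ACDF", None), ("rod", "AGGG", None)])
        dm = msa_distance_matrix(msa)
        assert dm.labels == ["chp", "hum", "rod"]
        get = lambda x, y: dm.values[dm.labels.index(x), dm.labels.index(y)]
        assert get("hum", "chp") == pytest.approx(25.0)
        assert get("hum", "rod") == pytest.approx(75.0)
        assert get("chp", "rod") == pytest.approx(100 - pairwise_identity("ACDF", "AGGG"))

    def test_identical_rows_give_zero_distances(self):
        msa = _msa([("a", "ACDE", None), ("b", "ACDE", None), ("c", "ACDE", None)])
        assert np.allclose(msa_distance_matrix(msa).values, 0.0)

    def test_symmetry_zero_diagonal_and_paralog_mean_collapse(self):
        msa = _msa([
            ("hum", "ACDE", None),
            ("mus", "ACDF", "1"),
            ("mus", "AGGG", "2"),
            ("rod", "ACGG", None),
        ])
        dm = msa_distance_matrix(msa)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        expected = np.mean([100 - 75.0, 100 - 25.0])  # mean over the two paralogs
        assert dm.values[dm.labels.index("hum"), dm.labels.index("mus")] == (
            pytest.approx(expected)
        )

    def test_tsv_roundtrip(self, tmp_path):
        dm = DistanceMatrix(["a", "b", "c"], np.array(
            [[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]]
        ))
        dm.to_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
        assert back.labels == dm.labels
        assert np.allclose(back.values, dm.values)

    def test_newick_patristic_distances(self):
        dm = DistanceMatrix.from_newick("((a:1,b:2):1,c:3);")
        get = lambda x, y: dm.values[dm.labels.index(x), dm.labels.index(y)]
        assert get("a", "b") == pytest.approx(3.0)
        assert get("a", "c") == pytest.approx(5.0)
        assert get("b", "c") == pytest.approx(6.0)


def _dm_from_upper(labels, upper):
    k = len(labels)
    values = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    values[iu] = upper
    values += values.T
    return DistanceMatrix(labels, values)


class TestMirrorTree:
    def test_identical_matrices_give_r_one(self):
        dm = _dm_from_upper(list("abcd"), [1, 2, 3, 4, 5, 6])
        res = mirror_correlation(dm, dm)
        assert res.r == pytest.approx(1.0)
        assert res.n_pairs == 6

    def test_affine_rescaling_invariance(self):
        da = _dm_from_upper(list("abcd"), [1, 2, 3, 4, 5, 6])
        db = _dm_from_upper(list("abcd"), [2 * x + 5 for x in [1, 2, 3, 4, 5, 6]])
        assert mirror_correlation(da, db).r == pytest.approx(1.0)

    def test_reversed_upper_triangle_hand_value(self):
        da = _dm_from_upper(list("abcd"), [1, 2, 3, 4, 5, 6])
        db = _dm_from_upper(list("abcd"), [6, 5, 4, 3, 2, 1])
        assert mirror_correlation(da, db).r == pytest.approx(-1.0)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(2)
        raw = rng.random((5, 5))
        vals = (raw + raw.T) / 2
        np.fill_diagonal(vals, 0)
        da = DistanceMatrix(list("abcde"), vals)
        order = [3, 0, 4, 1, 2]
        db = DistanceMatrix(
            [list("abcde")[i] for i in order], vals[np.ix_(order, order)]
        )
        assert mirror_correlation(da, db).r == pytest.approx(1.0)

    def test_too_few_common_labels_is_error(self):
        da = _dm_from_upper(list("abc"), [1, 2, 3])
        with pytest.raises(ValueError, match="common"):
            mirror_correlation(da, da)

    def test_exact_enumeration_on_small_label_set(self):
        rng = np.random.default_rng(8)
        raw = rng.random((4, 4))
        vals = (raw + raw.T) / 2
        np.fill_diagonal(vals, 0)
        da = DistanceMatrix(list("abcd"), vals)
        db = DistanceMatrix(list("abcd"), vals * 1.7)
        exact = exact_mirror_permutation_pvalue(da, db)
        assert exact.n_permutations == 24
        # identity and structure-preserving relabellings only
        assert 0 < exact.p_value <= 0.25

    def test_monte_carlo_matches_exact(self):
        rng = np.random.default_rng(12)
        raw = rng.random((5, 5))
        vals = (raw + raw.T) / 2
        np.fill_diagonal(vals, 0)
        da = DistanceMatrix(list("abcde"), vals)
        db = DistanceMatrix(list("abcde"), vals + rng.random((5, 5)) * 0)
        exact = exact_mirror_permutation_pvalue(da, db)
        mc = mirror_permutation_pvalue(da, db, n_perm=4999, seed=4)
        sigma = np.sqrt(exact.p_value * (1 - exact.p_value) / 4999)
        assert abs(mc.p_value - exact.p_value) < 4 * sigma + 2 / 4999

    def test_null_pvalues_roughly_uniform_under_shuffled_labels(self):
        """Calibration: shuffling one matrix's labels should give a flat p."""
        rng = np.random.default_rng(21)
        ps = []
        for rep in range(30):
            raw = rng.random((6, 6))
            va = (raw + raw.T) / 2
            np.fill_diagonal(va, 0)
            raw = rng.random((6, 6))
            vb = (raw + raw.T) / 2
            np.fill_diagonal(vb, 0)
            da = DistanceMatrix(list("abcdef"), va)
            db = DistanceMatrix(list("abcdef"), vb)
            ps.append(mirror_permutation_pvalue(da, db, n_perm=199, seed=rep).p_value)
        assert 0.25 < np.mean(ps) < 0.75
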
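"""Expression container, complete-linkage clustering, cuts, profiles, markers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage

from cslkit.catalog import record_from_row
from cslkit.coexpression import (
    CoexpressionError,
    CoexpressionGroup,
    ExpressionMatrix,
    SampleMeta,
    cut_tree,
    family_accumulative_profile,
    hcluster,
    log_transform,
    marker_coexpression,
    match_groups,
    pearson_matrix,
    specificity_score,
    two_level_labels,
)

from conftest import brute_force_complete_linkage, random_matrix


class TestExpressionMatrix:
    def test_negative_signals_rejected(self):
        with pytest.raises(CoexpressionError, match="nonnegative"):
            ExpressionMatrix(["g"], [SampleMeta("s", "t")], [[-1.0]])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(CoexpressionError, match="duplicate gene"):
            ExpressionMatrix(
                ["g", "g"],
                [SampleMeta("s", "t")],
                [[1.0], [2.0]],
            )

    def test_constant_genes_flagged(self, small_matrix):
        m = ExpressionMatrix(
            small_matrix.genes + ["flat"],
            small_matrix.samples,
            np.vstack([small_matrix.values, np.full(small_matrix.n_samples, 3.0)]),
        )
        assert m.constant_genes == ["flat"]


class TestLogTransform:
    def test_known_values(self, small_matrix):
        m = small_matrix
        m.values[0, 0] = 0.0
        m.values[0, 1] = 1023.0
        logged = log_transform(m)
        assert logged.values[0, 0] == 0.0
        assert logged.values[0, 1] == pytest.approx(10.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_on_random_matrices(self, seed):
        m = random_matrix(np.random.default_rng(seed), 4, 5)
        logged = log_transform(m)
        order = np.argsort(m.values, axis=None)
        assert np.all(np.diff(logged.values.flatten()[order]) >= 0)


class TestPearsonMatrix:
    def test_duplicated_gene_rows_correlate_perfectly(self, small_matrix):
        m = ExpressionMatrix(
            ["a", "b"],
            small_matrix.samples,
            np.vstack([small_matrix.values[0], small_matrix.values[0]]),
        )
        assert pearson_matrix(m).loc["a", "b"] == 1.0

    def test_anticorrelated_rows(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = ExpressionMatrix(
            ["a", "b"],
            [SampleMeta(f"s{j}", f"t{j}") for j in range(4)],
            np.vstack([x, x[::-1]]),
        )
        assert pearson_matrix(m).loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_from_definition_summation(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 6, 5)
        corr = pearson_matrix(m)
        for i in range(6):
            for j in range(6):
                a, b = m.values[i], m.values[j]
                ca, cb = a - a.mean(), b - b.mean()
                want = (ca * cb).sum() / math.sqrt((ca**2).sum() * (cb**2).sum())
                assert corr.iloc[i, j] == pytest.approx(want, abs=1e-12)

    def test_too_few_samples_rejected(self):
        m = ExpressionMatrix(
            ["a", "b"],
            [SampleMeta("s0", "t"), SampleMeta("s1", "t")],
            [[1.0, 2.0], [2.0, 1.0]],
        )
        with pytest.raises(CoexpressionError):
            pearson_matrix(m)


class TestHcluster:
    def test_two_genes_merge_at_their_distance(self):
        m = ExpressionMatrix(
            ["a", "b"],
            [SampleMeta("s0", "t0"), SampleMeta("s1", "t1")],
            [[0.0, 0.0], [3.0, 4.0]],
        )
        tree = hcluster(m)
        assert tree.merges == ((0, 1, 5.0),)

    def test_duplicate_rows_merge_first_at_height_zero(self, small_matrix):
        values = np.vstack([small_matrix.values, small_matrix.values[2]])
        m = ExpressionMatrix(
            small_matrix.genes + ["gdup"], small_matrix.samples, values
        )
        tree = hcluster(m)
        first = tree.merges[0]
        assert first[2] == 0.0
        assert tree.members(m.n_genes) == {"g2", "gdup"}

    def test_nan_rejected(self, small_matrix):
        small_matrix.values[1, 1] = np.nan
        with pytest.raises(CoexpressionError):
            hcluster(small_matrix)

    def test_matches_brute_force_rescan_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            m = random_matrix(rng, n, int(rng.integers(3, 6)))
            tree = hcluster(m)
            oracle = brute_force_complete_linkage(m.values, m.genes)
            assert [tuple(t[:2]) for t in tree.merges] == [
                tuple(t[:2]) for t in oracle
            ]
            assert np.allclose(
                [t[2] for t in tree.merges], [t[2] for t in oracle], rtol=1e-12
            )

    def test_heights_match_scipy_complete_linkage(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            m = random_matrix(rng, int(rng.integers(3, 15)), 4)
            ours = sorted(t[2] for t in hcluster(m).merges)
            scipys = sorted(linkage(m.values, method="complete")[:, 2])
            assert np.allclose(ours, scipys, rtol=1e-10)

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(29)
        for _ in range(1000):
            m = random_matrix(rng, int(rng.integers(2, 10)), 3)
            heights = [t[2] for t in hcluster(m).merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


class TestCutTree:
    def test_extreme_cuts(self, small_matrix):
        tree = hcluster(small_matrix)
        assert len(cut_tree(tree, 1)[0].members) == small_matrix.n_genes
        singles = cut_tree(tree, small_matrix.n_genes)
        assert all(len(g.members) == 1 for g in singles)

    def test_groups_partition_for_all_k(self, small_matrix):
        tree = hcluster(small_matrix)
        for k in range(1, small_matrix.n_genes + 1):
            groups = cut_tree(tree, k)
            assert len(groups) == k
            members = [g for grp in groups for g in grp.members]
            assert sorted(members) == sorted(small_matrix.genes)

    def test_out_of_range_k_rejected(self, small_matrix):
        tree = hcluster(small_matrix)
        with pytest.raises(CoexpressionError):
            cut_tree(tree, 0)
        with pytest.raises(CoexpressionError):
            cut_tree(tree, small_matrix.n_genes + 1)

    def test_two_level_labels_nest_majors(self, small_matrix):
        tree = hcluster(small_matrix)
        labelled = two_level_labels(tree, k_major=2, k_sub=4)
        assert len(labelled) == 4
        # every subgroup is nested in exactly one major group, so both roman
        # numerals appear and letters restart within each major
        romans = {g.group_id[:-1] for g in labelled}
        assert romans == {"I", "II"}
        for roman in romans:
            letters = sorted(
                g.group_id[-1] for g in labelled if g.group_id[:-1] == roman
            )
            assert letters == [chr(ord("A") + i) for i in range(len(letters))]


class TestProfilesAndMarkers:
    def test_single_member_family_profile_is_its_row(self, small_matrix):
        cat = [record_from_row("g0", "CESA", "LOC_Os01g00100")]
        profile, argmax = family_accumulative_profile(small_matrix, cat, "CESA")
        expected = small_matrix.tissue_profile("mean").loc["g0"]
        assert np.allclose(profile.values, expected.values)
        assert argmax == {profile.idxmax()}

    def test_absent_family_rejected(self, small_matrix):
        with pytest.raises(CoexpressionError):
            family_accumulative_profile(small_matrix, [], "CSLD")

    def test_tau_extremes(self):
        assert specificity_score([7.0, 7.0, 7.0, 7.0]) == 0.0
        assert specificity_score([50.0, 0.0, 0.0, 0.0]) == 1.0

    def test_tau_hand_summed_profile(self):
        x = np.log2(np.array([8.0, 4.0, 2.0, 1.0]) + 1.0)
        want = float(np.sum(1.0 - x / x.max()) / 3.0)
        assert specificity_score([8.0, 4.0, 2.0, 1.0]) == pytest.approx(want)

    def test_all_zero_profile_rejected(self):
        with pytest.raises(CoexpressionError):
            specificity_score([0.0, 0.0])

    def test_marker_equal_to_gene_row_links_perfectly(self, small_matrix):
        m = ExpressionMatrix(
            small_matrix.genes + ["marker"],
            small_matrix.samples,
            np.vstack([small_matrix.values, small_matrix.values[3]]),
        )
        (link,) = marker_coexpression(m, ["marker"], threshold=0.9)
        assert link.best_partner == "g3"
        assert link.r == pytest.approx(1.0)
        assert link.passed

    def test_constant_marker_excluded_with_warning(self, small_matrix, caplog):
        m = ExpressionMatrix(
            small_matrix.genes + ["flat"],
            small_matrix.samples,
            np.vstack([small_matrix.values, np.full(small_matrix.n_samples, 2.0)]),
        )
        with caplog.at_level("WARNING"):
            assert marker_coexpression(m, ["flat"]) == []
        assert "constant" in caplog.text


class TestMatchGroups:
    def _group(self, gid, signature):
        return CoexpressionGroup(gid, (gid + "_gene",), signature=signature)

    def test_identical_signatures_similarity_one(self):
        sig = {"root": 2.0, "leaf": 1.0, "stem": 0.5}
        ga = [self._group("A", sig)]
        gb = [self._group("B", sig)]
        matches = match_groups(ga, gb, {t: t for t in sig})
        assert matches["A"][0] == ("B", pytest.approx(1.0))

    def test_orthogonal_signatures_similarity_zero(self):
        ga = [self._group("A", {"root": 1.0, "leaf": 0.0, "stem": 0.0})]
        gb = [self._group("B", {"root": 0.0, "leaf": 1.0, "stem": 0.0})]
        matches = match_groups(ga, gb, {t: t for t in ("root", "leaf", "stem")})
        assert matches["A"][0][1] == pytest.approx(0.0)

    def test_permuted_groups_recovered_as_top_matches(self):
        rng = np.random.default_rng(9)
        tissues = [f"t{i}" for i in range(6)]
        groups = [
            self._group(f"G{i}", {t: float(v) for t, v in zip(tissues, rng.uniform(0.1, 5.0, 6))})
            for i in range(5)
        ]
        perm = [groups[i] for i in (3, 0, 4, 2, 1)]
        matches = match_groups(groups, perm, {t: t for t in tissues})
        for g in groups:
            assert matches[g.group_id][0][0] == g.group_id

    def test_empty_map_rejected(self):
        with pytest.raises(CoexpressionError):
            match_groups([], [], {})
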
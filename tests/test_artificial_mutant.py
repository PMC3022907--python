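"""In-silico deletion, minimal-subtree queries and the redundancy screen."""

import numpy as np
import pytest

from cslkit.artificial_mutant import (
    DeletionSpec,
    MutantError,
    apply_deletion,
    deletion_recluster,
    minimal_subtree,
    redundancy_screen,
)
from cslkit.coexpression import ExpressionMatrix, SampleMeta, hcluster, log_transform
from cslkit.synthetic_data import SimulationConfig, simulate

from conftest import brute_force_minimal_subtree, random_matrix


class TestApplyDeletion:
    def test_empty_spec_returns_equal_matrix(self, small_matrix):
        out = apply_deletion(small_matrix, DeletionSpec())
        assert out.equals(small_matrix)
        assert out is not small_matrix

    def test_gene_removal_drops_one_row(self, small_matrix):
        out = apply_deletion(small_matrix, DeletionSpec.of(genes=["g2"]))
        assert out.n_genes == small_matrix.n_genes - 1
        assert "g2" not in out.genes
        assert out.samples == small_matrix.samples

    def test_tissue_removal_drops_all_matching_samples(self, small_matrix):
        out = apply_deletion(small_matrix, DeletionSpec.of(samples=["root"]))
        assert out.genes == small_matrix.genes
        assert all(s.tissue != "root" for s in out.samples)
        assert out.n_samples == 3

    def test_unknown_id_rejected(self, small_matrix):
        with pytest.raises(MutantError, match="nope"):
            apply_deletion(small_matrix, DeletionSpec.of(genes=["nope"]))

    def test_original_matrix_untouched(self, small_matrix):
        before = small_matrix.values.copy()
        apply_deletion(small_matrix, DeletionSpec.of(genes=["g0"]))
        assert np.array_equal(small_matrix.values, before)


class TestMinimalSubtree:
    def test_single_focal_gene_returns_first_merge_partner(self, small_matrix):
        tree = hcluster(small_matrix)
        a, b, _ = tree.merges[0]
        gene = tree.leaves[a]
        report = minimal_subtree(tree, {gene})
        assert report.minimal_cluster_members == {tree.leaves[a], tree.leaves[b]}
        assert report.extra_members == 1

    def test_all_leaves_return_root_with_no_extras(self, small_matrix):
        tree = hcluster(small_matrix)
        report = minimal_subtree(tree, set(tree.leaves))
        assert report.extra_members == 0
        assert report.passed

    def test_absent_focal_leaf_rejected(self, small_matrix):
        tree = hcluster(small_matrix)
        with pytest.raises(MutantError):
            minimal_subtree(tree, {"nope"})

    def test_agrees_with_exhaustive_node_enumeration(self):
        rng = np.random.default_rng(31)
        for _ in range(1000):
            n = int(rng.integers(2, 13))
            tree = hcluster(random_matrix(rng, n, 3))
            size = int(rng.integers(1, n + 1))
            focal = frozenset(rng.choice(tree.leaves, size=size, replace=False))
            report = minimal_subtree(tree, focal)
            if len(focal) == n:
                assert report.minimal_cluster_members == focal
            else:
                assert report.minimal_cluster_members == brute_force_minimal_subtree(
                    tree, focal
                )


class TestDeletionRecluster:
    def test_empty_spec_reproduces_plain_clustering_bitwise(self, small_matrix):
        plain = hcluster(log_transform(small_matrix))
        tree, _ = deletion_recluster(small_matrix, DeletionSpec(), {"g0", "g1"})
        assert tree == plain

    def test_deleting_a_complex_member_leaves_pair_tight(self):
        # three co-generated genes with identical signatures: remove one,
        # the remaining pair still forms its own minimal cluster
        cfg = SimulationConfig(seed=4, noise_sigma=0.0, redundancy_triple=None,
                               marker_spec=None)
        res = simulate(cfg)
        trio = [g for g, grp in res.ground_truth.group_of.items() if grp == "IB"]
        tree, report = deletion_recluster(
            res.matrix, DeletionSpec.of(genes=[trio[2]]), set(trio[:2])
        )
        assert report.minimal_cluster_members == set(trio[:2])
        assert report.extra_members == 0


@pytest.fixture(scope="module")
def planted():
    res = simulate(SimulationConfig(seed=12, noise_sigma=0.2))
    genes = [r.gene_name for r in res.genome.records]
    return res.matrix, res.ground_truth, genes


class TestRedundancyScreen:
    def test_planted_triple_yields_tissue_dependent_verdict(self, planted):
        matrix, gt, genes = planted
        rd = gt.redundancy
        call = redundancy_screen(
            matrix,
            complex_genes=set(rd["complex_partners"]) | {rd["target"]},
            target=rd["target"],
            candidates=rd["candidates"],
            tissues_suspected=rd["tissues"],
            genes=genes,
        )
        assert call.verdict == "tissue_dependent"
        assert call.supporting_tissues == set(rd["tissues"])
        assert call.absorbed_candidates
        all_t, excl_t = call.evidence
        assert all_t.passed and not excl_t.passed

    def test_unrelated_candidate_not_supported(self, planted):
        matrix, gt, genes = planted
        rd = gt.redundancy
        # a gene from an orthogonal planted group cannot substitute: it is
        # either rejected at the gating step or never absorbed
        other = next(g for g in genes if gt.group_of[g] == "IIA")
        call = redundancy_screen(
            matrix,
            complex_genes=set(rd["complex_partners"]) | {rd["target"]},
            target=rd["target"],
            candidates=[other],
            tissues_suspected=rd["tissues"],
            genes=genes,
        )
        assert call.verdict == "not_supported"

    def test_target_not_low_fails_gating(self, planted):
        matrix, gt, genes = planted
        rd = gt.redundancy
        # screen a complex member that is NOT silenced anywhere: gating fails
        partner = rd["complex_partners"][0]
        call = redundancy_screen(
            matrix,
            complex_genes=set(rd["complex_partners"]) | {rd["target"]},
            target=partner,
            candidates=rd["candidates"],
            tissues_suspected=rd["tissues"],
            genes=genes,
        )
        assert call.verdict == "not_supported"
        assert call.reason == "precondition_low_expression"

    def test_unknown_tissue_rejected(self, planted):
        matrix, gt, genes = planted
        rd = gt.redundancy
        with pytest.raises(MutantError, match="nowhere"):
            redundancy_screen(
                matrix,
                complex_genes=set(rd["complex_partners"]) | {rd["target"]},
                target=rd["target"],
                candidates=rd["candidates"],
                tissues_suspected=["nowhere"],
            )

    def test_screen_is_deterministic(self, planted):
        matrix, gt, genes = planted
        rd = gt.redundancy
        kwargs = dict(
            complex_genes=set(rd["complex_partners"]) | {rd["target"]},
            target=rd["target"],
            candidates=rd["candidates"],
            tissues_suspected=rd["tissues"],
            genes=genes,
        )
        first = redundancy_screen(matrix, **kwargs)
        second = redundancy_screen(matrix, **kwargs)
        assert first.to_dict() == second.to_dict()
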
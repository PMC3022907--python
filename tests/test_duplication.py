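"""Tandem/segmental duplication calling and duplicate-fate classification."""

import numpy as np
import pytest

from cslkit.catalog import record_from_row
from cslkit.duplication import (
    Anchor,
    DuplicationCatalog,
    DuplicationError,
    SegmentalPair,
    TandemCluster,
    assign_segmental_sets,
    best_chain_score,
    call_tandem,
    chain_collinear,
    classify_fate,
    corr_significance,
    critical_r,
    duplication_summary,
    reported_duplication_catalog,
)

from conftest import brute_force_best_chain


class TestCallTandem:
    def test_packaged_catalog_recovers_reported_clusters(self, rice_catalog):
        clusters = call_tandem(rice_catalog, max_intervening=5)
        assert len(clusters) == 3
        by_size = sorted(clusters, key=lambda c: -len(c.members))
        assert by_size[0].chromosome == 7
        assert set(by_size[0].members) == {
            "OsCSLF1", "OsCSLF2", "OsCSLF3", "OsCSLF4", "OsCSLF8", "OsCSLF9",
        }
        pair_sets = {frozenset(c.members) for c in by_size[1:]}
        assert pair_sets == {
            frozenset({"OsCSLH2", "OsCSLH3"}),
            frozenset({"OsCSLE1", "OsCSLE6"}),
        }

    def test_six_intervening_models_break_the_link(self):
        # ordinals 10 and 17: six models lie between -> no cluster at the
        # default rule, but a cluster at max_intervening=6
        a = record_from_row("A", "CESA", "LOC_Os01g00100")
        b = record_from_row("B", "CESA", "LOC_Os01g00170")
        assert call_tandem([a, b], max_intervening=5) == []
        assert len(call_tandem([a, b], max_intervening=6)) == 1

    def test_negative_max_intervening_rejected(self, rice_catalog):
        with pytest.raises(DuplicationError):
            call_tandem(rice_catalog, max_intervening=-1)

    def test_different_families_never_link(self):
        a = record_from_row("A", "CESA", "LOC_Os01g00100")
        b = record_from_row("B", "CSLD", "LOC_Os01g00110")
        assert call_tandem([a, b]) == []


class TestChainCollinear:
    def test_five_collinear_anchors_form_one_block(self):
        anchors = [(i * 10_000, i * 10_000, 1.0) for i in range(5)]
        blocks = chain_collinear(anchors, min_anchors=5)
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == 5

    def test_large_gap_splits_and_min_anchors_filters(self):
        pos = [0, 10_000, 20_000, 170_000, 180_000, 190_000]
        anchors = [(p, p, 1.0) for p in pos]
        assert chain_collinear(anchors, min_anchors=5) == []
        blocks = chain_collinear(anchors, min_anchors=3)
        assert [len(b.anchors) for b in blocks] == [3, 3]

    def test_descending_orientation_chained(self):
        anchors = [(i * 10_000, (5 - i) * 10_000, 1.0) for i in range(5)]
        blocks = chain_collinear(anchors, min_anchors=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == -1

    def test_empty_anchor_list_gives_empty_result(self):
        assert chain_collinear([]) == []

    def test_chain_score_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        max_gap = 100_000
        for _ in range(50):
            n = int(rng.integers(2, 13))
            anchors = [
                Anchor(
                    f"a{i}",
                    f"b{i}",
                    int(rng.integers(0, 300_000)),
                    int(rng.integers(0, 300_000)),
                    float(rng.uniform(0.5, 2.0)),
                )
                for i in range(n)
            ]
            got = best_chain_score(anchors, max_gap=max_gap)
            want = brute_force_best_chain(anchors, max_gap=max_gap)
            assert got == pytest.approx(want, abs=1e-9)


class TestSegmentalAndSummary:
    def test_reported_sets_give_23_unique_genes(self, rice_catalog):
        summary = duplication_summary(reported_duplication_catalog(), rice_catalog)
        assert summary["unique_genes_involved"] == 23

    def test_csla_involvement_eight_of_nine(self, rice_catalog):
        summary = duplication_summary(reported_duplication_catalog(), rice_catalog)
        assert summary["per_family"]["CSLA"] == {"involved": 8, "total": 9}

    def test_empty_catalog_gives_zero(self):
        assert duplication_summary(DuplicationCatalog())["unique_genes_involved"] == 0

    def test_union_count_is_monotone_and_bounded(self, rice_catalog):
        dup = reported_duplication_catalog()
        base = duplication_summary(dup, rice_catalog)["unique_genes_involved"]
        dup.segmental.append(SegmentalPair("OsCSLD1", "OsCSLD2", 99))
        grown = duplication_summary(dup, rice_catalog)["unique_genes_involved"]
        assert base <= grown <= len(rice_catalog)

    def test_pairs_inside_block_regions_called(self):
        cat = [
            record_from_row("A1", "CSLA", "LOC_Os01g00100"),
            record_from_row("A2", "CSLA", "LOC_Os02g00100"),
            record_from_row("A3", "CSLA", "LOC_Os03g00500"),
        ]
        positions = {
            "A1": (1, 100_000, 103_000),
            "A2": (2, 100_000, 103_000),
            "A3": (3, 500_000, 503_000),
        }
        blocks = chain_collinear(
            [(100_000 + i * 10_000, 100_000 + i * 10_000, 1.0) for i in range(5)],
            min_anchors=5,
            chrom_a=1,
            chrom_b=2,
        )
        pairs = assign_segmental_sets(cat, blocks, positions)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("A1", "A2")]

    def test_tandem_pairs_excluded_from_segmental(self):
        cat = [
            record_from_row("A1", "CSLA", "LOC_Os01g00100"),
            record_from_row("A2", "CSLA", "LOC_Os01g00110"),
        ]
        positions = {"A1": (1, 100_000, 103_000), "A2": (1, 110_000, 113_000)}
        block_anchors = [(95_000 + i * 10_000, 95_000 + i * 10_000, 1.0) for i in range(5)]
        blocks = chain_collinear(block_anchors, min_anchors=5, chrom_a=1, chrom_b=1)
        tandem = call_tandem(cat)
        assert assign_segmental_sets(cat, blocks, positions, tandem) == []

    def test_missing_positions_reported_by_gene(self):
        cat = [record_from_row("A1", "CSLA", "LOC_Os01g00100")]
        with pytest.raises(DuplicationError, match="A1"):
            assign_segmental_sets(cat, [], {})


class TestCorrSignificance:
    def test_zero_correlation_not_significant(self):
        assert not corr_significance(0.0, 33)

    def test_critical_r_at_study_sample_size(self):
        # dense grid search over r locates the significance boundary
        grid = np.linspace(0.30, 0.40, 10_001)
        boundary = grid[np.argmax([corr_significance(r, 33) for r in grid])]
        assert boundary == pytest.approx(0.344, abs=5e-4)
        assert critical_r(33) == pytest.approx(boundary, abs=1e-4)

    def test_strong_marker_correlation_significant(self):
        assert corr_significance(0.94, 33)

    def test_perfect_correlation_significant_by_convention(self):
        assert corr_significance(1.0, 3)
        assert corr_significance(-1.0, 3)


class TestClassifyFate:
    def test_silenced_copy_is_nonfunctionalization(self):
        a = np.concatenate([np.full(10, 100.0), np.full(2, 5.0)])
        b = np.zeros(12)
        call = classify_fate(a, b, expressed_threshold=10.0)
        assert call.fate == "nonfunctionalization"
        assert not call.expressed_tissues_b

    def test_identical_vectors_conserved(self):
        v = np.array([5.0, 100.0, 40.0, 80.0, 3.0, 90.0])
        call = classify_fate(v, v, expressed_threshold=10.0)
        assert call.fate == "conserved"
        assert call.jaccard_overlap == 1.0

    def test_complementary_domains_subfunctionalization(self):
        a = np.concatenate([np.full(5, 100.0), np.zeros(5)])
        b = np.concatenate([np.zeros(5), np.full(5, 100.0)])
        call = classify_fate(a, b, expressed_threshold=10.0)
        assert call.fate == "subfunctionalization"
        assert call.jaccard_overlap == 0.0

    def test_nested_domains_flag_neofunctionalization_candidate(self):
        a = np.concatenate([np.full(2, 100.0), np.zeros(8)])
        b = np.full(10, 100.0)
        call = classify_fate(a, b, expressed_threshold=10.0)
        assert call.fate == "neofunctionalization_candidate"

    def test_swap_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.uniform(0, 100, 8)
            b = rng.uniform(0, 100, 8)
            ab = classify_fate(a, b, expressed_threshold=40.0)
            ba = classify_fate(b, a, expressed_threshold=40.0)
            assert ab.fate == ba.fate
            assert ab.expressed_tissues_a == ba.expressed_tissues_b
            assert ab.jaccard_overlap == ba.jaccard_overlap
            assert ab.corr_r == pytest.approx(ba.corr_r)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DuplicationError):
            classify_fate([1.0, 2.0, 3.0], [1.0, 2.0], expressed_threshold=1.0)
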
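"""TSS-window scoring: kernels, index queries, the MapReduce program,
transforms and quantile normalisation."""

import numpy as np
import pytest

from epimapred.engine import EngineConfig
from epimapred.io import GeneAnnotation, ScoreMatrix, SignalRecord
from epimapred.scoring import (
    EpigeneticScorer,
    ScoreColumn,
    ScoringConfig,
    TssIndex,
    assemble_score_matrix,
    genes_within,
    mr_epigenetic_scores,
    phi,
    quantile_normalise,
    transform_scores,
)

from conftest import brute_force_scores, random_signal

HISTONE = ScoringConfig(kind="histone")
TF = ScoringConfig(kind="tf", d0=5000.0)


class TestPhi:
    @pytest.mark.parametrize("d", [-2000, -1, 0, 1500, 2000])
    def test_histone_kernel_is_unit(self, d):
        assert phi(d, HISTONE) == 1.0

    def test_tf_kernel_at_tss(self):
        assert phi(0, TF) == 1.0

    @pytest.mark.parametrize("d", [5000, -5000])
    def test_tf_kernel_decays_symmetrically(self, d):
        assert phi(d, TF) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScoringConfig(d_star=0)
        with pytest.raises(ValueError):
            ScoringConfig(kind="atac")


class TestGenesWithin:
    def test_inside_window_signed_distance(self, toy_annotation):
        index = TssIndex.build(toy_annotation)
        assert genes_within(index, "chr1", 11_500, 2000) == [
            ("gA", 1500),
            ("gB", 1500),  # minus strand: upstream read, downstream-positive sign
        ]

    def test_outside_window(self, toy_annotation):
        index = TssIndex.build(toy_annotation)
        assert genes_within(index, "chr2", 53_000, 2000) == []

    def test_boundary_is_inclusive(self, toy_annotation):
        index = TssIndex.build(toy_annotation)
        assert ("gA", 2000) in genes_within(index, "chr1", 12_000, 2000)

    def test_unknown_chromosome_empty(self, toy_annotation):
        index = TssIndex.build(toy_annotation)
        assert genes_within(index, "chrM", 100, 2000) == []

    def test_matches_brute_force_scan(self, rng):
        """Index range queries equal an exhaustive annotation scan (120 cases)."""
        annotations = [
            GeneAnnotation(
                f"g{i}",
                f"chr{1 + i % 2}",
                int(rng.integers(2001, 60_000)),
                "+" if rng.random() < 0.5 else "-",
            )
            for i in range(40)
        ]
        index = TssIndex.build(annotations)
        for _ in range(120):
            chrom = f"chr{1 + rng.integers(2)}"
            pos = int(rng.integers(1, 62_000))
            expected = sorted(
                (a.gene_id, (pos - a.tss) * (1 if a.strand == "+" else -1))
                for a in annotations
                if a.chrom == chrom and abs(pos - a.tss) <= 2000
            )
            assert sorted(index.query(chrom, pos, 2000)) == expected


class TestMrEpigeneticScores:
    reads = [
        SignalRecord("chr1", 9_000, 1.0),
        SignalRecord("chr1", 11_500, 1.0),
        SignalRecord("chr1", 13_000, 1.0),
    ]
    gene = [GeneAnnotation("g", "chr1", 10_000, "+")]

    def test_histone_example(self):
        col = mr_epigenetic_scores(self.reads, TssIndex.build(self.gene), HISTONE)
        assert col.values[0] == 2.0  # distances 1000, 1500 in; 3000 out

    def test_tf_example(self):
        col = mr_epigenetic_scores(self.reads, TssIndex.build(self.gene), TF)
        expected = np.exp(-0.2) + np.exp(-0.3)
        assert col.values[0] == pytest.approx(expected, rel=1e-12)

    def test_empty_signal_gives_zero_column(self, toy_annotation):
        col = mr_epigenetic_scores([], TssIndex.build(toy_annotation), HISTONE)
        assert np.array_equal(col.values, np.zeros(3))

    def test_multi_gene_read_counts_for_every_gene(self):
        genes = [
            GeneAnnotation("gL", "chr1", 10_000, "+"),
            GeneAnnotation("gR", "chr1", 13_000, "+"),
        ]
        read = [SignalRecord("chr1", 11_500, 1.0)]
        col = mr_epigenetic_scores(read, TssIndex.build(genes), HISTONE)
        assert np.array_equal(col.values, [1.0, 1.0])

    @pytest.mark.parametrize("kind", ["histone", "tf"])
    def test_oracle_equivalence_randomized(self, kind, rng):
        """MapReduce path equals the literal double loop on 100 random fixtures."""
        config = ScoringConfig(kind=kind)
        for _ in range(100):
            n_genes = int(rng.integers(2, 8))
            annotations = [
                GeneAnnotation(
                    f"g{i}",
                    f"chr{1 + i % 2}",
                    int(rng.integers(2001, 30_000)),
                    "+" if rng.random() < 0.5 else "-",
                )
                for i in range(n_genes)
            ]
            reads = random_signal(rng, annotations, int(rng.integers(0, 30)))
            col = mr_epigenetic_scores(reads, TssIndex.build(annotations), config)
            oracle = brute_force_scores(reads, annotations, config)
            expected = np.array([oracle[a.gene_id] for a in annotations])
            if kind == "histone":
                assert np.array_equal(col.values, expected)
            else:
                np.testing.assert_allclose(col.values, expected, rtol=1e-9)

    def test_monotonicity_under_added_read(self, toy_annotation, rng):
        index = TssIndex.build(toy_annotation)
        reads = random_signal(rng, toy_annotation, 20)
        base = mr_epigenetic_scores(reads, index, HISTONE).values
        more = mr_epigenetic_scores(
            reads + [SignalRecord("chr1", 10_500, 2.0)], index, HISTONE
        ).values
        assert np.all(more >= base)
        assert more[0] == base[0] + 2.0

    def test_locality_across_chromosomes(self, toy_annotation, rng):
        index = TssIndex.build(toy_annotation)
        reads = random_signal(rng, toy_annotation, 20)
        perturbed = reads + [SignalRecord("chr2", 49_000, 5.0)]
        base = mr_epigenetic_scores(reads, index, HISTONE).values
        after = mr_epigenetic_scores(perturbed, index, HISTONE).values
        assert np.array_equal(base[:2], after[:2])  # chr1 genes untouched

    def test_worker_count_invariance(self, toy_annotation, rng):
        index = TssIndex.build(toy_annotation)
        reads = random_signal(rng, toy_annotation, 50)
        one = mr_epigenetic_scores(reads, index, TF, EngineConfig(1))
        four = mr_epigenetic_scores(reads, index, TF, EngineConfig(4))
        assert np.array_equal(one.values, four.values)


class TestAssemble:
    def test_bias_column_appended_last(self):
        cols = [
            ScoreColumn("a", ("g1", "g2", "g3"), np.array([1.0, 2.0, 3.0])),
            ScoreColumn("b", ("g1", "g2", "g3"), np.array([4.0, 5.0, 6.0])),
        ]
        m = assemble_score_matrix(cols, add_bias=True)
        assert m.feature_names == ["a", "b", "bias"]
        assert np.array_equal(m.values[:, -1], np.ones(3))
        assert m.has_bias

    def test_zero_columns_with_bias(self):
        m = assemble_score_matrix([], add_bias=True, gene_ids=["g1", "g2"])
        assert m.shape == (2, 1) and np.array_equal(m.values, np.ones((2, 1)))

    def test_mismatched_gene_sets_report_difference(self):
        cols = [
            ScoreColumn("a", ("g1", "g2"), np.zeros(2)),
            ScoreColumn("b", ("g1", "g3"), np.zeros(2)),
        ]
        with pytest.raises(ValueError, match="g2.*g3|g3.*g2"):
            assemble_score_matrix(cols)

    def test_permuted_gene_order_rejected(self):
        cols = [
            ScoreColumn("a", ("g1", "g2"), np.zeros(2)),
            ScoreColumn("b", ("g2", "g1"), np.zeros(2)),
        ]
        with pytest.raises(ValueError, match="order"):
            assemble_score_matrix(cols)


class TestTransforms:
    def _matrix(self, values, has_bias=False):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        names = [f"f{j}" for j in range(values.shape[1])]
        if has_bias:
            names[-1] = "bias"
        return ScoreMatrix(
            [f"g{i}" for i in range(values.shape[0])], names, values, has_bias
        )

    def test_log_of_zero_with_unit_pseudocount(self):
        m = transform_scores(self._matrix([[0.0]]), "log", pseudocount=1.0)
        assert m.values[0, 0] == 0.0

    def test_log_of_e_minus_one(self):
        m = transform_scores(self._matrix([[np.e - 1]]), "log")
        assert m.values[0, 0] == pytest.approx(1.0, rel=1e-12)

    def test_arsinh_of_zero(self):
        assert transform_scores(self._matrix([[0.0]]), "arsinh").values[0, 0] == 0.0

    def test_log_of_negative_raises(self):
        with pytest.raises(ValueError, match="non-positive"):
            transform_scores(self._matrix([[-2.0]]), "log")

    def test_bias_column_untouched(self):
        m = self._matrix([[3.0, 1.0], [7.0, 1.0]], has_bias=True)
        out = transform_scores(m, "log")
        assert np.array_equal(out.values[:, 1], np.ones(2))

    def test_quantile_identical_columns_fixed_point(self):
        m = self._matrix([[1.0, 1.0], [3.0, 3.0], [2.0, 2.0]])
        out = quantile_normalise(m)
        assert np.array_equal(out.values, m.values)

    def test_quantile_mean_order_statistics(self):
        m = self._matrix([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = quantile_normalise(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert np.array_equal(out.values, expected)

    def test_quantile_sorted_multisets_identical(self, rng):
        m = self._matrix(rng.normal(size=(40, 4)))
        out = quantile_normalise(m)
        ref = np.sort(out.values[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref, rtol=1e-12)

    def test_quantile_preserves_within_column_ranks(self, rng):
        m = self._matrix(rng.normal(size=(30, 3)))
        out = quantile_normalise(m)
        for j in range(3):
            assert np.array_equal(
                np.argsort(m.values[:, j]), np.argsort(out.values[:, j])
            )

    def test_quantile_single_column_unchanged(self):
        m = self._matrix([[1.0], [5.0]])
        out = quantile_normalise(m)
        assert np.array_equal(out.values, m.values)

    def test_quantile_skips_bias(self):
        m = self._matrix([[1.0, 9.0, 1.0], [2.0, 3.0, 1.0]], has_bias=True)
        out = quantile_normalise(m)
        assert np.array_equal(out.values[:, 2], np.ones(2))


class TestEpigeneticScorer:
    def test_sklearn_surface(self, toy_annotation):
        scorer = EpigeneticScorer(kind="tf", d0=4000)
        assert scorer.get_params()["d0"] == 4000
        scorer.set_params(kind="histone")
        fitted = scorer.fit(toy_annotation)
        assert fitted is scorer
        assert scorer.gene_ids_ == ["gA", "gB", "gC"]

    def test_transform_matches_function_route(self, toy_annotation, rng):
        reads = random_signal(rng, toy_annotation, 30)
        scorer = EpigeneticScorer().fit(toy_annotation)
        col = mr_epigenetic_scores(reads, TssIndex.build(toy_annotation), HISTONE)
        assert np.array_equal(scorer.transform(reads)[:, 0], col.values)

    def test_unfitted_transform_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            EpigeneticScorer().transform([])
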
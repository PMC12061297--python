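"""Chromatin-mark peak analytics and the poised-promoter caller."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chromoplast import SimConfig
from chromoplast.marks import (
    ChromDensityTable,
    GeneAnnotation,
    PeakSet,
    annotate_peak_features,
    assign_peaks_to_tss,
    call_poised,
    cluster_promoters,
    density_regression,
    gate_differential,
    merge_intervals,
    per_chromosome_density,
    promoter_signal_matrix,
)
from chromoplast.synthetic import (
    gen_annotation,
    gen_correlated_densities,
    gen_peaks,
)
from conftest import brute_force_tss_overlap


def peakset(mark, triples, **extra):
    df = pd.DataFrame(triples, columns=["chrom", "start", "end"])
    for k, v in extra.items():
        df[k] = v
    return PeakSet(mark, df)


class TestGateDifferential:
    def test_strict_threshold(self):
        ps = peakset(
            "H3K27me3",
            [("chr1", i * 100, i * 100 + 50) for i in range(4)],
            p_value=[0.05, 0.09, 0.10, 0.2],
        )
        gated, report = gate_differential(ps, p_max=0.1)
        assert report["retained"] == 2  # 0.10 excluded: strict <
        assert gated.intervals["p_value"].max() < 0.1

    def test_permissive_threshold_keeps_all(self):
        ps = peakset("m", [("chr1", 0, 10)], p_value=[1.0])
        gated, _ = gate_differential(ps, p_max=1.01)
        assert len(gated) == 1

    def test_empty_input(self):
        ps = PeakSet("m", pd.DataFrame(columns=["chrom", "start", "end", "p_value"]))
        gated, report = gate_differential(ps, 0.1)
        assert len(gated) == 0 and report["input"] == 0

    def test_missing_pvalues_rejected(self):
        ps = peakset("m", [("chr1", 0, 10)])
        with pytest.raises(ValueError, match="p_value"):
            gate_differential(ps, 0.1)


class TestDensity:
    def test_simple_fraction(self):
        ps = peakset("m", [("chr1", 100, 100_100)])
        table = per_chromosome_density(ps, {"chr1": 1_000_000})
        assert table.table["density"].iloc[0] == pytest.approx(0.1)

    def test_overlaps_merged_not_double_counted(self):
        ps = peakset("m", [("chr1", 0, 100), ("chr1", 50, 150)])
        table = per_chromosome_density(ps, {"chr1": 1_000})
        assert table.table["merged_bp"].iloc[0] == 150

    def test_chrx_excluded_by_default(self):
        ps = peakset("m", [("chrX", 0, 100), ("chr1", 0, 100)])
        table = per_chromosome_density(ps, {"chr1": 1_000, "chrX": 1_000})
        assert "chrX" not in set(table.table["chrom"])

    def test_out_of_bounds_peak_named(self):
        ps = peakset("m", [("chr1", 900, 1_100)])
        with pytest.raises(ValueError, match="chr1:900-1100"):
            per_chromosome_density(ps, {"chr1": 1_000})

    def test_merge_idempotent_and_sorted(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 1000, 50)
        ends = starts + rng.integers(1, 100, 50)
        s1, e1 = merge_intervals(starts, ends)
        s2, e2 = merge_intervals(s1, e1)
        assert np.array_equal(s1, s2) and np.array_equal(e1, e2)
        assert np.all(np.diff(s1) > 0) and np.all(s1 < e1)
        assert np.all(s1[1:] > e1[:-1])  # disjoint

    def test_generator_density_exact_within_one_bp(self, cfg):
        targets = {("chr1", "m"): 0.10}
        ps = gen_peaks(cfg, targets)["m"]
        table = per_chromosome_density(ps, cfg.chrom_sizes)
        got = table.table.set_index("chrom").loc["chr1", "merged_bp"]
        assert abs(got - 0.10 * cfg.chrom_sizes["chr1"]) <= 1.0


class TestDensityRegression:
    def test_exact_linear_relation(self):
        t = pd.DataFrame(
            {"chrom": ["chr1", "chr2", "chr3"], "density": [0.1, 0.2, 0.3]}
        )
        a = ChromDensityTable("a", t)
        b = ChromDensityTable("b", t.assign(density=t["density"] * 2))
        fit = density_regression(a, b)
        assert fit["r2"] == pytest.approx(1.0)
        assert fit["slope"] == pytest.approx(2.0)

    def test_constant_response_zero_r2(self):
        t = pd.DataFrame(
            {"chrom": ["chr1", "chr2", "chr3"], "density": [0.1, 0.2, 0.3]}
        )
        a = ChromDensityTable("a", t)
        b = ChromDensityTable("b", t.assign(density=0.5))
        assert density_regression(a, b)["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(1)
        chroms = [f"chr{i}" for i in range(1, 23)]
        x, y = rng.random(22), rng.random(22)
        a = ChromDensityTable("a", pd.DataFrame({"chrom": chroms, "density": x}))
        b = ChromDensityTable("b", pd.DataFrame({"chrom": chroms, "density": y}))
        fit = density_regression(a, b)
        assert fit["r2"] == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_zero_variance_predictor_rejected(self):
        t = pd.DataFrame({"chrom": ["chr1", "chr2", "chr3"], "density": [0.1] * 3})
        with pytest.raises(ValueError, match="variance"):
            density_regression(ChromDensityTable("a", t), ChromDensityTable("b", t))

    def test_planted_correlation_recovered_in_single_run(self, cfg):
        # full-cohort check lives in the acceptance suite; here one run,
        # wide tolerance around rho^2 = 0.67
        targets = gen_correlated_densities(cfg)
        ps = gen_peaks(cfg, targets)
        d4 = per_chromosome_density(ps["H3K4me3"], cfg.chrom_sizes)
        d27 = per_chromosome_density(ps["H3K27me3"], cfg.chrom_sizes)
        fit = density_regression(d4, d27)
        assert fit["n_chrom"] == 22
        assert 0.2 < fit["r2"] <= 1.0


class TestTssAssignment:
    def test_overlapping_peak_assigned(self):
        ann = GeneAnnotation(
            pd.DataFrame(
                [{"gene_id": "g1", "chrom": "chr1", "strand": "+", "tss": 10_000}]
            )
        )
        ps = peakset("m", [("chr1", 11_500, 12_500)])  # overlaps [8000,12000)
        assert assign_peaks_to_tss(ps, ann)["g1"] == [0]

    def test_bookended_peak_not_assigned(self):
        ann = GeneAnnotation(
            pd.DataFrame(
                [{"gene_id": "g1", "chrom": "chr1", "strand": "+", "tss": 10_000}]
            )
        )
        ps = peakset("m", [("chr1", 12_000, 13_000)])  # starts at window end
        assert assign_peaks_to_tss(ps, ann)["g1"] == []

    def test_matches_brute_force_on_twelve_gene_fixture(
        self, toy_peaks, twelve_gene_annotation
    ):
        for ps in toy_peaks.values():
            got = assign_peaks_to_tss(ps, twelve_gene_annotation)
            expected = brute_force_tss_overlap(ps, twelve_gene_annotation)
            assert got == expected

    def test_invariant_to_peak_order(self, toy_peaks, twelve_gene_annotation):
        ps = toy_peaks["H3K4me3"]
        shuffled = PeakSet(
            ps.mark, ps.intervals.iloc[::-1].reset_index(drop=True)
        )
        a = assign_peaks_to_tss(ps, twelve_gene_annotation)
        b = assign_peaks_to_tss(shuffled, twelve_gene_annotation)
        assert {g: bool(h) for g, h in a.items()} == {g: bool(h) for g, h in b.items()}


class TestPoisedCalling:
    def test_planted_bivalent_genes_called_exactly(self):
        cfg = SimConfig(seed=13, planted_poised=frozenset({"g3", "g7"}))
        targets = gen_correlated_densities(cfg)
        ps = gen_peaks(cfg, targets)
        ann = gen_annotation(cfg, ps, n_genes=12)
        assign = {
            "ct": {
                "H3K4me3": assign_peaks_to_tss(ps["H3K4me3"], ann),
                "H3K27me3": assign_peaks_to_tss(ps["H3K27me3"], ann),
            }
        }
        result = call_poised(assign)
        assert result.poised["ct"] == frozenset({"g3", "g7"})

    def test_empty_planted_set_gives_empty_call(self):
        cfg = SimConfig(seed=14, planted_poised=frozenset())
        ps = gen_peaks(cfg, gen_correlated_densities(cfg))
        ann = gen_annotation(cfg, ps, n_genes=10)
        assign = {
            "ct": {
                "H3K4me3": assign_peaks_to_tss(ps["H3K4me3"], ann),
                "H3K27me3": assign_peaks_to_tss(ps["H3K27me3"], ann),
            }
        }
        assert call_poised(assign).poised["ct"] == frozenset()

    def test_no_k27_assignments_empty_poised(self, twelve_gene_annotation, toy_peaks):
        k4 = assign_peaks_to_tss(toy_peaks["H3K4me3"], twelve_gene_annotation)
        empty = {g: [] for g in k4}
        result = call_poised({"ct": {"H3K4me3": k4, "H3K27me3": empty}})
        assert result.poised["ct"] == frozenset()

    def test_counts_shared_and_fold_match_set_oracle(self):
        k4a = {"g1": [0], "g2": [1], "g3": []}
        k27a = {"g1": [2], "g2": [], "g3": [3]}
        k4b = {"g1": [0], "g2": [], "g3": []}
        k27b = {"g1": [1], "g2": [], "g3": []}
        result = call_poised(
            {"A": {"H3K4me3": k4a, "H3K27me3": k27a},
             "B": {"H3K4me3": k4b, "H3K27me3": k27b}}
        )
        assert result.poised["A"] == frozenset({"g1"})
        assert result.shared == frozenset({"g1"})
        assert result.counts == {"A": 1, "B": 1}
        assert result.fold_ratio == 1.0

    def test_commutes_with_gene_relabeling(self):
        k4 = {"g1": [0], "g2": []}
        k27 = {"g1": [1], "g2": [2]}
        res = call_poised({"ct": {"H3K4me3": k4, "H3K27me3": k27}})
        relabel = {"g1": "x", "g2": "y"}
        k4r = {relabel[g]: v for g, v in k4.items()}
        k27r = {relabel[g]: v for g, v in k27.items()}
        res_r = call_poised({"ct": {"H3K4me3": k4r, "H3K27me3": k27r}})
        assert {relabel[g] for g in res.poised["ct"]} == set(res_r.poised["ct"])


class TestFeatureAnnotation:
    @pytest.fixture
    def toy_genome(self):
        ann = GeneAnnotation(
            pd.DataFrame(
                [{"gene_id": "g1", "chrom": "chr1", "strand": "+", "tss": 10_000}]
            )
        )
        models = pd.DataFrame(
            [
                {"gene_id": "g1", "chrom": "chr1", "start": 10_000, "end": 10_500,
                 "feature": "exon"},
                {"gene_id": "g1", "chrom": "chr1", "start": 14_000, "end": 15_000,
                 "feature": "exon"},
            ]
        )
        return ann, models

    def test_priority_classification(self, toy_genome):
        ann, models = toy_genome
        ps = peakset(
            "m",
            [
                ("chr1", 9_000, 9_100),     # midpoint in promoter window
                ("chr1", 14_100, 14_300),   # midpoint in exon (outside promoter)
                ("chr1", 13_000, 13_200),   # midpoint intronic
                ("chr1", 500_000, 500_200), # intergenic
            ],
        )
        table = annotate_peak_features(ps, ann, models)
        counts = table.set_index("category")["count"]
        assert counts.tolist() == [1, 1, 1, 1]
        assert table["fraction"].sum() == pytest.approx(1.0)

    def test_matches_brute_force_classification(self, toy_genome):
        ann, models = toy_genome
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 50_000, 40)
        ps = peakset("m", [("chr1", int(s), int(s) + 200) for s in starts])
        table = annotate_peak_features(ps, ann, models)
        # brute force on midpoints
        expected = {"promoter": 0, "exon": 0, "intron": 0, "intergenic": 0}
        for s in starts:
            mid = int(s) + 100
            if 8_000 <= mid < 12_000:
                expected["promoter"] += 1
            elif 10_000 <= mid < 10_500 or 14_000 <= mid < 15_000:
                expected["exon"] += 1
            elif 10_000 <= mid < 15_000:
                expected["intron"] += 1
            else:
                expected["intergenic"] += 1
        got = dict(zip(table["category"], table["count"]))
        assert got == expected


class TestPromoterSignalMatrix:
    def two_gene_annotation(self):
        return GeneAnnotation(
            pd.DataFrame(
                [
                    {"gene_id": "plus", "chrom": "chr1", "strand": "+", "tss": 10_000},
                    {"gene_id": "minus", "chrom": "chr1", "strand": "-", "tss": 10_000},
                ]
            )
        )

    def flat_track(self, value):
        return {"chr1": (np.array([0]), np.array([100_000]), np.array([value]))}

    def test_equal_coverage_gives_zero_matrix(self):
        matrix, skipped = promoter_signal_matrix(
            self.flat_track(2.0), self.flat_track(2.0), self.two_gene_annotation()
        )
        assert skipped == 0
        assert np.allclose(matrix.to_numpy(), 0.0)

    def test_threefold_coverage_hand_value(self):
        matrix, _ = promoter_signal_matrix(
            self.flat_track(3.0), self.flat_track(1.0), self.two_gene_annotation(),
            pseudocount=0.0,
        )
        assert np.allclose(matrix.to_numpy(), np.log2(3.0))

    def test_minus_strand_rows_reversed(self):
        starts = np.arange(0, 100_000, 100)
        track_a = {"chr1": (starts, starts + 100, np.linspace(1, 5, len(starts)))}
        matrix, _ = promoter_signal_matrix(
            track_a, self.flat_track(1.0), self.two_gene_annotation()
        )
        assert np.allclose(
            matrix.loc["minus"].to_numpy(), matrix.loc["plus"].to_numpy()[::-1]
        )

    def test_off_contig_gene_skipped(self):
        ann = GeneAnnotation(
            pd.DataFrame(
                [{"gene_id": "far", "chrom": "chr9", "strand": "+", "tss": 5_000}]
            )
        )
        matrix, skipped = promoter_signal_matrix(
            self.flat_track(1.0), self.flat_track(1.0), ann
        )
        assert skipped == 1 and matrix.empty


class TestClusterPromoters:
    def test_single_cluster_metaplot_is_column_mean(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(20, 8)))
        labels, metaplot = cluster_promoters(m, k=1, seed=0)
        assert labels.nunique() == 1
        assert np.allclose(metaplot.iloc[0], m.mean(axis=0))

    def test_separated_blocks_perfectly_partitioned(self):
        rng = np.random.default_rng(7)
        block1 = rng.normal(5.0, 0.1, size=(15, 6))
        block2 = rng.normal(-5.0, 0.1, size=(15, 6))
        m = pd.DataFrame(np.vstack([block1, block2]))
        labels, _ = cluster_promoters(m, k=2, seed=0)
        truth = [0] * 15 + [1] * 15
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_exceeding_rows_rejected(self):
        m = pd.DataFrame(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_promoters(m, k=6)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(40, 5)))
        l1, _ = cluster_promoters(m, k=3, seed=9)
        l2, _ = cluster_promoters(m, k=3, seed=9)
        assert l1.tolist() == l2.tolist()


class TestAnnotationGenerator:
    def test_brute_force_window_overlap_matches_caller(self):
        cfg = SimConfig(seed=21, planted_poised=frozenset({"g2", "g9"}))
        ps = gen_peaks(cfg, gen_correlated_densities(cfg))
        ann = gen_annotation(cfg, ps, n_genes=12)
        for mark in ("H3K4me3", "H3K27me3"):
            got = assign_peaks_to_tss(ps[mark], ann)
            expected = brute_force_tss_overlap(ps[mark], ann)
            assert got == expected

    def test_non_planted_genes_have_at_most_one_mark(self):
        cfg = SimConfig(seed=22, planted_poised=frozenset({"g1"}))
        ps = gen_peaks(cfg, gen_correlated_densities(cfg))
        ann = gen_annotation(cfg, ps, n_genes=20)
        k4 = assign_peaks_to_tss(ps["H3K4me3"], ann)
        k27 = assign_peaks_to_tss(ps["H3K27me3"], ann)
        for g in k4:
            both = bool(k4[g]) and bool(k27[g])
            assert both == (g in cfg.planted_poised)
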
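import dataclasses

import numpy as np
import pytest

from gradedpool.scan import QTLInterval, ScanConfig
from gradedpool.simulate import (
    QTL, SimConfig, evaluate_detection, grade_population, pool_reads,
    power_grid, simulate_f2,
)

SMALL = dict(n_chrom=2, chrom_len_bp=3_000_000, n_snps_per_chrom=60, n_f2=120,
             bulk_fractions=(1 / 3, 1 / 3, 1 / 3), per_individual_coverage=1.0)


class TestSimulateF2:
    def test_seeded_determinism_bit_identical(self):
        cfg = SimConfig(**SMALL, seed=42, qtls=(QTL(1, 1_000_000, 0.5),))
        a = pool_reads(simulate_f2(cfg), cfg)
        b = pool_reads(simulate_f2(cfg), cfg)
        assert np.array_equal(a.ref_counts, b.ref_counts)
        assert np.array_equal(a.alt_counts, b.alt_counts)
        assert np.array_equal(a.pos, b.pos)
        c = pool_reads(simulate_f2(dataclasses.replace(cfg, seed=43)),
                       dataclasses.replace(cfg, seed=43))
        assert not np.array_equal(a.alt_counts, c.alt_counts)

    def test_mendelian_dosage_frequencies(self):
        cfg = SimConfig(n_chrom=1, chrom_len_bp=3_000_000, n_snps_per_chrom=30,
                        n_f2=10_000, seed=1)
        truth = simulate_f2(cfg)
        freqs = np.stack([(truth.dosage == d).mean(axis=0) for d in (0, 1, 2)])
        se = np.sqrt(np.array([0.25, 0.5, 0.25]) * np.array([0.75, 0.5, 0.75]) / 10_000)
        assert (np.abs(freqs - [[0.25], [0.5], [0.25]]) < 3.5 * se[:, None]).all()

    def test_zero_map_length_means_fully_parental_chromosomes(self):
        cfg = SimConfig(**{**SMALL, "cM_per_Mb": 0.0}, seed=9)
        truth = simulate_f2(cfg)
        per_chrom = truth.dosage[:, :cfg.n_snps_per_chrom]
        # no recombination: every SNP on a chromosome shares one dosage
        assert (per_chrom == per_chrom[:, :1]).all()

    def test_complete_dominance_group_means(self):
        cfg = SimConfig(**{**SMALL, "n_f2": 3_000}, env_sd=1e-9, seed=3,
                        qtls=(QTL(1, 1_500_000, 0.7, 0.7),))
        truth = simulate_f2(cfg)
        d = truth.qtl_dosage[:, 0]
        y = truth.phenotypes
        assert y[d == 1].mean() == pytest.approx(y[d == 2].mean(), abs=1e-6)
        assert y[d == 0].mean() == pytest.approx(y[d == 2].mean() - 1.4, abs=1e-6)

    def test_qtl_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            SimConfig(**SMALL, qtls=(QTL(1, 99_000_000, 0.5),))


class TestGrading:
    def test_fraction_grading_orders_by_phenotype(self):
        cfg = SimConfig(**SMALL, seed=0)
        y = np.arange(120, dtype=float)  # 119 is the highest phenotype
        labels, observed = grade_population(y, cfg)
        assert (labels[y >= 80] == 1).all()
        assert (labels[(y >= 40) & (y < 80)] == 2).all()
        assert (labels[y < 40] == 3).all()
        assert np.array_equal(labels, observed)  # no misclassification

    def test_single_full_bulk_and_fraction_sum_guard(self):
        whole = SimConfig(**{**SMALL, "bulk_fractions": (1.0,)}, seed=0)
        labels, _ = grade_population(np.arange(120.0), whole)
        assert (labels == 1).all()
        with pytest.raises(ValueError):
            SimConfig(**{**SMALL, "bulk_fractions": (0.7, 0.7)})

    def test_boundary_mode_matches_trait_classes(self):
        """Explicit cut points reproduce an ordinal grain-weight pooling:
        three classes split at 29.155 and 31.095 g, grade 1 = heaviest."""
        cfg = SimConfig(**{**SMALL, "phenotype_cuts": (29.155, 31.095)}, seed=0)
        y = np.array([22.33, 29.15, 29.16, 31.09, 31.10, 37.3])
        labels, _ = grade_population(y, cfg)
        assert list(labels) == [3, 3, 2, 2, 1, 1]

    def test_misclassification_swaps_exact_count(self):
        cfg = SimConfig(**{**SMALL, "n_f2": 300}, misclass_rate=0.2,
                        misclass_bulk=1, seed=5)
        y = np.arange(300, dtype=float)
        true, observed = grade_population(y, cfg)
        moved_out = ((true == 1) & (observed != 1)).sum()
        moved_in = ((true != 1) & (observed == 1)).sum()
        assert moved_out == moved_in == 20  # floor(0.2 * 100)
        assert (np.bincount(observed)[1:] == np.bincount(true)[1:]).all()


class TestPoolReads:
    def test_fixed_dosage_without_error_gives_pure_pools(self):
        cfg = SimConfig(**SMALL, seed=2, seq_error=0.0, cM_per_Mb=0.0)
        truth = simulate_f2(cfg)
        table = pool_reads(truth, cfg)
        # every bulk's alt fraction equals its true pooled dosage frequency
        for g in range(1, 4):
            members = truth.observed_labels == g
            f = truth.dosage[members].mean(axis=0) / 2
            depth = table.depths[:, g - 1]
            pure = (f == 0) & (depth > 0)
            assert (table.alt_counts[pure, g - 1] == 0).all()

    def test_sequencing_error_rate_recovered(self):
        cfg = SimConfig(n_chrom=1, chrom_len_bp=2_000_000, n_snps_per_chrom=400,
                        n_f2=90, per_individual_coverage=3.0, seq_error=0.01, seed=8)
        truth = simulate_f2(cfg)
        truth.dosage[:] = 0  # force monomorphic low-parent genotype
        table = pool_reads(truth, cfg)
        frac = table.alt_counts.sum() / table.depths.sum()
        assert frac == pytest.approx(0.01, rel=0.2)

    def test_mean_pool_depth_tracks_coverage(self):
        cfg = SimConfig(**SMALL, seed=4)  # 40 individuals/bulk at 1x
        table = pool_reads(simulate_f2(cfg), cfg)
        assert table.depths.mean(axis=0) == pytest.approx([40, 40, 40], rel=0.1)

    def test_empty_bulk_rejected(self):
        cfg = SimConfig(**SMALL, seed=4)
        truth = simulate_f2(cfg)
        labels = np.zeros(cfg.n_f2, dtype=np.int64)
        labels[:10] = 1  # grades 2 and 3 empty
        with pytest.raises(ValueError, match="empty"):
            pool_reads(truth, cfg, labels=labels)


class TestDetection:
    def interval(self, chrom, start, rank=1):
        return QTLInterval(chrom=chrom, start=start, end=start + 400_000,
                           peak_ratio=1.0, n_snps=20, rank=rank)

    def truth_with_qtl(self):
        cfg = SimConfig(**SMALL, seed=0, qtls=(QTL(1, 1_500_000, 0.5),))
        return simulate_f2(cfg)

    def test_qtl_inside_interval_is_hit(self):
        truth = self.truth_with_qtl()
        det = evaluate_detection([self.interval("chr1", 1_200_000)], truth)
        assert det.hits == [True]
        assert det.n_false_positives == 0

    def test_no_intervals_means_all_missed(self):
        det = evaluate_detection([], self.truth_with_qtl())
        assert det.hits == [False]
        assert det.n_false_positives == 0

    def test_far_interval_is_false_positive(self):
        truth = self.truth_with_qtl()
        det = evaluate_detection(
            [self.interval("chr2", 2_000_000)], truth, tolerance_windows=1)
        assert det.hits == [False]
        assert det.n_false_positives == 1

    def test_tolerance_windows(self):
        truth = self.truth_with_qtl()  # QTL at chr1:1.5 Mb -> window [1.2,1.6)
        adjacent = self.interval("chr1", 1_600_000)
        assert evaluate_detection([adjacent], truth, tolerance_windows=1).hits == [True]
        assert evaluate_detection([adjacent], truth, tolerance_windows=0).hits == [False]


def test_power_grid_runs_and_is_seed_deterministic():
    base = SimConfig(n_chrom=2, chrom_len_bp=4_000_000, n_snps_per_chrom=150,
                     n_f2=240, per_individual_coverage=1.0,
                     qtls=(QTL(1, 2_000_000, 0.9),))
    grid = {"per_individual_coverage": [0.5, 1.0]}
    sc = ScanConfig(top_n=1, min_snps=5)
    a = power_grid(base, grid, n_reps=3, seed=17, scan_cfg=sc)
    b = power_grid(base, grid, n_reps=3, seed=17, scan_cfg=sc)
    assert a.equals(b)
    assert set(a.columns) >= {"per_individual_coverage", "power",
                              "false_positives_per_rep"}
    assert ((a.power >= 0) & (a.power <= 1)).all()
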
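import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gradedpool.ordinal import (
    DegenerateTableError, GradeTable, chisq_test, effective_counts,
    kruskal_wallis_test, ridit_scores, ridit_test,
)
from gradedpool.ordinal import test_track as run_track
from conftest import make_table
from _oracles import ranksum_z

count_rows = st.integers(min_value=2, max_value=5).flatmap(
    lambda k: st.tuples(
        st.lists(st.integers(0, 50), min_size=k, max_size=k),
        st.lists(st.integers(0, 50), min_size=k, max_size=k),
    )
)


class TestRiditScores:
    def test_cumulative_formula(self):
        assert ridit_scores((10, 10, 20)) == pytest.approx([0.125, 0.375, 0.75])

    def test_single_category_is_midpoint(self):
        assert ridit_scores((37,)) == pytest.approx([0.5])

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateTableError):
            ridit_scores((0, 0, 0))

    @given(st.lists(st.integers(0, 100), min_size=1, max_size=8).filter(lambda v: sum(v) > 0))
    @settings(deadline=None)
    def test_weighted_mean_is_half_and_scores_monotone(self, totals):
        r = ridit_scores(totals)
        n = np.asarray(totals, float)
        assert float((n * r).sum() / n.sum()) == pytest.approx(0.5)
        assert (np.diff(r) >= 0).all()
        # empty categories may sit on the boundary; occupied ones cannot
        occupied = n > 0
        assert ((r[occupied] > 0) & (r[occupied] < 1)).all()


class TestRiditTest:
    def test_perfect_separation_two_grades(self):
        """All ref reads in grade 1, all alt in grade 2: mean ridits 0.25 and
        0.75, |z| equal to the tie-corrected rank-sum on the 18 observations."""
        res = ridit_test(GradeTable((9, 0), (0, 9)))
        assert res.mean_ridits == pytest.approx((0.25, 0.75))
        assert abs(res.statistic) == pytest.approx(4.1231056, abs=1e-6)
        assert res.statistic == pytest.approx(ranksum_z((9, 0), (0, 9)), rel=1e-12)

    def test_balanced_table_is_null(self):
        # 50% reference and 50% alternate reads in all three bulks
        res = ridit_test(GradeTable((50, 50, 50), (50, 50, 50)))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_row_swap_negates_z_keeps_p(self):
        a = ridit_test(GradeTable((30, 60, 75), (70, 40, 25)))
        b = ridit_test(GradeTable((70, 40, 25), (30, 60, 75)))
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_degenerate_conventions(self):
        empty_row = ridit_test(GradeTable((0, 0), (5, 7)))
        assert (empty_row.statistic, empty_row.p_value) == (0.0, 1.0)
        assert "empty" in empty_row.note
        one_grade = ridit_test(GradeTable((5, 0), (7, 0)))
        assert (one_grade.statistic, one_grade.p_value) == (0.0, 1.0)

    @given(count_rows)
    @settings(deadline=None, max_examples=200)
    def test_matches_expanded_ranksum_oracle(self, rows):
        """Grouped-count z equals the brute-force tie-corrected rank-sum z
        computed on the table expanded to individual observations."""
        ref, alt = rows
        if sum(ref) == 0 or sum(alt) == 0:
            return
        res = ridit_test(GradeTable(tuple(ref), tuple(alt)))
        if res.note is not None:
            return
        assert res.statistic == pytest.approx(ranksum_z(ref, alt), rel=1e-12, abs=1e-12)


class TestComparators:
    def test_kw_null_and_identity_with_ridit_on_two_grades(self):
        assert kruskal_wallis_test(GradeTable((50, 50, 50), (50, 50, 50))).statistic == 0.0
        z = ridit_test(GradeTable((30, 70), (70, 30))).statistic
        h = kruskal_wallis_test(GradeTable((30, 70), (70, 30))).statistic
        assert z ** 2 == pytest.approx(h, rel=1e-9)

    def test_kw_all_reads_in_one_grade(self):
        res = kruskal_wallis_test(GradeTable((50, 0), (30, 0)))
        assert res.p_value == 1.0

    def test_chisq_hand_computed(self):
        res = chisq_test(GradeTable((90, 10), (10, 90)))
        assert res.statistic == pytest.approx(128.0)
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(128.0, 1))

    def test_chisq_zero_column_drops_df(self):
        res = chisq_test(GradeTable((50, 0, 50), (50, 0, 50)))
        assert res.df == 1
        assert res.statistic == pytest.approx(0.0)

    def test_chisq_empty_row_raises(self):
        with pytest.raises(DegenerateTableError):
            chisq_test(GradeTable((50, 50), (0, 0)))


class TestTrack:
    def test_empty_table_gives_empty_track(self, design3):
        track = run_track(make_table(design3, []))
        assert len(track) == 0

    def test_neg_log_p_always_finite(self, design3):
        recs = [("chr1", 100, 50.0, [(1000, 0), (500, 500), (0, 1000)])]
        track = run_track(make_table(design3, recs))
        assert np.isfinite(track.neg_log_p).all()

    def test_track_matches_scalar_tests(self, design3):
        recs = [("chr1", 100, 50.0, [(30, 70), (50, 50), (70, 30)]),
                ("chr1", 200, 50.0, [(50, 50), (50, 50), (50, 50)]),
                ("chr1", 300, 50.0, [(0, 90), (40, 60), (90, 0)])]
        table = make_table(design3, recs)
        for method, scalar in (("ridit", ridit_test), ("kw", kruskal_wallis_test),
                               ("chisq", chisq_test)):
            track = run_track(table, method=method)
            for i, v in enumerate(table):
                expect = scalar(GradeTable(tuple(c[0] for c in v.counts),
                                           tuple(c[1] for c in v.counts)))
                assert track.p[i] == pytest.approx(expect.p_value, rel=1e-12)

    def test_null_read_sampling_gives_uniform_p(self, design3):
        """Binomial(depth, 0.5) read counts in every bulk: the ridit p-value
        distribution is uniform (KS below the 1% critical value at M = 1e4).
        Depths vary as Poisson(100) per pool, matching the read model; with
        identical fixed depths the rank statistic sits on a coarse lattice
        and a continuous-uniform KS comparison is not meaningful."""
        rng = np.random.default_rng(2024)
        m = 10_000
        depth = rng.poisson(100, size=(m, 3))
        ref = rng.binomial(depth, 0.5)
        alt = depth - ref
        recs = [("chr1", i + 1, 50.0, list(zip(ref[i], alt[i]))) for i in range(m)]
        track = run_track(make_table(design3, recs))
        ks = stats.kstest(track.p, "uniform").statistic
        assert ks < 1.63 / np.sqrt(m)

    def test_monotone_gradient_steepening_lowers_expected_p(self, design3):
        """Averaged over seeded replicates, a steeper monotone allele-frequency
        gradient across grades never raises the mean ridit p-value."""
        rng = np.random.default_rng(7)
        depth, reps = 100, 400
        mean_p = []
        for half_step in (0.0, 0.05, 0.10, 0.20):
            freqs = np.array([0.5 - half_step, 0.5, 0.5 + half_step])
            alt = rng.binomial(depth, freqs, size=(reps, 3))
            ref = depth - alt
            recs = [("chr1", i + 1, 50.0, list(zip(ref[i], alt[i]))) for i in range(reps)]
            mean_p.append(run_track(make_table(design3, recs)).p.mean())
        assert all(a >= b - 0.02 for a, b in zip(mean_p, mean_p[1:]))


def test_effective_counts_scaling():
    """Counts shrink by 2n/(2n+D); the scaled depth is the classical
    effective number of chromosomes 2nD/(2n+D)."""
    ref, alt = effective_counts([[150]], [[60]], [300])
    depth = ref + alt
    assert depth[0, 0] == pytest.approx(2 * 300 * 210 / (2 * 300 + 210))
    assert ref[0, 0] / alt[0, 0] == pytest.approx(150 / 60)
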
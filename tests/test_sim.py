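import filecmp
import warnings
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bruwave import (
    ElongationProfile,
    GeneAnnotation,
    GeneKinetics,
    InitiationProfile,
    LabelingScheme,
    SimScenario,
    StrandedCoverageSet,
    expected_coverage,
    front_position,
    sample_reads,
    simulate_cohort,
    travel_time,
)
from conftest import make_scenario, single_gene_scenario

from _oracles import discrete_event_coverage, travel_time_stepping


# ---------------------------------------------------------------------------
# travel_time / front_position
# ---------------------------------------------------------------------------


class TestTravelTime:
    def test_linear_motion(self):
        p = ElongationProfile.constant(2.0, 100_000)
        assert travel_time(p, 60_000) == pytest.approx(30.0)

    def test_zero(self):
        p = ElongationProfile.constant(2.0, 100_000)
        assert travel_time(p, 0) == 0.0

    def test_two_segments_vs_stepping_oracle(self):
        segments = ((30_000, 1.0), (200_000, 2.0))
        p = ElongationProfile(segments)
        oracle = travel_time_stepping(segments, 60_000, dt=0.01)
        assert oracle == pytest.approx(45.0, abs=0.05)
        assert travel_time(p, 60_000) == pytest.approx(45.0)

    def test_out_of_range(self):
        p = ElongationProfile.constant(2.0, 100_000)
        with pytest.raises(ValueError):
            travel_time(p, 100_001)
        with pytest.raises(ValueError):
            travel_time(p, -1)

    def test_bad_profiles(self):
        with pytest.raises(ValueError):
            ElongationProfile(((0.0, 2.0),))
        with pytest.raises(ValueError):
            ElongationProfile(((1000.0, 0.0),))
        with pytest.raises(ValueError):
            ElongationProfile(())


class TestFrontPosition:
    def test_linear(self):
        p = ElongationProfile.constant(2.0, 100_000)
        assert front_position(p, 30.0) == pytest.approx(60_000)

    def test_zero(self):
        p = ElongationProfile.constant(2.0, 100_000)
        assert front_position(p, 0.0) == 0.0

    def test_two_segments(self):
        p = ElongationProfile(((30_000, 1.0), (200_000, 2.0)))
        assert front_position(p, 45.0) == pytest.approx(60_000)

    def test_cap(self):
        p = ElongationProfile.constant(2.0, 100_000)
        assert front_position(p, 1000.0) == pytest.approx(100_000)
        assert front_position(p, 40.0, cap=70_000) == pytest.approx(70_000)

    @given(
        st.lists(
            st.tuples(st.floats(1e3, 1e5), st.floats(0.1, 10.0)),
            min_size=1, max_size=5,
        ),
        st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, segments, frac):
        p = ElongationProfile(tuple(segments))
        total_t = travel_time(p, p.total_length)
        t = frac * total_t
        assert travel_time(p, front_position(p, t)) == pytest.approx(t, abs=1e-9)


# ---------------------------------------------------------------------------
# InitiationProfile
# ---------------------------------------------------------------------------


class TestInitiationProfile:
    def test_constant_has_no_epochs(self):
        with pytest.raises(ValueError):
            InitiationProfile(1.0, (0.0,), (2.0,), "constant")

    def test_change_times_increasing(self):
        with pytest.raises(ValueError):
            InitiationProfile(1.0, (10.0, 10.0), (2.0, 1.0), "reversal")

    def test_nonnegative_rates(self):
        with pytest.raises(ValueError):
            InitiationProfile(-1.0)
        with pytest.raises(ValueError):
            InitiationProfile(1.0, (0.0,), (-0.5,), "sustained_up")

    def test_rate_at_epochs(self):
        init = InitiationProfile.from_pattern("transient_up", 1.0, fold=3.0,
                                              onset=0.0, duration=30.0)
        assert init.rate_at(-5.0) == 1.0
        assert init.rate_at(5.0) == 3.0
        assert init.rate_at(35.0) == 1.0

    def test_integrate_matches_riemann(self):
        init = InitiationProfile.from_pattern("reversal", 2.0, fold=4.0,
                                              onset=0.0, reversal_lag=60.0)
        ts = np.linspace(-50, 150, 200001)
        riemann = np.trapezoid(init.rate_at(ts), ts)
        assert init.integrate(-50, 150) == pytest.approx(riemann, rel=1e-4)

    def test_from_rates_silent_baseline(self):
        init = InitiationProfile.from_rates(0.0, (0.0,), (2.0,))
        assert init.rate_at(-1.0) == 0.0
        assert init.rate_at(1.0) == 2.0
        assert init.integrate(-10.0, 10.0) == pytest.approx(20.0)


# ---------------------------------------------------------------------------
# expected_coverage
# ---------------------------------------------------------------------------


class TestExpectedCoverage:
    def test_zero_initiation(self, gene_100kb, const_elong_100kb):
        init = InitiationProfile.constant(0.0)
        cov = expected_coverage(gene_100kb, init, const_elong_100kb, (0, 30), 1000)
        assert np.all(cov == 0)

    @pytest.mark.parametrize("window", [(-30, 0), (0, 30), (60, 90)])
    def test_steady_state_uniform(self, gene_100kb, const_elong_100kb, window):
        init = InitiationProfile.constant(1.5)
        cov = expected_coverage(gene_100kb, init, const_elong_100kb, window, 1000)
        assert cov == pytest.approx(np.full(100, 45.0))

    def test_induction_wedge_vs_event_oracle(self, gene_100kb, const_elong_100kb):
        init = InitiationProfile.from_rates(0.0, (0.0,), (2.0,))
        cov = expected_coverage(gene_100kb, init, const_elong_100kb, (0, 30), 1000)
        oracle = discrete_event_coverage(init, const_elong_100kb, (0, 30), 1000,
                                         100_000, dt=0.01)
        # wedge: I1 * (30 - tau) down to zero at the 60 kb front
        assert cov[0] == pytest.approx(2.0 * (30 - 0.25))
        assert np.all(cov[60:] == 0)
        np.testing.assert_allclose(cov, oracle, atol=2.0 * 0.01 + 1e-12)

    def test_repression_clearing_vs_event_oracle(self, gene_100kb, const_elong_100kb):
        init = InitiationProfile.from_rates(1.0, (0.0,), (0.0,))
        cov = expected_coverage(gene_100kb, init, const_elong_100kb, (0, 30), 1000)
        oracle = discrete_event_coverage(init, const_elong_100kb, (0, 30), 1000,
                                         100_000, dt=0.01)
        # cleared 5' region: I0 * min(tau, 30), plateau past the 60 kb front
        assert cov[0] == pytest.approx(0.25)
        assert cov[-1] == pytest.approx(30.0)
        np.testing.assert_allclose(cov, oracle, atol=1.0 * 0.01 + 1e-12)

    def test_oracle_equivalence_invariant(self, gene_100kb, const_elong_100kb):
        """Max relative error < 1% against the discrete-event oracle."""
        init = InitiationProfile.from_pattern("sustained_up", 1.0, fold=3.0)
        for window in [(0, 30), (30, 60)]:
            cov = expected_coverage(gene_100kb, init, const_elong_100kb, window, 1000)
            oracle = discrete_event_coverage(init, const_elong_100kb, window, 1000,
                                             100_000, dt=0.01)
            assert np.max(np.abs(cov - oracle)) / np.max(oracle) < 0.01

    def test_bad_window(self, gene_100kb, const_elong_100kb):
        init = InitiationProfile.constant(1.0)
        with pytest.raises(ValueError):
            expected_coverage(gene_100kb, init, const_elong_100kb, (30, 30), 1000)


# ---------------------------------------------------------------------------
# sample_reads
# ---------------------------------------------------------------------------


class TestSampleReads:
    def test_zero_depth(self):
        assert np.all(sample_reads(np.ones(10), 0.0, 1) == 0)

    def test_noise_none_rounds(self):
        out = sample_reads(np.array([1.2, 3.7]), 10.0, 1, noise="none")
        assert out.tolist() == [12, 37]

    def test_poisson_law_of_large_numbers(self):
        # 10^4 independent draws of a bin with expectation 2 at depth 50
        out = sample_reads(np.full(10_000, 2.0), 50.0, 42)
        se = np.sqrt(100.0 / 10_000)
        assert abs(out.mean() - 100.0) < 3 * se

    def test_negative_depth_errors(self):
        with pytest.raises(ValueError):
            sample_reads(np.ones(3), -1.0, 1)

    def test_negative_expected_errors(self):
        with pytest.raises(ValueError):
            sample_reads(np.array([-0.1]), 1.0, 1)

    def test_reproducible(self):
        a = sample_reads(np.full(100, 5.0), 10.0, 7)
        b = sample_reads(np.full(100, 5.0), 10.0, 7)
        assert np.array_equal(a, b)


# ---------------------------------------------------------------------------
# LabelingScheme
# ---------------------------------------------------------------------------


class TestLabelingScheme:
    def test_default(self):
        s = LabelingScheme.default()
        assert s.names == ["starved", "0-30", "30-60", "60-90", "90-120"]
        assert s.duration == 30.0
        assert s.baseline == "starved"

    def test_overlapping_rejected(self):
        with pytest.raises(ValueError):
            LabelingScheme((("starved", -30, 0), ("a", -10, 20)))

    def test_unequal_duration_rejected(self):
        with pytest.raises(ValueError):
            LabelingScheme((("starved", -30, 0), ("a", 0, 20)))

    def test_onset_window(self):
        s = LabelingScheme.default()
        assert s.onset_window(0.0) == 1
        assert s.onset_window(60.0) == 3
        assert s.onset_window(119.0) == 4
        assert s.onset_window(120.0) is None


# ---------------------------------------------------------------------------
# simulate_cohort
# ---------------------------------------------------------------------------


class TestSimulateCohort:
    def test_noiseless_equals_expected_times_depth(self, tmp_path):
        sc = single_gene_scenario("sustained_up", length=100_000, rate=2.0,
                                  read_depth=5.0, noise="none", seed=3)
        out = simulate_cohort(sc, tmp_path / "sim")
        cov = StrandedCoverageSet.from_sample_sheet(out.sample_sheet, 1000)
        gk = sc.genes[0]
        for name, ws, we in sc.scheme.windows:
            expected = expected_coverage(gk.gene, gk.initiation, gk.elongation,
                                         (ws, we), 1000)
            profile = cov.gene_profile(name, gk.gene)
            np.testing.assert_allclose(profile, 5.0 * expected, rtol=1e-9)

    def test_conservation_noiseless(self, tmp_path):
        sc = single_gene_scenario("transient_up", read_depth=3.0, noise="none")
        out = simulate_cohort(sc, tmp_path / "sim")
        gk = sc.genes[0]
        for name, ws, we in sc.scheme.windows:
            total = sum(expected_coverage(gk.gene, gk.initiation, gk.elongation,
                                          (ws, we), 1000))
            assert out.library_sizes[name] == pytest.approx(3.0 * total, rel=1e-12)

    def test_byte_identical_reruns(self, tmp_path):
        sc = single_gene_scenario("reversal", read_depth=5.0, noise="poisson", seed=11)
        out1 = simulate_cohort(sc, tmp_path / "a")
        out2 = simulate_cohort(sc, tmp_path / "b")
        files1 = sorted(p.name for p in (tmp_path / "a").iterdir())
        files2 = sorted(p.name for p in (tmp_path / "b").iterdir())
        assert files1 == files2
        for name in files1:
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_gene_substreams_stable_under_cohort_changes(self, tmp_path):
        g1 = GeneKinetics(GeneAnnotation("gA", "c1", 0, 50_000, "+"),
                          InitiationProfile.constant(1.0),
                          ElongationProfile.constant(2.0, 50_000))
        g2 = GeneKinetics(GeneAnnotation("gB", "c2", 0, 50_000, "+"),
                          InitiationProfile.constant(1.0),
                          ElongationProfile.constant(2.0, 50_000))
        out1 = simulate_cohort(make_scenario([g1], seed=5), tmp_path / "one")
        out2 = simulate_cohort(make_scenario([g1, g2], seed=5), tmp_path / "two")
        cov1 = StrandedCoverageSet.from_sample_sheet(out1.sample_sheet, 1000)
        cov2 = StrandedCoverageSet.from_sample_sheet(out2.sample_sheet, 1000)
        np.testing.assert_array_equal(cov1.gene_profile("0-30", g1.gene),
                                      cov2.gene_profile("0-30", g1.gene))

    def test_constant_rate_manifest_displacements(self, tmp_path):
        genes = [
            GeneKinetics(
                GeneAnnotation(f"g{i}", f"c{i}", 0, 300_000, "+"),
                InitiationProfile.from_pattern("sustained_up", 1.0, fold=3.0),
                ElongationProfile.constant(2.0, 300_000),
            )
            for i in range(21)
        ]
        out = simulate_cohort(make_scenario(genes, noise="none"), tmp_path / "sim")
        from bruwave._tsv import read_tsv

        manifest = read_tsv(out.truth_manifest)
        for col in ("disp_30-60_kb", "disp_60-90_kb", "disp_90-120_kb"):
            assert np.allclose(manifest[col].astype(float), 60.0)

    def test_strand_mirror(self, tmp_path):
        init = InitiationProfile.from_pattern("sustained_up", 1.0, fold=3.0)
        elong = ElongationProfile.constant(2.0, 100_000)
        plus = GeneKinetics(GeneAnnotation("gp", "cp", 0, 100_000, "+"), init, elong)
        minus = GeneKinetics(GeneAnnotation("gm", "cm", 0, 100_000, "-"), init, elong)
        out = simulate_cohort(make_scenario([plus, minus], noise="none"), tmp_path / "sim")
        cov = StrandedCoverageSet.from_sample_sheet(out.sample_sheet, 1000)
        for name in ("0-30", "90-120"):
            p = cov.get_array(name, "+", "cp")[:100]
            m = cov.get_array(name, "-", "cm")[:100]
            np.testing.assert_allclose(m, p[::-1], rtol=1e-9)
            # TSS-oriented profiles are identical
            np.testing.assert_allclose(cov.gene_profile(name, plus.gene),
                                       cov.gene_profile(name, minus.gene), rtol=1e-9)

    def test_overlapping_genes_warn_and_flag(self, tmp_path):
        shared = ElongationProfile.constant(2.0, 40_000)
        g1 = GeneKinetics(GeneAnnotation("o1", "c1", 0, 40_000, "+"),
                          InitiationProfile.constant(1.0), shared)
        g2 = GeneKinetics(GeneAnnotation("o2", "c1", 20_000, 60_000, "+"),
                          InitiationProfile.constant(1.0), shared)
        with pytest.warns(UserWarning, match="overlap"):
            out = simulate_cohort(make_scenario([g1, g2], noise="none"), tmp_path / "sim")
        from bruwave._tsv import read_tsv

        manifest = read_tsv(out.truth_manifest).set_index("gene_id")
        assert bool(manifest.loc["o1", "overlap"]) and bool(manifest.loc["o2", "overlap"])

    def test_unaligned_gene_rejected(self):
        g = GeneKinetics(GeneAnnotation("g", "c", 500, 40_500, "+"),
                         InitiationProfile.constant(1.0),
                         ElongationProfile.constant(2.0, 40_000))
        with pytest.raises(ValueError, match="bin grid"):
            make_scenario([g])

    def test_truth_manifest_front_monotonic(self, tmp_path):
        sc = single_gene_scenario("sustained_up", length=300_000, rate=2.0, noise="none")
        out = simulate_cohort(sc, tmp_path / "sim")
        from bruwave._tsv import read_tsv

        manifest = read_tsv(out.truth_manifest)
        fronts = manifest[[c for c in manifest.columns if c.startswith("front_")]]
        vals = fronts.iloc[0].astype(float).to_numpy()
        assert np.all(np.diff(vals) >= 0)
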
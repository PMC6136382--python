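"""Fetal-fraction estimation: analytic MAF expectations, window filtering,
model fitting, and the two orthogonal validators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from niptkit.fetal_fraction import (build_sim_library, calibrate_male_chry_reference,
                                    degree_of_deviation, expected_maf,
                                    extract_maf_vector, ff_from_chry,
                                    ff_from_fetal_specific, fit_ff, MafVector)
from niptkit.simulate import (PlasmaSnpSample, PopulationModel, SimSampleConfig,
                              mix_mock_sample, simulate_family_pair,
                              simulate_plasma_snp_sample)
from niptkit.dosage import chry_proportion


class TestExpectedMaf:
    @pytest.mark.parametrize("combo,ff,expected", [
        (2, 0.22, 0.11),       # de novo fetal het at half the FF
        (4, 0.07, 0.5),
        (4, 0.31, 0.5),
        (3, 0.10, 0.45),
        (1, 0.2, 0.0),
        (2, 0.0, 0.0),
        (3, 0.0, 0.5),
    ])
    def test_analytic_values(self, combo, ff, expected):
        assert expected_maf(combo, ff) == pytest.approx(expected, abs=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            expected_maf(2, -0.1)
        with pytest.raises(ValueError):
            expected_maf(5, 0.1)

    @settings(deadline=None, derandomize=True)
    @given(lo=st.floats(0, 0.999), delta=st.floats(1e-6, 1.0))
    def test_monotone_in_ff(self, lo, delta):
        hi = min(lo + delta, 1.0)
        assert expected_maf(2, hi) >= expected_maf(2, lo)   # increasing
        assert expected_maf(3, hi) <= expected_maf(3, lo)   # decreasing
        for combo in (1, 4):
            assert expected_maf(combo, hi) == expected_maf(combo, lo)


class TestExtractMafVector:
    def _sample(self, chrom, depth, b):
        n = len(depth)
        return PlasmaSnpSample(np.array(chrom, dtype=object),
                               np.arange(1, n + 1), depth, b)

    def test_window_and_depth_filters(self):
        s = self._sample(["1", "1", "1", "18", "1"],
                         depth=[200, 200, 200, 200, 10],
                         b=[100, 10, 2, 10, 1])
        maf = extract_maf_vector(s, min_depth=20)
        # kept: only the depth-200 locus at MAF 0.05; 0.5 is above the
        # window, 0.01 below, chr18 excluded, depth-10 locus too shallow
        assert maf.values.tolist() == [0.05]
        assert maf.n_source_loci == 3

    def test_folding_is_symmetric(self):
        s = self._sample(["1", "1"], depth=[200, 200], b=[10, 190])
        maf = extract_maf_vector(s)
        assert maf.values.tolist() == pytest.approx([0.05, 0.05])

    def test_unusable_sample_raises(self):
        s = self._sample(["1"], depth=[200], b=[100])
        with pytest.raises(ValueError, match="unusable"):
            extract_maf_vector(s)

    def test_output_sorted_within_window(self, panel, pop, rng):
        cfg = SimSampleConfig(ff=0.12, n_snps=2000)
        maf = extract_maf_vector(
            simulate_plasma_snp_sample(cfg, pop, panel, rng=rng))
        assert np.all(np.diff(maf.values) >= 0)
        assert maf.values[0] >= 0.02 and maf.values[-1] <= 0.25

    def test_window_dominated_by_informative_combo(self, panel, pop, rng):
        """At FF ~ 0.12 the fitting window retains essentially only
        mother-homozygous / fetus-heterozygous loci."""
        cfg = SimSampleConfig(ff=0.12, mean_coverage=150, n_snps=2000)
        s = simulate_plasma_snp_sample(cfg, pop, panel, rng=rng)
        maf = np.minimum(s.b_count / s.depth, 1 - s.b_count / s.depth)
        in_window = (maf >= 0.02) & (maf <= 0.25)
        assert (s.true_combo[in_window] == 2).mean() > 0.95


class TestFitFF:
    def test_self_match_recovers_grid_point(self, panel, pop):
        lib = build_sim_library(ff_grid=[0.1], coverage=150, n_snps=1000,
                                n_reps=1, seed=9, panel=panel)
        cfg = SimSampleConfig(ff=0.1, mean_coverage=150, n_snps=1000)
        s = simulate_plasma_snp_sample(cfg, pop, panel,
                                       rng=np.random.default_rng(9))
        est = fit_ff(extract_maf_vector(s), lib)
        assert est.fitted_ff == pytest.approx(0.1)
        assert est.fit_distance == pytest.approx(0.0, abs=1e-9)

    def test_recovery_at_operating_point(self, panel, pop, lib150, rng):
        cfg = SimSampleConfig(ff=0.15, mean_coverage=150, n_snps=2000)
        s = simulate_plasma_snp_sample(cfg, pop, panel, rng=rng)
        est = fit_ff(extract_maf_vector(s), lib150)
        assert est.fitted_ff == pytest.approx(0.15, abs=0.02)
        assert est.method == "maf_model"

    def test_low_ff_sample_fits_low(self, panel, lib150):
        """A noisy non-pregnant-like sample (high error, no fetal signal)
        fits near zero, below the reporting QC gate."""
        noisy = PopulationModel(sequencing_error_rate=0.01)
        cfg = SimSampleConfig(ff=0.0, mean_coverage=150, n_snps=2000)
        s = simulate_plasma_snp_sample(cfg, noisy, panel,
                                       rng=np.random.default_rng(2))
        est = fit_ff(extract_maf_vector(s), lib150)
        assert est.fitted_ff <= 0.04

    def test_mismatched_coverage_warns(self, panel, pop, lib150):
        cfg = SimSampleConfig(ff=0.1, mean_coverage=400, n_snps=2000)
        s = simulate_plasma_snp_sample(cfg, pop, panel,
                                       rng=np.random.default_rng(5))
        with pytest.warns(UserWarning, match="coverage"):
            fit_ff(extract_maf_vector(s), lib150)

    def test_library_determinism(self, panel):
        a = build_sim_library(ff_grid=[0.05, 0.1], n_reps=2, n_snps=500,
                              seed=21, panel=panel)
        b = build_sim_library(ff_grid=[0.05, 0.1], n_reps=2, n_snps=500,
                              seed=21, panel=panel)
        assert np.array_equal(a.vectors, b.vectors)

    def test_library_round_trips_through_disk(self, panel, tmp_path):
        lib = build_sim_library(ff_grid=[0.05, 0.1], n_reps=2, n_snps=500,
                                seed=21, panel=panel)
        path = tmp_path / "lib.npz"
        lib.save(path)
        back = type(lib).load(path)
        assert np.array_equal(back.vectors, lib.vectors)
        assert back.window == lib.window and back.n_snps == lib.n_snps


@pytest.fixture(scope="module")
def male_pair(panel, pop):
    cfg = SimSampleConfig(fetal_sex="male", mean_coverage=200,
                          n_snps=3000, total_reads=15_000_000)
    return simulate_family_pair(cfg, pop, panel,
                                rng=np.random.default_rng(13))


class TestValidators:
    def test_fetal_specific_recovers_mock_ff(self, male_pair, panel, rng):
        snp, _ = mix_mock_sample(male_pair.mother_snp, male_pair.mother_counts,
                                 male_pair.child_snp, male_pair.child_counts,
                                 0.20, rng)
        est = ff_from_fetal_specific(snp, male_pair.maternal_genotypes)
        assert est.fitted_ff == pytest.approx(0.20, abs=0.01)
        assert est.method == "fetal_specific"

    def test_fetal_specific_near_zero_for_pure_maternal(self, male_pair, rng):
        snp, _ = mix_mock_sample(male_pair.mother_snp, male_pair.mother_counts,
                                 male_pair.child_snp, male_pair.child_counts,
                                 0.0, rng)
        try:
            est = ff_from_fetal_specific(snp, male_pair.maternal_genotypes)
            assert est.fitted_ff <= 0.03  # only sequencing-error reads left
        except ValueError:
            pass  # too few error loci to form an estimate: equally acceptable

    def test_fetal_specific_needs_informative_loci(self, male_pair):
        tiny = PlasmaSnpSample(male_pair.mother_snp.chrom[:5],
                               male_pair.mother_snp.pos[:5],
                               [200] * 5, [100] * 5)
        with pytest.raises(ValueError, match="informative"):
            ff_from_fetal_specific(tiny, male_pair.maternal_genotypes)

    def test_chry_scaling_is_linear(self):
        assert ff_from_chry(5e-4, 1e-3).fitted_ff == pytest.approx(0.5)
        with pytest.raises(ValueError):
            ff_from_chry(1e-4, 0.0)

    def test_chry_recovers_mock_ff(self, male_pair, panel, rng):
        _, counts = mix_mock_sample(male_pair.mother_snp,
                                    male_pair.mother_counts,
                                    male_pair.child_snp,
                                    male_pair.child_counts, 0.15, rng)
        est = ff_from_chry(chry_proportion(counts), panel.male_chry_proportion)
        assert est.fitted_ff == pytest.approx(0.15, abs=0.01)

    def test_simulated_calibration_matches_analytic_reference(self, panel):
        sim = calibrate_male_chry_reference(panel, "miseq", n=10, seed=4)
        assert sim == pytest.approx(panel.male_chry_proportion, rel=0.02)


class TestDegreeOfDeviation:
    @pytest.mark.parametrize("expected,fitted,result", [
        (0.10, 0.10, 0.0),
        (0.10, 0.095, 0.05),
        (0.2, 0.25, -0.25),
    ])
    def test_arithmetic(self, expected, fitted, result):
        assert degree_of_deviation(expected, fitted) == pytest.approx(result)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            degree_of_deviation(0.0, 0.1)
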
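"""Simulator correctness: genotype-combination MAF means, read-count
dosage structure, mock mixing, and determinism."""

import numpy as np
import pytest

from niptkit.dosage import chromosome_proportion, chry_proportion
from niptkit.panel import PanelDesign, default_panel
from niptkit.simulate import (PopulationModel, ReadCountSample, SimSampleConfig,
                              expected_chr21_inflation, mix_mock_sample,
                              simulate_family_pair, simulate_plasma_snp_sample,
                              simulate_readcount_sample,
                              simulate_reference_cohort)


class TestPlasmaSnpSample:
    def test_allele_counts_bounded_by_depth(self, panel, pop, rng):
        for ff in (0.0, 0.05, 0.3, 1.0):
            s = simulate_plasma_snp_sample(
                SimSampleConfig(ff=ff, n_snps=500), pop, panel, rng=rng)
            assert np.all(s.b_count >= 0)
            assert np.all(s.b_count <= s.depth)

    def test_combo_means_match_analytic_expectations(self, panel, rng):
        """Empirical per-combination allele fractions converge to
        (0, ff/2, 0.5-ff/2, 0.5) at high depth, within 3 binomial SEs."""
        ff = 0.1
        pop = PopulationModel(sequencing_error_rate=0.0)
        cfg = SimSampleConfig(ff=ff, mean_coverage=10_000, n_snps=2000)
        s = simulate_plasma_snp_sample(cfg, pop, panel, rng=rng)
        f = s.b_count / s.depth
        folded = np.minimum(f, 1.0 - f)
        # combos 1-3: check the folded MAF; combo 4: the raw B fraction
        # (folding at 0.5 would bias the mean of a distribution centred there)
        for combo, expected, values in [(1, 0.0, folded), (2, ff / 2, folded),
                                        (3, 0.5 - ff / 2, folded),
                                        (4, 0.5, f)]:
            sel = s.true_combo == combo
            assert sel.sum() > 20
            se = np.sqrt(np.mean(expected * (1 - expected) / s.depth[sel])
                         / sel.sum())
            assert abs(values[sel].mean() - expected) <= max(3 * se, 1e-4), combo

    def test_ff_zero_is_a_plain_individual(self, panel, pop, rng):
        """Without fetal DNA there is no mother-hom/fetus-het combination and
        maternal heterozygous loci sit at B fraction 0.5."""
        cfg = SimSampleConfig(ff=0.0, mean_coverage=1000, n_snps=2000)
        s = simulate_plasma_snp_sample(cfg, pop, panel, rng=rng)
        assert not np.any(np.isin(s.true_combo, (2, 3)))
        het = s.true_combo == 4
        f = (s.b_count[het] / s.depth[het]).mean()
        assert abs(f - 0.5) < 0.01

    def test_same_seed_reproduces_sample(self, panel, pop):
        cfg = SimSampleConfig(ff=0.12, seed=77, n_snps=300)
        a = simulate_plasma_snp_sample(cfg, pop, panel)
        b = simulate_plasma_snp_sample(cfg, pop, panel)
        assert np.array_equal(a.depth, b.depth)
        assert np.array_equal(a.b_count, b.b_count)
        assert np.array_equal(a.true_combo, b.true_combo)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimSampleConfig(ff=1.2)
        with pytest.raises(ValueError):
            SimSampleConfig(mean_coverage=0)
        with pytest.raises(ValueError):
            SimSampleConfig(n_snps=0)


class TestReadCounts:
    def test_t21_inflates_chr21_by_half_ff(self, panel, rng):
        """Trisomy multiplies the chr21 share by 1 + ff/2 (three fetal
        copies vs two); checked against the mean of repeated draws."""
        ff = 0.2
        assert expected_chr21_inflation(ff) == pytest.approx(1.10)
        base = SimSampleConfig(ff=ff, total_reads=200_000)
        t21 = SimSampleConfig(ff=ff, trisomy21=True, total_reads=200_000)
        draws = {}
        for name, cfg in [("eu", base), ("t21", t21)]:
            c21 = [simulate_readcount_sample(cfg, panel, rng=rng).counts["21"]
                   for _ in range(2000)]
            draws[name] = np.mean(c21)
        ratio = draws["t21"] / draws["eu"]
        assert ratio == pytest.approx(1.10, abs=0.01)

    def test_ff_zero_trisomy_has_no_signal(self, panel):
        cfg_t = SimSampleConfig(ff=0.0, trisomy21=True, seed=5)
        cfg_e = SimSampleConfig(ff=0.0, trisomy21=False, seed=5)
        a = simulate_readcount_sample(cfg_t, panel)
        b = simulate_readcount_sample(cfg_e, panel)
        assert a.counts == b.counts

    def test_chry_proportions_by_sex(self, panel, rng):
        female = simulate_readcount_sample(
            SimSampleConfig(ff=0.12, fetal_sex="female"), panel, rng=rng)
        male = simulate_readcount_sample(
            SimSampleConfig(ff=0.12, fetal_sex="male"), panel, rng=rng)
        assert chry_proportion(female) < 5e-6       # noise floor, ~5e-7 scale
        assert 1e-5 < chry_proportion(male) < 3e-4  # ~1e-4 scale

    def test_counts_complete_and_nonnegative(self, panel, rng):
        s = simulate_readcount_sample(SimSampleConfig(), panel, rng=rng)
        assert set(s.counts) == {str(c) for c in range(1, 23)} | {"Y"}
        assert all(v >= 0 for v in s.counts.values())

    def test_dispersion_below_one_rejected(self, panel):
        with pytest.raises(ValueError):
            simulate_readcount_sample(SimSampleConfig(), panel, dispersion=0.5)


@pytest.fixture(scope="module")
def pair(panel, pop):
    cfg = SimSampleConfig(fetal_sex="male", n_snps=1500,
                          mean_coverage=200, total_reads=1_000_000)
    return simulate_family_pair(cfg, pop, panel,
                                rng=np.random.default_rng(3))


class TestMockMixing:
    def test_mixture_means_interpolate_parents(self, pair, rng):
        ff = 0.3
        snp, _ = mix_mock_sample(pair.mother_snp, pair.mother_counts,
                                 pair.child_snp, pair.child_counts, ff, rng)
        fm = pair.mother_snp.b_count / np.maximum(pair.mother_snp.depth, 1)
        fc = pair.child_snp.b_count / np.maximum(pair.child_snp.depth, 1)
        expected = (1 - ff) * fm.mean() + ff * fc.mean()
        observed = (snp.b_count / np.maximum(snp.depth, 1)).mean()
        assert observed == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("ff,parent", [(0.0, "mother"), (1.0, "child")])
    def test_degenerate_mixtures_resample_one_parent(self, pair, rng, ff, parent):
        snp, counts = mix_mock_sample(pair.mother_snp, pair.mother_counts,
                                      pair.child_snp, pair.child_counts, ff, rng)
        src = pair.mother_snp if parent == "mother" else pair.child_snp
        assert np.array_equal(snp.depth, src.depth)
        assert np.array_equal(snp.b_count, src.b_count)
        assert counts.truth["ff"] == ff

    def test_locus_mismatch_reported(self, pair, rng):
        shifted = simulate_family_pair(
            SimSampleConfig(n_snps=1500, mean_coverage=200,
                            total_reads=1_000_000),
            panel=default_panel(), rng=np.random.default_rng(4))
        bad = shifted.child_snp
        bad.pos = bad.pos + 1
        with pytest.raises(ValueError, match="locus mismatch"):
            mix_mock_sample(pair.mother_snp, pair.mother_counts,
                            bad, shifted.child_counts, 0.1, rng)

    def test_child_genotypes_inherit_one_maternal_allele(self, pair):
        # mother hom-ref loci can never yield a hom-alt child
        g = pair.maternal_genotypes
        child = pair.child_snp
        mother_hom_ref = np.array(
            [g[(str(c), int(p))] == 0 for c, p in zip(child.chrom, child.pos)])
        child_b = child.b_count / np.maximum(child.depth, 1)
        assert np.all(child_b[mother_hom_ref] < 0.9)


class TestReferenceCohort:
    def test_too_small_cohort_rejected(self, panel):
        with pytest.raises(ValueError, match="at least 5"):
            simulate_reference_cohort(4, panel)

    def test_cohort_is_deterministic_under_seed(self, panel):
        a = simulate_reference_cohort(6, panel, "miseq", seed=30,
                                      total_reads=500_000)
        b = simulate_reference_cohort(6, panel, "miseq", seed=30,
                                      total_reads=500_000)
        assert [s.counts for s in a] == [s.counts for s in b]

    def test_cohort_size_and_platform_tag(self, panel):
        cohort = simulate_reference_cohort(5, panel, "hiseq", seed=1,
                                           total_reads=500_000)
        assert len(cohort) == 5
        assert all(s.platform == "hiseq" for s in cohort)
        assert all(not s.truth["trisomy21"] for s in cohort)


class TestPanel:
    def test_default_panel_composition(self, panel):
        totals = panel.totals_by_role
        probes = panel.probes
        assert (probes["role"] == "ff_informative").sum() == 6739
        assert (probes["role"] == "chr21_dosage").sum() == 240
        assert totals["chr21_dosage"] == pytest.approx(33_500, rel=0.05)
        assert totals["ff_informative"] == pytest.approx(1_500_000, rel=0.05)
        ff = panel.ff_probes()
        assert not ff["chrom"].isin(["18", "21"]).any()

    def test_bed_round_trip(self, panel, tmp_path):
        path = tmp_path / "panel.bed"
        panel.to_bed(path)
        back = PanelDesign.from_bed(path)
        assert back.probes.equals(panel.probes)

    def test_invalid_panels_rejected(self, panel):
        bad = panel.probes.copy()
        bad.loc[0, "chrom"] = "18"  # ff probe on excluded chromosome
        with pytest.raises(ValueError, match="18/21"):
            PanelDesign(bad)
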
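"""Forward simulator: panels, selfing decay, recombination, selection."""

from dataclasses import replace

import numpy as np
import pytest

from weedhyb.io import HET
from weedhyb.simulate import (
    CROP,
    SimConfig,
    SimulationError,
    expected_het_after_selfing,
    make_ancestral_panels,
    simulate_cohort,
    simulate_lineage,
)


def tiny_cfg(**kw):
    base = dict(
        n_chromosomes=1,
        chrom_length_bp=2_000_000,
        aim_density=10.0,
        neutral_snp_density=10.0,
        recomb_rate=1.0,
        g=2,
        n_lineages=4,
        n_panel_samples=4,
        seed=5,
    )
    base.update(kw)
    return SimConfig(**base)


class TestAncestralPanels:
    def test_aims_are_fixed_differences(self, small_sim):
        cfg, cohort, crop, weed, truth = small_sim
        sm = truth.sitemap
        crop_freq = crop.genotypes.mean(axis=0) / 2
        weed_freq = weed.genotypes.mean(axis=0) / 2
        diff = np.abs(crop_freq - weed_freq)
        assert np.all(diff[sm.is_aim] == 1.0)
        assert np.all(diff[~sm.is_aim] < 1.0)

    def test_panels_fully_homozygous(self, small_sim):
        _, _, crop, weed, _ = small_sim
        assert not (crop.genotypes == HET).any()
        assert not (weed.genotypes == HET).any()

    def test_same_seed_identical_panels(self):
        cfg = tiny_cfg()
        a = make_ancestral_panels(cfg)
        b = make_ancestral_panels(cfg)
        np.testing.assert_array_equal(a[0].genotypes, b[0].genotypes)
        assert a[0].sites.equals(b[0].sites)

    def test_fixed_count_option(self):
        cfg = tiny_cfg(chrom_length_bp=10_000_000, aim_density=5.0,
                       fixed_site_counts=True)
        _, _, sm = make_ancestral_panels(cfg)
        assert int(sm.is_aim.sum()) == 50

    def test_poisson_count_in_central_range(self):
        # Poisson(50): central 99.9% range is roughly [28, 74]
        cfg = tiny_cfg(chrom_length_bp=10_000_000, aim_density=5.0)
        _, _, sm = make_ancestral_panels(cfg)
        assert 28 <= int(sm.is_aim.sum()) <= 74


class TestSimulateLineage:
    def test_f1_heterozygous_at_every_aim(self):
        cfg = tiny_cfg(g=0)
        _, _, sm = make_ancestral_panels(cfg)
        rng = np.random.default_rng(0)
        geno, truth = simulate_lineage(sm, cfg, rng)
        assert np.all(truth.dosage == 1)
        assert np.all(geno[sm.is_aim] == HET)

    def test_mendelian_segregation_without_recombination(self):
        # one selfing generation, no crossovers: each chromosome is
        # crop/crop, weed/weed or crop/weed with probs 1/4, 1/4, 1/2
        cfg = tiny_cfg(recomb_rate=0.0, g=1)
        _, _, sm = make_ancestral_panels(cfg)
        rng = np.random.default_rng(42)
        n = 600
        counts = {0: 0, 1: 0, 2: 0}
        for _ in range(n):
            _, truth = simulate_lineage(sm, cfg, rng)
            d = truth.dosage
            assert len(set(d.tolist())) == 1  # whole chromosome one state
            counts[int(d[0])] += 1
        assert counts[0] / n == pytest.approx(0.25, abs=3 * 0.433 / np.sqrt(n))
        assert counts[2] / n == pytest.approx(0.25, abs=3 * 0.433 / np.sqrt(n))
        assert counts[1] / n == pytest.approx(0.50, abs=3 * 0.5 / np.sqrt(n))

    def test_strong_selection_retains_crop_allele(self):
        cfg = tiny_cfg(g=5, selection_site=(0, 1_000_000, 8.0),
                       n_lineages=1)
        _, _, sm = make_ancestral_panels(cfg)
        from weedhyb.simulate import _selection_index

        sel = _selection_index(sm, cfg)
        rng = np.random.default_rng(7)
        kept = 0
        n = 500
        for _ in range(n):
            _, truth = simulate_lineage(sm, cfg, rng)
            kept += truth.dosage[sel] >= 1
        assert kept / n > 0.9

    def test_impossible_selection_raises(self):
        cfg = tiny_cfg(g=3, background_penalty=0.5,
                       max_rejection_tries=5)
        _, _, sm = make_ancestral_panels(cfg)
        with pytest.raises(SimulationError):
            for _ in range(20):
                simulate_lineage(sm, cfg, np.random.default_rng(1))


class TestTruthConsistency:
    def test_segments_tile_and_genotypes_match_ancestry(self, small_sim):
        cfg, cohort, crop, weed, truth = small_sim
        sm = truth.sitemap
        pos0 = sm.sites["pos"].to_numpy() - 1
        for li, lin in enumerate(truth.lineages):
            for hap in lin.haplotypes:
                for segs in hap:
                    assert segs[0][0] == 0
                    assert segs[-1][1] == cfg.chrom_length_bp
                    for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
                        assert e1 == s2
            # genotype equals ancestry dosage applied to founder alleles:
            # at AIMs the dosage alone determines the genotype
            geno = cohort.genotypes[li]
            dosage = lin.dosage
            aim = sm.is_aim
            expected_alt = np.where(
                sm.crop_is_alt[aim], dosage[aim], 2 - dosage[aim]
            )
            np.testing.assert_array_equal(geno[aim], expected_alt)

    def test_het_survival_law_without_recombination(self):
        # with no crossovers, a chromosome's het indicator halves per
        # generation: P(still heterozygous after g) = 0.5**g
        rng_checks = []
        for g in (1, 3):
            cfg = tiny_cfg(recomb_rate=0.0, g=g)
            _, _, sm = make_ancestral_panels(cfg)
            rng = np.random.default_rng(100 + g)
            n = 800
            het = sum(
                int(simulate_lineage(sm, cfg, rng)[1].dosage[0] == 1)
                for _ in range(n)
            )
            p = expected_het_after_selfing(g)
            se = np.sqrt(p * (1 - p) / n)
            rng_checks.append(abs(het / n - p) < 3 * se)
        assert all(rng_checks)


class TestCohort:
    def test_mean_aim_het_matches_selfing_decay(self):
        cfg = tiny_cfg(n_chromosomes=4, g=2, n_lineages=48)
        cohort, _, _, truth = simulate_cohort(cfg)
        sm = truth.sitemap
        het = (cohort.genotypes[:, sm.is_aim] == HET).mean(axis=1)
        se = het.std(ddof=1) / np.sqrt(len(het))
        assert abs(het.mean() - 0.25) < 3 * max(se, 1e-9)

    def test_neutral_crop_fraction_near_half(self):
        cfg = tiny_cfg(n_chromosomes=4, g=4, n_lineages=48)
        _, _, _, truth = simulate_cohort(cfg)
        fr = np.array(
            [lin.crop_fraction(cfg.chrom_length_bp) for lin in truth.lineages]
        )
        assert abs(fr.mean() - 0.5) < 3 * fr.std(ddof=1) / np.sqrt(len(fr))

    def test_same_seed_byte_identical_vcf(self, tmp_path):
        cfg = tiny_cfg()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(cfg, d1)
        simulate_cohort(cfg, d2)
        assert (d1 / "cohort.vcf").read_bytes() == (d2 / "cohort.vcf").read_bytes()
        assert (d1 / "ancestry_truth.bed").read_bytes() == (
            d2 / "ancestry_truth.bed"
        ).read_bytes()


class TestExpectedHet:
    @pytest.mark.parametrize("g,expected", [(0, 1.0), (1, 0.5), (5, 0.03125)])
    def test_closed_form(self, g, expected):
        assert expected_het_after_selfing(g) == expected

    def test_negative_generations_rejected(self):
        with pytest.raises(ValueError):
            expected_het_after_selfing(-1)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(n_chromosomes=0)
    with pytest.raises(ValueError):
        SimConfig(aim_density=0.0)
    with pytest.raises(ValueError):
        SimConfig(background_penalty=1.0)
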
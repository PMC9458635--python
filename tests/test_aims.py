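"""AIM discovery, supervised ancestry, classification, generation dating."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from weedhyb.io import HET, HOM_ALT, HOM_REF, UndefinedInputError
from weedhyb.aims import (
    AIMSet,
    ClassifyThresholds,
    aim_heterozygosity,
    classify_accession,
    classify_all,
    estimate_generations,
    identify_aims,
    read_q_matrix,
    supervised_ancestry,
)
from weedhyb.simulate import expected_het_after_selfing
from conftest import make_matrix


@pytest.fixture(scope="module")
def sim_aims(small_sim):
    _, _, crop, weed, _ = small_sim
    return identify_aims(crop, weed)


class TestIdentifyAims:
    def test_recovers_simulated_aim_list_exactly(self, small_sim, sim_aims):
        _, _, _, _, truth = small_sim
        sm = truth.sitemap
        expected = sm.sites.loc[sm.is_aim, ["chrom", "pos"]].reset_index(drop=True)
        got = sim_aims.table[["chrom", "pos"]].reset_index(drop=True)
        pd.testing.assert_frame_equal(got, expected)

    def test_orientation_matches_simulator(self, small_sim, sim_aims):
        _, _, _, _, truth = small_sim
        sm = truth.sitemap
        np.testing.assert_array_equal(
            sim_aims.table["a_is_alt"].to_numpy(), sm.crop_is_alt[sm.is_aim]
        )

    def test_near_fixed_site_threshold(self):
        # fixed in A; frequency 0.9 in B
        panel_a = make_matrix([[HOM_REF]] * 10)
        panel_b = make_matrix([[HOM_ALT]] * 9 + [[HOM_REF]])
        strict = identify_aims(panel_a, panel_b, min_freq_diff=1.0)
        assert len(strict) == 0
        relaxed = identify_aims(panel_a, panel_b, min_freq_diff=0.8)
        assert len(relaxed) == 1
        row = relaxed.table.iloc[0]
        assert row["allele_a"] == "A" and row["allele_b"] == "G"
        assert not row["a_is_alt"]

    def test_round_trip_tsv(self, sim_aims, tmp_path):
        p = tmp_path / "aims.tsv"
        sim_aims.write_tsv(p)
        back = AIMSet.read_tsv(p)
        pd.testing.assert_frame_equal(back.table, sim_aims.table)


class TestSupervisedAncestry:
    def test_pure_panel_samples(self, small_sim, sim_aims):
        _, _, crop, weed, _ = small_sim
        assert supervised_ancestry(crop, crop.sample_ids[0], sim_aims) == {
            "A": 1.0, "B": 0.0,
        }
        assert supervised_ancestry(weed, weed.sample_ids[0], sim_aims) == {
            "A": 0.0, "B": 1.0,
        }

    def test_coefficient_equals_truth_dosage_mean(self, small_sim, sim_aims):
        # without genotype error the AIM allele count is the truth dosage
        cfg, cohort, _, _, truth = small_sim
        sm = truth.sitemap
        for i, s in enumerate(cohort.sample_ids):
            coeff = supervised_ancestry(cohort, s, sim_aims)
            truth_mean = truth.lineages[i].dosage[sm.is_aim].mean() / 2
            assert coeff["A"] == pytest.approx(truth_mean)

    def test_fifty_fifty_mixture_exact(self):
        aims = AIMSet(
            pd.DataFrame(
                {"chrom": ["chr1"] * 4, "pos": [100, 200, 300, 400],
                 "allele_a": list("GGGG"), "allele_b": list("AAAA"),
                 "a_is_alt": [True] * 4}
            )
        )
        gm = make_matrix([[HET, HET, HET, HET]])
        assert supervised_ancestry(gm, "s0", aims) == {"A": 0.5, "B": 0.5}

    def test_no_called_aims_rejected(self):
        aims = AIMSet(
            pd.DataFrame({"chrom": ["chr9"], "pos": [1], "allele_a": ["G"],
                          "allele_b": ["A"], "a_is_alt": [True]})
        )
        gm = make_matrix([[HOM_REF]])
        with pytest.raises(UndefinedInputError):
            supervised_ancestry(gm, "s0", aims)


class TestAimHeterozygosity:
    def test_f1_fraction_is_one(self, small_sim, sim_aims):
        from weedhyb.simulate import SimConfig, simulate_cohort
        from dataclasses import replace

        cfg = replace(small_sim[0], g=0, n_lineages=2)
        cohort, _, _, _ = simulate_cohort(cfg)
        aims = sim_aims  # same seed -> same site map
        _, _, frac = aim_heterozygosity(cohort, cohort.sample_ids[0], aims)
        assert frac == 1.0

    def test_homozygous_line_is_zero(self, small_sim, sim_aims):
        _, _, crop, _, _ = small_sim
        n_het, n_called, frac = aim_heterozygosity(
            crop, crop.sample_ids[0], sim_aims
        )
        assert n_het == 0 and frac == 0.0

    def test_cohort_mean_near_expected_decay(self, small_sim, sim_aims):
        cfg, cohort, _, _, _ = small_sim
        fracs = np.array(
            [aim_heterozygosity(cohort, s, sim_aims)[2]
             for s in cohort.sample_ids]
        )
        expected = expected_het_after_selfing(cfg.g)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - expected) < 3 * max(se, 0.01)


class TestEstimateGenerations:
    @pytest.mark.parametrize(
        "frac,expected", [(0.5, 1.0), (0.03125, 5.0), (1.0, 0.0)]
    )
    def test_point_estimates(self, frac, expected):
        est = estimate_generations(frac, 300)
        assert est.g_hat == pytest.approx(expected)

    @settings(max_examples=60, deadline=None)
    @given(g=st.floats(0.0, 12.0))
    def test_closed_form_inverse(self, g):
        frac = expected_het_after_selfing(g)
        est = estimate_generations(frac, 10**6, n_het=1)
        assert est.g_hat == pytest.approx(g, abs=1e-9)

    def test_zero_het_gives_open_lower_bound(self):
        est = estimate_generations(0.0, 256)
        assert est.lower_bound_only
        assert est.ci[0] == pytest.approx(8.0)
        assert math.isinf(est.g_hat)

    def test_ci_brackets_point_estimate(self):
        est = estimate_generations(0.25, 300, n_het=75)
        lo, hi = est.ci
        assert lo < est.g_hat < hi


Q_EXAMPLES = [
    ({"SH": 0.97, "BHA": 0.0, "TRJ": 0.03}, "non-admixed-SH", False),
    ({"SH": 0.40, "BHA": 0.0, "TRJ": 0.60}, "SH-like", True),
    ({"SH": 0.25, "BHA": 0.25, "TRJ": 0.50}, "complex", True),
    ({"SH": 0.0, "BHA": 0.60, "TRJ": 0.40}, "BHA-like", True),
    ({"SH": 0.02, "BHA": 0.06, "TRJ": 0.04, "BETA": 0.88}, "beta", False),
]


class TestClassifyAccession:
    @pytest.mark.parametrize("q,category,admixed", Q_EXAMPLES)
    def test_rule_examples(self, q, category, admixed):
        call = classify_accession(q)
        assert call.category == category
        assert call.admixed is admixed

    def test_invariant_to_population_order(self):
        q = {"TRJ": 0.60, "SH": 0.40, "BHA": 0.0}
        rev = dict(reversed(list(q.items())))
        assert classify_accession(q) == classify_accession(rev)

    def test_exactly_one_category(self):
        rng = np.random.default_rng(0)
        pops = ["TRJ", "TMJ", "ARO", "IND", "AUS", "SH", "BHA", "BETA"]
        for _ in range(200):
            w = rng.dirichlet(np.ones(len(pops)))
            call = classify_accession(dict(zip(pops, w)))
            assert isinstance(call.category, str) and call.category

    def test_missing_population_rejected(self):
        with pytest.raises(KeyError):
            classify_accession({"SH": 1.0})


def test_q_matrix_reader(tmp_path):
    from weedhyb.datasets import example_q_matrix, Q_POPULATIONS

    q = example_q_matrix()
    qp = tmp_path / "run.Q"
    sp = tmp_path / "samples.txt"
    qp.write_text(
        "\n".join(" ".join(f"{v:.4f}" for v in row) for row in q.to_numpy())
        + "\n"
    )
    sp.write_text("\n".join(q.index) + "\n")
    back = read_q_matrix(qp, sp, Q_POPULATIONS)
    assert back.shape == q.shape
    assert list(back.index) == list(q.index)
    counts = classify_all(back)["category"].value_counts()
    assert counts["BHA-like"] == 28 and counts["beta"] == 9
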
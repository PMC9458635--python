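"""Seeded calibration experiments on synthetic cohorts.

Each function simulates cohorts with known ground truth and measures how
well an estimator recovers it: heterozygosity-decay dating across
generations, genome-wide ancestry calibration under neutrality and under
genome-wide selection against crop alleles, and the power of the dual FST
scan to localise a selected crop allele. They are used both by the test
suite and by the reproducibility script, with sizes chosen so a laptop run
finishes in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import aims as am
from . import divergence as dv
from .io import PanelAssignment
from .simulate import SimConfig, simulate_cohort, stack_samples


def _derive_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


# 300 AIMs over a 12-chromosome genome (25 per 10-Mb chromosome, fixed).
_DATING_BASE = SimConfig(
    n_chromosomes=12,
    chrom_length_bp=10_000_000,
    aim_density=2.5,
    neutral_snp_density=0.0,
    recomb_rate=1.5,
    n_lineages=100,
    n_panel_samples=6,
    fixed_site_counts=True,
)


def generation_recovery(
    seed: int, generations: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    n_lineages: int = 100,
) -> dict[int, float]:
    """Median estimated generations-since-hybridization per true g.

    For each g, simulates ``n_lineages`` independent selfing lineages,
    estimates g from each lineage's AIM heterozygosity, and returns the
    cohort median (infinite estimates from fully homozygous lineages are
    kept; the median is robust to them).
    """
    out: dict[int, float] = {}
    for i, g in enumerate(generations):
        cfg = replace(_DATING_BASE, g=g, n_lineages=n_lineages,
                      seed=_derive_seed(seed, i))
        cohort, crop, weed, truth = simulate_cohort(cfg)
        aim_set = am.identify_aims(crop, weed)
        g_hats = []
        for s in cohort.sample_ids:
            n_het, n_called, frac = am.aim_heterozygosity(cohort, s, aim_set)
            est = am.estimate_generations(frac, n_called, n_het)
            g_hats.append(est.g_hat)
        out[g] = float(np.median(g_hats))
    return out


@dataclass(frozen=True)
class BiasResult:
    mean_crop_fraction: float
    mc_se: float


_BIAS_BASE = SimConfig(
    n_chromosomes=6,
    chrom_length_bp=10_000_000,
    aim_density=2.0,
    neutral_snp_density=0.0,
    recomb_rate=1.5,
    g=5,
    n_lineages=48,
    n_panel_samples=6,
    # early generations under the strongest penalty accept ~1 proposal in
    # 500; a deep cap keeps rejection sampling exact instead of aborting
    max_rejection_tries=50_000,
)


def ancestry_bias(seed: int, background_penalty: float = 0.0,
                  n_lineages: int = 48) -> BiasResult:
    """Mean genome-wide crop-ancestry fraction of a simulated cohort.

    Measured on the simulator's truth tracks (bp-weighted over both
    haplotypes). Under neutrality the expectation is 0.5; a per-crop-allele
    viability penalty pushes the cohort toward its weedy ancestor.
    """
    cfg = replace(_BIAS_BASE, background_penalty=background_penalty,
                  n_lineages=n_lineages, seed=seed)
    _, _, _, truth = simulate_cohort(cfg)
    fracs = np.array(
        [lin.crop_fraction(cfg.chrom_length_bp) for lin in truth.lineages]
    )
    return BiasResult(float(fracs.mean()),
                      float(fracs.std(ddof=1) / np.sqrt(len(fracs))))


def penalty_bias_curve(
    seed: int, penalties: tuple[float, ...] = (0.0, 0.02, 0.05),
    n_lineages: int = 96,
) -> dict[float, float]:
    """Mean weed-ancestry fraction across a grid of background penalties."""
    return {
        p: 1.0 - ancestry_bias(_derive_seed(seed, k), p, n_lineages).mean_crop_fraction
        for k, p in enumerate(penalties)
    }


# Scan scenario: designed so the swept haplotype block is narrower than one
# 500-kb window (high per-bp recombination and enough generations), making
# single-window localisation the correct expectation. Under rice-like
# per-chromosome recombination the hitchhiking block spans several Mb and
# the dip/peak plateaus across neighbouring windows instead.
_SCAN_BASE = SimConfig(
    n_chromosomes=1,
    chrom_length_bp=5_000_000,
    aim_density=4.0,
    neutral_snp_density=100.0,
    recomb_rate=10.0,
    g=10,
    n_lineages=48,
    n_panel_samples=8,
    # selected locus centred in a 500-kb window
    selection_site=(0, 2_750_000, 5.0),
)


def selection_scan_replicate(seed: int) -> tuple[bool, bool]:
    """One replicate of the dual FST scan with selection at a focal locus.

    Simulates a cohort under strong viability selection for the crop allele
    at mid-chromosome, runs 500 kb / 250 kb windowed FST of the cohort
    against each ancestral panel, and reports whether the top-rank
    weed-ancestor-FST window and the bottom-rank crop-ancestor-FST window
    each contain the selected locus. (With half-overlapping windows, two
    windows contain any locus; containment is the well-posed form of "the
    focal window has the extreme rank".)
    """
    from . import simulate as sim

    cfg = replace(_SCAN_BASE, seed=seed)
    cohort, crop, weed, truth = simulate_cohort(cfg)
    sitemap = truth.sitemap
    sel_idx = sim._selection_index(sitemap, cfg)
    sel_pos = int(sitemap.sites["pos"].iloc[sel_idx]) - 1
    gm = stack_samples([cohort, crop, weed])
    panel = PanelAssignment(
        {**{s: "contemporary" for s in cohort.sample_ids},
         **{s: "crop" for s in crop.sample_ids},
         **{s: "weed" for s in weed.sample_ids}})
    chrom_lengths = {c: cfg.chrom_length_bp for c in cfg.chrom_names}
    fst_weed = dv.fst_windows(gm, panel, "contemporary", "weed",
                              chrom_lengths=chrom_lengths)
    fst_crop = dv.fst_windows(gm, panel, "contemporary", "crop",
                              chrom_lengths=chrom_lengths)
    vw = fst_weed["value"].to_numpy()
    vc = fst_crop["value"].to_numpy()
    top = fst_weed.iloc[int(np.nanargmax(vw))]
    bottom = fst_crop.iloc[int(np.nanargmin(vc))]
    top_weed = bool(top["start"] <= sel_pos < top["end"])
    bottom_crop = bool(bottom["start"] <= sel_pos < bottom["end"])
    return top_weed, bottom_crop


def selection_scan_power(seed: int, n_replicates: int = 50) -> float:
    """Fraction of replicates where the focal window is jointly extreme.

    The focal window must carry the maximum weed-vs-weed-ancestor FST and
    the minimum weed-vs-crop-ancestor FST across all windows.
    """
    hits = 0
    for k in range(n_replicates):
        top_weed, bottom_crop = selection_scan_replicate(_derive_seed(seed, k))
        hits += top_weed and bottom_crop
    return hits / n_replicates
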
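"""Forward-in-time simulation of crop x weed hybridization under selfing.

The model: two fully inbred ancestral gene pools (a crop-like and a weed-like
panel) carry fixed differences at ancestry-informative marker (AIM) sites and
private polymorphism at neutral sites. A single outcross produces an F1 that
is heterozygous at every fixed difference; the lineage then returns to strict
self-fertilization for ``g`` generations. Each selfing meiosis draws a
Poisson number of crossovers placed uniformly along the chromosome (no
interference). Two selective forces are available, separately switchable:

* positive viability selection with coefficient ``s`` favouring the crop
  allele at one site (an herbicide-resistance locus analogue), and
* a small multiplicative fitness penalty per crop allele at AIM sites,
  modelling genome-wide selection against crop ancestry.

Selection acts by rejection sampling on offspring relative fitness
``(1+s)^d * (1-penalty)^c`` where ``d`` is the crop-allele dosage at the
selected site and ``c`` the crop-allele count over AIM sites.

Every lineage records complete ancestry truth (per-haplotype breakpoint
segments and per-site crop dosage), which downstream inference tests are
scored against. All coordinates here are half-open 0-based; conversion to
1-based happens only when VCF/TSV files are written.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PanelAssignment, write_vcf

CROP = 0
WEED = 1
_LABELS = {CROP: "crop", WEED: "weed"}
_BASES = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    """Raised when rejection sampling cannot produce a viable offspring."""


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for the hybridization-and-selfing simulator.

    Defaults describe a rice-like genome (12 chromosomes of 30 Mbp, ~1.5
    crossovers per chromosome per meiosis) and a cohort of 48 independent
    hybrid lineages five selfing generations past the F1 — the scale of a
    contemporary weedy-rice field collection.
    """

    n_chromosomes: int = 12
    chrom_length_bp: int = 30_000_000
    aim_density: float = 1.0          # AIMs per Mbp
    neutral_snp_density: float = 5.0  # within-panel SNPs per Mbp
    recomb_rate: float = 1.5          # expected crossovers / chromosome / meiosis
    g: int = 5                        # selfing generations after the F1
    n_lineages: int = 48
    n_panel_samples: int = 10
    selection_site: tuple[int, int, float] | None = None  # (chrom idx, pos, s)
    background_penalty: float = 0.0   # per-crop-allele fitness penalty at AIMs
    fixed_site_counts: bool = False   # exact (not Poisson) site counts
    max_rejection_tries: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.chrom_length_bp <= 0:
            raise ValueError("chromosome number and length must be positive")
        if self.aim_density <= 0 or self.neutral_snp_density < 0:
            raise ValueError("site densities must be positive")
        if self.recomb_rate < 0:
            raise ValueError("recombination rate must be non-negative")
        if self.g < 0:
            raise ValueError("generations must be non-negative")
        if not (0.0 <= self.background_penalty < 1.0):
            raise ValueError("background_penalty must lie in [0, 1)")
        if self.selection_site is not None and self.selection_site[2] < 0:
            raise ValueError("selection coefficient must be non-negative")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


# A haplotype is, per chromosome, a list of (start, end, ancestry) segments
# that tile [0, L). Allele content is fully determined by ancestry because
# both parents are inbred.
Segments = list[tuple[int, int, int]]
Haplotype = list[Segments]


@dataclass
class LineageTruth:
    """Ground truth for one simulated lineage."""

    g: int
    haplotypes: tuple[Haplotype, Haplotype]
    dosage: np.ndarray            # crop-allele dosage per site, values {0,1,2}
    fitness_history: list[float]  # accepted offspring fitness per generation

    def crop_fraction(self, chrom_length: int) -> float:
        """Genome-wide fraction of bp with crop ancestry (both haplotypes)."""
        total = crop_bp = 0
        for hap in self.haplotypes:
            for segs in hap:
                for s, e, lab in segs:
                    total += e - s
                    crop_bp += (e - s) * (lab == CROP)
        return crop_bp / total


@dataclass
class SimTruth:
    """Cohort-level ground truth: one :class:`LineageTruth` per lineage."""

    config: SimConfig
    lineages: list[LineageTruth] = field(default_factory=list)

    def dosage_matrix(self) -> np.ndarray:
        return np.stack([lin.dosage for lin in self.lineages])


# ---------------------------------------------------------------------------
# Ancestral panels
# ---------------------------------------------------------------------------

@dataclass
class SiteMap:
    """Site coordinates plus the allele layout shared by panels and cohort."""

    sites: pd.DataFrame          # chrom, pos (1-based), ref, alt
    is_aim: np.ndarray           # bool per site
    crop_is_alt: np.ndarray      # at AIMs: does the crop carry the alt allele
    crop_haps: np.ndarray        # (n_panel, n_sites) alt dosage 0/1 haplotypes
    weed_haps: np.ndarray        # (n_panel, n_sites) alt dosage 0/1 haplotypes
    chrom_site_index: dict[str, np.ndarray]


def _draw_positions(rng: np.random.Generator, length: int, density_per_mbp: float,
                    fixed: bool, taken: set[int]) -> np.ndarray:
    mean = density_per_mbp * length / 1e6
    n = int(round(mean)) if fixed else int(rng.poisson(mean))
    out: list[int] = []
    while len(out) < n:
        p = int(rng.integers(0, length))
        if p not in taken:
            taken.add(p)
            out.append(p)
    return np.array(sorted(out), dtype=np.int64)


def make_ancestral_panels(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix, SiteMap]:
    """Build fully inbred crop-like and weed-like ancestral panels.

    AIM sites are fixed for opposite alleles between the panels; neutral
    sites segregate within panels (individuals are homozygous everywhere, as
    in long-term selfers). Returns the two panels plus the shared site map
    used to genotype simulated hybrids.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_panel_samples
    rows = {"chrom": [], "pos": [], "ref": [], "alt": []}
    is_aim: list[bool] = []
    crop_alt_rows: list[np.ndarray] = []   # panel genotypes, alt dosage 0/2
    weed_alt_rows: list[np.ndarray] = []
    crop_is_alt: list[int] = []

    for ci, chrom in enumerate(cfg.chrom_names):
        taken: set[int] = set()
        forced: list[int] = []
        if cfg.selection_site is not None and cfg.selection_site[0] == ci:
            # guarantee an AIM exactly at the selected locus so selection
            # acts where the scenario says it does
            forced = [int(cfg.selection_site[1])]
            taken.update(forced)
        aim_pos = _draw_positions(rng, cfg.chrom_length_bp, cfg.aim_density,
                                  cfg.fixed_site_counts, taken)
        if forced:
            aim_pos = np.sort(np.concatenate([aim_pos, np.array(forced)]))
        neut_pos = _draw_positions(rng, cfg.chrom_length_bp,
                                   cfg.neutral_snp_density,
                                   cfg.fixed_site_counts, taken)
        pos = np.sort(np.concatenate([aim_pos, neut_pos]))
        aim_set = set(int(p) for p in aim_pos)
        for p in pos:
            ref_i, alt_i = rng.choice(4, size=2, replace=False)
            rows["chrom"].append(chrom)
            rows["pos"].append(int(p) + 1)
            rows["ref"].append(str(_BASES[ref_i]))
            rows["alt"].append(str(_BASES[alt_i]))
            if int(p) in aim_set:
                is_aim.append(True)
                crop_alt = int(rng.integers(2))  # orientation random per AIM
                crop_alt_rows.append(np.full(n, 2 * crop_alt, dtype=np.int8))
                weed_alt_rows.append(np.full(n, 2 * (1 - crop_alt), dtype=np.int8))
                crop_is_alt.append(crop_alt)
            else:
                is_aim.append(False)
                # within-panel polymorphism; the founder haplotype used for
                # hybridization is panel individual 0's allele
                which = rng.integers(2)  # which panel is polymorphic here
                freq = rng.uniform(0.1, 0.9)
                while True:  # condition on true within-panel polymorphism
                    draw = rng.random(n) < freq
                    if draw.any() and not draw.all():
                        break
                poly = draw.astype(np.int8) * 2
                mono = np.zeros(n, dtype=np.int8)
                if which == 0:
                    crop_alt_rows.append(poly)
                    weed_alt_rows.append(mono)
                else:
                    crop_alt_rows.append(mono)
                    weed_alt_rows.append(poly)
                crop_is_alt.append(0)

    sites = pd.DataFrame(rows)
    crop_gm = GenotypeMatrix(
        [f"crop{i + 1:02d}" for i in range(n)], sites.copy(),
        np.stack(crop_alt_rows, axis=1) if crop_alt_rows else np.zeros((n, 0), np.int8),
    )
    weed_gm = GenotypeMatrix(
        [f"weed{i + 1:02d}" for i in range(n)], sites.copy(),
        np.stack(weed_alt_rows, axis=1) if weed_alt_rows else np.zeros((n, 0), np.int8),
    )
    chrom_site_index = {
        chrom: np.flatnonzero(sites["chrom"].to_numpy() == chrom)
        for chrom in cfg.chrom_names
    }
    sitemap = SiteMap(
        sites=sites,
        is_aim=np.array(is_aim, dtype=bool),
        crop_is_alt=np.array(crop_is_alt, dtype=bool),
        crop_haps=(crop_gm.genotypes // 2).astype(np.int8),
        weed_haps=(weed_gm.genotypes // 2).astype(np.int8),
        chrom_site_index=chrom_site_index,
    )
    return crop_gm, weed_gm, sitemap


# ---------------------------------------------------------------------------
# Meiosis on breakpoint segments
# ---------------------------------------------------------------------------

def _slice_segments(segs: Segments, start: int, end: int) -> Segments:
    out: Segments = []
    for s, e, lab in segs:
        if e <= start or s >= end:
            continue
        out.append((max(s, start), min(e, end), lab))
    return out


def _merge_adjacent(segs: Segments) -> Segments:
    out: Segments = []
    for s, e, lab in segs:
        if out and out[-1][2] == lab and out[-1][1] == s:
            out[-1] = (out[-1][0], e, lab)
        else:
            out.append((s, e, lab))
    return out


def _gamete_chromosome(hap_a: Segments, hap_b: Segments, length: int,
                       rate: float, rng: np.random.Generator) -> Segments:
    """One recombinant chromosome: Poisson crossovers, uniform placement."""
    n_xo = int(rng.poisson(rate))
    cuts = np.sort(rng.integers(1, length, size=n_xo)) if n_xo else np.array([], int)
    source = int(rng.integers(2))
    bounds = [0, *[int(c) for c in cuts], length]
    out: Segments = []
    pair = (hap_a, hap_b)
    for i in range(len(bounds) - 1):
        s, e = bounds[i], bounds[i + 1]
        if s < e:
            out.extend(_slice_segments(pair[(source + i) % 2], s, e))
    return _merge_adjacent(out)


def _gamete(hap_pair: tuple[Haplotype, Haplotype], cfg: SimConfig,
            rng: np.random.Generator) -> Haplotype:
    return [
        _gamete_chromosome(hap_pair[0][c], hap_pair[1][c],
                           cfg.chrom_length_bp, cfg.recomb_rate, rng)
        for c in range(cfg.n_chromosomes)
    ]


def _dosage_from_haplotypes(haps: tuple[Haplotype, Haplotype],
                            sitemap: SiteMap, cfg: SimConfig) -> np.ndarray:
    """Crop-ancestry dosage (0/1/2) at every site."""
    n_sites = len(sitemap.sites)
    dosage = np.zeros(n_sites, dtype=np.int8)
    pos0 = sitemap.sites["pos"].to_numpy() - 1
    for hap in haps:
        for c, chrom in enumerate(cfg.chrom_names):
            idx = sitemap.chrom_site_index[chrom]
            if idx.size == 0:
                continue
            cpos = pos0[idx]
            ends = np.array([e for _, e, _ in hap[c]])
            labs = np.array([lab for _, _, lab in hap[c]])
            seg_of = np.searchsorted(ends, cpos, side="right")
            dosage[idx] += (labs[seg_of] == CROP).astype(np.int8)
    return dosage


def _ancestry_fitness(dosage: np.ndarray, sitemap: SiteMap, cfg: SimConfig,
                      sel_index: int | None) -> float:
    w = 1.0
    if sel_index is not None:
        s = cfg.selection_site[2]
        w *= (1.0 + s) ** int(dosage[sel_index])
    if cfg.background_penalty > 0:
        c = int(dosage[sitemap.is_aim].sum())
        w *= (1.0 - cfg.background_penalty) ** c
    return w


def _selection_index(sitemap: SiteMap, cfg: SimConfig) -> int | None:
    """Site index of the selected locus: the nearest AIM to the stated bp."""
    if cfg.selection_site is None:
        return None
    chrom_i, pos, _ = cfg.selection_site
    chrom = cfg.chrom_names[chrom_i]
    idx = sitemap.chrom_site_index[chrom]
    aim_idx = idx[sitemap.is_aim[idx]]
    if aim_idx.size == 0:
        raise SimulationError(f"no AIM on {chrom} to host the selected locus")
    pos0 = sitemap.sites["pos"].to_numpy()[aim_idx] - 1
    return int(aim_idx[np.argmin(np.abs(pos0 - pos))])


def simulate_lineage(
    sitemap: SiteMap,
    cfg: SimConfig,
    rng: np.random.Generator,
    crop_parent: int | None = None,
    weed_parent: int | None = None,
) -> tuple[np.ndarray, LineageTruth]:
    """Simulate one hybrid lineage: F1 then ``cfg.g`` selfing generations.

    The founding parents are panel individuals (indices drawn at random when
    not given), so independent lineages sample the ancestral populations'
    standing variation. Returns the genotype-code vector over all sites
    (0/1/2 alt dosage) and the lineage's ancestry truth. Offspring are
    accepted by relative-fitness rejection sampling when selection is
    configured.
    """
    if crop_parent is None:
        crop_parent = int(rng.integers(sitemap.crop_haps.shape[0]))
    if weed_parent is None:
        weed_parent = int(rng.integers(sitemap.weed_haps.shape[0]))
    L = cfg.chrom_length_bp
    crop_hap: Haplotype = [[(0, L, CROP)] for _ in range(cfg.n_chromosomes)]
    weed_hap: Haplotype = [[(0, L, WEED)] for _ in range(cfg.n_chromosomes)]
    haps: tuple[Haplotype, Haplotype] = (crop_hap, weed_hap)  # the F1
    sel_index = _selection_index(sitemap, cfg)
    fitness_history: list[float] = []
    selecting = sel_index is not None or cfg.background_penalty > 0

    for _ in range(cfg.g):
        if selecting:
            # tight, valid bound on offspring fitness given this parent:
            # best selected-site dosage is 2 unless the parent is fixed weed,
            # and the offspring crop-allele count cannot drop below the
            # parent's homozygous-crop AIM contribution
            parent_dosage = _dosage_from_haplotypes(haps, sitemap, cfg)
            w_max = 1.0
            if sel_index is not None:
                s = cfg.selection_site[2]
                d_best = 2 if parent_dosage[sel_index] >= 1 else 0
                w_max *= (1.0 + s) ** d_best
            if cfg.background_penalty > 0:
                c_min = int(
                    2 * (parent_dosage[sitemap.is_aim] == 2).sum()
                )
                w_max *= (1.0 - cfg.background_penalty) ** c_min
        for attempt in range(cfg.max_rejection_tries):
            child = (_gamete(haps, cfg, rng), _gamete(haps, cfg, rng))
            if not selecting:
                w = 1.0
                break
            dosage = _dosage_from_haplotypes(child, sitemap, cfg)
            w = _ancestry_fitness(dosage, sitemap, cfg, sel_index)
            if rng.random() < w / w_max:
                break
        else:
            raise SimulationError(
                f"no offspring accepted in {cfg.max_rejection_tries} tries "
                f"(selection too strong for this configuration)"
            )
        haps = child
        fitness_history.append(w)

    dosage = _dosage_from_haplotypes(haps, sitemap, cfg)
    # genotype = alt-allele dosage implied by ancestry + founder alleles
    geno = (dosage * sitemap.crop_haps[crop_parent]
            + (2 - dosage) * sitemap.weed_haps[weed_parent]).astype(np.int8)
    return geno, LineageTruth(cfg.g, haps, dosage, fitness_history)


def simulate_cohort(
    cfg: SimConfig,
    out_dir: str | Path | None = None,
) -> tuple[GenotypeMatrix, GenotypeMatrix, GenotypeMatrix, SimTruth]:
    """Simulate ``cfg.n_lineages`` independent hybrid lineages.

    Returns ``(cohort, crop_panel, weed_panel, truth)``. When ``out_dir`` is
    given, writes a combined VCF, a BED-like ancestry-truth file, a
    per-lineage truth TSV, and a panel-assignment TSV.
    """
    rng = np.random.default_rng(cfg.seed)
    crop_gm, weed_gm, sitemap = make_ancestral_panels(cfg, rng)
    truth = SimTruth(cfg)
    rows = []
    for _ in range(cfg.n_lineages):
        geno, lin = simulate_lineage(sitemap, cfg, rng)
        rows.append(geno)
        truth.lineages.append(lin)
    cohort = GenotypeMatrix(
        [f"hyb{i + 1:03d}" for i in range(cfg.n_lineages)],
        sitemap.sites.copy(),
        np.stack(rows) if rows else np.zeros((0, len(sitemap.sites)), np.int8),
    )
    if out_dir is not None:
        write_cohort_files(cohort, crop_gm, weed_gm, truth, sitemap, Path(out_dir))
    # stash the sitemap for callers that need AIM truth
    truth.sitemap = sitemap  # type: ignore[attr-defined]
    return cohort, crop_gm, weed_gm, truth


def stack_samples(matrices: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Combine matrices that share an identical site table."""
    first = matrices[0]
    for gm in matrices[1:]:
        if not first.sites[["chrom", "pos"]].equals(gm.sites[["chrom", "pos"]]):
            raise ValueError("matrices do not share a site table")
    ids = [s for gm in matrices for s in gm.sample_ids]
    geno = np.concatenate([gm.genotypes for gm in matrices], axis=0)
    return GenotypeMatrix(ids, first.sites.copy(), geno)


def write_cohort_files(cohort: GenotypeMatrix, crop_gm: GenotypeMatrix,
                       weed_gm: GenotypeMatrix, truth: SimTruth,
                       sitemap: SiteMap, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config
    combined = stack_samples([cohort, crop_gm, weed_gm])
    paths = {
        "vcf": out_dir / "cohort.vcf",
        "truth_bed": out_dir / "ancestry_truth.bed",
        "truth_tsv": out_dir / "lineage_truth.tsv",
        "panels": out_dir / "panels.tsv",
    }
    write_vcf(combined, paths["vcf"],
              {c: cfg.chrom_length_bp for c in cfg.chrom_names})
    with open(paths["truth_bed"], "w") as fh:
        for i, lin in enumerate(truth.lineages):
            sample = cohort.sample_ids[i]
            for h, hap in enumerate(lin.haplotypes):
                for c, chrom in enumerate(cfg.chrom_names):
                    for s, e, lab in hap[c]:
                        fh.write(f"{chrom}\t{s}\t{e}\t{sample}\t{h}\t{_LABELS[lab]}\n")
    with open(paths["truth_tsv"], "w") as fh:
        fh.write("sample\tg\tcrop_fraction\tmean_fitness\tseed\n")
        for i, lin in enumerate(truth.lineages):
            mean_w = (sum(lin.fitness_history) / len(lin.fitness_history)
                      if lin.fitness_history else 1.0)
            fh.write(f"{cohort.sample_ids[i]}\t{lin.g}\t"
                     f"{lin.crop_fraction(cfg.chrom_length_bp):.6f}\t"
                     f"{mean_w:.6f}\t{cfg.seed}\n")
    pa = PanelAssignment(
        {**{s: "contemporary" for s in cohort.sample_ids},
         **{s: "crop" for s in crop_gm.sample_ids},
         **{s: "weed" for s in weed_gm.sample_ids}})
    pa.write_tsv(paths["panels"])
    return paths


def expected_het_after_selfing(g: int | float) -> float:
    """Expected heterozygous fraction at fixed differences after g selfing
    generations: each generation of selfing halves heterozygosity, so 0.5**g."""
    if g < 0:
        raise ValueError("generations must be non-negative")
    return 0.5 ** g
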
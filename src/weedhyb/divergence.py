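"""Windowed population differentiation (FST) and nucleotide diversity (pi).

Site FST uses the Weir & Cockerham (1984) variance-components estimator for
two populations (r = 2) with the observed-heterozygosity correction; window
values are the ratio of sums, sum(a) / sum(a+b+c), over the window's sites —
the weighted estimator, with negative site components retained. Windows are
half-open [start, start + window) anchored at position 0 of each chromosome
and advanced by the step size; the defaults (500 kb window, 250 kb step)
match common whole-genome scan practice. Site pi is the average pairwise
difference among called haploid alleles; window pi averages over variant
sites by default (a per-base convention is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PanelAssignment, site_genotype_counts


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components (r = 2)
# ---------------------------------------------------------------------------

def wc_fst_components(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components for two populations.

    ``counts_a``/``counts_b``: ``(n_sites, 3)`` arrays of (hom-ref, het,
    hom-alt) genotype counts. Returns ``(a, b, c)``: the among-population,
    between-individual-within-population, and within-individual components.
    Site FST is ``a / (a + b + c)`` (may be negative; NaN where the
    denominator is 0 or a population has < 2 called genotypes).
    """
    counts_a = np.atleast_2d(counts_a).astype(float)
    counts_b = np.atleast_2d(counts_b).astype(float)
    r = 2.0
    n1 = counts_a.sum(axis=1)
    n2 = counts_b.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = (counts_a[:, 1] / 2 + counts_a[:, 2]) / n1
        p2 = (counts_b[:, 1] / 2 + counts_b[:, 2]) / n2
        h1 = counts_a[:, 1] / n1
        h2 = counts_b[:, 1] / n2
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - s2 * (r - 1) / r
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2
    bad = (n1 < 2) | (n2 < 2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def site_fst(counts_a: np.ndarray, counts_b: np.ndarray) -> np.ndarray:
    a, b, c = wc_fst_components(counts_a, counts_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        return np.where(denom != 0, a / denom, np.nan)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    window_bp: int = 500_000
    step_bp: int = 250_000

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise ValueError("window and step must be positive")


def _window_starts(extent: int, spec: WindowSpec) -> np.ndarray:
    n = max(1, int(np.ceil(max(extent - spec.window_bp, 0) / spec.step_bp)) + 1)
    return np.arange(n) * spec.step_bp


def _chrom_extents(
    gm: GenotypeMatrix, chrom_lengths: Mapping[str, int] | None
) -> dict[str, int]:
    out: dict[str, int] = {}
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        out[str(chrom)] = (chrom_lengths or {}).get(
            str(chrom), int(grp["pos"].max())
        )
    return out


def _group_counts(gm: GenotypeMatrix, panel: PanelAssignment, label: str) -> np.ndarray:
    samples = panel.samples(label)
    if len(samples) < 2:
        raise ValueError(f"population {label!r} needs >=2 samples")
    return site_genotype_counts(gm.take_samples(samples))


def _windowed(
    gm: GenotypeMatrix,
    site_num: np.ndarray,
    site_den: np.ndarray,
    spec: WindowSpec,
    statistic: str,
    chrom_lengths: Mapping[str, int] | None,
    mean_of_sites: bool,
) -> pd.DataFrame:
    """Aggregate per-site numerator/denominator into sliding windows.

    ``mean_of_sites``: value = mean of per-site ratios (used for pi);
    otherwise value = sum(num)/sum(den) (ratio-of-sums, used for FST).
    """
    rows = []
    pos0 = gm.sites["pos"].to_numpy() - 1
    chroms = gm.sites["chrom"].to_numpy()
    for chrom, extent in _chrom_extents(gm, chrom_lengths).items():
        on_chrom = chroms == chrom
        cpos = pos0[on_chrom]
        num = site_num[on_chrom]
        den = site_den[on_chrom]
        ok = ~np.isnan(num) & ~np.isnan(den)
        for start in _window_starts(extent, spec):
            end = start + spec.window_bp
            in_w = (cpos >= start) & (cpos < end) & ok
            n_sites = int(in_w.sum())
            if n_sites == 0:
                value = np.nan
            elif mean_of_sites:
                with np.errstate(invalid="ignore", divide="ignore"):
                    value = float(np.nanmean(num[in_w] / den[in_w]))
            else:
                d = float(den[in_w].sum())
                value = float(num[in_w].sum() / d) if d != 0 else np.nan
            rows.append((chrom, int(start), int(end), n_sites, statistic, value))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "statistic", "value"]
    )


def fst_windows(
    gm: GenotypeMatrix,
    panel: PanelAssignment,
    pop_a: str,
    pop_b: str,
    window_bp: int = 500_000,
    step_bp: int = 250_000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window Weir-Cockerham FST between two labelled populations.

    Window value is sum(a)/sum(a+b+c) over the window's usable sites; empty
    windows are NaN. Returns a tidy WindowStat table (chrom, start, end,
    n_sites, statistic, value) with half-open 0-based window bounds.
    """
    spec = WindowSpec(window_bp, step_bp)
    ca = _group_counts(gm, panel, pop_a)
    cb = _group_counts(gm, panel, pop_b)
    a, b, c = wc_fst_components(ca, cb)
    return _windowed(gm, a, a + b + c, spec, "fst", chrom_lengths, False)


def site_pi(counts: np.ndarray) -> np.ndarray:
    """Average pairwise difference among called haploid alleles at each site.

    For j alt alleles among n called alleles: pi = 2 j (n - j) / (n (n - 1)).
    Sites with fewer than 2 called genotypes are NaN.
    """
    counts = np.atleast_2d(counts).astype(float)
    n_geno = counts.sum(axis=1)
    n = 2 * n_geno
    j = counts[:, 1] + 2 * counts[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2 * j * (n - j) / (n * (n - 1))
    pi[n_geno < 2] = np.nan
    return pi


def pi_windows(
    gm: GenotypeMatrix,
    panel: PanelAssignment,
    population: str,
    window_bp: int = 500_000,
    step_bp: int = 250_000,
    chrom_lengths: Mapping[str, int] | None = None,
    per_base: bool = False,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity for one population.

    Default convention: window value = mean of site pi over variant sites in
    the window. With ``per_base``, value = sum of site pi / window length
    (treating unrepresented bases as monomorphic).
    """
    spec = WindowSpec(window_bp, step_bp)
    counts = _group_counts(gm, panel, population)
    pi = site_pi(counts)
    if per_base:
        table = _windowed(gm, pi, np.ones_like(pi), spec, "pi", chrom_lengths, False)
        table["value"] = table["value"] * table["n_sites"] / window_bp
        table.loc[table["n_sites"] == 0, "value"] = 0.0
        return table
    return _windowed(gm, pi, np.ones_like(pi), spec, "pi", chrom_lengths, True)


# ---------------------------------------------------------------------------
# Dual comparison at focal genes
# ---------------------------------------------------------------------------

def _percentile_rank(values: np.ndarray, x: float) -> float:
    ok = values[~np.isnan(values)]
    if ok.size == 0 or np.isnan(x):
        return float("nan")
    return float((ok <= x).mean())


def dual_comparison(
    gm: GenotypeMatrix,
    panel: PanelAssignment,
    weed_group: str,
    crop_ancestor: str,
    weed_ancestor: str,
    window_bp: int = 500_000,
    step_bp: int = 250_000,
    focal_regions: Sequence[tuple[str, int, int, str]] = (),
    chrom_lengths: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aligned weed-vs-crop-ancestor and weed-vs-weed-ancestor FST scans.

    At a locus where a crop allele swept into the weed group, the
    weed-vs-crop series dips (the weeds look crop-like) while the
    weed-vs-weed-ancestor series peaks — the signature of adaptive
    introgression.

    ``focal_regions``: (chrom, start, end, name) half-open 0-based intervals.
    Returns ``(windows, focal)``: the paired window table with columns
    ``fst_vs_crop`` / ``fst_vs_weed``, and one row per focal region with the
    containing window's values and their genome-wide percentile ranks.
    """
    crop_tab = fst_windows(gm, panel, weed_group, crop_ancestor,
                           window_bp, step_bp, chrom_lengths)
    weed_tab = fst_windows(gm, panel, weed_group, weed_ancestor,
                           window_bp, step_bp, chrom_lengths)
    paired = crop_tab.drop(columns=["statistic"]).rename(
        columns={"value": "fst_vs_crop", "n_sites": "n_sites_crop"}
    )
    paired["fst_vs_weed"] = weed_tab["value"].to_numpy()
    paired["n_sites_weed"] = weed_tab["n_sites"].to_numpy()

    crop_vals = paired["fst_vs_crop"].to_numpy()
    weed_vals = paired["fst_vs_weed"].to_numpy()
    focal_rows = []
    for chrom, start, end, name in focal_regions:
        on = paired["chrom"] == chrom
        if not on.any():
            raise KeyError(f"focal region {name!r}: chromosome {chrom!r} not covered")
        mid = (start + end) // 2
        contains = on & (paired["start"] <= mid) & (mid < paired["end"])
        if not contains.any():
            raise KeyError(f"focal region {name!r} outside windowed extent")
        # among co-containing (overlapping) windows keep the best-covered one
        cand = paired[contains]
        row = cand.iloc[int(np.argmax(cand["n_sites_crop"].to_numpy()))]
        focal_rows.append(
            {
                "name": name,
                "chrom": chrom,
                "window_start": int(row["start"]),
                "window_end": int(row["end"]),
                "fst_vs_crop": row["fst_vs_crop"],
                "fst_vs_weed": row["fst_vs_weed"],
                "crop_percentile": _percentile_rank(crop_vals, row["fst_vs_crop"]),
                "weed_percentile": _percentile_rank(weed_vals, row["fst_vs_weed"]),
            }
        )
    return paired, pd.DataFrame(focal_rows)
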
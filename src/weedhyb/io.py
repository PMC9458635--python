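"""Genotype containers, VCF input/output, and variant-level filters.

The central container is :class:`GenotypeMatrix`, a samples x sites matrix of
diploid genotype codes (0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternate, -1 = missing) with per-site chromosome/position/
allele metadata. Genotypes are unphased on input; phase only ever enters via
the haplotype-network phasing rule or the simulator's truth tracks.

Coordinates follow the VCF convention (1-based positions) at the file
boundary; interval arguments inside the library are half-open 0-based.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


class EmptyInputError(ValueError):
    """Raised when an operation receives no usable samples or sites."""


class UndefinedInputError(ValueError):
    """Raised when a statistic is undefined for the given input."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic-SNP genotypes for a set of samples.

    Parameters
    ----------
    sample_ids
        Ordered sample identifiers.
    sites
        DataFrame with columns ``chrom``, ``pos`` (1-based bp), ``ref``,
        ``alt``; positions strictly increasing within each chromosome.
    genotypes
        ``(n_samples, n_sites)`` int8 array of genotype codes.
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} != "
                f"({len(self.sample_ids)}, {len(self.sites)})"
            )
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        """Subset sites by boolean mask or integer index, preserving order."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.sample_ids),
            self.sites.iloc[idx],
            self.genotypes[:, idx],
        )

    def take_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(sample_ids)
        rows = [self.sample_index(s) for s in ids]
        return GenotypeMatrix(ids, self.sites.copy(), self.genotypes[rows, :])

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of sites in half-open 0-based interval [start, end)."""
        pos0 = self.sites["pos"].to_numpy() - 1
        return (
            (self.sites["chrom"].to_numpy() == chrom)
            & (pos0 >= start)
            & (pos0 < end)
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele count) over all samples."""
        g = self.genotypes
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)


@dataclass
class PanelAssignment:
    """Mapping of sample ids to disjoint panel/population labels."""

    assignments: dict[str, str] = field(default_factory=dict)

    def samples(self, panel: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == panel]

    def panels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    def validate_against(self, gm: GenotypeMatrix) -> None:
        known = set(gm.sample_ids)
        missing = [s for s in self.assignments if s not in known]
        if missing:
            raise KeyError(f"panel samples absent from matrix: {missing[:5]}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PanelAssignment":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "panel"],
                         dtype=str, comment="#")
        return cls(dict(zip(df["sample_id"], df["panel"])))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, p in self.assignments.items():
                fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

_ACGT = frozenset("ACGT")


def _is_snp(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in _ACGT and alt in _ACGT


def read_vcf(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
    drop_indels: bool = True,
    skip_multiallelic: bool = True,
) -> GenotypeMatrix:
    """Read GT fields of a VCF into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    region
        Optional ``(chrom, start, end)`` half-open 0-based interval; only
        sites inside are returned.
    drop_indels
        Skip records whose ref or alt allele is not a single nucleotide.
    skip_multiallelic
        Skip records with more than one alt allele (they are not split).
    """
    import cyvcf2

    try:
        vcf = cyvcf2.VCF(str(path))
    except OSError as exc:  # pragma: no cover - cyvcf2 error path
        raise IOError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise EmptyInputError(f"VCF {path} contains no samples")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    geno_rows: list[np.ndarray] = []
    for rec in vcf:
        alt_alleles = rec.ALT
        if skip_multiallelic and len(alt_alleles) > 1:
            continue
        if not alt_alleles:
            continue
        ref, alt = rec.REF, alt_alleles[0]
        if drop_indels and not _is_snp(ref, alt):
            continue
        if region is not None:
            chrom, start, end = region
            if rec.CHROM != chrom or not (start <= rec.POS - 1 < end):
                continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.copy()
        codes = np.full(gt.shape, MISSING, dtype=np.int8)
        codes[gt == 0] = HOM_REF
        codes[gt == 1] = HET
        codes[gt == 3] = HOM_ALT
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(ref)
        alts.append(alt)
        geno_rows.append(codes)
    vcf.close()

    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    if geno_rows:
        genotypes = np.stack(geno_rows, axis=1)
    else:
        genotypes = np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(samples, sites, genotypes)


_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal unphased VCF 4.2 with GT-only genotype fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        chrom_arr = gm.sites["chrom"].to_numpy()
        pos_arr = gm.sites["pos"].to_numpy()
        ref_arr = gm.sites["ref"].to_numpy()
        alt_arr = gm.sites["alt"].to_numpy()
        for j in range(gm.n_sites):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.genotypes[:, j])
            fh.write(
                f"{chrom_arr[j]}\t{pos_arr[j]}\t.\t{ref_arr[j]}\t{alt_arr[j]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _log_het_probabilities(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of each attainable heterozygote count.

    Conditional on ``n`` diploids carrying ``n_a`` copies of allele A, the
    probability of observing ``h`` heterozygotes (h same parity as n_a,
    0 <= h <= min(n_a, 2n - n_a)) is

        P(h) = n! / (n_AA! h! n_aa!) * 2^h * n_a! n_b! / (2n)!

    with n_AA = (n_a - h)/2 and n_aa = n - n_AA - h.
    """
    n_b = 2 * n - n_a
    h_max = min(n_a, n_b)
    hs = np.arange(n_a % 2, h_max + 1, 2)
    lg = math.lgamma
    const = lg(n + 1) + lg(n_a + 1) + lg(n_b + 1) - lg(2 * n + 1)
    logp = np.array(
        [
            const
            + h * math.log(2)
            - lg((n_a - h) // 2 + 1)
            - lg(h + 1)
            - lg(n - (n_a - h) // 2 - h + 1)
            for h in hs
        ]
    )
    return hs, logp


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact conditional two-sided Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts attainable given the observed allele
    totals, the probabilities that do not exceed the observed configuration's
    probability (the plain, not mid-, p convention used by standard variant
    filters). Returns a value in (0, 1].
    """
    for c in (n_aa_hom, n_het, n_bb_hom):
        if c < 0:
            raise UndefinedInputError("negative genotype count")
    n = n_aa_hom + n_het + n_bb_hom
    if n == 0:
        raise UndefinedInputError("all genotype counts are zero")
    n_a = 2 * n_aa_hom + n_het
    if n_a == 0 or n_a == 2 * n:
        return 1.0  # monomorphic: single attainable configuration
    hs, logp = _log_het_probabilities(n, n_a)
    obs = logp[np.searchsorted(hs, n_het)]
    # relative tolerance absorbs round-off when comparing equal masses
    p = float(np.exp(logp[logp <= obs + 1e-10]).sum())
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# Variant filters and per-sample heterozygosity
# ---------------------------------------------------------------------------

def site_genotype_counts(gm: GenotypeMatrix) -> np.ndarray:
    """Per-site (n_hom_ref, n_het, n_hom_alt) counts over called genotypes."""
    g = gm.genotypes
    return np.stack(
        [(g == HOM_REF).sum(axis=0), (g == HET).sum(axis=0),
         (g == HOM_ALT).sum(axis=0)],
        axis=1,
    )


def filter_variants(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-7,
    drop_indels: bool = True,
    min_call_rate: float = 0.5,
) -> GenotypeMatrix:
    """Apply minor-allele-frequency, HWE, indel and call-rate filters.

    Keeps sites with MAF >= ``maf_min`` (computed over called genotypes
    only), HWE exact p >= ``hwe_p_min``, call rate >= ``min_call_rate``, and
    (optionally) single-nucleotide ref/alt alleles. Site order is preserved.
    """
    if gm.n_sites == 0 or gm.n_samples == 0:
        raise EmptyInputError("empty genotype matrix")
    counts = site_genotype_counts(gm)
    n_called = counts.sum(axis=1)
    keep = n_called >= max(1, math.ceil(min_call_rate * gm.n_samples))
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n_called)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep &= np.where(n_called > 0, maf >= maf_min - 1e-12, False)
    if drop_indels:
        snp = np.array(
            [_is_snp(r, a) for r, a in zip(gm.sites["ref"], gm.sites["alt"])]
        )
        keep &= snp
    for j in np.flatnonzero(keep):
        if hwe_exact_test(*counts[j]) < hwe_p_min:
            keep[j] = False
    if not keep.any():
        warnings.warn("all sites removed by variant filters", stacklevel=2)
    return gm.take_sites(keep)


def het_fraction(gm: GenotypeMatrix, sample: str) -> float:
    """Fraction of called sites at which ``sample`` is heterozygous.

    Computed as (n_called - n_homozygous) / n_called, over non-missing
    genotypes only; missing sites are excluded from the denominator.
    """
    g = gm.genotypes[gm.sample_index(sample)]
    called = g >= 0
    n_called = int(called.sum())
    if n_called == 0:
        raise UndefinedInputError(f"sample {sample!r} has no called genotypes")
    n_hom = int(((g == HOM_REF) | (g == HOM_ALT)).sum())
    return (n_called - n_hom) / n_called
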
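"""Ancestry-informative markers (AIMs) and heterozygosity-decay dating.

An AIM is a site at which two ancestral panels are (near-)fixed for opposite
alleles, so the genotype of an admixed descendant directly reads out local
ancestry: heterozygotes carry one chromosome from each ancestor. In a
strictly selfing lineage the expected heterozygous fraction at AIMs halves
every generation, so the number of generations since hybridization can be
estimated as ``g_hat = -log2(observed het fraction)``.

Also here: supervised ancestry coefficients (allele-count proportions over
AIMs, a desk-scale analogue of a supervised admixture fit) and the
threshold rules used to classify admixed accessions from a membership (Q)
matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import HET, MISSING, GenotypeMatrix, UndefinedInputError


@dataclass
class AIMSet:
    """Sites fixed (or near-fixed) for opposite alleles between two panels.

    ``table`` columns: chrom, pos (1-based), allele_a, allele_b (nucleotides
    carried by ancestors A and B), a_is_alt (does ancestor A carry the site's
    alt allele). Provenance records panel sizes and thresholds used.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        if len(self.table):
            if (self.table["allele_a"] == self.table["allele_b"]).any():
                raise ValueError("AIM with identical ancestor alleles")

    def __len__(self) -> int:
        return len(self.table)

    def indices_in(
        self, gm: GenotypeMatrix
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Match AIMs to matrix site indices.

        Returns ``(site_idx, a_is_alt, matched_mask)``: the matrix site
        index and orientation of each AIM found in ``gm`` (matched on
        chrom/pos), plus the boolean mask of AIM-table rows that matched.
        """
        key = pd.MultiIndex.from_frame(gm.sites[["chrom", "pos"]])
        want = pd.MultiIndex.from_frame(self.table[["chrom", "pos"]])
        locs = key.get_indexer(want)
        hit = locs >= 0
        return locs[hit], self.table["a_is_alt"].to_numpy()[hit], hit

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AIMSet":
        return cls(pd.read_csv(path, sep="\t",
                               dtype={"chrom": str, "pos": int,
                                      "allele_a": str, "allele_b": str,
                                      "a_is_alt": bool}))


def _panel_alt_freq(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    alt, called = gm.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, alt / np.maximum(called, 1), np.nan)
    return freq, called / (2 * gm.n_samples)


def identify_aims(
    panel_a: GenotypeMatrix,
    panel_b: GenotypeMatrix,
    min_call_rate: float = 0.8,
    min_freq_diff: float = 1.0,
) -> AIMSet:
    """Find sites whose allele frequencies differ by >= ``min_freq_diff``.

    With the default ``min_freq_diff=1.0`` this is the strict fixed-difference
    definition. With a relaxed threshold, each ancestor's diagnostic allele is
    its majority allele at the site. Both panels must meet ``min_call_rate``.
    """
    if not panel_a.sites[["chrom", "pos"]].equals(panel_b.sites[["chrom", "pos"]]):
        raise ValueError("panels must share a site table")
    if panel_a.n_samples < 2 or panel_b.n_samples < 2:
        raise ValueError("each panel needs >=2 samples")
    fa, ca = _panel_alt_freq(panel_a)
    fb, cb = _panel_alt_freq(panel_b)
    with np.errstate(invalid="ignore"):
        keep = (
            (ca >= min_call_rate)
            & (cb >= min_call_rate)
            & (np.abs(fa - fb) >= min_freq_diff - 1e-12)
        )
    keep &= ~np.isnan(fa) & ~np.isnan(fb)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        import warnings

        warnings.warn("no ancestry-informative sites found", stacklevel=2)
    sites = panel_a.sites.iloc[idx]
    a_is_alt = fa[idx] > fb[idx]  # A's majority allele is alt iff fa > fb
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()
    table = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "allele_a": np.where(a_is_alt, alt, ref),
            "allele_b": np.where(a_is_alt, ref, alt),
            "a_is_alt": a_is_alt,
        }
    )
    return AIMSet(
        table,
        provenance={
            "panel_a_n": panel_a.n_samples,
            "panel_b_n": panel_b.n_samples,
            "min_call_rate": min_call_rate,
            "min_freq_diff": min_freq_diff,
        },
    )


def _aim_dosage(gm: GenotypeMatrix, sample: str, aims: AIMSet) -> np.ndarray:
    """Ancestor-A allele dosage (0/1/2, -1 missing) at each matched AIM."""
    idx, a_is_alt, _ = aims.indices_in(gm)
    g = gm.genotypes[gm.sample_index(sample), idx].astype(np.int8)
    dosage = np.where(a_is_alt, g, 2 - g)
    dosage[g == MISSING] = MISSING
    return dosage


def supervised_ancestry(
    gm: GenotypeMatrix, sample: str, aims: AIMSet,
    labels: tuple[str, str] = ("A", "B"),
) -> dict[str, float]:
    """Ancestry proportions from AIM allele counts.

    The coefficient for ancestor A is the fraction of A alleles among the
    sample's called AIM alleles; B is its complement. A supervised, model-free
    analogue of a two-population admixture membership coefficient.
    """
    dosage = _aim_dosage(gm, sample, aims)
    called = dosage >= 0
    n = int(called.sum())
    if n == 0:
        raise UndefinedInputError(f"sample {sample!r} has no called AIMs")
    prop_a = float(dosage[called].sum()) / (2 * n)
    return {labels[0]: prop_a, labels[1]: 1.0 - prop_a}


def aim_heterozygosity(
    gm: GenotypeMatrix, sample: str, aims: AIMSet
) -> tuple[int, int, float]:
    """(n_het, n_called, het fraction) of ``sample`` over AIM sites only."""
    idx, _, _ = aims.indices_in(gm)
    g = gm.genotypes[gm.sample_index(sample), idx]
    called = g != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise UndefinedInputError(f"sample {sample!r} has no called AIMs")
    n_het = int((g == HET).sum())
    return n_het, n_called, n_het / n_called


@dataclass(frozen=True)
class GenerationEstimate:
    """Generations since hybridization from AIM heterozygosity decay."""

    g_hat: float
    ci: tuple[float, float]
    lower_bound_only: bool = False


def estimate_generations(
    het_fraction: float,
    n_called: int,
    n_het: int | None = None,
    alpha: float = 0.05,
) -> GenerationEstimate:
    """Estimate selfing generations since hybridization.

    Under strict selfing the expected AIM het fraction after g generations is
    0.5**g, so ``g_hat = -log2(het_fraction)``. The confidence interval is a
    Clopper-Pearson (exact binomial) interval on the het proportion mapped
    through -log2; its exact coverage matters at the small AIM counts
    typical of reduced marker panels.

    When ``het_fraction`` is 0 no point estimate exists; an open lower bound
    ``g >= -log2(1/n_called)`` is returned with ``lower_bound_only`` set.
    """
    if not (0.0 <= het_fraction <= 1.0):
        raise ValueError("het_fraction must lie in [0, 1]")
    if n_called <= 0:
        raise ValueError("n_called must be positive")
    if n_het is None:
        n_het = int(round(het_fraction * n_called))
    if het_fraction == 0.0:
        bound = -math.log2(1.0 / n_called)
        return GenerationEstimate(math.inf, (bound, math.inf), True)
    g_hat = -math.log2(het_fraction)
    lo_p, hi_p = _clopper_pearson(n_het, n_called, alpha)
    g_hi = -math.log2(lo_p) if lo_p > 0 else math.inf
    g_lo = -math.log2(hi_p)
    return GenerationEstimate(g_hat, (max(g_lo, 0.0), g_hi), False)


def _clopper_pearson(k: int, n: int, alpha: float) -> tuple[float, float]:
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Q-matrix handling and accession classification
# ---------------------------------------------------------------------------

DEFAULT_POPULATIONS = ("TRJ", "TMJ", "ARO", "IND", "AUS", "SH", "BHA", "BETA")


def read_q_matrix(
    q_path: str | Path,
    sample_order_path: str | Path,
    populations: Sequence[str],
) -> pd.DataFrame:
    """Read a whitespace-delimited membership (Q) matrix.

    ``sample_order_path`` lists one sample id per line in Q-row order;
    ``populations`` names the K columns.
    """
    q = pd.read_csv(q_path, sep=r"\s+", header=None)
    samples = [ln.strip() for ln in open(sample_order_path) if ln.strip()]
    if len(q) != len(samples):
        raise ValueError(
            f"Q matrix has {len(q)} rows but {len(samples)} sample ids"
        )
    if q.shape[1] != len(populations):
        raise ValueError(
            f"Q matrix has {q.shape[1]} columns but {len(populations)} labels"
        )
    q.columns = list(populations)
    q.index = samples
    return q


@dataclass(frozen=True)
class ClassifyThresholds:
    """Thresholds of the accession classification rules.

    ``admixed_min``: membership needed in >=2 populations to flag a sample
    as admixed. ``like_min``: weed-ancestry floor for the SH-like/BHA-like
    calls. ``other_weed_max``: maximum membership from the *other* historic
    weed group tolerated by a -like call ("without contribution" floor).
    ``complex_min``: floor on SH, BHA and TRJ jointly for the complex call.
    ``purity_tol``: 1 - this is the membership needed to call a sample
    non-admixed (indistinguishable from a historic weed group).
    """

    admixed_min: float = 0.15
    like_min: float = 0.10
    other_weed_max: float = 0.05
    complex_min: float = 0.20
    purity_tol: float = 0.05


@dataclass(frozen=True)
class AccessionCall:
    category: str
    admixed: bool


CATEGORIES = ("non-admixed-SH", "non-admixed-BHA", "complex", "beta",
              "SH-like", "BHA-like", "admixed")


def classify_accession(
    q_row: Mapping[str, float],
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> AccessionCall:
    """Classify one accession from its membership coefficients.

    Rules, in precedence order: non-admixed (>= 1 - purity_tol membership in
    one historic weed group); complex (SH, BHA and TRJ all above
    ``complex_min``); beta (BETA is the majority population); SH-like /
    BHA-like (one weed group above ``like_min`` with at most
    ``other_weed_max`` from the other); otherwise the residual label
    "admixed". The admixed flag (>= 2 populations above ``admixed_min``) is
    reported independently of the category.
    """
    for pop in ("SH", "BHA", "TRJ"):
        if pop not in q_row:
            raise KeyError(f"Q row lacks required population {pop!r}")
    t = thresholds
    get = lambda p: float(q_row.get(p, 0.0))
    admixed = sum(v > t.admixed_min for v in q_row.values()) >= 2
    sh, bha, trj, beta = get("SH"), get("BHA"), get("TRJ"), get("BETA")

    if sh >= 1.0 - t.purity_tol:
        return AccessionCall("non-admixed-SH", admixed)
    if bha >= 1.0 - t.purity_tol:
        return AccessionCall("non-admixed-BHA", admixed)
    if sh > t.complex_min and bha > t.complex_min and trj > t.complex_min:
        return AccessionCall("complex", admixed)
    if q_row and beta == max(q_row.values()) and beta > 0:
        return AccessionCall("beta", admixed)
    if sh > t.like_min and bha <= t.other_weed_max:
        return AccessionCall("SH-like", admixed)
    if bha > t.like_min and sh <= t.other_weed_max:
        return AccessionCall("BHA-like", admixed)
    return AccessionCall("admixed", admixed)


def classify_all(
    q: pd.DataFrame, thresholds: ClassifyThresholds = ClassifyThresholds()
) -> pd.DataFrame:
    """Classify every row of a Q matrix; returns sample, category, admixed."""
    calls = [classify_accession(row.to_dict(), thresholds)
             for _, row in q.iterrows()]
    return pd.DataFrame(
        {"sample": q.index,
         "category": [c.category for c in calls],
         "admixed": [c.admixed for c in calls]}
    ).reset_index(drop=True)
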
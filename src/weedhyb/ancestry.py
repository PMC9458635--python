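"""Local-ancestry inference along chromosomes and weed-genome bias tables.

A three-state hidden Markov model over AIM sites infers the crop-ancestry
dosage (0, 1 or 2 crop haplotypes) of a diploid admixed sample at every
marker. States follow two independent per-haplotype ancestry chains whose
switch probability between adjacent AIMs grows with physical distance
(``q = (1 - exp(-rho * d)) / 2`` per haplotype, so single and double
switches both occur with the expected relative weight); genotypes are
emitted with a per-allele error rate ``epsilon``. The decoded
maximum-a-posteriori path is merged into segments whose ends snap to
midpoints between adjacent AIMs — breakpoints are never placed more
precisely than the marker spacing supports.

From a collection of tracks, :func:`genome_bias` builds the per-chromosome
weed-ancestry proportion table (with genome-wide average row), and
:func:`focal_block` summarises ancestry in a focal gene region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .aims import AIMSet, _aim_dosage


class InsufficientMarkerError(ValueError):
    """Raised when no chromosome carries enough AIMs to decode."""


@dataclass
class ChromosomeTrack:
    """Decoded ancestry for one sample on one chromosome."""

    positions: np.ndarray          # AIM positions, 0-based bp
    posterior: np.ndarray          # (n_aims, 3) state posteriors
    map_dosage: np.ndarray         # MAP crop dosage per AIM
    segments: list[tuple[int, int, int]]          # (start, end, dosage)
    hap_segments: tuple[list, list]               # per-haplotype (start,end,label)


@dataclass
class AncestryTrack:
    """Per-chromosome decoded ancestry for one diploid sample."""

    sample_id: str
    chromosomes: dict[str, ChromosomeTrack] = field(default_factory=dict)

    def aim_calls(self, chrom: str) -> tuple[int, int]:
        """(weed haplotype calls, total haplotype calls) on one chromosome."""
        tr = self.chromosomes[chrom]
        total = 2 * len(tr.map_dosage)
        weed = int((2 - tr.map_dosage).sum())
        return weed, total


def _transition_matrix(q: float) -> np.ndarray:
    """Dosage-state transition matrix for two independent haplotype chains,
    each switching ancestry with probability q."""
    p = 1.0 - q
    return np.array(
        [
            [p * p, 2 * p * q, q * q],
            [p * q, p * p + q * q, p * q],
            [q * q, 2 * p * q, p * p],
        ]
    )


def _emission_matrix(eps: float) -> np.ndarray:
    """P(observed crop-allele dosage | true dosage state), per-allele error."""
    e, c = eps, 1.0 - eps
    return np.array(
        [
            [c * c, 2 * c * e, e * e],
            [e * c, c * c + e * e, c * e],
            [e * e, 2 * c * e, c * c],
        ]
    )


def _decode_chromosome(
    obs: np.ndarray, positions: np.ndarray, eps: float, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior matrix and Viterbi MAP path for one chromosome.

    ``obs`` is the observed crop-allele dosage at each AIM (-1 = missing).
    """
    n = len(obs)
    emit = _emission_matrix(eps)
    log_emit = np.full((n, 3), 0.0)
    called = obs >= 0
    log_emit[called] = np.log(emit[:, obs[called]].T)
    d = np.diff(positions).astype(float)
    qs = 0.5 * (1.0 - np.exp(-rho * d))
    log_trans = np.log(np.stack([_transition_matrix(q) for q in qs]))
    log_pi = np.log(np.full(3, 1.0 / 3.0))

    # forward-backward (log domain)
    fwd = np.zeros((n, 3))
    fwd[0] = log_pi + log_emit[0]
    for t in range(1, n):
        fwd[t] = log_emit[t] + _logsumexp_cols(fwd[t - 1][:, None] + log_trans[t - 1])
    bwd = np.zeros((n, 3))
    for t in range(n - 2, -1, -1):
        bwd[t] = _logsumexp_cols(
            (log_trans[t] + log_emit[t + 1][None, :] + bwd[t + 1][None, :]).T
        )
    post = fwd + bwd
    post -= post.max(axis=1, keepdims=True)
    post = np.exp(post)
    post /= post.sum(axis=1, keepdims=True)

    # Viterbi
    vit = np.zeros((n, 3))
    back = np.zeros((n, 3), dtype=np.int8)
    vit[0] = log_pi + log_emit[0]
    for t in range(1, n):
        scores = vit[t - 1][:, None] + log_trans[t - 1]
        back[t] = scores.argmax(axis=0)
        vit[t] = log_emit[t] + scores.max(axis=0)
    path = np.zeros(n, dtype=np.int8)
    path[-1] = int(vit[-1].argmax())
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return post, path


def _logsumexp_cols(m: np.ndarray) -> np.ndarray:
    mx = m.max(axis=0)
    return mx + np.log(np.exp(m - mx[None, :]).sum(axis=0))


def _path_to_segments(
    path: np.ndarray, positions: np.ndarray, chrom_length: int
) -> list[tuple[int, int, int]]:
    """Merge equal-dosage runs; boundaries at inter-AIM midpoints."""
    segs: list[tuple[int, int, int]] = []
    start = 0
    for i in range(1, len(path)):
        if path[i] != path[i - 1]:
            mid = int((positions[i - 1] + positions[i]) // 2)
            segs.append((start, mid, int(path[i - 1])))
            start = mid
    segs.append((start, chrom_length, int(path[-1])))
    return segs


CROP_LABEL, WEED_LABEL = "crop", "weed"


def _hap_segments(segments: list[tuple[int, int, int]]) -> tuple[list, list]:
    """Split dosage segments into two haplotype tracks.

    Dosage 2 -> both crop; 0 -> both weed; 1 -> haplotype 0 carries the crop
    segment (the within-pair assignment is unidentifiable from unphased
    genotypes; the convention is deterministic).
    """
    hap0, hap1 = [], []
    for s, e, d in segments:
        hap0.append((s, e, CROP_LABEL if d >= 1 else WEED_LABEL))
        hap1.append((s, e, CROP_LABEL if d == 2 else WEED_LABEL))
    return hap0, hap1


def infer_tracks(
    gm: GenotypeMatrix,
    sample: str,
    aims: AIMSet,
    eps: float = 0.01,
    rho: float = 1e-7,
    chrom_lengths: Mapping[str, int] | None = None,
) -> AncestryTrack:
    """Decode crop/weed local ancestry for one sample over its AIM genotypes.

    Parameters
    ----------
    eps
        Per-allele genotype error rate of the emission model.
    rho
        Ancestry switch rate per bp (roughly crossovers x generations per
        bp); controls how fast ancestry may change between adjacent AIMs.
    chrom_lengths
        Chromosome lengths for segment tiling; defaults to the last AIM
        position + 1 on each chromosome.

    Here "crop" is ancestor A of the AIM set and "weed" ancestor B.
    """
    idx, _, matched = aims.indices_in(gm)
    if idx.size == 0:
        raise InsufficientMarkerError("no AIMs present in the matrix")
    dosage = _aim_dosage(gm, sample, aims)
    chroms = aims.table["chrom"].to_numpy()[matched]
    pos0 = aims.table["pos"].to_numpy()[matched] - 1
    track = AncestryTrack(sample)
    any_decoded = False
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        obs = dosage[sel].astype(np.int64)
        positions = pos0[sel]
        if (obs >= 0).sum() < 2:
            continue
        post, path = _decode_chromosome(obs, positions, eps, rho)
        length = (chrom_lengths or {}).get(chrom, int(positions[-1]) + 1)
        segs = _path_to_segments(path, positions, length)
        track.chromosomes[str(chrom)] = ChromosomeTrack(
            positions=positions,
            posterior=post,
            map_dosage=path.astype(np.int8),
            segments=segs,
            hap_segments=_hap_segments(segs),
        )
        any_decoded = True
    if not any_decoded:
        raise InsufficientMarkerError(
            f"sample {sample!r}: fewer than 2 called AIMs on every chromosome"
        )
    return track


# ---------------------------------------------------------------------------
# Weed-genome bias table
# ---------------------------------------------------------------------------

def genome_bias(
    tracks: Iterable[AncestryTrack],
    groups: Mapping[str, str],
    site_weighted_average: bool = False,
) -> pd.DataFrame:
    """Per-chromosome weed-ancestry proportions by sample group.

    Rows are chromosomes plus a final ``Average`` row; columns are groups.
    A cell is the proportion of haplotype ancestry calls (2 per sample per
    AIM) assigned to the weedy ancestor, pooled over the group's samples.
    The Average row is the unweighted mean of the chromosome rows by
    default, or the pooled (AIM-count-weighted) proportion when
    ``site_weighted_average`` is set.
    """
    import warnings

    weed: dict[tuple[str, str], int] = {}
    total: dict[tuple[str, str], int] = {}
    group_names: list[str] = []
    chrom_names: list[str] = []
    for tr in tracks:
        grp = groups.get(tr.sample_id)
        if grp is None:
            continue
        if grp not in group_names:
            group_names.append(grp)
        for chrom in tr.chromosomes:
            if chrom not in chrom_names:
                chrom_names.append(chrom)
            w, t = tr.aim_calls(chrom)
            weed[(chrom, grp)] = weed.get((chrom, grp), 0) + w
            total[(chrom, grp)] = total.get((chrom, grp), 0) + t
    for grp in set(groups.values()):
        if grp not in group_names:
            warnings.warn(f"group {grp!r} has no tracks; omitted", stacklevel=2)
    data = {
        grp: [
            weed.get((c, grp), 0) / total[(c, grp)] if total.get((c, grp)) else np.nan
            for c in chrom_names
        ]
        for grp in group_names
    }
    table = pd.DataFrame(data, index=chrom_names)
    if site_weighted_average:
        avg = {
            grp: sum(weed.get((c, grp), 0) for c in chrom_names)
            / max(sum(total.get((c, grp), 0) for c in chrom_names), 1)
            for grp in group_names
        }
        table.loc["Average"] = pd.Series(avg)
    else:
        table = append_average(table)
    return table


def append_average(per_chromosome: pd.DataFrame) -> pd.DataFrame:
    """Append the unweighted mean of per-chromosome rows as ``Average``."""
    out = per_chromosome.copy()
    out.loc["Average"] = per_chromosome.mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Focal-region summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FocalBlock:
    """Ancestry call of a focal region: crop, weed, mixed, or no-marker."""

    label: str
    n_aims: int
    mean_dosage: float
    hap_crop_fraction: tuple[float, float]


def focal_block(
    track: AncestryTrack, chrom: str, start: int, end: int
) -> FocalBlock:
    """Summarise decoded ancestry over ``[start, end)`` (0-based bp).

    ``crop``/``weed`` only when every overlapping AIM call agrees; otherwise
    ``mixed`` with per-haplotype crop fractions. A region with no AIMs gets
    the distinct ``no-marker`` label.
    """
    tr = track.chromosomes.get(chrom)
    if tr is None:
        return FocalBlock("no-marker", 0, float("nan"), (float("nan"),) * 2)
    in_region = (tr.positions >= start) & (tr.positions < end)
    if not in_region.any():
        return FocalBlock("no-marker", 0, float("nan"), (float("nan"),) * 2)
    d = tr.map_dosage[in_region]
    n = int(in_region.sum())
    hap0 = float((d >= 1).mean())
    hap1 = float((d == 2).mean())
    if (d == 2).all():
        label = "crop"
    elif (d == 0).all():
        label = "weed"
    else:
        label = "mixed"
    return FocalBlock(label, n, float(d.mean()), (hap0, hap1))


def write_tracks_bed(tracks: Iterable[AncestryTrack], path) -> None:
    """Write haplotype ancestry segments as BED-like TSV."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsample\thaplotype\tlabel\n")
        for tr in tracks:
            for chrom, ct in tr.chromosomes.items():
                for h, segs in enumerate(ct.hap_segments):
                    for s, e, lab in segs:
                        fh.write(f"{chrom}\t{s}\t{e}\t{tr.sample_id}\t{h}\t{lab}\n")
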
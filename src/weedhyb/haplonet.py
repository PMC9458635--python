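"""Focal-gene haplotype networks with a deterministic phasing rule.

Haplotypes are sequences over the variable sites of a gene region. Samples
homozygous throughout contribute their sequence directly; heterozygous
samples are resolved by a parsimony rule — among all ways of splitting the
het sites into two haplotypes, choose the split creating the fewest
haplotypes not already observed in homozygotes (lexicographic tie-break).
Samples that cannot be resolved without inventing new haplotypes are kept
but flagged; samples with more than ``max_het_sites`` het sites are excluded
(2**k phase ambiguity) and reported.

The network is a median-joining network: iteratively add majority-consensus
(median/Steiner) haplotypes of node triplets whenever they shorten the
minimum spanning tree over the node set, then connect nodes by the
epsilon-relaxed minimum spanning network. Ties among equally good medians
are broken lexicographically and counted, so equally parsimonious
alternative arrangements are surfaced rather than hidden.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .io import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING


@dataclass
class Haplotype:
    """One distinct haplotype over a region's variable sites."""

    seq: str
    count: int = 0
    carriers: list[str] = field(default_factory=list)
    flagged: bool = False              # phase not resolvable from homozygotes
    phenotypes: dict[str, float] = field(default_factory=dict)


@dataclass
class PhasingReport:
    excluded: list[tuple[str, int]] = field(default_factory=list)  # (sample, n_het)
    flagged: list[str] = field(default_factory=list)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Haplotype extraction
# ---------------------------------------------------------------------------

def extract_haplotypes(
    gm: GenotypeMatrix,
    region: tuple[str, int, int] | None = None,
    max_het_sites: int = 8,
    count_homozygotes_twice: bool = True,
) -> tuple[list[Haplotype], np.ndarray, PhasingReport]:
    """Extract phased haplotypes from unphased genotypes in a gene region.

    Returns ``(haplotypes, site_positions, report)`` where
    ``site_positions`` are the 0-based genomic positions of the variable
    sites the haplotype sequences index, and the report lists excluded and
    phase-flagged samples. Samples with missing genotypes in the region are
    excluded (consensus sequence undefined).
    """
    if region is not None:
        sub = gm.take_sites(gm.region_mask(*region))
    else:
        sub = gm
    if sub.n_sites == 0:
        raise ValueError("no variable sites in region")
    ref = sub.sites["ref"].to_numpy()
    alt = sub.sites["alt"].to_numpy()
    positions = sub.sites["pos"].to_numpy() - 1
    report = PhasingReport()

    def seq_from(alleles: np.ndarray) -> str:
        return "".join(alt[i] if alleles[i] else ref[i] for i in range(len(alleles)))

    # pass 1: homozygous samples define the observed haplotype set
    observed: dict[str, Haplotype] = {}
    het_samples: list[tuple[str, np.ndarray]] = []
    per_copy = 2 if count_homozygotes_twice else 1
    for i, sample in enumerate(sub.sample_ids):
        g = sub.genotypes[i]
        if (g == MISSING).any():
            report.excluded.append((sample, -1))
            continue
        het_idx = np.flatnonzero(g == HET)
        if het_idx.size == 0:
            s = seq_from(g == HOM_ALT)
            hap = observed.setdefault(s, Haplotype(s))
            hap.count += per_copy
            hap.carriers.append(sample)
        elif het_idx.size > max_het_sites:
            report.excluded.append((sample, int(het_idx.size)))
        else:
            het_samples.append((sample, g))

    # pass 2: resolve het samples against the homozygote haplotype set
    for sample, g in het_samples:
        het_idx = np.flatnonzero(g == HET)
        base = g == HOM_ALT
        best: tuple[int, tuple[str, str]] | None = None
        # 2^(k-1) unordered splits: fix the first het site's assignment
        for bits in itertools.product((0, 1), repeat=len(het_idx) - 1):
            assign = (0, *bits)
            h1, h2 = base.copy(), base.copy()
            for j, site in enumerate(het_idx):
                h1[site] = bool(assign[j])
                h2[site] = not assign[j]
            pair = tuple(sorted((seq_from(h1), seq_from(h2))))
            n_new = sum(s not in observed for s in pair)
            key = (n_new, pair)
            if best is None or key < best:
                best = key
        n_new, pair = best
        flagged = n_new > 0
        if flagged:
            report.flagged.append(sample)
        for s in pair:
            is_new = s not in observed
            hap = observed.setdefault(s, Haplotype(s))
            hap.count += 1
            hap.carriers.append(sample)
            if flagged and is_new:
                hap.flagged = True  # haplotype exists only via ambiguous phase
    haps = sorted(observed.values(), key=lambda h: h.seq)
    return haps, positions, report


def haplotypes_from_fasta(path: str | Path) -> tuple[list[Haplotype], np.ndarray]:
    """Read aligned, already-phased consensus sequences from FASTA.

    Sequences must share a common length; variable columns define the
    haplotype alphabet and the returned positions are alignment columns
    (0-based).
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise ValueError("need >=2 aligned sequences")
    seqs = [str(r.seq).upper() for r in records]
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences are not aligned to a common length")
    cols = np.array([list(s) for s in seqs])
    variable = np.array([len(set(cols[:, j])) > 1 for j in range(length)])
    positions = np.flatnonzero(variable)
    observed: dict[str, Haplotype] = {}
    for rec, s in zip(records, seqs):
        key = "".join(s[j] for j in positions)
        hap = observed.setdefault(key, Haplotype(key))
        hap.count += 1
        hap.carriers.append(rec.id)
    return sorted(observed.values(), key=lambda h: h.seq), positions


def attach_phenotypes(
    haps: Sequence[Haplotype], classes: Mapping[str, str]
) -> None:
    """Set per-haplotype phenotype-class proportions from a sample mapping."""
    for hap in haps:
        labels = [classes[c] for c in hap.carriers if c in classes]
        hap.phenotypes = (
            {k: labels.count(k) / len(labels) for k in sorted(set(labels))}
            if labels else {}
        )


# ---------------------------------------------------------------------------
# Median-joining network
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeNetwork:
    """Median-joining network over haplotype sequences.

    ``graph`` nodes are haplotype sequences with attributes ``count``,
    ``carriers``, ``is_median``, ``phenotypes``; edges carry ``steps`` (the
    number of mutational differences) and, after annotation, ``annotations``.
    ``co_optimal`` multiplies the sizes of every tie set met while choosing
    medians: the number of equally parsimonious construction paths.
    """

    graph: nx.Graph
    site_positions: np.ndarray | None = None
    co_optimal: int = 1

    def total_length(self) -> int:
        return int(sum(d["steps"] for _, _, d in self.graph.edges(data=True)))


def _mst_length(nodes: list[str]) -> int:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in itertools.combinations(nodes, 2):
        g.add_edge(u, v, weight=_hamming(u, v))
    return int(sum(d["weight"] for _, _, d in
                   nx.minimum_spanning_edges(g, data=True)))


def _msn_edges(nodes: list[str], epsilon: int) -> list[tuple[str, str, int]]:
    """Epsilon-relaxed minimum spanning network.

    An edge (u, v) is kept iff its length is within ``epsilon`` of the
    minimax path distance between u and v (for epsilon = 0: the union of
    all minimum spanning trees).
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in itertools.combinations(nodes, 2):
        g.add_edge(u, v, weight=_hamming(u, v))
    mst = nx.minimum_spanning_tree(g)
    edges = []
    for u, v in itertools.combinations(nodes, 2):
        path = nx.shortest_path(mst, u, v)
        minimax = max(
            mst[path[i]][path[i + 1]]["weight"] for i in range(len(path) - 1)
        )
        d = g[u][v]["weight"]
        if d <= minimax + epsilon:
            edges.append((u, v, d))
    return edges


def _median_vector(u: str, v: str, w: str) -> str:
    """Site-wise majority consensus; three-way ties take the smallest symbol."""
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(min(a, b, c))
    return "".join(out)


def median_joining(
    haps: Sequence[Haplotype], epsilon: int = 0
) -> HaplotypeNetwork:
    """Build a median-joining network from distinct haplotypes.

    Iterates: propose the majority-consensus median of every node triplet;
    add the median giving the largest reduction in minimum-spanning-tree
    length (lexicographically smallest on ties, with the tie multiplicity
    recorded); stop at a fixed point; prune inferred medians of degree < 3;
    connect the final node set by the epsilon-relaxed minimum spanning
    network. Deterministic for any input order (nodes are processed in
    lexicographic order throughout).
    """
    by_seq = {h.seq: h for h in haps}
    if len(by_seq) < 2:
        raise ValueError("need >=2 distinct haplotypes")
    lengths = {len(s) for s in by_seq}
    if len(lengths) != 1:
        raise ValueError("haplotypes of unequal length")
    nodes = sorted(by_seq)
    co_optimal = 1
    current_len = _mst_length(nodes)
    while True:
        candidates: dict[str, int] = {}
        for u, v, w in itertools.combinations(nodes, 3):
            m = _median_vector(u, v, w)
            if m in by_seq or m in candidates or m in nodes:
                continue
            candidates[m] = _mst_length(nodes + [m])
        if not candidates:
            break
        best_len = min(candidates.values())
        if best_len >= current_len:
            break
        ties = sorted(m for m, L in candidates.items() if L == best_len)
        co_optimal *= len(ties)
        nodes = sorted(nodes + [ties[0]])
        current_len = best_len

    # prune medians that end up peripheral (degree < 3, zero observations)
    while True:
        edges = _msn_edges(nodes, epsilon)
        deg: dict[str, int] = {n: 0 for n in nodes}
        for u, v, _ in edges:
            deg[u] += 1
            deg[v] += 1
        prune = [n for n in nodes if n not in by_seq and deg[n] < 3]
        if not prune:
            break
        nodes = [n for n in nodes if n not in prune]

    graph = nx.Graph()
    for n in nodes:
        hap = by_seq.get(n)
        graph.add_node(
            n,
            count=hap.count if hap else 0,
            carriers=list(hap.carriers) if hap else [],
            is_median=hap is None,
            flagged=bool(hap.flagged) if hap else False,
            phenotypes=dict(hap.phenotypes) if hap else {},
        )
    for u, v, d in _msn_edges(nodes, epsilon):
        graph.add_edge(u, v, steps=d)
    return HaplotypeNetwork(graph, co_optimal=co_optimal)


# ---------------------------------------------------------------------------
# Amino-acid annotation of mutational steps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CDSMap:
    """Coordinate map of a gene's coding sequence within a reference region.

    ``region_start``: 0-based genomic start of ``ref_seq``;
    ``cds_intervals``: half-open 0-based genomic intervals of the CDS in
    transcription order; ``strand``: '+' or '-'; ``codon_offset``: added to
    the 1-based codon number (for partial gene regions);
    ``resistance_changes``: amino-acid replacements to flag, e.g. "S653N".
    """

    region_start: int
    ref_seq: str
    cds_intervals: tuple[tuple[int, int], ...]
    strand: str = "+"
    codon_offset: int = 0
    resistance_changes: frozenset[str] = frozenset({"S653N", "G654E"})

    def cds_position(self, genomic_pos: int) -> int | None:
        """0-based position within the concatenated CDS, or None if non-coding."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= genomic_pos < e:
                cds_pos = offset + (genomic_pos - s)
                if self.strand == "-":
                    total = sum(b - a for a, b in self.cds_intervals)
                    return total - 1 - cds_pos
                return cds_pos
            offset += e - s
        return None

    def _cds_sequence(self, full_region: str) -> str:
        parts = [
            full_region[s - self.region_start : e - self.region_start]
            for s, e in self.cds_intervals
        ]
        seq = "".join(parts)
        if self.strand == "-":
            seq = _revcomp(seq)
        return seq


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _translate_codon(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def _node_region_sequence(
    node_seq: str, positions: np.ndarray, cds: CDSMap
) -> str:
    region = list(cds.ref_seq)
    for allele, pos in zip(node_seq, positions):
        region[pos - cds.region_start] = allele
    return "".join(region)


def annotate_steps(
    net: HaplotypeNetwork,
    cds: CDSMap,
    site_positions: np.ndarray | None = None,
) -> HaplotypeNetwork:
    """Annotate each edge's mutational steps with codon-level consequences.

    Each differing site between an edge's endpoints is labelled as
    non-coding, synonymous, or an amino-acid replacement (e.g. "S653N");
    replacements in ``cds.resistance_changes`` (in either direction along
    the undirected edge) are flagged as resistance steps.
    """
    positions = site_positions if site_positions is not None else net.site_positions
    if positions is None:
        raise ValueError("site positions required for annotation")
    for u, v, data in net.graph.edges(data=True):
        annotations = []
        region_u = _node_region_sequence(u, positions, cds)
        region_v = _node_region_sequence(v, positions, cds)
        for i, (x, y) in enumerate(zip(u, v)):
            if x == y:
                continue
            gpos = int(positions[i])
            cds_pos = cds.cds_position(gpos)
            if cds_pos is None:
                annotations.append(
                    {"pos": gpos, "change": f"{x}>{y}", "coding": False,
                     "label": "non-coding", "resistance": False}
                )
                continue
            codon_i = cds_pos // 3
            codon_no = codon_i + 1 + cds.codon_offset
            cds_u = cds._cds_sequence(region_u)
            cds_v = cds._cds_sequence(region_v)
            aa_u = _translate_codon(cds_u[3 * codon_i : 3 * codon_i + 3])
            aa_v = _translate_codon(cds_v[3 * codon_i : 3 * codon_i + 3])
            if aa_u == aa_v:
                label, resist = f"synonymous({aa_u}{codon_no})", False
            else:
                label = f"{aa_u}{codon_no}{aa_v}"
                rev = f"{aa_v}{codon_no}{aa_u}"
                resist = (label in cds.resistance_changes
                          or rev in cds.resistance_changes)
            annotations.append(
                {"pos": gpos, "change": f"{x}>{y}", "coding": True,
                 "codon": codon_no, "aa_from": aa_u, "aa_to": aa_v,
                 "label": label, "resistance": resist}
            )
        data["annotations"] = annotations
    return net


def write_network_tsv(net: HaplotypeNetwork, edge_path, node_path) -> None:
    """Export the network as edge-list and node-table TSVs."""
    with open(node_path, "w") as fh:
        fh.write("haplotype\tcount\tis_median\tflagged\tcarriers\tphenotypes\n")
        for n, d in sorted(net.graph.nodes(data=True)):
            phen = ";".join(f"{k}={v:.3f}" for k, v in d["phenotypes"].items())
            fh.write(f"{n}\t{d['count']}\t{int(d['is_median'])}\t"
                     f"{int(d['flagged'])}\t{','.join(d['carriers'])}\t{phen}\n")
    with open(edge_path, "w") as fh:
        fh.write("hap_from\thap_to\tsteps\tannotations\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            ann = ";".join(a["label"] for a in d.get("annotations", []))
            fh.write(f"{u}\t{v}\t{d['steps']}\t{ann}\n")
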
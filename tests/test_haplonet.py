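"""Haplotype extraction, median-joining networks, codon annotation."""

import itertools

import networkx as nx
import numpy as np
import pytest

from weedhyb.haplonet import (
    CDSMap,
    Haplotype,
    annotate_steps,
    extract_haplotypes,
    haplotypes_from_fasta,
    median_joining,
)
from weedhyb.io import HET, HOM_ALT, HOM_REF, MISSING
from conftest import make_matrix


def haps(*seqs):
    return [Haplotype(s, count=1) for s in seqs]


def steiner_oracle(observed, alphabet):
    """Brute-force minimal network length over every candidate median set.

    Enumerates all vectors over the site alphabet and all subsets of
    non-observed vectors, returning the smallest achievable minimum-
    spanning-tree length.
    """

    def mst_len(nodes):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v in itertools.combinations(nodes, 2):
            g.add_edge(u, v, weight=sum(x != y for x, y in zip(u, v)))
        return sum(d["weight"] for *_, d in nx.minimum_spanning_edges(g, data=True))

    L = len(observed[0])
    universe = ["".join(p) for p in itertools.product(alphabet, repeat=L)]
    extras = [v for v in universe if v not in observed]
    best = mst_len(observed)
    # a Steiner minimal tree on n terminals needs at most n - 2 extra points
    for r in range(1, max(len(observed) - 2, 0) + 1):
        for combo in itertools.combinations(extras, r):
            best = min(best, mst_len(list(observed) + list(combo)))
    return best


class TestMedianJoining:
    def test_two_haplotypes_single_edge(self):
        net = median_joining(haps("ACGT", "ACGA"))
        assert net.graph.number_of_edges() == 1
        (u, v, d), = net.graph.edges(data=True)
        assert d["steps"] == 1
        assert net.total_length() == steiner_oracle(["ACGT", "ACGA"], "ACGT")

    def test_median_node_shortens_star(self):
        observed = ["000", "110", "101"]
        net = median_joining(haps(*observed))
        assert "100" in net.graph
        assert net.graph.nodes["100"]["is_median"]
        assert net.graph.number_of_edges() == 3
        assert all(d["steps"] == 1 for *_, d in net.graph.edges(data=True))
        assert net.total_length() == 3 == steiner_oracle(observed, "01")

    def test_path_needs_no_medians(self):
        observed = ["000", "001", "011", "111"]
        net = median_joining(haps(*observed))
        assert set(net.graph.nodes) == set(observed)
        assert net.total_length() == 3 == steiner_oracle(observed, "01")
        assert sorted(net.graph.edges) == [
            ("000", "001"), ("001", "011"), ("011", "111")
        ]

    def test_input_order_invariance(self):
        observed = ["000", "110", "101", "011"]
        nets = [
            median_joining(haps(*perm))
            for perm in itertools.permutations(observed)
        ]
        first = nets[0]
        for net in nets[1:]:
            assert set(net.graph.nodes) == set(first.graph.nodes)
            assert sorted(net.graph.edges) == sorted(first.graph.edges)

    def test_total_length_bounded_by_observed_mst(self):
        rng = np.random.default_rng(8)
        observed = list({
            "".join(rng.choice(list("ACGT"), 5)) for _ in range(8)
        })
        net = median_joining(haps(*observed))
        g = nx.Graph()
        for u, v in itertools.combinations(observed, 2):
            g.add_edge(u, v, weight=sum(x != y for x, y in zip(u, v)))
        mst = sum(d["weight"] for *_, d in nx.minimum_spanning_edges(g, data=True))
        assert net.total_length() <= mst
        assert nx.is_connected(net.graph)
        assert net.co_optimal >= 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            median_joining(haps("AC", "ACG"))


class TestExtractHaplotypes:
    def test_homozygous_sample_verbatim(self):
        gm = make_matrix([[HOM_REF, HOM_ALT, HOM_REF]])
        out, positions, report = extract_haplotypes(gm)
        assert [h.seq for h in out] == ["AGA"]
        assert out[0].count == 2  # diploid carries two copies
        assert not report.flagged and not report.excluded

    def test_parsimony_resolution_against_homozygotes(self):
        # two homozygote-defined haplotypes AA.. and GG..; a sample het at
        # both sites resolves into exactly those, creating nothing new
        gm = make_matrix(
            [
                [HOM_REF, HOM_REF],
                [HOM_ALT, HOM_ALT],
                [HET, HET],
            ]
        )
        out, _, report = extract_haplotypes(gm)
        assert sorted(h.seq for h in out) == ["AA", "GG"]
        by_seq = {h.seq: h for h in out}
        assert by_seq["AA"].count == 3  # 2 from s0 + 1 from the het sample
        assert by_seq["GG"].count == 3
        assert report.flagged == []

    def test_unresolvable_sample_flagged(self):
        gm = make_matrix([[HOM_REF, HOM_REF], [HET, HET]])
        out, _, report = extract_haplotypes(gm)
        assert report.flagged == ["s1"]
        assert any(h.flagged for h in out)

    def test_excess_het_sites_excluded(self):
        gm = make_matrix([[HET] * 5])
        out, _, report = extract_haplotypes(gm, max_het_sites=3)
        assert report.excluded == [("s0", 5)]

    def test_missing_genotypes_excluded(self):
        gm = make_matrix([[HOM_REF, MISSING]])
        _, _, report = extract_haplotypes(gm)
        assert report.excluded[0][0] == "s0"

    def test_simulated_haplotypes_contained_in_panel_set(self, small_sim):
        # haplotypes of samples without an ancestry breakpoint inside a
        # gene-scale region must be verbatim founder-panel haplotypes
        cfg, cohort, crop, weed, truth = small_sim
        start, end = 2_000_000, 2_200_000
        region = ("chr1", start, end)
        out, positions, _ = extract_haplotypes(cohort, region)
        allowed = set()
        for panel in (crop, weed):
            sub = panel.take_sites(panel.region_mask(*region))
            ref = sub.sites["ref"].to_numpy()
            alt = sub.sites["alt"].to_numpy()
            for row in sub.genotypes:
                allowed.add(
                    "".join(alt[i] if row[i] == HOM_ALT else ref[i]
                            for i in range(len(row)))
                )

        def unbroken(lineage):
            return all(
                not (start < boundary < end)
                for hap in lineage.haplotypes
                for s, e, _ in hap[0]  # chr1 segments
                for boundary in (s, e)
            )

        clean = {
            cohort.sample_ids[i]
            for i, lin in enumerate(truth.lineages) if unbroken(lin)
        }
        assert clean  # the region is short enough that some lineages are intact
        for h in out:
            if set(h.carriers) & clean:
                assert h.seq in allowed


class TestFastaInput:
    def test_variable_columns_define_haplotypes(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nACGTAC\n>b\nACGTAC\n>c\nACCTAA\n")
        out, positions = haplotypes_from_fasta(p)
        assert positions.tolist() == [2, 5]
        assert sorted((h.seq, h.count) for h in out) == [("CA", 1), ("GC", 2)]


def synthetic_cds(n_codons=660):
    """A synthetic reference gene long enough to hold codon 653."""
    codons = ["CTT"] * n_codons  # leucine filler
    codons[652] = "AGT"  # serine at codon 653
    codons[653] = "GGG"  # glycine at codon 654
    seq = "".join(codons)
    return CDSMap(
        region_start=0,
        ref_seq=seq,
        cds_intervals=((0, len(seq)),),
        strand="+",
        resistance_changes=frozenset({"S653N", "G654E"}),
    )


class TestAnnotateSteps:
    def test_resistance_replacement_flagged(self):
        cds = synthetic_cds()
        pos = 653 * 3 - 2  # middle base of codon 653 (0-based 1957)
        net = median_joining(haps("G", "A"))
        net = annotate_steps(net, cds, site_positions=np.array([pos]))
        (ann,) = net.graph.edges["A", "G"]["annotations"]
        assert ann["codon"] == 653
        assert {ann["aa_from"], ann["aa_to"]} == {"S", "N"}
        assert ann["resistance"]

    def test_synonymous_change_not_flagged(self):
        cds = synthetic_cds()
        pos = 3 * 10 + 2  # third base of a CTT leucine codon
        net = median_joining(haps("T", "C"))  # CTT -> CTC, both Leu
        net = annotate_steps(net, cds, site_positions=np.array([pos]))
        (ann,) = net.graph.edges["C", "T"]["annotations"]
        assert ann["aa_from"] == ann["aa_to"] == "L"
        assert not ann["resistance"]
        assert ann["label"].startswith("synonymous")

    def test_noncoding_site_labelled(self):
        seq = "CTT" * 660 + "AAAA"
        cds = CDSMap(region_start=0, ref_seq=seq,
                     cds_intervals=((0, 1980),), strand="+")
        net = median_joining(haps("A", "G"))
        net = annotate_steps(net, cds, site_positions=np.array([1981]))
        (ann,) = net.graph.edges["A", "G"]["annotations"]
        assert ann["label"] == "non-coding"
        assert not ann["coding"]
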
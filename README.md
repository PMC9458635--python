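# weedhyb

Population-genomic analysis of **crop–weed hybrid genomes**, built around the
weedy rice (*Oryza* spp.) system: feral crop relatives that hybridize with
cultivated rice, then return to self-fertilization while herbicide pressure
drives adaptive introgression of crop resistance alleles.

The package is for researchers who have a multi-sample SNP VCF of admixed,
largely selfing plants together with reference panels for the two putative
ancestors, and want to answer:

- **How long ago did hybridization happen?** At ancestry-informative markers
  (AIMs — sites fixed for opposite alleles between the ancestral panels) an
  F1 is heterozygous everywhere, and strict selfing halves heterozygosity
  every generation: `E[h_g] = 0.5^g`, so `ĝ = -log2(h)` with an exact
  binomial (Clopper–Pearson) interval mapped through the same transform.
- **Which parts of the genome come from which ancestor?** A three-state
  hidden Markov model over AIMs decodes the crop-allele dosage (0/1/2) along
  each chromosome, with distance-dependent switch probabilities and a
  per-allele genotyping error `ε`; per-chromosome weed-ancestry proportions
  are tabulated with a genome-wide average row.
- **Where has selection acted?** Sliding-window Weir–Cockerham
  F<sub>ST</sub> (ratio of variance-component sums, `Σa / Σ(a+b+c)`, 500 kb
  windows / 250 kb steps by default) and per-site nucleotide diversity π,
  run as a *dual* comparison — hybrid cohort vs. crop ancestor and vs. weed
  ancestor — so adaptive introgression shows up as a joint dip/peak at the
  selected locus.
- **Which resistance haplotypes are segregating?** Median-joining haplotype
  networks of a focal gene (e.g. acetolactate synthase, *ALS*) with a
  deterministic parsimony phasing rule and codon-level annotation of
  mutational steps (S653N and G654E flagged as resistance replacements),
  plus binning of herbicide-injury phenotypes into resistance categories.

Everything is driven and validated by a forward simulator of
hybridization → selfing with Poisson recombination → optional viability
selection, which emits VCF output together with complete per-haplotype
ancestry truth.

## Worked example

```python
from weedhyb import (SimConfig, simulate_cohort, identify_aims,
                     aim_heterozygosity, estimate_generations,
                     infer_tracks, genome_bias)

cfg = SimConfig(n_chromosomes=4, chrom_length_bp=10_000_000, aim_density=3.0,
                g=4, n_lineages=12, n_panel_samples=6, seed=42)
cohort, crop, weed, truth = simulate_cohort(cfg)
aims = identify_aims(crop, weed)
print(f"{len(aims)} ancestry-informative markers")
for s in cohort.sample_ids[:3]:
    n_het, n_called, frac = aim_heterozygosity(cohort, s, aims)
    est = estimate_generations(frac, n_called, n_het)
    print(f"{s}: AIM het {frac:.3f} -> g = {est.g_hat:.2f} "
          f"(95% CI {est.ci[0]:.2f}-{est.ci[1]:.2f})")
lengths = {c: cfg.chrom_length_bp for c in cfg.chrom_names}
tracks = [infer_tracks(cohort, s, aims, chrom_lengths=lengths)
          for s in cohort.sample_ids]
print(genome_bias(tracks, {s: "hybrids" for s in cohort.sample_ids}).round(3))
```

prints

```
125 ancestry-informative markers
hyb001: AIM het 0.048 -> g = 4.38 (95% CI 3.30-5.81)
hyb002: AIM het 0.032 -> g = 4.97 (95% CI 3.65-6.83)
hyb003: AIM het 0.152 -> g = 2.72 (95% CI 2.14-3.41)
         hybrids
chr1       0.438
chr2       0.434
chr3       0.451
chr4       0.465
Average    0.447
```

The cohort was simulated four selfing generations past the F1: per-sample
AIM heterozygosity (~0.5⁴ ≈ 0.06 in expectation) dates each lineage, with
lineage-to-lineage spread reflecting real segregation variance, and the
neutral cohort's weed-ancestry table sits near the 50:50 expectation.

A command-line interface mirrors the library
(`weedhyb simulate | filter | aims | classify | tracks | bias | fst | pi |
haplonet | resistance | run-all`); `run-all` executes the whole pipeline from
a YAML config and writes a manifest with per-stage seeds and output digests
so reruns are byte-identical.

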
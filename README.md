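# mitoscan

Case-control association scanning for whole human mitochondrial genomes.

Given aligned consensus mitogenomes (one fixed-length FASTA record per
person, numbered against a 16,569-bp reference such as the rCRS) and a
binary phenotype split — e.g. subjects who completed a demanding physical
training course ("F") versus those who did not ("NF") — `mitoscan` runs the
full analysis a small mtDNA case-control study needs:

1. **Count matrix.** Per-position, per-group allele counts, polarized to the
   cohort-wide major allele, after two mtDNA-specific filters: heteroplasmic
   consensus calls (two-base IUPAC codes; called when the minor:major read
   ratio is at least 1:4) and indels inside homopolymeric blocks, which are
   treated as having no effect.
2. **δ-scan.** At every position, the absolute allele-frequency difference
   δ = |p_F − p_NF| of the non-major allele mass. Sites with δ more than
   three standard deviations from zero (δ > 3·√(Σδ²/(n−1)) over polymorphic
   sites) are flagged as candidate group-differential variants.
3. **Association statistics.** Per-outlier 2×2 tests (Pearson χ² without
   continuity correction when expected counts allow, otherwise Fisher's
   exact), odds ratios OR = ad/bc with Woolf log-intervals
   exp(ln OR ± z·√(1/a+1/b+1/c+1/d)) (exact conditional interval optional),
   an r×2 lineage-distribution χ², and summary-level Student's t and
   Cohen's d (d = |m₁−m₂| / √((s₁²+s₂²)/2)) for cohort covariates.
4. **Population structure.** Wright's F_ST over haplogroup frequencies
   (F_ST = (H_T − H_S)/H_T with haplogroups as alleles), AMOVA Φ_ST from
   squared pairwise sequence mismatches, both with label-permutation
   p-values p = (b+1)/(m+1), and a neighbor-joining QC tree.
5. **Haplogroups.** Classification against a user-supplied definition tree
   (cumulative defining variants, best match-fraction wins, deeper node on
   ties) and longest-prefix collapse to macro-lineages (L0–L3, M, N, R, H, …).
6. **Annotation.** Codon location within a mitochondrial gene model,
   amino-acid consequence under the vertebrate mitochondrial code (NCBI
   table 2), and the codon-usage molar ratio (frequency per thousand) for
   synonymous changes.

Because cohorts like this are rarely shareable, the package includes a
seeded synthetic-cohort generator (`mitoscan.synthetic_data`) that emulates
the relevant structure — haplogroup-founder haplotypes, two unequal groups,
planted group-differential sites, heteroplasmies, homopolymer deletions —
and writes a machine-readable truth file, so the whole pipeline is testable
end to end without any downloads.

## Worked example

Simulate a study-shaped cohort (88 genomes, 29 F / 59 NF, 22 haplogroups,
one planted site at position 11914 with derived-allele frequencies 4/29 vs
24/59) and run the pipeline:

```sh
mitoscan simulate --out demo/sim --seed 1
mitoscan run --config demo/config.yaml
```

with `demo/config.yaml` pointing at the simulated files:

```yaml
fasta: demo/sim/cohort.fasta
metadata: demo/sim/metadata.tsv
reference: demo/sim/reference.fasta
haplogroup_defs: demo/sim/haplogroups.tsv
lineage_map: demo/sim/lineage_map.tsv
outdir: demo/out
seed: 1
```

`demo/out/summary.txt` then reads (exact numbers depend on the seed):

```
mitoscan summary
seed: 1
polymorphic sites: 757
outliers (>3 SD delta): 4
top outlier: position 11914 delta=0.3705 p=0.000792 OR=6.466 95%CI 2.002-20.882 (chi_square)
haplogroups: 22
lineage chi-square: X2=10.0488 df=9 p=0.3465
haplogroup FST: 0.0063 (permutation p=0.9551)
PhiST: -0.0032 (permutation p=0.5127)
```

Reading: of 757 polymorphic positions, 4 exceed the 3-SD δ fence; the top
one is the planted site, significantly group-differential with an odds
ratio well above 1 (at this seed the realized carrier counts land somewhat
stronger than their configured expectations of 4/29 vs 24/59; the carrier
table those expectations define gives χ² p ≈ 0.011 and OR = 4.286).
Haplogroup and lineage composition are statistically indistinguishable
between groups (F_ST ≈ 0, permutation p ≫ 0.05). Equivalent calls are
available from Python; e.g. the same statistics directly:

```python
>>> from mitoscan import two_by_two_test, cohens_d_summary, codon_usage_ratio
>>> two_by_two_test(25, 4, 35, 24).odds_ratio
4.285714285714286
>>> cohens_d_summary(27.7, 4.2, 28.6, 4.0)     # age, F vs NF
0.21944691457271554
>>> codon_usage_ratio("ACA", "ACG", {"ACA": 32.7, "ACG": 2.6})
12.576923076923078
```

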
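# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions a user should know before
trusting or extending the results.

## Input model and coordinates

All positions are 1-based and inclusive against a single linear reference
(16,569 bp for the human mitogenome). The genome is treated as circular
only inside the gene model (a gene may wrap the origin when flagged);
everywhere else — scanning, distances, classification — coordinates are
linear, which is exact because the inputs are pre-aligned fixed-length
consensus sequences.

Consensus sequences use A/C/G/T plus `N` (missing), `-` (alignment gap,
i.e. deletion relative to the reference) and the six two-base IUPAC codes
(R/Y/S/W/K/M), which encode heteroplasmy at consensus level: a position
where the minor base reached at least the calling ratio (default 1:4,
`heteroplasmy_min_ratio = 0.25`). A consensus code carries no read-fraction
information, so variant calls derived from alignments record
`minor_fraction = 0.5` by convention; calls read from VCF use the
per-sample `AF` field when present.

## Filters

**Heteroplasmy.** How a heteroplasmic sample-site enters the allele-count
matrix is genuinely underdetermined by the study design this package
mirrors, so it is a policy knob: `exclude_site_sample` (default — the
sample contributes no count at that site; conservative, never invents an
allele), `count_major` (counts the reference base when it is one of the two
components, else the alphabetically first component), or `iupac` (the code
itself becomes an allele, useful for auditing). Count conservation holds
under every policy: counted + excluded = group size at every site.

**Homopolymer indels.** Insertion/deletion calls anchored inside a
single-base reference run of length ≥ `homopolymer_min_run` (default 5) are
masked and treated as reference downstream. Polymerase slippage makes indel
calls in such blocks unreliable within an individual; no published length
cutoff exists for this rule, so 5 — the shortest run length at which
slippage artifacts become common in practice — is the default and the knob
is exposed. SNPs are never masked.

## The δ-scan

Each site is polarized to the cohort-wide major allele (pooled argmax,
alphabetical tie-break for determinism). δ is the absolute difference
between the groups in non-major allele mass; at a biallelic site this is
|p_F − p_NF| of the minor allele. Multiallelic sites use the
total-variation distance ½·Σ|p_F,a − p_NF,a| by default (it reduces exactly
to |Δp| when two alleles segregate) or, optionally, the maximum over
non-major alleles.

Outliers are sites "more than three standard deviations" out. Two readings
are implemented:

- `three_sd_about_zero` (default): the spread of δ is measured about zero,
  its null value — sd_δ = √(Σδ²/(n−1)) over polymorphic sites — and sites
  with δ > 3·sd_δ are flagged. δ is a folded, non-negative quantity; under
  a binomial null it is approximately half-normal, for which the about-zero
  spread equals the underlying noise scale σ, so the fence sits at 3σ and
  flags ≈0.3% of null sites. Measuring spread about the mean instead would
  put the fence near 2.5σ and flag several percent of null sites, which is
  not what a "3 SD outlier" rule is for.
- `mean_plus_three_sd`: the conventional mean + 3·(sample SD about the
  mean), for users who want the textbook fence.

The SD is computed over polymorphic sites only (monomorphic sites are δ=0
by definition and would only dilute it), with n−1 in the denominator. If
sd_δ = 0 (e.g. every polymorphic site has identical group frequencies)
nothing is flagged and a warning is logged.

No multiple-testing correction is applied to the per-outlier tests by
default — the scan is a screening device, and the downstream contingency
tests are reported per site exactly as screened. Bonferroni (over the
polymorphic-site count) and Benjamini–Hochberg adjusters are provided for
users who want them.

## Association statistics

Per-site 2×2 tables are laid out as (group-1 allele-1, allele-2 / group-2
allele-1, allele-2). The test is Pearson χ² with 1 df and no continuity
correction when every expected cell is ≥ 5 and no observed cell is zero,
otherwise Fisher's exact two-sided test; which branch ran is recorded.
Note that a label-permutation null on a 2×2 table fixes both margins and
therefore reproduces Fisher's exact p, not the asymptotic χ² p; the two can
differ by a few hundredths even at n of several hundred. The test suite
checks each against the null it actually targets (permutation ↔ Fisher;
χ² ↔ an unconditional binomial bootstrap).

The odds ratio is ad/bc with a Woolf log-interval
exp(ln OR ± z·√(1/a+1/b+1/c+1/d)); any zero cell triggers the
Haldane–Anscombe +0.5 correction to all cells (recorded), or, if correction
is disabled, an infinite/zero point estimate with an open interval. The
exact conditional (hypergeometric) interval is available as an alternative
and is wider than Woolf on small tables; the method used is always recorded
in output because small-cohort intervals differ materially between methods.

Cohen's d defaults to the root-mean-square denominator
√((s₁²+s₂²)/2) — Cohen's original equal-weight form, and the only form that
reproduces standard worked examples computed from two group summaries
without sample sizes. The df-weighted pooled-SD variant is provided for
compatibility with the other convention. Student's pooled-variance t (df =
n₁+n₂−2) and a paired variant (summaries of differences, df = n−1) cover
the summary-level comparisons; note that t computed from rounded published
summaries can differ in the second decimal from the value computed on raw
data, so such t-values should not be treated as exact targets.

## Population structure

**Haplogroup-frequency F_ST** treats haplogroups as alleles of one locus:
H_T = 1 − Σp̄_k² on pooled frequencies, H_S = Σ_g w_g(1 − Σp_{g,k}²) with
w_g = n_g/N, F_ST = (H_T − H_S)/H_T. This G_ST-style estimator is the most
direct reading of "Wright's F-statistics on haplogroup distributions"; it
carries a positive O(1/n) sampling bias and no unbiased correction is
applied by default (the raw value is what the permutation null calibrates).

**Φ_ST** is the two-level AMOVA fixation index on squared pairwise
mismatch distances: SSD_total = ΣΣd²/(2N), SSD_within = Σ_g ΣΣ_{i,j∈g}
d²/(2n_g), variance components from the mean squares with
n_c = (N − Σn_g²/N)/(G−1), Φ_ST = σ²_a/(σ²_a+σ²_w). Slightly negative
estimates are reported raw (they are the estimator's own null behavior).
Distances count positions where both bases are unambiguous A/C/G/T
(pairwise deletion); per-pair usable-site counts are logged.

Both statistics get permutation p-values by shuffling sample group labels
with a seeded generator, p = (b+1)/(m+1) with m = 10,000 by default; the
same seed gives bit-identical p.

The neighbor-joining tree is a topology QC device (do the two groups or the
founders separate?), not a model-based phylogeny — no substitution model,
no bootstrap.

## Haplogroup classification

Definitions are an input file (`name<TAB>parent<TAB>variants`), not bundled
reference data: haplogroup trees are versioned external knowledge and any
snapshot would drift. Defining variants are cumulative along the root path.
A sample's score at a node is the unweighted fraction of path-defining
variants it carries; the best score wins, ties resolve to the deeper
(more specific) node, then alphabetically — deterministic by construction.
Back-mutations and recurrent mutations are ordinary mismatches; no
per-variant weighting is applied (rate-weighted scoring in the style of the
dedicated haplogroup callers is out of scope, and the classifier is
validated by recovery on generated cohorts instead). Lineage
simplification is longest-prefix matching on an ordered prefix table;
unmatched names go to `OTHER` with a warning.

## Consequence annotation

The gene model (`gene, start, end, strand, phase, coding[, wrap]`) is an
input file; the shipped fixture holds an ND4 entry trimmed to 10760–12136
so the span is an exact codon multiple (the genomic gene ends in an
incomplete stop codon completed by polyadenylation, which a codon-grid
model cannot represent) plus a non-coding tRNA entry. Coding spans must
satisfy (length − phase) ≡ 0 (mod 3); wrap-flagged genes unroll through the
circular origin. For a SNP the affected codon is read from the reference
(reverse-complemented for − strand), the substitution applied, and both
codons translated under the vertebrate mitochondrial code (NCBI table 2,
where ATA = Met, TGA = Trp, AGA/AGG = stop); synonymous means equal amino
acids. For synonymous changes the codon-usage molar ratio
usage(alt)/usage(ref) in frequency-per-thousand units is attached when a
usage table is supplied; the shipped table records the two mitochondrial
threonine codons (ACA 32.7, ACG 2.6, ratio 12.6) as a minimal snapshot.
Indels are rejected (annotation is SNP-only), and a stated reference allele
that contradicts the reference sequence is an error, never silently fixed.

## Synthetic cohorts

`SimConfig` defaults are the study-shaped conditions the pipeline targets:
16,569-bp genome; groups F = 29 and NF = 59; a 22-node haplogroup tree with
fixed macro-topology (L0–L3; M/N from L3; R under N; H/U/J/T/V under R;
subclades) and 3 random defining variants per edge; a shared uniform
haplogroup mixture in both groups, so between-group haplogroup F_ST is ≈ 0
and essentially all 22 haplogroups appear among 88 samples (the heavily
admixed regime); one planted site at position 11914 (ancestral G, derived
A) with derived-allele probabilities 4/29 vs 24/59 — the carrier table
whose odds ratio is 4.286; Poisson(8) private mutations per sample, which
yields on the order of 750 polymorphic sites in the default cohort; a 5%
per-sample chance each of one heteroplasmic position (IUPAC code) and one
deletion inside a homopolymeric block (a poly-C run is guaranteed in the
reference). One seeded generator drives all draws in a fixed order —
reference, tree, then per-sample haplogroup/planted/private draws, then
heteroplasmies, then indels — so a seed reproduces the cohort
byte-for-byte, and everything decided is written to `truth.json`
(per-sample haplogroups, tree definitions, planted positions with
configured probabilities and realized carrier counts, injected
heteroplasmies and indels, group sizes, seed, reference).

What the generator does **not** emulate: coalescent genealogy (founders are
star-like within haplogroups), mutation-rate heterogeneity along the
genome (privates are uniform, whereas real mtDNA hypervariable regions
concentrate variation), selection, site-frequency spectra of real
populations, and read-level error. Passing recovery tests therefore show
that the statistics recover structure *of the kind the model assumes*; they
do not certify behavior on real cohorts with rate heterogeneity or
population substructure beyond haplogroups.

## Problem sizes and determinism

Recovery suites run at deliberately reduced sizes chosen to make their
stochastic targets sharp but cheap: planted-site ranking uses 100 seeded
cohorts of 200 samples on a 1,200-bp genome with ~300 background
polymorphic sites (private rate 1.7 makes the expected distinct-site count
land there); Woolf coverage uses 2,000 tables at the 29/59 group sizes;
classifier recovery uses 500 samples on the full-length genome with 2
expected private mutations each. The acceptance script re-runs all of
these plus a full default-condition cohort from one `--seed`; with a fixed
seed every output, including permutation p-values and pipeline TSVs, is
bit-reproducible. Pipeline outputs are write-once per stage; a failed stage
records its error and downstream stages that do not depend on it still run.

## Known limitations

- Heteroplasmy policies operate on consensus codes only; fraction-aware
  dosage models would need per-sample read fractions throughout.
- The VCF writer targets the simple haploid/heteroplasmic calls the
  generator produces; it is not a general-purpose VCF emitter (no phasing,
  no multi-sample AD fields, left-anchored deletions only, and a deletion
  touching position 1 cannot be anchored and is skipped).
- Annotation handles one codon at a time; a SNP in overlapping coding genes
  is annotated against the first coding gene containing it.
- The G_ST-style F_ST and the AMOVA Φ_ST answer related but distinct
  questions (frequency differentiation vs distance-scaled differentiation);
  on the same data their values agree only qualitatively, and no equality
  between them is asserted anywhere.
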
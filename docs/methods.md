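# Methods

## Scope and data model

The package estimates the deleterious mutational load of curated disease
gene sets in one focal population and compares it across populations. All
coordinates are 1-based inclusive (GTF/VCF convention); BED export is the
single place where 0-based half-open conversion happens. Chromosome names
are normalized by stripping a leading `chr`, since GENCODE-style gene models
and cohort VCFs commonly disagree on the prefix and that mismatch is the
most frequent silent failure in region subsetting.

Only biallelic single-nucleotide substitutions enter the analysis;
multiallelic records are decomposed to one record per ALT allele first, so
the SNV filter sees biallelic records regardless of input representation.
Phase is ignored and half-calls (`./1`) are treated as missing, which is
conservative and logged. Indels and MNVs are counted and dropped.

## Gene regions and region labels

Genes are matched to the GTF by symbol (an alias table can bridge naming
drift); list symbols not found are reported, never fabricated. Each gene
body is extended by a flank (default **2000 bp** per side, the usual promoter
capture window) and clipped at position 1. Overlapping extended regions are
deliberately not merged: a variant inside two genes' regions belongs to
both, while variant-level counts deduplicate by variant.

Positions are labeled with a fixed precedence when feature intervals
overlap: `exonic (CDS) > UTR5 > UTR3 > upstream > downstream > intronic`,
with `intergenic` outside the extended region. Annotation pipelines differ
on this precedence, so it is fixed here, documented, and tested; upstream
and downstream are assigned relative to strand. Where a GTF provides only
generic `UTR` features they are oriented 5′/3′ against the gene's CDS span
and strand.

## Consensus deleteriousness

A variant is a **dSNV** when three predictors agree on a missense variant:

| predictor | call condition | boundary |
|---|---|---|
| SIFT | score < 0.05 | strict |
| PolyPhen-2 HDIV | score > 0.957 | strict |
| CADD phred | score ≥ 15 | inclusive |

A missing score never supports a call: the conjunction fails on absent
evidence. The missense requirement is stated explicitly even though SIFT
and PolyPhen only produce scores for amino-acid substitutions — making the
gate explicit keeps the classifier total and its behavior independent of
which upstream annotator filled the table. Tightening any cutoff can only
remove combined calls (a tested monotonicity property). The predictor Venn
is computed over raw per-tool calls; because CADD scores non-coding
variants, CADD-only regions dominate, and the combined (missense-gated)
count is bounded by the triple intersection.

Loss-of-function means exactly {stop_gained, stop_lost, start_lost,
frameshift_variant, splice_acceptor_variant, splice_donor_variant};
`splice_region_variant` is not LoF. With a single consequence per variant
and the missense gate, a dSNV can never simultaneously be LoF here (the
published analyses that report LoF-within-deleterious used a second,
transcript-aware annotation pass); `summarize_load` still carries the
`lof_in_dsnv` counter structurally and reports the total LoF count
separately.

ClinVar significance strings are split on `| / ; ,` and matched
case-insensitively after canonicalization ("Likely pathogenic" ≡
"Likely_pathogenic") to absorb release-to-release dialect drift. A record
with multiple significances passes the pathogenic filter once.

## Polarization and DAF

Ancestral states are consumed as a table (chrom, pos, ref, alt →
ancestral base). Ancestral = REF orients the derived allele to ALT (DAF =
alt AF); ancestral = ALT flips the orientation (DAF = 1 − alt AF). Bases
are upper-cased; anything outside ACGT is unknown. Sites with unknown or
mismatching ancestral state are **kept but carry no DAF** and are tallied in
an exclusion report — the source data does not say how such sites should be
treated, so exclusion-with-accounting is this package's documented choice.
DAF bins: rare < 0.5%, low 0.5%–5% (both ends inclusive), common > 5%.
DAF is kept at full precision internally; rounding happens only in report
tables.

Homozygous-dSNV accounting is done on the **derived** allele (a sample is a
homozygous carrier when it holds two derived copies); where polarization is
undefined the alt allele stands in and the fallback is logged.

## Sharing and fold differences

Only dSNVs with a defined DAF and ≥1 derived allele in the focal population
enter the sharing analysis. Shared-with-X means derived count > 0 in both;
private means derived count 0 in every compared population (the comparison
set is configuration, not hard-coded). Exact DAF ties are counted
separately rather than folded into "higher" or "lower" — the published
tables this mirrors contain no ties, and a hidden tie convention would
corrupt the higher/lower duality (higher(F vs X) = lower(X vs F), tested).
Sites where some population has zero called chromosomes are dropped from
that pairwise comparison only, with a log entry. Fold differences
DAF_focal/DAF_other are defined on the shared set only (both > 0), so no
division by zero can occur; variants with zero focal DAF stay in spectra
(they matter for privacy accounting) but never enter ratios.

## Weir–Cockerham FST

Per-site variance components follow the moment estimator: with `r`
populations, diploid sizes `n_i`, allele frequencies `p_i` and heterozygote
frequencies `h_i`,

```
n̄ = Σnᵢ/r;  n_c = (r·n̄ − Σnᵢ²/(r·n̄))/(r−1);  p̄ = Σnᵢpᵢ/(r·n̄)
s² = Σnᵢ(pᵢ−p̄)²/((r−1)·n̄);  h̄ = Σnᵢhᵢ/(r·n̄)
a  = (n̄/n_c)·[s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4)/(n̄−1)]
b  = (n̄/(n̄−1))·[p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)]
c  = h̄/2;   θ̂ = a/(a+b+c)
```

θ̂ may be negative and is not clamped; it is undefined exactly when
a+b+c = 0 (monomorphic, no heterozygotes anywhere). Sites where any
population contributes fewer than 2 called individuals are skipped with a
reason rather than estimated. Heterozygote frequencies come from genotypes;
for site-level data without genotypes they can be imputed under
Hardy–Weinberg (2p(1−p)) and the output flags the imputation.

Two summaries are emitted over the same site set: the **unweighted mean** of
per-site θ̂ including negatives (the convention of the widespread
command-line implementations, and the scale on which the enrichment ratio
deleterious-mean / background-mean is defined) and the **ratio of sums**
Σa/Σ(a+b+c), which is the better-behaved estimator and the one that
recovers the Balding–Nichols drift parameter. The per-site mean is a
shrunken estimate of F (rare sites contribute noisy, near-zero θ̂), which is
why the two summaries differ visibly on simulated data; both are always
reported.

Differentiation bins are left-closed/right-open — less < 0.05 ≤ moderate
< 0.15 ≤ high < 0.25 ≤ severe — because prose ranges like "0.05–0.15" do
not fix edge membership; the convention is documented and tested (0.05 →
moderate, 0.25 → severe). Percentile ranks are "top X%": the share of
background sites with strictly greater θ̂.

## PCA

Standard genotype PCA: missing dosages are imputed to the site mean, each
site is centered by its mean dosage and scaled by √(p̂(1−p̂)) with
p̂ = mean/2, zero-variance and all-missing sites are dropped, and the
eigensystem of the sample covariance (1/m)XXᵀ is computed via SVD of the
normalized matrix (numerically safer than forming the covariance, and
verified against the dense eigendecomposition in tests). Coordinates are
orthonormal eigenvectors; eigenvalues are non-negative, descending, and sum
to the total variance. No LD pruning is applied. `k` beyond the matrix rank
is truncated with a warning; a matrix with no variation is an error.

## Synthetic cohorts

The generator emulates a multi-population diploid cohort, not real genomes:

- **Frequencies.** Ancestral frequency p ~ Uniform(0.05, 0.95) per site;
  each population draws Beta(p(1−F)/F, (1−p)(1−F)/F) (Balding–Nichols), so
  E[freq] = p, Var = p(1−p)F and expected pairwise θ equals F. Genotypes
  are Binomial(2, freq) — sites are independent (no LD), there is no
  mutation-rate heterogeneity and no coalescent structure.
- **Gene model.** Six fixed genes (two chromosomes, one on the minus
  strand, categories covering all three disease lists and two overlaps)
  with a UTR–CDS–intron template; sites are laid out uniformly over gene
  bodies plus 2 kb flanks so every region class is populated. About half
  of all sites land in CDS.
- **Planting.** `deleterious_fraction` of sites (default 10%) become
  missense with scores passing all three thresholds; every other site fails
  at least one leg (non-deleterious missense draws a proper subset of
  passing predictors; non-missense sites carry only a CADD score, some
  above 15, which exercises the CADD-only Venn region). `lof_fraction`
  (2%) of sites get LoF consequences. Half the sites are ancestral-REF and
  half ancestral-ALT so polarization is exercised both ways.
  `private_site_fraction` per population (2%) get their derived allele
  zeroed outside the home population and at least one carrier inside.
  `clinvar_pathogenic_count` (5) sites get Pathogenic/Likely_pathogenic
  significance (one of them multi-term), with an equal number of
  benign/uncertain decoys.
- **Defaults.** Two populations × 50 diploids at F = 0.1 over 5000 sites —
  the reference conditions used by the end-to-end checks. The fractions
  above were chosen once as plausible magnitudes for an exome-style
  disease panel (enough planted signal that every code path is exercised,
  sparse enough that backgrounds dominate).
- **Determinism.** One RNG stream per file kind, all derived from the
  master seed, so changing one planting never perturbs another file; a
  fixed seed reproduces the bundle byte for byte.

Passing tests on these cohorts demonstrate the bookkeeping and estimators
are correct under the stated model; they do not demonstrate robustness to
LD, allele-frequency spectra shaped by demography, annotation errors, or
genotyping artifacts in real data.

## Numerical and degenerate-input conventions

- Allele frequencies with zero called chromosomes are NaN/undefined and
  flagged, never 0/0. Proportions with zero denominators are reported as
  undefined, not 0.
- The monomorphic flag means no variation cohort-wide (cohort AF 0 or 1);
  a fixed difference between populations is polymorphic.
- Downsampling draws without replacement from one seeded RNG, populations
  processed in declared order; at n_target = population size it reproduces
  the full-cohort statistics for any seed. Singletons are allele-count
  singletons (derived count exactly 1), the simpler and more common
  convention.
- Per-person load is cohort dSNV count ÷ sample size (the arithmetic the
  published tables use); it is not a genotype-weighted per-individual mean.
- Pipeline stages fail loudly with their stage name; outputs of completed
  stages are already on disk when a later stage aborts. Reruns with the
  same config and seed are byte-identical.

## Problem sizes

The default test suite runs in a few seconds: the shared reference cohort
is 2 × 20 samples × 800 sites, drift-recovery checks use 2 × 50 × 5000
sites per F value, and the end-to-end acceptance run uses the full
reference conditions (2 × 50 × 5000). These sizes were chosen as the
smallest at which the stochastic recovery targets (±0.02 on F) hold
comfortably.
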
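# Methods

This note documents the statistical model behind `clonalai`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions used throughout.

## The measurement model

Allelic counts for a gene in one technical replicate are modeled as
beta-binomial: given true allelic ratio `p` and total allelic reads `n`,
the maternal count has mean `np` and variance `np(1−p)(1+(n−1)ρ)`, where
`ρ` is the within-library intraclass correlation induced by library
preparation (duplicated fragments, amplification). `ρ = 0` recovers the
binomial. Totals per replicate are negative binomial with mean
`mean_gene_coverage` and variance `μ(1+αμ)` (`α = coverage_dispersion`;
`α = 0` is Poisson).

### The quality-control constant (QCC)

Two technical replicates of one library share the same cellular allelic
ratio, so the standardized replicate differences

    z_g = (AI₁ − AI₂) / sqrt(p̂(1−p̂)(1/n₁+1/n₂)),  p̂ pooled,

have unit variance under binomial sampling and variance `1+(n−1)ρ` under
the beta-binomial. The per-sample constant is

    QCC = sqrt( trim_mean(z², 10%) / κ ),  clipped to ≥ 1,

over genes with both replicate totals ≥ 10 and pooled AI strictly inside
(0, 1). The two-sided 10% trim makes the estimator robust to outlier genes
(residual allele-specific artifacts, mis-phased SNPs), but the trimmed mean
of the skewed chi-square(1) reference is 0.70, not 1; `κ` is that trimmed
reference mean, computed in closed form from `x·f_χ²(1)(x) = f_χ²(3)(x)`,
so the estimator is consistent under the null — the same logic as the
1.4826 constant that calibrates the MAD against the normal. Measured
accuracy: relative error vs `sqrt(1+(n−1)ρ)` is 1–5% for ρ ∈ {0.01, 0.05,
0.1} at 10,000 genes and coverage 100. Estimation uses autosomal genes
only: in a monoclonal female the X-linked ratios are nearly degenerate and
violate the normal approximation behind `z`.

All downstream binomial machinery runs on *effective counts*
`counts / QCC²`: Wilson confidence intervals, the one-sample test used in
escapee calling, and the two-sample differential-AI test.

### Differential AI test

The default test is the pooled two-proportion z-test on effective counts,
two-sided, with no continuity correction — a continuity correction on
effective totals (often < 30 after division by QCC²) is severely
conservative and would defeat the purpose of the calibration. When both
effective totals are integers ≤ 100 (in practice: QCC = 1 and modest
coverage) the implementation switches to an exact unconditional test that
enumerates all outcome pairs under the pooled plug-in null and sums the
probability of an AI difference at least as extreme. Degenerate pooled
ratios (both sides at the same extreme) return p = 1. No multiple-testing
correction is applied by default; callers may Bonferroni-adjust `alpha`.

Measured behavior: the corrected test rejects 4–5% of null genes at
α = 0.05 under matched overdispersion (ρ = 0.05, 10,000 genes, coverage
100), while the uncorrected test under ρ = 0.3 rejects ~75%.

## Abundance and filters

Abundance is trimmed-mean-of-M-values (TMM) normalized: reference library
by upper-quartile rule, 30%/5% two-sided trims on M and A, inverse
asymptotic-variance weights, factors rescaled to geometric mean 1.
Normalized counts are `count / (libsize·factor) × 10⁶` (a CPM-style unit);
the expression threshold "10 TMM-normalized counts" is interpreted on this
scale and both are configurable.

Filter boundary semantics are literal and deliberate:

| filter | rule | boundary |
|---|---|---|
| expression | keep if abundance ≥ 10 in all in-scope samples | 10 kept |
| nonrandom bias | remove if AI < 0.1 in ALL samples or > 0.9 in ALL | 0.1/0.9 kept |
| trans-deletion | as above with (0.25, 0.75), one experiment's samples | 0.25/0.75 kept |
| exome (LOH) | exclude study-wide if DNA total < 10 or DNA AI outside (0.25, 0.75) in any assayed sample | 0.25/0.75 kept |
| exome, immortalized-clone dialect | band (0.3, 0.7) | 0.3/0.7 kept |
| imprint screen | flag if expressed in all tissue samples and AI ≤ 0.15 in all or ≥ 0.85 in all | 0.15/0.85 flagged |

A gene missing an AI value in some in-scope sample can never satisfy an
"ALL samples" quantifier and is therefore not removable by the band rules
(logged). Genes without exome coverage are retained with a warning. All
filters are pure predicates, so the final retained set is order
independent.

## X-inactivation analysis

Contamination `c` per monoclonal sample is the recipient-marker read
fraction `recipient/(recipient+donor)` with a Wilson interval; at 10⁴
marker reads the mean absolute error is ~0.002 for `c` ∈ {0.01, 0.05,
0.10}. A sample's X profile is the median AI over X-linked genes (an
Xist-like inactive-X-expressed gene should be excluded via
`exclude_genes`; it is reported separately). Clonality is classified by
comparing the median with the mixture expectation `(1−c)·χ + c·q`
(χ ∈ {0,1}, `q` = control X AI, default tolerance 0.05); both a monoclonal
and a polyclonal fit within tolerance resolves to the nearer expectation,
neither resolves to "inconsistent" (mixed injection or leaky silencing).

Escapee calling per monoclonal sample uses the sample's own X-gene median
as the baseline — which implicitly absorbs contamination — requiring a
displacement of ≥ 0.1 toward 0.5 that is significant under the
QCC-corrected binomial test against the median (effective counts rounded
for the exact test). The explicit contamination correction is applied to
the inactive-X fraction magnitude instead:

    f = (f_obs − c·f_control) / (1 − c),  clipped to [0, 1],

with `f_obs` the Xi-side read fraction and `f_control` the Xi-side
fraction of the control median for that gene. A call requires support in
≥ 2 samples of one tissue or ≥ 1 B plus ≥ 1 T sample, balanced controls
(median within 0.5 ± 0.2), and mean corrected `f` ≥ 0.1. Whether the
displacement test should run against the median or against complete skew
is underdetermined; the median-null reading is the default because it is
the conservative one under contamination.

Allele labels are abstract throughout: "maternal" is simply the numerator
allele of the count tables, and the expressed-X label is inferred from the
data rather than trusted from metadata, so a reversed cross orientation
only relabels outputs.

## Stable-RME screen

Per gene, the sample standard deviation (n−1 denominator) of pooled AI is
computed across ≥ 3 monoclonal and ≥ 3 control samples of one tissue.
Flagging requires sd_mono ≥ 0.15 and sd_poly < 0.15 plus two prefilters:
significance in ≥ 1 pairwise comparison after QCC correction, and
expression in all samples (an unfiltered variant is always emitted
alongside). The 0.15 threshold is the screen's operating point, not a
fitted quantity. The flagged-set asymmetry is tested with an exact
one-sided paired signed-rank test of sd_mono > sd_poly (exact null for
n ≤ 25, normal approximation beyond; all-zero differences return p = 1).

Cross-lineage concordance correlates gene AI between B and T samples of
the same animal and, as a control, between deliberately mispaired animals
(cyclic shift), on the identical gene set. The loss-of-heterozygosity
bootstrap draws, per WES-assayed sample, `B` random same-size gene subsets
(without replacement within a subset) from the pool of expressed,
exome-covered autosomal genes and compares the flagged set's mean
`AI_DNA − AI_RNA` (and mean absolute difference) against that null with
the add-one tail rule `p = (1+#{null ≥ obs})/(B+1)`, so p is never 0 and
never below `1/(B+1)`. Null p-values are uniform by construction
(KS-checked in the tests); subset draws use random-key top-k selection in
memory-bounded chunks, so `B = 100,000` over a few-thousand-gene pool runs
in seconds.

AI PCA gene-centres the complete-case gene × sample matrix and uses SVD;
each loading vector is oriented so its largest-magnitude entry is
positive, making scores deterministic.

## The synthetic-study generator

`simulate_study` draws, from a single seeded stream: gene classes
(balanced / stable-RME / imprinted / allelic-loss on autosomes;
standard / escapee on the X), per-clone latent AI, RNA counts with
technical replicates (negative-binomial totals, beta-binomial allelic
draws), Poisson whole-exome counts for a 3-sample WES design, and Poisson
marker-locus counts. Defaults are the study conditions the analysis
assumes: ~8,000 autosomal and 500 X-linked informative genes; five
monoclonal animals (three assayed in B cells, two in both B and T), five
polyclonal plus one unmanipulated control; two technical replicates;
coverage 100 per replicate with dispersion α = 0.2; ρ_tech = 0.02
(QCC ≈ 1.7 at coverage 100); contamination cycling 1–7.5% across
monoclonal samples; control X AI q = 0.35 (an Xist-polymorphism-like
bias); escapee Xi fractions uniform on [0.15, 0.5]; stable-RME clone AI
drawn from {0.1, 0.5, 0.9}; imprinted genes fixed below 0.03 or above
0.97 in every sample; allelic losses shared by all samples (the
shared-deletion scenario) with DNA AI near 0 or 1. Contamination acts as
a linear mixture on AI, `(1−c)·AI_clone + c·AI_population`, i.e. equal
per-cell expression of donor and recipient cells. `rho_bio` (default 0)
adds truncated-normal between-sample jitter to autosomal AI; no published
value constrains it, so it is a free knob.

What the generator does **not** emulate: read-level artifacts (alignment
bias, phasing errors), SNP-density variation across genes, expression-level
heterogeneity beyond the negative binomial, correlated gene modules,
V(D)J repertoires, and partial-skew XCI in small polyclonal pools.
Passing tests therefore demonstrate the statistical machinery under the
declared noise model, not robustness to upstream artifacts — those are
assumed to be handled before the count tables enter the pipeline.

## Problem sizes used in the acceptance computations

QCC calibration and type-I: 10,000 genes, coverage 100 per replicate,
2 replicates; type-I averaged over 3 independent null pairs. Escapee
recovery: 500 X + 500 autosomal genes, 8 escapees, 3 monoclonal B + 2
monoclonal T samples, contamination ≤ 5%, coverage 100. Contamination:
10⁴ marker reads × 100 draws × c ∈ {0.01, 0.05, 0.10}. Stable-RME: 14
true genes among 8,000, five monoclonal + five polyclonal B samples,
coverage 150 (chosen from the power analysis above: per-sample AI noise
s.d. ≈ 0.058 gives expected false flags ≈ 0.15 per genome); null case
averaged over 3 seeds. Bootstrap calibration: 200 studies at B = 1,000,
pool 400, subsets of 14; one full-scale B = 100,000 run.

## Known limitations

- QCC is a single per-sample constant; coverage-dependent overdispersion
  is averaged over (a coverage-binned variant would slot into the same
  interface).
- The escapee support rule counts samples, not animals; replicate samples
  of one animal would double-count (the study design has one sample per
  animal-tissue).
- The exact differential test is unconditional with a plug-in null; it is
  mildly conservative, like all tests in this family.
- The SD rule cannot flag a stable-RME gene whose clone draws happen to
  coincide across the sampled animals; with five clones and three AI
  states this loses ~1% of true genes per screen.
- TMM abundance here is computed from total allelic counts; with real
  data, feature-level counts from the expression pipeline should be
  supplied instead.
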
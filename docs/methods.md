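# Methods

## Fine-mapping model

Loci are delineated per disease from genome-wide-significant variants
(p < 5×10⁻⁸, strict) after removing the MHC (default chr6:25–34 Mb, hg19
convention; configurable or disabled with `mhc="none"`). Merging is single
linkage on position with an inclusive 500 kb gap: consecutive significant
variants ≤ 500,000 bp apart share a locus. The lead variant is the smallest
p, ties broken by smaller position so results are order-independent.

Each locus is fine-mapped under the standard single-causal-variant
approximation. For a variant with estimated log-odds β and standard error s,
the approximate Bayes factor for association against the null under a
N(0, W) effect prior is

    ABF = sqrt(s² / (s² + W)) · exp( β² W / (2 s² (s² + W)) )

Posterior inclusion probabilities are the ABFs normalised over the locus
(computed on the log scale with a softmax, so arbitrarily large z-scores
cannot overflow). The 95% credible set adds variants in decreasing posterior
order until the cumulative posterior reaches the coverage target; posteriors
tied at the inclusion boundary (within 1e-12) are all included, so the set is
minimal up to ties.

`W` defaults to 0.04 (prior sd 0.2 on the log-odds scale, the common default
for binary traits) and is exposed everywhere as `prior_w`. When the effect
size distribution of the data is known — as it is for the synthetic
generator — matching `W` to the squared typical effect gives calibrated
coverage, and that is what the coverage validation uses.

## Synthetic data: what it emulates and what it does not

The generator produces every pipeline input with planted truth. Defaults
describe a seven-disease study: 35 loci per disease, ten candidate variants
per locus, 20,000 cases and 20,000 controls, causal log-odds 0.25,
African/European divergence FST = 0.1, and annotation coverage 0.334 at
enriched causal variants against a 0.2 background rate (OE ≈ 1.67, the scale
of open-chromatin enrichment such studies report).

Summary statistics: one causal variant per locus with effect β_c; each other
variant is an LD partner with correlation r ~ U(0.2, 0.95) and attenuated
true effect β_j = r_j β_c. Standard errors use the additive log-odds
approximation se = sqrt(1/(2 n_eff p(1−p))) with
n_eff = n_cases·n_controls/(n_cases+n_controls). Two modelling choices make
the attenuated-beta emulation internally consistent with how LD behaves in
real summary statistics:

- **Variants in a locus share one allele frequency** (drawn U(0.05, 0.95)
  per locus). Strongly correlated variants necessarily have similar
  frequencies; with independent per-variant frequencies, a beta-attenuated
  partner with a more common allele would carry a *larger* z-score than the
  causal variant, which cannot happen under real LD and destroys credible-set
  coverage.
- **Sampling noise is jointly one-factor**: noise_j = se_j (r_j η + √(1−r_j²) ε_j)
  with η shared across the locus, the standard sampling distribution of
  z-scores under LD with a single causal variant. Marginally each noise term
  is still Normal(0, se). With independent noise, a high-LD partner
  out-ranks the causal variant far too often (measured coverage ≈ 62% instead
  of ≈ 99% at the default settings).

The generator does **not** simulate haplotypes, realistic LD maps,
imputation error, multi-causal loci, or allele-frequency-dependent effect
sizes. Passing coverage and enrichment tests therefore demonstrate that the
statistics are correctly computed and calibrated under a well-specified
single-causal model — not that single-causal fine-mapping is adequate for
real multi-causal or mis-imputed loci.

Ancestry frequencies follow the Balding–Nichols model: each group frequency
is Beta(p(1−F)/F, (1−p)(1−F)/F)-distributed around the ancestral frequency p
with divergence F, clipped to [1/2N, 1−1/2N] (N = 5000) to avoid fixation.
The five constituent populations of each group scatter around the group
frequency with a small within-group FST (0.01); the reported group RAF is
their unweighted mean, matching the aggregation used in the analysis (a
sample-size-weighted mean is available).

Annotation tracks cover planted-enriched causal variants with the enriched
probability and every other position — non-causal variants and background
trait loci — at the null rate, using 200–1000 bp intervals placed uniformly
over the covering positions. eQTL target genes of AfrA-higher variants are
drawn preferentially (probability 0.7) from a planted 20-gene set,
producing a recoverable gene-set enrichment. The stimulation table plants
responder genes whose two group fold changes are 2^(1.25s) and 2^(0.75s) for
a gene-specific response scale s, so the group difference in log2 fold
change equals s/2 and is exactly proportional to the average response s —
the pattern the stimulation contrast is designed to detect.

## Enrichment statistics

A locus overlaps a track when **any** in-set credible variant does (the
membership rule is configurable down to variant-level counting). Points are
1-based, intervals 0-based half-open; the conversion happens once, in the
point query start < pos ≤ end. Background trait loci are points (best signal
per trait after 500 kb collapsing). The test is the one-sided upper-tail
exact binomial P(X ≥ observed | n loci, background rate) — enrichment only.
Raw p-values are reported across diseases and tracks; an optional
Benjamini–Hochberg column exists but is off by default. Degenerate
backgrounds (rate 0 or 1) are errors, not silently extreme results.

Using any-credible-variant membership makes the null slightly
anticonservative when credible sets hold several variants (the locus
coverage probability exceeds the per-point rate); at the default simulation
settings sets average ~1.05 variants and the measured null rejection rate at
0.05 stays below 0.05–0.07.

Cell-type specificity folds divide the reference cell type's overlap count
by each other cell type's count; zero denominators are excluded from the
arithmetic mean and flagged rather than reported as infinite.

## Ancestry GLM and gene sets

The higher-in-AfrA flag is a strict frequency comparison; exact ties are a
third category, excluded from the logistic regression (the outcome is coded
AfrA-higher = 1, EurA-higher = 0). Locus-level direction is the majority of
in-set variants (ties → tie); the locus-level GLM uses the same code path
and should be treated as experimental since locus-level outcomes are few.
The fit is maximum-likelihood logistic regression (statsmodels); constant
predictors and complete separation raise typed errors naming the term
instead of returning a huge odds ratio, and duplicate consistent flags
(diseases sharing a locus) collapse to one observation.

Gene-set enrichment is the one-sided Fisher exact test: p is the upper-tail
hypergeometric sum, the odds ratio is (a·d)/(b·c) with a Haldane–Anscombe
0.5 correction only when some cell is zero. Gene sets with ≥ 500 genes in
the universe are rejected (term-size filter, strict). Gene sets are flat
inputs; no ontology-hierarchy propagation is done.

## Expression analyses

The module score uses the binned-control scheme: genes are ranked by mean
expression and cut into 24 bins (rank-based so skew cannot empty bins); each
module gene contributes 100 control genes drawn from its bin excluding
module genes (with replacement when the bin is small; candidates are sorted
so the draw does not depend on matrix row order). The score per column is
mean(module) − mean(controls); an uninformative module scores ~0 by
construction. Group fold change is mean(a)/mean(b) on pseudocounted values
(pseudocount 1, recorded in output) with a two-sided Wilcoxon rank-sum
p-value.

The stimulation contrast computes per-gene per-donor
log2((stim+1)/(unstim+1)), calls genes induced when the geometric-mean fold
change is strictly above 1.5 and the Benjamini–Hochberg FDR of a paired
t-test on log2 values is ≤ 0.10, and correlates the between-group difference
of mean log2 fold change against the average across the induced genes
(Pearson; a raw-fold-change option exists). Fewer than three induced genes
makes the correlation undefined (NaN with a warning) rather than a
meaningless two-point value.

## Two-locus LD

All statistics derive from the marginals (p_a, p_b) and the observed
risk–risk haplotype frequency h_ab, validated against the Fréchet bounds.
D′ uses the sign-dependent maximum (min(p_a(1−p_b), (1−p_a)p_b) for D > 0;
min(p_a p_b, (1−p_a)(1−p_b)) for D < 0; D = 0 ⇒ D′ = 0). The feasibility
solver inverts a printed triple (h_theory, h_obs, r²) through the quadratic
t² − St + P with P = h_theory and S = 1 + P − D²/(r²P); a negative
discriminant, roots outside (0,1), or a Fréchet-violating h_obs return
"infeasible". r² = 0 is always infeasible-or-underdetermined and returns the
same. Published triples are printed at 3 decimals, so recovered marginals
carry that rounding (the worked triple recovers (0.374, 0.305); the values
printed alongside it round to (0.375, 0.304)). The association p-value a
genotype-panel LD lookup would report is out of scope: only the frequency
arithmetic, a count-table entry point, and exp(β) OR conversion are
implemented.

## Numerical and design choices

- Posterior normalisation is log-sum-exp; ABFs returned as floats may
  overflow to inf for extreme z, the log version never does.
- All readers reject malformed rows with line-numbered typed errors; no
  silent drops. Genome build is carried in a commented header and mixing
  builds is a hard error.
- The eQTL nominal filter is strict (p < 0.05); the genome-wide filter is
  strict (p < 5×10⁻⁸); the locus merge gap is inclusive (≤ 500,000);
  the induced-gene fold filter is strict (> 1.5) with inclusive FDR (≤ 0.10).
- The background catalogue is not p-value-filtered before collapsing by
  default (`p` is carried so a threshold can be applied upstream).
- The end-to-end run writes per-stage TSVs, `summary.json`, a config hash
  (excluding the output path) and is byte-identical under fixed inputs and
  seed. Validation problem sizes — 1000 loci for coverage, 500/200 seeds for
  calibration and power, 200 replicates for GLM recovery — were chosen as
  the smallest sizes at which the binomial/Monte-Carlo error of the checked
  proportion is well below the margin being asserted.

## Known limitations

- Single-causal credible sets only; no LD-aware multi-causal fine-mapping
  or conditional analysis.
- Enrichment is not LD-aware (no matched-SNP resampling); the background
  catalogue is the only null model.
- The generator's LD emulation is a one-factor approximation; it cannot
  produce multi-causal loci or realistic LD block structure.
- The locus-level ancestry GLM is implemented but statistically weak at
  realistic locus counts.
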
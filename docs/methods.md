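# Methods

## The annotation problem

Given a genes × samples count matrix and one designated target gene, the
package infers the target's functional context from co-expression alone.
Both routes assume bulk expression with enough samples for rank statistics
to be stable (hundreds, as in consortium tumor cohorts), and both consume
gene-set collections in GMT form; nothing here queries annotation databases.

## Normalization

Raw counts are scaled per sample by median-of-ratios size factors:
s_j = median over genes g of c_gj / geomean(c_g·), where only genes with
strictly positive counts in every sample enter the median (the geometric
mean of a gene with a zero is zero and its ratios are undefined or
degenerate). The median is taken in linear space, exactly as the formula
reads. The factors are then rescaled to unit geometric mean. That rescale is
this package's convention: it changes nothing proportional (relative library
sizes, every downstream rank statistic) but fixes the arbitrary overall
scale so that re-estimating factors on a normalized matrix returns exactly
1.0 per sample, which makes normalization idempotent and testable to
machine precision. Downstream analysis defaults to log2(x + 1); the
pseudocount is configurable (>0). Spearman correlation is rank-based and
thus indifferent to the log transform; the two-class GSEA metric is not,
which is why the log-normalized matrix is the documented default input for
it.

## Guilt by association

Spearman ρ between the target and every other gene uses average ranks for
ties, so results are invariant under strictly monotone transforms of any
gene. Zero-variance genes are excluded and reported; the target never scores
itself. Reported p-values use the t approximation with n−2 degrees of
freedom — they are for reporting only, since selection is by ρ. The selected
fraction is ceil(fraction · N) genes: ceiling, not rounding, is the
convention that makes 5% of 19,547 genes a selection of exactly 978. The
selection direction (`top`, `bottom`, `abs`) is explicit because a
suppressive relationship lives in the negative tail; the default is `top`.
ORA uses the hypergeometric upper tail within the universe of genes that
actually survived correlation (not the GMT union — sets are intersected with
that universe first), a [5, 500] set-size filter by default, and
Benjamini–Hochberg q-values across retained sets.

## Single-gene GSEA

The phenotype split sorts samples by target expression with ties broken by
sample id, making the split total and deterministic; high and low groups are
each ceil(q·n) samples, q ∈ (0, 0.5], default 0.10 — the decile convention
that gives 110 + 110 groups from 1,096 samples. The default ranking metric
is signal-to-noise with each group σ floored at max(σ, 0.2|μ|, 0.2)
(sample σ, ddof = 1); `log2_ratio` and `t_stat` are provided because the
split-and-rank construction does not dictate a metric. The weight exponent
on |r| defaults to 1.

The enrichment score is the first extremum (by |·|, ties to the earliest
position) of the weighted KS running sum; the leading edge is the set
members at or before the extremum for positive ES, strictly after it for
negative ES. The null is built by **gene-label permutation**: uniformly
random same-size gene subsets scored on the fixed ranking, 1,000 draws by
default. Phenotype permutation is deliberately not implemented — the method
is defined by its gene-label null, and with only one "phenotype" gene the
sample-label alternative would be a different method. NES divides ES by the
mean |ES| of same-sign null draws; nominal p is the same-sign tail fraction
with add-one smoothing ((1+k)/(1+B)), so a finite permutation count reports
p ≥ 1/(B+1) — never exactly zero. FWER is the smoothed fraction of draws
whose most extreme same-sign normalized null ES (max over all sets, aligned
by draw index) reaches |NES|. FDR q is the GSEA ratio of tails on the pooled
sign-specific normalized null, clipped to [0, 1] and made monotone by taking,
for each set, the minimum raw q among all sets at least as extreme (the BH
step-up shape, per sign).

Per-set permutation seeds are spawned from the master seed and a stable hash
of the set's sorted membership: adding, removing or renaming sets never
perturbs another set's null, and an identical set filed under two names
receives the identical null (hence identical ES, NES and nominal p; FWER and
FDR are collection-level quantities and legitimately shift when the
collection changes).

Numerical notes: running sums accumulate O(N) float error, so the extremum
is clipped to [−1, 1]; a set whose members all carry zero metric weight
falls back to equal hit weights; sets empty or universe-covering after
intersection with the ranked genes are rejected.

## Synthetic cohorts

The generator exists so the whole pipeline has ground truth. Counts are
negative binomial with variance μ + φμ² (φ = dispersion, default 0.2 — a
typical bulk RNA-seq order of magnitude). A standard-normal latent t_j plays
the target's activity per sample; the target's log-mean is a0 + a1·t_j
(a1 = 1), a planted gene's is base_g + β·t_j, a background gene's is base_g,
and every log-mean is offset by a lognormal library factor (log-sd 0.2).
Baselines are uniform on log-means [2, 6], covering low- to high-expressed
genes. The default cohort is 2,000 genes × 300 samples with one β = −0.8
and one β = +0.8 planted 50-gene set plus 20 decoy sets of 50 background
genes — desk-scale, but with the coupling strengths chosen so recovery is
decisive rather than marginal, mirroring a strong pathway association in a
large tumor cohort. Seeding fans a single seed out to per-component
`SeedSequence` children keyed by (seed, component, index), so enlarging the
gene panel leaves existing genes' draws untouched.

The paired clinical generator draws peritumor log expression N(5, 1) per
patient, adds a subtype-specific shift plus N(0, noise) for the tumor
tissue, allocates subtypes deterministically by largest remainder (default
proportions 19/23/31/25 per 98 — luminal A/luminal B/HER2-enriched/TNBC),
and draws exponential survival with the hazard multiplied by e^γ for the
below-median expression half (γ = 1 by default; baseline hazard
0.02/month ≈ 35-month median; uniform censoring on [0, 120] months).

What the simulations do **not** emulate: batch structure, tumor purity,
subtype-correlated expression programs, isoform effects, or realistic
gene–gene correlation beyond the single latent factor. Passing recovery and
calibration tests therefore shows the statistics behave correctly under
their own model assumptions — not that any particular biological finding on
real cohorts would replicate.

## Clinical statistics

Paired t-tests run on log-scale differences (tumor − peritumor), overall and
per subtype; zero-variance differences return p = NA with a warning rather
than an arbitrary number. Fraction downregulated counts strict tumor <
peritumor, ties conservatively not downregulated. Contingency tables use
Pearson chi-square without continuity correction, switching to the
two-sided Fisher exact test for 2×2 tables with any expected cell below 5.
Survival uses the Kaplan–Meier product-limit estimator and two-group
log-rank test with a median expression split by default (strictly above the
median is "high"); a quantile split is available. The xenograft volume
helper computes X·Y²/2 and sorts swapped axes with a warning.

## Problem sizes and defaults

The recovery and calibration suites run at the generator defaults
(2,000 × 300, B = 1,000 permutations, 20–100 seeds), which the vectorized
permutation scorer handles in a few seconds per cohort; these sizes were
chosen as the package's desk-scale study conditions, large enough that the
planted effects and null calibration are unambiguous. The constants carried
over from the study design this mirrors are: selection fraction 0.05,
phenotype quantile 0.10, and 1,000 gene-label permutations.

## Known limitations

- Gene ids are matched by exact string equality; no symbol/Ensembl mapping.
- FDR/FWER are per collection; running several GMT files pools nothing
  across them.
- Spearman p-values use the large-n t approximation, inaccurate below ~10
  samples (correlation itself requires ≥3).
- The permutation FWER is conservative for small B because of add-one
  smoothing (floor 1/(B+1)).
- No Cox regression, multivariable adjustment, or subtype classification;
  subtype labels are consumed as given.
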
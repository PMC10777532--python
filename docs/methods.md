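# Methods

This note documents the statistical models implemented in `coloclust`, the
numerical and design choices behind them, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Harmonization (`gwas_io`)

Coordinates are 1-based with closed region intervals `[start, end]`,
following summary-statistic convention.  A region is 500 kb on either side
of a lead variant (1 Mbp total); overlapping regions are processed
independently, and the lead/region table is treated as authoritative input
(how conditionally independent leads are grouped into loci is upstream of
this package).

Alleles are reconciled against the index trait by identity or swap only.
Strand flips (A/G recorded as T/C) are deliberately **not** attempted:
the variants for which strand actually matters — palindromic A/T and C/G
variants — cannot be resolved from allele labels at intermediate
frequencies, so the pipeline removes palindromic variants whose
minor-allele frequency lies strictly in (0.40, 0.60) and substitutes the
best LD proxy (r² > 0.80) when the removed variant anchored the region;
everything else is unambiguous under identity-or-swap.  Variants with
missing allele frequency are exempt from the palindromic test (logged) but
otherwise retained.  Harmonization orients every variant to the allele that
increases the index trait, so a positive z for any other trait always means
"the risk allele raises this trait"; the operation is idempotent and
invariant to allele-flip re-encodings of the input.

## Colocalization (`coloc`)

Per-variant association evidence is Wakefield's approximate Bayes factor
with prior effect variance `W` (default 0.04 on the standardized-beta
scale, per-trait configurable — binary traits may warrant a larger value).
Pairwise colocalization enumerates single-causal-variant configurations in
log space (log-sum-exp throughout) into PP.H0–H4 using priors
p1 = p2 = 1e-4, p12 = 1e-5 — the conventional defaults, config-exposed.
The colocalization lead is the variant with the largest per-variant H4
contribution.

The multi-trait test factorizes the decision into a regional posterior

    P_R = prod_t  pi1·S_t / (1 + pi1·S_t),     pi1 = p1 + p12,

with S_t the summed ABF of trait t over variants, and an alignment
posterior

    P_A = prior_c·C / (prior_c·C + prior_d·prod_t S_t),
    C   = sum_j prod_t ABF_tj,

with `prior_c = p12` (prior weight of each shared-variant configuration;
C sums over variants) and `prior_d = p1^T` (prior weight of a fully
independent T-trait configuration).  This is a deliberate, documented
simplification of branch-and-bound multi-trait colocalization: instead of
searching all trait subsets, traits are dropped greedily — each step
removes the trait whose removal most improves P_R·P_A (or, when only the
p-value gate fails, the trait with the weakest association at the candidate
variant) — until acceptance or two traits remain.  It is tractable,
reproduces the published decision rule (accept when P_R·P_A > 0.60 and the
candidate-variant p < 1e-5), and is validated by ≥ 95% decision concordance
with the pairwise enumeration at T = 2.

Two deliberate interpretations, both config-exposed:

* The p < 1e-5 gate is evaluated **at the candidate variant**, not
  region-wide, and must hold for **every** trait in the accepted set (the
  stricter reading of an ambiguous rule; `gate_all_traits=False` relaxes
  it to any-trait).
* The gate is applied to events from all three workflow stages (the
  published acceptance rule couples PP.H4 > 0.6 with the p-value gate for
  colocalized loci generally), not only to the multi-trait stage.

The staged workflow: single-signal regions take the multi-trait test
(stage A); multi-signal regions — and stage-A regions with P_R > 0.8 that
failed the joint threshold — are fine-mapped per trait with credible-set
pair colocalization against the index trait (stage B); when the index trait
yields no credible sets the pairwise single-causal-variant test is the
fallback (stage C).  Every non-emission is logged with its stage and
reason.

## Fine-mapping (`finemap`)

The sum-of-single-effects model runs on the z scale with unit standard
errors — sufficient for colocalization decisions, which never need effect
sizes in trait units.  Each of L effects (default L = 10) is updated
against residual z-scores `z − R·(sum of other effects)` via the Wakefield
ABF with prior variance `prior_w = 25` on the z² scale (effects detectable
at GWAS scale; the upstream literature leaves this unspecified, so it is
config-exposed), posterior shrinkage `W/(1+W)`, and softmax inclusion
probabilities.  Iteration stops when max |Δalpha| < 1e-4 or after 200
iterations; alpha rows are probability vectors at every iteration.  The
max |Δalpha| sequence is recorded (`delta_history`) as a convergence
diagnostic — in practice it is non-increasing over the final iterations in
≥ 95% of simulated fits, but this is logged, not guaranteed.

Credible sets take the smallest variant set with ≥ 95% cumulative alpha;
sets are discarded when their single-effect Bayes factor (log-mean ABF
relative to the null) does not exceed 1 or their purity (minimum absolute
LD among members) falls below 0.5, and duplicate sets from converged
surplus effects are merged.  Coverage 0.95 / purity 0.5 follow the
framework's conventions and are config-exposed.  The residual adjustment
uses the LD matrix exactly (no shrinkage); handling LD panels mismatched to
the GWAS sample is out of scope and a known limitation of this model class.

`coloc_susie` runs the pairwise enumeration on the per-effect log-ABF
vectors for every credible-set pair, one event per pair with PP.H4 > 0.6,
led by the index fit's highest-alpha member.

## Network clustering (`network`)

The variant × trait matrix holds z-scores (index-trait orientation) only
for trait associations that colocalized **and** pass the sample-size-aware
gate: p < 5e-8 when the trait GWAS has n > 60,000, p < 1e-5 otherwise;
everything else is exactly 0.  Traits significant but not colocalized at a
variant's region stay 0 — the matrix is a matrix of *colocalized*
associations.  Variant–variant Pearson correlations (zeros included as
values; zero-variance rows correlate 0, logged) define a weighted network.

The pruning cutoff is the highest threshold at which every vertex keeps at
least one edge, read literally as minimum degree ≥ 1 (a `require_connected`
switch implements the stricter connectivity reading).  Since a vertex keeps
an edge at cutoff c iff its largest |correlation| is ≥ c, the cutoff equals
the minimum over vertices of the per-row maximum; tests verify exact
agreement with an exhaustive scan.  Ties at the cutoff are kept (edges with
|corr| ≥ c).  Absolute correlation decides edge existence; surviving edges
keep their signed weight, and negative weights are clipped to 0 (removed)
for the spinglass null model, which requires non-negative weights.

Community detection minimizes the Reichardt–Bornholdt Hamiltonian
(configuration null model, resolution gamma = 1) by simulated annealing via
igraph — the same implementation practitioners use through R.  The number
of communities is emergent (up to 25 spins).  Twenty restarts with
consecutive seeds are run and the partition with the highest weighted
modularity Q = Σ_c [w_c/W − (d_c/2W)²] wins; modularity is computed by this
package and oracle-checked against networkx.  Disconnected graphs are
clustered per component with offset labels; components of ≤ 2 vertices are
assigned a single community directly (annealing is degenerate there — and
the igraph implementation can loop indefinitely on 2-vertex graphs).
Communities with fewer than 4 variants remain in the membership but are
excluded from the retained set, mirroring the practice of dropping
uninterpretable tiny clusters.

## Polygenic scores (`prs`)

A score is Σ (dosage × weight) over a cluster's variants, standardized to
mean 0 / SD 1 **within the analysed sample** (cross-cohort pooling is a
config option; the within-sample default matches scoring each cohort on its
own distribution).  Standardization makes every association invariant to a
global rescaling of the weights.  Missing dosages are mean-imputed (the
column mean estimates 2 × allele frequency), logged, rather than dropping
individuals.  Continuous outcomes: OLS with Wald CIs, estimates in outcome
SD units; binary outcomes: logistic regression reported as odds ratios.
Covariates default to age, sex, BMI and cohort, with BMI dropped when BMI
is the outcome; medication-use sensitivity analyses are represented as
extra binary covariates, not bespoke code.  Significance uses Bonferroni
alpha/m (0.05/6 = 0.008 for six scores; 0.05/3 = 0.017 for three).  The
tail contrast compares individuals at or above the 90th percentile of the
score against those at or below the 10th, requiring ≥ 30 per tail.

## Mendelian randomization (`mr`)

Fixed-effects IVW: weighted regression of outcome on exposure effects
through the origin, weights 1/se_out²; `multiplicative=True` inflates the
SE by residual dispersion (floored at 1).  Egger regression frees the
intercept after orienting all instruments to the exposure-increasing
allele; its SEs use residual dispersion floored at 1 and t-tests with k − 2
degrees of freedom, the conventional practice.  Steiger directionality
recovers per-variant r² from summary statistics via r² = z²/(z² + n − 2) —
exact for simple linear regression, which makes the two-sample setting
self-contained (no individual-level data needed) — sums r² over instruments
(simple summation; the aggregation rule is not standardized, so this choice
is flagged here), caps at 1 with a warning, Fisher-transforms, and tests
the difference.  Z > 0 infers exposure → outcome.  The effect-size Pearson
correlation is reported as a dose–response diagnostic.

Egger's slope is only meaningful when exposure-side measurement error is
negligible (the NOME assumption): with instruments estimated in a small
exposure GWAS the slope is diluted toward zero, which the recovery
experiments avoid by simulating a large exposure sample.

## Synthetic data (`synthetic`): what it emulates, and what it does not

Summary statistics are simulated directly at the sufficient-statistic
level: within a region with LD matrix R and non-centrality vector λ,
z ~ MVN(Rλ, R), β = z/√n, se = 1/√n.  This is the exact large-sample
distribution for a standardized trait and is orders of magnitude faster
than phenotype-level simulation.  LD is block-diagonal AR(1)
(r_ij = ρ^|i−j|, default ρ = 0.8).  It does **not** emulate real haplotype
structure, ancestry stratification, imputation error, sample overlap
between GWAS, or allele-frequency–dependent effect sizes; passing tests
demonstrate the pipeline's statistical machinery is correct and calibrated
under its stated model, not that real-data complications are handled.

The default scenario fixes the study conditions: 15 regions × 150 variants,
AR(1) ρ = 0.8, six traits whose sample sizes straddle the 60,000 gate
(74,124 / 250,000 / 210,000 / 62,000 / 55,000 / 48,000), index-trait
non-centrality 10 (GWAS leads are strong signals) and metabolic-trait
non-centrality ±8 per the planted cluster signatures, 5% palindromic
variants.  Three clusters are planted: adiposity-like (+bmi, +whr),
lipodystrophy-like (−bmi, +whr, +trig, −hdl) and glycemic (+fg), across
regions 0–9 (regions 8–9 carry two conditionally independent signals
each).  Regions 10 (distinct causal variants) and 11 (index-only) are
negative controls.

Regions 12–14 are colocalized **oddballs**: variants whose pleiotropy
profiles match no cluster and whose strongest profile correlations are
moderate and negative.  They are not padding — real pleiotropy networks
always contain such variants (they surface as the tiny communities that the
size filter drops), and they are what anchors the min-degree cutoff at a
realistic level (~0.5–0.7 here).  Without them, near-duplicate cluster
profiles push the cutoff to ~0.98 and the pruned graph shatters; a
cutoff-search rule defined as "the weakest vertex's best edge" is only
well-behaved when the network contains a range of profile similarities,
which is also why it worked on the real data it was designed for.  For the
same reason the z-matrix generator scales each planted entry by a
per-variant magnitude factor (uniform 0.8–1.2): loci differ in effect
size, and perfectly proportional profiles are not realistic.

Cohorts draw dosages Binomial(2, eaf); the continuous outcome is
`effect × standardized-true-score + covariate terms + N(0,1)`; binary
outcomes use a logistic link with the intercept fixed by the target
prevalence.  MR instrument sets are simulated with heterogeneous
per-variant explained variance (uniform shares, 0.2–1.8 relative weight) —
equal-magnitude instruments would leave Egger's intercept and slope nearly
collinear.

All generators are deterministic under a fixed seed, and scenario datasets
are byte-identical across runs.

## Problem sizes in the validation experiments

Calibration and recovery run at: 200 shared-signal + 200 null regions
(colocalization), 200 regions for multi-trait/pairwise concordance, 100
two-signal regions (fine-mapping), 100 random matrices/graphs (threshold
and modularity oracles), 20 seeds on the 30-variant cluster scenario, 50
cohorts of n = 20,000 (PRS), 500 × 50-instrument replicates (IVW) and
2 × 200 replicates (Steiger), plus one full pipeline run on the default
scenario.  These sizes give stable percentages while keeping the whole
validation suite around a minute on one CPU.

## Known limitations

* The multi-trait posterior is a greedy approximation; it can in principle
  drop a different trait subset than an exhaustive search would.
* No sample-overlap correction in colocalization or MR.
* Fine-mapping assumes the LD matrix matches the GWAS sample exactly.
* Hard clustering: a variant belongs to one cluster only; pleiotropic
  variants acting through several pathways are forced into one.
* PRSs use the input weights as-is (no LD-aware shrinkage or re-weighting).
* The min-degree cutoff rule is fragile on very small or near-duplicate
  networks (see the oddball discussion above); `require_connected` offers
  the stricter alternative reading.
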
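# coloclust

Colocalization-first partitioning of GWAS risk variants into pathway
clusters, with partitioned polygenic risk scores (PRSs) and
Mendelian-randomization (MR) directionality tests.

## The scientific problem

Complex diseases such as type 2 diabetes are driven by hundreds of risk
variants acting through heterogeneous biological pathways (adiposity,
insulin resistance, beta-cell function, hepatic metabolism, ...).  Grouping
risk variants by their pleiotropic effects on intermediary metabolic traits
can expose that heterogeneity — but naive grouping on marginal associations
is confounded by linkage disequilibrium (LD): two traits can be
"associated" at the same locus through entirely different causal variants.
`coloclust` implements a colocalization-first pipeline that only clusters
variant–trait relationships backed by evidence of a **shared causal
variant**:

1. **Harmonization** (`gwas_io`): per-region multi-trait summary-statistic
   panels, aligned to the disease risk-increasing allele, with ambiguous
   palindromic variants removed and leads proxy-substituted (r² > 0.8).
2. **Colocalization** (`coloc`, `finemap`): per variant *j* with effect
   estimate β̂ and variance *V* = se², evidence of association is Wakefield's
   approximate Bayes factor

       log ABF_j = ½ [ log(V/(V+W)) + z²·W/(V+W) ],   z = β̂/se,

   enumerated over single-causal-variant configurations into the posteriors
   PP.H0–PP.H4 for a trait pair (H4: both traits share one causal variant),
   or, multi-trait, into a regional × alignment posterior P_R·P_A.  A staged
   workflow mirrors practice: multi-trait screen for single-signal regions
   (accept when P_R·P_A > 0.60 and p < 1e-5), sum-of-single-effects
   fine-mapping (SuSiE-style, L effects, 95% credible sets with purity
   filters) plus credible-set-pair colocalization for multi-signal regions,
   and a single-causal-variant fallback when no credible sets emerge
   (accept when PP.H4 > 0.6).
3. **Network clustering** (`network`): a sparse variant × trait matrix of
   colocalized z-scores (gated at p < 5e-8 for GWAS with n > 60,000, p <
   1e-5 otherwise), Pearson-correlated across variants; edges below the
   highest cutoff at which every vertex keeps ≥ 1 edge are pruned; spinglass
   community detection (simulated annealing on the Reichardt–Bornholdt
   Hamiltonian) yields an emergent number of clusters scored by weighted
   modularity Q; clusters with < 4 variants are excluded.
4. **Partitioned PRSs** (`prs`): per-cluster dosage-weighted scores,
   standardized, tested against outcomes by OLS / logistic regression with
   covariate adjustment and Bonferroni correction (0.05/6 = 0.008 for six
   scores), plus a 90th-vs-10th percentile contrast.
5. **MR directionality** (`mr`): inverse-variance-weighted and Egger
   regression of outcome on exposure effects, and the Steiger *Z*-test
   comparing instrument r² on exposure vs outcome (r² = z²/(z²+n−2),
   Fisher-transformed) to infer causal direction.

Because the real inputs are consortium-scale GWAS downloads, the package
ships a first-class synthetic-data module (`synthetic`) that simulates
region z-scores from their large-sample distribution z ~ MVN(Rλ, R) with
planted shared/distinct causal variants, planted cluster signatures,
palindromic variants, and individual-level cohorts — every stage is
testable end to end without any download.

## Worked example

```bash
coloclust run-all --out demo/ --seed 1
```

simulates the default scenario (15 regions × 150 variants, 6 traits, 3
planted clusters plus oddball and negative-control regions) and runs every
stage.  It prints:

```
14 colocalization events
cutoff=0.628 k=5 Q=0.667 retained=[0, 3, 4]
overall -> y_cont: beta 0.285 (95% CI 0.271-0.299), p=0, n=20000 *
cluster0 -> y_cont: beta 0.148 (95% CI 0.134-0.163), p=5.85e-90, n=20000 *
...
-- cluster 0 vs whr --
MR report (4 instruments)
  IVW:    beta +0.4936 (se 0.0297), p=5.69e-62
  Egger:  beta +0.7910 (se 0.4060), p=0.191; intercept -0.0109, p=0.539
  Steiger: r2(g,x)=0.005386, r2(g,y)=0.001317, Z=+8.71, p=3.03e-18
  inferred direction: exposure->outcome
  effect-size correlation (Pearson r): 0.976
```

Reading this output: 13 of the 15 regions were planted with a causal
variant shared between the disease and at least one metabolic trait; the
workflow emitted events for 12 of them at this seed (two regions carry two
independent signals each, hence 14 events; one weak oddball region was
missed) and none for the two negative-control regions.  The correlation network pruned at cutoff 0.628 splits into k = 5
communities with modularity Q = 0.667; the three communities with ≥ 4
variants are retained — they are the three planted clusters, while the
oddball variants fall into small excluded communities.  Every retained
cluster's PRS is positively associated with the simulated outcome (the
planted direction), and the per-cluster MR recovers a positive causal slope
with a Steiger Z > 0, i.e. the instruments explain more variance in the
exposure than in the outcome, as planted.  Tabular outputs
(`coloc_events.tsv`, `zmatrix.tsv`, `clusters.tsv`, `signatures.tsv`,
`prs_assoc.tsv`, `mr.tsv`) land in `demo/`.

Library use follows the same shape, statsmodels-style, e.g.:

```python
from coloclust import SusieRSS, MRModel, simulate_ld
fit = SusieRSS(z, ld, L=10).fit()        # -> SusieFit with credible_sets, summary()
report = MRModel(instruments).fit()      # -> MRReport with ivw/egger/steiger, summary()
```

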
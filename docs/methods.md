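# Methods

`vigimech` re-implements, as a tested library, an analysis chain for
pregnancy pharmacovigilance reports of antiviral drugs: from a deduplicated
individual-case-safety-report (ICSR) table to harmonised ADR phenotypes,
drug–phenotype disproportionality, co-medication network robustness, a
seriousness regression, drug- and regimen-level prioritisation scores, and
exposure–liability plausibility checks.  Because public line-listing
extracts cannot be redistributed, the package ships a synthetic cohort
generator with a recorded ground truth; every statistical claim the test
suite makes is a parameter-recovery or oracle-equivalence statement against
that ground truth, not a re-analysis of real reports.

## Case model and expansion

A case is one deduplicated ICSR: suspect actives (reporter-designated causal
candidates), concomitant actives, reaction terms, a regulatory seriousness
flag (OR-combined when a case id spans several export rows), sex,
follow-up/literature flags, and a raw phenotype cluster label inherited from
an upstream reaction co-occurrence clustering (labels are inputs here and
never re-estimated).  Polypharmacy burden is the number of unique actives
(suspect ∪ concomitant).  Mechanistic linkage uses the structurally expanded
table — one row per (case, suspect drug, reaction) — while every
inference-sensitive analysis (seriousness proportions, regressions,
enrichment counts) stays at the one-row-per-case level to avoid
pseudo-replication.  Concomitants contribute to polypharmacy and the
network but are never treated as mechanistic drivers.

Multi-drug regimens are reduced to a primary active by the class hierarchy
INSTI > PI > NNRTI > NRTI > RdRp; drugs outside these classes rank last, and
ties within the winning class break lexicographically so the assignment is
deterministic and order-invariant.

## Phenotype harmonisation and signatures

Raw cluster labels whose case frequency falls below 2% (configurable)
collapse into a single "Other" phenotype.  Per harmonised phenotype the
package reports the serious fraction (flagged unstable below 5 cases), and
an ADMET signature: the median of each continuous ADMET feature over
expanded records, standardised across phenotypes within feature.  The
standardisation uses the sample (n−1) standard deviation of the (at most
five) phenotype medians; constant features are reported as z = 0 with a
flag.  Global phenotype differences are tested feature-wise with
tie-corrected Kruskal–Wallis statistics at the expanded-record level and
Benjamini–Hochberg correction across the feature panel; the record-level
unit of analysis is an interpretation (the source analyses report
record-scale significance) and is stated as such.

The share of composite-ADMET-risk variance attributable to phenotype
membership is the one-way random-effects intraclass correlation
ICC(1) = (MSB − MSW) / (MSB + (k₀ − 1)·MSW) with the unbalanced-design
group-size constant k₀ = (N − Σnᵢ²/N)/(k − 1), truncated at zero.  The unit
of analysis is the expanded record carrying its case's primary drug's
composite ADMET risk — the only level where phenotype membership and the
drug-level feature coexist; this too is a documented interpretation.
Reaction-class concordance (e.g. hepatobiliary terms vs the transporter
phenotype) is a case-level 2×2 odds ratio with Haldane–Anscombe 0.5
correction on zero cells and a Woolf log-normal 95% CI; the hepatobiliary
term list ships as a configurable default.

## Disproportionality

For every drug × phenotype pair a case-level 2×2 table yields the reporting
odds ratio (ad/bc), a Woolf CI (Haldane–Anscombe 0.5 on all four cells iff
any cell is zero; the correction never touches the exact test), a two-sided
Fisher exact p (scipy; verified against exhaustive hypergeometric
enumeration for all tables with N ≤ 12), and an observed/expected ratio
a / [(a+b)(a+c)/N].  q-values are Benjamini–Hochberg step-up with
monotonicity (statsmodels behind the package surface, verified against a
hand step-up oracle); an association is called enriched iff q < 0.05 and
ROR > 1.  The attribution sensitivity analysis recomputes the panel
crediting each case to all suspect drugs instead of the primary one and
reports per-phenotype Jaccard overlap of the top-10 drugs ranked by O/E
ratio (ties broken by q, then name).

## Co-medication network

Nodes are actives; an undirected edge joins actives co-reported in at least
one case, weighted by the co-reporting count.  Degree and betweenness
(normalised by 2/((n−1)(n−2))) are computed on the unweighted simple graph;
weights are retained as edge metadata only.  The robustness simulation
removes nodes either targeted — the current highest-degree node, degree
recomputed after every deletion, ties broken uniformly at random per
replicate so replicate variance is preserved — or uniformly at random, and
records at each depth the fraction of original edges removed and the
modularity of the best greedy agglomerative (CNM) partition of the remaining
graph (igraph's fast-greedy implementation; cross-checked in tests against
networkx's modularity score for the same style of partition).  Means and
percentile 95% intervals are taken over replicates (default 1200 per
strategy; the source figure does not say whether its 1200 are per strategy
or total, so per-strategy is the default and configurable).

## Seriousness regression

A maximum-likelihood logistic model of the seriousness flag on
`poly_actives_total`, one row per case, with Wald 95% CIs (matching the
tight symmetric intervals such models report) and an optional HC1 robust
covariance that leaves point estimates unchanged.  Perfect separation and
single-class outcomes raise a diagnostic error.  `compound_or(r, k) = r^k`
converts the per-active odds ratio into a cumulative multiplier (1.03⁵ ≈
1.16, 1.03¹⁰ ≈ 1.34).  The sensitivity refit restricts to female,
non-follow-up, non-literature reports and reports the retained fraction.

## Mechanistic vulnerability index

Per drug, with 25 drugs in the default catalog:

1. burden proxy: `adr_composite = total_reports × n_clusters`, where
   `total_reports` counts cases reporting the drug as suspect (the expanded
   row count is also reported, since the two denominators differ) and
   `n_clusters` is its phenotypic breadth;
2. high-burden label: `adr_composite ≥ Q0.75`, the upper quartile computed
   with linear-interpolation (type-7) quantiles — the most common default,
   stated explicitly because the labelled count at the boundary depends on
   it;
3. a random-forest (scikit-learn, 500 trees, fixed seed) out-of-bag
   probability of the high-burden label from drug-level aggregates
   (polypharmacy, centralities, serious fraction, continuous ADMET features
   and liability flags), with column-wise median imputation.  The label
   constituents `total_reports` and `n_clusters` are excluded by default to
   avoid leakage; the inclusive variant sits behind a flag;
4. composite: `0.60·P̂ + 0.15·z(poly) + 0.15·z(net) + 0.10·z(sev)`, where
   z(poly) standardises the mean per-report active count across drugs,
   z(net) averages z(degree) and z(betweenness), and z(sev) standardises
   the drug-level serious-report fraction (the component aggregates are
   package conventions — the weighted form names its components but not
   their construction);
5. percentile: `MVI = 100·(rank−1)/(n−1)` with average ranks on ties.  This
   convention is the unique one consistent with a printed top-three of
   100.0 / 95.8 / 91.7 over 25 tie-free drugs (spacing 100/24 ≈ 4.17); a
   single drug is defined as 100.0 with a flag.

Diagnostics: 70/30 stratified hold-out AUC, leave-one-drug-out AUC,
out-of-bag error, bootstrap (B = 500) percentile intervals on the predicted
probabilities with importance coefficients of variation, Spearman/Kendall
rank stability of the percentile MVI under an alternative weight set, and
variance inflation factors across the four composite components.  Each
diagnostic draws its own sub-seed from the master seed.

## Regimen prioritisation (DPS)

For each observed multi-drug suspect regimen: MOS = fraction of liability
axes flagged in ≥ 2 members; NAS = percent rank, within the evaluated
regimen universe, of the summed member degree; SVS = mean member MVI/100;
DPS = (MOS + NAS + SVS)/3, tiered at ≥ 0.75 (high) and ≥ 0.50 (moderate).
The component formulas are declared package conventions (the source names
the three components but not their arithmetic) and are config-overridable.
Tiering also supports a percentile mode; the two modes are both provided
because a fixed-percentile rule cannot yield zero regimens above the lowest
tier, which the absolute rule can — the source reports percentile-based
thresholds together with an all-low outcome, an inconsistency this package
documents rather than resolves.

## Exposure–liability Monte Carlo

For each drug × pregnancy stage × metric with literature-style bounds,
exposure is drawn uniformly on [min, max] (fixed at the central value when
bounds are absent; stages are never pooled), AUC0–24 is averaged to
Cavg24 = AUC/24, concentrations convert to µM as c·1000/MW, and the ratio
to a potency threshold (BSEP IC50, CYP Ki; µM) is summarised by its median,
2.5/97.5 percentiles, and strict exceedance probabilities P(ratio > 1) and
P(ratio > 10).  n = 10 000 samples per ratio by default (no sample size is
prescribed by the source); the uniform sampler is validated against the
closed form P = clamp((b−T)/(b−a), 0, 1) within three binomial standard
errors.  These are IVIVE-style plausibility margins, not PBPK predictions.

## Embedding

Drug-level features are z-scored with sample (n−1) scaling (constant
features dropped with a log entry) and decomposed by SVD.  Components are
ordered by variance; each component's sign is fixed so its
largest-magnitude loading is positive, making repeated runs bit-identical.
Two feature sets ship — the mixed system+mechanistic set (polypharmacy,
degree, betweenness, reports, breadth, four continuous ADMET features) and a
continuous-ADMET-only set — because the source describes both without
privileging one; neither is treated as canonical.  Leave-one-drug-out refits
report the Pearson correlation of each component's loadings with the
full-data loadings after sign alignment; rank-collapsed refits are flagged
and excluded.

## Synthetic cohort generator

The generator's defaults are the study conditions the tests assume:

- cohort size 1938; 25 antiviral actives in six classes plus 150 generic
  concomitant actives and the two boosters (ritonavir, cobicistat; present
  in 23.6% of cases);
- polypharmacy: 5 + NegBin(r = 0.35, µ = 18.4), which reproduces median 11
  and IQR 6–27 exactly (scipy quantile check), clipped at 40 actives.  The
  clip leaves a visible probability mass at the cap — the plain negative
  binomial tail implied by those quartiles is heavier than any plausible
  regimen — and is the price of keeping the binary co-occurrence graph
  sparse;
- seriousness: Bernoulli(logit⁻¹(0.9 + ln(1.05)·n_actives)) — a true
  per-active odds ratio of 1.05 with a marginal serious fraction near 0.82;
- raw phenotype labels with one dominant cluster (C1, 46%) and three
  clusters (1.2%, 1.0%, 0.8%) deliberately below the 2% harmonisation
  threshold so the collapse into "Other" is always exercised and exactly
  five harmonised phenotypes emerge;
- suspects: 1–3 antivirals per case, drawn with an 8-fold preference for
  drugs affiliated with the case's phenotype.  Drug–phenotype affiliations
  use a deterministic largest-remainder allocation so every phenotype keeps
  a stable affiliated-drug count; the 8-fold affinity makes roughly 70% of
  a phenotype's expanded records come from its own drugs, which is what
  lets median-based signatures recover planted shifts of ≥ 2 sd in sign;
- concomitants: drawn from phenotype-linked "regimen communities" arranged
  on a ring (weights 1 / 0.3 / 0.1 for the own and two adjacent
  communities, Zipf-decaying popularity within a community), plus the five
  globally shared hub antivirals at weight `hub_strength` (default 8) and
  the boosters.  Non-hub antivirals appear only as suspects.  This
  community-plus-hub construction is what produces a sparse, modular,
  hub-dominated co-occurrence graph; an unstructured sampler saturates into
  a complete graph at cohort scale, where degree is constant and the
  robustness contrast disappears;
- ADMET features: baseline mean + (planted phenotype shift + N(0,1) noise)
  × baseline sd per drug, with a configurable missing fraction (default
  10%) to exercise median imputation; binary liability flags Bernoulli(0.3);
- PK bounds: per drug × stage lognormal central values with min/max at
  0.6×/1.6×; potencies lognormal in µM.  All values are synthetic — the
  published stage-specific exposure bounds live in a supplementary appendix
  that is not redistributable, so the two published exceedance
  probabilities can only be recomputed when a user supplies that table
  (`data/supplementary_pk.csv`), and the corresponding check skips with an
  explanatory message otherwise.

All randomness descends from one seed through spawned generators; fixed
seeds give byte-identical tables.

What the generator does not emulate: MedDRA term hierarchies, real drug
identities, reporting-date structure, duplicate submissions, missing
seriousness, correlated ADMET features, or trimester physiology.  Passing
recovery tests therefore demonstrate that the pipeline's estimators are
correct and well-calibrated under the stated generative model — not that
real EudraVigilance extracts would yield the published point estimates,
which depend on the proprietary data.

## Numerical choices and degenerate inputs

Haldane–Anscombe 0.5 on all four cells only when a zero cell exists; BH
with explicit NaN exclusion; ICC truncated at 0 and defined 0 (flagged) for
constant data; percentile transform defined 100.0 (flagged) for a single
drug; modularity of an edgeless graph defined 0; betweenness defined 0 for
graphs with fewer than three nodes; z-scores of constant vectors defined 0;
rank-deficient PCA truncated and flagged; exceedance uses strict `>`;
degenerate exposure bounds (min = max or central-only) sample a constant.

## Problem sizes in the test suite

The suite exercises the estimators at sizes chosen for statistical
resolution: OR recovery over 200 cohorts of n = 2000; Fisher enumeration
over all 2×2 tables with N ≤ 12; robustness at 1200 replicates per strategy
on a ~50-node hub-dominated graph; signature sign recovery over 40 seeds;
ICC recovery averaged over 20 replicate simulations of 50 × 20 observations
(a single draw carries ≈ 0.04 estimator noise, so the ±0.05 recovery band
is asserted on the replicate mean); null FDR calibration over 200
independent panels.

## Known limitations

Drug-level analyses treat 25 drugs as the population; all z-scores and
percentiles are relative to that set.  The random-forest component is a
ranking heuristic, not a calibrated classifier (OOB and hold-out AUCs on 25
drugs are noisy by construction).  MOS/NAS/SVS arithmetic is a declared
convention.  The exposure engine ignores protein binding, fraction unbound
and any covariate structure.  Nothing here estimates causal effects or
clinical risk; outputs are prioritisation aids.
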
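# Methods

`allerules` reimplements, as a tested pipeline, a combined feature-selection
and rule-based-modelling analysis of how genetic variants, environmental
exposures and lifestyle factors act together in childhood allergic disease.
The real BAMSE and PARSIFAL cohort data are not public; a synthetic
two-cohort generator with the same statistical shape stands in for them, so
every stage of the pipeline is testable end to end.

## Data model

All stages operate on *decision tables*: children in rows, categorical
condition attributes in columns, plus one binary decision
(`affected`/`unaffected`). SNP genotypes are coded as the number of copies of
the cohort's major allele (0/1/2; ties in allele frequency resolve to the
reference allele). Children outside a phenotype's reference group are marked
`EXCLUDED`: they are kept in files but take part in no computation. Missing
values (`NA` in TSV) never match a rule condition and never discern two
objects — a deliberately conservative convention that keeps rule semantics
monotone under missingness.

## Phenotype derivation

Eleven phenotypes are derived from six raw health ingredients (doctor's
asthma/eczema diagnoses, wheeze and rhinitis symptoms in the last 12 months,
inhalant and food allergen-specific IgE). Atopic sensitization is IgE >= 0.35
kU/L against inhalant and/or food allergens, with a strict >= 3.5 kU/L
variant. The allergic/non-allergic subtypes of asthma and eczema share one
*restricted* reference group: children with neither the disease nor
sensitization; everyone else is excluded from that phenotype. For current
asthma (asthma plus recent wheeze) the reference is all non-asthmatics and
asthmatics without recent wheeze are excluded; this choice is configurable
since the source definitions leave it open. A missing ingredient excludes
the record from every phenotype that needs it. Age windows of the original
questionnaires are not modelled — the synthetic cohorts have no time axis, so
a single "ever" flag stands in.

## Synthetic cohort generator

The generator emulates the published study shapes: cohort A with 2033
children and 110 SNPs plus a subset of exposures, cohort B with 3113
children, 188 SNPs (the 110 shared ones identical in frequency and effects)
and 33 environmental/lifestyle factors.

* **Genotypes** are Hardy–Weinberg draws per SNP (major-allele count =
  Binomial(2, p)); no linkage disequilibrium or population structure.
* **Exposures** are independent categorical draws, except a "farm lifestyle"
  cluster (farm living, farm milk, animal contact, maternal farm work) whose
  binary members share a latent Bernoulli variable that raises their
  concordance while preserving each marginal. The cluster construct is a
  generator invention (the joint exposure distribution of the real studies
  is unknown) and is flagged in the output manifest.
* **Raw health ingredients** follow logistic models. Planted effects are
  multiplicative on the odds: an effect matches a child when *all* its
  conditions hold, and matching effects add their log odds ratios. The
  intercept of each ingredient is calibrated by root finding so the realized
  marginal prevalence equals the configured baseline (published-cohort-like
  values, e.g. 15% asthma in cohort A) even with effects present; with no
  effects it
  reduces exactly to logit(baseline).
* **IgE values** come from a two-component log-normal mixture, ln N(-2,
  0.5^2) and ln N(1.5, 1^2), each draw conditioned on the 0.35 kU/L threshold
  so that derived sensitization reproduces the sensitization ingredient
  exactly; only the 0.35 and 3.5 kU/L thresholds matter downstream, the
  magnitudes are cosmetic.

The default scenario plants two headline-like interactions, identical in
both cohorts:

* a **2-SNP risk-genotype combination** (both homozygous major, allele
  frequency 0.74) on the asthma and wheeze ingredients, so the derived
  current-asthma phenotype carries it. Each SNP also has a main effect of
  OR 1.6 — the loci the finding imitates are established susceptibility
  genes with marginal associations, and a detectable scenario requires them:
  a purely epistatic pair of this size is statistically invisible to *any*
  valid family-wise selection at these cohort sizes. The joint-cell odds
  multiplier is solved numerically so that the planted rule's **crude** odds
  ratio (children fulfilling both conditions versus all others) is exactly
  3.2 in cohort A;
* a **formula-feeding x early-antibiotics** pair with crude OR 7.0 on asthma
  in cohort B, solved the same way. The two solves are coupled (each
  effect's presence attenuates the other rule's crude OR, so the multipliers
  are found by alternating root finds over the genotype x exposure cells).

All randomness flows from one master seed through named substreams
(blake2s-hashed stream names feeding `numpy` `SeedSequence` spawn keys), so
each stage is independently reproducible.

What passing tests on this generator do **not** show: robustness to linkage
disequilibrium, correlated exposures beyond the single cluster, covariate
confounding (country, sex), genotyping error, or informative missingness.
The generator's missingness is completely at random at 2% per attribute.

## Monte Carlo feature selection

Attributes are ranked by relative importance over an ensemble of decision
trees. Each of `s` projections draws `m` attributes (default ceil(sqrt(d)));
each of `t` splits per projection grows a greedy information-gain tree on a
stratified 66% train fraction and scores it on the rest. For attribute g

    RI_g = sum over trees [ wAcc^u * sum over nodes splitting on g
                            IG(node) * (n_node / n_tree)^v ]

with u = v = 1 by default; wAcc is the mean of per-class recalls on the
tree's test split (trees with an empty test class are skipped). Trees split
multiway on all categories, break IG ties lexicographically by attribute
name, and send missing values to the majority child. The default depth cap
is 2: the analyses target main effects and pairwise interplay, one
conditioning level captures a two-way interaction, and every deeper level
adds small-sample noise nodes whose IG contributions accumulate in RI and
measurably destroy the separation between informative and noise attributes.

Object and attribute order never affect the result (objects and columns are
sorted internally), and the projection substreams are indexed so that a run
with `s` projections equals the sum of single-projection runs.

**Significance.** The whole ensemble is re-run B times (default 50) on
label-permuted tables. Each attribute gets a smooth descriptive p-value from
a Gaussian fit to its B null RIs, evaluated through the fit's Student-t
predictive distribution (df = B-1, scale inflated by sqrt(1+1/B)) — honest
about B being finite, but still a parametric approximation. The *selection*
does not rely on it: an attribute is significant when its observed RI beats
the global maximum null RI of the permutation runs (single-step max-null
adjustment, p_adj = (1 + #{runs whose max >= RI_obs}) / (B+1)). Under the
global null the observed run is exchangeable with the permuted runs, so this
controls the family-wise error rate at 1/(B+1) <= alpha exactly, whatever
the shape of the RI null. The RI null is strongly right-skewed (RI grows
roughly quadratically in a chance association), and plug-in Gaussian tails
at family-wise quantiles are off by orders of magnitude — simulated noise
tables put their family-wise error near 1 — which is why the permutation
max is the decision rule. B must be at least 1/alpha - 1 for any discovery
to be possible (B >= 20 at alpha = 0.05).

The randomization validation mirrors the published sanity check: the
selection is re-run on column-permuted data alone and on original + permuted
data combined, counting significant original and randomized factors.

## Rule induction

Rules come from rough-set *object-related reducts*: for a training object,
each opposite-class object contributes a discernibility clause (the
attributes where both values are known and differ), and a Johnson greedy
set-cover of the clauses yields the reduct; the object's values on the
reduct attributes form the rule's IF-side, its class the THEN-side.
Duplicate rules merge. Three defaults adapt the classical machinery to
case-control cohort tables:

* **Boundary-region semantics** (default): indiscernible opposite-class
  pairs drop out of the clause set instead of invalidating the object, so
  heavily inconsistent tables (few attributes, thousands of children) yield
  rules with accuracy < 1 rather than no rules. `inconsistent="skip"`
  restores the strict behaviour; `johnson_reduct` itself always refuses an
  empty clause.
* **Approximate covers**: the greedy stops once 90% of the clause weight is
  covered (`cover_fraction`), in the style of ROSETTA's approximate
  reducers. This is what produces the short, high-support, readable rules
  the analysis is about; exact covers on cohort tables give long
  object-specific rules of support ~1.
* **Class balancing**: induction (not statistics) runs on a seeded
  undersample of the majority class. On 8–15%-prevalence phenotypes this
  keeps affected-rule accuracies on the same scale as unaffected-rule
  accuracies and yields cross-validated model accuracies in the 50–65%
  range; rule filters default to min_support 5 and min_accuracy 0.6 on the
  balanced table.

Classification is voting: rules whose IF-side an object satisfies vote their
support; ties go to the larger class prior; objects matched by no rule
ABSTAIN. Model quality is stratified 10-fold cross-validation: *coverage* is
the fraction of held-out objects some rule fires on, *accuracy* the fraction
correct among those.

## Rule statistics

Every rule is scored on the full (unbalanced) cohort by an exact upper-tail
hypergeometric test — out of N classified children, K in the rule's class, n
matching the IF-side, the probability of k or more matches in the class —
Bonferroni-corrected within the rule family of its model. Effect sizes are
crude odds ratios for fulfilling all rule conditions versus all other
children; children missing a value on any condition attribute are excluded
from the 2x2 rather than counted unexposed. The default estimator is a
single-predictor logistic fit (Wald 95% CI); empty cells or non-convergence
fall back to the Haldane–Anscombe-corrected Woolf interval (flagged). z =
1.96 throughout.

Cross-cohort validation is direction-only, as in the original analyses: an
affected-rule replicates when its odds ratio in the other cohort exceeds 1,
an unaffected-rule when it is below 1; a rule is validatable only if every
condition's attribute and category exist in the other cohort. Dose-response
stratifies children by the number of fulfilled conditions and estimates each
level's OR against the zero-condition reference.

## Rule networks

For one phenotype and decision class, conditions become nodes and two
conditions are linked when they co-occur in at least one rule. Edge weight
is the summed support of contributing rules ("correctly classified
children"); the edge score is the best contributing rule's -log10
Bonferroni-adjusted hypergeometric p, binned into tertiles (no standard
definition of a chord-diagram rule-quality score exists, so the score
function is pluggable). Rendering is deterministic: nodes on a circle
sorted by display code, chord width proportional to weight, tertile colors
from red (high) to grey (low). Exports: GraphML, JSON (lossless round-trip)
and edge TSV.

## Pipeline designs

* **Gene–gene**: per phenotype and per cohort, the chain feature selection →
  rule induction on the significant attributes → cross-validation → rule
  statistics runs on the shared SNPs (22 models for 11 phenotypes); the
  Bonferroni-significant rules are validated by direction in the other
  cohort.
* **Gene–environment**: the same chain on one cohort's full genetic +
  exposure data (11 models); every rule whose factors exist in the other
  cohort is validated there.
* Transcriptions of the two published per-phenotype summary tables ship as
  package data; `summary_report` reproduces their printed per-column
  averages (e.g. 51.0 rules, 55.4% accuracy, 11.1 factors; 132/143 = 92.3%
  validated) by plain arithmetic on the rows.

## Evaluation experiments and problem sizes

`allerules.experiments` contains the package's own evaluation studies, also
used by `scripts/acceptance.py`:

* `mcfs_null_fwer`: family-wise false-positive rate of the selection on
  fresh pure-noise tables (n = 2000, d = 220, 1000 trees, B = 20). The
  per-seed rate is 1/21 by construction; the test suite estimates it over
  40 seeds because a 20-seed estimate of a 0.048 rate is itself noisy.
* `noise_cv_accuracy`: cross-validated rule-model accuracy on
  non-informative tables (n = 500, d = 10) — sits at chance.
* `recovery_study`: per seed, a fresh default cohort pair; the gene arm
  analyzes the shared SNPs of cohort A (ensemble 1400 trees, B = 40) and
  validates in cohort B, the environment arm analyzes cohort B's full data
  (600 trees, B = 40) and validates in cohort A. Checks per arm: both
  planted factors selected; a Bonferroni-significant induced rule containing
  both; the planted rule's crude-OR CI covering its generating value;
  same-direction replication; increasing dose-response. B = 40 lets the
  detection tolerate one spiking permutation run ((1+1)/41 < 0.05), which
  B = 20 cannot.

## Known limitations

* The feature-selection significance floor is 1/(B+1); resolving p-values
  near the printed per-factor threshold 2.3e-4 would need B in the
  thousands. The descriptive Gaussian-fit p is reported for ranking only.
* Reducts are greedy approximations; on random 8-attribute tables the
  Johnson reduct equals a brute-force minimal reduct most of the time
  (~80-95% in the test suite) and always covers the clauses.
* Crude odds ratios are unadjusted (no country/sex covariates); subgroup
  analyses are possible only by pre-stratifying the table.
* The generator is intentionally simple; see the generator section for what
  it does not emulate.
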
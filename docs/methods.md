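# Methods

## The individual set-unique burden

`isub` measures the rare-variant load of a case–control cohort without a
frequency threshold.  For a given phenotype labelling, a variant is
**case set-unique** if at least one case carries its minor allele and no
control does, and **control set-unique** symmetrically ("carrier" means
minor-allele dosage ≥ 1; missing genotypes never count as carriage, a
deliberately conservative choice for set-unique membership).  The
**individual set-unique burden (ISUB)** of a subject is the sum of
deleteriousness scores over the set-unique variants *of the subject's own
group* that the subject carries.  Three nested categories are scored:

- **NS** — all in-scope variants (non-synonymous, splice-site and
  stop-altering SNVs);
- **DEL** — the subset predicted deleterious;
- **NS − DEL** — the complement, predicted benign.

Per individual, `isub_NS = isub_DEL + isub_NSminusDEL` exactly; the test
suite asserts this identity on random cohorts.  Each carried variant
contributes its score once regardless of zygosity; at the minor-allele
frequencies this analysis targets (~5×10⁻⁴) homozygotes are vanishingly
rare, and a dosage-weighted variant of the score is available as a
configuration switch.

## Deleteriousness scores and augmentation

Scores are CONDEL-style consensus deleteriousness values in [0, 1] with
an accompanying deleterious/neutral flag, consumed as input — the package
never recomputes them from component predictors.  Splice-site and
stop-altering SNVs mostly cause no amino-acid change and therefore carry
no score; these are *augmented*: any non-scored splice or stop variant is
assigned the maximal score 1.0 and a deleterious label.  Splice/stop
variants that do carry a score keep it, as do all non-synonymous
variants.  Augmentation therefore never lowers a score and never removes
a deleterious flag.  Non-scored non-synonymous variants (absent by
construction in the synthetic data, possible in real annotation tables)
contribute score 0 while remaining in scope; they affect counts but not
burden sums.

Variants annotated to several genes appear as one row per (variant,
gene) pair; set-unique logic deduplicates on the variant id while gene
analyses use all pairs.

## Permutation inference

Because the set-unique sets themselves depend on the labelling, any
test statistic must be **re-derived per permutation**: for each of B
permuted phenotype vectors (group sizes preserved; optionally within
strata) the partition, every individual score, and the Wilcoxon rank-sum
of case scores (mid-ranks for ties) are recomputed from scratch, and the
empirical p-value is `(1 + #{null ≥ observed}) / (B + 1)` for the
one-sided "greater in cases" test (the default — the hypothesis is an
*increased* burden; a two-sided option doubles the smaller tail).
Freezing the observed partition and permuting only the frozen
per-individual scores is a subtle, wrong shortcut: with unequal group
sizes each individual's score depends on the size of the opposite group,
the frozen scores are not exchangeable, and calibration breaks.  The
test suite includes this wrong variant as a regression and asserts that
its null p-value distribution fails a uniformity test that the correct
path passes.

For tiny cohorts an exhaustive mode enumerates all C(n, n_case)
labellings and returns the exact p-value `#{stat ≥ observed} / N` (the
observed labelling counts itself, so p is never zero).

### Family-wise minP correction

Families of related tests (the NS/DEL/NS−DEL burden triple; the four
gene-count categories; gene-list overlaps) are corrected with the
permutation minP method: all tests in a family share one permutation
stream; each draw of each test is converted to its within-test empirical
p-value; the family minimum per draw forms the reference distribution;
and a test's adjusted p is the (smoothed) proportion of draws whose
family-minimum p is at or below the test's own p, floored at the raw p.
This controls the family-wise error rate under arbitrary dependence
between the tests.  Results carry a stream identifier and `minp_adjust`
refuses families whose members were not computed on the same stream.

## Quantitative vs qualitative decomposition

An increased burden can come from carrying *more* set-unique variants or
from carrying *more damaging* ones.  `decompose_burden` splits a profile
into (a) the per-individual variant count, compared with the usual
rank-sum, and (b) the per-individual mean score per carried variant,
compared among carriers only.  Because the carrier subset changes with
each permuted labelling, comparison (b) uses the normal-standardised
rank-sum so draws remain comparable across labellings.  On synthetic
cohorts the decomposition recovers the generating mechanism: count-mode
enrichment drives (a) and leaves (b) at the null rate, and vice versa.

## Normalised burden scores for regression

For use as a regression covariate the DEL burden is first corrected for
the group-size asymmetry: a variant is own-side set-unique only if absent
from every opposite-group member, so E[burden] scales roughly as
exp(−q·n_opposite) and the group facing the smaller opposite group runs
systematically high.  Each group's scores are multiplied by
`n_opposite / mean(n_cases, n_controls)` — shrinking the advantaged
group; to first order in q·n this equalises the null expectations, and
the factors are recorded in the output metadata.  The exact correction
used in prior work is not published, so this linear factor is this
package's own declared convention.  Corrected scores are then mapped to
Blom normal quantiles, `Φ⁻¹((rank − 3/8)/(n + 1/4))` with mid-ranks for
ties, computed on the combined sample.  Constant score vectors make the
transform undefined and are a hard error.  Heavy ties (many zero-burden
individuals) make the transformed mean deviate slightly from zero; this
is expected and harmless for regression.

## Gene-level burden and gene sets

Polygenicity is assessed by counting genes touched by own-side
set-unique variation: genes with ≥ 1 deleterious variant, with a splice
variant, with a stop-altering variant, and **double hits** — genes in
which a single individual carries ≥ 2 own-side set-unique in-scope
variants, at least one deleterious.  Case-minus-control gene-count
differences are tested by the same label permutation (gene sets
recomputed per labelling).

Per-gene carrier counts feed one-sided Fisher exact tests (carriers vs
non-carriers by case/control; individuals, not alleles).
**Differentially hit genes** of a side are those with deleterious
set-unique variants in more than two carriers, a strictly higher carrier
proportion than the other side, and Fisher p < 0.5 — a deliberately
lenient pre-filter whose point is noise reduction (highly polymorphic
genes hit in both groups drop out), not significance.  Genes with exactly
one or two carriers versus zero on the other side are emitted as a
separate secondary list.  Overlap of hit-gene lists with user-supplied
gene sets uses the upper-tail hypergeometric test; the default universe
is all genes with at least one in-scope variant on the platform
(configurable — the choice of universe is genuinely open and is logged
with the result).  Case-vs-control overlap differences are again
permutation-tested.  A burden re-run after excluding a candidate gene
set checks whether a signal is genome-wide polygenic rather than driven
by a few genes.

## Effect-size comparison

The relative contribution of common and rare susceptibility alleles is
measured on the Nagelkerke pseudo-R² scale from the logistic liability
model

    logit P(case) = β₀ + Σᵢ βᵢ·MDSᵢ + β_prs·PRS + β_isub·ISUB_norm

with MDS ancestry components (default: first 10), a polygenic risk score
and the normalised burden.  Nagelkerke R² =
(1 − (L₀/L₁)^(2/n)) / (1 − L₀^(2/n)) with L₀ the intercept-only
likelihood; a term's effect size is ΔR² = R²(full) − R²(full minus that
term), with all other terms retained in the reduced model.  Fitting is
by maximum likelihood (statsmodels), complete cases only, no imputation;
perfect separation and rank-deficient designs are hard errors.  The
PRS–burden correlation is Spearman by default (the burden distribution
is strongly skewed) with a permutation p-value.

The replication-style comparison takes the discovery run's case-unique
deleterious variant list into an independent cohort and compares
per-individual sums of minor-allele counts (dosages, not carrier
indicators) between groups, with an empirical one-sided p-value.

## Synthetic cohorts

The generator emulates an exome-array case–control cohort so that every
stage is testable without individual-level data:

- **Sizes** default to 1,002 cases / 931 controls (the post-QC cohort
  the analysis design targets); test suites use 100–500 per group.
- **MAF** per variant is log-uniform on [8×10⁻⁵, 1.6×10⁻³] (mean
  ≈ 5.1×10⁻⁴, median ≈ 3.6×10⁻⁴, matching the population frequencies of
  set-unique exome-array variants, mean 0.046% / median 0.035%); a point
  mass is available by setting both bounds equal.  Carriage is diploid
  Hardy–Weinberg.
- **Functional classes** are drawn as 65% non-synonymous, 12% splice
  site, 7% stop-altering, 16% synonymous, approximating exome-array
  coding content; 90% of splice/stop variants carry no score.
- **Scores** for scored variants are Beta(0.5, 0.5) (bimodal, pushing
  mass toward clearly-neutral and clearly-damaging, as consensus
  deleteriousness scores behave), flagged deleterious above 0.5.
- **Genes**: 15,000 genes with size-biased assignment (Pareto weights),
  so a few large polymorphic genes accumulate many variants — the noise
  source the differentially-hit filter exists to handle; uniform
  assignment is available.
- **Enrichment** multiplies the case carriage probability of deleterious
  variants (count mode), or raises the scores of case-unique deleterious
  scored variants by the monotone map s → s^(1/enrichment) while leaving
  carriage and flags untouched (score mode), so the two mechanisms of an
  increased burden can be generated separately.  The score-mode
  transform conditions on realised case-uniqueness — a generator device,
  not a causal model.  `enrichment = 1` is the exchangeable null in both
  modes.
- **Covariates**: 10 standard-normal MDS components shared between
  groups, and a PRS that is standard normal in controls and shifted by
  0.65 s.d. in cases by default, putting the common-variant signal an
  order of magnitude above a weak rare-variant enrichment on the ΔR²
  scale — the regime the effect-size comparison is designed for.

What the generator does **not** model: linkage disequilibrium,
population structure beyond the shared MDS draw, genotyping error or
differential missingness, relatedness, and gene length/variant-density
correlation beyond the size-biased assignment.  Passing tests therefore
demonstrate the statistical machinery (calibration, power, mechanism
recovery, family-wise error control) under a clean rare-variant model;
they do not certify robustness to confounding in real cohorts, which is
why the pipeline accepts ancestry covariates and stratified permutation.

## Numerical and scale choices

- Minor-allele orientation is computed on the combined sample, ties kept
  on the alt allele; orientation is idempotent.
- Empirical p-values use +1 smoothing and can never be zero; exhaustive
  enumeration returns exact tail proportions.
- Simulation studies in the tests and the acceptance script use reduced
  problem sizes chosen for tight Monte-Carlo bands at desk scale:
  null calibration on 300-per-group cohorts with 5,000 variants, B = 200
  permutations, 200–300 replicates; power at 500/500 with 1.3× count
  enrichment, 100 replicates; effect sizes at full cohort size with
  20,000 variants.  B = 10,000 remains the default for single analyses.
- Permutation statistics run on a sparse carrier-matrix representation;
  the observed analysis and the permutation null share this single code
  path, and brute-force loop oracles in the tests pin its correctness.

## Known limitations

- The sample-size correction factor is a first-order convention (exact
  only as q·n → 0); with strongly unequal groups the inverse-normal
  transform still absorbs most residual asymmetry, but the uncorrected
  asymmetry is visible in raw burden means.
- The lenient Fisher pre-filter threshold (0.5) and its one-sidedness
  are conventions; both are configurable.
- Exhaustive enumeration is limited to cohorts with at most ~200,000
  distinct labellings.
- PLINK input is restricted to text .ped/.map; binary .bed is out of
  scope.
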
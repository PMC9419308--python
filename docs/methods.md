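# Methods

## Scope and data model

`dietnet` analyses subject-level cohort data held in three aligned tables:
an intake matrix (subjects × food groups, grams/day), a covariate table
(age, sex, education, occupation, marital status, smoking, menopause,
physical activity, BMI, energy intake) and a biomarker table (waist
circumference, systolic/diastolic blood pressure, triglyceride, fasting
glucose, HDL). The canonical vocabulary is 39 food groups; FFQ item-level
input is aggregated by a user-supplied item→group map (the shipped default
map is the identity over the 39 groups, since no public item-level
assignment exists for this kind of instrument). Subjects with implausible
energy intake are excluded with strict comparisons — below 800 or above
4200 kcal/day — so the boundary values themselves are retained; exclusions
are logged, and the rule is idempotent.

## Gaussian graphical model

Intakes are standardized per group to mean 0 and **population** SD 1
(divide by n, applied consistently everywhere a variance is computed), and
the sample correlation matrix `S` of the standardized intakes is the input
to estimation. Correlation rather than covariance input makes the fit
invariant to the wildly different gram scales across food groups
(tea ≈ 570 g/day vs garlic ≈ 1 g/day).

The sparse precision matrix solves the graphical lasso problem with
unpenalized diagonal. The solver is ADMM: the likelihood step is an
eigendecomposition update, the penalty step an elementwise soft-threshold,
iterated until scaled primal and dual residuals fall below `tol`
(default 1e-8) with a cap of `max_iter = 5000`. Every returned estimate
carries its maximum KKT stationarity violation as a diagnostic; the test
suite requires ≤ 1e-6 and cross-checks the solution against two independent
solvers (an accelerated proximal-gradient oracle and scikit-learn's
coordinate descent). At λ = 0 the estimate is the exact inverse of `S`
(requires n > p). Entries with `|Ω_ij| < 1e-8` count as zero; that numeric
zero defines the sparsity pattern everywhere downstream.

### Penalty selection

λ defaults to the minimizer of EBIC over a log-spaced 15-point grid from
`λ_max` (the largest absolute off-diagonal of `S`) down to `λ_max/50`:

    EBIC(λ) = −2·ℓ(Ω̂_λ) + k·log n + 4·γ·k·log p,   γ = 0.5,

with `k` the nonzero upper-triangle count. The log-likelihood is evaluated
at the **support-refitted MLE** (the Gaussian MLE constrained to the
selected zero pattern), not at the shrunken estimate. This is a deliberate
design choice: the penalized estimate's likelihood carries L1 shrinkage
bias that grows with λ, which drags the criterion toward dense solutions —
in our planted-structure experiments the penalized-likelihood variant
admitted several false edges per fit at n = 5000, while the refit variant
selected clean supports (zero observed false edges) at the cost of missing
some |ρ| = 0.06 edges. Both variants are available
(`GGMConfig(refit_for_selection=...)`); k-fold cross-validated held-out
likelihood is provided as an alternative criterion with deterministic
contiguous folds. The λ actually used is always recorded in the run
manifest, and the full criterion curve is written out for audit.

### Networks

Adjacency is the glasso nonzero pattern — *not* a partial-correlation
threshold. The 0.30 threshold labels edges as "strong" (a display and
interpretation attribute, reflecting the convention that |ρ| ≥ 0.30 is a
strong conditional association); dietary networks routinely contain much
weaker edges, so using 0.30 as a hard filter would destroy them. A hard
filter is nevertheless available (`strong_edge_filter`) for sensitivity
analyses. Connected components with ≥ 3 nodes become dietary networks,
ordered by size (ties: alphabetical first node); pairs and singletons are
logged as leftovers.

## Link communities and centrality

Within one network, communities are communities of **edges**, so food
groups can belong to several. Adjacent edges (sharing exactly one node)
get the Jaccard similarity of the inclusive neighborhoods of their
non-shared endpoints; non-adjacent pairs are never merged directly. Edges
are agglomerated by single linkage — implemented as a deterministic
Kruskal-style union-find over pair similarities sorted by (−similarity,
lexicographic edge order) — and the dendrogram is cut at the height
maximizing the partition density

    D = (2/M) Σ_c m_c (m_c − (n_c−1)) / ((n_c−2)(n_c−1)),

where communities with n_c = 2 contribute zero. Ties are broken toward
fewer communities, then toward the higher cut. A weighted variant
(Tanimoto similarity over |ρ|) is available behind a flag; the unweighted
form is the default because the sparse support already encodes the
conditional-dependence structure.

Centrality: a node's community-membership count, with ties broken by
degree and then alphabetically. This reconciles the two natural readings
of "central food group" — belonging to the most communities, and being
correlated with the most other groups — in that order. All tied nodes are
flagged in the report so ties are never silent. For graphs with ≤ 7 edges
the cut is verified in the test suite against exhaustive search over all
dendrogram cuts on every connected graph with up to 7 nodes.

## Network scores and tertiles

For each network, the first principal component of the correlation matrix
of the network's standardized food groups supplies signed loadings (a unit
eigenvector — the single-component reading of "factor loadings obtained by
PCA"). The global sign is fixed so the loading sum is
positive, making "higher score = higher adherence" deterministic. The score
is the loading-weighted sum of z-scores; PCA is fit on the network's own
group submatrix (not all 39 groups). Tertiles T1 < T2 < T3 are assigned by
a stable sort on score into near-equal thirds (sizes differ by at most
one, remainder to the earliest tertiles: 850 → 284/283/283); the type-7
(linear interpolation) 1/3 and 2/3 quantiles are reported as cut points,
and per-tertile medians feed the trend test.

## Metabolic syndrome

NCEP-ATP III with strict comparisons throughout: central obesity WC > 102
cm (men) / > 88 cm (women); hypertension SBP > 130 **or** DBP > 80 mmHg
(the conventional reading of "BP > 130/80"; an AND variant is
configurable); triglyceride > 150 mg/dl; fasting glucose > 110 mg/dl; low
HDL < 40 (men) / < 50 (women) mg/dl. MetS = ≥ 3 components. No
drug-treatment criteria are modelled (the intended cohorts are apparently
healthy, with no medication variables). All cutoffs live in a config
object so JNC/IDF-style variants are one edit.

## Association models

Logistic regression (maximum likelihood) of each outcome (MetS and its
four component diagnoses) on tertile indicators (T1 reference) plus the
model's covariates; OR = exp(coef), Wald 95% CI = exp(coef ± 1.96·SE),
two-sided Wald p. Wald inference is used because exp(coef ± 1.96 SE) is
the standard construction behind printed OR/CI pairs. Model 1 is crude;
model 2 adjusts for age, sex, education, occupation, marital status,
smoking, menopause and physical activity; model 3 replaces physical
activity with BMI and energy intake. Categorical covariates enter as
indicator sets with the first schema level as reference; menopause is
coded 0 for all men and dropped (with a recorded flag) in an all-male
stratum; unobserved levels drop silently. The trend test replaces the
tertile indicators with one continuous exposure equal to the subject's
tertile median score. Separation or non-convergence yields a flagged
NaN row, never a silent omission; no multiple-testing correction is
applied. Descriptive output mirrors the usual cohort tables: biomarker
mean ± SD per tertile with one-way ANOVA p, and categorical frequencies by
sex with chi-square p (no continuity correction; sparse expected cells
flagged).

## Synthetic cohorts

The generator is the validation instrument: it plants a known truth at
every level.

* **Structure.** A planted structure is a set of named blocks, each a node
  list with target within-block partial correlations. With unit diagonal,
  the implied precision matrix has `−ρ` at each planted edge; the
  construction verifies positive definiteness and rejects infeasible
  requests naming the offending block (an optional diagonal-inflation
  rescue exists, which shrinks all edge magnitudes by a common factor and
  therefore forces a post-hoc partial-correlation check). Two presets ship:
  a *figure-like* structure with the published magnitudes of the three
  dietary networks (values printed as 0.9–0.99 are clamped to 0.30 —
  as printed they are mutually infeasible, the implied matrix is not
  positive definite, and they are generally regarded as typographical), and
  a *recovery* structure with the same block topologies restricted to
  |ρ| ∈ {0.06, 0.15, 0.30} and a connected 0.15 backbone per block, so that
  the three-network count is a property of the planted structure rather
  than of marginal edge detectability.
* **Intakes.** I.i.d. multivariate-Gaussian draws from the planted
  precision, rescaled to unit marginal variance and affine-mapped to
  per-group (mean, SD) in g/day (defaults follow the intake scale of an
  adult urban Iranian cohort, e.g. butter 3.50 ± 11.5 g/day). Optional
  truncation at zero mimics non-negative real intakes but biases partial
  correlations, so it is **off** by default in recovery settings — a
  deliberate fidelity/testability trade-off.
* **Covariates.** Drawn independently of diet (sex 69% female, age uniform
  20–59, categorical probabilities matching a screening population;
  physical activity (0.60, 0.35, 0.05) across light/moderate/heavy, the
  small heavy share being a generator choice to keep all three schema
  levels populated; menopause only among women). Real cohorts confound
  diet and demographics; the null coupling keeps planted effects exactly
  interpretable and is the main deliberate departure from realism.
* **Outcomes.** The MetS flag is Bernoulli with log-odds linear in the
  planted network-score tertiles (the score being the same PCA-weighted
  construction the pipeline uses, computed on the planted block) plus
  optional covariate effects. Given the flag, a component count is drawn
  (3–5 if MetS, 0–2 otherwise), components are chosen uniformly, and
  continuous biomarkers are placed uniformly in bands strictly on the
  correct side of each ATP III cut (SBP > DBP enforced throughout). Only
  the binary states carry the planted effect; the continuous values are
  cosmetic. By construction, classifying the generated biomarkers returns
  exactly the planted flags.

What passing tests on these cohorts shows: the estimation chain recovers
conditional-dependence structure, hub identity, and logistic effect sizes
when the data really are Gaussian with the assumed independence of diet
and covariates. What they cannot show: robustness to the skewness,
zero-inflation, measurement error and diet–covariate confounding of real
FFQ data.

## Problem sizes and defaults

Cohort defaults follow the motivating study design (850 subjects, 39
groups); structure-recovery analyses use n = 5000, where backbone edges
(|ρ| ≥ 0.15) are recovered essentially always and the EBIC-selected
support is clean. At n = 850 the refit-EBIC penalty is conservative
enough that the weak saturated-fats block (edges ≤ 0.15) is usually not
detected — a real power limit of sparse selection at that sample size,
reported as such by the analysis scripts rather than papered over.
Replicate counts: 50 for structure recovery, 200 for effect recovery
(planted OR 1.81; mean recovered ≈ 1.8, CI coverage ≈ 95%), 500 for
null-trend p-value uniformity.

## Reproducibility

Every stochastic step flows from a single integer seed through named
substreams (intakes / covariates / outcomes), so identical configs give
bit-identical tables; the pipeline writes a manifest recording λ and its
selection rule, γ, the strong-edge threshold, the quantile type, the
standardization and sign conventions, the BP rule and all cutoffs, plus a
config hash. Reruns of the full pipeline are byte-identical.

## Known limitations

* Gaussian latent intakes; no nonparanormal/copula extension, no mixed
  graphical models.
* One principal component per network score; no factor rotation, no
  energy-residual (Willett) adjustment.
* The item→group map must be supplied for item-level FFQ data; no
  household-measure or food-composition conversion.
* Odds ratios, not prevalence ratios, in a cross-sectional design — the
  usual interpretive caveats apply.
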
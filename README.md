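# dietnet

Dietary-pattern analysis with Gaussian graphical models: from a table of
food-group intakes to sparse partial-correlation networks, central food
groups, network adherence scores, and odds ratios of metabolic syndrome.

## The problem

Classical dietary-pattern methods (PCA, cluster analysis) describe how food
intakes co-vary *marginally*, so every pairwise association is contaminated by
all the other food groups. A Gaussian graphical model (GGM) instead estimates
the *conditional* dependence structure: food groups `i` and `j` are connected
only if they remain correlated after conditioning on every other group. The
resulting sparse networks are readable as consumption patterns — e.g. a
"saturated fats" network in which butter, margarine and animal fat are eaten
together — and the hub ("central") food group of each network anchors its
interpretation. Adherence scores built from these networks can then be related
to health outcomes such as NCEP-ATP III metabolic syndrome.

`dietnet` implements this whole chain as a tested pipeline for
epidemiologists working with FFQ-style intake data, and — because cohort data
of this kind are rarely shareable — ships a synthetic-cohort generator with
*planted* network structure and *planted* exposure–outcome effects, so every
stage can be validated against a known truth.

## The model

With `Z` the column-standardized intake matrix (mean 0, population SD 1) and
`S` its sample correlation matrix, the precision matrix is estimated by the
graphical lasso

```
Ω̂ = argmax_{Ω ≻ 0}  log det Ω − tr(SΩ) − λ Σ_{i≠j} |Ω_ij|
```

(diagonal unpenalized; solved by ADMM and verified against the KKT
conditions). Partial correlations are `ρ_ij = −Ω_ij / √(Ω_ii Ω_jj)`;
connected components with ≥ 3 food groups are dietary networks, with
`|ρ| ≥ 0.30` labelling an edge "strong". λ is chosen by EBIC
(`−2ℓ + k log n + 4γ k log p`, γ = 0.5) evaluated on the support-refitted MLE.

Within each network, communities of *edges* are found by single-linkage
clustering on inclusive-neighborhood Jaccard similarity, cut at the maximum
of the partition density; a food group's community-membership count is its
centrality. Per-subject scores are `Σ_g w_g z_g` with `w` the first-PC
loadings of the network's groups; scores are split into tertiles, and
logistic models estimate T2/T3 vs T1 odds ratios (Wald CIs) with a
median-coded trend test, under three adjustment models.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
validation cohort (5000 subjects, 39 food groups, three planted networks, a
planted saturated-fats → MetS tertile-3 odds ratio of 1.81):

```bash
python analysis/01_simulate_cohort.py     # write cohort tables + truth
python analysis/02_derive_networks.py     # GGM -> networks -> communities
python analysis/03_score_and_classify.py  # scores, tertiles, ATP III MetS
python analysis/04_associations.py        # tertile ORs + trend tests
python analysis/05_recovery_benchmark.py  # replicate truth-recovery benchmark
```

Step 02 prints (seed 1):

```
EBIC-selected lambda: 0.0641 (KKT violation 1.44e-07)
dietary networks: 3 (12 food groups in leftover pairs/singletons)
  network_1: 13 groups, 15 edges (0 strong), 5 communities, central: cooked_vegetables
  network_2: 11 groups, 13 edges (0 strong), 7 communities, central: carbonated_drinks
  network_3: 3 groups, 2 edges (0 strong), 1 communities, central: butter
```

— the three planted blocks are recovered with their planted central groups
(a healthy network around cooked vegetables, an unhealthy one around
processed meat/drinks, and the butter-centered saturated-fats triple). Step
04 then shows that only the saturated-fats network carries the planted
metabolic-syndrome signal:

```
MetS odds ratios for T3 vs T1:
  network_1  model 1: OR 0.96 (95% CI 0.83-1.11), p=0.556, P-trend=0.554
  network_2  model 1: OR 1.02 (95% CI 0.88-1.18), p=0.757, P-trend=0.756
  network_3  model 1: OR 1.80 (95% CI 1.55-2.09), p=0.000, P-trend=0.000
```

`OR 1.80` against the planted `1.81` is the point of the exercise: the
end-to-end pipeline (network detection → PCA score → tertiles → logistic
model) returns the effect that was planted, and returns null results where
nothing was planted.

The same chain is available as a library (`import dietnet`), as a YAML-driven
single command (`dietnet run --config run.yaml`), and as per-stage
subcommands (`dietnet simulate|networks|score|classify|associate`).

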
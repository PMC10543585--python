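# phyloconverge

Phylogenetic comparative analysis of convergent trait evolution, built
around a 17-species study of amygdala nucleus volumes in mammals. The
question the toolkit addresses: do species that must tolerate close
social contact — cooperative breeders (where allomothers handle and
provision infants) and domesticated species — share derived amygdala
proportions, in particular a relatively larger lateral nucleus (L) and a
relatively smaller basal nucleus (B) within the basolateral complex
(BLA)? Because species data are not independent, every analysis
conditions on the phylogeny.

The package is aimed at comparative biologists who want the whole
analysis stack — trait engineering, regression, signal, convergence,
ancestral states — as tested, seedable Python functions rather than a
collection of R scripts.

## What it computes

**PGLS with ML Pagel's λ.** For a response nucleus y and reference
volume x (both natural-log cm³), the model

&nbsp;&nbsp;&nbsp;&nbsp;log y = α + β·log x + Δ·g + ε, ε ~ N(0, σ²·C(λ))

where g is a binary regime (`elicit_care` = cooperative breeder OR
domesticated, or either flag alone) and C(λ) is the Brownian-motion
covariance of the tree with off-diagonals scaled by Pagel's λ, which is
maximised over [0, 1] by profile likelihood per regression. The group
coefficient Δ is the intercept difference; since both sides are logged,
`100·(exp(Δ·max g) − 1)` is the percentage volume effect of the regime
(reported only when Δ is significant at α = 0.05). Competing models for
one response are ranked by AIC (2k − 2 ln L) with the 2-unit support
window: Best / Tied / No.

**Phylogenetic signal.** Blomberg's K for continuous traits (K ≈ 1
under Brownian motion) with tip-permutation p-values, and the
entropy-based δ statistic for binary regimes: a symmetric two-state
Markov model is fitted by ML, marginal ancestral-state probabilities are
reduced to node entropies, a Beta(a, b) distribution is fitted to them
and δ = b̂/â, with significance from tip-label randomisation.

**Wheatsheaf index.** W = (mean penalised phenotypic distance among all
species) / (same among a focal set); distances between close relatives
are inflated by (1 + phylogenetic correlation) so that similarity among
relatives counts for less. Bootstrap over species gives a 95% CI and a
p-value against the index's expectation under randomly drawn focal sets.

**Phylogenetic ANOVA.** Classical one-way F referred to a null
distribution of F values from Brownian-motion simulation on the tree,
with Holm-corrected pairwise post-hoc tests against their own simulated
nulls.

**Ancestral states.** ML estimates of continuous (ratio) traits under
Brownian motion at every internal node, equal to the phylogenetic mean
of the tree re-rooted at that node.

**Synthetic studies.** `make_synthetic_study` generates an ultrametric
pure-birth tree plus a trait table with the full anatomical structure
(L + B + AB = BLA ≤ AC), known injected intercept shifts, and
seven-component allomaternal-care scores whose sums cluster so that
1-D k-means discretization recovers exactly the designed cooperative
breeders — so every stage of the pipeline can be tested without any
external data.

## Worked example

```python
import phyloconverge as pc

# a synthetic 17-species study with known shifts (+0.353 on log L,
# -0.298 on log B, in the six focal species)
table, tree = pc.make_synthetic_study(pc.SyntheticScenario(seed=1))

fit, eff = pc.fit_additive_model(table, tree, "L", "BLA", "elicit_care")
print(f"delta = {fit.intercept_difference:.3f}, p = {fit.p_value_group:.2e}, "
      f"lambda = {fit.lambda_hat:.2f}, effect = {eff.effect_pct:.1f}%")
```

prints

```
delta = 0.346, p = 2.65e-13, lambda = 1.00, effect = 41.4%
```

i.e. the fitted intercept difference 0.346 recovers the injected 0.353
(a ~41% larger lateral nucleus at any given BLA volume), λ̂ = 1 matches
the Brownian simulation, and the shift is highly significant.

The same workflow runs from the shell on any Newick + CSV pair:

```bash
phyloconverge simulate --seed 1 --out study/
phyloconverge run-all --tree study/tree.nwk --traits study/traits.csv \
    --seed 1 --out results/
```

`run-all` writes the engineered trait table, the 18-model PGLS grid with
AIC labels, the 8-row signal table (K for the five volumes, δ for the
three regimes), Wheatsheaf tests and phylogenetic ANOVAs for the L/BLA
and B/BLA ratios, ancestral-state CSVs with annotated Newicks, and a
machine-readable run log. Re-running with the same seed reproduces every
file byte for byte. To analyse real data, supply your own calibrated
tree and a per-individual CSV (volumes in cm³; see
`phyloconverge.traits.load_traits` for the schema).

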
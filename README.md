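# venomphylo

A phylogenetic comparative toolkit for analysing venom potency across
predator species, built around the question of *prey-specific* venoms:
are venoms more potent (lower LD50) when assayed on organisms that are
evolutionarily close to the predator's natural prey?

It is aimed at comparative biologists working with literature-collated
venom assays — median lethal doses (LD50, mg of lyophilized venom per kg
of test subject) measured on heterogeneous model organisms (mice, crickets,
flies) via heterogeneous injection routes — together with diet reports,
body sizes, venom yields and a time-calibrated phylogeny.

## What it computes

**Diet scoring.** Literature diet reports are a mix of quantitative
proportions and qualitative labels. Labels are scored
major → 0.60, common → 0.20, uncommon → 0.05, rare → 0.01, calibrated
against any co-reported quantitative values, merged, and normalized so
each species' prey weights sum to one.

**Prey-specificity statistic.** For a predator with diet weights *wᵢ*
over prey taxa *pᵢ* and an assay model organism *m*,

&nbsp;&nbsp;&nbsp;&nbsp;*D* = Σᵢ *wᵢ* · *T*(*m*, *pᵢ*)

where *T* is the divergence time (age of the most recent common ancestor,
in hundreds of millions of years, Hmya) on a calibrated reference tree.
*D* is the diet-weighted evolutionary distance between "what the venom was
tested on" and "what the predator actually eats".

**Allometry.** Body length (mm) converts to mass (g) via
mass = length^2.6; scaling exponents (e.g. venom yield vs mass, where
metabolic theory predicts 0.75) are estimated by OLS on log₁₀–log₁₀ scale.

**Phylogenetic mixed model.** A Bayesian Gaussian "animal model" fitted
by Gibbs sampling:

&nbsp;&nbsp;&nbsp;&nbsp;y = Xβ + Z a + Z s + e,&nbsp;
a ~ N(0, σ²ₐ·A),&nbsp; s ~ N(0, σ²ₛ·I),&nbsp; e ~ N(0, σ²ₑ·I)

with y = log₁₀ LD50 (or log₁₀ yield), A the Brownian-motion phylogenetic
correlation matrix, a species repeat-measure effect s, equal-tailed 95%
credibility intervals (an effect is *significant* when its CI excludes
zero), phylogenetic heritability h² = σ²ₐ/(σ²ₐ+σ²ₛ+σ²ₑ), and the
Gelman–Rubin R-hat over multiple seeded chains.

**Ancestral states.** Maximum-likelihood Mk-model (ER or ARD)
reconstruction of a binary trait such as silk use in prey capture, with
marginal node probabilities.

**Synthetic data.** Yule trees, Dirichlet diet profiles over a 12-class
prey universe, and LD50/yield datasets drawn from the exact generative
model the mixed model fits, with known ground truth — so every stage is
testable end to end without any external data.

## Worked example

```python
import venomphylo as vp
from venomphylo.diet_scoring import (QualitativeDietReport,
                                     QuantitativeDietReport)
from venomphylo.synthetic_data import prey_reference_tree

qual = QualitativeDietReport("Amaurobius similis", {
    "Insecta": "major", "Malacostraca": "common", "Arachnida": "common",
    "Gastropoda": "rare"})
quant = QuantitativeDietReport("Amaurobius similis",
                               {"Insecta": 0.75, "Malacostraca": 0.21})
est = vp.combine_reports(qual, quant)
profile = vp.normalize_profile(est, species="Amaurobius similis")
print("weights (3 dp):", profile.displayed(3))
tree = prey_reference_tree()
for model in ("Mus musculus", "Acheta domesticus"):
    res = vp.d_ld50_diet(tree, profile, model)
    print(f"D_LD50-Diet vs {model}: {res.d_hmya:.3f} Hmya")
```

prints

```
weights (3 dp): {'Insecta': 0.635, 'Malacostraca': 0.177, 'Arachnida': 0.177, 'Gastropoda': 0.008}
D_LD50-Diet vs Mus musculus: 7.000 Hmya
D_LD50-Diet vs Acheta domesticus: 1.886 Hmya
```

The qualitative-only "common" group (Arachnida) inherited 0.21 from the
co-reported quantitative "common" group rather than the 0.20 default; the
weights are each estimate divided by their sum. The mouse sits 7 Hmya
(the root of the reference tree) from this all-invertebrate diet, while a
cricket model — itself a member of the dominant prey class — is only
1.886 Hmya away: assays on the cricket probe the venom near its natural
targets.

Fitting the mixed model to a synthetic study generated with a true
prey-specificity slope of 0.4 and route contrasts 2.01 / 1.01:

```python
ds = vp.make_dataset(n_species=40, seed=21, n_assay_species=36)
spec = vp.ModelSpec(
    response="log10_ld50",
    continuous=["d_ld50_diet", "log10_mass", "silk_use"],
    categorical={"route": "IP"},
    chains=vp.ChainSettings(iterations=20000, burnin=4000, thin=16,
                            n_chains=3, seed=7))
summary = vp.summarize(vp.fit_pmm(ds.assays, spec, ds.tree))
print(summary.fixed_effects.round(3))
```

```
                              mean  lower  upper  significant
term
(Intercept)                 -0.278 -1.272  0.703        False
d_ld50_diet                  0.381  0.225  0.529         True
log10_mass                  -0.023 -0.203  0.155        False
silk_use                    -0.064 -0.415  0.287        False
route[IV]                    0.012 -0.613  0.627        False
route[SC]                   -0.214 -0.790  0.357        False
route[abdomen]               0.985  0.421  1.543         True
route[thorax_cephalothorax]  2.147  1.603  2.682         True
```

The credibility interval for the divergence slope covers the generating
0.4 (and excludes zero), the null mass and silk effects are correctly
non-significant, and the two invertebrate-route contrasts recover their
generating offsets; `summary.h2_mean` and `summary.rhat` give the
phylogenetic heritability and convergence diagnostics (max R-hat 1.002
here).

A `venomphylo` command-line tool exposes the same steps
(`simulate`, `score-diet`, `distance`, `allometry`, `fit`, `asr`); run
`venomphylo --help`.

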
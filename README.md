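# pedgrm

Quantitative-genetic analysis of a repeatedly measured trait under two
descriptions of relatedness: the **social pedigree** (numerator
relationship matrix **A**) and a **SNP-based genomic relatedness matrix**
(**G**).  The package is aimed at evolutionary ecologists working with
wild-population data — think nest-box passerines with field-observed
parentage, tarsus-length-style morphometrics measured by several people,
and a genotyping-by-sequencing SNP panel — who want to know how much of
their additive genetic variance estimate depends on trusting the social
pedigree.

Extra-pair paternity (EPP) makes social pedigrees wrong about fathers.
In a socially monogamous but genetically polygamous bird, ~20% of chicks
are sired by a male other than the social mate, so a pedigree-based
animal model misattributes sib and parent–offspring covariances.  The
predictable consequence, which this package both implements and
demonstrates end-to-end on synthetic data, is a *deflation* of the
additive genetic variance Va and a compensating *inflation* of the
permanent-environment variance Vpe, hence downwardly biased heritability.

## The model

For measurement *j* of individual *i*:

```
y_ij = mu + x_ij' b + a_i + p_i + e_ij
a ~ N(0, sigma2_a K)     additive genetic effects, K = A or G
p ~ N(0, sigma2_pe I)    permanent-environment effects
e ~ N(0, sigma2_e I)     residual
```

fitted by an exact blocked Gibbs sampler (parameter-expanded, giving
half-t(3) priors on random-effect SDs; see `docs/methods.md`).  Reported
summaries: posterior means and 95% credible intervals of the variance
components, heritability `h2 = sigma2_a / (sigma2_a + sigma2_pe +
sigma2_e)` computed per draw, the additive genetic coefficient
`sigma2_a / trait mean`, and split-Rhat convergence diagnostics.

Around the model sit the standard steps of this analysis: marker QC
(Hardy–Weinberg exact test, MAF, missingness, sex-chromosome exclusion),
A-matrix construction by the tabular method with dummy parents for
clutches of unknown parentage, IBS and centred (VanRaden) GRMs, Mantel
comparison of the two matrices, threshold-based paternity classification
(similarity > 0.3 keeps the social father, < 0.1 flags EPP), and a
synthetic-data generator with known variance components, controlled EPP
and gene-dropped genotypes.

## Worked example

Run the full synthetic pipeline (simulate → QC → A and G → Mantel + EPP →
two animal-model fits → comparison report):

```bash
pedgrm run --seed 4 --out-dir runs/demo
```

which prints a two-column variance-component table (P = social pedigree,
G = genomic matrix); this is the verbatim output of that command:

```
                                                   P                       G
Fixed effects
Measurer2                         0.43 (-0.01, 0.87)      0.40 (-0.03, 0.84)
Measurer3                          3.48 (3.03, 3.92)       3.47 (3.03, 3.90)
Measurer4                         0.04 (-0.38, 0.46)      0.04 (-0.37, 0.47)
Measurer5                        -0.31 (-0.73, 0.12)     -0.30 (-0.72, 0.13)
Random effects
Additive genetic                 14.53 (9.96, 19.73)    14.68 (10.46, 19.42)
Permanent environment             9.57 (6.90, 12.43)      8.87 (6.49, 11.44)
Residual                           3.98 (3.60, 4.39)       3.97 (3.59, 4.39)
Heritability                       0.52 (0.39, 0.64)       0.53 (0.41, 0.64)
Genetic coefficient                0.08 (0.06, 0.11)       0.08 (0.06, 0.11)

Mantel r = 0.772; EPP = 22.57%; h2 CrIs overlap: True
```

Reading it: the generator's truth is Va = 13.5, Vpe = 8.22, Vres = 3.89
around a trait mean of 174.8 (0.1 mm units) with 20% EPP.  The fits
recover the components and the measurer offsets (true non-reference
offsets 0.5, 3.9, 0.2, 0.0), the EPP rate estimated from
father–offspring genomic similarity lands near the simulated 20%, and
the pedigree column shows slightly less additive and more
permanent-environment variance than the genomic column.  On any *single*
run that contrast sits well inside the credible intervals — the
deflation is a mean effect of order 10–15% of Va.  The replicate
experiment is what demonstrates it:

```python
from pedgrm.experiments import deflation_experiment
res = deflation_experiment(n_replicates=20, epp_rate=0.2, seed=1000)
print(res[["va_p", "va_g", "vpe_p", "vpe_g"]].mean())
```

prints (true Va 12.5, Vpe 8.5, h² 0.5):

```
va_p     11.80
va_g     12.87
vpe_p     9.97
vpe_g     8.79
```

— the social-pedigree fit loses about one unit of additive variance to
the permanent-environment component, exactly the reallocation that
erroneous paternal links produce, while the genomic fit stays near the
truth.

The same stages are available piecemeal (`pedgrm simulate`, `qc`,
`relmat pedigree|grm`, `mantel`, `epp`, `fit`, `report`) and as library
functions:

```python
from pedgrm import (SimConfig, simulate_all, build_a_matrix,
                    build_grm_vanraden, ModelSpec, fit_animal_model,
                    summarize_heritability)

ped, geno, phen, truth = simulate_all(SimConfig(seed=1))
A = build_a_matrix(ped, which="social")
draws = fit_animal_model(phen, ModelSpec(relatedness=A, n_iter=5000,
                                         n_burnin=1000, n_chains=2, seed=2))
print(summarize_heritability(draws))
```

The replicate experiments behind the headline claim live in
`pedgrm.experiments`: `deflation_experiment()` (social-A vs genomic-G fits
across seeded replicates, at 20% and 0% EPP) and `coverage_experiment()`
(credible-interval calibration against the generating h² with the true
relatedness matrix).

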
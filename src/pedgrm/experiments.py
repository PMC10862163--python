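"""Replicate simulation studies: pedigree-error bias and CrI calibration.

Two designed experiments, both built from the synthetic generator and the
animal model:

* :func:`deflation_experiment` — the headline mechanism: with extra-pair
  paternity corrupting the social pedigree, the additive variance fitted
  with the social-pedigree A matrix falls below the fit with the genomic
  relatedness matrix, while the permanent-environment variance moves the
  opposite way.  At ``epp_rate = 0`` the same function serves as the null
  calibration (the two heritability credible intervals should overlap).
* :func:`coverage_experiment` — parameter recovery: with the *true*
  (genetic-pedigree) relatedness matrix supplied, the 95% credible
  interval for h² should cover the generating value at close to nominal
  rate.

Default replicate conditions: 402 individuals (134 founders, one offspring
generation of four-chick broods), 8,000 unlinked SNPs, true h² = 0.5
(Va = 12.5, Vpe = 8.5, Vres = 4.0 on a 0.1 mm trait scale), and
deliberately short single chains (1,200 iterations, 300 burn-in) so a
replicate batch stays desk-sized.  The wide founder base keeps the
realized genetic variance of each replicate close to the generating value:
the animal model quantifies uncertainty conditional on the pedigree, so a
coverage experiment against the generating h² is only well-posed when
founder-sampling noise is small relative to the credible interval.

The SNP panel for the deflation contrast is deliberately large (8,000
unlinked loci).  Marker-estimated relatedness carries Mendelian-sampling
noise of order 1/sqrt(n_loci) per pair, which attenuates the G-fitted Va
exactly like measurement error in a regressor; the panel must be large
enough that this attenuation is clearly smaller than the pedigree-error
attenuation under study.  Field studies of this design use panels an
order of magnitude larger still.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .animal_model import ModelSpec, fit_animal_model, summarize_heritability
from .relatedness import build_a_matrix, build_grm_vanraden
from .simulate import SimConfig, simulate_genotypes, simulate_pedigree, simulate_phenotypes

#: generating values with true h2 = 0.5 and total variance 25
REPLICATE_SIM = SimConfig(
    n_founders=134, n_generations=2, offspring_per_pair=4,
    Va=12.5, Vpe=8.5, Vres=4.0, n_snps=8000, epp_rate=0.2,
)

#: short-chain MCMC settings used per replicate
REPLICATE_MCMC = dict(n_iter=1200, n_burnin=300, n_chains=1, thin=1)


def _fit(phen, K, seed):
    spec = ModelSpec(relatedness=K, seed=seed, **REPLICATE_MCMC)
    return fit_animal_model(phen, spec)


def deflation_experiment(n_replicates: int = 20, epp_rate: float = 0.2,
                         seed: int = 0, sim: SimConfig = REPLICATE_SIM
                         ) -> pd.DataFrame:
    """Fit each replicate with the social A and the genomic G matrix.

    Returns one row per replicate with the posterior means of Va and Vpe
    under both matrices, the h² summaries, and whether the two h² credible
    intervals overlap.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = dataclasses.replace(sim, epp_rate=epp_rate, seed=seed + rep)
        ped = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        phen, _ = simulate_phenotypes(ped, cfg)
        A_social = build_a_matrix(ped, which="social")
        G = build_grm_vanraden(geno)
        d_p = _fit(phen, A_social, seed=seed + rep)
        d_g = _fit(phen, G, seed=seed + rep)
        h2_p = summarize_heritability(d_p)
        h2_g = summarize_heritability(d_g)
        rows.append(dict(
            replicate=rep,
            va_p=d_p.draws["Va"].mean(), va_g=d_g.draws["Va"].mean(),
            vpe_p=d_p.draws["Vpe"].mean(), vpe_g=d_g.draws["Vpe"].mean(),
            h2_p=h2_p.mean, h2_p_lower=h2_p.lower, h2_p_upper=h2_p.upper,
            h2_g=h2_g.mean, h2_g_lower=h2_g.lower, h2_g_upper=h2_g.upper,
            h2_cri_overlap=not (h2_p.lower > h2_g.upper
                                or h2_g.lower > h2_p.upper),
        ))
    return pd.DataFrame(rows)


def coverage_experiment(n_replicates: int = 100, seed: int = 0,
                        sim: SimConfig = REPLICATE_SIM) -> pd.DataFrame:
    """h² credible-interval coverage with the true relatedness matrix."""
    true_h2 = sim.Va / (sim.Va + sim.Vpe + sim.Vres)
    rows = []
    for rep in range(n_replicates):
        cfg = dataclasses.replace(sim, seed=seed + rep)
        ped = simulate_pedigree(cfg)
        phen, _ = simulate_phenotypes(ped, cfg)
        A_true = build_a_matrix(ped, which="genetic")
        draws = _fit(phen, A_true, seed=seed + rep)
        h2 = summarize_heritability(draws)
        rows.append(dict(replicate=rep, h2=h2.mean, lower=h2.lower,
                         upper=h2.upper,
                         covers=bool(h2.lower <= true_h2 <= h2.upper)))
    return pd.DataFrame(rows)
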
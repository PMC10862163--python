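"""Shared fixtures: small simulated populations and cached model fits."""

import numpy as np
import pandas as pd
import pytest

from pedgrm.animal_model import ModelSpec, fit_animal_model
from pedgrm.pedigree import Pedigree
from pedgrm.relatedness import build_a_matrix
from pedgrm.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_population():
    """~140 individuals, 400 loci — cheap end-to-end material."""
    cfg = SimConfig(seed=101, n_founders=30, n_generations=3,
                    offspring_per_pair=3, n_snps=400)
    return cfg, *simulate_all(cfg)


@pytest.fixture(scope="session")
def trio_pedigree():
    """Two founders, two shared offspring (full sibs)."""
    return Pedigree.from_records(
        [("f1", None, None), ("f2", None, None),
         ("o1", "f1", "f2"), ("o2", "f1", "f2")])


@pytest.fixture(scope="session")
def standard_fit(small_population):
    """One reusable two-chain fit of the small population (true matrix)."""
    cfg, ped, geno, phen, truth = small_population
    A = build_a_matrix(ped, which="genetic")
    spec = ModelSpec(relatedness=A, n_iter=1500, n_burnin=400,
                     n_chains=2, seed=17)
    return fit_animal_model(phen, spec)


def gene_drop_a_matrix(pedigree: Pedigree, n_rep: int = 20000,
                       seed: int = 0, which: str = "social") -> np.ndarray:
    """Monte-Carlo oracle for the additive relationship matrix.

    Drops ``n_rep`` independent loci through the pedigree with every
    founder carrying two unique allele labels, and estimates
    A_ij = 2 * (mean probability that one random allele from i is
    identical by descent to one random allele from j).  Independent of the
    tabular method it checks.
    """
    rng = np.random.default_rng(seed)
    order = pedigree.topological_order(which)
    parents = pedigree.parent_map(which)
    alleles = {}
    next_label = 0
    for ind in order:
        sire, dam = parents[ind]
        if sire is None and dam is None:
            alleles[ind] = np.stack([
                np.full(n_rep, next_label), np.full(n_rep, next_label + 1)])
            next_label += 2
        else:
            pick_s = rng.integers(2, size=n_rep)
            pick_d = rng.integers(2, size=n_rep)
            alleles[ind] = np.stack([
                alleles[sire][pick_s, np.arange(n_rep)],
                alleles[dam][pick_d, np.arange(n_rep)]])
    ids = pedigree.ids
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        ai = alleles[ids[i]]
        for j in range(i, n):
            aj = alleles[ids[j]]
            ibd = np.zeros(n_rep)
            for x in range(2):
                for y in range(2):
                    if i == j and x == y:
                        ibd += 1.0  # an allele is always IBD to itself
                    else:
                        ibd += ai[x] == aj[y]
            A[i, j] = A[j, i] = 2.0 * np.mean(ibd / 4.0)
    return A, ids
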
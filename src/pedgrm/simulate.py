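"""Synthetic population generator with known variance components.

The generator emulates the statistical structure of a nest-box passerine
study: a multi-generation population with strictly monogamous *social*
pairings, a controlled rate of extra-pair paternity (EPP) that corrupts the
paternal links of the social pedigree, gene-dropped unlinked SNPs, and
repeated, measurer-affected measurements of a polygenic trait.  Because the
true breeding values and variance components are known, every downstream
stage (relatedness construction, paternity classification, the animal
model) has an exact parameter-recovery test surface.

Generations are discrete and non-overlapping; each social pair is formed by
randomly matching one male and one female of the previous generation.  For
each offspring independently, the genetic sire equals the social sire with
probability ``1 - epp_rate``, otherwise a different male of the parental
generation is drawn uniformly.  Dams are never misassigned.

All randomness derives from ``SimConfig.seed`` through fixed stream keys
(``default_rng([seed, stage])`` with stage 0 = pedigree, 1 = genotypes,
2 = phenotypes), so identical configurations reproduce byte-identical
outputs and the three stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, PedigreeIntegrityError
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

_STAGE_PEDIGREE, _STAGE_GENOTYPES, _STAGE_PHENOTYPES = 0, 1, 2

#: autosome labels cycled over simulated loci
_AUTOSOMES = [str(c) for c in range(1, 21)]


@dataclass
class SimConfig:
    """Generating quantities of the synthetic study population.

    Defaults mirror the study conditions the package is designed around:
    ~750 individuals over four discrete generations, 20% extra-pair
    paternity, 8,000 unlinked SNPs with minor-allele frequencies uniform in
    [0.05, 0.5] (large enough that marker relatedness approximates realized
    relatedness; field panels are larger still), and a
    tarsus-length-like trait on a 0.1 mm scale with
    Va = 13.5, Vpe = 8.22, Vres = 3.89 (total ≈ 25.6) around a mean of
    174.8, measured 1–3 times per bird by one of five measurers.
    """

    n_founders: int = 50
    n_generations: int = 4
    offspring_per_pair: int = 4
    epp_rate: float = 0.2
    n_snps: int = 8000
    maf_low: float = 0.05
    maf_high: float = 0.5
    Va: float = 13.5
    Vpe: float = 8.22
    Vres: float = 3.89
    trait_mean: float = 174.8
    n_measurers: int = 5
    measurer_effects: tuple = (0.0, 0.5, 3.9, 0.2, 0.0)
    repeats_low: int = 1
    repeats_high: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 2 or self.n_founders % 2:
            raise InvalidConfigError("n_founders must be an even number >= 2")
        if self.offspring_per_pair < 1:
            raise InvalidConfigError("offspring_per_pair must be >= 1")
        if self.n_generations < 1:
            raise InvalidConfigError("n_generations must be >= 1")
        if not 0.0 <= self.epp_rate <= 1.0:
            raise InvalidConfigError("epp_rate must lie in [0, 1]")
        if not (0.0 < self.maf_low <= self.maf_high <= 0.5):
            raise InvalidConfigError("need 0 < maf_low <= maf_high <= 0.5")
        if min(self.Va, self.Vpe, self.Vres) < 0:
            raise InvalidConfigError("variance components must be >= 0")
        if self.n_snps < 1:
            raise InvalidConfigError("n_snps must be >= 1")
        if not 1 <= self.repeats_low <= self.repeats_high:
            raise InvalidConfigError("need 1 <= repeats_low <= repeats_high")
        if len(self.measurer_effects) != self.n_measurers:
            raise InvalidConfigError("measurer_effects length must equal n_measurers")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    sexes = np.array((["M", "F"] * ((n + 1) // 2))[:n])
    rng.shuffle(sexes)
    return sexes


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Simulate a dual (social + genetic) pedigree with controlled EPP."""
    config.validate()
    rng = config.rng(_STAGE_PEDIGREE)
    rows = []
    founder_ids = [f"G0I{k:04d}" for k in range(1, config.n_founders + 1)]
    founder_sex = _balanced_sexes(config.n_founders, rng)
    for fid, sex in zip(founder_ids, founder_sex):
        rows.append(dict(id=fid, sire=None, dam=None, genetic_sire=None,
                         genetic_dam=None, generation=0, sex=sex, clutch=None))
    current_ids, current_sex = founder_ids, founder_sex
    for gen in range(1, config.n_generations):
        males = [i for i, s in zip(current_ids, current_sex) if s == "M"]
        females = [i for i, s in zip(current_ids, current_sex) if s == "F"]
        rng.shuffle(males)
        rng.shuffle(females)
        pairs = list(zip(males, females))
        if not pairs:
            raise PedigreeIntegrityError(f"no breeding pairs in generation {gen - 1}")
        n_off = len(pairs) * config.offspring_per_pair
        off_ids = [f"G{gen}I{k:04d}" for k in range(1, n_off + 1)]
        off_sex = _balanced_sexes(n_off, rng)
        k = 0
        for c, (sire, dam) in enumerate(pairs):
            clutch = f"G{gen}C{c + 1:03d}"
            for _ in range(config.offspring_per_pair):
                genetic_sire = sire
                if len(males) > 1 and rng.random() < config.epp_rate:
                    other = males[rng.integers(len(males) - 1)]
                    # index skips the social sire so the extra-pair male differs
                    if other == sire:
                        other = males[-1]
                    genetic_sire = other
                rows.append(dict(id=off_ids[k], sire=sire, dam=dam,
                                 genetic_sire=genetic_sire, genetic_dam=dam,
                                 generation=gen, sex=off_sex[k], clutch=clutch))
                k += 1
        current_ids, current_sex = off_ids, off_sex
    pedigree = Pedigree.from_frame(pd.DataFrame(rows))
    pedigree.validate()
    return pedigree


def simulate_genotypes(pedigree: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Gene-drop unlinked biallelic SNPs through the *genetic* links.

    Founder genotypes are Hardy–Weinberg draws at per-locus allele
    frequencies uniform in [maf_low, maf_high]; each offspring receives one
    allele per locus sampled uniformly from each genetic parent,
    independently across loci.  Dosages count the designated (founder-minor)
    allele.
    """
    config.validate()
    rng = config.rng(_STAGE_GENOTYPES)
    order = pedigree.topological_order("genetic")
    parents = pedigree.parent_map("genetic")
    m = config.n_snps
    freqs = rng.uniform(config.maf_low, config.maf_high, size=m)
    geno = {}
    for ind in order:
        sire, dam = parents[ind]
        if sire is None and dam is None:
            geno[ind] = rng.binomial(2, freqs).astype(float)
        elif sire is None or dam is None:
            raise PedigreeIntegrityError(
                f"non-founder {ind!r} is missing a genetic parent")
        else:
            from_sire = (rng.random(m) < geno[sire] / 2.0).astype(float)
            from_dam = (rng.random(m) < geno[dam] / 2.0).astype(float)
            geno[ind] = from_sire + from_dam
    ids = pedigree.ids
    dosages = np.vstack([geno[i] for i in ids])
    loci = [f"rs{j:05d}" for j in range(1, m + 1)]
    chrom = [_AUTOSOMES[j % len(_AUTOSOMES)] for j in range(m)]
    return GenotypeMatrix(ids=ids, loci=loci, dosages=dosages, chrom=chrom)


def simulate_phenotypes(pedigree: Pedigree, config: SimConfig):
    """Repeated polygenic measurements; returns (phenotypes, truth).

    Breeding values follow the additive infinitesimal model through the
    genetic links: founders ~ N(0, Va); an offspring's value is the mean of
    its genetic parents' values plus a Mendelian-sampling deviation
    ~ N(0, Va/2) (non-inbred approximation).  Each measurement adds the
    individual's permanent-environment effect ~ N(0, Vpe), a measurer
    offset (measurer drawn uniformly per measurement) and residual noise
    ~ N(0, Vres).  ``truth`` carries the simulated breeding values and
    permanent effects for parameter-recovery tests.
    """
    config.validate()
    rng = config.rng(_STAGE_PHENOTYPES)
    order = pedigree.topological_order("genetic")
    parents = pedigree.parent_map("genetic")
    sd_founder = float(np.sqrt(config.Va))
    sd_mendel = float(np.sqrt(config.Va / 2.0))
    bv = {}
    for ind in order:
        sire, dam = parents[ind]
        if sire is None and dam is None:
            bv[ind] = rng.normal(0.0, sd_founder)
        else:
            mid = 0.5 * (bv[sire] + bv[dam])
            bv[ind] = mid + rng.normal(0.0, sd_mendel)
    ids = pedigree.ids
    pe = dict(zip(ids, rng.normal(0.0, np.sqrt(config.Vpe), size=len(ids))))
    table = pedigree.table
    gen_of = dict(zip(table["id"], table.get("generation", pd.Series([0] * len(table)))))
    sex_of = dict(zip(table["id"], table.get("sex", pd.Series(["U"] * len(table)))))
    measurers = [f"m{k + 1}" for k in range(config.n_measurers)]
    effects = np.asarray(config.measurer_effects, dtype=float)
    records = []
    for ind in ids:
        n_rep = int(rng.integers(config.repeats_low, config.repeats_high + 1))
        for rep in range(n_rep):
            mi = int(rng.integers(config.n_measurers))
            y = (config.trait_mean + effects[mi] + bv[ind] + pe[ind]
                 + rng.normal(0.0, np.sqrt(config.Vres)))
            gen = int(gen_of.get(ind, 0) or 0)
            records.append(dict(id=ind, value=y, measurer=measurers[mi],
                                year=2003 + gen * 2 + rep, sex=sex_of.get(ind, "U"),
                                age=1 + rep))
    phenotypes = pd.DataFrame.from_records(records)
    truth = pd.DataFrame({
        "id": ids,
        "breeding_value": [bv[i] for i in ids],
        "permanent_effect": [pe[i] for i in ids],
    })
    return phenotypes, truth


def simulate_all(config: SimConfig):
    """Convenience wrapper: pedigree, genotypes, phenotypes, truth."""
    pedigree = simulate_pedigree(config)
    genotypes = simulate_genotypes(pedigree, config)
    phenotypes, truth = simulate_phenotypes(pedigree, config)
    return pedigree, genotypes, phenotypes, truth
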
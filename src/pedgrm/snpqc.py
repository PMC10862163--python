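"""Marker quality control: HWE exact test, MAF, missingness, sex chromosomes.

The filter cascade is applied in a fixed, logged order:

1. drop loci on excluded (sex) chromosomes;
2. drop loci whose missing rate exceeds ``snp_missing_max``;
3. drop individuals whose missing rate exceeds ``indiv_missing_max``;
4. recompute per-locus statistics on the remaining individuals, then drop
   loci with minor-allele frequency strictly below ``maf_min`` and finally
   loci with Hardy–Weinberg exact p-value strictly below ``hwe_alpha``.

Missing-rate bounds are inclusive ("maximum missing rate" / "no more
than"), while the MAF and HWE cuts are strict, mirroring the usual PLINK
threshold semantics.  The HWE test is the two-sided exact conditional test
(sum of the probabilities of all heterozygote counts no more likely than
the observed one, under the hypergeometric distribution with allele counts
fixed), computed in log space for stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import EmptyResultError
from .genotypes import GenotypeMatrix

#: chromosome labels treated as sex-linked by default (mammal X/Y, bird Z/W)
SEX_CHROMOSOMES = frozenset({"X", "Y", "Z", "W", "XY", "x", "y", "z", "w"})


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value for one biallelic locus.

    Conditions on the observed allele counts; the p-value is the summed
    probability of every heterozygote count (same parity as the observed
    one) whose conditional probability does not exceed that of the observed
    count.  Monomorphic loci return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    ok = hom_common >= 0
    hets, hom_rare, hom_common = hets[ok], hom_rare[ok], hom_common[ok]
    # log P(het = h | n, n_rare) up to a common constant
    logp = (hets * np.log(2.0)
            - gammaln(hom_rare + 1) - gammaln(hom_common + 1) - gammaln(hets + 1))
    logp -= logsumexp(logp)
    obs = int(n_Aa)
    obs_idx = np.flatnonzero(hets == obs)
    if obs_idx.size == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    log_obs = logp[obs_idx[0]]
    p = float(np.exp(logsumexp(logp[logp <= log_obs + 1e-12])))
    return min(p, 1.0)


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    present = col[~np.isnan(col)]
    n2 = int((present == 2).sum())
    n1 = int((present == 1).sum())
    n0 = int((present == 0).sum())
    return n0, n1, n2


@dataclass
class QCResult:
    """Filtered matrix plus per-locus / per-individual audit trails."""

    genotypes: GenotypeMatrix
    locus_report: pd.DataFrame      # locus, chrom, maf, missing_rate, hwe_p, pass, reason
    individual_report: pd.DataFrame  # id, missing_rate, pass
    attrition: list = field(default_factory=list)  # (stage, n_removed) in order

    @property
    def n_loci_kept(self) -> int:
        return self.genotypes.n_loci

    @property
    def n_individuals_kept(self) -> int:
        return self.genotypes.n_individuals


def apply_qc(genotypes: GenotypeMatrix,
             hwe_alpha: float = 0.001,
             maf_min: float = 0.05,
             snp_missing_max: float = 0.1,
             indiv_missing_max: float = 0.05,
             excluded_chromosomes=SEX_CHROMOSOMES) -> QCResult:
    """Apply the full marker QC cascade; every removal is recorded with its rule."""
    excluded_chromosomes = {str(c) for c in excluded_chromosomes}
    n_loci = genotypes.n_loci
    reason = np.array([""] * n_loci, dtype=object)
    attrition = []

    chrom = np.array(genotypes.chrom)
    drop_chr = np.isin(chrom, list(excluded_chromosomes))
    reason[drop_chr] = "excluded_chromosome"
    attrition.append(("excluded_chromosomes", int(drop_chr.sum())))

    miss0 = genotypes.locus_missing_rates()
    drop_miss = (~drop_chr) & (miss0 > snp_missing_max)
    reason[drop_miss] = "snp_missingness"
    attrition.append(("snp_missingness", int(drop_miss.sum())))

    keep_loci = ~(drop_chr | drop_miss)
    if not keep_loci.any():
        stage = "excluded_chromosomes" if drop_chr.all() else "snp_missingness"
        raise EmptyResultError(stage, "all loci removed before individual QC")
    stage1 = genotypes.subset(loci=[genotypes.loci[j] for j in np.flatnonzero(keep_loci)])

    ind_miss = stage1.individual_missing_rates()
    ind_keep = ind_miss <= indiv_missing_max
    individual_report = pd.DataFrame({
        "id": stage1.ids,
        "missing_rate": ind_miss,
        "pass": ind_keep,
    })
    attrition.append(("individual_missingness", int((~ind_keep).sum())))
    if not ind_keep.any():
        raise EmptyResultError("individual_missingness", "all individuals removed")
    stage2 = stage1.subset(ids=[stage1.ids[i] for i in np.flatnonzero(ind_keep)])

    # recompute per-locus statistics on the retained individuals
    maf = stage2.minor_allele_frequencies()
    miss = stage2.locus_missing_rates()
    hwe_p = np.ones(stage2.n_loci)
    for j in range(stage2.n_loci):
        n0, n1, n2 = _genotype_counts(stage2.dosages[:, j])
        hwe_p[j] = hwe_exact_pvalue(n0, n1, n2) if (n0 + n1 + n2) else 1.0

    drop_maf = maf < maf_min
    drop_hwe = (~drop_maf) & (hwe_p < hwe_alpha)
    attrition.append(("maf", int(drop_maf.sum())))
    attrition.append(("hwe", int(drop_hwe.sum())))

    pos = {v: k for k, v in enumerate(stage2.loci)}
    maf_full = np.full(n_loci, np.nan)
    miss_full = np.full(n_loci, np.nan)
    hwe_full = np.full(n_loci, np.nan)
    for j, locus in enumerate(genotypes.loci):
        if locus in pos:
            k = pos[locus]
            maf_full[j], miss_full[j], hwe_full[j] = maf[k], miss[k], hwe_p[k]
            if drop_maf[k]:
                reason[j] = "maf"
            elif drop_hwe[k]:
                reason[j] = "hwe"
    passed = reason == ""
    locus_report = pd.DataFrame({
        "locus": genotypes.loci,
        "chrom": genotypes.chrom,
        "maf": maf_full,
        "missing_rate": np.where(np.isnan(miss_full), miss0, miss_full),
        "hwe_p": hwe_full,
        "pass": passed,
        "reason": reason,
    })
    final_loci = [stage2.loci[k] for k in np.flatnonzero(~(drop_maf | drop_hwe))]
    if not final_loci:
        raise EmptyResultError("hwe", "all loci removed by MAF/HWE filters")
    filtered = stage2.subset(loci=final_loci)
    return QCResult(genotypes=filtered, locus_report=locus_report,
                    individual_report=individual_report, attrition=attrition)
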
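"""Biallelic SNP dosage matrix (individuals x loci, minor-allele coded)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoverageError, IdCollisionError, IdLookupError


@dataclass
class GenotypeMatrix:
    """Dosages in {0, 1, 2}; missing calls are NaN.

    ``dosages`` is a float array of shape (n_individuals, n_loci); ``chrom``
    carries one chromosome label per locus so sex-linked loci can be
    excluded during QC.
    """

    ids: list
    loci: list
    dosages: np.ndarray
    chrom: list = field(default_factory=list)

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.loci = [str(s) for s in self.loci]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if len(set(self.ids)) != len(self.ids):
            raise IdCollisionError("duplicated individual ids in genotype matrix")
        if self.dosages.shape != (len(self.ids), len(self.loci)):
            raise ValueError("dosage matrix shape does not match labels")
        if not self.chrom:
            self.chrom = ["1"] * len(self.loci)
        self.chrom = [str(c) for c in self.chrom]
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise ValueError(f"dosages must be 0/1/2/missing; found {bad}")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def allele_frequencies(self) -> np.ndarray:
        """Per-locus frequency of the coded (minor) allele among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        freq = self.allele_frequencies()
        return np.minimum(freq, 1.0 - freq)

    def locus_missing_rates(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def individual_missing_rates(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def subset(self, ids=None, loci=None) -> "GenotypeMatrix":
        row_idx = np.arange(self.n_individuals)
        col_idx = np.arange(self.n_loci)
        out_ids, out_loci = self.ids, self.loci
        if ids is not None:
            pos = {v: k for k, v in enumerate(self.ids)}
            try:
                row_idx = np.array([pos[str(i)] for i in ids], dtype=int)
            except KeyError as exc:
                raise IdLookupError(f"unknown individual id {exc.args[0]!r}") from exc
            out_ids = [str(i) for i in ids]
        if loci is not None:
            pos = {v: k for k, v in enumerate(self.loci)}
            try:
                col_idx = np.array([pos[str(s)] for s in loci], dtype=int)
            except KeyError as exc:
                raise IdLookupError(f"unknown locus id {exc.args[0]!r}") from exc
            out_loci = [str(s) for s in loci]
        chrom = [self.chrom[j] for j in col_idx]
        return GenotypeMatrix(ids=out_ids, loci=out_loci,
                              dosages=self.dosages[np.ix_(row_idx, col_idx)],
                              chrom=chrom)

    def require_coverage(self) -> None:
        """Every individual must have at least one non-missing call."""
        all_missing = self.missing_mask().all(axis=1)
        if all_missing.any():
            who = [self.ids[i] for i in np.flatnonzero(all_missing)]
            raise CoverageError(f"individuals with no genotype calls: {who}")
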
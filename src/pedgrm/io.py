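"""Readers and writers for the package's plain-text file dialects.

Pedigree CSV        id,sire,dam[,clutch,...]; missing parent = empty or "0".
PLINK text .ped/.map
                    six leading columns (FID IID PAT MAT SEX PHENO) then two
                    allele columns per locus; missing call = "0 0".  On
                    write, the major allele is "1" and the coded minor
                    allele "2"; on read, the counted allele is the minor
                    one by frequency (lexicographic tie-break), matching
                    PLINK's convention.
Dosage CSV          id column then one 0/1/2 column per locus; missing =
                    empty cell; chromosome labels travel in a companion
                    .map file.
Phenotype CSV       id,value,measurer,year,sex,age (long format, repeated
                    rows per individual).
Relatedness CSV     labelled square matrix (header + first column are ids),
                    or long format id1,id2,value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import MISSING_TOKENS, Pedigree
from .relatedness import RelatednessMatrix


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def read_pedigree_csv(path) -> Pedigree:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = frame.replace({tok: None for tok in MISSING_TOKENS if tok is not None})
    return Pedigree.from_frame(frame)


def write_pedigree_csv(pedigree: Pedigree, path, which: str = "social",
                       include_dummies: bool = True) -> None:
    table = pedigree.table.copy()
    if which == "genetic" and pedigree.is_dual:
        table["sire"] = table["genetic_sire"]
        table["dam"] = table["genetic_dam"]
    cols = [c for c in ("id", "sire", "dam", "generation", "sex", "clutch")
            if c in table.columns]
    out = table[cols]
    if not include_dummies:
        out = out[~out["id"].isin(pedigree.dummy_ids)]
    out = out.fillna("")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_plink(genotypes: GenotypeMatrix, ped_path, map_path,
                pedigree: Pedigree | None = None) -> None:
    """Write PLINK text .ped/.map; parent columns filled from ``pedigree``."""
    parent_map = pedigree.parent_map("social") if pedigree is not None else {}
    sex_col = {}
    if pedigree is not None and "sex" in pedigree.table.columns:
        sex_col = dict(zip(pedigree.table["id"], pedigree.table["sex"]))
    allele = {0.0: ("1", "1"), 1.0: ("1", "2"), 2.0: ("2", "2")}
    with open(ped_path, "w", newline="") as fh:
        for i, ind in enumerate(genotypes.ids):
            sire, dam = parent_map.get(ind, (None, None))
            sex = {"M": "1", "F": "2"}.get(sex_col.get(ind, ""), "0")
            fields = ["FAM1", ind, sire or "0", dam or "0", sex, "-9"]
            for value in genotypes.dosages[i]:
                pair = ("0", "0") if np.isnan(value) else allele[value]
                fields.extend(pair)
            fh.write("\t".join(fields) + "\n")
    write_map(genotypes, map_path)


def write_map(genotypes: GenotypeMatrix, map_path) -> None:
    with open(map_path, "w", newline="") as fh:
        for j, locus in enumerate(genotypes.loci):
            fh.write(f"{genotypes.chrom[j]}\t{locus}\t0\t{j + 1}\n")


def read_map(map_path) -> tuple[list, list]:
    loci, chrom = [], []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chrom.append(parts[0])
            loci.append(parts[1])
    return loci, chrom


def read_plink(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text .ped/.map into a minor-allele dosage matrix."""
    loci, chrom = read_map(map_path)
    m = len(loci)
    ids, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}")
            ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype=object).reshape(len(ids), m, 2)
    dosages = np.full((len(ids), m), np.nan)
    for j in range(m):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if uniq.size == 0:
            continue
        if uniq.size == 1:
            minor = uniq[0]  # monomorphic: count the only allele seen
            dosages[:, j] = np.where((col == "0").any(axis=1), np.nan,
                                     (col == minor).sum(axis=1))
            continue
        order = np.lexsort((uniq, counts))  # rarest first, lexicographic ties
        minor = uniq[order[0]]
        missing = (col == "0").any(axis=1)
        dosages[:, j] = np.where(missing, np.nan, (col == minor).sum(axis=1))
    return GenotypeMatrix(ids=ids, loci=loci, dosages=dosages, chrom=chrom)


def write_dosage_csv(genotypes: GenotypeMatrix, path, map_path=None) -> None:
    frame = pd.DataFrame(genotypes.dosages, columns=genotypes.loci)
    frame.insert(0, "id", genotypes.ids)
    frame.to_csv(path, index=False, float_format="%.0f")
    if map_path is not None:
        write_map(genotypes, map_path)


def read_dosage_csv(path, map_path=None) -> GenotypeMatrix:
    frame = pd.read_csv(path, dtype={"id": str})
    ids = frame["id"].tolist()
    loci = [c for c in frame.columns if c != "id"]
    dosages = frame[loci].to_numpy(dtype=float)
    chrom = None
    if map_path is not None:
        map_loci, map_chrom = read_map(map_path)
        by_locus = dict(zip(map_loci, map_chrom))
        chrom = [by_locus.get(l, "1") for l in loci]
    return GenotypeMatrix(ids=ids, loci=loci, dosages=dosages, chrom=chrom or [])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    if not {"id", "value"} <= set(frame.columns):
        raise ValueError("phenotype CSV needs at least 'id' and 'value' columns")
    return frame


def write_phenotypes_csv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# relatedness matrices
# ---------------------------------------------------------------------------

def write_relatedness_csv(matrix: RelatednessMatrix, path) -> None:
    frame = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    frame.to_csv(path, index_label="id")


def read_relatedness_csv(path, source: str = "genomic") -> RelatednessMatrix:
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    frame.index = frame.index.map(str)
    values = frame.to_numpy(dtype=float)
    values = 0.5 * (values + values.T)  # forgive printed-precision asymmetry
    return RelatednessMatrix(labels=list(frame.index), values=values, source=source)


def write_relatedness_long_csv(matrix: RelatednessMatrix, path) -> None:
    matrix.to_long_frame().to_csv(path, index=False)
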
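"""Relatedness matrices from pedigrees and SNPs, and their comparison.

Two matrix constructions are provided:

* :func:`build_a_matrix` — the expected additive (numerator) relationship
  matrix A from a pedigree, filled by the tabular method in topological
  order (diagonal ``1 + 0.5 * A(sire, dam)``, off-diagonal the mean of the
  row's entries with the younger individual's parents).
* :func:`build_grm_ibs` — mean identity-by-state allele sharing,
  ``mean((2 - |g_i - g_j|) / 2)`` over pairwise-complete loci (entries in
  [0, 1]; unrelated pairs sit near 0.7 at intermediate allele
  frequencies), matching the classic PLINK IBS similarity.
* :func:`build_grm_vanraden` — the allele-frequency-centred genomic
  relationship matrix ``W W' / (2 Σ p_j (1 - p_j))`` with
  ``W = dosage - 2p``.  Its expectation equals the pedigree A, so it is
  the construction of choice whenever genomic and pedigree estimates of
  additive variance must live on the same scale (model fitting, paternity
  thresholds at 0.3/0.1).

Also here: dummy-parent insertion for clutches with unknown parents,
pedigree summaries, trimming/projection to a genotyped subset, the Mantel
matrix comparison and threshold-based paternity classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    IdCollisionError,
    IdLookupError,
    UndefinedCorrelationError,
)
from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

logger = logging.getLogger(__name__)


@dataclass
class RelatednessMatrix:
    """Labelled symmetric matrix of pairwise relatedness or similarity."""

    labels: list
    values: np.ndarray
    source: str  # "pedigree" or "genomic"

    def __post_init__(self):
        self.labels = [str(x) for x in self.labels]
        if len(set(self.labels)) != len(self.labels):
            raise IdCollisionError("duplicated labels in relatedness matrix")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if n and np.abs(self.values - self.values.T).max() > 1e-12:
            raise ValueError("relatedness matrix must be symmetric within 1e-12")
        if self.source not in ("pedigree", "genomic"):
            raise ValueError("source must be 'pedigree' or 'genomic'")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label) -> int:
        try:
            return self.labels.index(str(label))
        except ValueError as exc:
            raise IdLookupError(f"id {label!r} absent from matrix") from exc

    def loc(self, a, b) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def reorder(self, labels) -> "RelatednessMatrix":
        pos = {v: k for k, v in enumerate(self.labels)}
        try:
            idx = np.array([pos[str(x)] for x in labels], dtype=int)
        except KeyError as exc:
            raise IdLookupError(f"id {exc.args[0]!r} absent from matrix") from exc
        return RelatednessMatrix(labels=[str(x) for x in labels],
                                 values=self.values[np.ix_(idx, idx)],
                                 source=self.source)

    def offdiagonal(self) -> np.ndarray:
        iu = np.tril_indices(self.n, k=-1)
        return self.values[iu]

    def to_long_frame(self) -> pd.DataFrame:
        i, j = np.tril_indices(self.n, k=0)
        return pd.DataFrame({
            "id1": [self.labels[a] for a in i],
            "id2": [self.labels[b] for b in j],
            "value": self.values[i, j],
        })


@dataclass
class PedigreeSummary:
    n_individuals: int
    n_maternities: int
    n_paternities: int
    n_full_sib_pairs: int
    mean_pairwise_relatedness: float
    max_depth: int


@dataclass
class PaternityResult:
    """Per-pair paternity labels plus the EPP rate they imply."""

    assignments: pd.DataFrame  # columns: father, offspring, similarity, label
    high: float
    low: float
    unresolved_in_denominator: bool = True

    @property
    def n_epp(self) -> int:
        return int((self.assignments["label"] == "epp").sum())

    @property
    def n_within_pair(self) -> int:
        return int((self.assignments["label"] == "within_pair").sum())

    @property
    def n_unresolved(self) -> int:
        return int((self.assignments["label"] == "unresolved").sum())

    @property
    def n_classified(self) -> int:
        n = len(self.assignments)
        return n if self.unresolved_in_denominator else n - self.n_unresolved

    @property
    def epp_rate(self) -> float:
        return self.n_epp / self.n_classified if self.n_classified else float("nan")

    @property
    def epp_rate_percent(self) -> float:
        return 100.0 * self.epp_rate


# ---------------------------------------------------------------------------
# dummy parents
# ---------------------------------------------------------------------------

def insert_dummy_parents(pedigree: Pedigree) -> Pedigree:
    """Give each sibling group with an unknown parent one shared dummy founder.

    Sibling groups are identified by the ``clutch`` column when present,
    otherwise by the known co-parent of the missing slot.  One new dummy id
    is minted per group and per missing parental slot ("common" dummies are
    within-clutch only); dummy ids are flagged on the returned pedigree so
    phenotype joins and pedigree summaries can exclude them, while the
    A-matrix recursion still uses them to preserve within-clutch covariance.
    """
    frame = pedigree.table.copy()
    existing = set(frame["id"])
    has_clutch = "clutch" in frame.columns and frame["clutch"].notna().any()
    new_dummies: list[str] = []
    counter = 0

    def mint(prefix: str) -> str:
        nonlocal counter
        while True:
            counter += 1
            cand = f"{prefix}{counter:04d}"
            if cand in existing:
                raise IdCollisionError(f"dummy id {cand!r} collides with a real id")
            if cand not in new_dummies:
                new_dummies.append(cand)
                return cand

    # rows with no parents and no clutch are founders, not chicks of an
    # observed nest — they never receive dummies
    founder_like = (frame["sire"].map(lambda v: v is None)
                    & frame["dam"].map(lambda v: v is None))
    if has_clutch:
        founder_like &= frame["clutch"].map(lambda v: v is None)
    for slot, other, prefix in (("sire", "dam", "DS"), ("dam", "sire", "DD")):
        missing = frame[slot].map(lambda v: v is None) & ~founder_like
        if not missing.any():
            continue
        sub = frame.loc[missing]
        if has_clutch:
            keys = sub["clutch"].map(lambda c: ("clutch", c) if c is not None else None)
        else:
            keys = sub[other].map(lambda p: ("parent", p) if p is not None else None)
        groups: dict = {}
        for row_idx, key in zip(sub.index, keys):
            if key is None:  # no group information: each chick its own group
                key = ("solo", row_idx)
            groups.setdefault(key, []).append(row_idx)
        for key, row_ids in groups.items():
            dummy = mint(prefix)
            frame.loc[row_ids, slot] = dummy
    if not new_dummies:
        return pedigree
    extra = pd.DataFrame({"id": new_dummies})
    for col in frame.columns:
        if col != "id":
            extra[col] = None
    merged = pd.concat([extra, frame], ignore_index=True)
    merged = merged.where(pd.notna(merged), None)
    out = Pedigree.from_frame(merged, dummy_ids=pedigree.dummy_ids | set(new_dummies))
    out.validate()
    return out


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------

def build_a_matrix(pedigree: Pedigree, which: str = "social") -> RelatednessMatrix:
    """Expected additive relationship matrix A via the tabular method."""
    order = pedigree.topological_order(which)
    parents = pedigree.parent_map(which)
    idx = {v: k for k, v in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        sire, dam = parents[ind]
        si = idx[sire] if sire is not None else None
        di = idx[dam] if dam is not None else None
        row = np.zeros(i)
        if si is not None:
            row += 0.5 * A[si, :i]
        if di is not None:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    # return in the pedigree's own row order
    ids = pedigree.ids
    perm = np.array([idx[i] for i in ids], dtype=int)
    return RelatednessMatrix(labels=ids, values=A[np.ix_(perm, perm)], source="pedigree")


def build_grm_ibs(genotypes: GenotypeMatrix) -> RelatednessMatrix:
    """Mean IBS allele sharing over pairwise-complete loci (entries in [0, 1])."""
    genotypes.require_coverage()
    X = genotypes.dosages
    present = (~np.isnan(X)).astype(float)
    ind = [np.where(np.nan_to_num(X) == v, present, 0.0) for v in (0.0, 1.0, 2.0)]
    I0, I1, I2 = ind
    shared = present @ present.T
    if (shared + np.eye(len(shared)) <= 0).any():
        i, j = np.argwhere(shared <= 0)[0]
        raise CoverageError(
            f"no shared non-missing loci for pair ({genotypes.ids[i]!r}, {genotypes.ids[j]!r})")
    hetero = (I0 + I2) @ I1.T
    dist = hetero + hetero.T + 2.0 * (I0 @ I2.T + I2 @ I0.T)
    values = 1.0 - dist / (2.0 * shared)
    values = 0.5 * (values + values.T)
    return RelatednessMatrix(labels=genotypes.ids, values=values, source="genomic")


def build_grm_vanraden(genotypes: GenotypeMatrix) -> RelatednessMatrix:
    """Allele-frequency-weighted GRM, ``W W' / (2 Σ p(1-p))``; E[G] ≈ A."""
    genotypes.require_coverage()
    X = genotypes.dosages
    freq = genotypes.allele_frequencies()
    keep = (freq > 0) & (freq < 1) & ~np.isnan(freq)
    if not keep.any():
        raise CoverageError("no polymorphic loci available for the GRM")
    Xk = X[:, keep]
    p = freq[keep]
    W = Xk - 2.0 * p
    W[np.isnan(W)] = 0.0  # missing calls imputed at the population mean
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    values = (W @ W.T) / denom
    values = 0.5 * (values + values.T)
    return RelatednessMatrix(labels=genotypes.ids, values=values, source="genomic")


def trim_to_common(obj, ids):
    """Restrict a relatedness matrix or pedigree to ``ids``.

    Matrices are subset exactly (order as given).  Pedigrees keep the
    ancestor closure of ``ids`` so relatedness transmitted through removed
    intermediates survives: build A on the trimmed pedigree, then project
    the matrix onto the id set.
    """
    ids = [str(i) for i in ids]
    if len(ids) == 0:
        warnings.warn("trim_to_common called with an empty id list", stacklevel=2)
    if isinstance(obj, RelatednessMatrix):
        return obj.reorder(ids)
    if isinstance(obj, Pedigree):
        known = set(obj.table["id"])
        unknown = [i for i in ids if i not in known]
        if unknown:
            raise IdLookupError(f"ids absent from pedigree: {unknown[:5]}")
        closure = obj.ancestor_closure(ids, which="both")
        frame = obj.table[obj.table["id"].isin(closure)]
        return Pedigree(table=frame.reset_index(drop=True),
                        dummy_ids=frozenset(d for d in obj.dummy_ids if d in closure))
    raise TypeError(f"cannot trim object of type {type(obj).__name__}")


def a_matrix_for(pedigree: Pedigree, ids, which: str = "social") -> RelatednessMatrix:
    """A matrix projected onto ``ids``, links through removed ancestors kept."""
    trimmed = trim_to_common(pedigree, ids)
    return build_a_matrix(trimmed, which=which).reorder(ids)


# ---------------------------------------------------------------------------
# comparison and classification
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    ci: tuple
    n_permutations: int
    n_bootstrap: int


def mantel_correlation(m1: RelatednessMatrix, m2: RelatednessMatrix,
                       n_perm: int = 9999, seed: int | None = None,
                       n_boot: int = 1000) -> MantelResult:
    """Mantel test between two relatedness matrices over the same individuals.

    ``r`` is the Pearson correlation of the strictly-lower-triangle entries;
    the one-sided p-value comes from ``n_perm`` simultaneous row/column
    permutations of ``m2`` (add-one correction); the confidence interval is
    a bootstrap percentile interval over individuals, excluding pairs formed
    by two copies of the same resampled individual.
    """
    if set(m1.labels) != set(m2.labels):
        raise IdLookupError("matrices must cover the same individuals")
    if m1.n < 3:
        raise ValueError("need at least 3 individuals for a Mantel test")
    m2 = m2.reorder(m1.labels)
    rng = np.random.default_rng(seed)
    il, jl = np.tril_indices(m1.n, k=-1)
    x = m1.values[il, jl]
    A2 = m2.values

    def _corr(u, v):
        su, sv = u.std(), v.std()
        if su == 0.0 or sv == 0.0:
            raise UndefinedCorrelationError("zero variance in off-diagonal entries")
        return float(np.corrcoef(u, v)[0, 1])

    r_obs = _corr(x, A2[il, jl])
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(m1.n)
        y = A2[np.ix_(perm, perm)][il, jl]
        sy = y.std()
        r_p = 0.0 if sy == 0.0 else float(np.corrcoef(x, y)[0, 1])
        if r_p >= r_obs:
            n_ge += 1
    p = (n_ge + 1.0) / (n_perm + 1.0)
    boots = []
    for _ in range(n_boot):
        take = rng.integers(m1.n, size=m1.n)
        keep = take[il] != take[jl]
        if keep.sum() < 3:
            continue
        bi, bj = take[il[keep]], take[jl[keep]]
        u = m1.values[bi, bj]
        v = A2[bi, bj]
        if u.std() == 0.0 or v.std() == 0.0:
            continue
        boots.append(float(np.corrcoef(u, v)[0, 1]))
    if boots:
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        ci = (float("nan"), float("nan"))
    return MantelResult(r=r_obs, p_value=p, ci=ci,
                        n_permutations=n_perm, n_bootstrap=n_boot)


def classify_paternity(similarity: RelatednessMatrix, pairs,
                       high: float = 0.3, low: float = 0.1,
                       unresolved_in_denominator: bool = True) -> PaternityResult:
    """Label social father–offspring pairs as within-pair / EPP / unresolved.

    A pair whose genetic similarity exceeds ``high`` keeps the social father
    as genetic father; below ``low`` it is classified as extra-pair;
    anything between is unresolved (counted, and by default kept in the
    rate denominator).  The thresholds assume a relatedness-scale matrix
    (unrelated ≈ 0, parent–offspring ≈ 0.5), e.g. from
    :func:`build_grm_vanraden`.
    """
    rows = []
    pos = {v: k for k, v in enumerate(similarity.labels)}
    for father, offspring in pairs:
        try:
            i, j = pos[str(father)], pos[str(offspring)]
        except KeyError as exc:
            raise IdLookupError(f"pair member {exc.args[0]!r} absent from matrix") from exc
        sim = float(similarity.values[i, j])
        if sim > high:
            label = "within_pair"
        elif sim < low:
            label = "epp"
        else:
            label = "unresolved"
        rows.append(dict(father=str(father), offspring=str(offspring),
                         similarity=sim, label=label))
    frame = pd.DataFrame(rows, columns=["father", "offspring", "similarity", "label"])
    return PaternityResult(assignments=frame, high=high, low=low,
                           unresolved_in_denominator=unresolved_in_denominator)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def pedigree_summary(pedigree: Pedigree, which: str = "social") -> PedigreeSummary:
    """Counts, depth and mean A-matrix off-diagonal, dummy parents excluded."""
    links = pedigree.links(which)
    dummies = pedigree.dummy_ids
    real = links[~links["id"].isin(dummies)]
    n_ind = len(real)
    if n_ind == 0:
        return PedigreeSummary(0, 0, 0, 0, 0.0, 0)
    known_dam = real["dam"].map(lambda p: p is not None and p not in dummies)
    known_sire = real["sire"].map(lambda p: p is not None and p not in dummies)
    n_mat = int(known_dam.sum())
    n_pat = int(known_sire.sum())
    both = real[known_dam & known_sire]
    n_sib = 0
    for _, grp in both.groupby(["sire", "dam"]):
        k = len(grp)
        n_sib += k * (k - 1) // 2
    parents = pedigree.parent_map(which)
    depth_cache: dict = {}
    for ind in pedigree.topological_order(which):
        s, d = parents[ind]
        ds = depth_cache[s] if s is not None else 0
        dd = depth_cache[d] if d is not None else 0
        depth_cache[ind] = 1 + max(ds, dd)
    max_depth = max(depth_cache[i] for i in real["id"])
    A = build_a_matrix(pedigree, which=which)
    if dummies:
        A = A.reorder(list(real["id"]))
    mean_rel = float(A.offdiagonal().mean()) if A.n > 1 else 0.0
    return PedigreeSummary(
        n_individuals=n_ind,
        n_maternities=n_mat,
        n_paternities=n_pat,
        n_full_sib_pairs=n_sib,
        mean_pairwise_relatedness=mean_rel,
        max_depth=int(max_depth),
    )
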
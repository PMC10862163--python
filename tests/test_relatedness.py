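import numpy as np
import pandas as pd
import pytest

from conftest import gene_drop_a_matrix
from pedgrm.errors import (
    CoverageError,
    IdCollisionError,
    IdLookupError,
    UndefinedCorrelationError,
)
from pedgrm.genotypes import GenotypeMatrix
from pedgrm.pedigree import Pedigree
from pedgrm.relatedness import (
    RelatednessMatrix,
    a_matrix_for,
    build_a_matrix,
    build_grm_ibs,
    build_grm_vanraden,
    classify_paternity,
    insert_dummy_parents,
    mantel_correlation,
    pedigree_summary,
    trim_to_common,
)


def _rel(labels, values, source="genomic"):
    return RelatednessMatrix(labels=labels, values=np.asarray(values, float),
                             source=source)


# ---------------------------------------------------------------------------
# A matrix
# ---------------------------------------------------------------------------

def test_a_matrix_founders_only_is_identity():
    ped = Pedigree.from_records([("a", None, None), ("b", None, None)])
    A = build_a_matrix(ped)
    np.testing.assert_allclose(A.values, np.eye(2))


def test_a_matrix_classic_relationships(trio_pedigree):
    A = build_a_matrix(trio_pedigree)
    assert A.loc("f1", "o1") == pytest.approx(0.5)   # parent-offspring
    assert A.loc("o1", "o2") == pytest.approx(0.5)   # full sibs
    half = Pedigree.from_records(
        [("s", None, None), ("d1", None, None), ("d2", None, None),
         ("h1", "s", "d1"), ("h2", "s", "d2")])
    assert build_a_matrix(half).loc("h1", "h2") == pytest.approx(0.25)


def test_a_matrix_full_sib_mating_inbreeds_diagonal(trio_pedigree):
    frame = pd.concat([trio_pedigree.table,
                       pd.DataFrame([{"id": "x", "sire": "o1", "dam": "o2"}])],
                      ignore_index=True)
    A = build_a_matrix(Pedigree.from_frame(frame))
    assert A.loc("x", "x") == pytest.approx(1.25)


def test_a_matrix_matches_gene_dropping_oracle():
    """Tabular-method A equals Monte-Carlo genome sharing (tol 0.02)."""
    ped = Pedigree.from_records(
        [("f1", None, None), ("f2", None, None), ("f3", None, None),
         ("a", "f1", "f2"), ("b", "f1", "f2"), ("c", "f1", "f3"),
         ("d", "a", "f3"), ("e", "a", "b"), ("g", "e", "c")])
    A = build_a_matrix(ped)
    mc, ids = gene_drop_a_matrix(ped, n_rep=20000, seed=42)
    assert ids == A.labels
    assert np.abs(A.values - mc).max() < 0.02


def test_a_matrix_positive_semidefinite_on_simulated_pedigree(small_population):
    _, ped, _, _, _ = small_population
    A = build_a_matrix(ped)
    eigmin = np.linalg.eigvalsh(A.values).min()
    assert eigmin > -1e-8


# ---------------------------------------------------------------------------
# genomic matrices
# ---------------------------------------------------------------------------

def test_ibs_identical_and_opposite_genotypes():
    g = GenotypeMatrix(ids=["a", "b", "c"], loci=["l1", "l2", "l3"],
                       dosages=[[0, 2, 1], [0, 2, 1], [2, 0, 1]])
    G = build_grm_ibs(g)
    assert G.loc("a", "b") == pytest.approx(1.0)
    assert G.loc("a", "a") == pytest.approx(1.0)
    opp = GenotypeMatrix(ids=["a", "b"], loci=["l1", "l2"],
                         dosages=[[0, 0], [2, 2]])
    assert build_grm_ibs(opp).loc("a", "b") == pytest.approx(0.0)


def test_ibs_hand_enumerated_example():
    # per-locus sharing (2-|gi-gj|)/2: (1 + 0 + 1)/3 = 2/3
    g = GenotypeMatrix(ids=["i", "j"], loci=["l1", "l2", "l3"],
                       dosages=[[0, 2, 1], [0, 0, 1]])
    assert build_grm_ibs(g).loc("i", "j") == pytest.approx(2.0 / 3.0)


def test_ibs_pairwise_complete_ignores_missing_loci():
    g = GenotypeMatrix(ids=["i", "j"], loci=["l1", "l2", "l3"],
                       dosages=[[0, np.nan, 1], [0, 2, 1]])
    assert build_grm_ibs(g).loc("i", "j") == pytest.approx(1.0)


def test_ibs_all_missing_individual_raises():
    g = GenotypeMatrix(ids=["i", "j"], loci=["l1"],
                       dosages=[[np.nan], [1.0]])
    with pytest.raises(CoverageError, match="i"):
        build_grm_ibs(g)


def test_ibs_monotone_in_pedigree_kinship(small_population):
    """mean G(parent-offspring) > mean G(half sibs) > mean G(unrelated)."""
    from pedgrm.simulate import SimConfig, simulate_genotypes, simulate_pedigree
    cfg = SimConfig(seed=33, n_founders=60, n_generations=3,
                    offspring_per_pair=4, n_snps=1000, epp_rate=0.3)
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    G = build_grm_ibs(geno)
    A = build_a_matrix(ped, which="genetic")
    iu = np.tril_indices(A.n, k=-1)
    a_vals, g_vals = A.values[iu], G.reorder(A.labels).values[iu]
    po = g_vals[np.isclose(a_vals, 0.5)].mean()
    hs = g_vals[np.isclose(a_vals, 0.25)].mean()
    un = g_vals[np.isclose(a_vals, 0.0)].mean()
    assert po > hs > un


def test_vanraden_expectation_tracks_pedigree():
    """Centred GRM is on the A scale: parent-offspring ~ 0.5, unrelated ~ 0.

    Uses a shallow population with a wide founder base; in deep
    populations with few founders, centring on sample allele frequencies
    shifts all entries downward (documented limitation).
    """
    from pedgrm.simulate import SimConfig, simulate_genotypes, simulate_pedigree
    cfg = SimConfig(seed=44, n_founders=100, n_generations=2,
                    offspring_per_pair=4, n_snps=800)
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    G = build_grm_vanraden(geno)
    A = build_a_matrix(ped, which="genetic").reorder(G.labels)
    iu = np.tril_indices(G.n, k=-1)
    a_vals, g_vals = A.values[iu], G.values[iu]
    assert abs(g_vals[np.isclose(a_vals, 0.5)].mean() - 0.5) < 0.1
    assert abs(g_vals[np.isclose(a_vals, 0.0)].mean() - 0.0) < 0.1


# ---------------------------------------------------------------------------
# trimming / projection
# ---------------------------------------------------------------------------

def test_trim_matrix_identity_and_unknown_id(trio_pedigree):
    A = build_a_matrix(trio_pedigree)
    same = trim_to_common(A, A.labels)
    np.testing.assert_array_equal(same.values, A.values)
    with pytest.raises(IdLookupError):
        trim_to_common(A, ["nope"])


def test_trim_pedigree_projects_through_removed_intermediate():
    """Grandparent-grandchild entry 0.25 survives removal of the parent."""
    ped = Pedigree.from_records(
        [("gp", None, None), ("gm", None, None), ("d2", None, None),
         ("par", "gp", "gm"), ("kid", "par", "d2")])
    A_sub = a_matrix_for(ped, ["gp", "kid"])
    full = build_a_matrix(ped)
    assert A_sub.loc("gp", "kid") == pytest.approx(0.25)
    assert A_sub.loc("gp", "kid") == pytest.approx(full.loc("gp", "kid"))


def test_trim_empty_warns(trio_pedigree):
    A = build_a_matrix(trio_pedigree)
    with pytest.warns(UserWarning, match="empty"):
        out = trim_to_common(A, [])
    assert out.n == 0


# ---------------------------------------------------------------------------
# dummy parents
# ---------------------------------------------------------------------------

def test_dummy_sire_shared_within_clutch():
    ped = Pedigree.from_frame(pd.DataFrame({
        "id": ["d", "c1", "c2", "c3"],
        "sire": [None, None, None, None],
        "dam": [None, "d", "d", "d"],
        "clutch": [None, "n1", "n1", "n1"],
    }))
    out = insert_dummy_parents(ped)
    sires = out.table.set_index("id").loc[["c1", "c2", "c3"], "sire"]
    assert sires.nunique() == 1
    assert sires.iloc[0] in out.dummy_ids


def test_dummy_noop_on_complete_pedigree(trio_pedigree):
    out = insert_dummy_parents(trio_pedigree)
    assert out.dummy_ids == frozenset()
    pd.testing.assert_frame_equal(out.table, trio_pedigree.table)


def test_distinct_nests_get_distinct_dummies():
    ped = Pedigree.from_frame(pd.DataFrame({
        "id": ["d1", "d2", "a", "b"],
        "sire": [None] * 4,
        "dam": [None, None, "d1", "d2"],
        "clutch": [None, None, "n1", "n2"],
    }))
    out = insert_dummy_parents(ped)
    sires = out.table.set_index("id").loc[["a", "b"], "sire"]
    assert sires.nunique() == 2


def test_dummy_id_collision_detected():
    ped = Pedigree.from_frame(pd.DataFrame({
        "id": ["DS0001", "d", "c"],
        "sire": [None, None, None],
        "dam": [None, None, "d"],
        "clutch": [None, None, "n1"],
    }))
    with pytest.raises(IdCollisionError):
        insert_dummy_parents(ped)


def test_dummies_preserve_within_clutch_covariance():
    """Chicks sharing a dummy sire become full sibs in A (0.5)."""
    ped = Pedigree.from_frame(pd.DataFrame({
        "id": ["d", "c1", "c2"],
        "sire": [None, None, None],
        "dam": [None, "d", "d"],
        "clutch": [None, "n1", "n1"],
    }))
    out = insert_dummy_parents(ped)
    A = build_a_matrix(out)
    assert A.loc("c1", "c2") == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _random_sym(n, rng, source="genomic"):
    m = rng.random((n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 1.0)
    return _rel([f"i{k}" for k in range(n)], m, source)


def test_mantel_self_comparison_is_maximal():
    rng = np.random.default_rng(0)
    m = _random_sym(8, rng)
    res = mantel_correlation(m, m, n_perm=99, seed=1)
    assert res.r == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0 / 100.0)


def test_mantel_r_matches_direct_pearson_enumeration():
    """r equals the Pearson correlation of the 6 lower-triangle pairs."""
    m1 = _rel(list("abcd"), [[1, .1, .2, .3], [.1, 1, .4, .5],
                             [.2, .4, 1, .6], [.3, .5, .6, 1]])
    m2 = _rel(list("abcd"), [[1, .15, .1, .33], [.15, 1, .42, .18],
                             [.1, .42, 1, .61], [.33, .18, .61, 1]])
    res = mantel_correlation(m1, m2, n_perm=99, seed=2)
    x = [.1, .2, .4, .3, .5, .6]
    y = [.15, .1, .42, .33, .18, .61]
    assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)


def test_mantel_constant_matrix_rejected():
    m1 = _random_sym(5, np.random.default_rng(3))
    flat = _rel(m1.labels, np.ones((5, 5)))
    with pytest.raises(UndefinedCorrelationError):
        mantel_correlation(m1, flat, n_perm=9, seed=4)


def test_mantel_invariant_to_simultaneous_relabeling():
    rng = np.random.default_rng(5)
    m1, m2 = _random_sym(7, rng), _random_sym(7, rng)
    res1 = mantel_correlation(m1, m2, n_perm=199, seed=6)
    perm = rng.permutation(7)
    relab = [m1.labels[i] for i in perm]
    res2 = mantel_correlation(m1.reorder(relab), m2.reorder(relab),
                              n_perm=199, seed=6)
    assert res2.r == pytest.approx(res1.r, abs=1e-12)


# ---------------------------------------------------------------------------
# paternity classification
# ---------------------------------------------------------------------------

def test_classification_thresholds():
    sim = _rel(["f", "o1", "o2", "o3"],
               [[1, .5, .05, .2], [.5, 1, 0, 0], [.05, 0, 1, 0], [.2, 0, 0, 1]])
    res = classify_paternity(sim, [("f", "o1"), ("f", "o2"), ("f", "o3")])
    labels = dict(zip(res.assignments["offspring"], res.assignments["label"]))
    assert labels == {"o1": "within_pair", "o2": "epp", "o3": "unresolved"}
    assert res.n_unresolved == 1


def test_classification_rate_from_counts():
    n, k = 114, 20
    labels = [f"o{i}" for i in range(n)] + ["f"]
    vals = np.eye(n + 1)
    for i in range(n):
        vals[i, n] = vals[n, i] = 0.05 if i < k else 0.5
    res = classify_paternity(_rel(labels, vals), [("f", f"o{i}") for i in range(n)])
    assert res.n_epp == 20
    assert res.epp_rate_percent == pytest.approx(17.54, abs=0.005)


def test_classification_missing_member_raises():
    sim = _rel(["a", "b"], np.eye(2))
    with pytest.raises(IdLookupError):
        classify_paternity(sim, [("a", "zz")])


def test_classification_separates_truth_on_simulated_data():
    """0.3/0.1 on the centred GRM recover every simulated paternity.

    The thresholds presuppose a mostly unrelated population (as in wild
    study systems with mean pairwise relatedness near zero), hence the
    wide founder base here.
    """
    from pedgrm.simulate import SimConfig, simulate_genotypes, simulate_pedigree
    cfg = SimConfig(seed=77, n_founders=120, n_generations=2,
                    offspring_per_pair=4, n_snps=1000, epp_rate=0.25)
    ped = simulate_pedigree(cfg)
    geno = simulate_genotypes(ped, cfg)
    G = build_grm_vanraden(geno)
    rows = [r for r in ped.table.itertuples(index=False) if r.sire is not None]
    res = classify_paternity(G, [(r.sire, r.id) for r in rows])
    truth = ["within_pair" if r.genetic_sire == r.sire else "epp" for r in rows]
    assert res.n_unresolved == 0
    assert list(res.assignments["label"]) == truth


# ---------------------------------------------------------------------------
# pedigree summaries
# ---------------------------------------------------------------------------

def test_summary_empty_pedigree():
    s = pedigree_summary(Pedigree.from_frame(pd.DataFrame({"id": []})))
    assert (s.n_individuals, s.n_maternities, s.max_depth) == (0, 0, 0)


def test_summary_founders_only():
    ped = Pedigree.from_records([("a", None, None), ("b", None, None)])
    s = pedigree_summary(ped)
    assert s.max_depth == 1
    assert s.n_full_sib_pairs == 0
    assert s.mean_pairwise_relatedness == pytest.approx(0.0)


def test_summary_two_founders_two_offspring(trio_pedigree):
    """Hand-built A: off-diagonal mean = (0 + 4*0.5 + 0.5)/6 = 2.5/6."""
    s = pedigree_summary(trio_pedigree)
    assert s.n_individuals == 4
    assert s.n_maternities == 2 and s.n_paternities == 2
    assert s.n_full_sib_pairs == 1
    assert s.max_depth == 2
    assert s.mean_pairwise_relatedness == pytest.approx(2.5 / 6.0)


def test_summary_excludes_dummy_parents():
    ped = Pedigree.from_frame(pd.DataFrame({
        "id": ["d", "c1", "c2"],
        "sire": [None, None, None],
        "dam": [None, "d", "d"],
        "clutch": [None, "n1", "n1"],
    }))
    out = insert_dummy_parents(ped)
    s = pedigree_summary(out)
    assert s.n_individuals == 3          # the dummy sire is not counted
    assert s.n_paternities == 0          # dummy paternities do not count
    assert s.n_maternities == 2
    assert s.n_full_sib_pairs == 0       # sib pairs need two *known* parents
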
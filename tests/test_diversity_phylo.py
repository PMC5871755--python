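import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

import amplicord as ac
from conftest import random_profile, random_tree


# ---------------------------------------------------------------------------
# Brute-force UniFrac oracle: explicit per-branch enumeration in pure Python.


def oracle_generalized(tree, pa, pb, alpha):
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        tips = [t.name for t in node.tips()] or [node.name]
        a = sum(pa.get(t, 0.0) for t in tips)
        b = sum(pb.get(t, 0.0) for t in tips)
        m = a + b
        if m <= 0:
            continue
        w = (node.length or 0.0) * m**alpha
        num += w * abs(a - b) / m
        den += w
    return num / den if den else 0.0


def oracle_unweighted(tree, pa, pb):
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        tips = [t.name for t in node.tips()] or [node.name]
        a = sum(pa.get(t, 0.0) for t in tips) > 0
        b = sum(pb.get(t, 0.0) for t in tips) > 0
        if a or b:
            den += node.length or 0.0
        if a != b:
            num += node.length or 0.0
    return num / den if den else 0.0


def test_inverse_simpson():
    assert ac.inverse_simpson([1, 1]) == pytest.approx(2.0)
    assert ac.inverse_simpson([5, 0, 0]) == pytest.approx(1.0)
    for k in (3, 7, 20):
        assert ac.inverse_simpson([4] * k) == pytest.approx(k)
    with pytest.raises(ValueError):
        ac.inverse_simpson([0, 0])


def test_rarefaction_curve_limits():
    counts = [50, 30, 20]
    full = ac.rarefaction_curve(counts, [1, 100], n_reps=8, seed=0)
    assert full.mean[0] == pytest.approx(1.0)  # a single individual
    assert full.sd[0] == 0.0
    assert full.mean[1] == pytest.approx(ac.inverse_simpson(counts))
    assert full.sd[1] == 0.0

    sub = ac.rarefaction_curve(counts, [80], n_reps=50, seed=1)
    assert abs(sub.mean[0] - ac.inverse_simpson(counts)) <= 3 * max(sub.sd[0], 1e-9)

    with pytest.raises(ValueError):
        ac.rarefaction_curve(counts, [101], n_reps=3, seed=0)


def test_nj_tree_two_and_three_taxa():
    two = ac.nj_tree(DistanceMatrix(np.array([[0, 0.4], [0.4, 0]]), ids=["A", "B"]))
    assert {t.name: t.length for t in two.tips()} == {"A": 0.2, "B": 0.2}

    # closed-form three-point formulas: bx = (dxy + dxz - dyz)/2 etc.
    d = DistanceMatrix(
        np.array([[0, 0.6, 0.8], [0.6, 0, 1.0], [0.8, 1.0, 0]]), ids=["X", "Y", "Z"]
    )
    tree = ac.nj_tree(d)
    for pair, expected in (("XY", 0.6), ("XZ", 0.8), ("YZ", 1.0)):
        a, b = pair
        assert tree.find(a).distance(tree.find(b)) == pytest.approx(expected)


def test_nj_tree_additive_four_taxon_recovery():
    # distances generated by ((A:1,B:2):1,(C:2,D:3):1) as an additive matrix
    d = DistanceMatrix(
        np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 5], [6, 7, 5, 0]], dtype=float
        ),
        ids=list("ABCD"),
    )
    tree = ac.nj_tree(d)
    for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
        assert tree.find(a).distance(tree.find(b)) == pytest.approx(d.data[i, j])
    with pytest.raises(Exception):
        ac.nj_tree(np.array([[0, 1], [2, 0]]))


def test_midpoint_root_splits_longest_path():
    two = ac.midpoint_root(ac.parse_newick("(A:1,B:3);"))
    assert {t.name: t.distance(two) for t in two.tips()} == {"A": 2.0, "B": 2.0}

    sym = ac.midpoint_root(ac.parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
    for tip in sym.tips():
        assert tip.distance(sym) == pytest.approx(2.0)


def test_midpoint_root_preserves_pairwise_distances():
    rng = np.random.default_rng(10)
    tree = random_tree(rng, 7)
    rooted = ac.midpoint_root(tree)
    names = sorted(t.name for t in tree.tips())
    assert sorted(t.name for t in rooted.tips()) == names
    for a, b in itertools.combinations(names, 2):
        before = tree.find(a).distance(tree.find(b))
        after = rooted.find(a).distance(rooted.find(b))
        assert after == pytest.approx(before)


def test_generalized_unifrac_basic_values():
    tree = ac.parse_newick("((A:1,B:2):0.5,C:3);")
    for alpha in (0.0, 0.5, 1.0):
        assert ac.generalized_unifrac(tree, {"A": 1.0}, {"A": 1.0}, alpha) == 0.0
    # hand enumeration at alpha=1: branches A(1) and B(2) fully unshared,
    # internal branch (0.5) shared -> (1 + 2) / (1 + 2 + 0.5*2) = 0.75
    assert ac.generalized_unifrac(tree, {"A": 1.0}, {"B": 1.0}, 1.0) == pytest.approx(0.75)

    star = ac.parse_newick("(A:1,B:1,C:1);")
    for alpha in (0.0, 0.3, 1.0):
        assert ac.generalized_unifrac(star, {"A": 1.0}, {"B": 1.0}, alpha) == 1.0
    assert ac.unweighted_unifrac(star, {"A": 1.0}, {"B": 1.0}) == 1.0

    with pytest.raises(ValueError, match="missing"):
        ac.generalized_unifrac(star, {"Z": 1.0}, {"A": 1.0}, 0.5)


def test_generalized_unifrac_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    worst = 0.0
    for _ in range(300):
        n = int(rng.integers(3, 9))
        tree = random_tree(rng, n)
        leaves = [t.name for t in tree.tips()]
        pa = random_profile(rng, leaves)
        pb = random_profile(rng, leaves)
        alpha = float(rng.uniform(0, 1))
        mine = ac.generalized_unifrac(tree, pa, pb, alpha)
        worst = max(worst, abs(mine - oracle_generalized(tree, pa, pb, alpha)))
        worst = max(
            worst, abs(ac.unweighted_unifrac(tree, pa, pb) - oracle_unweighted(tree, pa, pb))
        )
    assert worst < 1e-12


def test_unweighted_unifrac_invariant_to_abundance_skew():
    rng = np.random.default_rng(12)
    tree = random_tree(rng, 6)
    leaves = [t.name for t in tree.tips()]
    pa = {leaves[0]: 0.5, leaves[1]: 0.5}
    pb = {leaves[2]: 0.5, leaves[3]: 0.5}
    base_u = ac.unweighted_unifrac(tree, pa, pb)
    base_w = ac.generalized_unifrac(tree, pa, pb, 1.0)
    skew_a = {leaves[0]: 0.99, leaves[1]: 0.01}
    assert ac.unweighted_unifrac(tree, skew_a, pb) == pytest.approx(base_u)
    assert ac.generalized_unifrac(tree, skew_a, pb, 1.0) != pytest.approx(base_w)


def test_weighted_and_unweighted_match_skbio():
    from skbio.diversity import beta_diversity

    tree = ac.parse_newick("((A:0.3,B:0.7):0.2,(C:1.1,D:0.4):0.6);")
    counts = np.array([[6, 2, 0, 0], [0, 2, 1, 1]])
    taxa = ["A", "B", "C", "D"]
    pa = {"A": 0.75, "B": 0.25}
    pb = {"B": 0.5, "C": 0.25, "D": 0.25}
    sk_w = beta_diversity(
        "weighted_unifrac", counts, ids=["x", "y"], taxa=taxa, tree=tree, normalized=True
    )[0, 1]
    sk_u = beta_diversity(
        "unweighted_unifrac", counts, ids=["x", "y"], taxa=taxa, tree=tree
    )[0, 1]
    assert ac.generalized_unifrac(tree, pa, pb, 1.0) == pytest.approx(sk_w, abs=1e-12)
    assert ac.unweighted_unifrac(tree, pa, pb) == pytest.approx(sk_u, abs=1e-12)


def test_unifrac_matrix_variants(db20, lineages20, index20):
    taxa = [t.accession for t in db20[:6]]
    table = ac.OTUTable(
        taxa=taxa,
        samples=["s1", "s2", "s3"],
        counts=np.array(
            [[30, 30, 0], [20, 20, 5], [10, 10, 45], [5, 5, 40], [5, 5, 0], [30, 30, 10]]
        ),
        lineages={t: lineages20[t] for t in taxa},
    )
    tree = ac.reference_tree([index20[t] for t in taxa])
    matrices = ac.unifrac_matrix(table, tree)
    assert set(matrices) == set(ac.diversity_phylo.UNIFRAC_VARIANTS)
    for dm in matrices.values():
        data = dm.data
        assert np.allclose(data, data.T)
        assert np.allclose(np.diag(data), 0)
        # duplicated sample columns s1 == s2 -> zero distance in every variant
        assert data[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert data[0, 2] > 0
    # d_W is the alpha=1 generalized form entrywise
    rel = table.relative_abundance()
    profiles = [dict(rel[s]) for s in table.samples]
    assert matrices["d_W"][0, 2] == pytest.approx(
        ac.generalized_unifrac(tree, profiles[0], profiles[2], 1.0)
    )


def test_pcoa_collinear_and_euclidean_exactness():
    d = DistanceMatrix(
        np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float), ids=["a", "b", "c"]
    )
    res = ac.pcoa(d)
    positive = [e for e in res.eigenvalues if e > 1e-9]
    assert len(positive) == 1  # three collinear points
    coords = res.coordinates["PC1"]
    assert abs(coords["a"] - coords["c"]) == pytest.approx(2.0)
    assert abs(coords["a"] - coords["b"]) == pytest.approx(1.0)
    assert sum(res.proportion_explained) == pytest.approx(1.0)

    rng = np.random.default_rng(13)
    pts = rng.normal(size=(6, 2))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    res2 = ac.pcoa(DistanceMatrix(D, ids=[f"s{i}" for i in range(6)]))
    C = res2.coordinates.to_numpy()
    D2 = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
    assert np.abs(D - D2).max() < 1e-9


def test_pcoa_zero_matrix_and_sign_convention():
    res = ac.pcoa(DistanceMatrix(np.zeros((3, 3)), ids=["a", "b", "c"]))
    assert res.coordinates.shape[1] == 0  # no positive axes at all

    rng = np.random.default_rng(14)
    pts = rng.normal(size=(5, 3))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    res2 = ac.pcoa(DistanceMatrix(D, ids=list("abcde")))
    for col in res2.coordinates.columns:
        vals = res2.coordinates[col].to_numpy()
        assert vals[np.argmax(np.abs(vals))] > 0


# ---------------------------------------------------------------------------
# perMANOVA


def _euclid_dm(points, prefix="s"):
    D = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(D, ids=[f"{prefix}{i}" for i in range(len(points))])


def oracle_exact_permanova(dm, labels):
    """Literal enumeration over all distinct label arrangements."""
    labels = list(labels)
    n = len(labels)

    def f_stat(lab):
        groups = sorted(set(lab))
        sst = sum(dm.data[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ssw = 0.0
        for g in groups:
            idx = [i for i, l in enumerate(lab) if l == g]
            ssw += sum(
                dm.data[i, j] ** 2 for i in idx for j in idx if i < j
            ) / len(idx)
        ssb = sst - ssw
        return (ssb / (len(groups) - 1)) / (ssw / (n - len(groups)))

    f_obs = f_stat(labels)
    arrangements = sorted(set(itertools.permutations(labels)))
    hits = sum(1 for arr in arrangements if f_stat(arr) >= f_obs - 1e-12)
    return f_obs, hits / len(arrangements)


def test_permanova_exact_matches_enumeration_oracle():
    rng = np.random.default_rng(15)
    pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(1.5, 1, (3, 2))])
    dm = _euclid_dm(pts)
    labels = ["g1"] * 3 + ["g2"] * 3
    mine = ac.permanova(dm, labels, exact=True)
    f_oracle, p_oracle = oracle_exact_permanova(dm, labels)
    assert mine.pseudo_f == pytest.approx(f_oracle)
    assert mine.p_value == pytest.approx(p_oracle)
    assert mine.n_permutations == 20  # 6!/(3!3!) label splits x orderings collapse


def test_permanova_matches_skbio_statistic():
    from skbio.stats.distance import permanova as sk_permanova

    rng = np.random.default_rng(16)
    pts = np.vstack([rng.normal(0, 1, (4, 3)), rng.normal(1, 1, (5, 3))])
    dm = _euclid_dm(pts)
    labels = ["a"] * 4 + ["b"] * 5
    mine = ac.permanova(dm, labels, n_permutations=99, seed=0)
    sk = sk_permanova(dm, grouping=labels, permutations=99)
    assert mine.pseudo_f == pytest.approx(float(sk["test statistic"]))


def test_permanova_degenerate_inputs():
    dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("abcd"))
    result = ac.permanova(dm, ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)
    assert result.p_value == 1.0  # constant distances: every labelling alike

    zero = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
    res0 = ac.permanova(zero, ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)
    assert res0.p_value == 1.0

    with pytest.raises(ValueError, match="single sample"):
        ac.permanova(dm, ["g1", "g2", "g2", "g2"])
    with pytest.raises(ValueError, match="2 groups"):
        ac.permanova(dm, ["g1", "g1", "g1", "g1"])


def test_permanova_p_floor():
    rng = np.random.default_rng(17)
    pts = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(10, 0.1, (4, 2))])
    dm = _euclid_dm(pts)
    res = ac.permanova(dm, ["a"] * 4 + ["b"] * 4, n_permutations=199, seed=3)
    assert res.p_value >= 1 / 200
    assert res.pseudo_f > 10
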
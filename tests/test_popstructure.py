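"""Kinship, distances, PCA, neighbor joining, admixture EM and deltaK."""

import numpy as np
import pytest

from panelgwas.io_formats import MISSING, GenotypeMatrix
from panelgwas.popstructure import (
    AdmixtureReplicate,
    admixture_fit,
    align_labels,
    centered_ibs_kinship,
    evanno_delta_k,
    ibs_distance,
    neighbor_joining,
    pca_genotypes,
)
from panelgwas.synthetic import SimulationConfig, simulate_population


def _gm(calls, prefix="a"):
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeMatrix(
        [f"m{i}" for i in range(calls.shape[0])],
        [f"{prefix}{j}" for j in range(calls.shape[1])],
        calls,
    )


# ---------------------------------------------------------------------- kinship

def test_kinship_hand_computed_2x2():
    """Dosages [[0,2],[2,0]]: W = [[-1,1],[1,-1]], c = 1 -> K = [[2,-2],[-2,2]]."""
    K = centered_ibs_kinship(_gm([[0, 2], [2, 0]]))
    assert np.allclose(K, [[2.0, -2.0], [-2.0, 2.0]])


def test_kinship_identical_accessions_equal_rows():
    K = centered_ibs_kinship(_gm([[0, 0, 2], [2, 2, 0], [1, 1, 1]]))
    assert np.allclose(K[0], K[1])
    assert K[0, 0] == pytest.approx(K[0, 1])


def test_kinship_psd_and_missing_rejected(small_panel):
    gm, _, _ = small_panel
    with pytest.raises(ValueError, match="imputation"):
        centered_ibs_kinship(gm)
    clean = gm.copy()
    clean.calls[clean.calls == MISSING] = 0
    K = centered_ibs_kinship(clean)
    assert np.linalg.eigvalsh(K).min() >= -1e-8
    assert np.allclose(K, K.T)


# ---------------------------------------------------------------------- distance

@pytest.mark.parametrize(
    "a,b,expected",
    [(0, 0, 0.0), (0, 2, 1.0), (0, 1, 0.5), (1, 1, 0.0)],
)
def test_ibs_distance_pairs(a, b, expected):
    gm = _gm(np.full((10, 2), [[a, b]]))
    D = ibs_distance(gm)
    assert D[0, 1] == pytest.approx(expected)
    assert D[0, 0] == 0.0


def test_ibs_distance_skips_missing_pairs():
    calls = np.array([[0, 2], [0, MISSING], [2, 0]], dtype=np.int8)
    D = ibs_distance(_gm(calls))
    assert D[0, 1] == pytest.approx(1.0)  # two informative markers, both opposite


# ---------------------------------------------------------------------- PCA

def test_pca_rank_one_matrix():
    gm = _gm([[0, 2, 0, 2], [0, 2, 0, 2], [0, 2, 0, 2]])
    scores, frac = pca_genotypes(gm, 2)
    assert frac[0] == pytest.approx(1.0)


def test_pca_matches_dense_eigensolver_up_to_sign():
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, size=(6, 4)).astype(np.int8)
    gm = _gm(calls)
    scores, frac = pca_genotypes(gm, 3)
    X = calls.astype(float)
    A = (X - X.mean(axis=1, keepdims=True)).T
    evals, evecs = np.linalg.eigh(A @ A.T)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    assert np.allclose(frac, (evals / evals.sum())[:3], atol=1e-10)
    for k in range(3):
        ref = evecs[:, k] * np.sqrt(evals[k])
        assert np.allclose(scores[:, k], ref, atol=1e-8) or np.allclose(
            scores[:, k], -ref, atol=1e-8
        )


def test_pca_variance_fractions_sum_to_one():
    rng = np.random.default_rng(1)
    gm = _gm(rng.integers(0, 3, size=(20, 8)).astype(np.int8))
    _, frac = pca_genotypes(gm, 8)
    assert frac.sum() == pytest.approx(1.0)


def test_pca_component_clipping_warns():
    gm = _gm([[0, 2, 1], [2, 0, 1]])
    with pytest.warns(UserWarning, match="clipped"):
        scores, _ = pca_genotypes(gm, 10)
    assert scores.shape[1] <= 3


# ---------------------------------------------------------------------- NJ

def _tip_distances(tree):
    tips = sorted(tree.tips(), key=lambda t: t.name)
    names = [t.name for t in tips]
    n = len(tips)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tips[i].distance(tips[j])
    return names, D


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path-length matrix
    D = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    tree = neighbor_joining(D, list("ABCD"), midpoint_root=False)
    names, D_hat = _tip_distances(tree)
    order = [names.index(x) for x in "ABCD"]
    assert np.allclose(D_hat[np.ix_(order, order)], D, atol=1e-9)
    # A and B are sisters
    a = [t for t in tree.tips() if t.name == "A"][0]
    assert {t.name for t in a.parent.tips()} == {"A", "B"}


def test_nj_exact_recovery_random_additive_matrices():
    """Path-length matrices of random binary trees are reproduced exactly."""
    rng = np.random.default_rng(7)
    for n_taxa in (5, 6, 7, 8):
        for _ in range(5):
            # random additive matrix via random binary tree with positive edges
            D = _random_additive_matrix(rng, n_taxa)
            labels = [f"t{i}" for i in range(n_taxa)]
            tree = neighbor_joining(D, labels, midpoint_root=False)
            names, D_hat = _tip_distances(tree)
            order = [names.index(x) for x in labels]
            assert np.allclose(D_hat[np.ix_(order, order)], D, atol=1e-8)


def _random_additive_matrix(rng, n_taxa):
    """Build a random binary tree by sequential attachment; return its
    tip-to-tip path lengths (the independent additivity oracle)."""
    # adjacency of a tree grown by splitting random edges
    import networkx as nx

    g = nx.Graph()
    g.add_edge(0, 1, w=float(rng.uniform(0.5, 2.0)))
    next_internal = n_taxa
    for leaf in range(2, n_taxa):
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        w = g[u][v]["w"]
        g.remove_edge(u, v)
        mid = next_internal
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, w=w * split)
        g.add_edge(mid, v, w=w * (1 - split))
        g.add_edge(mid, leaf, w=float(rng.uniform(0.5, 2.0)))
    D = np.zeros((n_taxa, n_taxa))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="w"))
    for i in range(n_taxa):
        for j in range(n_taxa):
            D[i, j] = lengths[i][j]
    return (D + D.T) / 2.0  # remove float asymmetry from path sums


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
    tree = neighbor_joining(D, list("ABC"), midpoint_root=False)
    names, D_hat = _tip_distances(tree)
    order = [names.index(x) for x in "ABC"]
    assert np.allclose(D_hat[np.ix_(order, order)], D, atol=1e-12)


def test_nj_matches_skbio_on_random_matrices():
    """Independent-implementation cross-check on additive inputs."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(3)
    D = _random_additive_matrix(rng, 6)
    labels = [f"t{i}" for i in range(6)]
    ours = neighbor_joining(D, labels, midpoint_root=False)
    theirs = skbio_nj(DistanceMatrix(D, labels))
    _, D_ours = _tip_distances(ours)
    _, D_theirs = _tip_distances(theirs)
    assert np.allclose(D_ours, D_theirs, atol=1e-8)


def test_nj_midpoint_rooting_separates_clusters():
    """Ultrametric 2-cluster matrix -> clusters monophyletic after midpoint."""
    n = 6
    D = np.full((n, n), 1.0)
    D[:3, :3] = 0.2
    D[3:, 3:] = 0.2
    np.fill_diagonal(D, 0.0)
    labels = ["x1", "x2", "x3", "y1", "y2", "y3"]
    tree = neighbor_joining(D, labels)
    children = tree.children
    sides = [{t.name for t in c.tips()} or {c.name} for c in children]
    assert {"x1", "x2", "x3"} in sides or {"y1", "y2", "y3"} in sides


def test_nj_input_validation():
    with pytest.raises(ValueError, match="3 taxa"):
        neighbor_joining(np.zeros((2, 2)), ["A", "B"])
    D = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]])
    with pytest.raises(ValueError, match="undefined"):
        neighbor_joining(D, list("ABC"))


# ---------------------------------------------------------------------- admixture

def test_admixture_k1_closed_form():
    rng = np.random.default_rng(0)
    gm = _gm(rng.integers(0, 3, size=(50, 20)).astype(np.int8))
    (rep,) = admixture_fit(gm, K=1)
    X = gm.calls.astype(float).T
    p = X.mean(axis=0) / 2.0
    p_c = np.clip(p, 1e-6, 1 - 1e-6)
    ll = float(np.sum(X * np.log(p_c) + (2 - X) * np.log(1 - p_c)))
    assert np.allclose(rep.P[:, 0], p)
    assert rep.log_likelihood == pytest.approx(ll, abs=1e-8)


def test_admixture_loglik_monotone_every_iteration():
    cfg = SimulationConfig(n_accessions=40, n_markers=80, rng_seed=2,
                           base_missing_rate=0.0, translocation=None)
    gm, _, _ = simulate_population(cfg)
    for seed in (0, 1, 2):
        (rep,) = admixture_fit(gm, K=3, seeds=[seed], keep_trajectory=True)
        diffs = np.diff(rep.trajectory)
        assert (diffs >= -1e-6).all()


def test_admixture_recovers_two_fixed_populations():
    """Two strongly diverged subpopulations: Q within 0.05 of truth."""
    cfg = SimulationConfig(n_accessions=80, n_markers=500, rng_seed=5,
                           divergence=0.5, admixture_fraction=0.0,
                           base_missing_rate=0.0, het_rate=0.0,
                           translocation=None)
    gm, _, truth = simulate_population(cfg)
    reps = admixture_fit(gm, K=2, seeds=[0, 1, 2])
    best = max(reps, key=lambda r: r.log_likelihood)
    Q = align_labels(best.Q, truth.ancestry)
    assert np.abs(Q - truth.ancestry).max() <= 0.05
    assert np.allclose(Q.sum(axis=1), 1.0)


def test_admixture_k_bounds():
    gm = _gm([[0, 2], [2, 0]])
    with pytest.raises(ValueError):
        admixture_fit(gm, K=0)
    with pytest.raises(ValueError):
        admixture_fit(gm, K=5)


# ---------------------------------------------------------------------- Evanno

def _reps(lls_by_k):
    out = []
    for k, lls in lls_by_k.items():
        for r, ll in enumerate(lls):
            out.append(AdmixtureReplicate(K=k, replicate=r, log_likelihood=ll,
                                          Q=np.zeros((1, k)), P=np.zeros((1, k))))
    return out


def test_evanno_hand_example():
    """deltaK(2) = mean |L(3) - 2 L(2) + L(1)| / sd(L(2)) = 90 / 1.414 = 63.6."""
    table = evanno_delta_k(_reps({1: [-1000, -1002], 2: [-900, -902],
                                  3: [-890, -892]}))
    row = table[table["K"] == 2].iloc[0]
    assert row["delta_K"] == pytest.approx(90 / np.std([-900, -902], ddof=1))
    assert row["delta_K"] == pytest.approx(63.64, abs=0.01)
    assert np.isnan(table[table["K"] == 1]["delta_K"].iloc[0])


def test_evanno_linear_in_k_gives_zero():
    table = evanno_delta_k(_reps({1: [-300, -301], 2: [-200, -201],
                                  3: [-100, -101]}))
    assert table[table["K"] == 2]["delta_K"].iloc[0] == pytest.approx(0.0)


def test_evanno_errors():
    with pytest.raises(ValueError, match="two K"):
        evanno_delta_k(_reps({2: [-1, -2]}))
    with pytest.raises(ValueError, match="contiguous"):
        evanno_delta_k(_reps({1: [-1, -2], 3: [-1, -2]}))
    with pytest.raises(ValueError, match="2 replicates"):
        evanno_delta_k(_reps({1: [-1], 2: [-1]}))
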
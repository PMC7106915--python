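"""Alignment, NJ consistency, bootstrap, clade mixture and MST networks."""

import itertools

import numpy as np
import pytest

from amp_typer.phylo import (DistanceMatrix, bootstrap_support,
                             clade_species_mixture, hamming_distance_matrix,
                             msa_center_star, mst_network, nj_tree,
                             p_distance_matrix)

from conftest import random_resolved_tree, tree_path_distances


def test_center_star_identity_and_single_gap():
    seqs = {"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"}
    assert msa_center_star(seqs) == seqs
    out = msa_center_star({"a": "ACGT", "b": "ACT"})
    assert len(out["a"]) == len(out["b"]) == 4
    assert out["b"].count("-") == 1
    assert out["a"].replace("-", "") == "ACGT"
    with pytest.raises(ValueError):
        msa_center_star({})


def test_center_star_merges_three_sequences_consistently():
    out = msa_center_star({"a": "ACGTGG", "b": "ACTGG", "c": "AGTGG"})
    L = {len(s) for s in out.values()}
    assert len(L) == 1
    for name, s in out.items():
        assert s.replace("-", "") == {"a": "ACGTGG", "b": "ACTGG",
                                      "c": "AGTGG"}[name]


def test_nj_recovers_additive_four_taxon_tree():
    # distances from ((A:1,B:2):1,(C:3,D:4))
    labels = ["A", "B", "C", "D"]
    m = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                 dtype=float)
    tree = nj_tree(DistanceMatrix(labels, m))
    assert set(tree.bipartitions()) == {frozenset({"C", "D"})}
    lengths = {lf.name: lf.length for lf in tree.root.leaves()}
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(2.0)


def test_nj_three_taxa_three_point_formulas():
    m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(["a", "b", "c"], m))
    lengths = {lf.name: lf.length for lf in tree.root.leaves()}
    assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def test_nj_consistent_on_random_additive_matrices():
    rng = np.random.default_rng(23)
    hits = 0
    for _ in range(100):
        true = random_resolved_tree(8, rng, lo=0.5, hi=2.0)
        labels, d = tree_path_distances(true)
        est = nj_tree(DistanceMatrix(labels, d))
        if set(est.bipartitions()) == set(true.bipartitions()):
            hits += 1
    assert hits == 100


def test_nj_matches_independent_implementation():
    # cross-check topology against scikit-bio's NJ on a noisy matrix
    import skbio
    rng = np.random.default_rng(5)
    true = random_resolved_tree(7, rng, lo=0.3, hi=1.5)
    labels, d = tree_path_distances(true)
    d = d + rng.uniform(0, 0.05, size=d.shape)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0)
    ours = nj_tree(DistanceMatrix(labels, d))
    ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
    ref_biparts = set()
    all_set = frozenset(labels)
    refleaf = min(labels)
    for node in ref.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(labels) - 2:
            ref_biparts.add(side if refleaf not in side else all_set - side)
    assert set(ours.bipartitions()) == ref_biparts


def _two_clade_alignment(rng, n_per=4, diagnostic=20, noise_cols=30):
    base = "".join(rng.choice(list("ACGT"), size=noise_cols))
    seqs = {}
    for i in range(n_per):
        seqs[f"x{i}"] = base + "A" * diagnostic
        seqs[f"y{i}"] = base + "C" * diagnostic
    # sprinkle private mutations so leaves are distinct
    for k, name in enumerate(sorted(seqs)):
        s = list(seqs[name])
        s[k] = "T"
        seqs[name] = "".join(s)
    return seqs


def test_bootstrap_supports_separated_clades():
    rng = np.random.default_rng(7)
    seqs = _two_clade_alignment(rng)
    tree = bootstrap_support(seqs, n_reps=200, seed=3)
    bp = {frozenset(k): v.support for k, v in tree.bipartitions().items()}
    split = frozenset(n for n in seqs if n.startswith(
        "y" if "x0" == min(seqs) else "x"))
    assert bp[split] >= 95
    # identical seeds give identical supports
    tree2 = bootstrap_support(seqs, n_reps=200, seed=3)
    assert {k: v.support for k, v in tree.bipartitions().items()} == \
        {k: v.support for k, v in tree2.bipartitions().items()}


def test_bootstrap_invariant_to_leaf_order():
    rng = np.random.default_rng(8)
    seqs = _two_clade_alignment(rng)
    t1 = bootstrap_support(seqs, n_reps=100, seed=1)
    reordered = dict(reversed(list(seqs.items())))
    t2 = bootstrap_support(reordered, n_reps=100, seed=1)
    assert {k: v.support for k, v in t1.bipartitions().items()} == \
        {k: v.support for k, v in t2.bipartitions().items()}


def test_clade_mixture_extremes():
    seqs = {"a_sp1": "AAAAAAAAAA", "b_sp1": "AAAAAAAAAT",
            "c_sp2": "CCCCCCCCCC", "d_sp2": "CCCCCCCCCT"}
    tree = nj_tree(p_distance_matrix(seqs))
    rep = clade_species_mixture(tree, {n: n.split("_")[1] for n in seqs})
    assert rep.fraction_mixed == 0.0
    mixed = {"a_sp1": "AAAAAAAAAA", "b_sp2": "AAAAAAAAAT",
             "c_sp1": "CCCCCCCCCC", "d_sp2": "CCCCCCCCCT"}
    tree = nj_tree(p_distance_matrix(mixed))
    rep = clade_species_mixture(tree, {n: n.split("_")[1] for n in mixed})
    assert rep.fraction_mixed == 1.0
    with pytest.raises(ValueError):
        clade_species_mixture(tree, {})


def test_shared_alleles_produce_mixed_clades():
    from amp_typer.synthdata import SimConfig, simulate_allele_pool
    shared = simulate_allele_pool(SimConfig(seed=21, shared_allele_frac=0.3))
    gp = shared.genes["Temporin"]
    seqs = {}
    for sp in gp.alleles:
        for i, s in enumerate(gp.species_alleles(sp)):
            seqs.setdefault(s, f"{sp}_{i}")
    inv = {name: s.split("_")[0] for s, name in
           ((s, n) for s, n in seqs.items())}
    aligned = {name: s for s, name in seqs.items()}
    tree = nj_tree(p_distance_matrix(aligned))
    rep = clade_species_mixture(tree, inv, support_threshold=0)
    assert rep.fraction_mixed > 0

    lone = simulate_allele_pool(SimConfig(seed=21, shared_allele_frac=0.0,
                                          species_divergence=0.3))
    gp = lone.genes["Temporin"]
    seqs = {f"{sp}_{i}": s for sp in gp.alleles
            for i, s in enumerate(gp.species_alleles(sp))}
    tree = nj_tree(p_distance_matrix(seqs))
    rep = clade_species_mixture(tree, {n: n.split("_")[0] for n in seqs},
                                support_threshold=0)
    # strongly diverged species ancestors: the two species separate cleanly
    assert rep.fraction_mixed < 0.3


def test_mst_basic_cases():
    dm = DistanceMatrix(["h1", "h2", "h3"],
                        np.array([[0, 1, 1], [1, 0, 2], [1, 2, 0]], float))
    edges = mst_network(dm)
    assert edges == [("h1", "h2", 1.0), ("h1", "h3", 1.0)]
    same = hamming_distance_matrix({"a": "AAAA", "b": "AAAA", "c": "AAAA"})
    edges = mst_network(same)
    assert len(edges) == 2 and all(w == 0 for *_, w in edges)


def _brute_force_mst_weight(dm):
    n = len(dm.labels)
    all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = None
    for combo in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x
        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            w = sum(dm.matrix[i, j] for i, j in combo)
            best = w if best is None else min(best, w)
    return best


def test_mst_weight_matches_exhaustive_enumeration():
    rng = np.random.default_rng(9)
    for n in (4, 5, 6, 7):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=12))
                for i in range(n)}
        dm = hamming_distance_matrix(seqs)
        got = sum(w for *_, w in mst_network(dm))
        assert got == pytest.approx(_brute_force_mst_weight(dm))


def test_mst_epsilon_adds_near_minimal_edges():
    dm = DistanceMatrix(["a", "b", "c"],
                        np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
    assert len(mst_network(dm)) == 2
    assert len(mst_network(dm, epsilon=0.5)) == 3
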
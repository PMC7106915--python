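"""Counting and likelihood machinery for positive-selection inference."""

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from amp_typer._codons import (CODON_INDEX, SENSE_CODONS, SYN_SITES,
                               path_counts)
from amp_typer.phylo import Tree, TreeNode
from amp_typer.selection import (CodonAlignment, CodonModelSpec,
                                 beta_class_means, build_rate_matrix,
                                 codon_loglik, f3x4_frequencies,
                                 fit_nested_pair, fit_site_model, lrt,
                                 neb_positive_sites, ng86_pairwise,
                                 simulate_codon_alignment, slac_site_scan)

from conftest import random_resolved_tree

UNIFORM_PI = np.ones(61) / 61


def test_ng86_site_fractions_reference_codon():
    # TTT: third position 1/3 synonymous (TTC), positions 1-2 nonsynonymous
    assert SYN_SITES[CODON_INDEX["TTT"]] == pytest.approx(1 / 3)
    # every sense codon satisfies S + N = 3 by construction
    assert np.allclose(SYN_SITES + (3 - SYN_SITES), 3.0)
    assert np.all(SYN_SITES >= 0) and np.all(SYN_SITES < 3)


def test_ng86_pairwise_examples():
    same = ng86_pairwise("TTTAAA", "TTTAAA")
    assert same.syn_diffs == 0 and same.nonsyn_diffs == 0
    assert same.ds == 0 and same.omega is None
    one_syn = ng86_pairwise("TTTAAA", "TTCAAA")
    assert one_syn.syn_diffs == pytest.approx(1.0)
    assert one_syn.nonsyn_diffs == pytest.approx(0.0)
    with pytest.raises(ValueError):
        ng86_pairwise("TTT", "TT")
    with pytest.raises(ValueError):
        ng86_pairwise("TAA", "TTT")


def test_path_counts_multi_hit_average():
    # TTT -> GTA: averaged over both orderings, excludes stop pathways
    s, n = path_counts("TTT", "CTC")  # F->L at pos1 (nonsyn), syn at pos3
    assert s + n == pytest.approx(2.0)


def _star3(lengths=(0.2, 0.3, 0.1)):
    leaves = [TreeNode(name=n, length=l) for n, l in zip("ABC", lengths)]
    return Tree(root=TreeNode(children=leaves))


def test_loglik_matches_bruteforce_three_taxon_oracle():
    rng = np.random.default_rng(0)
    tree = _star3()
    spec = CodonModelSpec(model="M0", kappa=3.0, omega=0.4,
                          codon_freqs=UNIFORM_PI)
    codons = {t: [SENSE_CODONS[i] for i in rng.integers(0, 61, 6)]
              for t in "ABC"}
    aln = CodonAlignment(taxa=["A", "B", "C"], codons=codons)
    lnl = codon_loglik(aln, tree, spec)
    q = build_rate_matrix(3.0, 0.4, UNIFORM_PI)
    p_mats = [expm(q * t) for t in (0.2, 0.3, 0.1)]
    brute = 0.0
    for s in range(6):
        idxs = [CODON_INDEX[codons[t][s]] for t in "ABC"]
        site = sum(UNIFORM_PI[r] * p_mats[0][r, idxs[0]]
                   * p_mats[1][r, idxs[1]] * p_mats[2][r, idxs[2]]
                   for r in range(61))
        brute += np.log(site)
    assert abs(lnl - brute) < 1e-8


def test_loglik_zero_branches_identical_sequences():
    tree = _star3(lengths=(0.0, 0.0, 0.0))
    codons = {t: ["ATG", "AAA"] for t in "ABC"}
    aln = CodonAlignment(taxa=["A", "B", "C"], codons=codons)
    spec = CodonModelSpec(model="M0", kappa=2.0, omega=1.0,
                          codon_freqs=UNIFORM_PI)
    lnl = codon_loglik(aln, tree, spec)
    expected = sum(np.log(UNIFORM_PI[CODON_INDEX[c]]) for c in ("ATG", "AAA"))
    assert lnl == pytest.approx(expected, abs=1e-9)


def test_loglik_invariant_to_taxon_relabeling():
    rng = np.random.default_rng(1)
    tree = random_resolved_tree(5, rng)
    spec = CodonModelSpec(model="M0", kappa=2.0, omega=0.5,
                          codon_freqs=UNIFORM_PI)
    aln, _, _ = simulate_codon_alignment(tree, spec, 40, seed=2)
    lnl = codon_loglik(aln, tree, spec)
    # swap two leaf names consistently in tree and alignment
    a, b = sorted(aln.taxa)[:2]
    swap = {a: b, b: a}
    for lf in tree.root.leaves():
        lf.name = swap.get(lf.name, lf.name)
    codons = {swap.get(t, t): c for t, c in aln.codons.items()}
    aln2 = CodonAlignment(taxa=sorted(codons), codons=codons)
    assert codon_loglik(aln2, tree, spec) == pytest.approx(lnl, abs=1e-9)


def test_f3x4_matches_simulated_root_frequencies():
    # chi-square goodness of fit of 50k root draws against the F3x4 target
    nf = np.array([[.3, .2, .3, .2], [.25, .25, .25, .25], [.4, .1, .2, .3]])
    from amp_typer._codons import NUC_INDEX
    pi = np.array([nf[0, NUC_INDEX[c[0]]] * nf[1, NUC_INDEX[c[1]]]
                   * nf[2, NUC_INDEX[c[2]]] for c in SENSE_CODONS])
    pi /= pi.sum()
    rng = np.random.default_rng(3)
    draws = rng.choice(61, size=50_000, p=pi)
    observed = np.bincount(draws, minlength=61)
    chi2 = (((observed - 50_000 * pi) ** 2) / (50_000 * pi)).sum()
    assert chi2 < stats.chi2.ppf(0.99, df=60)


def test_simulator_degenerate_cases():
    tree = _star3(lengths=(0.0, 0.0, 0.0))
    spec = CodonModelSpec(model="M0", kappa=2.0, omega=0.5,
                          codon_freqs=UNIFORM_PI)
    aln, _, _ = simulate_codon_alignment(tree, spec, 30, seed=4)
    cols = {tuple(aln.codons[t]) for t in aln.taxa}
    assert len(cols) == 1
    # omega ~ 0: no nonsynonymous substitutions anywhere
    from amp_typer._codons import translate
    spec0 = CodonModelSpec(model="M0", kappa=2.0, omega=1e-9,
                           codon_freqs=UNIFORM_PI)
    tree2 = _star3(lengths=(0.5, 0.5, 0.5))
    aln0, _, _ = simulate_codon_alignment(tree2, spec0, 60, seed=5)
    aas = {translate("".join(aln0.codons[t])) for t in aln0.taxa}
    assert len(aas) == 1


def test_beta_discretization_moments():
    for p, q in ((0.5, 2.0), (2.0, 2.0), (0.2, 0.3)):
        means = beta_class_means(p, q, 10)
        assert np.all((means > 0) & (means < 1))
        assert means.mean() == pytest.approx(p / (p + q), rel=1e-6)
        assert np.all(np.diff(means) > 0)


def test_m0_fit_recovers_parameters():
    rng = np.random.default_rng(6)
    tree = random_resolved_tree(6, rng)
    spec = CodonModelSpec(model="M0", kappa=2.0, omega=0.3,
                          codon_freqs=UNIFORM_PI)
    oms, kps = [], []
    for rep in range(3):
        aln, _, _ = simulate_codon_alignment(tree, spec, 300, seed=60 + rep)
        fit = fit_site_model(aln, tree, "M0", seed=0)
        oms.append(fit.spec.omega)
        kps.append(fit.spec.kappa)
    assert 0.2 < np.mean(oms) < 0.4
    assert 1.4 < np.mean(kps) < 2.6


def test_nested_fits_and_lrt():
    rng = np.random.default_rng(7)
    tree = random_resolved_tree(6, rng)
    spec = CodonModelSpec(model="M0", kappa=2.0, omega=0.2,
                          codon_freqs=UNIFORM_PI)
    aln, _, _ = simulate_codon_alignment(tree, spec, 120, seed=8)
    m0, nf, af = fit_nested_pair(aln, tree, "M1a", "M2a", seed=0,
                                 n_restarts=2)
    assert af.lnl >= nf.lnl  # nesting
    stat, df, p = lrt(nf, af)
    assert df == 2 and 0 < p <= 1
    # purifying data: the positive class collapses
    p2 = 1 - af.spec.p0 - af.spec.p1
    assert p2 < 0.05 or af.spec.omega2 <= 1.05
    with pytest.raises(ValueError):
        lrt(af, nf)


def test_lrt_reference_values():
    spec = CodonModelSpec(model="M1a")
    a = _fit_stub(spec, -100.0)
    b = _fit_stub(CodonModelSpec(model="M2a"), -100.0)
    stat, df, p = lrt(a, b)
    assert stat == 0.0 and p == 1.0
    c = _fit_stub(CodonModelSpec(model="M2a"), -100.0 + 5.99 / 2)
    stat, df, p = lrt(a, c)
    assert p == pytest.approx(stats.chi2.sf(5.99, 2), rel=1e-12)
    assert p == pytest.approx(0.05, abs=0.002)


def _fit_stub(spec, lnl):
    from amp_typer.selection import FitResult
    return FitResult(spec=spec, lnl=lnl, converged=True, n_restarts=1)


def test_neb_posteriors_normalize_and_empty_without_positive_class():
    rng = np.random.default_rng(9)
    tree = random_resolved_tree(5, rng)
    true = CodonModelSpec(model="M2a", kappa=2.0, omega0=0.2, p0=0.5, p1=0.3,
                          omega2=4.0, codon_freqs=UNIFORM_PI)
    aln, _, _ = simulate_codon_alignment(tree, true, 80, seed=10)
    from amp_typer.selection import FitResult
    fit = FitResult(spec=CodonModelSpec(
        model="M2a", kappa=2.0, omega0=0.2, p0=0.5, p1=0.3, omega2=4.0,
        codon_freqs=f3x4_frequencies(aln)), lnl=0.0, converged=True,
        n_restarts=1)
    sites, post = neb_positive_sites(fit, aln, tree)
    assert np.all((post >= 0) & (post <= 1))
    null_fit = _fit_stub(CodonModelSpec(model="M1a", kappa=2.0, omega0=0.2,
                                        p0=0.6, codon_freqs=UNIFORM_PI), 0.0)
    assert neb_positive_sites(null_fit, aln, tree)[0] == []


def test_slac_toy_and_invariant_alignment():
    codons = {"A": ["TTT", "AAA"], "B": ["TTC", "AAA"],
              "C": ["TTT", "AAA"], "D": ["TTT", "AAA"]}
    aln = CodonAlignment(taxa=sorted(codons), codons=codons)
    leaves = [TreeNode(name=n, length=0.1) for n in "ABCD"]
    tree = Tree(root=TreeNode(children=[
        TreeNode(children=leaves[:2], length=0.1), leaves[2], leaves[3]]))
    res = slac_site_scan(aln, tree)
    assert res.sites[0]["syn"] == pytest.approx(1.0)
    assert res.sites[0]["nonsyn"] == pytest.approx(0.0)
    assert res.sites[1]["syn"] == 0 and res.sites[1]["nonsyn"] == 0
    assert res.sites[1]["p_value"] == 1.0
    const = CodonAlignment(taxa=sorted(codons),
                           codons={t: ["ATG"] * 3 for t in codons})
    res = slac_site_scan(const, tree)
    assert res.total_syn == 0 and res.total_nonsyn == 0
    assert res.mean_omega is None


def test_codon_alignment_excludes_gap_and_stop_columns():
    seqs = {"A": "ATGTAAACG---", "B": "ATGAAAACGCCC"}
    aln = CodonAlignment.from_nucleotide(seqs)
    assert aln.n_sites == 2  # TAA column and gap column dropped
    assert aln.n_excluded == 2


def test_lrt_statistic_invariant_to_column_permutation():
    rng = np.random.default_rng(11)
    tree = random_resolved_tree(5, rng)
    spec = CodonModelSpec(model="M0", kappa=2.0, omega=0.4,
                          codon_freqs=UNIFORM_PI)
    aln, _, _ = simulate_codon_alignment(tree, spec, 60, seed=12)
    perm = rng.permutation(aln.n_sites)
    shuffled = CodonAlignment(
        taxa=aln.taxa,
        codons={t: [aln.codons[t][j] for j in perm] for t in aln.taxa})
    s1 = CodonModelSpec(model="M1a", kappa=2.0, omega0=0.3, p0=0.7,
                        codon_freqs=UNIFORM_PI)
    assert codon_loglik(aln, tree, s1) == pytest.approx(
        codon_loglik(shuffled, tree, s1), abs=1e-9)
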
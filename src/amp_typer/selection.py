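"""Detecting positive selection on AMP codon sites.

Two complementary routes are implemented: a counting route (Nei–Gojobori
pairwise dN/dS and a SLAC-style per-site scan over parsimony-reconstructed
ancestral codons) and a likelihood route (GY94 codon substitution model with
the standard site-model hierarchy M0, M1a, M2a, M7, M8, likelihood-ratio
tests of M1a-vs-M2a and M7-vs-M8, and naive empirical-Bayes posteriors for
the positive-selection class). A matching simulator evolves codon alignments
along a tree under any of the model specs, recording the true per-site class
for power/recovery studies.

Codon frequencies are F3x4; generators follow the mixture scaling convention
(one common factor makes the class-averaged substitution rate equal 1, so
branch lengths are expected substitutions per codon under the whole model and
positive-selection classes evolve genuinely faster).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._codons import (CODON_INDEX, N_SENSE, NUC_INDEX, PAIR_TYPE, SENSE_CODONS,
                      STOP_CODONS, SYN_SITES, path_counts)
from .phylo import Tree, TreeNode

# sparse structure of single-nucleotide codon changes (precomputed once)
_I, _J = np.nonzero(PAIR_TYPE)
_TYPES = PAIR_TYPE[_I, _J]  # 1 syn tv, 2 syn ts, 3 nonsyn tv, 4 nonsyn ts
_IS_TS = (_TYPES == 2) | (_TYPES == 4)
_IS_NONSYN = _TYPES >= 3


# ---------------------------------------------------------------------------
# alignment container


@dataclass
class CodonAlignment:
    """In-frame aligned codon data.

    ``codons[taxon]`` is the list of retained codon strings; columns that
    contained gaps, ambiguous bases or stop codons anywhere are excluded up
    front and counted in ``n_excluded``.
    """

    taxa: list[str]
    codons: dict[str, list[str]]
    n_excluded: int = 0

    def __post_init__(self):
        lengths = {len(c) for c in self.codons.values()}
        if len(lengths) > 1:
            raise ValueError("unequal codon counts across taxa")

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.codons.values())))

    def index_matrix(self) -> np.ndarray:
        """(n_taxa, n_sites) matrix of sense-codon indices."""
        return np.array([[CODON_INDEX[c] for c in self.codons[t]]
                         for t in self.taxa], dtype=np.int64)

    @classmethod
    def from_nucleotide(cls, seqs: dict[str, str], frame: int = 0
                        ) -> "CodonAlignment":
        taxa = sorted(seqs)
        L = min(len(s) for s in seqs.values())
        n_codons = (L - frame) // 3
        cols = []
        n_excluded = 0
        for k in range(n_codons):
            col = {t: seqs[t][frame + 3 * k: frame + 3 * k + 3] for t in taxa}
            ok = all(c in CODON_INDEX for c in col.values())
            if ok:
                cols.append(col)
            else:
                n_excluded += 1
        codons = {t: [col[t] for col in cols] for t in taxa}
        return cls(taxa=taxa, codons=codons, n_excluded=n_excluded)


def f3x4_frequencies(aln: CodonAlignment, floor: float = 1e-6) -> np.ndarray:
    """F3x4 codon equilibrium frequencies from position-specific nucleotide
    frequencies of the alignment; stop codons excluded, renormalized."""
    counts = np.zeros((3, 4))
    for t in aln.taxa:
        for codon in aln.codons[t]:
            for k, n in enumerate(codon):
                counts[k, NUC_INDEX[n]] += 1
    counts = np.maximum(counts, floor)
    nf = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([nf[0, NUC_INDEX[c[0]]] * nf[1, NUC_INDEX[c[1]]]
                   * nf[2, NUC_INDEX[c[2]]] for c in SENSE_CODONS])
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# model specs


@dataclass
class CodonModelSpec:
    """Parameters of one codon site model.

    M0: single omega. M1a: {omega0 < 1 w.p. p0, omega=1}. M2a adds a third
    class omega2 > 1 with weight p2 = 1 - p0 - p1. M7: omega ~ Beta(p, q)
    discretized into K equal-probability classes; M8 adds omega_s > 1 with
    weight 1 - p0.
    """

    model: str
    kappa: float = 2.0
    omega: float = 0.5          # M0
    p0: float = 0.5
    p1: float = 0.5             # M2a only (p2 = 1 - p0 - p1)
    omega0: float = 0.1         # M1a / M2a purifying class
    omega2: float = 3.0         # M2a positive class
    beta_p: float = 0.5
    beta_q: float = 2.0
    omega_s: float = 3.0        # M8 positive class
    n_beta_classes: int = 10
    codon_freqs: np.ndarray | None = None

    def class_omegas_props(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.model
        if m == "M0":
            return np.array([self.omega]), np.array([1.0])
        if m == "M1a":
            return (np.array([self.omega0, 1.0]),
                    np.array([self.p0, 1 - self.p0]))
        if m == "M2a":
            p2 = max(0.0, 1.0 - self.p0 - self.p1)
            return (np.array([self.omega0, 1.0, self.omega2]),
                    np.array([self.p0, self.p1, p2]))
        if m == "M7":
            om = beta_class_means(self.beta_p, self.beta_q, self.n_beta_classes)
            return om, np.full(self.n_beta_classes, 1.0 / self.n_beta_classes)
        if m == "M8":
            om = beta_class_means(self.beta_p, self.beta_q, self.n_beta_classes)
            props = np.full(self.n_beta_classes, self.p0 / self.n_beta_classes)
            return (np.append(om, self.omega_s),
                    np.append(props, 1.0 - self.p0))
        raise ValueError(f"unknown model {m}")

    def positive_class_mask(self) -> np.ndarray:
        om, _ = self.class_omegas_props()
        return om > 1.0


def beta_class_means(p: float, q: float, k: int = 10) -> np.ndarray:
    """Means of the K equal-probability slices of Beta(p, q) (the usual
    discretization for beta-distributed omega classes)."""
    edges = stats.beta.ppf(np.linspace(0, 1, k + 1), p, q)
    cdf_shift = stats.beta.cdf(edges, p + 1, q)
    mean = p / (p + q)
    return np.clip(mean * (cdf_shift[1:] - cdf_shift[:-1]) * k, 1e-8, None)


# ---------------------------------------------------------------------------
# rate matrix + likelihood machinery


def _raw_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unscaled GY94 generator: single-nucleotide changes only, with rate
    pi_j * kappa^[transition] * omega^[nonsynonymous]."""
    q = np.zeros((N_SENSE, N_SENSE))
    rates = pi[_J] * np.where(_IS_TS, kappa, 1.0) * np.where(_IS_NONSYN, omega, 1.0)
    q[_I, _J] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 generator scaled to one expected substitution per codon per unit
    time at equilibrium (single-class convenience wrapper)."""
    q = _raw_rate_matrix(kappa, omega, pi)
    scale = -float(pi @ np.diag(q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return q / scale


def class_rate_matrices(kappa: float, omegas: np.ndarray, props: np.ndarray,
                        pi: np.ndarray) -> list[np.ndarray]:
    """Per-class generators under the mixture scaling convention: one common
    factor makes the *average* rate over classes equal 1, so branch lengths
    are expected substitutions per codon under the whole site model."""
    qs = [_raw_rate_matrix(kappa, float(om), pi) for om in omegas]
    rates = np.array([-float(pi @ np.diag(q)) for q in qs])
    scale = float(props @ rates)
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return [q / scale for q in qs]


class _EigenQ:
    """Eigendecomposition of a reversible generator for fast P(t)."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        sq = np.sqrt(pi)
        b = (q * sq[:, None]) / sq[None, :]
        b = 0.5 * (b + b.T)
        w, v = np.linalg.eigh(b)
        self.w = w
        self.left = v / sq[:, None] * 1.0     # D^-1/2 V
        self.right = (v * sq[:, None]).T      # V^T D^1/2

    def p_matrix(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.w * t)) @ self.right
        return np.clip(p, 0.0, None)


def _site_class_likelihoods(idx: np.ndarray, tree: Tree, kappa: float,
                            omegas: np.ndarray, props: np.ndarray,
                            pi: np.ndarray,
                            branch_scale: float = 1.0) -> np.ndarray:
    """(n_classes, n_sites) per-site likelihoods by Felsenstein pruning.

    Rows of ``idx`` follow the sorted leaf names (CodonAlignment.taxa order).
    """
    # site-pattern compression: identical columns are computed once
    uniq, inverse = np.unique(idx, axis=1, return_inverse=True)
    idx = uniq
    n_sites = idx.shape[1]
    out = np.empty((len(omegas), n_sites))
    leaf_row = {name: i for i, name in enumerate(sorted(tree.leaf_names()))}
    qs = class_rate_matrices(kappa, omegas, props, pi)

    for ci in range(len(omegas)):
        eig = _EigenQ(qs[ci], pi)
        logscale = np.zeros(n_sites)

        def partial(node: TreeNode) -> np.ndarray:
            nonlocal logscale
            if node.is_leaf():
                row = leaf_row[node.name]
                p = eig.p_matrix(node.length * branch_scale)
                return p[:, idx[row]].T  # (sites, 61)
            res = None
            for child in node.children:
                cp = partial(child)
                if not child.is_leaf():
                    p = eig.p_matrix(child.length * branch_scale)
                    cp = cp @ p.T
                res = cp if res is None else res * cp
            mx = res.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            logscale += np.log(mx)
            return res / mx[:, None]

        root_partial = partial(tree.root)
        site_l = root_partial @ pi
        out[ci] = site_l * np.exp(logscale)
    return out[:, inverse]


def codon_loglik(aln: CodonAlignment, tree: Tree, spec: CodonModelSpec,
                 branch_scale: float = 1.0) -> float:
    """Log-likelihood of the alignment under a (possibly mixture) site model;
    mixture classes share branch lengths and kappa."""
    if set(tree.leaf_names()) != set(aln.taxa):
        raise ValueError("tree leaves do not match alignment taxa")
    pi = spec.codon_freqs if spec.codon_freqs is not None else f3x4_frequencies(aln)
    omegas, props = spec.class_omegas_props()
    idx = aln.index_matrix()
    site_l = _site_class_likelihoods(idx, tree, spec.kappa, omegas, props,
                                     pi, branch_scale)
    mixture = props @ site_l
    if np.any(mixture <= 0) or not np.all(np.isfinite(mixture)):
        raise FloatingPointError("non-finite site likelihood")
    return float(np.log(mixture).sum())


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    spec: CodonModelSpec
    lnl: float
    converged: bool
    n_restarts: int
    branch_scale: float = 1.0
    tree: Tree | None = None
    site_posteriors: np.ndarray | None = None  # P(positive class | data) per site


def _pack_unpack(model: str):
    """Bounded parameterizations per model (log / logit transforms)."""
    if model == "M0":
        names = ["kappa", "omega"]
    elif model == "M1a":
        names = ["kappa", "omega0", "p0"]
    elif model == "M2a":
        names = ["kappa", "omega0", "p0", "p1", "omega2"]
    elif model == "M7":
        names = ["kappa", "beta_p", "beta_q"]
    elif model == "M8":
        names = ["kappa", "beta_p", "beta_q", "p0", "omega_s"]
    else:
        raise ValueError(model)
    bounds = {
        "kappa": (0.1, 20.0), "omega": (1e-4, 50.0), "omega0": (1e-4, 1.0),
        "omega2": (1.0, 50.0), "omega_s": (1.0, 50.0),
        "p0": (1e-4, 1.0 - 1e-4), "p1": (1e-4, 1.0 - 1e-4),
        "beta_p": (0.05, 99.0), "beta_q": (0.05, 99.0),
    }
    return names, [bounds[n] for n in names]


def _apply_params(spec: CodonModelSpec, names, values):
    for n, v in zip(names, values):
        setattr(spec, n, float(v))
    if spec.model == "M2a":
        # keep the simplex feasible: p1 is the fraction of the remainder
        total = spec.p0 + spec.p1
        if total >= 1.0:
            spec.p0 /= total + 1e-9
            spec.p1 /= total + 1e-9


def fit_site_model(aln: CodonAlignment, tree: Tree, model: str,
                   n_restarts: int = 3, seed: int | None = 0,
                   branch_scale: float | None = None,
                   init: CodonModelSpec | None = None,
                   pi: np.ndarray | None = None) -> FitResult:
    """Maximum-likelihood fit of one site model on a fixed tree topology.

    Branch lengths are taken from the tree and rescaled by a single factor
    estimated under M0 (then held fixed for the mixture models, which also
    reuse the M0 kappa/omega as a starting point). Free parameters are
    optimized by bounded Powell search with ``n_restarts`` jittered starts;
    convergence is declared when the restart improvement falls below 1e-6.
    """
    if aln.n_sites < 1:
        raise ValueError("empty alignment")
    pi = pi if pi is not None else f3x4_frequencies(aln)
    names, bounds = _pack_unpack(model)
    rng = np.random.default_rng(seed)

    if branch_scale is None:
        m0 = _fit_m0_scale(aln, tree, pi)
        branch_scale = m0.branch_scale
        if model == "M0":
            return m0
        base = m0.spec
    else:
        base = init or CodonModelSpec(model="M0", codon_freqs=pi)

    spec = CodonModelSpec(model=model, kappa=base.kappa, codon_freqs=pi)
    if init is not None:
        for n in names:
            setattr(spec, n, getattr(init, n))
    else:
        # seed the purifying class from the M0 omega
        spec.omega0 = min(max(base.omega, 1e-3), 0.9)
        spec.omega = base.omega

    idx = aln.index_matrix()

    def neg_loglik(x):
        s = CodonModelSpec(model=model, codon_freqs=pi)
        _apply_params(s, names, x)
        try:
            omegas, props = s.class_omegas_props()
            site_l = _site_class_likelihoods(idx, tree, s.kappa, omegas,
                                             props, pi, branch_scale)
            mixture = props @ site_l
            if np.any(mixture <= 0) or not np.all(np.isfinite(mixture)):
                return 1e12
            return -float(np.log(mixture).sum())
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            return 1e12

    x0 = np.array([np.clip(getattr(spec, n), b[0], b[1])
                   for n, b in zip(names, bounds)])
    starts = [x0]
    if n_restarts >= 2:
        # second start with real weight on every class (keeps an uninformed
        # entry point when x0 was seeded from a nested null fit)
        default = _default_start(model, spec.kappa, pi)
        starts.append(np.array([np.clip(getattr(default, n), b[0], b[1])
                                for n, b in zip(names, bounds)]))
    for _ in range(max(0, n_restarts - 2)):
        jitter = np.array([rng.uniform(b[0], b[1]) for b in bounds])
        starts.append(0.5 * x0 + 0.5 * jitter)

    best = None
    prev_val = None
    converged = False
    for x_start in starts:
        res = optimize.minimize(neg_loglik, x_start, method="Powell",
                                bounds=bounds,
                                options={"ftol": 1e-8, "xtol": 1e-6,
                                         "maxfev": 4000})
        if best is None or res.fun < best.fun:
            best = res
        if prev_val is not None and abs(prev_val - best.fun) < 1e-6:
            converged = True
            break
        prev_val = best.fun
    converged = converged or (best is not None and best.success)

    final = CodonModelSpec(model=model, codon_freqs=pi)
    _apply_params(final, names, best.x)
    fit = FitResult(spec=final, lnl=-float(best.fun), converged=bool(converged),
                    n_restarts=len(starts), branch_scale=branch_scale, tree=tree)
    return fit


def _default_start(model: str, kappa: float, pi) -> CodonModelSpec:
    """Generic starting point giving every omega class non-trivial weight."""
    s = CodonModelSpec(model=model, kappa=kappa, codon_freqs=pi)
    if model == "M1a":
        s.omega0, s.p0 = 0.2, 0.8
    elif model == "M2a":
        s.omega0, s.p0, s.p1, s.omega2 = 0.2, 0.45, 0.35, 3.0
    elif model == "M7":
        s.beta_p, s.beta_q = 0.5, 2.0
    elif model == "M8":
        s.beta_p, s.beta_q, s.p0, s.omega_s = 0.5, 2.0, 0.9, 3.0
    return s


def fit_nested_pair(aln: CodonAlignment, tree: Tree, null: str = "M1a",
                    alt: str = "M2a", n_restarts: int = 3,
                    seed: int | None = 0, m0: FitResult | None = None):
    """Fit a nested null/alternative site-model pair sharing M0 branch lengths.

    The alternative model receives an extra start at the null's MLE with the
    positive-selection class collapsed (omega = 1, near-zero weight), which
    makes lnL(alt) >= lnL(null) hold by construction. Returns
    (m0_fit, null_fit, alt_fit).
    """
    if (null, alt) not in {("M1a", "M2a"), ("M7", "M8")}:
        raise ValueError(f"not a nested site-model pair: {(null, alt)}")
    pi = f3x4_frequencies(aln)
    if m0 is None:
        m0 = _fit_m0_scale(aln, tree, pi)
    null_fit = fit_site_model(aln, tree, null, n_restarts=n_restarts, seed=seed,
                              branch_scale=m0.branch_scale,
                              init=_null_seed(null, m0), pi=pi)
    alt_init = CodonModelSpec(model=alt, kappa=null_fit.spec.kappa, codon_freqs=pi)
    if alt == "M2a":
        alt_init.omega0 = null_fit.spec.omega0
        alt_init.p0 = null_fit.spec.p0
        alt_init.p1 = max(1e-4, 1.0 - null_fit.spec.p0 - 1e-4)
        alt_init.omega2 = 1.0
    else:  # M8 from M7
        alt_init.beta_p = null_fit.spec.beta_p
        alt_init.beta_q = null_fit.spec.beta_q
        alt_init.p0 = 1.0 - 1e-4
        alt_init.omega_s = 1.0
    alt_fit = fit_site_model(aln, tree, alt, n_restarts=n_restarts, seed=seed,
                             branch_scale=m0.branch_scale, init=alt_init, pi=pi)
    if alt_fit.lnl < null_fit.lnl:
        # Powell should never end below its start; guard numerically anyway
        alt_fit = FitResult(spec=alt_init, lnl=null_fit.lnl,
                            converged=alt_fit.converged,
                            n_restarts=alt_fit.n_restarts,
                            branch_scale=m0.branch_scale, tree=tree)
    return m0, null_fit, alt_fit


def _null_seed(model: str, m0: FitResult) -> CodonModelSpec:
    spec = CodonModelSpec(model=model, kappa=m0.spec.kappa,
                          codon_freqs=m0.spec.codon_freqs)
    if model == "M1a":
        spec.omega0 = min(max(m0.spec.omega, 1e-3), 0.999)
        spec.p0 = 0.8
    return spec


def _fit_m0_scale(aln: CodonAlignment, tree: Tree, pi: np.ndarray) -> FitResult:
    """Joint fit of kappa, omega and a global branch-length scale under M0."""
    idx = aln.index_matrix()

    def neg_loglik(x):
        kappa, omega, log_scale = x
        try:
            site_l = _site_class_likelihoods(idx, tree, kappa,
                                             np.array([omega]),
                                             np.array([1.0]), pi,
                                             math.exp(log_scale))
            s = site_l[0]
            if np.any(s <= 0) or not np.all(np.isfinite(s)):
                return 1e12
            return -float(np.log(s).sum())
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12

    res = optimize.minimize(
        neg_loglik, np.array([2.0, 0.4, 0.0]), method="Powell",
        bounds=[(0.1, 20.0), (1e-4, 50.0), (-4.0, 4.0)],
        options={"ftol": 1e-8, "xtol": 1e-6, "maxfev": 3000})
    kappa, omega, log_scale = res.x
    spec = CodonModelSpec(model="M0", kappa=float(kappa), omega=float(omega),
                          codon_freqs=pi)
    return FitResult(spec=spec, lnl=-float(res.fun), converged=bool(res.success),
                     n_restarts=1, branch_scale=float(math.exp(log_scale)),
                     tree=tree)


def lrt(fit_null: FitResult, fit_alt: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested site-model pairs (M1a<M2a, M7<M8):
    2*delta-lnL against chi-square with df=2; negative statistics clamp to 0."""
    pair = (fit_null.spec.model, fit_alt.spec.model)
    if pair not in {("M1a", "M2a"), ("M7", "M8")}:
        raise ValueError(f"not a nested site-model pair: {pair}")
    stat = max(0.0, 2.0 * (fit_alt.lnl - fit_null.lnl))
    df = 2
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


def neb_positive_sites(fit: FitResult, aln: CodonAlignment, tree: Tree,
                       threshold: float = 0.95):
    """Naive empirical-Bayes posteriors for the omega>1 class at the MLEs.

    Returns (positions, posteriors): 1-based codon coordinates of sites whose
    posterior probability of belonging to a positive-selection class exceeds
    ``threshold``, plus the full per-site posterior vector. Models without an
    omega>1 class yield an empty list.
    """
    spec = fit.spec
    mask = spec.positive_class_mask()
    pi = spec.codon_freqs if spec.codon_freqs is not None else f3x4_frequencies(aln)
    omegas, props = spec.class_omegas_props()
    if not mask.any() or props[mask].sum() <= 0:
        return [], np.zeros(aln.n_sites)
    idx = aln.index_matrix()
    site_l = _site_class_likelihoods(idx, tree, spec.kappa, omegas, props,
                                     pi, fit.branch_scale)
    weighted = props[:, None] * site_l
    posterior = weighted[mask].sum(axis=0) / weighted.sum(axis=0)
    positions = [i + 1 for i, p in enumerate(posterior) if p > threshold]
    return positions, posterior


# ---------------------------------------------------------------------------
# counting methods


@dataclass
class NG86Result:
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    ps: float
    pn: float
    ds: float | None
    dn: float | None
    omega: float | None


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_pairwise(seq1: str, seq2: str) -> NG86Result:
    """Nei–Gojobori (1986) pairwise dN/dS with Jukes–Cantor correction.

    Site counts average the two sequences; multi-hit codons average their
    synonymous/nonsynonymous difference split over all minimal pathways not
    passing through a stop codon. dS/dN are None where the JC correction is
    undefined (p >= 3/4); omega is None when dS is 0 or undefined.
    """
    if len(seq1) != len(seq2) or len(seq1) % 3:
        raise ValueError("need equal-length in-frame codon sequences")
    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    for k in range(0, len(seq1), 3):
        c1, c2 = seq1[k:k + 3], seq2[k:k + 3]
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            raise ValueError("internal stop codon")
        s1 = SYN_SITES[CODON_INDEX[c1]]
        s2 = SYN_SITES[CODON_INDEX[c2]]
        s_sites += (s1 + s2) / 2.0
        n_sites += 3.0 - (s1 + s2) / 2.0
        sd, nd = path_counts(c1, c2)
        s_diff += sd
        n_diff += nd
    ps = s_diff / s_sites if s_sites else 0.0
    pn = n_diff / n_sites if n_sites else 0.0
    ds = _jc(ps)
    dn = _jc(pn)
    omega = None
    if ds is not None and dn is not None and ds > 0:
        omega = dn / ds
    return NG86Result(s_sites, n_sites, s_diff, n_diff, ps, pn, ds, dn, omega)


@dataclass
class SiteCountResult:
    """Per-codon-site substitution counts over the tree plus the global
    counting-based omega."""

    sites: list[dict]
    mean_omega: float | None
    total_syn: float
    total_nonsyn: float


def _fitch_states(tree: Tree, leaf_state: dict[str, str]) -> dict[int, str]:
    """One-site Fitch parsimony on codon states.

    Ties are resolved by minimizing nonsynonymous changes against the parent
    (top-down pass), then lexicographically. Returns assignment per node id.
    """
    sets: dict[int, set[str]] = {}
    order = list(tree.root.postorder())
    for node in order:
        if node.is_leaf():
            sets[id(node)] = {leaf_state[node.name]}
        else:
            child_sets = [sets[id(c)] for c in node.children]
            inter = set.intersection(*child_sets)
            sets[id(node)] = inter if inter else set.union(*child_sets)

    assign: dict[int, str] = {}

    def choose(cands: set[str], parent_codon: str | None) -> str:
        if parent_codon is not None and parent_codon in cands:
            return parent_codon
        if parent_codon is None:
            return min(cands)
        def cost(c):
            _, nonsyn = path_counts(parent_codon, c)
            return (nonsyn, c)
        return min(cands, key=cost)

    def down(node: TreeNode, parent_codon: str | None):
        codon = (leaf_state[node.name] if node.is_leaf()
                 else choose(sets[id(node)], parent_codon))
        assign[id(node)] = codon
        for c in node.children:
            down(c, codon)

    down(tree.root, None)
    return assign


def slac_site_scan(aln: CodonAlignment, tree: Tree) -> SiteCountResult:
    """SLAC-style counting scan: per site, observed synonymous/nonsynonymous
    changes summed over tree edges (Fitch ancestors), compared with the NG86
    expectation by a two-tailed binomial test.
    """
    if set(tree.leaf_names()) != set(aln.taxa):
        raise ValueError("tree leaves do not match alignment taxa")
    edges = []
    for node in tree.root.postorder():
        for child in node.children:
            edges.append((node, child))

    sites = []
    tot_s = tot_n = 0.0
    tot_ssites = tot_nsites = 0.0
    for h in range(aln.n_sites):
        leaf_state = {t: aln.codons[t][h] for t in aln.taxa}
        assign = _fitch_states(tree, leaf_state)
        s_count = n_count = 0.0
        for parent, child in edges:
            sd, nd = path_counts(assign[id(parent)], assign[id(child)])
            s_count += sd
            n_count += nd
        obs = [CODON_INDEX[c] for c in leaf_state.values()]
        s_sites = float(np.mean(SYN_SITES[obs]))
        n_sites_ = 3.0 - s_sites
        total = s_count + n_count
        if total > 0:
            p_nonsyn = n_sites_ / 3.0
            k = int(round(n_count))
            n_tot = max(int(round(total)), k)
            pval = float(stats.binomtest(k, n_tot, p_nonsyn).pvalue)
        else:
            pval = 1.0
        sites.append({"site": h + 1, "syn": s_count, "nonsyn": n_count,
                      "syn_sites": s_sites, "nonsyn_sites": n_sites_,
                      "p_value": pval})
        tot_s += s_count
        tot_n += n_count
        tot_ssites += s_sites
        tot_nsites += n_sites_
    mean_omega = None
    if tot_s > 0 and tot_ssites > 0 and tot_nsites > 0:
        mean_omega = (tot_n / tot_nsites) / (tot_s / tot_ssites)
    return SiteCountResult(sites=sites, mean_omega=mean_omega,
                           total_syn=tot_s, total_nonsyn=tot_n)


# ---------------------------------------------------------------------------
# simulator


def simulate_codon_alignment(tree: Tree, spec: CodonModelSpec, n_codons: int,
                             seed: int | None = 0):
    """Evolve a codon alignment along ``tree`` under a site model.

    Site classes are drawn from the model proportions, root codons from the
    equilibrium frequencies, and each branch applies the exact transition
    probabilities of the scaled generator. Returns (CodonAlignment,
    true_class array, true_omega array).
    """
    rng = np.random.default_rng(seed)
    pi = spec.codon_freqs
    if pi is None:
        raise ValueError("spec.codon_freqs is required for simulation")
    omegas, props = spec.class_omegas_props()
    classes = rng.choice(len(omegas), size=n_codons, p=props / props.sum())
    eigs = [_EigenQ(q, pi)
            for q in class_rate_matrices(spec.kappa, omegas, props, pi)]

    states = {id(tree.root): rng.choice(N_SENSE, size=n_codons, p=pi)}

    def evolve(node: TreeNode):
        parent_state = states[id(node)]
        for child in node.children:
            child_state = parent_state.copy()
            for ci in range(len(omegas)):
                sel = np.where(classes == ci)[0]
                if sel.size == 0:
                    continue
                p = eigs[ci].p_matrix(child.length)
                p = p / p.sum(axis=1, keepdims=True)
                for s in sel:
                    child_state[s] = rng.choice(N_SENSE, p=p[parent_state[s]])
            states[id(child)] = child_state
            evolve(child)

    evolve(tree.root)
    codons = {}
    for leaf in tree.root.leaves():
        codons[leaf.name] = [SENSE_CODONS[i] for i in states[id(leaf)]]
    aln = CodonAlignment(taxa=sorted(codons), codons=codons)
    return aln, classes, omegas[classes]
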
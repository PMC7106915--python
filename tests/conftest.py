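import numpy as np
import pytest

from amp_typer.phylo import Tree, TreeNode
from amp_typer.synthdata import (SimConfig, make_tag_scheme,
                                 simulate_allele_pool, simulate_cohort,
                                 simulate_reads)


def small_config(**kw):
    """A reduced cohort for fast unit tests."""
    base = dict(seed=11, n_populations=2, inds_per_pop=3, depth_mean=800,
                alleles_per_locus=4)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def zero_noise_run():
    """Simulated study with no errors or chimeras, fully processed truth."""
    cfg = small_config(per_base_error=0.0, chimera_frac=0.0)
    pool = simulate_allele_pool(cfg)
    cohort = simulate_cohort(pool, cfg)
    tags, rep_of = make_tag_scheme(cohort, pool, cfg)
    reads, truth = simulate_reads(cohort, pool, tags, cfg, replicate_of=rep_of)
    return dict(cfg=cfg, pool=pool, cohort=cohort, tags=tags,
                replicate_of=rep_of, reads=reads, truth=truth)


@pytest.fixture(scope="session")
def default_noise_run():
    """Reference study conditions: 30 individuals x 3 genes (4/3/3 loci),
    depth ~2000, 0.2%/bp errors, 5% chimeras, technical replicates."""
    cfg = SimConfig(seed=101)
    pool = simulate_allele_pool(cfg)
    cohort = simulate_cohort(pool, cfg)
    tags, rep_of = make_tag_scheme(cohort, pool, cfg)
    reads, truth = simulate_reads(cohort, pool, tags, cfg, replicate_of=rep_of)
    return dict(cfg=cfg, pool=pool, cohort=cohort, tags=tags,
                replicate_of=rep_of, reads=reads, truth=truth)


def random_resolved_tree(n_taxa: int, rng: np.random.Generator,
                         lo: float = 0.05, hi: float = 0.3,
                         prefix: str = "T") -> Tree:
    """Random binary (root trifurcation) tree with uniform branch lengths."""
    nodes = [TreeNode(name=f"{prefix}{i}", length=float(rng.uniform(lo, hi)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b],
                              length=float(rng.uniform(lo, hi))))
    return Tree(root=TreeNode(children=nodes))


def tree_path_distances(tree: Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix (the additive distances of the tree)."""
    leaves = sorted(tree.leaf_names())
    paths = {}

    def walk(node, acc):
        acc = acc + [node]
        if node.is_leaf():
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    walk(tree.root, [])
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = paths[leaves[i]], paths[leaves[j]]
            common = 0
            for x, y in zip(pa, pb):
                if x is y:
                    common += 1
                else:
                    break
            dist = sum(nd.length for nd in pa[common:]) + \
                sum(nd.length for nd in pb[common:])
            d[i, j] = d[j, i] = dist
    return leaves, d
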
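"""Synthetic AMP amplicon study generator.

Emulates a two-species, multi-population deep-amplicon survey of
antimicrobial-peptide gene families: per gene a small multi-locus family with
a conserved signal-peptide region, an acidic propiece and a hypervariable,
cationic mature peptide; per-individual multi-locus genotypes; trans-specific
(shared) alleles; and tagged amplicon read pools with amplification bias,
point errors, PCR chimeras and technical replicates. Ground truth is recorded
for every amplicon and read so the whole downstream pipeline can be scored.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._codons import CODON_TO_AA, SENSE_CODONS, revcomp
from .peptide import net_charge

_NUCS = np.frombuffer(b"ACGT", dtype=np.uint8)

# codons per amino acid, for domain-biased ancestor construction
_AA_CODONS: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _AA_CODONS.setdefault(CODON_TO_AA[_c], []).append(_c)


@dataclass
class SimConfig:
    """All knobs of the synthetic study; the seed fully determines outputs.

    Defaults describe the reference condition used throughout the test
    suite: 3 gene families typed in 30 individuals of two species, with
    per-amplicon depth ~2000, 0.2%/bp substitution error and 5% chimeric
    reads.
    """

    seed: int = 0
    gene_names: tuple[str, ...] = ("Temporin", "Brevinin", "Palustrin")
    loci_per_gene: tuple[int, ...] = (4, 3, 3)
    alleles_per_locus: int = 6
    amplicon_len_range: tuple[int, int] = (120, 204)
    shared_allele_frac: float = 0.15
    per_base_error: float = 0.002
    chimera_frac: float = 0.05
    depth_mean: float = 2000.0
    depth_skew: float = 20.0
    n_populations: int = 6
    inds_per_pop: int = 5
    replicate_frac: float = 0.15
    species: tuple[str, str] = ("Raar", "Rate")
    regions: tuple[str, ...] = ("South", "Central", "North")
    signal_len: int = 18
    sub_rate_signal: float = 0.01
    sub_rate_propiece: float = 0.05
    sub_rate_mature: float = 0.22
    species_divergence: float = 0.06
    charge_coordination: float = 0.8
    read_len: int = 200
    tag_len: int = 8
    spacer_len: int = 3

    def __post_init__(self):
        self.validate()

    def validate(self):
        lo, hi = self.amplicon_len_range
        if not (100 <= lo <= hi <= 204):
            raise ValueError("amplicon_len_range must lie within [100, 204]")
        for name in ("shared_allele_frac", "per_base_error", "chimera_frac",
                     "replicate_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if len(self.loci_per_gene) != len(self.gene_names):
            raise ValueError("loci_per_gene must match gene_names")
        if not all(1 <= k <= 6 for k in self.loci_per_gene):
            raise ValueError("loci per gene must be in 1..6")
        if self.alleles_per_locus < 1 or self.depth_skew <= 0:
            raise ValueError("invalid pool size or depth_skew")
        if self.n_populations < len(self.species):
            raise ValueError("need at least one population per species")
        # alleles are derived by point substitution from a common ancestor;
        # the mutational space must plausibly hold the requested pool
        if self.alleles_per_locus > 4 ** (self.signal_len // 2):
            raise ValueError("alleles_per_locus exceeds mutational space")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("gene_names", "loci_per_gene", "amplicon_len_range",
                    "species", "regions"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path):
        data = asdict(self)
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class GenePool:
    """Allele pools of one gene family, per species and locus."""

    gene: str
    length: int
    frame_offset: int
    domains: dict[str, tuple[int, int]]  # signal / propiece / mature, nt coords
    # species -> list over loci -> list of allele sequences
    alleles: dict[str, list[list[str]]]

    def species_alleles(self, species: str) -> list[str]:
        """Distinct alleles of a species, in deterministic order."""
        seen, out = set(), []
        for locus in self.alleles[species]:
            for a in locus:
                if a not in seen:
                    seen.add(a)
                    out.append(a)
        return out


@dataclass
class AllelePool:
    genes: dict[str, GenePool]

    def shared_alleles(self, gene: str) -> set[str]:
        pools = self.genes[gene].alleles
        species = list(pools)
        sets = [set(a for locus in pools[s] for a in locus) for s in species]
        return set.intersection(*sets)


@dataclass
class Individual:
    id: str
    species: str
    population: str
    region: str
    # (gene, locus_index) -> pair of allele sequences
    genotype: dict[tuple[str, int], tuple[str, str]]

    def allele_set(self, gene: str) -> set[str]:
        out = set()
        for (g, _), pair in self.genotype.items():
            if g == gene:
                out.update(pair)
        return out


@dataclass
class Cohort:
    individuals: list[Individual]

    def by_species(self) -> dict[str, list[Individual]]:
        out: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            out.setdefault(ind.species, []).append(ind)
        return out


@dataclass
class TruthSet:
    """Per-amplicon and per-read ground truth for scoring the pipeline."""

    amplicons: pd.DataFrame  # amplicon_id, individual, gene, alleles, replicate_of
    reads: pd.DataFrame      # read_id, amplicon_id, source, chimera_parents, breakpoint

    def write(self, out_dir: str | Path):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.amplicons.to_csv(out / "truth_amplicons.tsv", sep="\t", index=False)
        self.reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele pool generation


def _random_codon(rng, aa_weights: dict[str, float]) -> str:
    aas = sorted(aa_weights)
    w = np.array([aa_weights[a] for a in aas])
    aa = aas[rng.choice(len(aas), p=w / w.sum())]
    return _AA_CODONS[aa][rng.integers(len(_AA_CODONS[aa]))]

# amino-acid biases reflecting domain chemistry: acidic propiece, cationic
# amphipathic mature peptide, generic hydrophobic signal region
_SIGNAL_W = {a: 1.0 for a in "ACDEFGHIKLMNPQRSTVWY"}
_SIGNAL_W.update({a: 4.0 for a in "LIVFA"})
_PROP_W = {a: 1.0 for a in "ACFGHIKLMNPQRSTVWY"}
_PROP_W.update({"D": 6.0, "E": 6.0})
_MATURE_W = {a: 1.0 for a in "ACDEFGHILMNPQSTVWY"}
_MATURE_W.update({"K": 5.0, "R": 2.0, "G": 3.0, "L": 4.0})


def _make_ancestor(rng, length: int, domains) -> str:
    codons = []
    for i in range(0, length, 3):
        if i < domains["signal"][1]:
            w = _SIGNAL_W
        elif i < domains["propiece"][1]:
            w = _PROP_W
        else:
            w = _MATURE_W
        codons.append(_random_codon(rng, w))
    return "".join(codons)


def _mutate_domain(rng, seq: str, start: int, end: int, rate: float) -> str:
    """Substitute sites in [start, end) at the given per-site rate, never
    creating a stop codon (the offending codon draw is rejected)."""
    s = list(seq)
    for pos in range(start, end):
        if rng.random() >= rate:
            continue
        cstart = pos - pos % 3
        for _ in range(20):
            old = s[pos]
            alts = [n for n in "ACGT" if n != old]
            s[pos] = alts[rng.integers(3)]
            codon = "".join(s[cstart:cstart + 3])
            if codon in CODON_TO_AA:
                break
            s[pos] = old
    return "".join(s)


def _adjust_propiece_charge(rng, seq: str, prop_iv, target: int) -> str:
    """Nudge the integer net charge of the propiece toward ``target`` by
    codon-level residue swaps (used to emulate coordinated domain evolution)."""
    a, b = prop_iv
    for _ in range(40):
        pep = [CODON_TO_AA["".join(seq[i:i + 3])] for i in range(a, b, 3)]
        charge = sum(x in "KR" for x in pep) - sum(x in "DE" for x in pep)
        if charge == target:
            return seq
        idxs = list(range(len(pep)))
        rng.shuffle(idxs)
        done = False
        for i in idxs:
            aa = pep[i]
            if charge > target and aa not in "DE":
                new_aa = "E" if rng.random() < 0.5 else "D"
            elif charge < target and aa in "DE":
                new_aa = "N" if aa == "D" else "Q"
            elif charge < target and aa not in "KR":
                new_aa = "K"
            else:
                continue
            codons = _AA_CODONS[new_aa]
            codon = codons[rng.integers(len(codons))]
            seq = seq[:a + 3 * i] + codon + seq[a + 3 * i + 3:]
            done = True
            break
        if not done:
            return seq
    return seq


def simulate_allele_pool(config: SimConfig) -> AllelePool:
    """Generate per-gene, per-species, per-locus allele pools.

    Alleles derive from a random in-frame gene ancestor by domain-specific
    substitution (mature >> propiece >> signal). Species ancestors diverge
    first; a fraction ``shared_allele_frac`` of each locus pool is then
    copied byte-identically across species (trans-specific polymorphism).
    The propiece charge of each allele is nudged opposite to its mature
    charge deviation, emulating coordinated domain evolution.
    """
    rng = np.random.default_rng(config.seed)
    genes: dict[str, GenePool] = {}
    for gi, gene in enumerate(config.gene_names):
        lo, hi = config.amplicon_len_range
        length = 3 * int(rng.integers(lo // 3 + (lo % 3 > 0), hi // 3 + 1))
        sig_end = min(config.signal_len - config.signal_len % 3, length - 12)
        prop_len = 3 * max(2, int(round((length - sig_end) * 0.4 / 3)))
        domains = {
            "signal": (0, sig_end),
            "propiece": (sig_end, sig_end + prop_len),
            "mature": (sig_end + prop_len, length),
        }
        ancestor = _make_ancestor(rng, length, domains)
        n_loci = config.loci_per_gene[gi]

        def derive(seq, scale=1.0):
            s = _mutate_domain(rng, seq, *domains["signal"],
                               rate=config.sub_rate_signal * scale)
            s = _mutate_domain(rng, s, *domains["propiece"],
                               rate=config.sub_rate_propiece * scale)
            return _mutate_domain(rng, s, *domains["mature"],
                                  rate=config.sub_rate_mature * scale)

        def coordinate(seq, anc_mature_charge, anc_prop_charge):
            if config.charge_coordination <= 0:
                return seq
            m0, m1 = domains["mature"]
            pep = [CODON_TO_AA[seq[i:i + 3]] for i in range(m0, m1, 3)]
            mcharge = sum(x in "KR" for x in pep) - sum(x in "DE" for x in pep)
            delta = mcharge - anc_mature_charge
            target = anc_prop_charge - int(round(config.charge_coordination * delta))
            return _adjust_propiece_charge(rng, seq, domains["propiece"], target)

        def domain_charge(seq, iv):
            pep = "".join(CODON_TO_AA[seq[i:i + 3]] for i in range(iv[0], iv[1], 3))
            return int(net_charge(pep))

        # species ancestors diverge from the gene ancestor
        sp_anc = {}
        for sp in config.species:
            scale = config.species_divergence / max(config.sub_rate_mature, 1e-9)
            sp_anc[sp] = derive(ancestor, scale=scale)

        pools: dict[str, list[list[str]]] = {sp: [] for sp in config.species}
        n_shared = int(round(config.shared_allele_frac * config.alleles_per_locus))
        sp_a, sp_b = config.species
        for locus in range(n_loci):
            # a per-locus founder keeps loci distinguishable
            founders = {sp: derive(sp_anc[sp], scale=0.5) for sp in config.species}
            for sp in config.species:
                anc_m = domain_charge(founders[sp], domains["mature"])
                anc_p = domain_charge(founders[sp], domains["propiece"])
                seen = set()
                pool = []
                attempts = 0
                while len(pool) < config.alleles_per_locus:
                    attempts += 1
                    if attempts > 200 * config.alleles_per_locus:
                        raise RuntimeError(
                            f"cannot generate {config.alleles_per_locus} distinct "
                            f"alleles for {gene} locus {locus}: mutational space "
                            "too small under the configured rates")
                    allele = coordinate(derive(founders[sp]), anc_m, anc_p)
                    if allele not in seen:
                        seen.add(allele)
                        pool.append(allele)
                pools[sp].append(pool)
            # copy shared alleles from species A into species B, byte-identical
            for k in range(n_shared):
                pools[sp_b][locus][k] = pools[sp_a][locus][k]
        genes[gene] = GenePool(gene=gene, length=length, frame_offset=0,
                               domains=domains, alleles=pools)
    return AllelePool(genes=genes)


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(pool: AllelePool, config: SimConfig) -> Cohort:
    """Assign populations to species/regions and draw per-locus genotypes.

    Per (gene, species, locus) a Dirichlet(1) allele-frequency vector is
    drawn once and shared by all populations of the species: the surveyed
    system shows little geographic structure at the nucleotide level, so the
    generator is panmictic within species by default.
    """
    if not pool.genes:
        raise ValueError("empty allele pool")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_sp = len(config.species)
    pops = []
    per_sp = math.ceil(config.n_populations / n_sp)
    for p in range(config.n_populations):
        sp = config.species[min(p // per_sp, n_sp - 1)]
        region = config.regions[p % len(config.regions)]
        pops.append((f"P{p + 1:02d}", sp, region))

    freqs: dict[tuple[str, str, int], np.ndarray] = {}
    for gene, gp in pool.genes.items():
        for sp in config.species:
            for locus, alleles in enumerate(gp.alleles[sp]):
                freqs[(gene, sp, locus)] = rng.dirichlet(np.ones(len(alleles)))

    individuals = []
    for pop_id, sp, region in pops:
        for i in range(config.inds_per_pop):
            ind_id = f"{sp}_{pop_id}_i{i + 1:02d}"
            genotype = {}
            for gene, gp in pool.genes.items():
                for locus, alleles in enumerate(gp.alleles[sp]):
                    f = freqs[(gene, sp, locus)]
                    picks = rng.choice(len(alleles), size=2, p=f)
                    genotype[(gene, locus)] = (alleles[picks[0]], alleles[picks[1]])
            individuals.append(Individual(ind_id, sp, pop_id, region, genotype))
    return Cohort(individuals=individuals)


# ---------------------------------------------------------------------------
# tag scheme + reads

_PRIMER_LEN = 20


def make_tag_scheme(cohort: Cohort, pool: AllelePool, config: SimConfig):
    """Build a TagScheme covering every amplicon (individual x gene), plus
    replicate amplicons for a ``replicate_frac`` subset of individuals."""
    from .amplicon import TagScheme  # local import avoids a cycle

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    primers = {}
    for gene in pool.genes:
        fwd = "".join("ACGT"[rng.integers(4)] for _ in range(_PRIMER_LEN))
        rev = "".join("ACGT"[rng.integers(4)] for _ in range(_PRIMER_LEN))
        primers[gene] = (fwd, rev)

    amplicon_ids = []
    n_rep = int(round(config.replicate_frac * len(cohort.individuals)))
    rep_inds = {ind.id for ind in cohort.individuals[:n_rep]}
    for ind in cohort.individuals:
        for gene in pool.genes:
            amplicon_ids.append((f"{ind.id}|{gene}", gene, None))
            if ind.id in rep_inds:
                amplicon_ids.append(
                    (f"{ind.id}|{gene}|rep", gene, f"{ind.id}|{gene}"))

    tags = set()
    while len(tags) < 2 * len(amplicon_ids):
        tags.add("".join("ACGT"[rng.integers(4)] for _ in range(config.tag_len)))
    tags = sorted(tags)
    rng.shuffle(tags)
    assignments = {}
    replicate_of = {}
    for k, (amp_id, gene, partner) in enumerate(amplicon_ids):
        assignments[amp_id] = (tags[2 * k], tags[2 * k + 1], gene)
        if partner:
            replicate_of[amp_id] = partner
    scheme = TagScheme(assignments=assignments, primers=primers,
                       spacer_len=config.spacer_len)
    return scheme, replicate_of


def _apply_errors(arr: np.ndarray, rate: float, rng) -> np.ndarray:
    """i.i.d. substitution errors on a (reads x length) uint8 base matrix."""
    if rate <= 0:
        return arr
    idx = np.searchsorted(_NUCS, arr)
    mask = rng.random(arr.shape) < rate
    shift = rng.integers(1, 4, size=arr.shape)
    idx = np.where(mask, (idx + shift) % 4, idx)
    return _NUCS[idx]


def simulate_reads(cohort: Cohort, pool: AllelePool, tags, config: SimConfig,
                   out_dir: str | Path | None = None, paired: bool = False,
                   replicate_of: dict[str, str] | None = None):
    """Emit amplicon reads and the matching TruthSet.

    One amplicon = one individual x gene (a single primer pair co-amplifies
    all loci of the family). Per-allele depths follow a Dirichlet-multinomial
    with symmetric concentration ``depth_skew``; ``chimera_frac`` of reads
    recombine two genotype alleles at a uniform breakpoint; substitution
    errors hit every emitted base. Returns (reads, truth) where reads is a
    list of (read_id, sequence) for merged mode or (read_id, r1, r2) for
    paired mode; FASTQ files are written when ``out_dir`` is given.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    replicate_of = replicate_of or {}
    ind_by_id = {ind.id: ind for ind in cohort.individuals}

    reads_out = []
    amp_rows = []
    read_rows = []
    for amp_id in sorted(tags.assignments):
        fwd_tag, rev_tag, gene = tags.assignments[amp_id]
        ind_id = amp_id.split("|")[0]
        ind = ind_by_id[ind_id]
        alleles = sorted(ind.allele_set(gene))
        fwd_primer, rev_primer = tags.primers[gene]
        amp_rows.append({
            "amplicon_id": amp_id, "individual": ind_id, "gene": gene,
            "alleles": ";".join(alleles),
            "replicate_of": replicate_of.get(amp_id, ""),
        })

        depth = int(rng.poisson(config.depth_mean))
        weights = rng.dirichlet(np.full(len(alleles), config.depth_skew))
        counts = rng.multinomial(depth, weights)
        n_chim = (rng.binomial(depth, config.chimera_frac)
                  if len(alleles) > 1 and config.chimera_frac > 0 else 0)
        # which reads (by serial) are chimeric
        chim_serials = set(rng.choice(depth, size=n_chim, replace=False)) if n_chim else set()

        inserts = []   # (insert, source_allele, breakpoint, parent_a, parent_b)
        serial = 0
        for allele, cnt in zip(alleles, counts):
            others = [a for a in alleles if a != allele]
            for _ in range(cnt):
                if serial in chim_serials and others:
                    other = others[int(rng.integers(len(others)))]
                    bp = int(rng.integers(1, min(len(allele), len(other))))
                    inserts.append((allele[:bp] + other[bp:], "", bp, allele, other))
                else:
                    inserts.append((allele, allele, -1, "", ""))
                serial += 1

        spacer_f = rng.integers(4, size=(depth, config.spacer_len))
        spacer_r = rng.integers(4, size=(depth, config.spacer_len))
        for k, (insert, source, bp, pa, pb) in enumerate(inserts):
            construct = (fwd_tag + "".join("ACGT"[x] for x in spacer_f[k])
                         + fwd_primer + insert + revcomp(rev_primer)
                         + "".join("ACGT"[x] for x in spacer_r[k])
                         + revcomp(rev_tag))
            read_id = f"{amp_id}:{k}"
            arr = np.frombuffer(construct.encode(), dtype=np.uint8).copy()
            if paired:
                r1 = _apply_errors(arr[None, :config.read_len].copy(),
                                   config.per_base_error, rng)[0]
                rc = np.frombuffer(revcomp(construct).encode(), np.uint8).copy()
                r2 = _apply_errors(rc[None, :config.read_len].copy(),
                                   config.per_base_error, rng)[0]
                reads_out.append((read_id, r1.tobytes().decode(),
                                  r2.tobytes().decode()))
            else:
                seq = _apply_errors(arr[None, :], config.per_base_error, rng)[0]
                reads_out.append((read_id, seq.tobytes().decode()))
            read_rows.append({
                "read_id": read_id, "amplicon_id": amp_id,
                "source_allele": source,
                "chimera_parents": (f"{pa}|{pb}" if bp >= 0 else ""),
                "breakpoint": bp,
            })

    truth = TruthSet(amplicons=pd.DataFrame(amp_rows),
                     reads=pd.DataFrame(read_rows))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if paired:
            _write_fastq(out / "reads_R1.fastq",
                         [(rid, r1) for rid, r1, _ in reads_out])
            _write_fastq(out / "reads_R2.fastq",
                         [(rid, r2) for rid, _, r2 in reads_out])
        else:
            _write_fastq(out / "reads.fastq", reads_out)
        truth.write(out)
    return reads_out, truth


def _write_fastq(path: Path, reads: list[tuple[str, str]]):
    """4-line FASTQ with constant high quality (quality is not modeled)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
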
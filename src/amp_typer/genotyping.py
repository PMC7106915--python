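"""Allele validation for multi-locus amplicon genotypes.

True alleles are separated from PCR/sequencing artifacts with two filters:
a relative-frequency threshold (alleles must carry >= 3% of the amplicon's
reads by default) and the degree-of-change (DOC) break-point statistic, the
relative depth drop after each depth-ranked variant. The variant followed by
the largest drop is taken as the last true allele; amplicons with fewer than
300 retained reads are discarded outright. Validated alleles are named with
species + gene codes and a dense registry number, and per-individual allele
counts bound the minimum number of gene copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon import VariantTable


@dataclass
class DOCResult:
    """DOC_i = 100 * (d_i - d_{i+1}) / d_i for ranks i = 1..n-1."""

    doc: list[float]
    break_rank: int


def doc_breakpoint(depths) -> DOCResult:
    """Locate the coverage break point in a non-increasing depth vector.

    The first ``break_rank`` variants are DOC-supported alleles. Ties at the
    maximal DOC go to the smallest rank (the conservative choice: fewest
    alleles); a single variant yields break_rank 1 and an empty DOC vector.
    """
    depths = list(depths)
    if not depths:
        raise ValueError("empty depth vector")
    if any(d <= 0 for d in depths):
        raise ValueError("depths must be positive")
    if any(depths[i] < depths[i + 1] for i in range(len(depths) - 1)):
        raise ValueError("depths must be sorted non-increasing")
    if len(depths) == 1:
        return DOCResult(doc=[], break_rank=1)
    doc = [100.0 * (depths[i] - depths[i + 1]) / depths[i]
           for i in range(len(depths) - 1)]
    best = max(range(len(doc)), key=lambda i: (doc[i], -i))
    return DOCResult(doc=doc, break_rank=best + 1)


@dataclass
class GenotypeCall:
    amplicon_id: str
    individual: str
    gene: str
    status: str  # ok | discarded_low_reads
    total_reads: int
    # (sequence, depth, fraction, flags) for each validated allele
    alleles: list[tuple[str, int, float, str]] = field(default_factory=list)
    names: dict[str, str] = field(default_factory=dict)  # sequence -> name

    def allele_set(self) -> set[str]:
        return {a[0] for a in self.alleles}


def _chimera_flag(seq: str, deeper: list[str]) -> bool:
    """True if ``seq`` equals prefix+suffix of two distinct deeper variants
    for some single breakpoint."""
    L = len(seq)
    for a in deeper:
        if len(a) != L or a == seq:
            continue
        # longest common prefix with a
        p = 0
        while p < L and seq[p] == a[p]:
            p += 1
        if p == 0:
            continue
        for b in deeper:
            if b is a or len(b) != L or b == seq:
                continue
            s = 0
            while s < L and seq[L - 1 - s] == b[L - 1 - s]:
                s += 1
            if p + s >= L:
                return True
    return False


def validate_alleles(table: VariantTable, individual: str = "", gene: str = "",
                     min_reads: int = 300, min_frac: float = 0.03,
                     use_doc: bool = True, chimera_check: bool = True,
                     combine: str = "intersection") -> GenotypeCall:
    """Validate true alleles of one amplicon.

    Amplicons with total depth < ``min_reads`` are discarded. Otherwise the
    validated set is the intersection (default) of the frequency filter
    (depth/total >= ``min_frac``) and the DOC-supported ranks; with
    ``combine="union"`` either filter suffices, and ``use_doc=False`` drops
    the DOC filter entirely. Chimera flags are advisory: a validated variant
    expressible as prefix+suffix of two deeper validated variants is marked
    ``putative_chimera`` but never removed.
    """
    rows = sorted(table.variants, key=lambda kv: (-kv[1], kv[0]))
    total = sum(d for _, d in rows)
    amp_id = table.amplicon_id
    if not individual or not gene:
        parts = amp_id.split("|")
        individual = individual or parts[0]
        gene = gene or (parts[1] if len(parts) > 1 else "")
    if total < min_reads:
        return GenotypeCall(amp_id, individual, gene,
                            status="discarded_low_reads", total_reads=total)
    keep_freq = {i for i, (_, d) in enumerate(rows) if d / total >= min_frac}
    # The DOC break point locates the boundary between true alleles and the
    # artifact tail. When no variant falls below the frequency threshold there
    # is no artifact region to bound, so the DOC filter abstains rather than
    # cutting inside the true alleles.
    if use_doc and len(keep_freq) < len(rows):
        br = doc_breakpoint([d for _, d in rows]).break_rank
        keep_doc = set(range(br))
        keep = (keep_freq & keep_doc if combine == "intersection"
                else keep_freq | keep_doc)
    else:
        keep = keep_freq
    kept = [rows[i] for i in sorted(keep)]
    alleles = []
    for k, (seq, depth) in enumerate(kept):
        flags = ""
        if chimera_check and k >= 2:
            deeper = [s for s, _ in kept[:k]]
            if _chimera_flag(seq, deeper):
                flags = "putative_chimera"
        alleles.append((seq, depth, depth / total, flags))
    return GenotypeCall(amp_id, individual, gene, status="ok",
                        total_reads=total, alleles=alleles)


@dataclass
class ReplicatePair:
    amplicon_id: str
    partner_id: str
    concordant: bool
    difference: set[str]


@dataclass
class ConcordanceReport:
    pairs: list[ReplicatePair]
    fraction_concordant: float


def replicate_concordance(calls: dict[str, GenotypeCall],
                          partners: dict[str, str]) -> ConcordanceReport:
    """Set-equality check of validated alleles between replicate amplicons.

    ``partners`` maps replicate amplicon id -> original amplicon id. Pairs
    where either member was discarded for low reads are skipped.
    """
    pairs = []
    for rep_id, orig_id in sorted(partners.items()):
        if rep_id not in calls or orig_id not in calls:
            raise ValueError(f"unpaired replicate label: {rep_id} / {orig_id}")
        a, b = calls[rep_id], calls[orig_id]
        if a.status != "ok" or b.status != "ok":
            continue
        sa, sb = a.allele_set(), b.allele_set()
        pairs.append(ReplicatePair(rep_id, orig_id, sa == sb,
                                   sa.symmetric_difference(sb)))
    frac = (sum(p.concordant for p in pairs) / len(pairs)) if pairs else float("nan")
    return ConcordanceReport(pairs=pairs, fraction_concordant=frac)


@dataclass
class AlleleRegistry:
    """Canonical allele names per gene.

    Naming follows the MHC-style convention: a four-letter species code (or
    several, joined in alphabetical order, for alleles observed in more than
    one species) + gene code + dense two-digit number, e.g. Raar_Brev*01 or
    Raar_Rate_Brev*02. The number is assigned at first observation and never
    changes when further species are added.
    """

    gene: str
    gene_code: str
    sequences: list[str] = field(default_factory=list)  # index = number - 1
    species_sets: dict[str, set[str]] = field(default_factory=dict)

    def name_of(self, seq: str) -> str:
        num = self.sequences.index(seq) + 1
        codes = "_".join(sorted(self.species_sets[seq]))
        return f"{codes}_{self.gene_code}*{num:02d}"

    def observe(self, seq: str, species: str) -> str:
        if seq not in self.species_sets:
            self.sequences.append(seq)
            self.species_sets[seq] = set()
        self.species_sets[seq].add(species)
        return self.name_of(seq)

    def as_fasta(self) -> str:
        return "".join(f">{self.name_of(s)}\n{s}\n" for s in self.sequences)

    def sidecar_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": [self.name_of(s) for s in self.sequences],
            "sequence": list(self.sequences),
            "species": [",".join(sorted(self.species_sets[s]))
                        for s in self.sequences],
        })


def name_alleles(calls: list[GenotypeCall], species_of: dict[str, str],
                 gene_codes: dict[str, str],
                 registries: dict[str, AlleleRegistry] | None = None):
    """Register every validated allele and attach canonical names to calls.

    Calls are processed in input order, so naming is stable across re-runs
    of the same data. Returns the per-gene registries.
    """
    registries = registries if registries is not None else {}
    for call in calls:
        if call.status != "ok":
            continue
        reg = registries.get(call.gene)
        if reg is None:
            reg = AlleleRegistry(gene=call.gene,
                                 gene_code=gene_codes.get(call.gene, call.gene[:4]))
            registries[call.gene] = reg
        if reg.gene != call.gene:
            raise ValueError("gene mismatch between call and registry")
        for seq, *_ in call.alleles:
            reg.observe(seq, species_of[call.individual])
    # names can gain species codes later; resolve once all calls are seen
    for call in calls:
        if call.status != "ok":
            continue
        reg = registries[call.gene]
        call.names = {seq: reg.name_of(seq) for seq, *_ in call.alleles}
    return registries


def copy_number_summary(calls: list[GenotypeCall],
                        species_of: dict[str, str]) -> pd.DataFrame:
    """Per species x gene: allele-count distribution and the implied minimum
    locus number ceil(max alleles per individual / 2)."""
    rows = {}
    for call in calls:
        if call.status != "ok":
            continue
        key = (species_of[call.individual], call.gene, call.individual)
        rows[key] = max(rows.get(key, 0), len(call.alleles))
    agg: dict[tuple[str, str], list[int]] = {}
    for (sp, gene, _), n in rows.items():
        agg.setdefault((sp, gene), []).append(n)
    out = []
    for (sp, gene), counts in sorted(agg.items()):
        arr = np.asarray(counts, dtype=float)
        out.append({
            "species": sp, "gene": gene, "n_individuals": len(counts),
            "max_alleles": int(arr.max()),
            "mean_alleles": float(arr.mean()),
            "sd_alleles": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "min_loci": math.ceil(arr.max() / 2),
        })
    return pd.DataFrame(out)


def calls_frame(calls: list[GenotypeCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        if c.status != "ok":
            rows.append({"amplicon_id": c.amplicon_id, "individual": c.individual,
                         "gene": c.gene, "status": c.status,
                         "allele_name": "", "sequence": "", "depth": 0,
                         "fraction": 0.0, "flags": ""})
            continue
        for seq, depth, frac, flags in c.alleles:
            rows.append({"amplicon_id": c.amplicon_id, "individual": c.individual,
                         "gene": c.gene, "status": c.status,
                         "allele_name": c.names.get(seq, ""), "sequence": seq,
                         "depth": depth, "fraction": frac, "flags": flags})
    return pd.DataFrame(rows)
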
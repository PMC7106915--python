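"""From raw amplicon reads to per-amplicon depth-ranked variant tables.

Covers the read-processing front end of the pipeline: overlap merging of
read pairs, exact-tag demultiplexing with primer stripping, and exact-sequence
variant tallying. Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._codons import revcomp


@dataclass
class TagScheme:
    """Per-amplicon barcode pairs plus per-gene primer sequences.

    assignments: amplicon_id -> (forward 8-bp tag, reverse 8-bp tag, gene).
    primers: gene -> (forward primer, reverse primer). The reverse tag/primer
    are stored in forward-strand orientation; on a merged forward read the
    reverse tag appears reverse-complemented at the 3' end.
    """

    assignments: dict[str, tuple[str, str, str]]
    primers: dict[str, tuple[str, str]]
    spacer_len: int = 3

    def __post_init__(self):
        pairs = [(f, r) for f, r, _ in self.assignments.values()]
        if len(set(pairs)) != len(pairs):
            raise ValueError("tag pairs must be unique per amplicon")
        for f, r, gene in self.assignments.values():
            if len(f) != 8 or len(r) != 8:
                raise ValueError("tags must be exactly 8 bases")
            if gene not in self.primers:
                raise ValueError(f"no primers registered for gene {gene}")
        for fwd, rev in self.primers.values():
            if not fwd or not rev:
                raise ValueError("primers must be non-empty")

    @classmethod
    def read(cls, tags_tsv: str | Path, primers_yaml: str | Path,
             spacer_len: int = 3) -> "TagScheme":
        assignments = {}
        with open(tags_tsv) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cols = {c: i for i, c in enumerate(header)}
            for line in fh:
                f = line.rstrip("\n").split("\t")
                assignments[f[cols["amplicon_id"]]] = (
                    f[cols["fwd_tag"]], f[cols["rev_tag"]], f[cols["gene"]])
        raw = yaml.safe_load(Path(primers_yaml).read_text())
        primers = {g: (v["forward"], v["reverse"]) for g, v in raw.items()}
        return cls(assignments=assignments, primers=primers, spacer_len=spacer_len)

    def write(self, tags_tsv: str | Path, primers_yaml: str | Path):
        with open(tags_tsv, "w") as fh:
            fh.write("amplicon_id\tfwd_tag\trev_tag\tgene\n")
            for amp_id in sorted(self.assignments):
                f, r, g = self.assignments[amp_id]
                fh.write(f"{amp_id}\t{f}\t{r}\t{g}\n")
        Path(primers_yaml).write_text(yaml.safe_dump(
            {g: {"forward": f, "reverse": r} for g, (f, r) in self.primers.items()},
            sort_keys=True))


@dataclass
class AmpliconBin:
    amplicon_id: str
    gene: str
    sequences: list[str] = field(default_factory=list)


@dataclass
class VariantTable:
    """Depth-ranked exact-sequence variants of one amplicon."""

    amplicon_id: str
    variants: list[tuple[str, int]]  # (sequence, depth), rank 1 first
    total_reads: int


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTQ(.gz) file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [(title.split()[0], seq) for title, seq, _ in
                FastqGeneralIterator(fh)]


def _best_overlap(r1: str, r2rc: str, min_overlap: int,
                  max_mismatch_frac: float) -> tuple[int, int] | None:
    """Best (score, overlap) for gluing r1 onto r2rc; None if no overlap
    satisfies the constraints. Score = matches - mismatches; ties go to the
    longer overlap (scanned first)."""
    best = None
    max_ov = min(len(r1), len(r2rc))
    for ov in range(max_ov, min_overlap - 1, -1):
        allowed = int(max_mismatch_frac * ov)
        mism = 0
        a = r1[-ov:]
        b = r2rc[:ov]
        ok = True
        for x, y in zip(a, b):
            if x != y:
                mism += 1
                if mism > allowed:
                    ok = False
                    break
        if ok:
            score = ov - 2 * mism
            if best is None or score > best[0]:
                best = (score, ov)
    return best


def merge_pairs(pairs: list[tuple[str, str, str]], min_overlap: int = 20,
                max_mismatch_frac: float = 0.1):
    """Combine read pairs into single forward reads over their best overlap.

    ``pairs`` holds (read_id, r1, r2) with r2 on the opposite strand.
    Overlap disagreements are resolved in favor of R1's base call. Returns
    (merged list of (read_id, sequence), n_unmerged).
    """
    merged = []
    unmerged = 0
    for rid, r1, r2 in pairs:
        r2rc = revcomp(r2)
        best = _best_overlap(r1, r2rc, min_overlap, max_mismatch_frac)
        if best is None:
            unmerged += 1
            continue
        _, ov = best
        merged.append((rid, r1 + r2rc[ov:]))
    return merged, unmerged


def merge_fastq_pair(r1_path, r2_path, min_overlap: int = 20,
                     max_mismatch_frac: float = 0.1):
    r1 = read_fastq(r1_path)
    r2 = read_fastq(r2_path)
    if len(r1) != len(r2):
        raise ValueError("R1/R2 streams differ in length")
    return merge_pairs([(a[0], a[1], b[1]) for a, b in zip(r1, r2)],
                       min_overlap, max_mismatch_frac)


def _mismatches(a: str, b: str, limit: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def demultiplex(reads: list[tuple[str, str]], tags: TagScheme,
                primer_mismatch: int = 2):
    """Assign merged reads to amplicons by exact 8-bp tag pairs.

    A read is assigned iff its leading 8 bases and trailing 8 bases
    (reverse-complemented) match a registered (forward, reverse) tag pair
    exactly, and both gene primers match with at most ``primer_mismatch``
    substitutions at their expected positions. Both orientations of the read
    are tried; the orientation with the forward tag first is canonical.
    Tag, spacer and primers are stripped. Unassigned reads are counted by
    failure reason. Returns (bins dict, counters dict).
    """
    lookup = {}
    for amp_id, (f, r, gene) in tags.assignments.items():
        lookup[(f, r)] = (amp_id, gene)
    bins: dict[str, AmpliconBin] = {
        amp_id: AmpliconBin(amp_id, gene)
        for amp_id, (_, _, gene) in tags.assignments.items()}
    counters = Counter(assigned=0, unknown_tag=0, primer_fail=0, too_short=0)
    sp = tags.spacer_len

    for _, seq in reads:
        hit = None
        for oriented in (seq, revcomp(seq)):
            key = (oriented[:8], revcomp(oriented[-8:]))
            if key in lookup:
                hit = (oriented, *lookup[key])
                break
        if hit is None:
            counters["unknown_tag"] += 1
            continue
        oriented, amp_id, gene = hit
        fwd_primer, rev_primer = tags.primers[gene]
        lead = 8 + sp
        tail = 8 + sp
        p_start = lead
        p_end = p_start + len(fwd_primer)
        r_end = len(oriented) - tail
        r_start = r_end - len(rev_primer)
        if r_start <= p_end:
            counters["too_short"] += 1
            continue
        if (_mismatches(oriented[p_start:p_end], fwd_primer, primer_mismatch)
                > primer_mismatch or
                _mismatches(oriented[r_start:r_end], revcomp(rev_primer),
                            primer_mismatch) > primer_mismatch):
            counters["primer_fail"] += 1
            continue
        bins[amp_id].sequences.append(oriented[p_end:r_start])
        counters["assigned"] += 1
    return bins, dict(counters)


def tally_variants(bin_: AmpliconBin) -> VariantTable:
    """Group identical sequences and rank by depth (ties broken by sequence,
    so ranks are deterministic)."""
    counts = Counter(bin_.sequences)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return VariantTable(amplicon_id=bin_.amplicon_id, variants=rows,
                        total_reads=sum(counts.values()))


def write_variant_tables(tables: list[VariantTable], path: str | Path):
    with open(path, "w") as fh:
        fh.write("amplicon_id\trank\tsequence\tdepth\n")
        for t in tables:
            for rank, (seq, depth) in enumerate(t.variants, start=1):
                fh.write(f"{t.amplicon_id}\t{rank}\t{seq}\t{depth}\n")


def read_variant_tables(path: str | Path) -> list[VariantTable]:
    by_amp: dict[str, list[tuple[str, int]]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            amp_id, _, seq, depth = line.rstrip("\n").split("\t")
            by_amp.setdefault(amp_id, []).append((seq, int(depth)))
    return [VariantTable(a, rows, sum(d for _, d in rows))
            for a, rows in by_amp.items()]
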
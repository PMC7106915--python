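"""Shared genetic-code tables and codon-level substitution classification.

Everything downstream of the standard genetic code (synonymous/nonsynonymous
classification, Nei–Gojobori site fractions, minimal mutational pathways) is
precomputed here once and reused by the peptide and selection modules.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

NUCS = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

STOP_CODONS = frozenset(_TABLE.stop_codons)
CODON_TO_AA = dict(_TABLE.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))  # 61 codons, lexicographic
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def codon_diffs(c1: str, c2: str) -> list[int]:
    """Positions (0..2) at which two codons differ."""
    return [k for k in range(3) if c1[k] != c2[k]]


def _single_step_type(c1: str, c2: str) -> tuple[bool, bool]:
    """(is_synonymous, is_transition) for codons differing at one position."""
    (k,) = codon_diffs(c1, c2)
    syn = CODON_TO_AA[c1] == CODON_TO_AA[c2]
    return syn, is_transition(c1[k], c2[k])


def _build_pair_tables():
    """61x61 classification of single-step codon changes.

    pair_type: 0 = same codon or multi-step, 1 = syn transversion,
    2 = syn transition, 3 = nonsyn transversion, 4 = nonsyn transition.
    """
    t = np.zeros((N_SENSE, N_SENSE), dtype=np.int8)
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i == j or len(codon_diffs(c1, c2)) != 1:
                continue
            syn, ts = _single_step_type(c1, c2)
            t[i, j] = (1 if syn else 3) + (1 if ts else 0)
    return t


PAIR_TYPE = _build_pair_tables()


def _ng86_site_fractions():
    """Nei–Gojobori synonymous site count per sense codon.

    At each codon position the three alternative nucleotides are examined;
    changes producing a stop codon are excluded and the synonymous fraction
    is renormalized over the remaining changes, so S + N = 3 per codon.
    """
    s = np.zeros(N_SENSE)
    for i, codon in enumerate(SENSE_CODONS):
        total = 0.0
        for k in range(3):
            syn = 0
            valid = 0
            for n in NUCS:
                if n == codon[k]:
                    continue
                alt = codon[:k] + n + codon[k + 1:]
                if alt in STOP_CODONS:
                    continue
                valid += 1
                if CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                    syn += 1
            if valid:
                total += syn / valid
        s[i] = total
    return s


SYN_SITES = _ng86_site_fractions()  # per codon; nonsyn sites = 3 - SYN_SITES


@lru_cache(maxsize=None)
def path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous difference counts between two codons.

    Counts are averaged over all minimal mutational pathways; pathways that
    pass through a stop codon are excluded. If every pathway is blocked the
    average falls back to all pathways (stop intermediates tolerated).
    """
    if c1 == c2:
        return 0.0, 0.0
    diffs = codon_diffs(c1, c2)
    paths = []
    for order in itertools.permutations(diffs):
        cur = c1
        syn = nonsyn = 0
        blocked = False
        for k in order:
            nxt = cur[:k] + c2[k] + cur[k + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            aa_cur = "*" if cur in STOP_CODONS else CODON_TO_AA[cur]
            aa_nxt = "*" if nxt in STOP_CODONS else CODON_TO_AA[nxt]
            if aa_cur == aa_nxt:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((blocked, syn, nonsyn))
    open_paths = [(s, n) for blocked, s, n in paths if not blocked]
    if not open_paths:
        open_paths = [(s, n) for _, s, n in paths]
    syn = sum(p[0] for p in open_paths) / len(open_paths)
    nonsyn = sum(p[1] for p in open_paths) / len(open_paths)
    return syn, nonsyn


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide sequence; '*' marks stop codons."""
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        aa.append("*" if codon in STOP_CODONS else CODON_TO_AA.get(codon, "X"))
    return "".join(aa)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
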
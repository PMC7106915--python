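"""Population-genetic summaries of validated AMP alleles.

Frequency tables per population/region/species and the classical diversity
statistics — segregating sites S, mean pairwise nucleotide differences k
(Theta k), per-site nucleotide diversity pi = k / L, and Tajima's D — for
whole amplicons or for the acidic-propiece / mature-peptide sub-intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AlignedAlleleSet:
    """Aligned alleles of one gene plus the observations referencing them.

    ``observations`` has one row per (individual, allele) occurrence with
    columns individual, population, region, species, allele_name. Domain
    sub-intervals are 0-based half-open columns of the alignment.
    """

    gene: str
    sequences: dict[str, str]  # allele name -> aligned sequence
    observations: pd.DataFrame | None = None
    domains: dict[str, tuple[int, int]] | None = None

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        if self.observations is not None:
            unknown = set(self.observations["allele_name"]) - set(self.sequences)
            if unknown:
                raise ValueError(f"observations reference unknown alleles: {unknown}")

    def interval(self, name: str) -> tuple[int, int]:
        if name == "whole":
            L = len(next(iter(self.sequences.values())))
            return (0, L)
        if self.domains is None or name not in self.domains:
            raise ValueError(f"no domain interval named {name!r}")
        return self.domains[name]


@dataclass
class FrequencyTable:
    grouping: str
    frequencies: dict[str, dict[str, float]]  # group -> allele -> freq
    n_alleles: dict[str, int] = field(default_factory=dict)  # A per group
    unique_alleles: dict[str, int] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = [{"group": g, "allele": a, "frequency": f}
                for g, d in sorted(self.frequencies.items())
                for a, f in sorted(d.items())]
        return pd.DataFrame(rows)


def allele_frequencies(observations: pd.DataFrame,
                       grouping: str = "population") -> FrequencyTable:
    """Occurrence-based relative allele frequencies per group.

    Each validated allele counts once per individual carrying it; the
    frequency is occurrences / total occurrences within the group. Also
    reports A (distinct alleles per group) and, for region/species grouping,
    the number of alleles unique to each group.
    """
    if grouping not in observations.columns:
        raise ValueError(f"unknown grouping column: {grouping}")
    freqs: dict[str, dict[str, float]] = {}
    n_alleles: dict[str, int] = {}
    group_alleles: dict[str, set[str]] = {}
    for group, sub in observations.groupby(grouping, sort=True):
        counts = sub["allele_name"].value_counts()
        total = int(counts.sum())
        if total == 0:
            continue
        freqs[str(group)] = {a: c / total for a, c in counts.items()}
        n_alleles[str(group)] = len(counts)
        group_alleles[str(group)] = set(counts.index)
    unique = {}
    for g, alleles in group_alleles.items():
        others = set().union(*(s for h, s in group_alleles.items() if h != g)) \
            if len(group_alleles) > 1 else set()
        unique[g] = len(alleles - others)
    return FrequencyTable(grouping=grouping, frequencies=freqs,
                          n_alleles=n_alleles, unique_alleles=unique)


@dataclass
class DiversitySummary:
    group: str
    interval: str
    n_seqs: int
    n_sites: int          # aligned bp analyzed after gap-column removal
    S: int
    k: float | None       # Theta k, mean pairwise differences
    pi: float | None
    tajima_d: float | None


def _gapless_columns(seqs: list[str], start: int, end: int,
                     gap_mode: str) -> list[str]:
    cols = []
    for j in range(start, end):
        column = [s[j] for s in seqs]
        if gap_mode == "complete" and any(c in "-.Nn" for c in column):
            continue
        cols.append("".join(column))
    return ["".join(col[i] for col in cols) for i in range(len(seqs))]


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def diversity_stats(seqs: list[str], counts: list[int] | None = None,
                    start: int = 0, end: int | None = None,
                    gap_mode: str = "complete",
                    group: str = "", interval: str = "whole") -> DiversitySummary:
    """S, Theta k, pi and Tajima's D for a set of aligned sequences.

    ``counts`` enables frequency weighting: sequence i is treated as counts[i]
    identical observations (pairs within a sequence contribute 0 differences).
    Gap-containing columns are excluded alignment-wide by default (complete
    deletion); ``gap_mode="pairwise"`` keeps all columns and compares only
    positions where both sequences are gap-free (pi then uses the full
    interval length). Tajima's D is undefined (None) when S = 0 or n < 2.
    """
    if not seqs:
        raise ValueError("no sequences")
    end = len(seqs[0]) if end is None else end
    if counts is None:
        counts = [1] * len(seqs)
    if len(counts) != len(seqs) or any(c < 1 for c in counts):
        raise ValueError("counts must be positive, one per sequence")
    if gap_mode == "complete":
        stripped = _gapless_columns(seqs, start, end, gap_mode)
    else:
        stripped = [s[start:end] for s in seqs]
    L = len(stripped[0]) if stripped else 0
    n = sum(counts)

    # segregating sites over the distinct sequences present
    S = 0
    for j in range(L):
        col = {s[j] for s in stripped if s[j] not in "-.Nn"}
        if len(col) > 1:
            S += 1

    if n < 2 or L == 0:
        return DiversitySummary(group, interval, n, L, S, None, None, None)

    total_diff = 0.0
    for i in range(len(stripped)):
        for j in range(i + 1, len(stripped)):
            d = sum(1 for a, b in zip(stripped[i], stripped[j])
                    if a != b and a not in "-.Nn" and b not in "-.Nn")
            total_diff += d * counts[i] * counts[j]
    n_pairs = n * (n - 1) / 2.0
    k = total_diff / n_pairs
    pi = k / L

    if S == 0:
        d_val = None
    else:
        c = tajima_constants(n)
        var = c["e1"] * S + c["e2"] * S * (S - 1)
        num = k - S / c["a1"]
        if var > 0:
            d_val = num / math.sqrt(var)
        else:
            # n = 3 gives exactly zero variance; D is 0 when the two
            # estimators coincide, undefined otherwise
            d_val = 0.0 if abs(num) < 1e-9 else None
    return DiversitySummary(group, interval, n, L, S, k, pi, d_val)


def diversity_by_group(aset: AlignedAlleleSet, grouping: str = "region",
                       interval: str = "whole",
                       weighting: str = "unique_alleles",
                       gap_mode: str = "complete") -> list[DiversitySummary]:
    """Diversity statistics per group of an aligned allele set.

    ``unique_alleles`` (default) computes over the distinct alleles observed
    in the group, matching analyses run on allele sets; ``by_frequency``
    weights each allele by its occurrence count in the group.
    """
    start, end = aset.interval(interval)
    out = []
    if aset.observations is None or grouping == "all":
        names = sorted(aset.sequences)
        seqs = [aset.sequences[n] for n in names]
        out.append(diversity_stats(seqs, None, start, end, gap_mode,
                                   group="all", interval=interval))
        return out
    for group, sub in aset.observations.groupby(grouping, sort=True):
        counts_ser = sub["allele_name"].value_counts().sort_index()
        names = list(counts_ser.index)
        seqs = [aset.sequences[n] for n in names]
        counts = None if weighting == "unique_alleles" else [int(c) for c in counts_ser]
        out.append(diversity_stats(seqs, counts, start, end, gap_mode,
                                   group=str(group), interval=interval))
    return out


def summaries_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group": s.group, "interval": s.interval, "n": s.n_seqs,
        "N_bp": s.n_sites, "S": s.S, "k": s.k, "pi": s.pi,
        "tajima_D": s.tajima_d,
    } for s in summaries])


def region_allele_count_test(counts, regions, n_perm: int = 9999,
                             seed: int | None = 0):
    """Permutation test for region differences in individual allele counts.

    Statistic: between-region variance of the regional means of per-individual
    allele counts. The null distribution permutes region labels over
    individuals; p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    counts = np.asarray(counts, dtype=float)
    regions = np.asarray(regions)
    labels = np.unique(regions)
    if len(labels) < 2:
        raise ValueError("need at least 2 regions")
    if any((regions == lab).sum() == 0 for lab in labels):
        raise ValueError("every region needs at least one individual")

    def stat(perm_regions):
        means = [counts[perm_regions == lab].mean() for lab in labels]
        return float(np.var(means))

    obs = stat(regions)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = regions.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if stat(perm) >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return obs, p
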
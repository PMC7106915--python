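"""Peptide-level analyses of AMP precursor alleles.

Antimicrobial-peptide precursors carry a conserved signal peptide, an acidic
propiece and a cationic, hypervariable mature peptide. This module translates
nucleotide alleles, cuts them into those domains, collapses synonymous
nucleotide alleles into amino-acid variants, computes net charges and fits
the propiece-charge ~ mature-charge regression used to detect coordinated
(charge-compensating) evolution between the two domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._codons import translate


class InvalidAlleleError(ValueError):
    """Raised when an allele cannot be translated (internal stop, bad frame)."""


@dataclass
class DomainMap:
    """Reading frame and domain boundaries for one gene's amplicon.

    ``intervals`` gives 0-based half-open *nucleotide* intervals for the
    acidic propiece and the mature peptide, relative to the amplicon start
    (they must be codon-aligned with respect to ``frame_offset``). When
    ``intervals`` is None the propiece/mature boundary is located by the
    canonical dibasic KR processing-site rule instead.
    """

    gene: str
    frame_offset: int = 0
    intervals: dict[str, tuple[int, int]] | None = None

    def __post_init__(self):
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0..2")
        if self.intervals is not None:
            prop = self.intervals["propiece"]
            mat = self.intervals["mature"]
            if not (prop[0] < prop[1] <= mat[0] < mat[1]):
                raise ValueError("domains must be ordered propiece < mature")
            for a, b in (prop, mat):
                if (a - self.frame_offset) % 3 or (b - self.frame_offset) % 3:
                    raise ValueError("domain boundaries must be codon-aligned")


@dataclass
class PeptideVariant:
    """A set of nucleotide alleles sharing one amino-acid sequence."""

    name: str
    aa_seq: str
    members: list[str] = field(default_factory=list)
    propiece: str = ""
    mature: str = ""


@dataclass
class ChargeRegressionResult:
    slope: float
    stderr: float
    intercept: float
    n: int


def translate_and_partition(seq: str, dmap: DomainMap) -> tuple[str, str, str]:
    """Translate one allele and return (full, propiece, mature) peptides.

    Raises InvalidAlleleError on internal stop codons; such alleles are
    excluded from peptide analyses.
    """
    if len(seq) < dmap.frame_offset + 6:
        raise InvalidAlleleError("sequence too short to translate")
    coding = seq[dmap.frame_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    full = translate(coding)
    if "*" in full[:-1] or (full.endswith("*") and dmap.intervals is not None):
        raise InvalidAlleleError(f"internal stop codon in allele of {dmap.gene}")
    if full.endswith("*"):
        full = full[:-1]
    if dmap.intervals is not None:
        prop = _cut(seq, dmap, "propiece")
        mature = _cut(seq, dmap, "mature")
        return full, prop, mature
    # dibasic KR processing-site rule: the mature peptide starts right after
    # the last K-R pair found upstream of the precursor midpoint
    mid = len(full) // 2
    boundary = None
    for i in range(mid - 1, -1, -1):
        if full[i:i + 2] == "KR":
            boundary = i + 2
            break
    if boundary is None:
        raise InvalidAlleleError("no dibasic KR processing site found")
    return full, full[:boundary], full[boundary:]


def _cut(seq: str, dmap: DomainMap, domain: str) -> str:
    a, b = dmap.intervals[domain]
    if b > len(seq):
        raise InvalidAlleleError(f"{domain} interval exceeds allele length")
    pep = translate(seq[a:b])
    if "*" in pep:
        raise InvalidAlleleError(f"stop codon inside {domain}")
    return pep


def collapse_synonymous(
    alleles: dict[str, str], gene_code: str, dmap: DomainMap | None = None
) -> list[PeptideVariant]:
    """Group nucleotide alleles that translate to the same amino-acid sequence.

    Variant names (``<Gene>_Amino*NN``) are assigned densely in order of
    first observation, following the allele-naming convention.
    """
    variants: dict[str, PeptideVariant] = {}
    for name, seq in alleles.items():
        if dmap is not None:
            full, prop, mature = translate_and_partition(seq, dmap)
        else:
            full = translate(seq)
            if "*" in full:
                raise InvalidAlleleError(f"internal stop codon in {name}")
            prop = mature = ""
        if full not in variants:
            num = len(variants) + 1
            variants[full] = PeptideVariant(
                name=f"{gene_code}_Amino*{num:02d}", aa_seq=full,
                propiece=prop, mature=mature,
            )
        variants[full].members.append(name)
    return list(variants.values())


# integer model: side chains only, His and termini neutral
_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")

_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Lehninger pKa set used by the Henderson–Hasselbalch model
_PKA_POS = {"K": 10.53, "R": 12.48, "H": 6.00}
_PKA_NEG = {"D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07}
_PKA_NTERM = 9.69
_PKA_CTERM = 2.34


def net_charge(peptide: str, model: str = "integer", ph: float = 7.0,
               termini: bool = True) -> float:
    """Net charge of a peptide.

    integer model (default): #(K,R) - #(D,E); histidine and termini count 0,
    matching the integer charge ranges conventionally reported for AMP
    domains. henderson_hasselbalch: per-group fractional charges at ``ph``
    using the Lehninger pKa set, termini included once.
    """
    bad = set(peptide) - _STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    if model == "integer":
        return float(sum(a in _POSITIVE for a in peptide)
                     - sum(a in _NEGATIVE for a in peptide))
    if model != "henderson_hasselbalch":
        raise ValueError(f"unknown charge model: {model}")
    charge = 0.0
    if termini and peptide:
        charge += 1.0 / (1.0 + 10 ** (ph - _PKA_NTERM))
        charge -= 1.0 / (1.0 + 10 ** (_PKA_CTERM - ph))
    for aa in peptide:
        if aa in _PKA_POS:
            charge += 1.0 / (1.0 + 10 ** (ph - _PKA_POS[aa]))
        elif aa in _PKA_NEG:
            charge -= 1.0 / (1.0 + 10 ** (_PKA_NEG[aa] - ph))
    return charge


def charge_regression(pairs: list[tuple[float, float]]) -> ChargeRegressionResult:
    """OLS of propiece charge (response) on mature charge (predictor).

    ``pairs`` holds (mature_charge, propiece_charge) per unique allele.
    A negative slope indicates charge-compensating, coordinated evolution of
    the two precursor domains.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (mature, propiece) charge pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in mature charge; slope undefined")
    fit = stats.linregress(x, y)
    stderr = 0.0 if np.isnan(fit.stderr) else float(fit.stderr)
    return ChargeRegressionResult(
        slope=float(fit.slope), stderr=stderr,
        intercept=float(fit.intercept), n=len(pairs),
    )
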
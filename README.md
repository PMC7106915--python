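# amp-typer

Genotyping and evolutionary analysis of **multi-locus antimicrobial-peptide
(AMP) gene families** from deep amplicon sequencing.

Frog skin AMPs (Temporin, Brevinin, Palustrin and relatives) are encoded by
small families of duplicated genes. One primer pair co-amplifies every paralog
of a family, so a single individual yields anywhere from one to ~10 distinct
alleles per amplicon — mixed with PCR chimeras and sequencing errors. The
precursor has a conserved signal peptide, a negatively charged *acidic
propiece* and a cationic, hypervariable *mature peptide*; the evolutionary
questions are how allelic diversity is distributed across populations and
species, whether alleles are shared across species boundaries (trans-specific
polymorphism), whether the two domains evolve in a charge-coordinated way,
and whether specific mature-peptide codons are under positive selection.

`amp-typer` implements the full desk side of such a study:

- **synthdata** — a truth-recording simulator of the whole design: allele
  pools with domain-specific substitution rates, two species with shared
  alleles, multi-locus genotypes, barcoded amplicon read pools with depth
  skew, point errors, chimeras and technical replicates.
- **amplicon** — read-pair overlap merging, exact 8-bp tag demultiplexing
  with primer stripping, and depth-ranked variant tables.
- **genotyping** — allele validation by the **degree-of-change (DOC)**
  break-point statistic (`DOC_i = 100 (d_i - d_{i+1}) / d_i` on depth-ranked
  variants; the variant before the largest drop is the last true allele)
  combined with a 3%-of-reads frequency filter and a 300-read amplicon
  minimum; replicate concordance; MHC-style allele naming (`Raar_Brev*01`,
  shared alleles `Raar_Rate_Brev*02`); copy-number bounds (min loci =
  ceil(max alleles / 2)).
- **popgen** — allele frequency tables and S, Theta k, pi, Tajima's D per
  population/region/domain, plus a permutation test for regional differences
  in individual allele counts.
- **peptide** — translation, propiece/mature partition (explicit intervals or
  the dibasic KR processing-site rule), synonymous collapse to amino-acid
  variants, net charges, and the OLS regression of propiece charge on mature
  charge (a negative slope = coordinated domain evolution).
- **phylo** — neighbor-joining trees with column-bootstrap support,
  species-mixture reports over supported clades (the trans-specific
  polymorphism signal), minimum-spanning haplotype networks, and a
  center-star aligner for unequal-length inputs.
- **selection** — Nei–Gojobori pairwise dN/dS, a SLAC-style per-site counting
  scan over Fitch-reconstructed ancestors, and GY94 codon site models
  (M0, M1a, M2a, M7, M8) with F3x4 frequencies, likelihood-ratio tests and
  naive-empirical-Bayes identification of positively selected sites, plus a
  matching alignment simulator for power/calibration studies.
- **pipeline / CLI** — `amp-typer run` executes everything into one
  seed-deterministic run directory with a manifest; per-stage subcommands
  (`simulate`, `demux`, `genotype`, `popgen`, `peptide`, `phylo`,
  `selection`) expose the stages individually.

## Worked example

```python
from amp_typer.synthdata import (SimConfig, simulate_allele_pool,
                                 simulate_cohort, make_tag_scheme,
                                 simulate_reads)
from amp_typer import amplicon, genotyping
from amp_typer.popgen import diversity_stats

cfg = SimConfig(seed=42, n_populations=2, inds_per_pop=2, depth_mean=1500)
pool = simulate_allele_pool(cfg)
cohort = simulate_cohort(pool, cfg)
tags, rep_of = make_tag_scheme(cohort, pool, cfg)
reads, truth = simulate_reads(cohort, pool, tags, cfg, replicate_of=rep_of)

print(f"{len(reads)} reads across {len(tags.assignments)} amplicons")
bins, counters = amplicon.demultiplex(reads, tags)
print("demux:", counters)

amp_id = sorted(bins)[0]
table = amplicon.tally_variants(bins[amp_id])
call = genotyping.validate_alleles(table)
print(f"{amp_id}: {table.total_reads} reads, {len(table.variants)} variants, "
      f"{len(call.alleles)} validated alleles")
doc = genotyping.doc_breakpoint([d for _, d in table.variants[:8]])
print("top depths:", [d for _, d in table.variants[:8]])
print("DOC:", [round(x, 1) for x in doc.doc[:7]], "break at rank", doc.break_rank)
```

This prints (seed 42):

```
22300 reads across 15 amplicons
demux: {'assigned': 21581, 'unknown_tag': 718, 'primer_fail': 1, 'too_short': 0}
Raar_P01_i01|Brevinin: 1428 reads, 468 variants, 5 validated alleles
top depths: [261, 218, 194, 143, 129, 2, 2, 2]
DOC: [16.5, 11.0, 26.3, 9.8, 98.4, 0.0, 0.0]  break at rank 5
```

The amplicon carries five true alleles: depth falls gently within the true
set (drops of 10–26%) and collapses by 98.4% between rank 5 (129 reads) and
the error tail (2 reads) — exactly where the DOC break point lands. The 718
`unknown_tag` reads are those whose barcode was hit by a simulated
sequencing error; they are counted, not guessed.

Domain-level diversity on the same pool shows the expected gradient — the
mature peptide is far more variable than the propiece:

```python
gp = pool.genes["Temporin"]
seqs = gp.species_alleles("Raar")
for name, (a, b) in (("mature", gp.domains["mature"]),
                     ("propiece", gp.domains["propiece"])):
    s = diversity_stats(seqs, start=a, end=b)
    print(f"Temporin {name}: S={s.S} k={s.k:.2f} pi={s.pi:.3f} D={s.tajima_d:.2f}")
```

```
Temporin mature: S=66 k=30.30 pi=0.459 D=2.80
Temporin propiece: S=41 k=10.80 pi=0.257 D=-0.06
```

A full run (`amp-typer run --out run/ --seed 7`) adds frequency tables,
bootstrap NJ trees with clade species-mixture reports, minimum-spanning
networks, charge regressions and codon-model selection tests under `run/`.

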
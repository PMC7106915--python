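# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `amp_typer`, and what the synthetic-data checks do and do not show.

## Synthetic study generator (`synthdata`)

The generator emulates a two-species amplicon survey of three AMP gene
families. Its defaults define the reference condition used by the test and
acceptance suites:

| knob | default | meaning / rationale |
|---|---|---|
| `gene_names`, `loci_per_gene` | Temporin/Brevinin/Palustrin, (4, 3, 3) | small multi-locus families; one primer pair per family co-amplifies all loci |
| `alleles_per_locus` | 6 | pool sizes give realistic per-individual allele counts (up to 8 distinct for a 4-locus gene) |
| `amplicon_len_range` | 120–204 bp | amplicon lengths vary between genes; multiples of 3 so frame offset is 0 |
| `shared_allele_frac` | 0.15 | fraction of each locus pool copied byte-identically across species (trans-specific polymorphism) |
| `depth_mean` | 2000 reads | Poisson per-amplicon depth |
| `depth_skew` | 20 | symmetric Dirichlet concentration for per-allele amplification bias; gives the ~2–3-fold depth differences seen between co-amplified alleles, while keeping true alleles above the 3% validation threshold (a system whose real alleles routinely fell below 3% could not show perfect replicate concordance) |
| `per_base_error` | 0.002/bp | i.i.d. substitution errors on every emitted base, tags and primers included |
| `chimera_frac` | 0.05 | reads formed from two genotype alleles of the *same* amplicon at a uniform breakpoint (PCR realism) |
| `replicate_frac` | 0.15 | individuals re-amplified under an independent tag pair with independent noise |
| substitution rates | signal 0.01, propiece 0.05, mature 0.22/site | the hypervariable-mature > propiece > signal gradient of AMP precursors |
| `species_divergence` | 0.06/site | divergence of the two species' gene ancestors |
| `charge_coordination` | 0.8 | when an allele's mature-domain integer charge deviates by Δ from its founder, the propiece is nudged toward −0.8·Δ by residue swaps — emulating charge-compensated (coordinated) domain evolution |

Ancestors are random in-frame codon strings with domain-biased amino-acid
composition (acidic propiece, cationic/glycine-leucine-rich mature domain);
mutation is codon-aware and rejects stops. Indels are off: length variation
exists between genes, not within a family, so alignment is trivial at default
settings and the aligner is exercised separately. Quality strings are
constant (quality-aware filtering is not part of the genotyping method).
Read structure: `tag(8) + spacer(3, random bases) + primer + insert +
rc(primer) + spacer + rc(tag)`; paired mode emits the first/last `read_len`
bases with independent errors per mate.

What the generator does **not** emulate: coalescent demography, quality-score
error profiles, indel errors, tag cross-contamination, and locus-specific
amplification dropout. Passing tests therefore demonstrate correctness of the
*methods* under controlled artifact models, not performance guarantees on any
particular sequencing chemistry.

## Read processing (`amplicon`)

Pair merging scans overlaps from longest to shortest, requires the mismatch
fraction ≤ `max_mismatch_frac` (default 0.1) over at least `min_overlap`
(default 20 bp), scores overlap as matches − mismatches, and resolves
disagreements in favor of R1. Demultiplexing requires an exact match of the
8-bp tag pair (both read orientations are tried; no tag error correction, so
reads with a tag error are counted as `unknown_tag`), and allows ≤ 2
substitutions per primer (no indels). Variant tables group exact sequences;
depth ties rank lexicographically so ranks are deterministic.

## Allele validation (`genotyping`)

`doc_breakpoint` implements the degree-of-change statistic as the relative
depth drop after each rank, `DOC_i = 100 (d_i − d_{i+1}) / d_i`, with the
break at the (first) maximal drop; a single variant yields break rank 1. An
alternative cumulative-depth inflection formulation exists in the literature;
the relative-drop form matches the verbal definition ("break point in
sequencing coverage") and is frozen here.

`validate_alleles` discards amplicons with fewer than 300 retained reads,
then takes the **intersection** of the ≥3%-of-reads frequency filter and the
DOC-supported ranks (a union mode exists but is not default). One design
choice needs stating: the DOC break point separates true alleles from an
artifact tail, so when *no* variant falls below the frequency threshold there
is no artifact region to bound and the DOC filter abstains (keeps all
frequency-passing variants). Without this rule a noise-free amplicon — whose
variant table contains only true alleles — would be truncated at the largest
depth drop *between true alleles*, and zero-noise recovery could never be
exact. Chimera flags are advisory (a validated variant expressible as
prefix + suffix of two deeper validated variants): artifacts are removed only
by thresholds, DOC and replication.

Naming follows the MHC convention: species code(s) in alphabetical order +
gene code + dense two-digit number assigned at first observation; an allele
later seen in the second species keeps its number and gains the second code.
Copy-number lower bounds are `ceil(max alleles per individual / 2)`; with up
to 11 alleles this yields 6, and any smaller published locus count implies a
counting rule beyond allele counts, which we do not attempt to reproduce.

## Diversity statistics (`popgen`)

S, k (mean pairwise differences, "Theta k"), pi = k / L and Tajima's D use the
standard constants (a1…e2). Gap-containing columns are excluded alignment-wide
by default (complete deletion, the DnaSP-like default); pairwise deletion is
available. Statistics are computed on **unique alleles** per group by default
— gene-family alleles have no meaningful diploid frequencies — with an
occurrence-weighted mode (`by_frequency`) for population-level use; the two
modes differ exactly when allele counts differ, which is documented behavior
rather than a bug. For n = 3 the variance of Tajima's D is exactly zero; D is
reported as 0 when the two estimators coincide and as missing otherwise.

Regional differences in per-individual allele counts are tested with a
permutation test (statistic: between-region variance of regional means;
labels permuted over individuals; p = (1 + #{perm ≥ obs}) / (n_perm + 1),
default 9999 permutations). This replaces an off-the-shelf mixed-model fit:
for a single response per individual a permutation test needs no variance
component assumptions and is exact under the null.

## Peptide analyses (`peptide`)

Domains cut either at explicit codon-aligned nucleotide intervals or, absent
intervals, right after the last dibasic K-R processing site upstream of the
precursor midpoint (canonical AMP precursor processing). Net charge defaults
to the integer model (#K + #R − #D − #E; histidine and termini 0), matching
the integer ranges conventionally reported for AMP domains; a
Henderson–Hasselbalch model (Lehninger pKa set, termini counted once, default
pH 7.0) is available. The coordinated-evolution regression is OLS of
**propiece charge on mature charge** (the regression direction is a choice;
the sign — the scientific claim — is direction-invariant, the magnitude is
not), with the slope standard error from the usual closed form
(`scipy.stats.linregress`). Each gene pool is one regression: pooling genes
mixes different ancestral charge baselines and can mask the within-family
covariation.

## Phylogenetics (`phylo`)

Distances default to p-distance with pairwise deletion (JC69 optional).
Neighbor joining is the standard Q-criterion algorithm with deterministic
tie-breaking (lowest label pair; cluster label = smallest contained leaf
name); negative branch lengths are clamped to zero and counted. Bootstrap
support resamples alignment columns, rebuilds NJ trees and reports the
percentage of replicates containing each bipartition of the point tree
(supports ≤ 50 can be masked for display). Trans-specific polymorphism is
quantified as the fraction of supported non-trivial bipartitions whose
smaller side contains both species. Minimum-spanning networks are Kruskal
MSTs on Hamming distances with deterministic edge order; `epsilon > 0`
additionally keeps every edge within epsilon of the weight at which its
endpoints' components merged (bottleneck weight), turning the tree into a
haplotype network. The center-star aligner (match +1, mismatch −1, gap −2,
deterministic traceback, "once a gap, always a gap" merging) covers
unequal-length inputs; edit distances for center selection use `edlib` when
present, a pure-Python fallback otherwise.

## Selection (`selection`)

The counting route: Nei–Gojobori (1986) site fractions are computed per codon
from the single-step mutational neighborhood, excluding changes to stop
codons and renormalizing (so S + N = 3 per codon); multi-hit codon pairs
average syn/nonsyn splits over all minimal pathways not passing through a
stop; proportions are Jukes–Cantor corrected (undefined at p ≥ 3/4). The
SLAC-style scan reconstructs ancestral codons by Fitch parsimony per site
(ties resolved by minimal nonsynonymous cost against the parent, then
lexicographically), sums syn/nonsyn changes over edges, and tests each site's
nonsynonymous count against its NG86 expected proportion with a two-tailed
binomial test (fractional pathway counts are rounded to integers for the
test; this is an approximation inherent to counting methods).

The likelihood route: GY94 rate matrix (single-nucleotide codon changes;
factors pi_j, kappa for transitions, omega for nonsynonymous), F3x4 codon
frequencies estimated from the alignment (stop codons excluded,
renormalized, frequencies floored at 1e-6 to avoid zero-likelihood
degeneracy). **Mixture scaling**: one common factor normalizes the expected
substitution rate averaged over site classes to 1, so branch lengths are
expected substitutions/codon under the whole model and positive-selection
classes are genuinely faster — scaling each class separately would erase the
rate elevation that site detection relies on. Likelihoods use Felsenstein
pruning with per-node rescaling and site-pattern compression; transition
matrices come from a symmetrized eigendecomposition of the reversible
generator.

Model fitting: branch lengths are taken from the input (NJ) topology and
rescaled by a single factor jointly optimized with kappa and omega under M0;
site models then hold branch lengths fixed (a documented simplification of
joint per-branch re-optimization). Free parameters are optimized by bounded
Powell search (kappa ∈ [0.1, 20], omega ∈ [1e-4, 50], omega0 ≤ 1, omega2,
omega_s ≥ 1, proportions in (0, 1), beta p, q ∈ [0.05, 99]), with multiple
starts: nested alternatives (M2a, M8) always receive one start at the null's
MLE with the positive class collapsed (omega = 1, near-zero weight), which
enforces lnL(alt) ≥ lnL(null) by construction, plus a start with real weight
on every class. M7/M8 discretize the beta into K = 10 equal-probability
classes represented by their conditional means. LRTs use chi-square with
df = 2, clamping negative statistics to zero.

Positive sites are identified by **naive empirical Bayes** (NEB): posterior
of the omega > 1 classes at the MLEs. Bayes empirical Bayes (which integrates
over parameter uncertainty) is the natural extension point; NEB uses
identical machinery and is the deliberate scope here — at the simulated data
sizes the difference is secondary, but NEB posteriors are known to be
overconfident on small alignments. FEL/REL-style per-site likelihood tests
are likewise out of scope; the counting scan plus NEB cover the
two-independent-routes design.

The simulator draws site classes from the model proportions, root codons
from the equilibrium frequencies, and evolves each branch by the exact
transition probabilities of the same scaled generators, recording per-site
truth.

## Pipeline

`run_pipeline` executes simulate/ingest → demux → genotype → popgen +
peptide + phylo + selection into one output directory with a JSON manifest
(parameters, per-stage tallies, input checksums in ingest mode). Identical
configuration (including seed) reproduces every output byte-for-byte;
timestamps exist only in the log. A missing upstream stage fails fast with a
message naming the dependency. Defaults carry the study constants: min_reads
300, min_frac 0.03, 1000 bootstrap replicates, 9999 permutations; the
selection stage defaults to the M1a/M2a pair (M7/M8 can be enabled, at
roughly 5x the fitting cost).

## Problem sizes in the checks

The test and acceptance suites run, per invocation: the reference cohort (30
individuals × 3 genes, ~200k reads) for recovery/concordance; 200 random
alignments (n ≤ 8, L ≤ 60) against the brute-force diversity oracle; ~1300
depth vectors against the DOC oracle; 100 additive 8-taxon matrices for NJ;
60 gene pools for the charge-slope sign; 20 × 300-codon M0 recoveries,
50 × 100-codon M1a/M2a type-I replicates and 10 × 500-codon NEB power
replicates (6–8 taxa); and two reduced pipeline runs for byte-level
determinism. These sizes keep a full run within minutes-scale budgets while
leaving the statistical assertions comfortably powered.

## Known limitations

- No diploid phasing: alleles are not assigned to specific paralogs, so copy
  number is a lower bound only.
- The demultiplexer's exact-tag rule discards reads with tag errors
  (~1.6% at the default error rate); with error-correcting barcode designs a
  relaxed matcher would be preferable.
- NEB rather than BEB; branch lengths fixed from the M0 global-scale fit
  rather than re-optimized per site model; NJ (not ML) trees feed the codon
  models.
- The SLAC binomial test rounds fractional pathway-averaged counts.
- The center-star aligner is adequate for the near-identical-length alleles
  of this system, not a general-purpose MSA tool.
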
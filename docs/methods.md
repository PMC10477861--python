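# Methods

## Problem setting

`acpmine` operates on a pool of candidate anticancer peptides (short,
bacterially encoded amino-acid sequences, typically 31–50 residues) and a
two-group collection of shotgun gut-metagenome samples (cases with
colorectal cancer, healthy controls). The working hypothesis is ecological:
peptides that genuinely suppress tumors should be more abundant in healthy
guts. The package turns that hypothesis into a reproducible filter cascade
over read-level abundance estimates.

## Protein-space read mapping

DNA reads are translated in all six frames under the standard genetic
code. Translation fragments are maximal runs between stop codons; codons
containing `N` translate to `X`, which likewise terminates a fragment.
Fragments shorter than `min_orf_len` (default 8 residues) are discarded.

Fragments are compared to catalog peptides without gaps. A *valid span* is
a pair of equal-length windows (one in the fragment, one in the peptide)
with length ≥ `min_match_len` (8) and identity ≥ `min_identity` (0.9); the
candidate score is the best BLOSUM62 sum over valid spans, and the read is
assigned to the highest-scoring peptide, ties broken by lexicographically
smallest peptide id. Candidate diagonals are discovered through exact
amino-acid k-mer seeds (k = 4): any valid span under the default
thresholds contains an exact run of at least five residues and therefore
at least two overlapping 4-mers on its diagonal, so seeding loses nothing.
Ungapped spans suffice because a 100-nt read covers ≤ 33 residues and the
mapper targets essentially exact coding matches; gapped alignment of reads
is deliberately out of scope.

Two code paths implement identical semantics: a readable pure-Python
`map_read` (the tested reference, also checked against an exhaustive
all-offsets oracle) and a numba batch kernel used by `profile_abundance`,
asserted equal to the reference on mixed random/coding read sets. The
kernel additionally skips candidate diagonals with a single seed whenever
the two-seed guarantee above holds for the active parameters, and falls
back to single-seed scoring otherwise.

Abundance is **coverage per million reads**: the mapped-read count scaled
to one million total sequenced reads. This is a count-based definition (a
read counts once even if it covers a peptide at two offsets); a per-residue
length-normalized variant is available via `length_normalize=True` but is
not the default. Normalization is by total, not mapped, reads.

## The differential funnel

Stages, in order, over a peptides × samples CPM matrix:

1. **presence** — CPM > 0 in at least one sample of either group;
2. **significant** — per-peptide two-tailed Wilcoxon rank-sum
   (control vs case values), Benjamini–Hochberg step-up adjustment
   computed over exactly the present peptides, FDR < 0.05;
3. **fc_pass** — |log₂FC| > 2 with
   log₂FC = log₂((μ_ctrl + c)/(μ_case + c)), pseudocount c = 0.5 CPM;
4. **ctrl_enriched** — log₂FC > 0;
5. **abundant** — mean *control*-group relative abundance (CPM/10⁶)
   > 2·10⁻⁴.

All inequalities are strict and every threshold is configurable
(`FunnelConfig`), including the scale ("relative" vs raw CPM) and group of
the abundance floor, because published descriptions of such funnels often
leave those two conventions implicit. BH over present-only peptides (rather
than the full input pool) mirrors the stage ordering of the cascade.
Samples from multiple cohorts are pooled into a single two-group
comparison; stratified or meta-analytic variants are out of scope.

The Wilcoxon p-value uses the exact null distribution when the smaller
group has ≤ 8 observations and the pooled values are tie-free, otherwise
the normal approximation with tie and continuity corrections (scipy's
`mannwhitneyu` underneath; the exact branch is verified against full
permutation enumeration, and BH against a brute-force step-up, in the test
suite). Identical constant inputs return p = 1 by convention.

## Alignment and identity

Candidate novelty is measured by optimal global alignment with affine gap
penalties (Gotoh's three-state recurrence): BLOSUM62, gap open 10, gap
extend 0.5, a gap of length L costing `open + (L−1)·extend`, end gaps
penalized. Scores are kept in half-unit integer arithmetic (doubled
internally) so the half-integer extend penalty can never produce float
ties; traceback is deterministic with state preference diagonal > up >
left. The score is the tested contract (against exhaustive enumeration of
all alignments for short pairs, and Biopython's `PairwiseAligner` for
longer ones); the alignment string itself is not unique. Identity is
identical columns over the full alignment length, gap columns included.
Identity distributions over within-set or cross-set pairs are summarized
in ten-point bins with configurable exceedance thresholds.

## Physicochemical descriptors

GRAVY is the mean Kyte–Doolittle hydropathy (computed via Biopython's
`ProteinAnalysis`). Net charge is the deterministic count formula
(#K + #R) − (#D + #E) at neutral pH, excluding histidine and termini; this
is a declared proxy, not a pKa titration (a Henderson–Hasselbalch variant
was considered and rejected as needlessly parameter-laden for set-level
contrasts of integer-scale differences). Amino-acid composition always
reports all 20 canonical fractions; length histograms use closed [lo, hi]
integer bins with an explicit overflow bin. Set contrasts use the Welch
(unequal-variance) t-test; sidedness is explicit, and one-sided tests are
taken in the direction of the observed mean difference. Two identical
constant sets are degenerate and report p = 1 with a flag.

## Synthetic cohorts

`simulate_cohort` draws, once per study: a baseline relative abundance per
peptide from LogNormal(ln 3·10⁻⁴, 0.5); a planted subset (default 5% of
peptides) whose abundance is multiplied by 2^(+log₂FC/2) in controls and
2^(−log₂FC/2) in cases (half the planted set control-enriched, half
case-enriched, |log₂FC| = 3); and one reverse-translated coding sequence
per peptide (uniform synonymous codons). Per sample, each peptide's
fraction is additionally multiplied by log-normal jitter (σ = 0.5) so the
rank tests face realistic overdispersion; read counts per peptide are
multinomial; coding reads are random windows of the coding sequence with
at least 24 nt of coding overlap, random strand, uniform-random flanks;
all remaining reads are uniform-random DNA. Per-sample random streams are
derived from the master seed by sample index, making output byte-identical
across runs and independent of generation order.

Parameter rationale: the abundance scale was set so that (i) the total
expected coding fraction stays well below 1 (~0.35 at 1000 peptides),
(ii) typical planted control-enriched peptides sit above the funnel's
2·10⁻⁴ relative-abundance floor, and (iii) per-peptide counts at 10⁵
reads/sample are deep enough (~30–100 mapped reads) for the rank test to
see the planted 8× ratio at n = 30 per group. A 24-nt overlap guarantees
at least seven complete codons in the read's correct frame (eight when the
window is codon-aligned), so nearly all coding reads clear the mapper's
8-residue threshold; the few boundary reads that do not are a <3% loss
well inside the binomial noise the calibration tests allow.

What the simulator does **not** emulate: sequencing errors, GC and strain
bias, real genomic background (background reads are uniform-random, which
makes spurious mapping essentially impossible), paired-end structure, and
compositionality between peptides beyond the shared multinomial. Passing
recovery tests therefore demonstrate correctness of the pipeline's
statistics and bookkeeping under its stated model, not performance on real
stool metagenomes, where background homology and lower signal would
reduce sensitivity.

## Benchmark sizes and determinism

The default benchmark cohort is 1000 peptides, 5% planted at |log₂FC| = 3,
30+30 samples of 10⁵ 100-nt reads — large enough for the funnel's FDR and
floor stages to operate in their intended regimes while a full simulate →
profile → mine cycle completes in about a minute on one CPU. The global-
null calibration uses 500 peptides × (30+30) samples drawn from a single
log-normal. Every stochastic routine takes an explicit seed; nothing reads
global random state.

## Known limitations

- The mapper is ungapped by design; indel-containing coding variants will
  not map.
- CPM normalizes by total reads; compositional effects between samples are
  not corrected (no CLR or similar transform).
- The funnel treats multi-cohort data as one pooled comparison.
- The charge formula ignores histidine protonation and terminal charges.
- `identity_distribution` is quadratic in the number of pairs; it is meant
  for candidate sets of tens to hundreds of peptides, not whole catalogs.
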
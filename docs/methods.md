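# Methods

This note documents the models, statistics and design choices behind
`thioscan`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic benchmarks do and do not demonstrate.

## Detection model

A thiopeptide biosynthetic locus is recognized through three layers of
evidence:

1. **Anchor co-localization.** A gene hitting the YcaO-like cyclase profile
   and a gene hitting the lantibiotic-type dehydratase profile, on one
   contig, with a nearest-edge inter-gene gap ≤ `anchor_window_bp`
   (default 20 000 bp). The literature describes co-localization without
   quantifying it; 20 kb covers known thiopeptide cluster spans and stays
   below the one distance that is documented (the 25-kb precursor flank).
   Candidate pairs are merged greedily, closest pair first, ties to the
   leftmost pair, so each gene anchors at most one candidate.
2. **Precursor peptide.** Genes of ≤119 aa fully contained in
   `[span_start − 25000, span_end + 25000]` qualify as precursor candidates
   when they (a) score ≥ `min_bits` against the Prep profile or (b) contain
   an exact match to the structural-peptide pattern
   `SCTT[CS][GI]CT[CS]S[CS]`. Both evidence sources are recorded per
   candidate. At most `max_prep_copies` (default 4, the maximum number of
   near-identical precursor genes reported in known clusters) are kept,
   best motif p-value first. Clusters with no precursor remain in the
   output with `complete=false`; known genome surveys contain exactly such
   framework-only loci.
3. **Accessory and marker genes.** Hits of the remaining framework families
   (nitroreductase, SpaB_C, NosO-like, NosH-like) and of the genotype
   markers inside the same flank interval are attached; a hit eligible for
   two candidates goes to the nearer anchor.

Genotype assignment is a pure function of the attached family set:
BATS → Type I; Radical_SAM and SnoaL together → Type II; neither → Type
III; both marker sets → `ambiguous` (a case the genotype scheme does not
define; it is surfaced, never silently resolved).

## Gene calling

The built-in caller scans all six frames: an ORF runs from a start codon
(ATG/GTG/TTG) to the first in-frame stop (TAA/TAG/TGA), the longest ORF per
stop is kept (leftmost start on the forward strand, mirrored on the
reverse), proteins shorter than `min_protein_aa` (default 30) are dropped,
the initiator codon always translates as Met, and ORFs truncated by contig
ends are not called. There is no coding-potential, RBS or codon-usage
model: the caller stands in for a full gene finder only to keep the
pipeline self-contained and deterministic, and user annotations can replace
it entirely. Codons containing N translate to X and are never starts or
stops; ambiguity characters other than N are coerced to N on input, so
gapped scaffolds are valid input.

The **rescue pass** re-scans the precursor flank with a 15–119-aa window
whenever no candidate was found among existing calls. This automates the
manual check that short precursor genes (<360 bp) classically need because
standard gene callers skip them; rescued calls are labelled
`source=rescue`.

## Profile HMMs

Profiles follow the match/insert/delete skeleton. From a seed alignment:
columns with gap fraction < 0.5 become match states; match emissions are
Laplace-smoothed counts (κ = 1.0); insert emissions equal the background;
transitions are smoothed path counts through the skeleton. The default
background is uniform (1/20); an empirical composition can be supplied.

Scoring is **local**: a path enters at any match state, traverses M/I/D,
and exits from any match state, with entry and exit carrying no score.
Path score = Σ emission log-odds + Σ transition log-probabilities, in bits.
Viterbi (reported bit score, with the best path's residue envelope) and
forward (sum over paths) are exact dynamic programming in log space —
no banding, no filters inside the kernels, single-hit architecture, no
Dirichlet priors. The free-entry/exit choice makes the score of an
embedded domain independent of flanking sequence length, which the test
suite asserts (appending background residues never lowers the score).

**E-values.** Each profile is calibrated by scoring `n_samples` (default
1000) random background sequences of 100 aa and fitting a Gumbel law by
the method of moments (λ = π/(σ√6), μ = mean − γ/λ). Then
`E(s) = N·(1 − exp(−exp(−λ(s−μ))))` for a search over N proteins. Hits
require `bit_score ≥ 20` and `E ≤ 10⁻³` by default; the source material
states no per-family cutoffs, so both are engineering defaults, exposed in
the configuration and recorded in the run report.

**Word prescreen.** `search_proteome` runs the full alignment only for
gene/profile pairs sharing at least one exact amino-acid 4-mer with the
profile consensus — deterministic BLAST-style seeding. For homologues at
the divergences the profiles are built to detect (≤ 0.2 per residue over
≥ 40 positions), the probability of sharing no 4-mer is ≈ 10⁻⁷; random
pairs collide at ≈ 1 %, and every reported score is still the exact
Viterbi DP value. `prefilter=False` disables the screen (the test suite
checks both paths agree).

## Motif scanning and cleavage sites

The structural-peptide motif is an 11-position degenerate pattern. Its PWM
gives each disallowed residue a 0.01 floor and splits the remaining mass
uniformly over the allowed residues, so log-odds stay finite. Scores are
binned at 0.01 bits; the p-value of a window score is the exact tail
probability of the binned score distribution under the background,
computed by convolution across positions. Scanner and p-value machinery
share the same integer grid, so DP p-values match brute-force window
enumeration up to float summation order. Windows containing X take the
column-minimum score.

The cleavage site is placed at the start of the best-p-value PWM match;
ties go to the rightmost match because known thiopeptide cores are
C-terminal. The core peptide is the match onward; the leader is everything
upstream (a match at offset 0 yields an empty leader and is flagged).
The default reporting threshold is p ≤ 10⁻⁴. Exact pattern matches always
pass it. Precursor *detection* uses the exact pattern (or the Prep
profile), not the p ≤ 10⁻⁴ PWM tail: in a 50-kb flank the PWM tail alone
would attach a few chance background ORFs per scan, while an exact 11-mer
match occurs by chance with probability ≈ 10⁻¹² per window.

## Synthetic data

The generator fixes, per family, a random consensus (40–80 aa; all pairs
< 30 % identical, asserted at generation) and derives 8-row seed
alignments by 10 % per-residue substitution. Planted proteins are sampled
from a profile's consensus at a configurable divergence (default 0.1,
matching the "remote homologue" regime the profiles target),
reverse-translated with uniform synonymous-codon choice (table 11), and
planted with ≥ 50 bp spacing on mixed strands; an in-frame stop codon is
written immediately upstream of each planted start so truth coordinates
are exactly recoverable. The planted precursor is a diverged 40-aa leader
plus an exact motif instance as core (≤ 119 aa total; the leader length is
configurable, e.g. 14 aa to exercise the rescue pass). Backgrounds are
i.i.d. nucleotides at a chosen GC.

What this emulates: cluster architecture, gene co-localization distances,
short-precursor behavior, strandedness, divergence from family consensus.
What it does not: real domain length/composition heterogeneity, codon
usage, repeats, mobile elements, draft-assembly fragmentation, or true
Pfam-scale family breadth. Passing the synthetic benchmarks therefore
demonstrates the pipeline's mechanics (detection logic, windows, scoring
exactness, determinism), not sensitivity/specificity on real genomes; for
real use, supply real seed alignments via `--profiles`.

## Problem sizes and numerical choices

The benchmark suite uses 1-Mb backgrounds (≈ 11 000 called ORFs each):
planted-cassette recovery over 100 seeded genomes cycling genotypes
I/II/III, and 20 null genomes for specificity; the acceptance script
re-measures the same quantities at 30 and 10 genomes respectively, sizes
chosen so a complete reproduction stays in the minutes range on one core.
Scoring kernels work in float64 natural-log space (−10³⁰ as the impossible
score); zero-probability emissions or transitions are admitted and treated
as impossible rather than raising. Oracle agreement between the DP kernels
and exhaustive path enumeration is asserted to 10⁻⁹ in log space on small
profiles. Determinism: every random draw flows from an explicit seed
(per-family calibration seeds are derived from the run seed), and repeated
runs produce byte-identical reports apart from the timestamp field.

## Known limitations

- The genotype scheme covers the documented marker families only; novel
  side-ring chemistries would fall into Type III.
- Single-hit local alignment: a protein carrying two copies of a domain is
  scored by the better copy.
- Gumbel calibration at one sample length (100 aa) slightly mis-estimates
  E-values for much longer proteins; the bit-score floor bounds the effect.
- Clusters never span contigs; draft genomes are processed per record.
- The bundled profile library is synthetic and is not a substitute for
  real seed alignments when scanning biological sequences.
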
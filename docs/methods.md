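# Methods

This note documents the models, algorithms and design choices behind
`preribo`, in the spirit of a methods supplement: what each pipeline
assumes, which knobs matter, and what the synthetic data do and do not
show about real libraries.

## Reference model

One 45S rDNA unit is modeled as an ordered, non-overlapping set of
subregions (NTS, 5′ETS, 18S, ITS1, 5.8S, ITS2, 25S, 3′ETS) plus named
processing sites. Validation pins `P2` to the 18S start and `D` to the
last templated base of 18S, requires `D < A2 < A3` inside ITS1, and
places the A1 hotspot window — a configurable pair of offsets from D,
default 8..13 — strictly between D and A2. A1 is a window rather than a
point because the upstream intermediates form a cluster of 3′ ends rather
than one discrete site. Internally all coordinates are 0-based half-open;
every report file is 1-based inclusive. The reference sequence itself is
user-supplied (any single-record FASTA plus a YAML annotation); the test
suite and simulators generate their own.

## Junction resolution (END-seq)

A circularized read is modeled as `[3′ arm][tail][5′ arm]` in sense
orientation. The caller:

1. anchors the 5′ arm with an exact k-mer (default k = 20) from the read
   end and extends it leftwards;
2. anchors the 3′ arm with an exact k-mer from the read start and extends
   it rightwards, capped at the junction, requiring the templated 3′ end
   to fall in `[D − 200, A3]`;
3. assigns the remaining middle bases to the nontemplated tail.

Extension tolerates up to m = 2 substitutions per arm via *bridging*: a
mismatch is accepted only when the next 4 bases match again. This is
equivalent to scoring splits by `templated_length − 4 × mismatches`, so a
mismatch can bridge an isolated sequencing error inside an arm but can
essentially never pay for nibbling into a random tail; on error-free
reads the caller reduces exactly to maximal exact extension. If the
terminal seed itself carries an error, the adjacent k-mer is used as a
fallback anchor and the terminal bases are verified with the remaining
mismatch budget.

Templated-vs-tail ambiguity follows **maximal templated extension**: a
read base equal to the next reference base is always counted as
templated. The same is true on the 5′ side — a tail base equal to the
base 5′ of the arm start is absorbed into the arm (that split has more
templated sequence and a shorter tail).

**Rotation ties.** Circularity creates a genuine ambiguity: when the tail
is empty and a junction-flanking base matches the reference on both arms,
two (or more) rotated splits have identical score. A greedy
longest-suffix rule would then shift the called 5′ end off P2 in a
sequence-dependent, all-or-nothing way (e.g. for every mature read
whenever `ref[D] == ref[P2−1]`), and the P2 filter would silently discard
them. Because the library design anchors molecules at P2 (reverse
transcription primes inside 18S and only P2-starting molecules are
analyzed), rotation ties are resolved in favour of the P2-anchored split
(`JunctionParams.anchor_to_p2`, default on, implemented by letting the
P2-trimmed 5′ arm compete in the joint scoring); among non-P2 candidates
the longest 5′ arm wins deterministically. Score ties between genuinely
distinct anchor positions are reported AMBIGUOUS, never guessed.

Other decisions: the P2 filter is exact by default (`tolerance = 0`),
configurable; reads with 3′ ends upstream of D are retained and labeled
`UPSTREAM_OF_D` (degradation products) but never enter the
precursor:mature ratio; read 1 of a pair is processed (the junction must
lie within it); per-read outcomes are encoded in a status enum whose
counts always sum to the number of input reads.

## Quantification and statistics

All precursor abundances are normalized against mature 18S, defined as
**tail-free** reads ending exactly at D. D-ending reads with nontemplated
tails appear in the tail tables but not in the denominator — "mature"
means the finished product. This is a deliberate reading of an
underspecified convention and is visible in the profile flags; with the
default simulator (5% of mature molecules tailed) it inflates the
measured ratio by the factor 1/0.95 relative to the planted value, which
the acceptance machinery accounts for.

The precursor:mature ratio sums offsets in `(0, A2 − D]`. The tailed
fraction counts reads of selected species (default 18S-A1 ∪ 18S-A2) with
tail length ≥ 1 over the mature denominator. Tail composition is the
per-nucleotide A/U/G/C fraction over all tail bases of the selected
species.

Two-group comparisons default to the Mann–Whitney U test; for small
samples (total n ≤ 14) the p value comes from the exact permutation null
(deterministic and tie-safe), otherwise from scipy's exact/asymptotic
choice. Welch and Student t tests are available, and the method used is
recorded in every output row. Per-position tests are reported unadjusted;
a Benjamini–Hochberg helper is provided but off by default.

The stalling summary uses a one-sample, one-sided t test of log2 fold
change against 0 (alternative: greater), with a two-sample option. A
fold-change table whose log2 values are all identical has no variance;
the test is then reported NA with a `degenerate_variance` flag.

## Small-RNA quantification

Reads of 18–40 nt are mapped ungapped, end-to-end, against the sense
strand and reverse complement of the single rDNA unit; the default allows
0 mismatches (configurable), matching common practice for short reads on
a single reference. A read matching several positions equally well gets
fractional weight 1/n at each — deterministic, unlike random placement —
and weights always sum to 1 per mapped read. Region assignment requires
≥ 50% of the read length inside a subregion; any read overlapping both
18S and ITS1 is the `18S-ITS1` linker class. 21- and 22-nt reads are
first-class size classes (the RDR/DCL-product sizes); everything else is
`other`. RPM uses the number of reads passing the length filter as the
denominator by default (a genome-mapped total can be supplied); fold
changes are pseudocounted, `(RPM_mut + 1)/(RPM_wt + 1)`, with log2 also
emitted. Note that RPM fold changes depend on the composition of the
whole library through the denominator; the acceptance simulations
therefore plant contrasts with equal library totals, where the RPM ratio
equals the count ratio.

## Ribosome profiling

Footprints live in transcript coordinates (transcriptome SAM/BAM or a
TSV of 5′ ends). Per footprint length, the P-site offset is the candidate
in 10..15 that maximizes the count landing exactly on annotated start
codons; ties break toward the canonical 12, and classes with fewer than
100 footprints fall back to 12 with a flag. Translated-ORF discovery is
out of scope: annotated CDSs are taken as the ORFs, which replaces
periodicity-based ORF calling with the annotation.

The metagene profile normalizes each transcript's 41-nt window by its own
total before averaging, so highly expressed genes do not dominate. Frame
fractions are computed over CDS P sites by `(pos − start) mod 3`; feature
fractions over 5′UTR/CDS/3′UTR.

The ATG stalling index counts the three nucleotides of the start codon
by default (a single-nucleotide mode exists) over all ORF P-site counts;
genes with fewer than `min_counts = 10` ORF P sites are undefined. For
fold changes, replicate indexes are averaged per genotype first; genes
undefined in either genotype or with a wild-type index of 0 are excluded
and counted (no pseudocount by default, to avoid manufacturing infinite
or arbitrary ratios).

**Depth matters for the median fold change.** With ORFs of 100–400
codons, the expected wild-type start-codon count is `depth/codons` per
gene; at shallow depth most genes have zero and the zero-exclusion
biases the median of per-gene ratios far below truth. The simulator's
default of 1,000 P sites per quantified gene (realistic for
well-expressed genes in a deeply sequenced plant ribo-seq library) puts
the estimator in its unbiased regime; the package intentionally reports
the low-count flags rather than hiding the issue.

## Synthetic data

The simulators generate the study conditions, seeded end-to-end: one
top-level seed feeds named substreams, so adding a generator never
perturbs existing outputs, and every dataset ships a truth table
sufficient to score the downstream pipeline without re-deriving ground
truth.

- **Reference**: random sequence with realistic region lengths (18S
  1.8 kb, ITS1 0.3 kb, 25S 3.4 kb, ~7.7 kb total), A2 at D+90, A3 at
  D+250. The bases that can immediately follow a simulated 3′ end
  (D+1..A2+1) and the base before P2 are drawn from {C, G} only, so the
  A/U-dominated tails of the default tail model are always identifiable
  as nontemplated. Plant ITS1 is genuinely GC-rich, but this hard
  constraint is an idealization: it removes the junction-identifiability
  noise from recovery experiments by construction.
- **END-seq reads**: 150-nt single-end; 3′ end sampled from a
  configurable offset distribution (default: precursor mass split half
  over the A1 window, half at A2, with a planted precursor:mature
  ratio); tails on 30% of precursors and 5% of mature molecules, lengths
  1–4 (geometric-like), composition A:U = 9:1; junction placed uniformly
  with both arms ≥ 20 nt; substitution errors at 0.1% (no indels — the
  substitution-only model keeps the exhaustive junction oracle exact).
  For tail models that can emit template-matching junction bases (e.g.
  uniform ACGT tails), the truth table is canonicalized by maximal
  templated extension: it records the anatomy of the read, which is the
  only quantity any caller can recover.
- **Small RNA**: reads sampled per (region, strand, length) cell,
  uniformly positioned inside the region (linker-class reads straddle
  the 18S/ITS1 boundary), reverse-complemented for the − strand.
- **Footprints**: per gene, P-site intensity uniform over ORF codons
  except the start codon, multiplied by a per-gene stall amplification
  (lognormal across genes, median configurable, ≥ 1); 90% of P sites in
  frame 0, the rest moved within their codon so the realized per-gene
  index stays exact in the truth table; footprint lengths peak at 28 nt
  (26–30), 5′ ends placed at P site minus the per-length offset.

What the simulations do **not** model: PCR duplicates, ligation and GC
bias, indels, quality-score structure, multi-copy rDNA variation, UTR
ribosome occupancy structure, and template switching during RT. Passing
recovery tests therefore demonstrates correctness of the computational
pipeline under its stated error model, not robustness to every artifact
of real libraries.

## Problem sizes and numerical conventions

Recovery experiments use 50,000-read END-seq libraries (20 seeds),
200,000-read sRNA libraries (10 seeds), and 2,000-gene footprint
experiments — sizes at which the binomial/Poisson recovery bounds are
tight but a full run stays fast on a single CPU. Oracle-equivalence
checks run 1,000 reads against a < 2 kb reference where exhaustive
enumeration is affordable. Ties anywhere (offset estimation, split
scoring, mode reporting) break deterministically and are documented at
the site; empty inputs yield empty-but-valid outputs with flags rather
than exceptions; division by a zero mature count yields NA plus a flag,
never silent zeros.

## Known limitations

- Rotation-tie resolution assumes P2-anchored library chemistry; for a
  hypothetical library without a fixed 5′ end, disable `anchor_to_p2`
  and accept the longest-suffix convention.
- Tails whose terminal base happens to match the reference continuation
  are irreducibly shortened by one base (an identifiability limit of
  circularized-read chemistry, not of this implementation).
- The sRNA mapper targets one small reference; it is not a general-purpose
  aligner and does not model indels.
- The ATG stalling median requires adequate per-gene depth (see above);
  at shallow depth, results carry low-count exclusions that bias a
  median-of-ratios summary and should be interpreted via the reported
  flags.
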
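# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Coordinates, alphabets, alignment contract

All coordinates are 0-based half-open; 1-based numbers appear only in
report headers that say so. Sequences are uppercase over {A,C,G,T,N};
lowercase and RNA U are normalized on input, any other IUPAC code is
rejected rather than converted, because exact k-mer matching must be
unambiguous about what counts as a match. Aligned FASTA with `-` as the
only gap character is the single accepted MSA dialect.

One pairwise-alignment configuration is shared by every stage so that
identities and coordinates are comparable: nucleotide match +1, mismatch
-1, gap open -5, gap extend -1 (global, or semiglobal with free end gaps
when anchoring a reference feature inside a larger window); protein local
alignment uses BLOSUM62 with gap open -11 / extend -1. After alignment,
indel runs are slid leftward through repeated bases (homopolymer
left-alignment), which fixes a canonical event coordinate regardless of
aligner tie-breaking; terminal gap runs are left in place since they encode
end raggedness, not events.

## Silencing potential

The cluster is decomposed into all substrings of length k (default k = 25,
matching the piRNA footprint; step 1; set semantics — the coverage
definition is binary, so k-mer multiplicity is irrelevant). A consensus
position is covered when at least one window containing it matches the
index; for the antisense orientation the window is reverse-complemented
before lookup. Dual-strand piRNA clusters are transcribed from both
strands, so their index includes the reverse complement of the cluster
sequence (`both_strands`); uni-strand clusters are indexed in transcribed
orientation only. k-mers containing N are dropped. A consensus shorter
than k has an all-false coverage track.

The optional mismatch tolerance is **Hamming** distance per window
(substitutions only, stated in output headers), with `max_mm = 0` exactly
reproducing the exact-match path. Because the default k is odd, no window
can equal its own reverse complement, so a sense-embedded copy of a random
consensus contributes essentially nothing to antisense coverage; chance
25-mer collisions in random sequence are negligible (4^-25 per pair).

## LTR dating

Model: both LTRs are copies of one template at integration and subsequently
accumulate substitutions independently at rate r, so the expected pairwise
divergence after time T is 2rT. The estimator inverts this: extract both
LTR copies (anchoring the reference LTR by semiglobal alignment inside the
first and last 1.5x-LTR-length windows; identity below 60% on either side
raises a solo/truncated error), align them globally, exclude gapped columns
(indel rates are not part of the clock), and compute p = mismatches /
ungapped columns. K is the Jukes-Cantor correction
K = -(3/4) ln(1 - (4/3) p) by default (the convention of the dating
literature this formula comes from); the raw p-distance is available as
`model="p"`. p >= 0.75 is outside the JC69 domain and raises. The default
rate r = 0.0346 substitutions/site/Myr is the Drosophila neutral rate with
ten generations per year already folded in; T = K/(2r) is reported in years
and TYA. Exact K is always reported — no mismatch count is rounded to
"no divergence".

**Resolution limit at young ages.** With 400-nt LTRs the expected number of
pairwise differences is 2rTL ~ 1.4 at T = 50 kyr and 4.2 at T = 150 kyr,
so the estimate is quantized in steps of 1/(2rL) ~ 36 kyr. The estimator is
unbiased (the mean over replicates recovers T within sampling error at all
ages tested), but the *median* relative error of single-insertion estimates
is dominated by this discreteness below a few hundred kyr: no integer
difference count lies within 25% of 50 kyr, so the median error there is
~45% regardless of implementation, falling to ~27% at 150 kyr and ~19% at
500 kyr (measured over 200 replicates per age by the acceptance script).
Individual young-insertion ages should be read as "0-70 kyr", not as point
values.

## ORF integrity

Each annotated reference ORF (gag, pol, env-F) is anchored by semiglobal
alignment inside the corresponding window of the insertion (window =
annotated interval padded by 200 nt; this assumes insertions are
near-full-length copies in element orientation — grossly rearranged
insertions should be handled upstream). Events against the reference ORF:

* indels, reported at their left-aligned reference position; length not a
  multiple of 3 marks a frameshift;
* substitutions that convert the query codon — read in the frame induced by
  upstream indels, i.e. straight translation of the query region — into a
  stop, reported with the substitution's reference position and the 1-based
  codon index of the stop. A mismatch inside a stop codon counts only if
  reverting that single base would remove the stop, so stops caused purely
  by an upstream frameshift are not double-reported as substitutions.

Status per ORF: frameshift > premature_stop > truncated/intact; "intact"
requires no such event and a translated product of at least 90% of the
reference length (the source analyses never define "intact" numerically;
90% tolerates terminal raggedness while rejecting real truncations, and is
a package constant). Terminal indels at the very ends of the aligned region
are treated as raggedness, not events. Overall class: all three ORFs intact
= retrovirus_active; gag and pol intact with env-F defective =
retroelement_active; otherwise inactive. Aligned identity below 50% on
every ORF raises an unrelated-element error; only ORFs are scanned on the
'+' strand since insertions are extracted in element orientation.

env-F remnants in a pol-to-3'LTR interval are found by locally aligning all
three forward-frame translations against the reference Env protein and
recursing on the flanking DNA after each accepted hit (score >= 60 by
default). Recursing at the DNA level — rather than harvesting hits per
frame independently — keeps hits non-overlapping on the query and prevents
a hit in one frame from extending through sequence claimed by a better hit
in another frame; this matters because different-frame readings of the same
DNA are correlated through the genetic code.

## Variant typing and recombination

`type_ltr` returns the library variant with the highest global-alignment
identity (gap columns count as differences; ties broken by smaller length
difference, then name); below 80% identity the query is "untyped".
A provirus whose 5' and 3' LTRs type as different variants is flagged as a
cross-variant recombinant; an untyped side makes the call indeterminate
rather than a mismatch.

Diagnostic sites are alignment columns where both A-parents share one
symbol, both B-parents share a different one; a shared `-` is a valid
allele (indel variants), and consecutive columns of one indel event are
collapsed to the event's first column so one biological variant is one
site. A degenerate parent pair (the same row twice) is allowed and flagged,
for variants with only one good complete copy. Query painting calls each
site A, B, or nonref; parental runs with at least `min_sites_per_segment`
sites (default 2 — one isolated convergent site does not create a segment;
the full per-site call track is still reported) form segments, and each
template switch is reported as the open column interval between flanking
sites of adjacent segments. Breakpoints are intervals, never point
estimates: resolution is bounded by the informative sites.

## Synthetic data

The generator emulates exactly the structures the analyses invert:

* elements LTR5+UTR5+gag+pol+envF+UTR3+LTR3 with byte-identical terminal
  repeats and stop-free ORFs; defaults 400/300/900/1500/900/150/400 nt
  (a ~4.5 kb element — mid-sized for this element family, chosen so whole
  panels of alignments remain cheap); uniform base composition by default,
  which minimizes chance k-mer hits in fixtures;
* insertions aged by placing Poisson(r·T·L) substitutions independently and
  uniformly on each LTR and on the internal sequence, JC-symmetric target
  base, **no indel evolution** (indels enter only via injected events and
  recombination), keeping truth exact;
* clusters as random spacers interleaved with oriented consensus fragments;
  the truth table alone predicts the expected coverage of each consensus up
  to junction effects confined to k-1 positions per fragment edge;
* recombinants as coordinate-based template switches, with homologous
  coordinates mapped 1:1 for equal-length parents and through the shared
  aligner otherwise; derived variants carry identical LTRs at both ends
  (substitutions landing in the 5' LTR are mirrored into the 3' LTR), as a
  real variant genome does;
* injected inactivations: single-base insertion/deletion (shifted off
  homopolymers by default, so the left-aligned call coordinate is
  unambiguous; the shift is recorded in the truth) or a single substitution
  converting the nearest convertible codon into a stop.

Same parameters and seed give byte-identical FASTA and truth tables. What
the generator does **not** emulate — and what passing tests therefore do
not demonstrate about real data: rate heterogeneity and biased substitution
spectra, indel evolution in the clock, nested/fragmented insertions, solo
LTRs inside clusters, gene conversion between LTRs (which rejuvenates real
pairwise-LTR ages), and alignment ambiguity in low-complexity regions.

## Pipeline

Stages (simulate, annotate, date, silencing, recombination) communicate
only through FASTA/TSV/BED files; every tabular writer emits a `#` header
with the tool version and the parameters that affect its numbers (FASTA
outputs carry no comment line, since `#` inside FASTA breaks standard
parsers). Each stage records a config hash and output checksums; re-running
a completed stage with unchanged config is a verified no-op. All randomness
derives from the single run seed, with per-stage streams obtained by
hashing the stage name into the seed (CRC32 XOR, reduced below 2^31).
Unknown configuration keys are rejected before any stage runs.

## Acceptance script

`scripts/acceptance.py --seed N --out results.json` regenerates every panel
from the given seed at the study conditions (200 random fixtures for the
coverage oracle; 200 dating replicates per true age in {50, 150, 500} kyr
with 400-nt LTRs and r = 0.0346; 100 recombination panels with >= 10
diagnostic sites per parental segment, alternating single and double
switches; 100 injected ORF events across 5 elements) and writes each
measured quantity with the panel size used. Everything it reports is
computed at run time by the package; nothing is looked up.
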
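# Methods

This note documents the models, defaults and design choices behind
`tispred`, in the spirit of a statistical-software methods appendix. It
states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Candidate windows and coordinates

A candidate is any ATG triplet read 5′→3′ on either strand. Its window is
a fixed-length stretch (default 300 nt) with the A of the codon at a
fixed 1-based offset (default 150, so the codon occupies 150–152 and the
window carries 149 nt of upstream and 148 nt of downstream context).
External coordinates are always 1-based inclusive on the forward strand
(GFF3 convention); a minus-strand candidate is reported at the forward
position of the base pairing with its A. Signed positions relative to the
codon follow the Kozak convention: the A is +1 (there is no 0), −3 is
three bases 5′ of it, +4 the first base 3′ of the G.

Candidates without a full flank on both sides are skipped rather than
padded — a fixed-geometry classifier should not silently score truncated
context. An opt-in flag N-pads windows for scanning short contigs.
Windows may contain N: N contributes zero to counts, is excluded from
G+C numerator and denominator, and contributes 0 to PWM log-odds, so
assembly gaps degrade scores gracefully instead of dropping candidates.

## Dataset construction

Positives: one window per annotated protein-coding translation start,
taken from CDS extremities when CDS children are present, else from the
gene record bounds. Starts with non-ATG codons are dropped with a warning
(non-canonical ACG/CTG initiation is out of scope), and exact duplicate
window sequences are collapsed to prevent train/test leakage through
repeated loci.

Negatives: ATG-centred windows, by default from the forward strand,
excluding annotated start coordinates and any window whose full sequence
occurs among the positives — and nothing stronger (genic ATGs are
legitimate decoys). Per-sequence quotas are proportional to sequence
length, apportioned by the largest-remainder method (ties broken toward
earlier sequences); within a sequence, sampling is uniform without
replacement from a seeded generator.

Splitting: per class, `floor(0.65·N)` windows train and the remainder
test. The training share is subdivided into a feature-estimation part
(default 5,000 per class), a validation part (default 2,920 per class)
and the network-training remainder. All partitions are class-balanced and
disjoint by window origin; the pipeline *asserts* that the
feature-estimation windows never reappear elsewhere rather than trusting
the caller.

## Feature model

Every feature is one descriptor (family + parameters) producing one real
value, so a catalogue is an ordered, serialisable list and a selection is
a subset of columns. The default catalogue is:

* **Fixed subset** (never removable by selection): PWM log-odds over
  [−10, +5]; base indicators at −3 and +4 (all four bases each);
  downstream in-frame ORF length (codons to the first TAA/TAG/TGA after
  the candidate, capped at the 49 complete codons the default geometry
  holds) and a has-stop indicator. These are the consensus signals of
  start-codon recognition and anchor every wrapper evaluation.
* **Selectable** (28 by default): upstream/downstream G+C, upstream ATG
  count, upstream in-frame stop count, mononucleotide frequencies on both
  flanks, and the 16 downstream dinucleotide frequencies.

PWM columns are estimated from positive windows only, with a pseudocount
of 0.25 per base per column (standard additive smoothing; keeps log-odds
finite at any sample size). The invariant +1..+3 positions are excluded —
they carry no information. Background composition is estimated from the
pooled feature-estimation windows with add-one smoothing. All features
are z-scaled with constants from the feature-estimation partition;
constant features get scale 1 so they stay centred instead of dividing by
zero. k-mer frequencies divide counts by the number of counted start
positions; frame-restricted variants count only positions congruent to
the frame mod 3 from the region start (the default downstream region
starts at +4, a codon boundary).

## Wrapper selection

Chromosomes are bit-vectors over the selectable descriptors; decoding
always adds the fixed subset (asserted inside the fitness function).
Fitness is mean accuracy over stratified 3-fold cross-validation of the
network trained on the decoded columns. The paper-style operators are
single-point crossover and independent 15 % per-bit mutation; the
remaining machinery is unavoidable implementation choice, defaulted as:
population 50, 30 generations, tournament selection of size 3, elitism 1,
Bernoulli(0.5) initialisation, fixed generation count (no convergence
heuristic — reproducibility first). Every knob is exposed in `GAConfig`.

Wrapper evaluations use a reduced training budget (60 epochs, no
validation set) with a raised full-batch learning rate of 0.5 to reach a
usable optimum inside that budget; the evaluation seed derives from the
GA seed XOR a CRC of the chromosome bits, making fitness a pure,
cacheable function of the chromosome. Fitness is plain accuracy: on
class-balanced folds it coincides with balanced accuracy.

## Network

One hidden layer of 31 logistic units, logistic output, cross-entropy
loss (the standard pairing that makes the output a probability and the
output-layer gradient linear in the residual). Weights initialise
uniformly in ±1/√fan-in; biases at zero. Optimisation is full-batch
gradient descent at learning rate 0.01 for up to 500 epochs — determinism
first; mini-batches are available and reshuffle per epoch from the seed.
Early stopping monitors validation cross-entropy with patience 20 and
restores the best-validation weights (not the last). A non-finite
training loss raises an error naming the epoch and learning rate instead
of returning garbage. The decision threshold defaults to 0.5 — symmetric,
appropriate for the balanced training design, and configurable at
scan/evaluation time.

The model artifact is one JSON document (versioned schema) bundling
weights, the selected descriptors, PWM/background/normalisation
constants, window geometry, threshold and training metadata, so a scan
needs nothing but the artifact and a FASTA.

## Synthetic genomes

The generator emulates exactly the structure the classifier exploits and
nothing more: i.i.d. background nucleotides (default uniform), planted
ATGs whose context positions in [−10, +5] each show a fixed consensus
base with probability β (`consensus_strength`), and downstream in-frame
codons drawn from a stop-free, compositionally biased pool with
probability given by `codon_bias_strength`, else from the background.
Annotation is emitted as GFF3 (`gene` + `CDS`, `biotype=protein_coding`)
with a ground-truth table. β = 0 *and* codon bias = 0 is the defined
no-signal condition; with either knob positive there is planted signal.

Deliberately absent: introns, UTRs, isoforms, dinucleotide/hexamer
background structure, GC heterogeneity, and any fitted plant-genome
model. Passing recovery tests therefore demonstrates that the pipeline
extracts a planted context signal from realistic-size windows — not that
it attains any particular accuracy on real genomes, where background
structure is richer and decoys are harder.

## Problem sizes in the test suite

The end-to-end recovery experiments train on synthetic genomes of
5 × 60 kb with 400 planted genes and 400 sampled decoys (feature
estimation 100/class, validation 60/class, network training 100/class,
test 140/class), with the selector at population 20 for 10 generations —
a deliberate desk-scale design that keeps the full pipeline exercisable
in seconds while leaving every mechanism identical to a full-scale run.
At 140 test windows per class, the chance band for Se+Sp−1 used by the
no-signal check (±0.2) is ≈3 binomial standard deviations.

## Known limitations

* Gene-record fallback uses annotation bounds as the translation start
  when no CDS children exist; for real annotations with UTRs, CDS
  features are required for correct starts.
* The feature catalogue is configurable rather than canonical: the
  default families cover the classic TIS signals, but the selected subset
  is an *output* of the wrapper, not a fixed published list.
* No momentum or adaptive optimisers; very large feature sets may train
  slowly at the default rate.
* Scores are probabilities under balanced training; on a genome scan the
  class prior is far from balanced, so the threshold governs an Se/Sp
  trade-off rather than a calibrated posterior.
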
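# Methods

This note documents the models, parameter choices, and known limitations of
`sagbin`. Nothing here is an empirical claim beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Feature space

Sequences are represented by the frequencies of their 64 overlapping
trinucleotides (sliding window, step 1, lexicographic order AAA…TTT). Windows
containing an ambiguous base are skipped and excluded from the normalizing
denominator; a sequence with no valid window is an explicit *no-signal* case
and is reported unclassifiable rather than fed to the model as a zero vector.

Counting is **strand-symmetric by default for both training segments and
reads**: the counts of a sequence and of its reverse complement are summed
before normalizing. Read orientation relative to the genome is unknown, so
classification must be strand-invariant, and train and test must live in the
same space — mixing a symmetrized test convention with an unsymmetrized
training convention would be an error, which is why the trained model records
its feature convention and refuses vectors produced under a different one.
The 64-dimensional layout is kept (rather than collapsing to 32 canonical
trimers); the collapse is an invertible linear projection and buys nothing.

Training examples are **non-overlapping 2,000-bp tiles** clipped from anchor
contigs starting at position 0, terminal remainders discarded. Overlapping
tiles would pseudo-replicate the training data.

## Classifier

A single-hidden-layer perceptron: 64 inputs, ⌊(64 + C)/2⌋ logistic hidden
units for C classes, softmax output, mean cross-entropy loss, full-batch
gradient descent with learning rate 0.3 and momentum 0.2 for 500 epochs,
weights initialized uniformly on [−0.5, 0.5] from a seeded generator. Inputs
are z-scored per feature with training-set statistics stored in the model.
These are the defaults of the classic desktop machine-learning tool this
stage reconstructs, and all are exposed as hyperparameters. One deliberate
deviation: that tool updates weights after every instance, while this
implementation uses full-batch updates. Both were measured during
development; per-instance updates drive the softmax into far harder
saturation (many more over-confident outputs on out-of-distribution reads)
and are an order of magnitude slower in vectorized form, so the better-
calibrated full-batch scheme is the package's choice.

Assignment is **strictly** greater-than the confidence threshold (default
0.9); argmax ties break to the lowest class index. Threshold calibration
requires a labeled holdout containing decoys (examples whose true population
is not among the model's classes): TPR(t) is the fraction of non-decoy
examples assigned to their true class, FPR(t) the fraction of decoys assigned
to any class, and the chosen threshold maximizes Youden's J = TPR − FPR with
ties resolved toward the higher (more conservative) threshold. Without
decoys the FPR is unmeasurable and calibration refuses to run. Whether the
original procedure used one multi-class model or several one-vs-rest models
is not recorded anywhere; a single multi-class softmax is implemented here.

## Homology recruitment

Anchor genes (or rRNA marker sequences) are searched against the read set by
exact k-mer seeding (k = 11) and ungapped bidirectional X-drop extension
(X = 20), on both strands, with overlapping extensions on a diagonal merged.
Scoring is +1/−1; significance uses exact ungapped Karlin–Altschul theory:

    E = K · m · n · e^(−λS)

with m the query length, n the total read-set length, K = 0.1 a fixed
configured constant, and λ the unique positive root of
Σᵢⱼ pᵢpⱼ e^(λ sᵢⱼ) = 1, found by bracketed root-finding to 10⁻¹² and verified
to 10⁻⁹ at construction (for +1/−1 on a uniform background the equation is a
quadratic in e^λ with root λ = ln 3). A read is recruited when its best hit
reaches E ≤ 10⁻¹⁵, and labeled by the anchor with the globally best bit score
(ties to the lowest anchor id).

Gapped alignment is deliberately omitted: gapped statistics require
simulation-fitted parameters, whereas ungapped statistics are exact and
desk-computable, and any biologically meaningful match (a 200-bp exact
substring scores E ≈ 10⁻⁸⁶ against a 10-Mb database) sits so far below the
cutoff that recruitment decisions are insensitive to the simplification. An
external aligner can be substituted wholesale through the 12-column tabular
hit interface. Marker ("rRNA") recovery is the same contract with marker
sequences as anchors, reported separately, because rRNA is precisely the
region that word-frequency classification misses.

## Merging and reporting

Reads claimed by both routes with the same label get provenance `both`; label
conflicts resolve in favor of homology (explicit gene identity beats
correlative composition) and the conflict count is a reported quality metric.
"Redundant sequences" is read minimally as exact or reverse-complement-exact
duplicates, collapsed to the lexicographically smallest id; near-duplicate
containment is out of scope. The pipeline's terminal artifact is the labeled
read set per bin — assembly belongs to external tools — and every run report
embeds the fully resolved configuration and seed and carries no timestamps,
so reruns are byte-identical.

Assembly statistics for user-supplied contig sets: N50 is the smallest length
ℓ such that contigs of length ≥ ℓ sum to at least half the assembly; L50 is
the number of contigs in that cumulative set; G+C is computed over
unambiguous bases only. Both N50 and L50 are always emitted because published
tables sometimes label one as the other.

## Genome comparison

ANI follows the classical fragment scheme: consecutive 1,000-bp fragments of
each genome aligned to the other (same ungapped core), best hit per fragment
kept when it reaches ≥ 70 % identity over ≥ 70 % of the fragment, one-way ANI
the mean identity of kept fragments, reported ANI the mean of the two
directions. Fewer than 50 passing fragments (combined) yields status
`below reliable range` instead of a number — the operational form of "too low
to accurately calculate". Exact parity with any particular web calculator is
not claimed; correctness is established against simulation oracles
(self-comparison = 100, 5 % mutant ≈ 95, unrelated genomes unreliable).

AAI: all-vs-all ungapped protein alignment (BLOSUM62 from biopython, 3-mer
seeds, Robinson–Robinson background for λ), reciprocal best hits by mutual
top bit score passing ≥ 30 % identity over ≥ 70 % of the query, AAI = mean of
the two directions' identities over RBH pairs (symmetric by construction).
The shared-gene fraction counts nucleotide genes with an RBH partner at
E ≤ 10⁻⁵ — the method behind the published shared-CDS counts is unstated, so
RBH at that cutoff is this package's documented choice. CDS translation uses
the bacterial/archaeal code (table 11), rejects internal stops naming the
codon, and drops the terminal stop.

## Synthetic communities

Population genomes are realized from order-2 Markov chains (16 conditioning
dinucleotides × 4 next-base probabilities). These chains control exactly the
statistic the classifier uses: the expected trimer profile is
p(abc) = π(ab)·P(c|ab) with π the stationary dinucleotide distribution, so
community difficulty is tunable. `design_populations` builds K matrices as a
shared Dirichlet-drawn base perturbed by independent Gaussian log-scale
directions, with the common scale found by bisection so the **minimum**
pairwise Jensen–Shannon divergence between stationary trimer profiles meets
the target; unreachable targets trigger a deterministic redraw of directions.

The default benchmark (`benchmark_community`) fixes the study conditions:
five populations, 1 Mb genomes (the size range of the real anchor genomes
this emulates), one decoy population contributing reads but no training
material, SAG-like anchors at 60 % completeness in 8 contigs (the real
anchors ranged from 40–78 % complete), 20,000 reads with skewed abundances
(0.30/0.25/0.20/0.15/0.10), truncated-normal lengths (mean 400, sd 100,
min 50 — pyrosequencing-like), 1 % i.i.d. substitution errors, and a minimum
pairwise profile JSD of 0.05 bits.

What the simulator does **not** model: homopolymer/indel errors (the dominant
error mode of the emulated platform), amplification bias and MDA chimeras,
paired ends, repeats and mobile elements, intra-population variation, and
conserved genes shared across populations. Passing tests therefore
demonstrate the statistical machinery under controlled compositional
structure, not performance on real sediment metagenomes, where inter-genome
homology and error structure make both classification and recruitment
harder.

## Calibration behavior at the default separation

At the default benchmark's 0.05-bit minimum separation, a 400-bp read's own
trimer-profile sampling noise is of the same order (≈ 63/(2·ln 2·n_windows)
≈ 0.06 bits), so decoy reads overlap the nearest trained class's read cloud.
The consequence, computed by the acceptance script: macro precision at the
fixed 0.9 threshold is high (≈ 0.99) while the decoy false-positive rate
stays in the several-percent range (≈ 0.065 at seed 1) — an uncalibrated
softmax is overconfident on out-of-distribution inputs. This is inherent to
fixed-threshold confidence filtering and is the reason the calibration stage
exists: on separable holdouts it finds thresholds with measured FPR 0 at
TPR 1. Users targeting a specific decoy FPR should calibrate on a decoy
holdout rather than adopt 0.9 unseen.

## Numerical and degenerate-case conventions

- Internal coordinates are 0-based half-open; conversion to 1-based inclusive
  happens only when writing/reading 12-column hit tables (minus-strand
  subject hits have sstart > send).
- Nucleotide characters outside {A,C,G,T} are mapped to N on input (logged),
  never silently dropped; structurally malformed FASTA/FASTQ/TSV is rejected
  with a line number.
- All stochastic stages consume explicit integer seeds through numpy
  Generators; fixed (inputs, seed) is bit-identical across runs.
- λ root-finding brackets [10⁻⁹, doubling]; degenerate scoring systems
  (non-negative expected score, no positive score) are rejected with an
  explanation.
- Ambiguous bases terminate alignment extensions (scored below the X-drop
  budget) rather than matching anything.
- Empty inputs refuse loudly (assembly stats, AAI, shared genes) or return
  empty results where the contract says so (no seeds → no hits; zero reads →
  empty community).
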
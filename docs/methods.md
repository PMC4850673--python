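# Methods

`iped` denoises Illumina MiSeq paired-end 16S rRNA amplicon reads in two
stages: a supervised classifier flags individual base calls as probable
sequencing errors, and a modified single-linkage preclustering then merges
rare error-containing sequences into abundant correct ones while the flagged
positions are excluded from the distance. This note records the model, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Contig assembly

Each read pair is merged ungapped: the reverse-complemented reverse read is
slid along the forward read over every offset with at least `min_overlap`
(default 10) overlapping columns, and the offset maximizing
*matches − mismatches* over non-N columns wins, ties going to the larger
overlap. A pure match count — the obvious alternative — is biased: a long
spurious overlap collects ~0.25 chance matches per column and outscores a
short true overlap, which mis-merged more than half of the pairs on a
70 nt read / 120 nt amplicon geometry during development. Substitutions
dominate MiSeq errors, so no gapped overlap alignment is attempted; pairs
whose reads are shorter than `min_overlap` are rejected rather than fatal.

Consensus inside the overlap: agreeing bases keep the maximum of the two
Phred scores; if one base is N the other wins (status UNKNOWN); conflicting
calls take the higher-quality base when the Phred difference is at least
`q_delta` (default 6), otherwise the position becomes N with quality 0
(status CONFLICT either way). Contigs containing N are culled before
dereplication, which mirrors how ambiguous contigs are discarded in standard
amplicon pre-processing and is also the mechanism by which badly merged
pairs leave the analysis. `q_delta`, `min_overlap` and the max-quality
consensus are artifact choices exposed as flags; the underlying heuristic —
resolve conflicts by the difference in Phred scores — is the method's.

Coordinates are 0-based half-open; reverse-read coordinates refer to the
reverse-complemented orientation throughout, i.e. the orientation in which
the read lies on the contig.

## Per-position features

Seventeen candidate features are computed per contig position: for each
mate, the position in the read, Phred score, homopolymer status, a
GGC-motif-immediately-upstream flag, and the homopolymer status and Phred of
the neighbouring read positions; plus the overlap status of the contig
position (NOT_OVERLAP / MATCH / CONFLICT / UNKNOWN). The retained 6-feature
subset — forward position, forward homopolymer status, forward Phred,
reverse position, reverse Phred, overlap status — is the default input of
the classifier.

Homopolymer status is 0 for a singleton, the 1-based index within the
maximal run for runs of length ≥ 2 (the minimal non-trivial threshold), and
−1 for N. The GGC window is exactly the three bases immediately preceding
the position, on each read's own sequence; phasing-driven quality crashes
follow the motif directly, which motivates the adjacency. Numeric features
use the sentinel −1 where a mate does not cover the position or at read
ends; the categorical overlap feature is one-hot encoded inside the model.

## Training labels and data hygiene

Training labels come from aligning contigs to the mock-community reference
sequences: affine-gap global alignment (match +1, mismatch −1, gap open −2,
gap extend −1) with free end gaps on the reference side, minimum-error
reference wins. Mismatch columns are ERROR; an inserted contig base is
ERROR at its own position; a deleted reference base labels the contig
position immediately left of the gap (a per-position labeling needs *some*
position for every indel). Contigs under 90 % identity to every reference
are skipped.

Two fast paths keep alignment costs amplicon-scale: exact matches, and a
Hamming scan over equal-length references. When the minimum Hamming
distance is ≤ 2 the ungapped alignment is provably optimal and
minimum-error under this scoring (an indel pair alone costs more than two
substitutions). Beyond that, the dynamic programming runs against only the
three nearest references by Hamming distance; a farther reference could in
principle win through indels only for shifted repeats, which neither 16S
amplicons nor the simulator produce.

Labeled instances are dereplicated (identical feature+label rows collapse),
shuffled, and split 60/20/20 into learning (a), validation (b) and test (c)
subsets, stratified by class. Subset (a) is downsampled to a 1:3
error:non-error ratio capped at 5,000/15,000 instances — the ratio and size
at which this family of classifiers performs best — and subset (b) is
balanced 1:1. Smaller datasets proceed at the achievable size with a
warning.

## The voting ensemble

Two members: a multilayer perceptron with one hidden layer of 6 logistic
units, learning rate 0.3 and momentum 0.2; and a random forest of unpruned
trees. Unstated knobs are recorded in `ClassifierConfig`: 500 epochs,
mini-batches of 200, standardized numeric inputs (statistics stored with
the model), 100 trees, √p candidate features per split. Prediction is
plurality voting on confidences: the class holding the single highest
confidence across both members wins; an exact tie resolves to CORRECT, so
doubt never masks. A position enters the error mask when the winning vote
is ERROR with confidence at least `threshold` (default 0.5). For ROC sweeps
the score is the best ERROR confidence across members.

Per-read masks are reconciled after dereplication by majority: a position
of a unique sequence is masked when more than half of its member reads
(ties included) predict an error there. The reconciliation rule is an
artifact choice; per-read masks must land on the dereplicated unit somehow.

Feature selection (used for analysis, not in the default pipeline, whose
6-feature subset is fixed) is a greedy forward search maximizing the
correlation-based merit k·r̄_cf / √(k + k(k−1)·r̄_ff) under 3-fold
cross-validation, keeping features chosen in a majority of folds.
Candidates whose class correlation is below the chance level 2/√n are
excluded up front — with near-orthogonal features the merit otherwise grows
like √k even for pure noise.

## Masked preclustering

Unique sequences are processed in abundance-descending order (ties
lexicographic). Each sequence is compared against every strictly more
abundant current representative; the masked distance counts differing
columns excluding positions masked on either sequence and gap–gap columns.
Within `diffs` differences — `auto` applies max(1, ⌊ungapped length/100⌋),
the 1-per-100-nt rule, to the rare sequence, reproducing the 2-differences
convention at 250 nt — the sequence merges into the *nearest* qualifying
representative (ties: highest current abundance, then earliest established),
transferring its abundance immediately so later sequences see post-merge
abundances. Merging into the nearest rather than the first qualifying
representative, and updating abundances during the pass, are deterministic
choices fixed here; the plain preclustering baseline (all-false masks) uses
the same semantics. Masks never mutate sequence content, so emitting the
representatives' stored sequences *is* the mask reversion: every output
sequence is byte-identical to an input sequence.

The pipeline inserts a minimal length screen (keep the modal contig length
by read count) between dereplication and preclustering, because
preclustering operates on same-region amplicons and rare spurious-offset
merges produce off-length contigs; full reference-alignment screening is
deliberately out of scope.

## Error-rate evaluation

The error rate is (deletions + insertions + substitutions) / total bases,
abundance-weighted, each unique sequence aligned to its minimum-error
reference with the scoring above. Among equal-score alignments the ungapped
one is preferred (it minimizes the error count), which recovers planted
substitution-only errors exactly. Position-wise rates attribute each error
event to a reference-anchored amplicon coordinate (insertions to the left
flanking base); coverage-weighted sums return the aggregate count exactly.

## What the simulator emulates

The generator reproduces the error structure that makes masked
preclustering worthwhile: Phred decays linearly along the read
(`q_start` 38 → `q_end` 23 by default), reverse reads run `rev_penalty` = 6
lower, a per-read Gaussian quality offset (`read_q_sd` = 4) models
cluster-to-cluster variability, a GGC motif depresses the next 5 positions
by 6, and ±2 integer jitter is added per position; realized qualities clamp
to [2, 40]. Substitutions are drawn independently at 10^(−Q/10) of the
*realized* quality — FASTQ qualities are calibrated by construction — with
0.6 of the miscall mass on the fluorophore-confusable partner (A↔C, G↔T).
Defaults were chosen once for realism: on the V34-like geometry (430 nt
amplicon, 2 × 250 nt reads, 70 nt overlap) they yield a raw contig error
rate of ≈ 0.0028, matching the order of magnitude reported for real V34
mock runs, and the per-read quality offset supplies the overdispersed
multi-error reads that plain preclustering cannot rescue (a read with more
than `diffs` errors merges only when masking hides the excess). References
default to 12–21 sequences at 90–97 % identity to a common ancestor.

What it does not emulate: indels (off by default; a crude per-read indel
option exists for labeling robustness tests), chimeras, PCR point errors
and bias, position-correlated error bursts beyond the quality model, and
real flow-cell physics. A green end-to-end test therefore establishes that
the method behaves correctly *given* quality-calibrated substitution noise
with read-level variability — not that it reproduces any particular real
run's numbers.

## Degenerate inputs and tie-breaks

Empty contig lists, empty reference sets, single-class training data and
unequal-length precluster input raise immediately with the failing stage
named. Ambiguity is conservative throughout: voting ties do not mask,
mask-majority ties do mask (erring toward rescuing the read), merge-target
ties prefer the more abundant then earlier representative, dereplication
ties order lexicographically. MCC is defined as 0 whenever a denominator
factor vanishes; sensitivity/specificity are 0 on empty denominators.

## Known limitations

- Preclustering is quadratic in the number of unique sequences; tables
  beyond ~10⁵ uniques need chunking or group-wise processing (not
  implemented).
- The classifier is trained per run on simulated or reference-labeled data;
  no pretrained model ships with the package.
- Equal-length input to preclustering restricts the tool to same-region
  amplicons or pre-aligned sequences.
- Error-rate alignment restricts the DP to Hamming-nearest references (see
  above); pathological reference sets with long shared repeats could in
  principle be misattributed.
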
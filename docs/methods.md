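# Methods

This note records the models, conventions and numerical choices behind
`modcaller`, and what the synthetic experiments do and do not establish.

## Signal model and preprocessing

Basecalled events arrive with a signal mean, standard deviation, sample
count, `move` annotation and k-mer.  Stay events (`move == 0`) are merged
into the preceding move event; pooled statistics are recomputed from the
raw samples the merged event spans when raw signal is available.  The
population variance convention (divide by *n*) is used so single-sample
events have stdv 0.  A read that begins with a stay is rejected by
default (`leading_stay="attach"` pools it into the first move event).
A `move = m > 1` event emits the last *m* bases of its k-mer; every
emitted base receives the event's pooled statistics, all but the last
flagged `shared`, which keeps read length and event count consistent.

Normalization maps each read's raw trace to [−5, 5] by median-centering,
scaling by MAD × 1.4826 and clipping; it is invariant under positive
affine transforms of the input, which is the property that makes reads
comparable across pores and runs.  Degenerate spreads fall back to the
standard deviation and then to all-zeros.  When raw samples are absent
(the portable event TSV carries only statistics), the stored event means
are normalized by the per-read median/MAD of the means and the stdvs are
scaled by the same factor; with raw signal available, statistics are
recomputed from the normalized samples instead.  The TSV dialect
(`read_id, start_index, n_samples, move, kmer, mean, stdv`) exists so
tests and small datasets need no HDF5 container; the FAST5 reader/writer
handles a single documented Albacore-2.x-like layout.

## Anchoring and labels

Coordinates are 0-based everywhere; BED output is 0-based half-open.
The CIGAR walk anchors match/mismatch columns, skips insertions, and
lets deletions consume reference only; spliced (`N`) operators are
rejected.  For reverse-strand alignments the stored reference base is
the complement of the forward base — the base in the molecule's reading
sense, which is what the signal reflects — and the site is summarized on
the `−` strand.  Mismatched (substituted) bases are anchored and used,
with `is_match` recorded for optional filtering.  Reads that are
unmapped, secondary, supplementary, or have MAPQ < 10 (strict
less-than) are discarded.

Motif labels scan both strands with overlaps counted; a reverse-strand
site is an occurrence of the motif along the reverse complement,
reported at its forward coordinate.  Bisulfite labels use the
complete-methylation rule: modified iff the methylation percentage is
≥ 0.90 in both replicates with coverage at or above a threshold in both
(the inclusive ≥ is the default; a flag switches to strict >, since both
conventions appear in the field); unmodified iff exactly 0 % in both
replicates; all other sites are excluded from binary evaluation.  The
default coverage threshold is 1 and is exposed (1/3/5/10 are all in
common use).

## Window features

Feature order is fixed: `[f_m, f_d, f_l, f_A, f_C, f_G, f_T]`.  `f_l`
(sample count) is used raw rather than standardized, keeping the inputs
interpretable; the extended 57-feature mode appends a 50-bin histogram of
the event's normalized samples over [−5, 5] (half-open bins, last bin
closed, normalized to sum to 1).  Window neighbors are consecutive
events of the same read in read order — not consecutive reference
positions — so deletions do not introduce gap rows.  Windows are
zero-padded at read ends; padding never touches the center row.
Unanchored neighbor events keep their signal features with an all-zero
base indicator.

## The window classifier

Three stacked bidirectional LSTM layers (hidden size *H* per direction,
default 100; the desk-scale studies use 32) read the *w* window rows;
each layer consumes the concatenated forward/backward outputs of the
previous one, and the center time-step's top-layer state feeds an affine
map to two logits and a softmax in `[unmodified, modified]` order.  The
cell is the standard LSTM: cell state
`v_j = f_i1 ∘ f_i2 + v_{j−1} ∘ f_f`, output `p_j = tanh(v_j) ∘ f_p`,
gates affine in `[x_j, p_{j−1}, 1]`.  Widths `w ∈ {7, 11, 15, 21, 31, 51}`
are accepted silently, others with a warning; `w = 21` is the default
(larger widths raise cost faster than accuracy).

Forward and backward passes are implemented directly in NumPy with
hand-derived backpropagation through time; the test suite verifies the
analytic gradient against central finite differences to < 1e−4 relative
error (whole-gradient norm, double precision — per-entry comparisons are
dominated by finite-difference roundoff on near-zero entries).  Training
uses Adam (lr 1e−3, batch 256) on the epsilon-clamped cross-entropy, and
loads the two classes as alternating chunks (default 2048 windows), the
smaller class cycling, which equalizes class exposure without
resampling; an optional class-weight argument reweights the loss
instead.  Computation is single precision by default
(`precision="double"` exists for gradient checks).  Checkpoints are NPZ
archives carrying the config and a format version.

Two validation protocols are provided: a read-based split (90 % of reads
per class train, 10 % test; reads may share genomic positions between
groups) and a region-based split in which every window centered in a
half-open genomic interval is held out — the stricter protocol, used by
the acceptance study, because at small genome scale a capable network
can otherwise memorize site contexts rather than read signal.

## Per-site summary and evaluation

Each anchored target base of each read contributes one count to its
position on the strand the read aligned to; modified calls (posterior
≥ 0.5) increment the modification coverage, and the percentage is the
exact ratio.  The BED dialect is 9 columns (`contig, start, end, name,
score = round(1000·pct), strand, coverage, mod_coverage, pct`),
single-base half-open intervals, sorted by (contig, start, strand);
percentages are recomputed from the counts on reading, so round trips
are lossless.

AP is the non-interpolated step sum Σ (R_k − R_{k−1})·P_k with
thresholds at each distinct score (ties collapse into one threshold);
AUC is the Mann–Whitney statistic with ties counted half.  Both are
verified against exhaustive brute-force oracles (threshold enumeration;
all positive/negative pairs) and against scikit-learn.  Site-level
evaluation restricts to truth-labeled sites at or above a coverage
threshold, ranks by predicted percentage, and takes binary calls at a
percentage threshold (default 0.1).  Precision with no positive calls
(and recall with no positive truth) is reported NaN with a warning.

## Cluster refinement network

The 14-value input is: own percentage, opposite-strand percentage (the
paired cytosine at +1/−1 depending on strand; 0 when uncovered), the
number of same-strand CpG neighbors within 25 bp (a flag widens this to
both strands), and an 11-bin histogram of the neighbors' percentages
with edges [0, 0.05), [0.05, 0.15), …, [0.95, 1.0] (half-open, last bin
closed).  The network is 14 → 100 → 20 → 1, ReLU hidden units, sigmoid
output, inverted dropout at rate 0.7 on both hidden layers during
training only, Adam for 100 epochs against bisulfite percentages with
binary cross-entropy (MSE by flag).  It is fitted on one contig and
applied everywhere else; refinement is a per-site map, so the site count
never changes.

## Synthetic data

The generator reproduces the *structure* of the study inputs, not pore
physics.  Genomes are i.i.d. with a set GC fraction.  Modifications are
planted in a seeded random fraction of motif target sites on both
strands (fraction 1 and 0 are the enzyme-treated and PCR control
analogs).  The pore model is a seeded pseudo-random k-mer table
(k = 5): event samples are normal around the k-mer level (level spread
1.8, per-sample noise sd 2.0 in arbitrary current units, 4 + Poisson(4)
samples per event), stays are geometric (probability 0.15), and a
modified base shifts its event mean by `mod_delta` (default 6.0), with
±2 flanking events shifted at 50 % attenuation per step — modifications
perturb several neighboring pore states.  The level spread is chosen so
that `mod_delta = 3 × noise_sd` yields an empirical Cohen's d ≈ 3
between modified and unmodified event means, i.e. the stated effect size
is realized in the generated data.  Alignments emitted by the simulator
are the exact ground truth (all-match CIGAR), so the pipeline runs
without an external aligner; real data goes through BWA-MEM or minimap2
and enters via SAM/BAM.

Bisulfite tables draw a true methylation level per site (near 1 for
modified, near 0 for unmodified, scaled by a heterogeneity parameter,
optionally an intermediate Beta(2, 2) fraction) and binomial replicate
percentages at sampled coverage.  The correlated-methylome generator for
the cluster study partitions the genome into exponential-length blocks
(mean 600 bp), gives each block a high (Beta(18, 2)) or low (Beta(2, 18))
level shared by all its CpGs on both strands, and produces noisy raw
per-site percentages (per-read call error 0.12 at coverage 10) plus
higher-coverage bisulfite targets.

What passing tests show — and do not.  The simulation demonstrates that
the implementation recovers planted signal of a stated effect size under
the stated protocol; it does not demonstrate performance on real pores,
where k-mer levels are structured rather than random, noise is
non-Gaussian and context-dependent, basecalls contain indels, and
modification effects vary by motif and chemistry.

## Study conditions and problem sizes

The recovery study uses a 100 kb genome at GC 0.5, CG motif with half
the sites modified, 30× coverage of 4 kb reads, H = 32, w = 21, 1200
optimizer steps, and holds out the region [60 000, 80 000) (~2 400
site-strand labels) for testing; it reaches site-level AP/AUC ≈ 0.99.
The null variant (mod_delta = 0) runs at 30 kb / 10× / 300 steps —
chance-level behavior is scale-free — and its AP lands at the positive
prevalence.  The cluster study uses two 60 kb contigs (~7 500 CpG sites
each), training on one and testing on the other.  These sizes keep the
whole validation suite within a few CPU-minutes while leaving hundreds
to thousands of evaluation sites per claim.

## Known limitations

Single-read FAST5 layout only (no multi-read FAST5 or POD5); no aligner
is bundled; spliced alignments are rejected; the cluster network applies
to CpG/5mC only; no per-read MM/ML BAM tag output; training is
CPU-scale NumPy — adequate at these problem sizes, not for genome-scale
production runs.
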
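# modcaller

Detection of DNA base modifications (5mC, 6mA) from basecalled Oxford
Nanopore event data with a bidirectional LSTM, written for epigenomics
researchers who want a transparent, CPU-scale, fully testable
implementation of signal-level modification calling.

A nanopore basecaller segments each read's raw ionic current into
*events*, one per pore state (k-mer), annotated with a `move` flag
(`move >= 1`: new base emitted; `move == 0`: stay).  Because a base
modification perturbs the current of several neighboring pore states,
modification status is decided per read base from a window of events.
`modcaller` implements the whole chain:

1. **Events** — merge stay events into their preceding move event,
   normalize each read's signal to [−5, 5] (median/MAD), recompute
   per-event mean, standard deviation and sample count.
2. **Anchoring** — walk SAM/BAM CIGARs to tie each read base to a
   reference contig/position/strand (reads with MAPQ < 10 are dropped;
   insertions are never anchored).
3. **Features** — each anchored event becomes
   `x_i = [f_m, f_d, f_l, f_A, f_C, f_G, f_T]` (signal mean, stdv, sample
   count, one-hot reference base); an optional 57-feature mode appends a
   50-bin histogram of the event's normalized samples.  A classification
   instance is the `w × 7` matrix of a base and its ⌊w/2⌋ up/downstream
   events (`w = 21` by default).
4. **Model** — a 3-layer bidirectional LSTM over the window.  Each cell
   computes `v_j = f_i1 ∘ f_i2 + v_{j−1} ∘ f_f` and
   `p_j = tanh(v_j) ∘ f_p`, with `f_i1 = tanh(·)` and sigmoid
   input/forget/output gates over `[x_j, p_{j−1}, 1]`; the center step's
   forward/backward states feed a 2-way softmax, trained by Adam on the
   cross-entropy `E = −y·log(ȳ_mod) − (1−y)·log(ȳ_unmod)` with
   chunk-interleaved positive/negative loading.  Forward and backward
   passes are hand-written NumPy, gradient-checked against finite
   differences.
5. **Summary** — per-read calls are aggregated strand-specifically per
   genomic position into coverage, modification coverage and methylation
   percentage, written as 9-column BED.
6. **Cluster network** — an optional 14 → 100 → 20 → 1 network (sigmoid
   output, dropout 0.7, 100 epochs) refines CpG percentages using
   neighbors within 25 bp and the opposite-strand cytosine.
7. **Evaluation** — accuracy / precision / recall / F1 from set counts,
   step-sum average precision (AP), and Mann–Whitney AUC, under coverage
   stratification; truth labels come from motifs (control libraries) or
   from duplicate bisulfite tables (complete methylation: ≥ 90 % in both
   replicates at sufficient coverage; complete un-methylation: 0 % in
   both).
8. **Simulator** — a seeded k-mer pore model with modification-induced
   mean shifts (attenuated over ±2 neighboring events), stay/move
   dynamics, exact ground-truth alignments and replicate bisulfite
   tables, so the entire pipeline trains and validates without external
   sequencing data.

## Worked example

```python
from modcaller.pipeline import run_detection_study

study = run_detection_study(seed=7, genome_length=20_000, coverage=10,
                            read_length=2000, hidden_size=32,
                            max_steps=400, test_region=(12_000, 16_000))
r = study.eval_result
print(r.ap, r.auc, r.precision, r.recall)
```

prints (seed 7):

```
trained on 8698 windows, tested on 3009 windows (523 genomic sites)
site-level AP  = 0.994   (ranking quality of methylation %)
site-level AUC = 0.994   (positive vs negative separability)
at call threshold 0.1: precision = 0.978, recall = 0.989, F1 = 0.983
```

Half of the 523 held-out CpG sites carried a planted modification whose
signal shift is three times the event noise; AP/AUC ≈ 0.99 means the
predicted per-site methylation percentages rank modified above
unmodified sites almost perfectly, for sites in a genomic region the
model never saw in training.  `examples/` contains this and three more
narrative scripts (simulation internals, metric arithmetic, cluster
refinement).

The same pipeline is available from the shell:

```bash
modcaller simulate --out-dir sim --genome-length 50000 --coverage 10 --seed 1
modcaller train  --events sim/events.tsv --alignments sim/reads.sam \
                 --reference sim/genome.fa --truth sim/truth.bed \
                 --motif CG --out model.npz
modcaller detect --events sim/events.tsv --alignments sim/reads.sam \
                 --reference sim/genome.fa --model model.npz \
                 --motif CG --out sites.bed
modcaller evaluate --bed sites.bed --truth sim/truth.bed
```

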
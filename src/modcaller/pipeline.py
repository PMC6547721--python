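"""End-to-end orchestration: reads -> anchored events -> windows -> calls
-> per-site summaries, plus the self-contained simulation studies used to
validate the caller at desk scale.

The study functions fix their conditions (genome size, coverage, signal
effect size, split) and return every metric they compute; they are the
programmatic equivalent of running ``simulate``/``train``/``detect``/
``evaluate`` from the command line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .anchor import AnchoredRead, anchor_read, filter_alignments
from .cluster import ClusterNet, ClusterNetConfig, build_cluster_matrix
from .events import (
    EventTable,
    MergedEvents,
    ReadSignal,
    merge_stay_events,
    normalize_event_stats,
    normalize_signals,
)
from .features import WindowSet, build_dataset
from .lstm import BiLstmClassifier, ModelConfig, split_region_based
from .metrics import EvalResult, average_precision, evaluate_sites
from .simulate import (
    PoreModel,
    SimConfig,
    alignments_to_pysam,
    generate_genome,
    plant_modifications,
    simulate_bisulfite_targets,
    simulate_correlated_methylome,
    simulate_dataset,
    simulate_raw_predictions,
)
from .summary import SiteSummary, accumulate_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "prepare_read",
    "anchor_reads",
    "call_modifications",
    "run_detection_study",
    "run_cluster_study",
]


def prepare_read(read: ReadSignal) -> MergedEvents:
    """Normalize a read's signal and merge its stay events.

    When raw samples are available the whole trace is normalized to
    [-5, 5] and merged-event statistics are recomputed from the samples;
    otherwise the stored event statistics are rescaled by the per-read
    median/MAD of the event means.
    """
    if read.raw is not None:
        return merge_stay_events(read.events, normalize_signals(read.raw))
    means, stdvs = normalize_event_stats(read.events.mean, read.events.stdv)
    ev = read.events
    table = EventTable(ev.start_index, ev.n_samples, ev.move, ev.kmers, means, stdvs)
    return merge_stay_events(table, None)


def anchor_reads(
    reads: Sequence[ReadSignal],
    alignment_records: Sequence,
    reference: Mapping[str, str],
    min_mapq: int = 10,
) -> list[AnchoredRead]:
    """Filter alignments, then anchor each read's merged events."""
    by_id = {r.read_id: r for r in reads}
    anchored = []
    for rec in filter_alignments(alignment_records, min_mapq=min_mapq):
        read = by_id.get(rec.query_name)
        if read is None:
            logger.warning("alignment for unknown read %s skipped", rec.query_name)
            continue
        merged = prepare_read(read)
        anchored.append(anchor_read(merged.sequence(), merged, rec, reference))
    return anchored


def call_modifications(
    anchored_reads: Sequence[AnchoredRead],
    model: BiLstmClassifier,
    reference: Mapping[str, str],
    target_base: str = "C",
    motif_restriction: tuple[str, int] | None = ("CG", 0),
    call_threshold: float = 0.5,
    mod_name: str = "5mC",
) -> dict[tuple[str, int, str], SiteSummary]:
    """Per-read calls for every anchored target base, summarized per site."""
    windows = build_dataset(
        anchored_reads, None, target_base,
        motif_restriction=motif_restriction, reference=reference,
        w=model.config.w, feature_mode=model.config.feature_mode,
        keep_unlabeled=True, require_label=False,
    )
    return summarize_windows(windows, model, call_threshold, mod_name)


def summarize_windows(
    windows: WindowSet,
    model: BiLstmClassifier,
    call_threshold: float = 0.5,
    mod_name: str = "5mC",
) -> dict[tuple[str, int, str], SiteSummary]:
    """Predict each window and accumulate strand-specific site summaries."""
    if len(windows) == 0:
        return {}
    p_mod = model.predict_proba(windows.X)
    calls = (p_mod >= call_threshold).astype(np.int64)
    summaries: dict[tuple[str, int, str], SiteSummary] = {}
    contigs = windows.contig.astype("U")
    for contig in np.unique(contigs):
        m = contigs == contig
        accumulate_arrays(
            str(contig), windows.pos[m], windows.strand[m], calls[m],
            out=summaries, name=mod_name,
        )
    return summaries


@dataclass
class DetectionStudyResult:
    """Everything the simulated detection study measures."""

    eval_result: EvalResult
    prevalence: float
    n_train_windows: int
    n_test_windows: int
    n_sites_evaluated: int
    history: list = field(default_factory=list)


def run_detection_study(
    seed: int = 1,
    genome_length: int = 100_000,
    gc: float = 0.5,
    motif: str = "CG",
    mod_offset: int = 0,
    frac_modified: float = 0.5,
    coverage: float = 30.0,
    read_length: int = 4000,
    stay_prob: float = 0.15,
    noise_sd: float = 2.0,
    mod_delta: float = 6.0,
    w: int = 21,
    hidden_size: int = 32,
    max_steps: int = 1200,
    test_region: tuple[int, int] = (60_000, 80_000),
    min_cov: int = 1,
    call_threshold: float = 0.1,
    contig_name: str = "sim1",
) -> DetectionStudyResult:
    """Simulate -> train -> detect -> summarize -> evaluate, region-split.

    Plants modifications in half the motif sites of a random genome,
    simulates event-level reads whose modified bases carry a signal mean
    shift of ``mod_delta`` (3x the sample noise by default), trains the
    window classifier on everything outside ``test_region`` and evaluates
    site-level AP/AUC inside it.  ``mod_delta=0`` gives the null experiment
    in which AP should fall near the positive-class prevalence.
    """
    reference = {contig_name: generate_genome(genome_length, gc, seed)}
    truth = plant_modifications(reference, motif, mod_offset, frac_modified, seed + 1)
    pore = PoreModel(noise_sd=noise_sd, mod_delta=mod_delta, seed=seed + 2)
    sim_cfg = SimConfig(
        genome_length=genome_length, gc=gc, motif=motif, mod_offset=mod_offset,
        frac_modified=frac_modified, read_length=read_length, coverage=coverage,
        stay_prob=stay_prob, seed=seed + 3,
    )
    reads, alignments = simulate_dataset(reference, truth, pore, sim_cfg)
    records, _ = alignments_to_pysam(alignments, reference)
    anchored = anchor_reads(reads, records, reference)

    windows = build_dataset(
        anchored, truth, target_base="C",
        motif_restriction=(motif, mod_offset), reference=reference, w=w,
    )
    train_set, test_set = split_region_based(windows, contig_name, *test_region)
    model = BiLstmClassifier(
        ModelConfig(w=w, hidden_size=hidden_size, max_steps=max_steps, seed=seed + 4)
    )
    history = model.train(
        train_set.subset(train_set.y == 1), train_set.subset(train_set.y == 0)
    )

    summaries = summarize_windows(test_set, model)
    region_truth = {
        k: v for k, v in truth.items()
        if k[0] == contig_name and test_region[0] <= k[1] < test_region[1]
    }
    result = evaluate_sites(summaries, region_truth, min_cov=min_cov,
                            call_threshold=call_threshold)
    labels = np.array(list(region_truth.values()))
    return DetectionStudyResult(
        eval_result=result,
        prevalence=float(labels.mean()),
        n_train_windows=len(train_set),
        n_test_windows=len(test_set),
        n_sites_evaluated=result.n_modified + result.n_unmodified,
        history=history,
    )


@dataclass
class ClusterStudyResult:
    ap_raw: float
    ap_refined: float
    n_train_sites: int
    n_test_sites: int


def run_cluster_study(
    seed: int = 1,
    contig_length: int = 60_000,
    gc: float = 0.5,
    raw_coverage: int = 10,
    per_read_error: float = 0.12,
    bisulfite_coverage: int = 30,
    config: ClusterNetConfig | None = None,
) -> ClusterStudyResult:
    """Train the refinement network on one contig, test on another.

    Generates a blockwise-correlated CpG methylome over two contigs, noisy
    raw per-site predictions and high-coverage bisulfite targets; the
    network is fitted on the first contig's sites (the chromosome-1 analog)
    and evaluated on the second by comparing AP against the binary block
    truth before and after refinement.
    """
    reference = {
        "chrA": generate_genome(contig_length, gc, seed),
        "chrB": generate_genome(contig_length, gc, seed + 1),
    }
    levels, block_labels = simulate_correlated_methylome(reference, seed=seed + 2)
    raw = simulate_raw_predictions(levels, raw_coverage, per_read_error, seed + 3)
    targets = simulate_bisulfite_targets(levels, bisulfite_coverage, seed + 4)

    train_sites = sorted(k for k in levels if k[0] == "chrA")
    test_sites = sorted(k for k in levels if k[0] == "chrB")
    X_train = build_cluster_matrix(train_sites, raw, reference)
    t_train = np.array([targets[s] for s in train_sites])
    net = ClusterNet(config or ClusterNetConfig(seed=seed + 5))
    net.train(X_train, t_train)

    X_test = build_cluster_matrix(test_sites, raw, reference)
    refined = net.predict(X_test)
    raw_pct = np.array([raw[s].pct for s in test_sites])
    y = np.array([block_labels[s] for s in test_sites])
    return ClusterStudyResult(
        ap_raw=average_precision(raw_pct, y),
        ap_refined=average_precision(refined, y),
        n_train_sites=len(train_sites),
        n_test_sites=len(test_sites),
    )
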
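"""Synthetic nanopore-like data generator.

Emulates the study's inputs end to end so the whole pipeline is trainable
and testable without external sequencing data: a random genome, motif-
planted modifications (the analog of enzyme-treated positive controls and
PCR negative controls), reads of basecaller-style events whose signals are
drawn from a seeded k-mer pore model with a modification-induced mean
shift that bleeds into a few neighboring events, exact ground-truth
alignments (all-match CIGAR, so no external aligner is needed), and
replicate bisulfite-style truth tables with heterogeneous methylation.

The pore model is a seeded pseudo-random k-mer table, not a measured one:
the generator aims for parameterized separability between modified and
unmodified signal distributions, not for signal realism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .anchor import BisulfiteSite, label_from_motifs
from .events import EventTable, ReadSignal

logger = logging.getLogger(__name__)

__all__ = [
    "PoreModel",
    "SimConfig",
    "SimAlignment",
    "generate_genome",
    "plant_modifications",
    "simulate_read",
    "simulate_dataset",
    "simulate_bisulfite",
    "write_sam",
    "alignments_to_pysam",
    "simulate_correlated_methylome",
    "simulate_raw_predictions",
    "simulate_bisulfite_targets",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _encode(seq: str) -> np.ndarray:
    """Sequence -> int8 codes (A=0, C=1, G=2, T=3)."""
    lut = np.full(256, -1, np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
        lut[b + 32] = i
    codes = lut[np.frombuffer(seq.encode(), np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


@dataclass
class PoreModel:
    """Seeded k-mer signal model with modification shift.

    ``mod_delta`` is added to the event mean of a modified base; flanking
    events within ``neighborhood`` positions receive the shift attenuated
    by ``attenuation`` per step, reflecting that a modification perturbs
    the current of several neighboring pore states.
    """

    k: int = 5
    level_mean: float = 100.0
    level_spread: float = 1.8
    noise_sd: float = 2.0
    mod_delta: float = 6.0
    neighborhood: int = 2
    attenuation: float = 0.5
    seed: int = 0
    means: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        rng = np.random.default_rng(self.seed)
        self.means = rng.normal(self.level_mean, self.level_spread, 4**self.k)

    def kmer_mean(self, kmer: str) -> float:
        idx = 0
        for b in kmer:
            idx = idx * 4 + int(_encode(b)[0])
        return float(self.means[idx])


@dataclass
class SimConfig:
    """Study conditions for the event simulator."""

    genome_length: int = 100_000
    gc: float = 0.5
    motif: str = "CG"
    mod_offset: int = 0
    frac_modified: float = 0.5
    read_length: int = 4000
    coverage: float = 30.0
    stay_prob: float = 0.15
    samples_min: int = 4
    samples_poisson_lam: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc", "frac_modified", "stay_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")


@dataclass
class SimAlignment:
    """Ground-truth all-match alignment of one simulated read."""

    read_id: str
    contig: str
    ref_start: int
    strand: str
    query: str  # forward-sense sequence, as a SAM record stores it

    @property
    def cigar(self) -> str:
        return f"{len(self.query)}M"


def generate_genome(length: int, gc: float = 0.5, seed: int = 0, k: int = 5) -> str:
    """Random i.i.d. genome with the requested GC fraction."""
    if length < k:
        raise ValueError(f"genome length {length} shorter than k-mer length {k}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode()


def plant_modifications(
    reference: Mapping[str, str],
    motif: str,
    offset: int,
    fraction: float,
    seed: int = 0,
) -> dict[tuple[str, int, str], int]:
    """Label a seeded random subset of motif target sites as modified.

    All motif target positions on both strands are returned; a ``fraction``
    of them (chosen at random) carries label 1, the rest 0.  ``fraction=1``
    is the enzyme-treated positive-control analog, ``fraction=0`` the PCR
    negative control.
    """
    labels = label_from_motifs(reference, motif, offset, control="negative")
    keys = sorted(labels)
    rng = np.random.default_rng(seed)
    n_mod = int(round(fraction * len(keys)))
    for i in rng.permutation(len(keys))[:n_mod]:
        labels[keys[i]] = 1
    return labels


def _shift_profile(
    codes_len: int,
    mod_positions: np.ndarray,
    pore: PoreModel,
) -> np.ndarray:
    """Per-position signal shift: full delta at modified sites, attenuated
    within the neighborhood, strongest contribution winning at overlaps."""
    ind = np.zeros(codes_len)
    ind[mod_positions] = 1.0
    shift = np.zeros(codes_len)
    for d in range(-pore.neighborhood, pore.neighborhood + 1):
        w = pore.attenuation ** abs(d)
        lo_src = max(0, -d)
        hi_src = codes_len - max(0, d)
        np.maximum(
            shift[lo_src + d : hi_src + d], w * ind[lo_src:hi_src],
            out=shift[lo_src + d : hi_src + d],
        )
    return shift * pore.mod_delta


def _truth_mod_index(
    truth: Mapping[tuple[str, int, str], int],
) -> dict[tuple[str, str], np.ndarray]:
    """Sorted modified-position arrays keyed by (contig, strand)."""
    idx: dict[tuple[str, str], list[int]] = {}
    for (contig, pos, strand), lab in truth.items():
        if lab == 1:
            idx.setdefault((contig, strand), []).append(pos)
    return {k: np.array(sorted(v), np.int64) for k, v in idx.items()}


def _read_kmers(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-base k-mer index and k-mer bytes (k-mer ends at the base)."""
    n = len(codes)
    pad = np.concatenate([np.full(k - 1, codes[0], codes.dtype), codes])
    win = np.lib.stride_tricks.sliding_window_view(pad, k)  # (n, k)
    powers = 4 ** np.arange(k - 1, -1, -1)
    idx = (win * powers).sum(axis=1)
    kmers = _BASES[win].view(f"S{k}")[:, 0]
    return idx, kmers


def simulate_read(
    reference: Mapping[str, str],
    contig: str,
    start: int,
    length: int,
    strand: str,
    pore_model: PoreModel,
    config: SimConfig,
    truth: Mapping[tuple[str, int, str], int],
    read_id: str = "read0",
    rng: np.random.Generator | None = None,
    _codes: np.ndarray | None = None,
    _mod_index: dict[tuple[str, str], np.ndarray] | None = None,
) -> tuple[ReadSignal, SimAlignment]:
    """Simulate one read: events base by base with stay insertions.

    Event samples are drawn around the k-mer baseline plus the modification
    shift profile; the returned alignment is the exact ground truth
    (all-match CIGAR) so the pipeline can run without an external aligner.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    codes_ref = _codes if _codes is not None else _encode(reference[contig])
    L = len(codes_ref)
    end = min(start + length, L)
    if end - start < length:
        logger.info("read %s truncated at contig end (%d < %d)", read_id, end - start, length)
    if end <= start:
        raise ValueError("read start beyond contig end")
    span = codes_ref[start:end]
    n = len(span)

    mod_index = _mod_index if _mod_index is not None else _truth_mod_index(truth)
    arr = mod_index.get((contig, strand), np.empty(0, np.int64))
    lo_i, hi_i = np.searchsorted(arr, [start, end])
    mod_pos = arr[lo_i:hi_i] - start
    shift_ref = _shift_profile(n, mod_pos, pore_model)

    if strand == "+":
        read_codes = span
        shift = shift_ref
    elif strand == "-":
        read_codes = (3 - span)[::-1]
        shift = shift_ref[::-1]
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")

    kidx, kmers = _read_kmers(read_codes, pore_model.k)
    mu = pore_model.means[kidx] + shift

    if config.stay_prob > 0:
        reps = rng.geometric(1.0 - config.stay_prob, n)
    else:
        reps = np.ones(n, np.int64)
    total = int(reps.sum())
    starts_ev = np.cumsum(reps) - reps
    move = np.zeros(total, np.int64)
    move[starts_ev] = 1
    base_of_event = np.repeat(np.arange(n), reps)

    n_samp = config.samples_min + rng.poisson(config.samples_poisson_lam, total)
    n_samp = np.maximum(n_samp, 1)
    S = int(n_samp.sum())
    raw = rng.standard_normal(S) * pore_model.noise_sd + np.repeat(
        mu[base_of_event], n_samp
    )
    start_index = np.concatenate([[0], np.cumsum(n_samp)[:-1]])
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    csum2 = np.concatenate([[0.0], np.cumsum(raw * raw)])
    hi = start_index + n_samp
    s1 = csum[hi] - csum[start_index]
    s2 = csum2[hi] - csum2[start_index]
    ev_mean = s1 / n_samp
    ev_std = np.sqrt(np.maximum(s2 / n_samp - ev_mean**2, 0.0))

    table = EventTable(start_index, n_samp, move, kmers[base_of_event], ev_mean, ev_std)
    read = ReadSignal(read_id, raw, table)
    query = _BASES[span].tobytes().decode()  # forward-sense, as SAM stores it
    return read, SimAlignment(read_id, contig, start, strand, query)


def simulate_dataset(
    reference: Mapping[str, str],
    truth: Mapping[tuple[str, int, str], int],
    pore_model: PoreModel,
    config: SimConfig,
) -> tuple[list[ReadSignal], list[SimAlignment]]:
    """Reads covering each contig to the configured depth, random strands."""
    rng = np.random.default_rng(config.seed)
    reads: list[ReadSignal] = []
    alignments: list[SimAlignment] = []
    mod_index = _truth_mod_index(truth)
    i = 0
    for contig, seq in reference.items():
        codes = _encode(seq)
        L = len(codes)
        rl = min(config.read_length, L)
        n_reads = max(1, math.ceil(L * config.coverage / rl))
        starts = rng.integers(0, max(1, L - rl + 1), n_reads)
        strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
        for start, strand in zip(starts.tolist(), strands.tolist()):
            read, aln = simulate_read(
                reference, contig, start, rl, strand, pore_model, config, truth,
                read_id=f"sim_{i:06d}", rng=rng, _codes=codes, _mod_index=mod_index,
            )
            reads.append(read)
            alignments.append(aln)
            i += 1
    return reads, alignments


def alignments_to_pysam(alignments: Sequence[SimAlignment], reference: Mapping[str, str]):
    """Convert ground-truth alignments into pysam records (MAPQ 60)."""
    import pysam

    contigs = list(reference)
    header = pysam.AlignmentHeader.from_references(
        contigs, [len(reference[c]) for c in contigs]
    )
    records = []
    for aln in alignments:
        rec = pysam.AlignedSegment(header)
        rec.query_name = aln.read_id
        rec.query_sequence = aln.query
        rec.flag = 16 if aln.strand == "-" else 0
        rec.reference_id = contigs.index(aln.contig)
        rec.reference_start = aln.ref_start
        rec.mapping_quality = 60
        rec.cigarstring = aln.cigar
        records.append(rec)
    return records, header


def write_sam(
    alignments: Sequence[SimAlignment], reference: Mapping[str, str], path: str | Path
) -> None:
    import pysam

    records, header = alignments_to_pysam(alignments, reference)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            fh.write(rec)


def simulate_bisulfite(
    truth: Mapping[tuple[str, int, str], int],
    heterogeneity: float = 0.1,
    coverage_range: tuple[int, int] = (10, 30),
    seed: int = 0,
    frac_intermediate: float = 0.0,
) -> list[BisulfiteSite]:
    """Replicate bisulfite tables consistent with the planted truth.

    Modified sites draw a true methylation level near 1 (``1 - h*Beta(1,4)``
    with ``h`` the heterogeneity), unmodified sites near 0 (``h*Beta(1,4)``),
    and an optional fraction of sites an intermediate ``Beta(2,2)`` level;
    each replicate's percentage is a binomial draw at its own sampled
    coverage.  With ``heterogeneity=0`` the tables recover the planted
    truth exactly under complete-methylation labeling.
    """
    if not 0.0 <= heterogeneity <= 1.0:
        raise ValueError("heterogeneity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = coverage_range
    sites = []
    for key in sorted(truth):
        contig, pos, strand = key
        lab = truth[key]
        if frac_intermediate > 0 and rng.random() < frac_intermediate:
            p = rng.beta(2, 2)
        elif lab == 1:
            p = 1.0 - heterogeneity * rng.beta(1, 4)
        else:
            p = heterogeneity * rng.beta(1, 4)
        cov1 = int(rng.integers(lo, hi + 1))
        cov2 = int(rng.integers(lo, hi + 1))
        pct1 = rng.binomial(cov1, p) / cov1
        pct2 = rng.binomial(cov2, p) / cov2
        sites.append(BisulfiteSite(contig, pos, strand, cov1, cov2, pct1, pct2))
    return sites


# ---------------------------------------------------------------------------
# Correlated CpG methylome (cluster-network study inputs)
# ---------------------------------------------------------------------------

def simulate_correlated_methylome(
    reference: Mapping[str, str],
    block_mean_len: int = 600,
    high_beta: tuple[float, float] = (18.0, 2.0),
    low_beta: tuple[float, float] = (2.0, 18.0),
    seed: int = 0,
) -> tuple[dict[tuple[str, int, str], float], dict[tuple[str, int, str], int]]:
    """Blockwise-correlated CpG methylation levels.

    The genome is partitioned into blocks of exponentially distributed
    length; each block is fully methylated-leaning or unmethylated-leaning,
    and every CpG in a block (both strands) shares the block's level drawn
    from the corresponding beta distribution.  Returns (true level per CpG
    site, binary block label per CpG site).
    """
    rng = np.random.default_rng(seed)
    sites = label_from_motifs(reference, "CG", 0, control="negative")
    levels: dict[tuple[str, int, str], float] = {}
    labels: dict[tuple[str, int, str], int] = {}
    for contig, seq in reference.items():
        L = len(seq)
        edges = [0]
        while edges[-1] < L:
            edges.append(edges[-1] + 1 + int(rng.exponential(block_mean_len)))
        edges = np.array(edges)
        n_blocks = len(edges) - 1
        high = rng.random(n_blocks) < 0.5
        level = np.where(
            high,
            rng.beta(*high_beta, n_blocks),
            rng.beta(*low_beta, n_blocks),
        )
        for (c, pos, strand) in sites:
            if c != contig:
                continue
            b = int(np.searchsorted(edges, pos, side="right") - 1)
            levels[(c, pos, strand)] = float(level[b])
            labels[(c, pos, strand)] = int(high[b])
    return levels, labels


def simulate_raw_predictions(
    levels: Mapping[tuple[str, int, str], float],
    coverage: int = 10,
    per_read_error: float = 0.1,
    seed: int = 0,
):
    """Noisy per-site summaries mimicking the classifier's raw output.

    Each of ``coverage`` reads calls the site modified with probability
    ``p*(1-e) + (1-p)*e`` where ``p`` is the true level and ``e`` the
    per-read call error rate.
    """
    from .summary import SiteSummary

    rng = np.random.default_rng(seed)
    out = {}
    e = per_read_error
    for key in sorted(levels):
        p = levels[key] * (1 - e) + (1 - levels[key]) * e
        mod = int(rng.binomial(coverage, p))
        contig, pos, strand = key
        out[key] = SiteSummary(contig, pos, strand, coverage, mod, "5mC")
    return out


def simulate_bisulfite_targets(
    levels: Mapping[tuple[str, int, str], float],
    coverage: int = 30,
    seed: int = 0,
) -> dict[tuple[str, int, str], float]:
    """Bisulfite methylation percentages at high coverage (training targets)."""
    rng = np.random.default_rng(seed)
    return {
        key: float(rng.binomial(coverage, levels[key]) / coverage)
        for key in sorted(levels)
    }
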
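"""Anchoring read events to reference positions and building truth labels.

Alignment itself is delegated to an external aligner (BWA-MEM or minimap2);
this module consumes SAM/BAM records, walks their CIGAR to tie each merged
event (read base) to a reference contig/position/strand, filters poorly
mapped reads, and derives per-site ground-truth modification labels either
from sequence motifs (enzyme-treated positive / PCR negative controls) or
from replicate bisulfite tables (complete methylation / un-methylation).

Coordinates are 0-based throughout; BED output is 0-based half-open.  For
reverse-strand alignments the stored reference base is the complement of
the forward-strand base — the base in the molecule's reading sense — and
sites are summarized on the '-' strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .events import MergedEvents

logger = logging.getLogger(__name__)

__all__ = [
    "AnchoredEvent",
    "AnchoredRead",
    "BisulfiteSite",
    "complement",
    "revcomp",
    "load_fasta",
    "anchor_read",
    "filter_alignments",
    "label_from_motifs",
    "label_from_bisulfite",
    "count_motif_occurrences",
    "read_bisulfite_table",
    "write_bisulfite_table",
    "write_truth_bed",
    "read_truth_bed",
]

_COMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))


def revcomp(seq: str) -> str:
    return complement(seq)[::-1]


def load_fasta(path: str | Path) -> dict[str, str]:
    """Load a reference FASTA into a dict of upper-case contig sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass(frozen=True)
class AnchoredEvent:
    """A merged event tied to a reference position.

    ``ref_base`` is read-sense: complemented for reverse-strand alignments.
    """

    read_offset: int
    contig: str
    ref_pos: int
    strand: str
    ref_base: str
    is_match: bool
    mean: float
    stdv: float
    n_samples: int


class AnchoredRead:
    """Per-read anchoring result, aligned index-for-index with its events.

    ``ref_pos[i] == -1`` marks an unanchored event (insertion or soft-clip).
    Iterating yields one :class:`AnchoredEvent` per anchored event, i.e. one
    per match/mismatch column of the CIGAR.
    """

    def __init__(
        self,
        read_id: str,
        contig: str,
        strand: str,
        events: MergedEvents,
        ref_pos: np.ndarray,
        ref_base: np.ndarray,
        is_match: np.ndarray,
    ):
        self.read_id = read_id
        self.contig = contig
        self.strand = strand
        self.events = events
        self.ref_pos = ref_pos
        self.ref_base = ref_base
        self.is_match = is_match

    @property
    def anchored_mask(self) -> np.ndarray:
        return self.ref_pos >= 0

    def __len__(self) -> int:
        return int(self.anchored_mask.sum())

    def __iter__(self) -> Iterator[AnchoredEvent]:
        ev = self.events
        for i in np.flatnonzero(self.anchored_mask):
            yield AnchoredEvent(
                int(i),
                self.contig,
                int(self.ref_pos[i]),
                self.strand,
                self.ref_base[i].decode(),
                bool(self.is_match[i]),
                float(ev.mean[i]),
                float(ev.stdv[i]),
                int(ev.n_samples[i]),
            )


# CIGAR op codes (pysam convention)
_CIG_M, _CIG_I, _CIG_D, _CIG_N, _CIG_S, _CIG_H, _CIG_P, _CIG_EQ, _CIG_X = range(9)
_QUERY_OPS = {_CIG_M, _CIG_I, _CIG_S, _CIG_EQ, _CIG_X}
_REF_OPS = {_CIG_M, _CIG_D, _CIG_EQ, _CIG_X}
_ALIGN_OPS = {_CIG_M, _CIG_EQ, _CIG_X}


def anchor_read(
    read_sequence: str,
    merged_events: MergedEvents,
    alignment_record,
    reference: Mapping[str, str],
) -> AnchoredRead:
    """Walk an alignment's CIGAR and anchor each aligned read base.

    Parameters
    ----------
    read_sequence
        The basecalled read sequence, in read (molecule) order; must match
        the record's query sequence (reverse-complemented for reverse-strand
        alignments), soft clips included.
    merged_events
        The read's merged events; ``merged_events.sequence()`` must equal
        ``read_sequence``.
    alignment_record
        A ``pysam.AlignedSegment``.
    reference
        Mapping contig -> upper-case sequence.

    Match/mismatch columns produce anchors, insertions are skipped and
    deletions consume reference only.  Spliced (N) operators are rejected.
    """
    rec = alignment_record
    if rec.reference_name not in reference:
        raise KeyError(f"contig {rec.reference_name!r} absent from reference")
    if merged_events.sequence() != read_sequence:
        raise ValueError("merged events do not reconstruct the given read sequence")
    qseq = rec.query_sequence
    expected = revcomp(read_sequence) if rec.is_reverse else read_sequence
    if qseq is not None and qseq != expected:
        raise ValueError(
            f"read {rec.query_name}: query sequence does not match the "
            "reconstructed read sequence"
        )
    cigar = rec.cigartuples
    if cigar is None:
        raise ValueError(f"read {rec.query_name}: alignment has no CIGAR")
    qlen = sum(ln for op, ln in cigar if op in _QUERY_OPS)
    if qlen != len(read_sequence):
        raise ValueError(
            f"read {rec.query_name}: CIGAR query length {qlen} != read length "
            f"{len(read_sequence)}"
        )

    contig_seq = reference[rec.reference_name]
    n = len(read_sequence)
    ref_pos = np.full(n, -1, dtype=np.int64)
    ref_base = np.full(n, b"N", dtype="S1")

    qpos = 0
    rpos = rec.reference_start
    q_idx_parts: list[np.ndarray] = []
    r_idx_parts: list[np.ndarray] = []
    for op, ln in cigar:
        if op == _CIG_N:
            raise ValueError("spliced alignments (N operator) are not supported")
        if op in _ALIGN_OPS:
            q_idx_parts.append(np.arange(qpos, qpos + ln))
            r_idx_parts.append(np.arange(rpos, rpos + ln))
        if op in _QUERY_OPS:
            qpos += ln
        if op in _REF_OPS:
            rpos += ln
    if rpos > len(contig_seq):
        raise ValueError(
            f"read {rec.query_name}: alignment extends past the end of "
            f"{rec.reference_name}"
        )
    if not q_idx_parts:
        return AnchoredRead(
            rec.query_name, rec.reference_name, "-" if rec.is_reverse else "+",
            merged_events, ref_pos, ref_base, np.zeros(n, dtype=bool),
        )
    q_idx = np.concatenate(q_idx_parts)
    r_idx = np.concatenate(r_idx_parts)

    strand = "-" if rec.is_reverse else "+"
    # query offset -> read offset (reverse alignments store the revcomp)
    read_idx = (n - 1 - q_idx) if rec.is_reverse else q_idx

    contig_arr = np.frombuffer(contig_seq.encode(), dtype="S1")
    bases_fwd = contig_arr[r_idx]
    if rec.is_reverse:
        bases = np.frombuffer(bases_fwd.tobytes().translate(_COMP), dtype="S1")
    else:
        bases = bases_fwd
    ref_pos[read_idx] = r_idx
    ref_base[read_idx] = bases

    read_arr = np.frombuffer(read_sequence.encode(), dtype="S1")
    is_match = (ref_pos >= 0) & (ref_base == read_arr)
    return AnchoredRead(
        rec.query_name, rec.reference_name, strand, merged_events,
        ref_pos, ref_base, is_match,
    )


def filter_alignments(records: Iterable, min_mapq: int = 10) -> list:
    """Drop unmapped, secondary, supplementary and low-MAPQ alignments.

    The mapping-quality cutoff is strict: records with MAPQ < ``min_mapq``
    are removed, MAPQ == ``min_mapq`` is kept.
    """
    kept, dropped = [], 0
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            dropped += 1
            continue
        if rec.mapping_quality < min_mapq:
            dropped += 1
            continue
        kept.append(rec)
    logger.info("filter_alignments: kept %d, dropped %d", len(kept), dropped)
    return kept


def _scan_occurrences(seq: str, motif: str) -> list[int]:
    """All (overlapping) start offsets of ``motif`` in ``seq``."""
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def count_motif_occurrences(reference: Mapping[str, str], motif: str) -> int:
    """Total overlapping occurrences of a motif on the forward strands."""
    return sum(len(_scan_occurrences(seq, motif)) for seq in reference.values())


def label_from_motifs(
    reference: Mapping[str, str],
    motif: str,
    modified_offset: int,
    control: str = "positive",
    strands: str = "both",
) -> dict[tuple[str, int, str], int]:
    """Label every motif target base on the reference as (un)modified.

    Positive controls (enzyme-treated libraries) label the target base of
    every motif occurrence as modified; negative controls (PCR-amplified,
    modification-free) label the same positions unmodified.  Both strands
    are scanned: a reverse-strand site is an occurrence of the motif read
    along the reverse complement, reported at its forward coordinate with
    strand '-'.  Overlapping occurrences all count.
    """
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    if not 0 <= modified_offset < len(motif):
        raise ValueError("modified_offset outside motif")
    if control not in ("positive", "negative"):
        raise ValueError(f"control must be positive or negative, got {control!r}")
    label = 1 if control == "positive" else 0
    rc = revcomp(motif)
    labels: dict[tuple[str, int, str], int] = {}
    for contig, seq in reference.items():
        if strands in ("both", "+"):
            for occ in _scan_occurrences(seq, motif):
                labels[(contig, occ + modified_offset, "+")] = label
        if strands in ("both", "-"):
            for occ in _scan_occurrences(seq, rc):
                pos = occ + len(motif) - 1 - modified_offset
                labels[(contig, pos, "-")] = label
    return labels


@dataclass(frozen=True)
class BisulfiteSite:
    """Per-site replicate bisulfite measurements (percentages in [0, 1])."""

    contig: str
    ref_pos: int
    strand: str
    coverage_rep1: int
    coverage_rep2: int
    pct_rep1: float
    pct_rep2: float

    def __post_init__(self) -> None:
        for p in (self.pct_rep1, self.pct_rep2):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"bisulfite percentage {p} outside [0, 1]")


def label_from_bisulfite(
    sites: Sequence[BisulfiteSite],
    min_pct: float = 0.90,
    min_cov: int = 1,
    inclusive: bool = True,
) -> dict[tuple[str, int, str], int]:
    """Complete-methylation labeling from duplicate bisulfite data.

    A site is labeled modified iff its methylation percentage passes
    ``min_pct`` (>= by default; strict > with ``inclusive=False``) in BOTH
    replicates at coverage >= ``min_cov`` in both; it is labeled unmodified
    iff the percentage is exactly 0 in both replicates.  Any other site is
    excluded (no label).
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    labels: dict[tuple[str, int, str], int] = {}
    for s in sites:
        key = (s.contig, s.ref_pos, s.strand)
        if s.pct_rep1 == 0.0 and s.pct_rep2 == 0.0:
            labels[key] = 0
        else:
            ok1 = s.pct_rep1 >= min_pct if inclusive else s.pct_rep1 > min_pct
            ok2 = s.pct_rep2 >= min_pct if inclusive else s.pct_rep2 > min_pct
            if ok1 and ok2 and s.coverage_rep1 >= min_cov and s.coverage_rep2 >= min_cov:
                labels[key] = 1
    return labels


BISULFITE_COLUMNS = ["contig", "pos", "strand", "cov1", "pct1", "cov2", "pct2"]


def write_bisulfite_table(sites: Sequence[BisulfiteSite], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            (s.contig, s.ref_pos, s.strand, s.coverage_rep1, s.pct_rep1,
             s.coverage_rep2, s.pct_rep2)
            for s in sites
        ],
        columns=BISULFITE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_bisulfite_table(path: str | Path, one_based: bool = False) -> list[BisulfiteSite]:
    """Read a replicate bisulfite TSV; ``one_based=True`` shifts positions."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BISULFITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bisulfite table missing column(s): {', '.join(missing)}")
    shift = 1 if one_based else 0
    return [
        BisulfiteSite(
            str(r.contig), int(r.pos) - shift, str(r.strand),
            int(r.cov1), int(r.cov2), float(r.pct1), float(r.pct2),
        )
        for r in df.itertuples()
    ]


def write_truth_bed(labels: Mapping[tuple[str, int, str], int], path: str | Path) -> None:
    """Write truth labels as BED6: name is the label, score 1000*label."""
    rows = sorted(labels.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
    with open(path, "w") as fh:
        for (contig, pos, strand), lab in rows:
            name = "modified" if lab else "unmodified"
            fh.write(f"{contig}\t{pos}\t{pos + 1}\t{name}\t{1000 * lab}\t{strand}\n")


def read_truth_bed(path: str | Path) -> dict[tuple[str, int, str], int]:
    labels: dict[tuple[str, int, str], int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected >= 6 BED columns")
            contig, start, _end, name, _score, strand = parts[:6]
            labels[(contig, int(start), strand)] = 1 if name == "modified" else 0
    return labels
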
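"""Feature encoding and window assembly.

Each anchored event is described by 7 features: the normalized signal mean
``f_m``, the signal standard deviation ``f_d``, the number of raw samples
``f_l``, and a one-hot 4-vector of the mapped reference base, in the fixed
order ``[f_m, f_d, f_l, f_A, f_C, f_G, f_T]``.  The optional extended mode
appends a 50-bin histogram of the event's normalized samples over [-5, 5]
(57 features total).

A classification instance is a window of ``w`` consecutive events of the
same read (w odd, default 21) centered on the base of interest; neighbors
are consecutive *read* events, so reference deletions do not introduce gap
rows.  Rows beyond the read ends are zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .anchor import AnchoredEvent, AnchoredRead, revcomp

__all__ = [
    "FeatureWindow",
    "WindowSet",
    "encode_event",
    "encode_event_extended",
    "encode_read",
    "make_window",
    "build_dataset",
]

BASE_ORDER = b"ACGT"
N_BINS_EXTENDED = 50
DEFAULT_W = 21


def encode_event(event: AnchoredEvent) -> np.ndarray:
    """7-feature vector ``[f_m, f_d, f_l, f_A, f_C, f_G, f_T]`` of one event."""
    idx = BASE_ORDER.find(event.ref_base.encode())
    if idx < 0:
        raise ValueError(f"ambiguous reference base {event.ref_base!r}")
    out = np.zeros(7)
    out[0] = event.mean
    out[1] = event.stdv
    out[2] = event.n_samples
    out[3 + idx] = 1.0
    return out


def _histogram50(samples: np.ndarray, n_bins: int = N_BINS_EXTENDED) -> np.ndarray:
    """Equal-width bins over [-5, 5], half-open with the last bin closed,
    normalized to sum to 1."""
    x = np.clip(np.asarray(samples, dtype=np.float64), -5.0, 5.0)
    idx = np.minimum(((x + 5.0) / (10.0 / n_bins)).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    return counts / counts.sum()


def encode_event_extended(
    event: AnchoredEvent,
    samples: np.ndarray | None = None,
    n_bins: int = N_BINS_EXTENDED,
) -> np.ndarray:
    """7-feature vector plus an ``n_bins`` histogram of normalized samples."""
    if samples is None:
        raise ValueError(
            "event carries no raw samples; extended encoding requires them "
            "(use the 7-feature mode for statistics-only inputs)"
        )
    if len(samples) == 0:
        raise ValueError("event has no raw samples")
    return np.concatenate([encode_event(event), _histogram50(samples, n_bins)])


def encode_read(anchored: AnchoredRead, feature_mode: int = 7) -> np.ndarray:
    """Feature matrix (n_events x 7 or 57) for a whole read, float32.

    Unanchored events (insertions / soft clips) keep their signal features
    but get an all-zero base indicator.
    """
    ev = anchored.events
    n = len(ev)
    if feature_mode not in (7, 57):
        raise ValueError(f"feature_mode must be 7 or 57, got {feature_mode}")
    F = np.zeros((n, feature_mode), dtype=np.float32)
    F[:, 0] = ev.mean
    F[:, 1] = ev.stdv
    F[:, 2] = ev.n_samples
    codes = anchored.ref_base.view(np.uint8)
    for j, b in enumerate(BASE_ORDER):
        F[codes == b, 3 + j] = 1.0
    if feature_mode == 57:
        if ev.sample_bounds is None or ev.raw is None:
            raise ValueError(
                "read carries no raw samples; extended encoding requires them "
                "(use the 7-feature mode for statistics-only inputs)"
            )
        for i in range(n):
            F[i, 7:] = _histogram50(ev.event_samples(i))
    return F


@dataclass
class FeatureWindow:
    """A w x n_features matrix centered on the base of interest."""

    matrix: np.ndarray
    contig: str
    ref_pos: int
    strand: str
    read_id: str
    label: int | None = None  # 1 modified, 0 unmodified, None unlabeled

    @property
    def w(self) -> int:
        return self.matrix.shape[0]

    @property
    def center_index(self) -> int:
        return self.w // 2


def make_window(
    anchored: AnchoredRead,
    center: int,
    w: int = DEFAULT_W,
    feature_mode: int = 7,
    label: int | None = None,
    feature_matrix: np.ndarray | None = None,
) -> FeatureWindow:
    """Window of ``w`` consecutive events centered on event ``center``.

    Rows beyond the read ends are zero feature vectors.  ``feature_matrix``
    may be passed to reuse a precomputed :func:`encode_read` result.
    """
    if w % 2 == 0 or w < 1:
        raise ValueError(f"window width must be odd and positive, got {w}")
    F = encode_read(anchored, feature_mode) if feature_matrix is None else feature_matrix
    n = F.shape[0]
    if not 0 <= center < n:
        raise IndexError(f"center {center} outside read of {n} events")
    half = w // 2
    padded = np.zeros((n + 2 * half, F.shape[1]), dtype=F.dtype)
    padded[half : half + n] = F
    return FeatureWindow(
        padded[center : center + w].copy(),
        anchored.contig,
        int(anchored.ref_pos[center]),
        anchored.strand,
        anchored.read_id,
        label,
    )


class WindowSet:
    """Array-backed collection of labeled feature windows.

    ``y`` is 1 (modified), 0 (unmodified) or -1 (no truth label; kept for
    prediction mode only).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        contig: np.ndarray,
        pos: np.ndarray,
        strand: np.ndarray,
        read_id: np.ndarray,
    ):
        self.X = np.asarray(X, dtype=np.float32)
        self.y = np.asarray(y, dtype=np.int8)
        self.contig = np.asarray(contig)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.strand = np.asarray(strand)
        self.read_id = np.asarray(read_id)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def w(self) -> int:
        return self.X.shape[1]

    @property
    def n_features(self) -> int:
        return self.X.shape[2]

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(
            self.X[mask], self.y[mask], self.contig[mask],
            self.pos[mask], self.strand[mask], self.read_id[mask],
        )

    @classmethod
    def concat(cls, sets: Sequence["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValueError("nothing to concatenate")
        return cls(
            np.concatenate([s.X for s in sets]),
            np.concatenate([s.y for s in sets]),
            np.concatenate([s.contig for s in sets]),
            np.concatenate([s.pos for s in sets]),
            np.concatenate([s.strand for s in sets]),
            np.concatenate([s.read_id for s in sets]),
        )

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, X=self.X, y=self.y, contig=self.contig.astype("U"),
            pos=self.pos, strand=self.strand.astype("U"), read_id=self.read_id.astype("U"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "WindowSet":
        with np.load(path) as z:
            return cls(z["X"], z["y"], z["contig"], z["pos"], z["strand"], z["read_id"])


def _motif_context_mask(
    contig_arr: np.ndarray,
    positions: np.ndarray,
    strand: str,
    motif: str,
    offset: int,
) -> np.ndarray:
    """True where ``positions`` sit at the modified offset of the motif.

    The motif is given in the molecule's reading sense, so reverse-strand
    sites are occurrences of its reverse complement on the forward sequence.
    """
    L = len(contig_arr)
    if strand == "+":
        pat, rel = motif.encode(), offset
    else:
        pat, rel = revcomp(motif).encode(), len(motif) - 1 - offset
    starts = positions - rel
    ok = (starts >= 0) & (starts + len(pat) <= L)
    mask = np.zeros(len(positions), dtype=bool)
    if ok.any():
        idx = starts[ok, None] + np.arange(len(pat))
        mask[ok] = np.all(contig_arr[idx] == np.frombuffer(pat, dtype="S1"), axis=1)
    return mask


def build_dataset(
    anchored_reads: Sequence[AnchoredRead],
    truth_labels: Mapping[tuple[str, int, str], int] | None,
    target_base: str,
    motif_restriction: tuple[str, int] | None = None,
    reference: Mapping[str, str] | None = None,
    w: int = DEFAULT_W,
    feature_mode: int = 7,
    region: tuple[str, int, int] | None = None,
    keep_unlabeled: bool = False,
    require_label: bool = True,
) -> WindowSet:
    """Assemble one window per anchored target-base event.

    ``truth_labels`` maps (contig, ref_pos, strand) to 1/0; windows whose
    site has no label are excluded unless ``keep_unlabeled`` (prediction
    mode).  ``motif_restriction=(motif, offset)`` keeps only events whose
    reference context matches the motif in the molecule's reading sense
    (requires ``reference``).  ``region=(contig, lo, hi)`` keeps windows
    centered in [lo, hi).
    """
    if target_base not in "ACGT" or len(target_base) != 1:
        raise ValueError(f"target_base must be one of A/C/G/T, got {target_base!r}")
    if motif_restriction is not None and reference is None:
        raise ValueError("motif_restriction requires the reference")
    half = w // 2
    parts: list[WindowSet] = []
    tbyte = target_base.encode()
    contig_cache: dict[str, np.ndarray] = {}
    for ar in anchored_reads:
        F = encode_read(ar, feature_mode)
        centers = np.flatnonzero((ar.ref_pos >= 0) & (ar.ref_base == tbyte))
        if len(centers) == 0:
            continue
        pos = ar.ref_pos[centers]
        if region is not None:
            rc, lo, hi = region
            keep = (ar.contig == rc) & (pos >= lo) & (pos < hi)
            centers, pos = centers[keep], pos[keep]
        if motif_restriction is not None and len(centers):
            if ar.contig not in contig_cache:
                contig_cache[ar.contig] = np.frombuffer(
                    reference[ar.contig].encode(), dtype="S1"
                )
            m = _motif_context_mask(
                contig_cache[ar.contig], pos, ar.strand, *motif_restriction
            )
            centers, pos = centers[m], pos[m]
        if len(centers) == 0:
            continue
        if truth_labels is not None:
            y = np.array(
                [truth_labels.get((ar.contig, int(p), ar.strand), -1) for p in pos],
                dtype=np.int8,
            )
        else:
            y = np.full(len(centers), -1, dtype=np.int8)
        if not keep_unlabeled:
            m = y >= 0
            centers, pos, y = centers[m], pos[m], y[m]
            if len(centers) == 0:
                continue
        n = F.shape[0]
        padded = np.zeros((n + 2 * half, F.shape[1]), dtype=F.dtype)
        padded[half : half + n] = F
        X = padded[centers[:, None] + np.arange(w)]
        parts.append(
            WindowSet(
                X, y,
                np.full(len(centers), ar.contig, dtype=object),
                pos,
                np.full(len(centers), ar.strand),
                np.full(len(centers), ar.read_id, dtype=object),
            )
        )
    if not parts:
        if require_label:
            raise ValueError("no labeled windows could be built from these reads")
        return WindowSet(
            np.zeros((0, w, feature_mode), np.float32), np.zeros(0, np.int8),
            np.zeros(0, object), np.zeros(0, np.int64), np.zeros(0, "U1"),
            np.zeros(0, object),
        )
    out = WindowSet.concat(parts)
    if require_label and not (out.y >= 0).any():
        raise ValueError("no labeled windows could be built from these reads")
    return out
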
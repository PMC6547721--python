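"""Basecalled nanopore event handling.

A basecaller segments the raw ionic-current trace of a read into *events*,
each attributed to one pore state (k-mer) and annotated with a ``move``:
``move >= 1`` means new bases were emitted, ``move == 0`` is a *stay* (the
pore state did not advance).  This module reads event tables (portable TSV
or FAST5/HDF5), merges stay events into their preceding move event,
normalizes raw signal to the [-5, 5] range, and recomputes per-event
summary statistics.

Population-variance convention (divide by n) is used throughout so that
single-sample events have a well-defined standard deviation of 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "RawEvent",
    "MergedEvent",
    "EventTable",
    "MergedEvents",
    "ReadSignal",
    "normalize_signals",
    "normalize_event_stats",
    "merge_stay_events",
    "summarize_event",
    "read_event_table",
    "write_event_table",
    "read_fast5",
    "write_fast5",
]

# MAD of a unit normal is 1/1.4826; the factor makes the scale estimate
# consistent with the standard deviation under normality.
MAD_SCALE = 1.4826
SIGNAL_CLIP = 5.0

EVENT_TSV_COLUMNS = ["read_id", "start_index", "n_samples", "move", "kmer", "mean", "stdv"]


@dataclass(frozen=True)
class RawEvent:
    """One basecaller event before stay-merging."""

    start_index: int
    n_samples: int
    move: int
    kmer: str
    mean: float
    stdv: float

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"event n_samples must be >= 1, got {self.n_samples}")
        if self.move < 0:
            raise ValueError(f"event move must be >= 0, got {self.move}")


@dataclass(frozen=True)
class MergedEvent:
    """One read base after stay-merging.

    ``shared`` marks bases emitted by a move > 1 event: they carry the same
    pooled statistics as the final base of that event.
    """

    base: str
    mean: float
    stdv: float
    n_samples: int
    read_offset: int
    shared: bool = False


class EventTable:
    """Struct-of-arrays container for the raw events of one read."""

    def __init__(
        self,
        start_index: np.ndarray,
        n_samples: np.ndarray,
        move: np.ndarray,
        kmers: np.ndarray,
        mean: np.ndarray,
        stdv: np.ndarray,
    ):
        self.start_index = np.asarray(start_index, dtype=np.int64)
        self.n_samples = np.asarray(n_samples, dtype=np.int64)
        self.move = np.asarray(move, dtype=np.int64)
        kmers = np.asarray(kmers)
        if kmers.dtype.kind != "S":
            kmers = kmers.astype("S")
        self.kmers = kmers
        self.mean = np.asarray(mean, dtype=np.float64)
        self.stdv = np.asarray(stdv, dtype=np.float64)
        if np.any(self.n_samples < 1):
            raise ValueError("all events must have n_samples >= 1")

    @classmethod
    def from_events(cls, events: Sequence[RawEvent]) -> "EventTable":
        if len(events) == 0:
            return cls(
                np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64),
                np.empty(0, "S1"), np.empty(0), np.empty(0),
            )
        k = max(len(e.kmer) for e in events)
        return cls(
            np.array([e.start_index for e in events], np.int64),
            np.array([e.n_samples for e in events], np.int64),
            np.array([e.move for e in events], np.int64),
            np.array([e.kmer.encode() for e in events], f"S{k}"),
            np.array([e.mean for e in events], np.float64),
            np.array([e.stdv for e in events], np.float64),
        )

    def __len__(self) -> int:
        return len(self.move)

    def __getitem__(self, i: int) -> RawEvent:
        return RawEvent(
            int(self.start_index[i]),
            int(self.n_samples[i]),
            int(self.move[i]),
            self.kmers[i].decode(),
            float(self.mean[i]),
            float(self.stdv[i]),
        )

    def __iter__(self) -> Iterator[RawEvent]:
        return (self[i] for i in range(len(self)))


class MergedEvents:
    """Struct-of-arrays container for the merged events of one read.

    One entry per read base, in read order.  ``sample_bounds`` (optional)
    gives, per event, the [start, stop) slice into the read's normalized
    raw-signal array, enabling the extended per-sample feature encoding.
    """

    def __init__(
        self,
        base: np.ndarray,
        mean: np.ndarray,
        stdv: np.ndarray,
        n_samples: np.ndarray,
        shared: np.ndarray | None = None,
        sample_bounds: np.ndarray | None = None,
        raw: np.ndarray | None = None,
    ):
        self.base = np.asarray(base, dtype="S1")
        self.mean = np.asarray(mean, dtype=np.float64)
        self.stdv = np.asarray(stdv, dtype=np.float64)
        self.n_samples = np.asarray(n_samples, dtype=np.int64)
        n = len(self.base)
        self.read_offset = np.arange(n, dtype=np.int64)
        self.shared = (
            np.zeros(n, dtype=bool) if shared is None else np.asarray(shared, dtype=bool)
        )
        self.sample_bounds = sample_bounds  # (n, 2) int array or None
        self.raw = raw  # normalized samples backing sample_bounds

    def __len__(self) -> int:
        return len(self.base)

    def __getitem__(self, i: int) -> MergedEvent:
        return MergedEvent(
            self.base[i].decode(),
            float(self.mean[i]),
            float(self.stdv[i]),
            int(self.n_samples[i]),
            int(self.read_offset[i]),
            bool(self.shared[i]),
        )

    def __iter__(self) -> Iterator[MergedEvent]:
        return (self[i] for i in range(len(self)))

    def sequence(self) -> str:
        """Reconstructed read sequence (one base per merged event)."""
        return self.base.tobytes().decode()

    def event_samples(self, i: int) -> np.ndarray:
        """Normalized raw samples backing event ``i`` (requires raw signal)."""
        if self.sample_bounds is None or self.raw is None:
            raise ValueError(
                "raw samples unavailable for this read; use the 7-feature mode"
            )
        lo, hi = self.sample_bounds[i]
        return self.raw[lo:hi]


@dataclass
class ReadSignal:
    """A read's raw current samples (optional) and its basecaller events."""

    read_id: str
    raw: np.ndarray | None
    events: EventTable

    def __post_init__(self) -> None:
        if self.raw is not None:
            self.raw = np.asarray(self.raw, dtype=np.float64)
            if len(self.events):
                last = self.events.start_index[-1] + self.events.n_samples[-1]
                if last > len(self.raw):
                    raise ValueError(
                        f"read {self.read_id}: events address {last} samples "
                        f"but raw signal has only {len(self.raw)}"
                    )


def normalize_signals(raw: Sequence[float] | np.ndarray) -> np.ndarray:
    """Normalize a read's raw signal to the range [-5, 5].

    Median-center, scale by MAD * 1.4826, then clip.  The result is
    invariant under positive affine transforms of the input.  Degenerate
    spreads fall back to the standard deviation, then to all-zeros.
    """
    x = np.asarray(raw, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty signal")
    med = np.median(x)
    scale = np.median(np.abs(x - med)) * MAD_SCALE
    if scale == 0.0:
        scale = x.std()
    if scale == 0.0:
        return np.zeros_like(x)
    return np.clip((x - med) / scale, -SIGNAL_CLIP, SIGNAL_CLIP)


def normalize_event_stats(
    means: np.ndarray, stdvs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize stored per-event statistics when raw samples are absent.

    The per-read median/MAD of the event means defines the affine map; the
    same scale factor is applied to the standard deviations.
    """
    means = np.asarray(means, dtype=np.float64)
    stdvs = np.asarray(stdvs, dtype=np.float64)
    if means.size == 0:
        raise ValueError("empty signal")
    med = np.median(means)
    scale = np.median(np.abs(means - med)) * MAD_SCALE
    if scale == 0.0:
        scale = means.std()
    if scale == 0.0:
        return np.zeros_like(means), np.zeros_like(stdvs)
    return (
        np.clip((means - med) / scale, -SIGNAL_CLIP, SIGNAL_CLIP),
        stdvs / scale,
    )


def summarize_event(samples: Sequence[float] | np.ndarray) -> tuple[float, float, int]:
    """Mean, population standard deviation and count of an event's samples."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty event: no samples")
    return float(x.mean()), float(x.std()), int(x.size)


def _kmer_char_matrix(kmers: np.ndarray) -> np.ndarray:
    """(n, k) uint8 view of an ``S{k}`` k-mer array."""
    k = kmers.dtype.itemsize
    return kmers.view("S1").reshape(len(kmers), k)


def merge_stay_events(
    events: EventTable | Sequence[RawEvent],
    raw: np.ndarray | None = None,
    leading_stay: str = "error",
) -> MergedEvents:
    """Merge stay events (move == 0) into the preceding move event.

    Parameters
    ----------
    events
        Events in read order.  The first event must have ``move >= 1``
        unless ``leading_stay="attach"``, in which case leading stays are
        attached to the first move event.
    raw
        The read's **normalized** raw samples.  When given, pooled means and
        population standard deviations are recomputed from the samples each
        merged event spans; otherwise they are pooled from the stored
        (already normalized) per-event statistics, sample-count weighted.

    Events with ``move == m > 1`` emit the last ``m`` bases of their k-mer;
    the pooled statistics are attributed to every emitted base, with all but
    the last flagged ``shared``.  Total sample count is conserved.
    """
    if not isinstance(events, EventTable):
        events = EventTable.from_events(list(events))
    n = len(events)
    if n == 0:
        return MergedEvents(
            np.empty(0, "S1"), np.empty(0), np.empty(0), np.empty(0, np.int64)
        )
    move = events.move
    if move[0] == 0:
        if leading_stay == "error":
            raise ValueError("read starts with a stay event (move == 0)")
        if leading_stay != "attach":
            raise ValueError(f"unknown leading_stay policy {leading_stay!r}")

    # ``heads`` are the move events (base/k-mer source); sample pooling may
    # start earlier when leading stays are attached to the first move event
    heads = np.flatnonzero(move >= 1)
    sample_starts = heads.copy()
    if move[0] == 0:  # leading_stay == "attach"
        sample_starts[0] = 0

    pooled_n = np.add.reduceat(events.n_samples, sample_starts)
    if raw is not None:
        raw = np.asarray(raw, dtype=np.float64)
        bounds_lo = events.start_index[sample_starts]
        bounds_hi = bounds_lo + pooled_n
        csum = np.concatenate([[0.0], np.cumsum(raw)])
        csum2 = np.concatenate([[0.0], np.cumsum(raw * raw)])
        s1 = csum[bounds_hi] - csum[bounds_lo]
        s2 = csum2[bounds_hi] - csum2[bounds_lo]
        pooled_mean = s1 / pooled_n
        pooled_var = np.maximum(s2 / pooled_n - pooled_mean**2, 0.0)
        pooled_std = np.sqrt(pooled_var)
    else:
        # pool stored statistics: E[x] and E[x^2] are sample-count weighted
        w = events.n_samples.astype(np.float64)
        s1 = np.add.reduceat(w * events.mean, sample_starts)
        s2 = np.add.reduceat(w * (events.stdv**2 + events.mean**2), sample_starts)
        pooled_mean = s1 / pooled_n
        pooled_std = np.sqrt(np.maximum(s2 / pooled_n - pooled_mean**2, 0.0))
        bounds_lo = bounds_hi = None

    moves_g = np.maximum(move[heads], 1)
    kchars = _kmer_char_matrix(events.kmers)

    if np.all(moves_g == 1):
        base = kchars[heads, -1].view("S1")
        merged = MergedEvents(
            base,
            pooled_mean,
            pooled_std,
            pooled_n,
            sample_bounds=(
                np.column_stack([bounds_lo, bounds_hi]) if raw is not None else None
            ),
            raw=raw,
        )
        return merged

    # general path: move > 1 events emit several bases sharing the stats
    reps = moves_g
    mean_out = np.repeat(pooled_mean, reps)
    std_out = np.repeat(pooled_std, reps)
    n_out = np.repeat(pooled_n, reps)
    shared = np.ones(int(reps.sum()), dtype=bool)
    last_of_group = np.cumsum(reps) - 1
    shared[last_of_group] = False
    bases = []
    k = kchars.shape[1]
    for g, start in enumerate(heads):
        m = int(moves_g[g])
        if m > k:
            raise ValueError(f"move {m} exceeds k-mer length {k}")
        bases.append(kchars[start, k - m :])
    base = np.concatenate(bases).view("S1")
    sb = None
    if raw is not None:
        sb = np.repeat(np.column_stack([bounds_lo, bounds_hi]), reps, axis=0)
    return MergedEvents(base, mean_out, std_out, n_out, shared=shared, sample_bounds=sb, raw=raw)


# ---------------------------------------------------------------------------
# IO: portable event TSV and FAST5/HDF5
# ---------------------------------------------------------------------------

def write_event_table(reads: Iterable[ReadSignal], path: str | Path) -> None:
    """Write reads to the portable tab-separated event dialect.

    Columns: read_id, start_index, n_samples, move, kmer, mean, stdv.
    Raw samples are not representable in this dialect.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EVENT_TSV_COLUMNS)
        for read in reads:
            ev = read.events
            for i in range(len(ev)):
                w.writerow(
                    [
                        read.read_id,
                        int(ev.start_index[i]),
                        int(ev.n_samples[i]),
                        int(ev.move[i]),
                        ev.kmers[i].decode(),
                        repr(float(ev.mean[i])),
                        repr(float(ev.stdv[i])),
                    ]
                )


def _read_event_tsv(path: str | Path) -> list[ReadSignal]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "kmer": str},
                     float_precision="round_trip")
    missing = [c for c in EVENT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} is missing column(s): {', '.join(missing)}")
    bad = df["n_samples"] < 1
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"malformed event row {row + 2} (read {df['read_id'].iloc[row]}): n_samples < 1"
        )
    reads = []
    for read_id, grp in df.groupby("read_id", sort=False):
        k = int(grp["kmer"].str.len().max())
        table = EventTable(
            grp["start_index"].to_numpy(np.int64),
            grp["n_samples"].to_numpy(np.int64),
            grp["move"].to_numpy(np.int64),
            grp["kmer"].to_numpy().astype(f"S{k}"),
            grp["mean"].to_numpy(np.float64),
            grp["stdv"].to_numpy(np.float64),
        )
        reads.append(ReadSignal(str(read_id), None, table))
    return reads


# Albacore-2.x-like single-read FAST5 layout
FAST5_EVENTS_PATH = "Analyses/Basecall_1D_000/BaseCalled_template/Events"
FAST5_RAW_GROUP = "Raw/Reads"


def write_fast5(
    reads: Iterable[ReadSignal],
    path: str | Path,
    events_path: str = FAST5_EVENTS_PATH,
    raw_group: str = FAST5_RAW_GROUP,
) -> None:
    """Write reads into one HDF5 container, one top-level group per read."""
    import h5py

    with h5py.File(path, "w") as fh:
        for read in reads:
            g = fh.create_group(f"read_{read.read_id}")
            ev = read.events
            dt = np.dtype(
                [
                    ("start", "<i8"),
                    ("length", "<i8"),
                    ("move", "<i8"),
                    ("model_state", f"S{ev.kmers.dtype.itemsize}"),
                    ("mean", "<f8"),
                    ("stdv", "<f8"),
                ]
            )
            rec = np.empty(len(ev), dtype=dt)
            rec["start"] = ev.start_index
            rec["length"] = ev.n_samples
            rec["move"] = ev.move
            rec["model_state"] = ev.kmers
            rec["mean"] = ev.mean
            rec["stdv"] = ev.stdv
            g.create_dataset(events_path, data=rec)
            if read.raw is not None:
                g.create_dataset(f"{raw_group}/Read_{read.read_id}/Signal", data=read.raw)


def read_fast5(
    path: str | Path,
    events_path: str = FAST5_EVENTS_PATH,
    raw_group: str = FAST5_RAW_GROUP,
) -> list[ReadSignal]:
    import h5py

    reads = []
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"unreadable HDF5 container {path}: {exc}") from exc
    with fh:
        for name in fh:
            if not name.startswith("read_"):
                continue
            read_id = name[len("read_") :]
            g = fh[name]
            if events_path not in g:
                raise ValueError(f"read {read_id}: no events dataset at {events_path}")
            rec = g[events_path][()]
            for col in ("start", "length", "move", "model_state", "mean", "stdv"):
                if col not in rec.dtype.names:
                    raise ValueError(f"read {read_id}: events missing column {col!r}")
            raw = None
            raw_path = f"{raw_group}/Read_{read_id}/Signal"
            if raw_path in g:
                raw = np.asarray(g[raw_path][()], dtype=np.float64)
            table = EventTable(
                rec["start"].astype(np.int64),
                rec["length"].astype(np.int64),
                rec["move"].astype(np.int64),
                rec["model_state"],
                rec["mean"].astype(np.float64),
                rec["stdv"].astype(np.float64),
            )
            reads.append(ReadSignal(read_id, raw, table))
    return reads


def read_event_table(path: str | Path, format: str = "tsv", **kwargs) -> list[ReadSignal]:
    """Read basecalled events from ``tsv`` (portable dialect) or ``fast5``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_event_tsv(path)
    if format == "fast5":
        return read_fast5(path, **kwargs)
    raise ValueError(f"unknown event-table format {format!r} (expected tsv or fast5)")
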
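"""Strand-specific per-site aggregation of per-read modification calls.

Every anchored target base of every read contributes one count to its
reference position on the strand its read aligned to; predicted-modified
bases additionally increment the modification coverage.  The per-site
modification percentage is the exact ratio of the two counts.  Summaries
are written as a 9-column bedMethyl-like BED dialect::

    contig  start  end  name  score  strand  coverage  mod_coverage  pct

with 0-based half-open single-base intervals (end = start + 1) and
score = round(1000 * pct); the percentage is recomputed from the counts on
reading, so round trips are lossless.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SiteSummary",
    "accumulate",
    "accumulate_arrays",
    "write_bed",
    "read_bed",
    "threshold_calls",
]


@dataclass
class SiteSummary:
    contig: str
    ref_pos: int
    strand: str
    coverage: int
    mod_coverage: int
    name: str = "mod"

    def __post_init__(self) -> None:
        if not 0 <= self.mod_coverage <= self.coverage:
            raise ValueError(
                f"mod_coverage {self.mod_coverage} outside [0, coverage={self.coverage}]"
            )

    @property
    def pct(self) -> float:
        return self.mod_coverage / self.coverage if self.coverage else 0.0


def accumulate(
    predictions: Iterable[tuple[tuple[str, int, str], int]],
    name: str = "mod",
) -> dict[tuple[str, int, str], SiteSummary]:
    """Single-pass, order-independent accumulation of per-read calls.

    ``predictions`` yields ((contig, ref_pos, strand), label) with label 1
    for a modified call, 0 otherwise.
    """
    out: dict[tuple[str, int, str], SiteSummary] = {}
    for key, label in predictions:
        s = out.get(key)
        if s is None:
            contig, pos, strand = key
            s = out[key] = SiteSummary(contig, pos, strand, 0, 0, name)
        s.coverage += 1
        if label:
            s.mod_coverage += 1
    return out


def accumulate_arrays(
    contig: str,
    pos: np.ndarray,
    strand: np.ndarray,
    labels: np.ndarray,
    out: dict | None = None,
    name: str = "mod",
) -> dict[tuple[str, int, str], SiteSummary]:
    """Vectorized accumulation for many calls on one contig."""
    out = {} if out is None else out
    pos = np.asarray(pos, dtype=np.int64)
    strand = np.asarray(strand).astype("U1")
    labels = np.asarray(labels).astype(np.int64)
    for s in ("+", "-"):
        m = strand == s
        if not m.any():
            continue
        p = pos[m]
        lab = labels[m]
        uniq, inv = np.unique(p, return_inverse=True)
        cov = np.bincount(inv)
        mod = np.bincount(inv, weights=lab).astype(np.int64)
        for u, c, md in zip(uniq.tolist(), cov.tolist(), mod.tolist()):
            key = (contig, u, s)
            prev = out.get(key)
            if prev is None:
                out[key] = SiteSummary(contig, u, s, int(c), int(md), name)
            else:
                prev.coverage += int(c)
                prev.mod_coverage += int(md)
    return out


def write_bed(
    summaries: Mapping[tuple[str, int, str], SiteSummary], path: str | Path
) -> None:
    """Write summaries sorted by (contig, start, strand)."""
    rows = sorted(summaries.values(), key=lambda s: (s.contig, s.ref_pos, s.strand))
    with open(path, "w") as fh:
        for s in rows:
            fh.write(
                f"{s.contig}\t{s.ref_pos}\t{s.ref_pos + 1}\t{s.name}\t"
                f"{round(1000 * s.pct)}\t{s.strand}\t{s.coverage}\t"
                f"{s.mod_coverage}\t{s.pct:.6f}\n"
            )


def read_bed(path: str | Path) -> dict[tuple[str, int, str], SiteSummary]:
    out: dict[tuple[str, int, str], SiteSummary] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 BED columns, got {len(parts)}")
            try:
                contig, start, end, name, _score, strand, cov, mod, _pct = parts
                start, end, cov, mod = int(start), int(end), int(cov), int(mod)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed line: {exc}") from exc
            if end != start + 1:
                raise ValueError(f"{path}:{ln}: expected single-base interval")
            out[(contig, start, strand)] = SiteSummary(contig, start, strand, cov, mod, name)
    return out


def threshold_calls(
    summaries: Mapping[tuple[str, int, str], SiteSummary],
    min_pct: float = 0.1,
    min_cov: int = 1,
) -> dict[tuple[str, int, str], bool]:
    """Site-level binary calls: modified iff coverage >= min_cov and
    percentage >= min_pct; under-covered sites are excluded entirely."""
    out = {}
    for key, s in summaries.items():
        if s.coverage >= min_cov:
            out[key] = s.pct >= min_pct
    return out
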
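"""Neighborhood refinement of CpG methylation percentages.

CpG methylation is spatially correlated: a cytosine's methylation level
tracks that of nearby CpG sites and of the paired cytosine on the opposite
strand.  This module exploits that with a small fully connected network
that maps a 14-value description of a CpG site — its own predicted
percentage, the opposite-strand percentage, the number of CpG neighbors
within 25 bp, and an 11-bin histogram of the neighbors' predicted
percentages — to a refined methylation percentage through layers of
14 -> 100 -> 20 -> 1 units with a sigmoid output.  Dropout (rate 0.7) is
applied to the hidden layers during training only; training runs 100
epochs against replicate-bisulfite percentages, typically on one
chromosome, and is applied genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .anchor import complement

__all__ = [
    "ClusterNetConfig",
    "build_cluster_features",
    "build_cluster_matrix",
    "ClusterNet",
]

# neighbor-percentage bin edges: [0,.05), [.05,.15), ..., [.85,.95), [.95,1]
BIN_EDGES = np.concatenate([[0.0], np.arange(0.05, 1.0, 0.10), [1.0 + 1e-12]])
N_FEATURES = 14
NEIGHBOR_RADIUS = 25


@dataclass
class ClusterNetConfig:
    hidden1: int = 100
    hidden2: int = 20
    dropout: float = 0.7
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 256
    loss: str = "bce"  # or "mse"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.loss not in ("bce", "mse"):
            raise ValueError("loss must be 'bce' or 'mse'")


def _is_cpg(reference: Mapping[str, str], contig: str, pos: int, strand: str) -> bool:
    seq = reference[contig]
    if strand == "+":
        return pos + 1 < len(seq) and seq[pos : pos + 2] == "CG"
    return pos >= 1 and seq[pos - 1 : pos + 1] == "CG"


def build_cluster_features(
    site: tuple[str, int, str],
    summaries: Mapping[tuple[str, int, str], "SiteSummary"],
    reference: Mapping[str, str],
    radius: int = NEIGHBOR_RADIUS,
    include_both_strands: bool = False,
) -> np.ndarray:
    """14-value input vector for one CpG site.

    Neighbors are summarized CpG sites within ``radius`` bp (same strand by
    default), the site itself excluded.  With no neighbors the histogram is
    all zero; a missing opposite-strand prediction contributes 0.
    """
    contig, pos, strand = site
    if not _is_cpg(reference, contig, pos, strand):
        raise ValueError(f"{contig}:{pos}:{strand} is not a CpG cytosine in the reference")
    own = summaries[site].pct if site in summaries else 0.0
    opp_pos = pos + 1 if strand == "+" else pos - 1
    opp_key = (contig, opp_pos, "-" if strand == "+" else "+")
    opposite = summaries[opp_key].pct if opp_key in summaries else 0.0

    strands = ("+", "-") if include_both_strands else (strand,)
    neigh_pcts = []
    for p in range(pos - radius, pos + radius + 1):
        for s in strands:
            if (p, s) == (pos, strand):
                continue
            key = (contig, p, s)
            if key in summaries and _is_cpg(reference, contig, p, s):
                neigh_pcts.append(summaries[key].pct)
    out = np.zeros(N_FEATURES)
    out[0] = own
    out[1] = opposite
    out[2] = len(neigh_pcts)
    if neigh_pcts:
        idx = np.searchsorted(BIN_EDGES, np.asarray(neigh_pcts), side="right") - 1
        idx = np.clip(idx, 0, 10)
        out[3:] = np.bincount(idx, minlength=11) / len(neigh_pcts)
    return out


def build_cluster_matrix(
    sites: Sequence[tuple[str, int, str]],
    summaries: Mapping,
    reference: Mapping[str, str],
    radius: int = NEIGHBOR_RADIUS,
    include_both_strands: bool = False,
) -> np.ndarray:
    """Stacked cluster features for many sites (n_sites x 14)."""
    return np.stack(
        [
            build_cluster_features(s, summaries, reference, radius, include_both_strands)
            for s in sites
        ]
    )


class ClusterNet:
    """14 -> 100 -> 20 -> 1 refinement network (sigmoid output)."""

    def __init__(self, config: ClusterNetConfig | None = None):
        self.config = config or ClusterNetConfig()
        rng = np.random.default_rng(self.config.seed)
        c = self.config
        self.W1 = rng.normal(0, np.sqrt(2.0 / N_FEATURES), (N_FEATURES, c.hidden1))
        self.b1 = np.zeros(c.hidden1)
        self.W2 = rng.normal(0, np.sqrt(2.0 / c.hidden1), (c.hidden1, c.hidden2))
        self.b2 = np.zeros(c.hidden2)
        self.W3 = rng.normal(0, np.sqrt(2.0 / c.hidden2), (c.hidden2, 1))
        self.b3 = np.zeros(1)

    def zero_parameters(self) -> None:
        for p in (self.W1, self.b1, self.W2, self.b2, self.W3, self.b3):
            p[...] = 0.0

    @staticmethod
    def _sigmoid(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))

    def forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> np.ndarray | tuple:
        """Refined percentages in [0, 1].  Dropout is active only when a
        training ``rng`` is supplied (inverted dropout; evaluation is
        deterministic)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != N_FEATURES:
            raise ValueError(f"cluster features must have {N_FEATURES} values")
        keep = 1.0 - self.config.dropout
        h1 = np.maximum(X @ self.W1 + self.b1, 0.0)
        m1 = None
        if rng is not None:
            m1 = (rng.random(h1.shape) < keep) / keep
            h1 = h1 * m1
        h2 = np.maximum(h1 @ self.W2 + self.b2, 0.0)
        m2 = None
        if rng is not None:
            m2 = (rng.random(h2.shape) < keep) / keep
            h2 = h2 * m2
        z = h2 @ self.W3 + self.b3
        out = self._sigmoid(z)[:, 0]
        if rng is not None:
            return out, (X, h1, m1, h2, m2)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def train(
        self, X: np.ndarray, targets: np.ndarray, epochs: int | None = None
    ) -> list[float]:
        """Fit against bisulfite methylation percentages; returns the
        per-epoch loss trace."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        t = np.asarray(targets, dtype=np.float64)
        if len(X) == 0:
            raise ValueError("empty cluster-network training set")
        if np.any((t < 0) | (t > 1)):
            raise ValueError("targets must be percentages in [0, 1]")
        c = self.config
        n_epochs = epochs if epochs is not None else c.epochs
        rng = np.random.default_rng(c.seed)
        params = [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1m, b2m, eps, step = 0.9, 0.999, 1e-8, 0
        trace = []
        for _ in range(n_epochs):
            order = rng.permutation(len(X))
            losses = []
            for lo in range(0, len(X), c.batch_size):
                idx = order[lo : lo + c.batch_size]
                xb, tb = X[idx], t[idx]
                out, (xc, h1, m1, h2, m2) = self.forward(xb, rng=rng)
                B = len(xb)
                if c.loss == "bce":
                    p = np.clip(out, 1e-9, 1 - 1e-9)
                    losses.append(float(-(tb * np.log(p) + (1 - tb) * np.log(1 - p)).mean()))
                    dz = (out - tb)[:, None] / B  # sigmoid + BCE
                else:
                    losses.append(float(((out - tb) ** 2).mean()))
                    dz = (2 * (out - tb) * out * (1 - out))[:, None] / B
                dW3 = h2.T @ dz
                db3 = dz.sum(0)
                dh2 = dz @ self.W3.T
                if m2 is not None:
                    dh2 = dh2 * m2
                dh2 *= h2 > 0
                dW2 = h1.T @ dh2
                db2 = dh2.sum(0)
                dh1 = dh2 @ self.W2.T
                if m1 is not None:
                    dh1 = dh1 * m1
                dh1 *= h1 > 0
                dW1 = xc.T @ dh1
                db1 = dh1.sum(0)
                grads = [dW1, db1, dW2, db2, dW3, db3]
                step += 1
                lr_t = c.learning_rate * np.sqrt(1 - b2m**step) / (1 - b1m**step)
                for p, g, mm, vv in zip(params, grads, m, v):
                    mm *= b1m
                    mm += (1 - b1m) * g
                    vv *= b2m
                    vv += (1 - b2m) * g * g
                    p -= lr_t * mm / (np.sqrt(vv) + eps)
            trace.append(float(np.mean(losses)))
        return trace

    def refine(
        self,
        sites: Sequence[tuple[str, int, str]],
        summaries: Mapping,
        reference: Mapping[str, str],
        radius: int = NEIGHBOR_RADIUS,
    ) -> dict[tuple[str, int, str], float]:
        """Refined methylation percentage per site (site count unchanged)."""
        if not sites:
            return {}
        X = build_cluster_matrix(sites, summaries, reference, radius)
        out = self.predict(X)
        return {s: float(p) for s, p in zip(sites, out)}
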
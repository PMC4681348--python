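"""Detection of leading edges of transcription in gRNA-seq coverage.

A transcription unit shows up in strand-specific global RNA-seq as a plateau
of coverage whose 5' boundary is a sharp step-up — the "leading edge of
transcription".  This module detects such steps algorithmically: at each
position the mean depth over a window on the 5' side is compared with the
mean over a window on the 3' side (strand-aware), and positions where the
downstream/upstream fold change passes a threshold, with adequate absolute
downstream depth, are reported.  Overlapping candidate runs are thinned to
the locally strongest edge so a noisy shoulder yields one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks_io import FORWARD, REVERSE, CoverageTrack
from .ma_enrichment import TSSCluster


class EdgeError(ValueError):
    pass


@dataclass(frozen=True)
class TranscriptEdge:
    """A step-increase in coverage; ``position`` is the first high base."""

    position: int
    strand: str
    upstream_mean: float
    downstream_mean: float
    fold_change: float
    passed: bool


def _window_means(depth: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """For each index p: mean over [p-window, p-1] and over [p, p+window-1].

    Out-of-range bases count as depth 0 (the genome ends are silent).
    """
    n = depth.size
    csum = np.concatenate(([0], np.cumsum(depth, dtype=np.float64)))
    idx = np.arange(n)
    lo = np.maximum(idx - window, 0)
    up_sum = csum[idx] - csum[lo]
    hi = np.minimum(idx + window, n)
    down_sum = csum[hi] - csum[idx]
    return up_sum / window, down_sum / window


def _detect_one_strand(depth: np.ndarray, window: int, min_fold: float,
                       min_depth: float, epsilon: float) -> list[tuple[int, float, float, float]]:
    """Edge candidates on a forward-oriented depth array.

    Returns (0-based position, upstream_mean, downstream_mean, fold) for the
    thinned passing candidates.
    """
    up, down = _window_means(depth, window)
    fold = (down + epsilon) / (up + epsilon)
    # require complete windows: a truncated upstream window at the array
    # boundary would mimic a step on uniform coverage
    valid = np.zeros(depth.size, dtype=bool)
    valid[window:depth.size - window + 1] = True
    passing = np.flatnonzero((fold >= min_fold) & (down >= min_depth) & valid)
    out: list[tuple[int, float, float, float]] = []
    if passing.size == 0:
        return out
    # split candidate positions into runs closer than `window`, keep max fold
    breaks = np.flatnonzero(np.diff(passing) >= window) + 1
    for run in np.split(passing, breaks):
        best = run[np.argmax(fold[run])]
        out.append((int(best), float(up[best]), float(down[best]),
                    float(fold[best])))
    return out


def detect_edges(cov: CoverageTrack, window: int = 50, min_fold: float = 4,
                 min_depth: float = 5, epsilon: float = 1) -> list[TranscriptEdge]:
    """Scan both strands for coverage step-ups.

    ``fold_change = (downstream_mean + epsilon) / (upstream_mean + epsilon)``
    with windows of ``window`` bp on the transcript's 5' and 3' side of each
    position; for reverse-strand transcripts "upstream" lies at higher
    coordinates.  An edge passes when the fold reaches ``min_fold`` and the
    downstream mean reaches ``min_depth``; at most one edge per ``window``-bp
    run of candidates is kept (the max-fold one).
    """
    if window < 1:
        raise EdgeError("window must be >= 1")
    if window > cov.genome.length:
        raise EdgeError(f"window {window} exceeds genome length "
                        f"{cov.genome.length}")
    edges: list[TranscriptEdge] = []
    for strand in (FORWARD, REVERSE):
        depth = cov.depth(strand)
        oriented = depth if strand == FORWARD else depth[::-1]
        for pos0, up, down, fold in _detect_one_strand(
                oriented, window, min_fold, min_depth, epsilon):
            position = pos0 + 1 if strand == FORWARD else depth.size - pos0
            edges.append(TranscriptEdge(position, strand, up, down, fold,
                                        passed=True))
    edges.sort(key=lambda e: (e.strand, e.position))
    return edges


def associate(clusters: list[TSSCluster], edges: list[TranscriptEdge],
              tolerance: int = 10) -> dict[int, TranscriptEdge | None]:
    """Map each cluster (by list index) to its nearest passing edge.

    A cluster is edge-associated iff a passing same-strand edge lies within
    ``tolerance`` bp of any member position; the nearest such edge (distance
    to the closest member) is recorded, else None.
    """
    by_strand: dict[str, list[TranscriptEdge]] = {FORWARD: [], REVERSE: []}
    for e in edges:
        if e.passed:
            by_strand[e.strand].append(e)

    result: dict[int, TranscriptEdge | None] = {}
    for i, cluster in enumerate(clusters):
        best: TranscriptEdge | None = None
        best_dist = tolerance + 1
        for e in by_strand[cluster.strand]:
            dist = min(abs(e.position - p) for p in cluster.positions)
            if dist < best_dist or (best is not None and dist == best_dist
                                    and e.position < best.position):
                best, best_dist = e, dist
        result[i] = best if best_dist <= tolerance else None
    return result
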
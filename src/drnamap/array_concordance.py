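"""Concordance between gRNA-seq coverage and tiling-microarray signals.

Each 60-mer probe's RNA-seq analogue is the log2 of the mean per-base read
depth over the interval the probe targets, taken from the coverage vector of
the probe's target strand.  Concordance between the array signal (log2
RNA/gDNA hybridization ratio) and the sequencing signal is summarized by a
Pearson correlation and a least-squares linear trend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .tracks_io import CoverageTrack


class ConcordanceError(ValueError):
    pass


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    strand: str
    start: int
    end: int
    array_signal: float
    seq_signal: float = float("nan")


@dataclass(frozen=True)
class ConcordanceSummary:
    r: float | None           # None when undefined (zero variance)
    slope: float | None
    intercept: float | None
    n: int
    n_dropped: int = 0


def probe_seq_signal(cov: CoverageTrack, probes: list[ProbeRecord],
                     pseudocount: float = 1.0) -> list[ProbeRecord]:
    """Fill in ``seq_signal = log2(mean depth over the probe + pseudocount)``.

    Forward-gene-targeting probes read the forward coverage vector and
    reverse probes the reverse one.  Intervals outside the genome raise.
    """
    out = []
    for probe in probes:
        if not (1 <= probe.start <= probe.end <= cov.genome.length):
            raise ConcordanceError(
                f"probe {probe.probe_id}: interval [{probe.start}, "
                f"{probe.end}] outside genome of length {cov.genome.length}")
        depth = cov.depth(probe.strand)[probe.start - 1:probe.end]
        mean = float(depth.mean())
        out.append(replace(probe, seq_signal=math.log2(mean + pseudocount)))
    return out


def concordance(records: list[ProbeRecord]) -> ConcordanceSummary:
    """Pearson r and linear trend between array and sequencing signals.

    Probes with non-finite signals are dropped (counted in ``n_dropped``);
    fewer than 3 usable probes or zero variance in either signal yields an
    undefined correlation (``r`` is None).
    """
    x = np.array([p.array_signal for p in records], dtype=float)
    y = np.array([p.seq_signal for p in records], dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return ConcordanceSummary(None, None, None, n, n_dropped)
    r = float(stats.pearsonr(x, y).statistic)
    fit = stats.linregress(x, y)
    return ConcordanceSummary(r, float(fit.slope), float(fit.intercept),
                              n, n_dropped)
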
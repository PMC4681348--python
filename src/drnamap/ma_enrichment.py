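"""M-A classification of 5' ends and clustering of enriched positions.

For every genome position carrying 5' ends in the minus-TAP and/or plus-TAP
library, the ratio-intensity pair

    M = log2(plus) - log2(minus)
    A = (log2(plus) + log2(minus)) / 2

is computed from (optionally depth-normalized, pseudocounted) counts.  In an
M-A scatterplot these positions fall into two populations: a large cone of
processing/degradation sites centred on M ~ 0, and a smaller TAP-enriched
population at high M corresponding to transcription start sites.  A
polynomial decision boundary M_threshold(A) separates the two; positions
strictly above the boundary are candidate TSS positions, and candidates
within a small gap of each other (default 8 nt, reflecting that many
promoters initiate from a cluster of adjacent positions) are merged into a
single TSS cluster.

The module ships the two published organism presets (a quadratic for
Streptomyces coelicolor, a cubic for Escherichia coli) and a quantile-style
refit for data where a manual boundary placement is to be reproduced
algorithmically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracks_io import FORWARD, REVERSE, FivePrimeTrack


class MAError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MAPoint:
    """One strand-position's M-A statistic with its raw counts."""

    position: int
    strand: str
    minus_count: int
    plus_count: int
    M: float
    A: float


@dataclass(frozen=True)
class BoundaryModel:
    """Polynomial M threshold as a function of A.

    ``coefficients[k]`` multiplies ``A**k`` (constant term first,
    highest degree last).
    """

    coefficients: tuple[float, ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        if len(self.coefficients) == 0:
            raise MAError("boundary polynomial needs at least one coefficient")

    def threshold(self, A) -> float | np.ndarray:
        return np.polynomial.polynomial.polyval(A, self.coefficients)


#: Published organism presets: M = 0.054 A^2 - 0.96 A + 4.68 (S. coelicolor)
#: and M = -0.003 A^3 + 0.13 A^2 - 1.57 A + 7.08 (E. coli).
PRESETS: dict[str, BoundaryModel] = {
    "scoelicolor": BoundaryModel((4.68, -0.96, 0.054), label="scoelicolor"),
    "ecoli": BoundaryModel((7.08, -1.57, 0.13, -0.003), label="ecoli"),
}


def get_preset(name: str) -> BoundaryModel:
    try:
        return PRESETS[name]
    except KeyError:
        raise MAError(f"unknown organism preset {name!r}; "
                      f"available: {sorted(PRESETS)}") from None


@dataclass(frozen=True)
class EnrichedSite:
    point: MAPoint
    enriched: bool

    @property
    def position(self) -> int:
        return self.point.position

    @property
    def strand(self) -> str:
        return self.point.strand


@dataclass
class TSSCluster:
    """A merged run of enriched positions treated as one TSS.

    ``representative`` is the member with the greatest plus-TAP count
    (smallest position on ties), rendered in tables as ``f<pos>``/``r<pos>``
    style labels, e.g. ``f1.60197``.
    """

    members: list[EnrichedSite]
    strand: str
    representative: int = field(init=False)
    total_plus: int = field(init=False)
    max_M: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise MAError("empty cluster")
        best = max(self.members,
                   key=lambda s: (s.point.plus_count, -s.position))
        self.representative = best.position
        self.total_plus = sum(s.point.plus_count for s in self.members)
        self.max_M = max(s.point.M for s in self.members)

    @property
    def start(self) -> int:
        return self.members[0].position

    @property
    def end(self) -> int:
        return self.members[-1].position

    @property
    def positions(self) -> list[int]:
        return [s.position for s in self.members]

    @property
    def label(self) -> str:
        letter = "f" if self.strand == FORWARD else "r"
        return f"{letter}1.{self.representative}"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def compute_ma(minus: FivePrimeTrack, plus: FivePrimeTrack,
               pseudocount: float = 1.0, normalize: bool = True,
               min_total: int = 5) -> list[MAPoint]:
    """Per-position M and A from a minus-/plus-TAP track pair.

    Only strand-positions whose summed raw counts reach ``min_total`` are
    reported.  With ``normalize`` each library is scaled to counts-per-million
    of its total mapped 5' ends before the pseudocount and logs, making M
    centre on 0 for processing sites even at unequal depths.
    """
    if minus.genome != plus.genome:
        raise MAError(f"track genomes differ: {minus.genome.name!r} vs "
                      f"{plus.genome.name!r}")
    if pseudocount < 0:
        raise MAError(f"pseudocount must be non-negative, got {pseudocount}")

    scale_minus = scale_plus = 1.0
    if normalize:
        if minus.total_mapped == 0 or plus.total_mapped == 0:
            raise MAError("cannot normalize an empty library")
        scale_minus = 1e6 / minus.total_mapped
        scale_plus = 1e6 / plus.total_mapped

    points: list[MAPoint] = []
    for strand in (FORWARD, REVERSE):
        m_arr, p_arr = minus.counts(strand), plus.counts(strand)
        total = m_arr + p_arr
        idx = np.flatnonzero(total >= max(min_total, 1))
        m_adj = m_arr[idx] * scale_minus + pseudocount
        p_adj = p_arr[idx] * scale_plus + pseudocount
        if np.any(m_adj <= 0) or np.any(p_adj <= 0):
            raise MAError("zero adjusted count with zero pseudocount; "
                          "use a positive pseudocount")
        log_m, log_p = np.log2(m_adj), np.log2(p_adj)
        M, A = log_p - log_m, (log_p + log_m) / 2
        for i, pos0 in enumerate(idx):
            points.append(MAPoint(int(pos0) + 1, strand,
                                  int(m_arr[pos0]), int(p_arr[pos0]),
                                  float(M[i]), float(A[i])))
    return points


def boundary_threshold(model: BoundaryModel, A: float) -> float:
    """Evaluate the boundary polynomial: sum_k c_k * A**k."""
    return float(model.threshold(A))


def call_enriched(points: list[MAPoint],
                  model: BoundaryModel) -> list[EnrichedSite]:
    """Flag points strictly above the boundary (ties are not enriched)."""
    return [EnrichedSite(p, bool(p.M > boundary_threshold(model, p.A)))
            for p in points]


def cluster_enriched(sites: list[EnrichedSite],
                     max_gap: int = 8) -> list[TSSCluster]:
    """Single-linkage chaining of enriched positions per strand.

    A site joins the current cluster iff its distance to the nearest
    previous member — with sorted input, the last member — is <= ``max_gap``.
    Input must be sorted by (strand, position); non-enriched sites are
    ignored.
    """
    keys = [(s.strand, s.position) for s in sites]
    if keys != sorted(keys):
        raise MAError("sites must be sorted by (strand, position)")

    clusters: list[TSSCluster] = []
    current: list[EnrichedSite] = []
    for site in sites:
        if not site.enriched:
            continue
        if (current
                and site.strand == current[-1].strand
                and site.position - current[-1].position <= max_gap):
            current.append(site)
        else:
            if current:
                clusters.append(TSSCluster(current, current[0].strand))
            current = [site]
    if current:
        clusters.append(TSSCluster(current, current[0].strand))
    return clusters


def fit_boundary(points: list[MAPoint], degree: int = 2,
                 quantile: float = 0.995, n_bins: int = 20,
                 label: str = "refit") -> BoundaryModel:
    """Quantile-style polynomial refit of the processing-population boundary.

    Bins points by A, takes the per-bin M quantile (default 99.5%) of the
    presumed processing population, and least-squares fits a polynomial of
    the given degree through the bin quantiles.  A programmatic stand-in for
    a manually placed upper boundary of the central cone.
    """
    if not 0 < quantile < 1:
        raise MAError("quantile must be in (0, 1)")
    if len(points) < (degree + 1) * 2:
        raise MAError("too few points to fit a boundary")
    A = np.array([p.A for p in points])
    M = np.array([p.M for p in points])
    edges = np.quantile(A, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    centers, qs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (A >= lo) & (A <= hi)
        if mask.sum() < 3:
            continue
        centers.append((lo + hi) / 2)
        qs.append(np.quantile(M[mask], quantile))
    if len(centers) < degree + 1:
        raise MAError("too few populated A bins for the requested degree")
    coefs = np.polynomial.polynomial.polyfit(centers, qs, degree)
    return BoundaryModel(tuple(float(c) for c in coefs), label=label)
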
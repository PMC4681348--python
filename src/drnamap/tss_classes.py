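"""TSS classification and the processing/degradation-site catalogue.

Candidate TSS clusters (TAP-enriched 5'-end positions) are cross-referenced
with leading edges of transcription detected in gRNA-seq coverage:

* Class I  — enriched cluster associated with a leading edge (both criteria);
* Class II — enriched cluster with no edge within tolerance;
* Class III — a passing leading edge with no enriched cluster nearby,
  reported at the edge position itself.

Positions that carry abundant 5' ends in the minus-TAP library but are NOT
enriched (M at or below the boundary) are sites of processing or
degradation: 5'-monophosphorylated ends left by ribonucleolytic cleavage.
Note the protocol is specific for 5'-monophosphorylated ends, so cleavages
leaving 5'-hydroxyl ends (e.g. MazF products) are invisible here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .tracks_io import FORWARD, REVERSE
from .ma_enrichment import BoundaryModel, MAPoint, TSSCluster, boundary_threshold
from .coverage_edges import TranscriptEdge, associate


@dataclass(frozen=True)
class ClassifiedTSS:
    position: int
    strand: str
    tss_class: str  # "I", "II" or "III"
    cluster: TSSCluster | None = None
    edge: TranscriptEdge | None = None

    @property
    def label(self) -> str:
        letter = "f" if self.strand == FORWARD else "r"
        return f"{letter}1.{self.position}"


@dataclass(frozen=True)
class ProcessingSite:
    position: int
    strand: str
    minus_count: int
    M: float
    A: float


def classify_tss(clusters: list[TSSCluster], edges: list[TranscriptEdge],
                 tolerance: int = 10) -> list[ClassifiedTSS]:
    """Label every enriched cluster I or II and emit unmatched edges as III.

    A cluster is Class I when a passing edge lies within ``tolerance`` bp of
    any member position, Class II otherwise.  Each passing edge that is not
    within tolerance of any enriched cluster becomes a Class III entry at
    the edge position (no 5'-end cluster exists there to anchor it).
    """
    assoc = associate(clusters, edges, tolerance)
    out: list[ClassifiedTSS] = []
    used_edges: set[tuple[str, int]] = set()
    for i, cluster in enumerate(clusters):
        edge = assoc[i]
        if edge is not None:
            used_edges.add((edge.strand, edge.position))
            out.append(ClassifiedTSS(cluster.representative, cluster.strand,
                                     "I", cluster, edge))
        else:
            out.append(ClassifiedTSS(cluster.representative, cluster.strand,
                                     "II", cluster, None))

    # an edge near ANY cluster member (even of a class I cluster matched to a
    # different edge) does not become class III
    member_positions: dict[str, list[int]] = {FORWARD: [], REVERSE: []}
    for cluster in clusters:
        member_positions[cluster.strand].extend(cluster.positions)

    for edge in edges:
        if not edge.passed:
            continue
        near_cluster = any(abs(edge.position - p) <= tolerance
                           for p in member_positions[edge.strand])
        if not near_cluster:
            out.append(ClassifiedTSS(edge.position, edge.strand, "III",
                                     None, edge))
    out.sort(key=lambda t: (t.strand, t.position))
    return out


def call_processing_sites(points: list[MAPoint], model: BoundaryModel,
                          min_reads: int = 10,
                          exclude: list[ClassifiedTSS] | None = None,
                          exclusion_radius: int = 8) -> list[ProcessingSite]:
    """Non-enriched positions with abundant minus-TAP 5' ends.

    Keeps positions with ``minus_count >= min_reads`` whose M is at or below
    the boundary, discarding anything within ``exclusion_radius`` of a
    class I/II TSS member position on the same strand.
    """
    tss_positions: dict[str, set[int]] = {FORWARD: set(), REVERSE: set()}
    for tss in exclude or []:
        if tss.tss_class in ("I", "II") and tss.cluster is not None:
            tss_positions[tss.strand].update(tss.cluster.positions)

    sites: list[ProcessingSite] = []
    for p in points:
        if p.minus_count < min_reads:
            continue
        if p.M > boundary_threshold(model, p.A):
            continue
        near_tss = any(abs(p.position - q) <= exclusion_radius
                       for q in tss_positions[p.strand])
        if near_tss:
            continue
        sites.append(ProcessingSite(p.position, p.strand, p.minus_count,
                                    p.M, p.A))
    sites.sort(key=lambda s: (s.strand, s.position))
    return sites


def class_counts(tss_list: list[ClassifiedTSS]) -> dict[str, int]:
    counts = {"I": 0, "II": 0, "III": 0}
    for t in tss_list:
        counts[t.tss_class] += 1
    return counts
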
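"""End-to-end orchestration of the transcription-map pipeline.

Runs, in order: M-A computation from the TAP± 5'-end tracks, boundary
classification and clustering, leading-edge detection in gRNA-seq coverage,
TSS class assignment (I/II/III), the processing-site catalogue, leader /
leaderless annotation, tRNA CCA checks, sRNA calling, and (when a probe
table is given) microarray concordance.  Every stage's table can be written
to a tab-delimited file, and a summary report collects the headline counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

from . import array_concordance as ac
from . import coverage_edges as ce
from . import feature_annotation as fa
from . import ma_enrichment as ma
from . import tss_classes as tc
from .tracks_io import CoverageTrack, FeatureSet, FivePrimeTrack

logger = logging.getLogger("drnamap")


@dataclass
class PipelineConfig:
    """All tunables, defaulting to the published constants where they exist
    (8-nt TSS clustering gap, <10-nt leaderless threshold, the organism
    boundary polynomials) and to this package's own defaults elsewhere."""

    organism_preset: str = "scoelicolor"
    boundary: ma.BoundaryModel | None = None
    # M-A stage
    pseudocount: float = 1.0
    normalize: bool = False    # presets are drawn on raw-read-count axes
    min_total: int = 5
    max_gap: int = 8
    # edge stage
    edge_window: int = 50
    edge_min_fold: float = 4.0
    edge_min_depth: float = 5.0
    edge_epsilon: float = 1.0
    # classification
    tolerance: int = 10
    proc_min_reads: int = 10
    # annotation
    leader_threshold: int = 10
    max_upstream: int = 500
    # sRNA stage
    srna_min_len: int = 50
    srna_max_len: int = 500
    srna_min_depth: float = 20.0
    srna_background_fold: float = 5.0

    def __post_init__(self) -> None:
        if self.boundary is None:
            self.boundary = ma.get_preset(self.organism_preset)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    points: list[ma.MAPoint]
    clusters: list[ma.TSSCluster]
    edges: list[ce.TranscriptEdge]
    tss: list[tc.ClassifiedTSS]
    processing_sites: list[tc.ProcessingSite]
    leaders: list[fa.LeaderAnnotation]
    cca_reports: list[fa.CCAReport]
    srnas: list[fa.SRNACandidate]
    concordance: ac.ConcordanceSummary | None
    report: dict = field(default_factory=dict)


def run_all(minus: FivePrimeTrack, plus: FivePrimeTrack, cov: CoverageTrack,
            features: FeatureSet, genome_seq: str | None = None,
            probes: list[ac.ProbeRecord] | None = None,
            config: PipelineConfig | None = None) -> PipelineResult:
    """Execute every stage on in-memory tracks and annotation."""
    cfg = config or PipelineConfig()
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    stage("ma")
    points = ma.compute_ma(minus, plus, pseudocount=cfg.pseudocount,
                           normalize=cfg.normalize, min_total=cfg.min_total)
    sites = ma.call_enriched(points, cfg.boundary)
    clusters = ma.cluster_enriched(sites, max_gap=cfg.max_gap)
    done("ma")

    stage("edges")
    edges = ce.detect_edges(cov, window=cfg.edge_window,
                            min_fold=cfg.edge_min_fold,
                            min_depth=cfg.edge_min_depth,
                            epsilon=cfg.edge_epsilon)
    done("edges")

    stage("classify")
    tss = tc.classify_tss(clusters, edges, tolerance=cfg.tolerance)
    processing = tc.call_processing_sites(points, cfg.boundary,
                                          min_reads=cfg.proc_min_reads,
                                          exclude=tss,
                                          exclusion_radius=cfg.max_gap)
    done("classify")

    stage("annotate")
    leaders = fa.annotate_leaders(tss, features,
                                  max_upstream=cfg.max_upstream,
                                  leader_threshold=cfg.leader_threshold)
    trnas = features.of_type("tRNA")
    cca = (fa.cca_cleavage_check(processing, trnas, genome_seq)
           if trnas and genome_seq else [])
    done("annotate")

    stage("srna")
    srnas = fa.call_srnas(cov, features, genome_seq,
                          min_len=cfg.srna_min_len, max_len=cfg.srna_max_len,
                          min_depth=cfg.srna_min_depth,
                          background_fold=cfg.srna_background_fold)
    done("srna")

    summary_conc = None
    if probes:
        stage("array")
        records = ac.probe_seq_signal(cov, probes)
        summary_conc = ac.concordance(records)
        done("array")

    counts = tc.class_counts(tss)
    report = {
        "config_digest": cfg.digest(),
        "boundary": cfg.boundary.label,
        "n_ma_points": len(points),
        "n_enriched_clusters": len(clusters),
        "n_edges": len(edges),
        "tss_class_I": counts["I"],
        "tss_class_II": counts["II"],
        "tss_class_III": counts["III"],
        "n_processing_sites": len(processing),
        "n_leaders": len(leaders),
        "n_leaderless": sum(l.leaderless for l in leaders),
        "n_srna_candidates": len(srnas),
        "n_srna_decay_intermediates": sum(s.decay_intermediate for s in srnas),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    if summary_conc is not None:
        report["pearson_r"] = summary_conc.r
        report["n_probes"] = summary_conc.n
    return PipelineResult(points, clusters, edges, tss, processing, leaders,
                          cca, srnas, summary_conc, report)


# ---------------------------------------------------------------------------
# Table writers (UTF-8, tab-delimited, commented header)
# ---------------------------------------------------------------------------

def _open_table(path: str, columns: list[str]):
    fh = open(path, "w")
    fh.write("# " + "\t".join(columns) + "\n")
    return fh


def write_ma_table(points, boundary: ma.BoundaryModel, path: str) -> str:
    with _open_table(path, ["strand", "position", "minus", "plus", "M", "A",
                            "threshold", "enriched"]) as out:
        for p in points:
            thr = ma.boundary_threshold(boundary, p.A)
            out.write(f"{p.strand}\t{p.position}\t{p.minus_count}\t"
                      f"{p.plus_count}\t{p.M:.4f}\t{p.A:.4f}\t{thr:.4f}\t"
                      f"{int(p.M > thr)}\n")
    return path


def write_cluster_table(clusters, path: str) -> str:
    with _open_table(path, ["strand", "label", "representative", "start",
                            "end", "n_members", "total_plus", "max_M"]) as out:
        for c in clusters:
            out.write(f"{c.strand}\t{c.label}\t{c.representative}\t{c.start}"
                      f"\t{c.end}\t{len(c.members)}\t{c.total_plus}\t"
                      f"{c.max_M:.4f}\n")
    return path


def write_edge_table(edges, path: str) -> str:
    with _open_table(path, ["strand", "position", "upstream_mean",
                            "downstream_mean", "fold_change", "passed"]) as out:
        for e in edges:
            out.write(f"{e.strand}\t{e.position}\t{e.upstream_mean:.3f}\t"
                      f"{e.downstream_mean:.3f}\t{e.fold_change:.3f}\t"
                      f"{int(e.passed)}\n")
    return path


def write_tss_gff3(tss_list, genome_name: str, path: str) -> str:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for i, t in enumerate(tss_list, start=1):
            out.write(f"{genome_name}\tdrnamap\tTSS\t{t.position}\t"
                      f"{t.position}\t.\t{t.strand}\t.\t"
                      f"ID=TSS{i:05d};class={t.tss_class};label={t.label}\n")
    return path


def write_processing_table(sites, path: str) -> str:
    with _open_table(path, ["strand", "position", "minus", "M", "A"]) as out:
        for s in sites:
            out.write(f"{s.strand}\t{s.position}\t{s.minus_count}\t"
                      f"{s.M:.4f}\t{s.A:.4f}\n")
    return path


def write_leader_table(leaders, path: str) -> str:
    with _open_table(path, ["gene_id", "tss_position", "strand", "tss_class",
                            "leader_length", "leaderless"]) as out:
        for l in leaders:
            out.write(f"{l.gene_id}\t{l.tss.position}\t{l.tss.strand}\t"
                      f"{l.tss.tss_class}\t{l.leader_length}\t"
                      f"{int(l.leaderless)}\n")
    return path


def write_srna_table(srnas, path: str) -> str:
    with _open_table(path, ["name", "strand", "start", "end", "length",
                            "max_depth", "mean_depth", "flags",
                            "decay_intermediate"]) as out:
        for s in srnas:
            flags = ",".join(sorted(s.flags)) or "."
            out.write(f"{s.name}\t{s.strand}\t{s.start}\t{s.end}\t{s.length}"
                      f"\t{s.max_depth:.1f}\t{s.mean_depth:.1f}\t{flags}\t"
                      f"{int(s.decay_intermediate)}\n")
    return path


def write_report(report: dict, path: str) -> str:
    with open(path, "w") as out:
        json.dump(report, out, indent=2, sort_keys=True)
        out.write("\n")
    return path


def write_all(result: PipelineResult, outdir: str, genome_name: str,
              config: PipelineConfig) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "ma": write_ma_table(result.points, config.boundary,
                             os.path.join(outdir, "ma_points.tsv")),
        "clusters": write_cluster_table(result.clusters,
                                        os.path.join(outdir, "tss_clusters.tsv")),
        "edges": write_edge_table(result.edges,
                                  os.path.join(outdir, "edges.tsv")),
        "tss": write_tss_gff3(result.tss, genome_name,
                              os.path.join(outdir, "tss.gff3")),
        "processing": write_processing_table(
            result.processing_sites,
            os.path.join(outdir, "processing_sites.tsv")),
        "leaders": write_leader_table(result.leaders,
                                      os.path.join(outdir, "leaders.tsv")),
        "srnas": write_srna_table(result.srnas,
                                  os.path.join(outdir, "srnas.tsv")),
        "report": write_report(result.report,
                               os.path.join(outdir, "report.json")),
    }
    return paths
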
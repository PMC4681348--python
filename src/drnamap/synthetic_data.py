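"""Synthetic genomes and RNA-seq tracks with known ground truth.

Generates the three-library input the pipeline expects — minus-TAP and
plus-TAP 5'-end tracks plus a global-RNA-seq coverage track — over a random
genome with annotated transcription units, mirroring the statistical
structure the analysis assumes:

* a large population of processing/degradation 5' ends whose plus/minus
  count ratio is ~1 (M centred on 0);
* a smaller population of TSS positions whose plus-TAP counts are enriched
  by a lognormal fold (default mean 16-fold on the log2 scale);
* step-shaped strand-specific coverage over each transcription unit on a
  low uniform background, so every unit start is a detectable leading edge;
* negative-binomial count noise throughout (RNA-seq counts are
  overdispersed relative to Poisson);
* minus-library counts at TSSs are nonzero — a fraction of nascent 5'
  triphosphates is de-pyrophosphorylated in vivo (E. coli carries an RNA
  pyrophosphohydrolase), so TSS positions appear in both libraries with
  mean ratio 1:fold;
* 5'-hydroxyl cleavage products are absent from both libraries: the
  protocol only captures 5'-monophosphorylated ends, so such sites simply
  do not appear in the truth.

Every run is reproducible from the config seed alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np

from .tracks_io import (FORWARD, REVERSE, CoverageTrack, Feature, FeatureSet,
                        FivePrimeTrack, GenomeRef)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic organism.

    Defaults model a 2-Mb GC-rich (Streptomyces-like) chromosome with a few
    hundred expressed transcription units, mean 16-fold TAP enrichment at
    TSSs, mean 5'-end depths of 30 reads at sites, and negative-binomial
    dispersion (size) 10.
    """

    genome_length: int = 2_000_000
    gc_content: float = 0.72          # 0.51 for the E. coli-like preset
    n_units: int = 250
    tss_enrichment_logmean: float = 4.0   # log2 fold; 2**4 = 16-fold
    tss_enrichment_logsd: float = 0.5
    processing_site_rate: float = 1.0     # sites per kb of transcribed unit
    depth_minus: float = 30.0             # mean minus-TAP 5'-end count/site
    depth_plus: float = 30.0              # mean plus-TAP count at fold 1
    depth_grna: float = 50.0              # mean coverage depth over a unit
    background_depth: float = 2.0         # mean coverage off units
    dispersion: float = 10.0              # negative-binomial size parameter
    seed: int = 42
    leaderless_fraction: float = 0.15
    srna_count: int = 20
    unit_length_range: tuple[int, int] = (600, 2000)
    srna_length_range: tuple[int, int] = (80, 300)
    background_site_count: int = 500      # spurious low-count 5' ends

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise SimulationError("gc_content must be in (0, 1)")
        for name in ("genome_length", "n_units", "srna_count",
                     "background_site_count"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        for name in ("processing_site_rate", "depth_minus", "depth_plus",
                     "depth_grna", "background_depth", "dispersion"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TruthSite:
    kind: str            # "tss", "processing" or "srna_boundary"
    position: int
    strand: str
    enrichment_fold: float
    unit_id: str


@dataclass(frozen=True)
class TruthUnit:
    start: int
    end: int
    strand: str
    expression_level: float
    gene_id: str
    leader_length: int
    is_srna: bool = False

    @property
    def tss_position(self) -> int:
        return self.start if self.strand == FORWARD else self.end


@dataclass
class SyntheticTruth:
    sites: list[TruthSite]
    units: list[TruthUnit]

    def of_kind(self, kind: str) -> list[TruthSite]:
        return [s for s in self.sites if s.kind == kind]


@dataclass
class SimResult:
    config: SimConfig
    genome: GenomeRef
    sequence: str
    features: FeatureSet
    minus: FivePrimeTrack
    plus: FivePrimeTrack
    coverage: CoverageTrack
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _nb(rng: np.random.Generator, mean, size_param: float) -> np.ndarray:
    """Negative-binomial draws with the given mean and size (dispersion)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = size_param / (size_param + mean[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _place_intervals(rng: np.random.Generator, genome_length: int,
                     lengths: list[int], strands: list[str],
                     occupied: dict[str, list[tuple[int, int]]],
                     gap: int = 100, max_tries: int = 200) -> list[tuple[int, int]]:
    """Place intervals without same-strand overlap (with a safety gap)."""
    placed = []
    for length, strand in zip(lengths, strands):
        ok = False
        for _ in range(max_tries):
            start = int(rng.integers(1, genome_length - length))
            end = start + length - 1
            if all(end + gap < s or start - gap > e
                   for s, e in occupied[strand]):
                occupied[strand].append((start, end))
                placed.append((start, end))
                ok = True
                break
        if not ok:
            raise SimulationError(
                "could not place all units; genome too crowded "
                f"({len(placed)} of {len(lengths)} placed)")
    return placed


def draw_truth(config: SimConfig) -> SyntheticTruth:
    """Sample transcription units, TSSs and processing sites."""
    rng = np.random.default_rng(config.seed)
    occupied: dict[str, list[tuple[int, int]]] = {FORWARD: [], REVERSE: []}

    lo, hi = config.unit_length_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_units)]
    strands = [FORWARD if rng.random() < 0.5 else REVERSE
               for _ in range(config.n_units)]
    spans = _place_intervals(rng, config.genome_length, lengths, strands,
                             occupied)

    units: list[TruthUnit] = []
    sites: list[TruthSite] = []
    for i, ((start, end), strand) in enumerate(zip(spans, strands)):
        uid = f"TU{i + 1:04d}"
        expression = float(rng.lognormal(mean=0.0, sigma=0.4))
        if rng.random() < config.leaderless_fraction:
            leader = int(rng.integers(0, 10))
        else:
            leader = int(rng.integers(20, 200))
        units.append(TruthUnit(start, end, strand, expression,
                               gene_id=f"SYN{i + 1:04d}", leader_length=leader))
        fold = float(2 ** rng.normal(config.tss_enrichment_logmean,
                                     config.tss_enrichment_logsd))
        tss_pos = start if strand == FORWARD else end
        sites.append(TruthSite("tss", tss_pos, strand, fold, uid))
        # processing sites inside the unit body, fold ~ 1
        n_proc = rng.poisson(config.processing_site_rate * (end - start + 1)
                             / 1000.0)
        if n_proc:
            body = rng.choice(np.arange(start + 30, end - 30), size=n_proc,
                              replace=False) if end - start > 70 else []
            for pos in np.sort(body):
                proc_fold = float(2 ** rng.normal(0.0, 0.1))
                sites.append(TruthSite("processing", int(pos), strand,
                                       proc_fold, uid))

    # short intergenic sRNA units: coverage islands with their own TSS
    lo_s, hi_s = config.srna_length_range
    s_lengths = [int(rng.integers(lo_s, hi_s + 1))
                 for _ in range(config.srna_count)]
    s_strands = [FORWARD if rng.random() < 0.5 else REVERSE
                 for _ in range(config.srna_count)]
    s_spans = _place_intervals(rng, config.genome_length, s_lengths,
                               s_strands, occupied)
    for j, ((start, end), strand) in enumerate(zip(s_spans, s_strands)):
        uid = f"SRNA{j + 1:03d}"
        expression = float(rng.lognormal(mean=1.0, sigma=0.3))
        units.append(TruthUnit(start, end, strand, expression, gene_id=uid,
                               leader_length=0, is_srna=True))
        sites.append(TruthSite("srna_boundary", start, strand, 1.0, uid))
        sites.append(TruthSite("srna_boundary", end, strand, 1.0, uid))

    sites.sort(key=lambda s: (s.strand, s.position))
    return SyntheticTruth(sites, units)


def render_tracks(truth: SyntheticTruth, config: SimConfig,
                  genome: GenomeRef) -> tuple[FivePrimeTrack, FivePrimeTrack,
                                              CoverageTrack]:
    """Draw count tracks from a truth object (seeded from the config)."""
    rng = np.random.default_rng(config.seed + 1)
    minus = FivePrimeTrack.zeros(genome, "minus_tap")
    plus = FivePrimeTrack.zeros(genome, "plus_tap")
    cov = CoverageTrack.zeros(genome)

    expr = {u.gene_id: u.expression_level for u in truth.units}
    unit_by_id = {f"TU{i + 1:04d}": u
                  for i, u in enumerate(u for u in truth.units if not u.is_srna)}

    for site in truth.sites:
        if site.kind == "srna_boundary":
            continue
        unit = unit_by_id.get(site.unit_id)
        scale = unit.expression_level if unit is not None else 1.0
        mean_minus = config.depth_minus * scale
        if site.kind == "tss":
            mean_plus = config.depth_plus * scale * site.enrichment_fold
        else:
            mean_plus = config.depth_plus * scale * site.enrichment_fold
        m = int(_nb(rng, np.array([mean_minus]), config.dispersion)[0])
        p = int(_nb(rng, np.array([mean_plus]), config.dispersion)[0])
        minus.counts(site.strand)[site.position - 1] += m
        plus.counts(site.strand)[site.position - 1] += p

    # spurious low-count 5' ends scattered over the genome (library noise)
    n_bg = config.background_site_count
    if n_bg:
        for track in (minus, plus):
            pos = rng.integers(1, genome.length + 1, size=n_bg)
            strands = rng.random(n_bg) < 0.5
            counts = _nb(rng, np.full(n_bg, 1.0), config.dispersion)
            for p0, fwd, c in zip(pos, strands, counts):
                if c:
                    track.counts(FORWARD if fwd else REVERSE)[p0 - 1] += int(c)

    # coverage: per-unit step on uniform background, NB-noised per position
    for strand in (FORWARD, REVERSE):
        mean = np.full(genome.length, config.background_depth, dtype=float)
        for u in truth.units:
            if u.strand != strand:
                continue
            mean[u.start - 1:u.end] += config.depth_grna * expr[u.gene_id]
        cov.depth(strand)[:] = _nb(rng, mean, config.dispersion)
    return minus, plus, cov


def _features_from_truth(truth: SyntheticTruth) -> FeatureSet:
    feats = []
    for u in truth.units:
        if u.is_srna:
            continue
        if u.strand == FORWARD:
            cds_start = u.start + u.leader_length
            cds_end = u.end - 30
        else:
            cds_start = u.start + 30
            cds_end = u.end - u.leader_length
        if cds_start > cds_end:
            cds_start, cds_end = u.start, u.end
        feats.append(Feature(u.gene_id, "CDS", u.strand, cds_start, cds_end,
                             {"ID": u.gene_id}))
    return FeatureSet(feats)


def simulate(config: SimConfig) -> SimResult:
    """Full simulation: genome, annotation, TAP± tracks, coverage, truth."""
    rng = np.random.default_rng(config.seed + 2)
    sequence = _random_sequence(rng, config.genome_length, config.gc_content)
    genome = GenomeRef("synthetic", config.genome_length)
    truth = draw_truth(config)
    minus, plus, cov = render_tracks(truth, config, genome)
    return SimResult(config, genome, sequence, _features_from_truth(truth),
                     minus, plus, cov, truth)


def mutate_truth(result: SimResult, op: str, params: dict) -> SimResult:
    """Controlled perturbation of the truth, with tracks re-rendered.

    ``shift_tss``: params ``unit_id`` and ``delta`` — move one TSS (and its
    unit 5' boundary) by delta bp.  ``drop_enrichment``: params ``unit_id``
    — set that TSS's plus/minus fold to 1.
    """
    truth = result.truth
    if op == "shift_tss":
        uid, delta = params["unit_id"], int(params["delta"])
        sites = [replace(s, position=s.position + delta)
                 if s.kind == "tss" and s.unit_id == uid else s
                 for s in truth.sites]
        new_truth = SyntheticTruth(sorted(sites,
                                          key=lambda s: (s.strand, s.position)),
                                   truth.units)
    elif op == "drop_enrichment":
        uid = params["unit_id"]
        sites = [replace(s, enrichment_fold=1.0)
                 if s.kind == "tss" and s.unit_id == uid else s
                 for s in truth.sites]
        new_truth = SyntheticTruth(sites, truth.units)
    else:
        raise SimulationError(f"unknown mutation op {op!r}")
    minus, plus, cov = render_tracks(new_truth, result.config, result.genome)
    return SimResult(result.config, result.genome, result.sequence,
                     result.features, minus, plus, cov, new_truth)


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

def tss_recovery(truth: SyntheticTruth, called_positions: list[tuple[str, int]],
                 tolerance: int = 8) -> dict[str, float]:
    """Recall/precision of TSS calls against the true TSS list.

    A true TSS is recovered if a call on its strand lies within
    ``tolerance`` bp; a call is correct if a true TSS lies within tolerance.
    """
    true_tss = [(s.strand, s.position) for s in truth.of_kind("tss")]
    recovered = sum(
        any(cs == ts and abs(cp - tp) <= tolerance
            for cs, cp in called_positions)
        for ts, tp in true_tss)
    correct = sum(
        any(cs == ts and abs(cp - tp) <= tolerance for ts, tp in true_tss)
        for cs, cp in called_positions)
    recall = recovered / len(true_tss) if true_tss else float("nan")
    precision = correct / len(called_positions) if called_positions else float("nan")
    return {"recall": recall, "precision": precision,
            "n_true": len(true_tss), "n_called": len(called_positions)}


def site_balanced_accuracy(truth: SyntheticTruth,
                           enriched_positions: set[tuple[str, int]],
                           tolerance: int = 8) -> float:
    """Balanced accuracy of the TSS-vs-processing decision at true sites.

    Sensitivity: fraction of true TSSs with an enriched call within
    tolerance.  Specificity: fraction of true processing sites with no
    enriched call within tolerance.
    """
    def near_enriched(strand: str, pos: int) -> bool:
        return any(s == strand and abs(p - pos) <= tolerance
                   for s, p in enriched_positions)

    tss = truth.of_kind("tss")
    proc = truth.of_kind("processing")
    if not tss or not proc:
        return float("nan")
    sens = sum(near_enriched(s.strand, s.position) for s in tss) / len(tss)
    spec = sum(not near_enriched(s.strand, s.position)
               for s in proc) / len(proc)
    return (sens + spec) / 2


# ---------------------------------------------------------------------------
# File writers (all plain text)
# ---------------------------------------------------------------------------

def write_fasta(result: SimResult, path: str) -> str:
    with open(path, "w") as out:
        out.write(f">{result.genome.name} synthetic length={result.genome.length}\n")
        seq = result.sequence
        for i in range(0, len(seq), 70):
            out.write(seq[i:i + 70] + "\n")
    return path


def write_gff3(result: SimResult, path: str) -> str:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        out.write(f"##sequence-region {result.genome.name} 1 "
                  f"{result.genome.length}\n")
        for f in result.features:
            out.write(f"{result.genome.name}\tsynthetic\t{f.type}\t{f.start}"
                      f"\t{f.end}\t.\t{f.strand}\t.\tID={f.id}\n")
    return path


def write_truth_tsv(truth: SyntheticTruth, path: str) -> str:
    with open(path, "w") as out:
        out.write("# kind\tposition\tstrand\tenrichment_fold\tunit_id\n")
        for s in truth.sites:
            out.write(f"{s.kind}\t{s.position}\t{s.strand}\t"
                      f"{s.enrichment_fold:.4f}\t{s.unit_id}\n")
    return path


def config_digest(config: SimConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]
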
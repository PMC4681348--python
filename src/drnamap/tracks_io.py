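"""Strand-specific read-end and coverage tracks.

Differential RNA-seq (dRNA-seq) counts, for every genome position, how often
that position was the first nucleotide of an aligned read — a 5' end observed
in vivo — separately for a library sequenced without tobacco acid
pyrophosphatase treatment (minus-TAP, 5'-monophosphorylated ends only) and
one sequenced after treatment (plus-TAP, which additionally captures nascent
5'-triphosphorylated ends).  Global RNA-seq (gRNA-seq) instead counts how
often each position was covered by any part of a read.

This module turns SAM/BAM alignments into those two track types, parses
GFF3/GTF annotation, and reads/writes per-strand bedGraph files.  All
coordinates are 1-based inclusive internally; bedGraph output uses the
format's native 0-based half-open convention, and reverse-strand values are
written as negative numbers so the two strands mirror each other in a
genome browser.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Mapping

import numpy as np
import pysam

FORWARD = "+"
REVERSE = "-"

FEATURE_TYPES = ("gene", "CDS", "rRNA", "tRNA", "other")


class TrackError(ValueError):
    """Raised for malformed tracks, alignments or annotation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeRef:
    """A reference sequence: name, length in bp, and circularity flag.

    Coordinates on this genome are 1-based inclusive; reads are never
    wrapped across the origin even when ``circular`` is set.
    """

    name: str
    length: int
    circular: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise TrackError(f"genome length must be positive, got {self.length}")

    def check_position(self, pos: int) -> None:
        if not 1 <= pos <= self.length:
            raise TrackError(
                f"position {pos} outside [1, {self.length}] on {self.name}"
            )


@dataclass
class FivePrimeTrack:
    """Per-strand counts of read 5' ends for one library.

    ``counts_forward``/``counts_reverse`` are dense integer arrays of length
    ``genome.length`` indexed so that array index ``pos - 1`` holds the count
    at 1-based position ``pos``.  ``library_label`` is ``minus_tap`` or
    ``plus_tap``.
    """

    genome: GenomeRef
    library_label: Literal["minus_tap", "plus_tap"]
    counts_forward: np.ndarray
    counts_reverse: np.ndarray

    @classmethod
    def zeros(cls, genome: GenomeRef, library_label: str) -> "FivePrimeTrack":
        n = genome.length
        return cls(genome, library_label,
                   np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64))

    @property
    def total_mapped(self) -> int:
        return int(self.counts_forward.sum() + self.counts_reverse.sum())

    def counts(self, strand: str) -> np.ndarray:
        return self.counts_forward if strand == FORWARD else self.counts_reverse

    def nonzero_positions(self, strand: str) -> np.ndarray:
        """1-based positions with at least one 5' end on ``strand``."""
        return np.flatnonzero(self.counts(strand)) + 1


@dataclass
class CoverageTrack:
    """Per-strand read coverage depth, one dense array per strand."""

    genome: GenomeRef
    depth_forward: np.ndarray
    depth_reverse: np.ndarray

    @classmethod
    def zeros(cls, genome: GenomeRef) -> "CoverageTrack":
        n = genome.length
        return cls(genome, np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64))

    @property
    def total(self) -> int:
        return int(self.depth_forward.sum() + self.depth_reverse.sum())

    def depth(self, strand: str) -> np.ndarray:
        return self.depth_forward if strand == FORWARD else self.depth_reverse


@dataclass(frozen=True)
class Feature:
    id: str
    type: str
    strand: str
    start: int
    end: int
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise TrackError(
                f"feature {self.id}: start {self.start} > end {self.end}"
            )
        if self.strand not in (FORWARD, REVERSE):
            raise TrackError(f"feature {self.id}: unknown strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """1-based position of the feature's 5' end (strand-aware)."""
        return self.start if self.strand == FORWARD else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == FORWARD else self.start

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class FeatureSet:
    features: list[Feature]

    def __post_init__(self) -> None:
        ids = [f.id for f in self.features]
        if len(ids) != len(set(ids)):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise TrackError(f"duplicate feature ids: {sorted(dupes)}")

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def of_type(self, *types: str) -> list[Feature]:
        return [f for f in self.features if f.type in types]

    def by_id(self, fid: str) -> Feature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------

def _canonical_type(ftype: str) -> str:
    return ftype if ftype in FEATURE_TYPES else "other"


def read_annotation(path: str,
                    feature_types: Iterable[str] | None = None) -> FeatureSet:
    """Parse a GFF3 or GTF file into a :class:`FeatureSet`.

    Feature types outside {gene, CDS, rRNA, tRNA} are mapped to ``other``
    unless ``feature_types`` restricts which raw types are kept.  Coordinates
    are taken 1-based inclusive as in the source format.  Malformed records
    raise :class:`TrackError` naming the line number.
    """
    import gffutils

    wanted = set(feature_types) if feature_types is not None else None
    # pre-validate line by line so errors carry a line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise TrackError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise TrackError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise TrackError(f"{path}:{lineno}: end {end} < start {start}")
            if cols[6] not in (FORWARD, REVERSE):
                raise TrackError(f"{path}:{lineno}: unknown strand {cols[6]!r}")

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    feats: list[Feature] = []
    for rec in db.all_features(order_by=("seqid", "start")):
        if wanted is not None and rec.featuretype not in wanted:
            continue
        attrs = {k: ",".join(v) for k, v in rec.attributes.items()}
        fid = (attrs.get("ID") or attrs.get("gene_id")
               or attrs.get("locus_tag") or rec.id)
        feats.append(Feature(id=fid, type=_canonical_type(rec.featuretype),
                             strand=rec.strand, start=rec.start, end=rec.end,
                             attributes=attrs))
    return FeatureSet(feats)


# ---------------------------------------------------------------------------
# Alignment-derived tracks
# ---------------------------------------------------------------------------

def _open_alignments(alignments) -> pysam.AlignmentFile:
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments
    return pysam.AlignmentFile(str(alignments))


def _retained(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.mapping_quality < min_mapq)


def five_prime_counts(alignments, genome: GenomeRef, min_mapq: int = 10,
                      library_label: str = "minus_tap") -> FivePrimeTrack:
    """Count read 5' ends per strand-position.

    For a forward-strand read the 5' end is its leftmost aligned reference
    base; for a reverse-strand read it is the rightmost.  Soft-clipped bases
    do not count (the first *aligned* base is used).  Unmapped, secondary,
    supplementary and sub-``min_mapq`` reads are skipped.
    """
    track = FivePrimeTrack.zeros(genome, library_label)
    af = _open_alignments(alignments)
    for read in af:
        if not _retained(read, min_mapq):
            continue
        if read.reference_name != genome.name:
            raise TrackError(
                f"read {read.query_name} aligned to {read.reference_name!r}, "
                f"not genome {genome.name!r}")
        if read.is_reverse:
            pos = read.reference_end  # 0-based exclusive == 1-based last base
            genome.check_position(pos)
            track.counts_reverse[pos - 1] += 1
        else:
            pos = read.reference_start + 1
            genome.check_position(pos)
            track.counts_forward[pos - 1] += 1
    return track


def coverage_from_alignments(alignments, genome: GenomeRef,
                             min_mapq: int = 10) -> CoverageTrack:
    """Per-base coverage: every aligned base of every retained read counts."""
    cov = CoverageTrack.zeros(genome)
    af = _open_alignments(alignments)
    for read in af:
        if not _retained(read, min_mapq):
            continue
        if read.reference_name != genome.name:
            raise TrackError(
                f"read {read.query_name} aligned to {read.reference_name!r}, "
                f"not genome {genome.name!r}")
        arr = cov.depth_reverse if read.is_reverse else cov.depth_forward
        for block_start, block_end in read.get_blocks():  # 0-based half-open
            arr[block_start:block_end] += 1
    return cov


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def _array_pair(track) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(track, FivePrimeTrack):
        return track.counts_forward, track.counts_reverse
    if isinstance(track, CoverageTrack):
        return track.depth_forward, track.depth_reverse
    raise TrackError(f"not a track: {type(track).__name__}")


def _write_bedgraph(arr: np.ndarray, genome: GenomeRef, path: str,
                    sign: int) -> None:
    with open(path, "w") as out:
        out.write(f"# bedGraph strand track for {genome.name}\n")
        if arr.size == 0:
            return
        # run-length encode
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [arr.size]))
        for s, e in zip(starts, ends):
            val = int(arr[s])
            if val != 0:
                out.write(f"{genome.name}\t{s}\t{e}\t{sign * val}\n")


def write_tracks(track, prefix: str) -> tuple[str, str]:
    """Write a track as two bedGraph files ``<prefix>.fwd.bedgraph`` and
    ``<prefix>.rev.bedgraph``; reverse-strand values are negated for mirrored
    browser display.  Returns the two paths."""
    fwd_arr, rev_arr = _array_pair(track)
    fwd_path, rev_path = f"{prefix}.fwd.bedgraph", f"{prefix}.rev.bedgraph"
    _write_bedgraph(fwd_arr, track.genome, fwd_path, sign=+1)
    _write_bedgraph(rev_arr, track.genome, rev_path, sign=-1)
    return fwd_path, rev_path


def _read_bedgraph(path: str, genome: GenomeRef, sign: int) -> np.ndarray:
    arr = np.zeros(genome.length, dtype=np.int64)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            name, s, e, v = line.rstrip("\n").split("\t")
            if name != genome.name:
                raise TrackError(f"{path}: contig {name!r} != {genome.name!r}")
            arr[int(s):int(e)] = sign * int(v)
    if (arr < 0).any():
        raise TrackError(f"{path}: negative value after sign correction")
    return arr


def read_tracks(prefix: str, genome: GenomeRef, kind: str = "coverage",
                library_label: str = "minus_tap"):
    """Inverse of :func:`write_tracks` for integer tracks."""
    fwd = _read_bedgraph(f"{prefix}.fwd.bedgraph", genome, sign=+1)
    rev = _read_bedgraph(f"{prefix}.rev.bedgraph", genome, sign=-1)
    if kind == "coverage":
        return CoverageTrack(genome, fwd, rev)
    return FivePrimeTrack(genome, library_label, fwd, rev)


def write_sam(path: str, genome: GenomeRef,
              reads: Iterable[tuple[str, str, int, int, int]]) -> str:
    """Write a minimal SAM file from (name, strand, start, end, mapq) tuples.

    Reads are ungapped full matches over [start, end] (1-based inclusive).
    Mainly used by the simulator and tests to exercise the alignment path.
    """
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:coordinate\n")
        out.write(f"@SQ\tSN:{genome.name}\tLN:{genome.length}\n")
        for name, strand, start, end, mapq in sorted(reads, key=lambda r: r[2]):
            flag = 16 if strand == REVERSE else 0
            length = end - start + 1
            out.write(f"{name}\t{flag}\t{genome.name}\t{start}\t{mapq}\t"
                      f"{length}M\t*\t0\t0\t{'N' * length}\t*\n")
    return path
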
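"""Feature-relative annotation: leaders, processing-site offsets, sRNAs.

Puts the site catalogues into gene context:

* leader lengths — the number of transcribed nucleotides between a TSS and
  the first base of the start codon of its downstream gene; mRNAs with a
  leader shorter than 10 nt cannot engage in a canonical Shine-Dalgarno
  interaction and are classed leaderless (lmRNA);
* feature-relative offsets for processing sites, e.g. the "-43" cleavage
  site numbered relative to the mature 3' end of 16S rRNA (a site k nt
  inside the feature from its 3' end has offset -k, k nt past it +k);
* cleavage within the genome-encoded CCA motif of tRNAs (between the Cs)
  and trailer cleavage just downstream of 3' ends of CCA-less tRNAs;
* candidate small RNAs — short abundant strand-specific coverage islands
  outside annotated genes, named after the nearest gene with (d/u, +/-)
  suffixes for downstream/upstream and same/opposite strand, and screened
  for palindromic (intrinsic-terminator-like) 3' structure, whose presence
  immediately downstream of a gene marks a probable decay intermediate
  rather than an independent sRNA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .tracks_io import FORWARD, REVERSE, CoverageTrack, Feature, FeatureSet
from .tss_classes import ClassifiedTSS, ProcessingSite


class AnnotationError(ValueError):
    pass


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Leader lengths / leaderless mRNAs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeaderAnnotation:
    gene_id: str
    tss: ClassifiedTSS
    leader_length: int
    leaderless: bool


def annotate_leaders(tss_list: list[ClassifiedTSS], features: FeatureSet,
                     max_upstream: int = 500,
                     leader_threshold: int = 10) -> list[LeaderAnnotation]:
    """Assign class I/III TSSs to their downstream gene and measure leaders.

    Each TSS is matched to the nearest same-strand gene/CDS start at or
    downstream of it (in the transcription direction) within
    ``max_upstream`` bp.  ``leader_length`` counts the transcribed nt before
    the start codon: a TSS at the A of the ATG has leader 0.  The leaderless
    flag uses a strict ``leader_length < leader_threshold``.  TSSs with no
    gene in range yield no annotation.
    """
    genes = features.of_type("gene", "CDS")
    out: list[LeaderAnnotation] = []
    for tss in tss_list:
        if tss.tss_class not in ("I", "III"):
            continue
        best: tuple[int, Feature] | None = None
        for gene in genes:
            if gene.strand != tss.strand:
                continue
            if tss.strand == FORWARD:
                leader = gene.five_prime - tss.position
            else:
                leader = tss.position - gene.five_prime
            if 0 <= leader <= max_upstream and (best is None or leader < best[0]):
                best = (leader, gene)
        if best is not None:
            leader, gene = best
            out.append(LeaderAnnotation(gene.id, tss, leader,
                                        leader < leader_threshold))
    return out


# ---------------------------------------------------------------------------
# Feature-relative coordinates for processing sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelativeSite:
    site: ProcessingSite
    feature_id: str
    offset: int
    convention: str


def _offset(position: int, feature: Feature, convention: str) -> int:
    # three_prime: 0 at the last base of the mature 3' end, negative inside
    # the feature, positive past it (strand-aware).
    if convention == "three_prime":
        anchor = feature.three_prime
        return (position - anchor if feature.strand == FORWARD
                else anchor - position)
    if convention == "five_prime":
        anchor = feature.five_prime
        return (position - anchor if feature.strand == FORWARD
                else anchor - position)
    raise AnnotationError(f"unknown convention {convention!r}")


def relative_offsets(sites: list[ProcessingSite], features: FeatureSet | list[Feature],
                     convention: str = "three_prime",
                     max_distance: int | None = None) -> list[RelativeSite]:
    """Express each site relative to the nearest same-strand feature anchor.

    Sites with no same-strand feature are skipped; ``max_distance`` (bp, on
    the offset) optionally drops far pairings.
    """
    feats = list(features)
    out: list[RelativeSite] = []
    for site in sites:
        candidates = [f for f in feats if f.strand == site.strand]
        if not candidates:
            continue
        best = min(candidates,
                   key=lambda f: abs(_offset(site.position, f, convention)))
        off = _offset(site.position, best, convention)
        if max_distance is not None and abs(off) > max_distance:
            continue
        out.append(RelativeSite(site, best.id, off, convention))
    return out


# ---------------------------------------------------------------------------
# tRNA CCA-motif cleavage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CCAReport:
    trna_id: str
    strand: str
    encodes_cca: bool
    cleaved_between_cs: bool
    intra_motif_sites: tuple[int, ...]
    trailer_sites: tuple[int, ...]


def _terminal_triplet(feature: Feature, genome_seq: str) -> str:
    if feature.end > len(genome_seq) or feature.start < 1:
        raise AnnotationError(
            f"{feature.id}: interval [{feature.start}, {feature.end}] outside "
            f"sequence of length {len(genome_seq)}")
    if feature.strand == FORWARD:
        return genome_seq[feature.end - 3:feature.end].upper()
    return revcomp(genome_seq[feature.start - 1:feature.start + 2]).upper()


def cca_cleavage_check(sites: list[ProcessingSite],
                       trna_features: FeatureSet | list[Feature],
                       genome_seq: str,
                       trailer_window: int = 5) -> list[CCAReport]:
    """Check each tRNA for cleavage inside its genome-encoded CCA motif.

    A detected 5' end at the second C of a 3'-terminal CCA means the
    upstream product ends ...C and the downstream product begins C-A: the
    tRNA was cut within the motif, between the Cs.  For tRNAs encoded
    without CCA, 5' ends within ``trailer_window`` nt downstream of the
    annotated 3' end are reported as trailer cleavage (sites that allow
    exonucleolytic trimming before CCA addition).
    """
    reports = []
    for trna in trna_features:
        triplet = _terminal_triplet(trna, genome_seq)
        encodes_cca = triplet == "CCA"
        same_strand = [s.position for s in sites if s.strand == trna.strand]
        intra: list[int] = []
        trailer: list[int] = []
        if trna.strand == FORWARD:
            second_c = trna.end - 1
            downstream = range(trna.end + 1, trna.end + trailer_window + 1)
        else:
            second_c = trna.start + 1
            downstream = range(trna.start - trailer_window, trna.start)
        if encodes_cca:
            intra = [p for p in same_strand if p == second_c]
        else:
            trailer = sorted(p for p in same_strand if p in downstream)
        reports.append(CCAReport(trna.id, trna.strand, encodes_cca,
                                 bool(intra), tuple(intra), tuple(trailer)))
    return reports


# ---------------------------------------------------------------------------
# Palindrome (intrinsic terminator) search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Palindrome:
    start: int        # 0-based offset of the left arm within the window
    stem: int
    loop: int
    mismatches: int


def find_palindrome(seq_window: str, min_stem: int = 8, max_loop: int = 12,
                    max_mismatch: int = 1, min_loop: int = 3) -> Palindrome | None:
    """Best inverted repeat in a short window, by exhaustive arm-pair scan.

    Ranks candidates by longest stem, then shortest loop, then fewest
    mismatches.  Non-ACGT characters never pair (they only contribute
    mismatches).  Windows longer than 200 nt are refused to keep the scan
    exhaustive and cheap.
    """
    n = len(seq_window)
    if n > 200:
        raise AnnotationError("window longer than 200 nt")
    seq = seq_window.upper()
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    best: Palindrome | None = None
    max_stem_possible = (n - min_loop) // 2
    for stem in range(min_stem, max_stem_possible + 1):
        for loop in range(min_loop, max_loop + 1):
            span = 2 * stem + loop
            if span > n:
                break
            for start in range(0, n - span + 1):
                left = seq[start:start + stem]
                right = seq[start + stem + loop:start + span]
                mism = sum((a, b) not in pairs
                           for a, b in zip(left, right[::-1]))
                if mism > max_mismatch:
                    continue
                cand = Palindrome(start, stem, loop, mism)
                if (best is None
                        or (cand.stem, -cand.loop, -cand.mismatches)
                        > (best.stem, -best.loop, -best.mismatches)):
                    best = cand
    return best


# ---------------------------------------------------------------------------
# Small-RNA candidates
# ---------------------------------------------------------------------------

@dataclass
class SRNACandidate:
    start: int
    end: int
    strand: str
    max_depth: float
    mean_depth: float
    name: str = ""
    flags: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def decay_intermediate(self) -> bool:
        """Terminator hairpin just downstream of a gene: probably the stable
        3' fragment of an mRNA rather than an independent sRNA."""
        return ("palindromic_terminator" in self.flags
                and "utr_adjacent" in self.flags)


def _gene_digits(gene_id: str) -> str | None:
    m = re.search(r"(\d+)$", gene_id)
    return m.group(1) if m else None


def name_srna(island_start: int, island_end: int, island_strand: str,
              gene: Feature) -> str:
    """Nearest-gene naming: scr<N>(d/u +/-).

    d/u says the island lies downstream/upstream of the gene in the *gene's*
    transcription direction; +/- says same/opposite strand.  For gene ids
    without a numeric suffix the full id is used in place of scr<N>.
    """
    mid = (island_start + island_end) / 2
    gene_mid = (gene.start + gene.end) / 2
    after = mid > gene_mid  # higher coordinates than the gene
    du = ("d" if after else "u") if gene.strand == FORWARD else \
         ("u" if after else "d")
    pm = "+" if island_strand == gene.strand else "-"
    digits = _gene_digits(gene.id)
    stem = f"scr{digits}" if digits else gene.id
    return f"{stem}({du}{pm})"


def _interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    if a_end < b_start:
        return b_start - a_end
    if b_end < a_start:
        return a_start - b_end
    return 0


def call_srnas(cov: CoverageTrack, features: FeatureSet, genome_seq: str | None,
               min_len: int = 50, max_len: int = 500, min_depth: float = 20,
               background_fold: float = 5, flank_window: int = 25,
               terminator_min_stem: int = 8,
               terminator_max_loop: int = 8) -> list[SRNACandidate]:
    """Short abundant coverage islands outside annotated genes.

    An island is a maximal same-strand run of depth >= ``min_depth`` whose
    flanking mean depth (over ``flank_window`` bp each side) is below the
    island mean divided by ``background_fold``, with length in
    [``min_len``, ``max_len``] and not fully inside a same-strand annotated
    CDS/rRNA/tRNA/gene.  Flags: ``palindromic_terminator`` (inverted repeat
    in the island's 3'-terminal 60 nt), ``antisense`` (overlaps an
    opposite-strand feature), ``utr_adjacent`` (lies within 100 bp
    downstream of a same-strand gene 3' end).  If ``genome_seq`` is None the
    palindrome flag is recorded as ``palindrome_unknown``.
    """
    annotated = features.of_type("gene", "CDS", "rRNA", "tRNA")
    candidates: list[SRNACandidate] = []
    n = cov.genome.length
    for strand in (FORWARD, REVERSE):
        depth = cov.depth(strand)
        high = depth >= min_depth
        if not high.any():
            continue
        diff = np.diff(high.astype(np.int8))
        starts = list(np.flatnonzero(diff == 1) + 1)
        ends = list(np.flatnonzero(diff == -1))
        if high[0]:
            starts.insert(0, 0)
        if high[-1]:
            ends.append(n - 1)
        for s0, e0 in zip(starts, ends):
            start, end = s0 + 1, e0 + 1  # 1-based inclusive
            length = end - start + 1
            if not min_len <= length <= max_len:
                continue
            island_mean = float(depth[s0:e0 + 1].mean())
            left = depth[max(s0 - flank_window, 0):s0]
            right = depth[e0 + 1:e0 + 1 + flank_window]
            flank = np.concatenate((left, right))
            flank_mean = float(flank.mean()) if flank.size else 0.0
            if flank_mean >= island_mean / background_fold:
                continue
            inside = any(f.strand == strand and f.start <= start
                         and end <= f.end for f in annotated)
            if inside:
                continue
            cand = SRNACandidate(start, end, strand,
                                 max_depth=float(depth[s0:e0 + 1].max()),
                                 mean_depth=island_mean)
            # 3'-terminal 60 nt, in transcript orientation
            if genome_seq is None:
                cand.flags.add("palindrome_unknown")
            else:
                if strand == FORWARD:
                    w0 = max(end - 60, start - 1)
                    window = genome_seq[w0:end]
                else:
                    w1 = min(start + 59, end)
                    window = revcomp(genome_seq[start - 1:w1])
                if find_palindrome(window, min_stem=terminator_min_stem,
                                   max_loop=terminator_max_loop) is not None:
                    cand.flags.add("palindromic_terminator")
            if any(f.strand != strand
                   and _interval_distance(start, end, f.start, f.end) == 0
                   for f in annotated):
                cand.flags.add("antisense")
            for f in annotated:
                if f.strand != strand:
                    continue
                if f.strand == FORWARD:
                    gap = start - f.end
                else:
                    gap = f.start - end
                if 0 < gap <= 100:
                    cand.flags.add("utr_adjacent")
                    break
            genes = [f for f in annotated] or None
            if genes:
                nearest = min(genes, key=lambda f: _interval_distance(
                    start, end, f.start, f.end))
                cand.name = name_srna(start, end, strand, nearest)
            candidates.append(cand)
    candidates.sort(key=lambda c: (c.strand, c.start))
    return candidates
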
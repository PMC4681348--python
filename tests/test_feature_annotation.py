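"""Leaders, feature-relative offsets, CCA cleavage, palindromes, sRNAs."""

import numpy as np
import pytest

import drnamap as d
from drnamap.feature_annotation import revcomp


def tss_at(pos, strand="+", tss_class="I"):
    point = d.MAPoint(pos, strand, 2, 50, 6.0, 5.0)
    cluster = d.TSSCluster([d.EnrichedSite(point, True)], strand)
    return d.ClassifiedTSS(pos, strand, tss_class, cluster, None)


def gene(gid, strand, start, end, ftype="CDS"):
    return d.Feature(gid, ftype, strand, start, end)


# ---------------------------------------------------------------------------
# leaders
# ---------------------------------------------------------------------------

def test_tss_at_start_codon_has_leader_zero_and_is_leaderless():
    features = d.FeatureSet([gene("g1", "+", 500, 900)])
    (ann,) = d.annotate_leaders([tss_at(500)], features)
    assert ann.leader_length == 0
    assert ann.leaderless


@pytest.mark.parametrize("leader, leaderless", [(9, True), (10, False)])
def test_leaderless_threshold_is_strictly_less_than_ten(leader, leaderless):
    features = d.FeatureSet([gene("g1", "+", 500, 900)])
    (ann,) = d.annotate_leaders([tss_at(500 - leader)], features)
    assert ann.leader_length == leader
    assert ann.leaderless is leaderless


def test_reverse_strand_leader_counts_from_gene_end():
    features = d.FeatureSet([gene("g1", "-", 500, 900)])
    (ann,) = d.annotate_leaders([tss_at(925, strand="-")], features)
    assert ann.leader_length == 25


def test_class_ii_tss_are_not_assigned():
    features = d.FeatureSet([gene("g1", "+", 500, 900)])
    assert d.annotate_leaders([tss_at(480, tss_class="II")], features) == []


def test_assignments_match_all_pairs_nearest_gene_oracle():
    rng = np.random.default_rng(53)
    genes = [gene(f"g{i}", str(rng.choice(["+", "-"])),
                  int(s), int(s) + 400)
             for i, s in enumerate(rng.choice(np.arange(500, 9000, 700), 6))]
    features = d.FeatureSet(genes)
    tss_list = [tss_at(int(p), str(s))
                for p, s in zip(rng.integers(1, 9500, 40),
                                rng.choice(["+", "-"], 40))]
    anns = {(a.tss.strand, a.tss.position): a
            for a in d.annotate_leaders(tss_list, features,
                                        max_upstream=500)}
    for tss in tss_list:
        leaders = []
        for g in genes:
            if g.strand != tss.strand:
                continue
            start = g.start if g.strand == "+" else g.end
            leader = (start - tss.position if g.strand == "+"
                      else tss.position - start)
            if 0 <= leader <= 500:
                leaders.append((leader, g.id))
        key = (tss.strand, tss.position)
        if leaders:
            exp_leader, exp_gene = min(leaders)
            assert anns[key].leader_length == exp_leader
            assert anns[key].gene_id == exp_gene
        else:
            assert key not in anns


def test_leader_lengths_survive_genome_mirroring():
    n = 10000
    features = d.FeatureSet([gene("g1", "+", 500, 900)])
    tss_list = [tss_at(460)]
    fwd = d.annotate_leaders(tss_list, features)
    # mirror: position p -> n - p + 1, strands swapped
    features_m = d.FeatureSet([gene("g1", "-", n - 900 + 1, n - 500 + 1)])
    tss_m = [tss_at(n - 460 + 1, strand="-")]
    mirrored = d.annotate_leaders(tss_m, features_m)
    assert [a.leader_length for a in fwd] == \
        [a.leader_length for a in mirrored]


# ---------------------------------------------------------------------------
# feature-relative offsets
# ---------------------------------------------------------------------------

def proc_site(pos, strand="+"):
    return d.ProcessingSite(pos, strand, 40, 0.0, 5.0)


def test_three_prime_offsets_reproduce_minus43_plus52_and_zero():
    rrna = gene("16S", "+", 1000, 2541, ftype="rRNA")
    sites = [proc_site(2541 - 43), proc_site(2541 + 52), proc_site(2541)]
    offs = d.relative_offsets(sites, [rrna], convention="three_prime")
    assert [o.offset for o in offs] == [-43, 52, 0]
    assert all(o.feature_id == "16S" for o in offs)


def test_reverse_strand_three_prime_offsets():
    rrna = gene("16S", "-", 1000, 2541, ftype="rRNA")
    # 3' end at position 1000; 43 nt inside lies at 1043
    offs = d.relative_offsets([proc_site(1043, "-"), proc_site(948, "-")],
                              [rrna])
    assert [o.offset for o in offs] == [-43, 52]


def test_offsets_monotone_along_feature_strand():
    rrna = gene("16S", "+", 1000, 2541, ftype="rRNA")
    sites = [proc_site(p) for p in range(2400, 2600, 13)]
    offs = d.relative_offsets(sites, [rrna])
    values = [o.offset for o in offs]
    assert values == sorted(values)


def test_opposite_strand_sites_are_skipped():
    rrna = gene("16S", "+", 1000, 2541, ftype="rRNA")
    assert d.relative_offsets([proc_site(2000, "-")], [rrna]) == []


# ---------------------------------------------------------------------------
# tRNA CCA cleavage
# ---------------------------------------------------------------------------

def test_cleavage_between_the_cs_of_encoded_cca():
    seq = "A" * 96 + "CCA" + "A" * 50   # tRNA 1..99 ends ...C-C-A
    trna = gene("tRNA1", "+", 1, 99, ftype="tRNA")
    (rep,) = d.cca_cleavage_check([proc_site(98)], [trna], seq)
    assert rep.encodes_cca
    assert rep.cleaved_between_cs
    assert rep.intra_motif_sites == (98,)


def test_non_cca_trna_reports_downstream_trailer_cleavage():
    seq = "A" * 99 + "G" * 50
    trna = gene("tRNA2", "+", 1, 99, ftype="tRNA")
    (rep,) = d.cca_cleavage_check([proc_site(101)], [trna], seq)
    assert not rep.encodes_cca
    assert rep.trailer_sites == (101,)


def test_trna_with_no_nearby_sites_is_unflagged():
    seq = "A" * 96 + "CCA" + "A" * 50
    trna = gene("tRNA1", "+", 1, 99, ftype="tRNA")
    (rep,) = d.cca_cleavage_check([proc_site(500)], [trna], seq)
    assert not rep.cleaved_between_cs and rep.trailer_sites == ()


def test_reverse_strand_cca_between_cs():
    # reverse tRNA over 101..199; encoded CCA read 5'->3' on minus strand
    seq = "G" * 100 + revcomp("T" * 96 + "CCA")[::-1][:0]  # build explicitly:
    seq = "G" * 100 + "TGG" + "T" * 96 + "G" * 50
    trna = gene("tRNA3", "-", 101, 199, ftype="tRNA")
    (rep,) = d.cca_cleavage_check([proc_site(102, "-")], [trna], seq)
    assert rep.encodes_cca
    assert rep.cleaved_between_cs


# ---------------------------------------------------------------------------
# palindromes
# ---------------------------------------------------------------------------

def test_constructed_hairpin_found_exactly():
    window = "GGGCGGCC" + "TTTT" + revcomp("GGGCGGCC")
    pal = d.find_palindrome(window)
    assert (pal.stem, pal.loop, pal.mismatches) == (8, 4, 0)


def test_poly_a_window_has_no_palindrome():
    assert d.find_palindrome("A" * 60) is None


def oracle_palindrome(seq, min_stem=8, max_loop=12, max_mismatch=1,
                      min_loop=3):
    pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    seq = seq.upper()
    best = None
    for start in range(len(seq)):
        for stem in range(min_stem, len(seq)):
            for loop in range(min_loop, max_loop + 1):
                end = start + 2 * stem + loop
                if end > len(seq):
                    continue
                left = seq[start:start + stem]
                right = seq[start + stem + loop:end]
                mism = sum((a, b) not in pairs
                           for a, b in zip(left, reversed(right)))
                if mism <= max_mismatch:
                    cand = (stem, -loop, -mism)
                    if best is None or cand > best:
                        best = cand
    return best


def test_palindrome_matches_brute_force_on_random_windows():
    rng = np.random.default_rng(59)
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), 60))
        pal = d.find_palindrome(seq)
        expected = oracle_palindrome(seq)
        if expected is None:
            assert pal is None
        else:
            assert (pal.stem, -pal.loop, -pal.mismatches) == expected


def test_window_over_200nt_is_refused():
    with pytest.raises(d.feature_annotation.AnnotationError):
        d.find_palindrome("A" * 201)


# ---------------------------------------------------------------------------
# sRNA calling and naming
# ---------------------------------------------------------------------------

def island_coverage(length=5000, islands=()):
    genome = d.GenomeRef("chr", length)
    cov = d.CoverageTrack.zeros(genome)
    for start, end, strand, depth in islands:
        cov.depth(strand)[start - 1:end] = depth
    return cov


def test_srna_downstream_opposite_strand_named_scr2100():
    cov = island_coverage(islands=[(1500, 1619, "-", 30)])
    features = d.FeatureSet([gene("SCO2100", "+", 1000, 1450)])
    (cand,) = d.call_srnas(cov, features, None)
    assert cand.name == "scr2100(d-)"
    assert cand.length == 120
    assert "palindrome_unknown" in cand.flags


def test_upstream_same_strand_naming_and_full_id_fallback():
    cov = island_coverage(islands=[(500, 619, "+", 30)])
    features = d.FeatureSet([gene("SCO2822", "+", 1000, 1450)])
    (cand,) = d.call_srnas(cov, features, None)
    assert cand.name == "scr2822(u+)"
    features2 = d.FeatureSet([gene("abcX", "+", 1000, 1450)])
    (cand2,) = d.call_srnas(cov, features2, None)
    assert cand2.name == "abcX(u+)"


def test_short_island_rejected_by_min_len():
    cov = island_coverage(islands=[(500, 529, "+", 30)])
    assert d.call_srnas(cov, d.FeatureSet([]), None) == []


def test_island_inside_same_strand_cds_rejected():
    cov = island_coverage(islands=[(1100, 1250, "+", 30)])
    features = d.FeatureSet([gene("g", "+", 1000, 1450)])
    assert d.call_srnas(cov, features, None) == []
    # opposite strand is kept and flagged antisense
    cov2 = island_coverage(islands=[(1100, 1250, "-", 30)])
    (cand,) = d.call_srnas(cov2, features, None)
    assert "antisense" in cand.flags


def test_terminator_hairpin_in_three_prime_end_sets_flag():
    hairpin = "GGGGCGCC" + "TTTT" + "GGCGCCCC"
    seq = list("A" * 5000)
    # island 1000..1119 forward; hairpin within its 3' 60 nt
    seq[1090:1090 + len(hairpin)] = hairpin
    seq = "".join(seq)
    cov = island_coverage(islands=[(1000, 1119, "+", 30)])
    (cand,) = d.call_srnas(cov, d.FeatureSet([]), seq)
    assert "palindromic_terminator" in cand.flags
    assert not cand.decay_intermediate  # not adjacent to any gene


def test_terminator_just_downstream_of_gene_marks_decay_intermediate():
    hairpin = "GGGGCGCC" + "TTTT" + "GGCGCCCC"
    seq = list("A" * 5000)
    seq[1540:1540 + len(hairpin)] = hairpin
    seq = "".join(seq)
    cov = island_coverage(islands=[(1460, 1579, "+", 30)])
    features = d.FeatureSet([gene("SCO0001", "+", 1000, 1450)])
    (cand,) = d.call_srnas(cov, features, seq)
    assert "utr_adjacent" in cand.flags
    assert cand.decay_intermediate


def test_srna_calls_invariant_to_uniform_depth_scaling():
    cov = island_coverage(islands=[(1500, 1619, "-", 30)])
    features = d.FeatureSet([gene("SCO2100", "+", 1000, 1450)])
    a = d.call_srnas(cov, features, None, min_depth=20)
    cov_scaled = island_coverage(islands=[(1500, 1619, "-", 300)])
    b = d.call_srnas(cov_scaled, features, None, min_depth=200)
    assert [(c.start, c.end, c.strand, c.name) for c in a] == \
        [(c.start, c.end, c.strand, c.name) for c in b]
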
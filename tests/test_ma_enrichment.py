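"""M-A statistics, boundary presets and TSS-cluster chaining."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import drnamap as d
from drnamap.ma_enrichment import MAError

GENOME = d.GenomeRef("chr", 2000)


def tracks_with(counts_minus, counts_plus):
    """Build a minus/plus track pair from {1-based pos: count} dicts (+)."""
    minus = d.FivePrimeTrack.zeros(GENOME, "minus_tap")
    plus = d.FivePrimeTrack.zeros(GENOME, "plus_tap")
    for pos, c in counts_minus.items():
        minus.counts_forward[pos - 1] = c
    for pos, c in counts_plus.items():
        plus.counts_forward[pos - 1] = c
    return minus, plus


def test_equal_counts_give_M_zero():
    minus, plus = tracks_with({10: 16}, {10: 16})
    (pt,) = d.compute_ma(minus, plus, pseudocount=0, normalize=False)
    assert pt.M == pytest.approx(0.0)
    assert pt.A == pytest.approx(4.0)


def test_sixteen_fold_gives_M_four():
    minus, plus = tracks_with({10: 1}, {10: 16})
    (pt,) = d.compute_ma(minus, plus, pseudocount=0, normalize=False,
                         min_total=5)
    assert pt.M == pytest.approx(4.0)
    assert pt.A == pytest.approx(2.0)


def test_compute_ma_matches_independent_formula_evaluation():
    rng = np.random.default_rng(5)
    cm = {int(p): int(c) for p, c in
          zip(rng.choice(np.arange(1, 2001), 50, replace=False),
              rng.integers(0, 200, 50))}
    cp = {p: int(rng.integers(0, 200)) for p in cm}
    minus, plus = tracks_with(cm, cp)
    points = d.compute_ma(minus, plus, pseudocount=1, normalize=True,
                          min_total=5)
    tot_m = sum(cm.values())
    tot_p = sum(cp.values())
    for pt in points:
        m_adj = cm[pt.position] * 1e6 / tot_m + 1
        p_adj = cp[pt.position] * 1e6 / tot_p + 1
        assert pt.M == pytest.approx(math.log2(p_adj) - math.log2(m_adj))
        assert pt.A == pytest.approx((math.log2(p_adj) + math.log2(m_adj)) / 2)
    expected_n = sum(cm[p] + cp[p] >= 5 for p in cm)
    assert len(points) == expected_n


def test_min_total_filters_low_count_positions():
    minus, plus = tracks_with({10: 2, 20: 3}, {10: 2, 20: 1})
    assert d.compute_ma(minus, plus, normalize=False, min_total=5) == []


def test_mismatched_genomes_and_negative_pseudocount_raise():
    minus = d.FivePrimeTrack.zeros(GENOME, "minus_tap")
    plus = d.FivePrimeTrack.zeros(d.GenomeRef("other", 2000), "plus_tap")
    with pytest.raises(MAError, match="genomes differ"):
        d.compute_ma(minus, plus)
    minus2, plus2 = tracks_with({10: 8}, {10: 8})
    with pytest.raises(MAError, match="non-negative"):
        d.compute_ma(minus2, plus2, pseudocount=-1, normalize=False)


def test_swapping_libraries_negates_M_and_preserves_A():
    rng = np.random.default_rng(8)
    cm = {int(p): int(c) + 1 for p, c in
          zip(rng.choice(np.arange(1, 2001), 100, replace=False),
              rng.integers(0, 100, 100))}
    cp = {p: int(rng.integers(1, 100)) for p in cm}
    minus, plus = tracks_with(cm, cp)
    fwd = d.compute_ma(minus, plus, normalize=False)
    swapped = d.compute_ma(plus, minus, normalize=False)
    assert len(fwd) == len(swapped)
    for a, b in zip(fwd, swapped):
        assert b.M == pytest.approx(-a.M)
        assert b.A == pytest.approx(a.A)


def test_scaling_both_libraries_leaves_ma_nearly_unchanged():
    # with normalization on, a common depth factor cancels except for the
    # pseudocount, whose effect vanishes at large counts
    cm = {10: 500, 50: 800, 90: 1200}
    cp = {10: 900, 50: 300, 90: 1200}
    minus, plus = tracks_with(cm, cp)
    minus10, plus10 = tracks_with({k: 10 * v for k, v in cm.items()},
                                  {k: 10 * v for k, v in cp.items()})
    a = d.compute_ma(minus, plus, normalize=True)
    b = d.compute_ma(minus10, plus10, normalize=True)
    for p1, p2 in zip(a, b):
        assert p2.M == pytest.approx(p1.M, abs=1e-6)
        assert p2.A == pytest.approx(p1.A, abs=1e-6)


@pytest.mark.parametrize("preset, A, expected", [
    ("scoelicolor", 0.0, 4.68),
    ("ecoli", 0.0, 7.08),
    ("scoelicolor", 10.0, 0.48),   # 0.054*100 - 9.6 + 4.68
])
def test_boundary_threshold_preset_values(preset, A, expected):
    assert d.boundary_threshold(d.get_preset(preset), A) == \
        pytest.approx(expected)


def test_scoelicolor_boundary_minimum_at_parabola_vertex():
    model = d.get_preset("scoelicolor")
    grid = np.linspace(0, 20, 20001)
    vals = model.threshold(grid)
    vertex = 0.96 / (2 * 0.054)
    assert grid[np.argmin(vals)] == pytest.approx(vertex, abs=1e-3)
    # decreasing before the vertex, increasing after
    assert vals[0] > vals.min() < vals[-1]


def test_call_enriched_is_strictly_above_boundary():
    model = d.get_preset("scoelicolor")
    above = d.MAPoint(1, "+", 1, 40, 5.0, 0.0)
    at = d.MAPoint(2, "+", 1, 30, 4.68, 0.0)
    sites = d.call_enriched([above, at], model)
    assert [s.enriched for s in sites] == [True, False]


def test_call_enriched_matches_elementwise_comparison():
    rng = np.random.default_rng(17)
    model = d.get_preset("ecoli")
    pts = [d.MAPoint(i + 1, "+", 1, 1, float(rng.normal(2, 3)),
                     float(rng.uniform(0, 15))) for i in range(1000)]
    flags = [s.enriched for s in d.call_enriched(pts, model)]
    coefs = (7.08, -1.57, 0.13, -0.003)
    expected = [p.M > sum(c * p.A ** k for k, c in enumerate(coefs))
                for p in pts]
    assert flags == expected


def enriched_sites(positions, strand="+", plus=None):
    plus = plus or {}
    sites = []
    for p in sorted(positions):
        point = d.MAPoint(p, strand, 2, plus.get(p, 50), 6.0, 5.0)
        sites.append(d.EnrichedSite(point, True))
    return sites


def test_positions_within_gap_chain_into_one_cluster():
    (cluster,) = d.cluster_enriched(enriched_sites([100, 105, 112]))
    assert cluster.positions == [100, 105, 112]


def test_gap_boundary_merges_at_8_and_splits_at_9():
    assert len(d.cluster_enriched(enriched_sites([100, 108]))) == 1
    assert len(d.cluster_enriched(enriched_sites([100, 109]))) == 2


def test_representative_is_max_plus_count_then_smallest_position():
    (c,) = d.cluster_enriched(enriched_sites([100, 104, 108],
                                             plus={100: 10, 104: 99, 108: 99}))
    assert c.representative == 104
    assert c.total_plus == 208
    assert c.label == "f1.104"


def test_unsorted_input_raises():
    sites = enriched_sites([100, 105])[::-1]
    with pytest.raises(MAError, match="sorted"):
        d.cluster_enriched(sites)


def brute_force_partition(positions, max_gap):
    """Union-find over all pairs within max_gap (independent oracle)."""
    parent = {p: p for p in positions}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for a in positions:
        for b in positions:
            if a < b and b - a <= max_gap:
                parent[find(b)] = find(a)
    groups = {}
    for p in positions:
        groups.setdefault(find(p), []).append(p)
    return sorted(sorted(g) for g in groups.values())


def test_chaining_matches_union_find_oracle():
    rng = np.random.default_rng(23)
    positions = sorted(int(p) for p in
                       rng.choice(np.arange(1, 5000), 200, replace=False))
    clusters = d.cluster_enriched(enriched_sites(positions), max_gap=8)
    assert sorted(c.positions for c in clusters) == \
        brute_force_partition(positions, 8)


@settings(max_examples=60, derandomize=True)
@given(st.sets(st.integers(min_value=1, max_value=800), min_size=1,
               max_size=60),
       st.integers(min_value=1, max_value=20))
def test_clustering_is_a_partition_with_separated_clusters(positions, gap):
    clusters = d.cluster_enriched(enriched_sites(sorted(positions)),
                                  max_gap=gap)
    covered = [p for c in clusters for p in c.positions]
    assert sorted(covered) == sorted(positions)   # every site exactly once
    spans = sorted((c.start, c.end) for c in clusters)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert s2 - e1 > gap   # no two clusters within the gap


def test_fit_boundary_encloses_requested_fraction():
    rng = np.random.default_rng(31)
    pts = [d.MAPoint(i + 1, "+", 1, 1, float(rng.normal(0, 1)),
                     float(rng.uniform(0, 12))) for i in range(4000)]
    model = d.fit_boundary(pts, degree=2, quantile=0.99)
    below = sum(p.M <= d.boundary_threshold(model, p.A) for p in pts)
    assert below / len(pts) > 0.95
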
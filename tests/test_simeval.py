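"""Synthetic panels, IBD-derived ground truth, and the overlap metrics."""

import numpy as np
import pytest

from rohdice import (
    GroundTruthCluster,
    IBDSegment,
    accuracy,
    ground_truth_clusters,
    overlap_ratio,
    plant_clusters,
    power,
    simulate_coalescent_panel,
)
from rohdice.panel import make_site_meta


def C(start, end, members):
    return GroundTruthCluster(start=start, end=end, members=frozenset(members))


class TestOverlapMetrics:
    def test_identical_clusters(self):
        a = C(10, 20, {1, 2, 3})
        assert overlap_ratio(a, a) == 1.0

    def test_disjoint_spans(self):
        assert overlap_ratio(C(0, 10, {1}), C(20, 30, {1})) == 0.0

    def test_nested_span_same_members(self):
        # reported covers half the truth span: every reported cell is real
        assert overlap_ratio(C(10, 15, {1, 2}), C(10, 20, {1, 2})) == 1.0

    def test_member_mismatch_scales_ratio(self):
        r = C(0, 10, {1, 2, 3, 4})
        t = C(0, 10, {1, 2})
        assert overlap_ratio(r, t) == pytest.approx(0.5)

    def test_site_space_mode_ignores_members(self):
        r = C(0, 10, {1, 2, 3, 4})
        t = C(5, 10, {9})
        assert overlap_ratio(r, t, mode="sites") == pytest.approx(0.5)

    def test_accuracy_and_power_perfect(self):
        xs = [C(0, 10, {1, 2}), C(20, 40, {3, 4, 5})]
        assert accuracy(xs, xs) == 1.0
        assert power(xs, xs) == 1.0

    def test_accuracy_zero_when_all_spurious(self):
        rep = [C(50, 60, {1, 2})]
        truth = [C(0, 10, {1, 2})]
        assert accuracy(rep, truth) == 0.0

    def test_power_credits_piecewise_recovery(self):
        truth = [C(0, 20, {1, 2, 3})]
        halves = [C(0, 10, {1, 2, 3}), C(10, 20, {1, 2, 3})]
        assert power(halves, truth) == 1.0

    def test_empty_inputs_signal(self):
        with pytest.raises(ValueError):
            accuracy([], [C(0, 1, {1, 2})])
        with pytest.raises(ValueError):
            power([C(0, 1, {1, 2})], [])


class TestPlantClusters:
    def test_truth_is_planted_exactly(self):
        panel, truth = plant_clusters(
            M=40, N=300, cluster_specs=[(50, 200, 25, 0.0)], seed=1
        )
        (t,) = truth
        assert (t.start, t.end, len(t.members)) == (50, 200, 25)
        vals = panel.values[sorted(t.members), 50:200]
        assert (vals == vals[0]).all()
        assert set(np.unique(vals)) <= {0, 2}

    def test_background_heterozygosity_near_18_percent(self):
        panel, _ = plant_clusters(M=100, N=500, cluster_specs=[], seed=2)
        het = (panel.values == 1).mean()
        assert 0.16 < het < 0.20

    def test_noise_rate_reflected_in_block(self):
        panel, truth = plant_clusters(
            M=100, N=600, cluster_specs=[(100, 500, 80, 0.01)], seed=3
        )
        (t,) = truth
        het = (panel.values[sorted(t.members), 100:500] == 1).mean()
        assert 0.005 < het < 0.015

    def test_contradictory_overlap_rejected(self):
        with pytest.raises(ValueError, match="contradictory|span|member"):
            plant_clusters(
                M=20,
                N=100,
                cluster_specs=[(10, 60, 15, 0.0), (40, 90, 15, 0.0)],
                seed=4,
            )

    def test_out_of_range_span_rejected(self):
        with pytest.raises(ValueError):
            plant_clusters(M=10, N=50, cluster_specs=[(40, 60, 5, 0.0)], seed=0)


class TestGroundTruth:
    def test_shared_segment_yields_one_cluster(self):
        meta = make_site_meta(np.arange(1, 301) * 100)  # sites every 100 bp
        segs = [
            IBDSegment(individual=0, bp_start=0, bp_end=25_000, ancestor=7),
            IBDSegment(individual=1, bp_start=0, bp_end=25_000, ancestor=7),
        ]
        _, truth = ground_truth_clusters(segs, meta, L=100, W=2, n_individuals=4)
        assert len(truth) == 1
        assert truth[0].members == frozenset({0, 1})

    def test_distinct_ancestors_do_not_share_alleles(self):
        meta = make_site_meta(np.arange(1, 301) * 100)
        segs = [
            IBDSegment(individual=0, bp_start=0, bp_end=25_000, ancestor=7),
            IBDSegment(individual=1, bp_start=0, bp_end=25_000, ancestor=9),
        ]
        _, truth = ground_truth_clusters(segs, meta, L=100, W=2, n_individuals=4)
        assert truth == []

    def test_no_segments_no_clusters(self):
        meta = make_site_meta(np.arange(1, 51) * 100)
        _, truth = ground_truth_clusters([], meta, L=10, W=2, n_individuals=5)
        assert truth == []

    def test_segment_outside_grid_warns(self):
        meta = make_site_meta(np.arange(1, 51) * 100)
        segs = [IBDSegment(individual=0, bp_start=10_000, bp_end=12_000, ancestor=1)]
        with pytest.warns(UserWarning, match="clipped"):
            ground_truth_clusters(segs, meta, L=5, W=2, n_individuals=2)

    def test_panel_painting_uses_real_homozygous_genotypes(self):
        panel, truth = plant_clusters(
            M=30, N=200, cluster_specs=[(40, 160, 12, 0.0)], seed=6
        )
        positions = panel.positions
        segs = [
            IBDSegment(
                individual=i,
                bp_start=int(positions[40]) - 1,
                bp_end=int(positions[160]) - 1,
                ancestor=3,
            )
            for i in sorted(truth[0].members)
        ]
        interim, got = ground_truth_clusters(
            segs, panel.site_meta, L=100, W=10, n_individuals=30, panel=panel
        )
        assert len(got) == 1
        assert got[0].members == truth[0].members


class TestCoalescentPanel:
    def test_shapes_metadata_and_determinism(self):
        p1, ibd1 = simulate_coalescent_panel(20, 500_000, seed=5)
        p2, ibd2 = simulate_coalescent_panel(20, 500_000, seed=5)
        assert p1.n_individuals == 20
        assert np.array_equal(p1.values, p2.values)
        assert ibd1 == ibd2
        assert np.all(np.diff(p1.positions) > 0)
        # MAF filter applied on diploid counts
        ac = p1.values.sum(axis=0)
        maf = np.minimum(ac, 40 - ac) / 40
        assert (maf >= 0.01).all()

    def test_error_rate_perturbs_expected_fraction(self):
        clean, _ = simulate_coalescent_panel(200, 1_000_000, seed=8)
        noisy, _ = simulate_coalescent_panel(200, 1_000_000, seed=8, error_rate=0.001)
        frac = (clean.values != noisy.values).mean()
        assert 0.0005 <= frac <= 0.0015

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            simulate_coalescent_panel(1, 500_000, seed=1)
        with pytest.raises(ValueError):
            simulate_coalescent_panel(10, 1_000, seed=1)


def test_relaxed_cutoffs_never_reduce_power():
    """Calls at smaller (L, W) recover at least as much of a fixed truth."""
    panel, truth = plant_clusters(
        M=120,
        N=900,
        cluster_specs=[(100, 320, 60, 0.0), (400, 700, 90, 0.0)],
        seed=11,
    )
    from rohdice import call_roh_clusters

    strict = call_roh_clusters(panel, L=200, W=50, seed=0)
    relaxed = call_roh_clusters(panel, L=100, W=25, seed=0)
    assert power(relaxed, truth) >= power(strict, truth)
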
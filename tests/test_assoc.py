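"""Association, linkage, hotspot-scan and power-simulation statistics."""

import numpy as np
import pytest
from scipy import stats

from rohdice import (
    GroundTruthCluster,
    chi_square_association,
    d_prime,
    plant_clusters,
    power_comparison,
    simulate_phenotype,
    site_score_scan,
)


def table_chi2(D1, N1, D2, N2):
    """Independent Sigma (O-E)^2 / E evaluation used as the oracle."""
    obs = np.array([[D1, N1], [D2, N2]], float)
    M = obs.sum()
    exp = obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True) / M
    return float(((obs - exp) ** 2 / exp).sum())


class TestChiSquare:
    @staticmethod
    def from_counts(D1, N1, D2, N2):
        members = {f"m{i}" for i in range(D1 + N1)}
        cases = {f"m{i}" for i in range(D1)} | {f"c{i}" for i in range(D2)}
        M = D1 + N1 + D2 + N2
        return chi_square_association(members, cases, M)

    def test_independent_table_is_null(self):
        res = self.from_counts(10, 10, 10, 10)
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.carrier_frequency == pytest.approx(0.5)

    def test_matches_direct_formula(self):
        # counts shaped like a biobank mortality table: 76 carriers of whom
        # 11 died, 190 further deaths among 8044 non-carriers
        res = self.from_counts(11, 65, 190, 7854)
        want = table_chi2(11, 65, 190, 7854)
        assert res.chi2 == pytest.approx(want, rel=1e-9)
        assert res.p_value == pytest.approx(stats.chi2.sf(want, 1), rel=1e-9)

    def test_doubling_counts_doubles_statistic(self):
        a = self.from_counts(12, 30, 40, 100)
        b = self.from_counts(24, 60, 80, 200)
        assert b.chi2 == pytest.approx(2 * a.chi2, rel=1e-12)

    def test_swapping_disease_labels_preserves_statistic(self):
        a = self.from_counts(11, 65, 190, 7854)
        b = self.from_counts(65, 11, 7854, 190)
        assert b.chi2 == pytest.approx(a.chi2, rel=1e-12)

    def test_degenerate_expected_cell_flagged(self):
        res = self.from_counts(0, 0, 5, 5)
        assert res.degenerate and np.isnan(res.p_value)

    def test_infinite_odds_ratio_flagged(self):
        res = self.from_counts(5, 0, 2, 10)
        assert res.odds_ratio == np.inf

    def test_counts_table_sums_to_cohort(self):
        res = self.from_counts(3, 7, 11, 20)
        assert res.table.M == 41


def textbook_dprime(p_R, p_S, p_RS):
    """Standard D' normalization evaluated from raw frequencies."""
    D = p_RS - p_R * p_S
    if D > 0:
        return D / min(p_R * (1 - p_S), (1 - p_R) * p_S)
    if D < 0:
        return D / min(p_R * p_S, (1 - p_R) * (1 - p_S))
    return 0.0


class TestDPrime:
    def test_perfect_linkage(self):
        cohort = [f"s{i}" for i in range(100)]
        members = set(cohort[:20])
        geno = {s: (2 if s in members else 0) for s in cohort}
        res = d_prime(members, geno, cohort)
        assert res.d_prime == pytest.approx(1.0)
        assert res.p_RS == pytest.approx(res.p_R)

    def test_independence_gives_zero(self):
        cohort = [f"s{i}" for i in range(8)]
        members = set(cohort[:4])
        # half of members and half of non-members are homozygous carriers,
        # so p_RS = p_R * p_S exactly
        geno = {"s0": 2, "s1": 2, "s2": 0, "s3": 0,
                "s4": 2, "s5": 2, "s6": 0, "s7": 0}
        res = d_prime(members, geno, cohort)
        assert res.D == pytest.approx(0.0)
        assert res.d_prime == pytest.approx(0.0)

    def test_matches_textbook_normalization(self, rng):
        cohort = [f"s{i}" for i in range(500)]
        for _ in range(20):
            members = set(rng.choice(cohort, size=80, replace=False))
            geno = {s: int(g) for s, g in zip(cohort, rng.integers(0, 3, 500))}
            res = d_prime(members, geno, cohort)
            if res.undefined:
                continue
            # frequencies recomputed from the raw inputs, not from the result
            p_R = len(members) / 500
            p_S = sum(geno.values()) / 1000
            p_RS = sum(1 for s in members if geno[s] >= 1) / 500
            want = textbook_dprime(p_R, p_S, p_RS)
            assert res.d_prime == pytest.approx(want, abs=1e-12)
            assert -1 - 1e-12 <= res.d_prime <= 1 + 1e-12

    def test_empty_off_diagonal_gives_unit_magnitude(self):
        cohort = [f"s{i}" for i in range(50)]
        members = set(cohort[:10])
        # every member carries the allele; some non-members do too
        geno = {s: 0 for s in cohort}
        for s in cohort[:25]:
            geno[s] = 2
        res = d_prime(members, geno, cohort)
        assert abs(res.d_prime) == pytest.approx(1.0)

    def test_degenerate_frequencies_flagged(self):
        cohort = ["a", "b", "c"]
        res = d_prime(set(), {s: 1 for s in cohort}, cohort)
        assert res.undefined and np.isnan(res.d_prime)

    def test_paper_literal_mode_evaluates_max_form(self):
        cohort = [f"s{i}" for i in range(100)]
        members = set(cohort[:20])
        geno = {s: (2 if s in members else 0) for s in cohort}
        res = d_prime(members, geno, cohort, mode="paper-literal")
        pR = pS = 0.2
        assert res.d_prime == pytest.approx(max(pR * pS, 0.8 * 0.8))


class TestSiteScoreScan:
    def test_no_clusters_all_zero(self):
        scan = site_score_scan([], 1000)
        assert scan.scores.sum() == 0
        assert scan.hotspots.size == 0

    def test_single_cluster_hotspot(self):
        c = GroundTruthCluster(start=10, end=20, members=frozenset(range(150)))
        scan = site_score_scan([c], 10_000)
        assert set(scan.hotspots) == set(range(10, 20))
        assert (scan.scores[10:20] == 150).all()
        # uncovered sites score 0, equal to the 0.5th percentile: no coldspots
        assert scan.coldspots.size == 0

    def test_score_is_max_not_sum(self):
        a = GroundTruthCluster(start=0, end=10, members=frozenset(range(30)))
        b = GroundTruthCluster(start=5, end=15, members=frozenset(range(50)))
        scan = site_score_scan([a, b], 20)
        assert scan.scores[7] == 50
        scan_rev = site_score_scan([b, a], 20)
        assert np.array_equal(scan.scores, scan_rev.scores)


class TestSimulatePhenotype:
    def test_null_mean_bound(self):
        cohort = list(range(10_000))
        sim = simulate_phenotype(set(), cohort, beta=0.0, sigma2=0.1, seed=1)
        assert abs(sim.Y.mean()) < 4 * np.sqrt(0.1 / 10_000)

    def test_small_noise_separates_groups(self):
        cohort = list(range(100))
        members = set(range(30))
        sim = simulate_phenotype(members, cohort, beta=0.3, sigma2=1e-8, seed=2)
        assert sim.Y[sim.X == 1].min() > sim.Y[sim.X == 0].max()

    def test_noise_variance_matches_sigma2(self):
        cohort = list(range(10_000))
        sim = simulate_phenotype(set(), cohort, beta=0.0, sigma2=0.1, seed=3)
        assert 0.09 < sim.Y.var() < 0.11

    def test_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            simulate_phenotype(set(), [1, 2], beta=0.1, sigma2=0.0, seed=0)


@pytest.fixture(scope="module")
def assoc_panel():
    panel, truth = plant_clusters(
        M=200,
        N=2000,
        cluster_specs=[
            (100, 400, 120, 0.0),
            (600, 900, 60, 0.0),
            (1100, 1500, 90, 0.0),
            (1600, 1950, 40, 0.0),
        ],
        seed=77,
    )
    from rohdice import call_roh_clusters

    clusters = call_roh_clusters(panel, L=100, W=20, seed=0)
    assert clusters
    return panel, clusters


class TestPowerComparison:
    def test_power_monotone_in_effect_size(self, assoc_panel):
        panel, clusters = assoc_panel
        tab = power_comparison(
            panel, clusters, betas=[0.0, 0.3], n_reps=40, seed=1
        )
        for method in tab.method.unique():
            sub = tab[tab.method == method].sort_values("beta")
            lo, hi = sub.power.tolist()
            # one-sided binomial check at 1%: hi may not be significantly
            # below lo under monotone truth
            k = round(hi * 40)
            assert stats.binomtest(k, 40, max(lo, 1e-9), alternative="less").pvalue > 0.01

    def test_tiny_noise_gives_full_cluster_power(self, assoc_panel):
        panel, clusters = assoc_panel
        tab = power_comparison(
            panel, clusters, betas=[0.3], n_reps=20, seed=2, sigma2=1e-6
        )
        roh = tab[tab.method == "roh"].power.iloc[0]
        assert roh == 1.0

    def test_requires_clusters_and_reps(self, assoc_panel):
        panel, _ = assoc_panel
        with pytest.raises(ValueError):
            power_comparison(panel, [], betas=[0.1], seed=0)
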
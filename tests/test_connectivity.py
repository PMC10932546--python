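"""Connection probabilities, chi-square/FDR comparisons, bootstrap, curve fit."""

import numpy as np
import pytest

from pcdhgamma import (
    PairRecord,
    PairTable,
    ProbabilityEstimate,
    benjamini_hochberg,
    bootstrap_probability,
    chi_square_2x2,
    compare_groups,
    connection_probability,
    similarity_connectivity_fit,
)
from pcdhgamma.synth import exact_count_pair_table


class TestConnectionProbability:
    @pytest.mark.parametrize("connected, tested, percent", [
        (103, 511, 20.2),   # gamma-Pcdhg cKO pooled recordings
        (5, 134, 3.7),      # complete-overlap (100% similarity) group
        (0, 10, 0.0),
    ])
    def test_printed_style_counts(self, connected, tested, percent):
        table = exact_count_pair_table({"g": (connected, tested)})
        est = connection_probability(table, group="g")
        assert est.connected == connected
        assert est.tested == tested
        assert round(est.percent, 1) == pytest.approx(percent)

    def test_pair_mode_counts_either_direction(self):
        table = PairTable(records=[
            PairRecord("p1", "g", connected_ab=False, connected_ba=True),
            PairRecord("p2", "g", connected_ab=True, connected_ba=True),
            PairRecord("p3", "g", connected_ab=False, connected_ba=False),
        ])
        pair = connection_probability(table, mode="pair")
        directed = connection_probability(table, mode="directed")
        assert (pair.connected, pair.tested) == (2, 3)
        assert (directed.connected, directed.tested) == (3, 6)

    def test_pair_probability_at_least_directed(self):
        rng = np.random.default_rng(0)
        records = [PairRecord(f"p{i}", "g",
                              connected_ab=bool(rng.random() < 0.3),
                              connected_ba=bool(rng.random() < 0.3))
                   for i in range(200)]
        table = PairTable(records=records)
        assert (connection_probability(table, mode="pair").probability
                >= connection_probability(table, mode="directed").probability)

    def test_strata_filters(self):
        table = PairTable(records=[
            PairRecord("p1", "g", True, False, soma_distance_um=60,
                       axis="vertical", age_days=11),
            PairRecord("p2", "g", False, False, soma_distance_um=150,
                       axis="horizontal", age_days=14),
        ])
        est = connection_probability(table, axis="vertical", max_distance=100)
        assert (est.connected, est.tested) == (1, 1)

    def test_empty_stratum_error_names_filters(self):
        table = PairTable(records=[PairRecord("p1", "g", True)])
        with pytest.raises(ValueError, match="axis='vertical'"):
            connection_probability(table, axis="vertical")


class TestGroupComparison:
    def test_identical_groups_are_null(self):
        est = ProbabilityEstimate(30, 100)
        chi2, p = chi_square_2x2(est, ProbabilityEstimate(30, 100))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        # N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on 50/208 vs 20/208
        a, b, c, d = 50, 158, 20, 188
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        chi2, p = chi_square_2x2(ProbabilityEstimate(50, 208),
                                 ProbabilityEstimate(20, 208))
        assert chi2 == pytest.approx(expected)   # ~15.46
        assert chi2 == pytest.approx(15.46, abs=0.01)
        assert p < 0.001

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(ProbabilityEstimate(0, 10), ProbabilityEstimate(0, 20))

    def test_bh_hand_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])

    def test_bh_monotone_and_never_decreases(self):
        rng = np.random.default_rng(1)
        raw = rng.random(20)
        adj = benjamini_hochberg(raw)
        assert np.all(adj >= raw)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_family_adjustment_and_significance(self):
        estimates = {
            "cKO_50_100um": ProbabilityEstimate(50, 208),
            "WT_50_100um": ProbabilityEstimate(20, 208),
            "other": ProbabilityEstimate(30, 200),
        }
        comps = compare_groups(
            estimates,
            comparisons=[("cKO_50_100um", "WT_50_100um"), ("other", "WT_50_100um")],
            alpha=0.05)
        assert len(comps) == 2
        lead = comps[0]
        assert lead.p_adjusted >= lead.p_raw
        assert lead.significant


class TestBootstrap:
    def test_all_connected_has_zero_spread(self):
        table = exact_count_pair_table({"g": (10, 10)})
        est = bootstrap_probability(table, group="g", nboot=50, seed=0)
        assert est.bootstrap_sd == 0.0
        assert est.bootstrap_mean == 1.0

    def test_binomial_se_oracle(self):
        # p = 0.5, n = 100: SE = sqrt(0.25 / 100) = 0.05
        table = exact_count_pair_table({"g": (50, 100)})
        est = bootstrap_probability(table, group="g", nboot=1000, seed=1)
        assert est.bootstrap_sd == pytest.approx(0.05, rel=0.2)
        # bootstrap mean converges to the plug-in estimate (within 2 SE)
        assert abs(est.bootstrap_mean - 0.5) < 2 * 0.05 / np.sqrt(1000) * 10

    def test_deterministic_given_seed(self):
        table = exact_count_pair_table({"g": (12, 40)})
        a = bootstrap_probability(table, group="g", nboot=100, seed=7)
        b = bootstrap_probability(table, group="g", nboot=100, seed=7)
        assert a.bootstrap_mean == b.bootstrap_mean
        assert a.bootstrap_sd == b.bootstrap_sd

    def test_too_few_resamples_rejected(self):
        table = exact_count_pair_table({"g": (1, 5)})
        with pytest.raises(ValueError):
            bootstrap_probability(table, group="g", nboot=1, seed=0)


class TestSimilarityCurve:
    def test_noiseless_line_recovered_exactly(self):
        points = [(s, ProbabilityEstimate(int(round((0.12 - 0.09 * s) * 10000)),
                                          10000))
                  for s in (0.0, 0.25, 0.5, 1.0)]
        fit = similarity_connectivity_fit(points, nboot=10, seed=0)
        assert fit.slope == pytest.approx(-0.09, abs=1e-12)
        assert fit.intercept == pytest.approx(0.12, abs=1e-12)

    def test_published_counts_give_negative_slope(self):
        # similarity levels 1.0, 0.33, 0.11, 0 with their connected/tested
        points = [(1.0, ProbabilityEstimate(5, 134)),
                  (0.33, ProbabilityEstimate(14, 165)),
                  (0.11, ProbabilityEstimate(12, 117)),
                  (0.0, ProbabilityEstimate(12, 114))]
        fit = similarity_connectivity_fit(points, nboot=100, seed=2)
        assert fit.slope < 0
        assert fit.correlation_sign == -1

    def test_band_contains_point_estimates(self):
        points = [(1.0, ProbabilityEstimate(5, 134)),
                  (0.33, ProbabilityEstimate(14, 165)),
                  (0.11, ProbabilityEstimate(12, 117)),
                  (0.0, ProbabilityEstimate(12, 114))]
        fit = similarity_connectivity_fit(points, nboot=200, seed=3)
        assert np.all(fit.ci_lower <= fit.probability + 0.02)
        assert np.all(fit.probability - 0.02 <= fit.ci_upper)

    def test_too_few_levels_rejected(self):
        points = [(0.0, ProbabilityEstimate(1, 10)),
                  (1.0, ProbabilityEstimate(2, 10))]
        with pytest.raises(ValueError):
            similarity_connectivity_fit(points)


class TestPairTableIO:
    def test_tsv_roundtrip(self, tmp_path):
        table = PairTable(records=[
            PairRecord("p1", "a", True, False, soma_distance_um=80.0,
                       axis="vertical", age_days=12),
            PairRecord("p2", "b", False, None),
        ])
        path = table.to_tsv(tmp_path / "pairs.tsv")
        back = PairTable.from_tsv(path)
        assert len(back) == 2
        assert back.records[0].pair_connected
        assert back.records[1].connected_ba is None
        assert back.records[0].age_days == 12
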
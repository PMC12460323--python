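"""GeoDetector: discretization, q-statistic, interactions, sensitivity."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatioepi.geodetector import (
    Stratification,
    classify_interaction,
    discretize,
    factor_screen,
    interaction_detect,
    jenks_breaks,
    optimal_discretization,
    overlay,
    q_statistic,
    sensitivity_analysis,
)
from spatioepi.synthetic import simulate_stratified_covariate


def q_bruteforce(y, labels) -> float:
    """Record-by-record SSW/SST computation."""
    y = np.asarray(y, float)
    labels = np.asarray(labels)
    ssw = 0.0
    for h in set(labels.tolist()):
        grp = [yi for yi, li in zip(y, labels) if li == h]
        m = sum(grp) / len(grp)
        ssw += sum((yi - m) ** 2 for yi in grp)
    ybar = sum(y) / len(y)
    sst = sum((yi - ybar) ** 2 for yi in y)
    return 1.0 - ssw / sst


class TestDiscretize:
    def test_equal_interval_1_to_10(self):
        s = discretize(np.arange(1.0, 11.0), "equal_interval", 2)
        assert s.labels.tolist() == [0] * 5 + [1] * 5
        assert s.edges == pytest.approx([1.0, 5.5, 10.0])

    def test_quantile_equal_counts(self):
        s = discretize(np.arange(1.0, 11.0), "quantile", 2)
        assert np.bincount(s.labels).tolist() == [5, 5]

    def test_natural_breaks_beats_any_single_threshold(self, rng):
        """Two separated Gaussian clumps: Jenks finds the gap, and no single
        threshold yields lower within-class SSD (exhaustive oracle)."""
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(10, 1, 40)])
        s = discretize(x, "natural_breaks", 2)
        cut = s.edges[1]
        assert 2.0 < cut < 8.0

        def ssd_at(threshold):
            lo, hi = x[x <= threshold], x[x > threshold]
            return sum(((g - g.mean()) ** 2).sum() for g in (lo, hi) if len(g))

        best_oracle = min(ssd_at(t) for t in np.unique(x)[:-1])
        assert ssd_at(cut) == pytest.approx(best_oracle, rel=1e-12)

    def test_jenks_matches_exhaustive_three_classes(self, rng):
        x = rng.normal(size=25)
        edges = jenks_breaks(x, 3)
        labels = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, 2)
        got = q_bruteforce(x, labels)  # within-SSD via 1 - q on x itself
        v = np.sort(x)
        best = -np.inf
        for i, j in itertools.combinations(range(1, 25), 2):
            lab = np.zeros(25, int)
            lab[i:j] = 1
            lab[j:] = 2
            best = max(best, q_bruteforce(v, lab))
        assert got == pytest.approx(best, abs=1e-12)

    def test_geometric_positive_progression(self):
        x = np.geomspace(1.0, 256.0, 50)
        s = discretize(x, "geometric", 4)
        ratios = np.diff(np.log(s.edges))
        assert np.allclose(ratios, ratios[0])

    def test_geometric_shifts_nonpositive(self):
        x = np.linspace(-5.0, 5.0, 30)
        s = discretize(x, "geometric", 3)
        assert s.n_strata >= 2
        assert s.edges[0] == pytest.approx(-5.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            discretize(np.ones(10), "quantile", 2)

    @given(st.integers(2, 6), st.sampled_from(["equal_interval", "quantile", "natural_breaks", "geometric"]))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_every_record_labeled(self, k, method):
        rng = np.random.default_rng(k)
        x = rng.normal(size=60)
        s = discretize(x, method, k)
        assert len(s.labels) == 60
        assert set(np.unique(s.labels)) == set(range(s.n_strata))
        assert 2 <= s.n_strata <= k


class TestQStatistic:
    def test_perfectly_stratified(self):
        y = np.repeat([1.0, 5.0, 9.0], 10)
        r = q_statistic(y, np.repeat([0, 1, 2], 10))
        assert r.q == pytest.approx(1.0)
        assert r.p == 0.0

    def test_closed_loop_with_generator(self):
        strata = np.repeat(np.arange(5), 10)
        for q0 in (0.0, 0.3, 0.7):
            sec, _ = simulate_stratified_covariate(strata, q0, seed=1)
            assert q_statistic(sec.values, strata).q == pytest.approx(q0, abs=1e-10)

    def test_matches_bruteforce(self, rng):
        y = rng.normal(size=80)
        labels = rng.integers(0, 4, size=80)
        assert q_statistic(y, labels).q == pytest.approx(q_bruteforce(y, labels), abs=1e-12)

    def test_affine_invariance(self, rng):
        y = rng.normal(size=60)
        labels = rng.integers(0, 3, size=60)
        q1 = q_statistic(y, labels).q
        q2 = q_statistic(-2.0 * y + 5.0, labels).q
        assert q2 == pytest.approx(q1, abs=1e-10)

    def test_single_stratum_warns_q_zero(self):
        with pytest.warns(UserWarning, match="single stratum"):
            r = q_statistic(np.arange(5.0), np.zeros(5))
        assert r.q == 0.0

    def test_null_f_calibration(self):
        """Random strata: noncentral-F rejection stays near nominal alpha."""
        rng = np.random.default_rng(4)
        n_sim = 1000
        rej = {0.01: 0, 0.05: 0}
        for _ in range(n_sim):
            y = rng.normal(size=120)
            labels = rng.integers(0, 4, size=120)
            p = q_statistic(y, labels).p
            for a in rej:
                rej[a] += p < a
        for a, k in rej.items():
            assert k / n_sim <= a + 0.02

    def test_null_mostly_nonsignificant(self, rng):
        hits = sum(
            q_statistic(rng.normal(size=200), rng.integers(0, 5, size=200)).p < 0.05
            for _ in range(500)
        )
        assert hits / 500 <= 0.10


class TestOptimalDiscretization:
    def test_piecewise_constant_reaches_q1(self):
        x = np.concatenate([np.linspace(0, 1, 16), np.linspace(5, 6, 16), np.linspace(10, 11, 16)])
        y = np.repeat([0.0, 10.0, -3.0], 16)
        s, qr, table = optimal_discretization(x, y, class_range=(3, 5))
        assert qr.q == pytest.approx(1.0, abs=1e-12)
        assert s.n_strata == 3  # ties broken toward fewer classes

    def test_matches_exhaustive_grid(self, rng):
        x = rng.normal(size=100)
        y = x**2 + rng.normal(0, 0.3, size=100)
        s, qr, table = optimal_discretization(x, y, class_range=(3, 6))
        assert qr.q == pytest.approx(table["q"].max())

    def test_method_tie_break_order(self):
        """Exact ties resolve by the documented method order."""
        x = np.arange(1.0, 13.0)
        y = np.repeat([0.0, 1.0], 6)  # both 2-class methods split identically
        s, qr, table = optimal_discretization(
            x, y, methods=("quantile", "equal_interval"), class_range=(2, 2)
        )
        assert s.method == "equal_interval"

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="candidate"):
            optimal_discretization(np.ones(20), np.arange(20.0))


class TestInteraction:
    def test_correlated_additive_is_bilinear(self, rng):
        """Two correlated drivers: overlay explains more than either alone but
        less than their sum."""
        n = 400
        u = rng.normal(size=n)
        z1 = u + 0.6 * rng.normal(size=n)
        z2 = u + 0.6 * rng.normal(size=n)
        y = z1 + z2 + 0.3 * rng.normal(size=n)
        s1 = discretize(z1, "quantile", 4, "z1")
        s2 = discretize(z2, "quantile", 4, "z2")
        res = interaction_detect(y, s1, s2)
        assert res.q12 > max(res.q1, res.q2)
        assert res.q12 < res.q1 + res.q2 - 0.01
        assert res.category == "enhance_bilinear"

    def test_xor_pattern_is_nonlinear_enhancement(self, rng):
        n = 400
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        y = (a ^ b).astype(float) + 0.05 * rng.normal(size=n)
        res = interaction_detect(
            y, Stratification("a", a, 2), Stratification("b", b, 2)
        )
        assert res.q1 < 0.05 and res.q2 < 0.05 and res.q12 > 0.9
        assert res.category == "enhance_nonlinear"

    def test_duplicate_factor_resolved_by_tolerance_rules(self, rng):
        y = rng.normal(size=100)
        labels = rng.integers(0, 3, 100)
        s = Stratification("f", labels, 3)
        res = interaction_detect(y, s, s)
        assert res.q12 == pytest.approx(res.q1, abs=1e-12)
        if abs(res.q12 - (res.q1 + res.q2)) <= 0.01:
            assert res.category == "independent"
        else:
            assert res.category == "weaken_unilateral"

    def test_additive_independent_factors_classified_independent(self, rng):
        """Balanced, independent additive drivers satisfy q12 ~ q1 + q2."""
        reps = 60
        a = np.repeat(np.arange(3), 3 * reps)
        b = np.tile(np.repeat(np.arange(3), reps), 3)  # full factorial: exact balance
        y = a + 2.0 * b + 0.1 * rng.normal(size=a.size)
        res = interaction_detect(
            y, Stratification("a", a, 3), Stratification("b", b, 3)
        )
        assert res.category == "independent"

    def test_overlay_monotonicity_200_random_pairs(self, rng):
        """Refining a stratification can never lower q."""
        for _ in range(200):
            n = rng.integers(30, 80)
            y = rng.normal(size=n)
            l1 = rng.integers(0, rng.integers(2, 5), n)
            l2 = rng.integers(0, rng.integers(2, 5), n)
            s1 = Stratification("a", l1, int(l1.max()) + 1)
            s2 = Stratification("b", l2, int(l2.max()) + 1)
            q1 = q_statistic(y, s1).q
            q2 = q_statistic(y, s2).q
            q12 = q_statistic(y, overlay(s1, s2)).q
            assert q12 >= max(q1, q2) - 1e-12

    @pytest.mark.parametrize(
        "q1,q2,q12,expected",
        [
            (0.3, 0.4, 0.702, "independent"),
            (0.3, 0.4, 0.9, "enhance_nonlinear"),
            (0.3, 0.4, 0.5, "enhance_bilinear"),
            (0.3, 0.4, 0.2, "weaken_nonlinear"),
            (0.3, 0.4, 0.35, "weaken_unilateral"),
        ],
    )
    def test_classification_rules(self, q1, q2, q12, expected):
        assert classify_interaction(q1, q2, q12) == expected


class TestScreenAndSensitivity:
    def test_planted_factor_ranked_first(self, planted_factor_panel):
        panel, strata, _ = planted_factor_panel
        table = factor_screen(panel, class_range=(3, 6))
        top = table[table["rank"] == 1]
        assert (top["factor"] == "strong").all()
        strong = table[(table["factor"] == "strong") & (table["window"] == "overall")]
        assert strong["q"].iloc[0] > 0.7
        assert strong["significant"].all()

    def test_true_stratification_is_q_ceiling(self, planted_factor_panel):
        panel, strata, q_true = planted_factor_panel
        from spatioepi.panel import cumulative

        y = cumulative(panel, op="mean").values
        q_direct = q_statistic(y, strata).q
        assert q_direct == pytest.approx(0.8, abs=1e-10)

    def test_alpha_one_flags_everything(self, planted_factor_panel):
        panel, _, _ = planted_factor_panel
        table = factor_screen(panel, alpha=1.0, class_range=(3, 4))
        assert table["significant"].all()

    def test_zero_perturbation_no_change(self, planted_factor_panel):
        panel, _, _ = planted_factor_panel
        res = sensitivity_analysis(panel, perturb_fraction=0.0, n_replicates=3, seed=1)
        assert all(v == 0.0 for v in res.per_factor.values())
        assert res.mean_rel_change == 0.0

    def test_fixed_seed_bit_identical(self, planted_factor_panel):
        panel, _, _ = planted_factor_panel
        a = sensitivity_analysis(panel, n_replicates=5, seed=9)
        b = sensitivity_analysis(panel, n_replicates=5, seed=9)
        assert a.per_factor == b.per_factor
        assert a.mean_rel_change == b.mean_rel_change

    def test_strong_factor_stable_under_10pct(self, planted_factor_panel):
        panel, _, _ = planted_factor_panel
        res = sensitivity_analysis(
            panel, ["strong"], perturb_fraction=0.10, n_replicates=20, seed=3
        )
        assert res.per_factor["strong"] < 0.10
        assert res.stable
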
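import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ventiqct as vq
from ventiqct.stats import strength_category


class TestPearson:
    def test_matches_brute_force_covariance(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x, y = rng.standard_normal((2, 60))
            xc, yc = x - x.mean(), y - y.mean()
            brute = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
            assert vq.pearson(x, y).r == pytest.approx(brute, abs=1e-12)

    def test_self_correlation(self):
        x = np.arange(10.0)
        res = vq.pearson(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.strength == "very strong"
        assert res.large_effect

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2, np.nan, 4, 5])
        y = np.array([2.0, 4, 6, np.nan, 10])
        res = vq.pearson(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            vq.pearson([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError, match=">= 3"):
            vq.pearson([1, 2], [3, 4])
        with pytest.raises(ValueError, match="missing"):
            vq.pearson([1, np.nan, 3], [1, 2, 3], missing="raise")

    @given(st.floats(min_value=-1.0, max_value=1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_strength_bands_are_exhaustive_and_exclusive(self, r):
        cat = strength_category(r)
        a = abs(r)
        expected = (
            "negligible" if a <= 0.3 else
            "weak" if a <= 0.5 else
            "moderate" if a <= 0.7 else
            "strong" if a <= 0.9 else
            "very strong"
        )
        assert cat == expected


class TestPartialCorrelation:
    def test_matches_residual_construction(self):
        """r(a,b|c) equals the correlation of the residuals of a~c and b~c."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            c = rng.standard_normal(80)
            a = 0.6 * c + rng.standard_normal(80)
            b = -0.3 * c + rng.standard_normal(80)
            ra = a - np.polyval(np.polyfit(c, a, 1), c)
            rb = b - np.polyval(np.polyfit(c, b, 1), c)
            expected = np.corrcoef(ra, rb)[0, 1]
            got, n = vq.partial_correlation(a, b, c)
            assert got == pytest.approx(expected, abs=1e-10)
            assert n == 80

    def test_perfect_conditioning_rejected(self):
        c = np.arange(10.0)
        with pytest.raises(ValueError, match="perfectly correlated"):
            vq.partial_correlation(c, np.random.default_rng(0).normal(size=10), c)


class TestCorrelationMap:
    def test_pooled_map_reproduces_cohort_cells(self, cohort_tables):
        tab = vq.subject_visit_table(cohort_tables)
        cm = vq.correlation_map(
            tab, ["CV_Total", "TC_Max"], ["fSAD_Total", "Emph_Total"],
            mode="cross_sectional_pooled",
        )
        assert cm.loc["CV_Total", "fSAD_Total"].r == pytest.approx(0.90, abs=0.05)
        assert cm.loc["TC_Max", "Emph_Total"].r == pytest.approx(0.77, abs=0.05)
        assert cm.loc["CV_Total", "fSAD_Total"].large_effect

    def test_delta_map_from_per_visit_values(self, cohort_tables):
        tab = vq.subject_visit_table(cohort_tables)
        cm = vq.correlation_map(
            tab, ["TC_Max"], ["fSAD_Total"], mode="delta(V2-V0)"
        )
        res = cm.loc["TC_Max", "fSAD_Total"]
        assert res.n == 6  # two subjects lack the V0 SPECT visit
        assert res.r == pytest.approx(-0.70, abs=0.05)

    def test_self_correlation_diagonal(self, cohort_tables):
        tab = vq.subject_visit_table(cohort_tables)
        cm = vq.correlation_map(tab, ["CV_Total"], ["CV_Total"])
        assert cm.loc["CV_Total", "CV_Total"].r == 1.0

    def test_unknown_mode_rejected(self, cohort_tables):
        tab = vq.subject_visit_table(cohort_tables)
        with pytest.raises(ValueError, match="unknown mode"):
            vq.correlation_map(tab, ["CV_Total"], ["fSAD_Total"], mode="delta(V3-V0)")

    def test_too_few_delta_subjects_rejected(self, cohort_tables):
        tab = vq.subject_visit_table(cohort_tables).drop(
            index=[3, 4, 5, 6], level="subject"
        )
        with pytest.raises(ValueError, match="subjects"):
            vq.correlation_map(tab, ["CV_Total"], ["fSAD_Total"], mode="delta(V2-V0)")


def _factor_data(seed, n=500, p=12, k=3, load=0.8):
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, k))
    L = np.zeros((p, k))
    for j in range(p):
        L[j, j % k] = load
    return F @ L.T + rng.standard_normal((n, p)) * np.sqrt(1 - load**2)


class TestParallelAnalysis:
    def test_recovers_three_factors(self):
        hits = sum(
            vq.parallel_analysis(_factor_data(s), n_reps=100, seed=s) == 3
            for s in range(10)
        )
        assert hits >= 9

    def test_pure_noise_retains_nothing(self):
        X = np.random.default_rng(11).standard_normal((300, 10))
        assert vq.parallel_analysis(X, n_reps=200, seed=0) == 0

    def test_errors(self):
        with pytest.raises(ValueError, match="n_reps"):
            vq.parallel_analysis(_factor_data(0), n_reps=0)
        X = _factor_data(0)
        X[:, 0] = 2.0
        with pytest.raises(ValueError, match="constant"):
            vq.parallel_analysis(X, n_reps=10, seed=0)


class TestEFAVarimax:
    def test_recovers_disjoint_blocks(self):
        """Variables built from three disjoint factors load > 0.6 on exactly
        one rotated factor each."""
        res = vq.efa_varimax(_factor_data(3), n_factors=3)
        claimed = [v for vars_ in res.key_variables.values() for v in vars_]
        assert sorted(claimed) == sorted(res.loadings.index)  # each var exactly once
        for factor, vars_ in res.key_variables.items():
            assert len(vars_) == 4

    def test_single_factor_rotation_is_identity(self):
        L = np.random.default_rng(0).uniform(0.3, 0.9, (6, 1))
        Lr, R, _ = vq.varimax(L)
        assert np.allclose(Lr, L)
        assert np.allclose(R, np.eye(1))

    def test_rotation_preserves_communalities(self):
        """Orthogonal rotation leaves L L^T (and hence the per-variable
        communalities) unchanged."""
        X = _factor_data(5)
        corr = np.corrcoef(X, rowvar=False)
        evals, evecs = np.linalg.eigh(corr)
        idx = np.argsort(evals)[::-1][:3]
        L = evecs[:, idx] * np.sqrt(evals[idx])
        Lr, R, _ = vq.varimax(L)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-10)
        assert np.allclose(Lr @ Lr.T, L @ L.T, atol=1e-10)

    def test_invariant_to_variable_ordering(self):
        X = _factor_data(9)
        res1 = vq.efa_varimax(pd.DataFrame(X, columns=[f"v{i}" for i in range(12)]), 3)
        perm = np.random.default_rng(1).permutation(12)
        res2 = vq.efa_varimax(
            pd.DataFrame(X[:, perm], columns=[f"v{i}" for i in perm]), 3
        )
        # same key-variable partition regardless of column order
        part1 = {frozenset(v) for v in res1.key_variables.values()}
        part2 = {frozenset(v) for v in res2.key_variables.values()}
        assert part1 == part2

    def test_bad_factor_count_rejected(self):
        with pytest.raises(ValueError):
            vq.efa_varimax(_factor_data(0), 0)
        with pytest.raises(ValueError):
            vq.efa_varimax(_factor_data(0), 13)


class TestCrossLaggedPanel:
    def test_degenerate_panel_rejected(self):
        """x2 == x1 and y2 == y1: stability correlations are 1 and the
        cross-lagged partials are undefined."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(10)
        y = 0.5 * x + rng.standard_normal(10)
        with pytest.raises(ValueError, match="partials undefined"):
            vq.cross_lagged_panel(x, x, y, y)

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            vq.cross_lagged_panel([1, 2, 3], [2, 3, 4], [1, 3, 2], [2, 4, 3])

    def test_recovers_seeded_causal_direction(self):
        hits = 0
        for i in range(30):
            df = vq.make_panel_dataset(200, 0.5, seed=1000 + i)
            res = vq.cross_lagged_panel(df.x1, df.x2, df.y1, df.y2)
            if res.causal_direction == "x->y":
                hits += 1
        assert hits >= 24  # >= 80% of replicates

    def test_all_six_correlations_reported(self):
        df = vq.make_panel_dataset(100, 0.3, seed=5)
        res = vq.cross_lagged_panel(df.x1, df.x2, df.y1, df.y2)
        assert set(res.p_values) == {
            "r_sync1", "r_sync2", "r_stab_x", "r_stab_y", "r_cross_xy", "r_cross_yx",
        }
        assert set(res.assumption_flags) == {"synchronicity", "stationarity"}
        assert -1 <= res.r_cross_xy <= 1
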
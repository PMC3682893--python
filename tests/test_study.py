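"""Strain summaries, Spearman permutation tests, combination classification."""

import itertools
import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from persisterfit import (
    AnalysisConfig,
    FractionInterval,
    classify_combination,
    cross_antibiotic_correlations,
    parameter_determinants,
    spearman,
    summarize_strain,
)
from persisterfit.inference import FitResult, KillCurve, Observation
from persisterfit.synthetic import switching_rate_for_fraction


def fake_fit(fp_mid, strain="s", treatment="d", converged=True, flags=()):
    obs = tuple(Observation(float(t), 1, 1e-5) for t in range(6))
    curve = KillCurve(strain, treatment, "r", obs)
    fr = FractionInterval(0.0, fp_mid, 2 * fp_mid) if fp_mid is not None else None
    return FitResult(
        curve=curve, obs_hat=None, loglik=-1.0, fraction=fr, mech_hat=None,
        slow_fraction=fp_mid, theta_hat=None, starts=(), converged=converged,
        flags=tuple(flags),
    )


class TestSummarizeStrain:
    def test_constant_replicates(self):
        s = summarize_strain([fake_fit(1e-3) for _ in range(3)])
        assert s.mean_log10_fp == pytest.approx(-3.0)
        assert s.se_log10_fp == pytest.approx(0.0)
        assert s.n_replicates == 3

    def test_two_point_log_arithmetic(self):
        s = summarize_strain([fake_fit(1e-2), fake_fit(1e-4)])
        assert s.mean_log10_fp == pytest.approx(-3.0)
        assert s.se_log10_fp == pytest.approx(1.0)

    def test_nonconverged_excluded_from_count(self):
        fits = [fake_fit(1e-3), fake_fit(1e-3, converged=False), fake_fit(None, converged=False)]
        s = summarize_strain(fits)
        assert s.n_replicates == 1
        assert s.n_nonconverged == 2

    def test_detection_limited_contributes_upper_bound(self):
        # flagged fit reports fp_max, not the midpoint
        f = fake_fit(5e-4, flags=("detection_limit",))
        s = summarize_strain([f])
        assert s.mean_log10_fp == pytest.approx(math.log10(1e-3))
        assert s.n_detection_limited == 1

    def test_no_usable_fit_yields_unavailable_summary(self):
        s = summarize_strain([fake_fit(None, converged=False)])
        assert not s.available
        assert s.n_replicates == 0


def brute_force_spearman(x, y):
    """Independent rank-based oracle: average ranks + Pearson product formula."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    den = math.sqrt((rx @ rx) * (ry @ ry))
    return float("nan") if den == 0 else float(rx @ ry / den)


class TestSpearman:
    def test_comonotone_is_one(self):
        r = spearman([1, 2, 3, 4], [2, 3, 5, 9])
        assert r.rho == pytest.approx(1.0)
        # exact two-sided enumeration: only identity and reversal reach |rho|=1
        assert r.p_value == pytest.approx(2 / 24)
        assert r.method == "exact-permutation"

    def test_three_point_example(self):
        r = spearman([1, 2, 3], [3, 1, 2])
        assert r.rho == pytest.approx(-0.5)

    def test_matches_brute_force_with_and_without_ties(self):
        rng = np.random.default_rng(21)
        for n in range(3, 9):
            for _ in range(25):
                x = rng.integers(0, 5, n).astype(float)  # heavy ties
                y = rng.normal(size=n)
                r = spearman(x, y)
                expect = brute_force_spearman(x, y)
                if math.isnan(expect):
                    assert r.flag == "constant-input"
                else:
                    assert r.rho == pytest.approx(expect, abs=1e-12)

    def test_constant_vector_flagged(self):
        r = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert math.isnan(r.rho)
        assert r.flag == "constant-input"

    def test_monte_carlo_seeded_and_in_unit_interval(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        cfg = AnalysisConfig(seed=7, n_permutations=2000)
        r1, r2 = spearman(x, y, cfg), spearman(x, y, cfg)
        assert r1.p_value == r2.p_value
        assert 0 < r1.p_value <= 1
        assert r1.method == "monte-carlo"

    def test_permutation_p_consistent_with_exact_at_boundary(self):
        # MC on a forced-large n uses the add-one estimator; sanity vs exact n=6
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]
        exact = spearman(x, y)
        mc = spearman(x, y, AnalysisConfig(seed=1, n_permutations=20000, exact_max_n=2))
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)


class TestCrossAntibioticCorrelations:
    @staticmethod
    def frame(fp_by_strain_treatment):
        return pd.DataFrame(
            [
                {"strain": s, "treatment": t, "mean_log10_fp": v, "se_log10_fp": 0.1}
                for (s, t), v in fp_by_strain_treatment.items()
            ]
        )

    def test_perfectly_shared_fractions_give_rho_one(self):
        vals = {}
        for i, s in enumerate("abcdefgh"):
            for t in ("amp", "cip"):
                vals[(s, t)] = -5 + 0.5 * i
        res, skipped = cross_antibiotic_correlations(self.frame(vals))
        assert not skipped
        assert len(res) == 1
        assert res[0].rho == pytest.approx(1.0)
        assert res[0].n == 8

    def test_incomplete_strains_dropped_and_small_pairs_skipped(self):
        vals = {("a", "amp"): -3, ("b", "amp"): -4, ("a", "cip"): -2, ("b", "cip"): -5}
        res, skipped = cross_antibiotic_correlations(self.frame(vals))
        assert res == []
        assert "2 complete strain pairs" in skipped[0]


class TestClassifyCombination:
    def test_coincident_case(self):
        call = classify_combination(1e-2, 1e-3, 1.2e-3)
        assert call.label == "coincident"
        assert call.d_coincident == pytest.approx(abs(math.log10(1.2)), abs=1e-9)
        assert call.d_independent == pytest.approx(abs(math.log10(1.2e-3) + 5), abs=1e-9)

    def test_independent_case(self):
        call = classify_combination(1e-2, 1e-3, 1e-5)
        assert call.label == "independent"
        assert call.d_independent == pytest.approx(0.0, abs=1e-12)

    def test_below_detection_is_exclusive_regardless(self):
        cfg = AnalysisConfig(detection_bound=1e-6)
        assert classify_combination(1e-2, 1e-3, 5e-7, cfg).label == "exclusive"
        assert classify_combination(1e-2, 1e-3, 0.0, cfg).label == "exclusive"

    def test_far_from_both_hypotheses_is_ambiguous(self):
        call = classify_combination(1e-1, 1e-1, 1e-4)
        assert call.label == "ambiguous"

    def test_nonpositive_single_fraction_rejected(self):
        with pytest.raises(ValueError):
            classify_combination(0.0, 1e-3, 1e-4)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        f_a=st.floats(1e-4, 0.1), f_b=st.floats(1e-4, 0.1),
        ratio=st.floats(0.4, 2.5), k=st.floats(0.05, 1.0),
    )
    def test_scale_equivariance_of_nonexclusive_labels(self, f_a, f_b, ratio, k):
        # multiply all three fractions by a common factor in (0, 1]
        f_ab = min(f_a, f_b) * ratio
        cfg = AnalysisConfig(detection_bound=1e-12)
        l1 = classify_combination(f_a, f_b, f_ab, cfg).label
        l2 = classify_combination(k * f_a, k * f_b, k * f_ab, cfg).label
        if l1 != "independent" and l2 != "independent":
            # d_ind is not scale-invariant (log10 f_AB - log10 f_A f_B shifts by -log10 k)
            assert l1 == l2


class TestParameterDeterminants:
    def test_fraction_tracks_entry_rate(self):
        fps = np.logspace(-5, -1, 15)
        table = pd.DataFrame(
            {
                "fp": fps,
                "a": [switching_rate_for_fraction(f, 0.01, 2.0) for f in fps],
                "b": 0.01,
                "m": 2.0,
            }
        )
        res = parameter_determinants(table)
        assert len(res) == 3
        by = {r.pair[1]: r for r in res}
        assert by["a"].rho > 0.9
        assert by["b"].flag == "constant-input"
        assert by["m"].flag == "constant-input"

    def test_unrelated_exit_rate_shows_no_correlation(self):
        rng = np.random.default_rng(2)
        n = 30
        fps = 10 ** rng.uniform(-5, -1, n)
        table = pd.DataFrame(
            {"fp": fps, "a": fps * 2.0, "b": 10 ** rng.uniform(-4, -1, n), "m": 2.0}
        )
        by = {r.pair[1]: r for r in parameter_determinants(table)}
        assert abs(by["b"].rho) < 0.36  # 5% two-sided critical value at n=30
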
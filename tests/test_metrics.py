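import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dissolvekit.metrics import (
    dissolution_efficiency,
    fold_change,
    mean_dissolution_time,
    monotonize,
    similarity_factor,
    summarize_profiles,
)
from dissolvekit.profiles import DissolutionProfile

from conftest import random_monotone_profile

GRID = np.array([0.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0])


def profile(label, dissolved, times=GRID):
    return DissolutionProfile(label, times, np.asarray(dissolved, dtype=float))


class TestSimilarityFactor:
    def test_identity_is_exactly_100(self, fast_profile):
        assert similarity_factor(fast_profile, fast_profile) == 100.0

    def test_constant_ten_point_gap_closed_form(self):
        r = profile("r", [0, 10, 20, 30, 50, 70, 90])
        t = profile("t", [0, 20, 30, 40, 60, 80, 100])
        expected = 100.0 - 25.0 * np.log10(101.0)  # = 49.8920
        assert similarity_factor(r, t) == pytest.approx(expected, abs=1e-9)
        assert similarity_factor(r, t) == pytest.approx(49.892, abs=1e-3)

    def test_symmetric_in_arguments(self, fast_profile, slow_profile):
        assert similarity_factor(fast_profile, slow_profile) == pytest.approx(
            similarity_factor(slow_profile, fast_profile)
        )

    def test_strictly_decreases_with_divergence(self):
        r = profile("r", [0, 10, 20, 30, 50, 70, 90])
        scores = []
        for gap in (2.0, 5.0, 12.0, 25.0):
            t = profile("t", r.dissolved + np.array([0, 0, 0, gap, 0, 0, 0]))
            scores.append(similarity_factor(r, t))
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_unaligned_grids_error(self, fast_profile):
        other = profile("o", [0, 5, 15, 25, 40, 60], times=np.array([0, 10, 20, 30, 40, 50.0]))
        with pytest.raises(ValueError, match="align_profiles"):
            similarity_factor(fast_profile, other)

    def test_t0_inclusion_flag(self):
        r = profile("r", [0, 10, 20, 30, 50, 70, 90])
        t = profile("t", [0, 20, 30, 40, 60, 80, 100])
        # including the (0,0) point shrinks the mean squared gap -> higher f2
        assert similarity_factor(r, t, include_t0=True) > similarity_factor(r, t)


class TestDissolutionEfficiency:
    def test_instant_dissolution_gives_100(self):
        p = profile("inst", [100.0] * len(GRID))
        assert dissolution_efficiency(p, 60.0) == pytest.approx(100.0)

    def test_linear_rise_gives_50(self):
        p = DissolutionProfile("lin", [0.0, 60.0], [0.0, 100.0])
        assert dissolution_efficiency(p, 60.0) == pytest.approx(50.0)

    def test_t_end_interpolated_when_unsampled(self):
        p = DissolutionProfile("lin", [0.0, 60.0], [0.0, 100.0])
        assert dissolution_efficiency(p, 45.0) == pytest.approx(37.5)

    def test_no_extrapolation(self, fast_profile):
        with pytest.raises(ValueError, match="extrapolation"):
            dissolution_efficiency(fast_profile, 120.0)

    def test_invariant_to_collinear_points(self):
        p = DissolutionProfile("a", [0.0, 30.0, 60.0], [0.0, 50.0, 100.0])
        q = DissolutionProfile("b", [0.0, 15.0, 30.0, 45.0, 60.0], [0.0, 25.0, 50.0, 75.0, 100.0])
        assert dissolution_efficiency(p, 60) == pytest.approx(dissolution_efficiency(q, 60))

    def test_de15_le_de60_after_monotonization(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = monotonize(random_monotone_profile(rng, 7))
            if p.times[-1] >= 60.0:
                assert dissolution_efficiency(p, 15.0) <= dissolution_efficiency(p, 60.0) + 1e-12


class TestMeanDissolutionTime:
    def test_single_interval_gives_midpoint(self):
        p = DissolutionProfile("one", [0.0, 10.0], [0.0, 100.0])
        assert mean_dissolution_time(p) == pytest.approx(5.0)

    def test_equal_increments_give_mean_of_midpoints(self):
        p = profile("eq", np.linspace(0, 60, 7) * (100.0 / 60.0), times=np.linspace(0, 60, 7))
        mid = 0.5 * (np.linspace(0, 60, 7)[:-1] + np.linspace(0, 60, 7)[1:])
        assert mean_dissolution_time(p) == pytest.approx(mid.mean())

    def test_exponential_limit_is_one_over_k(self):
        t = np.arange(0.0, 70.0001, 0.05)
        p = DissolutionProfile("exp", t, 100.0 * (1.0 - np.exp(-0.1 * t)))
        assert mean_dissolution_time(p) == pytest.approx(10.0, rel=0.02)

    def test_time_shift_adds_exactly_delta(self):
        rng = np.random.default_rng(11)
        p = random_monotone_profile(rng)
        delta = 7.5
        # genuine delay: nothing dissolves until t=delta, then the curve repeats
        shifted = DissolutionProfile(
            "sh",
            np.concatenate([[0.0, delta], p.times[1:] + delta]),
            np.concatenate([[0.0, 0.0], p.dissolved[1:]]),
        )
        base = mean_dissolution_time(p)
        assert mean_dissolution_time(shifted) == pytest.approx(base + delta)

    def test_flat_profile_errors(self):
        with pytest.raises(ValueError, match="no dissolution"):
            mean_dissolution_time(profile("flat", [0.0] * len(GRID)))

    def test_unanchored_profile_warns(self):
        p = DissolutionProfile("x", [5.0, 10.0], [10.0, 20.0])
        with pytest.warns(UserWarning, match="t=0"):
            mean_dissolution_time(p)


class TestRectangleSumOracle:
    """Trapezoid DE and midpoint MDT vs an independent fine rectangle sum."""

    @staticmethod
    def oracle_de(p, t_end, substeps=10_000):
        t = np.linspace(0.0, t_end, substeps + 1)
        y = np.interp(t, p.times, p.dissolved)
        mid = 0.5 * (y[:-1] + y[1:])
        return 100.0 * np.sum(mid * np.diff(t)) / (100.0 * t_end)

    @staticmethod
    def oracle_mdt(p, substeps=10_000):
        t = np.linspace(0.0, p.times[-1], substeps + 1)
        m = np.interp(t, p.times, p.dissolved)
        dm = np.diff(m)
        mid = 0.5 * (t[:-1] + t[1:])
        return np.sum(mid * dm) / np.sum(dm)

    def test_random_profiles_agree_within_half_percent(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            p = random_monotone_profile(rng)
            t_end = p.times[-1]
            de = dissolution_efficiency(p, t_end)
            assert de == pytest.approx(self.oracle_de(p, t_end), rel=5e-3)
            mdt = mean_dissolution_time(p)
            assert mdt == pytest.approx(self.oracle_mdt(p), rel=5e-3)


class TestFoldChange:
    @pytest.mark.parametrize(
        "test,ref,expected",
        [(76.35, 7.05, 10.83), (96.89, 28.30, 3.42), (5.0, 5.0, 1.00)],
    )
    def test_two_decimal_reporting(self, test, ref, expected):
        assert fold_change(test, ref) == expected

    def test_raw_ratio_retained(self):
        assert fold_change(76.35, 7.05, rounded=False) == pytest.approx(76.35 / 7.05)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    increments=st.lists(st.floats(0.0, 25.0), min_size=6, max_size=6),
    gaps=st.lists(st.floats(-15.0, 15.0), min_size=6, max_size=6),
)
def test_f2_symmetry_and_bound_property(increments, gaps):
    """For arbitrary monotone reference curves and bounded perturbations,
    f2 is symmetric in its arguments and never exceeds 100."""
    base = np.concatenate([[0.0], np.cumsum(increments)])
    perturbed = np.maximum(base + np.concatenate([[0.0], gaps]), 0.0)
    r = DissolutionProfile("r", GRID, base)
    t = DissolutionProfile("t", GRID, perturbed)
    f_rt = similarity_factor(r, t)
    assert f_rt == pytest.approx(similarity_factor(t, r), abs=1e-12)
    assert f_rt <= 100.0


def test_summary_table_columns(fast_profile, slow_profile):
    df = summarize_profiles([slow_profile, fast_profile], reference_label="slow")
    assert list(df["label"]) == ["slow", "fast"]
    row = df[df.label == "fast"].iloc[0]
    assert row["de15"] > df[df.label == "slow"].iloc[0]["de15"]
    assert row["f2"] < 50  # fast vs slow are grossly dissimilar
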
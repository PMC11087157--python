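"""Slope-ratio equivalence and reduction planning."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icmreduce import (
    ConfigError,
    DegenerateInputError,
    SlopeFit,
    equivalent_concentration,
    iodine_reduction,
    reduction_matrix,
)
from icmreduce.fit import FIT_COLUMNS


def fit(alpha, se=0.0, size="small", energy=50.0, mode="DECT-VMI", scanner="s", recon="ir"):
    return SlopeFit((scanner, mode, energy, size, recon), alpha, se, 1.0, 10)


def fits_frame(rows):
    """rows: (scanner, mode, energy, size, recon, alpha, alpha_se)"""
    data = [
        dict(
            zip(
                FIT_COLUMNS,
                [r[0], r[1], r[2], r[3], r[4], r[5], r[6], 1.0, 10, None, None, False],
            )
        )
        for r in rows
    ]
    return pd.DataFrame(data, columns=FIT_COLUMNS)


class TestEquivalentConcentration:
    def test_equal_slopes_identity(self):
        assert equivalent_concentration(10.0, fit(2.0), fit(2.0)) == pytest.approx(10.0)

    def test_double_slope_halves_concentration(self):
        assert equivalent_concentration(10.0, fit(1.5), fit(3.0)) == pytest.approx(5.0)

    def test_agrees_with_grid_search_oracle(self, rng):
        grid = np.arange(1, 30001) * 0.001
        for _ in range(25):
            ab = rng.uniform(0.5, 5.0)
            at = ab * 10.0 / rng.uniform(1.0, 29.0)
            c_formula = equivalent_concentration(10.0, fit(ab), fit(at))
            c_grid = grid[np.argmin(np.abs(at * grid - ab * 10.0))]
            assert abs(c_formula - c_grid) <= 0.001

    def test_degenerate_target_slope_rejected(self):
        with pytest.raises(DegenerateInputError):
            equivalent_concentration(10.0, fit(2.0), fit(0.0))

    def test_cross_size_refused_by_default_and_overridable(self):
        base, target = fit(2.0, size="small"), fit(3.0, size="large")
        with pytest.raises(ConfigError):
            equivalent_concentration(10.0, base, target)
        with pytest.warns(UserWarning):
            v = equivalent_concentration(10.0, base, target, allow_cross_size=True)
        assert v == pytest.approx(20.0 / 3.0)


class TestIodineReduction:
    def test_double_slope_fifty_percent(self):
        assert iodine_reduction(fit(1.0), fit(2.0)).reduction_pct == pytest.approx(50.0)

    def test_equal_slopes_zero(self):
        assert iodine_reduction(fit(2.0), fit(2.0)).reduction_pct == pytest.approx(0.0)

    def test_weaker_target_reports_required_increase(self):
        # target slope smaller by factor 1.16 -> 16% more contrast needed
        plan = iodine_reduction(fit(1.16), fit(1.0))
        assert plan.reduction_pct == pytest.approx(-16.0)
        assert plan.conc_ratio == pytest.approx(1.16)

    @given(
        ab=st.floats(0.1, 10.0),
        at=st.floats(0.1, 10.0),
    )
    def test_inversion_identity(self, ab, at):
        r_ab = iodine_reduction(fit(ab), fit(at)).reduction_pct
        r_ba = iodine_reduction(fit(at), fit(ab)).reduction_pct
        assert (1 - r_ab / 100.0) * (1 - r_ba / 100.0) == pytest.approx(1.0, abs=1e-12)

    @given(
        a=st.floats(0.2, 8.0),
        b=st.floats(0.2, 8.0),
        c=st.floats(0.2, 8.0),
    )
    def test_chaining_through_intermediate_technique(self, a, b, c):
        direct = equivalent_concentration(10.0, fit(a), fit(c))
        via = equivalent_concentration(
            equivalent_concentration(10.0, fit(a), fit(b)), fit(b), fit(c)
        )
        assert via == pytest.approx(direct, rel=1e-12)

    def test_uncertainty_propagation_formula(self):
        base, target = fit(2.0, se=0.1), fit(4.0, se=0.3)
        plan = iodine_reduction(base, target)
        ratio = 0.5
        expected = 100.0 * ratio * math.sqrt((0.1 / 2.0) ** 2 + (0.3 / 4.0) ** 2)
        assert plan.uncertainty_pct == pytest.approx(expected)


class TestReductionMatrix:
    def test_constructed_ratios_and_average(self):
        rows = [
            ("s", "SECT", 120.0, "small", "ir", 1.0, 0.0),
            ("s", "SECT", 120.0, "large", "ir", 2.0, 0.0),
            ("s", "DECT-VMI", 50.0, "small", "ir", 1.5, 0.0),
            ("s", "DECT-VMI", 50.0, "large", "ir", 4.0, 0.0),
        ]
        result = reduction_matrix(fits_frame(rows), baseline_energy=120)
        by_size = result.plans.set_index("size_label")["reduction_pct"]
        assert by_size["small"] == pytest.approx(100 * (1 - 1 / 1.5))
        assert by_size["large"] == pytest.approx(50.0)
        avg = result.averages.iloc[0]["mean_reduction_pct"]
        assert avg == pytest.approx((by_size["small"] + by_size["large"]) / 2)
        assert avg == pytest.approx((33.3333333 + 50.0) / 2, abs=1e-4)

    def test_missing_baseline_reported_unavailable(self):
        rows = [
            ("s", "SECT", 120.0, "small", "ir", 1.0, 0.0),
            ("s", "DECT-VMI", 50.0, "small", "ir", 1.5, 0.0),
            ("s", "DECT-VMI", 50.0, "large", "ir", 4.0, 0.0),  # no 120 kV baseline
        ]
        result = reduction_matrix(fits_frame(rows), baseline_energy=120)
        assert len(result.plans) == 1
        assert len(result.unavailable) == 1
        assert result.unavailable.iloc[0]["size_label"] == "large"

    def test_mode_filter_restricts_targets(self):
        rows = [
            ("s", "SECT", 120.0, "small", "ir", 1.0, 0.0),
            ("s", "SECT", 100.0, "small", "ir", 1.2, 0.0),
            ("s", "DECT-VMI", 50.0, "small", "ir", 1.5, 0.0),
        ]
        result = reduction_matrix(fits_frame(rows), mode_filter="DECT-VMI")
        assert set(result.plans["mode"]) == {"DECT-VMI"}

    def test_empty_fits_rejected(self):
        with pytest.raises(ConfigError):
            reduction_matrix(fits_frame([]))
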
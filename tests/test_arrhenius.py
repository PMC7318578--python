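"""Ratio-series construction and modified/classic Arrhenius fits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p450select import (
    DataValidationError,
    FitError,
    KineticParamTable,
    R_GAS,
    RatioSeries,
    build_ratio_series,
    fit_classic_arrhenius,
    fit_modified_arrhenius,
)
from tests.conftest import PAIR_34, PAIR_45


def make_params(temps, vmax_by_met, se_frac=0.05):
    rows = []
    for met, vmaxes in vmax_by_met.items():
        for t, v in zip(temps, vmaxes):
            rows.append(
                {"temperature_K": t, "metabolite": met, "Vmax": v,
                 "Vmax_SE": se_frac * v, "KM": 100.0, "KM_SE": 10.0}
            )
    return KineticParamTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ratio series


def test_ratio_point_from_reference_vmax_pair(bm3):
    # at 277.0 K the two pathways have Vmax 135 and 230
    s = build_ratio_series(bm3, PAIR_34)
    i = np.argmin(np.abs(s.x - 1000.0 / 277.0))
    assert s.x[i] == pytest.approx(3.610, abs=1e-3)
    assert s.y[i] == pytest.approx(math.log(135 / 230), abs=1e-12)
    assert s.y[i] == pytest.approx(-0.5329, abs=1e-4)


def test_delta_method_se_matches_monte_carlo(rng):
    # SEs 10 and 19 on Vmax 135 and 230 -> y_SE ~ 0.111
    se = math.hypot(10 / 135, 19 / 230)
    assert se == pytest.approx(0.111, abs=5e-4)
    draws = np.log(rng.normal(135, 10, 100_000) / rng.normal(230, 19, 100_000))
    assert np.std(draws) == pytest.approx(se, rel=0.05)


def test_identity_pair_gives_zero_series_and_zero_fit():
    temps = [280.0, 290.0, 300.0, 310.0]
    params = make_params(temps, {"a": [10, 20, 30, 40], "b": [10, 20, 30, 40]})
    s = build_ratio_series(params, ("a", "b"))
    assert np.all(s.y == 0)
    fit = fit_modified_arrhenius(s)
    assert fit.slope == pytest.approx(0.0, abs=1e-12)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.delta == pytest.approx(0.0, abs=1e-12)


def test_uncommon_temperatures_are_dropped_with_warning(caplog):
    params = make_params([280.0, 290.0, 300.0], {"a": [10, 20, 30]})
    extra = make_params([290.0, 300.0, 310.0], {"b": [5, 10, 15]})
    both = KineticParamTable(pd.concat([params.data, extra.data]))
    with caplog.at_level("WARNING"):
        s = build_ratio_series(both, ("a", "b"))
    assert len(s.x) == 2
    assert "dropping temperatures" in caplog.text


def test_no_common_temperatures_is_an_error():
    a = make_params([280.0, 290.0], {"a": [10, 20]})
    b = make_params([300.0, 310.0], {"b": [5, 10]})
    both = KineticParamTable(pd.concat([a.data, b.data]))
    with pytest.raises(DataValidationError, match="common"):
        build_ratio_series(both, ("a", "b"))


def test_same_metabolite_pair_is_rejected(bm3):
    with pytest.raises(DataValidationError):
        build_ratio_series(bm3, ("4'-OH-MF", "4'-OH-MF"))


# ---------------------------------------------------------------------------
# modified Arrhenius fit


def test_exact_line_is_recovered():
    x = np.linspace(3.1, 3.7, 6)
    s = RatioSeries(("a", "b"), x, 2.0 - 1.5 * x, np.full(6, 0.01))
    fit = fit_modified_arrhenius(s)
    assert fit.slope == pytest.approx(-1.5, abs=1e-12)
    assert fit.intercept == pytest.approx(2.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_delta_is_minus_slope_times_gas_constant():
    x = np.linspace(3.1, 3.7, 5)
    fit = fit_modified_arrhenius(RatioSeries(("a", "b"), x, 3.0 - 0.97 * x, np.full(5, 0.01)))
    assert fit.delta == pytest.approx(-fit.slope * R_GAS, rel=1e-12)
    assert fit.delta == pytest.approx(8.065, abs=1e-3)


def test_reference_table_pair_reproduces_published_line(bm3):
    fit = fit_modified_arrhenius(build_ratio_series(bm3, PAIR_34))
    assert fit.slope == pytest.approx(-0.97, abs=0.05)
    assert fit.intercept == pytest.approx(3.0, abs=0.2)
    assert fit.delta == pytest.approx(8.1, abs=0.5)
    assert fit.r_squared > 0.9


def test_two_point_series_is_flagged_non_inferential():
    s = RatioSeries(("a", "b"), np.array([3.2, 3.5]), np.array([0.5, 0.2]), np.array([0.1, 0.1]))
    fit = fit_modified_arrhenius(s)
    assert not fit.inferential
    assert math.isnan(fit.slope_se)
    # the exact line through both points
    assert fit.slope == pytest.approx((0.2 - 0.5) / (3.5 - 3.2))


def test_identical_abscissae_raise_singular_design():
    s = RatioSeries(("a", "b"), np.array([3.3, 3.3, 3.3]), np.array([0.1, 0.2, 0.3]), np.ones(3))
    with pytest.raises(FitError, match="singular"):
        fit_modified_arrhenius(s)


def test_weighted_fit_agrees_with_ols_under_equal_weights():
    x = np.linspace(3.1, 3.7, 8)
    y = 1.0 - 0.5 * x + np.sin(np.arange(8)) * 0.01
    s = RatioSeries(("a", "b"), x, y, np.full(8, 0.111))
    u = fit_modified_arrhenius(s, weighted=False)
    w = fit_modified_arrhenius(s, weighted=True)
    assert w.slope == pytest.approx(u.slope, rel=1e-9)
    assert w.slope_se == pytest.approx(u.slope_se, rel=1e-9)
    assert w.intercept_se == pytest.approx(u.intercept_se, rel=1e-9)


# ---------------------------------------------------------------------------
# structural invariants


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    ys=st.lists(st.floats(min_value=-5, max_value=5), min_size=3, max_size=10),
)
def test_pair_swap_negates_everything(ys):
    x = np.linspace(3.1, 3.7, len(ys))
    s = RatioSeries(("a", "b"), x, np.array(ys), np.full(len(ys), 0.1))
    f, g = fit_modified_arrhenius(s), fit_modified_arrhenius(s.swapped())
    assert g.slope == pytest.approx(-f.slope, abs=1e-9)
    assert g.intercept == pytest.approx(-f.intercept, abs=1e-9)
    assert g.delta == pytest.approx(-f.delta, abs=1e-9)
    assert abs(g.delta) == pytest.approx(abs(f.delta), abs=1e-12)


def test_slope_additivity_over_metabolite_chain(rng):
    temps = np.linspace(277, 318, 8)
    vm = {m: np.exp(rng.normal(3, 1, 8)) for m in "abc"}
    params = make_params(list(temps), vm)
    fits = {
        pair: fit_modified_arrhenius(build_ratio_series(params, pair))
        for pair in [("a", "b"), ("b", "c"), ("a", "c")]
    }
    assert fits[("a", "c")].slope == pytest.approx(
        fits[("a", "b")].slope + fits[("b", "c")].slope, abs=1e-9
    )
    assert fits[("a", "c")].intercept == pytest.approx(
        fits[("a", "b")].intercept + fits[("b", "c")].intercept, abs=1e-9
    )
    assert fits[("a", "c")].delta == pytest.approx(
        fits[("a", "b")].delta + fits[("b", "c")].delta, abs=1e-9
    )


# ---------------------------------------------------------------------------
# classic (diagnostic) Arrhenius


def test_pure_exponential_yields_apparent_ea_exactly():
    temps = np.linspace(277, 318, 6)
    vmax = 1e9 * np.exp(-50e3 / (R_GAS * temps))
    params = make_params(list(temps), {"m": vmax})
    fit = fit_classic_arrhenius(params, "m")
    assert fit.apparent_Ea == pytest.approx(50.0, rel=1e-6)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_single_pathway_fit_is_much_worse_than_ratio_fit(bm3):
    # individual ln Vmax curves rise then fall; the ratio is linear
    single = fit_classic_arrhenius(bm3, "4'-OH-MF")
    ratio = fit_modified_arrhenius(build_ratio_series(bm3, PAIR_34))
    assert single.r_squared < ratio.r_squared - 0.3


def test_too_few_temperatures_for_classic_fit():
    params = make_params([290.0, 300.0], {"m": [10.0, 20.0]})
    with pytest.raises(FitError, match=">= 3"):
        fit_classic_arrhenius(params, "m")
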
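"""Modified and classic Arrhenius analysis of parallel-pathway kinetics.

For two products of the same enzyme–substrate system, the temperature
dependence of the Vmax ratio follows

    ln(Vmax,1 / Vmax,2) = ln(A1/A2) − Δ / (R T),      Δ = ΔΔG_bind + ΔEa

because every catalytic-cycle step shared by the two pathways (reductase
coupling, oxygen binding, membrane effects, partial denaturation) cancels in
the ratio. Plotting ln(Vmax,1/Vmax,2) against 1000/T therefore gives a
straight line even when the individual ln Vmax plots are strongly curved:
the slope (in kelvin, because of the 10³ abscissa factor) is −Δ/(1000·R) and
the intercept is the relative collision efficiency ln(A1/A2) — an entropic
measure of how easily each bound pose reaches its transition state.

The classic single-pathway Arrhenius fit (ln Vmax vs 1000/T) is kept only as
a linearity diagnostic; its "apparent Ea" must not be read as an activation
energy for multi-step P450 catalysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataValidationError, FitError
from .kinetics import KineticParamTable

__all__ = [
    "R_GAS",
    "RatioSeries",
    "ArrheniusFit",
    "ClassicArrheniusFit",
    "build_ratio_series",
    "fit_modified_arrhenius",
    "fit_classic_arrhenius",
]

logger = logging.getLogger(__name__)

#: gas constant, J mol^-1 K^-1
R_GAS = 8.3145


@dataclass(frozen=True)
class RatioSeries:
    """ln(Vmax,1/Vmax,2) against 1000/T for one ordered metabolite pair.

    ``x`` is 10³/T in K⁻¹·10³ (so slopes carry units of kelvin); ``y_se`` is
    the delta-method SE of each log-ratio.
    """

    pair: tuple[str, str]
    x: np.ndarray
    y: np.ndarray
    y_se: np.ndarray

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise DataValidationError("pair members must differ")
        if len(self.x) < 2:
            raise DataValidationError("ratio series needs >= 2 points")
        if np.any(self.x <= 0) or not np.all(np.isfinite(self.y)):
            raise DataValidationError("invalid abscissa or non-finite log-ratio")

    def swapped(self) -> "RatioSeries":
        return RatioSeries(
            (self.pair[1], self.pair[0]), self.x.copy(), -self.y, self.y_se.copy()
        )


@dataclass(frozen=True)
class ArrheniusFit:
    """Line fit of a RatioSeries with the derived thermodynamic quantities.

    delta (kJ/mol) = −slope[K] × R; its sign convention is pathway-1 minus
    pathway-2 throughout the package. ``inferential`` is False for two-point
    fits, whose SEs are undefined.
    """

    pair: tuple[str, str]
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    n_points: int
    weighted: bool = False
    inferential: bool = True

    @property
    def delta(self) -> float:
        """Δ = ΔΔG_bind + ΔEa, kJ/mol."""
        return -self.slope * R_GAS * 1e-3 * 1e3

    @property
    def delta_se(self) -> float:
        return self.slope_se * R_GAS * 1e-3 * 1e3

    @property
    def ln_A_ratio(self) -> float:
        """Relative collision efficiency ln(A1/A2) (the intercept)."""
        return self.intercept


@dataclass(frozen=True)
class ClassicArrheniusFit:
    """Diagnostic single-pathway fit of ln Vmax on 1000/T."""

    metabolite: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    @property
    def apparent_Ea(self) -> float:
        """−slope × R in kJ/mol; apparent only, not a true barrier."""
        return -self.slope * R_GAS * 1e-3 * 1e3


def build_ratio_series(
    params: KineticParamTable, pair: tuple[str, str]
) -> RatioSeries:
    """Form the log-ratio series for an ordered metabolite pair.

    One point per temperature at which both metabolites were measured;
    y_SE propagates the Vmax SEs to first order:
    y_SE = sqrt((SE₁/Vmax₁)² + (SE₂/Vmax₂)²). Temperatures present for only
    one member are dropped with a warning.
    """
    m1, m2 = pair
    if m1 == m2:
        raise DataValidationError("pair members must differ")
    if params.enzymes and len(params.enzymes) > 1:
        raise DataValidationError(
            f"table mixes enzymes {params.enzymes}; use .subset(enzyme) first"
        )
    a = params.for_metabolite(m1).set_index("temperature_K")
    b = params.for_metabolite(m2).set_index("temperature_K")
    common = sorted(set(a.index) & set(b.index))
    dropped = (set(a.index) | set(b.index)) - set(common)
    if dropped:
        logger.warning(
            "dropping temperatures %s present for only one of %s", sorted(dropped), pair
        )
    if not common:
        raise DataValidationError(f"no common temperatures for pair {pair}")
    t = np.array(common, dtype=float)
    v1 = a.loc[common, "Vmax"].to_numpy(dtype=float)
    v2 = b.loc[common, "Vmax"].to_numpy(dtype=float)
    s1 = a.loc[common, "Vmax_SE"].to_numpy(dtype=float)
    s2 = b.loc[common, "Vmax_SE"].to_numpy(dtype=float)
    if np.any(v1 <= 0) or np.any(v2 <= 0):
        raise DataValidationError("Vmax values must be positive to take ratios")
    return RatioSeries(
        pair=(m1, m2),
        x=1000.0 / t,
        y=np.log(v1 / v2),
        y_se=np.sqrt((s1 / v1) ** 2 + (s2 / v2) ** 2),
    )


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least-squares line y = a + b x; returns (b, a, se_b, se_a, r2)."""
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    if sxx == 0:
        raise FitError("all abscissa values identical: singular design")
    b = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    a = ybar - b * xbar
    resid = y - (a + b * x)
    dof = len(x) - 2
    # scale the weight-based covariance by the weighted residual variance
    s2 = np.sum(w * resid**2) / dof if dof > 0 else np.nan
    se_b = math.sqrt(s2 / sxx) if dof > 0 else math.nan
    se_a = math.sqrt(s2 * (1.0 / W + xbar**2 / sxx)) if dof > 0 else math.nan
    sst = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - np.sum(w * resid**2) / sst if sst > 0 else 1.0
    return b, a, se_b, se_a, r2


def fit_modified_arrhenius(series: RatioSeries, weighted: bool = False) -> ArrheniusFit:
    """Fit the modified Arrhenius line to a ratio series.

    Ordinary least squares by default (this is what reproduces published
    slope/intercept tables from Vmax data); inverse-variance weighting by
    the propagated y_SE is available behind a flag. Two-point series are
    fitted exactly but flagged non-inferential with undefined SEs.
    """
    x, y = series.x, series.y
    if np.ptp(x) == 0:
        raise FitError("all abscissa values identical: singular design")
    if len(x) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        return ArrheniusFit(
            pair=series.pair,
            slope=float(slope),
            intercept=float(intercept),
            slope_se=math.nan,
            intercept_se=math.nan,
            r_squared=1.0,
            n_points=2,
            weighted=weighted,
            inferential=False,
        )
    if weighted:
        if np.any(series.y_se <= 0):
            raise DataValidationError("weighted fit requires strictly positive y_SE")
        b, a, se_b, se_a, r2 = _wls_line(x, y, 1.0 / series.y_se**2)
    else:
        res = stats.linregress(x, y)
        b, a, se_b, se_a = res.slope, res.intercept, res.stderr, res.intercept_stderr
        r2 = res.rvalue**2
    return ArrheniusFit(
        pair=series.pair,
        slope=float(b),
        intercept=float(a),
        slope_se=float(se_b),
        intercept_se=float(se_a),
        r_squared=float(r2),
        n_points=len(x),
        weighted=weighted,
    )


def fit_classic_arrhenius(
    params: KineticParamTable, metabolite: str
) -> ClassicArrheniusFit:
    """Diagnostic OLS of ln Vmax on 1000/T for a single pathway.

    A low R² here, against a high R² for the pairwise ratio fit, is the
    signature that shared temperature-dependent factors dominate the single
    pathway but cancel in ratios.
    """
    sub = params.for_metabolite(metabolite)
    if len(sub) < 3:
        raise FitError(f"need >= 3 temperatures for {metabolite!r}, got {len(sub)}")
    v = sub["Vmax"].to_numpy(dtype=float)
    if np.any(v <= 0):
        raise DataValidationError("Vmax values must be positive")
    x = 1000.0 / sub["temperature_K"].to_numpy(dtype=float)
    res = stats.linregress(x, np.log(v))
    return ClassicArrheniusFit(
        metabolite=metabolite,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(sub),
    )
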
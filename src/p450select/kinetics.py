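"""Michaelis–Menten kinetics: velocity-table ingestion and per-temperature fits.

The experimental unit of this package is a velocity table: initial rates of
product formation measured at several substrate concentrations, for one or
more metabolites (parallel oxidation pathways of one substrate) and one or
more incubation temperatures. Each (temperature, metabolite) group is fitted
to the Michaelis–Menten hyperbola

    v = Vmax * S / (KM + S)

by bounded nonlinear least squares, yielding the Vmax values that downstream
modules turn into modified Arrhenius ratio plots.

Velocities are normalized rates, nmol product / min / nmol enzyme; substrate
concentrations are micromolar; temperatures are kelvin internally (Celsius
input is converted at read time, and the unit must always be declared).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DataFormatError, DataParseError, DataValidationError, FitError

__all__ = [
    "VelocityTable",
    "MichaelisMentenFit",
    "KineticParamTable",
    "read_velocity_table",
    "fit_michaelis_menten",
    "fit_all_groups",
    "read_param_table",
]

ZERO_CELSIUS = 273.15

#: columns a velocity table must provide (replicate is optional)
VELOCITY_COLUMNS = ("temperature", "substrate_conc", "metabolite", "velocity")

#: columns a pre-fitted kinetic-parameter table must provide
PARAM_COLUMNS = ("temperature_K", "metabolite", "Vmax", "Vmax_SE", "KM", "KM_SE")


@dataclass
class VelocityTable:
    """Tidy velocity measurements, one row per (T, S, metabolite[, replicate]).

    ``data`` columns: temperature_K, substrate_conc_uM, metabolite, velocity,
    and optionally replicate. Temperatures are always kelvin.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        if len(d) == 0:
            raise DataFormatError("velocity table is empty")
        if (d["temperature_K"] <= 0).any():
            raise DataValidationError("temperatures must be > 0 K")
        if (d["substrate_conc_uM"] <= 0).any():
            raise DataValidationError("substrate concentrations must be > 0")
        if (d["velocity"] < 0).any():
            raise DataValidationError("velocities must be >= 0")

    def groups(self):
        """Yield ((temperature_K, metabolite), sub-frame) for each fit group."""
        return self.data.groupby(["temperature_K", "metabolite"], sort=True)


@dataclass(frozen=True)
class MichaelisMentenFit:
    """One Michaelis–Menten fit at a single temperature for one metabolite."""

    temperature_K: float
    metabolite: str
    Vmax: float
    Vmax_SE: float
    KM: float
    KM_SE: float
    converged: bool = True
    residual_sum_squares: float = math.nan
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (self.Vmax > 0 and self.KM > 0):
            raise DataValidationError(
                f"Vmax and KM must be positive, got Vmax={self.Vmax}, KM={self.KM} "
                f"({self.metabolite} @ {self.temperature_K} K)"
            )
        if self.Vmax_SE < 0 or self.KM_SE < 0:
            raise DataValidationError("standard errors must be >= 0")


class KineticParamTable:
    """Collection of per-temperature Michaelis–Menten parameters.

    Internally a DataFrame with columns ``temperature_K, metabolite, Vmax,
    Vmax_SE, KM, KM_SE`` (plus optional ``enzyme`` and diagnostics). Keys
    (enzyme, temperature_K, metabolite) must be unique.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in PARAM_COLUMNS if c not in data.columns]
        if missing:
            raise DataFormatError(f"parameter table missing columns: {missing}")
        data = data.copy()
        for c in ("temperature_K", "Vmax", "Vmax_SE", "KM", "KM_SE"):
            data[c] = pd.to_numeric(data[c], errors="raise")
        if (data["Vmax"] <= 0).any() or (data["KM"] <= 0).any():
            bad = data[(data["Vmax"] <= 0) | (data["KM"] <= 0)]
            raise DataValidationError(
                f"non-positive Vmax or KM in rows: {bad.index.tolist()}"
            )
        if (data[["Vmax_SE", "KM_SE"]] < 0).any().any():
            raise DataValidationError("negative standard errors")
        key_cols = ["temperature_K", "metabolite"]
        if "enzyme" in data.columns:
            key_cols = ["enzyme", *key_cols]
        dup = data.duplicated(subset=key_cols)
        if dup.any():
            raise DataValidationError(
                f"duplicate (temperature, metabolite) keys: "
                f"{data.loc[dup, key_cols].to_dict('records')}"
            )
        self.data = data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.data["metabolite"].unique())

    @property
    def enzymes(self) -> list[str]:
        if "enzyme" not in self.data.columns:
            return []
        return sorted(self.data["enzyme"].unique())

    def subset(self, enzyme: str) -> "KineticParamTable":
        """Restrict to one enzyme (required before pairwise analyses when
        the table mixes isoforms)."""
        if "enzyme" not in self.data.columns:
            raise DataValidationError("table has no 'enzyme' column to subset on")
        sub = self.data[self.data["enzyme"] == enzyme]
        if len(sub) == 0:
            raise DataValidationError(f"no rows for enzyme {enzyme!r}")
        return KineticParamTable(sub.drop(columns=["enzyme"]))

    def for_metabolite(self, metabolite: str) -> pd.DataFrame:
        sub = self.data[self.data["metabolite"] == metabolite]
        if len(sub) == 0:
            raise DataValidationError(f"metabolite {metabolite!r} not in table")
        return sub.sort_values("temperature_K")

    def vmax_at(self, temperature_K: float, metabolite: str) -> tuple[float, float]:
        """(Vmax, Vmax_SE) at an exact temperature key."""
        sub = self.for_metabolite(metabolite)
        row = sub[np.isclose(sub["temperature_K"], temperature_K)]
        if len(row) != 1:
            raise DataValidationError(
                f"no unique entry for ({temperature_K} K, {metabolite!r})"
            )
        return float(row["Vmax"].iloc[0]), float(row["Vmax_SE"].iloc[0])

    def nearest_temperature(self, target_K: float, metabolites: list[str]) -> float:
        """Measured temperature closest to ``target_K`` at which every listed
        metabolite has an entry."""
        common = None
        for m in metabolites:
            ts = set(self.for_metabolite(m)["temperature_K"])
            common = ts if common is None else common & ts
        if not common:
            raise DataValidationError(
                f"no common temperatures for metabolites {metabolites}"
            )
        return min(common, key=lambda t: abs(t - target_K))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_fits(cls, fits: list[MichaelisMentenFit]) -> "KineticParamTable":
        rows = [
            {
                "temperature_K": f.temperature_K,
                "metabolite": f.metabolite,
                "Vmax": f.Vmax,
                "Vmax_SE": f.Vmax_SE,
                "KM": f.KM,
                "KM_SE": f.KM_SE,
                "converged": f.converged,
                "residual_sum_squares": f.residual_sum_squares,
            }
            for f in fits
        ]
        return cls(pd.DataFrame(rows))


def _sniff_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_velocity_table(
    path,
    temperature_unit: str,
    conc_unit: str = "uM",
) -> VelocityTable:
    """Read a delimited velocity table.

    The temperature unit ("C" or "K") must be declared explicitly; it is never
    guessed from the magnitudes. Required columns: temperature, substrate_conc,
    metabolite, velocity. Comma or tab delimiting is detected from the header.
    """
    if temperature_unit not in ("C", "K"):
        raise DataFormatError(
            f"temperature_unit must be 'C' or 'K', got {temperature_unit!r}"
        )
    if conc_unit != "uM":
        raise DataFormatError(f"only micromolar ('uM') concentrations supported, got {conc_unit!r}")
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DataFormatError(f"{path}: empty file")
    sep = _sniff_sep(lines[0])
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in VELOCITY_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required column(s) {missing}")
    out = pd.DataFrame()
    for col in ("temperature", "substrate_conc", "velocity"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            i = int(bad.idxmax())
            raise DataParseError(
                f"non-numeric value {df[col][i]!r}", line=i + 2, column=col
            )
        if vals.isna().any():
            i = int(vals.isna().idxmax())
            raise DataParseError("missing value", line=i + 2, column=col)
        out[col] = vals.astype(float)
    out["metabolite"] = df["metabolite"].str.strip()
    if temperature_unit == "C":
        out["temperature"] = out["temperature"] + ZERO_CELSIUS
    out = out.rename(
        columns={"temperature": "temperature_K", "substrate_conc": "substrate_conc_uM"}
    )
    if "replicate" in df.columns:
        out["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    return VelocityTable(out)


def _mm_model(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


def fit_michaelis_menten(
    substrate_conc_uM: np.ndarray,
    velocity: np.ndarray,
    temperature_K: float,
    metabolite: str,
    max_iter: int = 500,
) -> MichaelisMentenFit:
    """Fit v = Vmax·S/(KM+S) to one (temperature, metabolite) group.

    Bounded trust-region least squares with the analytic Jacobian
    (∂r/∂Vmax = S/(KM+S), ∂r/∂KM = −Vmax·S/(KM+S)²); starting values are
    Vmax₀ = max observed velocity and KM₀ = the concentration whose velocity
    is nearest Vmax₀/2. Standard errors come from the Gauss–Newton
    approximation to the Hessian scaled by the residual variance — the
    asymptotic SEs conventionally reported with hyperbolic saturation fits.
    Replicates are pooled into one regression, never averaged first.
    """
    s = np.asarray(substrate_conc_uM, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if s.shape != v.shape or s.ndim != 1:
        raise DataValidationError("substrate and velocity arrays must match 1-D")
    if len(np.unique(s)) < 4:
        raise FitError(
            f"need >= 4 distinct substrate concentrations, got {len(np.unique(s))} "
            f"({metabolite} @ {temperature_K} K)"
        )
    if np.all(v == 0):
        raise DataValidationError(f"all velocities zero ({metabolite} @ {temperature_K} K)")
    if np.ptp(v) == 0:
        raise FitError("all velocities identical; saturation curve is degenerate")

    vmax0 = float(np.max(v))
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2.0))])

    def resid(p):
        return _mm_model(s, p[0], p[1]) - v

    def jac(p):
        denom = p[1] + s
        return np.column_stack([s / denom, -p[0] * s / denom**2])

    sol = least_squares(
        resid,
        x0=[vmax0, km0],
        jac=jac,
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        method="trf",
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_iter,
    )
    vmax, km = sol.x
    rss = float(2.0 * sol.cost)
    dof = len(s) - 2
    J = jac(sol.x)
    JTJ = J.T @ J
    try:
        cov = np.linalg.inv(JTJ) * (rss / dof if dof > 0 else np.nan)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        ses = np.array([np.nan, np.nan])
    return MichaelisMentenFit(
        temperature_K=float(temperature_K),
        metabolite=metabolite,
        Vmax=float(vmax),
        Vmax_SE=float(ses[0]) if np.isfinite(ses[0]) else 0.0,
        KM=float(km),
        KM_SE=float(ses[1]) if np.isfinite(ses[1]) else 0.0,
        converged=bool(sol.success),
        residual_sum_squares=rss,
        n_points=len(s),
    )


def fit_all_groups(table: VelocityTable, drop_failed: bool = True) -> KineticParamTable:
    """Fit every (temperature, metabolite) group of a velocity table.

    Non-converged fits are excluded (with their flag) when ``drop_failed``;
    downstream Arrhenius analysis must only see converged estimates.
    """
    fits = []
    for (t, met), grp in table.groups():
        fit = fit_michaelis_menten(
            grp["substrate_conc_uM"].to_numpy(),
            grp["velocity"].to_numpy(),
            temperature_K=t,
            metabolite=met,
        )
        if fit.converged or not drop_failed:
            fits.append(fit)
    if not fits:
        raise FitError("no group produced a converged fit")
    return KineticParamTable.from_fits(fits)


def read_param_table(path) -> KineticParamTable:
    """Read a pre-fitted kinetic-parameter table (Vmax/KM with SEs).

    Required columns: temperature_K, metabolite, Vmax, Vmax_SE, KM, KM_SE;
    an optional ``enzyme`` column keeps multiple isoforms in one file.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise DataFormatError(f"{path}: empty file")
    df = pd.read_csv(path, sep=_sniff_sep(first))
    df.columns = [c.strip() for c in df.columns]
    return KineticParamTable(df)
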
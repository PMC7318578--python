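"""Curtin–Hammett analysis, thermodynamic decomposition, and KIE ratios.

Under fast interconversion of reactive binding poses, the product ratio of
two parallel pathways reflects only the difference in overall transition-
state free energies: ΔΔG_overall = −RT ln(P1/P2), estimated here from the
Vmax ratio at a single reference temperature. Combining this with the
modified-Arrhenius composite Δ = ΔΔG_bind + ΔEa and an externally supplied
activation-energy difference ΔEa (e.g., from SMARTCyp or DFT) decomposes
selectivity into

    ΔΔG_bind = Δ − ΔEa                     (relative binding free energy)
    TΔΔS‡    = Δ − ΔΔG_overall             (relative collision entropy)

the latter using ΔΔH‡ ≈ ΔEa, adopted as an exact identity in code and
recorded as an approximation in the output metadata. All differences are
pathway-1 minus pathway-2.

Kinetic isotope effects are simple quotients of non-deuterated over
deuterated metabolite peak areas from competitive incubations.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

from .arrhenius import R_GAS, ArrheniusFit
from .errors import DataValidationError
from .kinetics import KineticParamTable

__all__ = [
    "CURTIN_HAMMETT_T",
    "ThermoDecomposition",
    "KieRatio",
    "curtin_hammett",
    "curtin_hammett_from_table",
    "decompose",
    "kie_ratio",
    "kie_replicates",
]

#: reference temperature (K) for single-temperature Curtin–Hammett estimates
CURTIN_HAMMETT_T = 300.0

#: note attached to every decomposition: the entropy estimate rests on
#: equating the enthalpic part of ΔΔG‡ with the electronic ΔEa
ENTHALPY_APPROXIMATION = "TddS assumes ddH_ts == dEa (electronic barrier)"


@dataclass(frozen=True)
class ThermoDecomposition:
    """Full selectivity decomposition for one ordered pathway pair (kJ/mol)."""

    pair: tuple[str, str]
    delta: float
    ddG_overall: float
    dEa: float
    reference_T: float
    dEa_provenance: str = "unspecified"
    notes: str = ENTHALPY_APPROXIMATION

    def __post_init__(self) -> None:
        for name in ("delta", "ddG_overall", "dEa", "reference_T"):
            if not math.isfinite(getattr(self, name)):
                raise DataValidationError(f"{name} must be finite")

    @property
    def ddG_bind(self) -> float:
        """Relative binding free energy of the two reactive poses."""
        return self.delta - self.dEa

    @property
    def TddS(self) -> float:
        """Relative entropy term of transition-state formation."""
        return self.delta - self.ddG_overall


@dataclass(frozen=True)
class KieRatio:
    """Ratio of non-deuterated to deuterated metabolite formation."""

    metabolite: str
    temperature_K: float
    ratio: float
    ratio_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise DataValidationError("KIE ratio must be positive")


def curtin_hammett(vmax1: float, vmax2: float, temperature_K: float = CURTIN_HAMMETT_T) -> float:
    """ΔΔG_overall = −R·T·ln(vmax1/vmax2), in kJ/mol.

    The product ratio at a single temperature, read through the
    Curtin–Hammett principle.
    """
    if vmax1 <= 0 or vmax2 <= 0:
        raise DataValidationError("velocities must be positive")
    if temperature_K <= 0:
        raise DataValidationError("temperature must be positive")
    return -R_GAS * 1e-3 * temperature_K * math.log(vmax1 / vmax2)


def curtin_hammett_from_table(
    params: KineticParamTable,
    pair: tuple[str, str],
    target_T: float = CURTIN_HAMMETT_T,
) -> tuple[float, float]:
    """ΔΔG_overall from the Vmax pair at the measured temperature nearest
    ``target_T``, evaluated with T = ``target_T`` in the formula.

    Returns (ddG_overall_kJ_per_mol, measured_temperature_used). The nearest
    measured temperature typically differs from the nominal reference by a
    fraction of a percent, below the resolution of the printed values;
    the choice is recorded by returning the temperature actually used.
    """
    t_meas = params.nearest_temperature(target_T, list(pair))
    v1, _ = params.vmax_at(t_meas, pair[0])
    v2, _ = params.vmax_at(t_meas, pair[1])
    return curtin_hammett(v1, v2, target_T), t_meas


def decompose(
    fit: ArrheniusFit,
    ddG_overall: float,
    dEa: float,
    reference_T: float = CURTIN_HAMMETT_T,
    dEa_provenance: str = "unspecified",
) -> ThermoDecomposition:
    """Assemble the selectivity decomposition for one pair.

    ``fit`` supplies Δ; ``ddG_overall`` comes from the Curtin–Hammett
    estimate; ``dEa`` is an external activation-energy difference with its
    provenance string (never computed here).
    """
    return ThermoDecomposition(
        pair=fit.pair,
        delta=fit.delta,
        ddG_overall=float(ddG_overall),
        dEa=float(dEa),
        reference_T=float(reference_T),
        dEa_provenance=dEa_provenance,
    )


def kie_ratio(area_D0: float, area_Dn: float) -> float:
    """KIE as the quotient of non-deuterated over deuterated peak areas."""
    if area_D0 <= 0 or area_Dn <= 0:
        raise DataValidationError("peak areas must be positive")
    return area_D0 / area_Dn


def kie_replicates(ratios: list[float]) -> tuple[float, float]:
    """Reduce replicate KIE ratios to (mean, SD); SD is 0 for one replicate."""
    if not ratios:
        raise DataValidationError("no replicate ratios given")
    if any(r <= 0 for r in ratios):
        raise DataValidationError("KIE ratios must be positive")
    mean = statistics.fmean(ratios)
    sd = statistics.stdev(ratios) if len(ratios) > 1 else 0.0
    return mean, sd
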
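"""Synthetic data with known ground truth, plus the packaged reference fixture.

Two generators make every stage of the pipeline testable without external
data:

``gen_kinetics``
    Velocity tables drawn from a two-or-more-pathway Arrhenius model,
    Vmax_i(T) = envelope(T) · A_i · exp(−G_i/(R·T)), so the modified
    Arrhenius slope/intercept that a downstream fit should recover are known
    by construction. The shared multiplicative envelope emulates the
    rise-and-fall of absolute Vmax with temperature (membrane effects,
    reductase coupling, partial denaturation) that makes single-pathway
    Arrhenius plots curved; because it multiplies every pathway equally it
    cancels exactly in ratios — the central cancellation the method relies
    on, made testable. Noise is multiplicative Gaussian on velocity
    (CV-parameterized, truncated at −99% to keep velocities positive),
    mirroring the roughly proportional standard errors of real kinetic
    fits.

``gen_pose_trajectory``
    Trajectory frames constructed to satisfy or violate the pose criteria
    with a safety margin of at least 3× the coordinate jitter, then jittered
    and put through a random rigid rotation + translation. The construction
    labels are returned, giving an exact oracle for the classifier.

``table1_fixture``
    The packaged temperature-dependent Michaelis–Menten parameter table for
    mefenamic acid hydroxylation (BM3 M11: 8 temperatures × 3 metabolites;
    CYP1A2: 4 × 2, the 3'-pathway being absent for CYP1A2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .arrhenius import R_GAS
from .errors import DataValidationError
from .kinetics import KineticParamTable, VelocityTable, read_param_table
from .poses import CriteriaConfig, PoseFrame, SomDefinition

__all__ = [
    "Pathway",
    "SyntheticKineticsConfig",
    "SyntheticPoseConfig",
    "constant_envelope",
    "bell_envelope",
    "gen_kinetics",
    "gen_pose_trajectory",
    "table1_fixture",
    "DEFAULT_TEMPERATURES",
    "DEFAULT_CONCENTRATIONS",
]

#: the eight incubation temperatures of the reference kinetics study (K)
DEFAULT_TEMPERATURES = (277.0, 283.4, 290.2, 292.7, 298.6, 304.4, 313.3, 317.6)

#: seven substrate concentrations, 10–750 micromolar
DEFAULT_CONCENTRATIONS = (10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 750.0)


def constant_envelope(_: float) -> float:
    return 1.0


def bell_envelope(T: float, T_opt: float = 298.0, width: float = 15.0) -> float:
    """Smooth rise-and-fall of absolute activity around an optimum."""
    return math.exp(-(((T - T_opt) / width) ** 2))


@dataclass(frozen=True)
class Pathway:
    """One product pathway of the generative Arrhenius model.

    ``A_rel`` is the relative pre-exponential (collision) factor,
    ``G_eff_kJ`` the effective energy entering exp(−G/(R·T)); a pathway pair
    with A ratio a and G difference g yields a modified Arrhenius line with
    intercept ln(a) and slope −g/R (slope in K against a 10³/T abscissa).
    """

    label: str
    A_rel: float
    G_eff_kJ: float
    KM_uM: float = 100.0

    def __post_init__(self) -> None:
        if self.A_rel <= 0 or self.KM_uM <= 0:
            raise DataValidationError("A_rel and KM must be positive")


@dataclass
class SyntheticKineticsConfig:
    """Study conditions for the kinetics generator.

    Defaults mirror the reference experiment: eight temperatures from 277.0
    to 317.6 K, seven substrate concentrations from 10 to 750 micromolar,
    pooled triplicate measurements, 5% multiplicative velocity noise, and a
    bell-shaped shared activity envelope peaking near 298 K. The default
    pathway pair encodes an intercept of 3.0 and a slope of −8.1/R
    (≈ −0.974 K), the composite observed for the aliphatic/aromatic
    mefenamic-acid pathway pair.
    """

    temperatures: Sequence[float] = DEFAULT_TEMPERATURES
    pathways: Sequence[Pathway] = (
        Pathway("path1", A_rel=math.exp(3.0) * 600.0, G_eff_kJ=8.1),
        Pathway("path2", A_rel=600.0, G_eff_kJ=0.0),
    )
    envelope: Callable[[float], float] = bell_envelope
    substrate_concs: Sequence[float] = DEFAULT_CONCENTRATIONS
    noise_cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if len(np.unique(t)) != len(t) or np.any(t <= 0):
            raise DataValidationError("temperatures must be distinct and positive")
        if self.noise_cv < 0:
            raise DataValidationError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise DataValidationError("need at least one replicate")
        labels = [p.label for p in self.pathways]
        if len(set(labels)) != len(labels):
            raise DataValidationError("pathway labels must be unique")

    def true_vmax(self, pathway: Pathway, T: float) -> float:
        return (
            self.envelope(T)
            * pathway.A_rel
            * math.exp(-pathway.G_eff_kJ * 1e3 / (R_GAS * T))
        )


def gen_kinetics(cfg: SyntheticKineticsConfig) -> tuple[VelocityTable, KineticParamTable]:
    """Generate a velocity table plus its ground-truth parameter table.

    Velocities are v = Vmax_i(T)·S/(KM_i+S)·(1+ε) with ε ~ N(0, noise_cv)
    truncated at −0.99. Bit-identical for a fixed seed. The returned truth
    table carries the noise-free Vmax/KM per (temperature, pathway) with
    zero SEs.
    """
    rng = np.random.default_rng(cfg.seed)
    vel_rows, truth_rows = [], []
    for T in cfg.temperatures:
        for p in cfg.pathways:
            vmax = cfg.true_vmax(p, T)
            truth_rows.append(
                {
                    "temperature_K": T,
                    "metabolite": p.label,
                    "Vmax": vmax,
                    "Vmax_SE": 0.0,
                    "KM": p.KM_uM,
                    "KM_SE": 0.0,
                }
            )
            for rep in range(cfg.n_replicates):
                for S in cfg.substrate_concs:
                    eps = max(rng.normal(0.0, cfg.noise_cv), -0.99) if cfg.noise_cv > 0 else 0.0
                    vel_rows.append(
                        {
                            "temperature_K": T,
                            "substrate_conc_uM": S,
                            "metabolite": p.label,
                            "velocity": vmax * S / (p.KM_uM + S) * (1.0 + eps),
                            "replicate": rep + 1,
                        }
                    )
    return (
        VelocityTable(pd.DataFrame(vel_rows)),
        KineticParamTable(pd.DataFrame(truth_rows)),
    )


# ---------------------------------------------------------------------------
# pose trajectories

#: Fe sits one ferryl bond length below the oxygen in the construction frame
_FE_O_BOND_NM = 0.163
_CH_BOND_NM = 0.109


@dataclass
class SyntheticPoseConfig:
    """Construction plan for an oracle pose trajectory.

    ``target_fraction`` maps each SOM label to the exact percentage of
    frames built catalytically active for it (realized as round(p·n) frames
    chosen by a seeded shuffle, so the constructed fraction is exact, not a
    Bernoulli draw). ``jitter`` is the per-coordinate Gaussian displacement
    (nm) applied after construction; geometric margins are at least 3×
    jitter so labels survive the perturbation.
    """

    n_frames: int = 100
    soms: Sequence[SomDefinition] = (
        SomDefinition("arom", "aromatic", c_atom="arom-C", h_atom="arom-H"),
        SomDefinition("aliph", "aliphatic", h_atom="aliph-H"),
    )
    target_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"arom": 60.0, "aliph": 40.0}
    )
    jitter: float = 0.005
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise DataValidationError("need at least one frame")
        for label, frac in self.target_fraction.items():
            if not 0.0 <= frac <= 100.0:
                raise DataValidationError(f"target fraction for {label!r} outside [0, 100]")
        if self.jitter < 0:
            raise DataValidationError("jitter must be >= 0")
        som_labels = {s.label for s in self.soms}
        unknown = set(self.target_fraction) - som_labels
        if unknown:
            raise DataValidationError(f"target fractions for unknown SOMs: {sorted(unknown)}")


def _place_h_for_angle(
    o: np.ndarray, c: np.ndarray, target_deg: float, bond: float = _CH_BOND_NM
) -> np.ndarray:
    """Place H at C–H bond length from C so the C–H–O angle hits target_deg.

    In-plane bisection on the direction of the C→H bond; the angle at H is
    monotone in the construction parameter over (0, π).
    """

    def angle_at_h(phi: float) -> float:
        h = c + bond * np.array([math.sin(phi), 0.0, math.cos(phi)])
        u, v = c - h, o - h
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))

    lo, hi = 1e-6, math.pi - 1e-6
    # angle_at_h(≈0) → 180 (H on the O–C axis beyond C ... on axis toward +z);
    # pick the bracket by sign of (angle − target)
    f_lo = angle_at_h(lo) - target_deg
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        f_mid = angle_at_h(mid) - target_deg
        if (f_mid > 0) == (f_lo > 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    phi = 0.5 * (lo + hi)
    return c + bond * np.array([math.sin(phi), 0.0, math.cos(phi)])


def _construct_som_atoms(
    som: SomDefinition, active: bool, variant: int, cfg: SyntheticPoseConfig
) -> dict[str, np.ndarray]:
    """Atom coordinates for one SOM in the canonical (unrotated) frame.

    The ferryl oxygen is at the origin and Fe directly below it. Margins:
    active/inactive distances sit max(3·jitter, 0.05) nm inside/outside the
    cutoff; angles sit at least 20° from the nearest window boundary.
    """
    crit = cfg.criteria
    margin = max(3.0 * cfg.jitter, 0.05)
    o = np.zeros(3)
    if som.kind == "aromatic":
        lo_excl = min(crit.aromatic_excluded_angle[0], 360.0 - crit.aromatic_excluded_angle[1])
        good_angle = max(20.0, lo_excl - 40.0)  # far below the exclusion onset
        bad_angle = min(180.0, lo_excl + 40.0)
        if active:
            d = crit.distance_cutoff - margin
            c = np.array([0.0, 0.0, d])
            h = _place_h_for_angle(o, c, good_angle)
        elif variant % 2 == 0:  # fail on distance
            d = crit.distance_cutoff + margin
            c = np.array([0.0, 0.0, d])
            h = _place_h_for_angle(o, c, good_angle)
        else:  # fail on the hydrogen-interposition angle
            d = crit.distance_cutoff - margin
            c = np.array([0.0, 0.0, d])
            h = _place_h_for_angle(o, c, bad_angle)
        return {som.c_atom: c, som.h_atom: h}
    # aliphatic: angle at the ferryl oxygen between H and Fe
    lo, hi = cfg.criteria.aliphatic_angle_window
    mid_angle = 0.5 * (lo + hi)
    bad_angle = max(5.0, lo - 40.0)
    if active:
        d, ang = crit.distance_cutoff - margin, mid_angle
    elif variant % 2 == 0:
        d, ang = crit.distance_cutoff + margin, mid_angle
    else:
        d, ang = crit.distance_cutoff - margin, bad_angle
    # Fe direction from O is (0,0,-1); place H at `ang` degrees from it
    theta = math.radians(ang)
    h = d * np.array([math.sin(theta), 0.0, -math.cos(theta)])
    return {som.h_atom: h}


def gen_pose_trajectory(
    cfg: SyntheticPoseConfig,
) -> tuple[list[PoseFrame], dict[str, np.ndarray]]:
    """Build an oracle trajectory; returns (frames, labels-per-SOM).

    Each frame carries the shared Fe/O_ferryl atoms plus per-SOM C/H atoms
    placed active or inactive by construction; inactive frames alternate
    between distance and angle violations. After jitter, each whole frame is
    subjected to a random rigid rotation and translation, which the
    classifier must be blind to.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    labels: dict[str, np.ndarray] = {}
    for som in cfg.soms:
        frac = cfg.target_fraction.get(som.label, 0.0)
        n_active = round(frac / 100.0 * n)
        lab = np.zeros(n, dtype=bool)
        lab[rng.permutation(n)[:n_active]] = True
        labels[som.label] = lab

    frames = []
    for i in range(n):
        coords: dict[str, np.ndarray] = {
            "O_ferryl": np.zeros(3),
            "Fe": np.array([0.0, 0.0, -_FE_O_BOND_NM]),
        }
        for som in cfg.soms:
            coords.update(
                _construct_som_atoms(som, bool(labels[som.label][i]), variant=i, cfg=cfg)
            )
        if cfg.jitter > 0:
            # redraw jitter that would carry a frame across a criterion
            # boundary: labels are a guarantee, not a probability. With
            # margins >= 3x jitter redraws are rare (worst case is the
            # narrow aliphatic angle window, whose angular sensitivity to
            # coordinate noise makes boundary crossings ~per-mille events).
            from .poses import classify_frame  # local import avoids a cycle

            for _ in range(100):
                jittered = {
                    role: xyz + rng.normal(0.0, cfg.jitter, size=3)
                    for role, xyz in coords.items()
                }
                probe = PoseFrame(frame_index=i, coords=jittered)
                if all(
                    classify_frame(probe, som, cfg.criteria)
                    == bool(labels[som.label][i])
                    for som in cfg.soms
                ):
                    coords = jittered
                    break
            else:  # pragma: no cover - margins make this unreachable
                raise DataValidationError(
                    "jitter repeatedly crossed a criterion boundary; "
                    "reduce jitter or widen margins"
                )
        # random rigid motion: rotation from a normalized quaternion + shift
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )
        shift = rng.uniform(-5.0, 5.0, size=3)
        coords = {role: rot @ xyz + shift for role, xyz in coords.items()}
        frames.append(PoseFrame(frame_index=i, coords=coords))
    return frames, labels


def table1_fixture() -> KineticParamTable:
    """The packaged mefenamic-acid kinetic-parameter table (both enzymes).

    Use ``.subset("BM3 M11")`` or ``.subset("CYP1A2")`` before pairwise
    analyses. The ± values of the source table are stored as standard
    errors of the per-temperature Michaelis–Menten fits.
    """
    path = resources.files("p450select.data") / "mefenamic_acid_kinetics.csv"
    with resources.as_file(path) as p:
        return read_param_table(p)
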
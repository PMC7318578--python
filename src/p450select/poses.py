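"""Geometric classification of catalytically active substrate poses.

A frame from a molecular-dynamics trajectory of substrate bound above the
heme is called catalytically active for a given site of metabolism (SOM)
when the SOM geometry relative to the ferryl oxygen of compound I satisfies
distance/angle criteria for transition-state formation:

aromatic hydroxylation
    C_SOM–O_ferryl distance < 0.35 nm, and the C_SOM–H_SOM–O_ferryl angle
    must NOT fall in the hydrogen-interposition window written as
    [140°, 220°] — with three-point angles confined to [0°, 180°], the
    [180°, 220°] half reflects onto [140°, 180°], so the exclusion is
    simply angle >= 140°.

aliphatic hydroxylation (hydrogen abstraction)
    H_SOM–O_ferryl distance < 0.35 nm, and the H_SOM–O_ferryl–Fe angle must
    lie within [110°, 130°] (inclusive).

Distances are strictly below the cutoff (as the criteria are printed);
angle windows are closed. The internal length unit is nanometres; ångström
input is accepted only with an explicit unit declaration.

Per-trajectory active-pose fractions are the entropic cross-check for the
collision-efficiency intercepts of the modified Arrhenius plots: a SOM whose
pose population satisfies the criteria more often has a higher ln A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, DataParseError, DataValidationError

__all__ = [
    "SomDefinition",
    "PoseFrame",
    "CriteriaConfig",
    "PoseFractionReport",
    "frame_geometry",
    "classify_frame",
    "active_fraction",
    "fraction_report",
    "read_pose_table",
    "read_xyz_trajectory",
]

ANGSTROM_PER_NM = 10.0
_UNIT_FACTORS = {"nm": 1.0, "a": 0.1, "angstrom": 0.1, "ang": 0.1}


@dataclass(frozen=True)
class SomDefinition:
    """Maps one site of metabolism onto the atom roles of a frame.

    ``c_atom``/``h_atom`` name the SOM carbon and hydrogen roles in the
    frame's coordinate dictionary; ``o_atom``/``fe_atom`` default to the
    shared compound-I roles.
    """

    label: str
    kind: Literal["aromatic", "aliphatic"]
    c_atom: str | None = None
    h_atom: str | None = None
    o_atom: str = "O_ferryl"
    fe_atom: str = "Fe"

    def __post_init__(self) -> None:
        if self.kind not in ("aromatic", "aliphatic"):
            raise DataValidationError(f"unknown hydroxylation type {self.kind!r}")
        if self.kind == "aromatic" and (self.c_atom is None or self.h_atom is None):
            raise DataValidationError(
                f"aromatic SOM {self.label!r} needs both c_atom and h_atom roles"
            )
        if self.kind == "aliphatic" and self.h_atom is None:
            raise DataValidationError(
                f"aliphatic SOM {self.label!r} needs an h_atom role"
            )

    @property
    def required_roles(self) -> tuple[str, ...]:
        if self.kind == "aromatic":
            return (self.c_atom, self.h_atom, self.o_atom)
        return (self.h_atom, self.o_atom, self.fe_atom)


@dataclass(frozen=True)
class PoseFrame:
    """One trajectory frame: role -> 3-vector coordinates in nanometres."""

    frame_index: int
    coords: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for role, xyz in self.coords.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise DataValidationError(
                    f"frame {self.frame_index}: role {role!r} has invalid coordinates"
                )
            self.coords[role] = arr

    def require(self, role: str) -> np.ndarray:
        if role not in self.coords:
            raise DataValidationError(
                f"frame {self.frame_index}: missing atom role {role!r}"
            )
        return self.coords[role]


@dataclass(frozen=True)
class CriteriaConfig:
    """Distance/angle thresholds of the pose criteria (nm, degrees)."""

    distance_cutoff: float = 0.35
    aromatic_excluded_angle: tuple[float, float] = (140.0, 220.0)
    aliphatic_angle_window: tuple[float, float] = (110.0, 130.0)

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise DataValidationError("distance cutoff must be positive")
        for lo, hi in (self.aromatic_excluded_angle, self.aliphatic_angle_window):
            if lo > hi:
                raise DataValidationError("angle interval bounds must be ordered")


@dataclass
class PoseFractionReport:
    """Per-(trajectory, SOM) active-pose percentages, never silently pooled."""

    rows: pd.DataFrame  # columns: trajectory, som, n_frames, n_active, percent_active

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def pivot(self) -> pd.DataFrame:
        """Trajectories as rows, SOMs as columns (publication-table shape)."""
        return self.rows.pivot(index="trajectory", columns="som", values="percent_active")


def _angle_deg(p_left: np.ndarray, p_vertex: np.ndarray, p_right: np.ndarray) -> float:
    """Three-point angle at ``p_vertex``, in [0, 180] degrees."""
    u = p_left - p_vertex
    v = p_right - p_vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DataValidationError("degenerate angle: coincident atoms")
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def frame_geometry(frame: PoseFrame, som: SomDefinition) -> dict[str, float]:
    """Distance (nm) and angle (degrees) defining the criteria for one SOM.

    Aromatic: distance C_SOM–O_ferryl, angle at H_SOM between C_SOM and
    O_ferryl. Aliphatic: distance H_SOM–O_ferryl, angle at O_ferryl between
    H_SOM and Fe.
    """
    if som.kind == "aromatic":
        c = frame.require(som.c_atom)
        h = frame.require(som.h_atom)
        o = frame.require(som.o_atom)
        return {
            "distance": float(np.linalg.norm(c - o)),
            "angle": _angle_deg(c, h, o),
        }
    h = frame.require(som.h_atom)
    o = frame.require(som.o_atom)
    fe = frame.require(som.fe_atom)
    return {
        "distance": float(np.linalg.norm(h - o)),
        "angle": _angle_deg(h, o, fe),
    }


def _excluded_lower_bound(interval: tuple[float, float]) -> float:
    """Map an exclusion interval possibly extending past 180° onto [0, 180].

    Since measured angles live in [0, 180], the part of [lo, hi] above 180°
    reflects onto [360 − hi, 180]; the effective exclusion is a single upper
    region starting at min(lo, 360 − hi).
    """
    lo, hi = interval
    return min(lo, 360.0 - hi) if hi > 180.0 else lo


def classify_frame(
    frame: PoseFrame, som: SomDefinition, cfg: CriteriaConfig | None = None
) -> bool:
    """True when the frame is a catalytically active pose for this SOM."""
    cfg = cfg or CriteriaConfig()
    g = frame_geometry(frame, som)
    if not g["distance"] < cfg.distance_cutoff:
        return False
    if som.kind == "aromatic":
        lo, hi = cfg.aromatic_excluded_angle
        if hi > 180.0:
            return g["angle"] < _excluded_lower_bound(cfg.aromatic_excluded_angle)
        return not (lo <= g["angle"] <= hi)
    lo, hi = cfg.aliphatic_angle_window
    return lo <= g["angle"] <= hi


def active_fraction(
    frames: Sequence[PoseFrame],
    som: SomDefinition,
    cfg: CriteriaConfig | None = None,
) -> tuple[int, int, float]:
    """(n_frames, n_active, percent_active) over one trajectory."""
    frames = list(frames)
    if not frames:
        raise DataValidationError("empty trajectory")
    n_active = sum(classify_frame(f, som, cfg) for f in frames)
    return len(frames), n_active, 100.0 * n_active / len(frames)


def fraction_report(
    trajectories: dict[str, Sequence[PoseFrame]],
    soms: Iterable[SomDefinition],
    cfg: CriteriaConfig | None = None,
) -> PoseFractionReport:
    """Active-pose percentages for every (trajectory, SOM) combination."""
    rows = []
    for traj_name, frames in trajectories.items():
        for som in soms:
            n, n_act, pct = active_fraction(frames, som, cfg)
            rows.append(
                {
                    "trajectory": traj_name,
                    "som": som.label,
                    "n_frames": n,
                    "n_active": n_act,
                    "percent_active": pct,
                }
            )
    return PoseFractionReport(pd.DataFrame(rows))


def read_pose_table(path, unit: str | None = None) -> list[PoseFrame]:
    """Read frames from delimited text: columns frame, role, x, y, z[, unit].

    The length unit must be declared — either a ``unit`` column per row or a
    single ``unit=`` argument ("nm" or "angstrom"); it is never inferred
    from coordinate magnitudes. Comma or tab delimited.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise DataFormatError(f"{path}: empty file")
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    required = ["frame", "role", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required column(s) {missing}")
    if "unit" in df.columns:
        units = df["unit"].str.strip().str.lower()
    elif unit is not None:
        units = pd.Series([unit.lower()] * len(df))
    else:
        raise DataFormatError(
            f"{path}: no 'unit' column and no unit declared; length units are never guessed"
        )
    bad_units = sorted(set(units) - set(_UNIT_FACTORS))
    if bad_units:
        raise DataParseError(f"unknown length unit(s) {bad_units}", column="unit")
    factors = units.map(_UNIT_FACTORS).to_numpy(dtype=float)
    for col in ("x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = int(vals.isna().idxmax())
            raise DataParseError(
                f"non-numeric coordinate {df[col][i]!r}", line=i + 2, column=col
            )
        df[col] = vals.astype(float) * factors
    frames = []
    for idx, grp in df.groupby(pd.to_numeric(df["frame"]), sort=True):
        coords = {
            str(r["role"]).strip(): np.array([r["x"], r["y"], r["z"]])
            for _, r in grp.iterrows()
        }
        frames.append(PoseFrame(frame_index=int(idx), coords=coords))
    return frames


def read_xyz_trajectory(path, role_map: dict[int, str], unit: str) -> list[PoseFrame]:
    """Read a multi-frame XYZ file, keeping only the atoms named in role_map.

    ``role_map`` maps 0-based atom indices within each frame to role names
    (e.g. {0: "Fe", 1: "O_ferryl", 2: "3'-C", 3: "3'-H"}); ``unit`` declares
    the file's length unit ("nm" or "angstrom" — plain XYZ is conventionally
    ångström, but the declaration is still mandatory).
    """
    factor = _UNIT_FACTORS.get(unit.lower())
    if factor is None:
        raise DataFormatError(f"unknown length unit {unit!r}")
    frames: list[PoseFrame] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_index = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise DataParseError(
                f"expected atom count, got {lines[i]!r}", line=i + 1
            ) from None
        block = lines[i + 2 : i + 2 + natoms]
        if len(block) < natoms:
            raise DataFormatError(f"{path}: truncated frame at line {i + 1}")
        coords = {}
        for j, ln in enumerate(block):
            if j in role_map:
                parts = ln.split()
                if len(parts) < 4:
                    raise DataParseError("short XYZ atom line", line=i + 3 + j)
                coords[role_map[j]] = np.array(
                    [float(parts[1]), float(parts[2]), float(parts[3])]
                ) * factor
        missing = set(role_map.values()) - set(coords)
        if missing:
            raise DataValidationError(
                f"frame {frame_index}: role indices beyond frame size for {sorted(missing)}"
            )
        frames.append(PoseFrame(frame_index=frame_index, coords=coords))
        frame_index += 1
        i += 2 + natoms
    if not frames:
        raise DataFormatError(f"{path}: no frames found")
    return frames
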
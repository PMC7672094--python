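"""Rigid-body kinematics of a bilateral, archaeostylic lower jaw.

The model: each hemimandible (Meckel's cartilage) is a rigid body hinged to
the fixed palatoquadrate at a single revolute axis through the jaw joint.
The axis is oblique — it makes an angle ``alpha`` with the mandibular long
axis and dips ``beta`` below the horizontal plane — so depressing the jaw
necessarily rotates the mandible about its own long axis.  That long-axis
*roll* (eversion of the biting surface on opening, inversion on closing) and
its consequences for the dentition are the quantities this module computes.

Frames and conventions
----------------------
* Hemimandible local frame: right-handed, ``+x`` anterior along the closed
  mandibular long axis, ``+z`` dorsal.  For the left hemimandible ``+y`` is
  lateral; the right side is its exact mirror image through the midsagittal
  plane.
* Assembly frame: midsagittal plane is ``x``–``z``; the closed hemimandibles
  are yawed ``±psi0/2`` about their hinge points so the anterior tips meet
  point-to-point at the symphysis (there is no broad symphysis to resist
  long-axis rotation).
* Gape ``theta_g``: angle of the long axis below the horizontal plane
  (the depression a lateral-view protractor would read off the model).
* Roll ``tau``: signed twist of the hinge rotation about the closed long
  axis, *eversion positive* (biting surface rotated outward) on both sides.
* Symphysial angle ``psi``: signed ventral-view angle between the left and
  right long axes, positive when anteriorly convergent (as when closed).

All public angles are degrees; lengths are mm; internal math is radians.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .errors import (
    InfeasibleGeometryError,
    InvalidInputError,
    NoFitError,
    UnreachableGapeError,
)
from .geometry import Rotation, swing_twist_decompose, unit_vector

_X = np.array([1.0, 0.0, 0.0])


class AxisConvention(str, Enum):
    """How ``alpha`` (axis vs. long axis) is measured.

    ``HORIZONTAL_PROJECTION``: alpha is the angle between the *horizontal
    projection* of the hinge axis and the long axis (default; keeps a
    mediolateral axis component at alpha = beta = 45 deg).
    ``DIRECT``: alpha is the true 3-D angle between axis and long axis; the
    two printed 45-deg constraints then force the axis into the sagittal
    plane of the hemimandible.
    """

    HORIZONTAL_PROJECTION = "horizontal-projection"
    DIRECT = "direct"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def lateral_sign(self) -> int:
        """Sign of the lateral direction on the assembly y-axis (+y = left)."""
        return +1 if self is Side.LEFT else -1


@dataclass(frozen=True)
class HingeAxisSpec:
    """Orientation of the jaw-joint rotation axis, in degrees."""

    alpha: float = 45.0
    beta: float = 45.0
    convention: AxisConvention = AxisConvention.HORIZONTAL_PROJECTION

    def __post_init__(self):
        if not 0.0 < self.alpha <= 90.0:
            raise InvalidInputError(f"alpha must be in (0, 90], got {self.alpha}")
        if not 0.0 <= self.beta < 90.0:
            raise InvalidInputError(f"beta must be in [0, 90), got {self.beta}")
        object.__setattr__(self, "convention", AxisConvention(self.convention))


def build_hinge_axis(spec: HingeAxisSpec, side: Side | str) -> np.ndarray:
    """Unit hinge-axis direction in the hemimandible local frame.

    The mediolateral component points *medially* on the ventrally-descending
    end of the axis; this is the orientation under which jaw depression both
    reaches the full gape range and everts the dentition, as observed on the
    physical model.
    """
    side = Side(side)
    a = np.radians(spec.alpha)
    b = np.radians(spec.beta)
    lat = side.lateral_sign
    if spec.convention is AxisConvention.HORIZONTAL_PROJECTION:
        n = np.array([np.cos(b) * np.cos(a), -lat * np.cos(b) * np.sin(a), -np.sin(b)])
    else:
        resid = 1.0 - np.cos(a) ** 2 - np.sin(b) ** 2
        if resid < -1e-12:
            raise InfeasibleGeometryError(
                f"direct convention infeasible: cos^2(alpha={spec.alpha}) + "
                f"sin^2(beta={spec.beta}) = {np.cos(a)**2 + np.sin(b)**2:.6f} > 1"
            )
        n = np.array([np.cos(a), -lat * np.sqrt(max(resid, 0.0)), -np.sin(b)])
    return n / np.linalg.norm(n)


@dataclass(frozen=True)
class ToothRow:
    """Tooth families along the dental platform.

    ``radii`` are perpendicular distances (mm) from the mandibular long
    axis; within a family the labial (older, more worn) tooth sits at a
    strictly larger radius than its lingual (younger) successor.
    ``axial_positions`` are mm anterior of the hinge point.
    """

    radii: np.ndarray
    axial_positions: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        x = np.asarray(self.axial_positions, dtype=float)
        if r.shape != x.shape or r.ndim != 1:
            raise InvalidInputError("radii and axial_positions must be equal-length 1-D")
        if np.any(r < 0):
            raise InvalidInputError("tooth radii must be non-negative")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "axial_positions", x)
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"t{i+1}" for i in range(len(r)))
            )

    def __len__(self) -> int:
        return len(self.radii)

    def local_positions(self) -> np.ndarray:
        """Tooth crown positions in the hemimandible local frame (dorsal offset)."""
        p = np.zeros((len(self), 3))
        p[:, 0] = self.axial_positions
        p[:, 2] = self.radii
        return p


@dataclass(frozen=True)
class Hemimandible:
    side: Side
    length: float
    hinge_axis: np.ndarray
    hinge_point: np.ndarray
    tooth_row: ToothRow
    long_axis_closed: np.ndarray = field(default_factory=lambda: _X.copy())

    def __post_init__(self):
        object.__setattr__(self, "side", Side(self.side))
        object.__setattr__(self, "hinge_axis", unit_vector(self.hinge_axis))
        object.__setattr__(self, "hinge_point", np.asarray(self.hinge_point, float))
        object.__setattr__(self, "long_axis_closed", unit_vector(self.long_axis_closed))


@dataclass(frozen=True)
class JawAssembly:
    """Bilateral jaw: mirror-symmetric hemimandibles plus the closed symphysial angle."""

    left: Hemimandible
    right: Hemimandible
    closed_symphysial_angle: float = 50.0
    axis_spec: HingeAxisSpec | None = None

    @property
    def psi0(self) -> float:
        return self.closed_symphysial_angle

    def hemimandible(self, side: Side | str) -> Hemimandible:
        return self.left if Side(side) is Side.LEFT else self.right

    def yaw_to_assembly(self, side: Side | str) -> Rotation:
        """Rotation taking the hemimandible local frame into the assembly frame."""
        lat = Side(side).lateral_sign
        return Rotation.from_axis_angle(
            [0.0, 0.0, 1.0], -lat * np.radians(self.psi0 / 2.0)
        )


def build_assembly(
    axis_spec: HingeAxisSpec | None = None,
    *,
    jaw_length: float = 30.0,
    closed_symphysial_angle: float = 50.0,
    tooth_radii: Sequence[float] | None = None,
    tooth_axial_positions: Sequence[float] | None = None,
) -> JawAssembly:
    """Construct a mirror-symmetric assembly from printed geometry.

    Defaults follow the fossil: the hinge axis at 45 deg to the long axis and
    dipping 45 deg below horizontal, a closed symphysial angle of 50 deg, and
    nine tooth families whose radii grade upward labially.
    """
    axis_spec = axis_spec or HingeAxisSpec()
    if tooth_radii is None:
        # nine families, radii graded from lingual (small) to labial (large)
        tooth_radii = np.linspace(3.0, 6.0, 9)
    if tooth_axial_positions is None:
        tooth_axial_positions = np.linspace(0.3, 0.9, len(tooth_radii)) * jaw_length
    row = ToothRow(np.asarray(tooth_radii, float), np.asarray(tooth_axial_positions, float))
    halves = {}
    w = jaw_length * np.sin(np.radians(closed_symphysial_angle / 2.0))
    for side in (Side.LEFT, Side.RIGHT):
        halves[side] = Hemimandible(
            side=side,
            length=jaw_length,
            hinge_axis=build_hinge_axis(axis_spec, side),
            hinge_point=np.array([0.0, side.lateral_sign * w, 0.0]),
            tooth_row=row,
        )
    return JawAssembly(
        left=halves[Side.LEFT],
        right=halves[Side.RIGHT],
        closed_symphysial_angle=closed_symphysial_angle,
        axis_spec=axis_spec,
    )


# ---------------------------------------------------------------------------
# Gape solving
# ---------------------------------------------------------------------------

def _depression_deg(axis: np.ndarray, chi: float) -> float:
    """Depression (deg) of the long axis after rotating by chi (rad) about axis."""
    uz = -axis[1] * np.sin(chi) + axis[2] * axis[0] * (1.0 - np.cos(chi))
    return float(np.degrees(np.arcsin(np.clip(-uz, -1.0, 1.0))))


def _depressing_sign(axis: np.ndarray, side: Side) -> float:
    # d(theta)/d(chi) at 0 is proportional to axis_y; when the axis lies in
    # the sagittal plane both signs depress and the everting branch is kept.
    if abs(axis[1]) > 1e-12:
        return float(np.sign(axis[1]))
    return -float(side.lateral_sign)


def max_gape(assembly: JawAssembly, side: Side | str = Side.LEFT) -> tuple[float, float]:
    """Maximum achievable depression (deg) and the hinge angle phi (deg) reaching it."""
    side = Side(side)
    n = assembly.hemimandible(side).hinge_axis
    s = _depressing_sign(n, side)
    # -u_z(chi) = c sin(chi) + b (cos(chi) - 1) with b = n_x n_z, c = n_y is a
    # single-harmonic sinusoid: starting from chi = 0 in the depressing
    # direction, the first stationary point is the unique maximum.
    b, c = n[0] * n[2], n[1]
    if abs(b) < 1e-15 and abs(c) < 1e-15:
        return 0.0, 0.0
    chi1 = float(np.arctan2(c, b))
    candidates = []
    for chi in (chi1, chi1 - np.pi, chi1 + np.pi, chi1 - 2 * np.pi, chi1 + 2 * np.pi):
        if chi * s > 1e-12 and abs(chi) <= 2 * np.pi:
            candidates.append(chi)
    chi_star = min(candidates, key=abs)
    theta_max = _depression_deg(n, chi_star)
    return theta_max, float(np.degrees(abs(chi_star)))


def solve_hinge_rotation_for_gape(
    assembly: JawAssembly, theta_g: float, side: Side | str = Side.LEFT
) -> float:
    """Hinge angle phi (deg, magnitude) depressing the long axis by ``theta_g`` deg."""
    side = Side(side)
    if theta_g < 0:
        raise InvalidInputError("gape must be non-negative")
    if theta_g == 0:
        return 0.0
    n = assembly.hemimandible(side).hinge_axis
    s = _depressing_sign(n, side)
    theta_max, phi_at_max = max_gape(assembly, side)
    if theta_g > theta_max + 1e-12:
        raise UnreachableGapeError(theta_g, theta_max)
    hi = np.radians(phi_at_max)
    f = lambda p: _depression_deg(n, s * p) - theta_g
    if f(hi) < 0:  # theta_g == theta_max up to rounding
        return float(np.degrees(hi))
    phi = brentq(f, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    return float(np.degrees(phi))


def _side_rotation(assembly: JawAssembly, side: Side, phi_deg: float) -> Rotation:
    n = assembly.hemimandible(side).hinge_axis
    s = _depressing_sign(n, side)
    return Rotation.from_axis_angle(n, s * np.radians(phi_deg))


@dataclass(frozen=True)
class GapePose:
    """Kinematic state of the assembly at one gape angle (degrees, mm)."""

    gape: float
    phi: float                    # hinge rotation magnitude, per side
    roll: float                   # eversion-positive long-axis roll, per side
    symphysial_angle: float       # signed ventral-view angle
    tip_left: np.ndarray
    tip_right: np.ndarray

    @property
    def combined_medial_rotation(self) -> float:
        """Combined closing rotation of both dental batteries, 2*tau (deg)."""
        return 2.0 * self.roll

    @property
    def tip_span(self) -> float:
        """Ventral-view distance between the anterior tips (mm)."""
        d = (self.tip_left - self.tip_right)[:2]
        return float(np.linalg.norm(d))


def pose_at_gape(assembly: JawAssembly, theta_g: float) -> GapePose:
    """Pose the assembly at gape ``theta_g`` and derive roll and symphysial angle.

    Roll is the signed twist of the hinge rotation about the closed long
    axis (swing--twist split), flipped to eversion-positive per side; the
    symphysial angle is the signed angle between ventral-view projections of
    the two rotated long axes.
    """
    phi = solve_hinge_rotation_for_gape(assembly, theta_g, Side.LEFT)
    dirs = {}
    rolls = {}
    tips = {}
    for side in (Side.LEFT, Side.RIGHT):
        hemi = assembly.hemimandible(side)
        phi_s = solve_hinge_rotation_for_gape(assembly, theta_g, side)
        rot = _side_rotation(assembly, side, phi_s)
        st = swing_twist_decompose(rot, hemi.long_axis_closed)
        rolls[side] = -side.lateral_sign * np.degrees(st.twist_angle)
        u = rot.apply(hemi.long_axis_closed)
        yaw = assembly.yaw_to_assembly(side)
        dirs[side] = yaw.apply(u)
        tips[side] = hemi.hinge_point + hemi.length * dirs[side]
    # signed ventral-view angle, positive when anteriorly convergent
    gamma_l = np.degrees(np.arctan2(dirs[Side.LEFT][1], dirs[Side.LEFT][0]))
    gamma_r = np.degrees(np.arctan2(dirs[Side.RIGHT][1], dirs[Side.RIGHT][0]))
    psi = gamma_r - gamma_l
    return GapePose(
        gape=float(theta_g),
        phi=float(phi),
        roll=float(rolls[Side.LEFT]),
        symphysial_angle=float(psi),
        tip_left=tips[Side.LEFT],
        tip_right=tips[Side.RIGHT],
    )


def landmark_positions(
    assembly: JawAssembly, side: Side | str, theta_g: float, points_local: np.ndarray
) -> np.ndarray:
    """Assembly-frame positions of hemimandible-fixed points at a given gape."""
    side = Side(side)
    hemi = assembly.hemimandible(side)
    phi = solve_hinge_rotation_for_gape(assembly, theta_g, side)
    rot = _side_rotation(assembly, side, phi)
    pts = np.asarray(points_local, dtype=float)
    if side is Side.RIGHT:
        pts = pts * np.array([1.0, -1.0, 1.0])  # mirror of the left-handed template
    posed = rot.apply(pts)
    return assembly.yaw_to_assembly(side).apply(posed) + hemi.hinge_point


@dataclass(frozen=True)
class RollCurve:
    """Observed or modelled (gape, roll) pairs in degrees."""

    gape: np.ndarray
    roll: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.gape, dtype=float)
        r = np.asarray(self.roll, dtype=float)
        if g.shape != r.shape or g.ndim != 1:
            raise InvalidInputError("gape and roll must be equal-length 1-D arrays")
        if len(g) and np.any(np.diff(g) <= 0):
            raise InvalidInputError("gape values must be strictly increasing")
        if len(g) and g[0] == 0.0 and abs(r[0]) > 1e-9:
            raise InvalidInputError("roll at zero gape must be zero")
        object.__setattr__(self, "gape", g)
        object.__setattr__(self, "roll", r)

    @classmethod
    def read_csv(cls, path) -> "RollCurve":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"gape_deg": self.gape, "roll_deg": self.roll}).to_csv(
            path, index=False
        )


def gape_sweep(assembly: JawAssembly, gapes: Sequence[float]) -> pd.DataFrame:
    """Pose table over a sequence of increasing gape angles.

    Columns: theta_gape_deg, phi_hinge_deg, tau_roll_deg, psi_symph_deg,
    tip_span_mm.
    """
    gapes = np.asarray(list(gapes), dtype=float)
    if len(gapes) > 1 and np.any(np.diff(gapes) <= 0):
        raise InvalidInputError("gape list must be strictly increasing")
    rows = []
    for th in gapes:
        p = pose_at_gape(assembly, th)
        rows.append(
            {
                "theta_gape_deg": p.gape,
                "phi_hinge_deg": p.phi,
                "tau_roll_deg": p.roll,
                "psi_symph_deg": p.symphysial_angle,
                "tip_span_mm": p.tip_span,
            }
        )
    return pd.DataFrame(rows)


def roll_curve(assembly: JawAssembly, gapes: Sequence[float]) -> RollCurve:
    table = gape_sweep(assembly, gapes)
    return RollCurve(table["theta_gape_deg"].to_numpy(), table["tau_roll_deg"].to_numpy())


# ---------------------------------------------------------------------------
# Dentition kinematics
# ---------------------------------------------------------------------------

def tooth_velocity_profile(tooth_row: ToothRow, roll_rate: float) -> np.ndarray:
    """Linear crown speeds v_i = r_i * omega (mm/s) for a roll rate in deg/s.

    Because speed is proportional to radius, the labial (larger-radius,
    older) teeth move strictly faster than lingual ones — the velocity
    advantage that sweeps prey-snagging teeth inward as the jaw closes.
    """
    if roll_rate < 0:
        raise InvalidInputError("roll rate must be non-negative")
    return tooth_row.radii * np.radians(roll_rate)


def crown_displacement(tooth_row: ToothRow, delta_tau: float) -> np.ndarray:
    """Chord displacement d_i = 2 r_i sin(delta_tau/2) (mm) of each crown.

    Crowns travel on circles about the mandibular long axis; the chord of
    the rolled arc is the straight-line displacement of each tooth tip.
    """
    if not 0.0 <= delta_tau <= 180.0:
        raise InvalidInputError("delta_tau must be in [0, 180] degrees")
    return 2.0 * tooth_row.radii * np.sin(np.radians(delta_tau) / 2.0)


# ---------------------------------------------------------------------------
# Axis calibration (inverse problem)
# ---------------------------------------------------------------------------

def _forward_roll(alpha: float, beta: float, convention, gapes: np.ndarray) -> np.ndarray:
    spec = HingeAxisSpec(alpha=alpha, beta=beta, convention=convention)
    asm = build_assembly(spec)
    theta_max, _ = max_gape(asm)
    out = np.empty(len(gapes))
    for i, th in enumerate(gapes):
        if th > theta_max - 1e-9:
            # graded penalty keeps least-squares away from infeasible axes
            out[i] = 1e3 + 10.0 * (th - theta_max)
            continue
        p = pose_at_gape(asm, th)
        out[i] = p.roll
    return out


def fit_axis_to_roll_curve(
    observed: RollCurve,
    convention: AxisConvention | str = AxisConvention.HORIZONTAL_PROJECTION,
    *,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[HingeAxisSpec, float]:
    """Calibrate (alpha, beta) to an observed roll-vs-gape table.

    Bounded least squares on the forward revolute model, multi-started from
    a coarse deterministic grid plus seeded jitter.  Returns the best spec
    and the root-mean-square roll residual in degrees.
    """
    convention = AxisConvention(convention)
    if len(observed.gape) < 3:
        raise InvalidInputError("need at least 3 observation pairs to fit an axis")
    gapes = observed.gape
    target = observed.roll
    mask = gapes > 0
    if not np.any(mask):
        raise InvalidInputError("roll curve must include positive gapes")

    def resid(p):
        return _forward_roll(p[0], p[1], convention, gapes[mask]) - target[mask]

    rng = np.random.default_rng(seed)
    lo, hi = np.array([1.0, 0.5]), np.array([89.9, 89.0])
    starts = [np.array([45.0, 45.0]), np.array([70.0, 20.0]), np.array([20.0, 70.0]),
              np.array([85.0, 10.0])]
    while len(starts) < n_starts:
        starts.append(lo + rng.random(2) * (hi - lo))
    best = None
    for p0 in starts[:n_starts]:
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.fun)) or np.any(np.abs(best.fun) > 900):
        raise NoFitError("no feasible hinge axis reproduces the observed gapes")
    rms = float(np.sqrt(np.mean(best.fun ** 2)))
    spec = HingeAxisSpec(alpha=float(best.x[0]), beta=float(best.x[1]),
                         convention=convention)
    return spec, rms


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def assembly_from_config(path) -> JawAssembly:
    """Build an assembly from a JSON/YAML config (degrees, mm)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    spec = HingeAxisSpec(
        alpha=cfg.get("alpha", 45.0),
        beta=cfg.get("beta", 45.0),
        convention=cfg.get("convention", "horizontal-projection"),
    )
    return build_assembly(
        spec,
        jaw_length=cfg.get("jaw_length", 30.0),
        closed_symphysial_angle=cfg.get("closed_symphysial_angle", 50.0),
        tooth_radii=cfg.get("tooth_radii"),
        tooth_axial_positions=cfg.get("tooth_axial_positions"),
    )
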
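"""Exact 3-D rotation algebra on unit quaternions.

Rotations are carried as unit quaternions ``(w, x, y, z)`` canonicalised to
``w >= 0`` so that equality tests are deterministic despite the double cover
of SO(3).  The swing--twist decomposition splits a rotation into a *twist*
about a reference axis (applied first, in the body frame) followed by a
*swing* about an axis perpendicular to it; the signed twist angle is the
quantity used as anatomical roll throughout the jaw-kinematics stage.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

_UNIT_TOL = 1e-9


def _as_unit_vector(v, tol: float = _UNIT_TOL) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise InvalidInputError(f"expected a 3-vector, got shape {v.shape}")
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > tol:
        raise InvalidInputError(f"axis must be unit-norm (|v| = {n:.12g})")
    return v / n


def unit_vector(v) -> np.ndarray:
    """Normalise ``v`` to unit length (for constructing axes from raw data)."""
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise InvalidInputError("cannot normalise the zero vector")
    return v / n


@dataclass(frozen=True)
class Rotation:
    """A proper rotation of R^3, stored as a unit quaternion with w >= 0."""

    q: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.shape != (4,):
            raise InvalidInputError("quaternion must have four components")
        n = float(np.linalg.norm(q))
        if abs(n - 1.0) > 1e-9:
            raise InvalidInputError(f"quaternion must be unit-norm (|q| = {n:.12g})")
        q = q / n
        if q[0] < 0.0 or (q[0] == 0.0 and q[(np.nonzero(q)[0][0] if q.any() else 0)] < 0.0):
            q = -q
        object.__setattr__(self, "q", q)

    # -- constructors ---------------------------------------------------
    @classmethod
    def identity(cls) -> "Rotation":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]))

    @classmethod
    def from_axis_angle(cls, axis, angle: float) -> "Rotation":
        """Rotation by ``angle`` radians about a unit ``axis`` (right-hand rule)."""
        axis = _as_unit_vector(axis)
        half = 0.5 * float(angle)
        return cls(np.concatenate(([np.cos(half)], np.sin(half) * axis)))

    @classmethod
    def from_matrix(cls, m) -> "Rotation":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise InvalidInputError("rotation matrix must be 3x3")
        # Shepperd's method, numerically stable for all quadrants.
        t = np.trace(m)
        if t > 0:
            r = np.sqrt(1.0 + t)
            w = 0.5 * r
            s = 0.5 / r
            q = np.array([w, (m[2, 1] - m[1, 2]) * s,
                          (m[0, 2] - m[2, 0]) * s,
                          (m[1, 0] - m[0, 1]) * s])
        else:
            i = int(np.argmax(np.diag(m)))
            j, k = (i + 1) % 3, (i + 2) % 3
            r = np.sqrt(1.0 + m[i, i] - m[j, j] - m[k, k])
            s = 0.5 / r
            q = np.empty(4)
            q[0] = (m[k, j] - m[j, k]) * s
            q[1 + i] = 0.5 * r
            q[1 + j] = (m[j, i] + m[i, j]) * s
            q[1 + k] = (m[k, i] + m[i, k]) * s
        return cls(q / np.linalg.norm(q))

    # -- accessors ------------------------------------------------------
    @property
    def w(self) -> float:
        return float(self.q[0])

    @property
    def vec(self) -> np.ndarray:
        return self.q[1:]

    @property
    def angle(self) -> float:
        """Rotation angle in [0, pi] (canonical form)."""
        return 2.0 * float(np.arctan2(np.linalg.norm(self.q[1:]), self.q[0]))

    @property
    def axis(self) -> np.ndarray:
        """Unit rotation axis; +x by convention for the identity."""
        n = float(np.linalg.norm(self.q[1:]))
        if n < 1e-15:
            return np.array([1.0, 0.0, 0.0])
        return self.q[1:] / n

    def matrix(self) -> np.ndarray:
        w, x, y, z = self.q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])

    # -- algebra --------------------------------------------------------
    def compose(self, other: "Rotation") -> "Rotation":
        """Return self ∘ other: ``other`` applied first."""
        w1, x1, y1, z1 = self.q
        w2, x2, y2, z2 = other.q
        return Rotation(np.array([
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]))

    def __matmul__(self, other: "Rotation") -> "Rotation":
        return self.compose(other)

    def inverse(self) -> "Rotation":
        return Rotation(self.q * np.array([1.0, -1.0, -1.0, -1.0]))

    def apply(self, v) -> np.ndarray:
        """Rotate one 3-vector or an (n, 3) array of vectors."""
        v = np.asarray(v, dtype=float)
        return v @ self.matrix().T

    def approx_equal(self, other: "Rotation", tol: float = 1e-10) -> bool:
        return bool(np.allclose(self.q, other.q, atol=tol))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        w, x, y, z = self.q
        return f"Rotation(w={w:.6f}, v=({x:.6f}, {y:.6f}, {z:.6f}))"


def rotation_from_axis_angle(axis, angle: float) -> Rotation:
    """Functional alias for :meth:`Rotation.from_axis_angle`."""
    return Rotation.from_axis_angle(axis, angle)


def compose(a: Rotation, b: Rotation) -> Rotation:
    """(a ∘ b)(v) = a(b(v))."""
    return a.compose(b)


@dataclass(frozen=True)
class SwingTwist:
    """Decomposition r = swing ∘ twist about a reference axis.

    ``twist`` rotates about ``reference_axis`` by the signed angle
    ``twist_angle`` (right-hand rule about the reference axis, in
    ``(-pi, pi]``); ``swing`` rotates about an axis perpendicular to it.
    """

    swing: Rotation
    twist: Rotation
    twist_angle: float
    reference_axis: np.ndarray


def swing_twist_decompose(r: Rotation, reference_axis) -> SwingTwist:
    """Split ``r`` into swing ∘ twist about ``reference_axis``.

    The twist quaternion is the projection of the quaternion onto the
    reference axis, renormalised.  In the degenerate case of a half-turn
    about an axis exactly perpendicular to the reference axis the
    projection vanishes; the twist is then defined as the identity (the
    whole rotation is swing).
    """
    a = _as_unit_vector(reference_axis)
    w = r.w
    proj = float(np.dot(r.vec, a))
    norm = float(np.hypot(w, proj))
    if norm < 1e-12:
        twist = Rotation.identity()
    else:
        twist = Rotation(np.concatenate(([w], proj * a)) / norm)
    swing = r.compose(twist.inverse())
    # Signed angle from the *canonicalised* twist (w >= 0), so it is
    # invariant under negation of the source quaternion.
    tau = 2.0 * float(np.arctan2(np.dot(twist.vec, a), twist.w))
    return SwingTwist(swing=swing, twist=twist, twist_angle=tau, reference_axis=a)


def random_rotation(rng: np.random.Generator) -> Rotation:
    """Uniform (Haar) random rotation from a normalised Gaussian quaternion."""
    q = rng.standard_normal(4)
    return Rotation(q / np.linalg.norm(q))
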
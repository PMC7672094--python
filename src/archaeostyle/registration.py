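"""Landmark-based similarity registration and mesh handling.

Rebuilds the composite-model workflow: separately preserved skeletal
elements are brought into a common frame by a seven-parameter similarity
transform (uniform scale, proper rotation, translation) estimated from
matched anatomical landmarks, and the quality of articulation contacts in
the composite is quantified as per-pair gap distances.

The scale/rotation/translation estimate is the closed-form least-squares
(Umeyama/Kabsch) construction: centroids removed, rotation from the SVD of
the cross-covariance with proper-rotation enforcement, scale from the
projected variance ratio.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import (
    DegenerateConfigurationError,
    InvalidInputError,
    MeshParseError,
    ReflectionRequiredError,
)
from .geometry import Rotation


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered, named 3-D points (mm)."""

    names: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InvalidInputError("coords must be (n, 3)")
        if len(self.names) != len(coords):
            raise InvalidInputError("one name per point required")
        if len(set(self.names)) != len(self.names):
            raise InvalidInputError("landmark names must be unique")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.names)

    def point(self, name: str) -> np.ndarray:
        try:
            return self.coords[self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown landmark {name!r}") from None

    @classmethod
    def read_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path)
        required = {"name", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise InvalidInputError(
                f"landmark CSV must have columns name,x,y,z; got {list(df.columns)}"
            )
        return cls(tuple(df["name"].astype(str)), df[["x", "y", "z"]].to_numpy(float))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"name": self.names, "x": self.coords[:, 0],
             "y": self.coords[:, 1], "z": self.coords[:, 2]}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SimilarityTransform:
    """x -> scale * R x + t with a proper rotation R."""

    scale: float
    rotation: Rotation
    translation: np.ndarray

    def __post_init__(self):
        if self.scale <= 0:
            raise InvalidInputError("scale must be positive")
        object.__setattr__(self, "translation", np.asarray(self.translation, float))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, Rotation.identity(), np.zeros(3))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return self.scale * self.rotation.apply(pts) + self.translation

    def compose(self, inner: "SimilarityTransform") -> "SimilarityTransform":
        """self ∘ inner: apply ``inner`` first."""
        rot = self.rotation.compose(inner.rotation)
        scale = self.scale * inner.scale
        t = self.scale * self.rotation.apply(inner.translation) + self.translation
        return SimilarityTransform(scale, rot, t)

    def inverse(self) -> "SimilarityTransform":
        rinv = self.rotation.inverse()
        return SimilarityTransform(
            1.0 / self.scale, rinv, -rinv.apply(self.translation) / self.scale
        )


def similarity_register(
    src: LandmarkSet, dst: LandmarkSet, *, allow_reflection: bool = False
) -> tuple[SimilarityTransform, float]:
    """Least-squares similarity transform mapping ``src`` onto ``dst``.

    Returns the transform and the RMSD (mm) of the aligned points.  By
    default a configuration whose optimum would require a reflection raises
    :class:`ReflectionRequiredError` rather than silently flipping
    chirality; pass ``allow_reflection=True`` to accept the proper-rotation
    optimum anyway (the best orientation-preserving fit).
    """
    if src.names != dst.names:
        raise InvalidInputError("landmark sets must share names and order")
    if len(src) < 3:
        raise InvalidInputError("need at least 3 landmarks")
    x = src.coords
    y = dst.coords
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    var_x = float((xc ** 2).sum()) / len(x)
    if var_x < 1e-24:
        raise DegenerateConfigurationError("source landmarks are coincident")
    cov = yc.T @ xc / len(x)
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise DegenerateConfigurationError(
            "landmarks are collinear; the rotation about their axis is unconstrained"
        )
    d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    if d < 0 and not allow_reflection:
        raise ReflectionRequiredError(
            "optimal alignment requires a reflection; the landmark sets have "
            "opposite chirality"
        )
    e = np.ones(3)
    e[-1] = d if d != 0 else 1.0
    rot_m = u @ np.diag(e) @ vt
    scale = float((s * e).sum()) / var_x
    if scale <= 0:
        raise DegenerateConfigurationError("non-positive optimal scale")
    rot = Rotation.from_matrix(rot_m)
    t = my - scale * rot.apply(mx)
    tf = SimilarityTransform(scale, rot, t)
    rmsd = float(np.sqrt(np.mean(np.sum((tf.apply_points(x) - y) ** 2, axis=1))))
    return tf, rmsd


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TriangleMesh:
    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or f.ndim != 2 or f.shape[1] != 3:
            raise InvalidInputError("vertices must be (n,3), faces (m,3)")
        if len(f) and (f.min() < 0 or f.max() >= len(v)):
            raise InvalidInputError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    def transformed(self, tf: SimilarityTransform) -> "TriangleMesh":
        return TriangleMesh(tf.apply_points(self.vertices), self.faces.copy())

    def is_watertight(self) -> bool:
        tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
        return bool(tm.is_watertight)


def _validate_stl_bytes(path: Path) -> None:
    data = path.read_bytes()
    if len(data) < 15:
        raise MeshParseError("file too short to be an STL", byte_offset=len(data))
    head = data[:512].lstrip()
    if head.startswith(b"solid") and b"facet" in data[:4096]:
        if b"endsolid" not in data:
            raise MeshParseError(
                "ASCII STL missing endsolid terminator", byte_offset=len(data)
            )
        return
    if len(data) < 84:
        raise MeshParseError("binary STL truncated before triangle count",
                             byte_offset=len(data))
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if len(data) < expected:
        raise MeshParseError(
            f"binary STL truncated: header declares {count} triangles "
            f"({expected} bytes) but file has {len(data)} bytes",
            byte_offset=len(data),
        )


def read_mesh(path) -> TriangleMesh:
    """Read a binary or ASCII STL file.

    Structural problems (truncation, missing terminator) raise
    :class:`MeshParseError` carrying a byte offset rather than silently
    yielding a partial mesh.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_stl_bytes(path)
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise MeshParseError(f"STL parse failed: {exc}") from exc
    if tm.vertices.size == 0:
        raise MeshParseError("STL contains no triangles")
    return TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces))


def write_mesh(mesh: TriangleMesh, path, *, ascii: bool = False) -> None:
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    file_type = "stl_ascii" if ascii else "stl"
    data = trimesh.exchange.export.export_mesh(tm, None, file_type=file_type)
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)


def apply_transform(obj, tf: SimilarityTransform):
    """Transformed copy of a mesh or landmark set."""
    if isinstance(obj, TriangleMesh):
        return obj.transformed(tf)
    if isinstance(obj, LandmarkSet):
        return LandmarkSet(obj.names, tf.apply_points(obj.coords))
    raise InvalidInputError(f"cannot transform object of type {type(obj).__name__}")


def articulation_gap_report(
    composite: list[tuple[LandmarkSet, SimilarityTransform]],
    contact_pairs: list[tuple[tuple[int, str], tuple[int, str]]],
) -> pd.DataFrame:
    """Euclidean gaps (mm) between matched articulation contacts.

    ``composite`` lists (landmarks, transform) per element; each contact
    pair references (element index, landmark name) on two distinct elements.
    """
    rows = []
    placed = [apply_transform(lm, tf) for lm, tf in composite]
    for (ia, name_a), (ib, name_b) in contact_pairs:
        pa = placed[ia].point(name_a)
        pb = placed[ib].point(name_b)
        rows.append(
            {"element_a": ia, "landmark_a": name_a,
             "element_b": ib, "landmark_b": name_b,
             "gap_mm": float(np.linalg.norm(pa - pb))}
        )
    return pd.DataFrame(rows)
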
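"""AC-PC (Talairach-style) frame fitting and related coordinate machinery.

The frame convention throughout the package is RAS-like with the anterior
commissure (AC) at the origin: x increases to the subject's right, y
increases anteriorly, z increases superiorly, all in millimetres.  The
posterior commissure (PC) therefore lies on the negative y axis after
alignment.

The chiasmatico-commissural (CH-PC) frame shares the x axis with the
AC-PC frame and is pitched about it by a fixed obliquity of 18.2 degrees,
which brings the horizontal plane parallel to the Sylvian fissure.  The
rotation sign is fixed here in one place (``chpc_rotation``): the CH-PC
horizontal is obtained by pitching the AC-PC horizontal anterior-end-down,
i.e. a rotation about +x by -18.2 degrees applied to AC-PC coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .errors import DegenerateLandmarkError, FrameMismatchError

__all__ = [
    "CHPC_OBLIQUITY_DEG",
    "FRAME_TAGS",
    "Point3",
    "RigidTransform",
    "HemisphereSide",
    "fit_acpc_transform",
    "apply_transform",
    "hemisphere_normalize",
    "acpc_to_chpc",
    "chpc_rotation",
]

#: Obliquity of the CH-PC line relative to the AC-PC line, degrees.
CHPC_OBLIQUITY_DEG = 18.2

#: Recognised coordinate-frame tags.
FRAME_TAGS = ("world", "acpc", "chpc", "limen_local")

#: Minimum landmark separation (mm) below which distinctness checks fail.
DEGENERACY_TOL_MM = 1.0


class HemisphereSide(str, Enum):
    """Cerebral hemisphere, used to mirror left-sided geometry onto the right."""

    RIGHT = "right"
    LEFT = "left"

    @classmethod
    def parse(cls, value: "HemisphereSide | str") -> "HemisphereSide":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValueError(
                f"hemisphere side must be 'right' or 'left', got {value!r}"
            ) from None


@dataclass(frozen=True)
class Point3:
    """A 3D point in millimetres with an explicit coordinate-frame tag.

    x: left-right axis, right positive.
    y: posterior-anterior axis, anterior positive.
    z: inferior-superior axis, superior positive.
    """

    x: float
    y: float
    z: float
    frame: str = "world"

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"Point3.{name} must be a finite number, got {v!r}")
        if self.frame not in FRAME_TAGS:
            raise ValueError(
                f"unknown frame tag {self.frame!r}; expected one of {FRAME_TAGS}"
            )

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray, frame: str) -> "Point3":
        a = np.asarray(arr, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]), frame)

    def with_frame(self, frame: str) -> "Point3":
        return replace(self, frame=frame)


def require_same_frame(*points: Point3) -> str:
    """Return the common frame tag, or raise :class:`FrameMismatchError`."""
    frames = {p.frame for p in points}
    if len(frames) != 1:
        raise FrameMismatchError(f"points mix coordinate frames: {sorted(frames)}")
    return points[0].frame


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion p -> R p + t between two tagged frames."""

    rotation: np.ndarray
    translation: np.ndarray
    source_frame: str = "world"
    dest_frame: str = "acpc"

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal within 1e-9")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
            raise ValueError("rotation matrix determinant is not +1 within 1e-9")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, source_frame: str = "world", dest_frame: str = "acpc") -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), source_frame, dest_frame)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(
            Rinv, -Rinv @ self.translation, self.dest_frame, self.source_frame
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first, then ``self``)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            other.source_frame,
            self.dest_frame,
        )


def fit_acpc_transform(
    ac: Point3, pc: Point3, midsagittal_point: Point3
) -> RigidTransform:
    """Fit the rigid world -> AC-PC transform from three fiducials.

    The returned transform maps AC to the origin, PC onto the negative y
    axis at its measured distance, and the mid-sagittal point into the
    x = 0 plane with positive z.  No scaling is applied: this is a pure
    reorientation, so all inter-landmark distances are preserved.

    Raises
    ------
    DegenerateLandmarkError
        If AC and PC are closer than 1 mm, or the mid-sagittal point lies
        within 1 mm of the AC-PC line (the sagittal plane is then
        undetermined).
    """
    require_same_frame(ac, pc, midsagittal_point)
    a, p, m = ac.to_array(), pc.to_array(), midsagittal_point.to_array()

    ap = a - p
    d = float(np.linalg.norm(ap))
    if d <= DEGENERACY_TOL_MM:
        raise DegenerateLandmarkError(
            f"AC and PC are {d:.3f} mm apart; need > {DEGENERACY_TOL_MM} mm"
        )
    y_hat = ap / d  # posterior -> anterior unit vector

    rel = m - a
    perp = rel - np.dot(rel, y_hat) * y_hat
    h = float(np.linalg.norm(perp))
    if h <= DEGENERACY_TOL_MM:
        raise DegenerateLandmarkError(
            f"mid-sagittal point is {h:.3f} mm from the AC-PC line; "
            f"need > {DEGENERACY_TOL_MM} mm"
        )
    z_hat = perp / h  # toward the vertex, by convention superior
    x_hat = np.cross(y_hat, z_hat)  # right-handed: x = y × z

    R = np.vstack([x_hat, y_hat, z_hat])  # rows are the new axes
    t = -R @ a
    return RigidTransform(R, t, source_frame=ac.frame, dest_frame="acpc")


def apply_transform(t: RigidTransform, p: Point3) -> Point3:
    """Apply a rigid transform to a point, retagging it to the destination frame."""
    if p.frame != t.source_frame:
        raise FrameMismatchError(
            f"transform expects frame {t.source_frame!r}, point is in {p.frame!r}"
        )
    out = t.rotation @ p.to_array() + t.translation
    return Point3.from_array(out, t.dest_frame)


def hemisphere_normalize(p: Point3, side: HemisphereSide | str) -> Point3:
    """Mirror left-hemisphere points about the mid-sagittal plane.

    Right-side points pass through unchanged; left-side points have their
    x coordinate negated.  After normalization, right and left trajectories
    live in a common (right-hemisphere) geometry so their angles are
    directly comparable.  The operation is an involution.
    """
    if p.frame != "acpc":
        raise FrameMismatchError(
            f"hemisphere_normalize requires an acpc point, got frame {p.frame!r}"
        )
    side = HemisphereSide.parse(side)
    if side is HemisphereSide.RIGHT:
        return p
    return Point3(-p.x, p.y, p.z, p.frame)


def chpc_rotation(obliquity_deg: float = CHPC_OBLIQUITY_DEG) -> np.ndarray:
    """Rotation matrix taking AC-PC coordinates to CH-PC coordinates.

    A rotation about the +x axis by ``-obliquity_deg``: the anterior end of
    the horizontal plane pitches down toward the optic chiasm, which lies
    antero-inferior to AC.  Flipping the sign convention means changing
    this one function.
    """
    phi = math.radians(-obliquity_deg)
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def acpc_to_chpc(p: Point3) -> Point3:
    """Re-express an AC-PC point in the CH-PC frame (x axis shared)."""
    if p.frame != "acpc":
        raise FrameMismatchError(
            f"acpc_to_chpc requires an acpc point, got frame {p.frame!r}"
        )
    out = chpc_rotation() @ p.to_array()
    return Point3.from_array(out, "chpc")
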
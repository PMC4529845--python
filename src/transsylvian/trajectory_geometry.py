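"""Approach-vector and sphenoid-ridge angle trigonometry.

The trajectory runs from the limen insulae (entry) to the target point,
the midpoint between the hippocampal and innominate sulci on the coronal
slice through the posterior edge of the amygdala.  Its direction is
summarised by two projection-plane angles measured from the left-right
(x) axis after mirroring left-sided geometry onto the right:

* theta_a — axial-plane angle, posterior displacement positive;
* theta_c — coronal-plane angle, inferior displacement positive.

With these sign conventions the cohort's mean angles are positive and a
negative coronal angle means a slightly superior trajectory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .coordinate_frames import (
    CHPC_OBLIQUITY_DEG,
    HemisphereSide,
    Point3,
    chpc_rotation,
    hemisphere_normalize,
    require_same_frame,
)
from .errors import (
    CoronalMismatchError,
    DegenerateLandmarkError,
    DegenerateLineError,
    DegenerateProjectionError,
)

__all__ = [
    "AngleSet",
    "ApproachVector",
    "SphenoidRidgeLine",
    "compute_target_point",
    "compute_approach_angles",
    "compute_sphenoid_angle",
    "compute_chpc_angles",
    "parallelism_offset",
]

#: Same-coronal-slice tolerance for the two target-defining sulci (mm);
#: half a typical 1 mm MPRAGE voxel.
CORONAL_SLICE_TOL_MM = 0.5

#: Below this |Δx| (mm) the projection angles are annotation-noise dominated.
MIN_ADJACENT_MM = 0.1


@dataclass(frozen=True)
class AngleSet:
    """Axial (theta_a) and coronal (theta_c) approach angles, degrees."""

    theta_a: float
    theta_c: float
    frame: str = "acpc"

    def __post_init__(self) -> None:
        for name in ("theta_a", "theta_c"):
            v = getattr(self, name)
            if not math.isfinite(v) or not (-180.0 < v <= 180.0):
                raise ValueError(f"{name} must be finite in (-180, 180], got {v!r}")
        if self.frame not in ("acpc", "chpc"):
            raise ValueError(f"AngleSet frame must be 'acpc' or 'chpc', got {self.frame!r}")


@dataclass(frozen=True)
class ApproachVector:
    """The limen-insulae -> target displacement for one hemisphere."""

    origin: Point3
    target: Point3
    side: HemisphereSide

    def __post_init__(self) -> None:
        require_same_frame(self.origin, self.target)
        object.__setattr__(self, "side", HemisphereSide.parse(self.side))
        d = float(np.linalg.norm(self.target.to_array() - self.origin.to_array()))
        if d <= 1.0:
            raise DegenerateLandmarkError(
                f"approach origin and target are {d:.3f} mm apart; need > 1 mm"
            )


@dataclass(frozen=True)
class SphenoidRidgeLine:
    """The sphenoid-ridge reference line, pterion (outer) to clinoid (inner)."""

    outer: Point3
    inner: Point3
    side: HemisphereSide

    def __post_init__(self) -> None:
        require_same_frame(self.outer, self.inner)
        object.__setattr__(self, "side", HemisphereSide.parse(self.side))
        d = float(np.linalg.norm(self.inner.to_array() - self.outer.to_array()))
        if d <= 1.0:
            raise DegenerateLandmarkError(
                f"sphenoid ridge points are {d:.3f} mm apart; need > 1 mm"
            )


def compute_target_point(
    hippocampal_sulcus: Point3, innominate_sulcus: Point3
) -> Point3:
    """Midpoint of the two sulcal landmarks defining the trajectory target.

    Both landmarks must sit on the same coronal slice (the slice through
    the posterior edge of the amygdala): their y coordinates may differ by
    at most 0.5 mm, otherwise a :class:`CoronalMismatchError` flags that
    they were placed on different slices.
    """
    frame = require_same_frame(hippocampal_sulcus, innominate_sulcus)
    dy = abs(hippocampal_sulcus.y - innominate_sulcus.y)
    if dy > CORONAL_SLICE_TOL_MM:
        raise CoronalMismatchError(
            f"sulcal landmarks differ by {dy:.2f} mm along y "
            f"(> {CORONAL_SLICE_TOL_MM} mm): placed on different coronal slices?"
        )
    mid = 0.5 * (hippocampal_sulcus.to_array() + innominate_sulcus.to_array())
    return Point3.from_array(mid, frame)


def _normalized_displacement(v: ApproachVector) -> np.ndarray:
    o = hemisphere_normalize(v.origin, v.side)
    t = hemisphere_normalize(v.target, v.side)
    return t.to_array() - o.to_array()


def _angles_from_displacement(d: np.ndarray, frame: str) -> AngleSet:
    if abs(d[0]) <= MIN_ADJACENT_MM:
        raise DegenerateProjectionError(
            f"|Δx| = {abs(d[0]):.3f} mm ≤ {MIN_ADJACENT_MM} mm: projection angles "
            "from the x axis are undefined up to annotation noise"
        )
    if d[0] < 0:
        warnings.warn(
            "approach displacement points medially past the mid-sagittal "
            "direction (Δx < 0 after hemisphere normalization); angles exceed 90°",
            stacklevel=3,
        )
    theta_a = math.degrees(math.atan2(-d[1], d[0]))
    theta_c = math.degrees(math.atan2(-d[2], d[0]))
    # atan2(-0.0, x<0) yields -180 exactly; canonicalise to +180
    if theta_a <= -180.0:
        theta_a += 360.0
    if theta_c <= -180.0:
        theta_c += 360.0
    return AngleSet(theta_a=theta_a, theta_c=theta_c, frame=frame)


def compute_approach_angles(v: ApproachVector) -> AngleSet:
    """Axial and coronal approach angles of a trajectory, in AC-PC space.

    Let d be the hemisphere-normalized target minus origin.  Then
    ``theta_a = atan2(-d_y, d_x)`` (posterior positive) and
    ``theta_c = atan2(-d_z, d_x)`` (inferior positive), both in degrees.
    """
    if v.origin.frame != "acpc":
        raise ValueError("approach angles are defined on acpc-frame points")
    return _angles_from_displacement(_normalized_displacement(v), "acpc")


def compute_sphenoid_angle(line: SphenoidRidgeLine) -> float:
    """Axial-plane angle between the sphenoid ridge and the x axis, degrees.

    The line is undirected, so the angle is folded into (-90, 90] with the
    same posterior-positive sign convention as theta_a.
    """
    if line.outer.frame != "acpc":
        raise ValueError("sphenoid angle is defined on acpc-frame points")
    o = hemisphere_normalize(line.outer, line.side)
    i = hemisphere_normalize(line.inner, line.side)
    d = i.to_array() - o.to_array()
    axial = d[:2]
    if float(np.linalg.norm(axial)) < 1.0:
        raise DegenerateLineError(
            "sphenoid ridge line's axial projection is shorter than 1 mm"
        )
    dx, dy = axial
    if dx < 0 or (dx == 0 and -dy < 0):
        dx, dy = -dx, -dy
    if dx == 0:
        return 90.0
    return math.degrees(math.atan2(-dy, dx))


def compute_chpc_angles(
    v: ApproachVector, obliquity_deg: float = CHPC_OBLIQUITY_DEG
) -> AngleSet:
    """Approach angles after transferring the displacement to the CH-PC frame.

    The displacement is rotated about the shared x axis by the CH-PC
    obliquity and the same angle formulas applied.  With ``obliquity_deg``
    set to 0 this reduces exactly to :func:`compute_approach_angles`.
    """
    if v.origin.frame != "acpc":
        raise ValueError("CH-PC transfer starts from acpc-frame points")
    d = chpc_rotation(obliquity_deg) @ _normalized_displacement(v)
    return _angles_from_displacement(d, "chpc" if obliquity_deg else "acpc")


def parallelism_offset(theta_a: float, sphenoid_angle: float) -> float:
    """Signed difference theta_a - sphenoid_angle, degrees."""
    if not (math.isfinite(theta_a) and math.isfinite(sphenoid_angle)):
        raise ValueError("angles must be finite")
    return theta_a - sphenoid_angle
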
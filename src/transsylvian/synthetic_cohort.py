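"""Synthetic landmark cohorts built by inverse construction from sampled angles.

Real study data (manual landmark placements on MPRAGE volumes) are not
distributable, so cohorts are simulated at the *angle* level and landmarks
are then constructed to realise those angles exactly.  Per subject and
hemisphere the generator samples

* the axial approach angle theta_a and the sphenoid-ridge angle jointly
  from a bivariate normal (side-specific theta_a mean; shared ridge mean
  and sd; a fixed correlation), and
* the coronal approach angle theta_c from an independent normal,

then places the limen insulae near its side-specific mean location with
isotropic positional noise and builds the target as
``limen + (dx, -dx*tan(theta_a), -dx*tan(theta_c))`` (hemisphere-mirrored
for the left side), the exact inverse of the measurement trigonometry.
The sulcal pair is constructed symmetrically about the target on its
coronal plane, and the sphenoid ridge line is laid out in the axial plane
at the sampled ridge angle.  Because noise enters only through anchor
positions, the latent angles are recoverable to machine precision, which
cleanly separates generator calibration from pipeline correctness.

Default parameter values encode the emulated study conditions:
side-specific axial means 54.6/50.2 degrees, coronal means 17.0/15.5,
ridge 49.7 +/- 3.5, approach/ridge correlation 0.462, 28 subjects
measured bilaterally, and a left limen insulae displaced 2 mm
postero-inferiorly relative to the mirrored right one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coordinate_frames import HemisphereSide, Point3
from .errors import InvalidConfigError
from .landmark_io import LandmarkSet, MaskVolume
from .ventricle_simulation import (
    HornProfile,
    TLE_RADIUS_MM,
    make_inferior_horn_mask,
)

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "generate_cohort",
    "generate_tle_cohort",
    "derive_cohort_seeds",
    "HORN_CENTERLINE_OFFSETS",
]


def derive_cohort_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit cohort seeds from one master seed.

    Used wherever a replicate-averaged experiment (e.g. the 10-cohort
    recovery runs) must be reproducible from a single seed.
    """
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s) for s in state % (2**31)]

#: Inferior-horn centerline control points relative to the trajectory
#: target, in hemisphere-normalized AC-PC mm (x lateral, y anterior,
#: z superior).  The tube runs from the temporal-tip region anteriorly,
#: through the target (the coronal level of the posterior amygdala, where
#: the horn is reliably identifiable), then rises posterosuperiorly toward
#: the atrium.  Engineering defaults for the phantom, not measured anatomy.
HORN_CENTERLINE_OFFSETS: tuple[tuple[float, float, float], ...] = (
    (-1.8, 14.0, 5.9),
    (-1.3, 8.0, -0.5),
    (-0.6, 3.0, -1.4),
    (0.0, 0.0, 0.0),
    (1.1, -5.0, 5.5),
    (2.8, -11.0, 17.4),
    (5.2, -18.0, 38.5),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-profile parameters of the synthetic cohort generator.

    Angles in degrees, lengths in mm.  The defaults are the emulated
    study conditions; ``axial_sd``, ``coronal_sd``, the limen coordinates
    and ``approach_dx`` are calibration choices documented in the package
    methods note.
    """

    n_subjects: int = 28
    seed: int = 0
    axial_mean_right: float = 54.6
    axial_mean_left: float = 50.2
    axial_sd: float = 6.5
    coronal_mean_right: float = 17.0
    coronal_mean_left: float = 15.5
    coronal_sd: float = 10.0
    ridge_mean: float = 49.7
    ridge_sd: float = 3.5
    ridge_correlation: float = 0.462
    interhemispheric_correlation: float = 0.58
    limen_mean_right: tuple[float, float, float] = (33.0, 6.0, -14.0)
    limen_left_offset: tuple[float, float] = (-2.0, -2.0)  # (dy, dz)
    landmark_noise_sd: float = 1.0
    approach_dx: float = 8.0
    n_tle: int = 12
    horn_radius: float = TLE_RADIUS_MM
    horn_centerline_offsets: tuple[tuple[float, float, float], ...] = field(
        default=HORN_CENTERLINE_OFFSETS
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidConfigError("n_subjects must be >= 1")
        if self.n_tle < 0:
            raise InvalidConfigError("n_tle must be >= 0")
        for name in ("axial_sd", "coronal_sd", "ridge_sd"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if not abs(self.ridge_correlation) < 1:
            raise InvalidConfigError("|ridge_correlation| must be < 1")
        if not 0 <= self.interhemispheric_correlation < 1:
            raise InvalidConfigError("interhemispheric_correlation must be in [0, 1)")
        if self.landmark_noise_sd < 0:
            raise InvalidConfigError("landmark_noise_sd must be >= 0")
        if self.approach_dx <= 0.1:
            raise InvalidConfigError("approach_dx must exceed the 0.1 mm guard")


@dataclass(frozen=True)
class TruthRecord:
    """Latent angles a generated trajectory was constructed to realise."""

    subject_id: str
    side: HemisphereSide
    true_theta_a: float
    true_theta_c: float
    true_ridge_angle: float


#: Cap on sampled |theta_a| so the inverse construction stays clear of the
#: 90-degree projection degeneracy.
_THETA_CAP_DEG = 89.0


def _denormalize(p: np.ndarray, side: HemisphereSide) -> np.ndarray:
    if side is HemisphereSide.LEFT:
        return np.array([-p[0], p[1], p[2]])
    return p


def _sample_subject_angles(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> dict[HemisphereSide, tuple[float, float, float]]:
    """Sample (theta_a, theta_c, ridge) for both hemispheres of one subject.

    Each angle decomposes into a subject-level component (variance
    rho * sigma^2, shared by the two sides) plus a side-level residual
    (variance (1 - rho) * sigma^2), where rho is the interhemispheric
    correlation.  The (theta_a, ridge) cross-correlation is carried by
    both components, so within a side it equals ``ridge_correlation``
    exactly while paired right-left differences have the reduced variance
    2 * (1 - rho) * sigma^2 that the study's paired tests imply.
    """
    rho = cfg.interhemispheric_correlation
    # ``ridge_correlation`` is the correlation the pooled bilateral cohort
    # should exhibit.  Pooling adds the between-side mean split to theta_a's
    # variance but not to the ridge's (whose mean is shared), diluting the
    # within-side correlation; invert that dilution here.
    half_split = 0.5 * (cfg.axial_mean_right - cfg.axial_mean_left)
    pooled_sd = math.hypot(cfg.axial_sd, half_split)
    r_within = cfg.ridge_correlation * pooled_sd / cfg.axial_sd
    if not abs(r_within) < 1:
        raise InvalidConfigError(
            "ridge_correlation is unattainable for this side-mean split"
        )
    cross = r_within * cfg.axial_sd * cfg.ridge_sd
    cov_m = np.array([[cfg.axial_sd**2, cross], [cross, cfg.ridge_sd**2]])
    shared_biv = rng.multivariate_normal(np.zeros(2), rho * cov_m, method="cholesky")
    shared_c = rng.normal(0.0, math.sqrt(rho) * cfg.coronal_sd)

    out: dict[HemisphereSide, tuple[float, float, float]] = {}
    for side in (HemisphereSide.RIGHT, HemisphereSide.LEFT):
        axial_mean = (
            cfg.axial_mean_right if side is HemisphereSide.RIGHT else cfg.axial_mean_left
        )
        coronal_mean = (
            cfg.coronal_mean_right
            if side is HemisphereSide.RIGHT
            else cfg.coronal_mean_left
        )
        resid_biv = rng.multivariate_normal(
            np.zeros(2), (1.0 - rho) * cov_m, method="cholesky"
        )
        resid_c = rng.normal(0.0, math.sqrt(1.0 - rho) * cfg.coronal_sd)
        theta_a = axial_mean + shared_biv[0] + resid_biv[0]
        ridge = cfg.ridge_mean + shared_biv[1] + resid_biv[1]
        theta_c = coronal_mean + shared_c + resid_c
        out[side] = (
            float(np.clip(theta_a, -_THETA_CAP_DEG, _THETA_CAP_DEG)),
            float(np.clip(theta_c, -_THETA_CAP_DEG, _THETA_CAP_DEG)),
            float(ridge),
        )
    return out


def _build_side(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str,
    side: HemisphereSide,
    angles: tuple[float, float, float],
) -> tuple[LandmarkSet, TruthRecord, np.ndarray]:
    """Construct one hemisphere's landmarks; returns the set, the latent
    truth, and the target position (acpc mm) used by the mask builder."""
    theta_a, theta_c, ridge = angles

    limen_norm = np.asarray(cfg.limen_mean_right, dtype=float).copy()
    if side is HemisphereSide.LEFT:
        limen_norm[1] += cfg.limen_left_offset[0]
        limen_norm[2] += cfg.limen_left_offset[1]
    limen_norm = limen_norm + rng.normal(0.0, cfg.landmark_noise_sd, 3)

    dx = cfg.approach_dx
    disp = np.array(
        [dx, -dx * math.tan(math.radians(theta_a)), -dx * math.tan(math.radians(theta_c))]
    )
    target_norm = limen_norm + disp

    # Sulcal pair: symmetric about the target in its coronal plane, the
    # hippocampal sulcus medial and slightly superior to the innominate.
    half_width = rng.uniform(5.0, 8.0)
    half_height = rng.uniform(1.0, 2.5)
    hipp_norm = target_norm + np.array([-half_width, 0.0, half_height])
    inno_norm = target_norm + np.array([half_width, 0.0, -half_height])

    # Sphenoid ridge: clinoid-side anchor plus a pterion-side point laid
    # out at the sampled ridge angle in the axial plane.  z plays no role
    # in the angle, so it only gets mild positional noise.
    inner_norm = np.array([12.0, 10.0, -16.0]) + rng.normal(
        0.0, cfg.landmark_noise_sd, 3
    )
    length = rng.uniform(38.0, 46.0)
    rho = math.radians(ridge)
    outer_norm = inner_norm + np.array(
        [length * math.cos(rho), -length * math.sin(rho), rng.normal(0.0, 1.0)]
    )

    ac = np.zeros(3)
    pc = np.array([0.0, -(24.0 + rng.normal(0.0, 1.0)), 0.0])
    midsag = np.array([0.0, rng.normal(5.0, 3.0), 45.0 + rng.normal(0.0, 2.0)])

    def pt(arr: np.ndarray) -> Point3:
        return Point3.from_array(arr, "acpc")

    entries = {
        "AC": pt(ac),
        "PC": pt(pc),
        "midsagittal": pt(midsag),
        "limen_insulae": pt(_denormalize(limen_norm, side)),
        "hippocampal_sulcus": pt(_denormalize(hipp_norm, side)),
        "innominate_sulcus": pt(_denormalize(inno_norm, side)),
        "sphenoid_outer": pt(_denormalize(outer_norm, side)),
        "sphenoid_inner": pt(_denormalize(inner_norm, side)),
    }
    lset = LandmarkSet(subject_id=subject_id, side=side, entries=entries)
    truth = TruthRecord(
        subject_id=subject_id,
        side=side,
        true_theta_a=theta_a,
        true_theta_c=theta_c,
        true_ridge_angle=ridge,
    )
    return lset, truth, target_norm


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[LandmarkSet], list[TruthRecord]]:
    """Generate a bilateral landmark cohort plus its latent truth records.

    Deterministic given ``config.seed``; subjects are "S01", "S02", ...
    with the right hemisphere generated before the left.
    """
    rng = np.random.default_rng(config.seed)
    width = max(2, len(str(config.n_subjects)))
    sets: list[LandmarkSet] = []
    truths: list[TruthRecord] = []
    for i in range(1, config.n_subjects + 1):
        sid = f"S{i:0{width}d}"
        angles = _sample_subject_angles(config, rng)
        for side in (HemisphereSide.RIGHT, HemisphereSide.LEFT):
            lset, truth, _ = _build_side(config, rng, sid, side, angles[side])
            sets.append(lset)
            truths.append(truth)
    return sets, truths


def generate_tle_cohort(
    config: GeneratorConfig, voxel_size: float = 1.0
) -> list[tuple[LandmarkSet, MaskVolume]]:
    """Generate the TLE validation cohort: landmarks plus horn masks.

    One hemisphere per patient (alternating right/left), each with an
    inferior-horn tube phantom whose centerline passes through that
    subject's own trajectory target, so the standard vector is tested
    against per-subject anatomy rather than its own endpoint.  Uses an
    independent random stream derived from ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    width = max(2, len(str(max(config.n_tle, 1))))
    out: list[tuple[LandmarkSet, MaskVolume]] = []
    for i in range(1, config.n_tle + 1):
        sid = f"T{i:0{width}d}"
        side = HemisphereSide.RIGHT if i % 2 == 1 else HemisphereSide.LEFT
        angles = _sample_subject_angles(config, rng)
        lset, _, target_norm = _build_side(config, rng, sid, side, angles[side])
        centerline = tuple(
            tuple(target_norm + np.asarray(off)) for off in config.horn_centerline_offsets
        )
        profile = HornProfile(
            centerline=centerline, radius=config.horn_radius, name="tle"
        )
        mask = make_inferior_horn_mask(profile, voxel_size=voxel_size, side=side)
        out.append((lset, mask))
    return out
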
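import numpy as np
import pytest

from transsylvian import (
    GeneratorConfig,
    HemisphereSide,
    LandmarkSet,
    Point3,
    RigidTransform,
    generate_cohort,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-profile cohort (28 subjects, both sides) plus its truth."""
    return generate_cohort(GeneratorConfig(n_subjects=28, seed=11))


def random_rigid_transform(rng, source="acpc", dest="world"):
    """A uniformly random proper rotation plus a bounded translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-50, 50, size=3)
    return RigidTransform(R, t, source_frame=source, dest_frame=dest)


def transform_landmark_set(lset: LandmarkSet, transform: RigidTransform) -> LandmarkSet:
    """Apply a rigid motion to every landmark, retagging to the dest frame."""
    entries = {}
    for name, p in lset.entries.items():
        arr = transform.rotation @ p.to_array() + transform.translation
        entries[name] = Point3.from_array(arr, transform.dest_frame)
    return LandmarkSet(
        subject_id=lset.subject_id, side=HemisphereSide(lset.side), entries=entries
    )
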
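"""Reading and writing landmark tables (TSV/JSON) and NIfTI mask volumes.

Landmark files are world-millimetre coordinates, one row per
(subject, side, landmark).  The TSV dialect is tab-separated UTF-8 with a
mandatory header ``subject_id  side  landmark  x  y  z  frame``; JSON files
are an array of ``{subject_id, side, landmarks: {name: [x, y, z]}, frame}``
objects.  Floats are written with ``repr`` so a write -> read round trip is
bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np

from .coordinate_frames import HemisphereSide, Point3
from .errors import (
    FrameMismatchError,
    LandmarkParseError,
    MaskFormatError,
    MissingLandmarkError,
    UnknownLandmarkError,
)

__all__ = [
    "CANONICAL_LANDMARKS",
    "LandmarkSet",
    "MaskVolume",
    "read_landmarks",
    "write_landmarks",
    "read_mask",
    "write_mask",
]

#: The canonical landmark vocabulary; anything else is rejected on input.
CANONICAL_LANDMARKS = (
    "AC",
    "PC",
    "midsagittal",
    "limen_insulae",
    "hippocampal_sulcus",
    "innominate_sulcus",
    "sphenoid_outer",
    "sphenoid_inner",
)

TSV_COLUMNS = ("subject_id", "side", "landmark", "x", "y", "z", "frame")


@dataclass
class LandmarkSet:
    """Named landmarks for one subject and one hemisphere.

    All points in a set must share one coordinate-frame tag; landmark
    names outside :data:`CANONICAL_LANDMARKS` are rejected.
    """

    subject_id: str
    side: HemisphereSide
    entries: dict[str, Point3] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.side = HemisphereSide.parse(self.side)
        for name in self.entries:
            if name not in CANONICAL_LANDMARKS:
                raise UnknownLandmarkError(
                    f"unknown landmark {name!r} for subject {self.subject_id!r} "
                    f"({self.side.value}); expected one of {CANONICAL_LANDMARKS}"
                )
        frames = {p.frame for p in self.entries.values()}
        if len(frames) > 1:
            raise FrameMismatchError(
                f"subject {self.subject_id!r} ({self.side.value}) mixes frames "
                f"{sorted(frames)}"
            )

    @property
    def frame(self) -> str | None:
        """The common frame tag, or None for an empty set."""
        for p in self.entries.values():
            return p.frame
        return None

    def require(self, *names: str) -> None:
        for name in names:
            if name not in self.entries:
                raise MissingLandmarkError(
                    f"subject {self.subject_id!r} ({self.side.value}) is missing "
                    f"landmark {name!r}"
                )

    def __getitem__(self, name: str) -> Point3:
        try:
            return self.entries[name]
        except KeyError:
            raise MissingLandmarkError(
                f"subject {self.subject_id!r} ({self.side.value}) is missing "
                f"landmark {name!r}"
            ) from None


@dataclass
class MaskVolume:
    """A binary 3D volume with a voxel-index-to-world affine (mm)."""

    voxels: np.ndarray
    affine: np.ndarray
    frame: str = "acpc"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise MaskFormatError(f"mask must be 3D, got {v.ndim}D data")
        if not np.isin(v, (0, 1)).all():
            raise MaskFormatError("mask voxels must be binary (0/1)")
        self.voxels = v.astype(np.uint8)
        A = np.asarray(self.affine, dtype=float)
        if A.shape != (4, 4):
            raise MaskFormatError("affine must be 4x4")
        if abs(np.linalg.det(A[:3, :3])) < 1e-12:
            raise MaskFormatError("affine upper-left 3x3 is singular")
        self.affine = A

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine[:3, :3])
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - self.affine[:3, 3]) @ inv.T

    def foreground_count(self) -> int:
        return int(self.voxels.sum())


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "json"):
            raise ValueError(f"format must be 'tsv' or 'json', got {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    return "tsv"


def _parse_float(text: str, what: str, where: str) -> float:
    try:
        v = float(text)
    except ValueError:
        raise LandmarkParseError(f"{where}: cannot parse {what} value {text!r}") from None
    if not np.isfinite(v):
        raise LandmarkParseError(f"{where}: non-finite {what} value {text!r}")
    return v


def read_landmarks(path: str | Path, format: str | None = None) -> list[LandmarkSet]:
    """Read landmark sets from a TSV or JSON file.

    Rows are grouped by (subject_id, side); within a group all points must
    share one frame tag and use canonical landmark names.  Errors name the
    offending line or record.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    records: list[tuple[str, str, str, float, float, float, str, str]] = []

    if fmt == "tsv":
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        if not lines:
            raise LandmarkParseError(f"{path}: empty file (missing header)")
        header = tuple(lines[0].split("\t"))
        if header != TSV_COLUMNS:
            raise LandmarkParseError(
                f"{path}: bad header {header!r}; expected columns {TSV_COLUMNS}"
            )
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            fields = line.split("\t")
            where = f"{path}:{lineno}"
            if len(fields) != len(TSV_COLUMNS):
                raise LandmarkParseError(
                    f"{where}: expected {len(TSV_COLUMNS)} tab-separated fields, "
                    f"got {len(fields)}"
                )
            sid, side, name, xs, ys, zs, frame = fields
            records.append(
                (
                    sid,
                    side,
                    name,
                    _parse_float(xs, "x", where),
                    _parse_float(ys, "y", where),
                    _parse_float(zs, "z", where),
                    frame,
                    where,
                )
            )
    else:
        with open(path, encoding="utf-8") as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise LandmarkParseError(f"{path}: invalid JSON ({exc})") from None
        if not isinstance(data, list):
            raise LandmarkParseError(f"{path}: top-level JSON must be an array")
        for i, obj in enumerate(data):
            where = f"{path}[{i}]"
            if not isinstance(obj, Mapping):
                raise LandmarkParseError(f"{where}: record must be an object")
            try:
                sid = str(obj["subject_id"])
                side = str(obj["side"])
                frame = str(obj["frame"])
                landmarks = obj["landmarks"]
            except KeyError as exc:
                raise LandmarkParseError(f"{where}: missing key {exc}") from None
            if not isinstance(landmarks, Mapping):
                raise LandmarkParseError(f"{where}: 'landmarks' must be an object")
            for name, xyz in landmarks.items():
                if not isinstance(xyz, (list, tuple)) or len(xyz) != 3:
                    raise LandmarkParseError(
                        f"{where}: landmark {name!r} must map to [x, y, z]"
                    )
                records.append(
                    (sid, side, name,
                     _parse_float(str(xyz[0]), "x", where),
                     _parse_float(str(xyz[1]), "y", where),
                     _parse_float(str(xyz[2]), "z", where),
                     frame, where)
                )

    grouped: dict[tuple[str, str], dict[str, Point3]] = {}
    order: list[tuple[str, str]] = []
    for sid, side, name, x, y, z, frame, where in records:
        if name not in CANONICAL_LANDMARKS:
            raise UnknownLandmarkError(
                f"{where}: unknown landmark {name!r} "
                f"(subject {sid!r}, side {side!r})"
            )
        try:
            side_norm = HemisphereSide.parse(side).value
        except ValueError:
            raise LandmarkParseError(f"{where}: bad side {side!r}") from None
        try:
            point = Point3(x, y, z, frame)
        except ValueError as exc:
            raise LandmarkParseError(f"{where}: {exc}") from None
        key = (sid, side_norm)
        if key not in grouped:
            grouped[key] = {}
            order.append(key)
        if name in grouped[key]:
            raise LandmarkParseError(
                f"{where}: duplicate landmark {name!r} for subject {sid!r} "
                f"({side_norm})"
            )
        existing_frame = next(iter(grouped[key].values())).frame if grouped[key] else None
        if existing_frame is not None and existing_frame != frame:
            raise FrameMismatchError(
                f"{where}: subject {sid!r} ({side_norm}) mixes frames "
                f"{existing_frame!r} and {frame!r}"
            )
        grouped[key][name] = point

    return [
        LandmarkSet(subject_id=sid, side=HemisphereSide(side), entries=grouped[(sid, side)])
        for sid, side in order
    ]


def write_landmarks(
    sets: Iterable[LandmarkSet], path: str | Path, format: str | None = None
) -> None:
    """Write landmark sets with deterministic row order and repr-exact floats.

    Rows are ordered by (subject_id, side, landmark name); the side order
    is right before left within a subject (mirroring report layout).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    sets = sorted(
        sets, key=lambda s: (s.subject_id, 0 if s.side is HemisphereSide.RIGHT else 1)
    )

    if fmt == "tsv":
        lines = ["\t".join(TSV_COLUMNS)]
        for lset in sets:
            for name in sorted(lset.entries):
                p = lset.entries[name]
                lines.append(
                    "\t".join(
                        (
                            lset.subject_id,
                            lset.side.value,
                            name,
                            repr(p.x),
                            repr(p.y),
                            repr(p.z),
                            p.frame,
                        )
                    )
                )
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        payload = []
        for lset in sets:
            frame = lset.frame or "world"
            payload.append(
                {
                    "subject_id": lset.subject_id,
                    "side": lset.side.value,
                    "frame": frame,
                    "landmarks": {
                        name: [lset.entries[name].x, lset.entries[name].y, lset.entries[name].z]
                        for name in sorted(lset.entries)
                    },
                }
            )
        path.write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_mask(path: str | Path, frame: str = "acpc") -> MaskVolume:
    """Load a NIfTI volume as a binary mask (threshold 0.5), keeping its affine."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise MaskFormatError(f"{path}: unreadable NIfTI file ({exc})") from None
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise MaskFormatError(f"{path}: expected 3D data, got {data.ndim}D")
    voxels = (data > 0.5).astype(np.uint8)
    return MaskVolume(voxels=voxels, affine=np.asarray(img.affine, float), frame=frame)


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    """Write a mask volume as NIfTI-1."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    nib.save(img, str(Path(path)))
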
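"""End-to-end orchestration: landmarks in, Results-style report out.

``run_analysis`` chains the pipeline in study order — load or synthesise
landmarks, AC-PC align and measure every trajectory, summarise by plane
and side, run the right-left paired tests, the approach/ridge correlation
and the ±10° parallelism count, transfer the mean approach vector to the
CH-PC frame, and (optionally) ray-cast the standard vector through
inferior-horn masks.  Reports are written as Markdown for humans and JSON
for machines; the JSON is deterministic (sorted keys, full precision) so
identical configurations produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .coordinate_frames import chpc_rotation
from .cohort_statistics import (
    build_cohort_table,
    correlate,
    paired_t_test,
    parallelism_analysis,
    summarize,
    write_cohort_table,
)
from .errors import TranssylvianError
from .landmark_io import read_landmarks, read_mask
from .synthetic_cohort import GeneratorConfig, generate_cohort, generate_tle_cohort
from .ventricle_simulation import StandardVector, simulate_cohort

__all__ = ["RunConfig", "AnalysisReport", "run_analysis", "validate_report"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    landmarks: str | None = None  # path; None -> synthetic cohort
    mask_dir: str | None = None  # optional NIfTI masks, {subject}_{side}.nii[.gz]
    out_dir: str = "results"
    n_subjects: int = 28
    seed: int = 7
    correlation_method: str = "pearson"
    tolerance_deg: float = 10.0
    alpha: float = 0.01
    theta_a: float = 52.4
    theta_c: float = 16.2
    simulate: bool = False  # synthetic TLE horn-mask simulation
    n_tle: int = 12
    step: float = 0.25
    max_distance: float = 60.0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.tolerance_deg <= 0:
            raise ValueError("tolerance_deg must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError("correlation_method must be 'pearson' or 'spearman'")


@dataclass
class AnalysisReport:
    """The machine-readable analysis report plus its Markdown rendering."""

    data: dict
    markdown: str

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "json": out / "report.json",
            "md": out / "report.md",
        }
        paths["json"].write_text(
            json.dumps(self.data, sort_keys=True, indent=2) + "\n", encoding="utf-8"
        )
        paths["md"].write_text(self.markdown, encoding="utf-8")
        return paths


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise module errors with stage context."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, TranssylvianError):
                raise type(exc)(f"[stage {name}] {exc}") from None
            return False

    return _Ctx()


def _summary_dict(s) -> dict:
    return dataclasses.asdict(s)


def _normalized_displacements(table: pd.DataFrame) -> np.ndarray:
    d = np.stack(
        [
            table["target_x"] - table["limen_x"],
            table["target_y"] - table["limen_y"],
            table["target_z"] - table["limen_z"],
        ],
        axis=1,
    ).astype(float)
    left = (table["side"] == "left").to_numpy()
    d[left, 0] = -d[left, 0]
    return d


def _angles_of(d: np.ndarray) -> tuple[float, float]:
    theta_a = math.degrees(math.atan2(-d[1], d[0]))
    theta_c = math.degrees(math.atan2(-d[2], d[0]))
    return theta_a, theta_c


def _chpc_section(table: pd.DataFrame) -> dict:
    """Mean-vector CH-PC transfer, computed both ways.

    The order of averaging and frame transfer is not interchangeable for
    angles, so both conventions are reported: (a) rotate each subject's
    displacement and average the per-subject CH-PC angles; (b) average the
    AC-PC displacements first and rotate the mean vector.
    """
    disps = _normalized_displacements(table)
    R = chpc_rotation()
    per_subject = np.array([_angles_of(R @ d) for d in disps])
    mean_disp = disps.mean(axis=0)
    avg_then_transform = _angles_of(R @ mean_disp)
    acpc_mean = _angles_of(mean_disp)
    return {
        "acpc_mean_vector_angles": {
            "theta_a": acpc_mean[0],
            "theta_c": acpc_mean[1],
        },
        "transform_then_average": {
            "theta_a": float(per_subject[:, 0].mean()),
            "theta_c": float(per_subject[:, 1].mean()),
        },
        "average_then_transform": {
            "theta_a": avg_then_transform[0],
            "theta_c": avg_then_transform[1],
        },
    }


def _find_mask(mask_dir: Path, subject_id: str, side: str) -> Path | None:
    for ext in (".nii.gz", ".nii"):
        p = mask_dir / f"{subject_id}_{side}{ext}"
        if p.exists():
            return p
    return None


def run_analysis(config: RunConfig) -> AnalysisReport:
    """Run the full pipeline and return the report (also writes ``out_dir``)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("load_landmarks"):
        if config.landmarks is not None:
            sets = read_landmarks(config.landmarks)
            source = {"kind": "file", "path": str(config.landmarks)}
        else:
            gen = GeneratorConfig(n_subjects=config.n_subjects, seed=config.seed)
            sets, _ = generate_cohort(gen)
            source = {
                "kind": "synthetic",
                "n_subjects": config.n_subjects,
                "seed": config.seed,
            }

    with _stage("build_cohort_table"):
        table = build_cohort_table(sets)
    write_cohort_table(table, out_dir / "cohort.tsv")

    right = table[table["side"] == "right"].sort_values("subject_id")
    left = table[table["side"] == "left"].sort_values("subject_id")
    paired = sorted(set(right["subject_id"]) & set(left["subject_id"]))
    r_idx = right.set_index("subject_id").loc[paired]
    l_idx = left.set_index("subject_id").loc[paired]

    with _stage("cohort_statistics"):
        summaries = {}
        for angle in ("theta_a", "theta_c", "sphenoid_angle"):
            summaries[angle] = {
                "overall": _summary_dict(summarize(table[angle])),
                "right": _summary_dict(summarize(right[angle]))
                if len(right)
                else None,
                "left": _summary_dict(summarize(left[angle])) if len(left) else None,
            }

        paired_tests = {}
        if len(paired) >= 2:
            for angle in ("theta_a", "theta_c"):
                res = paired_t_test(
                    r_idx[angle], l_idx[angle], alpha=config.alpha
                )
                paired_tests[angle] = dataclasses.asdict(res)

        correlations = {
            method: dataclasses.asdict(
                correlate(table["theta_a"], table["sphenoid_angle"], method=method)
            )
            for method in ("pearson", "spearman")
        }

        par = parallelism_analysis(table, tolerance=config.tolerance_deg)
        parallelism = dataclasses.asdict(par)
        parallelism["mean_offset"] = float(
            (table["theta_a"] - table["sphenoid_angle"]).mean()
        )

    with _stage("chpc_transfer"):
        chpc = _chpc_section(table)

    simulation = None
    if config.simulate or config.mask_dir is not None:
        with _stage("ventricle_simulation"):
            vector = StandardVector(theta_a=config.theta_a, theta_c=config.theta_c)
            if config.mask_dir is not None:
                subjects = []
                for lset in sets:
                    p = _find_mask(
                        Path(config.mask_dir), lset.subject_id, lset.side.value
                    )
                    if p is not None:
                        subjects.append((lset, read_mask(p)))
            else:
                gen = GeneratorConfig(n_tle=config.n_tle, seed=config.seed)
                subjects = generate_tle_cohort(gen)
            results = simulate_cohort(
                subjects,
                vector,
                max_distance=config.max_distance,
                step=config.step,
            )
            sim_rows = [
                {
                    "subject_id": r.subject_id,
                    "side": r.side.value,
                    "entered": bool(r.entered),
                    "entry_distance_mm": r.entry_distance,
                }
                for r in results
            ]
            simulation = {
                "vector": {"theta_a": config.theta_a, "theta_c": config.theta_c},
                "n_entered": int(sum(r.entered for r in results)),
                "n_total": len(results),
                "results": sim_rows,
            }
            pd.DataFrame(
                sim_rows,
                columns=["subject_id", "side", "entered", "entry_distance_mm"],
            ).to_csv(out_dir / "simulation.tsv", sep="\t", index=False)

    from . import __version__

    data = {
        "provenance": {
            "package": "transsylvian",
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "landmark_source": source,
        },
        "n_trajectories": int(len(table)),
        "summaries": summaries,
        "paired_tests": paired_tests,
        "correlations": correlations,
        "headline_correlation": config.correlation_method,
        "parallelism": parallelism,
        "chpc": chpc,
        "simulation": simulation,
    }
    report = AnalysisReport(data=data, markdown=_render_markdown(data))
    report.write(out_dir)
    return report


def _fmt(v: float | None) -> str:
    return "-" if v is None else f"{v:.1f}"


def _render_markdown(data: dict) -> str:
    """One-decimal, Results-style rendering; full precision stays in JSON."""
    lines = [
        "# Transsylvian trajectory analysis",
        "",
        f"Trajectories analysed: {data['n_trajectories']}",
        "",
        "## Approach and ridge angles (degrees)",
        "",
        "| measure | group | n | mean | sd | min | max | range |",
        "|---|---|---|---|---|---|---|---|",
    ]
    label = {
        "theta_a": "axial approach angle",
        "theta_c": "coronal approach angle",
        "sphenoid_angle": "sphenoid-ridge angle",
    }
    for angle, groups in data["summaries"].items():
        for group in ("overall", "right", "left"):
            s = groups.get(group)
            if s is None:
                continue
            lines.append(
                f"| {label[angle]} | {group} | {s['n']} | {_fmt(s['mean'])} | "
                f"{_fmt(s['sd'])} | {_fmt(s['min'])} | {_fmt(s['max'])} | "
                f"{_fmt(s['range'])} |"
            )
    lines += ["", "## Right-left paired t-tests", ""]
    if data["paired_tests"]:
        lines += ["| measure | n pairs | mean R-L | t | p | significant |", "|---|---|---|---|---|---|"]
        for angle, res in data["paired_tests"].items():
            lines.append(
                f"| {label[angle]} | {res['n_pairs']} | "
                f"{_fmt(res['mean_difference'])} | {res['t_statistic']:.2f} | "
                f"{res['p_value']:.3g} | {'yes' if res['significant'] else 'no'} |"
            )
    else:
        lines.append("Not enough right-left pairs.")
    lines += ["", "## Approach-angle / sphenoid-ridge correlation", ""]
    for method, res in data["correlations"].items():
        head = " (headline)" if method == data["headline_correlation"] else ""
        lines.append(
            f"- {method}{head}: r = {res['r']:.3f}, p = {res['p_value']:.3g} "
            f"(n = {res['n']})"
        )
    par = data["parallelism"]
    lines += [
        "",
        "## Parallelism with the sphenoid ridge",
        "",
        f"Within ±{par['tolerance']:.0f}°: {par['n_within']}/{par['n_total']} "
        f"({par['proportion']:.1f}%); mean offset "
        f"{par['mean_offset']:.1f}°.",
        "",
        "## Mean approach vector in the CH-PC frame",
        "",
    ]
    chpc = data["chpc"]
    acpc = chpc["acpc_mean_vector_angles"]
    lines.append(
        f"- AC-PC mean vector: theta_a = {acpc['theta_a']:.1f}°, "
        f"theta_c = {acpc['theta_c']:.1f}°"
    )
    for key, title in (
        ("transform_then_average", "per-subject transfer, then average"),
        ("average_then_transform", "average vector, then transfer"),
    ):
        v = chpc[key]
        lines.append(
            f"- CH-PC ({title}): theta_a = {v['theta_a']:.1f}°, "
            f"theta_c = {v['theta_c']:.1f}°"
        )
    sim = data.get("simulation")
    if sim is not None:
        lines += [
            "",
            "## Standard-vector ventricle simulation",
            "",
            f"Standard vector ({sim['vector']['theta_a']:.1f}°, "
            f"{sim['vector']['theta_c']:.1f}°) entered the inferior horn in "
            f"{sim['n_entered']}/{sim['n_total']} subjects.",
        ]
    return "\n".join(lines) + "\n"


# --- lightweight JSON-schema validation (subset: type/properties/required/items)


def _load_schema() -> dict:
    with resources.files("transsylvian").joinpath("report.schema.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
}


def _check(node: dict, value, path: str, errors: list[str]) -> None:
    typ = node.get("type")
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        ok = False
        for t in allowed:
            if t == "null" and value is None:
                ok = True
            elif t in _TYPES and isinstance(value, _TYPES[t]) and not (
                t in ("number", "integer") and isinstance(value, bool)
            ):
                ok = True
        if not ok:
            errors.append(f"{path}: expected type {typ}, got {type(value).__name__}")
            return
    if value is None:
        return
    if isinstance(value, dict):
        for key in node.get("required", []):
            if key not in value:
                errors.append(f"{path}: missing required key {key!r}")
        for key, sub in node.get("properties", {}).items():
            if key in value:
                _check(sub, value[key], f"{path}.{key}", errors)
    if isinstance(value, list) and "items" in node:
        for i, item in enumerate(value):
            _check(node["items"], item, f"{path}[{i}]", errors)


def validate_report(data: dict) -> list[str]:
    """Validate a report dict against the shipped schema; returns error list."""
    errors: list[str] = []
    _check(_load_schema(), data, "$", errors)
    return errors
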
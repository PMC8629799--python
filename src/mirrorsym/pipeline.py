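"""Orchestration of full symmetry cases and cohorts.

A case runs one registration direction end to end: mirror one side,
pre-register it to the contralateral original with landmarks, refine with
ICP driven by the articular region, compute the closest-point distance map
of that region against the original surface, and summarise.  LM2RO mirrors
the left mesh onto the right original; RM2LO is the converse.  A cohort
runs both directions for every case, pools distances per direction and
combined, compares per-case means between directions, and scores assessor
agreement on categorised means when a second assessor's landmarks are
given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distance_map import DistanceMap, surface_distance_map
from .mesh_core import LandmarkSet, RegionOfInterest, TriangleMesh, extract_region
from .registration import (
    IcpParams,
    IcpTrace,
    RigidTransform,
    apply_transform,
    icp_refine,
    landmark_register,
    mirror_mesh,
    mirror_points,
)
from .symmetry_stats import (
    AgreementCategory,
    DirectionComparison,
    MattaGrade,
    SymmetrySummary,
    ThresholdProfile,
    categorize_distance,
    compare_directions,
    cumulative_curve,
    matta_grade,
    percent_agreement,
    summarize,
    threshold_percentages,
)

__all__ = [
    "DIRECTIONS",
    "PipelineError",
    "CaseInput",
    "CaseResult",
    "CohortReport",
    "run_symmetry_case",
    "run_cohort",
    "write_cohort_report",
    "read_case_table",
]

log = logging.getLogger("mirrorsym")

DIRECTIONS = ("LM2RO", "RM2LO")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage (and case) where it arose."""

    def __init__(self, stage: str, message: str, case_id: str | None = None):
        self.stage = stage
        self.case_id = case_id
        prefix = f"[{case_id}] " if case_id else ""
        super().__init__(f"{prefix}{stage}: {message}")


@dataclass
class CaseInput:
    """Everything one phantom or patient case needs, for both directions."""

    case_id: str
    left: TriangleMesh
    right: TriangleMesh
    landmarks_left: LandmarkSet
    landmarks_right: LandmarkSet
    roi_left: RegionOfInterest
    roi_right: RegionOfInterest


@dataclass
class CaseResult:
    direction: str
    transform: RigidTransform
    dmap: DistanceMap
    summary: SymmetrySummary
    profile: ThresholdProfile
    grade: MattaGrade
    bin: AgreementCategory
    icp_trace: IcpTrace
    case_id: str = ""


@dataclass
class CohortReport:
    per_case: list[CaseResult]
    pooled: dict
    direction_test: DirectionComparison | None
    agreement: float | None = None
    per_case_second: list[CaseResult] = field(default_factory=list)


def run_symmetry_case(
    left: TriangleMesh,
    right: TriangleMesh,
    landmarks_left: LandmarkSet,
    landmarks_right: LandmarkSet,
    roi: RegionOfInterest,
    direction: str = "LM2RO",
    icp: IcpParams | None = None,
    mirror_plane="x=0",
    case_id: str = "",
) -> CaseResult:
    """Run one registration direction end to end.

    ``roi`` indexes the vertices of the side that is mirrored (the moving
    model); it both drives the ICP refinement and defines the distance-map
    query region.  The target is the full contralateral surface.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if direction == "LM2RO":
        moving, target = left, right
        lm_moving, lm_target = landmarks_left, landmarks_right
    else:
        moving, target = right, left
        lm_moving, lm_target = landmarks_right, landmarks_left

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(name, str(exc), case_id or None) from exc

        return wrap

    mirrored = stage("mirror")(mirror_mesh, moving, mirror_plane)
    lm_mirrored = LandmarkSet(
        stage("mirror")(mirror_points, lm_moving.points, mirror_plane),
        labels=lm_moving.labels,
    )
    init = stage("landmark_register")(landmark_register, lm_mirrored, lm_target)
    log.info(
        "%s %s: landmark init rotation %.3f deg, translation %.3f mm",
        case_id or "case",
        direction,
        init.rotation_angle_deg(),
        float(np.linalg.norm(init.translation)),
    )
    moving_region = stage("extract_region")(extract_region, mirrored, roi)
    transform, trace = stage("icp_refine")(
        icp_refine, moving_region, target, init, icp
    )
    log.info(
        "%s %s: ICP %d iterations, converged=%s, final RMS %.4f mm",
        case_id or "case",
        direction,
        trace.iterations_run,
        trace.converged,
        trace.rms_per_iteration[-1] if trace.rms_per_iteration else float("nan"),
    )
    for i, rms in enumerate(trace.rms_per_iteration):
        log.debug("%s %s: ICP iter %d RMS %.6f mm", case_id, direction, i, rms)
    registered = stage("apply_transform")(apply_transform, mirrored, transform)
    dmap = stage("distance_map")(surface_distance_map, registered, roi, target)
    summary = stage("summarize")(summarize, dmap)
    profile = stage("thresholds")(threshold_percentages, dmap)
    return CaseResult(
        direction=direction,
        transform=transform,
        dmap=dmap,
        summary=summary,
        profile=profile,
        grade=matta_grade(summary.mean_error),
        bin=categorize_distance(summary.mean_error),
        icp_trace=trace,
        case_id=case_id,
    )


def _run_case_both(case: CaseInput, icp: IcpParams | None, mirror_plane) -> list[CaseResult]:
    out = []
    for direction in DIRECTIONS:
        roi = case.roi_left if direction == "LM2RO" else case.roi_right
        out.append(
            run_symmetry_case(
                case.left,
                case.right,
                case.landmarks_left,
                case.landmarks_right,
                roi,
                direction=direction,
                icp=icp,
                mirror_plane=mirror_plane,
                case_id=case.case_id,
            )
        )
    return out


def _pool(results: list[CaseResult]) -> dict:
    """Pooled summary + threshold profile per direction and combined."""
    pooled = {}
    for key in (*DIRECTIONS, "combined"):
        sel = [r for r in results if key == "combined" or r.direction == key]
        if not sel:
            continue
        d = np.concatenate([r.dmap.distances for r in sel])
        pooled[key] = {
            "summary": summarize(d),
            "profile": threshold_percentages(d),
            "mean_of_p95": float(np.mean([r.summary.p95 for r in sel])),
            "mean_of_max": float(np.mean([r.summary.max_dev for r in sel])),
        }
    return pooled


def run_cohort(
    cases: list[CaseInput],
    repeat_assessors: dict[str, tuple[LandmarkSet, LandmarkSet]] | None = None,
    icp: IcpParams | None = None,
    mirror_plane="x=0",
) -> CohortReport:
    """Run both directions for every case (2N comparisons).

    ``repeat_assessors`` maps case_id to a second assessor's
    (landmarks_left, landmarks_right); agreement is the percentage of
    case-direction means falling in the same displacement category for both
    assessors.  Per-case means feed the direction comparison test; pooled
    rows concatenate all distance points.
    """
    if not cases:
        raise ValueError("cohort needs at least one case")
    results: list[CaseResult] = []
    for case in cases:
        results.extend(_run_case_both(case, icp, mirror_plane))

    means = {
        d: [r.summary.mean_error for r in results if r.direction == d]
        for d in DIRECTIONS
    }
    # the location test needs >= 3 cases per direction; skip below that
    direction_test = (
        compare_directions(means["LM2RO"], means["RM2LO"])
        if len(cases) >= 3
        else None
    )

    agreement = None
    second: list[CaseResult] = []
    if repeat_assessors:
        for case in cases:
            if case.case_id not in repeat_assessors:
                continue
            lml2, lmr2 = repeat_assessors[case.case_id]
            case2 = CaseInput(
                case.case_id, case.left, case.right, lml2, lmr2,
                case.roi_left, case.roi_right,
            )
            second.extend(_run_case_both(case2, icp, mirror_plane))
        key = lambda r: (r.case_id, r.direction)
        first_by = {key(r): r for r in results}
        pairs = [(first_by[key(r)], r) for r in second]
        agreement = percent_agreement(
            [a.bin for a, _ in pairs], [b.bin for _, b in pairs]
        )
    return CohortReport(
        per_case=results,
        pooled=_pool(results),
        direction_test=direction_test,
        agreement=agreement,
        per_case_second=second,
    )


# ---------------------------------------------------------------------------
# Report files
# ---------------------------------------------------------------------------

def _case_frame(results: list[CaseResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "case_id": r.case_id,
            "direction": r.direction,
            "n_points": r.summary.n_points,
            "mean_mm": r.summary.mean_error,
            "sd_mm": r.summary.sd,
            "p95_mm": r.summary.p95,
            "max_mm": r.summary.max_dev,
            "grade": r.grade.value,
            "bin": r.bin.value,
        }
        for t, p in zip(r.profile.thresholds, r.profile.surface_percent):
            row[f"pct_below_{t}mm"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_report(report: CohortReport, outdir, curve_grid=None) -> None:
    """Write per-case, pooled and cumulative-curve CSVs (tidy, plottable)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _case_frame(report.per_case).round(6).to_csv(out / "cases.csv", index=False)
    if report.per_case_second:
        _case_frame(report.per_case_second).round(6).to_csv(
            out / "cases_assessor2.csv", index=False
        )

    pooled_rows = []
    for key, entry in report.pooled.items():
        s = entry["summary"]
        row = {
            "group": key,
            "n_points": s.n_points,
            "mean_mm": s.mean_error,
            "sd_mm": s.sd,
            "p95_pooled_mm": s.p95,
            "p95_mean_of_cases_mm": entry["mean_of_p95"],
            "max_mean_of_cases_mm": entry["mean_of_max"],
        }
        for t, p in zip(entry["profile"].thresholds, entry["profile"].surface_percent):
            row[f"pct_below_{t}mm"] = p
        pooled_rows.append(row)
    pd.DataFrame(pooled_rows).round(6).to_csv(out / "pooled.csv", index=False)

    box_rows = []
    for r in report.per_case:
        q0, q25, q50, q75, q100 = np.percentile(r.dmap.distances, [0, 25, 50, 75, 100])
        box_rows.append(
            {
                "case_id": r.case_id,
                "direction": r.direction,
                "min_mm": q0,
                "q25_mm": q25,
                "median_mm": q50,
                "q75_mm": q75,
                "max_mm": q100,
            }
        )
    pd.DataFrame(box_rows).round(6).to_csv(out / "boxplot.csv", index=False)

    if curve_grid is None:
        curve_grid = np.round(np.arange(0.0, 3.01, 0.05), 2)
    curve_rows = []
    for r in report.per_case:
        pct = cumulative_curve(r.dmap, curve_grid)
        for g, p in zip(curve_grid, pct):
            curve_rows.append(
                {"case_id": r.case_id, "direction": r.direction, "distance_mm": g, "pct_below": p}
            )
    pd.DataFrame(curve_rows).round(6).to_csv(out / "cumulative_curve.csv", index=False)

    dt = report.direction_test
    stats_rows = [
        {
            "normality_p": dt.normality_p if dt else None,
            "normal": dt.normal if dt else None,
            "test": dt.test_name if dt else "not run (< 3 cases)",
            "statistic": dt.statistic if dt else None,
            "p_value": dt.p_value if dt else None,
            "significant": dt.significant if dt else None,
            "alpha": dt.alpha if dt else None,
            "assessor_agreement_pct": report.agreement,
        }
    ]
    pd.DataFrame(stats_rows).round(6).to_csv(out / "direction_test.csv", index=False)


def read_case_table(path) -> pd.DataFrame:
    """Round-trip helper: parse a written ``cases.csv`` report."""
    return pd.read_csv(path)
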
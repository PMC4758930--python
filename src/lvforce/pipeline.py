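"""End-to-end per-subject analysis and cohort comparison.

Stage order mirrors the acquisition-to-metric chain: velocity corrections
(unwrap, background) -> mask resampling onto the velocity grid -> pressure
gradients -> force integration -> anatomical axes, speed traces, phase
detection -> per-subject metrics.  Each stage failure is re-raised with the
stage name so cohort runs report where a subject broke.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Landmarks, VelocityField
from .geometry import build_axes, detect_phases, extract_speed_traces, project_force
from .hemodynamics import compute_force
from .io import Segmentation, read_subject, resample_mask, write_force_trace, write_metrics
from .metrics import SubjectMetrics, subject_metrics
from .preprocess import DEFAULT_SD_SCALE, preprocess
from .stats import ComparisonResult, regress_ratio_si, ttest_unpaired

__all__ = [
    "PipelineConfig",
    "StageError",
    "analyze_subject",
    "run_pipeline",
    "cohort_table",
    "compare_cohorts",
]

log = logging.getLogger("lvforce")

PRIMARY_METRICS = ("ratio_e", "ratio_a", "mean_sax_e", "mean_sax_a")


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


@dataclass(frozen=True)
class PipelineConfig:
    unwrap: bool = True
    background: bool = True
    background_degree: int = 4
    sd_scale: float = DEFAULT_SD_SCALE  # m/s, static-tissue weight scale
    include_viscous: bool = True
    erode: int = 0  # optional one-voxel mask erosion for border sensitivity
    onset_frac: float = 0.05
    smooth_window: int = 3
    ttest_variant: str = "student"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return replace(cls(), **d)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def analyze_subject(
    field: VelocityField,
    seg: Segmentation,
    landmarks: Landmarks,
    covariates: dict | None = None,
    config: PipelineConfig = PipelineConfig(),
    return_extras: bool = False,
):
    """Run the full chain on in-memory inputs -> :class:`SubjectMetrics`.

    With ``return_extras=True`` also returns a dict holding the corrected
    field's force trace, projected components, phases and traces.
    """
    with _stage("preprocess"):
        corrected = preprocess(
            field,
            unwrap=config.unwrap,
            background=config.background,
            degree=config.background_degree,
            sd_scale=config.sd_scale,
        )
    with _stage("mask_resample"):
        mask = resample_mask(seg, corrected)
    with _stage("force"):
        trace = compute_force(
            corrected, mask, include_viscous=config.include_viscous, erode=config.erode
        )
    with _stage("axes_phases"):
        traces = extract_speed_traces(corrected, landmarks)
        phases = detect_phases(
            traces, corrected.meta, onset_frac=config.onset_frac, smooth_window=config.smooth_window
        )
        axes = build_axes(landmarks, mask, phases)
        projected = project_force(trace, axes)
    with _stage("metrics"):
        metrics = subject_metrics(trace, traces, phases, axes, mask, covariates)
    if return_extras:
        return metrics, {
            "trace": trace,
            "projected": projected,
            "phases": phases,
            "speed_traces": traces,
            "axes": axes,
            "mask": mask,
        }
    return metrics


def run_pipeline(
    subject_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> SubjectMetrics:
    """File-based entry point: read a subject directory, analyze, optionally
    write ``metrics.csv`` and ``force_trace.csv``.  Deterministic for fixed
    inputs and config."""
    with _stage("read"):
        field, seg, landmarks, covariates = read_subject(subject_dir)
    metrics, extras = analyze_subject(
        field, seg, landmarks, covariates, config, return_extras=True
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        proj, phases, trace = extras["projected"], extras["phases"], extras["trace"]
        df = pd.DataFrame(
            {
                "frame": np.arange(len(trace.times)),
                "time_ms": trace.times,
                "Fx": trace.F[:, 0],
                "Fy": trace.F[:, 1],
                "Fz": trace.F[:, 2],
                "F_long": proj.long,
                "F_sax1": proj.sax1,
                "F_sax2": proj.sax2,
                "phase": phases.labels(),
            }
        )
        write_force_trace(df, out_dir / "force_trace.csv")
        write_metrics(metrics, out_dir / "metrics.csv")
    return metrics


def cohort_table(metrics_list, groups) -> pd.DataFrame:
    """Assemble per-subject metrics + group labels into a cohort table."""
    import dataclasses

    rows = []
    for m, g in zip(metrics_list, groups):
        d = dataclasses.asdict(m) if dataclasses.is_dataclass(m) else dict(m)
        d["group"] = g
        rows.append(d)
    return pd.DataFrame(rows)


def _group_summary(table: pd.DataFrame) -> pd.DataFrame:
    num = table.select_dtypes("number").columns
    out = table.groupby("group")[list(num)].agg(["mean", "std", "min", "max"])
    out.columns = ["_".join(c) for c in out.columns]
    return out.reset_index()


def compare_cohorts(
    dirs_a,
    dirs_b,
    config: PipelineConfig = PipelineConfig(),
    labels: tuple[str, str] = ("a", "b"),
    out_dir: str | Path | None = None,
):
    """Run the pipeline per subject in two groups and perform the primary
    comparisons (ratio and mean-SAx-force at E and A) plus the pooled
    ratio ~ SI regressions.

    ``dirs_a`` / ``dirs_b`` are iterables of subject directories.  Returns
    ``(cohort_table, comparisons, summary)``.
    """
    dirs_a, dirs_b = list(dirs_a), list(dirs_b)
    if len(dirs_a) < 2 or len(dirs_b) < 2:
        raise StageError("[cohort] each group needs >= 2 subjects")
    metrics, groups = [], []
    for label, dirs in ((labels[0], dirs_a), (labels[1], dirs_b)):
        for d in dirs:
            try:
                metrics.append(run_pipeline(d, config))
            except StageError as exc:
                raise StageError(f"subject {d}: {exc}") from exc
            groups.append(label)
    table = cohort_table(metrics, groups)
    comparisons = compare_tables(table, labels, config.ttest_variant)
    summary = _group_summary(table)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "cohort_metrics.csv", index=False)
        summary.to_csv(out_dir / "group_summary.csv", index=False)
        pd.DataFrame([c.__dict__ for c in comparisons]).to_csv(
            out_dir / "comparisons.csv", index=False
        )
    return table, comparisons, summary


def compare_tables(table: pd.DataFrame, labels, variant: str = "student"):
    """The primary comparison set on an assembled cohort table."""
    import warnings

    comparisons: list[ComparisonResult] = []
    ga = table[table["group"] == labels[0]]
    gb = table[table["group"] == labels[1]]
    for metric in PRIMARY_METRICS:
        a = ga[metric].to_numpy(float)
        b = gb[metric].to_numpy(float)
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            warnings.warn(f"dropping non-finite {metric} values from the comparison")
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        comparisons.append(ttest_unpaired(a, b, variant=variant, metric=metric))
    for wave in ("E", "A"):
        comparisons.append(regress_ratio_si(table, wave))
    return comparisons


def configure_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
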
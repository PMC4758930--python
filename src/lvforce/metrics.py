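"""Per-subject scalar summaries of the projected hemodynamic force.

The central metric is the "SAx-max/LAx-max" force ratio per filling wave: the
peak transverse (anteroseptal-inferolateral) force magnitude divided by the
peak long-axis force magnitude within the wave's frame window.  Values near 0
mean the filling force is aligned with the base-apex axis; larger values mean
more transverse force, as seen in remodelled, more spherical ventricles.
"Maximum force along an axis" is the maximum of the absolute signed
projection within the wave window, making the ratio direction-agnostic and
invariant to positive rescaling of the whole trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DomainError, MaskSeries
from .geometry import AxesFrame, PhaseMap, ProjectedForce, SpeedTraces
from .hemodynamics import ForceTrace

__all__ = [
    "SubjectMetrics",
    "sax_lax_ratio",
    "mean_sax_force",
    "loop_orientation",
    "peak_lag",
    "subject_metrics",
]

LOOP_AREA_TOL = 1e-6  # N^2; smaller |signed area| is reported indeterminate


@dataclass
class SubjectMetrics:
    """Scalar per-subject summaries (see module docstring for definitions)."""

    ratio_e: float
    ratio_a: float
    mean_sax_e: float
    mean_sax_a: float
    lax_max_e: float
    lax_max_a: float
    sax_max_e: float
    sax_max_a: float
    loop_dir_e: str
    loop_dir_a: str
    peak_lag_e: float  # ms, positive = force peak later than MV speed peak
    si: float  # sphericity index, supplied externally
    edv: float  # end-diastolic volume, mL

    def __post_init__(self) -> None:
        for name in ("ratio_e", "ratio_a", "mean_sax_e", "mean_sax_a"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise DomainError(f"{name} must be >= 0, got {v}")
        if not self.edv > 0:
            raise DomainError("edv must be > 0")


def _window(phases: PhaseMap, wave: str) -> np.ndarray:
    wave = {"E": "e_wave", "A": "a_wave"}.get(wave, wave)
    frames = phases.frames(wave)
    if len(frames) == 0:
        raise DomainError(f"empty {wave} window")
    return frames


def sax_lax_ratio(projected: ProjectedForce, phases: PhaseMap, wave: str) -> float:
    """max |F_sax1| / max |F_long| within the wave window (+inf if the
    long-axis peak is zero)."""
    w = _window(phases, wave)
    lax = np.abs(projected.long[w]).max()
    sax = np.abs(projected.sax1[w]).max()
    if lax == 0:
        return np.inf if sax > 0 else 0.0
    return float(sax / lax)


def mean_sax_force(projected: ProjectedForce, phases: PhaseMap, wave: str) -> float:
    """Time-averaged SAx-plane force magnitude over the wave window:
    mean of sqrt(F_sax1^2 + F_sax2^2)."""
    w = _window(phases, wave)
    return float(np.sqrt(projected.sax1[w] ** 2 + projected.sax2[w] ** 2).mean())


def loop_orientation(x: np.ndarray, y: np.ndarray, area_tol: float = LOOP_AREA_TOL) -> str:
    """Orientation of a closed planar trajectory by the shoelace signed area.

    Returns "CCW", "CW" or "indeterminate" (|area| below ``area_tol``, e.g. a
    collinear trajectory).  Flips under time reversal and under reflection of
    either axis.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise DomainError("need >= 3 points for a loop orientation")
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if abs(area) < area_tol:
        return "indeterminate"
    return "CCW" if area > 0 else "CW"


def peak_lag(
    traces: SpeedTraces, trace: ForceTrace, projected: ProjectedForce, phases: PhaseMap
) -> float:
    """E-wave delay (ms) from the MV speed peak to the |F| peak; positive
    means the force peaks later than the inflow velocity."""
    w = _window(phases, "E")
    fmag = np.sqrt(projected.long**2 + projected.sax1**2 + projected.sax2**2)
    t_force = trace.times[w[np.argmax(fmag[w])]]
    t_speed = trace.times[w[np.argmax(traces.mv_speed[w])]]
    return float(t_force - t_speed)


def subject_metrics(
    trace: ForceTrace,
    traces: SpeedTraces,
    phases: PhaseMap,
    axes: AxesFrame,
    mask: MaskSeries,
    covariates: dict | None = None,
) -> SubjectMetrics:
    """Aggregate all per-subject metrics for one pipeline run.

    ``edv`` is the maximum mask volume over the cycle (the mask is the only
    geometry the pipeline holds); ``si`` comes from the covariates (NaN when
    absent).
    """
    from .geometry import project_force

    covariates = covariates or {}
    projected = project_force(trace, axes)
    we = _window(phases, "E")

    def _wave_metrics(wave: str):
        try:
            w = _window(phases, wave)
        except DomainError:
            return np.nan, np.nan, np.nan, np.nan, "indeterminate"
        lax = float(np.abs(projected.long[w]).max())
        sax = float(np.abs(projected.sax1[w]).max())
        ratio = sax_lax_ratio(projected, phases, wave)
        mean_sax = mean_sax_force(projected, phases, wave)
        loop = (
            loop_orientation(projected.long[w], projected.sax1[w]) if len(w) >= 3 else "indeterminate"
        )
        return ratio, mean_sax, lax, sax, loop

    ratio_e, mean_e, lax_e, sax_e, loop_e = _wave_metrics("E")
    ratio_a, mean_a, lax_a, sax_a, loop_a = _wave_metrics("A")
    return SubjectMetrics(
        ratio_e=ratio_e,
        ratio_a=ratio_a,
        mean_sax_e=mean_e,
        mean_sax_a=mean_a,
        lax_max_e=lax_e,
        lax_max_a=lax_a,
        sax_max_e=sax_e,
        sax_max_a=sax_a,
        loop_dir_e=loop_e,
        loop_dir_a=loop_a,
        peak_lag_e=peak_lag(traces, trace, projected, phases),
        si=float(covariates.get("si", np.nan)),
        edv=float(mask.volumes_ml().max()),
    )
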
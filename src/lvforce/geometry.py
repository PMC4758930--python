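"""Anatomical reference frame, force projection, speed traces and division of
the cardiac cycle into systole, E-wave, diastasis and A-wave.

The anatomical triad: ``e_long`` points base-to-apex; ``e_sax1`` lies in the
three-chamber plane perpendicular to ``e_long`` and points from the
anteroseptal (aortic) side toward the inferolateral wall; ``e_sax2``
completes a right-handed orthonormal frame.  The "LAx plane" trajectory is
``(F_long, F_sax1)`` and the basal "SAx plane" trajectory is
``(F_sax1, F_sax2)`` (one fixed short-axis orientation for the whole cycle:
the force is a single global vector, so only the plane's orientation
matters).

Phase detection follows the transmitral/outflow speed traces: the E-wave runs
from the onset of the first diastolic rise of the mitral-valve speed (first
frame above ``onset_frac`` of the wave peak, walked back to the local
minimum) to the end of its deceleration; the A-wave is detected analogously
around the second diastolic peak and ends at end-diastole; diastasis is the
gap; everything before the E-wave onset (ejection plus isovolumic phases) is
labelled systole so the four windows partition the cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import AcquisitionMeta, DomainError, GeometryError, Landmarks, MaskSeries, VelocityField
from .hemodynamics import ForceTrace

__all__ = [
    "AxesFrame",
    "PhaseMap",
    "SpeedTraces",
    "ProjectedForce",
    "build_axes",
    "project_force",
    "extract_speed_traces",
    "detect_phases",
]

DEFAULT_ONSET_FRAC = 0.05


@dataclass(frozen=True)
class AxesFrame:
    """Orthonormal right-handed anatomical triad plus a reference origin (mm)."""

    e_long: np.ndarray
    e_sax1: np.ndarray
    e_sax2: np.ndarray
    origin: np.ndarray | None = None

    def __post_init__(self) -> None:
        M = np.stack([self.e_long, self.e_sax1, self.e_sax2])
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-9):
            raise GeometryError("axes must be orthonormal")
        if np.dot(np.cross(self.e_long, self.e_sax1), self.e_sax2) < 0:
            raise GeometryError("axes must be right-handed")


@dataclass(frozen=True)
class PhaseMap:
    """Half-open frame windows partitioning the cardiac cycle.

    Contiguous by construction: ``systole=[0,e0) -> e_wave=[e0,e1) ->
    diastasis=[e1,a0) -> a_wave=[a0,n)``.  ``a_wave`` may be empty for fused
    E/A inflow.
    """

    systole: tuple[int, int]
    e_wave: tuple[int, int]
    diastasis: tuple[int, int]
    a_wave: tuple[int, int]
    n_frames: int

    def __post_init__(self) -> None:
        w = [self.systole, self.e_wave, self.diastasis, self.a_wave]
        if any(b < a for a, b in w):
            raise DomainError("phase window with negative length")
        if w[0][0] != 0 or w[-1][1] != self.n_frames:
            raise DomainError("phase windows must cover [0, n_frames)")
        if any(w[i][1] != w[i + 1][0] for i in range(3)):
            raise DomainError(f"phase windows must be ordered and contiguous: {w}")

    def labels(self) -> np.ndarray:
        out = np.empty(self.n_frames, dtype=object)
        for name in ("systole", "e_wave", "diastasis", "a_wave"):
            a, b = getattr(self, name)
            out[a:b] = name
        return out

    def frames(self, wave: str) -> np.ndarray:
        a, b = getattr(self, wave)
        return np.arange(a, b)


@dataclass
class SpeedTraces:
    """Speed (m/s) per frame at the MV-orifice and AoV/LVOT landmark points."""

    mv_speed: np.ndarray
    aov_speed: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.mv_speed < 0) or np.any(self.aov_speed < 0):
            raise DomainError("speeds must be non-negative")


@dataclass
class ProjectedForce:
    """Force trace expressed in the anatomical triad (N)."""

    times: np.ndarray  # ms
    long: np.ndarray  # along e_long (base -> apex positive)
    sax1: np.ndarray  # anteroseptal -> inferolateral
    sax2: np.ndarray


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("cannot normalize a zero vector")
    return v / n


def build_axes(
    landmarks: Landmarks,
    mask: MaskSeries | None = None,
    early_diastolic_frame: int | "PhaseMap" | None = None,
) -> AxesFrame:
    """Construct the anatomical triad from landmarks.

    The long axis runs from the mitral-valve center to the apex; the
    three-chamber plane is spanned by the long axis and the (orthogonalized)
    MV-to-AoV direction.  ``e_sax1`` points away from the aortic/anteroseptal
    side unless ``rv_direction`` overrides the sign.  The origin is the mask
    center of mass at the requested early-diastolic frame (first E-wave frame
    when a :class:`PhaseMap` is given), or ``None`` without a mask.
    """
    e_long = _normalize(landmarks.apex - landmarks.mv_center)
    w = landmarks.aov_center - landmarks.mv_center
    in_plane = w - np.dot(w, e_long) * e_long
    if np.linalg.norm(in_plane) < 1e-9:
        raise GeometryError("landmarks are collinear; cannot span the three-chamber plane")
    toward_aov = _normalize(in_plane)
    if landmarks.rv_direction is not None:
        # RV lies on the septal (anteroseptal) side: point e_sax1 away from it
        e_sax1 = -toward_aov if np.dot(toward_aov, landmarks.rv_direction) > 0 else toward_aov
    else:
        e_sax1 = -toward_aov
    e_sax2 = np.cross(e_long, e_sax1)

    origin = None
    if mask is not None:
        if isinstance(early_diastolic_frame, PhaseMap):
            frame = early_diastolic_frame.e_wave[0]
        else:
            frame = int(early_diastolic_frame or 0)
        com_idx = np.asarray(ndimage.center_of_mass(mask.occupancy[frame]))
        origin = com_idx * np.asarray(mask.voxel_size)
    return AxesFrame(e_long=e_long, e_sax1=e_sax1, e_sax2=e_sax2, origin=origin)


def project_force(trace: ForceTrace, axes: AxesFrame) -> ProjectedForce:
    """Dot the force vectors with the unit axes; norm-preserving by
    orthonormality (``|F|^2 = F_long^2 + F_sax1^2 + F_sax2^2``)."""
    return ProjectedForce(
        times=trace.times.copy(),
        long=trace.F @ axes.e_long,
        sax1=trace.F @ axes.e_sax1,
        sax2=trace.F @ axes.e_sax2,
    )


def extract_speed_traces(field: VelocityField, landmarks: Landmarks) -> SpeedTraces:
    """Trilinearly interpolate the velocity at the MV and AoV points per frame."""
    vox = np.asarray(field.meta.voxel_size)
    shape = np.asarray(field.spatial_shape)
    pts = np.stack([landmarks.mv_center, landmarks.aov_center]) / vox  # voxel units
    if np.any(pts < 0) or np.any(pts > shape - 1):
        raise GeometryError("landmark point outside the velocity grid")
    n = field.meta.n_frames
    speeds = np.zeros((2, n))
    coords = pts.T  # (3, 2)
    for t in range(n):
        comps = [
            ndimage.map_coordinates(field.values[t, c], coords, order=1, mode="nearest")
            for c in range(3)
        ]
        speeds[:, t] = np.sqrt(sum(c**2 for c in comps))
    return SpeedTraces(mv_speed=speeds[0], aov_speed=speeds[1])


def _smooth_cyclic(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    k = np.ones(window) / window
    pad = window // 2
    ext = np.concatenate([x[-pad:], x, x[:pad]])
    return np.convolve(ext, k, mode="same")[pad:-pad]


def _walk_back_to_min(x: np.ndarray, f: int, lo: int) -> int:
    while f > lo and x[f - 1] < x[f]:
        f -= 1
    return f


def _onset(x: np.ndarray, lo: int, peak: int, frac: float) -> int:
    thr = frac * x[peak]
    f = peak
    for g in range(lo, peak + 1):
        if x[g] > thr:
            f = g
            break
    return _walk_back_to_min(x, f, lo)


def _end_of_decrease(x: np.ndarray, peak: int, hi: int) -> int:
    f = peak
    while f + 1 < hi and x[f + 1] < x[f]:
        f += 1
    return f


def detect_phases(
    traces: SpeedTraces,
    meta: AcquisitionMeta,
    onset_frac: float = DEFAULT_ONSET_FRAC,
    smooth_window: int = 3,
) -> PhaseMap:
    """Divide the cycle into systole / E-wave / diastasis / A-wave.

    Invariant to uniform scaling of the traces (all thresholds are relative).
    A missing second diastolic peak yields a single-wave map with an empty
    A-wave and a warning; flat traces raise :class:`DomainError`.
    """
    n = meta.n_frames
    mv = _smooth_cyclic(np.asarray(traces.mv_speed, float), smooth_window)
    aov = _smooth_cyclic(np.asarray(traces.aov_speed, float), smooth_window)
    if mv.max() <= 0 or aov.max() <= 0:
        raise DomainError("flat speed trace; cannot detect cardiac phases")

    # systolic outflow: locate the AoV peak and its fall-off, then search the
    # diastolic window after it for the inflow waves
    aov_peak = int(np.argmax(aov))
    thr = onset_frac * aov[aov_peak]
    dia_lo = aov_peak
    while dia_lo + 1 < n and aov[dia_lo] > thr:
        dia_lo += 1

    # E-wave = the FIRST prominent diastolic wave: a late (atrial) wave may
    # exceed the early one when relaxation is impaired, so take the first
    # local maximum reaching at least 40% of the diastolic peak rather than
    # the global maximum
    dia_max = mv[dia_lo:].max()
    if dia_max <= 0:
        raise DomainError("no diastolic inflow detected in the MV trace")
    e_peak = dia_lo + int(np.argmax(mv[dia_lo:]))
    for f in range(max(dia_lo, 1), n - 1):
        if mv[f] >= mv[f - 1] and mv[f] >= mv[f + 1] and mv[f] >= 0.4 * dia_max:
            e_peak = f
            break
    e_start = _onset(mv, dia_lo, e_peak, onset_frac)
    e_stop = _end_of_decrease(mv, e_peak, n)

    a_slice = mv[e_stop:]
    a_peak = e_stop + int(np.argmax(a_slice)) if e_stop < n else n - 1
    if e_stop >= n - 1 or mv[a_peak] <= onset_frac * mv[e_peak]:
        warnings.warn("no second diastolic MV peak: fused E/A inflow, empty A-wave")
        return PhaseMap(
            systole=(0, e_start),
            e_wave=(e_start, e_stop),
            diastasis=(e_stop, n),
            a_wave=(n, n),
            n_frames=n,
        )
    a_start = _onset(mv, e_stop, a_peak, onset_frac)
    return PhaseMap(
        systole=(0, e_start),
        e_wave=(e_start, e_stop),
        diastasis=(e_stop, a_start),
        a_wave=(a_start, n),
        n_frames=n,
    )
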
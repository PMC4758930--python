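"""Core domain types for 4D-flow hemodynamic force analysis.

The pipeline consumes a time-resolved three-component velocity field on a
regular voxel grid, a per-frame binary left-ventricular (LV) mask on the same
grid, and three anatomical landmarks (apex, mitral-valve center, aortic-valve /
LV-outflow-tract center).  Conventions used throughout the package:

* voxel indices are 0-based; the physical position of voxel ``(i, j, k)`` is
  ``index * voxel_size`` millimetres (voxel centers, right-handed axes);
* velocities are stored in m/s, times in ms, forces in newtons;
* the frame axis is cyclic: retrospective cardiac gating means frame
  ``n_frames - 1`` immediately precedes frame 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "AcquisitionMeta",
    "VelocityField",
    "MaskSeries",
    "Landmarks",
    "DomainError",
    "FormatError",
    "MetadataError",
    "GeometryError",
]

#: blood density, kg/m^3
DEFAULT_RHO = 1060.0
#: blood dynamic viscosity, N s/m^2
DEFAULT_MU = 0.004


class DomainError(ValueError):
    """Input violates a physical/domain precondition (e.g. empty mask frame)."""


class FormatError(ValueError):
    """On-disk data malformed or inconsistent (shape mismatch, missing file)."""


class MetadataError(ValueError):
    """Acquisition metadata missing or invalid."""


class GeometryError(ValueError):
    """Degenerate geometry (collinear landmarks, point outside grid, ...)."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Physical acquisition metadata for a velocity dataset.

    Parameters
    ----------
    venc : float
        Velocity-encoding limit in m/s.  Velocities beyond ``±venc`` alias by
        multiples of ``2 * venc``.
    voxel_size : tuple of float
        Grid spacing (mm) along the three spatial axes.
    n_frames : int
        Number of reconstructed frames per cardiac cycle.
    rr_interval : float
        Cardiac cycle duration in ms.
    frame_times : ndarray
        Frame midpoint times in ms, strictly increasing, all < ``rr_interval``.
        Defaults to uniform spacing ``rr_interval / n_frames`` (retrospective
        gating reconstructs uniformly spaced frames).
    rho, mu : float
        Blood density (kg/m^3) and dynamic viscosity (N s/m^2).
    """

    venc: float
    voxel_size: tuple[float, float, float]
    n_frames: int
    rr_interval: float
    frame_times: np.ndarray = field(default=None)  # type: ignore[assignment]
    rho: float = DEFAULT_RHO
    mu: float = DEFAULT_MU

    def __post_init__(self) -> None:
        if not self.venc > 0:
            raise MetadataError(f"venc must be > 0, got {self.venc}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise MetadataError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        object.__setattr__(self, "voxel_size", vs)
        if self.n_frames < 1:
            raise MetadataError("n_frames must be >= 1")
        if not self.rr_interval > 0:
            raise MetadataError("rr_interval must be > 0")
        if self.frame_times is None:
            ft = (np.arange(self.n_frames) + 0.5) * self.rr_interval / self.n_frames
        else:
            ft = np.asarray(self.frame_times, dtype=float)
        if ft.shape != (self.n_frames,):
            raise MetadataError("frame_times length must equal n_frames")
        if np.any(np.diff(ft) <= 0) or ft[-1] >= self.rr_interval or ft[0] < 0:
            raise MetadataError("frame_times must be strictly increasing and < rr_interval")
        object.__setattr__(self, "frame_times", ft)
        if not self.rho > 0:
            raise MetadataError("rho must be > 0")
        if self.mu < 0:
            raise MetadataError("mu must be >= 0")

    @property
    def voxel_volume_m3(self) -> float:
        """Voxel volume in m^3 (voxel_size is in mm)."""
        v = self.voxel_size
        return float(v[0] * v[1] * v[2]) * 1e-9

    @property
    def dt_s(self) -> np.ndarray:
        """Cyclic frame-to-frame intervals in seconds (len n_frames).

        ``dt_s[i]`` is the time from frame ``i`` to frame ``i+1``; the last
        entry wraps around the cycle.
        """
        ft = self.frame_times
        d = np.empty(self.n_frames)
        d[:-1] = np.diff(ft)
        d[-1] = self.rr_interval - ft[-1] + ft[0]
        return d * 1e-3


@dataclass
class VelocityField:
    """Per-frame three-component voxel velocities (m/s).

    ``values`` has axes ``[frame, component(x,y,z), i, j, k]``.
    """

    values: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 5 or v.shape[1] != 3:
            raise FormatError(f"velocity array must be [frame, 3, i, j, k], got shape {v.shape}")
        if v.shape[0] != self.meta.n_frames:
            raise FormatError(
                f"frame count {v.shape[0]} does not match metadata n_frames {self.meta.n_frames}"
            )
        if not np.all(np.isfinite(v)):
            raise FormatError("velocity values must be finite")
        self.values = v

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[2:]

    def copy(self) -> "VelocityField":
        return VelocityField(self.values.copy(), self.meta)


@dataclass
class MaskSeries:
    """Per-frame binary LV occupancy on the velocity grid.

    ``occupancy`` has axes ``[frame, i, j, k]``; every frame must contain at
    least one occupied voxel.
    """

    occupancy: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy).astype(bool)
        if occ.ndim != 4:
            raise FormatError(f"mask array must be [frame, i, j, k], got shape {occ.shape}")
        counts = occ.reshape(occ.shape[0], -1).sum(axis=1)
        if np.any(counts == 0):
            empty = int(np.argmax(counts == 0))
            raise DomainError(f"mask frame {empty} has no occupied voxel")
        self.occupancy = occ
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def n_frames(self) -> int:
        return self.occupancy.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape[1:]

    def volumes_ml(self) -> np.ndarray:
        """Mask volume per frame in millilitres."""
        voxvol_mm3 = self.voxel_size[0] * self.voxel_size[1] * self.voxel_size[2]
        return self.occupancy.reshape(self.n_frames, -1).sum(axis=1) * voxvol_mm3 * 1e-3


@dataclass(frozen=True)
class Landmarks:
    """Anatomical landmark points in physical coordinates (mm).

    ``rv_direction`` optionally marks the septal side (unit vector); when
    absent the aortic-valve landmark resolves the in-plane axis sign.
    """

    apex: np.ndarray
    mv_center: np.ndarray
    aov_center: np.ndarray
    rv_direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("apex", "mv_center", "aov_center"):
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, p)
        if np.allclose(self.apex, self.mv_center):
            raise GeometryError("apex and mv_center coincide")
        # collinearity of the three points would leave the three-chamber
        # plane undefined
        u = self.apex - self.mv_center
        w = self.aov_center - self.mv_center
        cr = np.cross(u, w)
        if np.linalg.norm(cr) < 1e-9 * max(np.linalg.norm(u), 1.0) * max(np.linalg.norm(w), 1.0):
            raise GeometryError("landmarks are collinear; three-chamber plane undefined")
        if self.rv_direction is not None:
            d = np.asarray(self.rv_direction, dtype=float).reshape(3)
            n = np.linalg.norm(d)
            if n == 0:
                raise GeometryError("rv_direction must be a nonzero vector")
            object.__setattr__(self, "rv_direction", d / n)
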
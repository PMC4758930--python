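"""Readers, writers and mask resampling.

On-disk layout of a subject directory::

    subject/
      vel_x.nii, vel_y.nii, vel_z.nii   one 4D NIfTI per velocity component
                                        (alternatively a single 5D file)
      velocity.json                     acquisition sidecar (see below)
      mask.nii                          4D uint8 segmentation, own grid/time base
      mask.json                         {"voxel_size_mm", "rr_interval_ms", "n_frames"}
      landmarks.json                    {"apex_mm", "mv_center_mm", "aov_center_mm"}
      covariates.json                   optional, e.g. {"si": 0.56, "group": "healthy"}

Velocity sidecar keys: ``venc`` (number in m/s, or a string such as
``"100 cm/s"``), ``voxel_size_mm``, ``n_frames``, ``rr_interval_ms``, optional
``frame_times_ms``, ``rho_kg_m3``, ``mu_Ns_m2``, ``velocity_unit`` ("m/s" or
"cm/s") and ``velocity_scale`` (extra multiplier applied to stored values).
Velocities are always returned in m/s regardless of on-disk scaling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    AcquisitionMeta,
    DomainError,
    FormatError,
    Landmarks,
    MaskSeries,
    MetadataError,
    VelocityField,
)

__all__ = [
    "Segmentation",
    "parse_meta",
    "read_velocity",
    "write_velocity",
    "read_segmentation",
    "write_segmentation",
    "read_landmarks",
    "write_landmarks",
    "resample_mask",
    "write_force_trace",
    "write_metrics",
    "read_subject",
]

_UNIT_TO_M_PER_S = {"m/s": 1.0, "cm/s": 0.01, "mm/s": 0.001}


@dataclass
class Segmentation:
    """A binary segmentation series on its own grid and time base.

    May differ from the velocity grid in spatial resolution and frame count
    (e.g. 30 morphology frames against 40 velocity frames); ``resample_mask``
    maps it onto a velocity field.  Grids are assumed co-registered (shared
    origin and orientation).
    """

    occupancy: np.ndarray  # [frame, i, j, k] bool
    voxel_size: tuple[float, float, float]  # mm
    rr_interval: float  # ms
    frame_times: np.ndarray | None = None  # ms; default uniform midpoints

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy).astype(bool)
        if occ.ndim != 4:
            raise FormatError(f"segmentation must be [frame, i, j, k], got {occ.shape}")
        self.occupancy = occ
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.frame_times is None:
            n = occ.shape[0]
            self.frame_times = (np.arange(n) + 0.5) * self.rr_interval / n
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)


def _parse_quantity(value, unit_table: dict[str, float], what: str) -> float:
    """Parse ``1.0`` or ``"100 cm/s"`` into a float in the table's base unit."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        parts = value.split()
        if len(parts) == 2 and parts[1] in unit_table:
            try:
                return float(parts[0]) * unit_table[parts[1]]
            except ValueError:
                pass
        raise MetadataError(f"cannot parse {what} {value!r}")
    raise MetadataError(f"cannot parse {what} {value!r}")


def parse_meta(sidecar: dict) -> AcquisitionMeta:
    """Build :class:`AcquisitionMeta` from a velocity sidecar dictionary."""
    missing = [k for k in ("venc", "voxel_size_mm", "n_frames", "rr_interval_ms") if k not in sidecar]
    if missing:
        raise MetadataError(f"sidecar missing required keys: {missing}")
    venc = _parse_quantity(sidecar["venc"], _UNIT_TO_M_PER_S, "venc")
    kwargs = {}
    if "frame_times_ms" in sidecar and sidecar["frame_times_ms"] is not None:
        kwargs["frame_times"] = np.asarray(sidecar["frame_times_ms"], dtype=float)
    if "rho_kg_m3" in sidecar:
        kwargs["rho"] = float(sidecar["rho_kg_m3"])
    if "mu_Ns_m2" in sidecar:
        kwargs["mu"] = float(sidecar["mu_Ns_m2"])
    return AcquisitionMeta(
        venc=venc,
        voxel_size=tuple(float(v) for v in sidecar["voxel_size_mm"]),
        n_frames=int(sidecar["n_frames"]),
        rr_interval=float(sidecar["rr_interval_ms"]),
        **kwargs,
    )


def _velocity_scale(sidecar: dict) -> float:
    scale = float(sidecar.get("velocity_scale", 1.0))
    unit = sidecar.get("velocity_unit", "m/s")
    if unit not in _UNIT_TO_M_PER_S:
        raise MetadataError(f"unknown velocity_unit {unit!r}")
    return scale * _UNIT_TO_M_PER_S[unit]


def read_velocity(paths: Sequence[str | Path] | str | Path, sidecar: str | Path | dict) -> VelocityField:
    """Read a velocity field from NIfTI volumes plus a JSON sidecar.

    ``paths`` is either three 4D component files ``(i, j, k, frame)`` in x, y,
    z order, or a single 5D file ``(i, j, k, frame, component)``.
    """
    if not isinstance(sidecar, dict):
        with open(sidecar) as fh:
            sidecar = json.load(fh)
    meta = parse_meta(sidecar)
    scale = _velocity_scale(sidecar)

    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FormatError(f"velocity component file missing: {p}")

    if len(paths) == 1:
        arr = np.asanyarray(nib.load(paths[0]).dataobj)
        if arr.ndim != 5 or arr.shape[4] != 3:
            raise FormatError(f"single-file velocity must be (i,j,k,frame,3), got {arr.shape}")
        comps = [arr[..., c] for c in range(3)]
    elif len(paths) == 3:
        comps = [np.asanyarray(nib.load(p).dataobj) for p in paths]
        shapes = {c.shape for c in comps}
        if len(shapes) != 1:
            raise FormatError(f"velocity component shapes differ: {[c.shape for c in comps]}")
        if comps[0].ndim != 4:
            raise FormatError(f"velocity components must be 4D (i,j,k,frame), got {comps[0].shape}")
    else:
        raise FormatError(f"expected 1 or 3 velocity files, got {len(paths)}")

    if comps[0].shape[3] != meta.n_frames:
        raise FormatError(
            f"velocity frame count {comps[0].shape[3]} does not match sidecar n_frames {meta.n_frames}"
        )
    # (i,j,k,t) x 3  ->  [t, c, i, j, k]
    values = np.stack([np.moveaxis(c, 3, 0) for c in comps], axis=1).astype(float) * scale
    return VelocityField(values, meta)


def write_velocity(field: VelocityField, out_dir: str | Path, dtype=np.float32) -> dict:
    """Write a field as three component NIfTIs plus ``velocity.json``.

    Returns the sidecar dictionary.  Values are stored in m/s.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(field.meta.voxel_size) + [1.0])
    for c, name in enumerate(("vel_x.nii", "vel_y.nii", "vel_z.nii")):
        arr = np.moveaxis(field.values[:, c], 0, 3).astype(dtype)
        nib.save(nib.Nifti1Image(arr, affine), out_dir / name)
    m = field.meta
    sidecar = {
        "venc": m.venc,
        "voxel_size_mm": list(m.voxel_size),
        "n_frames": m.n_frames,
        "rr_interval_ms": m.rr_interval,
        "frame_times_ms": m.frame_times.tolist(),
        "rho_kg_m3": m.rho,
        "mu_Ns_m2": m.mu,
        "velocity_unit": "m/s",
    }
    with open(out_dir / "velocity.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return sidecar


def read_segmentation(path: str | Path, sidecar: str | Path | dict) -> Segmentation:
    if not isinstance(sidecar, dict):
        with open(sidecar) as fh:
            sidecar = json.load(fh)
    arr = np.asanyarray(nib.load(path).dataobj)
    if arr.ndim != 4:
        raise FormatError(f"segmentation must be 4D (i,j,k,frame), got {arr.shape}")
    occ = np.moveaxis(arr, 3, 0) > 0
    ft = sidecar.get("frame_times_ms")
    return Segmentation(
        occupancy=occ,
        voxel_size=tuple(float(v) for v in sidecar["voxel_size_mm"]),
        rr_interval=float(sidecar["rr_interval_ms"]),
        frame_times=None if ft is None else np.asarray(ft, dtype=float),
    )


def write_segmentation(seg: Segmentation, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(seg.voxel_size) + [1.0])
    arr = np.moveaxis(seg.occupancy.astype(np.uint8), 0, 3)
    nib.save(nib.Nifti1Image(arr, affine), out_dir / "mask.nii")
    with open(out_dir / "mask.json", "w") as fh:
        json.dump(
            {
                "voxel_size_mm": list(seg.voxel_size),
                "rr_interval_ms": seg.rr_interval,
                "n_frames": int(seg.occupancy.shape[0]),
                "frame_times_ms": seg.frame_times.tolist(),
            },
            fh,
            indent=1,
        )


def read_landmarks(path: str | Path | dict) -> Landmarks:
    if not isinstance(path, dict):
        with open(path) as fh:
            path = json.load(fh)
    try:
        rv = path.get("rv_direction")
        return Landmarks(
            apex=np.asarray(path["apex_mm"], dtype=float),
            mv_center=np.asarray(path["mv_center_mm"], dtype=float),
            aov_center=np.asarray(path["aov_center_mm"], dtype=float),
            rv_direction=None if rv is None else np.asarray(rv, dtype=float),
        )
    except KeyError as exc:
        raise MetadataError(f"landmarks JSON missing key {exc}") from exc


def write_landmarks(landmarks: Landmarks, path: str | Path) -> None:
    d = {
        "apex_mm": landmarks.apex.tolist(),
        "mv_center_mm": landmarks.mv_center.tolist(),
        "aov_center_mm": landmarks.aov_center.tolist(),
    }
    if landmarks.rv_direction is not None:
        d["rv_direction"] = landmarks.rv_direction.tolist()
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def resample_mask(seg: Segmentation, target: VelocityField) -> MaskSeries:
    """Resample a segmentation onto a velocity field's grid and time base.

    Spatial resampling is voxel-center nearest neighbour; temporal resampling
    is nearest neighbour in normalized cycle time (so a 30-frame morphology
    series maps onto a 40-frame velocity series).  Target voxels whose centers
    fall outside the segmentation grid are unoccupied.
    """
    meta = target.meta
    tshape = target.spatial_shape

    # temporal: nearest source frame in normalized cycle time
    t_norm = meta.frame_times / meta.rr_interval
    s_norm = seg.frame_times / seg.rr_interval
    src_frame = np.argmin(np.abs(t_norm[:, None] - s_norm[None, :]), axis=1)

    # spatial: voxel centers at index * voxel_size
    idx = []
    inside = np.ones(tshape, dtype=bool)
    for ax in range(3):
        centers_mm = np.arange(tshape[ax]) * meta.voxel_size[ax]
        src = np.rint(centers_mm / seg.voxel_size[ax]).astype(int)
        ok = (src >= 0) & (src < seg.occupancy.shape[1 + ax])
        shape = [1, 1, 1]
        shape[ax] = tshape[ax]
        inside &= ok.reshape(shape)
        idx.append(np.clip(src, 0, seg.occupancy.shape[1 + ax] - 1))
    ii, jj, kk = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")

    occ = np.zeros((meta.n_frames,) + tuple(tshape), dtype=bool)
    for t in range(meta.n_frames):
        sf = seg.occupancy[src_frame[t]]
        if not sf.any():
            raise DomainError(f"segmentation frame {int(src_frame[t])} is empty")
        occ[t] = sf[ii, jj, kk] & inside
    return MaskSeries(occ, meta.voxel_size)


def write_force_trace(df: pd.DataFrame, path: str | Path) -> None:
    """Write a projected force-trace table (built by the pipeline) to CSV."""
    df.to_csv(path, index=False)


def write_metrics(metrics, path: str | Path) -> pd.DataFrame:
    """Write per-subject metrics (a dataclass, dict, or iterable of them) to CSV."""
    if dataclasses.is_dataclass(metrics) and not isinstance(metrics, type):
        rows = [dataclasses.asdict(metrics)]
    elif isinstance(metrics, dict):
        rows = [metrics]
    elif isinstance(metrics, pd.DataFrame):
        metrics.to_csv(path, index=False)
        return metrics
    else:
        rows = [
            dataclasses.asdict(m) if dataclasses.is_dataclass(m) else dict(m) for m in metrics
        ]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_subject(subject_dir: str | Path):
    """Read one subject directory -> (VelocityField, Segmentation, Landmarks, covariates)."""
    d = Path(subject_dir)
    single = d / "velocity.nii"
    if single.exists():
        field = read_velocity(single, d / "velocity.json")
    else:
        field = read_velocity(
            [d / "vel_x.nii", d / "vel_y.nii", d / "vel_z.nii"], d / "velocity.json"
        )
    seg = read_segmentation(d / "mask.nii", d / "mask.json")
    landmarks = read_landmarks(d / "landmarks.json")
    cov_path = d / "covariates.json"
    covariates = {}
    if cov_path.exists():
        with open(cov_path) as fh:
            covariates = json.load(fh)
    return field, seg, landmarks, covariates
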
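"""Navier-Stokes pressure gradients on the masked LV domain and their volume
integral, the global hemodynamic force.

For an incompressible Newtonian fluid with body forces excluded, the pressure
gradient is

    grad p = -rho dv/dt - rho (v . grad) v + mu laplacian(v)      [Pa/m]

computed voxelwise inside the LV mask: spatial derivatives by second-order
central differences using only in-mask neighbours, degrading to one-sided
stencils at the mask boundary, and marking a voxel invalid for a term when no
usable in-mask stencil exists (invalid voxels are excluded from integration
rather than zero-filled, which would bias the boundary contribution that
dominates the integral).  The temporal derivative is cyclic over the cardiac
cycle (retrospective gating: the last frame precedes frame 0) and is gated by
each frame's own mask.

The hemodynamic force is F(t) = + integral of grad p over the instantaneous
LV volume.  By the divergence theorem this equals the surface integral of
p n_hat with outward normal, i.e. the pressure force the blood exerts on its
surroundings (the action-reaction framing: the decelerating myocardium feels
an equal and opposite push from the blood).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .core import AcquisitionMeta, DomainError, MaskSeries, VelocityField

__all__ = [
    "PressureGradientField",
    "ForceTrace",
    "pressure_gradient",
    "integrate_force",
    "compute_force",
]


def _shift(a: np.ndarray, step: int, axis: int, fill=0):
    """Shift a 3D array so out[i] = a[i + step] along ``axis``; edges filled."""
    out = np.full_like(a, fill)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if step > 0:
        src[axis] = slice(step, None)
        dst[axis] = slice(None, -step)
    elif step < 0:
        src[axis] = slice(None, step)
        dst[axis] = slice(-step, None)
    else:
        return a.copy()
    out[tuple(dst)] = a[tuple(src)]
    return out


def _masked_d1(v: np.ndarray, mask: np.ndarray, axis: int, h: float):
    """First derivative of a 3D array using only in-mask neighbours.

    Returns (derivative, valid): central where both neighbours are in-mask,
    one-sided where one is, invalid where neither is.
    """
    vp, vm = _shift(v, 1, axis), _shift(v, -1, axis)
    mp, mm = _shift(mask, 1, axis, False), _shift(mask, -1, axis, False)
    both = mp & mm
    d = np.where(
        both,
        (vp - vm) / (2.0 * h),
        np.where(mp, (vp - v) / h, np.where(mm, (v - vm) / h, 0.0)),
    )
    return d, mp | mm


def _masked_d2(v: np.ndarray, mask: np.ndarray, axis: int, h: float):
    """Second derivative with in-mask stencils; one-sided (first-order) at the
    boundary where a same-side next-next neighbour is available."""
    vp, vm = _shift(v, 1, axis), _shift(v, -1, axis)
    vpp, vmm = _shift(v, 2, axis), _shift(v, -2, axis)
    mp, mm = _shift(mask, 1, axis, False), _shift(mask, -1, axis, False)
    mpp, mmm = _shift(mask, 2, axis, False), _shift(mask, -2, axis, False)
    h2 = h * h
    both = mp & mm
    fwd = mp & ~mm & mpp
    bwd = mm & ~mp & mmm
    d = np.where(
        both,
        (vp - 2.0 * v + vm) / h2,
        np.where(
            fwd,
            (v - 2.0 * vp + vpp) / h2,
            np.where(bwd, (v - 2.0 * vm + vmm) / h2, 0.0),
        ),
    )
    return d, both | fwd | bwd


@dataclass
class PressureGradientField:
    """Pressure-gradient field (Pa/m) with per-term decomposition.

    Validity is tracked per term (``term_valid``): a voxel whose viscous
    stencil is unavailable at the mask boundary still contributes its
    transient and convective parts — excluding it entirely would bias the
    dominant surface contribution.  ``valid`` is the conjunction, and
    ``values = transient + convective + viscous`` wherever ``valid``; each
    term carries zeros outside its own valid set.
    """

    values: np.ndarray  # [frame, 3, i, j, k]
    transient: np.ndarray
    convective: np.ndarray
    viscous: np.ndarray
    valid: np.ndarray  # [frame, i, j, k] bool, all terms available
    term_valid: dict = dc_field(default_factory=dict)  # name -> [frame, i, j, k]


@dataclass
class ForceTrace:
    """Global hemodynamic force per cardiac frame.

    ``F`` (N) has one 3-vector per frame and equals the per-frame sum of the
    term forces; ``lv_volume`` is the integrated mask volume (m^3).
    """

    times: np.ndarray  # ms
    F: np.ndarray  # [n_frames, 3] N
    terms: dict = dc_field(default_factory=dict)  # name -> [n_frames, 3]
    lv_volume: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.F)):
            raise DomainError("force trace contains non-finite values")


def pressure_gradient(
    field: VelocityField, mask: MaskSeries, include_viscous: bool = True
) -> PressureGradientField:
    """Evaluate the three Navier-Stokes terms on the masked domain."""
    meta = field.meta
    n = meta.n_frames
    if n < 2:
        raise DomainError("cannot form dv/dt from a single frame")
    if mask.n_frames != n or mask.spatial_shape != field.spatial_shape:
        raise DomainError("mask must be resampled to the velocity grid/time base")
    rho, mu = meta.rho, meta.mu
    h_m = np.asarray(meta.voxel_size) * 1e-3
    dt = meta.dt_s  # dt[t]: frame t -> t+1, cyclic

    # restrict the stencil work to a padded bounding box of the mask union
    union = mask.occupancy.any(axis=0)
    box = []
    for ax in range(3):
        hit = np.flatnonzero(union.any(axis=tuple(a for a in range(3) if a != ax)))
        box.append(slice(max(hit[0] - 2, 0), min(hit[-1] + 3, union.shape[ax])))
    box = tuple(box)
    full = (slice(None), slice(None)) + box
    v = field.values[full]
    occ = mask.occupancy[(slice(None),) + box]

    full_shape = (n, 3) + tuple(field.spatial_shape)
    transient = np.zeros(full_shape)
    convective = np.zeros(full_shape)
    viscous = np.zeros(full_shape)
    tr_c = np.zeros((n, 3) + v.shape[2:])
    cv_c = np.zeros_like(tr_c)
    vs_c = np.zeros_like(tr_c)
    tva_c = np.zeros((n,) + v.shape[2:], dtype=bool)
    cva_c = np.zeros_like(tva_c)
    lva_c = np.zeros_like(tva_c)

    for t in range(n):
        m = occ[t]
        tn, tp = (t + 1) % n, (t - 1) % n
        dtf, dtb = dt[t], dt[tp]
        mn, mp = occ[tn], occ[tp]

        # temporal term, gated by the stencil frames' masks
        both = mn & mp
        tvalid = mn | mp
        v_t = np.where(
            both[None],
            (v[tn] - v[tp]) / (dtf + dtb),
            np.where(
                mn[None],
                (v[tn] - v[t]) / dtf,
                np.where(mp[None], (v[t] - v[tp]) / dtb, 0.0),
            ),
        )
        tr_c[t] = -rho * v_t

        # spatial first derivatives -> convective term
        cvalid = np.ones_like(m)
        conv = np.zeros((3,) + m.shape)
        for c in range(3):
            for d in range(3):
                g, ok = _masked_d1(v[t, c], m, d, h_m[d])
                conv[c] += v[t, d] * g
                cvalid &= ok
        cv_c[t] = -rho * conv

        # viscous term
        if include_viscous and mu > 0:
            lvalid = np.ones_like(m)
            lap = np.zeros((3,) + m.shape)
            for c in range(3):
                for d in range(3):
                    g, ok = _masked_d2(v[t, c], m, d, h_m[d])
                    lap[c] += g
                    lvalid &= ok
            vs_c[t] = mu * lap
        else:
            lvalid = np.ones_like(m)

        tva_c[t] = m & tvalid
        cva_c[t] = m & cvalid
        lva_c[t] = m & lvalid

    # zero-fill each term outside its own valid set
    tr_c *= tva_c[:, None]
    cv_c *= cva_c[:, None]
    vs_c *= lva_c[:, None]
    transient[full] = tr_c
    convective[full] = cv_c
    viscous[full] = vs_c
    term_valid = {}
    for name, arr in (("transient", tva_c), ("convective", cva_c), ("viscous", lva_c)):
        out = np.zeros((n,) + tuple(field.spatial_shape), dtype=bool)
        out[(slice(None),) + box] = arr
        term_valid[name] = out
    return PressureGradientField(
        values=transient + convective + viscous,
        transient=transient,
        convective=convective,
        viscous=viscous,
        valid=term_valid["transient"] & term_valid["convective"] & term_valid["viscous"],
        term_valid=term_valid,
    )


def integrate_force(
    gradients: PressureGradientField, mask: MaskSeries, meta: AcquisitionMeta
) -> ForceTrace:
    """F(t) = sum over valid in-mask voxels of grad p * voxel volume, each
    Navier-Stokes term integrated over its own valid set."""
    voxvol = meta.voxel_volume_m3
    n = mask.n_frames
    counts = (gradients.term_valid["transient"] & mask.occupancy).reshape(n, -1).sum(axis=1)
    if np.any(counts == 0):
        raise DomainError(f"frame {int(np.argmax(counts == 0))} has no valid voxel to integrate")
    terms = {}
    for name in ("transient", "convective", "viscous"):
        arr = getattr(gradients, name)
        dom = gradients.term_valid[name] & mask.occupancy
        terms[name] = np.stack(
            [(arr[:, c] * dom).reshape(n, -1).sum(axis=1) * voxvol for c in range(3)], axis=1
        )
    F = terms["transient"] + terms["convective"] + terms["viscous"]
    lv_volume = mask.occupancy.reshape(n, -1).sum(axis=1) * voxvol
    return ForceTrace(times=meta.frame_times.copy(), F=F, terms=terms, lv_volume=lv_volume)


def erode_mask(mask: MaskSeries, iterations: int = 1) -> MaskSeries:
    """Peel ``iterations`` voxel shells off every frame (border-voxel
    sensitivity analysis)."""
    if iterations <= 0:
        return mask
    occ = np.stack(
        [ndimage.binary_erosion(mask.occupancy[t], iterations=iterations) for t in range(mask.n_frames)]
    )
    return MaskSeries(occ, mask.voxel_size)


def compute_force(
    field: VelocityField,
    mask: MaskSeries,
    include_viscous: bool = True,
    erode: int = 0,
) -> ForceTrace:
    """Convenience wrapper: (optional erosion) -> gradients -> integration."""
    m = erode_mask(mask, erode)
    grads = pressure_gradient(field, m, include_viscous=include_viscous)
    return integrate_force(grads, m, field.meta)
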
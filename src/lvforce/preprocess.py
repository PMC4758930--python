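"""Velocity corrections applied before the physics: aliasing (phase-wrap)
correction and polynomial background-offset removal.

Phase-contrast velocities beyond the encoding limit alias into
``[-venc, venc)`` by multiples of ``2*venc``.  The unwrap here is temporal:
each voxel/component time series is walked cyclically from a reference frame
of minimal global speed, and every frame is shifted by the multiple of
``2*venc`` (within ``{-2..2}``) that minimizes the jump from its unwrapped
predecessor.  True speeds are assumed below ``2*venc``.

Eddy-current background offsets are modelled as a time-constant polynomial of
total degree <= 4 in physical coordinates, fit per component to the
time-averaged velocity by weighted least squares.  The weight ("soft mask")
for each voxel is a Gaussian in the temporal standard deviation of its speed,
``exp(-(sd/scale)^2)``, so that static tissue dominates the fit.  The exact
weighting of the originally published correction is not public; this weight
function is this package's stand-in (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DomainError, VelocityField

__all__ = [
    "BackgroundModel",
    "unwrap_velocity",
    "static_tissue_weights",
    "fit_background",
    "apply_background",
    "preprocess",
]

DEFAULT_SD_SCALE = 0.05  # m/s, scale of the soft-mask weight function
MAX_WRAPS = 2  # candidate wrap integers in {-2..2}


def unwrap_velocity(field: VelocityField, max_wraps: int = MAX_WRAPS) -> VelocityField:
    """Correct temporal phase wraps; output values may exceed ``±venc``."""
    venc = field.meta.venc
    v = field.values
    n = field.meta.n_frames
    if n < 2:
        return field.copy()
    # reference frame: minimal mean speed over the whole volume
    speed = np.sqrt((v**2).sum(axis=1))
    ref = int(np.argmin(speed.reshape(n, -1).mean(axis=1)))

    out = v.copy()
    prev = out[ref]
    for step in range(1, n):
        t = (ref + step) % n
        k = np.rint((prev - v[t]) / (2.0 * venc))
        np.clip(k, -max_wraps, max_wraps, out=k)
        out[t] = v[t] + 2.0 * venc * k
        prev = out[t]
    return VelocityField(out, field.meta)


def wrap_velocity(field: VelocityField) -> VelocityField:
    """Alias velocities into ``[-venc, venc)`` (the inverse operation, used by
    the phantom's artifact injection)."""
    venc = field.meta.venc
    wrapped = np.mod(field.values + venc, 2.0 * venc) - venc
    return VelocityField(wrapped, field.meta)


def static_tissue_weights(field: VelocityField, sd_scale: float = DEFAULT_SD_SCALE) -> np.ndarray:
    """Per-voxel soft-mask weights in [0, 1] for the background fit.

    ``weight = exp(-(temporal SD of speed / sd_scale)^2)``: 1 for perfectly
    static voxels, ~0 for moving blood.
    """
    if field.meta.n_frames < 2:
        raise DomainError("need >= 2 frames to estimate temporal variation")
    speed = np.sqrt((field.values**2).sum(axis=1))
    sd = speed.std(axis=0)
    return np.exp(-((sd / sd_scale) ** 2))


def _poly_terms(degree: int) -> list[tuple[int, int, int]]:
    return [
        (px, py, pz)
        for px in range(degree + 1)
        for py in range(degree + 1 - px)
        for pz in range(degree + 1 - px - py)
    ]


def _design_matrix(shape, voxel_size, degree: int, half_extent_mm: np.ndarray):
    """Monomial design matrix in scaled physical coordinates.

    Coordinates are mapped to roughly [-1, 1] for conditioning; the scaling is
    stored on the model so evaluation is consistent.
    """
    coords = [
        (np.arange(shape[ax]) * voxel_size[ax] - half_extent_mm[ax]) / max(half_extent_mm[ax], 1.0)
        for ax in range(3)
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    terms = _poly_terms(degree)
    A = np.empty((X.size, len(terms)))
    for i, (px, py, pz) in enumerate(terms):
        A[:, i] = (X**px * Y**py * Z**pz).ravel()
    return A, terms


@dataclass
class BackgroundModel:
    """Per-component degree-<=4 polynomial background offsets (m/s)."""

    coefficients: np.ndarray  # [3, n_terms]
    terms: list
    degree: int
    voxel_size: tuple[float, float, float]
    shape: tuple[int, int, int]
    half_extent_mm: np.ndarray
    weights: np.ndarray  # the soft mask used for the fit
    residual_rms: np.ndarray  # [3], weighted residual RMS per component

    def evaluate(self) -> np.ndarray:
        """Offset field, axes [component, i, j, k]."""
        A, _ = _design_matrix(self.shape, self.voxel_size, self.degree, self.half_extent_mm)
        out = (A @ self.coefficients.T).T
        return out.reshape((3,) + tuple(self.shape))


def fit_background(
    field: VelocityField, static_weights: np.ndarray, degree: int = 4
) -> BackgroundModel:
    """Weighted least-squares polynomial fit to the time-averaged velocity."""
    w = np.asarray(static_weights, dtype=float)
    if w.shape != field.spatial_shape:
        raise ValueError("weights shape must match the velocity grid")
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    n_terms = len(_poly_terms(degree))
    if np.count_nonzero(w) < n_terms:
        raise DomainError(
            f"need >= {n_terms} voxels with nonzero weight for a degree-{degree} fit"
        )
    shape = field.spatial_shape
    half_extent = np.array(
        [(shape[ax] - 1) * field.meta.voxel_size[ax] / 2.0 for ax in range(3)]
    )
    A, terms = _design_matrix(shape, field.meta.voxel_size, degree, half_extent)
    sw = np.sqrt(w).ravel()
    Aw = A * sw[:, None]
    mean_v = field.values.mean(axis=0).reshape(3, -1)
    coeffs = np.empty((3, len(terms)))
    resid_rms = np.empty(3)
    wsum = (sw**2).sum()
    for c in range(3):
        sol, _, rank, _ = np.linalg.lstsq(Aw, mean_v[c] * sw, rcond=None)
        if rank < len(terms):
            raise DomainError("rank-deficient background fit (degenerate weight support)")
        coeffs[c] = sol
        r = (A @ sol - mean_v[c]) * sw
        resid_rms[c] = np.sqrt((r**2).sum() / wsum)
    return BackgroundModel(
        coefficients=coeffs,
        terms=terms,
        degree=degree,
        voxel_size=field.meta.voxel_size,
        shape=tuple(shape),
        half_extent_mm=half_extent,
        weights=w,
        residual_rms=resid_rms,
    )


def apply_background(field: VelocityField, model: BackgroundModel) -> VelocityField:
    """Subtract the evaluated polynomial offsets from every frame."""
    offset = model.evaluate()
    return VelocityField(field.values - offset[None], field.meta)


def preprocess(
    field: VelocityField,
    unwrap: bool = True,
    background: bool = True,
    degree: int = 4,
    sd_scale: float = DEFAULT_SD_SCALE,
) -> VelocityField:
    """Standard correction chain: unwrap first (wraps corrupt the temporal
    mean used by the background fit), then background removal."""
    out = field
    if unwrap:
        out = unwrap_velocity(out)
    if background:
        w = static_tissue_weights(out, sd_scale=sd_scale)
        model = fit_background(out, w, degree=degree)
        out = apply_background(out, model)
    return out
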
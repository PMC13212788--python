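"""Convective-dispersion parameter estimation from neighboring TICs (4D CUDI).

Ultrasound-contrast-agent transport is modeled locally by the
convection-diffusion equation

    dC/dt = D * laplacian(C) - v . grad(C),

with per-voxel blood velocity v (mm/s) and diffusion coefficient D (mm^2/s).
Spatiotemporal derivatives are formed by central finite differences in
physical units, and (D, v) are estimated per voxel by ordinary least squares
over a local spatiotemporal window.  A voxel is invalidated when the normal
matrix is ill-conditioned (near-constant concentration) or D comes out
negative.  Both ||v|| and D have been reported to increase in malignant
tissue, which is what makes them useful feature maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cudi_temporal import TICVolume

__all__ = ["DispersionEstimate", "estimate_convective_dispersion"]

COND_LIMIT = 1e6  # condition-number threshold for invalidation


@dataclass
class DispersionEstimate:
    """Per-voxel velocity/diffusion volumes from the window-wise regression."""

    v: np.ndarray  # (X, Y, Z, 3) mm/s
    v_mag: np.ndarray  # (X, Y, Z) mm/s
    D: np.ndarray  # (X, Y, Z) mm^2/s
    residual: np.ndarray  # normalized residual power in [0, 1]
    valid: np.ndarray  # bool


def estimate_convective_dispersion(
    ticvol: TICVolume,
    window_vox: int = 5,
    time_window_s: tuple[float, float] | None = None,
    voxel_size_mm: tuple[float, float, float] | float | None = None,
    cond_limit: float = COND_LIMIT,
) -> DispersionEstimate:
    """Least-squares (D, v) per voxel from a spatiotemporal window.

    The regression dC/dt = D*lap(C) - v.grad(C) is solved independently at
    each voxel, accumulating the normal equations over a ``window_vox``-cubed
    spatial window and the frames inside ``time_window_s`` (default: all).
    Anisotropic voxel spacing is honored by physical-unit differences.
    """
    if window_vox % 2 == 0 or window_vox < 1:
        raise ValueError("window_vox must be odd and positive")
    if any(window_vox > s for s in ticvol.grid_shape):
        raise ValueError("window larger than volume")
    if voxel_size_mm is None:
        voxel_size_mm = ticvol.voxel_size_mm
    spacing = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))

    C = ticvol.data
    t = ticvol.time_s
    if time_window_s is not None:
        sel = (t >= time_window_s[0]) & (t <= time_window_s[1])
        if sel.sum() < 3:
            raise ValueError("time window must contain at least 3 frames")
        C = C[..., sel]
        t = t[sel]

    dt = t[1] - t[0]
    dCdt = np.gradient(C, dt, axis=3)
    gx = np.gradient(C, spacing[0], axis=0)
    gy = np.gradient(C, spacing[1], axis=1)
    gz = np.gradient(C, spacing[2], axis=2)
    lap = (
        np.gradient(gx, spacing[0], axis=0)
        + np.gradient(gy, spacing[1], axis=1)
        + np.gradient(gz, spacing[2], axis=2)
    )

    # regressors x = (lap, -gx, -gy, -gz); target y = dC/dt
    regs = [lap, -gx, -gy, -gz]
    size = (window_vox,) * 3 + (C.shape[-1],)

    def wsum(a: np.ndarray) -> np.ndarray:
        # sum over the spatial window and all frames
        return ndimage.uniform_filter(
            a.sum(axis=-1), size=window_vox, mode="constant"
        ) * window_vox**3

    A = np.empty(C.shape[:3] + (4, 4))
    b = np.empty(C.shape[:3] + (4,))
    for i in range(4):
        b[..., i] = wsum(regs[i] * dCdt)
        for j in range(i, 4):
            A[..., i, j] = A[..., j, i] = wsum(regs[i] * regs[j])
    yy = wsum(dCdt * dCdt)

    eig = np.linalg.eigvalsh(A)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = eig[..., -1] / np.where(eig[..., 0] > 0, eig[..., 0], np.nan)
    ok = np.isfinite(cond) & (cond < cond_limit)

    sol = np.zeros(C.shape[:3] + (4,))
    if ok.any():
        sol[ok] = np.linalg.solve(A[ok], b[ok][..., None])[..., 0]
    D = sol[..., 0]
    v = sol[..., 1:]
    fitted_power = np.einsum("...i,...i->...", sol, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        residual = np.clip(1.0 - fitted_power / np.where(yy > 0, yy, np.nan), 0.0, 1.0)
    valid = ok & (D >= 0) & np.isfinite(residual)
    D = np.where(valid, D, np.nan)
    v = np.where(valid[..., None], v, np.nan)
    return DispersionEstimate(
        v=v,
        v_mag=np.linalg.norm(v, axis=-1),
        D=D,
        residual=np.where(valid, residual, np.nan),
        valid=valid,
    )
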
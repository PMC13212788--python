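"""Shear-wave elastography: particle velocity, speed, elasticity, stacking.

Tissue is pushed by an acoustic radiation force and the induced shear wave is
tracked as it propagates laterally.  Particle velocity is estimated from
complex IQ ensembles with the one-dimensional Loupas autocorrelator; the local
shear-wave speed (SWS) follows from the time-of-flight between adjacent
lateral positions via normalized cross-correlation with parabolic sub-sample
refinement; Young's modulus is E = 3 rho c^2 with rho = 1000 kg/m^3.
Per-plane 2D maps from a fan of planes rotated about the probe axis are
stacked and linearly interpolated in rotation angle onto the common 3D
prostate grid.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "SWEPlane",
    "ElasticityMaps",
    "RHO_KG_M3",
    "loupas_velocity",
    "sws_crosscorr",
    "stack_planes",
]

RHO_KG_M3 = 1000.0  # soft-tissue density assumption
QUALITY_FLOOR = 0.6  # minimum normalized-correlation peak for a valid voxel


@dataclass
class SWEPlane:
    """One tracked plane of the motorized sweep.

    ``particle_velocity`` is (lateral, depth, slow-time) in m/s on a uniform
    lateral grid (propagation direction, radially away from the probe) and a
    uniform slow-time axis; ``plane_pose_rad`` is the plane's rotation angle
    about the probe axis.
    """

    particle_velocity: np.ndarray
    lateral_spacing_mm: float
    frame_interval_s: float
    plane_pose_rad: float = 0.0
    lateral_origin_mm: float = 0.0
    depth_coords_mm: np.ndarray | None = None
    iq: np.ndarray | None = None  # optional (gate, lateral, depth, slow-time)


@dataclass
class ElasticityMaps:
    """Per-plane (or stacked) SWS / Young's modulus / quality maps."""

    sws: np.ndarray  # m/s, NaN where missing
    E: np.ndarray  # kPa
    quality: np.ndarray  # peak normalized cross-correlation in [0, 1]


def loupas_velocity(
    iq_ensemble: np.ndarray,
    prf_hz: float,
    f_c_hz: float,
    c_us_mps: float = 1540.0,
    aliasing_margin: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial particle velocity from slow-time lag-one autocorrelation.

    v = (c_us * PRF / (4 pi f_c)) * arg( sum_gate x[m, n+1] * conj(x[m, n]) ),
    where the sum runs over the axial gate (leading axis of the ensemble).
    Input shape is (gate, ..., slow_time) with >= 2 slow-time frames; the
    returned velocity has one fewer slow-time frame.  Also returns a boolean
    aliasing flag marking inter-frame phases within 5% of +-pi.
    """
    x = np.asarray(iq_ensemble)
    if not np.iscomplexobj(x):
        raise ValueError("IQ ensemble must be complex")
    if x.shape[-1] < 2:
        raise ValueError("need at least 2 slow-time frames")
    ac = np.sum(x[..., 1:] * np.conj(x[..., :-1]), axis=0)
    phase = np.angle(ac)
    aliased = np.abs(phase) >= aliasing_margin * np.pi
    v = c_us_mps * prf_hz * phase / (4.0 * np.pi * f_c_hz)
    return v, aliased


def _xcorr_delay(a: np.ndarray, b: np.ndarray, dt: float) -> tuple[float, float]:
    """Delay of b relative to a by normalized cross-correlation.

    Positive delay means b lags a.  Returns (delay_s, peak_correlation);
    parabolic sub-sample refinement around the integer-lag peak.
    """
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan, 0.0
    n = a.size
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    c = np.fft.irfft(np.fft.rfft(b, nfft) * np.conj(np.fft.rfft(a, nfft)), nfft)
    lags = np.concatenate([np.arange(0, n), np.arange(-(n - 1), 0)])
    c = np.concatenate([c[-(n - 1):], c[:n]])
    lags = np.concatenate([lags[-(n - 1):], lags[:n]])
    c = c / (na * nb)
    i = int(np.argmax(c))
    peak = float(c[i])
    lag = float(lags[i])
    if 0 < i < c.size - 1:
        y0, y1, y2 = c[i - 1], c[i], c[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            lag += 0.5 * (y0 - y2) / denom
    return lag * dt, min(max(peak, 0.0), 1.0)


def sws_crosscorr(plane: SWEPlane, quality_floor: float = QUALITY_FLOOR) -> ElasticityMaps:
    """Shear-wave speed per lateral pair by time-of-flight cross-correlation.

    For each depth and each adjacent lateral pair (i, i+1), the delay of the
    downstream trace gives sws = lateral_spacing / delay (assigned to position
    i); non-positive delays (reverse propagation) and correlation peaks below
    the quality floor are missing.  E = 3 rho c^2, reported in kPa.
    """
    pv = np.asarray(plane.particle_velocity, dtype=float)
    if pv.ndim != 3 or pv.shape[0] < 2:
        raise ValueError("plane must have >= 2 lateral positions and a time axis")
    n_lat, n_dep, n_t = pv.shape
    dt = plane.frame_interval_s
    dx_m = plane.lateral_spacing_mm / 1000.0

    # batched normalized cross-correlation over all (pair, depth) traces
    a = pv[:-1] - pv[:-1].mean(axis=-1, keepdims=True)
    b = pv[1:] - pv[1:].mean(axis=-1, keepdims=True)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    nfft = 1 << int(np.ceil(np.log2(2 * n_t - 1)))
    c = np.fft.irfft(
        np.fft.rfft(b, nfft, axis=-1) * np.conj(np.fft.rfft(a, nfft, axis=-1)),
        nfft, axis=-1,
    )
    # reorder to lags -(n_t-1) .. n_t-1
    c = np.concatenate([c[..., -(n_t - 1):], c[..., :n_t]], axis=-1)
    lags = np.arange(-(n_t - 1), n_t)
    denom_n = na * nb
    flat = denom_n == 0
    c = c / np.where(denom_n, denom_n, 1.0)[..., None]
    i_pk = np.argmax(c, axis=-1)
    peak = np.take_along_axis(c, i_pk[..., None], axis=-1)[..., 0]
    lag = lags[i_pk].astype(float)
    inner = (i_pk > 0) & (i_pk < c.shape[-1] - 1)
    y0 = np.take_along_axis(c, np.clip(i_pk - 1, 0, None)[..., None], axis=-1)[..., 0]
    y2 = np.take_along_axis(c, np.clip(i_pk + 1, None, c.shape[-1] - 1)[..., None], axis=-1)[..., 0]
    curv = y0 - 2 * peak + y2
    refine = inner & (curv < 0)
    lag = np.where(refine, lag + 0.5 * (y0 - y2) / np.where(curv, curv, 1.0), lag)
    delay = lag * dt
    quality_pair = np.clip(np.where(flat, 0.0, peak), 0.0, 1.0)
    valid = np.isfinite(delay) & (delay > 0) & (quality_pair >= quality_floor) & ~flat
    sws_pair = np.where(valid, dx_m / np.where(delay > 0, delay, np.nan), np.nan)

    sws = np.full((n_lat, n_dep), np.nan)
    quality = np.zeros((n_lat, n_dep))
    sws[:-1] = sws_pair
    quality[:-1] = quality_pair
    # last lateral position has no downstream partner; carry the previous pair
    sws[-1] = sws_pair[-1]
    quality[-1] = quality_pair[-1]
    E = 3.0 * RHO_KG_M3 * sws**2 / 1000.0  # kPa
    return ElasticityMaps(sws=sws, E=E, quality=quality)


def stack_planes(
    maps: list[ElasticityMaps],
    planes: list[SWEPlane],
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float,
    probe_standoff_mm: float = 10.0,
) -> dict[str, np.ndarray]:
    """Linearly interpolate per-plane maps in rotation angle onto the 3D grid.

    Each plane samples (rho, z) with rho the radial distance from the probe
    axis; a voxel's fan angle is atan2(y, x) in world coordinates.  Voxels
    outside the fan or the sampled (rho, z) footprint are missing.
    """
    if len(maps) < 2:
        raise ValueError("need at least two planes to stack")
    from .phantom import world_coordinates  # local import avoids cycle at load

    angles = np.array([p.plane_pose_rad for p in planes])
    order = np.argsort(angles)
    angles = angles[order]
    n_lat, n_dep = maps[0].sws.shape
    rho_ax = planes[0].lateral_origin_mm + np.arange(n_lat) * planes[0].lateral_spacing_mm
    z_ax = (
        planes[0].depth_coords_mm
        if planes[0].depth_coords_mm is not None
        else np.arange(n_dep) * voxel_size_mm
    )
    X, Y, Z = world_coordinates(grid_shape, voxel_size_mm, probe_standoff_mm)
    phi = np.arctan2(Y, X)
    rho = np.hypot(X, Y)
    pts = np.stack([phi.ravel(), rho.ravel(), Z.ravel()], axis=1)

    out: dict[str, np.ndarray] = {}
    for name in ("sws", "E", "quality"):
        cube = np.stack([getattr(maps[i], name) for i in order], axis=0)
        interp = RegularGridInterpolator(
            (angles, rho_ax, z_ax), cube, method="linear",
            bounds_error=False, fill_value=np.nan,
        )
        out[name] = interp(pts).reshape(grid_shape)
    return out
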
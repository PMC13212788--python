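"""Blood-velocity field from contrast arrival times, and its entropy (VE).

The arrival time tau of the contrast bolus at each voxel is the earliest time
the (fitted) TIC reaches a set fraction of its peak.  A local plane fit of tau
gives the slowness vector grad(tau) (s/mm); flow points from early to late
arrival, v_dir = -grad(tau)/||grad(tau)||, with speed v_mag = 1/||grad(tau)||.
Flow directions are quantized into azimuth x elevation bins, and the Shannon
entropy H and conditional entropy H_cond = H(center | face-adjacent neighbor)
of the direction distribution are estimated over a local window: disordered
(tumor-like) microvascular flow raises both.

Both entropies are computed from the same pooled joint histogram of
face-adjacent direction pairs inside the window (H is the center marginal's
entropy), which makes 0 <= H_cond <= H <= log2(n_bins) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cudi_temporal import TICVolume, mldrw_curve

__all__ = [
    "VelocityField",
    "EntropyMaps",
    "arrival_time_map",
    "velocity_field_from_delays",
    "velocity_entropy_maps",
]


@dataclass
class VelocityField:
    slowness: np.ndarray  # (X, Y, Z, 3) s/mm, the arrival-time gradient
    v_dir: np.ndarray  # (X, Y, Z, 3) unit vectors
    v_mag: np.ndarray  # (X, Y, Z) mm/s
    valid: np.ndarray  # bool


@dataclass
class EntropyMaps:
    H: np.ndarray  # bits
    H_cond: np.ndarray  # bits


# --------------------------------------------------------------------------
# arrival times
# --------------------------------------------------------------------------

def arrival_time_map(
    source: TICVolume | dict[str, np.ndarray],
    threshold_fraction: float = 0.5,
    time_s: np.ndarray | None = None,
    n_dense: int = 2048,
) -> np.ndarray:
    """Earliest time each TIC reaches ``threshold_fraction`` of its peak.

    Accepts either a raw :class:`TICVolume` (linear interpolation between
    frames) or a dict of mLDRW fit volumes (dense evaluation of the fitted
    curve, preferred).  Voxels with no crossing are NaN.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    if isinstance(source, dict):
        conv = source["converged"]
        tau = np.full(conv.shape, np.nan)
        if conv.any():
            k = source["kappa"][conv][:, None]
            m = source["mu"][conv][:, None]
            t0 = source["t0"][conv][:, None]
            a = source["auc"][conv][:, None]
            frac = (np.arange(1, n_dense + 1) / n_dense)[None, :]
            tg = t0 + frac * np.maximum(3.0 * m, 1.0)
            curves = mldrw_curve(tg, k, m, t0, a)
            pk = curves.max(axis=1, keepdims=True)
            idx = (curves >= threshold_fraction * pk).argmax(axis=1)
            tau[conv] = np.take_along_axis(tg, idx[:, None], axis=1)[:, 0]
        return tau

    vol = source
    y = vol.data
    t = vol.time_s
    pk = y.max(axis=-1)
    thr = threshold_fraction * pk
    above = y >= thr[..., None]
    idx = above.argmax(axis=-1)
    crossed = above.any(axis=-1) & (pk > 0)
    # linear interpolation between the frame before and the crossing frame
    i1 = idx
    i0 = np.maximum(i1 - 1, 0)
    y1 = np.take_along_axis(y, i1[..., None], axis=-1)[..., 0]
    y0 = np.take_along_axis(y, i0[..., None], axis=-1)[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.clip((thr - y0) / (y1 - y0), 0.0, 1.0)
    f = np.where((i1 > i0) & np.isfinite(f), f, 0.0)
    tau = t[i0] + f * (t[i1] - t[i0])
    tau = np.where(crossed & vol.mask, tau, np.nan)
    return tau


# --------------------------------------------------------------------------
# velocity from delays
# --------------------------------------------------------------------------

def velocity_field_from_delays(
    tau: np.ndarray,
    window_vox: int = 5,
    voxel_size_mm: float = 1.0,
    slowness_floor_s_per_mm: float = 1e-3,
) -> VelocityField:
    """Local plane fit of the arrival-time map; slowness = grad(tau).

    The fit tau ~ a + g.x is solved per voxel over a cubic window by weighted
    normal equations accumulated with box filters, honoring missing tau;
    voxels are invalid where fewer than half the window is defined or where
    ||grad tau|| falls below the resolution floor (near-constant tau means an
    unresolvably fast flow).
    """
    if window_vox % 2 == 0 or window_vox < 3:
        raise ValueError("window_vox must be odd and >= 3")
    shape = tau.shape
    m = np.isfinite(tau).astype(float)
    tz = np.nan_to_num(tau, nan=0.0)
    ax = [np.arange(n) * voxel_size_mm for n in shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    coords = [np.ones(shape), X, Y, Z]

    def box(a):
        return ndimage.uniform_filter(a, size=window_vox, mode="constant") * window_vox**3

    A = np.empty(shape + (4, 4))
    b = np.empty(shape + (4,))
    for i in range(4):
        b[..., i] = box(m * coords[i] * tz)
        for j in range(i, 4):
            A[..., i, j] = A[..., j, i] = box(m * coords[i] * coords[j])
    n_valid = box(m)
    enough = n_valid >= window_vox**3 / 2.0
    # guard the solve on voxels with a well-posed system
    eig = np.linalg.eigvalsh(A)
    solvable = enough & (eig[..., 0] > 1e-12 * np.maximum(eig[..., -1], 1e-300))
    sol = np.zeros(shape + (4,))
    if solvable.any():
        sol[solvable] = np.linalg.solve(A[solvable], b[solvable][..., None])[..., 0]
    g = sol[..., 1:]  # s/mm
    gn = np.linalg.norm(g, axis=-1)
    valid = solvable & (gn >= slowness_floor_s_per_mm)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_dir = -g / np.where(gn > 0, gn, 1.0)[..., None]
        v_mag = np.where(valid, 1.0 / gn, np.nan)
    return VelocityField(
        slowness=np.where(valid[..., None], g, np.nan),
        v_dir=np.where(valid[..., None], v_dir, np.nan),
        v_mag=v_mag,
        valid=valid,
    )


# --------------------------------------------------------------------------
# direction entropy
# --------------------------------------------------------------------------

def direction_bins(
    v_dir: np.ndarray, valid: np.ndarray, azimuth_bins: int = 8, elevation_bins: int = 3
) -> np.ndarray:
    """Quantize unit vectors into azimuth x elevation bins; -1 where invalid."""
    vd = np.nan_to_num(v_dir, nan=0.0)
    # snap numerically-zero components so axis-aligned flows always land in
    # the same bin (sign noise at the +-pi seam would otherwise split them)
    vd = np.where(np.abs(vd) < 1e-9, 0.0, vd)
    az = np.arctan2(vd[..., 1], vd[..., 0])  # (-pi, pi]
    el = np.arcsin(np.clip(vd[..., 2], -1.0, 1.0))  # [-pi/2, pi/2]
    # azimuth bins are offset by half a bin (with wraparound) so that all
    # axis-aligned directions — including the +-pi seam — fall mid-bin
    w = 2 * np.pi / azimuth_bins
    ia = np.floor((az + np.pi) / w + 0.5).astype(int) % azimuth_bins
    ie = np.clip(((el + np.pi / 2) / np.pi * elevation_bins).astype(int), 0, elevation_bins - 1)
    code = ia * elevation_bins + ie
    return np.where(valid, code, -1)


def _entropy_from_counts(counts: np.ndarray) -> np.ndarray:
    tot = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / np.where(tot > 0, tot, 1)
    return -(p * np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)).sum(axis=-1)


def velocity_entropy_maps(
    field: VelocityField,
    window_vox: int = 7,
    azimuth_bins: int = 8,
    elevation_bins: int = 3,
    min_pairs: int = 8,
) -> EntropyMaps:
    """Entropy and conditional entropy of the flow direction per voxel.

    Face-adjacent direction pairs (3 axis pairings) are pooled over the cubic
    window into a joint histogram; H is the entropy of the center marginal and
    H_cond = H(joint) - H(neighbor marginal).  Windows with fewer than
    ``min_pairs`` valid pairs are missing.
    """
    n_bins = azimuth_bins * elevation_bins
    if n_bins < 2:
        raise ValueError("need at least 2 direction bins")
    code = direction_bins(field.v_dir, field.valid, azimuth_bins, elevation_bins)
    shape = code.shape
    n_vox = code.size
    half = window_vox // 2

    counts = np.zeros((n_vox, n_bins * n_bins), dtype=np.int32)
    flat_idx = np.arange(n_vox).reshape(shape)

    # pair code volumes per axis: center code * n_bins + neighbor code
    for ax in range(3):
        c1 = code
        c2 = np.full(shape, -1, dtype=code.dtype)
        sl_src = [slice(None)] * 3
        sl_dst = [slice(None)] * 3
        sl_src[ax] = slice(1, None)
        sl_dst[ax] = slice(0, -1)
        c2[tuple(sl_dst)] = code[tuple(sl_src)]
        pair_ok = (c1 >= 0) & (c2 >= 0)
        pcode = np.where(pair_ok, c1 * n_bins + c2, -1)
        # accumulate the pair anchored at x+off into center x's histogram:
        # gather (center index, pair code) over all window offsets, then one
        # bincount on the combined index
        ci_parts: list[np.ndarray] = []
        pc_parts: list[np.ndarray] = []
        for dx in range(-half, half + 1):
            for dy in range(-half, half + 1):
                for dz in range(-half, half + 1):
                    src = [slice(None)] * 3
                    dst = [slice(None)] * 3
                    for a, d in zip(range(3), (dx, dy, dz)):
                        n = shape[a]
                        if d >= 0:
                            dst[a] = slice(0, n - d)
                            src[a] = slice(d, n)
                        else:
                            dst[a] = slice(-d, n)
                            src[a] = slice(0, n + d)
                    pc = pcode[tuple(src)]
                    ci = flat_idx[tuple(dst)]
                    sel = pc >= 0
                    if sel.any():
                        ci_parts.append(ci[sel].ravel())
                        pc_parts.append(pc[sel].ravel())
        if ci_parts:
            combined = np.concatenate(ci_parts).astype(np.int64) * (n_bins * n_bins)
            combined += np.concatenate(pc_parts)
            counts += np.bincount(
                combined, minlength=n_vox * n_bins * n_bins
            ).reshape(n_vox, n_bins * n_bins).astype(np.int32)

    # entropies only where any pair was observed (typically the organ mask)
    n_pairs_flat = counts.sum(axis=1)
    rows = np.flatnonzero(n_pairs_flat >= min_pairs)
    H = np.full(n_vox, np.nan)
    H_cond = np.full(n_vox, np.nan)
    if rows.size:
        joint = counts[rows].reshape(rows.size, n_bins, n_bins)
        h_joint = _entropy_from_counts(joint.reshape(rows.size, -1))
        h_center = _entropy_from_counts(joint.sum(axis=2))
        h_neigh = _entropy_from_counts(joint.sum(axis=1))
        H[rows] = h_center
        H_cond[rows] = np.clip(h_joint - h_neigh, 0.0, None)
    return EntropyMaps(H=H.reshape(shape), H_cond=H_cond.reshape(shape))
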
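"""Spatiotemporal TIC similarity maps (SA feature group).

In tissue whose microvasculature is disordered, time-intensity curves of
neighboring voxels become more alike; this is quantified by (i) the mean
Pearson correlation between a voxel's TIC and the TICs on a spatial ring
around it, (ii) the mean magnitude-squared spectral coherence over a frequency
band, and (iii) the mean mutual information of the amplitude pairs.  Mutual
information uses equal-frequency (quantile) binning, which makes the marginal
histograms uniform and the estimate invariant to monotone amplitude
transformations.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .cudi_temporal import TICVolume

__all__ = [
    "ring_offsets",
    "tic_correlation_map",
    "tic_coherence_map",
    "tic_mutual_information_map",
]


def ring_offsets(ring_radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Integer voxel offsets whose physical distance is within half a voxel
    of the requested ring radius."""
    if ring_radius_mm < voxel_size_mm:
        raise ValueError("ring radius must be >= voxel size")
    r_vox = ring_radius_mm / voxel_size_mm
    n = int(np.ceil(r_vox)) + 1
    g = np.arange(-n, n + 1)
    dx, dy, dz = np.meshgrid(g, g, g, indexing="ij")
    dist = np.sqrt(dx**2 + dy**2 + dz**2)
    sel = np.abs(dist - r_vox) <= 0.5
    return np.stack([dx[sel], dy[sel], dz[sel]], axis=1)


def _shifted(vol: np.ndarray, off: np.ndarray, fill=np.nan) -> np.ndarray:
    """Volume translated by an integer offset, padded with ``fill``."""
    out = np.full_like(vol, fill)
    src = [slice(None)] * vol.ndim
    dst = [slice(None)] * vol.ndim
    for ax, d in enumerate(off):
        n = vol.shape[ax]
        if abs(d) >= n:
            return out
        if d >= 0:
            dst[ax] = slice(d, n)
            src[ax] = slice(0, n - d)
        else:
            dst[ax] = slice(0, n + d)
            src[ax] = slice(-d, n)
    out[tuple(dst)] = vol[tuple(src)]
    return out


def _select_window(ticvol: TICVolume, time_window_s) -> np.ndarray:
    """Restrict the TICs to an analysis window.

    Default: from the bolus appearance (5% of the peak of the mean masked TIC)
    to 60 s later, the portion that carries the wash-in/wash-out dynamics.
    """
    t = ticvol.time_s
    if time_window_s is None:
        mean_tic = ticvol.data[ticvol.mask].mean(axis=0) if ticvol.mask.any() else ticvol.data.mean((0, 1, 2))
        peak = mean_tic.max()
        if peak > 0:
            i0 = int(np.argmax(mean_tic >= 0.05 * peak))
            time_window_s = (t[i0], t[i0] + 60.0)
        else:
            time_window_s = (t[0], t[-1])
    sel = (t >= time_window_s[0]) & (t <= time_window_s[1])
    if sel.sum() < 8:
        sel = np.ones_like(t, dtype=bool)
    return sel


def _neighbor_mean(
    ticvol: TICVolume,
    ring_radius_mm: float,
    pair_metric,
    time_window_s=None,
) -> np.ndarray:
    """Average a pairwise metric over the ring neighbors of every voxel."""
    sel = _select_window(ticvol, time_window_s)
    X = ticvol.data[..., sel]
    offsets = ring_offsets(ring_radius_mm, ticvol.voxel_size_mm)
    acc = np.zeros(ticvol.grid_shape)
    cnt = np.zeros(ticvol.grid_shape)
    maskf = ticvol.mask.astype(float)
    for off in offsets:
        Y = _shifted(X, off, fill=0.0)
        ok = ticvol.mask & (_shifted(maskf, off, fill=0.0) > 0)
        val, pair_ok = pair_metric(X, Y)
        good = ok & pair_ok
        acc[good] += val[good]
        cnt[good] += 1
    out = np.full(ticvol.grid_shape, np.nan)
    np.divide(acc, cnt, out=out, where=cnt > 0)
    return np.where(ticvol.mask, out, np.nan)


def tic_correlation_map(
    ticvol: TICVolume, ring_radius_mm: float = 2.0, time_window_s=None
) -> np.ndarray:
    """Mean Pearson correlation between each TIC and its ring neighbors.

    Pairs where either TIC has zero variance are skipped; a voxel with no
    usable pair is missing.
    """

    def metric(X, Y):
        Xc = X - X.mean(axis=-1, keepdims=True)
        Yc = Y - Y.mean(axis=-1, keepdims=True)
        sx = np.sqrt((Xc**2).sum(axis=-1))
        sy = np.sqrt((Yc**2).sum(axis=-1))
        ok = (sx > 0) & (sy > 0)
        denom = np.where(ok, sx * sy, 1.0)
        r = (Xc * Yc).sum(axis=-1) / denom
        return np.clip(r, -1.0, 1.0), ok

    return _neighbor_mean(ticvol, ring_radius_mm, metric, time_window_s)


def tic_coherence_map(
    ticvol: TICVolume,
    ring_radius_mm: float = 2.0,
    band_hz: tuple[float, float] | None = None,
    nperseg: int | None = None,
    time_window_s=None,
) -> np.ndarray:
    """Mean magnitude-squared coherence with the ring neighbors over a band.

    Welch cross-spectra with 50% overlap; the band defaults to the full
    (0, Nyquist] range and must lie within Nyquist.
    """
    fs = 1.0 / ticvol.frame_interval_s
    nyq = fs / 2.0
    if band_hz is None:
        band_hz = (0.0, nyq)
    if band_hz[1] > nyq + 1e-12 or band_hz[0] < 0:
        raise ValueError("band outside Nyquist range")

    sel = _select_window(ticvol, time_window_s)
    n_t = int(sel.sum())
    seg = nperseg if nperseg is not None else max(8, min(32, n_t // 2))
    if n_t < 2 * seg:
        seg = max(4, n_t // 2)

    # Welch cross-spectra with Hann windows and 50% overlap.  The segment
    # FFTs of the whole volume are computed once and reused for every ring
    # offset (matches scipy.signal.coherence with detrend='constant').
    X = ticvol.data[..., sel]
    step = seg // 2
    starts = np.arange(0, n_t - seg + 1, step)
    win = signal.get_window("hann", seg)
    segs = np.stack([X[..., s:s + seg] for s in starts], axis=-2)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    F = np.fft.rfft(segs * win, axis=-1)  # (x, y, z, n_seg, n_freq)
    P = (F * np.conj(F)).real.mean(axis=-2)  # auto-spectra, (x, y, z, n_freq)
    freqs = np.fft.rfftfreq(seg, d=1.0 / fs)
    inband = (freqs >= band_hz[0]) & (freqs <= band_hz[1])

    offsets = ring_offsets(ring_radius_mm, ticvol.voxel_size_mm)
    acc = np.zeros(ticvol.grid_shape)
    cnt = np.zeros(ticvol.grid_shape)
    maskf = ticvol.mask.astype(float)
    ptp_ok = np.ptp(X, axis=-1) > 0
    for off in offsets:
        Fn = _shifted(F, np.concatenate([off, [0, 0]]), fill=0.0)
        Pn = _shifted(P, np.concatenate([off, [0]]), fill=0.0)
        ok = (
            ticvol.mask & (_shifted(maskf, off, fill=0.0) > 0)
            & ptp_ok & (_shifted(ptp_ok.astype(float), off, fill=0.0) > 0)
        )
        Pxy = (F * np.conj(Fn)).mean(axis=-2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cxy = np.abs(Pxy) ** 2 / (P * Pn)
        val = np.nan_to_num(cxy[..., inband]).mean(axis=-1)
        acc[ok] += np.clip(val, 0.0, 1.0)[ok]
        cnt[ok] += 1
    out = np.full(ticvol.grid_shape, np.nan)
    np.divide(acc, cnt, out=out, where=cnt > 0)
    return np.where(ticvol.mask, out, np.nan)


def tic_mutual_information_map(
    ticvol: TICVolume,
    ring_radius_mm: float = 2.0,
    n_bins: int = 16,
    time_window_s=None,
) -> np.ndarray:
    """Mean plug-in mutual information (bits) with the ring neighbors.

    Amplitudes are quantile-binned per TIC (equal-frequency), so the marginals
    are uniform and MI = 2*log2(B) - H_joint with H_joint from the joint
    histogram over time samples.  When the window has fewer samples than
    n_bins**2 the bins are widened (with a warning) to keep the joint
    histogram populated.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    sel = _select_window(ticvol, time_window_s)
    n_t = int(sel.sum())
    B = n_bins
    if n_t < B * B:
        B = max(2, int(np.sqrt(n_t)))
        warnings.warn(
            f"{n_t} samples < n_bins^2 = {n_bins**2}: widening bins to B={B}",
            stacklevel=2,
        )

    X = ticvol.data[..., sel]
    # equal-frequency bin index per voxel: rank along time -> B quantile bins
    order = np.argsort(X, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n_t)[None, None, None, :], axis=-1)
    bins = (ranks * B) // n_t

    def metric(Xb, Yb):
        joint = (Xb * B + Yb).astype(np.int64)
        flat = joint.reshape(-1, n_t)
        n_vox = flat.shape[0]
        combined = (np.arange(n_vox)[:, None] * (B * B) + flat).ravel()
        counts = np.bincount(combined, minlength=n_vox * B * B).reshape(n_vox, B * B)
        p = counts / n_t
        with np.errstate(divide="ignore", invalid="ignore"):
            h_joint = -(p * np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)).sum(axis=-1)
        px = counts.reshape(-1, B, B).sum(axis=2) / n_t
        py = counts.reshape(-1, B, B).sum(axis=1) / n_t
        hx = -(px * np.where(px > 0, np.log2(np.where(px > 0, px, 1.0)), 0.0)).sum(axis=-1)
        hy = -(py * np.where(py > 0, np.log2(np.where(py > 0, py, 1.0)), 0.0)).sum(axis=-1)
        mi = (hx + hy - h_joint).reshape(Xb.shape[:3])
        return np.clip(mi, 0.0, None), np.ones(Xb.shape[:3], dtype=bool)

    # wrap the binned volume in a shim so _neighbor_mean shifts bin indices
    shim = TICVolume(
        bins.astype(float), ticvol.time_s[sel], mask=ticvol.mask,
        voxel_size_mm=ticvol.voxel_size_mm,
    )

    def metric_int(Xf, Yf):
        return metric(Xf.astype(np.int64), Yf.astype(np.int64))

    return _neighbor_mean(shim, ring_radius_mm, metric_int, time_window_s=(shim.time_s[0], shim.time_s[-1]))
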
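"""Voxel-wise probabilistic reference standard from sparse histology slices.

Radical-prostatectomy histology provides binary malignancy labels only on
transverse slices a few mm apart.  Between slices the probability p that a
voxel is malignant is obtained by Wiener (simple-kriging) interpolation using
the label field's isotropic autocorrelation, estimated on the slices and
fitted with an exponential decay.  On a slice, p reproduces the observed
label; far from every slice, p relaxes to the dataset prevalence prior
(about 5%).  Hard labels are p >= 0.5, and each voxel carries a confidence
weight

    w_vox = alpha / (sigma^2 + alpha),    sigma^2 = p (1 - p),  alpha = 0.2,

which down-weights uncertain voxels (p near 0.5) in the training loss and in
the confidence-weighted ROC evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "AutocorrelationModel",
    "ReferenceVolume",
    "estimate_slice_autocorrelation",
    "wiener_interpolate",
    "confidence_weights",
    "binarize_reference",
    "build_reference",
]

ALPHA_DEFAULT = 0.2  # loss-weight regularization constant
PRIOR_FLOOR = 0.01  # replaces a degenerate all-benign prior


@dataclass
class AutocorrelationModel:
    """Isotropic exponential autocorrelation rho(r) = exp(-r / length_mm).

    ``prior`` is the overall malignant fraction; ``prior_only`` marks models
    fitted from single-class slices where no correlation could be estimated.
    """

    length_mm: float
    prior: float
    lags_mm: np.ndarray = field(default_factory=lambda: np.array([]))
    empirical: np.ndarray = field(default_factory=lambda: np.array([]))
    prior_only: bool = False

    def __call__(self, r_mm: np.ndarray) -> np.ndarray:
        return np.exp(-np.asarray(r_mm, dtype=float) / self.length_mm)


def estimate_slice_autocorrelation(
    slices: list[tuple[int, np.ndarray]],
    voxel_size_mm: float,
    max_lag_mm: float | None = None,
    default_length_mm: float = 5.0,
) -> AutocorrelationModel:
    """Radial autocorrelation of the centered binary label field on the slices.

    The 2D autocorrelation of each slice (FFT-based, unnormalized lags pooled
    over slices) is radially averaged, normalized to 1 at lag 0, and fitted
    with exp(-r/L).  Slices containing a single class carry no correlation
    information; if all are single-class a prior-only model is returned, and
    an all-benign stack gets the configured prior floor with a warning.
    """
    if not slices:
        raise ValueError("no slices given")
    masks = [np.asarray(s[1], dtype=float) for s in slices]
    total = sum(m.sum() for m in masks)
    n_vox = sum(m.size for m in masks)
    prior = float(total) / float(n_vox)
    if prior <= 0.0:
        warnings.warn("all-benign slices: prior replaced by floor", stacklevel=2)
        return AutocorrelationModel(default_length_mm, PRIOR_FLOOR, prior_only=True)
    if prior >= 1.0:
        return AutocorrelationModel(default_length_mm, 1.0 - PRIOR_FLOOR, prior_only=True)

    mixed = [m for m in masks if 0 < m.sum() < m.size]
    if not mixed:
        return AutocorrelationModel(default_length_mm, prior, prior_only=True)

    num = None
    den = None
    for m in mixed:
        c = m - m.mean()
        nx, ny = c.shape
        F = np.fft.rfft2(c, s=(2 * nx, 2 * ny))
        ac = np.fft.irfft2(F * np.conj(F), s=(2 * nx, 2 * ny))
        ac = np.fft.fftshift(ac)[nx - nx // 2: nx + nx // 2, ny - ny // 2: ny + ny // 2]
        # overlap counts for unbiased normalization
        ones = np.ones_like(c)
        Fo = np.fft.rfft2(ones, s=(2 * nx, 2 * ny))
        cnt = np.fft.irfft2(Fo * np.conj(Fo), s=(2 * nx, 2 * ny))
        cnt = np.fft.fftshift(cnt)[nx - nx // 2: nx + nx // 2, ny - ny // 2: ny + ny // 2]
        num = ac if num is None else num + ac
        den = cnt if den is None else den + cnt

    nx, ny = num.shape
    yy, xx = np.meshgrid(
        (np.arange(ny) - ny // 2) * voxel_size_mm,
        (np.arange(nx) - nx // 2) * voxel_size_mm,
        indexing="xy",
    )
    r = np.hypot(xx, yy).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (num / np.maximum(den, 1.0)).ravel()
    if max_lag_mm is None:
        max_lag_mm = 0.45 * min(nx, ny) * voxel_size_mm
    bins = np.arange(0.0, max_lag_mm + voxel_size_mm, voxel_size_mm)
    which = np.digitize(r, bins) - 1
    radial = np.array([
        cov[which == i].mean() if np.any(which == i) else np.nan
        for i in range(len(bins) - 1)
    ])
    lags = 0.5 * (bins[:-1] + bins[1:])
    lags[0] = 0.0
    c0 = radial[0]
    if not np.isfinite(c0) or c0 <= 0:
        return AutocorrelationModel(default_length_mm, prior, prior_only=True)
    rho = radial / c0
    rho[0] = 1.0
    good = np.isfinite(rho) & (lags <= max_lag_mm)

    def loss(log_L):
        return np.exp(-lags[good] / np.exp(log_L)) - rho[good]

    res = optimize.least_squares(loss, np.log(default_length_mm))
    length = float(np.exp(res.x[0]))
    return AutocorrelationModel(length, prior, lags_mm=lags[good], empirical=rho[good])


# --------------------------------------------------------------------------
# Wiener / simple-kriging interpolation
# --------------------------------------------------------------------------

def wiener_interpolate(
    slices: list[tuple[int, np.ndarray]],
    model: AutocorrelationModel,
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float,
    slice_spacing_mm: float | None = None,
    support_radius_mm: float | None = None,
    jitter: float = 1e-9,
) -> np.ndarray:
    """Simple-kriging probability volume p(x) = m + k(x)' K^-1 (y - m).

    For each off-slice z-level the data are the label values of the two
    nearest slices within a local in-plane support radius (default 3
    correlation lengths).  Because the covariance is stationary and the data
    stencil is the same at every (x, y), the kriging weights are solved once
    per z-level and applied as array shifts, which makes the interpolation
    exact yet fast.  On-slice voxels reproduce their observed label exactly;
    the result is clipped to [0, 1].
    """
    if not slices:
        raise ValueError("no slices given")
    m = model.prior
    L = model.length_mm
    if support_radius_mm is None:
        support_radius_mm = 3.0 * L
    r_vox = max(int(round(support_radius_mm / voxel_size_mm)), 0)

    slice_z = np.array([s[0] for s in slices])
    fields = {int(s[0]): np.asarray(s[1], dtype=float) for s in slices}
    p = np.full(grid_shape, m)
    nz = grid_shape[2]

    # in-plane stencil offsets within the support radius
    g = np.arange(-r_vox, r_vox + 1)
    ox, oy = np.meshgrid(g, g, indexing="ij")
    keep = np.hypot(ox, oy) * voxel_size_mm <= support_radius_mm + 1e-9
    off = np.stack([ox[keep], oy[keep]], axis=1)  # (S, 2), includes (0, 0)

    def shifted_plane(f: np.ndarray, d: np.ndarray) -> np.ndarray:
        out = np.full_like(f, m)  # beyond-edge data behave as the prior
        nx, ny = f.shape
        sx = slice(max(d[0], 0), min(nx + d[0], nx))
        tx = slice(max(-d[0], 0), min(nx - d[0], nx))
        sy = slice(max(d[1], 0), min(ny + d[1], ny))
        ty = slice(max(-d[1], 0), min(ny - d[1], ny))
        out[tx, ty] = f[sx, sy]
        return out

    for z in range(nz):
        if z in fields:
            p[:, :, z] = fields[z]
            continue
        dz = np.abs(slice_z - z)
        near = slice_z[np.argsort(dz, kind="stable")[:2]]
        data_pts = []  # (slice z, dx, dy)
        for zs in near:
            for d in off:
                data_pts.append((zs, d[0], d[1]))
        n_d = len(data_pts)
        P = np.array(
            [[d[1], d[2], (d[0] - z)] for d in data_pts], dtype=float
        ) * voxel_size_mm
        diff = P[:, None, :] - P[None, :, :]
        K = model(np.linalg.norm(diff, axis=-1)) + jitter * np.eye(n_d)
        k = model(np.linalg.norm(P, axis=-1))
        try:
            w = np.linalg.solve(K, k)
        except np.linalg.LinAlgError:
            warnings.warn("singular kriging system: extra jitter applied", stacklevel=2)
            w = np.linalg.solve(K + 1e-6 * np.eye(n_d), k)
        plane = np.full(grid_shape[:2], 0.0)
        for (zs, dx, dy), wi in zip(data_pts, w):
            plane += wi * (shifted_plane(fields[int(zs)], np.array([dx, dy])) - m)
        p[:, :, z] = m + plane
    return np.clip(p, 0.0, 1.0)


def confidence_weights(p: np.ndarray, alpha: float = ALPHA_DEFAULT) -> np.ndarray:
    """w = alpha / (p(1-p) + alpha); equals 1 at p in {0, 1}, minimal at 0.5."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must lie in [0, 1]")
    return alpha / (p * (1.0 - p) + alpha)


def binarize_reference(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: 1 where p >= threshold."""
    return (np.asarray(p, dtype=float) >= threshold).astype(np.int8)


@dataclass
class ReferenceVolume:
    """Probability, label, weight and anatomy masks for one patient."""

    p: np.ndarray
    label: np.ndarray
    weight: np.ndarray
    prostate_mask: np.ndarray
    pz_mask: np.ndarray
    tz_mask: np.ndarray


def build_reference(
    slices: list[tuple[int, np.ndarray]],
    prostate_mask: np.ndarray,
    pz_mask: np.ndarray,
    tz_mask: np.ndarray,
    voxel_size_mm: float,
    alpha: float = ALPHA_DEFAULT,
    model: AutocorrelationModel | None = None,
    support_radius_mm: float | None = None,
) -> ReferenceVolume:
    """Autocorrelation fit + kriging + labels + weights in one call."""
    if model is None:
        model = estimate_slice_autocorrelation(slices, voxel_size_mm)
    p = wiener_interpolate(
        slices, model, prostate_mask.shape, voxel_size_mm,
        support_radius_mm=support_radius_mm,
    )
    return ReferenceVolume(
        p=p,
        label=binarize_reference(p),
        weight=confidence_weights(p, alpha),
        prostate_mask=prostate_mask,
        pz_mask=pz_mask,
        tz_mask=tz_mask,
    )
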
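"""Synthetic multiparametric-ultrasound phantom studies with known ground truth.

A phantom study emulates every input the clinical pipeline consumes:

* anatomy — an ellipsoidal prostate split into an inner transitional zone (TZ)
  and a posterior-weighted peripheral-zone (PZ) shell, with ellipsoidal
  lesions whose total volume is controlled to a target prevalence;
* a 4D contrast-enhanced ultrasound loop whose per-voxel time-intensity curve
  is the mLDRW bolus model with spatially smooth, tissue-class-dependent
  parameters plus additive Gaussian noise;
* an analytic convecting–diffusing Gaussian bolus field (the oracle for the
  convective-dispersion estimator);
* per-plane shear-wave particle-velocity movies (optionally complex IQ
  ensembles) with region-dependent propagation speed, on a fan of planes
  rotated about the probe axis;
* sparse binary histology slices at a fixed transverse spacing; and
* scalar clinical values (PSA, prostate volume).

Coordinates: 0-based voxel indices; world coordinates in mm with the probe at
the origin, the probe axis along z, and transverse planes orthogonal to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cudi_temporal import TICVolume, mldrw_curve
from .swe import SWEPlane

__all__ = [
    "PhantomConfig",
    "PhantomStudy",
    "PhantomError",
    "InfeasiblePrevalenceError",
    "AliasingError",
    "generate_geometry",
    "simulate_ceus_loop",
    "simulate_dispersion_field",
    "simulate_swe_planes",
    "slice_histology",
    "generate_study",
    "world_coordinates",
]


class PhantomError(RuntimeError):
    pass


class InfeasiblePrevalenceError(PhantomError):
    """The requested prevalence cannot be met with the configured lesions."""


class AliasingError(PhantomError):
    """Shear-wave pulse bandwidth incompatible with the tracking PRF."""


@dataclass
class PhantomConfig:
    """All knobs of one synthetic study; the seed makes it fully reproducible.

    Hemodynamic ranges are mLDRW parameters (kappa 1/s, mu s, t0 s, auc a.u.);
    stiffness ranges are shear-wave speeds in m/s.  Defaults give benign and
    malignant classes that are separable but overlapping.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 2.0
    probe_standoff_mm: float = 10.0
    n_lesions: int = 2
    lesion_radius_mm_range: tuple[float, float] = (4.0, 12.0)
    lesion_zone: str = "any"  # 'any' | 'pz' | 'tz'
    target_prevalence: float = 0.05  # fraction of prostate voxels malignant
    # mLDRW parameter ranges per tissue class
    hemodynamics_benign: dict = field(
        default_factory=lambda: {
            "kappa": (0.5, 1.2), "mu": (25.0, 40.0), "t0": (8.0, 14.0),
            "auc": (80.0, 140.0),
        }
    )
    hemodynamics_malignant: dict = field(
        default_factory=lambda: {
            "kappa": (1.0, 2.5), "mu": (12.0, 25.0), "t0": (5.0, 10.0),
            "auc": (120.0, 220.0),
        }
    )
    # shear-wave speed m/s per class
    stiffness_benign: tuple[float, float] = (1.3, 2.3)
    stiffness_malignant: tuple[float, float] = (2.8, 4.5)
    # spatial smoothness (Gaussian sigma, voxels) of parameter fields
    param_smoothness_benign_vox: float = 1.5
    param_smoothness_malignant_vox: float = 3.0
    # arrival-time structure: uniform flow gradient (s/mm) and in-lesion jitter (s)
    t0_gradient_s_per_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lesion_t0_jitter_s: float = 0.0
    # CEUS acquisition
    frame_interval_s: float = 1.0
    duration_s: float = 120.0
    noise_sigma: float = 0.0  # additive noise scale, linear a.u.
    # SWE acquisition
    n_swe_planes: int = 25
    swe_prf_hz: float = 4000.0
    swe_pulse_sigma_s: float = 0.0008
    swe_noise_sigma: float = 0.0
    histology_spacing_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        # sequence fields may arrive as lists (e.g. from YAML configs)
        for name in ("grid_shape", "lesion_radius_mm_range", "t0_gradient_s_per_mm",
                     "stiffness_benign", "stiffness_malignant"):
            setattr(self, name, tuple(getattr(self, name)))
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")
        if self.lesion_radius_mm_range[0] <= 0:
            raise ValueError("lesion radii must be positive")
        if self.lesion_zone not in ("any", "pz", "tz"):
            raise ValueError("lesion_zone must be 'any', 'pz' or 'tz'")


@dataclass
class PhantomStudy:
    """One synthetic patient: anatomy, acquisitions, truth maps, clinical data."""

    config: PhantomConfig
    prostate_mask: np.ndarray
    pz_mask: np.ndarray
    tz_mask: np.ndarray
    lesion_mask: np.ndarray
    ceus_loop: TICVolume | None = None
    swe_planes: list[SWEPlane] | None = None
    histology_slices: list[tuple[int, np.ndarray]] | None = None  # (z index, xy mask)
    truth_maps: dict[str, np.ndarray] = field(default_factory=dict)
    clinical: dict[str, float] = field(default_factory=dict)

    @property
    def prevalence(self) -> float:
        n = int(self.prostate_mask.sum())
        return float((self.lesion_mask & self.prostate_mask).sum()) / n if n else 0.0


def world_coordinates(
    grid_shape: tuple[int, int, int], voxel_size_mm: float, standoff_mm: float = 10.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World (mm) coordinates of voxel centers; probe at the origin.

    x is lateral (centered), y points away from the probe face (all positive,
    offset by the probe standoff), z runs along the probe axis (centered).
    """
    nx, ny, nz = grid_shape
    v = voxel_size_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * v
    y = np.arange(ny) * v + standoff_mm
    z = (np.arange(nz) - (nz - 1) / 2.0) * v
    return np.meshgrid(x, y, z, indexing="ij")


def _ellipsoid(shape, center_vox, semi_axes_vox) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    u = [(idx[d] - center_vox[d]) / semi_axes_vox[d] for d in range(3)]
    return (u[0] ** 2 + u[1] ** 2 + u[2] ** 2) <= 1.0


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def generate_geometry(config: PhantomConfig) -> PhantomStudy:
    """Masks only: prostate ellipsoid, TZ core / PZ shell, and lesions.

    Lesion radii are drawn from the configured range and rescaled (within the
    range) so the malignant fraction of prostate voxels lands within +-20%
    relative of ``target_prevalence``; an infeasible combination raises
    :class:`InfeasiblePrevalenceError` rather than silently clipping.
    """
    rng = np.random.default_rng([config.seed, 101])
    shape = config.grid_shape
    center = np.array([(s - 1) / 2.0 for s in shape])
    semi = np.array([0.40 * s for s in shape]) * np.array([1.0, 0.85, 0.92])
    prostate = _ellipsoid(shape, center, semi)
    if not prostate.any():
        raise PhantomError("grid too small for prostate")
    # TZ: inner ellipsoid shifted anteriorly (toward the probe, -y in index
    # space since y grows away from the probe face ... the prostate's anterior
    # side is the far field); PZ is the remaining posterior/lateral shell.
    tz_center = center + np.array([0.0, 0.12 * shape[1], 0.0])
    tz = _ellipsoid(shape, tz_center, semi * 0.62) & prostate
    pz = prostate & ~tz

    lesion = np.zeros(shape, dtype=bool)
    if config.n_lesions > 0:
        if config.lesion_zone == "pz":
            allowed = pz
        elif config.lesion_zone == "tz":
            allowed = tz
        else:
            allowed = prostate
        cand = np.argwhere(ndimage.binary_erosion(allowed, iterations=2))
        if cand.size == 0:
            cand = np.argwhere(allowed)
        r_lo, r_hi = config.lesion_radius_mm_range
        n_pro = prostate.sum()
        target = config.target_prevalence

        def build(centers, radii, aniso, scale: float) -> np.ndarray:
            m = np.zeros(shape, dtype=bool)
            for c, r, a in zip(centers, radii, aniso):
                ax = np.clip(r * scale, r_lo, r_hi) * a / config.voxel_size_mm
                m |= _ellipsoid(shape, c, np.maximum(ax, 0.6))
            return m & prostate

        # coarse grids quantize the achievable prevalence, so a single
        # placement can oscillate around the band: re-draw the lesion layout a
        # few times and keep the best attempt
        best_mask, best_err = None, np.inf
        for _attempt in range(6):
            centers = cand[rng.choice(len(cand), size=config.n_lesions, replace=False)]
            radii = rng.uniform(r_lo, r_hi, size=config.n_lesions)
            aniso = rng.uniform(0.8, 1.2, size=(config.n_lesions, 3))
            scale = 1.0
            for _ in range(8):
                m = build(centers, radii, aniso, scale)
                prev = m.sum() / n_pro
                err = abs(prev - target) / target
                if err < best_err:
                    best_mask, best_err = m, err
                if err <= 0.15:
                    break
                scale *= (target / max(prev, 1e-9)) ** (1.0 / 3.0)
            if best_err <= 0.15:
                break
        lesion = best_mask
        if best_err > 0.20:
            raise InfeasiblePrevalenceError(
                f"achieved prevalence {lesion.sum() / n_pro:.4f} vs target "
                f"{target:.4f} with radii in {config.lesion_radius_mm_range}"
            )
    return PhantomStudy(
        config=config, prostate_mask=prostate, pz_mask=pz, tz_mask=tz,
        lesion_mask=lesion,
    )


# --------------------------------------------------------------------------
# CEUS loop
# --------------------------------------------------------------------------

def _smooth_field(rng, shape, sigma_vox) -> np.ndarray:
    """Gaussian-filtered white noise mapped through the normal CDF to (0, 1)."""
    from scipy.special import ndtr

    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = f.std()
    return ndtr(f / sd) if sd > 0 else np.full(shape, 0.5)


def simulate_ceus_loop(study: PhantomStudy, config: PhantomConfig | None = None) -> TICVolume:
    """Per-voxel mLDRW TICs with class-dependent parameters plus noise.

    Parameter fields are spatially smooth within each tissue class; the drawn
    per-voxel parameters are recorded in ``study.truth_maps`` as
    ``true_kappa/true_mu/true_t0/true_auc``.  With ``noise_sigma = 0`` every
    TIC equals the forward model at its truth parameters exactly.
    """
    config = config or study.config
    rng = np.random.default_rng([config.seed, 202])
    shape = config.grid_shape
    t = np.arange(0.0, config.duration_s, config.frame_interval_s)

    params: dict[str, np.ndarray] = {}
    for name in ("kappa", "mu", "t0", "auc"):
        lo_b, hi_b = config.hemodynamics_benign[name]
        lo_m, hi_m = config.hemodynamics_malignant[name]
        fb = _smooth_field(rng, shape, config.param_smoothness_benign_vox)
        fm = _smooth_field(rng, shape, config.param_smoothness_malignant_vox)
        vol = lo_b + (hi_b - lo_b) * fb
        vol = np.where(study.lesion_mask, lo_m + (hi_m - lo_m) * fm, vol)
        params[name] = vol

    gx, gy, gz = config.t0_gradient_s_per_mm
    if any(config.t0_gradient_s_per_mm):
        X, Y, Z = world_coordinates(shape, config.voxel_size_mm, config.probe_standoff_mm)
        c = [a[tuple(np.array(shape) // 2)] for a in (X, Y, Z)]
        params["t0"] = params["t0"] + gx * (X - c[0]) + gy * (Y - c[1]) + gz * (Z - c[2])
    if config.lesion_t0_jitter_s > 0:
        jit = rng.uniform(-config.lesion_t0_jitter_s, config.lesion_t0_jitter_s, shape)
        params["t0"] = params["t0"] + np.where(study.lesion_mask, jit, 0.0)
    params["t0"] = np.clip(params["t0"], 0.5, None)

    worst = float(np.max((params["mu"] + params["t0"])[study.prostate_mask]))
    if config.duration_s < worst:
        warnings.warn(
            f"loop duration {config.duration_s:.0f}s shorter than mu+t0="
            f"{worst:.0f}s somewhere: wash-out truncated", stacklevel=2
        )

    data = np.zeros(shape + (t.size,))
    m = study.prostate_mask
    data[m] = mldrw_curve(
        t, params["kappa"][m], params["mu"][m], params["t0"][m], params["auc"][m]
    )
    if config.noise_sigma > 0:
        data[m] += config.noise_sigma * rng.standard_normal(data[m].shape)
        data = np.clip(data, 0.0, None)

    for name, vol in params.items():
        study.truth_maps[f"true_{name}"] = np.where(m, vol, np.nan)
    loop = TICVolume(data, t, mask=m.copy(), voxel_size_mm=config.voxel_size_mm)
    study.ceus_loop = loop
    return loop


# --------------------------------------------------------------------------
# analytic convection-diffusion field
# --------------------------------------------------------------------------

def simulate_dispersion_field(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float,
    time_s: np.ndarray,
    v_mm_s: tuple[float, float, float] = (0.0, 0.0, 0.0),
    d_mm2_s: float = 1.0,
    t_ref_s: float = 20.0,
    x0_mm: tuple[float, float, float] | None = None,
    peak: float = 1.0,
) -> tuple[TICVolume, dict[str, float | np.ndarray]]:
    """Analytic convecting–diffusing Gaussian bolus sampled on the grid.

    C(x, t) = (4 pi D (t + t_ref))^(-3/2) exp(-||x - x0 - v t||^2 /
    (4 D (t + t_ref))), rescaled so its global maximum equals ``peak``.
    Returns the TIC volume and the ground-truth (v, D).
    """
    if d_mm2_s <= 0:
        raise ValueError("diffusion coefficient D must be positive")
    time_s = np.asarray(time_s, dtype=float)
    nx, ny, nz = grid_shape
    ax = [(np.arange(n) - (n - 1) / 2.0) * voxel_size_mm for n in (nx, ny, nz)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    if x0_mm is None:
        x0_mm = (0.0, 0.0, 0.0)
    v = np.asarray(v_mm_s, dtype=float)
    data = np.empty(grid_shape + (time_s.size,))
    for i, t in enumerate(time_s):
        s = 4.0 * d_mm2_s * (t + t_ref_s)
        r2 = (
            (X - x0_mm[0] - v[0] * t) ** 2
            + (Y - x0_mm[1] - v[1] * t) ** 2
            + (Z - x0_mm[2] - v[2] * t) ** 2
        )
        data[..., i] = (np.pi * s) ** -1.5 * np.exp(-r2 / s)
    data *= peak / data.max()
    vol = TICVolume(data, time_s, voxel_size_mm=voxel_size_mm)
    return vol, {"v": v, "D": d_mm2_s}


# --------------------------------------------------------------------------
# shear-wave planes
# --------------------------------------------------------------------------

def _plane_angles(n_planes: int) -> np.ndarray:
    # fan about the probe axis covering the prostate's angular extent
    return np.linspace(np.deg2rad(35.0), np.deg2rad(145.0), n_planes)


def simulate_swe_planes(
    study: PhantomStudy,
    config: PhantomConfig | None = None,
    with_iq: bool = False,
    iq_fc_hz: float = 6e6,
    iq_c_us_mps: float = 1540.0,
) -> list[SWEPlane]:
    """Per-plane shear-wave particle-velocity movies from the true speed field.

    The true shear-wave speed field (``true_sws``, m/s) is drawn per tissue
    class (smooth within class) on first call.  Each plane lies in the fan
    about the probe axis; a Gaussian velocity pulse propagates radially away
    from the probe with the local speed, v(rho, z, t) = g(t - tau(rho, z))
    where tau accumulates the local slowness along the path.  With ``with_iq``
    the particle velocity is also encoded as slow-time IQ phase shifts
    phi = 4 pi f_c v_p / (c_us PRF) for testing the Loupas stage.
    """
    config = config or study.config
    rng = np.random.default_rng([config.seed, 303])
    shape = config.grid_shape

    if "true_sws" not in study.truth_maps:
        fb = _smooth_field(rng, shape, config.param_smoothness_benign_vox)
        fm = _smooth_field(rng, shape, config.param_smoothness_malignant_vox)
        lo_b, hi_b = config.stiffness_benign
        lo_m, hi_m = config.stiffness_malignant
        sws = lo_b + (hi_b - lo_b) * fb
        sws = np.where(study.lesion_mask, lo_m + (hi_m - lo_m) * fm, sws)
        study.truth_maps["true_sws"] = np.where(study.prostate_mask, sws, np.nan)
    sws_vol = np.nan_to_num(study.truth_maps["true_sws"], nan=float(np.mean(config.stiffness_benign)))

    prf = config.swe_prf_hz
    sig = config.swe_pulse_sigma_s
    if sig < 2.0 / prf:
        raise AliasingError(
            f"pulse sigma {sig * 1e3:.2f} ms too short for PRF {prf:.0f} Hz"
        )
    v = config.voxel_size_mm
    nx, ny, nz = shape
    X, Y, Z = world_coordinates(shape, v, config.probe_standoff_mm)
    rho_max = float(np.hypot(X, Y).max())
    rho = np.arange(0.5 * config.probe_standoff_mm, rho_max + v, v)  # mm
    zax = (np.arange(nz) - (nz - 1) / 2.0) * v
    c_min = min(config.stiffness_benign[0], config.stiffness_malignant[0])
    t_max = (rho[-1] - rho[0]) / 1000.0 / c_min + 8.0 * sig
    t = np.arange(0.0, t_max, 1.0 / prf)

    # sample the true speed on each plane by nearest-voxel lookup
    planes: list[SWEPlane] = []
    for ang in _plane_angles(config.n_swe_planes):
        px = rho * np.cos(ang)  # mm, lateral world coord
        py = rho * np.sin(ang)
        ix = np.clip(np.round(px / v + (nx - 1) / 2.0).astype(int), 0, nx - 1)
        iy = np.clip(np.round((py - config.probe_standoff_mm) / v).astype(int), 0, ny - 1)
        iz = np.clip(np.round(zax / v + (nz - 1) / 2.0).astype(int), 0, nz - 1)
        c_plane = sws_vol[ix[:, None], iy[:, None], iz[None, :]]  # (n_rho, nz)
        slowness = 1.0 / np.maximum(c_plane, 1e-3)  # s/m
        drho_m = v / 1000.0
        tau = np.concatenate(
            [np.zeros((1, nz)), np.cumsum(slowness[:-1] * drho_m, axis=0)], axis=0
        ) + 4.0 * sig
        pv = np.exp(-((t[None, None, :] - tau[..., None]) ** 2) / (2.0 * sig**2))
        pv *= 0.01  # peak particle velocity 1 cm/s
        if config.swe_noise_sigma > 0:
            pv = pv + config.swe_noise_sigma * 0.01 * rng.standard_normal(pv.shape)
        plane = SWEPlane(
            particle_velocity=pv,
            lateral_spacing_mm=v,
            frame_interval_s=1.0 / prf,
            plane_pose_rad=float(ang),
            lateral_origin_mm=float(rho[0]),
            depth_coords_mm=zax.copy(),
        )
        if with_iq:
            plane.iq = iq_from_velocity(pv, prf, iq_fc_hz, iq_c_us_mps)
        planes.append(plane)
    study.swe_planes = planes
    return planes


def iq_from_velocity(
    particle_velocity: np.ndarray,
    prf_hz: float,
    f_c_hz: float,
    c_us_mps: float,
    n_gate: int = 4,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Synthesize a complex IQ ensemble encoding particle velocity as phase.

    The inter-frame phase shift is phi = 4 pi f_c v_p / (c_us PRF); the
    ensemble has an axial gate of ``n_gate`` identical samples (leading axis)
    so gate averaging in the Loupas estimator is exercised.  Raises
    :class:`AliasingError` when |phi| >= pi anywhere.
    """
    v = np.asarray(particle_velocity, dtype=float)
    phi = 4.0 * np.pi * f_c_hz * v / (c_us_mps * prf_hz)
    if np.max(np.abs(phi)) >= np.pi:
        raise AliasingError("inter-frame phase exceeds +-pi: velocity aliases at this PRF")
    # cumulative phase along slow time; frame n carries the sum of previous shifts
    cum = np.concatenate(
        [np.zeros_like(phi[..., :1]), np.cumsum(phi[..., :-1], axis=-1)], axis=-1
    )
    iq = amplitude * np.exp(1j * cum)
    return np.broadcast_to(iq, (n_gate,) + iq.shape).copy()


# --------------------------------------------------------------------------
# histology
# --------------------------------------------------------------------------

def slice_histology(
    study: PhantomStudy, spacing_mm: float | None = None
) -> list[tuple[int, np.ndarray]]:
    """Binary lesion masks on transverse planes every ``spacing_mm`` (default 4).

    Returns (z index, xy mask) pairs; spacing below the voxel size is an error.
    """
    config = study.config
    spacing = config.histology_spacing_mm if spacing_mm is None else spacing_mm
    if spacing < config.voxel_size_mm:
        raise ValueError("histology spacing must be >= voxel size")
    step = max(int(round(spacing / config.voxel_size_mm)), 1)
    nz = config.grid_shape[2]
    slices = [(k, study.lesion_mask[:, :, k].copy()) for k in range(0, nz, step)]
    study.histology_slices = slices
    return slices


# --------------------------------------------------------------------------
# full study
# --------------------------------------------------------------------------

def generate_study(config: PhantomConfig, with_swe: bool = True) -> PhantomStudy:
    """Geometry + CEUS loop + SWE planes + histology + clinical scalars."""
    study = generate_geometry(config)
    simulate_ceus_loop(study, config)
    if with_swe:
        simulate_swe_planes(study, config)
    slice_histology(study)
    rng = np.random.default_rng([config.seed, 404])
    volume_cc = float(study.prostate_mask.sum()) * config.voxel_size_mm**3 / 1000.0
    burden = study.prevalence / max(config.target_prevalence, 1e-9)
    psa = float(np.exp(rng.normal(np.log(8.0), 0.35)) * (1.0 + 0.3 * burden))
    study.clinical = {"psa_ng_ml": psa, "volume_cc": volume_cc}
    return study
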
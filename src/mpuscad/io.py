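"""Standard-format I/O: NIfTI volumes, HDF5 4D loops and SWE movies, YAML.

Volumes live on the common prostate grid with an isotropic voxel size; the
NIfTI affine is diag(voxel, voxel, voxel, 1).  4D CEUS loops and per-plane
shear-wave movies go to HDF5 groups with their time-axis metadata; configs
and clinical scalars go to YAML sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .cudi_temporal import TICVolume
from .swe import SWEPlane

__all__ = [
    "save_volume", "load_volume", "save_feature_maps", "load_feature_maps",
    "save_ticvolume", "load_ticvolume", "save_swe_planes", "load_swe_planes",
    "save_yaml", "load_yaml",
]


def save_volume(path: str | Path, data: np.ndarray, voxel_size_mm: float = 1.0) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel = float(img.affine[0, 0])
    return np.asarray(img.get_fdata()), voxel


def save_feature_maps(
    out_dir: str | Path,
    features: dict[str, np.ndarray],
    voxel_size_mm: float,
    units: dict[str, str] | None = None,
) -> None:
    """One NIfTI per feature plus a JSON index of names and units."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = {}
    for name, vol in features.items():
        fname = f"{name}.nii.gz"
        save_volume(out / fname, vol, voxel_size_mm)
        index[name] = {"file": fname, "unit": (units or {}).get(name, "a.u.")}
    (out / "index.json").write_text(json.dumps(index, indent=2))


def load_feature_maps(out_dir: str | Path) -> dict[str, np.ndarray]:
    out = Path(out_dir)
    index = json.loads((out / "index.json").read_text())
    return {name: load_volume(out / meta["file"])[0] for name, meta in index.items()}


def save_ticvolume(group: h5py.Group, vol: TICVolume) -> None:
    group.create_dataset("data", data=vol.data.astype(np.float32), compression="gzip")
    group.create_dataset("time_s", data=vol.time_s)
    group.create_dataset("mask", data=vol.mask)
    group.attrs["voxel_size_mm"] = vol.voxel_size_mm
    group.attrs["frame_interval_s"] = vol.frame_interval_s


def load_ticvolume(group: h5py.Group) -> TICVolume:
    return TICVolume(
        data=np.asarray(group["data"], dtype=float),
        time_s=np.asarray(group["time_s"]),
        mask=np.asarray(group["mask"], dtype=bool),
        voxel_size_mm=float(group.attrs["voxel_size_mm"]),
    )


def save_swe_planes(group: h5py.Group, planes: list[SWEPlane]) -> None:
    for i, p in enumerate(planes):
        g = group.create_group(f"plane_{i:03d}")
        g.create_dataset("particle_velocity", data=p.particle_velocity.astype(np.float32),
                         compression="gzip")
        g.attrs["lateral_spacing_mm"] = p.lateral_spacing_mm
        g.attrs["frame_interval_s"] = p.frame_interval_s
        g.attrs["plane_pose_rad"] = p.plane_pose_rad
        g.attrs["lateral_origin_mm"] = p.lateral_origin_mm
        if p.depth_coords_mm is not None:
            g.create_dataset("depth_coords_mm", data=p.depth_coords_mm)


def load_swe_planes(group: h5py.Group) -> list[SWEPlane]:
    planes = []
    for key in sorted(group):
        g = group[key]
        planes.append(SWEPlane(
            particle_velocity=np.asarray(g["particle_velocity"], dtype=float),
            lateral_spacing_mm=float(g.attrs["lateral_spacing_mm"]),
            frame_interval_s=float(g.attrs["frame_interval_s"]),
            plane_pose_rad=float(g.attrs["plane_pose_rad"]),
            lateral_origin_mm=float(g.attrs["lateral_origin_mm"]),
            depth_coords_mm=np.asarray(g["depth_coords_mm"]) if "depth_coords_mm" in g else None,
        ))
    return planes


def save_yaml(path: str | Path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path: str | Path):
    return yaml.safe_load(Path(path).read_text())
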
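"""HDF5 / TIFF / JSON persistence for stacks, scenes and results.

HDF5 carries the 3D/4D data (complex stored as paired real datasets for
portability); TIFF is used only for 2D exports; CSV/JSON for tabular
results.  Every data dataset carries an ``axes`` attribute naming its
dimensions; files written with a permuted axis order are transposed back to
the canonical order on read.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Any

import h5py
import numpy as np
import tifffile

from .preprocess import InterferogramStack, SpectralStack
from .rotation import DirectorField, RotationSeries
from .synth import DomainSpec, GridSpec, SyntheticScene, TextureModel

__all__ = [
    "write_stack",
    "read_stack",
    "export_tiff",
    "save_phase_map",
    "scene_to_json",
    "scene_from_json",
]

_CANONICAL_AXES = {
    "InterferogramStack": ("y", "x", "delay"),
    "SpectralStack": ("y", "x", "wavenumber"),
    "RotationSeries": ("rotation", "y", "x", "wavenumber"),
}


def _write_axis(g: h5py.Group, name: str, values: np.ndarray, units: str) -> None:
    d = g.create_dataset(name, data=np.asarray(values))
    d.attrs["units"] = units


def write_stack(path: str, stack) -> None:
    """Write a stack to HDF5 with named axes and scale attributes."""
    with h5py.File(path, "w") as f:
        if isinstance(stack, InterferogramStack):
            f.attrs["type"] = "InterferogramStack"
            f.attrs["rotation_deg"] = stack.rotation_deg
            d = f.create_dataset("data", data=stack.data)
            d.attrs["axes"] = ",".join(_CANONICAL_AXES["InterferogramStack"])
            _write_axis(f, "delay", stack.delay_fs, "fs")
        elif isinstance(stack, SpectralStack):
            f.attrs["type"] = "SpectralStack"
            f.attrs["rotation_deg"] = stack.rotation_deg
            f.attrs["frame"] = stack.frame
            for k, v in stack.flags.items():
                f.attrs[f"flag_{k}"] = bool(v)
            for part, arr in (("data_re", stack.data.real), ("data_im", stack.data.imag)):
                d = f.create_dataset(part, data=arr)
                d.attrs["axes"] = ",".join(_CANONICAL_AXES["SpectralStack"])
            _write_axis(f, "wavenumber", stack.wavenumber, "cm^-1")
        elif isinstance(stack, RotationSeries):
            f.attrs["type"] = "RotationSeries"
            f.attrs["frame"] = stack.frame
            f.attrs["pixel_size_um"] = stack.pixel_size_um
            if stack.rot_centre_px is not None:
                f.attrs["rot_centre_px"] = list(stack.rot_centre_px)
            for part, arr in (("data_re", stack.data.real), ("data_im", stack.data.imag)):
                d = f.create_dataset(part, data=arr)
                d.attrs["axes"] = ",".join(_CANONICAL_AXES["RotationSeries"])
            _write_axis(f, "wavenumber", stack.wavenumber, "cm^-1")
            _write_axis(f, "rotation", stack.angles_deg, "deg")
        else:
            raise TypeError(f"cannot write object of type {type(stack).__name__}")


def _canonical(arr: np.ndarray, axes_attr: Any, canonical: tuple[str, ...], name: str) -> np.ndarray:
    if axes_attr is None:
        raise ValueError(f"dataset {name!r} is missing its 'axes' attribute")
    axes = tuple(str(axes_attr).split(","))
    if sorted(axes) != sorted(canonical):
        raise ValueError(f"dataset {name!r} has axes {axes}, expected a permutation of {canonical}")
    if axes == canonical:
        return arr
    return np.transpose(arr, [axes.index(a) for a in canonical])


def read_stack(path: str):
    """Read a stack written by :func:`write_stack` (axis order normalised)."""
    with h5py.File(path, "r") as f:
        kind = f.attrs.get("type")
        if kind == "InterferogramStack":
            if "delay" not in f:
                raise ValueError("missing 'delay' axis dataset")
            canon = _CANONICAL_AXES["InterferogramStack"]
            data = _canonical(f["data"][()], f["data"].attrs.get("axes"), canon, "data")
            return InterferogramStack(
                data=data, delay_fs=f["delay"][()], rotation_deg=float(f.attrs["rotation_deg"])
            )
        if kind == "SpectralStack":
            canon = _CANONICAL_AXES["SpectralStack"]
            re = _canonical(f["data_re"][()], f["data_re"].attrs.get("axes"), canon, "data_re")
            im = _canonical(f["data_im"][()], f["data_im"].attrs.get("axes"), canon, "data_im")
            if "wavenumber" not in f:
                raise ValueError("missing 'wavenumber' axis dataset")
            flags = {
                k[len("flag_"):]: bool(v) for k, v in f.attrs.items() if k.startswith("flag_")
            }
            out = SpectralStack(
                data=re + 1j * im,
                wavenumber=f["wavenumber"][()],
                frame=str(f.attrs.get("frame", "lab")),
                rotation_deg=float(f.attrs.get("rotation_deg", 0.0)),
            )
            out.flags.update(flags)
            return out
        if kind == "RotationSeries":
            canon = _CANONICAL_AXES["RotationSeries"]
            re = _canonical(f["data_re"][()], f["data_re"].attrs.get("axes"), canon, "data_re")
            im = _canonical(f["data_im"][()], f["data_im"].attrs.get("axes"), canon, "data_im")
            centre = f.attrs.get("rot_centre_px")
            return RotationSeries(
                data=re + 1j * im,
                angles_deg=f["rotation"][()],
                wavenumber=f["wavenumber"][()],
                pixel_size_um=float(f.attrs.get("pixel_size_um", 1.0)),
                rot_centre_px=tuple(centre) if centre is not None else None,
                frame=str(f.attrs.get("frame", "lab")),
            )
        raise ValueError(f"unknown or missing stack type in {path!r}: {kind}")


def export_tiff(path: str, image: np.ndarray) -> None:
    """Export a 2D (or multi-page 3D) image as float32 TIFF."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def save_phase_map(field: DirectorField, path: str, arrows=None) -> None:
    """Phase colour-map figure (hue = direction, colour-wheel legend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import hsv_to_rgb

    h = field.theta_deg / 360.0
    v = np.where(field.mask, 1.0, 0.15)
    sat = np.clip(field.magnitude / max(field.magnitude.max(), 1e-12), 0, 1)
    rgb = hsv_to_rgb(np.stack([h, np.where(field.mask, sat, 0.0), v], axis=-1))
    fig = plt.figure(figsize=(7, 4))
    ax = fig.add_subplot(1, 2, 1)
    ny, nx = field.theta_deg.shape
    half_x = (nx - 1) / 2 * field.pixel_size_um
    half_y = (ny - 1) / 2 * field.pixel_size_um
    ax.imshow(rgb, origin="lower", extent=[-half_x, half_x, -half_y, half_y])
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    if arrows is not None and len(arrows):
        ax.quiver(
            arrows["x_um"], arrows["y_um"],
            np.cos(np.deg2rad(arrows["theta_deg"])), np.sin(np.deg2rad(arrows["theta_deg"])),
            color="white", scale=25, width=0.004,
        )
    # colour wheel legend
    t = np.linspace(0, 2 * np.pi, 256)
    rr = np.linspace(0.5, 1.0, 16)
    T, R = np.meshgrid(t, rr)
    wheel = hsv_to_rgb(np.stack([T / (2 * np.pi), np.ones_like(T), np.ones_like(T)], axis=-1))
    axw = fig.add_subplot(1, 2, 2, projection="polar")
    axw.pcolormesh(T, R, np.zeros_like(T), color=wheel.reshape(-1, 3), shading="auto")
    axw.set_yticks([])
    axw.set_xticks(np.deg2rad([0, 90, 180, 270]))
    axw.set_title("molecular direction", fontsize=8)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scene_to_json(scene: SyntheticScene) -> str:
    """Serialise the scene parameters (maps are regenerated, not stored)."""

    def enc(o):
        if dataclasses.is_dataclass(o):
            return {"__type__": type(o).__name__, **dataclasses.asdict(o)}
        raise TypeError(type(o))

    return json.dumps(dataclasses.asdict(scene) | {"__type__": "SyntheticScene"},
                      default=enc, indent=2)


def scene_from_json(text: str) -> SyntheticScene:
    d = json.loads(text)
    if d.pop("__type__", None) != "SyntheticScene":
        raise ValueError("not a serialised SyntheticScene")
    grid = GridSpec(**d.pop("grid"))
    domains = []
    for dd in d.pop("domains"):
        tex = dd.pop("texture")
        tex.pop("__type__", None)
        tex["centre_um"] = tuple(tex["centre_um"])
        tex["g_deg_per_um"] = tuple(tex["g_deg_per_um"])
        dd["centre_um"] = tuple(dd["centre_um"])
        domains.append(DomainSpec(texture=TextureModel(**tex), **dd))
    d["rot_centre_um"] = tuple(d["rot_centre_um"])
    return SyntheticScene(grid=grid, domains=tuple(domains), **d)
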
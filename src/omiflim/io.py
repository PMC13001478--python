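"""Disk formats: multi-page TIFF decay cubes, label images, IRF tables,
fit-map rasters and feature tables.

Conventions: a decay cube is stored as a multi-page TIFF with one page per
time bin (page k = counts in bin k) or as an HDF5 file with one dataset per
channel; label images are single-page 16-bit TIFFs; IRFs are 2-column CSVs
(time_ps, weight); fit maps are one 32-bit float TIFF per parameter plane
plus a JSON sidecar recording bin factor, thresholds and convergence stats.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .fitting import DecayCube, PixelFitMap
from .model import BIN_WIDTH_PS, bin_centers
from .simulate import SyntheticScene


def save_cube_tiff(cube: DecayCube, path) -> None:
    """One page per time bin, uint16 (counts clipped at 65535)."""
    arr = np.moveaxis(cube.counts, 2, 0)
    tifffile.imwrite(path, np.clip(arr, 0, 65535).astype(np.uint16))


def load_cube_tiff(path, bin_width: float = BIN_WIDTH_PS, channel: str = "other") -> DecayCube:
    arr = tifffile.imread(path)
    if arr.ndim != 3:
        raise ValueError("expected a multi-page TIFF (time, rows, cols)")
    return DecayCube(np.moveaxis(arr, 0, 2).astype(np.int64), bin_width, channel)


def save_labels_tiff(label_image: np.ndarray, path) -> None:
    if label_image.max() > 65535:
        raise ValueError("more than 65535 labels do not fit a 16-bit TIFF")
    tifffile.imwrite(path, label_image.astype(np.uint16))


def load_labels_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def save_irf_csv(irf: np.ndarray, path, bin_width: float = BIN_WIDTH_PS) -> None:
    pd.DataFrame(
        {"time_ps": bin_centers(len(irf), bin_width), "weight": irf}
    ).to_csv(path, index=False)


def load_irf_csv(path) -> tuple[np.ndarray, float]:
    """Returns (unit-sum IRF, bin width in ps)."""
    df = pd.read_csv(path)
    t = df["time_ps"].to_numpy(dtype=float)
    w = df["weight"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("IRF table needs at least 2 rows")
    return w / w.sum(), float(t[1] - t[0])


def save_scene(scene: SyntheticScene, outdir) -> None:
    """Write a synthetic scene as TIFF/CSV files in ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for ch, cube in scene.cubes.items():
        save_cube_tiff(DecayCube(cube, scene.bin_width, ch), out / f"{ch}.tif")
        save_irf_csv(scene.irfs[ch], out / f"irf_{ch}.csv", scene.bin_width)
    save_labels_tiff(scene.label_image, out / "labels.tif")
    scene.truth_table.to_csv(out / "truth.csv", index=False)
    (out / "scene.json").write_text(
        json.dumps({"bin_width_ps": scene.bin_width, "rng_seed": scene.rng_seed})
    )


def save_scene_hdf5(scene: SyntheticScene, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["bin_width_ps"] = scene.bin_width
        f.attrs["rng_seed"] = scene.rng_seed
        f.create_dataset("labels", data=scene.label_image, compression="gzip")
        for ch, cube in scene.cubes.items():
            f.create_dataset(f"cubes/{ch}", data=cube, compression="gzip")
            f.create_dataset(f"irfs/{ch}", data=scene.irfs[ch])


def load_scene_hdf5(path) -> dict:
    """Load cubes/irfs/labels back; the truth table is not stored in HDF5."""
    with h5py.File(path, "r") as f:
        bw = float(f.attrs["bin_width_ps"])
        out = {
            "bin_width": bw,
            "rng_seed": int(f.attrs["rng_seed"]),
            "label_image": f["labels"][()].astype(np.int32),
            "cubes": {
                ch: DecayCube(f[f"cubes/{ch}"][()], bw, ch) for ch in f["cubes"]
            },
            "irfs": {ch: f[f"irfs/{ch}"][()] for ch in f["irfs"]},
        }
    return out


def save_fitmap(fitmap: PixelFitMap, outdir, channel: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for plane in PixelFitMap.PARAM_PLANES:
        tifffile.imwrite(
            out / f"{channel}_{plane}.tif", getattr(fitmap, plane).astype(np.float32)
        )
    tifffile.imwrite(out / f"{channel}_n_photons.tif", fitmap.n_photons.astype(np.float32))
    tifffile.imwrite(out / f"{channel}_valid.tif", fitmap.valid_mask.astype(np.uint8))
    sidecar = {
        "channel": channel,
        "bin_factor": fitmap.bin_factor,
        "min_photons": fitmap.min_photons,
        "n_pixels_fit": int(fitmap.valid_mask.sum()),
        "n_pixels_converged": int(fitmap.converged.sum()),
    }
    (out / f"{channel}_fit.json").write_text(json.dumps(sidecar, indent=2))


def load_fitmap(outdir, channel: str) -> PixelFitMap:
    out = Path(outdir)
    sidecar = json.loads((out / f"{channel}_fit.json").read_text())
    planes = {
        plane: tifffile.imread(out / f"{channel}_{plane}.tif").astype(float)
        for plane in PixelFitMap.PARAM_PLANES
    }
    valid = tifffile.imread(out / f"{channel}_valid.tif").astype(bool)
    return PixelFitMap(
        **planes,
        n_photons=tifffile.imread(out / f"{channel}_n_photons.tif").astype(np.int64),
        converged=valid,
        valid_mask=valid,
        bin_factor=sidecar["bin_factor"],
        min_photons=sidecar["min_photons"],
    )
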
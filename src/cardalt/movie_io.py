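"""Reading and writing mapping movies (HDF5 container or per-channel TIFF).

The HDF5 layout is one file per recording with datasets ``/calcium``,
``/voltage`` (optional) and ``/mask``, and root attributes
``frame_rate_hz``, ``bcl_ms``, ``pacing_times_ms``, ``fov_mm`` and
``condition``.  The TIFF dialect writes one multi-page file per channel
(pages are frames) plus a JSON sidecar carrying the metadata and mask.
Ground truth, when present, goes to a ``<stem>.truth.json`` sidecar.
Both round-trip bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .mapping import MappingMovie

FOV_MM_DEFAULT = (7.0, 7.0)


def _truth_jsonable(truth: dict) -> dict:
    return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in truth.items()}


def load_truth(path: Path | str) -> dict:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: (np.asarray(v) if isinstance(v, list) else v)
            for k, v in raw.items()}


def write_movie_h5(path: Path | str, movie: MappingMovie,
                   truth: dict | None = None,
                   fov_mm: tuple[float, float] = FOV_MM_DEFAULT) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("calcium", data=movie.calcium)
        if movie.voltage is not None:
            fh.create_dataset("voltage", data=movie.voltage)
        if movie.bz_mask is not None:
            fh.create_dataset("mask", data=movie.bz_mask)
        fh.attrs["frame_rate_hz"] = movie.frame_rate
        fh.attrs["bcl_ms"] = movie.bcl
        fh.attrs["pacing_times_ms"] = movie.pacing_times
        fh.attrs["fov_mm"] = fov_mm
        fh.attrs["condition"] = movie.condition_label
    if truth is not None:
        truth_path = path.with_suffix(".truth.json")
        truth_path.write_text(json.dumps(_truth_jsonable(truth)))
    return path


def read_movie_h5(path: Path | str) -> MappingMovie:
    with h5py.File(path, "r") as fh:
        movie = MappingMovie(
            calcium=fh["calcium"][()],
            voltage=fh["voltage"][()] if "voltage" in fh else None,
            bz_mask=fh["mask"][()].astype(bool) if "mask" in fh else None,
            frame_rate=float(fh.attrs["frame_rate_hz"]),
            bcl=float(fh.attrs["bcl_ms"]),
            pacing_times=np.asarray(fh.attrs["pacing_times_ms"], dtype=float),
            condition_label=str(fh.attrs.get("condition", "control")))
    return movie


def write_movie_tiff(stem: Path | str, movie: MappingMovie,
                     truth: dict | None = None,
                     fov_mm: tuple[float, float] = FOV_MM_DEFAULT) -> list[Path]:
    """Write ``<stem>.calcium.tif`` (+ voltage), metadata JSON sidecar."""
    stem = Path(stem)
    written = []
    for name, stack in (("calcium", movie.calcium), ("voltage", movie.voltage)):
        if stack is None:
            continue
        p = stem.with_suffix(f".{name}.tif")
        # pages = time; tifffile expects (frames, rows, cols)
        tifffile.imwrite(p, np.moveaxis(stack, -1, 0))
        written.append(p)
    meta = {
        "frame_rate_hz": movie.frame_rate,
        "bcl_ms": movie.bcl,
        "pacing_times_ms": movie.pacing_times.tolist(),
        "fov_mm": list(fov_mm),
        "condition": movie.condition_label,
        "mask": movie.bz_mask.tolist() if movie.bz_mask is not None else None,
    }
    meta_path = stem.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(meta))
    written.append(meta_path)
    if truth is not None:
        tp = stem.with_suffix(".truth.json")
        tp.write_text(json.dumps(_truth_jsonable(truth)))
        written.append(tp)
    return written


def read_movie_tiff(stem: Path | str) -> MappingMovie:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".meta.json").read_text())
    ca = np.moveaxis(tifffile.imread(stem.with_suffix(".calcium.tif")), 0, -1)
    vpath = stem.with_suffix(".voltage.tif")
    voltage = np.moveaxis(tifffile.imread(vpath), 0, -1) if vpath.exists() else None
    mask = meta.get("mask")
    return MappingMovie(
        calcium=ca, voltage=voltage,
        bz_mask=np.asarray(mask, dtype=bool) if mask is not None else None,
        frame_rate=float(meta["frame_rate_hz"]), bcl=float(meta["bcl_ms"]),
        pacing_times=np.asarray(meta["pacing_times_ms"], dtype=float),
        condition_label=meta.get("condition", "control"))


def read_movie(path: Path | str) -> MappingMovie:
    """Dispatch on extension: ``.h5``/``.hdf5`` container or TIFF stem."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return read_movie_h5(path)
    return read_movie_tiff(path)
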
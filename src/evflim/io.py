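"""Readers and writers for decay stacks, label masks, and result tables.

Two interchange dialects are supported for decay stacks:

* **HDF5** (canonical): dataset ``/counts`` (uint32, row x col x time) with
  attributes ``bin_width_ps``, ``period_ps``, ``origin_ps``,
  ``pixel_size_um``, ``frames_accumulated``, ``fov_id``.
* **multi-page TIFF**: one page per time bin, with a JSON sidecar
  ``<name>.json`` carrying the same attribute names.

Masks are single-page TIFFs with a JSON legend sidecar.  All integer data
round-trips bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .datamodel import DecayStack, LabelMask, TimeAxis

__all__ = [
    "save_decay_stack",
    "load_decay_stack",
    "save_mask",
    "load_mask",
    "ev_records_to_frame",
    "save_ev_records",
    "load_ev_records",
]

_STACK_ATTRS = (
    "bin_width_ps",
    "period_ps",
    "origin_ps",
    "pixel_size_um",
    "frames_accumulated",
    "fov_id",
)

_HDF5_SUFFIXES = {".h5", ".hdf5"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _stack_attrs(stack: DecayStack) -> dict:
    return {
        "bin_width_ps": float(stack.axis.bin_width_ps),
        "period_ps": float(stack.axis.period_ps),
        "origin_ps": float(stack.axis.origin_ps),
        "pixel_size_um": float(stack.pixel_size_um),
        "frames_accumulated": int(stack.frames_accumulated),
        "fov_id": str(stack.fov_id),
    }


def save_decay_stack(stack: DecayStack, path: str | Path) -> Path:
    """Write a stack as HDF5 (.h5/.hdf5) or multi-page TIFF + JSON sidecar."""
    path = Path(path)
    counts = np.ascontiguousarray(stack.counts)
    if counts.max(initial=0) > np.iinfo(np.uint32).max:
        raise ValueError("counts exceed uint32 range")
    counts = counts.astype(np.uint32)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as f:
            dset = f.create_dataset("counts", data=counts, compression="gzip", compression_opts=4)
            for k, v in _stack_attrs(stack).items():
                dset.attrs[k] = v
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        # pages indexed by time bin
        tifffile.imwrite(path, np.moveaxis(counts, 2, 0), photometric="minisblack")
        meta = _stack_attrs(stack)
        meta["n_bins"] = int(stack.axis.n_bins)
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unsupported stack format {path.suffix!r}; use .h5 or .tif")
    return path


def _require(meta: dict, field: str, path: Path):
    if field not in meta:
        raise ValueError(f"{path}: missing metadata field {field!r}")
    return meta[field]


def _build_stack(counts: np.ndarray, meta: dict, path: Path) -> DecayStack:
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.all(counts == np.round(counts)):
            raise ValueError(f"{path}: non-integer photon counts")
        counts = counts.astype(np.int64)
    if counts.size and counts.min() < 0:
        raise ValueError(f"{path}: negative photon counts")
    axis = TimeAxis(
        bin_width_ps=float(_require(meta, "bin_width_ps", path)),
        n_bins=counts.shape[2],
        period_ps=float(_require(meta, "period_ps", path)),
        origin_ps=float(_require(meta, "origin_ps", path)),
    )
    return DecayStack(
        counts=counts,
        axis=axis,
        pixel_size_um=float(_require(meta, "pixel_size_um", path)),
        frames_accumulated=int(_require(meta, "frames_accumulated", path)),
        fov_id=str(_require(meta, "fov_id", path)),
    )


def load_decay_stack(path: str | Path) -> DecayStack:
    """Load a stack saved by :func:`save_decay_stack` (either dialect)."""
    path = Path(path)
    if path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as f:
            if "counts" not in f:
                raise ValueError(f"{path}: missing /counts dataset")
            dset = f["counts"]
            counts = dset[...]
            meta = {k: dset.attrs[k] for k in dset.attrs}
        return _build_stack(counts, meta, path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"{path}: missing JSON sidecar {sidecar.name}")
        meta = json.loads(sidecar.read_text())
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        declared = int(_require(meta, "n_bins", sidecar))
        if pages.shape[0] != declared:
            raise ValueError(
                f"{path}: has {pages.shape[0]} pages but sidecar declares "
                f"n_bins={declared}"
            )
        counts = np.moveaxis(pages, 0, 2)
        return _build_stack(counts, meta, path)
    raise ValueError(f"unsupported stack format {path.suffix!r}")


def save_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a label mask as single-page TIFF with a JSON legend sidecar."""
    path = Path(path)
    labels = np.asarray(mask.labels)
    if labels.max(initial=0) > np.iinfo(np.uint32).max:
        raise ValueError("labels exceed uint32 range")
    tifffile.imwrite(path, labels.astype(np.uint32), photometric="minisblack")
    legend = {str(int(k)): str(v) for k, v in mask.legend.items()}
    _sidecar_path(path).write_text(json.dumps({"legend": legend}, indent=1))
    return path


def load_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"{path}: missing JSON sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    legend = {int(k): str(v) for k, v in meta.get("legend", {}).items()}
    labels = tifffile.imread(path)
    return LabelMask(labels=labels.astype(np.int64), legend=legend)


_EV_COLUMNS = [
    "fov_id",
    "ev_id",
    "row",
    "col",
    "n_pixels",
    "photons",
    "g",
    "s",
    "tau_ns",
    "f_bound",
    "clamped",
]


def ev_records_to_frame(records: Sequence) -> pd.DataFrame:
    """Tabulate :class:`~evflim.ev.EVRecord` objects, one row per EV."""
    rows = [
        {
            "fov_id": r.fov_id,
            "ev_id": r.ev_id,
            "row": r.centroid[0],
            "col": r.centroid[1],
            "n_pixels": r.n_pixels,
            "photons": r.photons,
            "g": r.phasor.g,
            "s": r.phasor.s,
            "tau_ns": r.tau_ns,
            "f_bound": r.f_bound,
            "clamped": r.clamped,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_EV_COLUMNS)


def save_ev_records(records: Sequence, path: str | Path) -> Path:
    path = Path(path)
    ev_records_to_frame(records).to_csv(path, index=False)
    return path


def load_ev_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
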
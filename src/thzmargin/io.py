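"""File-format round-tripping: HDF5 cubes, TIFF/PNG maps and masks, CSV/JSON
summaries, provenance records."""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from . import __version__
from .errors import ValidationError
from .inversion import FieldCube, IndexMap, SpectralTrace

__all__ = [
    "save_cube",
    "load_cube",
    "save_index_map",
    "load_index_map",
    "save_mask",
    "load_mask",
    "save_roc_csv",
    "save_json",
    "load_json",
    "write_provenance",
]


def save_cube(path, cube: FieldCube, reference: SpectralTrace) -> None:
    """Field cube + reference trace as HDF5 (real/imag split datasets)."""
    if not np.allclose(cube.frequencies, reference.frequencies):
        raise ValidationError("cube and reference must share one frequency axis")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("frequencies", data=cube.frequencies)
        fh.create_dataset("field_real", data=cube.field.real)
        fh.create_dataset("field_imag", data=cube.field.imag)
        fh.create_dataset("reference_real", data=reference.field.real)
        fh.create_dataset("reference_imag", data=reference.field.imag)
        fh.attrs["pixel_pitch"] = cube.pixel_pitch


def load_cube(path) -> tuple[FieldCube, SpectralTrace]:
    with h5py.File(path, "r") as fh:
        freqs = fh["frequencies"][()]
        field = fh["field_real"][()] + 1j * fh["field_imag"][()]
        ref = fh["reference_real"][()] + 1j * fh["reference_imag"][()]
        pitch = float(fh.attrs.get("pixel_pitch", 1.0))
    return FieldCube(freqs, field, pixel_pitch=pitch), SpectralTrace(freqs, ref)


def save_index_map(path, index_map: IndexMap) -> None:
    """32-bit float TIFF (values, kappa, support as pages) + JSON sidecar."""
    path = Path(path)
    pages = [index_map.values.astype(np.float32)]
    if index_map.kappa is not None:
        pages.append(index_map.kappa.astype(np.float32))
    pages.append(index_map.support.astype(np.float32))
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    sidecar = {"frequency": index_map.frequency, "mode": index_map.mode,
               "has_kappa": index_map.kappa is not None}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_index_map(path) -> IndexMap:
    path = Path(path)
    stack = tifffile.imread(path).astype(float)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    if sidecar.get("has_kappa", False):
        values, kappa, support = stack[0], stack[1], stack[2]
    else:
        values, kappa, support = stack[0], None, stack[1]
    return IndexMap(values=values, frequency=float(sidecar["frequency"]),
                    support=support > 0.5, kappa=kappa,
                    mode=sidecar.get("mode", "complex"))


def save_mask(path, mask: np.ndarray) -> None:
    """8-bit PNG/TIFF: 0 = benign/outside, 255 = malignant/inside."""
    data = (np.asarray(mask, dtype=bool) * np.uint8(255))
    iio.imwrite(Path(path), data)


def load_mask(path) -> np.ndarray:
    data = np.asarray(iio.imread(Path(path)))
    if data.ndim == 3:
        data = data[..., 0]
    return data > 127


def save_roc_csv(path, curve) -> None:
    """Per-threshold table: threshold, counts, tpr, fpr, youden."""
    import pandas as pd

    rows = []
    for p in curve.points:
        c = p.counts
        rows.append({
            "threshold": p.threshold,
            "tp": c.tp if c else "", "fp": c.fp if c else "",
            "tn": c.tn if c else "", "fn": c.fn if c else "",
            "tpr": p.tpr, "fpr": p.fpr, "youden": p.youden,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def save_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def write_provenance(path, config: dict) -> None:
    """Provenance record next to every CLI output: config, its hash, version."""
    blob = json.dumps(config, sort_keys=True, default=_jsonable)
    save_json(path, {
        "config": json.loads(blob),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "package_version": __version__,
    })
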
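"""File-format helpers for the command-line layer.

CSV is the canonical exchange format for tabular data (observations,
profiles, solutions, spectra); TIFF stacks carry 3D masks/skeletons and 2D
element maps; metadata travels in small JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .chem import XRFMap
from .xanes import Spectrum


def read_volume(path) -> np.ndarray:
    """Read a 3D TIFF stack as a numpy array."""
    return np.asarray(tifffile.imread(path))


def write_volume(path, volume: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(volume))


def read_map(path) -> np.ndarray:
    """Read a single-channel 2D map from TIFF or CSV."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return np.asarray(tifffile.imread(path), float)
    return pd.read_csv(path, header=None).to_numpy(dtype=float)


def read_xrf_maps(paths: dict[str, str], meta_path) -> XRFMap:
    """Assemble an `XRFMap` from per-element files and a JSON metadata block.

    Metadata keys: ``pixel_size_um`` (required), ``units`` and ``affine``
    (3x4 row-major list) optional.
    """
    meta = json.loads(Path(meta_path).read_text())
    elements = {el: read_map(p) for el, p in paths.items()}
    kwargs = {"pixel_size_um": float(meta["pixel_size_um"])}
    if "units" in meta:
        kwargs["units"] = meta["units"]
    if "affine" in meta:
        kwargs["affine"] = np.asarray(meta["affine"], float).reshape(3, 4)
    return XRFMap(elements=elements, **kwargs)


def read_spectrum(path, **kw) -> Spectrum:
    return Spectrum.from_csv(path, **kw)


def load_spectra_library(directory, edge: str = "S-K") -> dict[str, Spectrum]:
    """Load every ``*.csv`` in a directory as a named standard spectrum."""
    out = {}
    for path in sorted(Path(directory).glob("*.csv")):
        out[path.stem] = Spectrum.from_csv(path, edge=edge, name=path.stem)
    if not out:
        raise FileNotFoundError(f"no spectra found in {directory}")
    return out


def read_annotations(path) -> pd.DataFrame:
    """Sidecar annotations: columns file, distance_um[, group]."""
    table = pd.read_csv(path)
    if "file" not in table.columns or "distance_um" not in table.columns:
        raise ValueError("annotations need 'file' and 'distance_um' columns")
    return table


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
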
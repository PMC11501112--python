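"""Artifact export: PSF stacks, MTF curves, mask maps, sidecar metadata."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .optics_core import MTFCurve, PSFStack

__all__ = ["save_psf_stack", "save_mtf_csv", "save_map", "write_sidecar",
           "config_hash"]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration dict."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_sidecar(path, metadata: dict) -> None:
    Path(str(path) + ".meta.json").write_text(json.dumps(metadata, indent=2,
                                                         default=str))


def save_psf_stack(stack: PSFStack, path, metadata: dict | None = None) -> None:
    """Multi-page 32-bit float TIFF, one page per depth."""
    pages = np.stack(stack.psfs).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack",
                     metadata={"depths_m": list(stack.depths)})
    if metadata:
        write_sidecar(path, metadata)


def save_mtf_csv(mtf: MTFCurve, path, metadata: dict | None = None) -> None:
    """Radially averaged MTF as CSV (frequency in cycles/m)."""
    pd.DataFrame({"frequency_cyc_per_m": mtf.radial_frequencies,
                  "mtf": mtf.radial}).to_csv(path, index=False)
    if metadata:
        write_sidecar(path, metadata)


def save_map(array: np.ndarray, path, metadata: dict | None = None) -> None:
    """Height or radius map (meters) as 32-bit TIFF or CSV by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, array.astype(np.float32),
                         photometric="minisblack")
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, array, delimiter=",")
    else:
        raise ValueError(f"unsupported map format {path.suffix!r}")
    if metadata:
        write_sidecar(path, metadata)
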
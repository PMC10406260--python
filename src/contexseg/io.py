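"""File formats: NIfTI images, PNG previews, CSV manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np


def save_nifti(array: np.ndarray, path: str | Path) -> Path:
    """Write a 2D array as a single-slice RAS NIfTI volume."""
    arr = np.asarray(array)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    img = nib.Nifti1Image(arr.astype(np.float32), affine=np.eye(4))
    path = Path(path)
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> np.ndarray:
    """Read a NIfTI file; single-slice volumes come back as 2D."""
    arr = np.asarray(nib.load(str(path)).dataobj)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    return arr


def save_png(array: np.ndarray, path: str | Path, cmap: str = "gray") -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(np.asarray(array), cmap=cmap)
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
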
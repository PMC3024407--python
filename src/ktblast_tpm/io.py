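"""NIfTI / CSV / JSON readers and writers for phantom, image and curve data.

Encoded and reconstructed cines are written as 4-D NIfTI stacks (one file
per encoding segment, complex64, dims x-y-1-t) with a JSON sidecar carrying
VENC, the encoding order, sign conventions and the seed/background used.
Masks are uint8 NIfTI; curves tidy CSV; features JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import EncodedCine, PhantomCine
from .quantify import VelocityCurve

__all__ = [
    "save_image_series",
    "load_image_series",
    "save_encoded_cine",
    "load_encoded_cine",
    "save_masks",
    "load_masks",
    "curves_to_csv",
    "curves_from_csv",
]

_SIGN_CONVENTIONS = {
    "radial": "positive toward the blood-pool centroid (systolic contraction positive)",
    "longitudinal": "positive toward the apex",
}


def _affine(pixel_mm=(2.0, 2.0)) -> np.ndarray:
    return np.diag([pixel_mm[0], pixel_mm[1], 1.0, 1.0])


def save_image_series(path: str | Path, images: np.ndarray, pixel_mm=(2.0, 2.0)) -> None:
    """Write one encoding's (n_phases, ny, nx) complex series as 4-D NIfTI."""
    arr = np.moveaxis(np.asarray(images, dtype=np.complex64), 0, -1)[:, :, None, :]
    nib.save(nib.Nifti1Image(arr, _affine(pixel_mm)), str(path))


def load_image_series(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    return np.moveaxis(arr[:, :, 0, :], -1, 0)


def save_encoded_cine(
    out_dir: str | Path,
    enc: EncodedCine,
    ph: PhantomCine | None = None,
    seed: int | None = None,
    prefix: str = "encoded",
) -> None:
    """One NIfTI per encoding segment plus JSON sidecar (and masks if given)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pixel = ph.pixel_mm if ph is not None else (2.0, 2.0)
    for e, name in enumerate(enc.encoding_order):
        save_image_series(out / f"{prefix}_{name}.nii", enc.images[e], pixel)
    sidecar = {
        "venc_cm_s": enc.venc_cm_s,
        "encoding_order": list(enc.encoding_order),
        "background_coeffs_rad": list(enc.background_coeffs),
        "sign_conventions": _SIGN_CONVENTIONS,
        "seed": seed,
    }
    if ph is not None:
        sidecar.update(
            n_phases=ph.n_phases,
            matrix=list(ph.matrix),
            pixel_mm=list(ph.pixel_mm),
            centroid=list(ph.centroid),
            rr_ms=ph.rr_ms,
            times_frac=[float(t) for t in ph.times_frac],
        )
        save_masks(out, ph, prefix=prefix)
    (out / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


def load_encoded_cine(out_dir: str | Path, prefix: str = "encoded") -> tuple[EncodedCine, dict]:
    out = Path(out_dir)
    sidecar = json.loads((out / f"{prefix}.json").read_text())
    images = np.stack(
        [load_image_series(out / f"{prefix}_{name}.nii") for name in sidecar["encoding_order"]]
    )
    enc = EncodedCine(
        images=images,
        venc_cm_s=sidecar["venc_cm_s"],
        background_coeffs=tuple(sidecar["background_coeffs_rad"]),
        encoding_order=tuple(sidecar["encoding_order"]),
    )
    return enc, sidecar


def save_masks(out_dir: str | Path, ph: PhantomCine, prefix: str = "encoded") -> None:
    out = Path(out_dir)
    aff = _affine(ph.pixel_mm)
    myo = np.moveaxis(ph.myo_mask.astype(np.uint8), 0, -1)[:, :, None, :]
    nib.save(nib.Nifti1Image(myo, aff), str(out / f"{prefix}_myo_mask.nii"))
    static = ph.static_mask.astype(np.uint8)[:, :, None]
    nib.save(nib.Nifti1Image(static, aff), str(out / f"{prefix}_static_mask.nii"))


def load_masks(out_dir: str | Path, prefix: str = "encoded") -> tuple[np.ndarray, np.ndarray]:
    out = Path(out_dir)
    myo = np.asarray(nib.load(str(out / f"{prefix}_myo_mask.nii")).dataobj)
    static = np.asarray(nib.load(str(out / f"{prefix}_static_mask.nii")).dataobj)
    return np.moveaxis(myo[:, :, 0, :], -1, 0).astype(bool), static[:, :, 0].astype(bool)


def curves_to_csv(path: str | Path, curves: dict[str, VelocityCurve], **labels) -> None:
    """Tidy CSV of the per-phase samples of each direction's curve."""
    rows = []
    for direction, c in curves.items():
        for t, v in zip(c.t_ms, c.v_cm_s):
            rows.append({"direction": direction, "t_ms": t, "v_cm_s": v, **labels})
    pd.DataFrame(rows).to_csv(path, index=False)


def curves_from_csv(path: str | Path) -> dict[str, VelocityCurve]:
    df = pd.read_csv(path)
    out = {}
    for direction, g in df.groupby("direction"):
        g = g.sort_values("t_ms")
        out[str(direction)] = VelocityCurve(
            str(direction), g["t_ms"].to_numpy(), g["v_cm_s"].to_numpy()
        )
    return out
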
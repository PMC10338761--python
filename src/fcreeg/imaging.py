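"""Rendering connectivity matrices as FCR images.

An FCR (functional connectivity representation) is the image form of a
16x16 PLI matrix: the matrix is upsampled to a 342x342 scalar field,
mapped through a fixed colormap on the fixed value range [0, 1], and
later resized to the 224x224 network input size.  The value range is
deliberately *not* normalized per image — between-class differences in
absolute connectivity strength are exactly what the classifier must see.
Rendering is fully deterministic: the same matrix yields byte-identical
PNG output.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
import matplotlib

from .connectivity import ConnectivityMatrix

RENDER_SIZE = 342
FINAL_SIZE = 224
DEFAULT_COLORMAP = "viridis"

_RESAMPLE = {"bicubic": Image.Resampling.BICUBIC,
             "bilinear": Image.Resampling.BILINEAR,
             "nearest": Image.Resampling.NEAREST}


@dataclass
class FCRImage:
    """Rendered connectivity image with its class label and provenance."""

    pixels: np.ndarray  # H x W x 3 uint8
    label: str
    subject_id: str
    epoch_index: int
    band: str

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] != p.shape[1]:
            raise ValueError(f"pixels must be square HxWx3, got {p.shape}")
        if p.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")
        self.pixels = p

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def png_bytes(self) -> bytes:
        buf = _io.BytesIO()
        Image.fromarray(self.pixels).save(buf, format="PNG")
        return buf.getvalue()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_bytes(self.png_bytes())
        return path


def upsample_field(values: np.ndarray, size: int,
                   interpolation: str = "bicubic") -> np.ndarray:
    """Upsample a matrix to a size x size scalar field, clipped to [0, 1].

    With bilinear interpolation the mapping is order-preserving: m1 <= m2
    elementwise implies field1 <= field2 pointwise.  Bicubic (the default
    renderer) is sharper but its negative lobes can locally overshoot.
    """
    img = Image.fromarray(np.asarray(values, dtype=np.float32), mode="F")
    resample = _RESAMPLE[interpolation]
    up = np.asarray(img.resize((size, size), resample=resample), dtype=float)
    return np.clip(up, 0.0, 1.0)


def render_fcr(m: ConnectivityMatrix, size: int = RENDER_SIZE, *,
               colormap: str = DEFAULT_COLORMAP,
               interpolation: str = "bicubic") -> FCRImage:
    """Render one connectivity matrix as an FCR image.

    Deterministic: fixed colormap, fixed [0, 1] value range, no axes or
    colorbar — the data area only.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    field_ = upsample_field(m.values, size, interpolation)
    cmap = matplotlib.colormaps[colormap]
    rgb = (cmap(field_)[:, :, :3] * 255.0).round().astype(np.uint8)
    return FCRImage(pixels=rgb, label=m.group, subject_id=m.subject_id,
                    epoch_index=m.epoch_index, band=m.band)


def resize_fcr(img: FCRImage, size: int = FINAL_SIZE) -> FCRImage:
    """Bilinear resize to the network input size; metadata preserved."""
    if size < 1:
        raise ValueError("size must be >= 1")
    if size == img.size:
        return replace(img, pixels=img.pixels.copy())
    pil = Image.fromarray(img.pixels).resize((size, size),
                                             Image.Resampling.BILINEAR)
    return replace(img, pixels=np.asarray(pil, dtype=np.uint8))


@dataclass
class FCRDataset:
    """Labelled FCR images for one band, one image per (subject, epoch)."""

    band: str
    images: list[FCRImage] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c = {"SZ": 0, "HC": 0}
        for im in self.images:
            c[im.label] = c.get(im.label, 0) + 1
        return c

    def __len__(self) -> int:
        return len(self.images)

    @property
    def subjects(self) -> list[tuple[str, str]]:
        seen: dict[str, str] = {}
        for im in self.images:
            seen.setdefault(im.subject_id, im.label)
        return sorted(seen.items())


def build_dataset(matrices: list[ConnectivityMatrix], band: str, *,
                  render_size: int = RENDER_SIZE, final_size: int = FINAL_SIZE,
                  colormap: str = DEFAULT_COLORMAP,
                  interpolation: str = "bicubic") -> FCRDataset:
    """Render + resize one image per matrix; a cohort of 84 subjects with
    6 epochs each yields 504 images (270 SZ / 234 HC at 45/39 subjects)."""
    seen: set[tuple[str, int]] = set()
    images = []
    for m in matrices:
        if m.band != band:
            raise ValueError(f"matrix band {m.band!r} != requested {band!r}")
        key = (m.subject_id, m.epoch_index)
        if key in seen:
            raise ValueError(f"duplicate (subject, epoch): {key}")
        seen.add(key)
        img = render_fcr(m, render_size, colormap=colormap,
                         interpolation=interpolation)
        images.append(resize_fcr(img, final_size))
    return FCRDataset(band=band, images=images)


def save_dataset(ds: FCRDataset, out_dir: str | Path) -> Path:
    """Write PNGs in band/class/subject_epoch.png layout plus a manifest CSV."""
    import pandas as pd

    out_dir = Path(out_dir)
    rows = []
    for im in ds.images:
        rel = Path(ds.band) / im.label / f"{im.subject_id}_ep{im.epoch_index}.png"
        im.save(out_dir / rel)
        rows.append({"path": str(rel), "subject": im.subject_id,
                     "epoch": im.epoch_index, "band": im.band,
                     "label": im.label})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir
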
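"""Dataset loading and preprocessing for the public fundus layouts.

Supported layouts
-----------------
DRIVE-style (also produced by the synthetic writer)::

    root/training/{images,1st_manual,mask}/...
    root/test/{images,1st_manual,mask}/...

STARE (flat, ``im####.ppm`` images with ``im####.ah.ppm`` first-expert
labels) and CHASE_DB1 (flat, ``Image_##X.jpg`` with ``Image_##X_1stHO.png``
labels).  Neither distributes FOV masks; they are derived by
luminance thresholding.  All three benchmarks use a 1:1 train/test
split; STARE and CHASE_DB1 have no official split, so the first half of
the lexicographically sorted ids is train (overridable via
``DatasetSpec.split_rule``).

Nothing is downloaded: loaders read whatever directory they are pointed
at and validate image count and resolution against the DatasetSpec when those
are declared.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SampleRecord", "DatasetSpec", "DATASET_PRESETS", "load_dataset",
           "preprocess", "crop_prediction", "binarize_mask", "PadInfo"]


@dataclass
class SampleRecord:
    """One fundus case: image, vessel ground truth, FOV mask, identity."""

    id: str
    image: np.ndarray        # (H, W, 3) uint8
    vessel_mask: np.ndarray  # (H, W) binary
    fov_mask: np.ndarray     # (H, W) binary
    split: str = "train"     # {train, test}

    def validate(self):
        h, w = self.vessel_mask.shape
        if self.image.shape[:2] != (h, w) or self.fov_mask.shape != (h, w):
            raise ValueError(f"{self.id}: image/mask extents disagree")
        for name, m in (("vessel_mask", self.vessel_mask),
                        ("fov_mask", self.fov_mask)):
            if not np.isin(np.unique(m), (0, 1)).all():
                raise ValueError(f"{self.id}: {name} is not binary")
        if self.split not in ("train", "test"):
            raise ValueError(f"{self.id}: split must be 'train' or 'test'")


@dataclass
class DatasetSpec:
    """Which layout to read and what to expect there.

    ``resolution`` is (width, height) as conventionally quoted for these
    benchmarks; ``expected_count``/``resolution`` of ``None`` skip
    validation (used for synthetic data of arbitrary size).
    """

    name: str                      # {DRIVE, STARE, CHASE_DB1, synthetic}
    root: str = "."
    resolution: tuple | None = None
    expected_count: int | None = None
    split_rule: str = "first_half_train"
    fov_threshold: int = 30        # 8-bit luminance cutoff for derived FOVs


DATASET_PRESETS = {
    "DRIVE": dict(resolution=(565, 584), expected_count=40),
    "CHASE_DB1": dict(resolution=(999, 960), expected_count=28),
    "STARE": dict(resolution=(700, 605), expected_count=20),
    "synthetic": dict(resolution=None, expected_count=None),
}


def dataset_spec(name: str, root: str, **overrides) -> DatasetSpec:
    """Build a DatasetSpec from the named preset."""
    if name not in DATASET_PRESETS:
        raise ValueError(f"unknown dataset '{name}'")
    kw = dict(DATASET_PRESETS[name])
    kw.update(overrides)
    return DatasetSpec(name=name, root=root, **kw)


def binarize_mask(raster) -> np.ndarray:
    """Normalise mask dialects (GIF 0/255, PPM, unit floats) to {0, 1}."""
    arr = np.asarray(raster)
    if arr.ndim != 2:
        raise ValueError(f"mask must be single-channel, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        return (arr > 0.5).astype(np.uint8)
    return (arr > 127).astype(np.uint8)


def _read_image(path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def _read_mask(path) -> np.ndarray:
    arr = _read_image(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return binarize_mask(arr)


def _to_rgb(arr) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr.astype(np.uint8)


def _id_token(filename: str) -> str:
    """Leading id token of a benchmark filename (digits or synth id)."""
    stem = os.path.splitext(os.path.basename(filename))[0]
    m = re.match(r"(synth_\d+|Image_\d+[A-Za-z]?|im\d+|\d+)", stem)
    return m.group(1) if m else stem


def _listdir(path):
    if not os.path.isdir(path):
        raise FileNotFoundError(f"expected directory '{path}' in dataset layout")
    return sorted(os.listdir(path))


def _luminance_fov(image: np.ndarray, threshold: int) -> np.ndarray:
    """Derive a FOV mask by thresholding luminance (for STARE/CHASE_DB1,
    which ship no FOV masks); small holes are closed morphologically."""
    from scipy.ndimage import binary_closing, binary_fill_holes

    lum = image.mean(axis=2) if image.ndim == 3 else image
    fov = lum > threshold
    fov = binary_fill_holes(binary_closing(fov, iterations=3))
    return fov.astype(np.uint8)


def _apply_split(records, rule: str):
    records.sort(key=lambda r: r.id)
    if rule == "first_half_train":
        half = (len(records) + 1) // 2
        for i, rec in enumerate(records):
            rec.split = "train" if i < half else "test"
    elif rule == "keep":
        pass
    else:
        raise ValueError(f"unknown split rule '{rule}'")
    return records


def _load_drive_layout(spec: DatasetSpec):
    records = []
    for sub, split in (("training", "train"), ("test", "test")):
        base = os.path.join(spec.root, sub)
        images = _listdir(os.path.join(base, "images"))
        manual = _listdir(os.path.join(base, "1st_manual"))
        fovs = _listdir(os.path.join(base, "mask"))
        manual_by_id = {_id_token(f): f for f in manual}
        fov_by_id = {_id_token(f): f for f in fovs}
        for fname in images:
            ident = _id_token(fname)
            if ident not in manual_by_id or ident not in fov_by_id:
                raise FileNotFoundError(
                    f"no annotation/FOV for image id '{ident}' under {base}")
            records.append(SampleRecord(
                id=ident,
                image=_to_rgb(_read_image(os.path.join(base, "images", fname))),
                vessel_mask=_read_mask(os.path.join(base, "1st_manual",
                                                    manual_by_id[ident])),
                fov_mask=_read_mask(os.path.join(base, "mask",
                                                 fov_by_id[ident])),
                split=split))
    records.sort(key=lambda r: r.id)
    return records


def _load_flat_layout(spec: DatasetSpec):
    """STARE / CHASE_DB1: images and first-expert labels in one directory."""
    files = _listdir(spec.root)
    if spec.name == "STARE":
        label_pat = re.compile(r"\.ah\.", re.IGNORECASE)
        labels = [f for f in files if label_pat.search(f)]
        images = [f for f in files if re.match(r"im\d+\.(ppm|png|tif|tiff|jpg)$",
                                               f, re.IGNORECASE)]
    else:  # CHASE_DB1
        labels = [f for f in files if "_1stHO" in f]
        images = [f for f in files
                  if re.match(r"Image_\d+[A-Za-z]?\.(jpg|jpeg|png|tif|tiff)$",
                              f, re.IGNORECASE)]
    label_by_id = {_id_token(f): f for f in labels}
    records = []
    for fname in images:
        ident = _id_token(fname)
        if ident not in label_by_id:
            raise FileNotFoundError(f"no first-expert label for '{ident}'")
        image = _to_rgb(_read_image(os.path.join(spec.root, fname)))
        records.append(SampleRecord(
            id=ident, image=image,
            vessel_mask=_read_mask(os.path.join(spec.root, label_by_id[ident])),
            fov_mask=_luminance_fov(image, spec.fov_threshold),
            split="train"))
    return _apply_split(records, spec.split_rule)


def load_dataset(spec: DatasetSpec):
    """Read a dataset directory into SampleRecords (sorted by id).

    Raises a layout error naming the discrepancy when the image count or
    resolution disagrees with the DatasetSpec.
    """
    if spec.name in ("DRIVE", "synthetic"):
        records = _load_drive_layout(spec)
    elif spec.name in ("STARE", "CHASE_DB1"):
        records = _load_flat_layout(spec)
    else:
        raise ValueError(f"unknown dataset '{spec.name}'")
    if spec.expected_count is not None and len(records) != spec.expected_count:
        raise ValueError(
            f"{spec.name}: expected {spec.expected_count} images, "
            f"found {len(records)}")
    if spec.resolution is not None:
        w, h = spec.resolution
        for rec in records:
            if rec.image.shape[:2] != (h, w):
                raise ValueError(
                    f"{spec.name}: image {rec.id} has extents "
                    f"{rec.image.shape[:2]}, expected {(h, w)}")
    for rec in records:
        rec.validate()
    return records


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PadInfo:
    """Reflective padding applied before the network (bottom/right)."""

    orig_h: int
    orig_w: int
    pad_h: int
    pad_w: int


def preprocess(image: np.ndarray, *, depth: int = 4):
    """Scale an 8-bit RGB image to [0, 1] CHW and pad to extents
    divisible by 2**(depth-1).

    Returns ``(chw, pad)``; use :func:`crop_prediction` with ``pad`` to
    undo the padding on the network output.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    h, w = arr.shape[:2]
    div = 2 ** (depth - 1)
    pad_h = (-h) % div
    pad_w = (-w) % div
    x = arr.astype(np.float64) / 255.0
    if pad_h or pad_w:
        x = np.pad(x, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
    return x.transpose(2, 0, 1), PadInfo(h, w, pad_h, pad_w)


def crop_prediction(pred: np.ndarray, pad: PadInfo) -> np.ndarray:
    """Crop a (H+pad, W+pad) map back to the original extents."""
    return pred[..., :pad.orig_h, :pad.orig_w]
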
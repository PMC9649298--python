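"""Procedural fundus-like test images: branching vessel trees on a
circular field of view.

The generator emulates the structure of public fundus benchmarks — a
bright retinal disc on black background, a dark branching vascular tree
whose calibre tapers from ~4-5 px main vessels down to 1 px
microvessels, and sensor noise — so the whole pipeline (loading,
training, evaluation) is exercisable without downloads.  It makes no
attempt at photorealism: no optic disc, fovea, lesions or illumination
artefacts.

All randomness flows through ``numpy.random.Generator`` seeded from the
config, and rasters are integer-valued, so outputs are bit-identical
across platforms for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import disk as _draw_disk

from .data import SampleRecord

__all__ = ["SyntheticConfig", "generate_vessel_tree", "render_fundus",
           "make_dataset", "write_drive_layout"]


@dataclass
class SyntheticConfig:
    """Knobs of the procedural generator.

    size : (H, W) in pixels, both >= 32.
    n_trees : number of vessel trees seeded on the FOV boundary.
    branch_prob : per-step probability of spawning a side branch.
    width_root / width_min : stroke calibre in px at the root / the
        termination threshold (microvessels bottom out at 1 px).
    contrast : vessel darkening factor in (0, 1]; at 1 vessels separate
        strictly from the background in the noiseless image.
    noise_sd : additive Gaussian noise, 8-bit intensity units.
    fov_radius_frac : FOV disc radius as a fraction of min(H, W)/2.
    """

    size: tuple = (256, 256)
    n_trees: int = 5
    branch_prob: float = 0.035
    width_root: float = 4.5
    width_min: float = 1.0
    contrast: float = 0.7
    noise_sd: float = 8.0
    fov_radius_frac: float = 0.94
    seed: int = 0

    def validate(self):
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError("size must be at least 32x32")
        if self.width_min > self.width_root:
            raise ValueError("width_min must not exceed width_root")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must lie in [0, 1]")
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.fov_radius_frac <= 1.0):
            raise ValueError("fov_radius_frac must lie in (0, 1]")


def _fov_disc(cfg: SyntheticConfig):
    h, w = cfg.size
    radius = cfg.fov_radius_frac * min(h, w) / 2.0
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    return (rr <= radius).astype(np.uint8), rr, radius


def generate_vessel_tree(cfg: SyntheticConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Rasterise a random branching vascular tree as a binary mask.

    Trees start on the FOV boundary heading inward and perform smoothly
    turning random walks; side branches spawn with ``branch_prob`` per
    step at reduced calibre, and every stroke is drawn as a disc of the
    current half-width.  The result is clipped to the FOV.
    """
    cfg.validate()
    h, w = cfg.size
    fov, _, radius = _fov_disc(cfg)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    mask = np.zeros((h, w), dtype=np.uint8)
    if cfg.n_trees == 0:
        return mask

    max_steps = int(3.0 * max(h, w))
    stack = []
    for _ in range(cfg.n_trees):
        theta = rng.uniform(0, 2 * np.pi)
        y0 = cy + radius * np.sin(theta)
        x0 = cx + radius * np.cos(theta)
        heading = theta + np.pi + rng.normal(0.0, 0.35)  # roughly inward
        stack.append((y0, x0, heading, float(cfg.width_root), 0))

    while stack:
        y, x, heading, width, step = stack.pop()
        while width >= cfg.width_min and step < max_steps:
            r = max(width / 2.0, 0.5)
            rr, cc = _draw_disk((y, x), max(r, 0.6), shape=(h, w))
            mask[rr, cc] = 1
            step_len = max(1.0, r)
            heading += rng.normal(0.0, 0.18)
            y += step_len * np.sin(heading)
            x += step_len * np.cos(heading)
            if not (0 <= y < h and 0 <= x < w):
                break
            if (y - cy) ** 2 + (x - cx) ** 2 > (1.05 * radius) ** 2:
                break
            width *= 0.995  # continuous taper
            if rng.random() < cfg.branch_prob and width > 1.4 * cfg.width_min:
                side = np.sign(rng.random() - 0.5) or 1.0
                child_heading = heading + side * rng.uniform(0.4, 1.0)
                stack.append((y, x, child_heading, width * 0.72, step))
                width *= 0.88  # parent narrows past the bifurcation
            step += 1
    mask &= fov
    return mask


def render_fundus(mask: np.ndarray, cfg: SyntheticConfig,
                  rng: np.random.Generator):
    """Render (image, fov) from a vessel mask.

    Background: a warm-toned disc with smooth radial brightness falloff;
    vessels are darkened by ``contrast`` (factor 1 - 0.45*contrast, so at
    contrast = 1 and zero noise every vessel pixel is strictly darker
    than every background pixel inside the FOV); Gaussian noise of
    ``noise_sd`` 8-bit units is added and everything outside the FOV is
    black.  Returns (H, W, 3) uint8 image and (H, W) uint8 FOV mask.
    """
    cfg.validate()
    h, w = cfg.size
    fov, rr, radius = _fov_disc(cfg)
    rnorm = np.clip(rr / radius, 0.0, 1.0)
    base = 255.0 * (0.72 - 0.25 * rnorm**2)
    vessel_factor = np.where(mask > 0, 1.0 - 0.45 * cfg.contrast, 1.0)
    lum = base * vessel_factor
    tint = np.array([1.0, 0.55, 0.30])  # fundus-like warm cast
    img = lum[..., None] * tint[None, None, :]
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    img[fov == 0] = 0
    return img, fov


def make_dataset(n: int, cfg: SyntheticConfig | None = None) -> list:
    """Generate ``n`` SampleRecords, deterministic in (n, cfg.seed).

    Ids are ``synth_0000`` ...; the first half (lexicographically) is the
    train split and the second half the test split, mirroring the 1:1
    protocol of the public benchmarks.
    """
    cfg = cfg or SyntheticConfig()
    cfg.validate()
    records = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), i]))
        mask = generate_vessel_tree(cfg, rng)
        img, fov = render_fundus(mask, cfg, rng)
        split = "train" if i < (n + 1) // 2 else "test"
        records.append(SampleRecord(id=f"synth_{i:04d}", image=img,
                                    vessel_mask=mask.astype(np.uint8),
                                    fov_mask=fov, split=split))
    return records


def write_drive_layout(records, out_dir):
    """Write records as a DRIVE-style directory tree.

    ``out_dir/{training,test}/{images,1st_manual,mask}/<id>.png`` — the
    exact layout the dataset loader consumes, so synthetic data flows
    through the same path as real data.
    """
    import os

    import imageio.v3 as iio

    for rec in records:
        sub = "training" if rec.split == "train" else "test"
        for folder, arr in (("images", rec.image),
                            ("1st_manual", rec.vessel_mask * 255),
                            ("mask", rec.fov_mask * 255)):
            d = os.path.join(out_dir, sub, folder)
            os.makedirs(d, exist_ok=True)
            iio.imwrite(os.path.join(d, f"{rec.id}.png"),
                        np.asarray(arr, dtype=np.uint8))
    return out_dir
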
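"""Synthetic multi-spectral apple phantoms with exact ground truth.

The generator emulates the structure the segmentation method assumes:
a bright, softly shaded, textured elliptical apple region on a
near-black background, imaged in up to four bands (R, G, B, NIR), with
one to three irregular defect blobs of class-dependent contrast stamped
inside the apple.  One class (``russet`` by default) is rendered at
near-zero contrast in the NIR band, mimicking real defects that are
hard to see in some spectral bands.  Because the generator knows its
own apple ellipse and defect blobs, masks are exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_data import (SUB_CLASSES, SUB_TO_MACRO, DatasetManifest,
                        DefectAnnotation, Sample, write_sample)

#: per-band base reflectance of the apple surface (R, G, B, NIR)
BAND_BASE = np.array([0.72, 0.62, 0.40, 0.80])

#: multiplicative defect contrast per sub-class (applied to all bands
#: unless overridden per band): < 1 darkens, the dominant appearance of
#: surface damage
DEFAULT_CONTRAST = {
    "bruise": 0.55, "flesh_damage": 0.40, "frost_damage": 0.50,
    "hail_damage": 0.45, "hail_damage_perf": 0.35, "limb_rub": 0.60,
    "other": 0.58, "rot": 0.30, "russet": 0.62, "scald": 0.52,
}

#: per-class, per-band contrast attenuation toward invisibility
#: (factor 1 = defect invisible in that band); emulates band-dependent
#: defect visibility of real multi-spectral imagery
DEFAULT_VISIBILITY = {"russet": {3: 1.0}}  # russet invisible in NIR


@dataclass
class PhantomConfig:
    image_size: tuple = (128, 128)
    n_healthy: int = 8
    n_defective: int = 8
    channels: int = 4
    apple_radius_range: tuple | None = None   # semi-axes, pixels; default
    #   scales with the frame (~0.34-0.44 of the short side)
    defect_count_range: tuple = (1, 3)
    defect_radius_range: tuple | None = None  # blob half-size, pixels;
    #   default ~0.05-0.11 of the short side
    defect_contrast: dict = field(default_factory=lambda: dict(DEFAULT_CONTRAST))
    channel_visibility: dict = field(default_factory=lambda: dict(DEFAULT_VISIBILITY))
    texture_noise_sigma: float = 0.02
    background_level: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.channels not in (3, 4):
            raise ValueError("channels must be 3 or 4")
        h, w = self.image_size
        short = min(h, w)
        if self.apple_radius_range is None:
            self.apple_radius_range = (round(0.344 * short), round(0.438 * short))
        if self.defect_radius_range is None:
            self.defect_radius_range = (max(2, round(0.047 * short)),
                                        max(3, round(0.109 * short)))
        if 2 * max(self.apple_radius_range) >= min(h, w):
            raise ValueError("apple does not fit in the frame")
        if max(self.defect_radius_range) * 2 >= min(self.apple_radius_range):
            raise ValueError("defects must fit inside the apple")


def _apple_ellipse(cfg: PhantomConfig, rng):
    h, w = cfg.image_size
    ra = rng.uniform(*cfg.apple_radius_range)
    rb = rng.uniform(*cfg.apple_radius_range)
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - cy) / ra) ** 2 + ((xx - cx) / rb) ** 2
    return r2, (cy, cx, ra, rb)


def generate_apple(cfg: PhantomConfig, rng) -> Sample:
    """One healthy apple phantom (all-zero mask)."""
    h, w = cfg.image_size
    r2, _ = _apple_ellipse(cfg, rng)
    inside = r2 <= 1.0
    shading = np.clip(1.0 - 0.45 * r2, 0.0, 1.0)
    # band-correlated smooth texture: one shared field plus per-band detail
    shared = ndimage.gaussian_filter(rng.standard_normal((h, w)), 4.0)
    img = np.empty((h, w, cfg.channels))
    for b in range(cfg.channels):
        own = ndimage.gaussian_filter(rng.standard_normal((h, w)), 2.0)
        tex = cfg.texture_noise_sigma * (shared + 0.5 * own) / 1.1
        band = BAND_BASE[b] * shading + tex
        bg = cfg.background_level * (1.0 + 0.3 * rng.standard_normal((h, w)))
        img[:, :, b] = np.where(inside, band, bg)
    img = np.clip(img, 0.0, 1.0)
    sample = Sample(image=img, mask=np.zeros((h, w), dtype=np.uint8))
    sample._ellipse_mask = inside  # generator ground truth, for tests
    return sample


def _defect_blob(radius: int, rng) -> np.ndarray:
    """Irregular organic blob: thresholded Gaussian-filtered noise."""
    box = int(np.ceil(radius * 2.6)) | 1
    field = ndimage.gaussian_filter(rng.standard_normal((box, box)),
                                    radius / 2.5)
    yy, xx = np.mgrid[0:box, 0:box] - box // 2
    taper = np.exp(-0.5 * (yy * yy + xx * xx) / (radius * radius))
    field = field * taper + 1.5 * taper
    target = np.pi * radius * radius
    thr = np.quantile(field, max(0.0, 1.0 - target / field.size))
    blob = field > thr
    lab, nlab = ndimage.label(blob)
    if nlab > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, nlab + 1))
        blob = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(blob)


def generate_defective(cfg: PhantomConfig, rng) -> Sample:
    """One defective phantom with 1-3 annotated defect blobs."""
    sample = generate_apple(cfg, rng)
    inside = sample._ellipse_mask
    h, w = cfg.image_size
    k = int(rng.integers(cfg.defect_count_range[0],
                         cfg.defect_count_range[1] + 1))
    img = sample.image
    mask = np.zeros((h, w), dtype=np.uint8)
    defects = []
    for _ in range(k):
        sub = str(rng.choice(SUB_CLASSES))
        radius = int(rng.integers(*cfg.defect_radius_range))
        blob = _defect_blob(radius, rng)
        bh, bw = blob.shape
        # the whole blob must land inside the apple ellipse
        allowed = ndimage.binary_erosion(
            inside, structure=np.ones((bh, bw)), border_value=0)
        ys, xs = np.nonzero(allowed)
        if len(ys) == 0:
            continue  # bounded retry budget: skip oversized draw
        j = int(rng.integers(len(ys)))
        cy, cx = ys[j], xs[j]
        y0, x0 = cy - bh // 2, cx - bw // 2
        region = np.zeros((h, w), dtype=bool)
        region[y0:y0 + bh, x0:x0 + bw] = blob
        base_contrast = cfg.defect_contrast[sub]
        soft = ndimage.gaussian_filter(region.astype(float), 1.0)
        soft = np.where(region, np.maximum(soft, 0.6), 0.0)
        for b in range(cfg.channels):
            vis = cfg.channel_visibility.get(sub, {}).get(b, 0.0)
            contrast = base_contrast + (1.0 - base_contrast) * vis
            factor = 1.0 - (1.0 - contrast) * soft
            img[:, :, b] = img[:, :, b] * factor
        mask |= region.astype(np.uint8)
        defects.append(DefectAnnotation(defect_mask=region, sub_class=sub))
    if not defects:
        raise RuntimeError("no defect could be placed inside the apple")
    out = Sample(image=np.clip(img, 0, 1), mask=mask, defects=defects)
    out._ellipse_mask = inside
    return out


def generate_dataset(cfg: PhantomConfig, outdir) -> DatasetManifest:
    """Write a phantom dataset in the package's on-disk format.

    Defective samples cycle through the sub-class list so every class is
    represented as evenly as the sample count allows.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    rows, classes = [], {}
    for i in range(cfg.n_healthy):
        sid = f"healthy_{i:04d}"
        s = generate_apple(cfg, rng)
        _write(outdir, sid, s, rows)
    for i in range(cfg.n_defective):
        sid = f"defective_{i:04d}"
        forced = SUB_CLASSES[i % len(SUB_CLASSES)]
        s = _generate_defective_forced(cfg, rng, forced)
        _write(outdir, sid, s, rows)
        classes[sid] = [a.sub_class for a in s.defects]
    records = pd.DataFrame(rows)
    manifest = DatasetManifest(records=records, classes=classes, root=outdir)
    manifest.save(outdir)
    return manifest


def _generate_defective_forced(cfg, rng, forced_sub):
    """Defective phantom whose first defect has the requested sub-class."""
    s = generate_defective(cfg, rng)
    first = s.defects[0]
    if first.sub_class != forced_sub:
        # restamp class label only; geometry and contrast stay as drawn
        s.defects[0] = DefectAnnotation(defect_mask=first.defect_mask,
                                        sub_class=forced_sub)
    return s


def _write(outdir, sid, sample, rows):
    image_path = f"images/{sid}.tif"
    mask_path = f"masks/{sid}.png"
    sample.sample_id = sid
    write_sample(sample, outdir / image_path, outdir / mask_path)
    rows.append({"sample_id": sid, "image_path": image_path,
                 "mask_path": mask_path, "split": "train",
                 "is_healthy": sample.is_healthy})


def generate_samples(cfg: PhantomConfig, rng=None):
    """In-memory phantom set: (healthy list, defective list).

    Defective samples cycle the sub-class list like :func:`generate_dataset`.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    healthy = []
    for i in range(cfg.n_healthy):
        s = generate_apple(cfg, rng)
        s.sample_id = f"healthy_{i:04d}"
        healthy.append(s)
    defective = []
    for i in range(cfg.n_defective):
        s = _generate_defective_forced(cfg, rng, SUB_CLASSES[i % len(SUB_CLASSES)])
        s.sample_id = f"defective_{i:04d}"
        defective.append(s)
    return healthy, defective
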
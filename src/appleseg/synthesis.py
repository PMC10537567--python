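"""Copy-paste defect synthesis and classic augmentation.

New defective training images are synthesised by extracting annotated
defect regions from defective apples, optionally rotating (uniform
angle in [0, 360) degrees) and/or elastically warping them, and
hard-pasting one to three of them at uniformly random positions fully
inside the apple region of a healthy image.  Six setups toggle the
defect count and the two transforms:

    setup 1: no synthesis          setup 4: 1 defect, rotate + warp
    setup 2: 1 defect, no transform setup 5: 1-3 defects, rotate
    setup 3: 1 defect, rotate       setup 6: 1-3 defects, rotate + warp

During training the whole procedure fires independently per image with
probability ``P`` (default 0.8).  Classic augmentation applies, behind
a 50% outer gate, horizontal flip, vertical flip and a rotation by a
uniform angle in [0, 90] degrees, each with independent probability 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_data import DefectAnnotation, Sample

log = logging.getLogger(__name__)

#: (n_defects_range, rotate, warp) per setup id
SETUP_TABLE = {
    1: ((0, 0), False, False),
    2: ((1, 1), False, False),
    3: ((1, 1), True, False),
    4: ((1, 1), True, True),
    5: ((1, 3), True, False),
    6: ((1, 3), True, True),
}


@dataclass
class SynthesisConfig:
    setup_id: int = 5
    probability_p: float = 0.8
    warp_grid: tuple = (3, 0.1)  # control points per axis, displacement scale
    max_placement_attempts: int = 50
    roi_threshold: float = 0.04  # mean-intensity cut separating apple from background

    def __post_init__(self):
        if self.setup_id not in SETUP_TABLE:
            raise ValueError(f"setup_id must be 1..6, got {self.setup_id}")
        if not 0.0 <= self.probability_p <= 1.0:
            raise ValueError("probability_p must lie in [0,1]")

    @property
    def n_defects_range(self):
        return SETUP_TABLE[self.setup_id][0]

    @property
    def rotate(self):
        return SETUP_TABLE[self.setup_id][1]

    @property
    def warp(self):
        return SETUP_TABLE[self.setup_id][2]


@dataclass
class DefectPatch:
    """A defect cropped to its bounding box, with mask and class label."""

    pixels: np.ndarray  # (h,w,C)
    mask: np.ndarray    # (h,w) bool
    sub_class: str
    source_id: str = ""

    def __post_init__(self):
        if self.pixels.shape[:2] != self.mask.shape:
            raise ValueError("patch pixels/mask shape mismatch")
        if not self.mask.any():
            raise ValueError("patch mask has no positive pixel")


@dataclass
class RoiMask:
    """Apple-surface mask: largest bright component, holes filled."""

    mask: np.ndarray  # (H,W) bool


def compute_roi(sample: Sample, intensity_threshold: float = 0.04) -> RoiMask:
    """Apple region of interest by background removal.

    Thresholds the channel-mean intensity, keeps the largest connected
    component and fills its holes; the near-black background is excluded.
    """
    mean = sample.image.mean(axis=2)
    bright = mean > intensity_threshold
    if not bright.any():
        raise ValueError("empty ROI: no pixel exceeds the intensity threshold")
    lab, nlab = ndimage.label(bright)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, nlab + 1))
    largest = lab == (1 + int(np.argmax(sizes)))
    return RoiMask(mask=ndimage.binary_fill_holes(largest))


def extract_defects(sample: Sample) -> list[DefectPatch]:
    """One patch per annotation, pixels copied under the annotation mask."""
    if sample.is_healthy:
        raise ValueError("cannot extract defects from a healthy sample")
    patches = []
    for ann in sample.defects:
        ys, xs = np.nonzero(ann.defect_mask)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        patches.append(DefectPatch(
            pixels=sample.image[y0:y1, x0:x1].copy(),
            mask=ann.defect_mask[y0:y1, x0:x1].astype(bool),
            sub_class=ann.sub_class,
            source_id=sample.sample_id))
    return patches


def _crop_to_mask(pixels, mask):
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    return pixels[y0:y1, x0:x1], mask[y0:y1, x0:x1]


def rotate_patch(patch: DefectPatch, angle: float) -> DefectPatch:
    """Rotate pixels (bilinear) and mask (re-binarized at 0.5) together.

    The bounding box expands to contain the rotated support and is then
    cropped back to the mask extent.
    """
    angle = float(angle) % 360.0
    if angle == 0.0:
        return DefectPatch(pixels=patch.pixels.copy(), mask=patch.mask.copy(),
                           sub_class=patch.sub_class, source_id=patch.source_id)
    pix = ndimage.rotate(patch.pixels, angle, axes=(1, 0), reshape=True,
                         order=1, mode="constant", cval=0.0)
    msk = ndimage.rotate(patch.mask.astype(float), angle, axes=(1, 0),
                         reshape=True, order=1, mode="constant", cval=0.0)
    msk = msk >= 0.5
    if not msk.any():
        raise ValueError("rotation emptied the patch mask")
    pix, msk = _crop_to_mask(pix, msk)
    return DefectPatch(pixels=np.clip(pix, 0, 1), mask=msk,
                       sub_class=patch.sub_class, source_id=patch.source_id)


def warp_patch(patch: DefectPatch, config: SynthesisConfig, rng) -> DefectPatch:
    """Elastic deformation from a coarse random displacement grid.

    Per-axis displacements are drawn uniformly in ±scale·patch_size on an
    ``n×n`` control grid and interpolated (cubic spline) to a dense field;
    the same field resamples pixels (bilinear) and mask (re-binarized).
    """
    ncp, scale = config.warp_grid
    h, w = patch.mask.shape
    pad = int(np.ceil(scale * max(h, w))) + 1
    pix = np.pad(patch.pixels, ((pad, pad), (pad, pad), (0, 0)))
    msk = np.pad(patch.mask.astype(float), pad)
    hh, ww = msk.shape
    field = []
    for size in (h, w):
        coarse = rng.uniform(-scale * size, scale * size, size=(ncp, ncp))
        field.append(ndimage.zoom(coarse, (hh / ncp, ww / ncp), order=3))
    yy, xx = np.mgrid[0:hh, 0:ww].astype(float)
    coords = np.array([yy + field[0], xx + field[1]])
    out_mask = ndimage.map_coordinates(msk, coords, order=1, cval=0.0) >= 0.5
    if not out_mask.any():
        raise ValueError("warp emptied the patch mask")
    out_pix = np.stack(
        [ndimage.map_coordinates(pix[:, :, c], coords, order=1, cval=0.0)
         for c in range(pix.shape[2])], axis=2)
    out_pix, out_mask = _crop_to_mask(out_pix, out_mask)
    return DefectPatch(pixels=np.clip(out_pix, 0, 1), mask=out_mask,
                       sub_class=patch.sub_class, source_id=patch.source_id)


def place_defects(healthy: Sample, patches: list[DefectPatch], roi: RoiMask,
                  config: SynthesisConfig, rng) -> Sample:
    """Hard-paste patches at uniform positions fully inside the ROI.

    Placement is rejection-sampled: a location is accepted only when every
    patch-mask pixel falls inside the ROI; after
    ``max_placement_attempts`` rejections the patch is skipped with a
    warning.  Pasted pixels overwrite all channels under the patch mask
    (later pastes overwrite earlier ones); everything outside the placed
    masks is bit-identical to the input.
    """
    if not healthy.is_healthy:
        raise ValueError("placement target must be a healthy sample")
    if not 1 <= len(patches) <= 3:
        raise ValueError("1 to 3 patches expected")
    if not roi.mask.any():
        raise ValueError("empty ROI")
    h, w = healthy.mask.shape
    image = healthy.image.copy()
    mask = np.zeros((h, w), dtype=np.uint8)
    annotations = []
    for patch in patches:
        ph, pw = patch.mask.shape
        if ph > h or pw > w:
            log.warning("patch %s larger than the frame; skipped",
                        patch.sub_class)
            continue
        placed = False
        for _ in range(config.max_placement_attempts):
            y0 = int(rng.integers(0, h - ph + 1))
            x0 = int(rng.integers(0, w - pw + 1))
            window = roi.mask[y0:y0 + ph, x0:x0 + pw]
            if window[patch.mask].all():
                placed = True
                break
        if not placed:
            log.warning("no in-ROI position found for a %s patch after %d "
                        "attempts; skipped", patch.sub_class,
                        config.max_placement_attempts)
            continue
        region = np.zeros((h, w), dtype=bool)
        region[y0:y0 + ph, x0:x0 + pw] = patch.mask
        nch = min(image.shape[2], patch.pixels.shape[2])
        image[y0:y0 + ph, x0:x0 + pw][patch.mask, :nch] = \
            patch.pixels[patch.mask][:, :nch]
        mask |= region.astype(np.uint8)
        annotations.append(DefectAnnotation(defect_mask=region,
                                            sub_class=patch.sub_class))
    # later pastes overwrite earlier: clip each annotation to surviving pixels
    return Sample(image=image, mask=mask, defects=annotations,
                  sample_id=healthy.sample_id)


def synthesize(healthy: Sample, defective_pool: list[Sample],
               config: SynthesisConfig, rng) -> Sample:
    """Full synthesis procedure for one healthy training image.

    With probability ``1-P`` (and always for setup 1) the input is
    returned unchanged.  Otherwise ``k`` is drawn from the setup's defect
    count range, ``k`` patches are taken from randomly picked defective
    samples, rotated and/or warped per the setup flags, and placed inside
    the ROI of the healthy image.
    """
    if config.setup_id == 1:
        return healthy
    if not defective_pool:
        raise ValueError("defective pool is empty")
    if rng.random() >= config.probability_p:
        return healthy
    lo, hi = config.n_defects_range
    k = int(rng.integers(lo, hi + 1))
    patches = []
    for _ in range(k):
        source = defective_pool[int(rng.integers(len(defective_pool)))]
        pool = extract_defects(source)
        patch = pool[int(rng.integers(len(pool)))]
        if config.rotate:
            patch = rotate_patch(patch, rng.uniform(0.0, 360.0))
        if config.warp:
            patch = warp_patch(patch, config, rng)
        patches.append(patch)
    roi = compute_roi(healthy, config.roi_threshold)
    out = place_defects(healthy, patches, roi, config, rng)
    return out if not out.is_healthy else healthy


def classic_augment(sample: Sample, rng) -> Sample:
    """Flip/rotate augmentation applied identically to image and mask."""
    if rng.random() >= 0.5:  # outer gate
        return sample
    image, mask = sample.image, sample.mask
    defects = sample.defects
    if rng.random() < 0.5:  # horizontal flip
        image, mask = image[:, ::-1], mask[:, ::-1]
        defects = [DefectAnnotation(a.defect_mask[:, ::-1], a.sub_class)
                   for a in defects]
    if rng.random() < 0.5:  # vertical flip
        image, mask = image[::-1], mask[::-1]
        defects = [DefectAnnotation(a.defect_mask[::-1], a.sub_class)
                   for a in defects]
    if rng.random() < 0.5:  # rotation by a uniform angle in [0, 90] degrees
        angle = rng.uniform(0.0, 90.0)
        image = np.clip(ndimage.rotate(image, angle, axes=(1, 0),
                                       reshape=False, order=1), 0, 1)
        mask01 = ndimage.rotate(mask.astype(float), angle, axes=(1, 0),
                                reshape=False, order=1) >= 0.5
        mask = mask01.astype(np.uint8)
        new_defects = []
        for a in defects:
            dm = ndimage.rotate(a.defect_mask.astype(float), angle,
                                axes=(1, 0), reshape=False, order=1) >= 0.5
            if dm.any():
                new_defects.append(DefectAnnotation(dm & mask01, a.sub_class))
        defects = new_defects
    return Sample(image=np.ascontiguousarray(image),
                  mask=np.ascontiguousarray(mask),
                  defects=defects, sample_id=sample.sample_id)
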
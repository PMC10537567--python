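"""Domain types, on-disk formats and the dataset split protocol.

A dataset on disk is a directory of per-sample multi-channel TIFFs
(channel order R, G, B, NIR; 8-bit per band), single-band labeled PNG
masks (0 = healthy pixel, 1..k = per-defect region index), a
``manifest.csv`` and a ``classes.json`` sidecar mapping each sample's
defect labels to their sub-class names.  Pixel values are divided by
255 at load so the whole pipeline works in unit range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

#: the ten defect sub-classes annotated in multi-spectral apple imagery
SUB_CLASSES = (
    "bruise", "flesh_damage", "frost_damage", "hail_damage",
    "hail_damage_perf", "limb_rub", "other", "rot", "russet", "scald",
)

#: four-way severity grouping of the sub-classes
MACRO_CLASSES = ("bruises", "reject", "serious_defect", "slight_defect")

# Severity lookup: recent bruises form their own group; rot and visible
# flesh damage lead to rejection; russet exemplifies a slight defect; the
# remaining surface damage classes are grouped as serious.  Overridable
# where a dataset defines its own grading.
SUB_TO_MACRO = {
    "bruise": "bruises",
    "rot": "reject",
    "flesh_damage": "reject",
    "frost_damage": "serious_defect",
    "hail_damage": "serious_defect",
    "hail_damage_perf": "serious_defect",
    "limb_rub": "serious_defect",
    "scald": "serious_defect",
    "other": "serious_defect",
    "russet": "slight_defect",
}


@dataclass
class DefectAnnotation:
    """One connected defect region with its class labels."""

    defect_mask: np.ndarray  # binary (H,W), subset of the sample mask
    sub_class: str
    macro_class: str = ""

    def __post_init__(self):
        if self.sub_class not in SUB_CLASSES:
            raise ValueError(f"unknown sub_class {self.sub_class!r}")
        if not self.macro_class:
            self.macro_class = SUB_TO_MACRO[self.sub_class]
        if self.macro_class not in MACRO_CLASSES:
            raise ValueError(f"unknown macro_class {self.macro_class!r}")


@dataclass
class Sample:
    """One apple image with its pixel-wise defect ground truth."""

    image: np.ndarray  # (H,W,C) float in [0,1], C in {3,4}
    mask: np.ndarray   # (H,W) uint8 in {0,1}
    defects: list[DefectAnnotation] = field(default_factory=list)
    sample_id: str = ""

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} / mask {self.mask.shape} "
                "shape mismatch")
        if self.image.ndim != 3 or self.image.shape[2] not in (3, 4):
            raise ValueError("image must be (H,W,C) with C in {3,4}")
        if not np.isin(np.unique(self.mask), (0, 1)).all():
            raise ValueError("mask must be binary")
        for a in self.defects:
            if np.any(a.defect_mask & ~self.mask.astype(bool)):
                raise ValueError("annotation mask exceeds the sample mask")

    @property
    def is_healthy(self) -> bool:
        return not np.any(self.mask)

    @property
    def n_channels(self) -> int:
        return self.image.shape[2]


# ---------------------------------------------------------------------------
# readers / writers


def _to_unit(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    arr = arr.astype(np.float64)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("non-8-bit image must already be in [0,1]")
    return arr


def read_sample(image_path, mask_path, channel_mode: str = "rgbnir",
                classes: list[str] | None = None, sample_id: str = "") -> Sample:
    """Load one sample from disk.

    ``channel_mode='rgb'`` keeps the first three channels of a 4-band
    image; ``'rgbnir'`` requires all four.  ``classes`` gives the
    sub-class name of each mask label 1..k in order.
    """
    if channel_mode not in ("rgb", "rgbnir"):
        raise ValueError(f"unknown channel_mode {channel_mode!r}")
    image_path, mask_path = Path(image_path), Path(mask_path)
    for p in (image_path, mask_path):
        if not p.exists():
            raise FileNotFoundError(str(p))
    if image_path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(image_path)
    else:
        img = iio.imread(image_path)
    if img.ndim == 2:
        img = img[:, :, None]
    need = 4 if channel_mode == "rgbnir" else 3
    if img.shape[2] < need:
        raise ValueError(
            f"image has {img.shape[2]} channels, mode {channel_mode!r} "
            f"needs {need}")
    img = _to_unit(img[:, :, :need])
    labels = iio.imread(mask_path)
    if labels.ndim != 2:
        raise ValueError("mask must be single-band")
    if labels.shape != img.shape[:2]:
        raise ValueError(
            f"image {img.shape[:2]} / mask {labels.shape} shape mismatch")
    mask = (labels > 0).astype(np.uint8)
    defects = []
    if classes:
        for idx, sub in enumerate(classes, start=1):
            region = labels == idx
            if region.any():
                defects.append(DefectAnnotation(defect_mask=region, sub_class=sub))
    return Sample(image=img, mask=mask, defects=defects,
                  sample_id=sample_id or image_path.stem)


def write_sample(sample: Sample, image_path, mask_path) -> None:
    """Write image (8-bit TIFF) and labeled mask (PNG) for one sample."""
    img8 = np.clip(np.round(sample.image * 255.0), 0, 255).astype(np.uint8)
    tifffile.imwrite(image_path, img8, photometric="minisblack")
    labels = np.zeros(sample.mask.shape, dtype=np.uint8)
    if sample.defects:
        for idx, a in enumerate(sample.defects, start=1):
            labels[a.defect_mask.astype(bool)] = idx
    else:
        labels[sample.mask.astype(bool)] = 255
    iio.imwrite(mask_path, labels)


def write_prediction(prob_map: np.ndarray, path) -> None:
    """Write a probability map as an 8-bit grayscale image."""
    prob_map = np.asarray(prob_map)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probability map values must lie in [0,1]")
    iio.imwrite(path, np.round(prob_map * 255.0).astype(np.uint8))


def read_prediction(path) -> np.ndarray:
    return iio.imread(path).astype(np.float64) / 255.0


# ---------------------------------------------------------------------------
# manifest


@dataclass
class DatasetManifest:
    """Table of samples (id, paths, split, health flag) + class sidecar."""

    records: pd.DataFrame
    classes: dict = field(default_factory=dict)  # sample_id -> [sub_class,...]
    root: Path | None = None

    REQUIRED = ("sample_id", "image_path", "mask_path", "split", "is_healthy")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise ValueError(f"manifest missing column {col!r}")
        if self.records["sample_id"].duplicated().any():
            raise ValueError("sample_ids must be unique")

    def __len__(self):
        return len(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        sub = self.records[self.records["split"] == split].reset_index(drop=True)
        return DatasetManifest(records=sub, classes=self.classes, root=self.root)

    def load_sample(self, sample_id: str, channel_mode: str = "rgbnir") -> Sample:
        row = self.records[self.records["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        row = row.iloc[0]
        root = self.root or Path(".")
        return read_sample(root / row["image_path"], root / row["mask_path"],
                           channel_mode=channel_mode,
                           classes=self.classes.get(sample_id),
                           sample_id=sample_id)

    def load_split(self, split: str, channel_mode: str = "rgbnir") -> list[Sample]:
        sub = self.subset(split)
        return [sub.load_sample(sid, channel_mode)
                for sid in sub.records["sample_id"]]

    def save(self, root) -> None:
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(root / "manifest.csv", index=False)
        (root / "classes.json").write_text(json.dumps(self.classes, indent=2))

    @classmethod
    def load(cls, root) -> "DatasetManifest":
        root = Path(root)
        records = pd.read_csv(root / "manifest.csv")
        records["is_healthy"] = records["is_healthy"].astype(bool)
        classes_file = root / "classes.json"
        classes = json.loads(classes_file.read_text()) if classes_file.exists() else {}
        return cls(records=records, classes=classes, root=root)


def _stratum_key(row, classes):
    if row["is_healthy"]:
        return "healthy"
    subs = classes.get(row["sample_id"], [])
    macros = sorted({SUB_TO_MACRO[s] for s in subs})
    return "|".join(macros) if macros else "defective"


def split_dataset(manifest: DatasetManifest, fractions, seed: int
                  ) -> DatasetManifest:
    """Assign train/val/test splits, stratified by health flag and macro class.

    Global counts follow ``round(n * fraction)`` for val and test with the
    remainder assigned to train; deterministic given ``seed``.
    """
    ftrain, fval, ftest = fractions
    if abs(ftrain + fval + ftest - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if min(fractions) < 0:
        raise ValueError("fractions must be non-negative")
    n = len(manifest)
    if n == 0:
        raise ValueError("empty manifest")
    n_val = round(n * fval)
    n_test = round(n * ftest)
    n_train = n - n_val - n_test
    rng = np.random.default_rng(seed)
    records = manifest.records.reset_index(drop=True)
    strata: dict[str, list[int]] = {}
    for i, row in records.iterrows():
        strata.setdefault(_stratum_key(row, manifest.classes), []).append(i)
    assign = np.full(n, "train", dtype=object)
    # proportional floor allocation per stratum, then top up globally from
    # the largest strata so totals are exact
    want = {"val": n_val, "test": n_test}
    leftover: list[int] = []
    for key in sorted(strata):
        idx = np.array(strata[key])
        rng.shuffle(idx)
        m = len(idx)
        k_val = int(np.floor(m * fval))
        k_test = int(np.floor(m * ftest))
        assign[idx[:k_val]] = "val"
        assign[idx[k_val:k_val + k_test]] = "test"
        leftover.extend(idx[k_val + k_test:])
    rng.shuffle(leftover_arr := np.array(leftover, dtype=int))
    pos = 0
    for name in ("val", "test"):
        need = want[name] - int((assign == name).sum())
        for _ in range(need):
            while assign[leftover_arr[pos]] != "train":
                pos += 1
            assign[leftover_arr[pos]] = name
            pos += 1
    assert int((assign == "val").sum()) == n_val
    assert int((assign == "test").sum()) == n_test
    assert int((assign == "train").sum()) == n_train
    out = records.copy()
    out["split"] = assign
    return DatasetManifest(records=out, classes=manifest.classes,
                           root=manifest.root)
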
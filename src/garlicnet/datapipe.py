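"""Dataset handling: class-folder loading, offline x3 augmentation,
6:2:2 splitting and stratified k-fold partitioning.

The augmentation expands every original image into ``factor`` images —
the original plus noise-injected and rotated copies — deterministically from
a seed, so class counts scale exactly by ``factor``.  The 6:2:2 split uses a
fixed largest-remainder rule (ties toward the test set) so the arithmetic is
reproducible; per-class splits are stratified.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import transform as sktransform

__all__ = [
    "ImageSample",
    "Dataset",
    "SplitPlan",
    "augment_dataset",
    "split_622",
    "make_split",
    "kfold",
    "load_image_folder",
    "save_image_folder",
    "write_manifest",
]

#: Augmentation defaults: additive Gaussian noise sigma (in [0,1] pixel
#: units) and the rotation range in degrees.  Rotated images keep their
#: canvas size with black padding, consistent with a black-cloth background.
NOISE_SIGMA = 0.02
ROTATION_RANGE = 30.0


@dataclass
class ImageSample:
    """One labelled image: H x W x 3 float pixels in [0, 1]."""

    image: np.ndarray
    label: str
    source: str = ""


@dataclass
class Dataset:
    """A list of labelled samples with an ordered class vocabulary."""

    samples: list
    class_names: list

    def __post_init__(self):
        for s in self.samples:
            if s.label not in self.class_names:
                raise ValueError(f"label {s.label!r} not in class_names")

    def __len__(self):
        return len(self.samples)

    @property
    def labels(self):
        return [s.label for s in self.samples]

    def label_indices(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lut[s.label] for s in self.samples], dtype=int)

    def class_counts(self) -> dict:
        counts = {c: 0 for c in self.class_names}
        for s in self.samples:
            counts[s.label] += 1
        return counts

    def subset(self, indices) -> "Dataset":
        return Dataset([self.samples[i] for i in indices], self.class_names)


def _noise_copy(image: np.ndarray, rng) -> np.ndarray:
    noisy = image + rng.normal(0.0, NOISE_SIGMA, size=image.shape)
    return np.clip(noisy, 0.0, 1.0)


def _rotation_copy(image: np.ndarray, rng) -> np.ndarray:
    angle = rng.uniform(-ROTATION_RANGE, ROTATION_RANGE)
    return sktransform.rotate(image, angle, resize=False, mode="constant",
                              cval=0.0, preserve_range=True)


def augment_dataset(originals: Dataset, factor: int = 3,
                    seed: int = 0) -> Dataset:
    """Offline expansion: each original yields itself plus ``factor - 1``
    transformed copies (alternating noise injection and random rotation), so
    every per-class count is exactly multiplied by ``factor``."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    counts = originals.class_counts()
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"cannot augment empty classes: {empty}")
    rng = np.random.default_rng(seed)
    out = []
    for s in originals.samples:
        out.append(s)
        for j in range(1, factor):
            if j % 2 == 1:
                img = _noise_copy(s.image, rng)
                kind = "noise"
            else:
                img = _rotation_copy(s.image, rng)
                kind = "rot"
            out.append(ImageSample(img, s.label, f"{s.source}+{kind}{j}"))
    return Dataset(out, list(originals.class_names))


def split_622(n: int) -> tuple:
    """Counts of a 6:2:2 train/val/test split of ``n`` items.

    Train gets round(0.6 n); the remainder is halved between validation and
    test by largest remainder, the odd item (a tie, both ratios being 0.2)
    going to test.  Counts always sum to ``n``.
    """
    if n < 5:
        raise ValueError("need at least 5 items for a 6:2:2 split")
    n_train = int(np.floor(0.6 * n + 0.5))
    rem = n - n_train
    n_val = rem // 2
    n_test = rem - n_val
    return n_train, n_val, n_test


@dataclass
class SplitPlan:
    """Disjoint train/val/test index lists covering a dataset exactly once."""

    train_idx: list
    val_idx: list
    test_idx: list
    seed: int
    ratios: tuple = (0.6, 0.2, 0.2)

    def partitions(self):
        return {"train": self.train_idx, "val": self.val_idx,
                "test": self.test_idx}


def make_split(dataset: Dataset, seed: int = 0) -> SplitPlan:
    """Stratified 6:2:2 split: :func:`split_622` applied per class after a
    seeded shuffle of each class's indices."""
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    labels = np.asarray(dataset.labels)
    for cls in dataset.class_names:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_tr, n_va, n_te = split_622(len(idx))
        train.extend(idx[:n_tr].tolist())
        val.extend(idx[n_tr:n_tr + n_va].tolist())
        test.extend(idx[n_tr + n_va:].tolist())
    return SplitPlan(train, val, test, seed=seed)


def kfold(labels, k: int = 5, seed: int = 0) -> list:
    """Stratified k-fold partition of ``range(len(labels))``.

    Returns ``k`` ``(train_idx, val_idx)`` pairs whose validation folds are
    pairwise disjoint, cover every index, and differ in size by at most one.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"need at least k={k} items, got {n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.tolist(), va.tolist())
            for tr, va in skf.split(np.zeros(n), labels)]


def segment_dataset(dataset: Dataset, threshold: float = 0.3,
                    mode: str = "crop"):
    """Run foreground segmentation over a dataset, for the two-stage pipeline.

    ``mode="crop"`` (default) replaces each image by the tight crop of the
    segmented bulb; ``mode="mask"`` keeps the full frame with the background
    blacked out.  Returns ``(Dataset, bboxes)`` where ``bboxes[i]`` is the
    half-open foreground box in the *original* frame, so downstream
    coordinates (e.g. damage ground truth) can be remapped into the crop.
    """
    from .preprocess import segment

    if mode not in ("crop", "mask"):
        raise ValueError("mode must be 'crop' or 'mask'")
    out, bboxes = [], []
    for s in dataset.samples:
        res = segment(s.image, threshold=threshold)
        r0, c0, r1, c1 = res.bbox
        img = (res.masked_image[r0:r1, c0:c1] if mode == "crop"
               else res.masked_image)
        out.append(ImageSample(img, s.label, s.source + "#seg"))
        bboxes.append(res.bbox)
    return Dataset(out, list(dataset.class_names)), bboxes


def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def load_image_folder(root) -> Dataset:
    """Load a class-per-subdirectory image tree into a :class:`Dataset`.

    Unreadable files are skipped with a warning (mirroring manual curation of
    corrupt captures); classes and files are visited in sorted order so the
    result is deterministic.
    """
    root = Path(root)
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    samples = []
    class_names = [p.name for p in class_dirs]
    for cdir in class_dirs:
        for f in sorted(cdir.iterdir()):
            if f.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
                continue
            try:
                img = _read_image(f)
            except Exception as exc:  # corrupted file
                warnings.warn(f"skipping unreadable image {f}: {exc}")
                continue
            samples.append(ImageSample(img, cdir.name, str(f)))
    if not samples:
        raise ValueError(f"no readable images under {root}")
    return Dataset(samples, class_names)


def save_image_folder(dataset: Dataset, root) -> None:
    """Write a dataset back out as a class-folder tree of 8-bit PNGs."""
    import imageio.v3 as iio

    root = Path(root)
    per_class = {c: 0 for c in dataset.class_names}
    for s in dataset.samples:
        cdir = root / s.label
        cdir.mkdir(parents=True, exist_ok=True)
        i = per_class[s.label]
        per_class[s.label] += 1
        arr = (np.clip(s.image, 0.0, 1.0) * 255).round().astype(np.uint8)
        iio.imwrite(cdir / f"{s.label}_{i:04d}.png", arr)


def write_manifest(dataset: Dataset, plan: SplitPlan, path) -> None:
    """CSV manifest: one row per sample with its partition assignment."""
    partition = {}
    for name, idx in plan.partitions().items():
        for i in idx:
            partition[i] = name
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "source", "class", "partition"])
        for i, s in enumerate(dataset.samples):
            writer.writerow([i, s.source, s.label, partition.get(i, "")])
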
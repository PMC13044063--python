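"""Deterministic generator of garlic-like labelled test images.

Emulates the imaging setup of a produce-sorting line: a bright, textured
garlic bulb (an ellipse with clove ridges) centred on a near-black cloth
background, in three conditions:

* ``normal`` — intact bulb, no damage;
* ``local_damage`` — a reddish-brown bruise patch on the bulb body;
* ``root_damage`` — a dark grey-blue decay patch anchored at the bulb base.

The two damage classes differ in both location and colour statistics, which
makes the classes separable enough for a small CNN to learn at desk scale.
Every image is fully determined by its seed, and the generator returns the
ground-truth bulb/damage geometry so segmentation and attention maps can be
scored against known answers.  Background intensity is near-black but not
exactly zero, so the fixed 0.3 binarisation threshold is genuinely exercised.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .datapipe import Dataset, ImageSample

__all__ = ["CLASSES", "FixtureSpec", "generate_image", "generate_dataset",
           "write_dataset"]

#: Ordered class vocabulary used throughout the package.
CLASSES = ("local_damage", "root_damage", "normal")

_BULB_COLOR = np.array([0.86, 0.79, 0.66])       # warm off-white skin
_LOCAL_COLOR = np.array([0.55, 0.14, 0.05])      # dark reddish-brown bruise
_ROOT_COLOR = np.array([0.25, 0.40, 0.70])       # blue-grey basal decay


@dataclass
class FixtureSpec:
    """Recipe plus (after generation) ground-truth geometry of one image.

    Bounding boxes are 0-based half-open ``(r0, c0, r1, c1)``; ``damage_bbox``
    is present exactly when the class is not ``normal``.
    """

    image_size: int
    class_label: str
    seed: int
    noise_sigma: float = 0.01
    bulb_center: Optional[tuple] = None
    bulb_radii: Optional[tuple] = None
    bulb_bbox: Optional[tuple] = None
    damage_bbox: Optional[tuple] = None


def _bbox_of(mask: np.ndarray) -> tuple:
    rows, cols = np.nonzero(mask)
    return (int(rows.min()), int(cols.min()),
            int(rows.max()) + 1, int(cols.max()) + 1)


def generate_image(spec: FixtureSpec):
    """Render one image; returns ``(ImageSample, ground_truth)``.

    The ground truth is a copy of ``spec`` with the realised bulb centre,
    radii and bounding boxes filled in.
    """
    S = spec.image_size
    if S < 64:
        raise ValueError("image_size must be >= 64")
    if spec.class_label not in CLASSES:
        raise ValueError(f"unknown class {spec.class_label!r}")
    rng = np.random.default_rng(spec.seed)

    img = np.clip(rng.normal(0.02, 0.008, size=(S, S, 3)), 0.0, 0.05)

    cy = S * (0.5 + rng.uniform(-0.04, 0.04))
    cx = S * (0.5 + rng.uniform(-0.04, 0.04))
    ry = S * rng.uniform(0.26, 0.34)
    rx = S * rng.uniform(0.22, 0.30)
    rr, cc = np.mgrid[0:S, 0:S].astype(float)
    d2 = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2
    bulb = d2 <= 1.0
    rad = np.sqrt(d2)
    theta = np.arctan2(rr - cy, cc - cx)
    n_cloves = rng.integers(6, 10)
    ridges = 0.07 * np.sin(n_cloves * theta) * rad
    shading = 0.06 * (1.0 - rad)  # slightly brighter crown
    intensity = 0.80 + ridges + shading + rng.normal(
        0.0, spec.noise_sigma, size=(S, S))
    img[bulb] = np.clip(intensity[bulb, None] * _BULB_COLOR[None, :], 0.0, 1.0)

    damage_bbox = None
    if spec.class_label != "normal":
        if spec.class_label == "local_damage":
            # bruise somewhere on the bulb body (upper two thirds)
            py = cy + ry * rng.uniform(-0.40, 0.05)
            px = cx + rx * rng.uniform(-0.30, 0.30)
            pry = ry * rng.uniform(0.40, 0.55)
            prx = rx * rng.uniform(0.40, 0.55)
            color = _LOCAL_COLOR
        else:
            # decay anchored at the bulb base (bottom of the ellipse)
            py = cy + ry * rng.uniform(0.60, 0.75)
            px = cx + rx * rng.uniform(-0.12, 0.12)
            pry = ry * rng.uniform(0.35, 0.48)
            prx = rx * rng.uniform(0.50, 0.65)
            color = _ROOT_COLOR
        pd2 = ((rr - py) / pry) ** 2 + ((cc - px) / prx) ** 2
        patch = (pd2 <= 1.0) & bulb
        if not patch.any():  # degenerate draw; fall back to bulb centre
            pd2 = ((rr - cy) / pry) ** 2 + ((cc - cx) / prx) ** 2
            patch = (pd2 <= 1.0) & bulb
        mottle = 1.0 + 0.10 * np.cos(3.0 * theta) * rad + rng.normal(
            0.0, spec.noise_sigma, size=(S, S))
        img[patch] = np.clip(mottle[patch, None] * color[None, :], 0.0, 1.0)
        damage_bbox = _bbox_of(patch)

    truth = dataclasses.replace(
        spec,
        bulb_center=(float(cy), float(cx)),
        bulb_radii=(float(ry), float(rx)),
        bulb_bbox=_bbox_of(bulb),
        damage_bbox=damage_bbox,
    )
    sample = ImageSample(img, spec.class_label,
                         f"synth/{spec.class_label}/{spec.seed}")
    return sample, truth


def generate_dataset(n_per_class: int, image_size: int = 96, seed: int = 0,
                     classes=CLASSES):
    """Balanced synthetic dataset: ``(Dataset, list of ground truths)``.

    Per-image seeds are derived from ``seed`` via a seed sequence, so
    different base seeds give disjoint pixel content.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(classes) * n_per_class)
    samples, truths = [], []
    i = 0
    for cls in classes:
        for _ in range(n_per_class):
            spec = FixtureSpec(image_size=image_size, class_label=cls,
                               seed=int(child_seeds[i] % (2**31)))
            s, t = generate_image(spec)
            samples.append(s)
            truths.append(t)
            i += 1
    return Dataset(samples, list(classes)), truths


def write_dataset(dataset: Dataset, truths, root) -> None:
    """Write images as a class-folder PNG tree plus a geometry manifest CSV."""
    from .datapipe import save_image_folder

    root = Path(root)
    save_image_folder(dataset, root)
    with open(root / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "class", "seed", "bulb_bbox", "damage_bbox"])
        for s, t in zip(dataset.samples, truths):
            writer.writerow([
                s.source, s.label, t.seed,
                " ".join(map(str, t.bulb_bbox)),
                " ".join(map(str, t.damage_bbox)) if t.damage_bbox else "",
            ])
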
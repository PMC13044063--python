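"""Gradient-weighted class activation mapping (Grad-CAM).

For a chosen class logit, the gradients w.r.t. the final convolutional
feature map are spatially averaged into per-channel weights; the rectified,
weighted channel sum — upsampled to the input size and min-max normalised to
[0, 1] — highlights the image regions driving that class score.  The hook
point is the output of the last residual block (the final convolutional
stage, 512 x 7 x 7 at full width and 224 input).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import transform as sktransform

__all__ = ["Heatmap", "gradcam", "overlay_heatmap"]


@dataclass
class Heatmap:
    """H x W attention map in [0, 1] (identically 0 if the class gradient
    carries no signal), plus an optional colour overlay on the source."""

    values: np.ndarray
    overlay: Optional[np.ndarray] = None


def gradcam(net, image: np.ndarray, target_class: int) -> Heatmap:
    """Grad-CAM heatmap of ``target_class`` for one H x W x 3 image."""
    if not 0 <= target_class < net.spec.num_classes:
        raise ValueError(
            f"target_class {target_class} out of range "
            f"(num_classes={net.spec.num_classes})"
        )
    net.eval()
    x = np.transpose(np.asarray(image, dtype=float), (2, 0, 1))[None]
    feats = net.forward_features(x)            # (1, C, h, w)
    logits = net.head_forward(feats)
    grad_logits = np.zeros_like(logits)
    grad_logits[0, target_class] = 1.0
    grad_feats = net.head_backward(grad_logits)  # (1, C, h, w)

    weights = grad_feats[0].mean(axis=(1, 2))                 # (C,)
    cam = np.maximum((weights[:, None, None] * feats[0]).sum(axis=0), 0.0)
    peak = cam.max()
    if peak <= 0.0:
        warnings.warn("Grad-CAM map is identically zero for this class")
        values = np.zeros(image.shape[:2])
    else:
        cam = sktransform.resize(cam, image.shape[:2], preserve_range=True,
                                 anti_aliasing=False)
        cam = np.maximum(cam, 0.0)
        values = cam / cam.max()
    return Heatmap(values=values, overlay=overlay_heatmap(image, values))


def overlay_heatmap(image: np.ndarray, values: np.ndarray,
                    alpha: float = 0.5) -> np.ndarray:
    """Blend a blue (low attention) to red (high attention) colouring of the
    map onto the source image."""
    colored = np.stack([values,                      # red ramps up
                        0.2 * np.ones_like(values),  # faint green midtone
                        1.0 - values], axis=-1)      # blue ramps down
    return np.clip((1 - alpha) * image + alpha * colored, 0.0, 1.0)
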
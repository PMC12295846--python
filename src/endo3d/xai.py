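"""3D Guided Grad-CAM saliency.

Grad-CAM weighs the final convolutional stage's activation maps by the
spatiotemporal average of the target-class logit gradient, rectifies the
weighted sum, and upsamples it trilinearly to the segment's frame grid.
Guided backpropagation recomputes the input gradient with every ReLU
backward pass additionally zeroing negative incoming gradients. Guided
Grad-CAM is the elementwise product of the upsampled Grad-CAM map with the
channel-summed magnitude of the guided gradients; the absolute value avoids
sign cancellation in the visualization. All heatmaps are nonnegative and
max-normalized to 1 when nonzero.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .blocks import Model
from .segmenter import CLASS_TO_INDEX, Segment

__all__ = [
    "Heatmap",
    "grad_cam_3d",
    "guided_backprop",
    "guided_grad_cam",
    "overlay",
    "reference_disc_model",
]


@dataclass
class Heatmap:
    """Nonnegative saliency volume aligned to a segment's (N, H, W) grid."""

    values: np.ndarray
    segment_id: str
    target_class: str

    def __post_init__(self):
        if np.any(self.values < 0):
            raise ValueError("heatmap values must be nonnegative")

    def mass_fraction(self, mask: np.ndarray) -> float:
        """Fraction of total heatmap mass inside a boolean (H, W) mask."""
        total = float(self.values.sum())
        if total == 0:
            return 0.0
        return float((self.values * mask[None, :, :]).sum() / total)


def _normalize(volume: np.ndarray) -> np.ndarray:
    peak = volume.max()
    return volume / peak if peak > 0 else volume


def _target_backward(model: Model, segment: Segment, target_class: str,
                     capture_cam: bool = False) -> np.ndarray:
    """Forward the segment, backpropagate a one-hot logit gradient."""
    x = segment.data[None].astype(np.float64)
    logits = model.forward(x, capture_cam=capture_cam)
    d = np.zeros_like(logits)
    d[0, CLASS_TO_INDEX[target_class]] = 1.0
    return model.backward(d)


def grad_cam_3d(model: Model, segment: Segment, target_class: str) -> Heatmap:
    """Class-gradient-weighted activation map of the last convolution.

    Channel weights are the global average of the logit gradient over the
    stage's (T', H', W') grid; the rectified weighted activation sum is
    upsampled trilinearly to the segment's (N, H, W) frame grid and
    max-normalized. An everywhere-zero gradient produces an all-zero map
    with a warning.
    """
    from skimage.transform import resize

    _target_backward(model, segment, target_class, capture_cam=True)
    act = model.cam_activation[0]   # T',H',W',C
    grad = model.cam_gradient[0]
    weights = grad.mean(axis=(0, 1, 2))
    cam = np.maximum((act * weights).sum(axis=-1), 0.0)
    if cam.max() == 0.0:
        warnings.warn(
            f"Grad-CAM for class {target_class!r} is identically zero", RuntimeWarning,
            stacklevel=2,
        )
    n, h, w = segment.data.shape[:3]
    cam = resize(cam, (n, h, w), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return Heatmap(_normalize(np.maximum(cam, 0.0)), segment.source_id, target_class)


def guided_backprop(model: Model, segment: Segment, target_class: str) -> np.ndarray:
    """Signed input gradient of the target logit under guided ReLU backward.

    Returns a volume of the segment's shape (N, H, W, 3). With no ReLU on
    the path this reduces to the ordinary gradient.
    """
    with nn.guided_gradients():
        return _target_backward(model, segment, target_class)[0]


def guided_grad_cam(model: Model, segment: Segment, target_class: str) -> Heatmap:
    """Product of the upsampled Grad-CAM map and |guided gradients|.

    The guided-gradient magnitude is summed over color channels before the
    product; the result is max-normalized.
    """
    cam = grad_cam_3d(model, segment, target_class)
    gbp = np.abs(guided_backprop(model, segment, target_class)).sum(axis=-1)
    return Heatmap(_normalize(cam.values * gbp), segment.source_id, target_class)


def reference_disc_model() -> Model:
    """A constructed (synthetic, not trained) color-opponency reference model.

    Built to validate saliency localization against ground truth: its only
    informative pathway detects the red-green opponency the planted-signal
    corpus confines to a known disc, so Guided Grad-CAM heatmaps must
    concentrate there. Construction: stage 1 computes R-G and G-R channels
    through center-tap kernels; every layer norm is put in its linear regime
    (huge eps with compensating scale, so it only subtracts the channel
    mean) with a small negative offset before the first ReLU that gates out
    pixel noise; later stages are center-tap identities; attention blocks
    are neutralized (zero squeeze weights give constant 0.5 gates, and the
    shorted sum restores the input); the head maps the two opponency
    channels to the two class logits.
    """
    from .blocks import ArchitectureConfig, CSE3D, Model, SSE3D

    arch = ArchitectureConfig(
        stage_widths=(4, 4, 4, 4, 4),
        stage_overrides={i: {"mid_channels": 4} for i in range(5)},
    )
    model = Model(arch, seed=0)

    def linearize(ln, beta=0.0):
        # (x - mean)/sqrt(var + eps)*gamma + beta ~= (x - mean) + beta for huge eps
        ln.eps = 1e8
        ln.gamma.value[...] = np.sqrt(ln.eps)
        ln.beta.value[...] = beta

    def center_identity(conv):
        """Center-tap identity on matching channels of a (2+1)D conv."""
        conv.spatial.w.value[...] = 0.0
        conv.temporal.w.value[...] = 0.0
        conv.spatial.b.value[...] = 0.0
        conv.temporal.b.value[...] = 0.0
        k = conv.spatial.k // 2
        for c in range(min(conv.c_in, conv.mid_channels)):
            conv.spatial.w.value[k, k, c, c] = 1.0
        t = conv.temporal.t // 2
        for c in range(min(conv.mid_channels, conv.c_out)):
            conv.temporal.w.value[t, c, c] = 1.0

    def neutral_attention(att):
        if att is None:
            return
        for layer in (att.cse.fc1, att.cse.fc2, att.sse.squeeze):
            layer.w.value[...] = 0.0
            layer.b.value[...] = 0.0

    for i, rpa in enumerate(model.rpa_blocks):
        rb = rpa.residual
        center_identity(rb.conv1)
        center_identity(rb.conv2)
        linearize(rb.ln1, beta=-0.02 if i == 0 else 0.0)
        linearize(rb.ln2)
        if rb.proj is not None:
            rb.proj.w.value[...] = 0.0
            rb.proj.b.value[...] = 0.0
        neutral_attention(rpa.attention)

    # Stage-1 spatial conv, center tap: channel 0 = background-nulled red-green
    # opponency, channel 1 its negation. The brightness correction makes the
    # class-neutral field color *and* the black border both read exactly zero,
    # so only the planted disc can open the first ReLU (offset -0.02 gates
    # out pixel noise).
    from .synthgi import LOWER_COLOR, UPPER_COLOR

    mid = 0.5 * (UPPER_COLOR + LOWER_COLOR)
    opp = np.array([1.0, -1.0, 0.0])
    w0 = opp - (opp @ mid) / mid.sum() * np.ones(3)
    conv1 = model.rpa_blocks[0].residual.conv1
    conv1.spatial.w.value[...] = 0.0
    k = conv1.spatial.k // 2
    conv1.spatial.w.value[k, k, :, 0] = w0
    conv1.spatial.w.value[k, k, :, 1] = -w0

    # head: R-G evidence (ch 0) -> upper logit, G-R evidence (ch 1) -> lower
    pos = CLASS_TO_INDEX["upper"]
    model.head.w.value[...] = 0.0
    model.head.b.value[...] = 0.0
    model.head.w.value[0, pos] = +1.0
    model.head.w.value[0, 1 - pos] = -1.0
    model.head.w.value[1, pos] = -1.0
    model.head.w.value[1, 1 - pos] = +1.0
    return model


def overlay(
    heatmap: Heatmap,
    segment: Segment,
    out_dir: str,
    cmap: str = "jet",
    alpha: float = 0.4,
) -> list[str]:
    """Blend the heatmap over each frame and write one PNG per frame."""
    import imageio.v3 as iio
    import matplotlib

    colormap = matplotlib.colormaps[cmap]
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i in range(segment.data.shape[0]):
        base = np.clip(segment.data[i], 0.0, 1.0)
        colored = colormap(heatmap.values[i])[..., :3]
        blend = (1.0 - alpha) * base + alpha * colored
        path = os.path.join(out_dir, f"{heatmap.segment_id}_frame{i:03d}.png")
        iio.imwrite(path, (np.clip(blend, 0, 1) * 255).astype(np.uint8))
        paths.append(path)
    return paths
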
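"""Per-image unsupervised mask refinement.

A detector's coarse mask is usually right about *where* the animal is but
wrong about its extremities.  This stage trains a small conv net on the crop
itself, with no labels at all: the net's per-pixel argmax is snapped to
precomputed superpixels (every superpixel takes its modal label) and the
cross-entropy between the net's outputs and those snapped labels is
backpropagated.  Alternating the two steps makes clusters follow color and
texture boundaries while staying spatially coherent.  Unlike the original
cluster-discovery formulation, the goal here is not many clusters — the
clusters are only used to *vote* on the coarse mask: each final cluster is
foreground iff at least ``overlap_threshold`` of its pixels fall inside the
coarse mask.  Clusters that straddle the true object boundary therefore
restore limbs and tails the coarse mask clipped, and background clusters
that leak into the coarse mask are voted out.

The refined mask is then cleaned: median filter, small foreground islands
and background holes removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import felzenszwalb

from .nnet import SegNet, softmax_xent_grad


@dataclass(frozen=True)
class RefinementConfig:
    """Knobs of the self-training loop.

    ``channels`` bounds the number of clusters; ``iterations`` is the fixed
    number of forward-refine/backward-update rounds (the loop also stops
    early if the label count collapses to ``min_labels``).  Superpixels are
    precomputed once per crop with a graph-based segmentation at a scale
    giving roughly 100-500 segments on a 128 px crop.
    """

    channels: int = 32
    n_layers: int = 3
    kernel: int = 3
    learning_rate: float = 0.1
    momentum: float = 0.9
    iterations: int = 48
    superpixel_method: str = "felzenszwalb"
    superpixel_scale: float = 30.0
    superpixel_min_size: int = 12
    min_labels: int = 2
    seed: int = 0


@dataclass
class LabelMap:
    """Per-pixel integer cluster labels over a crop (compacted, 0..n-1)."""

    labels: np.ndarray
    n_labels: int
    log: list = field(default_factory=list)  # (iteration, loss, n_labels)


@dataclass(frozen=True)
class MaskCleanConfig:
    median_kernel: int = 5          # odd; scaled with crop size by the caller
    min_island_frac: float = 0.01   # of crop area
    fill_rgb: tuple[int, int, int] = (255, 255, 255)

    def validate(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median kernel must be odd and >= 1")


def _superpixels(crop: np.ndarray, config: RefinementConfig) -> list[np.ndarray]:
    if config.superpixel_method != "felzenszwalb":
        raise ValueError(f"unknown superpixel method {config.superpixel_method!r}")
    seg = felzenszwalb(crop, scale=config.superpixel_scale, sigma=0.6,
                       min_size=config.superpixel_min_size)
    flat = seg.ravel()
    order = np.argsort(flat, kind="stable")
    bounds = np.searchsorted(flat[order], np.arange(flat.max() + 2))
    return [order[bounds[i]:bounds[i + 1]]
            for i in range(flat.max() + 1) if bounds[i + 1] > bounds[i]]


def _compact(labels: np.ndarray) -> tuple[np.ndarray, int]:
    uniq, inv = np.unique(labels, return_inverse=True)
    return inv.reshape(labels.shape).astype(np.int32), len(uniq)


def unsupervised_segment(crop: np.ndarray, config: RefinementConfig = RefinementConfig()
                         ) -> LabelMap:
    """Cluster the pixels of one RGB crop by self-trained features.

    Deterministic for a fixed (crop, config, seed).  Raises ``ValueError``
    for crops smaller than 16x16.
    """
    crop = np.asarray(crop)
    if crop.ndim != 3 or crop.shape[2] != 3:
        raise ValueError("crop must be an (H, W, 3) RGB array")
    if crop.shape[0] < 16 or crop.shape[1] < 16:
        raise ValueError("crop too small to refine (need at least 16x16)")

    x = crop.astype(np.float32) / 255.0
    sp = _superpixels(crop, config)
    net = SegNet(channels=config.channels, n_layers=config.n_layers,
                 kernel=config.kernel, seed=config.seed)

    labels = np.zeros(crop.shape[:2], dtype=np.int64)
    log: list[tuple[int, float, int, int]] = []  # (iter, loss, n_pre, n_post)
    for it in range(config.iterations):
        scores = net.forward(x)
        labels = scores.argmax(axis=2)
        n_pre = len(np.unique(labels))
        # superpixel refinement: each segment takes its modal label
        flat = labels.ravel()
        for idx in sp:
            seg_labels = flat[idx]
            flat[idx] = np.bincount(seg_labels).argmax()
        labels = flat.reshape(labels.shape)
        n_labels = len(np.unique(labels))
        loss, dscores = softmax_xent_grad(scores, labels)
        log.append((it, loss, n_pre, n_labels))
        if n_labels <= config.min_labels:
            break
        net.backward(dscores)
        net.step(config.learning_rate, config.momentum)

    compacted, n = _compact(labels)
    return LabelMap(labels=compacted, n_labels=n, log=log)


def fuse_with_coarse(labels: LabelMap | np.ndarray, coarse: np.ndarray,
                     overlap_threshold: float = 0.5) -> np.ndarray:
    """Vote each cluster region in or out of the mask by coarse-mask overlap.

    Voting happens per 8-connected component of each cluster: a region is
    foreground iff ``|region & coarse| / |region| >= overlap_threshold``.
    Spatial continuity is one of the clustering's own assumptions, and the
    component granularity keeps a coat patch from being dragged out of the
    mask by a remote, similarly colored background region of the same
    cluster (for connected clusters this is exactly global cluster voting).
    Raising the threshold can only remove regions, so the result is monotone
    non-increasing in it.  Raises ``ValueError`` on an empty coarse mask
    (nothing to improve).
    """
    lab = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    coarse = np.asarray(coarse, dtype=bool)
    if lab.shape != coarse.shape:
        raise ValueError("label map and coarse mask shapes differ")
    if not coarse.any():
        raise ValueError("coarse mask is empty: nothing to refine")
    eight = np.ones((3, 3), dtype=int)
    regions = np.zeros(lab.shape, dtype=np.int64)
    offset = 0
    for c in np.unique(lab):
        comp, n = ndimage.label(lab == c, structure=eight)
        regions[comp > 0] = comp[comp > 0] + offset
        offset += n
    flat = regions.ravel() - 1  # region ids 0..offset-1
    total = np.bincount(flat, minlength=offset)
    inside = np.bincount(flat[coarse.ravel()], minlength=offset)
    frac = inside / np.maximum(total, 1)
    return (frac >= overlap_threshold)[flat].reshape(lab.shape)


def clean_mask(mask: np.ndarray, config: MaskCleanConfig = MaskCleanConfig()
               ) -> np.ndarray:
    """Median-filter the mask, then drop small islands and fill small holes.

    The island/hole step is idempotent: applying it twice changes nothing.
    """
    config.validate()
    mask = np.asarray(mask, dtype=bool)
    out = mask
    if config.median_kernel > 1:
        out = ndimage.median_filter(out.astype(np.uint8),
                                    size=config.median_kernel) > 0
    min_area = max(1, int(round(config.min_island_frac * mask.size)))
    out = _remove_small(out, min_area)          # foreground islands
    out = ~_remove_small(~out, min_area)        # background holes
    return out


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[lab]


def apply_mask(image: np.ndarray, mask: np.ndarray,
               fill: tuple[int, int, int] = (255, 255, 255)) -> np.ndarray:
    """Copy foreground pixels verbatim; paint the background a solid color."""
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    out = np.empty_like(image)
    out[:] = np.asarray(fill, dtype=image.dtype)
    out[mask] = image[mask]
    return out


def scaled_clean_config(crop_shape: tuple[int, ...],
                        base: MaskCleanConfig = MaskCleanConfig()) -> MaskCleanConfig:
    """Median kernel 5 at 128 px, scaled (to the nearest odd) with crop size."""
    ref = max(crop_shape[0], crop_shape[1])
    k = max(3, int(round(base.median_kernel * ref / 128.0)) | 1)
    return MaskCleanConfig(median_kernel=k, min_island_frac=base.min_island_frac,
                           fill_rgb=base.fill_rgb)
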
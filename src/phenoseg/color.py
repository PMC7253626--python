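"""Coat-color quantification within a foreground mask.

Dairy-breed coats are well described by one or two color components (e.g.
white patches on near-black).  The foreground pixels are clustered with
k-means at k=2 in RGB space; if the two centroids land closer than a merge
threshold the coat is treated as monochrome.  The reported scalar phenotype
is ``white_proportion`` — the fraction of foreground pixels belonging to
the *lighter* component (by luminance), 1.0 for an all-light coat and 0.0
for an all-dark one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import MissingTargetError

#: Rec. 601 luma weights, used to order components light-first.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Single-component coats at or above this luminance count as "light".
_LIGHT_CUTOFF = 127.5


@dataclass
class ColorSummary:
    n_components: int                 # 1 or 2
    proportions: tuple[float, ...]    # sums to 1 over foreground, light first
    mean_rgb: tuple[tuple[float, float, float], ...]
    white_proportion: float

    def as_row(self) -> dict[str, float]:
        comp2 = self.mean_rgb[1] if self.n_components == 2 else (np.nan,) * 3
        return {
            "white_proportion": self.white_proportion,
            "n_color_components": self.n_components,
            "comp1_r": self.mean_rgb[0][0], "comp1_g": self.mean_rgb[0][1],
            "comp1_b": self.mean_rgb[0][2],
            "comp2_r": comp2[0], "comp2_g": comp2[1], "comp2_b": comp2[2],
        }


def coat_color_proportions(image: np.ndarray, mask: np.ndarray,
                           merge_distance: float = 30.0, seed: int = 0
                           ) -> ColorSummary:
    """Proportion and mean RGB of the light/dark coat components.

    k-means with k=2 (10 restarts, seeded) on the foreground pixels; the
    two components are merged into one when their centroids are closer than
    ``merge_distance`` in RGB Euclidean distance.  Requires at least 100
    foreground pixels.  Only pixels inside the mask ever influence the
    result.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    px = image[mask].reshape(-1, 3).astype(float)
    if px.shape[0] < 100:
        raise MissingTargetError(
            f"only {px.shape[0]} foreground pixels; need at least 100")

    uniq = np.unique(px, axis=0)
    if uniq.shape[0] < 2:
        centers = np.vstack([uniq[0], uniq[0]])
        sizes = np.array([px.shape[0], 0])
    else:
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        assign = km.fit_predict(px)
        centers = km.cluster_centers_
        sizes = np.bincount(assign, minlength=2)

    merged = np.linalg.norm(centers[0] - centers[1]) < merge_distance or sizes.min() == 0
    if merged:
        mean = tuple(px.mean(axis=0))
        luma = float(mean @ _LUMA)
        white = 1.0 if luma >= _LIGHT_CUTOFF else 0.0
        return ColorSummary(n_components=1, proportions=(1.0,),
                            mean_rgb=(mean,), white_proportion=white)

    order = np.argsort(-(centers @ _LUMA))  # light first
    props = sizes[order] / sizes.sum()
    return ColorSummary(
        n_components=2,
        proportions=tuple(float(p) for p in props),
        mean_rgb=tuple(tuple(float(v) for v in centers[i]) for i in order),
        white_proportion=float(props[0]),
    )
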
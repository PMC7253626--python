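"""Coarse detection stage: class label, region of interest, approximate mask.

The refinement stage only needs, per image, the three classic instance-
detection outputs — a class label, a bounding box (region of interest), and
an approximate object mask.  Where those come from is pluggable:

* ``OracleBackend`` serves ground-truth masks from generated fixtures,
  optionally degraded (eroded, parts dropped, pixels deleted) to mimic the
  imprecision of a real detector.  This is the backend the test-suite and
  the synthetic experiments use.
* A pretrained instance-segmentation backend would require deep-learning
  weights that are not shipped; requesting it raises
  :class:`~phenoseg.errors.BackendUnavailableError` so callers can fail
  cleanly rather than crash.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BackendUnavailableError, MissingTargetError
from .synthetic import degrade_mask


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open pixel rectangle [x0, x1) x [y0, y1), 0-based."""

    x0: int
    y0: int
    x1: int
    y1: int

    def validate(self, width: int, height: int) -> None:
        if not (0 <= self.x0 < self.x1 <= width and 0 <= self.y0 < self.y1 <= height):
            raise ValueError(f"invalid RoI {self} for {width}x{height} image")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


@dataclass
class Detection:
    """One candidate object: class label, confidence, RoI, full-frame mask."""

    class_label: str
    score: float
    roi: RegionOfInterest
    coarse_mask: np.ndarray  # bool, full image frame

    @property
    def area(self) -> int:
        return int(self.coarse_mask.sum())


def tight_roi(mask: np.ndarray) -> RegionOfInterest:
    """Smallest half-open rectangle containing the mask foreground."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise MissingTargetError("cannot take the RoI of an empty mask")
    return RegionOfInterest(x0=int(cols.min()), y0=int(rows.min()),
                            x1=int(cols.max()) + 1, y1=int(rows.max()) + 1)


@dataclass
class OracleBackend:
    """Fixture-backed detector: returns registered masks, possibly degraded.

    Register each image under an id together with its ground-truth mask (and
    optionally the generator's part sub-masks); ``detect`` then returns a
    single detection whose coarse mask is ``degrade_mask(truth)`` with this
    backend's degradation settings and whose RoI is the degraded mask's
    tight bounding box.  Unregistered ids yield no detections.
    """

    class_label: str = "cow"
    erosion_radius: int = 0
    drop_parts: tuple[str, ...] = ()
    noise_rate: float = 0.0
    seed: int = 0
    _registry: dict = field(default_factory=dict)

    def register(self, image_id: str, mask: np.ndarray,
                 parts: dict[str, np.ndarray] | None = None) -> None:
        self._registry[image_id] = (np.asarray(mask, dtype=bool), parts)

    @classmethod
    def from_fixture_dir(cls, fixture_dir, **kwargs) -> "OracleBackend":
        """Build a backend from a ``write_fixture_set`` directory."""
        from pathlib import Path

        from PIL import Image

        from .synthetic import PART_NAMES

        backend = cls(**kwargs)
        fixture_dir = Path(fixture_dir)
        for mask_path in sorted((fixture_dir / "masks").glob("*.png")):
            image_id = mask_path.stem
            mask = np.asarray(Image.open(mask_path)) > 127
            parts = {}
            for pname in PART_NAMES:
                ppath = fixture_dir / "parts" / f"{image_id}_{pname}.png"
                if ppath.exists():
                    parts[pname] = np.asarray(Image.open(ppath)) > 127
            backend.register(image_id, mask, parts or None)
        return backend

    def detect(self, image: np.ndarray, image_id: str | None = None
               ) -> list[Detection]:
        entry = self._registry.get(image_id)
        if entry is None:
            return []
        mask, parts = entry
        degraded = degrade_mask(mask, erosion_radius=self.erosion_radius,
                                drop_parts=self.drop_parts,
                                noise_rate=self.noise_rate,
                                seed=self.seed, parts=parts)
        if not degraded.any():
            return []
        degraded_clean = 1.0 if (self.erosion_radius == 0
                                 and not self.drop_parts
                                 and self.noise_rate == 0) else 0.9
        return [Detection(class_label=self.class_label, score=degraded_clean,
                          roi=tight_roi(degraded), coarse_mask=degraded)]


class PretrainedBackend:
    """Placeholder for a pretrained instance-segmentation detector.

    No pretrained weights ship with this package, so instantiation always
    raises :class:`BackendUnavailableError`.
    """

    def __init__(self, *args, **kwargs):
        raise BackendUnavailableError(
            "the 'pretrained' detector backend requires instance-segmentation "
            "weights that are not installed; use the 'oracle' backend")


def make_backend(name: str, **kwargs):
    if name == "oracle":
        return OracleBackend(**kwargs)
    if name == "pretrained":
        return PretrainedBackend(**kwargs)
    raise BackendUnavailableError(f"unknown detector backend {name!r}")


def detect(image: np.ndarray, backend, image_id: str | None = None
           ) -> list[Detection]:
    """Run a backend on one image; every detection satisfies the invariants
    (mask foreground inside the RoI rectangle)."""
    if np.asarray(image).size == 0:
        raise ValueError("empty image")
    return backend.detect(image, image_id=image_id)


def select_target(detections: list[Detection], wanted_class: str,
                  min_score: float = 0.5) -> Detection:
    """Pick the wanted-class detection with the largest mask area.

    Ties break on higher score, then on smaller RoI x0.  Raises
    :class:`MissingTargetError` when nothing of the wanted class (at or
    above ``min_score``) is present — callers record the image as failed.
    """
    cands = [d for d in detections
             if d.class_label == wanted_class and d.score >= min_score]
    if not cands:
        raise MissingTargetError(
            f"no detection of class {wanted_class!r} with score >= {min_score}")
    return max(cands, key=lambda d: (d.area, d.score, -d.roi.x0))


def crop_to_roi(image: np.ndarray, roi: RegionOfInterest, margin: int = 10
                ) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop the RoI expanded by ``margin``, clipped to the image bounds.

    Returns (crop, (x_offset, y_offset)); pasting the crop back at the
    offset reproduces the original pixels.
    """
    h, w = image.shape[:2]
    roi.validate(w, h)
    x0 = max(0, roi.x0 - margin)
    y0 = max(0, roi.y0 - margin)
    x1 = min(w, roi.x1 + margin)
    y1 = min(h, roi.y1 + margin)
    return image[y0:y1, x0:x1].copy(), (x0, y0)
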
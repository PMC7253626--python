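"""Synthetic side-view quadruped fixtures with exact ground truth.

Real sire-catalogue photographs cannot be redistributed, so every stage of
the pipeline is exercised on generated scenes instead: a two-tone quadruped
silhouette (body, humped withers, neck, head, four legs, tail, chest and
belly bulges) rasterized without anti-aliasing onto a flat, gradient, or
textured background.  Because the silhouette is a union of analytic shapes,
the generator knows the exact mask, the exact per-part sub-masks, the exact
light-coat fraction, and the exact landmark coordinates — so downstream
accuracy can be measured, not eyeballed.

The module also simulates pedigrees with phenotypes of known heritability by
gene dropping, for testing the genetics stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk

from . import morphometry
from .errors import InvalidSpecError
from .morphometry import LANDMARK_NAMES, TraitVector

PART_NAMES = ("tail", "rear_hoof", "front_hoof", "ear", "nose")

# ---------------------------------------------------------------------------
# template geometry, in fractions of the canvas (x right, y down)
# ---------------------------------------------------------------------------
_BODY_C = (0.42, 0.48)
_BODY_RY = 0.15
_HUMP_X, _HUMP_SIGMA, _HUMP_AMP = 0.58, 0.035, 0.09  # withers bump on the back
_BELLY = ((0.41, 0.625), (0.05, 0.04))    # belly bulge between leg pairs
_BRISKET = ((0.67, 0.545), (0.04, 0.05))  # chest bulge ahead of front legs
_LEG_X = ((0.19, 0.25), (0.27, 0.32), (0.50, 0.555), (0.60, 0.655))
_GROUND = 0.92
_NECK_TOP = ((0.62, 0.34), (0.78, 0.245))  # top edge of the neck band
_HEAD_C = (0.82, 0.28)
_HEAD_R0 = (0.095, 0.075)
_TAIL = (0.125, 0.185, 0.42, 0.72)         # x0, x1, y0, y1
_EAR = ((0.80, 0.235), 0.03)
_NOSE_X = 0.88
_HOOF_DEPTH = 0.06


@dataclass(frozen=True)
class SilhouetteSpec:
    """Parameters of one synthetic scene.

    Proportions are fractions of the canvas: ``body_length`` the horizontal
    diameter of the trunk, ``leg_length`` ground-to-leg-top, ``head_size``
    the head's horizontal diameter, ``neck_width`` the vertical thickness of
    the neck band.  ``target_white_proportion`` is the requested fraction of
    light coat within the silhouette; the achieved value (recorded in the
    ground truth) may differ by up to ±0.05.
    """

    width: int = 128
    height: int = 128
    body_length: float = 0.52
    leg_length: float = 0.42
    head_size: float = 0.19
    neck_width: float = 0.085
    n_patches: int = 6
    light_rgb: tuple[int, int, int] = (235, 233, 228)
    dark_rgb: tuple[int, int, int] = (48, 40, 32)
    target_white_proportion: float = 0.35
    background: str = "gradient"  # flat | gradient | textured
    background_rgb: tuple[int, int, int] = (115, 145, 95)
    noise_sigma: float = 1.0

    def validate(self) -> None:
        if self.width < 48 or self.height < 48:
            raise InvalidSpecError("canvas must be at least 48x48")
        if not 0.0 <= self.target_white_proportion <= 1.0:
            raise InvalidSpecError("target_white_proportion must be in [0, 1]")
        if self.background not in ("flat", "gradient", "textured"):
            raise InvalidSpecError(f"unknown background {self.background!r}")
        if self.n_patches < 1 and 0.0 < self.target_white_proportion < 1.0:
            raise InvalidSpecError("need n_patches >= 1 for a two-tone coat")
        for frac in (self.body_length, self.leg_length, self.head_size,
                     self.neck_width):
            if not 0.01 < frac < 0.95:
                raise InvalidSpecError("proportions must be fractions in (0.01, 0.95)")


@dataclass
class GroundTruth:
    """Everything the generator knows exactly about one scene."""

    mask: np.ndarray                       # bool (H, W)
    parts: dict[str, np.ndarray]           # droppable sub-masks
    landmarks: dict[str, tuple[int, int]]  # all 13, on the mask boundary
    light_mask: np.ndarray                 # light-coat pixels (subset of mask)
    white_proportion: float                # light / foreground, exact
    traits: TraitVector
    noise_sigma: float
    spec: SilhouetteSpec


def _grid(spec: SilhouetteSpec):
    xs = (np.arange(spec.width) + 0.5) / spec.width
    ys = (np.arange(spec.height) + 0.5) / spec.height
    return np.meshgrid(xs, ys)


def _ellipse(gx, gy, c, r):
    return ((gx - c[0]) / r[0]) ** 2 + ((gy - c[1]) / r[1]) ** 2 <= 1.0


def _rect(gx, gy, x0, x1, y0, y1):
    return (gx >= x0) & (gx <= x1) & (gy >= y0) & (gy <= y1)


def _build_shapes(spec: SilhouetteSpec) -> dict[str, np.ndarray]:
    gx, gy = _grid(spec)
    body_rx = spec.body_length / 2.0
    head_r = (spec.head_size / 0.19 * _HEAD_R0[0],
              spec.head_size / 0.19 * _HEAD_R0[1])
    leg_top = _GROUND - spec.leg_length

    # Torso: one region per column between a top profile (ellipse top lowered
    # by a smooth withers bump) and the ellipse bottom, so no column of the
    # torso ever splits into separate vertical runs.
    cx, cy = _BODY_C
    el = (gx - cx) / body_rx
    inside = np.abs(el) <= 1.0
    half = _BODY_RY * np.sqrt(np.clip(1.0 - el ** 2, 0.0, 1.0))
    bump = _HUMP_AMP * np.exp(-(((gx - _HUMP_X) / _HUMP_SIGMA) ** 2))
    torso = inside & (gy >= cy - half - bump) & (gy <= cy + half)
    body_ellipse = _ellipse(gx, gy, _BODY_C, (body_rx, _BODY_RY))

    shapes = {
        "torso": torso,
        "body": body_ellipse,
        "hump": torso & ~body_ellipse,
        "belly": _ellipse(gx, gy, *_BELLY),
        "brisket": _ellipse(gx, gy, *_BRISKET),
        "head": _ellipse(gx, gy, _HEAD_C, head_r),
        "tail": _rect(gx, gy, *_TAIL),
    }
    for i, (x0, x1) in enumerate(_LEG_X):
        shapes[f"leg{i}"] = _rect(gx, gy, x0, x1, leg_top, _GROUND)
    (nx0, ny0), (nx1, ny1) = _NECK_TOP
    t = np.clip((gx - nx0) / (nx1 - nx0), 0.0, 1.0)
    y_top = ny0 + t * (ny1 - ny0)
    shapes["neck"] = ((gx >= nx0) & (gx <= nx1)
                      & (gy >= y_top) & (gy <= y_top + spec.neck_width))
    return shapes


def _part_masks(shapes: dict[str, np.ndarray], spec: SilhouetteSpec,
                gx, gy) -> dict[str, np.ndarray]:
    hoof_y = _GROUND - _HOOF_DEPTH
    (ec, er) = _EAR
    return {
        "tail": shapes["tail"] & ~shapes["body"],
        "rear_hoof": shapes["leg0"] & (gy >= hoof_y),
        "front_hoof": shapes["leg3"] & (gy >= hoof_y),
        "ear": shapes["head"] & (((gx - ec[0]) ** 2 + (gy - ec[1]) ** 2) <= er ** 2),
        "nose": shapes["head"] & (gx > _NOSE_X),
        # not in the detector-degradation vocabulary, but recorded so tests
        # can emulate a silhouette whose whole head went missing
        "head": shapes["head"] & ~shapes["neck"],
    }


def _raster_extreme(part: np.ndarray, which: str) -> tuple[int, int]:
    """Extreme pixel of a part raster with the shared tie-break rules."""
    rows, cols = np.nonzero(part)
    if rows.size == 0:
        raise InvalidSpecError("degenerate part raster")
    if which == "bottom_left":
        r = rows.max()
        return int(cols[rows == r].min()), int(r)
    if which == "bottom_right":
        r = rows.max()
        return int(cols[rows == r].max()), int(r)
    if which == "top_left":
        c = cols.min()
        return int(c), int(rows[cols == c].min())
    if which == "rightmost_top":
        c = cols.max()
        return int(c), int(rows[cols == c].min())
    if which == "top_median":
        r = rows.min()
        xs = np.sort(cols[rows == r])
        return int(xs[len(xs) // 2]), int(r)
    if which == "bottom_median":
        r = rows.max()
        xs = np.sort(cols[rows == r])
        return int(xs[len(xs) // 2]), int(r)
    raise ValueError(which)


def _true_landmarks(shapes: dict[str, np.ndarray], spec: SilhouetteSpec,
                    mask: np.ndarray) -> dict[str, tuple[int, int]]:
    """Landmark coordinates from the generator's private part geometry.

    These apply the same documented landmark definitions as the outline
    extractor, but evaluate them on the per-part rasters the generator
    alone knows — an independent computation path.
    """
    w = spec.width
    lm: dict[str, tuple[int, int]] = {}
    lm["rear_hoof"] = _raster_extreme(shapes["leg0"], "bottom_left")
    lm["front_hoof"] = _raster_extreme(shapes["leg3"], "bottom_right")
    lm["nose_tip"] = _raster_extreme(shapes["head"], "rightmost_top")
    lm["tail_head"] = _raster_extreme(shapes["tail"], "top_left")
    lm["poll"] = _raster_extreme(shapes["head"], "top_median")
    lm["back_top"] = _raster_extreme(shapes["body"], "top_median")
    lm["withers"] = _raster_extreme(shapes["hump"], "top_median")
    lm["brisket"] = _raster_extreme(shapes["brisket"], "bottom_median")
    lm["belly_rear"] = _raster_extreme(shapes["belly"], "bottom_median")

    # neck cut: leftmost column where the neck band is clear of both the
    # torso (>=1 px gap) and the head, offset a little into the plateau
    body_region = shapes["torso"] | shapes["belly"] | shapes["brisket"]
    neck = shapes["neck"]
    head = shapes["head"]
    plateau = []
    for cx in range(w):
        ncol = np.nonzero(neck[:, cx])[0]
        if ncol.size == 0 or head[:, cx].any():
            continue
        bcol = np.nonzero(body_region[:, cx])[0]
        if bcol.size == 0 or ncol[-1] + 1 < bcol[0]:
            plateau.append(cx)
    if not plateau:
        raise InvalidSpecError("neck band never separates from the torso")
    cols_any = np.nonzero(mask.any(axis=0))[0]
    length = int(cols_any[-1] - cols_any[0] + 1)
    xc = min(plateau) + max(2, round(0.03 * length))
    ncol = np.nonzero(neck[:, xc])[0]
    lm["neck_top"] = (int(xc), int(ncol[0]))
    lm["throat"] = (int(xc), int(ncol[-1]))
    xj = int(round((xc + lm["nose_tip"][0]) / 2.0))
    hcol = np.nonzero((head | neck)[:, xj])[0]
    lm["muzzle_top"] = (xj, int(hcol[0]))
    lm["jaw"] = (xj, int(hcol[-1]))
    return lm


def _coat_light_mask(mask: np.ndarray, spec: SilhouetteSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """Light-coat region: union of random disks, scaled to hit the target.

    A bisection on the common radius scale drives the rendered light
    fraction to the requested value; the achieved fraction is whatever the
    final raster says.
    """
    target = spec.target_white_proportion
    if target >= 0.999:
        return mask.copy()
    light = np.zeros_like(mask)
    if target <= 0.001:
        return light
    rows, cols = np.nonzero(mask)
    idx = rng.integers(0, rows.size, size=spec.n_patches)
    cy, cx = rows[idx].astype(float), cols[idx].astype(float)
    base = rng.uniform(0.4, 1.0, size=spec.n_patches) * 0.10 * max(spec.width,
                                                                   spec.height)
    yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    d2 = np.stack([(yy - y) ** 2 + (xx - x) ** 2 for y, x in zip(cy, cx)])
    nfg = mask.sum()

    def frac(s: float) -> tuple[float, np.ndarray]:
        r2 = (s * base) ** 2
        lt = (d2 <= r2[:, None, None]).any(axis=0) & mask
        return lt.sum() / nfg, lt

    lo, hi = 0.0, 8.0
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        f, lt = frac(mid)
        if abs(f - target) <= 0.005:
            return lt
        if f < target:
            lo = mid
        else:
            hi = mid
    return frac(0.5 * (lo + hi))[1]


def _render_background(spec: SilhouetteSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    base = np.asarray(spec.background_rgb, dtype=float)
    img = np.empty((h, w, 3), dtype=float)
    if spec.background == "flat":
        img[:] = base
    elif spec.background == "gradient":
        ramp = np.linspace(1.25, 0.75, h)[:, None, None]
        img[:] = base[None, None, :] * ramp
    else:  # textured
        fieldn = rng.standard_normal((h, w))
        fieldn = ndimage.gaussian_filter(fieldn, sigma=6.0)
        sd = fieldn.std()
        if sd > 0:
            fieldn = fieldn / sd
        img[:] = base[None, None, :] + 20.0 * fieldn[:, :, None]
    return img


def make_silhouette_image(spec: SilhouetteSpec, seed: int = 0
                          ) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; returns (uint8 RGB image, exact ground truth).

    Deterministic for fixed (spec, seed).  Raises
    :class:`~phenoseg.errors.InvalidSpecError` when the silhouette would
    touch the canvas border or fall apart into disconnected pieces.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    gx, gy = _grid(spec)
    shapes = _build_shapes(spec)
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for m in shapes.values():
        mask |= m

    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise InvalidSpecError("silhouette touches the canvas border")
    _, ncomp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if ncomp != 1:
        raise InvalidSpecError("silhouette is not a single connected shape")

    parts = _part_masks(shapes, spec, gx, gy)
    landmarks = _true_landmarks(shapes, spec, mask)

    light = _coat_light_mask(mask, spec, rng)
    white_prop = float(light.sum() / mask.sum())

    img = _render_background(spec, rng)
    img[mask] = np.asarray(spec.dark_rgb, dtype=float)
    img[light] = np.asarray(spec.light_rgb, dtype=float)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    outline = morphometry.extract_outline(mask)
    traits = morphometry.compute_traits(landmarks, outline)
    truth = GroundTruth(mask=mask, parts=parts, landmarks=landmarks,
                        light_mask=light, white_proportion=white_prop,
                        traits=traits, noise_sigma=spec.noise_sigma, spec=spec)
    return img, truth


# ---------------------------------------------------------------------------
# mask degradation (mimics an imprecise detector mask)
# ---------------------------------------------------------------------------

def degrade_mask(mask: np.ndarray, erosion_radius: int = 0,
                 drop_parts: tuple[str, ...] = (), noise_rate: float = 0.0,
                 seed: int = 0, parts: dict[str, np.ndarray] | None = None
                 ) -> np.ndarray:
    """Simulate detector imprecision: erode, delete named parts, drop pixels.

    With all knobs at zero the input is returned unchanged.  Dropped parts
    must be provided via ``parts`` (the generator's sub-masks).  ``noise_rate``
    deletes that fraction of the remaining foreground pixels at random, so
    the output foreground is always a subset of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot degrade an empty mask")
    out = mask.copy()
    if erosion_radius > 0:
        out = ndimage.binary_erosion(out, structure=disk(erosion_radius),
                                     border_value=0)
    for name in drop_parts:
        if parts is None or name not in parts:
            raise ValueError(f"part {name!r} not available; pass parts=")
        out &= ~parts[name]
    if noise_rate > 0:
        rng = np.random.default_rng(seed)
        rows, cols = np.nonzero(out)
        k = int(round(noise_rate * rows.size))
        if k:
            sel = rng.choice(rows.size, size=k, replace=False)
            out[rows[sel], cols[sel]] = False
    return out


# ---------------------------------------------------------------------------
# fixture sets
# ---------------------------------------------------------------------------

def make_fixture_batch(n: int, seed: int = 0, size: int = 128,
                       white_range: tuple[float, float] = (0.05, 0.95),
                       noise_sigma: float = 1.0
                       ) -> list[tuple[np.ndarray, GroundTruth]]:
    """Generate ``n`` varied scenes (in memory) with evenly spread coat targets.

    Backgrounds cycle through the three kinds and body proportions get a
    small jitter so no two scenes are identical.
    """
    rng = np.random.default_rng(seed)
    targets = np.linspace(white_range[0], white_range[1], n)
    kinds = ("flat", "gradient", "textured")
    out = []
    for i in range(n):
        spec = SilhouetteSpec(
            width=size, height=size,
            body_length=0.52 * rng.uniform(0.96, 1.04),
            leg_length=0.42 * rng.uniform(0.96, 1.04),
            head_size=0.19 * rng.uniform(0.96, 1.04),
            neck_width=0.085 * rng.uniform(0.96, 1.04),
            n_patches=int(rng.integers(3, 9)),
            target_white_proportion=float(targets[i]),
            background=kinds[i % 3],
            background_rgb=tuple(int(v) for v in
                                 rng.integers(80, 170, size=3)),
            noise_sigma=noise_sigma,
        )
        out.append(make_silhouette_image(spec, seed=int(rng.integers(2 ** 31))))
    return out


def write_fixture_set(out_dir, n: int, seed: int = 0, size: int = 128,
                      noise_sigma: float = 1.0) -> pd.DataFrame:
    """Write a fixture set to disk: images/, masks/, parts/, truth.csv.

    Returns the truth table (one row per image: landmark coordinates, the
    achieved white proportion, and the 14 traits).
    """
    from pathlib import Path

    from PIL import Image

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(exist_ok=True)
    (out_dir / "parts").mkdir(exist_ok=True)
    rows = []
    for i, (img, truth) in enumerate(make_fixture_batch(n, seed=seed, size=size,
                                                        noise_sigma=noise_sigma)):
        name = f"fix{i:03d}"
        Image.fromarray(img).save(out_dir / "images" / f"{name}.png")
        Image.fromarray((truth.mask * 255).astype(np.uint8)).save(
            out_dir / "masks" / f"{name}.png")
        for pname, pmask in truth.parts.items():
            Image.fromarray((pmask * 255).astype(np.uint8)).save(
                out_dir / "parts" / f"{name}_{pname}.png")
        row = {"image_id": name, "white_proportion": truth.white_proportion}
        for lname in LANDMARK_NAMES:
            row[f"{lname}_x"], row[f"{lname}_y"] = truth.landmarks[lname]
        row.update(truth.traits.as_row())
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "truth.csv", index=False)
    return df


# ---------------------------------------------------------------------------
# pedigree + phenotype simulation (gene dropping)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeSimSpec:
    """Simulated pedigree design with known heritability.

    Phenotypes follow y = mu + a + e with additive values generated by gene
    dropping: founders draw a ~ N(0, sigma2_a); offspring take the mean of
    their known parents' values plus a Mendelian-sampling deviation whose
    variance is sigma2_a/2 with both parents known and 3*sigma2_a/4 with one.
    """

    n_founders: int = 100
    n_generations: int = 4
    family_size_mean: float = 2.6
    h2: float = 0.5
    phenotypic_var: float = 1.0
    missing_parent_rate: float = 0.0
    mu: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 2:
            raise InvalidSpecError("need at least 2 founders")
        if not 0.0 <= self.h2 < 1.0:
            raise InvalidSpecError("h2 must lie in [0, 1)")
        if self.phenotypic_var <= 0:
            raise InvalidSpecError("phenotypic variance must be positive")
        if not 0.0 <= self.missing_parent_rate < 1.0:
            raise InvalidSpecError("missing_parent_rate must be in [0, 1)")


def simulate_pedigree_phenotypes(spec: PedigreeSimSpec, trait: str = "trait"
                                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate a multi-generation pedigree and one phenotype by gene dropping.

    Returns (pedigree, phenotypes, breeding_values): the pedigree table uses
    '0' for unknown parents (all founders, plus a ``missing_parent_rate``
    share of recorded parents masked to mimic incomplete records — gene
    dropping then treats those parents as unknown, exactly as an analyst
    using the recorded pedigree would).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    s2a = spec.h2 * spec.phenotypic_var
    s2e = (1.0 - spec.h2) * spec.phenotypic_var

    sires: list[int] = []
    dams: list [int] = []
    for _ in range(spec.n_founders):
        sires.append(0)
        dams.append(0)
    pool = list(range(1, spec.n_founders + 1))
    for _ in range(spec.n_generations):
        if len(pool) < 2:
            break
        perm = rng.permutation(pool)
        half = len(perm) // 2
        couples = list(zip(perm[:half], perm[half:2 * half]))
        newborn = []
        for s, d in couples:
            for _ in range(max(1, int(rng.poisson(spec.family_size_mean)))):
                child = len(sires) + 1
                keep_s = rng.random() >= spec.missing_parent_rate
                keep_d = rng.random() >= spec.missing_parent_rate
                sires.append(int(s) if keep_s else 0)
                dams.append(int(d) if keep_d else 0)
                newborn.append(child)
        pool = newborn

    n = len(sires)
    a = np.zeros(n)
    sd_a = np.sqrt(s2a)
    for i in range(n):
        s, d = sires[i], dams[i]
        if s == 0 and d == 0:
            a[i] = rng.normal(0.0, sd_a)
        elif s != 0 and d != 0:
            a[i] = 0.5 * (a[s - 1] + a[d - 1]) + rng.normal(0.0, np.sqrt(0.5 * s2a))
        else:
            p = s if s != 0 else d
            a[i] = 0.5 * a[p - 1] + rng.normal(0.0, np.sqrt(0.75 * s2a))
    e = rng.normal(0.0, np.sqrt(s2e), size=n)
    y = spec.mu + a + e

    ids = [str(i) for i in range(1, n + 1)]
    pedigree = pd.DataFrame({"id": ids,
                             "sire": [str(s) for s in sires],
                             "dam": [str(d) for d in dams]})
    phenotypes = pd.DataFrame({"id": ids, trait: y})
    bv = pd.Series(a, index=ids, name="breeding_value")
    return pedigree, phenotypes, bv
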
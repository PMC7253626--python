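"""Batch orchestration: images -> masks -> phenotypes -> heritability.

Each stage is resumable from the previous stage's on-disk outputs (masks as
0/255 PNGs, phenotypes as CSV), failures are recorded per image and never
abort a batch, and a fixed global seed makes every stage bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import coarse, color, genetics, morphometry, refine
from .errors import PhenosegError
from .morphometry import LANDMARK_NAMES, TRAIT_NAMES

log = logging.getLogger("phenoseg")

PHENOTYPE_NAMES = ("white_proportion",) + TRAIT_NAMES


@dataclass(frozen=True)
class PipelineConfig:
    backend: str = "oracle"
    wanted_class: str = "cow"
    min_score: float = 0.5
    margin: int = 10
    orientation: str = "assume_right"
    overlap_threshold: float = 0.5
    merge_distance: float = 30.0
    min_outline_object: int = 20
    refinement: refine.RefinementConfig = field(default_factory=refine.RefinementConfig)
    clean: refine.MaskCleanConfig = field(default_factory=refine.MaskCleanConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        ref = refine.RefinementConfig(**raw.pop("refinement", {}))
        cln = refine.MaskCleanConfig(**raw.pop("clean", {}))
        return cls(refinement=ref, clean=cln, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _image_seed(global_seed: int, image_id: str) -> int:
    return (global_seed * 1000003 + zlib.crc32(image_id.encode())) % (2 ** 31)


def segment_image(image: np.ndarray, backend, image_id: str,
                  config: PipelineConfig) -> np.ndarray:
    """Full-frame refined mask for one image (may raise MissingTargetError).

    Orientation is normalised by the batch driver; this function assumes a
    right-facing animal."""
    dets = coarse.detect(image, backend, image_id=image_id)
    det = coarse.select_target(dets, config.wanted_class, config.min_score)
    crop, (ox, oy) = coarse.crop_to_roi(image, det.roi, margin=config.margin)
    ccrop = det.coarse_mask[oy:oy + crop.shape[0], ox:ox + crop.shape[1]]
    seed = _image_seed(config.seed, image_id)
    ref_cfg = dataclasses.replace(config.refinement, seed=seed)
    labels = refine.unsupervised_segment(crop, ref_cfg)
    fused = refine.fuse_with_coarse(labels, ccrop, config.overlap_threshold)
    cleaned = refine.clean_mask(fused, refine.scaled_clean_config(crop.shape,
                                                                 config.clean))
    full = np.zeros(image.shape[:2], dtype=bool)
    full[oy:oy + crop.shape[0], ox:ox + crop.shape[1]] = cleaned
    return full


def run_segment(images: dict[str, np.ndarray] | Path | str, backend,
                config: PipelineConfig = PipelineConfig(),
                out_dir: Path | str | None = None
                ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Segment a batch; returns (masks by id, manifest).

    ``images`` is either {image_id: RGB array} or a directory of PNG/JPEG
    files.  One bad image never aborts the batch: its manifest row records
    the failure reason instead.
    """
    if not isinstance(images, dict):
        img_dir = Path(images)
        paths = sorted(p for p in img_dir.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        images = {}
        unreadable = {}
        for p in paths:
            try:
                images[p.stem] = np.asarray(Image.open(p).convert("RGB"))
            except OSError as exc:
                unreadable[p.stem] = str(exc)
    else:
        unreadable = {}

    masks: dict[str, np.ndarray] = {}
    rows = []
    for image_id in sorted(images):
        t0 = time.perf_counter()
        status, reason = "ok", ""
        try:
            image = images[image_id]
            if config.orientation != "assume_right":
                image, _, _ = morphometry.orient_right(
                    image, np.ones(image.shape[:2], bool), config.orientation)
            masks[image_id] = segment_image(image, backend, image_id, config)
        except PhenosegError as exc:
            status, reason = "missing-target", str(exc)
        except (ValueError, OSError) as exc:
            status, reason = "failed", str(exc)
        rows.append({"image_id": image_id, "status": status, "reason": reason,
                     "seconds": round(time.perf_counter() - t0, 3)})
    for image_id, reason in unreadable.items():
        rows.append({"image_id": image_id, "status": "failed", "reason": reason,
                     "seconds": 0.0})
    manifest = pd.DataFrame(rows).sort_values("image_id").reset_index(drop=True)
    manifest["config_hash"] = config.config_hash()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for image_id, mask in masks.items():
            Image.fromarray((mask * 255).astype(np.uint8)).save(
                out_dir / f"{image_id}.png")
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return masks, manifest


def phenotype_image(image: np.ndarray, mask: np.ndarray,
                    config: PipelineConfig = PipelineConfig()) -> dict:
    """One phenotype row: coat color, 13 landmarks, 14 traits, missing flags."""
    summary = color.coat_color_proportions(image, mask,
                                           merge_distance=config.merge_distance,
                                           seed=config.seed)
    outline = morphometry.extract_outline(mask, min_object=config.min_outline_object)
    lm = morphometry.extract_landmarks(outline)
    traits = morphometry.compute_traits(lm, outline)
    row: dict = {}
    row.update(summary.as_row())
    for name in LANDMARK_NAMES:
        pt = lm[name]
        row[f"{name}_x"] = np.nan if pt is None else pt[0]
        row[f"{name}_y"] = np.nan if pt is None else pt[1]
    row.update(traits.as_row())
    row["missing_landmarks"] = ";".join(n for n in LANDMARK_NAMES if lm[n] is None)
    row["n_missing_traits"] = len(traits.missing)
    return row


def run_phenotypes(images: dict[str, np.ndarray] | Path | str,
                   masks: dict[str, np.ndarray] | Path | str,
                   config: PipelineConfig = PipelineConfig(),
                   out_csv: Path | str | None = None) -> pd.DataFrame:
    """Phenotype every image that has a mask; one row per image.

    Rows with missing landmarks are retained and flagged (their dependent
    traits are NaN); the heritability stage later drops flagged records per
    trait.
    """
    if not isinstance(images, dict):
        img_dir = Path(images)
        images = {p.stem: np.asarray(Image.open(p).convert("RGB"))
                  for p in sorted(img_dir.iterdir())
                  if p.suffix.lower() in (".png", ".jpg", ".jpeg")}
    if not isinstance(masks, dict):
        mask_dir = Path(masks)
        masks = {p.stem: np.asarray(Image.open(p)) > 127
                 for p in sorted(mask_dir.glob("*.png"))}

    rows = []
    for image_id in sorted(masks):
        if image_id not in images:
            continue
        row = {"image_id": image_id, "status": "ok", "reason": ""}
        try:
            row.update(phenotype_image(images[image_id], masks[image_id], config))
        except PhenosegError as exc:
            row["status"], row["reason"] = "missing-target", str(exc)
        except ValueError as exc:
            row["status"], row["reason"] = "failed", str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_csv, index=False)
    return df


def run_heritability(phenotypes: pd.DataFrame | Path | str,
                     pedigree: pd.DataFrame | Path | str,
                     traits: list[str] | str = "all",
                     gibbs: genetics.GibbsConfig = genetics.GibbsConfig(),
                     out_dir: Path | str | None = None,
                     id_column: str = "image_id") -> pd.DataFrame:
    """Per-trait heritability from a phenotype table and pedigree.

    The relationship matrix is built once on the full pedigree (ancestors
    contribute relationship information even without records) and subsetted
    per trait to the individuals with a non-missing phenotype.  Traits with
    fewer than 10 phenotyped individuals are skipped with a logged reason.
    """
    phen = phenotypes if isinstance(phenotypes, pd.DataFrame) else pd.read_csv(
        phenotypes)
    ped = genetics.read_pedigree(pedigree)
    a_full = genetics.build_a_matrix(ped)
    index = ped.index

    if traits == "all":
        traits = [t for t in phen.columns
                  if t in PHENOTYPE_NAMES or
                  (t not in (id_column, "id", "status", "reason")
                   and pd.api.types.is_numeric_dtype(phen[t])
                   and not t.endswith(("_x", "_y"))
                   and t not in ("n_color_components", "n_missing_traits",
                                 "comp1_r", "comp1_g", "comp1_b",
                                 "comp2_r", "comp2_g", "comp2_b"))]
    idc = id_column if id_column in phen.columns else "id"
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for k, trait in enumerate(traits):
        sub = phen[[idc, trait]].dropna()
        sub = sub[sub[idc].astype(str).isin(index)]
        if len(sub) < 10:
            log.warning("trait %s skipped: only %d phenotyped records",
                        trait, len(sub))
            rows.append({"trait": trait, "n": len(sub), "status": "skipped"})
            continue
        pos = np.array([index[str(i)] for i in sub[idc]])
        order = np.argsort(pos)
        pos = pos[order]
        yv = sub[trait].to_numpy(dtype=float)[order]
        cfg = dataclasses.replace(gibbs, seed=(gibbs.seed * 997 + k) % (2 ** 31))
        post = genetics.gibbs_animal_model(yv, a_full[np.ix_(pos, pos)], cfg)
        summ, dens = genetics.summarize_posterior(post)
        rows.append({"trait": trait, "n": len(sub), "status": "ok", **summ})
        if out_dir is not None:
            pd.DataFrame({"sigma2_a": post.sigma2_a, "sigma2_e": post.sigma2_e,
                          "h2": post.h2}).to_csv(
                out_dir / f"samples_{trait}.csv", index=False)
            pd.DataFrame(dens, columns=["h2", "density"]).to_csv(
                out_dir / f"density_{trait}.csv", index=False)
    summary = pd.DataFrame(rows)
    if out_dir is not None:
        summary.to_csv(Path(out_dir) / "summary.csv", index=False)
    return summary
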
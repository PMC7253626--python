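"""Silhouette morphometrics: outline, anatomical landmarks, conformation traits.

The input is a cleaned binary mask of a single right-facing quadruped seen in
side profile.  From the mask we trace the object outline, locate 13 named
anatomical points by documented geometric rules, and derive 14 conformation
measurements (distances in pixels, areas in squared pixels).  Because the
source images carry no physical scale, all traits are reported in raw pixel
units.

Coordinates are 0-based with x increasing rightward and y increasing
downward; points are (x, y) tuples.  A landmark rule that finds no
satisfying point returns ``None`` (missing) rather than guessing, and any
trait depending on a missing landmark is flagged missing.

Landmark rules (the animal faces right, so "front" is the right side):

==============  ============================================================
rear_hoof       boundary point nearest the image's bottom-left corner
front_hoof      boundary point nearest the image's bottom-right corner
nose_tip        rightmost boundary point (requires the head to be present)
tail_head       leftmost boundary point in the upper half of the silhouette
poll            highest boundary point right of the neck cut (top of head)
back_top        highest boundary point in the rear band of the back
withers         highest boundary point between mid-back and the neck cut
neck_top,       top and bottom of the silhouette at the neck cut: the
throat          column of minimal vertical thickness between body and head
muzzle_top,     top and bottom of the head at the column midway between the
jaw             neck cut and the nose tip
brisket         deepest non-leg boundary point forward of the front legs
belly_rear      deepest boundary point in the widest gap between leg pairs
==============  ============================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import MissingTargetError


def _drop_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 8-connected foreground components smaller than ``min_area``."""
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[lab]

LANDMARK_NAMES = (
    "rear_hoof", "front_hoof", "nose_tip", "muzzle_top", "poll", "jaw",
    "throat", "neck_top", "withers", "back_top", "tail_head", "brisket",
    "belly_rear",
)

TRAIT_NAMES = (
    "gait", "chest_depth", "back_height", "back_deviation", "front_height",
    "back_leg_height", "front_leg_height", "cow_length", "face_length",
    "head_length", "head_width", "neck_width", "body_area_triangle",
    "body_area_polygon",
)

#: Landmarks each trait depends on (used for missingness propagation).
TRAIT_REQUIREMENTS: dict[str, frozenset[str]] = {
    "gait": frozenset({"front_hoof", "rear_hoof"}),
    "chest_depth": frozenset({"brisket", "withers"}),
    "back_height": frozenset({"back_top", "rear_hoof", "front_hoof"}),
    "back_deviation": frozenset({"withers", "tail_head"}),
    "front_height": frozenset({"withers", "rear_hoof", "front_hoof"}),
    "back_leg_height": frozenset({"belly_rear", "rear_hoof", "front_hoof"}),
    "front_leg_height": frozenset({"brisket", "rear_hoof", "front_hoof"}),
    "cow_length": frozenset({"nose_tip", "tail_head"}),
    "face_length": frozenset({"nose_tip", "poll"}),
    "head_length": frozenset({"nose_tip", "neck_top"}),
    "head_width": frozenset({"muzzle_top", "jaw"}),
    "neck_width": frozenset({"neck_top", "throat"}),
    "body_area_triangle": frozenset({"withers", "tail_head", "brisket"}),
    "body_area_polygon": frozenset(
        {"tail_head", "back_top", "withers", "brisket", "belly_rear"}),
}

LandmarkSet = dict  # name -> (x, y) or None


@dataclass
class Outline:
    """Binary edge map plus the ordered boundary of the largest object."""

    edge: np.ndarray               # bool (H, W): inner boundaries of all kept objects
    points: np.ndarray             # (N, 2) int array of (x, y), 8-connected ring
    shape: tuple[int, int] = field(init=False)

    def __post_init__(self):
        self.shape = self.edge.shape


@dataclass
class TraitVector:
    values: dict[str, float]
    missing: frozenset[str]

    def as_row(self) -> dict[str, float]:
        """Flat dict with NaN for missing traits, for tabular export."""
        return {t: (np.nan if t in self.missing else self.values[t])
                for t in TRAIT_NAMES}


# ---------------------------------------------------------------------------
# outline
# ---------------------------------------------------------------------------

_TRACE_STEPS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbour tracing of a single 8-connected component.

    Returns ordered (x, y) boundary pixels, closed (successive points are
    8-adjacent, last adjacent to first).
    """
    rows, cols = np.nonzero(mask)
    start = (rows[0], cols[np.argmin(cols[rows == rows[0]])])
    h, w = mask.shape

    def at(r, c):
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    boundary = [start]
    # backtrack starts pointing up-left of the start pixel
    prev_dir = 6  # coming from the left
    cur = start
    while True:
        found = False
        for i in range(8):
            d = (prev_dir + 1 + i) % 8
            dr, dc = _TRACE_STEPS[d]
            nr, nc = cur[0] + dr, cur[1] + dc
            if at(nr, nc):
                cur = (nr, nc)
                prev_dir = (d + 4) % 8
                found = True
                break
        if not found:  # isolated pixel
            break
        if cur == start and len(boundary) > 1:
            break
        boundary.append(cur)
    pts = np.array([(c, r) for r, c in boundary], dtype=np.int64)
    return pts


def extract_outline(mask: np.ndarray, min_object: int = 20) -> Outline:
    """Edge map of the mask with small islands removed; ordered largest boundary.

    Raises :class:`MissingTargetError` when no connected component of at
    least ``min_object`` pixels remains.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MissingTargetError("empty mask: nothing to outline")
    kept = _drop_small_components(mask, max(1, int(min_object)))
    if not kept.any():
        raise MissingTargetError(
            f"no connected component of at least {min_object} pixels")
    lab, n = ndimage.label(kept, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    largest = lab == (1 + int(np.argmax(sizes)))
    edge = kept & ~ndimage.binary_erosion(kept, border_value=0)
    pts = _trace_boundary(largest)
    return Outline(edge=edge, points=pts)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def _column_top_runs(filled: np.ndarray):
    """Per column: (top, bottom, thickness) of the run containing the topmost
    foreground pixel; -1 for empty columns."""
    h, w = filled.shape
    top = np.full(w, -1)
    bot = np.full(w, -1)
    thick = np.zeros(w, dtype=int)
    for x in range(w):
        col = np.nonzero(filled[:, x])[0]
        if col.size == 0:
            continue
        t = col[0]
        # end of the contiguous run starting at t
        breaks = np.nonzero(np.diff(col) > 1)[0]
        b = col[breaks[0]] if breaks.size else col[-1]
        top[x], bot[x], thick[x] = t, b, b - t + 1
    return top, bot, thick


def _topmost(points: np.ndarray, sel: np.ndarray):
    """(x, y) with minimal y among selected points; tie broken by median x."""
    p = points[sel]
    if p.size == 0:
        return None
    ymin = p[:, 1].min()
    xs = np.sort(p[p[:, 1] == ymin, 0])
    return int(xs[len(xs) // 2]), int(ymin)


def extract_landmarks(outline: Outline) -> LandmarkSet:
    """Locate the 13 named points on a right-facing silhouette outline.

    Rules that cannot be satisfied (e.g. the head region is absent from the
    mask) yield ``None`` for the affected landmarks; the others are still
    computed.
    """
    h, w = outline.shape
    pts = outline.points
    lm: LandmarkSet = {name: None for name in LANDMARK_NAMES}
    if pts.shape[0] < 8:
        return lm

    ring = np.zeros((h, w), dtype=bool)
    ring[pts[:, 1], pts[:, 0]] = True
    filled = ndimage.binary_fill_holes(ring)
    cols_any = filled.any(axis=0)
    xmin, xmax = int(np.argmax(cols_any)), int(w - 1 - np.argmax(cols_any[::-1]))
    rows_any = filled.any(axis=1)
    ymin, ymax = int(np.argmax(rows_any)), int(h - 1 - np.argmax(rows_any[::-1]))
    length = xmax - xmin + 1

    x, y = pts[:, 0], pts[:, 1]

    # hooves: closest boundary points to the bottom image corners
    d_bl = x.astype(float) ** 2 + (y - (h - 1.0)) ** 2
    lm["rear_hoof"] = tuple(int(v) for v in pts[np.argmin(d_bl)])
    d_br = (x - (w - 1.0)) ** 2 + (y - (h - 1.0)) ** 2
    lm["front_hoof"] = tuple(int(v) for v in pts[np.argmin(d_br)])
    baseline = max(lm["rear_hoof"][1], lm["front_hoof"][1])

    # tail head: leftmost point in the upper half, tie -> topmost
    upper = y <= (ymin + ymax) / 2.0
    if upper.any():
        xm = x[upper].min()
        cand = pts[upper & (x == xm)]
        lm["tail_head"] = (int(xm), int(cand[:, 1].min()))

    # back top: highest point in the rear band of the back
    band = (x >= xmin + 0.15 * length) & (x <= xmin + 0.50 * length)
    lm["back_top"] = _topmost(pts, band)

    # --- neck cut: column of minimal top-run thickness between back and head
    top, bot, thick = _column_top_runs(filled)
    xc = None
    plateau_right = None
    head_present = False
    if lm["back_top"] is not None:
        lo = lm["back_top"][0]
        hi = int(xmax - 0.15 * length)
        cand_cols = [cx for cx in range(lo, hi + 1) if thick[cx] > 0]
        if cand_cols:
            tmin = min(thick[cx] for cx in cand_cols)
            near = [cx for cx in cand_cols if thick[cx] <= tmin + 1]
            plateau_left = min(near)
            plateau_right = plateau_left
            while plateau_right + 1 in near or (
                    plateau_right + 1 <= hi and thick[plateau_right + 1] <= tmin + 1):
                plateau_right += 1
            xc = plateau_left + max(2, round(0.03 * length))
            if xc > plateau_right:
                xc = plateau_right
            if thick[xc] > 0:
                lm["neck_top"] = (int(xc), int(top[xc]))
                lm["throat"] = (int(xc), int(bot[xc]))
            # the head, if present, is a clearly thicker blob right of the cut
            rest = thick[plateau_right + 1: xmax + 1]
            head_present = bool(rest.size) and bool(
                (rest >= 1.4 * max(thick[xc], 1)).any())

    if head_present:
        lm["poll"] = _topmost(pts, x > plateau_right)
        xr = x.max()
        cand = pts[x == xr]
        lm["nose_tip"] = (int(xr), int(cand[:, 1].min()))
        xj = int(round((xc + xr) / 2.0))
        if 0 <= xj < w and thick[xj] > 0:
            lm["muzzle_top"] = (xj, int(top[xj]))
            lm["jaw"] = (xj, int(bot[xj]))

    # withers: highest point between mid-back and the neck cut
    if xc is not None:
        wband = (x >= xmin + 0.50 * length) & (x <= xc)
        lm["withers"] = _topmost(pts, wband)

    # --- underline landmarks, via leg-column analysis
    col_bottom = np.full(w, -1)
    for cx in range(xmin, xmax + 1):
        col = np.nonzero(filled[:, cx])[0]
        if col.size:
            col_bottom[cx] = col[-1]
    leg_tol = max(2, round(0.02 * (ymax - ymin + 1)))
    is_leg = (col_bottom >= 0) & (col_bottom >= baseline - leg_tol)
    leg_cols = np.nonzero(is_leg)[0]
    if leg_cols.size:
        # group into maximal runs of consecutive leg columns
        groups = np.split(leg_cols, np.nonzero(np.diff(leg_cols) > 1)[0] + 1)
        front_group = max(groups, key=lambda g: g[-1])
        # brisket: deepest non-leg point forward of the front legs
        sel = np.arange(front_group[-1] + 1, xmax + 1)
        sel = sel[(col_bottom[sel] >= 0) & ~is_leg[sel]]
        if sel.size:
            deep = col_bottom[sel].max()
            xs = np.sort(sel[col_bottom[sel] == deep])
            lm["brisket"] = (int(xs[len(xs) // 2]), int(deep))
        # belly_rear: deepest point in the widest inter-leg gap
        if len(groups) >= 2:
            gaps = [(groups[i][-1] + 1, groups[i + 1][0] - 1)
                    for i in range(len(groups) - 1)]
            g0, g1 = max(gaps, key=lambda g: g[1] - g[0])
            sel = np.arange(g0, g1 + 1)
            sel = sel[col_bottom[sel] >= 0]
            if sel.size:
                deep = col_bottom[sel].max()
                xs = np.sort(sel[col_bottom[sel] == deep])
                lm["belly_rear"] = (int(xs[len(xs) // 2]), int(deep))
    return lm


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _dist(a, b) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def _shoelace(points) -> float:
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def compute_traits(landmarks: LandmarkSet, outline: Outline) -> TraitVector:
    """Derive the 14 conformation traits from landmarks (pixel units).

    Vertical body measures are axis-projected; head/face/neck measures are
    Euclidean.  ``back_deviation`` is the maximal perpendicular distance of
    the dorsal outline arc from the tail_head->withers chord.  Any trait
    whose landmarks are missing is flagged missing, never guessed.
    """
    lm = landmarks
    missing = {t for t, req in TRAIT_REQUIREMENTS.items()
               if any(lm.get(name) is None for name in req)}
    vals: dict[str, float] = {t: np.nan for t in TRAIT_NAMES}

    def have(*names):
        return all(lm.get(n) is not None for n in names)

    if have("rear_hoof", "front_hoof"):
        baseline = max(lm["rear_hoof"][1], lm["front_hoof"][1])
        vals["gait"] = float(abs(lm["front_hoof"][0] - lm["rear_hoof"][0]))
        if have("back_top"):
            vals["back_height"] = float(baseline - lm["back_top"][1])
        if have("withers"):
            vals["front_height"] = float(baseline - lm["withers"][1])
        if have("belly_rear"):
            vals["back_leg_height"] = float(baseline - lm["belly_rear"][1])
        if have("brisket"):
            vals["front_leg_height"] = float(baseline - lm["brisket"][1])
    if have("brisket", "withers"):
        vals["chest_depth"] = float(lm["brisket"][1] - lm["withers"][1])
    if have("nose_tip", "tail_head"):
        vals["cow_length"] = float(abs(lm["nose_tip"][0] - lm["tail_head"][0]))
    if have("nose_tip", "poll"):
        vals["face_length"] = _dist(lm["nose_tip"], lm["poll"])
    if have("nose_tip", "neck_top"):
        vals["head_length"] = _dist(lm["nose_tip"], lm["neck_top"])
    if have("muzzle_top", "jaw"):
        vals["head_width"] = _dist(lm["muzzle_top"], lm["jaw"])
    if have("neck_top", "throat"):
        vals["neck_width"] = _dist(lm["neck_top"], lm["throat"])
    if have("withers", "tail_head", "brisket"):
        vals["body_area_triangle"] = _shoelace(
            [lm["withers"], lm["tail_head"], lm["brisket"]])
    if have("tail_head", "back_top", "withers", "brisket", "belly_rear"):
        vals["body_area_polygon"] = _shoelace(
            [lm["tail_head"], lm["back_top"], lm["withers"],
             lm["brisket"], lm["belly_rear"]])

    if have("withers", "tail_head"):
        a = np.asarray(lm["tail_head"], dtype=float)
        b = np.asarray(lm["withers"], dtype=float)
        x0, x1 = int(min(a[0], b[0])), int(max(a[0], b[0]))
        pts = outline.points
        sel = (pts[:, 0] >= x0) & (pts[:, 0] <= x1)
        dev = 0.0
        if sel.any() and x1 > x0:
            # dorsal arc: topmost boundary point per column in the chord span
            arc = pts[sel]
            order = np.lexsort((arc[:, 1], arc[:, 0]))
            arc = arc[order]
            tops = arc[np.unique(arc[:, 0], return_index=True)[1]]
            chord = b - a
            nrm = np.hypot(*chord)
            if nrm > 0:
                rel = tops - a
                d = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / nrm
                dev = float(d.max())
        vals["back_deviation"] = dev

    return TraitVector(values=vals, missing=frozenset(missing))


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def orient_right(image: np.ndarray, mask: np.ndarray, mode: str = "auto"
                 ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Ensure the animal faces right (head toward larger x).

    ``auto`` flips when the horizontal centre of mass of the top third of the
    silhouette lies left of the whole-silhouette centre: the head and neck
    are carried high and forward, so their mass marks the facing direction.
    """
    if mode not in ("assume_right", "flip", "auto"):
        raise ValueError(f"unknown orientation mode: {mode!r}")
    mask = np.asarray(mask, dtype=bool)
    flip = False
    if mode == "flip":
        flip = True
    elif mode == "auto" and mask.any():
        rows = np.nonzero(mask.any(axis=1))[0]
        ytop = rows[0] + max(1, (rows[-1] - rows[0] + 1) // 3)
        top = mask[:ytop]
        if top.any():
            com_top = np.nonzero(top)[1].mean()
            com_all = np.nonzero(mask)[1].mean()
            flip = com_top < com_all
    if flip:
        return np.ascontiguousarray(image[:, ::-1]), np.ascontiguousarray(mask[:, ::-1]), True
    return image, mask, False
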
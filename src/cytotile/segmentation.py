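"""Nucleus and cell segmentation.

Nucleus detection is split into two decoupled halves:

* a *probability generator* producing per-pixel scores for three classes
  (background, nucleus interior, nucleus boundary).  Any semantic
  segmentation model can fill this contract; the default is a classical
  smooth/threshold/erode construction that needs no trained weights.
* deterministic *post-processing* of the probability map into labeled
  nuclei: select pixels whose argmax class is the interior, drop connected
  components below a size threshold, then dilate each surviving component by
  exactly one pixel without ever merging two labels (a contested pixel goes
  to the nearer label; exact ties to the smaller label).

Cells are grown from nuclei by one of three modes: a fixed-radius Euclidean
expansion, a seeded watershed restricted to a thresholded membrane mask, or
propagation segmentation -- seeded lowest-cost region growing whose step
cost trades off membrane-intensity differences against spatial distance via
a regularization weight lambda.  Every mode preserves the invariants: cells
and nuclei share one label set, and nucleus k is contained in cell k.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import filters, segmentation as sk_seg

_FOUR_CONN = ndimage.generate_binary_structure(2, 1)


class ProbabilityMapError(ValueError):
    """The three class planes do not form a per-pixel distribution."""


@dataclass
class ProbabilityMap:
    """Per-pixel 3-class scores: background / nucleus interior / boundary."""

    background: np.ndarray
    interior: np.ndarray
    boundary: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.background.shape, self.interior.shape, self.boundary.shape}
        if len(shapes) != 1:
            raise ProbabilityMapError(f"class planes differ in shape: {shapes}")
        total = self.background + self.interior + self.boundary
        if not np.allclose(total, 1.0, atol=1e-6):
            raise ProbabilityMapError("per-pixel class scores must sum to 1")

    def stacked(self) -> np.ndarray:
        """(3, y, x) array ordered background, interior, boundary."""
        return np.stack([self.background, self.interior, self.boundary])


@dataclass
class LabelImage:
    """Integer object mask; 0 is background, labels are 1..K."""

    labels: np.ndarray
    kind: str = "nucleus"  # "nucleus" or "cell"

    def __post_init__(self) -> None:
        if self.labels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")

    @property
    def label_set(self) -> set[int]:
        return set(np.unique(self.labels)) - {0}


def default_probability_map(
    nuclear_image: np.ndarray, smoothing_sigma: float = 2.0
) -> ProbabilityMap:
    """Classical 3-class probability generator from a nuclear-stain plane.

    Gaussian-smooth, Otsu-threshold, fill holes; the eroded mask becomes the
    interior class, the one-pixel rim the boundary class, the complement the
    background.  Hard class masks are softened to (0.9, 0.05, 0.05) margins
    so the output is a genuine per-pixel distribution while preserving the
    argmax everywhere.  A constant image yields an all-background map.
    """
    img = np.asarray(nuclear_image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    smoothed = ndimage.gaussian_filter(img, smoothing_sigma)
    if np.ptp(smoothed) == 0:
        mask = np.zeros(img.shape, dtype=bool)
    else:
        mask = smoothed > filters.threshold_otsu(smoothed)
        mask = ndimage.binary_fill_holes(mask)
    interior_mask = ndimage.binary_erosion(mask, structure=_FOUR_CONN)
    boundary_mask = mask & ~interior_mask

    soft = np.full(img.shape + (3,), 0.05)
    soft[..., 0] = np.where(~mask, 0.9, 0.05)
    soft[..., 1] = np.where(interior_mask, 0.9, 0.05)
    soft[..., 2] = np.where(boundary_mask, 0.9, 0.05)
    soft /= soft.sum(axis=-1, keepdims=True)
    return ProbabilityMap(
        background=soft[..., 0], interior=soft[..., 1], boundary=soft[..., 2]
    )


# ---------------------------------------------------------------------------
# label-preserving geometry helpers

_NEIGHBOR_OFFSETS_8 = [
    (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
]


def _nearest_label_within(
    labels: np.ndarray, max_dist: float, tol: float = 1e-6
) -> np.ndarray:
    """Assign each background pixel within ``max_dist`` of any labeled pixel
    to its nearest label; exact distance ties go to the smaller label.

    Exactness matters: the usual distance-transform feature assignment picks
    an arbitrary site on ties, which would make contested boundary pixels
    nondeterministic with respect to the stated tie rule.
    """
    out = labels.copy()
    bg = labels == 0
    if not bg.any() or not (~bg).any():
        return out
    # restrict candidates using a cheap distance transform
    dist = ndimage.distance_transform_edt(bg)
    cand = bg & (dist <= max_dist + tol)
    if not cand.any():
        return out

    fg_yx = np.column_stack(np.nonzero(labels))
    fg_labels = labels[fg_yx[:, 0], fg_yx[:, 1]]
    order = np.lexsort((fg_yx[:, 1], fg_yx[:, 0], fg_labels))
    fg_yx, fg_labels = fg_yx[order], fg_labels[order]
    tree = cKDTree(fg_yx)

    cand_yx = np.column_stack(np.nonzero(cand))
    k = min(8, len(fg_yx))
    dists, idxs = tree.query(cand_yx, k=k)
    dists = dists.reshape(len(cand_yx), k)
    idxs = idxs.reshape(len(cand_yx), k)
    labs = fg_labels[idxs].astype(np.int64)
    tied = dists <= dists[:, :1] + tol
    labs[~tied] = np.iinfo(np.int64).max
    best = labs.min(axis=1).astype(labels.dtype)
    sel = dists[:, 0] <= max_dist + tol
    out[cand_yx[sel, 0], cand_yx[sel, 1]] = best[sel]
    return out


def dilate_labels_one_pixel(labels: np.ndarray) -> np.ndarray:
    """Dilate every label by one pixel (8-neighbourhood) without merging.

    A background pixel adjacent to several labels takes the nearer one
    (edge-adjacency, distance 1, beats diagonal adjacency, distance
    sqrt(2)); exact ties take the smaller label.
    """
    return _nearest_label_within(labels, max_dist=float(np.sqrt(2.0)))


def nuclei_from_probabilities(
    prob_map: ProbabilityMap, min_size: int = 0
) -> LabelImage:
    """Post-process a 3-class probability map into labeled nuclei.

    Pixels whose argmax class is the nucleus interior form a binary mask;
    4-connected components smaller than ``min_size`` pixels are removed; the
    survivors are labeled 1..K and each is dilated by exactly one pixel
    under the label-preserving rule.
    """
    stacked = prob_map.stacked()
    interior_mask = np.argmax(stacked, axis=0) == 1
    labels, _ = ndimage.label(interior_mask, structure=_FOUR_CONN)
    if min_size > 0 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        too_small = np.nonzero(sizes < min_size)[0]
        labels[np.isin(labels, too_small[too_small > 0])] = 0
    # relabel survivors 1..K in scan order
    labels, _ = ndimage.label(labels > 0, structure=_FOUR_CONN)
    labels = dilate_labels_one_pixel(labels)
    return LabelImage(labels=labels, kind="nucleus")


# ---------------------------------------------------------------------------
# cell expansion modes

def cells_fixed_radius(nuclei: LabelImage, radius: float) -> LabelImage:
    """Expand each nucleus to all pixels within Euclidean ``radius`` of it."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    labels = _nearest_label_within(nuclei.labels, max_dist=float(radius))
    return LabelImage(labels=labels, kind="cell")


def membrane_mask(
    membrane_image: np.ndarray,
    smoothing_sigma: float = 2.0,
    threshold_method: str = "otsu",
) -> np.ndarray:
    """Binary mask from a (smoothed) membrane-stain image."""
    img = ndimage.gaussian_filter(np.asarray(membrane_image, float), smoothing_sigma)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    if threshold_method == "otsu":
        thr = filters.threshold_otsu(img)
    elif threshold_method == "mean":
        thr = img.mean()
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    return img > thr


def _seeded_support(mask: np.ndarray, nuclei_labels: np.ndarray) -> np.ndarray:
    """Union mask with nucleus support, keeping only components holding a seed.

    Masked islands containing no nucleus cannot be claimed by any cell;
    dropping them keeps the pixel-conservation property (total cell area ==
    masked area) meaningful.
    """
    allowed = mask | (nuclei_labels > 0)
    comp, n = ndimage.label(allowed, structure=_FOUR_CONN)
    if n == 0:
        return allowed
    seeded = np.unique(comp[nuclei_labels > 0])
    return np.isin(comp, seeded[seeded > 0])


def cells_watershed(
    nuclei: LabelImage,
    membrane_image: np.ndarray,
    threshold_method: str = "otsu",
    smoothing_sigma: float = 2.0,
    precomputed_mask: np.ndarray | None = None,
) -> LabelImage:
    """Watershed cell expansion inside a membrane-derived mask.

    The smoothed membrane image is thresholded into a binary mask, union-ed
    with the nucleus support; the watershed then floods the
    distance-to-nearest-nucleus landscape from the nucleus seeds, restricted
    to that mask, so labels carry over from nuclei unchanged.
    """
    if membrane_image.shape != nuclei.labels.shape:
        raise ValueError("membrane image and nuclei shapes differ")
    mask = (precomputed_mask.astype(bool) if precomputed_mask is not None
            else membrane_mask(membrane_image, smoothing_sigma, threshold_method))
    allowed = _seeded_support(mask, nuclei.labels)
    dist_to_nucleus = ndimage.distance_transform_edt(nuclei.labels == 0)
    labels = sk_seg.watershed(
        dist_to_nucleus, markers=nuclei.labels, mask=allowed, connectivity=1
    )
    return LabelImage(labels=labels, kind="cell")


def cells_propagation(
    nuclei: LabelImage,
    membrane_image: np.ndarray,
    mask: np.ndarray | None = None,
    lam: float = 1.0,
) -> LabelImage:
    """Propagation segmentation: seeded lowest-cost region growing.

    Pixels are claimed in Dijkstra order over the 4-connected grid restricted
    to the mask.  The step cost between adjacent pixels p, q is

        (I(p) - I(q))^2 + lambda

    on the max-normalized membrane image, i.e. squared intensity difference
    plus ``lam`` times the squared (unit) spatial step.  Large ``lam``
    approaches a pure distance partition; ``lam = 0`` follows intensity
    ridges.  Cost ties are resolved toward the smaller label.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    labels0 = nuclei.labels
    img = np.asarray(membrane_image, dtype=np.float64)
    if img.shape != labels0.shape:
        raise ValueError("membrane image and nuclei shapes differ")
    peak = img.max()
    if peak > 0:
        img = img / peak
    if mask is None:
        allowed = labels0 > 0
    else:
        allowed = _seeded_support(mask.astype(bool), labels0)

    h, w = labels0.shape
    out = np.zeros_like(labels0)
    cost = np.full((h, w), np.inf)
    heap: list[tuple[float, int, int, int]] = []
    ys, xs = np.nonzero(labels0)
    for y, x in zip(ys.tolist(), xs.tolist()):
        heapq.heappush(heap, (0.0, int(labels0[y, x]), y, x))
        cost[y, x] = 0.0
    while heap:
        c, lab, y, x = heapq.heappop(heap)
        if out[y, x] != 0:
            continue
        out[y, x] = lab
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ny, nx = y + dy, x + dx
            if not (0 <= ny < h and 0 <= nx < w):
                continue
            if out[ny, nx] != 0 or not allowed[ny, nx]:
                continue
            step = (img[y, x] - img[ny, nx]) ** 2 + lam
            nc = c + step
            if nc < cost[ny, nx]:
                cost[ny, nx] = nc
                heapq.heappush(heap, (nc, lab, ny, nx))
            elif nc == cost[ny, nx]:
                # equal-cost path from a different seed: keep both candidates,
                # the heap ordering (cost, label) resolves the tie on pop
                heapq.heappush(heap, (nc, lab, ny, nx))
    # nuclei always keep their own labels
    out[labels0 > 0] = labels0[labels0 > 0]
    return LabelImage(labels=out, kind="cell")


def segment_cells(
    nuclei: LabelImage,
    mode: str,
    membrane_image: np.ndarray | None = None,
    radius: float = 5.0,
    lam: float = 1.0,
    smoothing_sigma: float = 2.0,
) -> LabelImage:
    """Dispatch over the three cell-expansion modes by name."""
    if mode == "radius":
        return cells_fixed_radius(nuclei, radius)
    if membrane_image is None:
        raise ValueError(f"cell mode {mode!r} requires a membrane image")
    if mode == "watershed":
        return cells_watershed(nuclei, membrane_image,
                               smoothing_sigma=smoothing_sigma)
    if mode == "propagation":
        mask = membrane_mask(membrane_image, smoothing_sigma)
        return cells_propagation(nuclei, membrane_image, mask=mask, lam=lam)
    raise ValueError(f"unknown cell mode {mode!r}")


def remove_border_cells(cells: LabelImage, nuclei: LabelImage) -> tuple[LabelImage, LabelImage]:
    """Drop cells touching the image border (and their nuclei)."""
    edge_labels = np.unique(np.concatenate([
        cells.labels[0], cells.labels[-1],
        cells.labels[:, 0], cells.labels[:, -1],
    ]))
    edge_labels = edge_labels[edge_labels > 0]
    cl = cells.labels.copy()
    nl = nuclei.labels.copy()
    cl[np.isin(cl, edge_labels)] = 0
    nl[np.isin(nl, edge_labels)] = 0
    return LabelImage(cl, kind="cell"), LabelImage(nl, kind="nucleus")
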
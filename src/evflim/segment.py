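"""Multi-scale blob detection of single vesicles in intensity images.

Five stages: (1) background flattening by subtracting a large-kernel
Gaussian blur; (2) scale-normalised Laplacian-of-Gaussian (LoG) filtering at
a geometric ladder of scales; (3) strict 3-D local-maximum detection across
(row, col, scale); (4) noise thresholding against a robust (MAD-based)
estimate of the background noise; (5) mask synthesis as disks of radius
``sqrt(2) * sigma`` (the LoG zero-crossing radius) around accepted maxima,
with overlaps resolved to the nearer centre.

All convolutions use reflective padding, so a constant image flattens to
zero and no spurious edge maxima appear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datamodel import LabelMask

__all__ = [
    "DetectionConfig",
    "BlobDetection",
    "flatten_background",
    "log_filter_stack",
    "find_maxima_3d",
    "threshold_detections",
    "detections_to_mask",
    "segment_evs",
    "match_centers",
]

_DEFAULT_SCALES = (0.8, 0.8 * math.sqrt(2), 1.6, 1.6 * math.sqrt(2), 3.2)


@dataclass(frozen=True)
class DetectionConfig:
    """Parameters of the blob-detection pipeline.

    ``scales`` is a geometric ladder (ratio sqrt(2)) spanning sub-resolution
    vesicles through small aggregates at ~0.35 um/px; ``threshold_k`` is the
    acceptance threshold in units of the robust background-noise scale.
    """

    background_sigma: float = 20.0  # px
    scales: tuple[float, ...] = _DEFAULT_SCALES
    threshold_k: float = 3.0
    min_separation: float = 4.0  # px
    mask_radius_factor: float = math.sqrt(2)

    def __post_init__(self) -> None:
        scales = tuple(sorted(float(s) for s in self.scales))
        if len(scales) < 2:
            raise ValueError("need at least 2 scales")
        if len(set(scales)) != len(scales):
            raise ValueError("scales must be distinct")
        if scales[0] <= 0:
            raise ValueError("scales must be > 0")
        object.__setattr__(self, "scales", scales)
        if self.background_sigma <= max(scales):
            raise ValueError("background_sigma must exceed the largest scale")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be > 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.mask_radius_factor <= 0:
            raise ValueError("mask_radius_factor must be > 0")


@dataclass(frozen=True)
class BlobDetection:
    center: tuple[int, int]  # (row, col)
    sigma: float  # detected scale, px
    response: float  # scale-normalised LoG response
    accepted: bool = False


def flatten_background(img: np.ndarray, background_sigma: float) -> np.ndarray:
    """Subtract a large-kernel Gaussian blur to remove slow background
    non-uniformity; zero-mean over background-only regions."""
    if background_sigma <= 0:
        raise ValueError("background_sigma must be > 0")
    img = np.asarray(img, dtype=float)
    return img - ndimage.gaussian_filter(img, background_sigma, mode="reflect")


def log_filter_stack(img: np.ndarray, scales) -> np.ndarray:
    """Scale-normalised LoG responses, shape (rows, cols, n_scales).

    Slice i is ``-sigma_i^2 * (Laplacian-of-Gaussian_{sigma_i} * img)``; the
    sign makes bright blobs positive maxima and the sigma^2 factor makes
    peak responses comparable across scales.
    """
    scales = tuple(scales)
    if len(scales) == 0:
        raise ValueError("empty scale list")
    img = np.asarray(img, dtype=float)
    out = np.empty(img.shape + (len(scales),))
    for i, sig in enumerate(scales):
        out[:, :, i] = -(sig**2) * ndimage.gaussian_laplace(img, sig, mode="reflect")
    return out


def _plateau_detections(stack: np.ndarray, flat: np.ndarray) -> list[tuple[int, int, int]]:
    """Plateau maxima: connected equal-valued regions whose entire exterior
    boundary is strictly smaller.  Returns one voxel (earliest in raster
    order) per qualifying plateau."""
    out: list[tuple[int, int, int]] = []
    if not flat.any():
        return out
    structure = np.ones((3, 3, 3), dtype=bool)
    comp, n_comp = ndimage.label(flat, structure=structure)
    slices = ndimage.find_objects(comp)
    for lab, sl in enumerate(slices, start=1):
        # work on the component's bounding box padded by one voxel
        pad = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, stack.shape)
        )
        region = comp[pad] == lab
        vals = stack[pad][region]
        v = vals[0]
        if not np.all(vals == v):
            continue  # adjacent flat voxels of different value: not a plateau
        dil = ndimage.binary_dilation(region, structure=structure)
        exterior = dil & ~region
        # voxels outside the padded box exist iff the box was clipped at the
        # array edge; the component then touches the border there and its
        # in-box exterior already bounds it
        if not exterior.any():
            continue  # plateau fills the array: nothing to dominate
        if np.all(stack[pad][exterior] < v):
            local = np.argwhere(region)
            first = local[np.lexsort((local[:, 2], local[:, 1], local[:, 0]))][0]
            out.append(
                (
                    int(first[0] + pad[0].start),
                    int(first[1] + pad[1].start),
                    int(first[2] + pad[2].start),
                )
            )
    return out


def find_maxima_3d(
    stack: np.ndarray, scales, min_separation: float = 4.0
) -> list[BlobDetection]:
    """Candidate blobs: voxels strictly greater than all 26 neighbours of the
    (row, col, scale) response stack.

    Equal-valued plateaus that dominate their whole surrounding yield a
    single detection at their earliest raster voxel.  Candidates closer than
    ``min_separation`` in the image plane keep only the larger response.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("response stack must be 3-D (row, col, scale)")
    scales = tuple(scales)
    if stack.shape[2] != len(scales):
        raise ValueError("stack depth must match the number of scales")
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(stack, footprint=footprint, mode="nearest")
    strict = stack > neigh_max
    coords = [tuple(idx) for idx in np.argwhere(strict)]
    coords += _plateau_detections(stack, stack == neigh_max)
    cands = sorted(
        ((stack[r, c, k], r, c, k) for r, c, k in coords), key=lambda t: -t[0]
    )
    kept: list[BlobDetection] = []
    if cands:
        from scipy.spatial import cKDTree

        xy = np.array([(r, c) for _resp, r, c, _k in cands], dtype=float)
        tree = cKDTree(xy)
        neighbors = tree.query_ball_point(xy, r=min_separation, p=2.0)
        alive = np.ones(len(cands), dtype=bool)
        taken = np.zeros(len(cands), dtype=bool)
        for i, (resp, r, c, k) in enumerate(cands):
            if not alive[i]:
                continue
            taken[i] = True
            for j in neighbors[i]:
                if j != i and not taken[j]:
                    # strict inequality in the distance keeps detections at
                    # exactly min_separation apart
                    if ((xy[i] - xy[j]) ** 2).sum() < min_separation**2:
                        alive[j] = False
            kept.append(
                BlobDetection(
                    center=(int(r), int(c)), sigma=scales[k], response=float(resp)
                )
            )
    return kept


def threshold_detections(
    dets: list[BlobDetection], flattened_img: np.ndarray, threshold_k: float
) -> list[BlobDetection]:
    """Accept detections whose LoG response exceeds ``threshold_k`` times the
    robust background-noise scale (1.4826 x MAD of the flattened image)."""
    flat = np.asarray(flattened_img, dtype=float)
    med = np.median(flat)
    sigma_noise = 1.4826 * np.median(np.abs(flat - med))
    threshold = threshold_k * sigma_noise if sigma_noise > 0 else 0.0
    return [
        BlobDetection(d.center, d.sigma, d.response, accepted=d.response > threshold)
        for d in dets
    ]


def detections_to_mask(
    dets: list[BlobDetection],
    shape: tuple[int, int],
    mask_radius_factor: float = math.sqrt(2),
) -> LabelMask:
    """Filled disks of radius ``factor * sigma`` around accepted detections.

    Pixels covered by several disks go to the nearer centre (ties to the
    lower label id); labels are consecutive from 1 in detection order.
    """
    accepted = [d for d in dets if d.accepted]
    labels = np.zeros(shape, dtype=np.int64)
    owner_d2 = np.full(shape, np.inf)
    for lab, d in enumerate(accepted, start=1):
        r0, c0 = d.center
        radius = mask_radius_factor * d.sigma
        half = int(math.floor(radius))
        rr = np.arange(max(r0 - half, 0), min(r0 + half + 1, shape[0]))
        cc = np.arange(max(c0 - half, 0), min(c0 + half + 1, shape[1]))
        if rr.size == 0 or cc.size == 0:
            continue
        d2 = (rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2
        inside = d2 <= radius * radius
        sub = (slice(rr[0], rr[-1] + 1), slice(cc[0], cc[-1] + 1))
        take = inside & (d2 < owner_d2[sub])  # strict: ties keep lower label
        labels[sub] = np.where(take, lab, labels[sub])
        owner_d2[sub] = np.where(take, d2, owner_d2[sub])
    legend = {lab: f"ev-{lab}" for lab in range(1, len(accepted) + 1)}
    return LabelMask(labels=labels, legend=legend)


def segment_evs(
    img: np.ndarray, config: DetectionConfig | None = None
) -> tuple[LabelMask, list[BlobDetection]]:
    """Full pipeline: flatten -> LoG ladder -> 3-D maxima -> threshold -> mask."""
    if config is None:
        config = DetectionConfig()
    flat = flatten_background(img, config.background_sigma)
    stack = log_filter_stack(flat, config.scales)
    dets = find_maxima_3d(stack, config.scales, config.min_separation)
    dets = threshold_detections(dets, flat, config.threshold_k)
    mask = detections_to_mask(dets, np.asarray(img).shape, config.mask_radius_factor)
    return mask, dets


def match_centers(
    detected: np.ndarray, truth: np.ndarray, radius: float = 3.0
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to true centres.

    Returns ``(n_matched, n_detected, n_truth)``; precision and recall
    follow as ``matched/detected`` and ``matched/truth``.
    """
    detected = np.asarray(detected, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if detected.size == 0 or truth.size == 0:
        return 0, len(detected), len(truth)
    d2 = ((detected[:, None, :] - truth[None, :, :]) ** 2).sum(axis=2)
    pairs = sorted(
        ((d2[i, j], i, j) for i in range(len(detected)) for j in range(len(truth))
         if d2[i, j] <= radius * radius)
    )
    used_i: set[int] = set()
    used_j: set[int] = set()
    matched = 0
    for _, i, j in pairs:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        matched += 1
    return matched, len(detected), len(truth)
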
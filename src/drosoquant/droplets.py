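"""Lipid-droplet segmentation and morphometry.

Droplets stained with Nile Red / BODIPY 493 (or marked by Lsd-2-GFP) are
segmented by histogram auto-thresholding — the triangle method for dye
stains, the Renyi-entropy method for the GFP marker — applied either to
individual z slices or to a maximum projection.  Particle analysis of the
binary result yields droplet count, fractional area covered, and mean
droplet size (total droplet area / count) per brain.

Both thresholding algorithms are implemented here with explicit,
documented tie-breaking so results are exactly reproducible:

* triangle — threshold at the bin maximizing the perpendicular distance
  between the histogram curve and the chord from the histogram peak to
  the farthest nonzero bin on the longer-tail side; ties take the lowest
  bin.
* Renyi entropy — for entropic orders alpha in {0.5, 1, 2} the bin
  maximizing the summed background+foreground Renyi entropy is found
  exhaustively (alpha=1 is the Shannon/maximum-entropy limit); the three
  maximizers are combined by the published spacing-weighted rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage import measure

__all__ = [
    "IntensityHistogram",
    "SegmentationConfig",
    "DropletMorphometry",
    "DegenerateHistogramError",
    "triangle_threshold",
    "renyi_entropy_threshold",
    "segment_droplets",
    "droplet_metrics",
    "analyze_droplets",
]

N_BINS = 256


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two nonzero bins; no threshold exists."""


@dataclass
class IntensityHistogram:
    """A 256-bin intensity histogram with its intensity-range mapping."""

    bin_counts: np.ndarray
    intensity_min: float = 0.0
    intensity_max: float = 255.0

    def __post_init__(self) -> None:
        counts = np.asarray(self.bin_counts)
        if counts.ndim != 1 or counts.size != N_BINS:
            raise ValueError(f"bin_counts must have {N_BINS} entries")
        if np.any(counts < 0):
            raise ValueError("bin counts must be nonnegative")
        if not np.any(counts > 0):
            raise ValueError("histogram is empty")
        self.bin_counts = counts.astype(np.int64)

    @classmethod
    def from_pixels(cls, pixels: np.ndarray) -> "IntensityHistogram":
        """Histogram of 256 equal bins over the pixel data range."""
        pixels = np.asarray(pixels, dtype=float).ravel()
        if pixels.size == 0:
            raise ValueError("no pixels to histogram")
        lo, hi = float(pixels.min()), float(pixels.max())
        if hi == lo:
            hi = lo + 1.0  # constant image: everything falls in bin 0
        counts, _ = np.histogram(pixels, bins=N_BINS, range=(lo, hi))
        return cls(counts, intensity_min=lo, intensity_max=hi)

    def bin_of(self, pixels: np.ndarray) -> np.ndarray:
        """Bin index of each pixel under this histogram's range mapping."""
        pixels = np.asarray(pixels, dtype=float)
        width = (self.intensity_max - self.intensity_min) / N_BINS
        idx = np.floor((pixels - self.intensity_min) / width).astype(np.int64)
        return np.clip(idx, 0, N_BINS - 1)


@dataclass
class SegmentationConfig:
    method: Literal["triangle", "renyi_entropy", "fixed"] = "triangle"
    mode: Literal["per_slice", "max_projection"] = "per_slice"
    connectivity: Literal[4, 8] = 8
    min_area_px: int = 0
    fixed_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class DropletMorphometry:
    """Per-brain droplet summary: count, area fraction, mean size."""

    count: int
    fractional_area: float
    mean_size_px: float | None
    total_area_px: int
    analyzed_px: int
    per_slice_counts: list[int] | None = None


# ---------------------------------------------------------------------------
# Auto-thresholds
# ---------------------------------------------------------------------------


def triangle_threshold(hist: IntensityHistogram) -> int:
    """Triangle auto-threshold bin.

    A chord is drawn from the histogram peak to the farthest nonzero bin
    on the longer-tail side (histogram flipped if the long tail is on the
    left); the threshold is the bin between them whose point
    (bin, count) lies farthest from the chord.  Tie-breaks: the peak is
    the lowest bin attaining the maximum count; among equidistant bins
    the lowest (in original coordinates) wins.
    """
    h = hist.bin_counts.astype(float)
    nz = np.flatnonzero(h)
    if nz.size < 2:
        raise DegenerateHistogramError("need >= 2 nonzero bins")
    peak = int(np.argmax(h))
    left, right = int(nz[0]), int(nz[-1])
    end = right if (right - peak) >= (peak - left) else left
    if end == peak:
        raise DegenerateHistogramError("histogram has no tail to threshold")
    lo, hi = sorted((peak, end))
    idx = np.arange(lo, hi + 1)
    # |cross product| of (end-peak, h[end]-h[peak]) with (i-peak, h[i]-h[peak]);
    # proportional to point-to-chord distance, scale-invariant in argmax
    cross = np.abs(
        (end - peak) * (h[idx] - h[peak]) - (idx - peak) * (h[end] - h[peak])
    )
    return int(idx[np.argmax(cross)])


def _renyi_entropy_maximizer(p: np.ndarray, alpha: float) -> int:
    """Bin t maximizing background+foreground Renyi entropy of order alpha.

    Background is bins <= t, foreground bins > t; candidate t runs over
    bins where both classes have positive mass.  The lowest maximizer is
    returned; candidates whose entropy is within a 1e-10 relative
    tolerance of the maximum count as tied (runs of empty bins produce
    mathematically identical splits that differ only by float noise).
    """
    nz = np.flatnonzero(p)
    if nz.size < 2:
        raise DegenerateHistogramError("no valid split point")
    P1 = np.cumsum(p)
    P2 = 1.0 - P1
    cand = np.arange(int(nz[0]), int(nz[-1]))
    ents = np.empty(cand.size)
    for j, t in enumerate(cand):
        pb = p[: t + 1] / P1[t]
        pf = p[t + 1 :] / P2[t]
        pb = pb[pb > 0]
        pf = pf[pf > 0]
        if alpha == 1.0:
            ent = -(pb * np.log(pb)).sum() - (pf * np.log(pf)).sum()
        else:
            ent = (
                np.log((pb**alpha).sum()) + np.log((pf**alpha).sum())
            ) / (1.0 - alpha)
        ents[j] = ent
    top = ents.max()
    tol = 1e-10 * max(1.0, abs(top))
    return int(cand[ents >= top - tol][0])


def renyi_entropy_threshold(hist: IntensityHistogram) -> int:
    """Renyi-entropy auto-threshold bin (Sahoo three-order method).

    Entropic-sum maximizers t* are computed for alpha = 0.5, 1, 2, sorted,
    and combined with spacing-dependent weights beta: nearby maximizers
    (within 5 bins end to end) weight (1,2,1); one outlying low/high
    maximizer shifts weight to the far pair.  The combined threshold is

        t = t1*(P(t1) + w*b1/4) + t2*w*b2/4 + t3*(1 - P(t3) + w*b3/4)

    with P the cumulative histogram and w = P(t3) - P(t1).
    """
    h = hist.bin_counts.astype(float)
    if np.count_nonzero(h) < 2:
        raise DegenerateHistogramError("need >= 2 nonzero bins")
    p = h / h.sum()
    t1, t2, t3 = sorted(
        _renyi_entropy_maximizer(p, a) for a in (0.5, 1.0, 2.0)
    )
    P1 = np.cumsum(p)
    if abs(t1 - t3) <= 5:
        b1, b2, b3 = 1, 2, 1
    elif (t2 - t1) <= 5 < (t3 - t2):
        b1, b2, b3 = 0, 1, 3
    elif (t2 - t1) > 5 >= (t3 - t2):
        b1, b2, b3 = 3, 1, 0
    else:
        b1, b2, b3 = 1, 2, 1
    w = P1[t3] - P1[t1]
    t = (
        t1 * (P1[t1] + 0.25 * w * b1)
        + 0.25 * t2 * w * b2
        + t3 * ((1.0 - P1[t3]) + 0.25 * w * b3)
    )
    return int(t)


_METHODS = {
    "triangle": triangle_threshold,
    "renyi_entropy": renyi_entropy_threshold,
}


# ---------------------------------------------------------------------------
# Segmentation and particle metrics
# ---------------------------------------------------------------------------


def _threshold_plane(
    plane: np.ndarray, keep: np.ndarray, config: SegmentationConfig
) -> np.ndarray:
    """Binarize one 2-D plane; excluded pixels are background."""
    out = np.zeros(plane.shape, dtype=bool)
    vals = plane[keep]
    if vals.size == 0:
        return out
    if config.method == "fixed":
        out[keep] = vals > config.fixed_threshold
        return out
    hist = IntensityHistogram.from_pixels(vals)
    try:
        t_bin = _METHODS[config.method](hist)
    except DegenerateHistogramError:
        # constant plane: nothing separable, treat as all background
        return out
    out[keep] = hist.bin_of(vals) > t_bin
    return out


def segment_droplets(
    stack,
    exclusion_mask: np.ndarray | None = None,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Binary droplet mask of a stack (or of its maximum projection).

    ``stack`` is a :class:`~drosoquant.redox.ChannelStack` or a 2-D/3-D
    array.  Excluded (nonzero-mask) pixels are removed before
    histogramming and forced to background.  ``per_slice`` mode
    thresholds each slice independently with its own 256-bin histogram
    over that slice's data range; ``max_projection`` projects first and
    thresholds once, returning a (1, rows, cols) mask.
    """
    config = config or SegmentationConfig()
    voxels = getattr(stack, "voxels", None)
    if voxels is None:
        voxels = np.asarray(stack, dtype=float)
        if voxels.ndim == 2:
            voxels = voxels[np.newaxis]
    keep = np.ones(voxels.shape, dtype=bool)
    if exclusion_mask is not None:
        mask = np.asarray(exclusion_mask)
        if mask.ndim == 2:
            mask = np.broadcast_to(mask[np.newaxis], voxels.shape)
        if mask.shape != voxels.shape:
            raise ValueError("exclusion mask shape mismatch")
        keep &= mask == 0
    if not keep.any():
        raise ValueError("all pixels are excluded by the mask")

    if config.mode == "max_projection":
        proj = np.where(keep, voxels, -np.inf).max(axis=0)
        keep2d = keep.any(axis=0)
        proj = np.where(keep2d, proj, 0.0)
        return _threshold_plane(proj, keep2d, config)[np.newaxis]
    return np.stack(
        [
            _threshold_plane(voxels[z], keep[z], config)
            for z in range(voxels.shape[0])
        ]
    )


def droplet_metrics(
    binary: np.ndarray,
    config: SegmentationConfig | None = None,
    analyzed_px: int | None = None,
) -> DropletMorphometry:
    """Particle metrics of a binary droplet stack.

    Connected components are labeled in 2-D per slice (no 3-D merging, so
    per-brain counts sum across slices exactly as per-slice particle
    analysis would); components smaller than ``min_area_px`` are dropped.
    ``analyzed_px`` defaults to the full pixel count and should be reduced
    by the caller when an exclusion mask shrank the analyzed region.
    """
    config = config or SegmentationConfig()
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim == 2:
        binary = binary[np.newaxis]
    if analyzed_px is None:
        analyzed_px = binary.size
    skconn = 2 if config.connectivity == 8 else 1
    count = 0
    total_area = 0
    per_slice = []
    for z in range(binary.shape[0]):
        labels = measure.label(binary[z], connectivity=skconn)
        n_slice = 0
        for region in measure.regionprops(labels):
            if region.area >= config.min_area_px:
                n_slice += 1
                total_area += int(region.area)
        count += n_slice
        per_slice.append(n_slice)
    return DropletMorphometry(
        count=count,
        fractional_area=total_area / analyzed_px if analyzed_px else 0.0,
        mean_size_px=(total_area / count) if count else None,
        total_area_px=total_area,
        analyzed_px=int(analyzed_px),
        per_slice_counts=per_slice,
    )


def analyze_droplets(
    stack,
    exclusion_mask: np.ndarray | None = None,
    config: SegmentationConfig | None = None,
) -> DropletMorphometry:
    """Segment then measure in one call (the per-brain pipeline)."""
    config = config or SegmentationConfig()
    binary = segment_droplets(stack, exclusion_mask, config)
    if exclusion_mask is not None:
        mask = np.asarray(exclusion_mask)
        voxels = getattr(stack, "voxels", np.asarray(stack))
        if voxels.ndim == 2:
            voxels = voxels[np.newaxis]
        if mask.ndim == 2:
            mask = np.broadcast_to(mask[np.newaxis], voxels.shape)
        keep = mask == 0
        analyzed = (
            int(keep.any(axis=0).sum())
            if config.mode == "max_projection"
            else int(keep.sum())
        )
    else:
        analyzed = binary.size
    return droplet_metrics(binary, config, analyzed_px=analyzed)
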
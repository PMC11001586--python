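"""Ratiometric oxidation scoring of two-channel fluorescence stacks.

mito-roGFP2-Grx1 reports glutathione redox state as a 405:488 excitation
ratio; MitoTimer reports cumulative mitochondrial oxidation as a red:green
ratio.  A brain's score is the mean per-pixel ratio after two exclusion
passes: (1) pixels whose ratio falls outside a plausible range (debris and
autofluorescent trachea produce extreme ratios) and (2) residual background,
removed per channel as pixels dimmer than a fixed fraction of that
channel's mean over the surviving pixels.  A diamide (DA) / dithiothreitol
(DTT) calibration maps control-normalized scores onto a percent-oxidized
scale.  Also here: CaLexA GFP:RFP total-signal ratio and MDA mean intensity
above a background threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ChannelStack",
    "RatioConfig",
    "RatioResult",
    "RedoxCalibration",
    "RATIO_PRESETS",
    "NoSignalError",
    "read_stack",
    "compute_ratio_result",
    "percent_oxidized",
    "normalize_to_group_mean",
    "calexa_index",
    "mda_mean_intensity",
]


class NoSignalError(ValueError):
    """All pixels were excluded; no signal remains to score."""


@dataclass
class ChannelStack:
    """A single-channel z-stack of nonnegative intensities.

    ``voxels`` is (slice, row, col); a 2-D image is promoted to one slice.
    """

    voxels: np.ndarray
    channel_label: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim == 2:
            v = v[np.newaxis]
        if v.ndim != 3:
            raise ValueError("voxels must be 2-D or 3-D (slice, row, col)")
        if np.any(v < 0):
            raise ValueError("intensities must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        self.voxels = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def read_stack(path, channel_label: str = "", bit_depth: int | None = None) -> ChannelStack:
    """Load a (multi-page) grayscale TIFF as a :class:`ChannelStack`."""
    arr = tifffile.imread(path)
    if bit_depth is None:
        bit_depth = 8 if arr.dtype.itemsize == 1 else 16
    return ChannelStack(arr, channel_label=channel_label, bit_depth=bit_depth)


@dataclass
class RatioConfig:
    """Ratio gate and background cut for one sensor / experimental set.

    ``ratio_low``/``ratio_high`` bound the admissible per-pixel ratio;
    ``bg_factor`` scales each channel's survivor mean into the dimness
    cut.  roGFP2-Grx1 defaults: gate 0.25-4.0, bg_factor 0.5.
    """

    ratio_low: float = 0.25
    ratio_high: float = 4.0
    bg_factor: float = 0.5
    numerator_label: str = "405"
    denominator_label: str = "488"

    def __post_init__(self) -> None:
        if not 0 < self.ratio_low < self.ratio_high:
            raise ValueError("require 0 < ratio_low < ratio_high")
        if self.bg_factor <= 0:
            raise ValueError("bg_factor must be positive")


#: Per-experimental-set gating constants. MitoTimer sets differ in signal
#: and background level, so their gates were tuned per set.
RATIO_PRESETS: dict[str, RatioConfig] = {
    "rogfp": RatioConfig(0.25, 4.0, 0.5, "405", "488"),
    "mitotimer_repo": RatioConfig(1 / 2.5, 2.5, 0.4, "red", "green"),
    "mitotimer_nsyb": RatioConfig(0.25, 4.0, 0.25, "red", "green"),
}


@dataclass
class RatioResult:
    """Per-brain oxidation score with pixel-inclusion accounting."""

    mean_ratio: float
    n_included: int
    n_excluded_ratio: int
    n_excluded_bg: int
    per_slice_means: np.ndarray | None = None

    @property
    def n_total(self) -> int:
        return self.n_included + self.n_excluded_ratio + self.n_excluded_bg


@dataclass
class RedoxCalibration:
    """DA (maximal) / DTT (minimal) oxidation references, control-normalized."""

    da_mean: float
    dtt_mean: float
    cell_type: str = ""

    def __post_init__(self) -> None:
        if not self.da_mean > self.dtt_mean > 0:
            raise ValueError("require da_mean > dtt_mean > 0")


def compute_ratio_result(
    numerator: ChannelStack,
    denominator: ChannelStack,
    config: RatioConfig | None = None,
    exclusion_mask: np.ndarray | None = None,
    per_slice: bool = False,
) -> RatioResult:
    """Mean per-pixel ratio after ratio-gate and background exclusion.

    Pipeline order: per-pixel ratio (zero-denominator pixels are
    ratio-excluded, their ratio being out of bounds by definition); drop
    pixels with ratio outside [ratio_low, ratio_high]; among survivors,
    drop pixels dimmer than ``bg_factor`` x that channel's survivor mean
    in either channel; average the remaining per-pixel ratios.

    ``exclusion_mask`` (nonzero = excluded) removes debris pixels before
    any accounting, standing in for manual deletion.
    """
    config = config or RatioConfig()
    num = numerator.voxels
    den = denominator.voxels
    if num.shape != den.shape:
        raise ValueError(
            f"channel shapes differ: {num.shape} vs {den.shape}"
        )
    keep = np.ones(num.shape, dtype=bool)
    if exclusion_mask is not None:
        mask = np.asarray(exclusion_mask)
        if mask.ndim == 2:
            mask = mask[np.newaxis]
        if mask.shape != num.shape:
            raise ValueError("exclusion mask shape mismatch")
        keep &= mask == 0

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)

    in_gate = keep & (ratio >= config.ratio_low) & (ratio <= config.ratio_high)
    n_excluded_ratio = int(keep.sum() - in_gate.sum())

    if not in_gate.any():
        raise NoSignalError("all pixels excluded by the ratio gate")

    num_cut = config.bg_factor * num[in_gate].mean()
    den_cut = config.bg_factor * den[in_gate].mean()
    included = in_gate & (num >= num_cut) & (den >= den_cut)
    n_excluded_bg = int(in_gate.sum() - included.sum())
    n_included = int(included.sum())
    if n_included == 0:
        raise NoSignalError("all pixels excluded by the background cut")

    per_slice_means = None
    if per_slice:
        per_slice_means = np.array(
            [
                ratio[z][included[z]].mean() if included[z].any() else np.nan
                for z in range(num.shape[0])
            ]
        )
    return RatioResult(
        mean_ratio=float(ratio[included].mean()),
        n_included=n_included,
        n_excluded_ratio=n_excluded_ratio,
        n_excluded_bg=n_excluded_bg,
        per_slice_means=per_slice_means,
    )


def percent_oxidized(x: float, cal: RedoxCalibration) -> float:
    """Map a control-normalized score to oxidized fraction.

    (x - DTT) / (DA - DTT): 0 at the fully reduced (DTT) reference, 1 at
    the fully oxidized (DA) reference.  Values outside [0, 1] are
    returned as-is with a warning (sensor noise can overshoot the
    calibration points).
    """
    if cal.da_mean == cal.dtt_mean:
        raise ValueError("degenerate calibration: da_mean == dtt_mean")
    frac = (x - cal.dtt_mean) / (cal.da_mean - cal.dtt_mean)
    if not 0.0 <= frac <= 1.0:
        warnings.warn(
            f"percent oxidized {100 * frac:.1f}% outside [0, 100]%",
            stacklevel=2,
        )
    return frac


def normalize_to_group_mean(
    values: Sequence[float], control_values: Sequence[float]
) -> np.ndarray:
    """Divide per-brain values by the control-group mean.

    Normalizing each group of an experiment by its control mean makes the
    control mean exactly 1, allowing pooling across experiments imaged on
    different days with different acquisition settings.
    """
    vals = np.asarray(values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if ctrl.size == 0:
        raise ValueError("control group is empty")
    cmean = ctrl.mean()
    if not cmean > 0:
        raise ValueError("control mean must be positive")
    return vals / cmean


def calexa_index(
    gfp: ChannelStack, rfp: ChannelStack, projection: str = "sum"
) -> float:
    """CaLexA activity index: GFP:RFP ratio of total z-projected signal.

    ``sum`` projection (default) makes the index the ratio of whole-stack
    totals; ``max`` projects by per-pixel maximum first.
    """
    if gfp.shape != rfp.shape:
        raise ValueError("channel shapes differ")
    if projection == "sum":
        g, r = gfp.voxels.sum(axis=0), rfp.voxels.sum(axis=0)
    elif projection == "max":
        g, r = gfp.voxels.max(axis=0), rfp.voxels.max(axis=0)
    else:
        raise ValueError("projection must be 'sum' or 'max'")
    total_r = r.sum()
    if total_r == 0:
        raise ValueError("RFP channel has zero total signal")
    return float(g.sum() / total_r)


def mda_mean_intensity(stack: ChannelStack, bg_threshold: float) -> float:
    """Mean of sum-projected pixels strictly above a background threshold.

    All z slices are summed into one image per brain; the score is the
    mean of projected pixels exceeding ``bg_threshold`` (held constant
    across brains within an experiment).
    """
    if bg_threshold < 0:
        raise ValueError("bg_threshold must be >= 0")
    projected = stack.voxels.sum(axis=0)
    above = projected > bg_threshold
    if not above.any():
        raise NoSignalError("no pixels above the background threshold")
    return float(projected[above].mean())
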
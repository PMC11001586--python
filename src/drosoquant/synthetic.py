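"""Ground-truthed synthetic fixtures for every pipeline stage.

Each generator is a pure function of its parameters and seed and emits
machine-readable ground truth alongside the data, so end-to-end recovery
tests never need real microscopy or behavior files.  The scenes emulate
the study conditions, not the full physics of acquisition: droplet scenes
are hard disks plus white noise (no point-spread function), redox scenes
put a single true ratio on all signal pixels, sleep traces alternate
geometric wake/sleep bouts on a 12:12 light:dark grid, and OCR traces are
smooth baseline/decline curves with optional injected step artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from drosoquant import dam

__all__ = [
    "DropletSceneParams",
    "RedoxSceneParams",
    "SleepArchitectureParams",
    "OcrSceneParams",
    "gen_droplet_scene",
    "gen_redox_scene",
    "gen_coloc_scene",
    "gen_dam_traces",
    "gen_ocr_traces",
]

MINUTES_PER_DAY = 1440


# ---------------------------------------------------------------------------
# Droplet scenes
# ---------------------------------------------------------------------------


@dataclass
class DropletSceneParams:
    """Disks of known radius over noisy background.

    Defaults give SNR (fg - bg)/sigma = 10, disks well separated.
    """

    image_size: tuple[int, int] = (256, 256)
    n_slices: int = 1
    n_droplets: int = 50
    radius_range: tuple[int, int] = (4, 4)
    fg_intensity: float = 160.0
    bg_intensity: float = 40.0
    noise_model: str = "gaussian"  # or "poisson"
    noise_sigma: float = 12.0
    min_separation_px: int = 3
    seed: int = 0

    @property
    def snr(self) -> float:
        scale = (
            self.noise_sigma
            if self.noise_model == "gaussian"
            else float(np.sqrt(self.bg_intensity))
        )
        if scale == 0:
            return float("inf")
        return (self.fg_intensity - self.bg_intensity) / scale


def _place_disks(rng, params: DropletSceneParams):
    """Rejection-sample non-overlapping disk centers; error when infeasible."""
    rows, cols = params.image_size
    rmin, rmax = params.radius_range
    centers, radii, slices = [], [], []
    max_tries = 200 * max(params.n_droplets, 1)
    tries = 0
    while len(centers) < params.n_droplets:
        if tries >= max_tries:
            raise ValueError(
                "could not place droplets at the requested separation; "
                "reduce n_droplets or min_separation_px"
            )
        tries += 1
        r = int(rng.integers(rmin, rmax + 1))
        cy = float(rng.uniform(r + 1, rows - r - 1))
        cx = float(rng.uniform(r + 1, cols - r - 1))
        z = int(rng.integers(0, params.n_slices))
        ok = all(
            zz != z
            or np.hypot(cy - y, cx - x) >= r + rr + params.min_separation_px
            for (y, x), rr, zz in zip(centers, radii, slices)
        )
        if ok:
            centers.append((cy, cx))
            radii.append(r)
            slices.append(z)
    return centers, radii, slices


def gen_droplet_scene(params: DropletSceneParams):
    """Generate (stack, truth) where truth holds exact disk geometry.

    A pixel belongs to a disk when its center lies within the disk
    radius.  Returns the float stack (slices, rows, cols) and a dict with
    centers, radii, per-disk slice, the boolean truth mask, per-disk
    pixel areas, total area, count, and the recorded SNR.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.image_size
    clean = np.full((params.n_slices, rows, cols), params.bg_intensity)
    truth_mask = np.zeros_like(clean, dtype=bool)
    centers, radii, slices = _place_disks(rng, params)
    yy, xx = np.mgrid[0:rows, 0:cols]
    areas = []
    for (cy, cx), r, z in zip(centers, radii, slices):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        clean[z][disk] = params.fg_intensity
        truth_mask[z] |= disk
        areas.append(int(disk.sum()))
    if params.noise_model == "gaussian":
        stack = clean + rng.normal(0.0, params.noise_sigma, clean.shape)
    elif params.noise_model == "poisson":
        stack = rng.poisson(clean).astype(float)
    else:
        raise ValueError("noise_model must be 'gaussian' or 'poisson'")
    stack = np.clip(stack, 0.0, None)
    truth = {
        "centers": centers,
        "radii": radii,
        "slice_of_droplet": slices,
        "areas_px": areas,
        "total_area_px": int(truth_mask.sum()),
        "count": params.n_droplets,
        "snr": params.snr,
        "mask": truth_mask,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# Redox scenes
# ---------------------------------------------------------------------------


@dataclass
class RedoxSceneParams:
    """Two-channel scene with a known true ratio on signal pixels.

    Signal pixels carry denominator ~= base and numerator ~= true_ratio *
    base (noise sigma = level/snr per channel; snr=inf means noise-free);
    background pixels are dim in both channels, below any bg_factor cut
    of the survivor means by construction.
    """

    image_size: tuple[int, int] = (128, 128)
    n_slices: int = 1
    true_ratio: float = 2.0
    signal_fraction: float = 0.3
    base_intensity: float = 100.0
    bg_intensity: float = 1.0
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.signal_fraction <= 1:
            raise ValueError("signal_fraction must be in (0, 1]")
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be positive")


def gen_redox_scene(params: RedoxSceneParams):
    """Generate (numerator stack, denominator stack, truth dict)."""
    rng = np.random.default_rng(params.seed)
    shape = (params.n_slices, *params.image_size)
    signal = rng.random(shape) < params.signal_fraction
    den = np.full(shape, params.bg_intensity)
    num = np.full(shape, params.bg_intensity * params.true_ratio)
    den[signal] = params.base_intensity
    num[signal] = params.true_ratio * params.base_intensity
    if np.isfinite(params.snr):
        sd_den = params.base_intensity / params.snr
        sd_num = params.true_ratio * params.base_intensity / params.snr
        den = den + np.where(signal, rng.normal(0, sd_den, shape), 0.0)
        num = num + np.where(signal, rng.normal(0, sd_num, shape), 0.0)
    den = np.clip(den, 0.0, None)
    num = np.clip(num, 0.0, None)
    truth = {
        "true_ratio": params.true_ratio,
        "signal_mask": signal,
        "n_signal": int(signal.sum()),
    }
    return num, den, truth


# ---------------------------------------------------------------------------
# Colocalization scenes
# ---------------------------------------------------------------------------


def gen_coloc_scene(
    overlap_fractions,
    image_size: tuple[int, int] = (32, 32),
    mito_px: int = 100,
    extra_atg_px: int = 20,
    seed: int = 0,
):
    """Mask stacks realizing |mito AND atg| / |mito| = f_z exactly per slice.

    Each slice carries ``mito_px`` mitochondrial pixels laid out in raster
    order; the first round(f_z * mito_px) of them are also autophagosome
    pixels, plus ``extra_atg_px`` autophagosome-only pixels elsewhere.
    Every f_z must make f_z * mito_px an integer (within 1e-9), else the
    fraction is not representable and an error suggests a mask size.
    """
    fractions = [float(f) for f in overlap_fractions]
    rows, cols = image_size
    if mito_px + extra_atg_px > rows * cols:
        raise ValueError("image too small for requested pixel budget")
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError("overlap fractions must be in [0, 1]")
        if abs(f * mito_px - round(f * mito_px)) > 1e-9:
            raise ValueError(
                f"fraction {f} not representable with mito_px={mito_px}; "
                "use a mask size whose product with every fraction is integer"
            )
    n_slices = len(fractions)
    mito = np.zeros((n_slices, rows, cols), dtype=bool)
    atg = np.zeros_like(mito)
    flat_m = mito.reshape(n_slices, -1)
    flat_a = atg.reshape(n_slices, -1)
    for z, f in enumerate(fractions):
        overlap = int(round(f * mito_px))
        flat_m[z, :mito_px] = True
        flat_a[z, :overlap] = True
        flat_a[z, mito_px : mito_px + extra_atg_px] = True
    truth = {"overlap_fractions": fractions, "expected_index": float(np.sum(fractions))}
    return mito, atg, truth


# ---------------------------------------------------------------------------
# Sleep architecture traces
# ---------------------------------------------------------------------------


@dataclass
class SleepArchitectureParams:
    """Alternating geometric wake/sleep bouts on a 12:12 LD grid.

    Bout lengths are geometric (memoryless, integer minutes) with the
    given means, switching on the phase at bout start; wake minutes carry
    Poisson(lambda) counts clipped to >= 1 so they are never misread as
    sleep; deprivation windows (ZT minutes, [start, end)) force every
    minute active, emulating mechanical shaking at sub-minute cadence.
    """

    mean_sleep_bout_day_min: float = 20.0
    mean_sleep_bout_night_min: float = 60.0
    mean_wake_bout_day_min: float = 30.0
    mean_wake_bout_night_min: float = 10.0
    waking_activity_rate: float = 2.0
    n_days: int = 2
    deprivation_window_zt: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for m in (
            self.mean_sleep_bout_day_min,
            self.mean_sleep_bout_night_min,
            self.mean_wake_bout_day_min,
            self.mean_wake_bout_night_min,
        ):
            if m < 1:
                raise ValueError("mean bout lengths must be >= 1 min")
        if self.waking_activity_rate <= 0:
            raise ValueError("waking activity rate must be positive")


def _geometric_minutes(rng, mean: float) -> int:
    # geometric on {1, 2, ...} with the requested mean
    p = min(1.0, 1.0 / mean)
    return int(rng.geometric(p))


def gen_dam_traces(
    params: SleepArchitectureParams,
    n_flies: int,
    monitor_path=None,
):
    """Generate activity traces plus ground truth; optionally a monitor file.

    Returns (traces, truth) where truth maps fly_id to its true bout list
    (computed by run-length analysis of the emitted counts, so generator
    and detector share one sleep definition) and true total sleep.  At
    most 32 flies fit one monitor file.
    """
    if not 1 <= n_flies <= 32:
        raise ValueError("n_flies must be in [1, 32]")
    rng = np.random.default_rng(params.seed)
    n_min = params.n_days * MINUTES_PER_DAY
    dep = params.deprivation_window_zt
    traces = []
    truth = {}
    for j in range(n_flies):
        counts = np.zeros(n_min, dtype=np.int64)
        t = 0
        asleep = bool(rng.integers(0, 2))
        while t < n_min:
            zt = t % MINUTES_PER_DAY
            night = zt >= 720
            if asleep:
                mean = (
                    params.mean_sleep_bout_night_min
                    if night
                    else params.mean_sleep_bout_day_min
                )
            else:
                mean = (
                    params.mean_wake_bout_night_min
                    if night
                    else params.mean_wake_bout_day_min
                )
            dur = min(_geometric_minutes(rng, mean), n_min - t)
            if not asleep:
                counts[t : t + dur] = np.maximum(
                    1, rng.poisson(params.waking_activity_rate, dur)
                )
            t += dur
            asleep = not asleep
        if dep is not None:
            zts = np.arange(n_min) % MINUTES_PER_DAY
            shaken = (zts >= dep[0]) & (zts < dep[1])
            forced = np.maximum(
                1, rng.poisson(params.waking_activity_rate, n_min)
            )
            counts = np.where(shaken, forced, counts)
        fly_id = f"ch{j + 1:02d}"
        trace = dam.ActivityTrace(fly_id=fly_id, counts=counts)
        traces.append(trace)
        bouts = dam.detect_bouts(trace)
        truth[fly_id] = {
            "bouts": [(b.start_min, b.duration_min) for b in bouts],
            "total_sleep_min": int(sum(b.duration_min for b in bouts)),
        }
    if monitor_path is not None:
        matrix = np.stack([t.counts for t in traces], axis=1)
        dam.write_dam_monitor(matrix, monitor_path)
    return traces, truth


# ---------------------------------------------------------------------------
# OCR traces
# ---------------------------------------------------------------------------


@dataclass
class OcrSceneParams:
    """Seahorse-like cohort: drifting baseline, post-injection decline.

    ``step_fraction`` of wells get a single injected relative step of
    ``step_size`` at ``step_cycle`` (the QC artifact); the rotenone-like
    decline is a smooth exponential approach to ``decline_floor`` of
    baseline, slow enough never to trip the 30% consecutive-step rule by
    itself.
    """

    n_wells: int = 24
    n_baseline_cycles: int = 6
    n_post_cycles: int = 32
    baseline_level: float = 8.0
    drift_per_cycle: float = -0.002
    noise_sigma: float = 0.02
    step_fraction: float = 0.25
    step_size: float = 0.40
    step_cycle: int = 15
    decline_floor: float = 0.35
    decline_rate: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.step_fraction <= 1.0:
            raise ValueError("step_fraction must be in [0, 1]")


def gen_ocr_traces(params: OcrSceneParams):
    """Generate (DataFrame in tidy OCR-table form, truth labels per well)."""
    rng = np.random.default_rng(params.seed)
    n_cycles = params.n_baseline_cycles + params.n_post_cycles
    cycles = np.arange(n_cycles)
    n_step = int(round(params.step_fraction * params.n_wells))
    step_wells = set(
        rng.choice(params.n_wells, size=n_step, replace=False).tolist()
    )
    rows = []
    truth = {}
    for w in range(params.n_wells):
        level = params.baseline_level * (1 + rng.normal(0, 0.1))
        base = level * (1.0 + params.drift_per_cycle * cycles)
        post = cycles - params.n_baseline_cycles
        decline = np.where(
            post >= 0,
            params.decline_floor
            + (1 - params.decline_floor) * np.exp(-params.decline_rate * np.maximum(post, 0)),
            1.0,
        )
        ocr = base * decline
        if w in step_wells:
            # scale the tail so the noise-free consecutive ratio at the
            # step cycle is exactly 1 + step_size
            sc = params.step_cycle
            factor = (
                (1.0 + params.step_size) * ocr[sc - 1] / ocr[sc]
            )
            ocr = ocr.copy()
            ocr[sc:] *= factor
        if params.noise_sigma > 0:
            ocr = ocr * (1.0 + rng.normal(0, params.noise_sigma, n_cycles))
        ocr = np.clip(ocr, 1e-3, None)
        well_id = f"W{w + 1:02d}"
        truth[well_id] = "artifact" if w in step_wells else "clean"
        for c, v in zip(cycles, ocr):
            rows.append({"well_id": well_id, "cycle": int(c), "ocr": float(v)})
    return pd.DataFrame(rows), truth


def write_truth_json(truth: dict, path) -> None:
    """Write a truth dict as JSON, dropping non-serializable arrays."""
    clean = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in truth.items()
        if not (isinstance(v, np.ndarray) and v.ndim > 1)
    }
    Path(path).write_text(json.dumps(clean, indent=2, default=str))
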
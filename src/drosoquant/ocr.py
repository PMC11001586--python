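"""Seahorse-style oxygen consumption rate (OCR) normalization and QC.

Ex vivo brains respire in a 96-well flux plate on a 4.5-min
mix/wait/measure cycle (1 min / 30 s / 3 min).  Baseline OCR is recorded
for 6 cycles before drug injection; each well is normalized to the end of
its own baseline.  Mixing can shift tissue away from the sensor probe,
producing sudden jumps, so wells with a >30% change between consecutive
measurements are excluded; injection failures are flagged manually (from
cartridge inspection) rather than inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OcrTrace",
    "OcrQcReport",
    "normalize_baseline",
    "flag_unstable",
    "summarize_group",
    "read_ocr_table",
]

DEFAULT_MAX_REL_STEP = 0.30


@dataclass
class OcrTrace:
    """One well's OCR series (pmol O2/min per measurement cycle)."""

    well_id: str
    ocr: np.ndarray
    n_baseline_cycles: int = 6
    injection_cycle: int | None = None
    cycle_minutes: float = 4.5
    injection_failed: bool = False

    def __post_init__(self) -> None:
        self.ocr = np.asarray(self.ocr, dtype=float)
        if self.ocr.ndim != 1:
            raise ValueError("ocr must be 1-D")
        if not np.all(np.isfinite(self.ocr)):
            raise ValueError("OCR values must be finite")
        if np.any(self.ocr <= 0):
            raise ValueError("OCR values must be positive")
        if self.ocr.size <= self.n_baseline_cycles:
            raise ValueError("trace must extend beyond the baseline period")
        if self.injection_cycle is None:
            self.injection_cycle = self.n_baseline_cycles


@dataclass
class OcrQcReport:
    well_id: str
    normalized: np.ndarray
    excluded: bool
    reason: str  # "unstable_step" | "injection_failure" | "none"
    max_rel_step: float


def normalize_baseline(trace: OcrTrace, reference_cycles: int = 3) -> np.ndarray:
    """Divide the series by the mean of the last baseline cycles.

    The reference window is the final ``reference_cycles`` cycles of the
    baseline period, so the normalized series ends its baseline at mean 1.
    """
    if not 1 <= reference_cycles <= trace.n_baseline_cycles:
        raise ValueError(
            "reference_cycles must be in [1, n_baseline_cycles]"
        )
    ref = trace.ocr[
        trace.n_baseline_cycles - reference_cycles : trace.n_baseline_cycles
    ].mean()
    if not ref > 0:
        raise ValueError("nonpositive baseline reference mean")
    return trace.ocr / ref


def flag_unstable(
    trace: OcrTrace,
    max_rel_step: float = DEFAULT_MAX_REL_STEP,
    reference_cycles: int = 3,
) -> OcrQcReport:
    """QC one well: exclude on instability or manual injection failure.

    A well is unstable iff any consecutive pair changes by strictly more
    than ``max_rel_step`` of the earlier value (|x[t+1]-x[t]| / x[t];
    rises and falls count equally; exactly the bound is kept).  The step
    check runs on raw values, so it commutes with normalization.
    """
    if trace.ocr.size < 2:
        raise ValueError("need at least two cycles to assess stability")
    steps = np.abs(np.diff(trace.ocr)) / trace.ocr[:-1]
    max_step = float(steps.max())
    if trace.injection_failed:
        excluded, reason = True, "injection_failure"
    elif max_step > max_rel_step:
        excluded, reason = True, "unstable_step"
    else:
        excluded, reason = False, "none"
    return OcrQcReport(
        well_id=trace.well_id,
        normalized=normalize_baseline(trace, reference_cycles),
        excluded=excluded,
        reason=reason,
        max_rel_step=max_step,
    )


def summarize_group(reports: list[OcrQcReport]) -> pd.DataFrame:
    """Per-cycle mean +/- SEM of normalized OCR over non-excluded wells.

    Returns a tidy frame (cycle, mean, sem, n); the exclusion roster is
    attached as ``DataFrame.attrs['excluded']``.
    """
    kept = [r for r in reports if not r.excluded]
    if not kept:
        raise ValueError("all wells excluded")
    mat = np.array([r.normalized for r in kept])
    mean = mat.mean(axis=0)
    if mat.shape[0] > 1:
        sem = mat.std(axis=0, ddof=1) / math.sqrt(mat.shape[0])
    else:
        sem = np.zeros(mat.shape[1])
    df = pd.DataFrame(
        {
            "cycle": np.arange(mat.shape[1]),
            "mean": mean,
            "sem": sem,
            "n": mat.shape[0],
        }
    )
    df.attrs["excluded"] = [
        {"well_id": r.well_id, "reason": r.reason} for r in reports if r.excluded
    ]
    return df


def read_ocr_table(
    path, n_baseline_cycles: int = 6, cycle_minutes: float = 4.5
) -> list[OcrTrace]:
    """Load per-well OCR traces from a tidy CSV.

    Expected columns: ``well_id``, ``cycle``, ``ocr``; optional boolean
    ``injection_failed`` (manual flag, constant per well).
    """
    df = pd.read_csv(path)
    required = {"well_id", "cycle", "ocr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"OCR table missing columns: {sorted(missing)}")
    traces = []
    for well, sub in df.groupby("well_id", sort=True):
        sub = sub.sort_values("cycle")
        failed = (
            bool(sub["injection_failed"].any())
            if "injection_failed" in sub.columns
            else False
        )
        traces.append(
            OcrTrace(
                well_id=str(well),
                ocr=sub["ocr"].to_numpy(),
                n_baseline_cycles=n_baseline_cycles,
                cycle_minutes=cycle_minutes,
                injection_failed=failed,
            )
        )
    return traces
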
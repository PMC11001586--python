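"""Run configuration: validation, defaults, and pipeline orchestration.

A run is described by one YAML file with a ``seed``, an ``alpha``, and a
``stages`` mapping whose blocks mirror the per-module configuration
types.  Validation resolves every default (each application is logged),
rejects unknown keys, checks parameter ranges, and verifies that every
referenced input file exists — all before any stage runs.  Errors are
aggregated into a single report rather than raised one at a time.

``run_pipeline`` executes the configured stages into a write-once output
directory and records a manifest (config hash, seed, package version,
per-stage status, output checksums) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import drosoquant
from drosoquant import dam, droplets, mitophagy, ocr, redox, stats, synthetic

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Aggregated configuration problems (one message per line)."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid run configuration:\n" + "\n".join(f"- {p}" for p in problems)
        )


# schema: stage -> key -> (default, validator or None). "__file__" keys
# must name existing files when present.
_STAGE_SCHEMA: dict[str, dict[str, tuple]] = {
    "sleep": {
        "monitor": (None, "file"),
        "simulate": (None, "dict"),
        "min_bout": (5, lambda v: v >= 1),
        "bin_min": (30, lambda v: 1440 % v == 0),
        "exclude_dead": (True, None),
        "death_window": (1440, lambda v: v >= 1),
    },
    "droplets": {
        "stack": (None, "file"),
        "simulate": (None, "dict"),
        "mask": (None, "file"),
        "method": ("triangle", lambda v: v in ("triangle", "renyi_entropy", "fixed")),
        "mode": ("per_slice", lambda v: v in ("per_slice", "max_projection")),
        "min_area_px": (0, lambda v: v >= 0),
        "fixed_threshold": (None, None),
    },
    "redox": {
        "num": (None, "file"),
        "den": (None, "file"),
        "simulate": (None, "dict"),
        "mask": (None, "file"),
        "preset": ("rogfp", lambda v: v in redox.RATIO_PRESETS),
        "ratio_low": (0.25, lambda v: v > 0),
        "ratio_high": (4.0, lambda v: v > 0),
        "bg_factor": (0.5, lambda v: v > 0),
        "calibration": (None, "dict"),
    },
    "mitophagy": {
        "mito": (None, "file"),
        "atg": (None, "file"),
        "simulate": (None, "dict"),
        "binarized": (True, None),
        "n_slices": (30, lambda v: v >= 1),
        "start_mode": (
            "max_mito_area",
            lambda v: v in ("max_mito_area", "first_slice"),
        ),
    },
    "ocr": {
        "table": (None, "file"),
        "simulate": (None, "dict"),
        "baseline_cycles": (6, lambda v: v >= 1),
        "reference_cycles": (3, lambda v: v >= 1),
        "max_step": (0.30, lambda v: v > 0),
    },
    "stats": {
        "table": (None, "file"),
        "design": (
            "multi_group_vs_reference",
            lambda v: v in ("two_group", "multi_group_vs_reference"),
        ),
        "reference": (None, None),
    },
}

_TOP_KEYS = {"seed", "alpha", "stages"}


@dataclass
class RunConfig:
    seed: int
    alpha: float
    stages: dict[str, dict]
    applied_defaults: list[str] = field(default_factory=list)


def validate_config(path) -> RunConfig:
    """Parse and fully resolve a YAML run config, or raise ConfigError."""
    path = Path(path)
    problems: list[str] = []
    if not path.exists():
        raise ConfigError([f"config file not found: {path}"])
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])

    for key in raw:
        if key not in _TOP_KEYS:
            problems.append(f"unknown top-level key: {key!r}")
    seed = raw.get("seed", 0)
    alpha = raw.get("alpha", 0.05)
    applied = []
    if "seed" not in raw:
        applied.append("seed = 0")
    if "alpha" not in raw:
        applied.append("alpha = 0.05")
    if not isinstance(seed, int):
        problems.append(f"seed must be an integer, got {seed!r}")
    if not (isinstance(alpha, (int, float)) and 0 < alpha < 1):
        problems.append(f"alpha must lie in (0, 1), got {alpha!r}")

    stages_raw = raw.get("stages", {})
    if not isinstance(stages_raw, dict):
        problems.append("stages must be a mapping of stage blocks")
        stages_raw = {}
    stages: dict[str, dict] = {}
    for stage, block in stages_raw.items():
        if stage not in _STAGE_SCHEMA:
            problems.append(f"unknown stage: {stage!r}")
            continue
        if block is None:
            block = {}
        if not isinstance(block, dict):
            problems.append(f"stage {stage!r} must be a mapping")
            continue
        schema = _STAGE_SCHEMA[stage]
        resolved = {}
        for key, value in block.items():
            if key not in schema:
                problems.append(f"stage {stage!r}: unknown key {key!r}")
        for key, (default, check) in schema.items():
            if key in block:
                value = block[key]
                if check == "file":
                    if value is not None and not Path(value).exists():
                        problems.append(
                            f"stage {stage!r}: {key} file not found: {value}"
                        )
                elif check == "dict":
                    if value is not None and not isinstance(value, dict):
                        problems.append(f"stage {stage!r}: {key} must be a mapping")
                elif check is not None:
                    try:
                        ok = check(value)
                    except TypeError:
                        ok = False
                    if not ok:
                        problems.append(
                            f"stage {stage!r}: invalid value for {key}: {value!r}"
                        )
            else:
                value = default
                applied.append(f"{stage}.{key} = {default!r}")
            resolved[key] = value
        stages[stage] = resolved

    # cross-field checks
    if "redox" in stages:
        blk = stages["redox"]
        if not blk["ratio_low"] < blk["ratio_high"]:
            problems.append("stage 'redox': require ratio_low < ratio_high")
    for stage, file_keys, sim_ok in (
        ("sleep", ["monitor"], True),
        ("droplets", ["stack"], True),
        ("redox", ["num", "den"], True),
        ("mitophagy", ["mito", "atg"], True),
        ("ocr", ["table"], True),
        ("stats", ["table"], False),
    ):
        if stage in stages:
            blk = stages[stage]
            has_files = all(blk.get(k) is not None for k in file_keys)
            has_sim = sim_ok and blk.get("simulate") is not None
            if not has_files and not has_sim:
                need = "/".join(file_keys)
                alt = " or a simulate block" if sim_ok else ""
                problems.append(f"stage {stage!r}: needs {need}{alt}")

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        seed=seed, alpha=float(alpha), stages=stages, applied_defaults=applied
    )


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    if path.exists():
        raise FileExistsError(f"refusing to overwrite {path}")
    df.to_csv(path, index=False, float_format="%.10g")


def _run_sleep(blk: dict, seed: int, out: Path) -> list[Path]:
    if blk["monitor"] is not None:
        traces = dam.read_dam_monitor(blk["monitor"])
    else:
        sim = dict(blk["simulate"] or {})
        n_flies = int(sim.pop("n_flies", 8))
        params = synthetic.SleepArchitectureParams(seed=seed, **sim)
        traces, _ = synthetic.gen_dam_traces(params, n_flies)
    outputs = []
    if blk["exclude_dead"]:
        traces, _, log = dam.exclude_dead(traces, blk["death_window"])
        p = out / "sleep_exclusions.csv"
        _write_csv(log, p)
        outputs.append(p)
    rows, bout_rows = [], []
    for t in traces:
        for m in dam.daily_metrics(t, blk["min_bout"]):
            rows.append({"fly_id": t.fly_id, **m.__dict__})
        for b in dam.detect_bouts(t, blk["min_bout"]):
            bout_rows.append(
                {
                    "fly_id": t.fly_id,
                    "start_min": b.start_min,
                    "duration_min": b.duration_min,
                }
            )
    p1 = out / "sleep_daily_metrics.csv"
    _write_csv(pd.DataFrame(rows), p1)
    p2 = out / "sleep_bouts.csv"
    _write_csv(pd.DataFrame(bout_rows), p2)
    tc = dam.sleep_timecourse(traces, blk["bin_min"], blk["min_bout"])
    p3 = out / "sleep_timecourse.csv"
    _write_csv(tc, p3)
    return outputs + [p1, p2, p3]


def _run_droplets(blk: dict, seed: int, out: Path) -> list[Path]:
    cfg = droplets.SegmentationConfig(
        method=blk["method"],
        mode=blk["mode"],
        min_area_px=blk["min_area_px"],
        fixed_threshold=blk["fixed_threshold"],
    )
    mask = None
    if blk["mask"] is not None:
        mask = redox.read_stack(blk["mask"]).voxels
    rows = []
    if blk["stack"] is not None:
        stack = redox.read_stack(blk["stack"]).voxels
        result = droplets.analyze_droplets(stack, mask, cfg)
        rows.append({"scene": Path(blk["stack"]).name, **_droplet_row(result)})
    else:
        sim = dict(blk["simulate"] or {})
        n_scenes = int(sim.pop("n_scenes", 1))
        for i in range(n_scenes):
            params = synthetic.DropletSceneParams(seed=seed + i, **sim)
            stack, truth = synthetic.gen_droplet_scene(params)
            result = droplets.analyze_droplets(stack, mask, cfg)
            rows.append(
                {
                    "scene": f"sim{i:03d}",
                    **_droplet_row(result),
                    "true_count": truth["count"],
                    "true_total_area_px": truth["total_area_px"],
                }
            )
    p = out / "droplet_metrics.csv"
    _write_csv(pd.DataFrame(rows), p)
    return [p]


def _droplet_row(m: droplets.DropletMorphometry) -> dict:
    return {
        "count": m.count,
        "fractional_area": m.fractional_area,
        "mean_size_px": m.mean_size_px,
        "total_area_px": m.total_area_px,
        "analyzed_px": m.analyzed_px,
    }


def _run_redox(blk: dict, seed: int, out: Path) -> list[Path]:
    cfg = redox.RATIO_PRESETS[blk["preset"]]
    if blk["preset"] == "rogfp" and (
        blk["ratio_low"] != 0.25 or blk["ratio_high"] != 4.0 or blk["bg_factor"] != 0.5
    ):
        cfg = redox.RatioConfig(blk["ratio_low"], blk["ratio_high"], blk["bg_factor"])
    mask = redox.read_stack(blk["mask"]).voxels if blk["mask"] else None
    if blk["num"] is not None:
        num = redox.read_stack(blk["num"])
        den = redox.read_stack(blk["den"])
        truth = None
    else:
        params = synthetic.RedoxSceneParams(seed=seed, **(blk["simulate"] or {}))
        num_v, den_v, truth = synthetic.gen_redox_scene(params)
        num, den = redox.ChannelStack(num_v), redox.ChannelStack(den_v)
    result = redox.compute_ratio_result(num, den, cfg, exclusion_mask=mask)
    row = {
        "mean_ratio": result.mean_ratio,
        "n_included": result.n_included,
        "n_excluded_ratio": result.n_excluded_ratio,
        "n_excluded_bg": result.n_excluded_bg,
    }
    if truth is not None:
        row["true_ratio"] = truth["true_ratio"]
    if blk["calibration"]:
        cal = redox.RedoxCalibration(
            da_mean=float(blk["calibration"]["da"]),
            dtt_mean=float(blk["calibration"]["dtt"]),
        )
        row["percent_oxidized"] = 100.0 * redox.percent_oxidized(
            result.mean_ratio, cal
        )
    p = out / "redox_ratio.csv"
    _write_csv(pd.DataFrame([row]), p)
    return [p]


def _run_mitophagy(blk: dict, seed: int, out: Path) -> list[Path]:
    cfg = mitophagy.ColocConfig(
        n_slices=blk["n_slices"], start_mode=blk["start_mode"]
    )
    if blk["mito"] is not None:
        mito = redox.read_stack(blk["mito"]).voxels
        atg = redox.read_stack(blk["atg"]).voxels
        if not blk["binarized"]:
            mito = mitophagy.binarize_stack(mito, cfg)
            atg = mitophagy.binarize_stack(atg, cfg)
        truth = None
    else:
        sim = dict(blk["simulate"] or {})
        fractions = sim.pop("overlap_fractions", [0.5] * blk["n_slices"])
        mito, atg, truth = synthetic.gen_coloc_scene(fractions, seed=seed, **sim)
    result = mitophagy.coloc_index(mito, atg, cfg)
    row = {
        "window_start": result.window_start,
        "index": result.index,
        "n_slices_used": result.per_slice_ratio.size,
    }
    if truth is not None:
        row["expected_index"] = truth["expected_index"]
    p = out / "mitophagy_index.csv"
    _write_csv(pd.DataFrame([row]), p)
    p2 = out / "mitophagy_per_slice.csv"
    _write_csv(
        pd.DataFrame(
            {
                "slice": np.arange(result.per_slice_ratio.size) + result.window_start,
                "coloc_ratio": result.per_slice_ratio,
            }
        ),
        p2,
    )
    return [p, p2]


def _run_ocr(blk: dict, seed: int, out: Path) -> list[Path]:
    if blk["table"] is not None:
        traces = ocr.read_ocr_table(blk["table"], blk["baseline_cycles"])
    else:
        params = synthetic.OcrSceneParams(seed=seed, **(blk["simulate"] or {}))
        df, _ = synthetic.gen_ocr_traces(params)
        tmp = out / "ocr_input.csv"
        _write_csv(df, tmp)
        traces = ocr.read_ocr_table(tmp, blk["baseline_cycles"])
    reports = [
        ocr.flag_unstable(t, blk["max_step"], blk["reference_cycles"])
        for t in traces
    ]
    qc = pd.DataFrame(
        {
            "well_id": [r.well_id for r in reports],
            "excluded": [r.excluded for r in reports],
            "reason": [r.reason for r in reports],
            "max_rel_step": [r.max_rel_step for r in reports],
        }
    )
    p1 = out / "ocr_qc.csv"
    _write_csv(qc, p1)
    summary = ocr.summarize_group(reports)
    p2 = out / "ocr_group_summary.csv"
    _write_csv(summary, p2)
    return [p1, p2]


def _run_stats(blk: dict, alpha: float, out: Path) -> list[Path]:
    df = pd.read_csv(blk["table"])
    if "value" not in df.columns or "group" not in df.columns:
        raise ValueError("stats table needs 'value' and 'group' columns")
    reference = blk["reference"] or df["group"].iloc[0]
    groups = {
        str(g): sub["value"].to_numpy() for g, sub in df.groupby("group")
    }
    gs = stats.GroupSet(
        groups=groups, reference_label=str(reference), design=blk["design"]
    )
    res = stats.compare(gs, alpha=alpha)
    report = {
        "branch": res.branch,
        "gate_details": res.gate_details,
        "tests_used": res.tests_used,
        "omnibus_p": res.omnibus_p,
        "p_values": res.p_values,
        "significant": res.significant,
        "alpha": res.alpha,
    }
    p = out / "stats_report.json"
    if p.exists():
        raise FileExistsError(f"refusing to overwrite {p}")
    p.write_text(json.dumps(report, indent=2, default=float))
    return [p]


_RUNNERS = {
    "sleep": _run_sleep,
    "droplets": _run_droplets,
    "redox": _run_redox,
    "mitophagy": _run_mitophagy,
    "ocr": _run_ocr,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Execute all configured stages; return the manifest path.

    Outputs are write-once: a stage refuses to overwrite existing files.
    The manifest records enough to reproduce the run (config hash, seed,
    version, per-stage status, output checksums); a stage failure is
    recorded and re-raised after the manifest is written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(
        {"seed": cfg.seed, "alpha": cfg.alpha, "stages": cfg.stages},
        sort_keys=True,
        default=str,
    )
    manifest = {
        "package_version": drosoquant.__version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "applied_defaults": cfg.applied_defaults,
        "stages": {},
        "outputs": {},
    }
    failure: Exception | None = None
    for stage, blk in cfg.stages.items():
        try:
            if stage == "stats":
                paths = _run_stats(blk, cfg.alpha, out)
            else:
                paths = _RUNNERS[stage](blk, cfg.seed, out)
            manifest["stages"][stage] = "ok"
            for p in paths:
                manifest["outputs"][p.name] = _sha256(p)
        except Exception as exc:  # noqa: BLE001 - recorded then re-raised
            manifest["stages"][stage] = f"failed: {exc}"
            failure = exc
            break
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    if failure is not None:
        raise failure
    return mpath
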
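"""Normality-gated group comparisons and related study-wide policies.

Test selection is gated on distributional checks: every group is tested
for normality (Shapiro-Wilk) and the set for variance homogeneity
(median-centered Levene).  If all pass at the gate alpha, parametric
tests are used (two-group t-test, or one-way ANOVA with Holm-Sidak
corrected comparisons against the reference group); if any fails, the
whole experiment drops to the nonparametric branch (Mann-Whitney, or
Kruskal-Wallis with Dunn's rank comparisons against the reference).

Two further policies travel with the statistics:

* dual-control conservatism — when an experimental group has both a GAL4
  and a UAS control, only the larger (most conservative) of the two
  p-values is reported, and a difference is declared only when both
  comparisons are individually significant;
* per-experiment normalization — values are divided by their own
  experiment's control-group mean before pooling across repeats, putting
  every experiment's control mean at exactly 1.

A small ddCt helper quantifies qPCR expression relative to a reference
gene and control condition (expression = 2**(-ddCt)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSet",
    "ComparisonResult",
    "normality_gate",
    "compare",
    "dunn_vs_reference",
    "conservative_p",
    "normalize_and_pool",
    "qpcr_ddct",
]

ALPHA_GATE = 0.05


@dataclass
class GroupSet:
    """Labeled groups of per-animal values with a designated reference."""

    groups: dict[str, np.ndarray]
    reference_label: str
    design: Literal["two_group", "multi_group_vs_reference"] = "two_group"

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        if self.reference_label not in self.groups:
            raise ValueError(
                f"reference group {self.reference_label!r} not present"
            )
        self.groups = {
            k: np.asarray(v, dtype=float) for k, v in self.groups.items()
        }
        for label, vals in self.groups.items():
            if vals.size == 0:
                raise ValueError(f"group {label!r} is empty")
        if self.design == "two_group" and len(self.groups) != 2:
            raise ValueError("two_group design requires exactly two groups")

    def others(self) -> list[str]:
        return [k for k in self.groups if k != self.reference_label]


@dataclass
class ComparisonResult:
    branch: Literal["parametric", "nonparametric"]
    gate_details: dict
    tests_used: list[str]
    p_values: dict[str, float]
    significant: dict[str, bool]
    alpha: float = 0.05
    omnibus_p: float | None = None


def normality_gate(gs: GroupSet, alpha_gate: float = ALPHA_GATE) -> tuple[str, dict]:
    """Decide parametric vs nonparametric branch for a group set.

    Parametric iff every group's Shapiro-Wilk p exceeds ``alpha_gate``
    and median-centered Levene finds no variance heterogeneity.
    Zero-variance (degenerate) groups cannot be tested for normality and
    route the experiment to the nonparametric branch with a warning.
    """
    shapiro_p: dict[str, float] = {}
    degenerate = []
    for label, vals in gs.groups.items():
        if vals.size < 3:
            raise ValueError(
                f"group {label!r} has n={vals.size} < 3; too small to gate"
            )
        if np.ptp(vals) == 0:
            degenerate.append(label)
            shapiro_p[label] = float("nan")
        else:
            shapiro_p[label] = float(sps.shapiro(vals).pvalue)
    if degenerate:
        warnings.warn(
            f"zero-variance group(s) {degenerate}: normality untestable, "
            "using nonparametric branch",
            stacklevel=2,
        )
        levene_p = float("nan")
        branch = "nonparametric"
    else:
        levene_p = float(
            sps.levene(*gs.groups.values(), center="median").pvalue
        )
        all_normal = all(p > alpha_gate for p in shapiro_p.values())
        branch = (
            "parametric"
            if all_normal and levene_p > alpha_gate
            else "nonparametric"
        )
    details = {
        "shapiro_p": shapiro_p,
        "levene_p": levene_p,
        "variance_test": "levene_median",
        "alpha_gate": alpha_gate,
        "degenerate_groups": degenerate,
    }
    return branch, details


def _mwu_method(a: np.ndarray, b: np.ndarray) -> str:
    """Exact Mann-Whitney enumeration for small tie-free samples."""
    values = np.concatenate([a, b])
    no_ties = np.unique(values).size == values.size
    return "exact" if no_ties and max(a.size, b.size) <= 25 else "auto"


def _tie_correction(all_values: np.ndarray) -> float:
    """Dunn tie correction term sum(t^3 - t) / (12 (N - 1))."""
    _, counts = np.unique(all_values, return_counts=True)
    n = all_values.size
    return float(((counts**3 - counts).sum()) / (12.0 * (n - 1)))


def dunn_vs_reference(
    gs: GroupSet, p_adjust: str = "holm-sidak"
) -> dict[str, float]:
    """Dunn's rank comparisons of each group against the reference.

    All observations are ranked jointly (midranks on ties); for each
    non-reference group a z statistic compares mean ranks with the
    tie-corrected variance N(N+1)/12 - sum(t^3-t)/(12(N-1)); two-sided
    normal p-values are then adjusted across the comparisons
    (``holm-sidak`` default; ``bonferroni`` or ``none`` available).
    """
    labels = list(gs.groups)
    values = np.concatenate([gs.groups[k] for k in labels])
    ranks = sps.rankdata(values)
    n_total = values.size
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    pos = 0
    for k in labels:
        n_k = gs.groups[k].size
        mean_ranks[k] = float(ranks[pos : pos + n_k].mean())
        sizes[k] = n_k
        pos += n_k
    var_term = n_total * (n_total + 1) / 12.0 - _tie_correction(values)
    raw = {}
    ref = gs.reference_label
    for k in gs.others():
        se = math.sqrt(
            max(var_term, 0.0) * (1.0 / sizes[k] + 1.0 / sizes[ref])
        )
        if se == 0.0:
            # total degeneracy (all observations tied): no rank evidence
            raw[k] = 1.0
            continue
        z = (mean_ranks[k] - mean_ranks[ref]) / se
        raw[k] = 2.0 * sps.norm.sf(abs(z))
    if p_adjust == "none" or len(raw) == 1:
        return {k: min(1.0, p) for k, p in raw.items()}
    keys = list(raw)
    adj = multipletests(
        [raw[k] for k in keys],
        method={"holm-sidak": "holm-sidak", "bonferroni": "bonferroni"}[
            p_adjust
        ],
    )[1]
    return dict(zip(keys, adj.tolist()))


def compare(
    gs: GroupSet,
    alpha: float = 0.05,
    alpha_gate: float = ALPHA_GATE,
    p_adjust: str = "holm-sidak",
) -> ComparisonResult:
    """Run the gated comparison appropriate for the design.

    two_group: pooled-variance t-test (parametric branch; the gate has
    already checked variance homogeneity) or two-sided Mann-Whitney.
    multi_group_vs_reference: one-way ANOVA followed by per-group t-tests
    against the reference with Holm-Sidak adjustment, or Kruskal-Wallis
    followed by Dunn's comparisons against the reference.  Each
    comparison's p is keyed by the non-reference group label.
    """
    branch, gate = normality_gate(gs, alpha_gate)
    ref_vals = gs.groups[gs.reference_label]
    p_values: dict[str, float] = {}
    tests_used: list[str] = []
    omnibus_p = None

    if gs.design == "two_group":
        (other,) = gs.others()
        if branch == "parametric":
            p = sps.ttest_ind(gs.groups[other], ref_vals).pvalue
            tests_used = ["t_test"]
        else:
            p = sps.mannwhitneyu(
                gs.groups[other],
                ref_vals,
                alternative="two-sided",
                method=_mwu_method(gs.groups[other], ref_vals),
            ).pvalue
            tests_used = ["mann_whitney"]
        p_values[other] = float(p)
    elif gs.design == "multi_group_vs_reference":
        if branch == "parametric":
            omnibus_p = float(sps.f_oneway(*gs.groups.values()).pvalue)
            raw = {
                k: float(sps.ttest_ind(gs.groups[k], ref_vals).pvalue)
                for k in gs.others()
            }
            keys = list(raw)
            if p_adjust == "none" or len(keys) == 1:
                p_values = raw
            else:
                adj = multipletests(
                    [raw[k] for k in keys], method="holm-sidak"
                )[1]
                p_values = dict(zip(keys, adj.tolist()))
            tests_used = ["anova", "holm_sidak_t_vs_reference"]
        else:
            omnibus_p = float(sps.kruskal(*gs.groups.values()).pvalue)
            p_values = dunn_vs_reference(gs, p_adjust=p_adjust)
            tests_used = ["kruskal_wallis", "dunn_vs_reference"]
    else:
        raise ValueError(f"unknown design {gs.design!r}")

    significant = {k: p < alpha for k, p in p_values.items()}
    return ComparisonResult(
        branch=branch,
        gate_details=gate,
        tests_used=tests_used,
        p_values=p_values,
        significant=significant,
        alpha=alpha,
        omnibus_p=omnibus_p,
    )


def conservative_p(
    p_vs_control_a: float, p_vs_control_b: float, alpha: float = 0.05
) -> tuple[float, bool]:
    """Dual-control policy: report the larger p; significant iff both pass.

    With both a GAL4 and a UAS control, the experimental group must
    differ from each control individually; only the most conservative
    (numerically greatest) p-value is reported, and no difference is
    declared if either comparison misses alpha (boundary inclusive:
    p == alpha is not significant).
    """
    for p in (p_vs_control_a, p_vs_control_b):
        if p is None or not 0.0 <= p <= 1.0:
            raise ValueError("both control p-values must lie in [0, 1]")
    reported = max(p_vs_control_a, p_vs_control_b)
    significant = p_vs_control_a < alpha and p_vs_control_b < alpha
    return reported, significant


def normalize_and_pool(
    df: pd.DataFrame,
    control_label: str,
    value_col: str = "value",
    group_col: str = "group",
    experiment_col: str = "experiment",
) -> pd.DataFrame:
    """Divide each experiment's values by its control mean, then pool.

    Every experiment must contain the control group with a positive
    mean.  Returns a copy with a ``normalized`` column; within each
    experiment the control's normalized mean is exactly 1.
    """
    out = df.copy()
    out["normalized"] = np.nan
    for exp, sub in df.groupby(experiment_col, sort=False):
        ctrl = sub.loc[sub[group_col] == control_label, value_col]
        if ctrl.empty:
            raise ValueError(
                f"experiment {exp!r} lacks control group {control_label!r}"
            )
        cmean = ctrl.mean()
        if not cmean > 0:
            raise ValueError(
                f"experiment {exp!r}: control mean {cmean} is not positive"
            )
        out.loc[sub.index, "normalized"] = sub[value_col] / cmean
    return out


def qpcr_ddct(
    table: pd.DataFrame,
    target_col: str = "ct_target",
    reference_col: str = "ct_reference",
    condition_col: str = "condition",
    control_condition: str = "control",
) -> pd.DataFrame:
    """Relative expression by the ddCt method.

    Per sample, dCt = Ct(target) - Ct(reference gene); ddCt subtracts the
    mean dCt of the control condition; expression = 2**(-ddCt).  The
    control condition's mean expression is 1 by construction only in the
    noise-free case; its mean dCt is exactly centered.
    """
    for col in (target_col, reference_col, condition_col):
        if col not in table.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    if table[[target_col, reference_col]].isna().any().any():
        raise ValueError("missing Ct value (reference gene required per sample)")
    if not (table[[target_col, reference_col]] > 0).all().all():
        raise ValueError("Ct values must be positive")
    out = table.copy()
    out["dct"] = out[target_col] - out[reference_col]
    ctrl = out.loc[out[condition_col] == control_condition, "dct"]
    if ctrl.empty:
        raise ValueError(
            f"no samples with condition {control_condition!r}"
        )
    out["ddct"] = out["dct"] - ctrl.mean()
    out["rel_expression"] = 2.0 ** (-out["ddct"])
    return out


def simulate_type_i_error(
    null: str = "gaussian",
    n_per_group: int = 20,
    n_reps: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Empirical type-I error of the gated two-group procedure.

    Draws both groups from the same null (``gaussian`` or ``lognormal``)
    and runs the full gate-then-test pipeline each repetition, so the
    rate reflects the composite procedure including branch switching.
    Returns the rejection rate and the fraction of repetitions routed to
    the parametric branch.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    parametric = 0
    for _ in range(n_reps):
        if null == "gaussian":
            a = rng.normal(0.0, 1.0, n_per_group)
            b = rng.normal(0.0, 1.0, n_per_group)
        elif null == "lognormal":
            a = rng.lognormal(0.0, 1.0, n_per_group)
            b = rng.lognormal(0.0, 1.0, n_per_group)
        else:
            raise ValueError("null must be 'gaussian' or 'lognormal'")
        gs = GroupSet({"exp": a, "ctrl": b}, "ctrl")
        res = compare(gs, alpha=alpha)
        rejections += res.significant["exp"]
        parametric += res.branch == "parametric"
    return {
        "rejection_rate": rejections / n_reps,
        "parametric_fraction": parametric / n_reps,
    }
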
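"""Statistical layer and report assembly.

Conventions reproduced here: normalized current ratios are compared with an
unpaired ratio t-test (a two-sample t-test on log-transformed values, the
appropriate scale for positive multiplicative quantities normalized to
different control batches); absolute current groups use one-way ANOVA with
Tukey's HSD post hoc; per-voltage comparisons are annotated with
significance stars at the fixed thresholds

    no star: p >= 0.05,  *: p < 0.05,  **: p < 0.01,  ***: p < 0.001

with strict inequalities. The Welch (unequal-variance) form is the default
two-sample test; the pooled-variance Student form and a raw-scale (non-log)
ratio test are available behind flags for sensitivity analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["StatResult", "ratio_t_test", "anova_tukey", "anova_by_voltage", "stars", "build_report"]


@dataclass
class StatResult:
    test: str
    groups: tuple
    statistic: float
    p_value: float
    stars: str
    n: tuple
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "groups": list(self.groups),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "stars": self.stars,
            "n": list(self.n),
            **self.extra,
        }


def stars(p: float) -> str:
    """Significance star string at the printed thresholds (strict)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p-value outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ratio_t_test(
    variant_values: Sequence[float],
    reference_values: Sequence[float],
    *,
    log: bool = True,
    welch: bool = True,
) -> StatResult:
    """Unpaired ratio t-test between two groups of normalized currents.

    By default the test runs on natural logs of the (positive) values —
    the standard meaning of a ratio t-test, in its unpaired form because
    variant and control come from different batches. ``log=False`` gives
    the plain t-test on raw ratios.
    """
    a = np.asarray(variant_values, dtype=float)
    b = np.asarray(reference_values, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    if log:
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("ratio t-test requires positive values on the log scale")
        a, b = np.log(a), np.log(b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups have zero variance; test undefined")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return StatResult(
        test="ratio_t" if log else "t",
        groups=("variant", "reference"),
        statistic=float(t),
        p_value=float(p),
        stars=stars(float(p)),
        n=(a.size, b.size),
        extra={"welch": welch, "log": log},
    )


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
    *,
    reference: str | None = None,
) -> tuple[StatResult, list[StatResult]]:
    """One-way ANOVA with Tukey HSD post hoc.

    Returns the omnibus result and pairwise results — against ``reference``
    only if given, otherwise all pairs. Pairwise p-values are invariant to
    group labelling order (Tukey HSD is symmetric).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    for k, arr in zip(names, arrays):
        if arr.size < 3:
            raise ValueError(f"group {k!r} has n < 3")
    f, p = sps.f_oneway(*arrays)
    omnibus = StatResult(
        test="anova",
        groups=tuple(names),
        statistic=float(f),
        p_value=float(p),
        stars=stars(float(p)),
        n=tuple(a.size for a in arrays),
    )
    hsd = sps.tukey_hsd(*arrays)
    pairs = []
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if j <= i:
                continue
            if reference is not None and reference not in (ni, nj):
                continue
            pij = float(hsd.pvalue[i, j])
            pairs.append(
                StatResult(
                    test="tukey_hsd",
                    groups=(ni, nj),
                    statistic=float(hsd.statistic[i, j]),
                    p_value=pij,
                    stars=stars(pij),
                    n=(arrays[i].size, arrays[j].size),
                )
            )
    return omnibus, pairs


def anova_by_voltage(
    ivs: Mapping[str, "np.ndarray"],
    voltages_mv,
    *,
    reference: str,
    v_min: float = 30.0,
) -> list[dict]:
    """Per-voltage ANOVA + Tukey vs a reference group for V >= v_min.

    ``ivs`` maps group label -> (cells x voltages) value matrix. Returns a
    record per retained voltage with the pairwise stars vs the reference.
    """
    v = np.asarray(voltages_mv, dtype=float)
    out = []
    for j, volt in enumerate(v):
        if volt < v_min:
            continue
        groups = {k: m[:, j] for k, m in ivs.items()}
        omni, pairs = anova_tukey(groups, reference=reference)
        rec = {"voltage_mv": float(volt), "anova_p": omni.p_value}
        for pr in pairs:
            other = pr.groups[0] if pr.groups[1] == reference else pr.groups[1]
            rec[other] = {"p": pr.p_value, "stars": pr.stars}
        out.append(rec)
    return out


def build_report(
    phenotypes: Mapping[str, object] | None = None,
    stat_results: Sequence[StatResult] = (),
    ratio_curves: Mapping[str, object] | None = None,
    *,
    seed: int | None = None,
    config: Mapping | None = None,
) -> tuple[dict, str]:
    """Assemble a self-describing JSON report and a markdown summary.

    Deterministic: the same inputs (and seed/config) produce an identical
    report, including its provenance hash.
    """
    report: dict = {"phenotypes": {}, "stats": [s.to_dict() for s in stat_results]}
    for name, call in (phenotypes or {}).items():
        report["phenotypes"][name] = {
            "label": call.label,
            "slope_per_mv": call.slope_per_mv,
            "slope_ci": list(call.slope_ci),
            "mean_ratio": call.mean_ratio,
            "trace": list(call.trace),
        }
    if ratio_curves:
        report["ratios"] = {
            name: {
                "voltages_mv": rc.voltages_mv.tolist(),
                "mean": np.where(rc.mask, None, rc.per_batch.mean(axis=0)).tolist(),
                "sd": np.where(rc.mask, None, rc.per_batch.std(axis=0, ddof=1) if rc.n_batches > 1 else 0.0).tolist(),
                "n_batches": rc.n_batches,
                "masked": rc.mask.tolist(),
            }
            for name, rc in ratio_curves.items()
        }
    prov = {"seed": seed, "config": dict(config or {})}
    prov["hash"] = hashlib.sha256(
        json.dumps([report, seed, prov["config"]], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report["provenance"] = prov

    lines = ["# Analysis report", ""]
    for name, ph in report["phenotypes"].items():
        lines.append(f"- **{name}**: {ph['label']} (mean ratio {ph['mean_ratio']:.3f}, "
                     f"slope {ph['slope_per_mv']:.2e}/mV)")
    if report["stats"]:
        lines.append("")
        lines.append("| test | groups | p | stars |")
        lines.append("|---|---|---|---|")
        for s in report["stats"]:
            lines.append(f"| {s['test']} | {' vs '.join(map(str, s['groups']))} | "
                         f"{s['p_value']:.3g} | {s['stars'] or 'ns'} |")
    lines.append("")
    lines.append(f"provenance hash: {prov['hash']}")
    return report, "\n".join(lines)
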
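"""Acidic-pH gain-of-function assay.

Some variants that look loss-of-function in homomeric complexes conduct an
anomalous inward current at acidic external pH. The assay: record the same
cell at pH 7.3 and at pH 5.3; fit the pH 7.3 current-voltage relation with
a straight line over -120 mV <= V <= 0 mV (where, at neutral pH, current
is assumed to be pure leak); extrapolate the line to all voltages and
subtract it from every condition; normalize each cell to its own
leak-subtracted current at pH 7.3, +160 mV; compare the groups' inward
currents (V <= 20 mV) voltage by voltage.

Per-cell normalization makes the pipeline invariant to expression level,
and the per-cell leak fit removes each oocyte's individual ohmic leak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .stats_report import StatResult, stars
from .traces import IVCurve

__all__ = [
    "LeakLine",
    "NormalizedIV",
    "fit_leak_line",
    "subtract_and_normalize",
    "normalize_cells",
    "compare_inward",
]


@dataclass(frozen=True)
class LeakLine:
    """Straight-line leak estimate I = slope*V + intercept.

    slope is in current units per mV (µA/mV for oocyte recordings; 1 µA/mV
    corresponds to 1 mS of ohmic conductance).
    """

    slope: float
    intercept: float
    v_range: tuple[float, float]
    residual_rms: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("leak line parameters must be finite")

    def predict(self, v_mv) -> np.ndarray:
        return self.slope * np.asarray(v_mv, dtype=float) + self.intercept


@dataclass
class NormalizedIV:
    """Per-cell leak-subtracted, expression-normalized IV curves."""

    voltages_mv: np.ndarray
    values: np.ndarray  # cells x voltages
    condition: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltages_mv = np.asarray(self.voltages_mv, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.values.std(axis=0, ddof=1) if self.n > 1 else np.zeros(self.voltages_mv.size)


def fit_leak_line(
    voltages_mv,
    currents,
    *,
    v_min: float = -120.0,
    v_max: float = 0.0,
) -> LeakLine:
    """Ordinary least-squares leak line for one cell over [v_min, v_max]."""
    v = np.asarray(voltages_mv, dtype=float)
    i = np.asarray(currents, dtype=float)
    sel = (v >= v_min) & (v <= v_max)
    if sel.sum() < 3:
        raise ValueError("need at least 3 voltages in the leak fit range")
    slope, intercept = np.polyfit(v[sel], i[sel], 1)
    resid = i[sel] - (slope * v[sel] + intercept)
    return LeakLine(float(slope), float(intercept), (v_min, v_max), float(np.sqrt(np.mean(resid**2))))


def subtract_and_normalize(
    voltages_mv,
    currents_cond,
    leak: LeakLine,
    denom: float,
) -> np.ndarray:
    """Leak-subtract one cell's condition IV and scale by its denominator."""
    if denom <= 0:
        raise ValueError("normalization denominator must be positive")
    v = np.asarray(voltages_mv, dtype=float)
    return (np.asarray(currents_cond, dtype=float) - leak.predict(v)) / denom


def normalize_cells(
    iv_ph73: IVCurve,
    iv_cond: IVCurve,
    *,
    anchor_mv: float = 160.0,
    v_min: float = -120.0,
    v_max: float = 0.0,
    raw_denominator: bool = False,
) -> NormalizedIV:
    """Full per-cell pipeline for a group recorded at pH 7.3 and a condition.

    Rows of ``iv_ph73`` and ``iv_cond`` must be the same cells in the same
    order. The denominator is the leak-subtracted pH 7.3 current at the
    anchor voltage (raw current with ``raw_denominator=True``).
    """
    if not np.array_equal(iv_ph73.voltages_mv, iv_cond.voltages_mv):
        raise ValueError("pH 7.3 and condition IVs use different voltage grids")
    if iv_ph73.n != iv_cond.n:
        raise ValueError("pH 7.3 and condition IVs have different cell counts")
    v = iv_ph73.voltages_mv
    ia = int(np.argmin(np.abs(v - anchor_mv)))
    if abs(v[ia] - anchor_mv) > 1e-6:
        raise ValueError(f"anchor voltage {anchor_mv} mV not in the protocol")
    rows = []
    for cell73, cellc in zip(iv_ph73.values, iv_cond.values):
        leak = fit_leak_line(v, cell73, v_min=v_min, v_max=v_max)
        denom = cell73[ia] if raw_denominator else cell73[ia] - leak.predict(v[ia])
        rows.append(subtract_and_normalize(v, cellc, leak, denom))
    cond = iv_cond.meta.get("ph", "cond")
    return NormalizedIV(v, np.vstack(rows), cond, meta=dict(iv_cond.meta))


def compare_inward(
    group_a: NormalizedIV,
    group_b: NormalizedIV,
    *,
    v_max: float = 20.0,
    alpha: float = 0.05,
) -> list[StatResult]:
    """Per-voltage Welch comparison of two groups for V <= v_max.

    Mirrors per-voltage significance stars; no multiplicity correction is
    applied (a deliberately liberal presentation convention).
    """
    if not np.array_equal(group_a.voltages_mv, group_b.voltages_mv):
        raise ValueError("voltage grids differ between groups")
    if group_a.n < 3 or group_b.n < 3:
        raise ValueError("need n >= 3 cells in each group")
    out = []
    for j, v in enumerate(group_a.voltages_mv):
        if v > v_max:
            continue
        a = group_a.values[:, j]
        b = group_b.values[:, j]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out.append(
            StatResult(
                test="welch_t",
                groups=(f"A@{v:g}mV", f"B@{v:g}mV"),
                statistic=float(t),
                p_value=float(p),
                stars=stars(float(p)),
                n=(group_a.n, group_b.n),
                extra={"voltage_mv": float(v), "mean_diff": float(a.mean() - b.mean())},
            )
        )
    return out
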
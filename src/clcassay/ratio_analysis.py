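"""Voltage-resolved variant-to-reference current ratios and phenotype calls.

The central statistic: within each batch, the mean variant current at every
voltage is divided by the mean current of the matched wild-type reference
at the same voltage, and the per-batch ratio curves are pooled. The shape
of the pooled curve classifies the variant:

* a flat ratio of 1 - indistinguishable from wild type;
* a flat ratio < 1 - uniform amplitude reduction;
* a positive slope - activation shifted to more positive voltages (the
  dominant-negative gating signature);
* a negative slope - gain of function (gating destabilized at less
  positive voltages);
* a ratio collapsing below the reference-alone control band - suppression
  beyond what losing the variant subunit's transport would produce.

Voltages where the reference current is too small for a meaningful ratio
are masked. The silent-subunit assay (:func:`e281a_assay`) normalizes
per-cell currents at a single voltage to the within-batch mean of the
silenced-partner wild-type control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .traces import IVCurve

__all__ = ["RatioCurve", "PhenotypeCall", "normalize_to_reference", "classify_ratio", "e281a_assay"]


@dataclass
class RatioCurve:
    """Per-batch and pooled variant/reference current ratios.

    ``per_batch`` is (n_batches x n_voltages); ``mask`` is True where the
    ratio is undefined because the reference failed the magnitude gate in
    at least one batch.
    """

    voltages_mv: np.ndarray
    per_batch: np.ndarray
    batch_ids: list
    mask: np.ndarray
    reference_label: str = "WT"
    #: per-batch, per-voltage measurement-noise SE of the ratio (delta
    #: method from the steady-state noise of both group means); None when
    #: the input IV curves carry no noise estimate
    noise_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voltages_mv = np.asarray(self.voltages_mv, dtype=float)
        self.per_batch = np.atleast_2d(np.asarray(self.per_batch, dtype=float))
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.per_batch.shape[1] != self.voltages_mv.size:
            raise ValueError("per_batch must have one column per voltage")
        if self.noise_se is not None:
            self.noise_se = np.atleast_2d(np.asarray(self.noise_se, dtype=float))
            if self.noise_se.shape != self.per_batch.shape:
                raise ValueError("noise_se must match per_batch in shape")

    @property
    def n_batches(self) -> int:
        return self.per_batch.shape[0]

    @property
    def mean(self) -> np.ndarray:
        m = self.per_batch.mean(axis=0)
        return np.where(self.mask, np.nan, m)

    @property
    def sd(self) -> np.ndarray:
        s = self.per_batch.std(axis=0, ddof=1) if self.n_batches > 1 else np.zeros(self.voltages_mv.size)
        return np.where(self.mask, np.nan, s)

    @property
    def unmasked_voltages(self) -> np.ndarray:
        return self.voltages_mv[~self.mask]


@dataclass
class PhenotypeCall:
    """Slope-based functional classification of a ratio curve."""

    label: str
    slope_per_mv: float
    slope_ci: tuple[float, float]
    mean_ratio: float
    trace: list = field(default_factory=list)


def normalize_to_reference(
    variant_by_batch: Mapping[object, IVCurve],
    reference_by_batch: Mapping[object, IVCurve],
    *,
    gate_mult: float = 5.0,
    gate_abs: float = 0.0,
    reference_label: str = "WT",
    per_cell_ratios: bool = False,
) -> RatioCurve:
    """Batchwise variant-to-reference ratio at every voltage.

    The reference magnitude gate masks voltages where, in any batch, the
    reference batch mean lies within ``gate_mult`` measurement-noise
    standard errors of zero (small currents make the ratio meaningless).
    The noise SE comes from the IVCurve's per-cell steady-state noise
    estimate; for curves without one, only ``gate_abs`` applies (mask where
    |mean| <= gate_abs). Batches pair by identifier, never by order.
    ``per_cell_ratios`` averages per-cell ratios against the batch
    reference mean instead of dividing batch means (an alternative
    estimator; identical for balanced noise-free data).
    """
    common = [b for b in variant_by_batch if b in reference_by_batch]
    if not common:
        raise ValueError("variant and reference share no batch identifiers")
    v0 = next(iter(variant_by_batch.values())).voltages_mv
    rows, se_rows, mask = [], [], np.zeros(v0.size, dtype=bool)
    for b in common:
        var, ref = variant_by_batch[b], reference_by_batch[b]
        if not np.array_equal(var.voltages_mv, v0) or not np.array_equal(ref.voltages_mv, v0):
            raise ValueError("voltage grids differ across batches")
        ref_mean = ref.mean
        ref_se = (
            np.sqrt((ref.noise_se**2).sum(axis=0)) / ref.n if ref.noise_se is not None else None
        )
        if ref_se is not None:
            gate = np.maximum(gate_mult * ref_se, gate_abs)
        else:
            gate = np.full(v0.size, gate_abs)
        mask |= np.abs(ref_mean) <= gate
        with np.errstate(divide="ignore", invalid="ignore"):
            if per_cell_ratios:
                r = (var.values / ref_mean).mean(axis=0)
            else:
                r = var.mean / ref_mean
            rows.append(r)
            if ref_se is not None and var.noise_se is not None:
                var_se = np.sqrt((var.noise_se**2).sum(axis=0)) / var.n
                # delta method for a ratio of independent noisy means
                se_rows.append(np.sqrt(var_se**2 + (r * ref_se) ** 2) / np.abs(ref_mean))
    mask |= ~np.isfinite(np.vstack(rows)).all(axis=0)
    if mask.all():
        raise ValueError("all voltages masked by the reference magnitude gate")
    noise_se = np.vstack(se_rows) if len(se_rows) == len(rows) else None
    return RatioCurve(v0, np.vstack(rows), list(common), mask, reference_label, noise_se)


def _slope_ci(rc: RatioCurve, alpha: float) -> tuple[float, tuple[float, float]]:
    """Ratio-vs-voltage slope with a batch-intercept (ANCOVA) fit.

    Per-cell expression and per-batch factors scale a batch's whole ratio
    curve, so each batch contributes c_b * r(V) plus independent
    steady-state measurement noise. Fitting one intercept per batch and a
    common slope absorbs the batch levels exactly; the slope's t-interval
    then rests on the independent per-voltage noise, with
    N - n_batches - 1 residual degrees of freedom. (A single pooled fit
    without batch intercepts would let batch-level scatter masquerade as
    slope evidence.)
    """
    v = rc.voltages_mv[~rc.mask]
    nb, m = rc.n_batches, v.size
    y = rc.per_batch[:, ~rc.mask].ravel()
    dof = y.size - (nb + 1)
    if dof < 1:
        raise ValueError("too few unmasked voltages for slope inference")
    # design: batch dummies then centred voltage
    X = np.zeros((nb * m, nb + 1))
    for b in range(nb):
        X[b * m:(b + 1) * m, b] = 1.0
    X[:, nb] = np.tile(v - v.mean(), nb)

    w = None
    if rc.noise_se is not None:
        se_pts = rc.noise_se[:, ~rc.mask].ravel()
        if np.all(se_pts > 0):
            w = 1.0 / se_pts
    if w is not None:
        # heteroscedastic WLS with known (propagated) noise variances:
        # whiten, then the coefficient covariance is (X'WX)^-1
        Xw = X * w[:, None]
        yw = y * w
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        cov = np.linalg.inv(Xw.T @ Xw)
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / dof
        cov = s2 * np.linalg.inv(X.T @ X)
    est = float(beta[nb])
    se = float(np.sqrt(cov[nb, nb]))
    tcrit = stats.t.ppf(1 - alpha / 2, dof)
    if se == 0:
        return est, (est, est)
    return est, (est - tcrit * se, est + tcrit * se)


def classify_ratio(
    rc: RatioCurve,
    *,
    reduction_threshold: float = 0.8,
    control_floor: float = 0.3,
    alpha: float = 0.01,
) -> PhenotypeCall:
    """Assign a functional phenotype from a ratio curve.

    Ordered rule set: (1) ``below_reference_control`` if the pooled ratio
    at the top three voltages falls below ``control_floor`` (suppression
    below the reference-alone band); (2) ``positive_shift`` /
    ``negative_slope_gof`` if the slope CI excludes zero, by sign; (3)
    ``uniform_reduction`` if the mean ratio is below
    ``reduction_threshold`` with a slope CI containing zero; (4)
    ``wt_like`` otherwise.

    The default call threshold (``alpha=0.01``) is stricter than a
    conventional 95% interval: a categorical phenotype label warrants high
    specificity, and the batch-intercept slope test has enough power that
    the stricter level costs essentially no sensitivity.
    """
    n_unmasked = int((~rc.mask).sum())
    if n_unmasked < 4:
        raise ValueError("need at least 4 unmasked voltages to classify")
    slope, ci = _slope_ci(rc, alpha)
    pooled = rc.per_batch.mean(axis=0)
    mean_ratio = float(pooled[~rc.mask].mean())
    order = np.argsort(rc.voltages_mv)
    top3 = [i for i in order[::-1] if not rc.mask[i]][:3]
    top_mean = float(pooled[top3].mean())
    trace = [
        f"unmasked voltages: {n_unmasked}",
        f"slope {slope:.3e}/mV, {100 * (1 - alpha):g}% CI [{ci[0]:.3e}, {ci[1]:.3e}]",
        f"mean ratio {mean_ratio:.3f}; top-3-voltage mean {top_mean:.3f}",
    ]
    # numerical floor so that an exactly-flat noise-free curve (degenerate
    # point CI at ~1e-17) is not read as a shift
    slope_tol = 1e-12
    if top_mean < control_floor:
        trace.append(f"rule 1: top-voltage mean < control floor {control_floor}")
        label = "below_reference_control"
    elif ci[0] > slope_tol:
        trace.append("rule 2: slope CI excludes 0 (positive)")
        label = "positive_shift"
    elif ci[1] < -slope_tol:
        trace.append("rule 2: slope CI excludes 0 (negative)")
        label = "negative_slope_gof"
    elif mean_ratio < reduction_threshold:
        trace.append(f"rule 3: mean ratio < {reduction_threshold} with flat slope")
        label = "uniform_reduction"
    else:
        trace.append("rule 4: default")
        label = "wt_like"
    return PhenotypeCall(label, slope, ci, mean_ratio, trace)


def e281a_assay(
    variant_currents: Sequence[float],
    variant_batches: Sequence[object],
    reference_currents: Sequence[float],
    reference_batches: Sequence[object],
) -> dict:
    """Silent-subunit assay: per-cell currents normalized within batch.

    Each variant cell's current (at the assay voltage, typically +170 mV)
    is divided by the mean current of the silenced-partner wild-type
    control cells of the same batch. Returns the normalized values and a
    mean/SD/n summary.
    """
    variant_currents = np.asarray(variant_currents, dtype=float)
    reference_currents = np.asarray(reference_currents, dtype=float)
    variant_batches = list(variant_batches)
    reference_batches = list(reference_batches)
    if len(variant_batches) != variant_currents.size or len(reference_batches) != reference_currents.size:
        raise ValueError("batch labels must match current values one-to-one")
    ref_means = {}
    for b in set(variant_batches):
        sel = [i for i, rb in enumerate(reference_batches) if rb == b]
        if not sel:
            raise ValueError(f"batch {b!r} has no reference cells")
        ref_means[b] = reference_currents[sel].mean()
    values = np.array([i / ref_means[b] for i, b in zip(variant_currents, variant_batches)])
    return {
        "values": values,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "n": int(values.size),
    }
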
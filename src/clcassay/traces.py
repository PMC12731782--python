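"""Voltage-clamp trace processing.

Turns raw step-clamp sweep families into leak-corrected steady-state
current-voltage (I-V) relationships:

* :class:`VoltageProtocol` describes the stimulus (holding potential, step
  ladder, segment durations, sampling rate, P/N scale).
* :func:`pn_subtract` removes linear leak and capacitive components using a
  scaled-down P/N companion recording.
* :func:`steady_state` averages each sweep over the last third of the step
  segment.
* :func:`build_iv` stacks per-cell steady-state vectors into a group-level
  :class:`IVCurve`; :func:`current_density` converts whole-cell currents to
  pA/pF.

Conventions: voltages in mV, time in seconds internally, currents in µA
(oocyte two-electrode recordings) or pA (whole-cell patch recordings).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "VoltageProtocol",
    "SweepSet",
    "IVCurve",
    "pn_subtract",
    "steady_state",
    "steady_state_noise_se",
    "build_iv",
    "current_density",
]


@dataclass(frozen=True)
class VoltageProtocol:
    """Step-clamp stimulus description.

    The default values are the standard transport-current protocol: 5 ms
    steps from +200 mV to -40 mV in -10 mV increments from a holding
    potential of 0 mV, sampled at 100 kHz, with P/N correction sweeps
    acquired at 0.2x amplitude.
    """

    holding_mv: float = 0.0
    step_start_mv: float = 200.0
    step_delta_mv: float = -10.0
    step_end_mv: float = -40.0
    step_duration_ms: float = 5.0
    pre_ms: float = 2.0
    post_ms: float = 2.0
    sampling_hz: float = 100_000.0
    pn_scale: float = 0.2

    def __post_init__(self) -> None:
        if self.step_delta_mv == 0:
            raise ValueError("step_delta_mv must be nonzero")
        span = self.step_start_mv - self.step_end_mv
        n = span / -self.step_delta_mv
        # ladder must land exactly on step_end_mv
        if abs(round(n) - n) > 1e-9 or n < 0:
            raise ValueError("(step_start - step_end) must be divisible by step_delta")
        if not (0.0 < self.pn_scale < 1.0):
            raise ValueError("pn_scale must lie in (0, 1)")
        if self.sampling_hz <= 0 or self.step_duration_ms <= 0:
            raise ValueError("sampling rate and step duration must be positive")

    @property
    def step_voltages_mv(self) -> np.ndarray:
        n = int(round((self.step_start_mv - self.step_end_mv) / -self.step_delta_mv)) + 1
        return self.step_start_mv + self.step_delta_mv * np.arange(n)

    @property
    def n_steps(self) -> int:
        return self.step_voltages_mv.size

    def _samples(self, ms: float) -> int:
        return int(round(ms * 1e-3 * self.sampling_hz))

    @property
    def n_pre(self) -> int:
        return self._samples(self.pre_ms)

    @property
    def n_step(self) -> int:
        return self._samples(self.step_duration_ms)

    @property
    def n_post(self) -> int:
        return self._samples(self.post_ms)

    @property
    def n_samples(self) -> int:
        return self.n_pre + self.n_step + self.n_post

    @property
    def step_slice(self) -> slice:
        return slice(self.n_pre, self.n_pre + self.n_step)

    @property
    def last_third_slice(self) -> slice:
        """Index window used for steady-state averaging.

        The step segment of length L is split at floor(2L/3); the window is
        [floor(2L/3), L) relative to the segment start.
        """
        L = self.n_step
        return slice(self.n_pre + (2 * L) // 3, self.n_pre + L)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_hz

    def scaled(self, factor: float) -> "VoltageProtocol":
        """Protocol with all command voltages multiplied by ``factor``
        (used for P/N correction sweeps)."""
        return replace(
            self,
            holding_mv=self.holding_mv * factor,
            step_start_mv=self.step_start_mv * factor,
            step_delta_mv=self.step_delta_mv * factor,
            step_end_mv=self.step_end_mv * factor,
        )


# Protocol used for the acidic-pH assay: symmetric ladder reaching the
# negative voltages where gain-of-function inward currents appear, with
# the same 10 mV step convention as the transport protocol.
PH_ASSAY_PROTOCOL = VoltageProtocol(
    step_start_mv=160.0, step_delta_mv=-10.0, step_end_mv=-160.0
)


@dataclass
class SweepSet:
    """One cell's sweep family: a (samples x sweeps) current matrix.

    ``current`` columns follow the protocol's step ladder order. Units are
    µA for oocyte (``mode='oocyte_tevc'``) and pA for whole-cell
    (``mode='cell_patch'``) recordings.
    """

    time_s: np.ndarray
    current: np.ndarray
    protocol: VoltageProtocol
    meta: dict = field(default_factory=dict)
    corrected: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.current.ndim != 2:
            raise ValueError("current must be a 2-D (samples x sweeps) array")
        if self.current.shape[1] != self.protocol.n_steps:
            raise ValueError(
                f"sweep count {self.current.shape[1]} does not match protocol "
                f"step count {self.protocol.n_steps}"
            )
        if self.current.shape[0] != self.time_s.size:
            raise ValueError("time base length does not match sample count")

    @property
    def voltages_mv(self) -> np.ndarray:
        return self.protocol.step_voltages_mv


@dataclass
class IVCurve:
    """Group-level current-voltage relationship.

    ``values`` holds per-cell steady-state currents (cells x voltages);
    summary statistics are derived properties so they can never go stale.
    """

    voltages_mv: np.ndarray
    values: np.ndarray
    units: str = "uA"
    meta: dict = field(default_factory=dict)
    cell_ids: list = field(default_factory=list)
    #: per-cell standard error of each steady-state estimate (measurement
    #: noise only, excluding biological scatter); used by the reference
    #: magnitude gate of the ratio analysis
    noise_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voltages_mv = np.asarray(self.voltages_mv, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.voltages_mv.size:
            raise ValueError("values must have one column per voltage")
        if self.noise_se is not None:
            self.noise_se = np.atleast_2d(np.asarray(self.noise_se, dtype=float))
            if self.noise_se.shape != self.values.shape:
                raise ValueError("noise_se must match values in shape")
        if not self.cell_ids:
            self.cell_ids = [f"cell{i}" for i in range(self.values.shape[0])]
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length must match number of cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.values.std(axis=0, ddof=1) if self.n > 1 else np.zeros(self.voltages_mv.size)

    @property
    def sem(self) -> np.ndarray:
        return self.sd / np.sqrt(self.n)


def pn_subtract(raw: SweepSet, pn: SweepSet) -> SweepSet:
    """Remove linear leak and capacitive components by P/N subtraction.

    The P/N companion is acquired with the same protocol scaled by
    ``pn_scale`` and contains only components linear in voltage; the
    corrected family is ``raw - pn / pn_scale``, sample by sample.
    """
    if raw.current.shape != pn.current.shape:
        raise ValueError("raw and P/N sweep families differ in shape")
    if raw.protocol.sampling_hz != pn.protocol.sampling_hz:
        raise ValueError("raw and P/N sampling rates differ")
    scale = raw.protocol.pn_scale
    corrected = raw.current - pn.current / scale
    meta = dict(raw.meta)
    return SweepSet(raw.time_s, corrected, raw.protocol, meta, corrected=True)


def steady_state(sweeps: SweepSet, *, allow_raw: bool = False) -> np.ndarray:
    """Per-sweep steady-state current: mean over the last third of the step.

    Refuses uncorrected input unless ``allow_raw`` is set (diagnostic use).
    """
    if not sweeps.corrected and not allow_raw:
        raise ValueError(
            "sweeps are not leak-corrected; pass allow_raw=True to analyse raw data"
        )
    if sweeps.protocol.n_step < 3:
        raise ValueError("step segment has fewer than 3 samples")
    window = sweeps.current[sweeps.protocol.last_third_slice]
    return window.mean(axis=0)


def steady_state_noise_se(sweeps: SweepSet) -> np.ndarray:
    """Standard error of each sweep's steady-state estimate.

    Estimated from the within-window sample variance; valid when the signal
    has settled inside the averaging window, so residual variation is noise.
    """
    window = sweeps.current[sweeps.protocol.last_third_slice]
    m = window.shape[0]
    if m < 2:
        raise ValueError("steady-state window has fewer than 2 samples")
    return window.std(axis=0, ddof=1) / np.sqrt(m)


def build_iv(
    cells: Sequence[SweepSet],
    *,
    allow_mixed: bool = False,
    allow_raw: bool = False,
) -> IVCurve:
    """Stack per-cell steady-state vectors into a group :class:`IVCurve`.

    All cells must share the protocol and (unless ``allow_mixed``) the
    construct and pH condition recorded in their metadata.
    """
    if not cells:
        raise ValueError("no cells supplied")
    proto = cells[0].protocol
    ref_keys = {k: cells[0].meta.get(k) for k in ("construct", "ph")}
    rows = []
    ses = []
    ids = []
    for c in cells:
        if c.protocol.step_voltages_mv.shape != proto.step_voltages_mv.shape or not np.allclose(
            c.protocol.step_voltages_mv, proto.step_voltages_mv
        ):
            raise ValueError("cells do not share a voltage protocol")
        if not allow_mixed:
            for k, v in ref_keys.items():
                if c.meta.get(k) != v:
                    raise ValueError(
                        f"mixed '{k}' across cells ({c.meta.get(k)!r} vs {v!r}); "
                        "pass allow_mixed=True to override"
                    )
        rows.append(steady_state(c, allow_raw=allow_raw))
        ses.append(steady_state_noise_se(c))
        ids.append(c.meta.get("cell_id", f"cell{len(ids)}"))
    units = "uA" if cells[0].meta.get("mode", "oocyte_tevc") == "oocyte_tevc" else "pA"
    meta = {k: v for k, v in cells[0].meta.items() if k in ("construct", "batch", "ph", "mode")}
    return IVCurve(
        proto.step_voltages_mv, np.vstack(rows), units=units, meta=meta,
        cell_ids=ids, noise_se=np.vstack(ses),
    )


def current_density(iv: IVCurve, capacitance_pf: Mapping[str, float] | Sequence[float]) -> IVCurve:
    """Convert a whole-cell IVCurve from pA to pA/pF.

    ``capacitance_pf`` maps cell id -> capacitance, or gives one value per
    cell in order. Zero, negative or missing capacitances are hard errors.
    """
    if iv.units != "pA":
        raise ValueError("current density is defined for whole-cell (pA) recordings only")
    if isinstance(capacitance_pf, Mapping):
        try:
            caps = np.array([capacitance_pf[c] for c in iv.cell_ids], dtype=float)
        except KeyError as exc:
            raise ValueError(f"missing capacitance for cell {exc.args[0]!r}") from exc
    else:
        caps = np.asarray(capacitance_pf, dtype=float)
        if caps.size != iv.n:
            raise ValueError("need one capacitance per cell")
    if np.any(caps <= 0):
        raise ValueError("capacitances must be positive")
    vals = iv.values / caps[:, None]
    se = iv.noise_se / caps[:, None] if iv.noise_se is not None else None
    return IVCurve(
        iv.voltages_mv, vals, units="pA/pF", meta=dict(iv.meta),
        cell_ids=list(iv.cell_ids), noise_se=se,
    )
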
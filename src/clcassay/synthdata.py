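"""Synthetic electrophysiology sessions and FLIM decay images.

Generates data possessing the statistical and biophysical structure the
analysis pipeline assumes, so every downstream stage is testable without
any experimental recordings.

Biophysical model
-----------------
CLC transporters are dimers; each protomer carries an independent transport
pathway and a shared ("common") gate closes both simultaneously. The common
gate is modelled as a Boltzmann activation that saturates at large positive
voltages,

    p(V) = 1 / (1 + exp(-(V - V_half)/k)),

and the transport current of a dimer is the number of active protomers
times a per-protomer unit current times p(V) times a linear driving-force
term d(V) = V / 100 mV (zero at the 0 mV holding potential). Co-expression
of two subunits at ratio r produces a binomial homodimer/heterodimer
mixture a^2 : 2ab : b^2 with a = r/(1+r). A dominant variant protomer
shifts the common-gate V_half of every dimer that contains it by its full
dv_half. Gain-of-function variants additionally conduct an inward current
at acidic pH, -g_gof * max(0, -(V - V_rev)), carried by variant-bearing
heterodimers.

Recordings add, on top of the model current: a per-cell lognormal
expression factor, a per-batch lognormal factor, ohmic leak g*V, a single
exponential capacitive transient at each step edge (amplitude proportional
to the voltage jump), and Gaussian noise. Companion P/N sweeps contain the
linear components only, at the scaled-down (0.2x) protocol.

All randomness derives from a single integer seed expanded through
``numpy`` SeedSequence keys per batch/cell/pixel, so outputs are
byte-stable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .flim_phasor import DecayStack
from .traces import IVCurve, SweepSet, VoltageProtocol

__all__ = [
    "VariantParams",
    "GateModel",
    "DimerPopulation",
    "ConstructModel",
    "SessionSpec",
    "FlimSpec",
    "variant_library",
    "assemble_dimers",
    "boltzmann",
    "model_iv",
    "coexpression_construct",
    "homodimer_construct",
    "simulate_cell",
    "simulate_study",
    "simulate_session",
    "simulate_iv_cells",
    "decay_profile",
    "simulate_flim",
]


@dataclass(frozen=True)
class VariantParams:
    """Biophysical parameterization of a CLCN4 variant.

    dv_half: common-gate half-activation shift in mV imposed on dimers
        containing the variant protomer (all dimers if ``dominant``).
    amp_factor: per-protomer transport amplitude scale (0 = transport-dead).
    gof_inward_g: inward conductance at acidic pH, µS per unit expression
        (0 for variants without the gain-of-function component).
    """

    label: str
    dv_half: float = 0.0
    amp_factor: float = 1.0
    gof_inward_g: float = 0.0
    dominant: bool = False

    def __post_init__(self) -> None:
        if self.amp_factor < 0:
            raise ValueError("amp_factor must be >= 0")
        if self.gof_inward_g < 0:
            raise ValueError("gof_inward_g must be >= 0")


@dataclass(frozen=True)
class GateModel:
    """Common-gate and transport parameters shared by a recording mode.

    i_unit is the transport current per protomer per unit expression at the
    reference driving force of +100 mV with the gate fully open (µA for
    oocytes, pA for whole-cell recordings).
    """

    v_half: float = 120.0
    slope_k: float = 40.0
    i_unit: float = 1.5
    v_rev: float = 0.0

    def __post_init__(self) -> None:
        if self.slope_k <= 0:
            raise ValueError("slope_k must be positive")


# Whole-cell recordings are in pA; unit current rescaled so peak currents
# land in the few-nA range typical of transfected cells.
CELL_GATE = GateModel(i_unit=400.0)


@dataclass(frozen=True)
class DimerPopulation:
    """Homodimer/heterodimer mixture from co-expressing protomers A and B.

    ``transport_a``/``transport_b`` flag per-protomer transport competence
    (set ``transport_b=False`` to encode a proton-glutamate-silenced
    partner subunit that still dimerizes).
    """

    frac_aa: float
    frac_ab: float
    frac_bb: float
    transport_a: bool = True
    transport_b: bool = True

    def __post_init__(self) -> None:
        fr = (self.frac_aa, self.frac_ab, self.frac_bb)
        if min(fr) < 0:
            raise ValueError("dimer fractions must be nonnegative")
        if abs(sum(fr) - 1.0) > 1e-12:
            raise ValueError("dimer fractions must sum to 1")


def variant_library() -> dict[str, VariantParams]:
    """Reference parameterizations of the studied CLCN4 variants.

    Signs and ordering encode the reported phenotypes: WT is the reference;
    R360S is transport-dead as a homodimer but gains an inward acidic-pH
    conductance in heteromers and has the weakest common-gate shift;
    V536M, G545S and K560E shift activation to more positive voltages with
    K560E > G545S > V536M. The shift magnitudes are configurable defaults,
    not measured values: they are calibrated so that the graded reduction
    in the silenced-partner assay is reliably resolvable at the reported
    study size (3 batches of 6-8 oocytes per construct) under the default
    expression variability.
    """
    return {
        "WT": VariantParams("WT"),
        "R360S": VariantParams("R360S", dv_half=10.0, amp_factor=0.0, gof_inward_g=1.5, dominant=True),
        "V536M": VariantParams("V536M", dv_half=30.0, dominant=True),
        "G545S": VariantParams("G545S", dv_half=60.0, dominant=True),
        "K560E": VariantParams("K560E", dv_half=130.0, dominant=True),
    }


def assemble_dimers(expr_ratio_ab: float, silent_b: bool = False) -> DimerPopulation:
    """Binomial dimer mixture for independent pairing at expression ratio A:B.

    With a = r/(1+r) and b = 1/(1+r): fractions a^2, 2ab, b^2.
    """
    if not expr_ratio_ab > 0:
        raise ValueError("expression ratio must be positive")
    a = expr_ratio_ab / (1.0 + expr_ratio_ab)
    b = 1.0 - a
    return DimerPopulation(a * a, 2 * a * b, b * b, transport_b=not silent_b)


def boltzmann(v: np.ndarray | float, v_half: float, k: float) -> np.ndarray:
    """Saturating common-gate open probability."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - v_half) / k))


def model_iv(
    gate: GateModel,
    pop: DimerPopulation,
    variant: VariantParams,
    voltages_mv: np.ndarray | Sequence[float],
    ph: str = "ph7.3",
) -> np.ndarray:
    """Noise- and leak-free transport current per unit expression.

    Protomer A is the reference (wild-type ClC-3-like) subunit; protomer B
    carries ``variant``. Current units follow ``gate.i_unit``.
    """
    v = np.asarray(voltages_mv, dtype=float)
    if np.any(np.abs(v) > 250):
        raise ValueError("voltages outside +/-250 mV")
    d = v / 100.0
    vh_aa = gate.v_half
    vh_bb = gate.v_half + variant.dv_half
    vh_ab = gate.v_half + (variant.dv_half if variant.dominant else 0.0)
    amp_aa = 2.0 * float(pop.transport_a)
    amp_ab = float(pop.transport_a) + float(pop.transport_b) * variant.amp_factor
    amp_bb = 2.0 * float(pop.transport_b) * variant.amp_factor
    i = gate.i_unit * d * (
        pop.frac_aa * amp_aa * boltzmann(v, vh_aa, gate.slope_k)
        + pop.frac_ab * amp_ab * boltzmann(v, vh_ab, gate.slope_k)
        + pop.frac_bb * amp_bb * boltzmann(v, vh_bb, gate.slope_k)
    )
    if ph == "ph5.3" and variant.gof_inward_g > 0:
        # inward gain-of-function component of variant-bearing heteromers;
        # conductance in µS against mV gives nA, hence the 1e-3 to µA
        i = i + pop.frac_ab * variant.gof_inward_g * np.minimum(0.0, v - gate.v_rev) * 1e-3
    return i


@dataclass(frozen=True)
class ConstructModel:
    """A named expression condition: dimer mixture plus variant parameters."""

    label: str
    pop: DimerPopulation
    variant: VariantParams

    def iv(self, gate: GateModel, voltages_mv, ph: str = "ph7.3") -> np.ndarray:
        return model_iv(gate, self.pop, self.variant, voltages_mv, ph)


def coexpression_construct(
    variant: VariantParams,
    *,
    expr_ratio: float = 1.0,
    silent_partner: bool = False,
    label: str | None = None,
) -> ConstructModel:
    """Reference subunit co-expressed 1:1 (by default) with a variant subunit."""
    pop = assemble_dimers(expr_ratio, silent_b=silent_partner)
    name = label or f"ClC-3/ClC-4_{variant.label}" + ("_E281A" if silent_partner else "")
    return ConstructModel(name, pop, variant)


def homodimer_construct(variant: VariantParams, *, label: str | None = None) -> ConstructModel:
    """Pure homodimer of the given subunit expressed alone.

    Modelled as a B-homodimer so the subunit's own amplitude factor and
    gating shift apply to both protomers (for the wild-type reference this
    is indistinguishable from an A-homodimer).
    """
    pop = DimerPopulation(0.0, 0.0, 1.0)
    return ConstructModel(label or variant.label, pop, variant)


@dataclass
class SessionSpec:
    """Study layout and noise model for a simulated recording session.

    Defaults follow the reported designs: 3 oocyte batches of ~7 cells per
    construct, lognormal per-cell expression (sigma 0.3) and per-batch
    factors (sigma 0.2), ohmic leak ~1 µS, additive current noise 0.05 µA.
    ``cells_per_batch`` may be an int or an inclusive (low, high) range
    sampled per batch.
    """

    mode: str = "oocyte_tevc"
    constructs: list = field(default_factory=list)
    n_batches: int = 3
    cells_per_batch: int | tuple[int, int] = 7
    expression_cv: float = 0.3
    batch_cv: float = 0.2
    leak_g_mean: float = 1.0
    leak_g_sd: float = 0.3
    noise_sd: float = 0.05
    cap_gain: float = 0.01
    cap_tau_ms: float = 0.2
    seed: int = 0
    ph_condition: str = "ph7.3"
    protocol: VoltageProtocol = field(default_factory=VoltageProtocol)

    def __post_init__(self) -> None:
        if self.mode not in ("oocyte_tevc", "cell_patch"):
            raise ValueError("mode must be 'oocyte_tevc' or 'cell_patch'")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        low = self.cells_per_batch if isinstance(self.cells_per_batch, int) else self.cells_per_batch[0]
        if low < 1:
            raise ValueError("cells_per_batch must be >= 1")
        if self.ph_condition not in ("ph7.3", "ph5.3", "paired"):
            raise ValueError("ph_condition must be ph7.3, ph5.3 or paired")


def _cell_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])


def _sweep_family(
    protocol: VoltageProtocol,
    step_current,
    leak_g_us: float,
    cap_gain: float,
    cap_tau_ms: float,
    noise_sd: float,
    rng: np.random.Generator | None,
    *,
    voltage_scale: float = 1.0,
) -> np.ndarray:
    """Raw sample matrix for one sweep family.

    ``step_current`` gives the (quasi-steady-state) transport current per
    step; linear components are evaluated at ``voltage_scale`` times the
    protocol's command voltages (P/N acquisition uses the scale factor).
    """
    n = protocol.n_samples
    t = protocol.time_s
    volts = np.full((n, protocol.n_steps), protocol.holding_mv)
    volts[protocol.step_slice] = protocol.step_voltages_mv
    volts = volts * voltage_scale

    current = np.zeros((n, protocol.n_steps))
    step_current = np.asarray(step_current, dtype=float)
    current[protocol.step_slice] = step_current
    # ohmic leak: µS * mV * 1e-3 -> µA (pA-mode callers pass leak in nS)
    current += leak_g_us * volts * 1e-3

    # capacitive transients at both step edges, single exponential
    tau_s = cap_tau_ms * 1e-3
    dv_on = (protocol.step_voltages_mv - protocol.holding_mv) * voltage_scale
    i_on = protocol.n_pre
    i_off = protocol.n_pre + protocol.n_step
    t_on = t[i_on:, None] - t[i_on]
    current[i_on:] += cap_gain * dv_on[None, :] * np.exp(-t_on / tau_s)
    t_off = t[i_off:, None] - t[i_off]
    current[i_off:] += cap_gain * (-dv_on)[None, :] * np.exp(-t_off / tau_s)

    if noise_sd > 0 and rng is not None:
        current = current + rng.normal(0.0, noise_sd, size=current.shape)
    return current


def simulate_cell(
    spec: SessionSpec,
    gate: GateModel,
    construct: ConstructModel,
    *,
    expression: float,
    batch_factor: float,
    leak_g: float,
    rng: np.random.Generator | None,
    meta: Mapping | None = None,
    ph: str = "ph7.3",
) -> tuple[SweepSet, SweepSet]:
    """One cell's raw sweep family and its P/N companion."""
    proto = spec.protocol
    iv = construct.iv(gate, proto.step_voltages_mv, ph) * expression * batch_factor
    raw = _sweep_family(proto, iv, leak_g, spec.cap_gain, spec.cap_tau_ms, spec.noise_sd, rng)
    # instrument noise does not scale with the stimulus, so the P/N family
    # carries the same noise_sd as the raw family
    pn = _sweep_family(
        proto, np.zeros(proto.n_steps), leak_g, spec.cap_gain, spec.cap_tau_ms,
        spec.noise_sd, rng, voltage_scale=proto.pn_scale,
    )
    base = dict(meta or {})
    base.setdefault("construct", construct.label)
    base.setdefault("mode", spec.mode)
    base["ph"] = ph
    raw_set = SweepSet(proto.time_s, raw, proto, dict(base))
    pn_meta = dict(base)
    pn_meta["pn"] = True
    pn_set = SweepSet(proto.time_s, pn, proto, pn_meta)
    return raw_set, pn_set


def simulate_study(
    spec: SessionSpec,
    gate: GateModel,
    constructs: Sequence[ConstructModel],
) -> dict[str, dict[int, list[tuple[SweepSet, SweepSet]]]]:
    """In-memory study: {construct label: {batch: [(raw, pn), ...]}}.

    Batch factors are shared across constructs within a batch (oocytes of
    one frog harvest expressing different constructs), which is exactly
    what within-batch normalization exploits downstream. For the 'paired'
    pH condition each cell is recorded twice (pH 7.3 then pH 5.3) with the
    same leak and expression but independent noise.
    """
    out: dict[str, dict[int, list]] = {c.label: {} for c in constructs}
    for b in range(spec.n_batches):
        batch_rng = _cell_rng(spec.seed, 0xBA, b)
        batch_factor = float(np.exp(batch_rng.normal(0.0, spec.batch_cv))) if spec.batch_cv > 0 else 1.0
        if isinstance(spec.cells_per_batch, int):
            n_cells = spec.cells_per_batch
        else:
            lo, hi = spec.cells_per_batch
            n_cells = int(batch_rng.integers(lo, hi + 1))
        for gi, construct in enumerate(constructs):
            cells = []
            for ci in range(n_cells):
                rng = _cell_rng(spec.seed, 1, b, gi, ci)
                expression = float(np.exp(rng.normal(0.0, spec.expression_cv))) if spec.expression_cv > 0 else 1.0
                leak_g = max(0.0, float(rng.normal(spec.leak_g_mean, spec.leak_g_sd))) if spec.leak_g_sd > 0 else spec.leak_g_mean
                meta = {"cell_id": f"{construct.label}_b{b}c{ci}", "batch": b}
                if spec.ph_condition == "paired":
                    pair = {}
                    for ph in ("ph7.3", "ph5.3"):
                        pair[ph] = simulate_cell(
                            spec, gate, construct, expression=expression,
                            batch_factor=batch_factor, leak_g=leak_g, rng=rng,
                            meta=meta, ph=ph,
                        )
                    cells.append(pair)
                else:
                    cells.append(
                        simulate_cell(
                            spec, gate, construct, expression=expression,
                            batch_factor=batch_factor, leak_g=leak_g, rng=rng,
                            meta=meta, ph=spec.ph_condition,
                        )
                    )
            out[construct.label][b] = cells
    return out


def simulate_session(
    spec: SessionSpec,
    gate: GateModel,
    constructs: Sequence[ConstructModel],
    out_dir: str | Path,
) -> Path:
    """Write a simulated session to disk: sweep CSVs plus a JSON manifest.

    Returns the manifest path. Same spec and seed give byte-identical files.
    """
    from . import io as _io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(spec, gate, constructs)
    records = []
    for label, batches in study.items():
        safe = label.replace("/", "-").replace(" ", "_")
        for b, cells in batches.items():
            for ci, cell in enumerate(cells):
                entries = cell.items() if isinstance(cell, dict) else [(spec.ph_condition, cell)]
                for ph, (raw, pn) in entries:
                    stem = f"{safe}_b{b}c{ci}_{ph.replace('.', '')}"
                    _io.write_sweep_csv(out_dir / f"{stem}.csv", raw)
                    _io.write_sweep_csv(out_dir / f"{stem}_pn.csv", pn)
                    records.append(
                        {"file": f"{stem}.csv", "construct": label, "batch": b,
                         "ph": ph, "mode": spec.mode}
                    )
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(records, indent=1, sort_keys=True) + "\n")
    return manifest


def simulate_iv_cells(
    gate: GateModel,
    construct: ConstructModel,
    voltages_mv,
    *,
    n_cells: int,
    seed: int,
    expression_cv: float = 0.3,
    batch_factor: float = 1.0,
    leak_g_mean: float = 1.0,
    leak_g_sd: float = 0.3,
    noise_sd: float = 0.02,
    ph: str = "ph7.3",
    subtract_leak: bool = False,
    stream: int = 0,
) -> IVCurve:
    """Steady-state-level generator: per-cell IV values without sweep traces.

    ``noise_sd`` here is the noise of the steady-state *estimate* (already
    averaged over the window). With ``subtract_leak`` the ohmic component is
    omitted, emulating P/N-corrected data; otherwise leak g*V is included
    (the acidic-pH pipeline estimates and removes it itself).
    """
    v = np.asarray(voltages_mv, dtype=float)
    base = construct.iv(gate, v, ph)
    rows = np.empty((n_cells, v.size))
    for ci in range(n_cells):
        rng = _cell_rng(seed, 2, stream, ci)
        expr = float(np.exp(rng.normal(0.0, expression_cv))) if expression_cv > 0 else 1.0
        leak = 0.0 if subtract_leak else max(0.0, float(rng.normal(leak_g_mean, leak_g_sd)))
        rows[ci] = base * expr * batch_factor + leak * v * 1e-3
        if noise_sd > 0:
            rows[ci] += rng.normal(0.0, noise_sd, size=v.size)
    se = np.full_like(rows, noise_sd) if noise_sd > 0 else None
    return IVCurve(
        v, rows, units="uA", meta={"construct": construct.label, "ph": ph}, noise_se=se
    )


def simulate_paired_iv_cells(
    gate: GateModel,
    construct: ConstructModel,
    voltages_mv,
    *,
    n_cells: int,
    seed: int,
    expression_cv: float = 0.3,
    batch_factor: float = 1.0,
    leak_g_mean: float = 1.0,
    leak_g_sd: float = 0.3,
    noise_sd: float = 0.02,
    stream: int = 0,
) -> tuple[IVCurve, IVCurve]:
    """Per-cell IVs of the same cells at pH 7.3 and pH 5.3.

    Expression and leak are drawn once per cell and shared between the two
    condition recordings; only the measurement noise is independent —
    matching paired same-oocyte recordings.
    """
    v = np.asarray(voltages_mv, dtype=float)
    base73 = construct.iv(gate, v, "ph7.3")
    base53 = construct.iv(gate, v, "ph5.3")
    rows73 = np.empty((n_cells, v.size))
    rows53 = np.empty((n_cells, v.size))
    for ci in range(n_cells):
        rng = _cell_rng(seed, 4, stream, ci)
        expr = float(np.exp(rng.normal(0.0, expression_cv))) if expression_cv > 0 else 1.0
        leak = max(0.0, float(rng.normal(leak_g_mean, leak_g_sd))) if leak_g_sd > 0 else leak_g_mean
        leak_i = leak * v * 1e-3
        rows73[ci] = base73 * expr * batch_factor + leak_i
        rows53[ci] = base53 * expr * batch_factor + leak_i
        if noise_sd > 0:
            rows73[ci] += rng.normal(0.0, noise_sd, size=v.size)
            rows53[ci] += rng.normal(0.0, noise_sd, size=v.size)
    se = np.full_like(rows73, noise_sd) if noise_sd > 0 else None
    meta = {"construct": construct.label}
    iv73 = IVCurve(v, rows73, meta={**meta, "ph": "ph7.3"}, noise_se=se)
    iv53 = IVCurve(v, rows53, meta={**meta, "ph": "ph5.3"}, noise_se=se)
    return iv73, iv53


# ---------------------------------------------------------------------------
# FLIM decay image simulation


@dataclass
class FlimSpec:
    """Layout of a synthetic time-correlated photon-count decay image.

    ``tau_map`` assigns one monoexponential lifetime (ns) per named region;
    regions default to equal vertical bands of the image unless explicit
    boolean ``masks`` are supplied. ``photons_per_pixel`` is the mean
    photon budget; ``None`` produces noise-free (expected-value) decays.
    """

    image_shape: tuple[int, int] = (32, 32)
    n_bins: int = 256
    rep_rate_mhz: float = 80.0
    tau_map: dict[str, float] = field(default_factory=lambda: {"donor_only": 2.5})
    masks: dict[str, np.ndarray] | None = None
    photons_per_pixel: float | None = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 64:
            raise ValueError("n_bins must be >= 64")
        if self.rep_rate_mhz <= 0:
            raise ValueError("rep_rate_mhz must be positive")
        period = 1e3 / self.rep_rate_mhz
        for name, tau in self.tau_map.items():
            if not (0 < tau < period):
                raise ValueError(
                    f"lifetime of region {name!r} must lie in (0, period={period:.3g} ns)"
                )

    def region_masks(self) -> dict[str, np.ndarray]:
        if self.masks is not None:
            return self.masks
        names = list(self.tau_map)
        rows, cols = self.image_shape
        edges = np.linspace(0, cols, len(names) + 1).astype(int)
        out = {}
        for i, name in enumerate(names):
            m = np.zeros(self.image_shape, dtype=bool)
            m[:, edges[i]:edges[i + 1]] = True
            out[name] = m
        return out


def decay_profile(tau_ns: float, n_bins: int, rep_rate_mhz: float) -> np.ndarray:
    """Bin-integrated, period-wrapped monoexponential decay (sums to 1).

    The tail beyond one excitation period folds back onto the start, so the
    profile's first-harmonic phasor equals the analytic semicircle value
    exactly (up to the n_bins discretization of the transform).
    """
    period = 1e3 / rep_rate_mhz
    edges = np.linspace(0.0, period, n_bins + 1)
    seg = np.exp(-edges[:-1] / tau_ns) - np.exp(-edges[1:] / tau_ns)
    return seg / (1.0 - np.exp(-period / tau_ns))


def simulate_flim(spec: FlimSpec, out_path: str | Path | None = None) -> DecayStack:
    """Synthesize a decay image stack; optionally write TIFF + JSON sidecar.

    Counts are Poisson around ``photons_per_pixel`` times the wrapped decay
    profile of the pixel's region; with ``photons_per_pixel=None`` the
    expected (noise-free, float) profile is stored instead. A zero photon
    budget yields an all-zero stack.
    """
    period = 1e3 / spec.rep_rate_mhz
    centers = (np.arange(spec.n_bins) + 0.5) * period / spec.n_bins
    masks = spec.region_masks()
    rows, cols = spec.image_shape
    noise_free = spec.photons_per_pixel is None
    budget = 1.0 if noise_free else float(spec.photons_per_pixel)
    counts = np.zeros((rows, cols, spec.n_bins), dtype=float)
    for name, tau in spec.tau_map.items():
        mask = masks[name]
        expected = budget * decay_profile(tau, spec.n_bins, spec.rep_rate_mhz)
        counts[mask] = expected
    if not noise_free:
        idx = np.argwhere(np.ones(spec.image_shape, dtype=bool))
        for r, c in idx:
            rng = _cell_rng(spec.seed, 3, int(r), int(c))
            counts[r, c] = rng.poisson(counts[r, c])
        counts = counts.astype(np.uint32)
    stack = DecayStack(counts, centers, spec.rep_rate_mhz, region_masks=dict(masks))
    if out_path is not None:
        from . import io as _io

        _io.write_decay_stack(out_path, stack)
    return stack
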
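"""File formats: sweep CSVs, session manifests, IV tables, decay stacks.

Sweep CSV: '#'-prefixed ``key=value`` metadata lines, then a header row
``time_s,V_200,V_190,...`` (one column per step voltage in mV) and the
sample matrix. A P/N companion shares the stem with suffix ``_pn``.

Session manifest: JSON array of ``{file, construct, batch, ph, mode}``.

Decay stack: multi-page TIFF (one page per time bin, 16-bit counts, or
float32 for noise-free synthetic stacks) with a JSON sidecar holding the
repetition rate, binning and named region masks as run-length encodings of
the flattened (row-major) pixel grid.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flim_phasor import DecayStack
from .traces import IVCurve, SweepSet, VoltageProtocol

__all__ = [
    "write_sweep_csv",
    "read_sweep_csv",
    "read_manifest",
    "load_session",
    "write_iv_csv",
    "read_iv_csv",
    "write_ratio_csv",
    "write_phasor_csv",
    "write_decay_stack",
    "read_decay_stack",
    "mask_to_runs",
    "runs_to_mask",
]

_PROTO_KEYS = (
    "holding_mv", "step_start_mv", "step_delta_mv", "step_end_mv",
    "step_duration_ms", "pre_ms", "post_ms", "sampling_hz", "pn_scale",
)


def _fmt_volt(v: float) -> str:
    return f"V_{v:g}"


def write_sweep_csv(path: str | Path, sweeps: SweepSet) -> Path:
    path = Path(path)
    lines = []
    for k, v in sorted(sweeps.meta.items()):
        lines.append(f"# {k}={v}")
    for k in _PROTO_KEYS:
        lines.append(f"# protocol.{k}={getattr(sweeps.protocol, k):g}")
    lines.append(f"# corrected={sweeps.corrected}")
    cols = ",".join(_fmt_volt(v) for v in sweeps.voltages_mv)
    lines.append("time_s," + cols)
    body = np.column_stack([sweeps.time_s, sweeps.current])
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, body, delimiter=",", fmt="%.9g")
    return path


def read_sweep_csv(path: str | Path) -> SweepSet:
    path = Path(path)
    meta: dict = {}
    proto_kwargs: dict = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, val = line[1:].strip().partition("=")
            key = key.strip()
            if key.startswith("protocol."):
                proto_kwargs[key[len("protocol."):]] = float(val)
            elif key == "corrected":
                meta["corrected"] = val == "True"
            else:
                meta[key] = _coerce(val)
    data = pd.read_csv(path, skiprows=n_header)
    protocol = VoltageProtocol(**proto_kwargs)
    corrected = meta.pop("corrected", False)
    current = data.iloc[:, 1:].to_numpy(dtype=float)
    return SweepSet(data.iloc[:, 0].to_numpy(dtype=float), current, protocol, meta, corrected)


def _coerce(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    if val in ("True", "False"):
        return val == "True"
    return val


def read_manifest(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())


def load_session(manifest_path: str | Path) -> list[dict]:
    """Load every recording listed in a manifest.

    Returns the manifest records with ``raw`` and ``pn`` :class:`SweepSet`
    entries attached. A missing P/N companion is a hard error.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    records = []
    for rec in read_manifest(manifest_path):
        raw = read_sweep_csv(base / rec["file"])
        pn_path = base / (Path(rec["file"]).stem + "_pn.csv")
        if not pn_path.exists():
            raise FileNotFoundError(f"P/N companion missing for {rec['file']}")
        out = dict(rec)
        out["raw"] = raw
        out["pn"] = read_sweep_csv(pn_path)
        records.append(out)
    return records


def write_iv_csv(path: str | Path, iv: IVCurve) -> Path:
    """IV table: voltage_mV, mean, sd, n, then one column per cell."""
    path = Path(path)
    df = pd.DataFrame({"voltage_mV": iv.voltages_mv, "mean": iv.mean, "sd": iv.sd})
    df["n"] = iv.n
    for cid, row in zip(iv.cell_ids, iv.values):
        df[cid] = row
    if iv.noise_se is not None:
        for cid, row in zip(iv.cell_ids, iv.noise_se):
            df[f"se:{cid}"] = row
    header = [f"# units={iv.units}"] + [f"# {k}={v}" for k, v in sorted(iv.meta.items())]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=False, float_format="%.9g")
    return path


def read_iv_csv(path: str | Path) -> IVCurve:
    path = Path(path)
    meta: dict = {}
    units = "uA"
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "units":
                units = val
            else:
                meta[key.strip()] = _coerce(val)
    df = pd.read_csv(path, skiprows=n_header)
    cell_cols = [
        c for c in df.columns
        if c not in ("voltage_mV", "mean", "sd", "n") and not c.startswith("se:")
    ]
    values = df[cell_cols].to_numpy(dtype=float).T
    se_cols = [f"se:{c}" for c in cell_cols]
    noise_se = df[se_cols].to_numpy(dtype=float).T if all(c in df.columns for c in se_cols) else None
    return IVCurve(
        df["voltage_mV"].to_numpy(), values, units=units, meta=meta,
        cell_ids=cell_cols, noise_se=noise_se,
    )


def write_ratio_csv(path: str | Path, rc) -> Path:
    """Ratio table: voltage_mV, ratio_mean, ratio_sd, n_batches, masked."""
    path = Path(path)
    nb = rc.n_batches
    df = pd.DataFrame(
        {
            "voltage_mV": rc.voltages_mv,
            "ratio_mean": rc.per_batch.mean(axis=0),
            "ratio_sd": rc.per_batch.std(axis=0, ddof=1) if nb > 1 else 0.0,
            "n_batches": nb,
            "masked": rc.mask.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def write_phasor_csv(path: str | Path, rows: list[dict]) -> Path:
    """Per-ROI phasor results: roi, G, S, tau_ns, n_pixels."""
    path = Path(path)
    pd.DataFrame(rows, columns=["roi", "G", "S", "tau_ns", "n_pixels"]).to_csv(
        path, index=False, float_format="%.9g"
    )
    return path


def mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    """Run-length encode a boolean mask (row-major): [[start, length], ...]."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if not flat.any():
        return []
    padded = np.concatenate(([False], flat, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [[int(a), int(b - a)] for a, b in zip(starts, ends)]


def runs_to_mask(runs: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in runs:
        flat[start:start + length] = True
    return flat.reshape(shape)


def write_decay_stack(path: str | Path, stack: DecayStack) -> Path:
    """Write a decay stack as multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    pages = np.moveaxis(stack.counts, 2, 0)  # one page per time bin
    if np.issubdtype(pages.dtype, np.integer):
        if pages.max() >= 2**16:
            raise ValueError("counts exceed 16-bit range")
        pages = pages.astype(np.uint16)
    else:
        pages = pages.astype(np.float32)
    # one grayscale page per time bin (never RGB, whatever the shape)
    tifffile.imwrite(path, pages, photometric="minisblack")
    period = stack.period_ns
    sidecar = {
        "rep_rate_mhz": stack.rep_rate_mhz,
        "n_bins": stack.n_bins,
        "bin_width_ns": period / stack.n_bins,
        "shape": list(stack.counts.shape[:2]),
        "regions": {name: mask_to_runs(m) for name, m in stack.region_masks.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    return path


def read_decay_stack(path: str | Path) -> DecayStack:
    path = Path(path)
    pages = tifffile.imread(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    counts = np.moveaxis(pages, 0, 2)
    n_bins = sidecar["n_bins"]
    width = sidecar["bin_width_ns"]
    centers = (np.arange(n_bins) + 0.5) * width
    shape = tuple(sidecar["shape"])
    masks = {name: runs_to_mask(runs, shape) for name, runs in sidecar["regions"].items()}
    return DecayStack(counts, centers, sidecar["rep_rate_mhz"], region_masks=masks)
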
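"""Simulate a voltage-clamp session on disk and process it back to IV curves.

Writes sweep CSVs plus a JSON manifest for a small oocyte study, reloads
them, applies P/N leak correction and steady-state extraction, and prints
the group current-voltage relationship.
"""

import tempfile
from pathlib import Path

import numpy as np

from clcassay.io import load_session
from clcassay.synthdata import GateModel, SessionSpec, coexpression_construct, simulate_session, variant_library
from clcassay.traces import build_iv, pn_subtract

gate = GateModel()
lib = variant_library()
construct = coexpression_construct(lib["WT"])

with tempfile.TemporaryDirectory() as tmp:
    spec = SessionSpec(seed=1, n_batches=1, cells_per_batch=6)
    manifest = simulate_session(spec, gate, [construct], Path(tmp))
    records = load_session(manifest)
    print(f"loaded {len(records)} cells of {records[0]['construct']}")

    corrected = [pn_subtract(r["raw"], r["pn"]) for r in records]
    iv = build_iv(corrected)
    print("\n  V (mV)   mean (uA)   sd (uA)   [n=%d cells]" % iv.n)
    for v, m, s in list(zip(iv.voltages_mv, iv.mean, iv.sd))[::4]:
        print(f"  {v:6.0f}   {m:9.3f}   {s:7.3f}")

print(
    "\nCurrents activate steeply above ~+100 mV (the common gate opens at"
    "\ndepolarized voltages); the spread across cells reflects expression"
    "\nvariability, which downstream ratio analysis removes batch-wise."
)
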
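"""Batch-normalized ratio curves and slope-based phenotype classification.

Simulates two co-expression studies against a matched wild-type reference
(one true-null variant and one with a +40 mV dominant gating shift),
normalizes each batch to its reference, and classifies the resulting
ratio curves.
"""

import numpy as np

from clcassay.ratio_analysis import classify_ratio, normalize_to_reference
from clcassay.synthdata import (
    GateModel,
    SessionSpec,
    VariantParams,
    coexpression_construct,
    simulate_study,
    variant_library,
)
from clcassay.traces import build_iv, pn_subtract


def corrected_ivs(study):
    return {
        lab: {b: build_iv([pn_subtract(r, p) for r, p in cells]) for b, cells in batches.items()}
        for lab, batches in study.items()
    }


gate = GateModel()
lib = variant_library()

for name, variant in [("null (WT-like)", lib["WT"]),
                      ("dominant +40 mV shift", VariantParams("S40", dv_half=40.0, dominant=True))]:
    cons = [coexpression_construct(lib["WT"], label="REF"),
            coexpression_construct(variant, label="VAR")]
    study = simulate_study(SessionSpec(seed=3, cells_per_batch=(6, 8)), gate, cons)
    ivs = corrected_ivs(study)
    rc = normalize_to_reference(ivs["VAR"], ivs["REF"])
    call = classify_ratio(rc)
    print(f"\n=== variant: {name} ===")
    for v, m, s, masked in list(zip(rc.voltages_mv, rc.mean, rc.sd, rc.mask))[::4]:
        flag = " (masked)" if masked else ""
        print(f"  {v:6.0f} mV  ratio {m:6.3f} +/- {s:5.3f}{flag}")
    print(f"  phenotype: {call.label}")
    print(f"  slope {call.slope_per_mv:.2e}/mV, 99% CI [{call.slope_ci[0]:.2e}, {call.slope_ci[1]:.2e}]")

print(
    "\nA flat ratio near 1 is wild-type-like; a rising ratio (smaller at"
    "\nless positive voltages) is the signature of a dominant positive"
    "\nshift in the voltage dependence of the common gate."
)
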
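import numpy as np
import pytest

from clcassay.synthdata import (
    GateModel,
    SessionSpec,
    coexpression_construct,
    simulate_study,
    variant_library,
)
from clcassay.traces import build_iv, pn_subtract


@pytest.fixture(scope="session")
def gate():
    return GateModel()


@pytest.fixture(scope="session")
def library():
    return variant_library()


def _study_ivs(gate, variant, seed, *, cells_per_batch=(6, 8), **spec_kwargs):
    """Simulate a two-group co-expression study and return leak-corrected
    IV curves keyed by group then batch."""
    lib = variant_library()
    cons = [
        coexpression_construct(lib["WT"], label="REF"),
        coexpression_construct(variant, label="VAR"),
    ]
    spec = SessionSpec(seed=seed, cells_per_batch=cells_per_batch, **spec_kwargs)
    study = simulate_study(spec, gate, cons)
    return {
        lab: {b: build_iv([pn_subtract(r, p) for r, p in cells]) for b, cells in batches.items()}
        for lab, batches in study.items()
    }


@pytest.fixture(scope="session")
def study_ivs():
    """Factory: simulate a two-group study and return corrected IV curves."""
    return _study_ivs
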
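import numpy as np
import pandas as pd
import pytest

from uvrecover import ExpressionMatrix


def make_matrix(values: dict, samples: list[dict], state="counts",
                genes=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from {sample_id: column} and metadata rows."""
    meta = pd.DataFrame(samples)
    genes = genes or [f"g{i}" for i in range(len(next(iter(values.values()))))]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"))
    return ExpressionMatrix(frame, meta, state=state)


@pytest.fixture
def two_condition_matrix():
    """4 genes x {control, knockdown_A} x {0, 0.5, 2.5, 24.5} h, scaled state.

    Gene g0: repressed (fast), full dependency on the knockdown factor;
    g1: repressed (slow), independent; g2: induced; g3: unchanged.
    Baselines are 10 everywhere so values double as ratios x10.
    """
    samples = []
    values = {}
    curves = {
        "control": {
            0.0: [10, 10, 10, 10],
            0.5: [4, 9, 25, 10],
            2.5: [3, 4, 10, 10],
            24.5: [9, 9, 10, 10],
        },
        "knockdown_A": {
            0.0: [10, 10, 10, 10],
            0.5: [4, 9, 25, 10],
            2.5: [3, 4, 10, 10],
            24.5: [4.5, 9, 10, 10],
        },
    }
    for cond, curve in curves.items():
        for tp, col in curve.items():
            sid = f"{cond}_{tp}"
            values[sid] = col
            samples.append({"sample_id": sid, "condition": cond,
                            "timepoint_h": tp, "replicate": 1,
                            "library_size": 1_000_000})
    return make_matrix(values, samples, state="scaled_rpkm")
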
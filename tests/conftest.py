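import numpy as np
import pandas as pd
import pytest

from psorstrat.containers import ExpressionMatrix, SignatureSet
from psorstrat.synthetic import generate_cohort, planted_signature_sets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sets():
    """4 cell-type + 2x2 cytokine planted sets on 4000 probes, size 200."""
    return planted_signature_sets(
        4000, n_cell_sigs=4, n_cytokine_pairs=2, size=200,
        overlap_fraction=0.1, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_sets):
    """12-subject test-profile cohort with planted tier structure."""
    cell_sigs, cyt_sigs = small_sets
    return generate_cohort(
        12, 4000, cell_sigs, seed=21, cytokine_signatures=cyt_sigs,
    )


@pytest.fixture
def paired_matrix():
    """Tiny hand-made paired PP/PN expression matrix (3 subjects)."""
    probes = pd.Index([f"g{i}" for i in range(6)], name="probe_id")
    cols = ["A_PP", "A_PN", "B_PP", "B_PN", "C_PP", "C_PN"]
    vals = pd.DataFrame(
        np.arange(36, dtype=float).reshape(6, 6) / 4.0 + 5.0,
        index=probes, columns=cols,
    )
    meta = pd.DataFrame(
        {
            "subject": [c.split("_")[0] for c in cols],
            "condition": [c.split("_")[1] for c in cols],
            "sex": ["M", "M", "F", "F", "M", "M"],
            "batch": ["b1"] * 4 + ["b2"] * 2,
        },
        index=pd.Index(cols),
    )
    return ExpressionMatrix(vals, meta)


def make_signature(name, probes, direction="high-in-population"):
    return SignatureSet(name, direction, list(probes))
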
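import numpy as np
import pandas as pd
import pytest

from pericolor.segregation import STANDARD_MODELS
from pericolor.simulate import (
    ScanSpec,
    SimTruth,
    default_marker_map,
    generate_kernel_scan,
    simulate_dh_population,
)


@pytest.fixture(scope="session")
def clean_scan():
    """A 12-kernel disjoint scan with known truth (no debris, no damage)."""
    spec = ScanSpec(n_kernels=12)
    image, truth = generate_kernel_scan(spec, seed=3)
    return image, truth


@pytest.fixture(scope="session")
def single_qtl_sim():
    """150-line DH population, single pigment gene, one 2-degree QTL."""
    mm = default_marker_map(3, 40, 2.5)
    truth = SimTruth(
        model=STANDARD_MODELS[0],
        causal_markers={"A": "c1m10"},
        qtl=[("c1m10", 2.0)],
        seed=11,
    )
    return simulate_dh_population(150, mm, truth), mm


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def balanced_records():
    """Balanced 80 lines x 2 reps with known variance components (4, 1, 1)."""
    gen = np.random.default_rng(42)
    p, r = 80, 2
    g = gen.normal(0, 2.0, p)
    rep = gen.normal(0, 1.0, r)
    rows = []
    for i in range(p):
        for j in range(r):
            rows.append(
                {"line_id": f"L{i:03d}", "replicate": j + 1,
                 "hue": 30 + g[i] + rep[j] + gen.normal(0, 1.0)}
            )
    return pd.DataFrame(rows)
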
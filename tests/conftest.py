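import numpy as np
import pytest

import markerfit as mf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20100579)


@pytest.fixture(scope="session")
def random_scenarios(rng):
    """200 random feasible (scenario, penetrance) pairs for oracle comparisons."""
    out = []
    mois = ["dominant", "recessive", "multiplicative"]
    while len(out) < 200:
        p_a = rng.uniform(0.05, 0.95)
        r2 = rng.uniform(0.2, 1.0)
        lo, hi = mf.feasible_marker_freq_range(p_a, r2)
        p_b = rng.uniform(max(lo, 0.02), min(hi, 0.98))
        if not (0.0 < p_b < 1.0):
            continue
        pen = mf.PenetranceModel(mois[len(out) % 3], grr=rng.uniform(1.05, 2.5))
        out.append((mf.TwoLocusScenario(p_a, p_b, r2), pen))
    return out


@pytest.fixture(scope="session")
def dominant13():
    return mf.PenetranceModel("dominant", 1.3)


@pytest.fixture(scope="session")
def fig_grid_table():
    """The full matched-frequency grid (both MOIs, all GRRs and r2 levels)."""
    return mf.sweep_matched_frequency(n_required_at_r2=None)
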
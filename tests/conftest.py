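import numpy as np
import pytest

from temir import MiRNA, SimParams, repression_records
from temir.simdata import simulate


@pytest.fixture(scope="session")
def mirna():
    # let-7-family-like mature sequence; seed (pos 2-8) GAGGUAG
    return MiRNA("miR-sim", "UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture(scope="session")
def small_sim(mirna):
    """One modest simulated experiment shared by read-only tests."""
    params = SimParams(n_genes=400, seed=7)
    tx, tables, truth = simulate(params, mirna)
    return {"params": params, "tx": tx, "tables": tables, "truth": truth}


@pytest.fixture(scope="session")
def small_records(small_sim):
    t = small_sim["tables"]
    return repression_records(
        t[("RPF", "mock")], t[("RPF", "mir")], t[("RNA", "mock")], t[("RNA", "mir")]
    )


def brute_force_ks(x, y):
    """Independent KS-D oracle: scan every pooled threshold."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = 0.0
    for t in np.concatenate([x, y]):
        d = abs(np.mean(x <= t) - np.mean(y <= t))
        best = max(best, d)
    return best
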
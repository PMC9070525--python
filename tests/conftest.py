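import numpy as np
import pandas as pd
import pytest

from migrx import CohortTable, SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient three-class cohort shared across read-only tests."""
    cfg = SyntheticConfig(n_patients=300,
                          classes=("tca", "topiramate", "betablockers"),
                          seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def large_cohort():
    """5000-patient default cohort for distributional checks."""
    cfg = SyntheticConfig(n_patients=5000, seed=17)
    return generate_cohort(cfg)


def make_cohort(trials_spec, n_features=4, seed=0):
    """Hand-built cohort: trials_spec is a list of (patient_id, class, response)."""
    rng = np.random.default_rng(seed)
    pids = sorted({p for p, _, _ in trials_spec})
    cols = [f"x{j:02d}" for j in range(n_features)]
    patients = pd.DataFrame(rng.standard_normal((len(pids), n_features)),
                            index=pd.Index(pids, name="patient_id"), columns=cols)
    patients["headache_days"] = rng.integers(5, 31, len(pids))
    patients["exacerbation_intensity"] = rng.integers(3, 11, len(pids))
    order = {}
    rows = []
    for pid, cname, resp in trials_spec:
        rows.append((pid, cname, int(resp), order.setdefault(pid, 0)))
        order[pid] += 1
    trials = pd.DataFrame(rows, columns=["patient_id", "class_name",
                                         "response", "order_index"])
    return CohortTable(patients, trials, cols, [])
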
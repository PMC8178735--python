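"""Shared fixtures.

The heavyweight fixture runs the four triage-stage study scenarios at
their full 5000-replication plan once per session and exposes the
per-replication outcome arrays; both the results-reproduction tests and
the oracle-equivalence tests draw on it.
"""

from __future__ import annotations

import numpy as np
import pytest

from uccflow import baseline_config, simulate_run
from uccflow.metrics import compute_run_metrics
from uccflow.sweep import scenario_seed

# the four scenarios whose triage stage the study tabulates
STUDY_SCENARIOS = {
    "baseline": dict(),
    "extra_nurse": dict(name="baseline+nurse", n_triage=3),
    "min_saving": dict(name="app_min", triage_saving=2.5, consult_saving=1.5),
    "max_saving": dict(name="app_max", triage_saving=5.0, consult_saving=3.5),
}

N_REPS_FULL = 5000
ROOT_SEED = 20210521


def run_study_scenario(key: str, n_reps: int, root_seed: int = ROOT_SEED) -> dict:
    """Replicate one study scenario and collect per-replication arrays."""
    cfg = baseline_config(**STUDY_SCENARIOS[key])
    seed = scenario_seed(root_seed, list(STUDY_SCENARIOS).index(key))
    out = {"cfg": cfg, "queue_avg": [], "queue_sampled": [], "wait": [],
           "vwait": [], "util": []}
    for i in range(n_reps):
        m = compute_run_metrics(simulate_run(cfg, i, base_seed=seed))
        out["queue_avg"].append(m.queue_len["triage"])
        out["queue_sampled"].append(m.queue_sampled["triage"])
        out["wait"].append(m.wait_triage)
        out["vwait"].append(m.virtual_wait_triage)
        out["util"].append(m.utilization["triage"])
    for k in ("queue_avg", "queue_sampled", "wait", "vwait", "util"):
        out[k] = np.asarray(out[k])
    return out


@pytest.fixture(scope="session")
def study_runs() -> dict[str, dict]:
    """Full-plan (5000-replication) runs of the four study scenarios."""
    return {key: run_study_scenario(key, N_REPS_FULL) for key in STUDY_SCENARIOS}


@pytest.fixture()
def baseline_cfg():
    return baseline_config()
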
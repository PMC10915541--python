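"""Shared fixtures.

Expensive artefacts (the 5000-step HMM recovery fit, the end-to-end
pipeline run) are session-scoped so the cost is paid once and reused by
unit and acceptance tests alike.
"""

import numpy as np
import pandas as pd
import pytest

import whaletrack as wt


@pytest.fixture(scope="session")
def hmm_recovery():
    """5000-step simulated 2-state track, fitted pooled HMM, decoded path.

    Returns dict with the generating params, true states, steps, fitted
    model and Viterbi decoding.
    """
    params = wt.simulate.SimTrackParams(
        n_steps=5001, seed=11,
        transition=np.array([[0.9, 0.1], [0.1, 0.9]]),
        initial=np.array([0.5, 0.5]))
    path, states = wt.simulate.simulate_switching_track(params)
    steps = wt.regularize.step_metrics(path.assign(animal_id="sim"))
    model, report = wt.hmm.fit_hmm(steps, n_restarts=3, seed=2)
    decoded = wt.hmm.viterbi(model, steps)
    return {"params": params, "states": states, "steps": steps,
            "model": model, "report": report, "decoded": decoded}


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two pipeline runs with the same small config and seed (determinism)."""
    cfg = {"simulate": {"n_animals": 3, "chl_days": 8},
           "hmm": {"n_restarts": 2}}
    outs = []
    for name in ("runA", "runB"):
        out = tmp_path_factory.mktemp(name)
        report = wt.pipeline.run_pipeline(cfg, out, seed=7)
        outs.append((out, report))
    return outs


@pytest.fixture()
def small_steps():
    """Short deterministic step series with one missing angle."""
    return pd.DataFrame({
        "animal_id": "a",
        "step_km": [2.0, 11.0, 9.5, 1.2, 0.8, 14.0],
        "turn_rad": [np.nan, 0.2, -0.1, 2.5, -2.9, 0.05],
    })


@pytest.fixture()
def toy_model():
    return wt.hmm.HMMModel(
        step_mean=[2.0, 12.0], step_sd=[1.6, 6.0],
        angle_mean=[0.0, 0.0], angle_kappa=[0.6, 9.0],
        transition=np.array([[0.95, 0.05], [0.35, 0.65]]))


def argos_table(rows):
    """Helper: build a Wildlife Computers-dialect table from tuples
    (id, iso_time, quality, lat, lon)."""
    recs = []
    for aid, t, q, lat, lon in rows:
        ts = pd.Timestamp(t)
        recs.append({"DeployID": aid, "Date": ts.strftime("%H:%M:%S %d-%b-%Y"),
                     "Quality": q, "Latitude": lat, "Longitude": lon})
    return pd.DataFrame(recs)


@pytest.fixture()
def argos_csv(tmp_path):
    def _write(rows, name="fixes.csv"):
        p = tmp_path / name
        argos_table(rows).to_csv(p, index=False)
        return p
    return _write
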
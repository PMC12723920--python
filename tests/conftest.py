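"""Shared fixtures: scaled-down two-scenario replication experiments.

The expensive toy ensembles are session-scoped and shared between tests;
they are the same drivers exposed in :mod:`replisim.experiments`
(time-rescaled so the replication program is unchanged on the compressed
time axis).
"""

import numpy as np
import pytest

from replisim.engine import run_s_phase
from replisim.experiments import (_fountain_setup, dip_runs, fountain_runs,
                                  replicated_fraction_per_frame,
                                  subset_frames)
from replisim.genome import GenomeSpec
from replisim.nucleus import free_chains
from replisim.world import EngineParameters, Trajectory

__all__ = ["subset_frames", "replicated_fraction_per_frame"]


@pytest.fixture(scope="session")
def fountain_data():
    """Two-scenario early-S ensemble on a 300 kb chromosome with three
    planted early origins (time-rescaled x400, sparse box)."""
    spec, track, _ = _fountain_setup(True)
    return {
        "spec": spec,
        "track": track,
        "origins": np.array([60, 150, 240]),
        "params": lambda interacting: _fountain_setup(interacting)[2],
        "runs": {
            True: fountain_runs(True, n_traj=5, seed=100),
            False: fountain_runs(False, n_traj=5, seed=100),
        },
    }


@pytest.fixture(scope="session")
def dyn_data():
    """Two-scenario single-origin chromosome (time-rescaled x400) with G1
    and post-replication recordings, for the mobility analyses."""
    spec = GenomeSpec.toy([200])
    vals = np.full(200, 0.01)
    vals[100] = 8.0
    from replisim.kinetics import IPLSTrack
    track = IPLSTrack(spec, vals)

    def params(interacting):
        p = EngineParameters(interacting=interacting,
                             n_factors=2).rescaled(400)
        p.origin_rate *= 50
        return p

    data = {}
    for interacting in (True, False):
        s_runs, g1_runs, post_runs = [], [], []
        for i in range(4):
            w = free_chains([200], 15, params(interacting), spec=spec,
                            seed=800 + 10 * i + interacting)
            w.run(2000)
            g1_runs.append(w.record(6000, 300))
            s_runs.append(run_s_phase(w, track, frame_every_mcs=250,
                                      max_minutes=1e9))
            post_runs.append(w.record(6000, 300))
        data[interacting] = {"s": s_runs, "g1": g1_runs, "post": post_runs}
    data["spec"] = spec
    data["track"] = track
    data["rescale"] = 400
    return data


@pytest.fixture(scope="session")
def dip_data():
    """Single-origin early-S ensemble at a gentle rescale (x40), where the
    15 s-scale lag stays below the fork residence time per monomer — the
    regime in which the sister-pairing constraint is visible in the
    replication-aligned squared displacement."""
    data = {
        True: dip_runs(True, n_traj=5, seed=5000),
        False: dip_runs(False, n_traj=5, seed=5000),
    }
    data["ids"] = np.arange(40, 121)
    return data
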
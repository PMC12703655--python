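import warnings

import numpy as np
import pytest

from ionflux.kinetics import (KineticModelParams, simulate_trajectory,
                              _scaffold_atoms, universe_from_records)
from ionflux.pore import PoreSpec, frame_geometry


@pytest.fixture(scope="session")
def pore_spec() -> PoreSpec:
    return PoreSpec()


@pytest.fixture(scope="session")
def sim_small():
    """A short default-parameter run with frames every 0.5 ns."""
    params = KineticModelParams(duration_ns=40.0, frame_interval=0.5, seed=42)
    return simulate_trajectory(params)


@pytest.fixture(scope="session")
def sim_universe(sim_small):
    return sim_small.to_universe()


@pytest.fixture(scope="session")
def geometry(sim_universe, pore_spec):
    """Frame geometry of the rigid scaffold (identical in every frame)."""
    sim_universe.trajectory[0]
    return frame_geometry(sim_universe, pore_spec)


@pytest.fixture(scope="session")
def written_run(tmp_path_factory):
    """Topology + multi-model PDB trajectory + ground truth written to disk."""
    outdir = tmp_path_factory.mktemp("run")
    params = KineticModelParams(duration_ns=10.0, frame_interval=0.5, seed=9)
    result = simulate_trajectory(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        paths = result.write(outdir)
    return result, paths


@pytest.fixture()
def make_universe():
    """Factory: universe of the protein scaffold plus freely positioned particles.

    ``particles`` is a list of (resname, atom_name, positions) where positions
    has shape (n_frames, 3) or (3,); all particles must agree on n_frames.
    """

    def _make(particles, gate_width=16.0, n_frames=None):
        params = KineticModelParams(gate_width=gate_width)
        records = list(_scaffold_atoms(params))
        n_scaffold = len(records)
        pos_list = []
        for i, (resname, name, positions) in enumerate(particles):
            positions = np.atleast_2d(np.asarray(positions, dtype=float))
            pos_list.append(positions)
            records.append(("", 200 + i, resname, name, (0.0, 0.0, 0.0)))
        if n_frames is None:
            n_frames = max((p.shape[0] for p in pos_list), default=1)
        coords = np.empty((n_frames, len(records), 3), dtype=np.float32)
        coords[:, :n_scaffold] = np.asarray([r[4] for r in records[:n_scaffold]])
        for i, positions in enumerate(pos_list):
            if positions.shape[0] == 1:
                positions = np.repeat(positions, n_frames, axis=0)
            coords[:, n_scaffold + i] = positions
        return universe_from_records(records, coords)

    return _make
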
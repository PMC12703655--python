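"""Axial densities, gate distances and flexibility metrics."""

import numpy as np
import pytest

from ionflux.pore import PoreSpec
from ionflux.profiles import axial_density, gate_distance, rmsd_rmsf


class TestAxialDensity:
    def test_single_ion_lands_in_its_bin(self, make_universe, pore_spec):
        u = make_universe([("POT", "K", (0.0, 0.0, -5.2))])
        prof = axial_density(u, pore_spec, species=("K",), bin_width=0.5,
                             z_range=(-25.0, 5.0))
        k = int(np.floor((-5.2 - (-25.0)) / 0.5))
        assert prof.counts["K"][k] == 1
        assert prof.counts["K"].sum() == 1
        assert prof.bin_edges[k] == pytest.approx(-5.5)

    def test_uniform_cylinder_is_flat_within_poisson(self, make_universe, pore_spec):
        rng = np.random.default_rng(77)
        n = 10_000
        r = np.sqrt(rng.uniform(0.0, 1.0, n)) * 7.9
        phi = rng.uniform(0.0, 2 * np.pi, n)
        z = rng.uniform(-25.0, 5.0, n)
        pts = np.c_[r * np.cos(phi), r * np.sin(phi), z]
        u = make_universe([("POT", "K", p) for p in pts])
        prof = axial_density(u, pore_spec, species=("K",), radial_cutoff=8.0,
                             bin_width=1.0, z_range=(-25.0, 5.0))
        expected = n / len(prof.counts["K"])
        dev = np.abs(prof.counts["K"] - expected) / np.sqrt(expected)
        assert dev.max() < 3.0 + 1.0   # 3σ Poisson with a small finite-n margin

    def test_mass_conservation_exact(self, make_universe, pore_spec):
        rng = np.random.default_rng(3)
        pts = rng.uniform([-15, -15, -35], [15, 15, 15], size=(200, 3))
        frames = np.repeat(pts[None, :, :], 4, axis=0)
        u = make_universe([("POT", "K", frames[:, i]) for i in range(200)])
        prof = axial_density(u, pore_spec, species=("K",), radial_cutoff=8.0,
                             bin_width=0.5, z_range=(-25.0, 5.0))
        z = pts[:, 2]
        r = np.linalg.norm(pts[:, :2], axis=1)
        in_region = ((r < 8.0) & (z >= -25.0) & (z < 5.0)).sum()
        assert abs(prof.total_mass("K") - in_region) < 1e-9

    def test_empty_z_range_rejected(self, sim_universe, pore_spec):
        with pytest.raises(ValueError, match="z_range"):
            axial_density(sim_universe, pore_spec, z_range=(5.0, 5.0))

    def test_ca_peak_appears_at_f87_under_positive_voltage(self):
        from ionflux.kinetics import KineticModelParams, simulate_trajectory

        prof = {}
        for V in (300.0, -300.0):
            p = KineticModelParams(voltage_mV=V, duration_ns=150.0,
                                   frame_interval=0.5, seed=21)
            u = simulate_trajectory(p).to_universe()
            prof[V] = axial_density(u, PoreSpec(), species=("CA",),
                                    bin_width=0.5, z_range=(-25.0, 5.0))
        centers = prof[300.0].bin_centers
        f87_zone = (centers > -8.0) & (centers < -2.5)
        peak_pos = prof[300.0].per_frame_mean["CA"][f87_zone].sum()
        peak_neg = prof[-300.0].per_frame_mean["CA"][f87_zone].sum()
        assert peak_pos > 0.5          # Ca parked below the SF most of the time
        assert peak_neg < 0.05         # drastically reduced at negative voltage


class TestGateDistance:
    def test_square_diagonals(self, make_universe, pore_spec):
        u = make_universe([], gate_width=10.0)
        gm = gate_distance(u, pore_spec)
        assert gm.diagonal_ac[0] == pytest.approx(14.1421, abs=1e-3)
        assert gm.diagonal_bd[0] == pytest.approx(14.1421, abs=1e-3)

    def test_single_atom_shift_moves_one_diagonal(self, make_universe, pore_spec):
        u = make_universe([], gate_width=10.0)
        ag = u.select_atoms("segid A and resid 97 and name CA")
        direction = ag.positions[0][:2] / np.linalg.norm(ag.positions[0][:2])
        ag.positions = ag.positions + np.array([*(2.0 * direction), 0.0])
        gm = gate_distance(u, pore_spec)
        assert gm.diagonal_ac[0] == pytest.approx(14.1421 + 2.0, abs=1e-3)
        assert gm.diagonal_bd[0] == pytest.approx(14.1421, abs=1e-3)

    def test_gate_width_difference_recovered(self):
        from ionflux.kinetics import KineticModelParams, simulate_trajectory

        means = []
        for width in (18.0, 16.0):
            p = KineticModelParams(gate_width=width, duration_ns=5.0,
                                   frame_interval=0.5, seed=2,
                                   scaffold_jitter_sigma=0.15)
            u = simulate_trajectory(p).to_universe()
            means.append(float(np.mean(gate_distance(u, PoreSpec()).mean_per_frame)))
        assert means[0] - means[1] == pytest.approx(2.0 * np.sqrt(2.0), abs=0.1)


class TestFlexibility:
    def test_identity_trajectory_has_zero_rmsd_rmsf(self, make_universe):
        u = make_universe([("POT", "K", np.tile([3.0, 2.0, 1.0], (5, 1)))])
        ref = make_universe([("POT", "K", (3.0, 2.0, 1.0))])
        fm = rmsd_rmsf(u, ref, selection="all", fit_selection="all")
        assert np.allclose(fm.rmsd, 0.0, atol=1e-5)
        assert np.allclose(fm.rmsf_atoms, 0.0, atol=1e-5)

    def test_fit_removes_global_translation(self, make_universe):
        u = make_universe([("POT", "K", np.tile([3.0, 2.0, 1.0], (3, 1)))])
        shifted = make_universe([("POT", "K", (3.0, 2.0, 1.0))])
        shifted.atoms.positions = shifted.atoms.positions + np.array([3.0, 4.0, 0.0])
        fm = rmsd_rmsf(u, shifted, selection="all", fit_selection="all")
        assert np.allclose(fm.rmsd, 0.0, atol=1e-5)

    def test_gaussian_jitter_gives_sigma_root3(self, make_universe):
        """Isotropic σ jitter per atom → RMSF ≈ σ√3 (within 5% at 10⁴ frames)."""
        rng = np.random.default_rng(11)
        sigma = 0.5
        n_frames = 10_000
        base = np.array([[4.0, 0.0, -20.0], [0.0, 4.0, 10.0], [-4.0, 2.0, 0.0],
                         [6.0, -3.0, 5.0]])
        particles = []
        for i in range(len(base)):
            pos = base[i] + rng.normal(0.0, sigma, size=(n_frames, 3))
            particles.append(("POT", "K", pos))
        u = make_universe(particles, n_frames=n_frames)
        ref = make_universe([("POT", "K", b) for b in base])
        fm = rmsd_rmsf(u, ref, selection="resname POT",
                       fit_selection="resid 59-63 and name O")
        expected = sigma * np.sqrt(3.0)
        assert np.allclose(fm.rmsf_atoms, expected, rtol=0.05)

    def test_mismatched_selection_rejected(self, make_universe):
        u = make_universe([("POT", "K", (0.0, 0.0, 0.0))])
        ref = make_universe([])
        with pytest.raises(ValueError, match="selection"):
            rmsd_rmsf(u, ref, selection="resname POT")
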
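"""Site assignment, state-string encoding and conditional occupancy statistics."""

import numpy as np
import pytest

from ionflux.occupancy import (ALL_SITES, EMPTY, FrameParticles, SiteAssignment,
                               aggregate_occupancy, assign_frame, encode_state,
                               extract_particles, label_ca_bound, particle_atoms)
from oracles import brute_force_assign


def particles_at(geometry, entries, frame_index=0):
    """Build FrameParticles from (species, site-or-z, radial_offset) entries."""
    ids, species, positions = [], [], []
    for i, (sp, where, roff) in enumerate(entries):
        if isinstance(where, str):
            lo, hi = geometry.site_intervals[where]
            z = 0.5 * (lo + hi)
        else:
            z = float(where)
        pos = geometry.axis_origin + z * geometry.axis_direction
        pos = pos + roff * np.array([1.0, 0.0, 0.0])
        ids.append(i + 1)
        species.append(sp)
        positions.append(pos)
    return FrameParticles(ids=np.array(ids), species=np.array(species, dtype=object),
                          positions=np.array(positions).reshape(-1, 3),
                          frame_index=frame_index)


class TestAssignFrame:
    def test_single_ion_at_s3_midpoint(self, geometry, pore_spec):
        parts = particles_at(geometry, [("K", "S3", 0.0)])
        a = assign_frame(parts, geometry, pore_spec)
        assert a.occupants["S3"] == "K"
        for site in ("S1", "S2", "S4", "Scav"):
            assert a.occupants[site] == EMPTY
        assert not a.ca_f87_bound and not a.ca_e92_bound

    def test_multi_site_with_ca_below_filter(self, geometry, pore_spec):
        f_lo, f_hi = geometry.f87_interval
        parts = particles_at(geometry, [
            ("K", "S1", 0.0), ("K", "S3", 0.0), ("K", "S4", 0.0),
            ("CA", 0.5 * (f_lo + f_hi), 0.0),
        ])
        a = assign_frame(parts, geometry, pore_spec)
        assert [a.occupants[s] for s in ("S1", "S2", "S3", "S4")] == \
            ["K", EMPTY, "K", "K"]
        assert a.ca_f87_bound

    def test_nearer_particle_wins_contested_site(self, geometry, pore_spec):
        lo, hi = geometry.site_intervals["S2"]
        mid = 0.5 * (lo + hi)
        parts = particles_at(geometry, [("K", mid - 0.3, 0.0), ("K", mid + 0.2, 0.0)])
        a = assign_frame(parts, geometry, pore_spec)
        assert a.occupant_ids["S2"] == 2           # the nearer one (0.2 Å off)
        assert a.extra_occupants == (("S2", 1),)

    def test_exact_tie_resolves_to_lower_id(self, geometry, pore_spec):
        # identical axial offset from the midpoint → deterministic id tie-break
        lo, hi = geometry.site_intervals["S2"]
        mid = 0.5 * (lo + hi)
        parts = particles_at(geometry, [("K", mid, 1.0), ("K", mid, -1.0)])
        a = assign_frame(parts, geometry, pore_spec)
        assert a.occupant_ids["S2"] == 1
        assert a.extra_occupants == (("S2", 2),)

    def test_boundary_particle_assigned_to_site_above(self, geometry, pore_spec):
        lo, hi = geometry.site_intervals["S3"]
        parts = particles_at(geometry, [("K", hi, 0.0)])   # exactly on S2/S3 plane
        a = assign_frame(parts, geometry, pore_spec)
        assert a.occupants["S2"] == "K"
        assert a.occupants["S3"] == EMPTY

    def test_radial_cutoff_excludes_cavity_ions(self, geometry, pore_spec):
        parts = particles_at(geometry, [("K", "S3", pore_spec.sf_radial_cutoff + 0.5)])
        a = assign_frame(parts, geometry, pore_spec)
        assert a.occupants["S3"] == EMPTY

    def test_matches_brute_force_oracle_on_random_frames(self, geometry, pore_spec):
        rng = np.random.default_rng(1234)
        species_pool = np.array(["K", "CA", "WAT", "CL", "NH4"], dtype=object)
        for _ in range(200):
            n = rng.integers(1, 25)
            parts = FrameParticles(
                ids=np.arange(1, n + 1),
                species=rng.choice(species_pool, size=n),
                positions=rng.uniform([-12, -12, -30], [12, 12, 20], size=(n, 3)),
                frame_index=0,
            )
            a = assign_frame(parts, geometry, pore_spec)
            occ, ids, extras, f87, e92 = brute_force_assign(parts, geometry, pore_spec)
            assert {s: a.occupants[s] for s in ALL_SITES} == occ
            assert {s: a.occupant_ids[s] for s in ALL_SITES} == ids
            assert sorted(a.extra_occupants) == sorted(extras)
            assert a.ca_f87_bound == f87 and a.ca_e92_bound == e92


class TestEncodeAndLabel:
    @pytest.mark.parametrize("occupants,code", [
        ({"S1": "K", "S2": EMPTY, "S3": "K", "S4": EMPTY}, "KOKO"),
        ({"S1": "K", "S2": "K", "S3": EMPTY, "S4": "K"}, "KKOK"),
        ({"S1": EMPTY, "S2": EMPTY, "S3": EMPTY, "S4": EMPTY}, "OOOO"),
        ({"S1": "NH4", "S2": "WAT", "S3": EMPTY, "S4": "K"}, "NWOK"),
    ])
    def test_state_codes(self, occupants, code):
        a = SiteAssignment(0, {**occupants, "Scav": EMPTY},
                           {s: None for s in ALL_SITES}, (), False, False)
        assert encode_state(a) == code

    def test_label_conditions_only_on_f87_site(self, geometry, pore_spec):
        f_lo, f_hi = geometry.f87_interval
        at_f87 = assign_frame(particles_at(
            geometry, [("CA", 0.5 * (f_lo + f_hi), 0.0)]), geometry, pore_spec)
        # Ca only at the glutamate ring: e92 flag set, but the label stays False
        ox = geometry.e92_oxygens[0]
        z = float((ox - geometry.axis_origin) @ geometry.axis_direction)
        at_e92 = assign_frame(particles_at(
            geometry, [("CA", z, 2.0)]), geometry, pore_spec)
        no_ca = assign_frame(particles_at(geometry, [("K", "S1", 0.0)]),
                             geometry, pore_spec)
        assert at_e92.ca_e92_bound and not at_e92.ca_f87_bound
        labels = label_ca_bound([at_f87, at_e92, no_ca])
        assert labels.tolist() == [True, False, False]


class TestAggregate:
    def _assignment(self, code, ca=False):
        occ = {s: EMPTY for s in ALL_SITES}
        for site, letter in zip(("S1", "S2", "S3", "S4"), code):
            if letter == "K":
                occ[site] = "K"
        return SiteAssignment(0, occ, {s: None for s in ALL_SITES}, (), ca, False)

    def test_constant_stream(self):
        assigns = [self._assignment("KOKO") for _ in range(100)]
        bound, free = aggregate_occupancy(assigns, [False] * 100, 0.0)
        assert free.n_frames == 100 and bound.n_frames == 0
        assert free.site_fractions["S1"]["K"] == 1.0
        assert free.site_fractions["S2"][EMPTY] == 1.0
        assert free.state_frequencies == {"KOKO": 1.0}
        free.validate()
        bound.validate()

    def test_even_mixture_counts(self):
        assigns = ([self._assignment("KOKO") for _ in range(50)]
                   + [self._assignment("KKOK") for _ in range(50)])
        _, free = aggregate_occupancy(assigns, [False] * 100, 0.0)
        assert free.state_frequencies == {"KKOK": 0.5, "KOKO": 0.5}
        assert free.site_fractions["S2"]["K"] == 0.5
        assert free.site_fractions["S4"]["K"] == 0.5

    def test_zero_frames_errors(self):
        with pytest.raises(ValueError, match="zero frames"):
            aggregate_occupancy([], [], 0.0)

    def test_tables_normalized_on_simulation(self, sim_universe, pore_spec):
        from ionflux.pore import frame_geometry

        atoms = particle_atoms(sim_universe, pore_spec)
        assigns = []
        for _ in sim_universe.trajectory:
            geom = frame_geometry(sim_universe, pore_spec)
            parts = extract_particles(sim_universe, pore_spec, atoms=atoms)
            assigns.append(assign_frame(parts, geom, pore_spec))
        bound, free = aggregate_occupancy(assigns, label_ca_bound(assigns), 0.0)
        bound.validate(tol=1e-9)
        free.validate(tol=1e-9)

    def test_single_file_exclusion_never_double_occupies(self, sim_universe, pore_spec):
        from ionflux.pore import frame_geometry

        atoms = particle_atoms(sim_universe, pore_spec)
        for _ in sim_universe.trajectory:
            geom = frame_geometry(sim_universe, pore_spec)
            parts = extract_particles(sim_universe, pore_spec, atoms=atoms)
            assert assign_frame(parts, geom, pore_spec).extra_occupants == ()
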
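"""The kinetic hopping generator and its exact stationary-distribution oracle."""

import json
import math

import numpy as np
import pytest

from ionflux import kinetics
from ionflux.kinetics import (KineticModelParams, simulate_trajectory,
                              stationary_occupancy)
from ionflux.permeation import detect_events


class TestParams:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            KineticModelParams(n_ions=-1)
        with pytest.raises(ValueError):
            KineticModelParams(frames="sometimes")
        with pytest.raises(ValueError):
            KineticModelParams(ion_species="NA")

    def test_thermal_voltage_at_310K(self):
        assert KineticModelParams().kT_mV == pytest.approx(26.71, abs=0.01)


class TestMoveCatalog:
    def test_rate_rule_consistent_with_total_energy(self):
        """Incremental ΔU in the move catalog equals the full energy difference."""
        params = KineticModelParams(water_sf_attempt_rate=0.5)
        cache = kinetics._RateCache(params)
        rng = np.random.default_rng(0)
        options = [None, "K", "CA", "W"]
        allowed = {i: [None, "K"] for i in range(kinetics.N_PORE)}
        allowed[kinetics._I_F87] = [None, "CA"]
        allowed[kinetics._I_E92CA] = [None, "CA"]
        allowed[kinetics._I_S1] = [None, "K", "W"]
        allowed[kinetics._I_S4] = [None, "K", "W"]
        checked = 0
        for _ in range(300):
            occ = tuple(allowed[i][rng.integers(len(allowed[i]))]
                        for i in range(kinetics.N_PORE))
            n_pore = sum(1 for s in occ if s == "K")
            if n_pore > params.n_ions:
                continue
            n_in = int(rng.integers(0, params.n_ions - n_pore + 1))
            n_out = params.n_ions - n_pore - n_in
            n_ca_free = params.n_ca - sum(1 for s in occ if s == "CA")
            u0 = kinetics._energy(params, occ)
            for rate, tag in kinetics._moves(cache, occ, n_in, n_out, n_ca_free):
                if tag[0] == "WRAP" or tag[0] == "W":
                    continue
                new, _ = kinetics._apply(occ, n_in, tag, "K")
                dU = kinetics._energy(params, new) - u0
                mult = 1.0
                if tag[0] == "K":
                    base = params.base_rate
                    if tag[1] == kinetics.B_IN:
                        mult = n_in
                    elif tag[1] == kinetics.B_OUT:
                        mult = n_out
                else:
                    base = (params.ca_f87_attempt_rate
                            if tag[2] == kinetics._I_F87
                            else params.ca_e92_attempt_rate)
                    if tag[1] > 0:
                        mult = n_ca_free
                assert rate == pytest.approx(base * mult * math.exp(-dU / 2.0),
                                             rel=1e-12), (occ, tag)
                checked += 1
        assert checked > 500

    def test_block_rule_closes_scav_s4_passage(self):
        params = KineticModelParams()
        cache = kinetics._RateCache(params)
        occ = [None] * kinetics.N_PORE
        occ[kinetics._I_F87] = "CA"
        occ[kinetics._I_SCAV] = "K"
        tags = [t for _, t in kinetics._moves(cache, tuple(occ), 2, 2, 1)]
        assert ("K", kinetics._I_SCAV, kinetics._I_S4) not in tags
        occ[kinetics._I_F87] = None
        tags = [t for _, t in kinetics._moves(cache, tuple(occ), 2, 2, 2)]
        assert ("K", kinetics._I_SCAV, kinetics._I_S4) in tags


class TestStationary:
    def test_probabilities_normalized(self):
        st = stationary_occupancy(KineticModelParams(n_ions=3, n_ca=1))
        assert sum(st.state_distribution.values()) == pytest.approx(1.0, abs=1e-12)
        for dist in st.state_given_ca.values():
            if dist:
                assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_ion_matches_detailed_balance_closed_form(self):
        """One ion, V=0: π(site)/π(bulk) = exp(−E_site), bulk sides equal."""
        params = KineticModelParams(n_ions=1, n_ca=0)
        st = stationary_occupancy(params)
        E = params.site_energies_kT
        # closed form: weights 1 (bulk_in) + Σ exp(−E_s) + 1 (bulk_out)
        weights = {s: math.exp(-E[s]) for s in ("E92", "Scav", "S4", "S3", "S2", "S1")}
        Z = 2.0 + sum(weights.values())
        for site, w in weights.items():
            assert st.site_probability[site].get("K", 0.0) == pytest.approx(
                w / Z, abs=1e-10)

    def test_asymmetric_energies_give_boltzmann_ratio(self):
        """Hand check: two sites differing by ln 2 are occupied 2:1."""
        E = {"E92": 0.0, "Scav": 0.0, "S4": 0.0, "S3": -math.log(2.0),
             "S2": 0.0, "S1": 0.0}
        st = stationary_occupancy(
            KineticModelParams(n_ions=1, n_ca=0, site_energies_kT=E))
        p3 = st.site_probability["S3"]["K"]
        p2 = st.site_probability["S2"]["K"]
        assert p3 / p2 == pytest.approx(2.0, rel=1e-9)

    def test_enumeration_cap_enforced(self):
        with pytest.raises(ValueError, match="cap"):
            stationary_occupancy(KineticModelParams(), max_states=10)

    def test_f87_ca_binding_monotone_in_voltage(self):
        fractions = [stationary_occupancy(KineticModelParams(voltage_mV=v)).p_ca_f87
                     for v in (-300.0, 0.0, 300.0)]
        assert fractions[0] < fractions[1] < fractions[2]
        assert fractions[0] < 0.05 and fractions[2] > 0.8

    def test_e92_ca_binding_voltage_independent(self):
        fractions = [stationary_occupancy(KineticModelParams(voltage_mV=v)).p_ca_e92
                     for v in (-300.0, 0.0, 300.0)]
        assert max(fractions) - min(fractions) < 0.25
        assert min(fractions) > 0.4


class TestSimulate:
    def test_empty_system_is_static(self):
        p = KineticModelParams(n_ions=0, n_ca=0, duration_ns=5.0, frame_interval=1.0)
        r = simulate_trajectory(p)
        gt = r.ground_truth
        assert gt.n_out == gt.n_in == 0
        assert set(gt.state_codes) == {"OOOO"}
        assert len(gt.frame_times) == 6

    def test_zero_voltage_flux_is_balanced(self):
        """Symmetric driving: |n_out − n_in| within 3√(n_out+n_in)."""
        p = KineticModelParams(voltage_mV=0.0, duration_ns=20_000.0, frames="none",
                               n_ca=0, seed=8)
        gt = simulate_trajectory(p).ground_truth
        total = gt.n_out + gt.n_in
        assert total > 20
        assert abs(gt.n_out - gt.n_in) <= 3.0 * math.sqrt(total) + 1.0

    def test_ca_block_shuts_outward_current(self):
        """High Ca2+ on-rate at +V: outward events collapse vs the Ca-free run."""
        base = dict(voltage_mV=300.0, duration_ns=400.0, frames="none", seed=13)
        blocked = simulate_trajectory(KineticModelParams(
            **base, n_ca=2, ca_f87_attempt_rate=20.0,
            ca_f87_energy_kT=1.0)).ground_truth
        free = simulate_trajectory(KineticModelParams(**base, n_ca=0)).ground_truth
        assert free.n_out > 50
        assert blocked.n_out < 0.05 * free.n_out

    def test_seeded_runs_bit_reproducible(self):
        p = KineticModelParams(duration_ns=20.0, frame_interval=0.5, seed=99)
        r1, r2 = simulate_trajectory(p), simulate_trajectory(p)
        j1 = json.dumps(r1.ground_truth.to_json_dict(), sort_keys=True)
        j2 = json.dumps(r2.ground_truth.to_json_dict(), sort_keys=True)
        assert j1 == j2
        c1, _ = kinetics.render_coordinates(p, r1.ground_truth)
        c2, _ = kinetics.render_coordinates(p, r2.ground_truth)
        assert np.array_equal(c1, c2)
        r3 = simulate_trajectory(KineticModelParams(
            duration_ns=20.0, frame_interval=0.5, seed=100))
        assert json.dumps(r3.ground_truth.to_json_dict(), sort_keys=True) != j1

    def test_event_log_replays_through_detector(self):
        """Noise-free traces through the analysis detector reproduce the log."""
        p = KineticModelParams(voltage_mV=150.0, duration_ns=150.0,
                               frames="transitions", jitter_sigma=0.0, seed=4)
        r = simulate_trajectory(p)
        gt = r.ground_truth
        events = detect_events(r.true_axial_traces(),
                               (kinetics.SCAFFOLD_PLANES["F87"],
                                kinetics.SCAFFOLD_PLANES["G63"]),
                               p.box_z)
        n_out = sum(1 for e in events if e.direction == +1)
        n_in = sum(1 for e in events if e.direction == -1)
        assert (n_out, n_in) == (gt.n_out, gt.n_in)
        assert gt.n_out > 0

    def test_empirical_occupancy_approaches_stationary(self):
        """Long-run time-weighted occupancies near the enumerated distribution."""
        p = KineticModelParams(duration_ns=10_000.0, frames="none", seed=17)
        gt = simulate_trajectory(p).ground_truth
        st = stationary_occupancy(p)
        for site in ("S1", "S2", "S3", "S4", "Scav", "E92"):
            emp = gt.occupancy_fraction[site].get("K", 0.0)
            batches = np.asarray(gt.occupancy_batches[site])[2:]
            se = batches.std(ddof=1) / math.sqrt(len(batches))
            exact = st.site_probability[site].get("K", 0.0)
            assert abs(emp - exact) < 4.0 * se + 0.02, site

    def test_transient_sf_water_option(self):
        p = KineticModelParams(water_sf_attempt_rate=3.0, water_sf_energy_kT=0.0,
                               duration_ns=50.0, frame_interval=0.1, seed=6)
        gt = simulate_trajectory(p).ground_truth
        codes = set(gt.state_codes)
        assert any("W" in c for c in codes)
        # water appears only in the outer sites S1/S4
        for code in codes:
            assert code[1] != "W" and code[2] != "W"
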
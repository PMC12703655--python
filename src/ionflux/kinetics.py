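"""Kinetic ion-hopping trajectory generator with exact ground truth.

This module stands in for molecular dynamics upstream of the analysis: it
produces desk-scale trajectories with the statistical structure the analysis
assumes, together with exact logs of every quantity the analysis estimates.

Model
-----
A continuous-time Markov chain of single-file hops over a ladder of binding
sites along the pore axis::

    bulk_in ↔ E92 ↔ Scav ↔ S4 ↔ S3 ↔ S2 ↔ S1 ↔ bulk_out

with at-most-one-ion-per-site exclusion inside the pore.  Two Ca2+-only
binding sites sit off the permeant path: the F87 site (axially inside the
Scav slab, reached from the intracellular bulk) and the E92 glutamate-ring
site ("E92ca", off-axis at the ring); a ring-bound Ca2+ does not obstruct
K+ passing the E92 waypoint, matching the observation that a glutamate-ring
Ca2+ does not block conduction.  Hop rates follow a
symmetric-barrier rule, ``k = A · exp(-ΔU/2kT) · exp(±q·V·δ/2kT)``, where ΔU
collects per-site energies, a nearest-neighbour repulsion between ions in
adjacent SF sites, and a Ca-coupling term (below); δ is the fractional
electrical distance of the hop and V the transmembrane voltage.  At V = 0 the
chain satisfies detailed balance.

Ca2+ (charge +2) binds from the intracellular bulk to two sites: the F87 site
just below the cavity, whose on-rate carries the voltage factor (so binding is
strongly enhanced at positive voltage and suppressed at negative voltage), and
the E92 glutamate ring, which is voltage-independent.  While a Ca2+ ion is
seated at F87 it (i) sterically occludes the Scav↔S4 passage in both
directions (the "ball" of the check valve) and (ii) stabilises ions in the
filter by ``ca_sf_stabilization_kT`` per ion, which shifts the filter toward
higher-occupancy states on Ca-bound frames.

Periodic boundaries are represented by a bulk_out↔bulk_in exchange hop that
carries no voltage bias (the field drops across the pore, not the bulk); in
rendered coordinates it appears as a z-jump larger than half the box, exactly
what the permeation detector must unwrap.

The companion :func:`stationary_occupancy` enumerates the full state space of
the same chain and solves the balance equations exactly; it is the oracle that
long-run empirical occupancies are tested against.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .occupancy import STATE_LETTER

__all__ = [
    "KineticModelParams",
    "SyntheticGroundTruth",
    "SimulationResult",
    "StationaryResult",
    "simulate_trajectory",
    "stationary_occupancy",
    "build_universe",
    "SCAFFOLD_PLANES",
]

BOLTZMANN_mV_per_K = 0.08617333262  # k_B in meV/K ≡ mV per unit charge per K

#: axial positions (Å) of the scaffold's boundary-oxygen rings / F87 ring plane
SCAFFOLD_PLANES = {
    "G63": 12.4, "Y62": 9.3, "G61": 6.2, "V60": 3.1,
    "T59O": 0.0, "T59OG1": -2.5, "F87": -8.0,
}

#: pore sites in intracellular→extracellular order (index into occupancy tuples)
PORE_SITES = ("E92", "E92ca", "F87", "Scav", "S4", "S3", "S2", "S1")
_I_E92, _I_E92CA, _I_F87, _I_SCAV, _I_S4, _I_S3, _I_S2, _I_S1 = range(8)
N_PORE = 8
_SF_IDX = (_I_S4, _I_S3, _I_S2, _I_S1)
_SF_ADJ = ((_I_S4, _I_S3), (_I_S3, _I_S2), (_I_S2, _I_S1))

# K+ path: (from, to, fractional electrical distance of the hop), outward order.
# Bulk endpoints are encoded as -1 (bulk_in) and -2 (bulk_out).
B_IN, B_OUT = -1, -2
_K_PATH = (
    (B_IN, _I_E92, 0.10),
    (_I_E92, _I_SCAV, 0.20),
    (_I_SCAV, _I_S4, 0.15),
    (_I_S4, _I_S3, 0.15),
    (_I_S3, _I_S2, 0.15),
    (_I_S2, _I_S1, 0.15),
    (_I_S1, B_OUT, 0.10),
)

_DEFAULT_LADDER = (
    ("bulk_in", -25.0), ("E92", -12.0), ("F87", -6.5), ("Scav", -4.0),
    ("S4", -1.25), ("S3", 4.65), ("S2", 7.75), ("S1", 10.85), ("bulk_out", 25.0),
)


@dataclass(frozen=True)
class KineticModelParams:
    """Parameters of the kinetic hopping model.

    Defaults place the model in the regime the analysis is meant for: a
    voltage-gated Ca2+ block at F87 (electrical distance 0.25, charge +2), a
    voltage-independent E92 site with higher zero-voltage Ca2+ occupancy than
    F87, KOKO as the dominant filter state on Ca-free frames at ≤ 0 mV and a
    shift toward KKOK on Ca-bound frames, and a water-free filter.
    """

    site_ladder: tuple = _DEFAULT_LADDER
    ion_species: str = "K"          # permeant cation: "K" or "NH4"
    n_ions: int = 6
    n_ca: int = 2
    n_waters: int = 24
    n_cl: int = 4
    base_rate: float = 4.0          # hop attempt rate, 1/ns
    wrap_rate: float = 1.5          # bulk_out↔bulk_in exchange, 1/ns per ion
    voltage_mV: float = 0.0
    temperature_K: float = 310.0
    site_energies_kT: Mapping[str, float] = field(default_factory=lambda: {
        "E92": 0.5, "Scav": 0.8, "S4": 0.6, "S3": 0.0, "S2": -0.2, "S1": -1.0,
    })
    pair_repulsion_kT: float = 1.3  # adjacent-SF-site ion-ion repulsion
    ca_f87_energy_kT: float = 4.4   # bare; binding is driven by the SF coupling
    ca_e92_energy_kT: float = -0.4
    ca_f87_attempt_rate: float = 1.0
    ca_e92_attempt_rate: float = 1.0
    ca_delta_f87: float = 0.25      # electrical distance of Ca2+ binding at F87
    ca_delta_e92: float = 0.0       # E92 binding is voltage-independent
    ca_sf_stabilization_kT: float = 1.7
    block_rule: bool = True         # Ca at F87 occludes Scav↔S4 (both directions)
    water_sf_attempt_rate: float = 0.0   # optional transient S1/S4 waters
    water_sf_energy_kT: float = 1.5
    jitter_sigma: float = 0.3       # Å, isotropic positional noise on particles
    scaffold_jitter_sigma: float = 0.0
    frame_interval: float = 0.1     # ns between saved frames ("interval" mode)
    frames: str = "interval"        # "interval" | "transitions" | "none"
    duration_ns: float = 200.0
    gate_width: float = 16.0        # F97 Cα square side, Å
    box_z: float = 100.0
    box_xy: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.n_ions < 0 or self.n_ca < 0:
            raise ValueError("particle counts must be non-negative")
        if self.base_rate < 0 or self.wrap_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")
        if self.frames not in ("interval", "transitions", "none"):
            raise ValueError("frames must be 'interval', 'transitions' or 'none'")
        if self.ion_species not in ("K", "NH4"):
            raise ValueError("ion_species must be 'K' or 'NH4'")
        z = [z for _, z in self.site_ladder]
        if not all(a < b for a, b in zip(z, z[1:])):
            raise ValueError("site ladder centers must be strictly ordered along z")
        for _, d in enumerate(self._deltas()):
            if not (0.0 < d <= 1.0):
                raise ValueError("electrical distances must lie in (0, 1]")

    def _deltas(self):
        return [d for _, _, d in _K_PATH]

    @property
    def kT_mV(self) -> float:
        """Thermal voltage k_B·T/e in mV (26.71 mV at 310 K)."""
        return BOLTZMANN_mV_per_K * self.temperature_K

    @property
    def site_centers(self) -> dict[str, float]:
        return dict(self.site_ladder)

    def replace(self, **kw) -> "KineticModelParams":
        d = asdict(self)
        d["site_ladder"] = self.site_ladder
        d.update(kw)
        return KineticModelParams(**d)


# ---------------------------------------------------------------------------
# move catalog (shared by the stochastic simulator and the exact enumerator)
# ---------------------------------------------------------------------------

def _energy(params: KineticModelParams, occ: tuple) -> float:
    """Total configurational energy (kT units) of a pore occupancy tuple."""
    ion = params.ion_species
    E = params.site_energies_kT
    u = 0.0
    for i, s in enumerate(occ):
        if s == ion:
            u += E[PORE_SITES[i]]
        elif s == "CA":
            u += params.ca_f87_energy_kT if i == _I_F87 else params.ca_e92_energy_kT
        elif s == "W":
            u += params.water_sf_energy_kT
    for a, b in _SF_ADJ:
        if occ[a] == ion and occ[b] == ion:
            u += params.pair_repulsion_kT
    if occ[_I_F87] == "CA":
        n_sf = sum(1 for i in _SF_IDX if occ[i] == ion)
        u -= params.ca_sf_stabilization_kT * n_sf
    return u


#: SF-internal adjacency for the ion-ion repulsion term
_SF_NEIGHBOURS = {
    _I_S4: (_I_S3,), _I_S3: (_I_S4, _I_S2), _I_S2: (_I_S3, _I_S1), _I_S1: (_I_S2,),
}
_SF_SET = frozenset(_SF_IDX)


class _RateCache:
    """Per-parameter-set constants for the move catalog (voltage factors etc.)."""

    def __init__(self, params: KineticModelParams):
        V, kT = params.voltage_mV, params.kT_mV
        self.params = params
        self.site_E = [0.0] * N_PORE
        for i, name in enumerate(PORE_SITES):
            self.site_E[i] = params.site_energies_kT.get(name, 0.0)
        # directed K hops: (src, dst, voltage factor)
        self.k_hops = []
        for a, b, delta in _K_PATH:
            vf = math.exp(V * delta / (2.0 * kT))
            self.k_hops.append((a, b, vf))
            self.k_hops.append((b, a, 1.0 / vf))
        self.ca_vf = {
            _I_F87: math.exp(2.0 * V * params.ca_delta_f87 / (2.0 * kT)),
            _I_E92CA: math.exp(2.0 * V * params.ca_delta_e92 / (2.0 * kT)),
        }
        self.w_on = params.water_sf_attempt_rate * math.exp(-params.water_sf_energy_kT / 2.0)
        self.w_off = params.water_sf_attempt_rate * math.exp(+params.water_sf_energy_kT / 2.0)


def _moves(cache: _RateCache, occ: tuple, n_in: int, n_out: int,
           n_ca_free: int) -> list[tuple[float, tuple]]:
    """Enumerate (rate, move-tag) pairs for one canonical state.

    Move tags: ("K", a, b) hop of the permeant ion from a to b (−1/−2 = bulk),
    ("CA", ±1, site) bind/unbind, ("W", ±1, site) water insert/remove,
    ("WRAP", a, b) bulk exchange.  Rates use energy differences computed
    incrementally; they agree exactly with differences of :func:`_energy`.
    """
    p = cache.params
    ion = p.ion_species
    exp = math.exp
    site_E = cache.site_E
    u_rep = p.pair_repulsion_kT
    ca_at_f87 = occ[_I_F87] == "CA"
    stab = p.ca_sf_stabilization_kT if ca_at_f87 else 0.0
    blocked = p.block_rule and ca_at_f87
    out: list[tuple[float, tuple]] = []

    def nn_ions(site: int, excluding: int) -> int:
        n = 0
        for nb in _SF_NEIGHBOURS.get(site, ()):
            if nb != excluding and occ[nb] == ion:
                n += 1
        return n

    for src, dst, vf in cache.k_hops:
        if blocked and (src == _I_SCAV or src == _I_S4) and (dst == _I_SCAV or dst == _I_S4):
            continue
        if src >= 0:
            if occ[src] != ion:
                continue
            mult = 1.0
            e_src = site_E[src]
        else:
            n_src = n_in if src == B_IN else n_out
            if n_src == 0:
                continue
            mult = float(n_src)
            e_src = 0.0
        if dst >= 0:
            if occ[dst] is not None:
                continue
            e_dst = site_E[dst]
        else:
            e_dst = 0.0
        dU = e_dst - e_src
        if u_rep:
            dU += u_rep * (nn_ions(dst, src) - nn_ions(src, dst)) \
                if (src in _SF_SET or dst in _SF_SET) else 0.0
        if stab:
            dU -= stab * ((dst in _SF_SET) - (src in _SF_SET))
        out.append((p.base_rate * mult * exp(-dU / 2.0) * vf, ("K", src, dst)))

    n_sf_ions = sum(1 for i in _SF_IDX if occ[i] == ion)
    for site, attempt, e_ca in (
        (_I_F87, p.ca_f87_attempt_rate, p.ca_f87_energy_kT),
        (_I_E92CA, p.ca_e92_attempt_rate, p.ca_e92_energy_kT),
    ):
        coupling = p.ca_sf_stabilization_kT * n_sf_ions if site == _I_F87 else 0.0
        if occ[site] is None and n_ca_free > 0:
            dU = e_ca - coupling
            out.append((attempt * n_ca_free * exp(-dU / 2.0) * cache.ca_vf[site],
                        ("CA", +1, site)))
        elif occ[site] == "CA":
            dU = -e_ca + coupling
            out.append((attempt * exp(-dU / 2.0) / cache.ca_vf[site],
                        ("CA", -1, site)))

    if p.water_sf_attempt_rate > 0:
        for site in (_I_S1, _I_S4):
            if occ[site] is None:
                out.append((cache.w_on, ("W", +1, site)))
            elif occ[site] == "W":
                out.append((cache.w_off, ("W", -1, site)))

    if n_out > 0:
        out.append((p.wrap_rate * n_out, ("WRAP", B_OUT, B_IN)))
    if n_in > 0:
        out.append((p.wrap_rate * n_in, ("WRAP", B_IN, B_OUT)))
    return out


def _apply(occ: tuple, n_in: int, tag: tuple, ion: str) -> tuple[tuple, int]:
    """Apply a move tag to a canonical state; returns (occ', n_in')."""
    kind = tag[0]
    new = list(occ)
    if kind == "K":
        _, src, dst = tag
        if src >= 0:
            new[src] = None
        elif src == B_IN:
            n_in -= 1
        if dst >= 0:
            new[dst] = ion
        elif dst == B_IN:
            n_in += 1
    elif kind == "CA":
        _, sign, site = tag
        new[site] = "CA" if sign > 0 else None
    elif kind == "W":
        _, sign, site = tag
        new[site] = "W" if sign > 0 else None
    elif kind == "WRAP":
        _, src, _ = tag
        n_in += 1 if src == B_OUT else -1
    return tuple(new), n_in


# ---------------------------------------------------------------------------
# exact stationary distribution (enumeration oracle)
# ---------------------------------------------------------------------------

@dataclass
class StationaryResult:
    """Exact stationary statistics of the hopping chain."""

    site_probability: dict[str, dict[str, float]]   # site → species → P(occupied by)
    state_distribution: dict[str, float]            # 4-letter code → probability
    state_given_ca: dict[str, dict[str, float]]     # "bound"/"free" → code → P
    p_ca_f87: float
    p_ca_e92: float
    n_states: int


def stationary_occupancy(params: KineticModelParams,
                         max_states: int = 200_000) -> StationaryResult:
    """Solve the balance equations of the hopping chain over its full state space.

    The state space (pore occupancy pattern × intracellular/extracellular bulk
    split) is enumerated by breadth-first search from the empty-pore state;
    raises if it exceeds ``max_states``.
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    ion = params.ion_species
    cache = _RateCache(params)
    start = ((None,) * N_PORE, params.n_ions - params.n_ions // 2)
    index: dict[tuple, int] = {start: 0}
    frontier = [start]
    transitions: list[tuple[int, int, float]] = []
    while frontier:
        nxt = []
        for state in frontier:
            occ, n_in = state
            i = index[state]
            n_pore = sum(1 for s in occ if s == ion)
            n_out = params.n_ions - n_pore - n_in
            n_ca_free = params.n_ca - sum(1 for s in occ if s == "CA")
            for rate, tag in _moves(cache, occ, n_in, n_out, n_ca_free):
                if rate <= 0.0:
                    continue
                new = _apply(occ, n_in, tag, ion)
                j = index.get(new)
                if j is None:
                    j = index[new] = len(index)
                    if len(index) > max_states:
                        raise ValueError(
                            f"state space exceeds enumeration cap ({max_states})"
                        )
                    nxt.append(new)
                transitions.append((i, j, rate))
        frontier = nxt

    n = len(index)
    if n == 1:
        pi = np.ones(1)
    else:
        A = lil_matrix((n, n))
        for i, j, rate in transitions:
            A[j, i] += rate
            A[i, i] -= rate
        A[n - 1, :] = 1.0
        b = np.zeros(n)
        b[n - 1] = 1.0
        pi = spsolve(A.tocsr(), b)
        pi = np.clip(pi, 0.0, None)
        pi /= pi.sum()

    site_probability: dict[str, dict[str, float]] = {s: {} for s in PORE_SITES}
    state_distribution: dict[str, float] = {}
    joint: dict[str, dict[str, float]] = {"bound": {}, "free": {}}
    p_ca_f87 = p_ca_e92 = 0.0
    for (occ, n_in), i in index.items():
        p = float(pi[i])
        for k, s in enumerate(occ):
            if s is not None:
                d = site_probability[PORE_SITES[k]]
                d[s] = d.get(s, 0.0) + p
        code = _state_code(occ, ion)
        state_distribution[code] = state_distribution.get(code, 0.0) + p
        ca = occ[_I_F87] == "CA"
        key = "bound" if ca else "free"
        joint[key][code] = joint[key].get(code, 0.0) + p
        if ca:
            p_ca_f87 += p
        if occ[_I_E92CA] == "CA":
            p_ca_e92 += p

    state_given_ca = {}
    for key, dist in joint.items():
        tot = sum(dist.values())
        state_given_ca[key] = {c: v / tot for c, v in dist.items()} if tot > 0 else {}
    return StationaryResult(
        site_probability=site_probability,
        state_distribution=state_distribution,
        state_given_ca=state_given_ca,
        p_ca_f87=p_ca_f87,
        p_ca_e92=p_ca_e92,
        n_states=n,
    )


def _state_code(occ: tuple, ion: str) -> str:
    letters = []
    for i in (_I_S1, _I_S2, _I_S3, _I_S4):
        s = occ[i]
        if s == ion:
            letters.append(STATE_LETTER[ion])
        elif s == "W":
            letters.append("W")
        else:
            letters.append("O")
    return "".join(letters)


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------

#: compartment of each ladder location for ground-truth event logging
_COMPARTMENT = {B_IN: -1, _I_E92: -1, _I_E92CA: -1, B_OUT: +1,
                _I_F87: 0, _I_SCAV: 0, _I_S4: 0, _I_S3: 0, _I_S2: 0, _I_S1: 0}

# particle-site codes used in the per-frame ground-truth log
SITE_CODES = tuple(PORE_SITES) + ("bulk_in", "bulk_out", "ca_bulk")
_SC_BULK_IN, _SC_BULK_OUT, _SC_CA_BULK = 8, 9, 10


@dataclass
class SyntheticGroundTruth:
    """Generator-side log of true states, events and Ca-bound flags."""

    frame_times: np.ndarray
    particle_sites: np.ndarray        # (n_frames, n_ions + n_ca) int8 site codes
    site_species: np.ndarray          # (n_frames, 7) 0=empty 1=ion 2=Ca 3=water
    state_codes: list[str]
    ca_f87: np.ndarray                # bool per frame
    ca_e92: np.ndarray
    events: list[dict]                # ion, direction, t_entry, t_exit, frames
    n_out: int
    n_in: int
    occupancy_fraction: dict[str, dict[str, float]]   # time-weighted, exact
    occupancy_batches: dict[str, list[float]]         # per-batch ion occupancy
    occupancy_batches_ca: dict[str, list[float]]      # per-batch Ca occupancy
    total_time_ns: float
    n_steps: int
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "total_time_ns": self.total_time_ns,
            "n_steps": self.n_steps,
            "n_out": self.n_out,
            "n_in": self.n_in,
            "frame_times": np.asarray(self.frame_times).tolist(),
            "state_codes": list(self.state_codes),
            "ca_f87": np.asarray(self.ca_f87).astype(int).tolist(),
            "ca_e92": np.asarray(self.ca_e92).astype(int).tolist(),
            "particle_sites": np.asarray(self.particle_sites).tolist(),
            "site_species": np.asarray(self.site_species).tolist(),
            "events": self.events,
            "occupancy_fraction": self.occupancy_fraction,
            "occupancy_batches": self.occupancy_batches,
            "occupancy_batches_ca": self.occupancy_batches_ca,
        }


class _EventTracker:
    """Per-ion three-compartment bookkeeping, mirroring the analysis detector."""

    def __init__(self):
        self.origin: dict[int, int] = {}
        self.filter_entry: dict[int, float] = {}

    def init_ion(self, ion: int, comp: int) -> None:
        self.origin[ion] = comp

    def hop(self, ion: int, c_from: int, c_to: int, t: float,
            events: list, counts: list) -> None:
        if c_to == 0:
            if c_from != 0:
                self.filter_entry[ion] = t
            return
        if c_from == 0 and self.origin.get(ion) is not None and c_to != self.origin[ion]:
            direction = +1 if self.origin[ion] == -1 else -1
            events.append({
                "ion": ion,
                "direction": direction,
                "t_entry": self.filter_entry.get(ion, t),
                "t_exit": t,
            })
            counts[0 if direction > 0 else 1] += 1
        self.origin[ion] = c_to
        self.filter_entry.pop(ion, None)


@dataclass
class SimulationResult:
    """Output of :func:`simulate_trajectory`: ground truth + renderable frames."""

    params: KineticModelParams
    ground_truth: SyntheticGroundTruth
    n_scaffold_atoms: int = 0
    _universe: object = None

    @property
    def ion_atom_ids(self) -> np.ndarray:
        """Atom ids (1-based serials) of the permeant ions, in ion order."""
        return np.arange(self.params.n_ions) + self.n_scaffold_atoms + 1

    @property
    def ca_atom_ids(self) -> np.ndarray:
        return np.arange(self.params.n_ca) + self.n_scaffold_atoms + self.params.n_ions + 1

    def to_universe(self):
        if self._universe is None:
            self._universe = build_universe(self.params, self.ground_truth)
        return self._universe

    def true_axial_traces(self) -> dict[int, np.ndarray]:
        """Noise-free axial traces per ion atom id (site centers, Å rel. T59)."""
        centers = _site_code_z(self.params)
        sites = self.ground_truth.particle_sites[:, :self.params.n_ions]
        return {
            int(self.ion_atom_ids[i]): centers[sites[:, i]]
            for i in range(self.params.n_ions)
        }

    def write(self, outdir) -> dict[str, str]:
        """Write topology.pdb, trajectory.pdb (multi-model), ground_truth.json, params.yaml."""
        import pathlib
        import yaml
        import MDAnalysis as mda

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        u = self.to_universe()
        paths = {
            "topology": str(outdir / "topology.pdb"),
            "trajectory": str(outdir / "trajectory.pdb"),
            "ground_truth": str(outdir / "ground_truth.json"),
            "params": str(outdir / "params.yaml"),
        }
        u.trajectory[0]
        u.atoms.write(paths["topology"])
        with mda.Writer(paths["trajectory"], n_atoms=len(u.atoms), multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.ground_truth.to_json_dict(), fh, sort_keys=True)
        pdict = asdict(self.params)
        pdict["site_ladder"] = [[name, z] for name, z in self.params.site_ladder]
        pdict["site_energies_kT"] = dict(self.params.site_energies_kT)
        with open(paths["params"], "w") as fh:
            yaml.safe_dump(pdict, fh, sort_keys=True)
        return paths


def simulate_trajectory(params: KineticModelParams,
                        n_batches: int = 20) -> SimulationResult:
    """Run the exact continuous-time stochastic simulation.

    Frames are sampled every ``params.frame_interval`` ns ("interval" mode),
    after every transition ("transitions" mode — the mode in which the
    analysis can recover the ground truth exactly), or not at all ("none").
    """
    rng = np.random.default_rng(params.seed)
    ion = params.ion_species
    T = float(params.duration_ns)
    if T <= 0:
        raise ValueError("duration_ns must be positive")

    occ: list = [None] * N_PORE                 # pore occupancy (species labels)
    occ_ids: list = [None] * N_PORE             # particle id at each pore site
    n_in0 = params.n_ions - params.n_ions // 2
    bulk_in = list(range(n_in0))
    bulk_out = list(range(n_in0, params.n_ions))
    ca_bulk = list(range(params.n_ca))

    tracker = _EventTracker()
    for i in bulk_in:
        tracker.init_ion(i, -1)
    for i in bulk_out:
        tracker.init_ion(i, +1)
    events: list[dict] = []
    counts = [0, 0]  # outward, inward

    # time-weighted occupancy accumulators
    occ_time: dict[str, dict[str, float]] = {s: {} for s in PORE_SITES}
    batch_time = np.zeros((n_batches, N_PORE))
    batch_time_ca = np.zeros((n_batches, N_PORE))
    batch_len = T / n_batches

    # frame sampling
    mode = params.frames
    frame_times: list[float] = []
    frame_sites: list[np.ndarray] = []
    frame_occ: list[np.ndarray] = []

    def particle_site_codes() -> np.ndarray:
        codes = np.empty(params.n_ions + params.n_ca, dtype=np.int8)
        codes[:params.n_ions] = _SC_BULK_IN
        for i in bulk_out:
            codes[i] = _SC_BULK_OUT
        for s, pid in enumerate(occ_ids):
            if pid is not None and occ[s] == ion:
                codes[pid] = s
        for j in range(params.n_ca):
            codes[params.n_ions + j] = _SC_CA_BULK
        for s in (_I_F87, _I_E92CA):
            if occ[s] == "CA":
                codes[params.n_ions + occ_ids[s]] = s
        return codes

    def snapshot(t: float) -> None:
        frame_times.append(t)
        frame_sites.append(particle_site_codes())
        frame_occ.append(np.array(
            [0 if s is None else (1 if s == ion else (2 if s == "CA" else 3))
             for s in occ], dtype=np.int8))

    t = 0.0
    n_steps = 0
    if mode == "interval" and params.frame_interval <= 0:
        raise ValueError("frame_interval must be positive in interval mode")
    next_sample = 0.0 if mode == "interval" else math.inf
    if mode == "transitions":
        snapshot(0.0)

    def accumulate(t0: float, t1: float) -> None:
        dt = t1 - t0
        if dt <= 0:
            return
        for s, sp in enumerate(occ):
            if sp is not None:
                d = occ_time[PORE_SITES[s]]
                d[sp] = d.get(sp, 0.0) + dt
        # batch accumulation (permeant-ion occupancy per pore site)
        b0 = min(int(t0 / batch_len), n_batches - 1)
        b1 = min(int(t1 / batch_len), n_batches - 1)
        for s, sp in enumerate(occ):
            if sp == ion:
                arr = batch_time
            elif sp == "CA":
                arr = batch_time_ca
            else:
                continue
            if b0 == b1:
                arr[b0, s] += dt
            else:
                arr[b0, s] += (b0 + 1) * batch_len - t0
                arr[b1, s] += t1 - b1 * batch_len
                for b in range(b0 + 1, b1):
                    arr[b, s] += batch_len

    cache = _RateCache(params)
    while True:
        moves = _moves(cache, tuple(occ), len(bulk_in), len(bulk_out), len(ca_bulk))
        total = 0.0
        for r, _ in moves:
            total += r
        if total <= 0.0:
            if params.n_ions + params.n_ca > 0:
                raise RuntimeError("zero total transition rate with mobile particles present")
            break
        t_new = t + rng.exponential(1.0 / total)
        if t_new >= T:
            break
        # emit interval frames falling in [t, t_new) — the state is constant there
        while next_sample < t_new:
            snapshot(next_sample)
            next_sample += params.frame_interval
        accumulate(t, t_new)
        t = t_new
        n_steps += 1

        choice = rng.random() * total
        acc = 0.0
        tag = moves[-1][1]
        for r, m in moves:
            acc += r
            if acc >= choice:
                tag = m
                break
        _apply_id_state(tag, ion, occ, occ_ids, bulk_in, bulk_out, ca_bulk,
                        tracker, events, counts, t, rng)
        if mode == "transitions":
            snapshot(t)

    accumulate(t, T)
    if mode == "interval":
        while next_sample <= T + 1e-9:
            snapshot(min(next_sample, T))
            next_sample += params.frame_interval
    if mode == "none" and not frame_times:
        snapshot(T)

    ft = np.asarray(frame_times)
    sites = np.asarray(frame_sites, dtype=np.int8)
    occ_species = np.asarray(frame_occ, dtype=np.int8)
    codes = [_occ_code(row, ion) for row in occ_species]
    ca_f87 = occ_species[:, _I_F87] == 2
    ca_e92 = occ_species[:, _I_E92CA] == 2

    for ev in events:
        ev["entry_frame"] = int(np.searchsorted(ft, ev["t_entry"], side="left"))
        ev["exit_frame"] = int(np.searchsorted(ft, ev["t_exit"], side="left"))

    occupancy_fraction = {
        s: {sp: v / T for sp, v in sorted(d.items())} for s, d in occ_time.items()
    }
    occupancy_batches = {
        PORE_SITES[s]: (batch_time[:, s] / batch_len).tolist() for s in range(N_PORE)
    }
    occupancy_batches_ca = {
        PORE_SITES[s]: (batch_time_ca[:, s] / batch_len).tolist()
        for s in (_I_F87, _I_E92CA)
    }

    gt = SyntheticGroundTruth(
        frame_times=ft,
        particle_sites=sites,
        site_species=occ_species,
        state_codes=codes,
        ca_f87=ca_f87,
        ca_e92=ca_e92,
        events=events,
        n_out=counts[0],
        n_in=counts[1],
        occupancy_fraction=occupancy_fraction,
        occupancy_batches=occupancy_batches,
        occupancy_batches_ca=occupancy_batches_ca,
        total_time_ns=T,
        n_steps=n_steps,
        seed=params.seed,
    )
    result = SimulationResult(params=params, ground_truth=gt)
    result.n_scaffold_atoms = len(_scaffold_atoms(params))
    return result


def _apply_id_state(tag, ion, occ, occ_ids, bulk_in, bulk_out, ca_bulk,
                    tracker: _EventTracker, events, counts, t, rng) -> None:
    kind = tag[0]
    if kind == "K":
        _, src, dst = tag
        if src >= 0:
            pid = occ_ids[src]
            occ[src] = None
            occ_ids[src] = None
            c_from = _COMPARTMENT[src]
        else:
            pool = bulk_in if src == B_IN else bulk_out
            pid = pool.pop(int(rng.integers(len(pool))))
            c_from = _COMPARTMENT[src]
        if dst >= 0:
            occ[dst] = ion
            occ_ids[dst] = pid
            c_to = _COMPARTMENT[dst]
        else:
            (bulk_in if dst == B_IN else bulk_out).append(pid)
            c_to = _COMPARTMENT[dst]
        tracker.hop(pid, c_from, c_to, t, events, counts)
    elif kind == "CA":
        _, sign, site = tag
        if sign > 0:
            cid = ca_bulk.pop(int(rng.integers(len(ca_bulk))))
            occ[site] = "CA"
            occ_ids[site] = cid
        else:
            ca_bulk.append(occ_ids[site])
            occ[site] = None
            occ_ids[site] = None
    elif kind == "W":
        _, sign, site = tag
        occ[site] = "W" if sign > 0 else None
        occ_ids[site] = None
    elif kind == "WRAP":
        _, src, dst = tag
        pool_src = bulk_in if src == B_IN else bulk_out
        pool_dst = bulk_in if dst == B_IN else bulk_out
        pid = pool_src.pop(int(rng.integers(len(pool_src))))
        pool_dst.append(pid)
        # a wrap is a bulk-side crossing: it resets the origin, never an event
        tracker.origin[pid] = _COMPARTMENT[dst]
        tracker.filter_entry.pop(pid, None)


def _occ_code(occ_row: np.ndarray, ion: str) -> str:
    letters = []
    for site_idx in (_I_S1, _I_S2, _I_S3, _I_S4):
        v = occ_row[site_idx]
        if v == 1:
            letters.append(STATE_LETTER[ion])
        elif v == 3:
            letters.append("W")
        else:
            letters.append("O")
    return "".join(letters)


def _site_code_z(params: KineticModelParams) -> np.ndarray:
    """Axial center (Å) for each ground-truth site code (bulk → slab centers)."""
    centers = params.site_centers
    z = [centers["E92"] if s == "E92ca" else centers[s] for s in PORE_SITES]
    z += [centers["bulk_in"], centers["bulk_out"], centers["bulk_in"]]
    return np.asarray(z)


# ---------------------------------------------------------------------------
# coordinate rendering
# ---------------------------------------------------------------------------

def _scaffold_atoms(params: KineticModelParams) -> list[tuple]:
    """(chain, resid, resname, atom name, xyz) for the minimal protein scaffold."""
    atoms = []
    g = params.gate_width / 2.0
    corners = {"A": (g, g), "B": (-g, g), "C": (-g, -g), "D": (g, -g)}
    for k, chain in enumerate("ABCD"):
        th = math.pi / 2.0 * k
        c, s = math.cos(th), math.sin(th)

        def ring(radius, z):
            return (radius * c, radius * s, z)

        atoms.append((chain, 59, "THR", "O", ring(2.8, SCAFFOLD_PLANES["T59O"])))
        atoms.append((chain, 59, "THR", "OG1", ring(3.0, SCAFFOLD_PLANES["T59OG1"])))
        atoms.append((chain, 60, "VAL", "O", ring(2.8, SCAFFOLD_PLANES["V60"])))
        atoms.append((chain, 61, "GLY", "O", ring(2.8, SCAFFOLD_PLANES["G61"])))
        atoms.append((chain, 62, "TYR", "O", ring(2.8, SCAFFOLD_PLANES["Y62"])))
        atoms.append((chain, 63, "GLY", "O", ring(2.8, SCAFFOLD_PLANES["G63"])))
        # F87 aromatic ring: regular hexagon, centroid at radius 6.0, z = F87 plane
        cx, cy, cz = ring(6.0, SCAFFOLD_PLANES["F87"])
        for m, name in enumerate(("CG", "CD1", "CE1", "CZ", "CE2", "CD2")):
            phi = math.pi / 3.0 * m
            atoms.append((chain, 87, "PHE", name,
                          (cx + 1.4 * math.cos(phi) * -s + 0.0,
                           cy + 1.4 * math.cos(phi) * c,
                           cz + 1.4 * math.sin(phi))))
        # E92 carboxylate oxygens: radius 4.0, z = -12
        for name, dphi in (("OE1", -0.25), ("OE2", +0.25)):
            atoms.append((chain, 92, "GLU", name,
                          (4.0 * math.cos(th + dphi), 4.0 * math.sin(th + dphi), -12.0)))
        # E96 ring, further out (little Ca binding there)
        for name, dphi in (("OE1", -0.2), ("OE2", +0.2)):
            atoms.append((chain, 96, "GLU", name,
                          (7.0 * math.cos(th + dphi), 7.0 * math.sin(th + dphi), -15.0)))
        # F97 gate Cα at the corners of a square of side gate_width
        x, y = corners[chain]
        atoms.append((chain, 97, "PHE", "CA", (x, y, -16.0)))
    return atoms


def _bulk_slot(i: int, z_center: float) -> tuple[float, float, float]:
    """Deterministic resting position for bulk particle slot *i* (golden-angle)."""
    r = 5.0 + 3.0 * ((i * 0.6180339887) % 1.0)
    phi = 2.0 * math.pi * ((i * 0.3819660113) % 1.0)
    zoff = -3.0 + 6.0 * ((i * 0.2360679775) % 1.0)
    return (r * math.cos(phi), r * math.sin(phi), z_center + zoff)


def _water_sites(params: KineticModelParams) -> np.ndarray:
    """Static water resting positions: cavity shell + both bulk slabs."""
    n = params.n_waters
    centers = params.site_centers
    out = []
    for i in range(n):
        kind = i % 3
        if kind == 0:  # cavity shell, outside the Scav radial cutoff
            r = 4.5 + 2.5 * ((i * 0.618) % 1.0)
            phi = 2.0 * math.pi * ((i * 0.382) % 1.0)
            z = -8.0 + 5.0 * ((i * 0.236) % 1.0)
            out.append((r * math.cos(phi), r * math.sin(phi), z))
        elif kind == 1:
            out.append(_bulk_slot(i + 7, centers["bulk_in"]))
        else:
            out.append(_bulk_slot(i + 13, centers["bulk_out"]))
    return np.asarray(out).reshape(-1, 3)


def render_coordinates(params: KineticModelParams, gt: SyntheticGroundTruth,
                       rng: np.random.Generator | None = None) -> tuple[np.ndarray, list]:
    """Per-frame coordinates for scaffold + particles.

    Returns ``(coords, atom_records)`` with coords of shape
    (n_frames, n_atoms, 3).  Particle positions are site centers (or bulk
    slots) plus isotropic Gaussian jitter; the scaffold is rigid unless
    ``scaffold_jitter_sigma > 0``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    scaffold = _scaffold_atoms(params)
    n_frames = len(gt.frame_times)
    centers = params.site_centers

    records: list[tuple] = list(scaffold)
    base = np.asarray([a[4] for a in scaffold])

    ion_resname = "POT" if params.ion_species == "K" else "NH4"
    ion_atom = "K" if params.ion_species == "K" else "N"
    for i in range(params.n_ions):
        records.append(("", 200 + i, ion_resname, ion_atom, (0, 0, 0)))
    for i in range(params.n_ca):
        records.append(("", 300 + i, "CAL", "CA", (0, 0, 0)))
    for i in range(params.n_cl):
        records.append(("", 400 + i, "CLA", "CL", (0, 0, 0)))
    for i in range(params.n_waters):
        records.append(("", 500 + i, "HOH", "O", (0, 0, 0)))

    n_atoms = len(records)
    coords = np.empty((n_frames, n_atoms, 3), dtype=np.float32)
    coords[:, :len(scaffold)] = base[None, :, :]
    if params.scaffold_jitter_sigma > 0:
        coords[:, :len(scaffold)] += rng.normal(
            0.0, params.scaffold_jitter_sigma, size=(n_frames, len(scaffold), 3)
        )

    # mobile particles: site centers / bulk slots per frame
    n_part = params.n_ions + params.n_ca
    pore_xyz = np.zeros((N_PORE + 3, 3))
    for s, name in enumerate(PORE_SITES):
        if name == "E92ca":
            # Ca at the glutamate ring sits off-axis, near the carboxylates
            pore_xyz[s] = (2.5, 0.0, centers["E92"])
        else:
            pore_xyz[s] = (0.0, 0.0, centers[name])
    part = np.empty((n_frames, n_part, 3))
    for p in range(n_part):
        sites = gt.particle_sites[:, p].astype(int)
        xyz = pore_xyz[sites]
        for code, zc in ((_SC_BULK_IN, centers["bulk_in"]),
                         (_SC_BULK_OUT, centers["bulk_out"]),
                         (_SC_CA_BULK, centers["bulk_in"])):
            mask = sites == code
            if mask.any():
                xyz = xyz.copy()
                xyz[mask] = _bulk_slot(p, zc)
        part[:, p] = xyz
    i0 = len(scaffold)
    coords[:, i0:i0 + n_part] = part

    cl_xyz = np.asarray([
        _bulk_slot(i + 3, centers["bulk_in"] if i % 2 else centers["bulk_out"])
        for i in range(params.n_cl)
    ]).reshape(-1, 3)
    coords[:, i0 + n_part:i0 + n_part + params.n_cl] = cl_xyz[None, :, :]
    w0 = i0 + n_part + params.n_cl
    coords[:, w0:] = _water_sites(params)[None, :, :]
    # transient SF waters: the last two water slots occupy S1/S4 when bound
    if params.water_sf_attempt_rate > 0 and params.n_waters >= 2:
        for slot, site in ((params.n_waters - 1, _I_S1), (params.n_waters - 2, _I_S4)):
            bound = gt.site_species[:, site] == 3
            coords[bound, w0 + slot] = (0.0, 0.0, centers[PORE_SITES[site]])

    if params.jitter_sigma > 0:
        coords[:, i0:] += rng.normal(
            0.0, params.jitter_sigma, size=(n_frames, n_atoms - i0, 3)
        ).astype(np.float32)
    return coords, records


def build_universe(params: KineticModelParams, gt: SyntheticGroundTruth):
    """Build an in-memory MDAnalysis universe of the rendered trajectory."""
    coords, records = render_coordinates(params, gt)
    return universe_from_records(records, coords, params.box_xy, params.box_z)


def universe_from_records(records: list, coords: np.ndarray,
                          box_xy: float = 60.0, box_z: float = 100.0):
    """Assemble an in-memory universe from (chain, resid, resname, name, xyz) records.

    ``coords`` has shape (n_frames, n_atoms, 3) and overrides the record xyz.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n_atoms = len(records)

    # group atoms into residues (chain, resid) in record order
    res_keys: list[tuple] = []
    atom_resindex = []
    for chain, resid, resname, name, _ in records:
        key = (chain, resid, resname)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex.append(len(res_keys) - 1)
    seg_keys: list[str] = []
    res_segindex = []
    for chain, _, _ in res_keys:
        seg = chain if chain else "X"
        if seg not in seg_keys:
            seg_keys.append(seg)
        res_segindex.append(seg_keys.index(seg))

    u = mda.Universe.empty(
        n_atoms,
        n_residues=len(res_keys),
        n_segments=len(seg_keys),
        atom_resindex=np.asarray(atom_resindex),
        residue_segindex=np.asarray(res_segindex),
        trajectory=False,
    )
    u.add_TopologyAttr("names", [r[3] for r in records])
    u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
    u.add_TopologyAttr("resids", [k[1] for k in res_keys])
    u.add_TopologyAttr("segids", seg_keys)
    u.add_TopologyAttr("chainIDs", [res_keys[atom_resindex[i]][0] or "X"
                                    for i in range(n_atoms)])
    u.add_TopologyAttr("ids", np.arange(1, n_atoms + 1))
    # uniform masses: geometric (unweighted) superposition and centroids
    u.add_TopologyAttr("masses", np.ones(n_atoms))
    dims = np.tile(
        [box_xy, box_xy, box_z, 90.0, 90.0, 90.0],
        (len(coords), 1),
    ).astype(np.float32)
    u.load_new(coords.astype(np.float32), format=MemoryReader, dimensions=dims)
    return u
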
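"""Per-frame site assignment, occupancy-state encoding and conditional statistics.

A frame's filter occupancy is encoded as a 4-letter string over {K, N, W, O}
for sites S1..S4 (K = K+, N = NH4+, W = water, O = empty) — e.g. "KOKO" for
ions in S1 and S3.  Frames are additionally labelled by whether a Ca2+ ion is
bound below the filter (in the F87 slab), and occupancy statistics are
aggregated separately for Ca-bound and Ca-free frames, per voltage, which is
how the divalent block manifests in the filter statistics.

Assignment is geometric and memoryless per frame: a particle occupies an SF
site iff its axial coordinate lies in the site interval (lower-inclusive;
a particle exactly on a boundary plane resolves to the site above) and its
radial distance from the axis is below the SF cutoff.  NH4+ is located by its
nitrogen and water by its oxygen.  If two particles satisfy one site, the one
nearer the interval midpoint is recorded as the occupant and the rest go to
``extra_occupants``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import MDAnalysis as mda

from .pore import FrameGeometry, PoreSpec, frame_geometry

__all__ = [
    "SF_SITES",
    "ALL_SITES",
    "EMPTY",
    "STATE_LETTER",
    "FrameParticles",
    "SiteAssignment",
    "OccupancyTable",
    "extract_particles",
    "assign_frame",
    "encode_state",
    "label_ca_bound",
    "aggregate_occupancy",
    "assignments_to_frame",
]

SF_SITES: tuple[str, ...] = ("S1", "S2", "S3", "S4")
ALL_SITES: tuple[str, ...] = SF_SITES + ("Scav",)
EMPTY = "EMPTY"

#: species label → state-string letter
STATE_LETTER: Mapping[str, str] = {"K": "K", "NH4": "N", "WAT": "W", EMPTY: "O"}

#: species that may occupy the SF sites / Scav
_SITE_SPECIES = ("K", "NH4", "WAT")

# atom names accepted as the single reference point of a particle, per species
_POINT_ATOMS = {
    "K": ("K", "POT"),
    "NH4": ("N",),
    "CA": ("CA", "CAL"),
    "CL": ("CL", "CLA"),
    "WAT": ("O", "OW", "OH2"),
}


@dataclass(frozen=True)
class FrameParticles:
    """Point particles of one frame: ids, species labels and positions (Å)."""

    ids: np.ndarray          # (n,) int
    species: np.ndarray      # (n,) str
    positions: np.ndarray    # (n, 3) float
    frame_index: int = 0

    def __post_init__(self):
        n = len(self.ids)
        if len(self.species) != n or self.positions.shape != (n, 3):
            raise ValueError("ids, species and positions must have matching lengths")


@dataclass(frozen=True)
class SiteAssignment:
    """Mapping of particles to sites for one frame."""

    frame_index: int
    occupants: Mapping[str, str]            # site → species label or EMPTY
    occupant_ids: Mapping[str, int | None]  # site → particle id
    extra_occupants: tuple[tuple[str, int], ...]
    ca_f87_bound: bool
    ca_e92_bound: bool


def particle_atoms(u: mda.Universe, spec: PoreSpec) -> mda.AtomGroup:
    """The single reference atom of every ion/water particle in the universe."""
    groups = []
    for resname, species in spec.species_map.items():
        if species not in _POINT_ATOMS:
            continue
        names = " or ".join(f"name {n}" for n in _POINT_ATOMS[species])
        ag = u.select_atoms(f"resname {resname} and ({names})")
        if len(ag):
            groups.append(ag)
    if not groups:
        return u.atoms[[]]
    out = groups[0]
    for g in groups[1:]:
        out = out + g
    return out


def extract_particles(u: mda.Universe, spec: PoreSpec,
                      atoms: mda.AtomGroup | None = None,
                      frame_index: int | None = None) -> FrameParticles:
    """Snapshot the ion/water particles of the current frame.

    ``atoms`` may be passed to reuse the (frame-independent) selection from
    :func:`particle_atoms` across frames.
    """
    if atoms is None:
        atoms = particle_atoms(u, spec)
    species = np.array([spec.species_of(r) for r in atoms.resnames], dtype=object)
    return FrameParticles(
        ids=atoms.ids.astype(int),
        species=species,
        positions=atoms.positions.astype(float),
        frame_index=u.trajectory.frame if frame_index is None else frame_index,
    )


def assign_frame(particles: FrameParticles, geometry: FrameGeometry,
                 spec: PoreSpec) -> SiteAssignment:
    """Assign the frame's particles to S1..S4, Scav and the Ca2+ sites."""
    z = geometry.axial(particles.positions)
    r = geometry.radial(particles.positions)
    intervals = geometry.site_intervals

    occupants: dict[str, str] = {s: EMPTY for s in ALL_SITES}
    occupant_ids: dict[str, int | None] = {s: None for s in ALL_SITES}
    extras: list[tuple[str, int]] = []

    site_eligible = np.isin(particles.species, _SITE_SPECIES) & (r < spec.sf_radial_cutoff)
    for site in ALL_SITES:
        lo, hi = intervals[site]
        inside = site_eligible & (z >= lo) & (z < hi)
        idx = np.flatnonzero(inside)
        if idx.size == 0:
            continue
        mid = 0.5 * (lo + hi)
        # nearest to the interval midpoint wins; ties break on particle id
        order = np.lexsort((particles.ids[idx], np.abs(z[idx] - mid)))
        winner = idx[order[0]]
        occupants[site] = str(particles.species[winner])
        occupant_ids[site] = int(particles.ids[winner])
        extras.extend((site, int(particles.ids[idx[o]])) for o in order[1:])

    is_ca = particles.species == "CA"
    f_lo, f_hi = geometry.f87_interval
    ca_f87 = bool(np.any(is_ca & (z >= f_lo) & (z < f_hi) & (r < spec.f87_radial_cutoff)))

    ca_e92 = False
    if is_ca.any() and len(geometry.e92_oxygens):
        d = np.linalg.norm(
            particles.positions[is_ca, None, :] - geometry.e92_oxygens[None, :, :], axis=2
        )
        ca_e92 = bool((d < spec.e92_contact_cutoff).any())

    return SiteAssignment(
        frame_index=particles.frame_index,
        occupants=occupants,
        occupant_ids=occupant_ids,
        extra_occupants=tuple(extras),
        ca_f87_bound=ca_f87,
        ca_e92_bound=ca_e92,
    )


def encode_state(assignment: SiteAssignment) -> str:
    """4-letter occupancy code for S1..S4 (Scav excluded), e.g. 'KOKO'."""
    return "".join(STATE_LETTER.get(assignment.occupants[s], "O") for s in SF_SITES)


def label_ca_bound(assignments: Iterable[SiteAssignment]) -> np.ndarray:
    """Per-frame boolean labels: Ca2+ bound below the SF (F87 slab only).

    A Ca2+ at the E92 glutamate ring does not set the label — the conditional
    occupancy statistics condition only on the below-SF (F87) site.
    """
    return np.array([a.ca_f87_bound for a in assignments], dtype=bool)


@dataclass
class OccupancyTable:
    """Normalized occupancy statistics for one condition at one voltage."""

    voltage_mV: float
    condition: str                                   # "ca_bound" | "ca_free"
    n_frames: int
    site_fractions: dict[str, dict[str, float]]      # site → species/EMPTY → fraction
    state_frequencies: dict[str, float]              # 4-letter code → frequency

    def validate(self, tol: float = 1e-9) -> None:
        """Check the normalization invariants (fractions per site and state freqs sum to 1)."""
        if self.n_frames == 0:
            if self.site_fractions or self.state_frequencies:
                raise ValueError("empty table must carry no fractions")
            return
        for site, fr in self.site_fractions.items():
            total = sum(fr.values())
            if abs(total - 1.0) > tol:
                raise ValueError(f"site {site} fractions sum to {total!r}")
        total = sum(self.state_frequencies.values())
        if abs(total - 1.0) > tol:
            raise ValueError(f"state frequencies sum to {total!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"site": site, "species": sp, "fraction": f}
            for site, fr in self.site_fractions.items()
            for sp, f in fr.items()
        ]
        return pd.DataFrame(rows, columns=["site", "species", "fraction"])


def aggregate_occupancy(assignments: Sequence[SiteAssignment],
                        labels: Sequence[bool] | np.ndarray,
                        voltage_mV: float) -> tuple[OccupancyTable, OccupancyTable]:
    """Aggregate per-site and state-string statistics, split by the Ca-bound label.

    Returns ``(bound_table, free_table)``.  A condition that never occurs
    (e.g. Ca-bound frames at strongly negative voltage) yields an empty table
    with ``n_frames == 0``.
    """
    labels = np.asarray(labels, dtype=bool)
    if len(assignments) != len(labels):
        raise ValueError("assignments and labels must have equal length")
    if len(assignments) == 0:
        raise ValueError("cannot aggregate zero frames")

    def _table(sub: list[SiteAssignment], condition: str) -> OccupancyTable:
        if not sub:
            return OccupancyTable(voltage_mV, condition, 0, {}, {})
        n = len(sub)
        site_fractions: dict[str, dict[str, float]] = {}
        for site in ALL_SITES:
            counts: dict[str, int] = {}
            for a in sub:
                occ = a.occupants[site]
                counts[occ] = counts.get(occ, 0) + 1
            site_fractions[site] = {sp: c / n for sp, c in sorted(counts.items())}
        state_counts: dict[str, int] = {}
        for a in sub:
            code = encode_state(a)
            state_counts[code] = state_counts.get(code, 0) + 1
        state_frequencies = {c: k / n for c, k in sorted(state_counts.items())}
        return OccupancyTable(voltage_mV, condition, n, site_fractions, state_frequencies)

    bound = _table([a for a, l in zip(assignments, labels) if l], "ca_bound")
    free = _table([a for a, l in zip(assignments, labels) if not l], "ca_free")
    return bound, free


def assignments_to_frame(assignments: Sequence[SiteAssignment]) -> pd.DataFrame:
    """Per-frame state table (frame, code, ca_f87, ca_e92), TSV-ready."""
    return pd.DataFrame(
        {
            "frame": [a.frame_index for a in assignments],
            "code": [encode_state(a) for a in assignments],
            "ca_f87": [int(a.ca_f87_bound) for a in assignments],
            "ca_e92": [int(a.ca_e92_bound) for a in assignments],
        }
    )
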
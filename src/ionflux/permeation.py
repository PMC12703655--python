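"""Permeation-event detection and single-channel current estimation.

Events are full pore transits detected with a three-compartment scheme on each
ion's axial trace (relative to the T59 reference): INTRA below the F87 ring
plane, FILTER between the F87 and G63 planes, EXTRA above the G63 plane.  An
outward event is the ordered visit INTRA→FILTER→EXTRA by one ion without
returning to INTRA in between; inward is the mirror image.  Incomplete
excursions count nothing.  Using the full F87→G63 span (rather than the S4/S1
planes) makes events insensitive to shuttling between filter sites.

Periodic-boundary handling: per-frame displacements with \\|Δz\\| > box_z/2 are
treated as wraps and the trace is unwrapped before compartment logic; in the
unwrapped coordinate the compartments repeat with period box_z, with the bulk
region split into EXTRA (adjacent to G63) and INTRA (adjacent to F87 of the
next periodic image) at its midplane.  A bulk-side crossing of that midplane —
which is what a wrap is — is therefore never an event.

The applied-field voltage convention is V = E_z · L_z (mV), positive voltage
driving cations outward (+z); current is net outward elementary charges per
simulation time, reported in pA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pore import FrameGeometry

__all__ = [
    "ELEMENTARY_CHARGE_C",
    "PermeationEvent",
    "FieldSpec",
    "CurrentEstimate",
    "detect_events",
    "voltage_from_field",
    "compute_current",
    "rectification_ratio",
    "INTRA",
    "FILTER",
    "EXTRA",
]

ELEMENTARY_CHARGE_C = 1.602176634e-19

INTRA, FILTER, EXTRA = -1, 0, 1


@dataclass(frozen=True)
class PermeationEvent:
    """One completed directional crossing of the filter by one ion."""

    particle_id: int
    direction: int            # +1 outward, -1 inward
    entry_frame: int
    exit_frame: int
    species: str = "K"

    def __post_init__(self):
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 (outward) or -1 (inward)")
        if not self.entry_frame < self.exit_frame:
            raise ValueError("entry_frame must precede exit_frame")


@dataclass(frozen=True)
class FieldSpec:
    """Uniform applied electric field along z and the box height it acts over."""

    E_z: float    # mV/Å, sign along +z
    box_z: float  # Å

    def __post_init__(self):
        if self.box_z <= 0:
            raise ValueError("box_z must be positive")


@dataclass(frozen=True)
class CurrentEstimate:
    n_outward: int
    n_inward: int
    sim_time_ns: float
    voltage_mV: float
    current_pA: float


def voltage_from_field(field: FieldSpec) -> float:
    """Transmembrane voltage in mV: V = E_z × box_z (positive drives cations out)."""
    return field.E_z * field.box_z


def unwrap_trace(z: np.ndarray, box_z: float) -> np.ndarray:
    """Undo periodic wraps: displacements with \\|Δz\\| > box_z/2 are wraps."""
    z = np.asarray(z, dtype=float)
    if z.size < 2:
        return z.copy()
    d = np.diff(z)
    d -= box_z * np.round(d / box_z)
    return np.concatenate(([z[0]], z[0] + np.cumsum(d)))


def _compartments(z_unwrapped: np.ndarray, lower: np.ndarray | float,
                  upper: np.ndarray | float, box_z: float) -> np.ndarray:
    """Classify axial positions into INTRA/FILTER/EXTRA, periodic in box_z."""
    lower = np.broadcast_to(np.asarray(lower, dtype=float), z_unwrapped.shape)
    upper = np.broadcast_to(np.asarray(upper, dtype=float), z_unwrapped.shape)
    zr = lower + np.mod(z_unwrapped - lower, box_z)
    bulk_mid = 0.5 * (upper + lower + box_z)
    out = np.full(z_unwrapped.shape, INTRA, dtype=int)
    out[zr < bulk_mid] = EXTRA
    out[zr < upper] = FILTER
    return out


def detect_events(axial_traces: Mapping[int, np.ndarray],
                  geometry: "FrameGeometry | Iterable[FrameGeometry] | tuple[float, float]",
                  box_z: float,
                  species: Mapping[int, str] | str = "K",
                  frame_indices: Sequence[int] | None = None) -> list[PermeationEvent]:
    """Detect completed permeation events from per-ion axial traces.

    Parameters
    ----------
    axial_traces
        Mapping particle id → axial coordinates (Å, relative to the T59
        reference), one value per frame, evenly spaced frames.
    geometry
        A single :class:`FrameGeometry`, a per-frame iterable of them, or a
        plain ``(f87_plane, g63_plane)`` tuple of axial coordinates.
    box_z
        Periodic box height along the pore axis, Å.
    species
        Species label per particle id, or one label for all.
    frame_indices
        Optional explicit frame numbering; must be strictly increasing.
    """
    lower, upper = _planes_from_geometry(geometry)
    events: list[PermeationEvent] = []
    for pid in sorted(axial_traces):
        z = np.asarray(axial_traces[pid], dtype=float)
        if frame_indices is not None:
            frames = np.asarray(frame_indices, dtype=int)
            if len(frames) != len(z):
                raise ValueError("frame_indices length does not match trace length")
            if np.any(np.diff(frames) <= 0):
                raise ValueError("frame indices must be strictly increasing")
        else:
            frames = np.arange(len(z))
        # The compartment map is periodic in box_z, so classifying the raw
        # coordinates is exactly equivalent to unwrapping first (and avoids
        # accumulating floating-point error along the trace); a wrap jump
        # lands in the opposite bulk compartment without touching FILTER and
        # therefore never creates an event.
        comps = _compartments(z, lower, upper, box_z)
        sp = species if isinstance(species, str) else species.get(pid, "K")
        events.extend(_scan_compartments(comps, frames, pid, sp))
    events.sort(key=lambda e: (e.exit_frame, e.entry_frame, e.particle_id))
    return events


def _planes_from_geometry(geometry) -> tuple[np.ndarray | float, np.ndarray | float]:
    if isinstance(geometry, FrameGeometry):
        return geometry.f87_plane, geometry.g63_plane
    if isinstance(geometry, tuple) and len(geometry) == 2 and np.isscalar(geometry[0]):
        return float(geometry[0]), float(geometry[1])
    geoms = list(geometry)
    return (np.array([g.f87_plane for g in geoms]),
            np.array([g.g63_plane for g in geoms]))


def _scan_compartments(comps: np.ndarray, frames: np.ndarray,
                       pid: int, species: str) -> list[PermeationEvent]:
    """Finite-state scan: bulk origin + filter passage → event on opposite bulk."""
    events = []
    origin = None          # last bulk compartment visited
    filter_entry = None    # frame at which the filter was entered from `origin`
    prev = None
    for c, f in zip(comps, frames):
        if c == FILTER:
            if prev != FILTER:
                filter_entry = int(f)
            prev = c
            continue
        # c is a bulk compartment
        if origin is not None and c != origin and prev == FILTER:
            events.append(PermeationEvent(
                particle_id=pid,
                direction=+1 if origin == INTRA else -1,
                entry_frame=filter_entry if filter_entry is not None else int(f) - 1,
                exit_frame=int(f),
                species=species,
            ))
        origin = c
        filter_entry = None
        prev = c
    return events


def compute_current(events: Sequence[PermeationEvent], sim_time_ns: float,
                    voltage_mV: float = 0.0) -> CurrentEstimate:
    """Net single-channel current from event counts.

    current [pA] = (n_outward − n_inward) × e / sim_time, with e the elementary
    charge (monovalent permeant ions); positive sign is net outward flow.
    """
    if sim_time_ns <= 0:
        raise ValueError("sim_time_ns must be positive")
    n_out = sum(1 for e in events if e.direction == +1)
    n_in = sum(1 for e in events if e.direction == -1)
    current = (n_out - n_in) * ELEMENTARY_CHARGE_C / (sim_time_ns * 1e-9) * 1e12
    return CurrentEstimate(n_out, n_in, float(sim_time_ns), float(voltage_mV), current)


def rectification_ratio(current_pos: float, current_neg: float) -> float:
    """Inward-rectification ratio \\|I(−V)\\|/\\|I(+V)\\| at equal \\|V\\|.

    Returns ``math.inf`` (flagged perfect inward rectifier) if I(+V) = 0 with
    I(−V) ≠ 0, and ``math.nan`` (undefined) if both currents are zero.
    """
    if current_pos == 0.0:
        return math.nan if current_neg == 0.0 else math.inf
    return abs(current_neg) / abs(current_pos)
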
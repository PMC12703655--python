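"""Axial density profiles, F97 gate distances and RMSD/RMSF flexibility metrics.

Densities are binned along the pore axis relative to the T59 reference (the
same frame used for site assignment), inside a cylinder around the axis, which
is how the sharp Ca2+ peak at the F87 ring plane and the broader E92-ring
density below it are resolved.  Both a raw-count and a per-frame-mean
normalization are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import MDAnalysis as mda
from MDAnalysis.analysis import align, rms

from .pore import PoreSpec, frame_geometry
from .occupancy import extract_particles, particle_atoms

__all__ = [
    "DensityProfile",
    "GateMetric",
    "FlexibilityMetric",
    "axial_density",
    "gate_distance",
    "rmsd_rmsf",
]

DEFAULT_SPECIES = ("K", "NH4", "CA", "CL", "WAT")


@dataclass
class DensityProfile:
    """Binned axial number density of each species relative to the T59 reference."""

    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]      # species → raw counts per bin
    frames: int
    radial_cutoff: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def per_frame_mean(self) -> dict[str, np.ndarray]:
        """Counts divided by the number of frames (mean occupancy per bin)."""
        return {sp: c / self.frames for sp, c in self.counts.items()}

    def total_mass(self, species: str) -> float:
        """Per-frame-mean histogram mass = mean in-region particle count."""
        return float(self.counts[species].sum()) / self.frames

    def to_frame(self, normalization: str = "per-frame-mean") -> pd.DataFrame:
        if normalization not in ("raw-count", "per-frame-mean"):
            raise ValueError("normalization must be 'raw-count' or 'per-frame-mean'")
        data = self.counts if normalization == "raw-count" else self.per_frame_mean
        out = pd.DataFrame({"bin_center": self.bin_centers})
        for sp, c in data.items():
            out[sp] = c
        return out


@dataclass
class GateMetric:
    """Cross-pore distances between opposing F97 Cα atoms (the lower gate)."""

    diagonal_ac: np.ndarray   # per-frame, chains[0]–chains[2]
    diagonal_bd: np.ndarray   # per-frame, chains[1]–chains[3]

    @property
    def mean_per_frame(self) -> np.ndarray:
        return 0.5 * (self.diagonal_ac + self.diagonal_bd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.diagonal_ac)),
            "diagonal_ac": self.diagonal_ac,
            "diagonal_bd": self.diagonal_bd,
            "mean": self.mean_per_frame,
        })


@dataclass
class FlexibilityMetric:
    """RMSD time series against a reference and per-atom/per-residue RMSF."""

    rmsd: np.ndarray                   # Å per frame, over `selection` after fitting
    rmsf_atoms: np.ndarray             # Å per selected atom
    rmsf_residues: pd.DataFrame        # columns: segid, resid, rmsf


def axial_density(u: mda.Universe, spec: PoreSpec,
                  species: Sequence[str] = DEFAULT_SPECIES,
                  radial_cutoff: float = 8.0,
                  bin_width: float = 0.5,
                  z_range: tuple[float, float] = (-25.0, 5.0)) -> DensityProfile:
    """Histogram species positions along the axis, within a cylinder.

    Per frame, particles of each species with radial distance below
    ``radial_cutoff`` and axial coordinate (relative to T59) in ``z_range``
    are binned with uniform ``bin_width``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    z0, z1 = map(float, z_range)
    if not z1 > z0:
        raise ValueError(f"empty z_range: {z_range}")
    n_bins = max(1, int(round((z1 - z0) / bin_width)))
    edges = z0 + bin_width * np.arange(n_bins + 1)

    atoms = particle_atoms(u, spec)
    counts = {sp: np.zeros(n_bins) for sp in species}
    n_frames = 0
    for ts in u.trajectory:
        geom = frame_geometry(u, spec)
        parts = extract_particles(u, spec, atoms=atoms)
        z = geom.axial(parts.positions)
        r = geom.radial(parts.positions)
        keep = (r < radial_cutoff) & (z >= edges[0]) & (z < edges[-1])
        for sp in species:
            sel = keep & (parts.species == sp)
            if sel.any():
                hist, _ = np.histogram(z[sel], bins=edges)
                counts[sp] += hist
        n_frames += 1
    if n_frames == 0:
        raise ValueError("trajectory has no frames")
    return DensityProfile(bin_edges=edges, counts=counts, frames=n_frames,
                          radial_cutoff=radial_cutoff)


def gate_distance(u: mda.Universe, spec: PoreSpec) -> GateMetric:
    """Per-frame distances between the two opposing F97 Cα pairs.

    The pairs are the cross-pore diagonals: chains[0]–chains[2] and
    chains[1]–chains[3] of the spec's chain ordering.
    """
    if len(spec.chains) < 4:
        raise ValueError("gate distance requires F97 Cα in at least 4 chains")
    cas = []
    for chain in spec.chains[:4]:
        ag = u.select_atoms(f"segid {chain} and resid {spec.f97_resid} and name CA")
        if len(ag) != 1:
            raise ValueError(f"F97 CA not found uniquely in chain {chain}")
        cas.append(ag)
    d_ac, d_bd = [], []
    for ts in u.trajectory:
        d_ac.append(np.linalg.norm(cas[0].positions[0] - cas[2].positions[0]))
        d_bd.append(np.linalg.norm(cas[1].positions[0] - cas[3].positions[0]))
    return GateMetric(diagonal_ac=np.asarray(d_ac), diagonal_bd=np.asarray(d_bd))


def rmsd_rmsf(u: mda.Universe, reference: mda.Universe,
              selection: str = "protein",
              fit_selection: str | None = None) -> FlexibilityMetric:
    """Rigid-body-fitted RMSD per frame and RMSF about the time-averaged structure.

    Every frame is superposed onto the reference on ``fit_selection``
    (default: ``selection``), then the RMSD over ``selection`` is recorded.
    For the RMSF, the trajectory is aligned to its own time-averaged
    structure and the per-atom root-mean-square deviation from that average
    is computed, then aggregated per residue (RMS over the residue's atoms).
    """
    fit_selection = fit_selection or selection
    sel = u.select_atoms(selection)
    if len(sel) == 0:
        raise ValueError(f"empty selection: {selection!r}")
    if len(u.select_atoms(fit_selection)) == 0:
        raise ValueError(f"empty fit selection: {fit_selection!r}")
    if len(reference.select_atoms(selection)) != len(sel):
        raise ValueError("selection atom count differs between trajectory and reference")

    r = rms.RMSD(u, reference, select=fit_selection, groupselections=[selection])
    r.run()
    rmsd_series = r.results.rmsd[:, 3]

    # work on an in-memory copy so the caller's trajectory is not re-aligned
    u2 = _memory_copy(u)
    avg = align.AverageStructure(u2, select=fit_selection).run()
    align.AlignTraj(u2, avg.results.universe, select=fit_selection, in_memory=True).run()
    sel2 = u2.select_atoms(selection)
    rmsf = rms.RMSF(sel2).run().results.rmsf

    df = pd.DataFrame({
        "segid": sel2.segids,
        "resid": sel2.resids,
        "sq": rmsf ** 2,
    })
    per_res = (
        df.groupby(["segid", "resid"], sort=True)["sq"].mean().pow(0.5)
        .rename("rmsf").reset_index()
    )
    return FlexibilityMetric(rmsd=rmsd_series, rmsf_atoms=rmsf, rmsf_residues=per_res)


def _memory_copy(u: mda.Universe) -> mda.Universe:
    from MDAnalysis.coordinates.memory import MemoryReader

    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=np.float32)
    u2 = mda.Merge(u.atoms)
    u2.load_new(coords, format=MemoryReader)
    return u2
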
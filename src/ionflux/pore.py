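"""Pore geometry: channel parsing, pore axis and selectivity-filter site planes.

The selectivity filter (SF) of a K+ channel is the TVGYG backbone stretch whose
carbonyl oxygens form four stacked ion-coordination cages, S1 (extracellular-most)
to S4, with the cavity site Scav just below.  All site boundaries here are rings
of symmetry-equivalent oxygen atoms:

========  =======================================
plane     atoms (one per chain)
========  =======================================
G63       Gly63 backbone O      (top of S1)
Y62       Tyr62 backbone O      (S1/S2 boundary)
G61       Gly61 backbone O      (S2/S3 boundary)
V60       Val60 backbone O      (S3/S4... bottom of S3)
T59O      Thr59 backbone O      (top of S4)
T59OG1    Thr59 side-chain OG1  (bottom of S4)
F87       Phe87 aromatic-ring centroids (bottom of Scav)
========  =======================================

Axial coordinates are reported relative to the centroid of the four T59
carbonyl oxygens, with +z pointing extracellular.  Two auxiliary Ca2+ binding
regions are defined below the filter: a slab between the F87 ring plane and the
T59-OG1 plane (radial cutoff from the axis), and a contact region around the
E92 glutamate carboxylate oxygens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import MDAnalysis as mda

__all__ = [
    "PoreSpec",
    "FrameGeometry",
    "PoreGeometryError",
    "load_pore_spec",
    "frame_geometry",
    "geometry_from_rings",
    "geometry_stream",
    "DEFAULT_SPECIES_MAP",
]

#: residue-name → species label used throughout the package
DEFAULT_SPECIES_MAP: dict[str, str] = {
    "K": "K",
    "POT": "K",
    "NH4": "NH4",
    "CA": "CA",
    "CAL": "CA",
    "CA2": "CA",
    "CL": "CL",
    "CLA": "CL",
    "HOH": "WAT",
    "SOL": "WAT",
    "WAT": "WAT",
    "TIP3": "WAT",
}

_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

#: default SF residue numbering (MthK pore domain): T59 V60 G61 Y62 G63
DEFAULT_SF_RESIDS = (59, 60, 61, 62, 63)
DEFAULT_SF_RESNAMES = ("THR", "VAL", "GLY", "TYR", "GLY")

_F87_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


class PoreGeometryError(ValueError):
    """Raised when the structure does not support a valid pore geometry."""


@dataclass(frozen=True)
class PoreSpec:
    """Validated description of the pore: residues, chains, species and cutoffs."""

    chains: tuple[str, ...] = ("A", "B", "C", "D")
    sf_resids: tuple[int, ...] = DEFAULT_SF_RESIDS
    sf_resnames: tuple[str, ...] = DEFAULT_SF_RESNAMES
    f87_resid: int = 87
    e92_resid: int = 92
    e96_resid: int = 96
    f97_resid: int = 97
    species_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SPECIES_MAP))
    sf_radial_cutoff: float = 3.5
    f87_radial_cutoff: float = 5.0
    e92_contact_cutoff: float = 4.5

    def __post_init__(self) -> None:
        if len(self.sf_resids) != 5 or len(self.sf_resnames) != 5:
            raise ValueError("sf_resids/sf_resnames must list exactly 5 residues per chain")
        if len(self.chains) < 3:
            raise ValueError(f"need at least 3 chains, got {len(self.chains)}")
        for cutoff in (self.sf_radial_cutoff, self.f87_radial_cutoff, self.e92_contact_cutoff):
            if cutoff <= 0:
                raise ValueError("radial/contact cutoffs must be positive")

    @property
    def chain_count(self) -> int:
        return len(self.chains)

    def species_of(self, resname: str) -> str:
        """Map a residue name to a species label; unknown names map to 'other'."""
        return self.species_map.get(resname.strip(), "other")

    def sf_label(self, index: int) -> str:
        """One-letter + resid label for SF residue *index* (0-based), e.g. 'G61'."""
        return _ONE_LETTER.get(self.sf_resnames[index], "X") + str(self.sf_resids[index])


@dataclass(frozen=True)
class FrameGeometry:
    """Per-frame pore axis, site boundary planes and Ca2+-site definitions.

    Plane coordinates are axial positions in Å relative to ``axis_origin``
    (the T59 carbonyl-oxygen ring centroid), increasing toward the
    extracellular side.
    """

    axis_origin: np.ndarray
    axis_direction: np.ndarray
    plane_z: Mapping[str, float]          # G63, Y62, G61, V60, T59O, T59OG1, F87
    sf_radial_cutoff: float
    f87_radial_cutoff: float
    e92_contact_cutoff: float
    e92_oxygens: np.ndarray               # absolute coordinates, shape (n, 3)

    #: sites bounded as (lower, upper) axial coordinates
    @property
    def site_intervals(self) -> dict[str, tuple[float, float]]:
        p = self.plane_z
        return {
            "S1": (p["Y62"], p["G63"]),
            "S2": (p["G61"], p["Y62"]),
            "S3": (p["V60"], p["G61"]),
            "S4": (p["T59OG1"], p["T59O"]),
            "Scav": (p["F87"], p["T59OG1"]),
        }

    @property
    def f87_interval(self) -> tuple[float, float]:
        return (self.plane_z["F87"], self.plane_z["T59OG1"])

    @property
    def g63_plane(self) -> float:
        return self.plane_z["G63"]

    @property
    def f87_plane(self) -> float:
        return self.plane_z["F87"]

    def axial(self, positions: np.ndarray) -> np.ndarray:
        """Axial coordinate(s) relative to the T59 reference, in Å."""
        return np.atleast_2d(positions - self.axis_origin) @ self.axis_direction

    def radial(self, positions: np.ndarray) -> np.ndarray:
        """Distance(s) from the pore axis, in Å."""
        rel = np.atleast_2d(positions - self.axis_origin)
        z = rel @ self.axis_direction
        perp = rel - np.outer(z, self.axis_direction)
        return np.linalg.norm(perp, axis=1)


def load_pore_spec(topology_path, config: Mapping | None = None) -> PoreSpec:
    """Parse the channel topology and return a validated :class:`PoreSpec`.

    ``config`` may override ``chains``, ``sf_resids``, ``sf_resnames``, the
    auxiliary residue numbers, ``species_map`` and the cutoffs.  Every SF
    residue must be present (with its backbone O, plus OG1 for the threonine)
    in every chain; a missing residue is a hard error naming residue and
    chain.  A three-chain channel is accepted with a warning.
    """
    config = dict(config or {})
    u = mda.Universe(str(topology_path))
    segids = _chain_ids(u)

    chains = tuple(config.get("chains") or ())
    if not chains:
        # auto-detect: chains that contain the first SF residue
        sf_resids = tuple(config.get("sf_resids", DEFAULT_SF_RESIDS))
        chains = tuple(
            c for c in segids
            if len(u.select_atoms(f"segid {c} and resid {sf_resids[0]}")) > 0
        )
    if len(chains) < 3:
        raise PoreGeometryError(
            f"found only {len(chains)} chain(s) with SF residues; at least 3 required"
        )
    if len(chains) != 4:
        warnings.warn(
            f"channel has {len(chains)} chains (tetramer expected); proceeding",
            stacklevel=2,
        )

    kwargs = {
        "chains": chains,
        "sf_resids": tuple(config.get("sf_resids", DEFAULT_SF_RESIDS)),
        "sf_resnames": tuple(config.get("sf_resnames", DEFAULT_SF_RESNAMES)),
    }
    for key in ("f87_resid", "e92_resid", "e96_resid", "f97_resid",
                "sf_radial_cutoff", "f87_radial_cutoff", "e92_contact_cutoff"):
        if key in config:
            kwargs[key] = config[key]
    species_map = dict(DEFAULT_SPECIES_MAP)
    species_map.update(config.get("species_map", {}))
    spec = PoreSpec(species_map=species_map, **kwargs)

    # validate SF residues chain by chain
    for chain in spec.chains:
        for i, (resid, resname) in enumerate(zip(spec.sf_resids, spec.sf_resnames)):
            res = u.select_atoms(f"segid {chain} and resid {resid}")
            if len(res) == 0:
                raise PoreGeometryError(
                    f"SF residue {spec.sf_label(i)} missing in chain {chain}"
                )
            names = set(res.names)
            if "O" not in names:
                raise PoreGeometryError(
                    f"SF residue {spec.sf_label(i)} in chain {chain} lacks a backbone O"
                )
            if i == 0 and "OG1" not in names:
                raise PoreGeometryError(
                    f"SF residue {spec.sf_label(0)} in chain {chain} lacks OG1"
                )
    return spec


def _chain_ids(u: mda.Universe) -> list[str]:
    try:
        ids = list(dict.fromkeys(u.atoms.chainIDs))
    except (AttributeError, mda.exceptions.NoDataError):
        ids = []
    if not ids or set(ids) == {""}:
        ids = list(dict.fromkeys(u.atoms.segids))
    return [i for i in ids if i.strip()]


class _RingSelections:
    """Frame-independent atom selections for the geometry rings (built once)."""

    def __init__(self, u: mda.Universe, spec: PoreSpec):
        t59, v60, g61, y62, g63 = spec.sf_resids
        self.rings: dict[str, list[mda.AtomGroup]] = {
            "G63": self._per_chain(u, spec, g63, ("O",), "G63-O"),
            "Y62": self._per_chain(u, spec, y62, ("O",), "Y62-O"),
            "G61": self._per_chain(u, spec, g61, ("O",), "G61-O"),
            "V60": self._per_chain(u, spec, v60, ("O",), "V60-O"),
            "T59O": self._per_chain(u, spec, t59, ("O",), "T59-O"),
            "T59OG1": self._per_chain(u, spec, t59, ("OG1",), "T59-OG1"),
        }
        self.f87 = self._per_chain(u, spec, spec.f87_resid, _F87_RING_ATOMS,
                                   "F87-ring")
        self.e92 = u.select_atoms(
            "resid {} and (name OE1 or name OE2) and ({})".format(
                spec.e92_resid, " or ".join(f"segid {c}" for c in spec.chains)
            )
        )

    @staticmethod
    def _per_chain(u, spec, resid, names, what) -> list[mda.AtomGroup]:
        name_sel = " or ".join(f"name {n}" for n in names)
        groups = []
        for chain in spec.chains:
            ag = u.select_atoms(f"segid {chain} and resid {resid} and ({name_sel})")
            if len(ag):
                groups.append(ag)
        if len(groups) < 3:
            raise PoreGeometryError(
                f"fewer than 3 chains contribute to the {what} ring ({len(groups)} found)"
            )
        return groups

    def ring_positions(self, name: str) -> np.ndarray:
        return np.asarray([g.positions.mean(axis=0) for g in self.rings[name]])

    def f87_centroids(self) -> np.ndarray:
        return np.asarray([g.positions.mean(axis=0) for g in self.f87])


def _selections(u: mda.Universe, spec: PoreSpec) -> _RingSelections:
    key = (spec.chains, spec.sf_resids, spec.f87_resid, spec.e92_resid)
    cache = getattr(u, "_ionflux_ring_cache", None)
    if cache is None:
        cache = {}
        try:
            u._ionflux_ring_cache = cache
        except AttributeError:
            pass
    sel = cache.get(key)
    if sel is None:
        sel = cache[key] = _RingSelections(u, spec)
    return sel


def frame_geometry(u: mda.Universe, spec: PoreSpec) -> FrameGeometry:
    """Compute the pore axis and site planes for the current trajectory frame.

    The axis is the principal axis of the SF boundary-oxygen set (robust to
    channel tilt; no global alignment needed), signed so that the Y62 ring lies
    extracellular of the T59 carbonyl ring.  The origin is the T59
    carbonyl-oxygen ring centroid, recomputed every frame.  Boundary planes are
    the mean axial positions of the symmetry-equivalent oxygen rings; the F87
    plane is the mean axial position of the per-chain aromatic-ring centroids.

    Raises :class:`PoreGeometryError` if any ring has fewer than 3 chains or if
    the planes are not strictly ordered along the axis.
    """
    sel = _selections(u, spec)
    rings = {name: sel.ring_positions(name) for name in sel.rings}
    return geometry_from_rings(rings, sel.f87_centroids(),
                               sel.e92.positions.copy(), spec)


def geometry_from_rings(rings: Mapping[str, np.ndarray],
                        f87_centroids: np.ndarray,
                        e92_oxygens: np.ndarray,
                        spec: PoreSpec) -> FrameGeometry:
    """Pure-geometry core of :func:`frame_geometry`, on raw ring coordinates.

    ``rings`` maps G63/Y62/G61/V60/T59O/T59OG1 to (n_chains, 3) arrays of
    boundary-oxygen positions; computations are done in double precision.
    """
    rings = {k: np.asarray(v, dtype=float) for k, v in rings.items()}
    f87_centroids = np.asarray(f87_centroids, dtype=float)

    all_ring_atoms = np.vstack(list(rings.values()))
    axis = _principal_axis(all_ring_atoms)
    origin = rings["T59O"].mean(axis=0)
    # sign: +z toward extracellular (Y62 above T59)
    if (rings["Y62"].mean(axis=0) - origin) @ axis < 0:
        axis = -axis

    plane_z = {name: float(np.mean((ring - origin) @ axis))
               for name, ring in rings.items()}
    plane_z["F87"] = float(np.mean((f87_centroids - origin) @ axis))

    ordered = [plane_z[k] for k in ("G63", "Y62", "G61", "V60", "T59O", "T59OG1", "F87")]
    if not all(a > b for a, b in zip(ordered, ordered[1:])):
        raise PoreGeometryError(
            "site boundary planes are not strictly ordered along the pore axis: "
            + ", ".join(f"{k}={plane_z[k]:.2f}" for k in plane_z)
        )

    return FrameGeometry(
        axis_origin=origin,
        axis_direction=axis,
        plane_z=plane_z,
        sf_radial_cutoff=spec.sf_radial_cutoff,
        f87_radial_cutoff=spec.f87_radial_cutoff,
        e92_contact_cutoff=spec.e92_contact_cutoff,
        e92_oxygens=np.asarray(e92_oxygens, dtype=float),
    )


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered
    eigval, eigvec = np.linalg.eigh(cov)
    return eigvec[:, np.argmax(eigval)]


def geometry_stream(u: mda.Universe, spec: PoreSpec) -> Iterator[FrameGeometry]:
    """Yield a :class:`FrameGeometry` for every frame of the trajectory."""
    for _ in u.trajectory:
        yield frame_geometry(u, spec)
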
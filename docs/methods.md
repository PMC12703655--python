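# Methods

## Scope

`ionflux` post-processes ion-channel pore trajectories — a tetrameric K⁺
channel with the TVGYG selectivity filter (SF), modelled on the MthK pore
domain numbering (T59…G63, with F87, E92, E96, F97 below the filter) — and
quantifies:

* per-frame occupancy of the SF sites S1–S4 and the cavity site S~cav~,
  encoded as 4-letter state strings over {K, N, W, O};
* Ca²⁺ binding below the filter (the F87 site) and at the E92 glutamate
  ring, and occupancy statistics conditioned on the below-SF Ca²⁺ state;
* completed permeation events and the single-channel current under an
  applied-field voltage V = E_z·L_z;
* axial number-density profiles relative to the T59 reference, F97 Cα gate
  distances, and RMSD/RMSF flexibility metrics.

A kinetic ion-hopping generator supplies synthetic trajectories with exact
ground truth so every estimator can be validated end to end.

## Pore geometry

All site definitions are built per frame from rings of symmetry-equivalent
oxygen atoms, so no global trajectory alignment is needed:

* **Axis** — the principal axis of the SF boundary-oxygen set (all six rings
  pooled), signed so that the Y62 carbonyl ring lies extracellular (+z) of
  the T59 carbonyl ring. The instantaneous principal axis is robust to
  channel tilt.
* **Origin** — the centroid of the four T59 carbonyl oxygens. All axial
  coordinates ("relative to T59") are measured from here.
* **Boundary planes** — mean axial positions of the G63-O, Y62-O, G61-O,
  V60-O, T59-O and T59-OG1 rings, plus the plane of the four F87
  aromatic-ring centroids. Sites: S1 = [Y62, G63], S2 = [G61, Y62],
  S3 = [V60, G61], S4 = [T59-OG1, T59-O], S~cav~ = [F87, T59-OG1]. The S4
  lower bound uses the threonine side-chain hydroxyl ring, the standard
  K-channel convention.
* **Ca²⁺ sites** — the F87 site is the axial slab between the F87 ring plane
  and the T59-OG1 plane with a 5.0 Å radial cutoff from the axis (the site
  sits "just below" S~cav~; axially the two slabs coincide and are told apart
  by species). The E92 site is a contact criterion: any position within
  4.5 Å of an E92 carboxylate oxygen, because the glutamate-ring density is
  broad rather than slab-like.
* A violated plane ordering (e.g. a scrambled ring) raises an error; it is
  never silently reordered. Each frame is treated independently (no
  smoothing of planes).

The geometry arithmetic lives in a double-precision core
(`geometry_from_rings`); the trajectory wrapper reads coordinates through
MDAnalysis, whose float32 storage bounds the attainable precision of the
file pathway at roughly 10⁻⁵ Å for coordinates of this magnitude.

## Site assignment and state strings

Assignment is geometric and memoryless per frame: a K⁺/NH₄⁺/water particle
occupies an SF site iff its axial coordinate lies in the site interval
(boundary ties resolve to the extracellular site — deterministic and
measure-zero) and its distance from the axis is below the SF radial cutoff
(default 3.5 Å: wide enough to accept coordinated ions, narrow enough to
reject cavity ions). NH₄⁺ is located by its nitrogen, water by its oxygen.
When two particles satisfy one site, the one nearer the interval midpoint is
the occupant; the rest are recorded as `extra_occupants` (never observed
under the generator's exclusion, which the tests assert). Hysteresis belongs
to event detection, not to occupancy — this matches how occupancy histograms
are normally built.

Frames are labelled Ca-bound by the F87 site only; a Ca²⁺ at the glutamate
ring does not set the label, because the conditional statistics of interest
concern the below-SF blocking site. No dwell-time filter is applied to
transient F87 visits. S~cav~ is reported in the tables but excluded from the
4-letter code.

## Permeation events and current

Events use three compartments on each ion's axial trace: INTRA below the F87
ring plane, FILTER between the F87 and G63 planes (so an event is a full
pore transit, insensitive to SF-internal shuttling), EXTRA above G63. An
outward event is the ordered visit INTRA→FILTER→EXTRA with no intervening
return to INTRA; inward is the mirror; incomplete excursions count nothing;
no minimum dwell is required to commit an event (the full-traversal
requirement already provides the hysteresis).

The compartment map is periodic in the box height, with the bulk region
split at its midplane into EXTRA (adjacent to G63) and INTRA (adjacent to
the next periodic image of F87). Classifying raw coordinates through this
periodic map is exactly equivalent to unwrapping jumps larger than half the
box first, and avoids accumulating floating-point error along the trace; a
periodic wrap lands in the opposite bulk compartment without touching
FILTER and therefore can never fabricate an event.

Current is net outward elementary charges per unit time,
I [pA] = (n_out − n_in)·e / T, for monovalent permeant ions; the voltage
convention is V = E_z·L_z with positive V driving cations outward. The
inward-rectification ratio is |I(−V)|/|I(+V)|, flagged infinite for a
perfect inward rectifier and undefined when both currents vanish.

## Profiles and flexibility

Densities are per-frame histograms of axial position (relative to T59)
inside a cylinder. Defaults: radius 8 Å and z ∈ [−25, +5] Å, covering
S~cav~, F87 and E92; bin width 0.5 Å, fine enough to separate the sharp F87
peak from the broad E92 ring density. Both raw counts and per-frame means
are available since the appropriate normalization depends on use. Gate
distance is the two cross-pore F97 Cα diagonals (chains A–C and B–D) per
frame. RMSD superposes each frame on a fit selection; RMSF aligns the
trajectory to its own time average and reports per-atom and per-residue
(RMS over atoms) fluctuation; the pipeline default fits on the SF backbone,
the stable part of the structure.

## The kinetic generator

The generator replaces MD production, not the analysis: it is a
continuous-time Markov chain (exact stochastic simulation, direct method)
of single-file hops over

    bulk_in ↔ E92 ↔ S_cav ↔ S4 ↔ S3 ↔ S2 ↔ S1 ↔ bulk_out

with per-site exclusion, plus two Ca²⁺-only sites (F87, E92 ring) bound
from the intracellular bulk, and a bulk_out↔bulk_in exchange hop standing in
for the periodic boundary (rendered as a >L_z/2 coordinate jump, exercising
the detector's wrap handling). Hop rates follow a symmetric-barrier rule
k = A·exp(−ΔU/2kT)·exp(±qVδ/2kT): ΔU collects per-site energies, a
nearest-neighbour repulsion u between ions in adjacent SF sites, and the
Ca-coupling below; δ is the hop's fraction of the transmembrane voltage
drop (uniform 0.15 per SF hop, 0.1 at the bulk interfaces, 0.2 across the
E92→S~cav~ stretch, summing to 1); kT is fixed at 310 K (26.71 mV). At
V = 0 the chain satisfies detailed balance.

Ca²⁺ (q = +2) binding at F87 carries the voltage factor with electrical
distance 0.25, making binding strongly voltage-dependent (occupancy odds
scale as e^{2Vδ/kT} ≈ 275-fold between 0 and +300 mV); E92-ring binding has
δ = 0 and is voltage-independent, as its density is observed to be. While
Ca²⁺ is seated at F87 it (i) occludes the S~cav~↔S4 passage in both
directions — the "ball" of the check valve; a one-way closure would break
detailed balance at 0 mV and drive a spurious steady flux — and (ii)
stabilises each SF ion by `ca_sf_stabilization_kT`. A ring-bound Ca²⁺ does
not obstruct the K⁺ pathway (the four glutamates admit multiple binding
configurations), so at negative voltage, where F87 is essentially never
occupied, inward current is unaffected by Ca²⁺.

Frames are sampled on a fixed interval, after every transition
("transitions" mode — the mode in which the analysis can recover the ground
truth exactly, since no excursion can fall between frames), or not at all
(fast long runs accumulating exact time-weighted occupancies and 20-batch
means for standard errors). Rendered coordinates are site centers (bulk
particles occupy deterministic slots in slabs at ±25 Å) plus isotropic
Gaussian jitter; the protein scaffold — SF oxygen rings, F87 hexagons, E92
and E96 carboxylate oxygens, F97 Cα at the corners of a `gate_width` square
— is rigid by default. Water never enters S1–S4 by default; an option
injects transient S1/S4 waters (rendered by repositioning designated water
particles). Seeded runs are bit-reproducible.

`stationary_occupancy` enumerates the reachable state space (pore occupancy
pattern × bulk split; ~10³ states at the defaults) by breadth-first search
over the same move catalog and solves the balance equations sparsely. It is
the oracle for long-run occupancy tests; the catalog's incremental energy
differences are themselves unit-tested against the total-energy function.

### Default parameters

The defaults are the study conditions, chosen once at design time by
equilibrium analysis plus the exact enumerator so that the model sits in
the regime reported for this channel, and not revisited:

| parameter | default | role |
|---|---|---|
| n_ions / n_ca | 6 / 2 | K⁺ and Ca²⁺ copies in the box |
| base_rate | 4 ns⁻¹ | hop attempt frequency (ns-scale SF hopping) |
| wrap_rate | 1.5 ns⁻¹ | bulk mixing across the periodic boundary |
| site energies (kT) | S1 −1.0, S2 −0.2, S3 0.0, S4 0.6, S~cav~ 0.8, E92 0.5 | mean SF load ≈ 2 ions; KOKO favoured |
| pair_repulsion_kT | 1.3 | adjacent-site ion–ion repulsion (knock-on contacts are costly, full KKKK suppressed) |
| ca_f87_energy_kT / stabilization | +4.4 / 1.7 | together give F87 Ca²⁺ occupancy ≈ 0.002 / 0.43 / 0.97 at −300/0/+300 mV |
| ca_e92_energy_kT | −0.4 | ring occupancy ≈ 0.6–0.75, voltage-independent |
| jitter_sigma | 0.3 Å | well below half the narrowest site half-width |
| frame_interval | 0.1 ns | resolves site dwell times |
| gate_width | 16 Å | F97 Cα square side |
| box | 60 × 60 × 100 Å | bulk slabs at ±25 Å; wrap jump ≈ 50–58 Å > L_z/2 |

Under these conditions the exact stationary law gives: KOKO the dominant
state on Ca-free frames at ≤ 0 mV; KKOK the dominant state on Ca-bound
frames at 0 mV (the stabilization shifts the filter toward three-ion
states); E92-ring Ca²⁺ occupancy above F87 occupancy at 0 mV; and a
monotone F87 Ca-bound fraction across −300/0/+300 mV. Under applied voltage
the measured current collapses ~12-fold at +300 mV when Ca²⁺ is present
and is statistically unchanged at −300 mV.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: single-file
exclusion, voltage-biased hopping, a voltage-gated below-SF Ca²⁺ block, a
voltage-independent ring site, complete bidirectional permeation events,
periodic wraps, and positional noise. It does **not** attempt molecular
mechanics, explicit water dynamics, a membrane, absolute MD currents or
conductances, sub-site ion positions (e.g. the S3 positional splitting seen
spectroscopically), Ca²⁺–K⁺ electrostatic competition at the ring, or
protein conformational dynamics beyond optional Gaussian scaffold jitter.
Passing tests therefore demonstrate the correctness of the estimators on
data with known truth — not that real trajectories satisfy the model's
assumptions.

## Numerical choices and degenerate inputs

* Boundary ties in site assignment go to the extracellular site; contested
  sites resolve by distance-to-midpoint, then by particle id.
* A trimeric channel is analysed with a warning; fewer than three chains
  contributing to any oxygen ring is an error, as is a missing SF residue
  (named with residue and chain).
* An empty filter is a valid assignment outcome; a condition with zero
  frames (e.g. Ca-bound at −300 mV) yields an empty table, not an error.
* Occupancy tables assert Σ(fractions) = 1 to 1e-9; the stationary solver
  normalizes after clipping negative round-off.
* Simulation child seeds are derived by hashing (seed, stage index) and
  stay below 2³¹.

## Problem sizes used in validation

Oracle-equivalence checks use 10³ randomized frames; ground-truth recovery
uses 250 ns transition-sampled runs (~5·10³ frames); stationary recovery
uses a single 10⁵ ns run (~2.5·10⁶ transitions) against the enumerated
distribution with batch-mean standard errors; the block phenomenology uses
10 paired 600 ns runs per voltage; closed-form RMSF recovery uses 10⁴
frames. These sizes give standard errors comfortably inside the asserted
bounds while keeping the whole suite at desk scale.
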
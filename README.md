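# ionflux

Post-processing for ion-channel pore trajectories: selectivity-filter (SF)
occupancy states, Ca²⁺-conditional occupancy statistics, permeation-event
counting and single-channel currents under an applied field, axial ion
densities, gate distances and flexibility metrics — together with a kinetic
ion-hopping trajectory generator that produces synthetic data with exact
ground truth.

## Who it is for, and the problem it addresses

Inwardly rectifying K⁺ channels conduct well in one direction only. For the
MthK pore domain, the proposed mechanism is a *ball-check valve*: under
positive (outward-driving) voltage a Ca²⁺ ion seats at a site near F87 just
below the cavity K⁺ site S~cav~, physically blocking outward K⁺ flow, while
at negative voltage the site is essentially unoccupied and inward flow is
unhindered. A second Ca²⁺ site at the intracellular E92 glutamate ring binds
voltage-independently and does not block conduction. Testing this picture on
simulation data requires a set of small, well-defined measurements:

* per-frame assignment of ions and waters to the SF sites S1–S4 (built from
  the TVGYG backbone oxygen rings) and S~cav~, encoded as state strings over
  {K, N, W, O} such as `KOKO` or `KKOK`;
* frames sorted by whether a Ca²⁺ is bound below the SF, and occupancy
  statistics per voltage and condition;
* complete outward/inward permeation events from axial ion traces
  (periodic-boundary aware), converted to current,
  I = (n_out − n_in)·e/T, under the applied-field convention V = E_z·L_z;
* axial number densities relative to the T59 reference; F97 Cα gate
  distances; RMSD/RMSF.

`ionflux` implements these estimators over MDAnalysis and validates every
one of them against brute-force oracles and against a kinetic Monte Carlo
generator (continuous-time, single-file hopping with exclusion, voltage
bias exp(±qVδ/2kT), a voltage-gated Ca²⁺ block at F87 and a
voltage-independent E92 ring site) whose exact stationary distribution is
computed independently by state-space enumeration. See `docs/methods.md`
for the model and all conventions.

## Worked example

Measure the single-channel current at +300 mV with and without Ca²⁺ in the
box, using the generator's defaults (1 µs per run):

```python
from ionflux.kinetics import KineticModelParams, simulate_trajectory, SCAFFOLD_PLANES
from ionflux.permeation import detect_events, compute_current

for n_ca in (0, 2):
    p = KineticModelParams(voltage_mV=300.0, n_ca=n_ca, duration_ns=1000.0,
                           frame_interval=0.1, jitter_sigma=0.0, seed=1)
    r = simulate_trajectory(p)
    events = detect_events(r.true_axial_traces(),
                           (SCAFFOLD_PLANES["F87"], SCAFFOLD_PLANES["G63"]), p.box_z)
    est = compute_current(events, p.duration_ns, p.voltage_mV)
    f87 = r.ground_truth.occupancy_fraction["F87"].get("CA", 0.0)
    print(f"n_ca={n_ca}: {est.n_outward} out / {est.n_inward} in"
          f" -> {est.current_pA:.1f} pA   (F87 Ca-bound fraction {f87:.3f})")
```

Output:

```
n_ca=0: 1841 out / 116 in -> 276.4 pA   (F87 Ca-bound fraction 0.000)
n_ca=2: 202 out / 94 in -> 17.3 pA   (F87 Ca-bound fraction 0.974)
```

With Ca²⁺ present the F87 site is occupied 97% of the time at +300 mV and
the outward current collapses ~16-fold; repeating at −300 mV leaves the
inward current unchanged, because Ca²⁺ almost never binds below the SF at
negative voltage — the check-valve asymmetry. (Absolute currents are a
property of the generator's hop-rate scale, not a prediction of real
conductance.)

The same pipeline runs from the shell over a voltage ladder, writing a JSON
report plus TSV tables (I–V with rectification ratios, per-frame states,
events, occupancy tables keyed by voltage and Ca condition, profiles, gate
series):

```bash
ionflux generate --seed 1 --out out/          # synthetic ladder −300/0/+300 mV
ionflux analyze --topology top.pdb --trajectory traj.pdb --out out/
ionflux report --report out/report.json --out tables/
```

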
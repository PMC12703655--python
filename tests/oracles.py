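"""Independent brute-force oracles used to check the package's fast paths.

These deliberately re-derive results from first principles (plain loops,
string scanning) and share no code with the implementation.
"""

from __future__ import annotations

import numpy as np

SF_SITES = ("S1", "S2", "S3", "S4", "Scav")


def brute_force_assign(particles, geometry, spec):
    """Test every particle against every site region; slow and literal.

    Returns (occupants, occupant_ids, extras, ca_f87, ca_e92) in the same
    shapes as SiteAssignment fields.
    """
    occupants = {s: "EMPTY" for s in SF_SITES}
    occupant_ids = {s: None for s in SF_SITES}
    extras = []
    intervals = geometry.site_intervals
    for site in SF_SITES:
        lo, hi = intervals[site]
        mid = (lo + hi) / 2.0
        candidates = []
        for i in range(len(particles.ids)):
            if particles.species[i] not in ("K", "NH4", "WAT"):
                continue
            pos = particles.positions[i]
            z = float((pos - geometry.axis_origin) @ geometry.axis_direction)
            rvec = (pos - geometry.axis_origin) - z * geometry.axis_direction
            r = float(np.sqrt((rvec ** 2).sum()))
            if lo <= z < hi and r < spec.sf_radial_cutoff:
                candidates.append((abs(z - mid), int(particles.ids[i]),
                                   str(particles.species[i])))
        candidates.sort()
        if candidates:
            occupants[site] = candidates[0][2]
            occupant_ids[site] = candidates[0][1]
            for _, pid, _ in candidates[1:]:
                extras.append((site, pid))
    ca_f87 = False
    ca_e92 = False
    f_lo, f_hi = geometry.f87_interval
    for i in range(len(particles.ids)):
        if particles.species[i] != "CA":
            continue
        pos = particles.positions[i]
        z = float((pos - geometry.axis_origin) @ geometry.axis_direction)
        rvec = (pos - geometry.axis_origin) - z * geometry.axis_direction
        r = float(np.sqrt((rvec ** 2).sum()))
        if f_lo <= z < f_hi and r < spec.f87_radial_cutoff:
            ca_f87 = True
        for ox in geometry.e92_oxygens:
            if np.sqrt(((pos - ox) ** 2).sum()) < spec.e92_contact_cutoff:
                ca_e92 = True
                break
    return occupants, occupant_ids, extras, ca_f87, ca_e92


def compartment_string(z_series, lower, upper, box_z) -> str:
    """Classify a trace into 'I'/'F'/'E' characters (periodic in box_z)."""
    out = []
    for z in z_series:
        zr = float(z)
        while zr < lower:
            zr += box_z
        while zr >= lower + box_z:
            zr -= box_z
        if zr < upper:
            out.append("F")
        elif zr < (upper + lower + box_z) / 2.0:
            out.append("E")
        else:
            out.append("I")
    return "".join(out)


def brute_event_counts(comp: str) -> tuple[int, int]:
    """Count full filter transits by scanning the collapsed compartment string."""
    collapsed = []
    for c in comp:
        if not collapsed or collapsed[-1] != c:
            collapsed.append(c)
    s = "".join(collapsed)
    n_out = n_in = 0
    for i in range(len(s) - 2):
        if s[i + 1] == "F" and {s[i], s[i + 2]} == {"I", "E"}:
            if s[i] == "I":
                n_out += 1
            else:
                n_in += 1
    return n_out, n_in
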
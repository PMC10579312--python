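"""Independent brute-force oracles used to cross-check the vectorised
implementations.  These deliberately share no code with the package: the
enumeration oracle is a plain nested loop with the mass test applied last,
and the network oracle is an all-pairs exact-mass-difference search."""

from __future__ import annotations

import itertools

# element masses restated independently (CODATA/AME values to the same
# precision the package uses)
MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.9720707,
    "Na": 22.98976928,
    "Mg": 23.9850417,
    "Cl": 34.96885268,
}
ORDER = ("C", "H", "N", "O", "S", "Na", "Mg", "Cl")


def oracle_enumerate(neutral_mass, tol_ppm, bounds):
    """Exhaustive nested-loop enumeration over an ElementBounds object.

    Loops every composition inside the count bounds, applies the same
    ratio/structural rules the bounds object defines, and tests the mass
    window last.  Returns a set of count tuples in canonical order.
    """
    lo = neutral_mass * (1 - tol_ppm * 1e-6)
    hi = neutral_mass * (1 + tol_ppm * 1e-6)
    out = set()
    rngs = [range(b[0], b[1] + 1) for b in bounds.ranges]
    for c in rngs[0]:
        for h in rngs[1]:
            for n in rngs[2]:
                for o in rngs[3]:
                    for s in rngs[4]:
                        for na, mg, cl in itertools.product(rngs[5], rngs[6], rngs[7]):
                            if c < 1:
                                continue
                            pure_chs = (
                                s >= 1 and n == 0 and o == 0
                                and na == 0 and mg == 0 and cl == 0
                            )
                            if not (bounds.hc_range[0] * c <= h <= bounds.hc_range[1] * c):
                                continue
                            if o > bounds.oc_max * c or n > bounds.nc_max * c:
                                continue
                            if s > bounds.sc_max * c and not pure_chs:
                                continue
                            if (na >= 1 or mg >= 1) and o < bounds.metal_o_min:
                                continue
                            if s > bounds.s_mixed_max and not pure_chs:
                                continue
                            mass = (
                                c * MASS["C"] + h * MASS["H"] + n * MASS["N"]
                                + o * MASS["O"] + s * MASS["S"] + na * MASS["Na"]
                                + mg * MASS["Mg"] + cl * MASS["Cl"]
                            )
                            if lo <= mass <= hi:
                                out.add((c, h, n, o, s, na, mg, cl))
    return out


def oracle_mass_edges(masses, delta_masses, tol_da=1e-6):
    """All unordered index pairs whose mass difference matches any of the
    given exact masses within ``tol_da`` (absolute)."""
    edges = set()
    for i in range(len(masses)):
        for j in range(i + 1, len(masses)):
            d = abs(masses[j] - masses[i])
            for dm in delta_masses:
                if abs(d - dm) <= tol_da:
                    edges.add((i, j))
    return edges
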
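"""Compositional descriptors, family labels and homologous-series structure.

Per-formula descriptors place each elemental composition in the standard
projections used for complex organic mixtures: the van Krevelen plane
(H/C vs O/C), double-bond equivalents, the aromaticity equivalent Xc
(DBE corrected for the fraction of O and S assumed bound in pi systems),
mass defect and CH2-based Kendrick mass defect.  Population-level
structure is captured as homologous series (repeated addition of a fixed
elemental unit, CH2 by default) and as CH4-vs-O substitution pairs, the
pair of compositions at the same nominal mass separated by the
characteristic 36.3855 mDa spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .formula_assign import (
    MolecularFormula,
    delta_from_dict,
    monoisotopic_mass,
    senior_check,
)
from .peaklist_io import PeakList

#: CH2 homologous-series step.
CH2_STEP = delta_from_dict({"C": 1, "H": 2})
CH2_MASS = monoisotopic_mass(CH2_STEP)

#: CH4 -> O substitution delta (f - CH4 + O) and its exact mass spacing.
CH4_TO_O = delta_from_dict({"C": -1, "H": -4, "O": 1})
CH4_O_SPACING = monoisotopic_mass(delta_from_dict({"C": 1, "H": 4})) - monoisotopic_mass(
    delta_from_dict({"O": 1})
)  # 0.0363855 Da


@dataclass(frozen=True)
class DescriptorRecord:
    formula: MolecularFormula
    mass: float
    hc_ratio: float
    oc_ratio: float
    dbe: float
    xc: float
    family: str
    nominal_mass: int
    mass_defect: float
    kendrick_mass_defect: float


def classify_family(f: MolecularFormula) -> str:
    """Chemical-family label from element presence.

    Concatenates the present hetero-elements in the fixed order C, H, N,
    O, S, then appends ``Na`` (or ``Cl``) for the sodiated/chlorinated
    neutrals; Mg-bearing compositions get the separate label
    ``Mg-organic``.
    """
    if f["Mg"] >= 1:
        return "Mg-organic"
    label = "CH"
    for sym in ("N", "O", "S"):
        if f[sym] >= 1:
            label += sym
    for sym in ("Na", "Cl"):
        if f[sym] >= 1:
            label += sym
    return label


def compute_descriptors(
    f: MolecularFormula, xc_m: float = 0.5, xc_n: float = 0.5
) -> DescriptorRecord:
    """Full descriptor record of one formula.

    The aromaticity equivalent uses the corrected DBE
    ``d = DBE - m*O - n*S`` with pi-bond fractions ``m`` (oxygen) and
    ``n`` (sulfur), both 0.5 by default:

        Xc = (3 d - 2) / d   if d > 0 and DBE > 0, else Xc = 0.

    Xc >= 2.5 indicates aromatic and Xc >= 2.71 condensed-aromatic cores.
    """
    if f["C"] < 1:
        raise ValueError(f"descriptors require at least one carbon, got {f.hill}")
    _, dbe_ = senior_check(f)
    mass = monoisotopic_mass(f)
    corrected = dbe_ - xc_m * f["O"] - xc_n * f["S"]
    xc = (3.0 * corrected - 2.0) / corrected if (corrected > 0 and dbe_ > 0) else 0.0
    nm = formula_nominal_mass(f)
    km = mass * (14.0 / CH2_MASS)
    return DescriptorRecord(
        formula=f,
        mass=mass,
        hc_ratio=f["H"] / f["C"],
        oc_ratio=f["O"] / f["C"],
        dbe=dbe_,
        xc=xc,
        family=classify_family(f),
        nominal_mass=nm,
        mass_defect=mass - nm,
        kendrick_mass_defect=round(km) - km,
    )


#: Integer (nominal) atomic masses.
_NOMINAL = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32, "Na": 23, "Mg": 24, "Cl": 35}


def nominal_mass(mass: float) -> int:
    """Nearest-integer nominal mass of a *measured* mass.  Note that for
    hydrogen-rich compositions above ~600 Da the accumulated mass defect
    exceeds +0.5 and this rounds one unit above the formula-based nominal
    mass; use :func:`formula_nominal_mass` when the composition is known."""
    return int(round(mass))


def formula_nominal_mass(f: MolecularFormula) -> int:
    """Nominal mass of a composition: sum of integer atomic masses.  Exact
    under elemental substitutions (e.g. CH4 vs O, both nominally 16)."""
    return sum(f[sym] * m for sym, m in _NOMINAL.items())


@dataclass(frozen=True)
class HomologousSeries:
    """A maximal chain of formulas under repeated addition of ``step``."""

    base_formula: MolecularFormula
    step: tuple[int, ...]
    members: tuple[MolecularFormula, ...]

    @property
    def length(self) -> int:
        return len(self.members)


def detect_series(
    formulas: Iterable[MolecularFormula],
    step: Sequence[int] = CH2_STEP,
) -> list[HomologousSeries]:
    """Maximal homologous chains (length >= 2) in a formula population.

    Each formula belongs to exactly one maximal chain per step; chains are
    found by walking forward from the formulas whose predecessor
    (formula - step) is absent from the population.
    """
    step = tuple(step)
    if monoisotopic_mass(step) <= 0:
        raise ValueError("series step must have positive monoisotopic mass")
    pop = set(formulas)
    neg = tuple(-d for d in step)
    series: list[HomologousSeries] = []
    for f in sorted(pop):
        prev = f.shift(neg)
        if prev is not None and prev in pop:
            continue  # not a chain start
        members = [f]
        cur = f
        while True:
            nxt = cur.shift(step)
            if nxt is None or nxt not in pop:
                break
            members.append(nxt)
            cur = nxt
        if len(members) >= 2:
            series.append(HomologousSeries(f, step, tuple(members)))
    series.sort(key=lambda s: s.base_formula.hill)
    return series


def ch4_o_substitution_pairs(
    formulas: Iterable[MolecularFormula],
) -> list[tuple[MolecularFormula, MolecularFormula]]:
    """Pairs (f, g) with g = f - CH4 + O: isobaric at the nominal mass and
    split by the exact spacing ``CH4_O_SPACING`` (36.3855 mDa)."""
    pop = set(formulas)
    pairs = []
    for f in sorted(pop):
        g = f.shift(CH4_TO_O)
        if g is not None and g in pop:
            pairs.append((f, g))
    return pairs


def nominal_mass_profile(
    pl: PeakList,
) -> dict[int, list[tuple[float, float]]]:
    """Group peaks by nominal mass; within each group, (mass defect,
    intensity) pairs ordered by mass defect.  Purely descriptive — it
    exposes the per-nominal-mass signal distribution of a spectrum."""
    profile: dict[int, list[tuple[float, float]]] = {}
    for p in pl.peaks:
        nm = nominal_mass(p.mz)
        profile.setdefault(nm, []).append((p.mz - nm, p.intensity))
    for group in profile.values():
        group.sort(key=lambda t: t[0])
    return profile


def descriptor_table(formulas: Iterable[MolecularFormula], xc_m: float = 0.5,
                     xc_n: float = 0.5):
    """DataFrame of descriptor records, one row per formula."""
    import pandas as pd

    rows = []
    for f in formulas:
        r = compute_descriptors(f, xc_m=xc_m, xc_n=xc_n)
        rows.append(
            {
                "formula": f.hill,
                "mass": r.mass,
                "hc_ratio": r.hc_ratio,
                "oc_ratio": r.oc_ratio,
                "dbe": r.dbe,
                "xc": r.xc,
                "family": r.family,
                "nominal_mass": r.nominal_mass,
                "mass_defect": r.mass_defect,
                "kendrick_mass_defect": r.kendrick_mass_defect,
            }
        )
    return pd.DataFrame(rows)


_FAMILY_COLORS = {
    "CH": "#555555",
    "CHO": "#1f77b4",
    "CHN": "#9467bd",
    "CHS": "#8c564b",
    "CHNO": "#ff7f0e",
    "CHOS": "#2ca02c",
    "CHNOS": "#d62728",
}


def van_krevelen_plot(
    table,
    path,
    intensities: Optional[Mapping[str, float]] = None,
) -> None:
    """Render a van Krevelen scatter (H/C vs O/C) colored by family; bubble
    area proportional to intensity when provided."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for family, sub in table.groupby("family"):
        if intensities is not None:
            w = np.array([intensities.get(f, 1.0) for f in sub["formula"]])
            sizes = 4 + 60 * w / max(w.max(), 1e-12)
        else:
            sizes = 12
        ax.scatter(
            sub["oc_ratio"], sub["hc_ratio"], s=sizes, alpha=0.6,
            color=_FAMILY_COLORS.get(family, "#17becf"), label=family,
            linewidths=0,
        )
    ax.set_xlabel("O/C")
    ax.set_ylabel("H/C")
    ax.legend(fontsize=8, markerscale=1.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
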
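"""Molecular-formula assignment from accurate mass.

The central capability of the pipeline: converting sub-ppm-accurate ion
masses into unique elemental compositions over the atomic space
{C, H, N, O, S, Na, Mg, Cl}.  Candidate formulas are enumerated
combinatorially within a mass-accuracy window, validated by the
Senior/cyclomatic-number valence rules (S is treated as divalent and Mg
as tetravalent, i.e. by coordination number) and filtered by conservative
elemental-ratio rules; ion chemistry covers deprotonation, protonation,
Na+/Cl- adduction and radical cations, with the electron mass included in
all arithmetic.

The enumeration is exact: it returns every composition inside the element
bounds and ratio filters whose monoisotopic mass falls in the window, and
is verified in the test suite against an exhaustive nested-loop oracle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .peaklist_io import Peak, PeakList

# ---------------------------------------------------------------------------
# Element table
# ---------------------------------------------------------------------------

#: Canonical element order used for the internal count tuples.
ELEMENTS = ("C", "H", "N", "O", "S", "Na", "Mg", "Cl")
_EIDX = {e: i for i, e in enumerate(ELEMENTS)}

#: Monoisotopic atomic masses (Da) of the most abundant isotope.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.9720707,
    "Na": 22.98976928,
    "Mg": 23.9850417,
    "Cl": 34.96885268,
}
_MASSES = np.array([MONOISOTOPIC_MASS[e] for e in ELEMENTS])

#: Valences used by the Senior rules (S divalent; Mg coordination number 4).
VALENCE = {"C": 4, "H": 1, "N": 3, "O": 2, "S": 2, "Na": 1, "Mg": 4, "Cl": 1}
_VALENCES = np.array([VALENCE[e] for e in ELEMENTS])
_ODD_VALENCE = tuple(e for e in ELEMENTS if VALENCE[e] % 2 == 1)  # H, N, Na, Cl

ELECTRON_MASS = 0.00054858  # Da

#: Mass excess of the 13C and 34S isotopologue companions (Da).
C13_DELTA = 1.0033548
S34_DELTA = 1.9957959
C13_ABUNDANCE = 0.0107  # expected companion/parent ratio per carbon
S34_ABUNDANCE = 0.0442  # per sulfur

# Hill order: C, H, then remaining symbols alphabetically.
_HILL_ORDER = ("C", "H") + tuple(sorted(e for e in ELEMENTS if e not in ("C", "H")))

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """An elemental composition over {C,H,N,O,S,Na,Mg,Cl}.

    Immutable and hashable; the canonical text form is Hill order
    (C, H, then alphabetical), e.g. ``C8H11NO2`` or ``C6H5NaO``.
    """

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(ELEMENTS):
            raise ValueError("counts must cover all supported elements")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"negative element count in {self.counts}")
        if sum(self.counts) == 0:
            raise ValueError("formula must contain at least one atom")

    @classmethod
    def from_dict(cls, counts: Mapping[str, int]) -> "MolecularFormula":
        vec = [0] * len(ELEMENTS)
        for sym, n in counts.items():
            if sym not in _EIDX:
                raise UnknownElementError(f"unsupported element {sym!r}")
            vec[_EIDX[sym]] = int(n)
        return cls(tuple(vec))

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a formula string such as ``C6H12O6`` or ``CH4``."""
        vec = [0] * len(ELEMENTS)
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            sym = m.group(1)
            if sym not in _EIDX:
                raise UnknownElementError(f"unsupported element {sym!r} in {text!r}")
            vec[_EIDX[sym]] += int(m.group(2) or 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(tuple(vec))

    def __getitem__(self, element: str) -> int:
        return self.counts[_EIDX[element]]

    @property
    def hill(self) -> str:
        parts = []
        for sym in _HILL_ORDER:
            n = self[sym]
            if n == 1:
                parts.append(sym)
            elif n > 1:
                parts.append(f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill

    def __repr__(self) -> str:
        return f"MolecularFormula({self.hill!r})"

    def shift(self, delta: Sequence[int]) -> Optional["MolecularFormula"]:
        """Add a signed elemental delta; None if any count would go negative."""
        new = tuple(c + d for c, d in zip(self.counts, delta))
        if any(c < 0 for c in new) or sum(new) == 0:
            return None
        return MolecularFormula(new)

    def difference(self, other: "MolecularFormula") -> tuple[int, ...]:
        """Signed elemental delta ``self - other``."""
        return tuple(a - b for a, b in zip(self.counts, other.counts))


def delta_from_dict(counts: Mapping[str, int]) -> tuple[int, ...]:
    """Build a signed elemental delta tuple, e.g. ``{"C": -1, "O": 1}``."""
    vec = [0] * len(ELEMENTS)
    for sym, n in counts.items():
        if sym not in _EIDX:
            raise UnknownElementError(f"unsupported element {sym!r}")
        vec[_EIDX[sym]] = int(n)
    return tuple(vec)


def monoisotopic_mass(f: MolecularFormula | Sequence[int]) -> float:
    """Monoisotopic mass (Da) of a formula or signed elemental delta."""
    counts = f.counts if isinstance(f, MolecularFormula) else tuple(f)
    return float(np.dot(counts, _MASSES))


# ---------------------------------------------------------------------------
# Ion types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IonType:
    """Ionization arithmetic for a singly charged ion type.

    ``mz = neutral_mass + adduct_mass - charge * electron_mass`` where
    ``adduct_mass`` is the monoisotopic mass of ``adduct_delta`` (signed)
    and ``charge`` is +1 or -1.
    """

    label: str
    adduct_delta: tuple[int, ...]
    charge: int  # +1 or -1

    @property
    def adduct_mass(self) -> float:
        return monoisotopic_mass(self.adduct_delta)

    def mz_from_neutral(self, neutral_mass: float) -> float:
        return neutral_mass + self.adduct_mass - self.charge * ELECTRON_MASS

    def neutral_from_mz(self, mz: float) -> float:
        return mz - self.adduct_mass + self.charge * ELECTRON_MASS


ION_TYPES: dict[str, IonType] = {
    "[M-H]-": IonType("[M-H]-", delta_from_dict({"H": -1}), -1),
    "[M+H]+": IonType("[M+H]+", delta_from_dict({"H": 1}), +1),
    "[M+Na]+": IonType("[M+Na]+", delta_from_dict({"Na": 1}), +1),
    "[M+Cl]-": IonType("[M+Cl]-", delta_from_dict({"Cl": 1}), -1),
    "M+.": IonType("M+.", delta_from_dict({}), +1),
}

#: Default ion types searched per ionization mode.
DEFAULT_MODE_IONS: dict[str, tuple[str, ...]] = {
    "esi_neg": ("[M-H]-", "[M+Cl]-"),
    "esi_pos": ("[M+H]+", "[M+Na]+"),
    "appi_pos": ("[M+H]+", "M+."),
}


def _ion(ion_type: str | IonType) -> IonType:
    if isinstance(ion_type, IonType):
        return ion_type
    try:
        return ION_TYPES[ion_type]
    except KeyError:
        raise ValueError(
            f"unknown ion type {ion_type!r}; known: {sorted(ION_TYPES)}"
        ) from None


def ion_mz_from_neutral(neutral_mass: float, ion_type: str | IonType) -> float:
    """Theoretical m/z of a neutral of given monoisotopic mass as ``ion_type``."""
    return _ion(ion_type).mz_from_neutral(neutral_mass)


def neutral_mass_from_mz(mz: float, ion_type: str | IonType) -> float:
    """Invert the adduct arithmetic (electron mass included)."""
    if mz <= 0:
        raise ValueError("mz must be positive")
    neutral = _ion(ion_type).neutral_from_mz(mz)
    if neutral <= 0:
        raise ValueError(
            f"ion type {_ion(ion_type).label} at mz {mz} implies a non-positive "
            f"neutral mass"
        )
    return neutral


# ---------------------------------------------------------------------------
# Senior rules
# ---------------------------------------------------------------------------


def senior_check(f: MolecularFormula) -> tuple[bool, float]:
    """Validate a neutral composition by the Senior/cyclomatic-number rules.

    Returns ``(passes, dbe)`` with double-bond equivalents
    ``dbe = 1 + sum_i n_i (v_i - 2) / 2``.  A composition passes iff

    (a) dbe is a non-negative integer (the cyclomatic number of a connected
        even-electron molecule),
    (b) the total count of odd-valence atoms (H, N, Na, Cl) is even, and
    (c) ``sum_i n_i v_i >= 2 (sum_i n_i - 1)`` (enough bonds to connect).
    """
    counts = np.asarray(f.counts)
    dbe = 1.0 + float(np.dot(counts, _VALENCES - 2)) / 2.0
    odd_total = sum(f[e] for e in _ODD_VALENCE)
    passes = (
        abs(dbe - round(dbe)) < 1e-9
        and dbe >= 0
        and odd_total % 2 == 0
        and int(np.dot(counts, _VALENCES)) >= 2 * (int(counts.sum()) - 1)
    )
    return passes, dbe


def dbe(f: MolecularFormula) -> float:
    """Double-bond equivalents of the neutral formula."""
    return senior_check(f)[1]


# ---------------------------------------------------------------------------
# Element bounds and ratio filters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementBounds:
    """Per-element count ranges plus conservative elemental-ratio filters.

    The ratio filters emulate the "conservative filter rules" applied to
    complex-organic-mixture spectra: plausible H/C saturation range, caps
    on O/C, N/C and S/C.  Pure CHS compositions (polysulfur chains) are
    exempt from the S/C cap and governed by the S count bound alone, so
    that e.g. S3-S9 polysulfane series survive.  All values are
    configurable; the defaults are pipeline choices.
    """

    c: tuple[int, int] = (1, 100)
    h: tuple[int, int] = (0, 200)
    n: tuple[int, int] = (0, 5)
    o: tuple[int, int] = (0, 40)
    s: tuple[int, int] = (0, 9)
    na: tuple[int, int] = (0, 1)
    # Mg-organics are searchable (valence 4) but absent from such spectra;
    # widen to (0, 1) to test for CHOMg/CHOSMg explicitly
    mg: tuple[int, int] = (0, 0)
    # chlorine reaches the spectra of these mixtures as an adduct, not as a
    # constituent of the neutral; widen to (0, 1) to search chlorinated
    # organics explicitly
    cl: tuple[int, int] = (0, 0)
    hc_range: tuple[float, float] = (0.4, 3.2)
    oc_max: float = 1.2
    nc_max: float = 1.3
    sc_max: float = 0.8
    # minimum O count of a Na/Mg-bearing neutral (acid-salt constraint);
    # set to 0 to lift
    metal_o_min: int = 2
    # S counts above this value are reserved for saturated polysulfur
    # chains (pure CHS, DBE <= 1); raise to admit S-rich mixed families
    s_mixed_max: int = 3

    def __post_init__(self) -> None:
        for lo, hi in (self.c, self.h, self.n, self.o, self.s, self.na, self.mg, self.cl):
            if lo < 0 or lo > hi:
                raise ValueError("element bounds must satisfy 0 <= min <= max")

    @property
    def ranges(self) -> tuple[tuple[int, int], ...]:
        """(min, max) per element in canonical order."""
        return (self.c, self.h, self.n, self.o, self.s, self.na, self.mg, self.cl)

    def without_elements(self, *symbols: str) -> "ElementBounds":
        """Copy with the max count of the given elements forced to zero."""
        kw = {}
        names = {"C": "c", "H": "h", "N": "n", "O": "o", "S": "s",
                 "Na": "na", "Mg": "mg", "Cl": "cl"}
        for sym in symbols:
            kw[names[sym]] = (0, 0)
        return replace(self, **kw)


def _is_pure_chs(f: MolecularFormula) -> bool:
    return (
        f["S"] >= 1
        and f["N"] == 0 and f["O"] == 0
        and f["Na"] == 0 and f["Mg"] == 0 and f["Cl"] == 0
    )


def check_ratio_filters(f: MolecularFormula, bounds: ElementBounds) -> list[str]:
    """Names of the ratio/count rules that a formula violates (empty = pass)."""
    failed: list[str] = []
    for sym, (lo, hi) in zip(ELEMENTS, bounds.ranges):
        if not (lo <= f[sym] <= hi):
            failed.append("bounds")
            break
    c = f["C"]
    if c >= 1:
        hc = f["H"] / c
        if not (bounds.hc_range[0] <= hc <= bounds.hc_range[1]):
            failed.append("H/C")
        if f["O"] / c > bounds.oc_max:
            failed.append("O/C")
        if f["N"] / c > bounds.nc_max:
            failed.append("N/C")
        if f["S"] / c > bounds.sc_max and not _is_pure_chs(f):
            failed.append("S/C")
    # metal-bearing neutrals are salts of organic acids: they require a
    # deprotonatable oxygen-bearing group (all observed Na families are
    # CHO(N/S)Na; no CHNa or CHSNa)
    if (f["Na"] >= 1 or f["Mg"] >= 1) and f["O"] < bounds.metal_o_min:
        failed.append("metal-O")
    # sulfur counts beyond the mixed-family cap occur only as saturated
    # polysulfur chains
    if f["S"] > bounds.s_mixed_max:
        if not _is_pure_chs(f) or senior_check(f)[1] > 1:
            failed.append("polysulfur")
    return failed


# ---------------------------------------------------------------------------
# Combinatorial enumeration
# ---------------------------------------------------------------------------

_H = _EIDX["H"]
_NON_H = tuple(i for i in range(len(ELEMENTS)) if i != _H)


@lru_cache(maxsize=8)
def _candidate_grid(bounds: ElementBounds) -> tuple[np.ndarray, np.ndarray]:
    """All non-H count combinations within bounds that can pass the
    C-independent ratio filters, with their partial (H-free) masses,
    sorted by partial mass.

    Returns ``(counts, base_mass)`` where counts has one column per
    element in canonical order (H column all zero).
    """
    axes = []
    for i in range(len(ELEMENTS)):
        lo, hi = bounds.ranges[i]
        if i == _H:
            axes.append(np.array([0], dtype=np.int16))
        else:
            axes.append(np.arange(lo, hi + 1, dtype=np.int16))
    mesh = np.meshgrid(*axes, indexing="ij")
    counts = np.stack([m.ravel() for m in mesh], axis=1).astype(np.int32)
    c = counts[:, _EIDX["C"]].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (
            (counts[:, _EIDX["O"]] <= bounds.oc_max * c)
            & (counts[:, _EIDX["N"]] <= bounds.nc_max * c)
        )
        pure_chs = (
            (counts[:, _EIDX["S"]] >= 1)
            & (counts[:, _EIDX["N"]] == 0)
            & (counts[:, _EIDX["O"]] == 0)
            & (counts[:, _EIDX["Na"]] == 0)
            & (counts[:, _EIDX["Mg"]] == 0)
            & (counts[:, _EIDX["Cl"]] == 0)
        )
        ok &= (counts[:, _EIDX["S"]] <= bounds.sc_max * c) | pure_chs
        has_metal = (counts[:, _EIDX["Na"]] >= 1) | (counts[:, _EIDX["Mg"]] >= 1)
        ok &= ~has_metal | (counts[:, _EIDX["O"]] >= bounds.metal_o_min)
        ok &= (counts[:, _EIDX["S"]] <= bounds.s_mixed_max) | pure_chs
    counts = counts[ok]
    base = counts.astype(float) @ _MASSES
    order = np.argsort(base, kind="stable")
    return counts[order], base[order]


def enumerate_formulas(
    neutral_mass: float,
    tol_ppm: float,
    bounds: ElementBounds | None = None,
) -> list[MolecularFormula]:
    """All compositions within ``bounds`` whose monoisotopic mass lies in
    ``[m (1 - tol_ppm 1e-6), m (1 + tol_ppm 1e-6)]``, sorted by |ppm error|.

    The search loops over heteroatom combinations (vectorised) and solves
    the hydrogen count per branch; it is exact with respect to the element
    bounds and elemental-ratio filters (Senior validation is a separate,
    later step).
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")
    bounds = bounds or ElementBounds()
    counts, base = _candidate_grid(bounds)
    m_lo = neutral_mass * (1.0 - tol_ppm * 1e-6)
    m_hi = neutral_mass * (1.0 + tol_ppm * 1e-6)
    hi = int(np.searchsorted(base, m_hi, side="right"))
    if hi == 0:
        return []
    cts = counts[:hi]
    bm = base[:hi]
    mh = MONOISOTOPIC_MASS["H"]
    h_lo_f = (m_lo - bm) / mh
    h_hi_f = (m_hi - bm) / mh
    h_first = np.ceil(h_lo_f - 1e-12).astype(np.int64)
    h_first = np.maximum(h_first, bounds.h[0])
    results: list[tuple[float, MolecularFormula]] = []
    # the window is normally far narrower than one H mass, so this loop
    # usually runs once
    max_span = int(np.floor((m_hi - m_lo) / mh)) + 1
    for k in range(max_span + 1):
        h = h_first + k
        mass = bm + h * mh
        c = cts[:, _EIDX["C"]].astype(float)
        ok = (
            (h <= h_hi_f + 1e-12)
            & (h <= bounds.h[1])
            & (mass >= m_lo) & (mass <= m_hi)
            & (h >= bounds.hc_range[0] * c - 1e-12)
            & (h <= bounds.hc_range[1] * c + 1e-12)
        )
        for idx in np.nonzero(ok)[0]:
            vec = cts[idx].copy()
            vec[_H] = h[idx]
            f = MolecularFormula(tuple(int(x) for x in vec))
            err = (neutral_mass - mass[idx]) / mass[idx] * 1e6
            results.append((abs(err), f))
    results.sort(key=lambda t: (t[0], t[1].hill))
    return [f for _, f in results]


# ---------------------------------------------------------------------------
# Filtering, assignment, isotope verification
# ---------------------------------------------------------------------------


@dataclass
class FilterResult:
    passed: list[MolecularFormula]
    rejected: list[tuple[MolecularFormula, list[str]]]


def apply_filters(
    candidates: Iterable[MolecularFormula],
    bounds: ElementBounds | None = None,
) -> FilterResult:
    """Drop candidates violating the Senior rules or the ratio filters,
    recording which rule fired for each rejection.  Idempotent."""
    bounds = bounds or ElementBounds()
    passed: list[MolecularFormula] = []
    rejected: list[tuple[MolecularFormula, list[str]]] = []
    for f in candidates:
        rules = check_ratio_filters(f, bounds)
        ok, _ = senior_check(f)
        if not ok:
            rules.append("senior")
        if rules:
            rejected.append((f, rules))
        else:
            passed.append(f)
    return FilterResult(passed, rejected)


@dataclass
class Assignment:
    """One peak <-> (ion type, neutral formula) hypothesis that survived
    the mass window and all filters."""

    peak_index: int
    peak: Peak
    ion_type: str
    formula: MolecularFormula
    neutral_mass: float
    error_ppm: float
    dbe: float
    is_primary: bool = False
    isotope_verified: str = "unchecked"  # unchecked | confirmed | contradicted


@dataclass
class AssignmentTable:
    """All surviving formula candidates of one sample's peak list.

    ``ambiguity`` maps peak index -> number of surviving candidates; every
    retained peak has exactly one candidate flagged primary (the lowest
    |ppm error|, with isotope-verified candidates promoted at near ties).
    """

    sample_id: str
    assignments: list[Assignment]
    ambiguity: dict[int, int]

    @property
    def primaries(self) -> list[Assignment]:
        return [a for a in self.assignments if a.is_primary]

    def to_dataframe(self):
        import pandas as pd
        from .descriptors import classify_family

        rows = []
        for a in self.assignments:
            rows.append(
                {
                    "sample_id": self.sample_id,
                    "mz": a.peak.mz,
                    "intensity": a.peak.intensity,
                    "snr": a.peak.snr,
                    "ion_type": a.ion_type,
                    "formula": a.formula.hill,
                    "neutral_mass": a.neutral_mass,
                    "error_ppm": a.error_ppm,
                    "dbe": a.dbe,
                    "family": classify_family(a.formula),
                    "is_primary": a.is_primary,
                    "isotope_verified": a.isotope_verified,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AssignConfig:
    """Tolerance, bounds and per-mode ion-type configuration.

    ``require_adduct_partner`` applies the adduct corroboration rule: a
    Na+/Cl- adduct hypothesis is retained only if the same neutral is also
    visible through the mode's primary ion channel ([M-H]- resp. [M+H]+)
    elsewhere in the peak list (within ``partner_tol_ppm``).  Adducts
    accompany the main ionization product in electrospray, so an adduct
    with no primary-channel partner is far more likely a near-isobar of a
    different composition; this rule resolves the micro-Dalton ion-type
    coincidences of the CHNOS space (e.g. the 13 uDa overlap between
    [M-H]- of C4O7-richer and [M+Cl]- of N4S2-richer compositions).
    """

    tol_ppm: float = 0.2
    bounds: ElementBounds = field(default_factory=ElementBounds)
    ion_types: Optional[tuple[str, ...]] = None  # None -> mode default
    require_adduct_partner: bool = True
    partner_tol_ppm: float = 0.25


def _bounds_for_ion(bounds: ElementBounds, ion_label: str) -> ElementBounds:
    # adduct atoms are not also allowed in the neutral: an [M+Na]+ hit is
    # reported as the Na adduct of the Na-free neutral (likewise [M+Cl]-),
    # while deprotonated Na-bearing neutrals (CHONa families) remain legal
    if ion_label == "[M+Na]+":
        return bounds.without_elements("Na")
    if ion_label == "[M+Cl]-":
        return bounds.without_elements("Cl")
    return bounds


#: Adduct ion types and the primary channel that must corroborate them.
_ADDUCT_PARTNER = {"[M+Cl]-": "[M-H]-", "[M+Na]+": "[M+H]+"}


def assign_peaklist(pl: PeakList, config: AssignConfig | None = None) -> AssignmentTable:
    """Assign every peak of a list: enumerate candidates per ion type of the
    ionization mode, validate, and flag the lowest-|error| survivor primary."""
    config = config or AssignConfig()
    if pl.ionization_mode not in DEFAULT_MODE_IONS:
        raise ValueError(f"unknown ionization mode {pl.ionization_mode!r}")
    ion_labels = config.ion_types or DEFAULT_MODE_IONS[pl.ionization_mode]
    mz_arr = pl.mz

    def has_peak_near(target: float, tol_ppm: float) -> bool:
        if len(mz_arr) == 0:
            return False
        j = int(np.argmin(np.abs(mz_arr - target)))
        return abs(mz_arr[j] - target) <= tol_ppm * 1e-6 * target

    assignments: list[Assignment] = []
    ambiguity: dict[int, int] = {}
    for i, peak in enumerate(pl.peaks):
        cands: list[Assignment] = []
        for label in ion_labels:
            ion = _ion(label)
            try:
                neutral_obs = neutral_mass_from_mz(peak.mz, ion)
            except ValueError:
                continue
            ion_bounds = _bounds_for_ion(config.bounds, label)
            for f in enumerate_formulas(neutral_obs, config.tol_ppm, ion_bounds):
                ok, f_dbe = senior_check(f)
                if not ok or check_ratio_filters(f, ion_bounds):
                    continue
                theo_mz = ion.mz_from_neutral(monoisotopic_mass(f))
                err = (peak.mz - theo_mz) / theo_mz * 1e6
                if abs(err) > config.tol_ppm:
                    continue
                if config.require_adduct_partner and label in _ADDUCT_PARTNER:
                    partner = _ion(_ADDUCT_PARTNER[label])
                    partner_mz = partner.mz_from_neutral(monoisotopic_mass(f))
                    if not has_peak_near(partner_mz, config.partner_tol_ppm):
                        continue
                if config.require_adduct_partner and f["Na"] >= 1:
                    # a sodiated neutral is the salt of an acid; its free
                    # acid (Na -> H) co-occurs in the same spectrum
                    free_acid = f.shift(delta_from_dict({"Na": -1, "H": 1}))
                    if free_acid is None or not has_peak_near(
                        ion.mz_from_neutral(monoisotopic_mass(free_acid)),
                        config.partner_tol_ppm,
                    ):
                        continue
                cands.append(
                    Assignment(
                        peak_index=i,
                        peak=peak,
                        ion_type=label,
                        formula=f,
                        neutral_mass=monoisotopic_mass(f),
                        error_ppm=err,
                        dbe=f_dbe,
                    )
                )
        if cands:
            cands.sort(key=lambda a: (abs(a.error_ppm), a.formula.hill, a.ion_type))
            cands[0].is_primary = True
            ambiguity[i] = len(cands)
            assignments.extend(cands)
    return AssignmentTable(pl.sample_id, assignments, ambiguity)


def _find_companion(pl: PeakList, target_mz: float, tol_ppm: float) -> Optional[Peak]:
    mz = pl.mz
    if len(mz) == 0:
        return None
    i = int(np.argmin(np.abs(mz - target_mz)))
    if abs(mz[i] - target_mz) <= tol_ppm * 1e-6 * target_mz:
        return pl.peaks[i]
    return None


def isotope_verify(a: Assignment, pl: PeakList, tol_ppm: float = 1.0) -> Assignment:
    """Check the natural-abundance isotopologue companions of an assignment.

    Looks for the +1.0033548 Da 13C companion (and the +1.9957959 Da 34S
    companion when the formula contains sulfur).  A companion whose
    intensity ratio to the parent lies within a factor-2 band of the
    expectation (n_C x 0.0107, resp. n_S x 0.0442) confirms the formula; a
    companion far outside the band contradicts it.  An *absent* 13C
    companion contradicts the formula only when it should have been easily
    visible (n_C >= 10 and parent S/N >= 30); otherwise the verdict is
    "unchecked" (insufficient evidence).
    """
    verdicts: list[str] = []
    checks = [(C13_DELTA, a.formula["C"], C13_ABUNDANCE, True)]
    if a.formula["S"] >= 1:
        checks.append((S34_DELTA, a.formula["S"], S34_ABUNDANCE, False))
    for delta, n_atoms, abundance, is_carbon in checks:
        if n_atoms == 0:
            continue
        expected_ratio = n_atoms * abundance
        companion = _find_companion(pl, a.peak.mz + delta, tol_ppm)
        if companion is not None and a.peak.intensity > 0:
            ratio = companion.intensity / a.peak.intensity
            if expected_ratio / 2 <= ratio <= expected_ratio * 2:
                verdicts.append("confirmed")
            else:
                verdicts.append("contradicted")
        elif is_carbon and n_atoms >= 10 and a.peak.snr >= 30:
            verdicts.append("contradicted")
    if "contradicted" in verdicts:
        a.isotope_verified = "contradicted"
    elif "confirmed" in verdicts:
        a.isotope_verified = "confirmed"
    else:
        a.isotope_verified = "unchecked"
    return a


def verify_table(
    table: AssignmentTable, pl: PeakList, tol_ppm: float = 1.0,
    promote_window_ppm: float = 0.02,
) -> AssignmentTable:
    """Isotope-verify every assignment and re-resolve primaries: a confirmed
    candidate within ``promote_window_ppm`` of the best |error| outranks an
    unverified one."""
    by_peak: dict[int, list[Assignment]] = {}
    for a in table.assignments:
        isotope_verify(a, pl, tol_ppm)
        by_peak.setdefault(a.peak_index, []).append(a)
    for cands in by_peak.values():
        cands.sort(key=lambda a: (abs(a.error_ppm), a.formula.hill, a.ion_type))
        best = cands[0]
        winner = best
        if best.isotope_verified != "confirmed":
            for a in cands[1:]:
                if (
                    a.isotope_verified == "confirmed"
                    and abs(a.error_ppm) - abs(best.error_ppm) <= promote_window_ppm
                ):
                    winner = a
                    break
        for a in cands:
            a.is_primary = a is winner
    return table
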
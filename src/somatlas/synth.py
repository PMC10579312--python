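"""Synthetic formula populations, peak lists and multi-sample studies.

No machine-readable peak lists accompany the meteorite soluble-organic-
matter studies this pipeline targets, so every stage is exercised on
generated data with planted ground truth.  The generator emulates the
salient features of such spectra: CHNOS formula populations organised in
CH2 homologous series across the chemical families (CH, CHO, CHN, CHS,
CHNO, CHOS, CHNOS), sulfur-rich chains up to S9, a ~120-700 Da mass
range, per-peak mass error at the 0.05-0.2 ppm scale, unassignable noise
peaks, log-normal intensities, and a two-class multi-sample intensity
structure with a 25-sample work / 11-sample prediction split.

What it deliberately does not model: isotopic fine structure beyond the
13C/34S companions, resolution/peak-shape effects, and instrument drift.
All outputs are bitwise deterministic under a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .formula_assign import (
    DEFAULT_MODE_IONS,
    ELEMENTS,
    ElementBounds,
    MolecularFormula,
    check_ratio_filters,
    enumerate_formulas,
    ion_mz_from_neutral,
    monoisotopic_mass,
    senior_check,
)
from .multivariate import IntensityMatrix
from .peaklist_io import Peak, PeakList

__all__ = [
    "PopulationConfig",
    "SimulatedPeakList",
    "SimulatedStudy",
    "generate_population",
    "simulate_peaklist",
    "generate_two_class_study",
]

#: Family mix loosely mimicking meteoritic SOM: N-bearing families dominate,
#: then CHO, CHOS, with small CH and CHS fractions.
DEFAULT_FAMILY_PROPORTIONS: dict[str, float] = {
    "CHNO": 0.30,
    "CHO": 0.27,
    "CHOS": 0.15,
    "CHN": 0.12,
    "CHNOS": 0.10,
    "CH": 0.04,
    "CHS": 0.02,
}

_FAMILY_ELEMENTS = {
    "CH": (),
    "CHO": ("O",),
    "CHN": ("N",),
    "CHS": ("S",),
    "CHNO": ("N", "O"),
    "CHOS": ("O", "S"),
    "CHNOS": ("N", "O", "S"),
}


class InfeasibleConfigError(RuntimeError):
    pass


@dataclass(frozen=True)
class PopulationConfig:
    """Ground-truth formula-population recipe.

    ``series`` plants explicit homologous chains ((base formula, step
    delta, length)); ``sulfur_series`` adds CH2 chains of saturated
    polysulfur compounds with S counts 3 through 9.  Planted chains are
    appended to the ``n_formulas`` family-sampled compositions.
    """

    n_formulas: int = 2000
    family_proportions: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_FAMILY_PROPORTIONS.items()
    )
    series: tuple[tuple[str, tuple[int, ...], int], ...] = ()
    sulfur_series: bool = False
    mass_range: tuple[float, float] = (120.0, 700.0)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.family_proportions)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"family proportions must sum to 1, got {total}")
        if not self.mass_range[0] < self.mass_range[1]:
            raise ValueError("mass_range must satisfy min < max")


def _family_quotas(cfg: PopulationConfig) -> dict[str, int]:
    # largest-remainder allocation: quotas are exact for the sampled part
    raw = {fam: p * cfg.n_formulas for fam, p in cfg.family_proportions}
    quotas = {fam: math.floor(v) for fam, v in raw.items()}
    short = cfg.n_formulas - sum(quotas.values())
    for fam, _ in sorted(raw.items(), key=lambda kv: kv[1] - math.floor(kv[1]),
                         reverse=True)[:short]:
        quotas[fam] += 1
    return quotas


def _sample_family_formula(
    rng: np.random.Generator,
    family: str,
    mass_range: tuple[float, float],
    bounds: ElementBounds,
    max_tries: int = 500,
) -> Optional[MolecularFormula]:
    present = _FAMILY_ELEMENTS[family]
    for _ in range(max_tries):
        c = int(rng.integers(4, 45))
        n = int(rng.integers(1, 5)) if "N" in present else 0
        o = int(rng.integers(1, 14)) if "O" in present else 0
        s = int(rng.integers(1, 4)) if "S" in present else 0
        h_lo = max(2, math.ceil(bounds.hc_range[0] * c))
        h_hi = min(math.floor(bounds.hc_range[1] * c), 2 * c + n + 2)
        if h_hi < h_lo:
            continue
        h = int(rng.integers(h_lo, h_hi + 1))
        if (h + n) % 2 == 1:
            h += 1 if h + 1 <= h_hi else -1
        f = MolecularFormula.from_dict({"C": c, "H": h, "N": n, "O": o, "S": s})
        mass = monoisotopic_mass(f)
        if not (mass_range[0] <= mass <= mass_range[1]):
            continue
        if not senior_check(f)[0] or check_ratio_filters(f, bounds):
            continue
        return f
    return None


def _polysulfur_chains(mass_range: tuple[float, float]) -> list[MolecularFormula]:
    """Saturated C_n H_{2n+2} S_k chains for k = 3..9, up to six CH2
    homologues each, over a carbon range that keeps S/C plausible."""
    out = []
    for k in range(3, 10):
        c0 = max(8, 2 * k - 4)
        for c in range(c0, min(c0 + 6, 18)):
            f = MolecularFormula.from_dict({"C": c, "H": 2 * c + 2, "S": k})
            if mass_range[0] <= monoisotopic_mass(f) <= mass_range[1]:
                out.append(f)
    return out


def generate_population(cfg: PopulationConfig) -> list[MolecularFormula]:
    """Draw a deterministic ground-truth formula population.

    Every member passes the Senior rules and the default ratio filters;
    the family mix of the sampled part matches the configured proportions
    exactly (largest-remainder quotas); planted series are appended in
    full.  The result is deduplicated and sorted by monoisotopic mass.
    """
    rng = np.random.default_rng(cfg.seed)
    bounds = ElementBounds()
    population: list[MolecularFormula] = []
    seen: set[MolecularFormula] = set()
    for family, quota in _family_quotas(cfg).items():
        placed = 0
        failures = 0
        while placed < quota:
            f = _sample_family_formula(rng, family, cfg.mass_range, bounds)
            if f is None or f in seen:
                failures += 1
                if failures > 50 * max(quota, 1):
                    raise InfeasibleConfigError(
                        f"cannot place {quota} valid {family} formulas in "
                        f"mass range {cfg.mass_range}"
                    )
                continue
            seen.add(f)
            population.append(f)
            placed += 1
    for base_text, step, length in cfg.series:
        f = MolecularFormula.parse(base_text)
        for _ in range(length):
            if f not in seen:
                seen.add(f)
                population.append(f)
            nxt = f.shift(step)
            if nxt is None:
                raise InfeasibleConfigError(
                    f"planted series from {base_text} leaves the element space"
                )
            f = nxt
    if cfg.sulfur_series:
        for f in _polysulfur_chains(cfg.mass_range):
            if f not in seen:
                seen.add(f)
                population.append(f)
    population.sort(key=monoisotopic_mass)
    return population


@dataclass
class SimulatedPeakList:
    """A synthetic peak list plus its planted ground truth.

    ``truth`` is aligned with ``peaklist.peaks``: the planted neutral
    formula of each signal peak, None for noise peaks.
    """

    peaklist: PeakList
    truth: tuple[Optional[MolecularFormula], ...]
    ion_types: tuple[Optional[str], ...]

    @property
    def n_noise(self) -> int:
        return sum(1 for t in self.truth if t is None)


def _draw_noise_mz(
    rng: np.random.Generator,
    lo: float,
    hi: float,
    mode: str,
    bounds: ElementBounds,
    guard_ppm: float = 0.5,
    max_tries: int = 2000,
) -> float:
    """Rejection-sample an m/z at least ``guard_ppm`` away from every
    assignable composition, so a noise peak can never be legitimately
    assigned."""
    for _ in range(max_tries):
        mz = float(rng.uniform(lo, hi))
        clean = True
        for label in DEFAULT_MODE_IONS[mode]:
            try:
                from .formula_assign import neutral_mass_from_mz

                neutral = neutral_mass_from_mz(mz, label)
            except ValueError:
                continue
            if enumerate_formulas(neutral, guard_ppm, bounds):
                clean = False
                break
        if clean:
            return mz
    raise RuntimeError("could not place a noise peak away from all formulas")


def simulate_peaklist(
    population: Sequence[MolecularFormula],
    mode: str = "esi_neg",
    ppm_sigma: float = 0.05,
    noise_fraction: float = 0.05,
    intensity_model: tuple[float, float] = (14.0, 1.2),
    seed: int = 0,
    sample_id: str = "synthetic",
    intensities: Optional[Mapping[str, float]] = None,
) -> SimulatedPeakList:
    """Turn a formula population into one synthetic peak list.

    Each formula appears as the mode's primary ion type with a zero-mean
    normal m/z jitter of ``ppm_sigma`` ppm and a log-normal intensity
    (natural-log mean/sigma from ``intensity_model``, overridable
    per-formula through ``intensities``); S/N scales with intensity.
    ``noise_fraction`` of the final peaks are unassignable noise placed by
    rejection against the formula-enumeration oracle (>= 0.5 ppm from any
    bounded composition).
    """
    if ppm_sigma < 0:
        raise ValueError("ppm_sigma must be >= 0")
    if not (0 <= noise_fraction < 1):
        raise ValueError("noise_fraction must be in [0, 1)")
    if mode not in DEFAULT_MODE_IONS:
        raise ValueError(f"unknown ionization mode {mode!r}")
    rng = np.random.default_rng(seed)
    bounds = ElementBounds()
    ion_label = DEFAULT_MODE_IONS[mode][0]
    mu, sigma = intensity_model
    rows: list[tuple[float, float, float, Optional[MolecularFormula], Optional[str]]] = []
    for f in population:
        theo = ion_mz_from_neutral(monoisotopic_mass(f), ion_label)
        mz = theo * (1.0 + ppm_sigma * 1e-6 * rng.standard_normal())
        if intensities is not None:
            inten = float(intensities[f.hill])
        else:
            inten = float(np.exp(rng.normal(mu, sigma)))
        snr = max(3.0, inten / 3000.0)
        rows.append((mz, inten, snr, f, ion_label))
    n_signal = len(rows)
    n_noise = round(noise_fraction * n_signal / (1.0 - noise_fraction))
    if n_noise:
        lo = min(r[0] for r in rows)
        hi = max(r[0] for r in rows)
        for _ in range(n_noise):
            mz = _draw_noise_mz(rng, lo, hi, mode, bounds)
            inten = float(np.exp(rng.normal(mu - 4.0, 0.5)))
            snr = float(rng.uniform(3.0, 12.0))
            rows.append((mz, inten, snr, None, None))
    rows.sort(key=lambda r: r[0])
    peaks = tuple(Peak(mz, inten, snr) for mz, inten, snr, _, _ in rows)
    pl = PeakList(sample_id, mode, peaks)
    return SimulatedPeakList(
        pl,
        tuple(r[3] for r in rows),
        tuple(r[4] for r in rows),
    )


@dataclass
class SimulatedStudy:
    """A planted two-class multi-sample study with work/prediction split."""

    peak_lists: dict[str, SimulatedPeakList]
    intensities: pd.DataFrame  # samples x formulas, ground-truth values
    class_assignments: dict[str, str]
    discriminating_formulas: set[str]
    work_ids: list[str]
    prediction_ids: list[str]
    seed: int

    def to_intensity_matrix(self) -> IntensityMatrix:
        """Ground-truth intensity matrix (bypasses peak-list assignment)."""
        return IntensityMatrix(self.intensities.copy(), dict(self.class_assignments))


def generate_two_class_study(
    n_per_class: tuple[int, int] = (18, 18),
    population: Optional[Sequence[MolecularFormula]] = None,
    effect: float = 4.0,
    noise_sigma: float = 0.25,
    seed: int = 0,
    n_work: int = 25,
    discriminating_fraction: float = 0.10,
    ppm_sigma: float = 0.05,
    noise_fraction: float = 0.0,
    population_size: int = 400,
    mode: str = "esi_neg",
) -> SimulatedStudy:
    """Simulate a two-class study mirroring a 36-sample, 25-work /
    11-prediction multivariate design.

    Class B multiplies the intensities of a planted discriminating formula
    subset (``discriminating_fraction`` of the population) by ``effect``;
    every intensity additionally carries multiplicative log-normal noise of
    scale ``noise_sigma`` (natural-log units).  The work/prediction split
    is a seeded permutation of the samples.
    """
    if effect <= 0:
        raise ValueError("effect must be positive")
    rng = np.random.default_rng(seed)
    if population is None:
        population = generate_population(
            PopulationConfig(
                n_formulas=population_size,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    hills = [f.hill for f in population]
    n_total = sum(n_per_class)
    if not (1 <= n_work < n_total):
        raise ValueError("n_work must leave at least one prediction sample")
    n_disc = max(1, round(discriminating_fraction * len(population)))
    disc_idx = rng.choice(len(population), size=n_disc, replace=False)
    disc = {hills[i] for i in disc_idx}
    base_log = rng.normal(14.0, 1.2, size=len(population))
    sample_ids = [f"S{i + 1:02d}" for i in range(n_total)]
    classes = ["A"] * n_per_class[0] + ["B"] * n_per_class[1]
    order = rng.permutation(n_total)
    class_assignments = {sample_ids[i]: classes[order[i]] for i in range(n_total)}
    rows = {}
    peak_lists = {}
    for sid in sample_ids:
        shift = np.array(
            [math.log(effect) if (class_assignments[sid] == "B" and h in disc) else 0.0
             for h in hills]
        )
        log_int = base_log + shift + rng.normal(0.0, noise_sigma, size=len(population))
        inten = np.exp(log_int)
        rows[sid] = inten
        peak_lists[sid] = simulate_peaklist(
            population,
            mode=mode,
            ppm_sigma=ppm_sigma,
            noise_fraction=noise_fraction,
            seed=int(rng.integers(2**31 - 1)),
            sample_id=sid,
            intensities=dict(zip(hills, inten)),
        )
    df = pd.DataFrame.from_dict(rows, orient="index", columns=hills)
    split = rng.permutation(n_total)
    work_ids = [sample_ids[i] for i in sorted(split[:n_work])]
    prediction_ids = [sample_ids[i] for i in sorted(split[n_work:])]
    return SimulatedStudy(
        peak_lists=peak_lists,
        intensities=df,
        class_assignments=class_assignments,
        discriminating_formulas=disc,
        work_ids=work_ids,
        prediction_ids=prediction_ids,
        seed=seed,
    )
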
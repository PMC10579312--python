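"""Peak-list input/output, signal-to-noise filtering and mass recalibration.

This is the I/O boundary of the pipeline.  Peak lists are the exported,
centroided output of an ultrahigh-resolution (FT-ICR) mass spectrometer:
one row per detected ion with m/z, abundance and signal-to-noise ratio.
All ions are treated as singly charged; multiply charged species are
assumed to have been rejected upstream.

File dialect
------------
Tab-separated text with a required header row naming at least the columns
``mz``, ``intensity`` and ``snr`` (extra columns are ignored).  Lines
starting with ``#`` are comments.  ``write_peaklist`` serialises floats at
full (round-trip exact) precision.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

IONIZATION_MODES = ("esi_neg", "esi_pos", "appi_pos")
EXTRACTION_SOLVENTS = ("hexane", "dichloromethane", "methanol", "water", "other")

__all__ = [
    "IONIZATION_MODES",
    "EXTRACTION_SOLVENTS",
    "Peak",
    "PeakList",
    "CalibrationFit",
    "PeaklistFormatError",
    "PeaklistParseError",
    "CalibrationError",
    "read_peaklist",
    "write_peaklist",
    "filter_snr",
    "recalibrate",
]


class PeaklistFormatError(ValueError):
    """Structural problem with a peak-list file (e.g. a missing column)."""


class PeaklistParseError(ValueError):
    """A cell in a peak-list file could not be parsed as a number."""


class CalibrationError(RuntimeError):
    """Too few reference masses matched to fit the requested model."""


@dataclass(frozen=True)
class Peak:
    """One detected ion: m/z (Da, charge 1), abundance and S/N ratio."""

    mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")
        if self.snr < 0:
            raise ValueError(f"snr must be >= 0, got {self.snr}")


@dataclass(frozen=True)
class PeakList:
    """A sample's peaks, strictly sorted by m/z, with acquisition metadata."""

    sample_id: str
    ionization_mode: str
    peaks: tuple[Peak, ...]
    extraction_solvent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ionization_mode not in IONIZATION_MODES:
            raise ValueError(
                f"unknown ionization_mode {self.ionization_mode!r}; "
                f"expected one of {IONIZATION_MODES}"
            )
        mz = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mz, mz[1:])):
            raise ValueError("peaks must be strictly increasing in mz")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)

    @property
    def snr(self) -> np.ndarray:
        return np.array([p.snr for p in self.peaks], dtype=float)


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted systematic ppm-error model of a spectrum.

    ``coefficients`` is ``(offset_ppm,)`` for the constant model and
    ``(offset_ppm, slope_ppm_per_da)`` for the linear model, so that the
    predicted error at mass m is ``offset + slope * m`` (ppm).
    """

    model_kind: Literal["constant_ppm", "linear_ppm"]
    coefficients: tuple[float, ...]
    n_reference_points: int
    residual_rms_ppm: float

    def predict_ppm(self, mz: np.ndarray | float) -> np.ndarray | float:
        if self.model_kind == "constant_ppm":
            return np.zeros_like(np.asarray(mz, dtype=float)) + self.coefficients[0]
        offset, slope = self.coefficients
        return offset + slope * np.asarray(mz, dtype=float)


def _merge_duplicates(rows: list[tuple[float, float, float]]) -> list[tuple[float, float, float]]:
    # identical mz rows: intensities sum, snr takes the max (order independent)
    merged: dict[float, list[float]] = {}
    for mz, inten, snr in rows:
        if mz in merged:
            merged[mz][0] += inten
            merged[mz][1] = max(merged[mz][1], snr)
        else:
            merged[mz] = [inten, snr]
    return [(mz, v[0], v[1]) for mz, v in merged.items()]


def read_peaklist(
    path: str | Path,
    sample_id: str,
    ionization_mode: str,
    extraction_solvent: Optional[str] = None,
) -> PeakList:
    """Read a TSV peak list.

    Raises :class:`PeaklistFormatError` if a required column is absent and
    :class:`PeaklistParseError` (with the 1-based file line number) if a
    cell is not numeric.  Duplicate identical m/z rows are merged (summed
    intensity, max S/N) and the result is sorted by m/z.
    """
    path = Path(path)
    rows: list[tuple[float, float, float]] = []
    header: Optional[dict[str, int]] = None
    with path.open(newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = next(csv.reader([line], delimiter="\t"))
            if header is None:
                names = [c.strip() for c in cells]
                header = {name: i for i, name in enumerate(names)}
                for col in ("mz", "intensity", "snr"):
                    if col not in header:
                        raise PeaklistFormatError(
                            f"{path}: missing required column {col!r} "
                            f"(found {names})"
                        )
                continue
            values = []
            for col in ("mz", "intensity", "snr"):
                cell = cells[header[col]].strip()
                try:
                    values.append(float(cell))
                except ValueError:
                    raise PeaklistParseError(
                        f"{path}:{lineno}: non-numeric value {cell!r} "
                        f"in column {col!r}"
                    ) from None
            rows.append((values[0], values[1], values[2]))
    rows = _merge_duplicates(rows)
    rows.sort(key=lambda r: r[0])
    peaks = tuple(Peak(mz, inten, snr) for mz, inten, snr in rows)
    return PeakList(sample_id, ionization_mode, peaks, extraction_solvent)


def write_peaklist(pl: PeakList, path: str | Path) -> None:
    """Write a peak list in the TSV dialect read by :func:`read_peaklist`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_id: {pl.sample_id}\n")
        fh.write(f"# ionization_mode: {pl.ionization_mode}\n")
        if pl.extraction_solvent is not None:
            fh.write(f"# extraction_solvent: {pl.extraction_solvent}\n")
        fh.write("mz\tintensity\tsnr\n")
        for p in pl.peaks:
            fh.write(f"{p.mz!r}\t{p.intensity!r}\t{p.snr!r}\n")


def filter_snr(pl: PeakList, threshold: float) -> PeakList:
    """Retain exactly the peaks with S/N >= ``threshold`` (order preserved).

    The boundary is inclusive: the conventional export cut-off "S/N >= 3"
    keeps a peak whose ratio is exactly 3.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    kept = tuple(p for p in pl.peaks if p.snr >= threshold)
    return replace(pl, peaks=kept)


def fatty_acid_calibrants(
    c_range: tuple[int, int] = (8, 24), ion_type: str = "[M-H]-"
) -> list[tuple[float, str]]:
    """Example internal-calibration reference series: saturated fatty acids
    CnH2nO2 over the given carbon range, as ``(neutral mass, ion type)``
    pairs.  A ubiquitous CHO homologous series; substitute a user-supplied
    list for instrument-specific calibrants."""
    from .formula_assign import MolecularFormula, monoisotopic_mass

    refs = []
    for c in range(c_range[0], c_range[1] + 1):
        f = MolecularFormula.from_dict({"C": c, "H": 2 * c, "O": 2})
        refs.append((monoisotopic_mass(f), ion_type))
    return refs


def recalibrate(
    pl: PeakList,
    reference_masses: Sequence[tuple[float, str]],
    tol_ppm: float = 1.0,
    model_kind: Literal["constant_ppm", "linear_ppm"] = "constant_ppm",
) -> tuple[PeakList, CalibrationFit]:
    """Internally recalibrate a peak list against known reference ions.

    ``reference_masses`` is a list of ``(neutral monoisotopic mass, ion type
    label)`` pairs (e.g. a homologous fatty-acid series).  Each reference
    whose theoretical ion m/z matches a peak within ``tol_ppm`` contributes
    an observed ppm error ``(observed - expected) / expected * 1e6``; a
    constant or linear (in m/z) ppm-error model is fitted to the matched
    references and inverted on every peak.  The residual RMS is recomputed
    on the matched references *after* correction.
    """
    from .formula_assign import ion_mz_from_neutral  # local import: avoids cycle

    need = 1 if model_kind == "constant_ppm" else 2
    mz = pl.mz
    matched_obs: list[float] = []
    matched_exp: list[float] = []
    for neutral, ion_label in reference_masses:
        expected = ion_mz_from_neutral(neutral, ion_label)
        if len(mz) == 0:
            continue
        i = int(np.argmin(np.abs(mz - expected)))
        err_ppm = (mz[i] - expected) / expected * 1e6
        if abs(err_ppm) <= tol_ppm:
            matched_obs.append(mz[i])
            matched_exp.append(expected)
    n = len(matched_obs)
    if n < need:
        raise CalibrationError(
            f"{model_kind} calibration needs >= {need} matched references, "
            f"matched {n} of {len(reference_masses)} within {tol_ppm} ppm"
        )
    obs = np.asarray(matched_obs)
    exp = np.asarray(matched_exp)
    err = (obs - exp) / exp * 1e6
    if model_kind == "constant_ppm":
        coeffs = (float(np.mean(err)),)
    else:
        slope, offset = np.polyfit(obs, err, 1)
        coeffs = (float(offset), float(slope))
    fit = CalibrationFit(model_kind, coeffs, n, 0.0)
    corrected = mz / (1.0 + np.asarray(fit.predict_ppm(mz)) * 1e-6)
    # residual on references after correction
    obs_corr = obs / (1.0 + np.asarray(fit.predict_ppm(obs)) * 1e-6)
    resid = (obs_corr - exp) / exp * 1e6
    fit = replace(fit, residual_rms_ppm=float(np.sqrt(np.mean(resid**2))))
    peaks = tuple(
        Peak(float(m), p.intensity, p.snr) for m, p in zip(corrected, pl.peaks)
    )
    return replace(pl, peaks=peaks), fit
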
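import numpy as np
import pytest

from somatlas import MolecularFormula, Peak, PeakList


@pytest.fixture
def small_bounds():
    """A narrow element space for exhaustive-oracle comparisons."""
    from somatlas import ElementBounds

    return ElementBounds(
        c=(1, 15), h=(0, 30), n=(0, 2), o=(0, 6), s=(0, 2),
        na=(0, 1), mg=(0, 0), cl=(0, 0),
    )


@pytest.fixture
def fatty_acid_refs():
    """A CHO homologous reference series (saturated fatty acids C8-C18)
    with theoretical deprotonated masses, for calibration tests."""
    from somatlas import ion_mz_from_neutral, monoisotopic_mass

    refs = []
    for c in range(8, 19):
        f = MolecularFormula.from_dict({"C": c, "H": 2 * c, "O": 2})
        refs.append((monoisotopic_mass(f), "[M-H]-"))
    return refs


def make_peaklist(mz, intensity=None, snr=None, mode="esi_neg", sample_id="s"):
    mz = list(mz)
    intensity = intensity or [1000.0] * len(mz)
    snr = snr or [50.0] * len(mz)
    peaks = tuple(
        Peak(m, i, s) for m, i, s in sorted(zip(mz, intensity, snr))
    )
    return PeakList(sample_id, mode, peaks)


@pytest.fixture
def peaklist_factory():
    return make_peaklist
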
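import numpy as np
import pandas as pd
import pytest

import wormetab as w
from wormetab.synthdata import render_spectrum

AFFECTED_FOLD2 = {"alanine": 2.0, "betaine": 2.0, "fumarate": 2.0, "ATP": 2.0}


@pytest.fixture(scope="session")
def library43():
    return w.default_library(43)


@pytest.fixture(scope="session")
def two_group_study(library43):
    """A fold-2, 10+10 synthetic study at default noise, fully preprocessed."""
    design = w.StudyDesign(
        groups=[("CON", 10), ("T", 10)],
        effects={m: {"T": f} for m, f in AFFECTED_FOLD2.items()},
        seed=42,
    )
    sset, truth = w.simulate_study(library43, design)
    trimmed = w.exclude_region(sset, 4.70, 5.25)
    bt = w.adaptive_bin(trimmed)
    fm = w.pqn_normalize(bt)
    return dict(sset=sset, trimmed=trimmed, bt=bt, fm=fm, truth=truth,
                design=design)


@pytest.fixture()
def flat_spectra_set():
    """Constant-intensity spectra on the default grid (binning arithmetic)."""
    ppm = np.linspace(0.0, 10.0, 2**14)
    X = np.ones((2, ppm.size))
    man = pd.DataFrame({"group": ["a", "a"]}, index=["s1", "s2"])
    return w.SpectraSet(ppm, X, ["s1", "s2"], man)


def signal_bins(bins, ppm, library, names, frac=0.10):
    """Bins receiving >= frac of a metabolite's strongest bin signal,
    from a noiseless single-metabolite render (the planted-signal map)."""
    defs = {m.name: m for m in library}
    out = set()
    for name in names:
        y = render_spectrum([defs[name]], {name: 1.0}, ppm)
        vals = np.zeros(len(bins))
        for k, b in enumerate(bins):
            sel = (ppm >= b.lo_ppm) & (ppm < b.hi_ppm)
            if sel.any():
                vals[k] = np.trapezoid(y[sel], ppm[sel])
        out |= set(np.nonzero(vals >= frac * vals.max())[0])
    return out
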
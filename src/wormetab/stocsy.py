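"""Statistical total correlation spectroscopy (STOCSY).

Correlates the intensity of one spectral bin (the driver) against every
other bin across samples; resonances belonging to the same molecule vary
together with concentration and therefore correlate near 1, which assists
metabolite assignment. Correlations are computed on the normalized,
uncentered bin matrix (Pearson centering is implicit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .spectra import FeatureMatrix


@dataclass
class StocsyResult:
    driver_ppm: float
    driver_bin: int
    correlations: np.ndarray
    covariances: np.ndarray


def _resolve_driver(fm: FeatureMatrix, driver_ppm: float) -> int:
    for j, b in enumerate(fm.bins):
        if b.lo_ppm <= driver_ppm < b.hi_ppm:
            return j
    mids = fm.feature_ppm
    order = np.argsort(np.abs(mids - driver_ppm))[:2]
    near = ", ".join(f"{mids[j]:.4f}" for j in sorted(order))
    raise InputError(
        f"driver {driver_ppm} ppm falls in no bin; nearest bin midpoints: {near}"
    )


def _corr_cov(X: np.ndarray, driver: np.ndarray):
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    dc = driver - driver.mean()
    cov = Xc.T @ dc / (n - 1)
    sd = Xc.std(axis=0, ddof=1)
    sdd = dc.std(ddof=1)
    corr = np.zeros_like(cov)
    nz = (sd > 0) & (sdd > 0)
    corr[nz] = cov[nz] / (sd[nz] * sdd)
    return corr, cov


def stocsy_1d(fm: FeatureMatrix, driver_ppm: float) -> StocsyResult:
    """1D STOCSY trace for one driver position."""
    if fm.X.shape[0] < 3:
        raise InputError("STOCSY needs at least 3 samples")
    j = _resolve_driver(fm, driver_ppm)
    corr, cov = _corr_cov(fm.X, fm.X[:, j])
    return StocsyResult(driver_ppm, j, corr, cov)


def stocsy_2d(fm: FeatureMatrix, max_features: int = 2000) -> np.ndarray:
    """Full feature x feature correlation matrix (symmetric, unit diagonal)."""
    if fm.X.shape[0] < 3:
        raise InputError("STOCSY needs at least 3 samples")
    p = fm.X.shape[1]
    if p > max_features:
        raise InputError(
            f"{p} features exceeds the 2D STOCSY cap ({max_features}); "
            "restrict the ppm window or raise max_features"
        )
    sd = fm.X.std(axis=0, ddof=1)
    Xc = fm.X - fm.X.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, Xc / sd, 0.0)
        C = Z.T @ Z / (fm.X.shape[0] - 1)
    C[np.diag_indices(p)] = 1.0
    return np.clip((C + C.T) / 2.0, -1.0, 1.0)


def write_stocsy_csv(fm: FeatureMatrix, result: StocsyResult, path: str) -> None:
    import pandas as pd

    pd.DataFrame({
        "ppm": fm.feature_ppm,
        "correlation": result.correlations,
        "covariance": result.covariances,
    }).to_csv(path, index=False, float_format="%.6g")
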
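"""Univariate layer: metabolite integrals, fold changes, Student's t-tests,
Benjamini-Hochberg adjustment and the colored fold-change table.

Fold change is mean(dosed)/mean(control); stars follow the conventional
raw-p thresholds (* < 0.05, ** < 0.01, *** < 0.001) while the BH-adjusted
q value is reported alongside. The BH family is, by default, all
metabolites within one treated-vs-control comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .spectra import FeatureMatrix


def load_assignments(path: str) -> pd.DataFrame:
    """Assignment CSV with columns metabolite, lo_ppm, hi_ppm (several rows
    per metabolite allowed)."""
    df = pd.read_csv(path)
    for col in ("metabolite", "lo_ppm", "hi_ppm"):
        if col not in df.columns:
            raise InputError(f"{path}: assignment table lacks column {col!r}")
    bad = df[df.lo_ppm >= df.hi_ppm]
    if len(bad):
        raise InputError(f"{path}: windows with lo >= hi for {bad.metabolite.tolist()}")
    return df


def metabolite_integrals(fm: FeatureMatrix, assignments: pd.DataFrame) -> pd.DataFrame:
    """Sample x metabolite matrix: sum of bin values whose midpoints fall in
    any of the metabolite's ppm windows."""
    if fm.centered:
        raise InputError("metabolite_integrals expects the uncentered matrix")
    mids = fm.feature_ppm
    out = {}
    for met, sub in assignments.groupby("metabolite", sort=False):
        mask = np.zeros(mids.size, bool)
        for _, row in sub.iterrows():
            mask |= (mids >= row.lo_ppm) & (mids < row.hi_ppm)
        if not mask.any():
            raise InputError(f"metabolite {met!r}: windows intersect no bins")
        out[met] = fm.X[:, mask].sum(axis=1)
    return pd.DataFrame(out, index=fm.sample_ids)


def fold_change(treated: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """(fold, log2 fold) of group means, dosed over control."""
    treated = np.asarray(treated, float)
    control = np.asarray(control, float)
    cm = control.mean()
    if not cm > 0:
        raise InputError(f"control mean must be positive (got {cm})")
    fold = treated.mean() / cm
    return float(fold), float(np.log2(fold))


def t_test(treated: np.ndarray, control: np.ndarray, welch: bool = False) -> float:
    """Two-sided Student's t-test p-value (pooled variance by default;
    ``welch=True`` for unequal variances)."""
    treated = np.asarray(treated, float)
    control = np.asarray(control, float)
    if treated.size < 2 or control.size < 2:
        raise InputError("t_test needs n >= 2 per group")
    if treated.var(ddof=1) == 0 and control.var(ddof=1) == 0:
        return 1.0 if treated.mean() == control.mean() else 1e-300
    res = sps.ttest_ind(treated, control, equal_var=not welch)
    return float(max(res.pvalue, 1e-300))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise InputError("bh_adjust: empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise InputError("bh_adjust: p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class FoldChangeTable:
    table: pd.DataFrame  # metabolite, comparison, fold, log2_fold, p_raw, q_bh, stars

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")

    def to_html(self, path: str, max_abs_log2: float = 2.0) -> None:
        """Colored export: red = increased, blue = decreased, stars by p."""
        rows = []
        for _, r in self.table.iterrows():
            x = np.clip(r.log2_fold / max_abs_log2, -1, 1)
            if x > 0:
                color = f"rgb(255,{int(255 * (1 - x))},{int(255 * (1 - x))})"
            elif x < 0:
                color = f"rgb({int(255 * (1 + x))},{int(255 * (1 + x))},255)"
            else:
                color = "rgb(255,255,255)"
            rows.append(
                f"<tr><td>{r.metabolite}</td><td>{r.comparison}</td>"
                f"<td style='background-color:{color}'>{r.fold:.3f}{r.stars}</td>"
                f"<td>{r.log2_fold:.3f}</td><td>{r.p_raw:.3g}</td>"
                f"<td>{r.q_bh:.3g}</td></tr>"
            )
        html = (
            "<table border=1><tr><th>metabolite</th><th>comparison</th>"
            "<th>fold</th><th>log2(fold)</th><th>p</th><th>q(BH)</th></tr>"
            + "".join(rows) + "</table>"
        )
        with open(path, "w") as fh:
            fh.write(html)


def build_fold_change_table(
    integrals: pd.DataFrame,
    manifest: pd.DataFrame,
    comparisons: list[tuple[str, str]],
    stars_on: str = "raw",
    welch: bool = False,
) -> FoldChangeTable:
    """One row per (metabolite, treated-vs-control comparison); BH applied
    within each comparison across metabolites."""
    groups = manifest.loc[integrals.index, "group"]
    known = set(groups)
    for treated, control in comparisons:
        missing = {treated, control} - known
        if missing:
            raise InputError(f"unknown group(s) in comparison: {sorted(missing)}")
    if stars_on not in ("raw", "adjusted"):
        raise InputError("stars_on must be 'raw' or 'adjusted'")
    frames = []
    for treated, control in comparisons:
        ti = integrals[groups == treated]
        ci = integrals[groups == control]
        recs = []
        for met in integrals.columns:
            f, lf = fold_change(ti[met].to_numpy(), ci[met].to_numpy())
            p = t_test(ti[met].to_numpy(), ci[met].to_numpy(), welch=welch)
            recs.append((met, f"{treated}/{control}", f, lf, p))
        df = pd.DataFrame(recs, columns=["metabolite", "comparison", "fold",
                                         "log2_fold", "p_raw"])
        df["q_bh"] = bh_adjust(df.p_raw.to_numpy())
        key = df.p_raw if stars_on == "raw" else df.q_bh
        df["stars"] = [_stars(p) for p in key]
        frames.append(df)
    return FoldChangeTable(pd.concat(frames, ignore_index=True))


def significant_metabolites(
    fct: FoldChangeTable, comparison: str | None = None,
    on: str = "p_raw", alpha: float = 0.05,
) -> list[str]:
    """Metabolite names below ``alpha`` (on raw p or BH q), for pathway input."""
    t = fct.table
    if comparison is not None:
        t = t[t.comparison == comparison]
    return sorted(t.loc[t[on] < alpha, "metabolite"].unique().tolist())
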
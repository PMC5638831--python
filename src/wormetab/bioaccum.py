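"""Metal bookkeeping: bioaccumulation factors (BAF) and survival rates.

BAF = metal concentration in the organism (mg/kg dry weight) divided by the
metal concentration of the soil (mg/kg). Soil-dwelling invertebrates
typically show BAF well below 1 for Pb and well above 10 for Cd, which the
summary flags (Pb < 0.3, Cd > 10) make explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

PB_BOUND = 0.3  # Pb BAF expected below this
CD_BOUND = 10.0  # Cd BAF expected above this


def compute_baf(worm_conc: float, soil_conc: float) -> float:
    """worm concentration / soil concentration (3-decimal rounding is
    applied only in report tables)."""
    if not soil_conc > 0:
        raise InputError(f"soil concentration must be > 0 (got {soil_conc})")
    if worm_conc < 0:
        raise InputError(f"worm concentration must be >= 0 (got {worm_conc})")
    return worm_conc / soil_conc


def survival_rate(n_initial: int, n_deaths: int) -> float:
    """1 - deaths/initial over the whole exposure period."""
    if n_initial <= 0:
        raise InputError("n_initial must be > 0")
    if not 0 <= n_deaths <= n_initial:
        raise InputError(f"n_deaths {n_deaths} outside [0, {n_initial}]")
    return 1.0 - n_deaths / n_initial


@dataclass
class BafTable:
    table: pd.DataFrame  # group, soil, metal, day, worm_conc, soil_conc, baf
    summary: pd.DataFrame  # per metal: min, max
    flags: pd.DataFrame  # rows violating the expected per-metal bounds

    def to_csv(self, path: str) -> None:
        out = self.table.copy()
        out["baf"] = out["baf"].round(3)
        out.to_csv(path, index=False)

    def to_markdown(self) -> str:
        lines = ["| metal | min BAF | max BAF |", "|---|---|---|"]
        for metal, row in self.summary.iterrows():
            lines.append(f"| {metal} | {row['min']:.3f} | {row['max']:.3f} |")
        if len(self.flags):
            lines.append("")
            lines.append(f"{len(self.flags)} row(s) outside the expected bounds "
                         f"(Pb < {PB_BOUND}, Cd > {CD_BOUND}).")
        return "\n".join(lines)


def _infer_metal(group: str) -> str:
    return "".join(ch for ch in str(group) if not ch.isdigit())


def baf_table(records: pd.DataFrame) -> BafTable:
    """Row-wise BAF plus per-metal min/max summary.

    ``records`` needs columns group, soil, day, worm_conc, soil_conc
    (``metal`` optional; inferred from the group label otherwise).
    Duplicate (group, soil, day) rows are rejected.
    """
    if len(records) == 0:
        raise InputError("no exposure records")
    req = {"group", "soil", "day", "worm_conc", "soil_conc"}
    missing = req - set(records.columns)
    if missing:
        raise InputError(f"exposure records lack column(s): {sorted(missing)}")
    df = records.copy()
    dup = df.duplicated(subset=["group", "soil", "day"])
    if dup.any():
        raise InputError(
            f"duplicate (group, soil, day) rows: "
            f"{df.loc[dup, ['group', 'soil', 'day']].to_records(index=False).tolist()}"
        )
    if "metal" not in df.columns:
        df["metal"] = df["group"].map(_infer_metal)
    df["baf"] = [
        compute_baf(w, s) for w, s in zip(df["worm_conc"], df["soil_conc"])
    ]
    summary = df.groupby("metal")["baf"].agg(["min", "max"])
    bad = np.zeros(len(df), bool)
    bad |= (df["metal"].str.contains("Pb")) & (df["baf"] >= PB_BOUND)
    bad |= (df["metal"].str.contains("Cd")) & (df["baf"] <= CD_BOUND)
    return BafTable(table=df, summary=summary, flags=df[bad])


def survival_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-group survival rates from n_initial / n_deaths columns."""
    req = {"group", "n_initial", "n_deaths"}
    if not req <= set(records.columns):
        raise InputError(f"survival summary needs columns {sorted(req)}")
    g = records.drop_duplicates(subset=["group"])
    return pd.DataFrame({
        "group": g["group"],
        "survival_rate": [
            survival_rate(int(a), int(d))
            for a, d in zip(g["n_initial"], g["n_deaths"])
        ],
    }).reset_index(drop=True)
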
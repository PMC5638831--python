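"""Bundled reference data: group-mean metal concentrations from a
two-week Eisenia fetida exposure to Pb-spiked cambosol ('C') and ferrosol
('F') and Cd-spiked ferrosol, sampled on days 1, 7 and 14.

Earthworm concentrations are group means in mg/kg dry weight; soil
concentrations are the measured totals of the aged spiked soils in mg/kg.
These numbers are the inputs for the worked bioaccumulation-factor
examples (Pb BAF spans 0.005-0.266; Cd BAF stays above 10).
"""

from __future__ import annotations

import pandas as pd

# soil metal concentrations, mg/kg: (soil, dose label) -> concentration
SOIL_PB = {("C", "Pb1"): 152.23, ("C", "Pb2"): 324.99,
           ("F", "Pb1"): 133.20, ("F", "Pb2"): 248.67}
SOIL_CD = {("F", "Cd1"): 0.252, ("F", "Cd2"): 0.524}

# earthworm group means, mg/kg dry weight, on days 1/7/14
WORM_PB = {
    ("C", "Pb1"): (0.76, 1.23, 1.75),
    ("C", "Pb2"): (1.72, 2.43, 7.52),
    ("F", "Pb1"): (0.97, 9.26, 26.46),
    ("F", "Pb2"): (1.86, 34.72, 66.24),
}
WORM_CD = {
    ("F", "Cd1"): (4.69, 5.59, 5.93),
    ("F", "Cd2"): (5.33, 7.12, 9.45),
}

DAYS = (1, 7, 14)


def pb_cd_exposure() -> pd.DataFrame:
    """Exposure records (one row per group x soil x day) ready for
    :func:`wormetab.bioaccum.baf_table`. Each group started with 30 worms
    (3 replicates x 10); survival was 97-100%."""
    rows = []
    # isolated deaths occurred in a few beakers, independent of treatment
    deaths = {("C", "Pb1"): 1, ("F", "Cd2"): 1}
    for (soil, grp), worms in {**WORM_PB, **WORM_CD}.items():
        metal = "Pb" if grp.startswith("Pb") else "Cd"
        soilc = (SOIL_PB if metal == "Pb" else SOIL_CD)[(soil, grp)]
        for day, w in zip(DAYS, worms):
            rows.append({
                "group": grp, "soil": soil, "metal": metal, "day": day,
                "worm_conc": w, "soil_conc": soilc,
                "n_initial": 30, "n_deaths": deaths.get((soil, grp), 0),
            })
    return pd.DataFrame(rows)
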
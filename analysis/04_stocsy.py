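"""STOCSY assignment check.

Drives STOCSY from lactate's methyl doublet (1.33 ppm) and reports the
strongest correlations; in a correct simulation + preprocessing chain the
methine quartet near 4.11 ppm lights up (same molecule, shared
concentration), while unrelated metabolites stay near the correlation
noise floor. Writes the 1D trace and the significant cross-peaks.
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

import wormetab as w
from wormetab.stocsy import write_stocsy_csv

ROOT = pathlib.Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--matrix", default=str(ROOT / "results" / "feature_matrix.csv"))
    ap.add_argument("--driver", type=float, default=1.33)
    ap.add_argument("--out", default=str(ROOT / "results" / "stocsy"))
    args = ap.parse_args()

    fm = w.FeatureMatrix.from_csv(args.matrix)
    res = w.stocsy_1d(fm, args.driver)
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    write_stocsy_csv(fm, res, str(out / f"stocsy_{args.driver:.2f}.csv"))

    mids = fm.feature_ppm
    order = np.argsort(-np.abs(res.correlations))
    print(f"driver {args.driver} ppm (bin midpoint {mids[res.driver_bin]:.3f})")
    print("strongest correlations outside the driver's own multiplet:")
    shown = 0
    for j in order:
        if abs(mids[j] - args.driver) < 0.05:
            continue
        print(f"  {mids[j]:7.3f} ppm   r = {res.correlations[j]:+.3f}")
        shown += 1
        if shown >= 6:
            break


if __name__ == "__main__":
    main()
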
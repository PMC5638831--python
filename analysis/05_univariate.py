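"""Univariate fold-change tables.

Integrates the normalized bins into metabolite-level values using the ppm
assignment windows, then per dose-vs-control comparison computes fold
changes, Student's t-tests and BH-adjusted q values, exporting the CSV
and the colored HTML table (red = increased, blue = decreased, stars by
raw p). Prints the significantly changed metabolites per comparison.
"""

import argparse
import pathlib

import pandas as pd

import wormetab as w
from wormetab.stats import load_assignments, significant_metabolites

ROOT = pathlib.Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--matrix", default=str(ROOT / "results" / "feature_matrix.csv"))
    ap.add_argument("--manifest",
                    default=str(ROOT / "results" / "simulated_study" / "manifest.csv"))
    ap.add_argument("--assignments",
                    default=str(ROOT / "results" / "simulated_study" / "assignments.csv"))
    ap.add_argument("--out", default=str(ROOT / "results"))
    args = ap.parse_args()

    man = pd.read_csv(args.manifest).set_index("sample_id")
    fm = w.FeatureMatrix.from_csv(args.matrix, man)
    asg = load_assignments(args.assignments)
    integrals = w.metabolite_integrals(fm, asg)

    labels = fm.group_labels()
    control = "CON"
    comparisons = [(g, control) for g in pd.unique(labels) if g != control]
    fct = w.build_fold_change_table(integrals, man, comparisons)

    out = pathlib.Path(args.out)
    fct.to_csv(str(out / "fold_changes.csv"))
    fct.to_html(str(out / "fold_changes.html"))
    for treated, ctrl in comparisons:
        sig = significant_metabolites(fct, comparison=f"{treated}/{ctrl}",
                                      on="q_bh")
        sub = fct.table[(fct.table.comparison == f"{treated}/{ctrl}")
                        & fct.table.metabolite.isin(sig)]
        print(f"{treated} vs {ctrl}: {len(sig)} metabolites with q < 0.05")
        for _, r in sub.iterrows():
            print(f"  {r.metabolite:30s} fold {r.fold:5.2f}  "
                  f"p {r.p_raw:.2e}{r.stars}  q {r.q_bh:.2e}")


if __name__ == "__main__":
    main()
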
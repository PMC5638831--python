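"""Pathway impact analysis of the significantly changed metabolites.

Feeds each comparison's significant metabolites into the MetPA-style
analysis (hypergeometric over-representation + relative-betweenness
topology impact) over the bundled toy pathway library, writes the per-
pathway tables and bubble plots, and prints the top pathways.
"""

import argparse
import pathlib

import pandas as pd

import wormetab as w
from wormetab import plots
from wormetab.pathway import toy_library
from wormetab.stats import FoldChangeTable, significant_metabolites

ROOT = pathlib.Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fold-changes", default=str(ROOT / "results" / "fold_changes.csv"))
    ap.add_argument("--assignments",
                    default=str(ROOT / "results" / "simulated_study" / "assignments.csv"))
    ap.add_argument("--out", default=str(ROOT / "results" / "pathway"))
    args = ap.parse_args()

    table = pd.read_csv(args.fold_changes)
    fct = FoldChangeTable(table)
    library = toy_library()
    universe = set(pd.read_csv(args.assignments).metabolite)
    universe |= set().union(*(pg.nodes for pg in library))

    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    for comparison in table.comparison.unique():
        hits = set(significant_metabolites(fct, comparison=comparison))
        res = w.metpa(hits, library, universe)
        tag = comparison.replace("/", "_vs_")
        res.to_csv(str(out / f"metpa_{tag}.csv"), index=False)
        plots.pathway_bubble_plot(res, str(out / f"bubble_{tag}.png"))
        print(f"{comparison}: {len(hits)} hit metabolites")
        for _, r in res.head(3).iterrows():
            print(f"  {r.pathway:45s} raw_p {r.raw_p:.3g}  impact {r.impact:.2f}")


if __name__ == "__main__":
    main()
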
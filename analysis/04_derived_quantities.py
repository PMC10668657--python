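#!/usr/bin/env python
"""Derive the headline quantities from the fitted posterior.

Reads the fitted run's estimates/contrasts tables and prints the
period-by-period story: apparent survival per age class, the transient
proportion among newly marked immatures and adults, the later-minus-
earlier period differences with 95% credible intervals, and the
trap-response labels. Writes results/derived/summary.txt.
"""

import argparse
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def fmt(row) -> str:
    return f"{row['mean']:.3f} [{row['lo95']:.3f}, {row['hi95']:.3f}]"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fit", type=Path, default=ROOT / "results" / "fit")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "derived")
    args = parser.parse_args()

    est = pd.read_csv(args.fit / "estimates.csv")
    con = pd.read_csv(args.fit / "contrasts.csv")
    lines = []

    def emit(text=""):
        lines.append(text)
        print(text)

    emit("Posterior mean [95% BCI] by period "
         "(1 = before the WTC, 2 = substantial reduction, 3 = extreme reduction)")
    for quantity, label in (("phi", "apparent survival"),
                            ("tau", "transient proportion"),
                            ("p", "recapture probability")):
        emit(f"\n{label}:")
        sub = est[est.quantity == quantity]
        for cat in sub.category.unique():
            cells = [fmt(r) for _, r in sub[sub.category == cat].iterrows()]
            emit(f"  {cat:>24}: " + " | ".join(cells))

    emit("\nPeriod contrasts (later minus earlier):")
    key_cells = [("phi", "1"), ("phi", "3"), ("phi", "5"),
                 ("tau", "immature"), ("tau", "adult")]
    names = {"1": "juvenile phi", "3": "resident immature phi",
             "5": "resident adult phi", "immature": "immature tau",
             "adult": "adult tau"}
    for quantity, cell in key_cells:
        sub = con[(con.quantity == quantity) & (con.cell == cell)]
        for _, r in sub.iterrows():
            emit(f"  {names[cell]:>22} P{r.later}-P{r.earlier}: "
                 f"{r.mean_difference:+.3f} [{r.lo95:+.3f}, {r.hi95:+.3f}] "
                 f"({r.direction})")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "summary.txt").write_text("\n".join(lines) + "\n")
    print(f"\nwrote {args.out / 'summary.txt'}")


if __name__ == "__main__":
    main()
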
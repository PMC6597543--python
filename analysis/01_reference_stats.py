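#!/usr/bin/env python
"""Recompute the species-comparison statistics from the published index table.

Aggregates the bundled per-specimen rows (six indices, 12 species, four
genera) to species values and runs the cross-genus exact binomial tests.
Writes results/reference_species_table.tsv and results/reference_binomial.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from genovuln.reference import load_species_table
from genovuln.stats import EXPECTED_DIRECTIONS, INDEX_NAMES, build_comparisons, exact_binomial

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    OUT.mkdir(exist_ok=True)

    table = load_species_table()
    table.round(3).to_csv(OUT / "reference_species_table.tsv", sep="\t", index=False)

    rows = []
    for name in INDEX_NAMES:
        s = exact_binomial(build_comparisons(table, name), EXPECTED_DIRECTIONS[name])
        rows.append(
            {"index": name, "expected_direction": s.expected_direction,
             "n_pairs": s.n_pairs, "n_concordant": s.n_concordant,
             "p_two_sided": round(s.p_two_sided, 3)}
        )
    report = pd.DataFrame(rows)
    report.to_csv(OUT / "reference_binomial.tsv", sep="\t", index=False)

    print("Cross-genus sign tests on the published species values:")
    print(report.to_string(index=False))
    print(
        "\nFive indices are concordant in all 10 congeneric EIE-NE pairs "
        "(p = 0.002); the duplicated-gene proportion is concordant in 9 of 10 "
        "(p = 0.021), the exception being C. ameristophyllum vs C. keiskeanum."
    )


if __name__ == "__main__":
    main()
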
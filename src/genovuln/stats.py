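"""Species aggregation, congeneric t-tests, and cross-genus exact binomial tests.

Each index is estimated per specimen; the species value is the unweighted
mean over its specimens (a single specimen passes through).  Within a genus
every endangered-island-endemic (EIE) species is compared with every
non-endangered (NE) congener; the per-gene value distributions feed a
two-sided Welch t-test, and the direction of the species-value difference
feeds a cross-genus two-sided exact binomial (sign) test with null success
probability 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: index name -> direction expected for the EIE member of a pair
EXPECTED_DIRECTIONS = {
    "pd": "eie_lower",
    "syn_per_kb": "eie_lower",
    "nonsyn_fraction": "eie_higher",
    "nonsense_fraction": "eie_higher",
    "provean_fraction": "eie_higher",
    "sift_fraction": "eie_higher",
}
INDEX_NAMES = tuple(EXPECTED_DIRECTIONS)


class TieError(ValueError):
    """A species pair with exactly equal values cannot be assigned a direction."""


def species_value(specimen_values: Sequence[float]) -> float:
    """Mean of per-specimen values; the species-level unit of comparison."""
    vals = [float(v) for v in specimen_values]
    if not vals:
        raise ValueError("species with no specimen values")
    return sum(vals) / len(vals)


def pairwise_ttest(
    values_eie: Sequence[float],
    values_ne: Sequence[float],
    welch: bool = True,
) -> float | None:
    """Two-sided two-sample t-test on per-gene value distributions.

    Welch's unequal-variance form by default; ``welch=False`` gives Student's.
    Returns None when either side has fewer than two values.  Two degenerate
    zero-variance samples with equal means are reported as p = 1.
    """
    x = np.asarray(values_eie, dtype=float)
    y = np.asarray(values_ne, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        return None
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 1.0 if x[0] == y[0] else 0.0
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.pvalue)


@dataclass(frozen=True)
class ComparisonOutcome:
    genus: str
    eie_species: str
    ne_species: str
    index_name: str
    eie_value: float
    ne_value: float
    t_test_p: float | None = None

    @property
    def direction(self) -> str:
        if self.eie_value < self.ne_value:
            return "eie_lower"
        if self.eie_value > self.ne_value:
            return "eie_higher"
        return "tie"


@dataclass(frozen=True)
class BinomialSummary:
    index_name: str
    expected_direction: str
    n_pairs: int
    n_concordant: int
    p_two_sided: float


def build_comparisons(
    species_table: pd.DataFrame,
    index_name: str,
    ttest_values: dict[str, Sequence[float]] | None = None,
    welch: bool = True,
) -> list[ComparisonOutcome]:
    """Full bipartite EIE x NE pairing within each genus for one index.

    ``species_table`` needs columns species, genus, category (EIE/NE) and a
    column named ``index_name`` holding the species value.  When
    ``ttest_values`` maps species -> per-gene values, each pair also gets a
    Welch t-test p-value.
    """
    required = {"species", "genus", "category", index_name}
    missing = required - set(species_table.columns)
    if missing:
        raise ValueError(f"species table missing columns {sorted(missing)}")
    outcomes: list[ComparisonOutcome] = []
    for genus, sub in species_table.groupby("genus", sort=True):
        eie = sub[sub["category"] == "EIE"]
        ne = sub[sub["category"] == "NE"]
        for e in eie.itertuples():
            for n in ne.itertuples():
                p = None
                if ttest_values is not None:
                    p = pairwise_ttest(
                        ttest_values[e.species], ttest_values[n.species], welch=welch
                    )
                outcomes.append(
                    ComparisonOutcome(
                        genus=genus,
                        eie_species=e.species,
                        ne_species=n.species,
                        index_name=index_name,
                        eie_value=float(getattr(e, index_name)),
                        ne_value=float(getattr(n, index_name)),
                        t_test_p=p,
                    )
                )
    return outcomes


def exact_binomial(
    outcomes: Iterable[ComparisonOutcome], expected_direction: str
) -> BinomialSummary:
    """Two-sided exact binomial test on direction concordance across pairs.

    Counts pairs whose species-value direction matches ``expected_direction``
    against a fair-coin null.  A tied pair is an error: it has no direction.
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no comparison outcomes")
    ties = [o for o in outcomes if o.direction == "tie"]
    if ties:
        raise TieError(
            f"{len(ties)} tied species pair(s), first: "
            f"{ties[0].eie_species} vs {ties[0].ne_species}"
        )
    n = len(outcomes)
    k = sum(1 for o in outcomes if o.direction == expected_direction)
    p = sps.binomtest(k, n, p=0.5, alternative="two-sided").pvalue
    return BinomialSummary(
        index_name=outcomes[0].index_name,
        expected_direction=expected_direction,
        n_pairs=n,
        n_concordant=k,
        p_two_sided=float(min(1.0, p)),
    )


def species_table_from_specimens(specimen_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a per-specimen index table to species values.

    Input columns: genus, species, category, specimen, plus one column per
    index.  Output: one row per species with the specimen means.
    """
    index_cols = [c for c in specimen_table.columns if c in INDEX_NAMES]
    grouped = (
        specimen_table.groupby(["genus", "species", "category"], sort=True)[index_cols]
        .mean()
        .reset_index()
    )
    return grouped


def binomial_layer(
    species_table: pd.DataFrame, index_names: Sequence[str] = INDEX_NAMES
) -> dict[str, BinomialSummary]:
    """Run the cross-genus sign test for every index in one species table."""
    out: dict[str, BinomialSummary] = {}
    for name in index_names:
        outcomes = build_comparisons(species_table, name)
        out[name] = exact_binomial(outcomes, EXPECTED_DIRECTIONS[name])
    return out


def round3(x: float) -> float:
    """Reporting precision used in all emitted tables (3 decimals)."""
    return float(f"{x:.3f}") if not math.isnan(x) else x
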
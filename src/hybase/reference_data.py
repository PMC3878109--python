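"""Published summary statistics from the three-way indica rice hybrid ASE
study this pipeline models (crosses GL x TQ, GL x 93-11, 93-11 x TQ).

These per-cross numbers are worked-example inputs: the package's summary
arithmetic (pooled totals, sampling and validation percentages, averaged
class percentages) recomputes the study's printed aggregate figures from
them, which serves as a fast sanity check of the reporting conventions.
"""

from __future__ import annotations

import numpy as np

CROSSES = ("GLxTQ", "GLx9311", "9311xTQ")

#: Monoallelically expressed genes identified per cross.
MONOALLELIC_COUNTS = {"GLxTQ": 143, "GLx9311": 129, "9311xTQ": 141}

#: Monoallelic genes sampled for RT-PCR confirmation, and how many confirmed.
MONOALLELIC_SAMPLED = 134
MONOALLELIC_CONFIRMED = 123

#: Percent of strongly divergent genes called monoallelic in the F1, per
#: cross: class IV = expressed in only one parent; class III = >10-fold
#: parental difference with F1 enhancement.
CLASS_IV_MONOALLELIC_PCT = {"GLxTQ": 53.1, "GLx9311": 55.0, "9311xTQ": 46.8}
CLASS_III_MONOALLELIC_PCT = {"GLxTQ": 29.4, "GLx9311": 27.1, "9311xTQ": 34.0}


def pooled_total(per_cross: dict[str, int]) -> int:
    """Sum a per-cross count over all crosses."""
    return int(sum(per_cross.values()))


def percentage(part: float, whole: float, decimals: int = 1) -> float:
    """Percentage rounded to the reporting precision (1 decimal place)."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round(100.0 * part / whole, decimals)


def cross_average(per_cross: dict[str, float], decimals: int = 1) -> float:
    """Unweighted mean over crosses, at reporting precision."""
    return round(float(np.mean(list(per_cross.values()))), decimals)
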
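"""Bundled example dataset.

Induction ratios for four SAM-riboswitch-controlled B. subtilis genes/operons
and a non-riboswitch control (gyrA), measured with and without site-directed
cleavage at four time points of methionine starvation.  Values are published
measurements; they serve as the worked example for the with/without-cleavage
comparison and as a regression surface for the percent-difference summary.
"""

from __future__ import annotations

import math

from pttquant.ptt import InductionResult

TIMEPOINTS_H = (0.0, 1.0, 2.0, 3.0)

CONTROL_GENES = ("gyrA",)
RIBOSWITCH_GENES = ("samT", "metIC", "metE", "mtnKA")

#: gene -> (IRs without cleavage, IRs with cleavage) at TIMEPOINTS_H.
EXAMPLE_IR_TABLE: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "gyrA": ((0.83, 1.33, 1.21, 0.84), (0.94, 1.11, 1.14, 1.04)),
    "samT": ((0.96, 3.69, 14.93, 9.24), (1.14, 4.67, 17.44, 9.75)),
    "metIC": ((1.07, 1.02, 17.38, 1.07), (1.21, 1.43, 25.91, 1.25)),
    "metE": ((1.08, 5.72, 37.21, 18.79), (1.21, 7.60, 44.66, 30.02)),
    "mtnKA": ((0.98, 2.01, 1.05, 0.40), (0.92, 2.35, 1.27, 0.50)),
}

#: The rounded percent-difference row printed alongside the source table,
#: kept for regression tests (recomputed values agree within rounding).
EXAMPLE_PRINTED_DIFFERENCES: dict[str, tuple[int, ...]] = {
    "gyrA": (14, -17, -6, 25),
    "samT": (18, 26, 17, 5),
    "metIC": (13, 40, 49, 17),
    "metE": (11, 33, 20, 60),
    "mtnKA": (-6, 17, 21, 27),
}


def example_induction_results() -> list[InductionResult]:
    """The example table as InductionResult rows (IR* unknown: NaN)."""
    results = []
    for gene, (without, with_) in EXAMPLE_IR_TABLE.items():
        for t, ir_wo, ir_wi in zip(TIMEPOINTS_H, without, with_):
            results.append(
                InductionResult(gene=gene, timepoint_h=t, IR=ir_wo,
                                IR_star=math.nan, cleaved=False)
            )
            results.append(
                InductionResult(gene=gene, timepoint_h=t, IR=ir_wi,
                                IR_star=math.nan, cleaved=True)
            )
    return results
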
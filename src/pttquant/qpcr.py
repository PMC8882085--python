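"""RT-qPCR comparison arm: delta-delta-Ct quantification and primer QC.

Sign convention: one PCR cycle is one template doubling, so a *lower* Ct
means *more* template.  With

    ddCt = (Ct_target - Ct_ref_target) - (Ct_calibrator - Ct_ref_calibrator)

the relative quantity is ``RQ = 2**(-ddCt)``; the literature often writes
"2^ddCt" as shorthand with the opposite sign folded in.  The convention here
is tested: a target one cycle earlier than its calibrator has RQ = 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pttquant.errors import DataError, DegenerateRatioError

#: Acceptance band for amplification efficiency, percent.
EFFICIENCY_BOUNDS = (90.0, 110.0)
#: Minimum R-squared of the dilution-series fit (exclusive).
R_SQUARED_MIN = 0.985

CT_PLAUSIBLE_BAND = (5.0, 40.0)


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: a cycle-threshold value with its annotations."""

    sample_id: str
    primer_pair: str  # "P1" | "P2" | "P3"
    gene: str
    condition: str
    timepoint_h: float
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        lo, hi = CT_PLAUSIBLE_BAND
        if not (lo <= self.ct <= hi):
            raise DataError(
                f"Ct {self.ct} outside plausible band [{lo}, {hi}] "
                f"for sample {self.sample_id!r}"
            )


@dataclass(frozen=True)
class EfficiencyQC:
    """Primer-pair QC from a log10 dilution series."""

    primer_pair: str
    slope: float
    efficiency_percent: float
    r_squared: float

    @property
    def passes(self) -> bool:
        lo, hi = EFFICIENCY_BOUNDS
        return lo <= self.efficiency_percent <= hi and self.r_squared > R_SQUARED_MIN


def delta_delta_ct(
    ct_target: float,
    ct_calibrator: float,
    ct_ref_target: float,
    ct_ref_calibrator: float,
) -> float:
    for v in (ct_target, ct_calibrator, ct_ref_target, ct_ref_calibrator):
        if not math.isfinite(v):
            raise DataError(f"non-finite Ct value: {v}")
    return (ct_target - ct_ref_target) - (ct_calibrator - ct_ref_calibrator)


def relative_quantity(
    ct_target: float,
    ct_calibrator: float,
    ct_ref_target: float | None = None,
    ct_ref_calibrator: float | None = None,
) -> float:
    """RQ of target vs calibrator, optionally normalized to a reference gene.

    Passing only the first two arguments gives the no-reference (delta-Ct)
    mode, ``RQ = 2**(ct_calibrator - ct_target)``.  With reference Cts the
    full delta-delta-Ct correction is applied.  Invariant to adding a
    constant to all four Cts.
    """
    if (ct_ref_target is None) != (ct_ref_calibrator is None):
        raise DataError("provide both reference Cts or neither")
    if ct_ref_target is None:
        ct_ref_target = ct_ref_calibrator = 0.0
    ddct = delta_delta_ct(ct_target, ct_calibrator, ct_ref_target, ct_ref_calibrator)
    return 2.0 ** (-ddct)


def mean_ct(cts: Sequence[float]) -> float:
    """Arithmetic replicate mean, the standard pre-averaging for ddCt."""
    if not cts:
        raise DataError("no Ct replicates to average")
    return float(np.mean(cts))


def primer_efficiency(
    dilution_log10: Sequence[float],
    cts: Sequence[float],
    primer_pair: str = "",
) -> EfficiencyQC:
    """Amplification efficiency from a serial-dilution standard curve.

    Fits ``Ct = intercept + slope * log10(dilution)`` by least squares; the
    per-cycle amplification factor is ``10**(-1/slope)`` and the efficiency
    is ``100 * (10**(-1/slope) - 1)`` percent (slope -3.32 = 100%).
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(cts, dtype=float)
    if x.shape != y.shape:
        raise DataError("dilution and Ct lists must have equal length")
    if x.size < 3:
        raise DataError("need at least 3 dilution points")
    if np.ptp(x) == 0:
        raise DataError("degenerate dilution series: all dilutions equal")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise DataError(
            f"non-negative standard-curve slope ({fit.slope:.3g}); "
            "check dilution orientation"
        )
    efficiency = 100.0 * (10.0 ** (-1.0 / fit.slope) - 1.0)
    return EfficiencyQC(
        primer_pair=primer_pair,
        slope=float(fit.slope),
        efficiency_percent=float(efficiency),
        r_squared=float(fit.rvalue**2),
    )


def ir_star_from_rq(
    rq_p3_met_minus: float,
    rq_p3_met_plus: float,
    rq_p1_met_minus: float,
    rq_p1_met_plus: float,
) -> float:
    """IR* from relative quantities.

    ``IR* = (RQ_P3/RQ_P1)_minus / (RQ_P3/RQ_P1)_plus``; identical to the
    concentration-based IR* whenever RQ is proportional to concentration.
    """
    for name, v in (
        ("rq_p3_met_minus", rq_p3_met_minus),
        ("rq_p3_met_plus", rq_p3_met_plus),
        ("rq_p1_met_minus", rq_p1_met_minus),
        ("rq_p1_met_plus", rq_p1_met_plus),
    ):
        if not (math.isfinite(v) and v > 0):
            raise DegenerateRatioError(f"{name} must be finite and > 0, got {v}")
    return (rq_p3_met_minus / rq_p1_met_minus) / (rq_p3_met_plus / rq_p1_met_plus)


def ir_star_table(records) -> pd.DataFrame:
    """Per-gene/timepoint IR* from a collection of :class:`CtRecord`.

    Replicate Cts are averaged arithmetically per (gene, timepoint,
    condition, primer pair).  The ligand-present condition serves as its own
    calibrator (RQ = 1), so the ligand-starved RQ per primer pair is
    ``2**(Ct_plus - Ct_minus)`` and IR* follows from the P3/P1 RQ ratio.
    """
    rows = [
        {
            "gene": r.gene,
            "timepoint_h": r.timepoint_h,
            "condition": r.condition,
            "primer_pair": r.primer_pair,
            "ct": r.ct,
        }
        for r in records
    ]
    if not rows:
        raise DataError("no Ct records provided")
    df = pd.DataFrame(rows)
    mean = (
        df.groupby(["gene", "timepoint_h", "condition", "primer_pair"])["ct"]
        .mean()
        .unstack(["condition", "primer_pair"])
    )
    out = []
    for (gene, t), cts in mean.iterrows():
        try:
            rq_p1 = relative_quantity(cts[("Met_minus", "P1")], cts[("Met_plus", "P1")])
            rq_p3 = relative_quantity(cts[("Met_minus", "P3")], cts[("Met_plus", "P3")])
        except KeyError as exc:
            raise DataError(
                f"{gene} @ {t} h: missing Ct data for {exc.args[0]}"
            ) from exc
        out.append(
            {
                "gene": gene,
                "timepoint_h": t,
                "rq_p1_met_minus": rq_p1,
                "rq_p3_met_minus": rq_p3,
                "IR_star": ir_star_from_rq(rq_p3, 1.0, rq_p1, 1.0),
            }
        )
    return pd.DataFrame(out)
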
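"""Premature-transcription-termination statistics.

The assay measures each transcript with three amplicons:

* ``P1`` — upstream of the termination site; amplifies full-length *and*
  terminated transcripts (total expression).
* ``P2`` — flanking the oligomer-directed cleavage site; its disappearance
  after cleavage reports cleavage efficiency.
* ``P3`` — downstream of the cleavage site; amplifies full-length
  transcripts only.

From absolute concentrations the terminated fraction is ``T = P1 - P3`` with
``FL = P3``.  Two condition-contrast statistics are defined between an
induced (ligand-starved, "Met-") and a repressed ("Met+") condition:

* ``IR  = (FL/T)_minus / (FL/T)_plus`` — full-length over terminated,
  computable only when T is measured directly (absolute quantification).
* ``IR* = (FL/(FL+T))_minus / (FL/(FL+T))_plus = (P3/P1)_minus /
  (P3/P1)_plus`` — full-length over total, also computable from relative
  qPCR quantities.

When the termination fraction is at least as high in the repressed condition
as in the induced one, ``IR >= IR*`` with equality only at equal fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from pttquant.errors import ConfigError, DataError, DegenerateRatioError

DEFAULT_3PRIME_DISTANCE_NT = 200
DEFAULT_3PRIME_TOLERANCE_NT = 25


class Condition(str, Enum):
    """Growth condition: ligand present (repressing) or starved (inducing)."""

    MET_PLUS = "Met_plus"
    MET_MINUS = "Met_minus"


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Python's built-in ``round`` uses banker's rounding; percent-difference
    tables conventionally round 0.5 up in magnitude instead.
    """
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class AssayDesign:
    """Per-gene amplicon geometry.

    Coordinates are 1-based inclusive on the transcript, counted from the
    5' end.  The 3'-distance of an amplicon ``[a, b]`` on a molecule of
    length ``l`` is ``l - b + 1``.  The design constraint is that the P1
    amplicon sits at the same 3'-distance on the 5' cleavage fragment as the
    P3 amplicon does on the full-length transcript (within
    ``distance_tolerance_nt``), so that reverse-transcription coverage bias
    cancels between them.
    """

    gene: str
    amplicon_p1: tuple[int, int]
    amplicon_p2: tuple[int, int]
    amplicon_p3: tuple[int, int]
    ptt_site: int
    cleavage_site: int
    full_length: int
    target_3prime_distance: int = DEFAULT_3PRIME_DISTANCE_NT
    distance_tolerance_nt: int = DEFAULT_3PRIME_TOLERANCE_NT

    def __post_init__(self) -> None:
        for name, (a, b) in (
            ("amplicon_p1", self.amplicon_p1),
            ("amplicon_p2", self.amplicon_p2),
            ("amplicon_p3", self.amplicon_p3),
        ):
            if not (1 <= a <= b <= self.full_length):
                raise ConfigError(
                    f"{self.gene}: {name} [{a}, {b}] outside transcript "
                    f"[1, {self.full_length}]"
                )
        if not self.ptt_site < self.cleavage_site < self.full_length:
            raise ConfigError(
                f"{self.gene}: require ptt_site < cleavage_site < full_length, "
                f"got {self.ptt_site}, {self.cleavage_site}, {self.full_length}"
            )
        if self.amplicon_p1[1] >= self.ptt_site:
            raise ConfigError(
                f"{self.gene}: P1 amplicon must lie entirely 5' of the PTT site"
            )
        if not (self.amplicon_p2[0] <= self.cleavage_site < self.amplicon_p2[1]):
            raise ConfigError(
                f"{self.gene}: P2 amplicon must span the cleavage site"
            )
        if self.amplicon_p3[0] <= self.cleavage_site:
            raise ConfigError(
                f"{self.gene}: P3 amplicon must lie entirely 3' of the cleavage site"
            )
        mismatch = abs(
            self.p1_distance_on_5prime_fragment - self.p3_distance_on_full_length
        )
        if mismatch > self.distance_tolerance_nt:
            raise ConfigError(
                f"{self.gene}: P1 and P3 3'-distances differ by {mismatch} nt "
                f"(> {self.distance_tolerance_nt} nt tolerance); the design "
                "no longer cancels the reverse-transcription coverage bias"
            )

    @property
    def p1_distance_on_5prime_fragment(self) -> int:
        """3'-distance of P1 on the 5' cleavage fragment (length = cleavage_site)."""
        return self.cleavage_site - self.amplicon_p1[1] + 1

    @property
    def p1_distance_on_full_length(self) -> int:
        return self.full_length - self.amplicon_p1[1] + 1

    @property
    def p3_distance_on_full_length(self) -> int:
        return self.full_length - self.amplicon_p3[1] + 1


@dataclass(frozen=True)
class SampleMeasurement:
    """P1/P2/P3 concentrations (copies/ul) for one gene, condition, time point."""

    gene: str
    condition: Condition
    timepoint_h: float
    cleaved: bool
    P1: float
    P2: float = math.nan
    P3: float = 0.0

    def __post_init__(self) -> None:
        for name in ("P1", "P3"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise DataError(f"{self.gene}: {name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class PttEstimate:
    """Full-length/terminated decomposition of one measurement.

    ``FL + T == P1`` exactly.  A negative ``T`` (P3 > P1, possible through
    measurement noise) is propagated as computed with ``negative_T_flag``
    set rather than clamped, so QC can catch assay failures; the ratio
    operations refuse flagged inputs.
    """

    gene: str
    condition: Condition
    timepoint_h: float
    cleaved: bool
    FL: float
    T: float
    termination_fraction: float
    fl_to_t_ratio: float
    negative_T_flag: bool

    @property
    def P1(self) -> float:
        return self.FL + self.T


@dataclass(frozen=True)
class InductionResult:
    gene: str
    timepoint_h: float
    IR: float
    IR_star: float
    cleaved: bool


def ptt_estimate(m: SampleMeasurement) -> PttEstimate:
    """Decompose a measurement into full-length and terminated concentrations.

    ``T = P1 - P3`` and ``FL = P3``.  ``termination_fraction = T / P1``;
    ``fl_to_t_ratio = FL / T`` when ``T > 0`` and NaN otherwise.
    Raises :class:`~pttquant.errors.DegenerateRatioError` when ``P1 = 0``.
    """
    if m.P1 <= 0:
        raise DegenerateRatioError(
            f"{m.gene} ({m.condition.value}, {m.timepoint_h} h): P1 = 0, "
            "termination fraction undefined"
        )
    T = m.P1 - m.P3
    FL = m.P3
    return PttEstimate(
        gene=m.gene,
        condition=m.condition,
        timepoint_h=m.timepoint_h,
        cleaved=m.cleaved,
        FL=FL,
        T=T,
        termination_fraction=T / m.P1,
        fl_to_t_ratio=FL / T if T > 0 else math.nan,
        negative_T_flag=T < 0,
    )


def cleavage_efficiency(
    p2_with_oligo: float, p2_without_oligo: float
) -> tuple[float, bool]:
    """Fraction of templates cut at the directed site.

    Computed as ``1 - P2(with oligomer) / P2(without oligomer)`` from the
    cleavage-site-spanning amplicon, clamped to [0, 1].  Returns
    ``(efficiency, out_of_range)`` where the flag marks a with-oligomer
    signal exceeding the without-oligomer control (negative raw efficiency).
    """
    if p2_without_oligo <= 0:
        raise DegenerateRatioError(
            "cleavage efficiency undefined: no signal without oligomer"
        )
    if p2_with_oligo < 0:
        raise DataError(f"negative concentration: {p2_with_oligo}")
    raw = 1.0 - p2_with_oligo / p2_without_oligo
    return min(max(raw, 0.0), 1.0), raw < 0


def _require_positive(e: PttEstimate, what: str) -> None:
    label = f"{e.gene} ({e.condition.value}, {e.timepoint_h} h)"
    if e.negative_T_flag:
        raise DegenerateRatioError(f"{label}: negative T (P3 > P1), refusing {what}")
    if e.FL <= 0:
        raise DegenerateRatioError(f"{label}: FL = 0, {what} undefined")
    if e.T <= 0:
        raise DegenerateRatioError(f"{label}: T = 0, {what} undefined")


def induction_ratio(met_minus: PttEstimate, met_plus: PttEstimate) -> float:
    """IR — fold change of the full-length:terminated ratio between conditions.

    ``IR = (FL/T)_minus / (FL/T)_plus``.  Requires strictly positive FL and
    T in both conditions and refuses negative-T-flagged inputs, naming the
    failing condition in the error.
    """
    _require_positive(met_minus, "IR")
    _require_positive(met_plus, "IR")
    return (met_minus.FL / met_minus.T) / (met_plus.FL / met_plus.T)


def induction_ratio_star(met_minus: PttEstimate, met_plus: PttEstimate) -> float:
    """IR* — fold change of the full-length fraction ``FL/(FL+T) = P3/P1``.

    Unlike IR, this statistic never needs T in isolation and is therefore
    also computable from relative qPCR quantities.  A zero full-length
    signal in the induced condition yields 0 with a warning; a zero in the
    repressed condition is an error (zero denominator).
    """
    for e in (met_minus, met_plus):
        if e.negative_T_flag:
            raise DegenerateRatioError(
                f"{e.gene} ({e.condition.value}): negative T, refusing IR*"
            )
    if met_plus.FL <= 0:
        raise DegenerateRatioError(
            f"{met_plus.gene} ({met_plus.condition.value}): FL = 0 in the "
            "denominator condition, IR* undefined"
        )
    if met_minus.FL <= 0:
        warnings.warn(
            f"{met_minus.gene}: no full-length signal in the induced "
            "condition; IR* = 0",
            stacklevel=2,
        )
        return 0.0
    return (met_minus.FL / met_minus.P1) / (met_plus.FL / met_plus.P1)


def ir_percent_difference(
    ir_without_cleavage: float, ir_with_cleavage: float, rounded: bool = False
) -> float:
    """Percent change of the induction ratio introduced by cleavage.

    ``100 * (IR_with - IR_without) / IR_without``; with ``rounded=True`` the
    result is rounded half-away-from-zero to an integer (the convention of
    published comparison tables).
    """
    if ir_without_cleavage <= 0:
        raise DegenerateRatioError(
            f"baseline IR must be > 0, got {ir_without_cleavage}"
        )
    raw = 100.0 * (ir_with_cleavage - ir_without_cleavage) / ir_without_cleavage
    return float(round_half_away(raw)) if rounded else raw


@dataclass(frozen=True)
class CleavageEffectSummary:
    """Per-pair percent differences plus their mean and maximum."""

    table: pd.DataFrame
    included_genes: tuple[str, ...]
    mean_percent: float
    max_percent: float

    @property
    def mean_percent_rounded(self) -> int:
        return round_half_away(self.mean_percent)

    @property
    def max_percent_rounded(self) -> int:
        # max over per-cell rounded values, matching table conventions
        return int(self.table.loc[self.table["included"], "percent_difference_rounded"].max())


def summarize_cleavage_effect(
    results: Iterable[InductionResult],
    control_genes: Sequence[str] = (),
    genes: Sequence[str] | None = None,
) -> CleavageEffectSummary:
    """Compare induction ratios with and without cleavage, per gene/time point.

    ``results`` must contain, for each (gene, timepoint) pair, exactly one
    cleaved and one uncleaved :class:`InductionResult`; orphans raise a
    :class:`~pttquant.errors.DataError` listing them.  The mean and maximum
    percent difference are taken over ``genes`` (default: every gene except
    ``control_genes``); excluded pairs remain in the table with
    ``included=False``.
    """
    by_key: dict[tuple[str, float, bool], InductionResult] = {}
    for r in results:
        key = (r.gene, r.timepoint_h, r.cleaved)
        if key in by_key:
            raise DataError(f"duplicate induction result for {key}")
        by_key[key] = r

    pairs = sorted({(g, t) for (g, t, _) in by_key})
    orphans = [
        (g, t)
        for (g, t) in pairs
        if (g, t, True) not in by_key or (g, t, False) not in by_key
    ]
    if orphans:
        raise DataError(
            "unmatched cleaved/uncleaved induction results for: "
            + ", ".join(f"{g} @ {t} h" for g, t in orphans)
        )
    if not pairs:
        raise DataError("no induction results to summarize")

    all_genes = sorted({g for g, _ in pairs})
    if genes is None:
        included_genes = tuple(g for g in all_genes if g not in set(control_genes))
    else:
        included_genes = tuple(genes)

    rows = []
    for g, t in pairs:
        without = by_key[(g, t, False)]
        with_ = by_key[(g, t, True)]
        diff = ir_percent_difference(without.IR, with_.IR)
        rows.append(
            {
                "gene": g,
                "timepoint_h": t,
                "ir_without": without.IR,
                "ir_with": with_.IR,
                "percent_difference": diff,
                "percent_difference_rounded": round_half_away(diff),
                "included": g in included_genes,
            }
        )
    table = pd.DataFrame(rows)
    incl = table.loc[table["included"], "percent_difference"]
    if incl.empty:
        raise DataError("gene selection excludes every pair")
    return CleavageEffectSummary(
        table=table,
        included_genes=included_genes,
        mean_percent=float(incl.mean()),
        max_percent=float(incl.max()),
    )
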
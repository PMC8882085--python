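"""Glue between quantification and statistics: joins, grouping, reports."""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd

from pttquant.ddpcr import ConcentrationEstimate, DropletCount, merge_replicates, quantify_wells
from pttquant.errors import DataError
from pttquant.ptt import (
    Condition,
    InductionResult,
    PttEstimate,
    SampleMeasurement,
    cleavage_efficiency,
    induction_ratio,
    induction_ratio_star,
    ptt_estimate,
)

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "gene",
    "condition",
    "timepoint_h",
    "cleaved",
    "assay_p1",
    "assay_p2",
    "assay_p3",
]


def estimates_to_frame(estimates: Iterable[ConcentrationEstimate]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": e.sample_id,
            "assay_id": e.assay_id,
            "positives": e.positives,
            "total": e.total,
            "lambda_per_droplet": e.lambda_per_droplet,
            "copies_per_ul": e.copies_per_ul,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "confidence_level": e.confidence_level,
            "saturated": e.saturated_flag,
            "dilution_factor": e.dilution_factor,
            "droplet_volume_nl": e.droplet_volume_nl,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)


def pool_replicate_wells(
    estimates: Iterable[ConcentrationEstimate],
) -> list[ConcentrationEstimate]:
    """Merge wells sharing (sample_id, assay_id) by count-level pooling."""
    groups: dict[tuple[str, str], list[ConcentrationEstimate]] = defaultdict(list)
    for e in estimates:
        groups[(e.sample_id, e.assay_id)].append(e)
    return [merge_replicates(v) for v in groups.values()]


def measurements_from_sample_sheet(
    sample_sheet: pd.DataFrame,
    estimates: Iterable[ConcentrationEstimate],
) -> list[SampleMeasurement]:
    """Join concentration estimates onto the sample sheet's P1/P2/P3 assays.

    Replicate wells are pooled first.  A saturated or absent P1/P3 assay for
    any sample is an error naming the sample.
    """
    missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in sample_sheet.columns]
    if missing_cols:
        raise DataError(f"sample sheet missing columns: {missing_cols}")
    pooled = pool_replicate_wells(estimates)
    by_key = {(e.sample_id, e.assay_id): e for e in pooled}

    measurements = []
    for row in sample_sheet.itertuples(index=False):
        values = {}
        for p, assay_col in (("P1", "assay_p1"), ("P2", "assay_p2"), ("P3", "assay_p3")):
            est = by_key.get((row.sample_id, getattr(row, assay_col)))
            if est is None:
                if p == "P2":
                    values[p] = float("nan")
                    continue
                raise DataError(
                    f"no droplet data for sample {row.sample_id!r} assay "
                    f"{getattr(row, assay_col)!r}"
                )
            if est.saturated_flag:
                raise DataError(
                    f"assay {est.assay_id!r} of sample {row.sample_id!r} is "
                    "saturated; re-run at higher dilution"
                )
            values[p] = est.copies_per_ul
        measurements.append(
            SampleMeasurement(
                gene=row.gene,
                condition=Condition(row.condition),
                timepoint_h=float(row.timepoint_h),
                cleaved=bool(row.cleaved),
                P1=values["P1"],
                P2=values["P2"],
                P3=values["P3"],
            )
        )
    return measurements


def ptt_table(measurements: Sequence[SampleMeasurement]) -> pd.DataFrame:
    """Tidy per-sample full-length/terminated decomposition."""
    rows = []
    for m in measurements:
        est = ptt_estimate(m)
        rows.append(
            {
                "gene": est.gene,
                "condition": est.condition.value,
                "timepoint_h": est.timepoint_h,
                "cleaved": est.cleaved,
                "P1": m.P1,
                "P3": m.P3,
                "FL": est.FL,
                "T": est.T,
                "termination_fraction": est.termination_fraction,
                "fl_to_t_ratio": est.fl_to_t_ratio,
                "negative_T_flag": est.negative_T_flag,
            }
        )
    return pd.DataFrame(rows)


def induction_results(
    measurements: Sequence[SampleMeasurement],
) -> list[InductionResult]:
    """Pair Met-/Met+ measurements per gene/timepoint/arm and compute IR, IR*."""
    by_key: dict[tuple[str, float, bool], dict[Condition, PttEstimate]] = defaultdict(dict)
    for m in measurements:
        est = ptt_estimate(m)
        key = (m.gene, m.timepoint_h, m.cleaved)
        if m.condition in by_key[key]:
            raise DataError(
                f"duplicate measurement for {m.gene} @ {m.timepoint_h} h "
                f"({m.condition.value}, cleaved={m.cleaved})"
            )
        by_key[key][m.condition] = est

    results = []
    for (gene, t, cleaved), conds in sorted(by_key.items()):
        if Condition.MET_MINUS not in conds or Condition.MET_PLUS not in conds:
            have = ", ".join(c.value for c in conds)
            raise DataError(
                f"{gene} @ {t} h (cleaved={cleaved}): need both conditions, "
                f"have only [{have}]"
            )
        minus, plus = conds[Condition.MET_MINUS], conds[Condition.MET_PLUS]
        results.append(
            InductionResult(
                gene=gene,
                timepoint_h=t,
                IR=induction_ratio(minus, plus),
                IR_star=induction_ratio_star(minus, plus),
                cleaved=cleaved,
            )
        )
    return results


def induction_to_frame(results: Sequence[InductionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "timepoint_h": r.timepoint_h,
                "cleaved": r.cleaved,
                "IR": r.IR,
                "IR_star": r.IR_star,
            }
            for r in results
        ]
    )


def cleavage_efficiency_table(
    measurements: Sequence[SampleMeasurement],
) -> pd.DataFrame:
    """Per gene/condition/timepoint cleavage efficiency from the P2 assay."""
    by_key: dict[tuple[str, str, float], dict[bool, float]] = defaultdict(dict)
    for m in measurements:
        by_key[(m.gene, m.condition.value, m.timepoint_h)][m.cleaved] = m.P2
    rows = []
    for (gene, cond, t), arms in sorted(by_key.items()):
        if True not in arms or False not in arms:
            continue
        if not pd.notna(arms[True]) or not pd.notna(arms[False]):
            continue
        eff, out_of_range = cleavage_efficiency(arms[True], arms[False])
        rows.append(
            {
                "gene": gene,
                "condition": cond,
                "timepoint_h": t,
                "p2_with_oligo": arms[True],
                "p2_without_oligo": arms[False],
                "efficiency": eff,
                "out_of_range": out_of_range,
            }
        )
    return pd.DataFrame(rows)


def run_ptt_pipeline(
    droplet_counts: Iterable[DropletCount],
    sample_sheet: pd.DataFrame,
    confidence_level: float = 0.95,
) -> tuple[pd.DataFrame, list[InductionResult], pd.DataFrame]:
    """Droplet counts -> (PTT table, induction results, cleavage-efficiency table)."""
    estimates = quantify_wells(droplet_counts, confidence_level=confidence_level)
    measurements = measurements_from_sample_sheet(sample_sheet, estimates)
    return (
        ptt_table(measurements),
        induction_results(measurements),
        cleavage_efficiency_table(measurements),
    )
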
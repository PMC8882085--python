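"""File formats: plain CSV/YAML/JSON readers and writers.

All tables are UTF-8, comma-separated, dot-decimal CSV with documented
headers.  The droplet reader also accepts a QuantaSoft-style export layout
(``Well, Sample, Positives, AcceptedDroplets``) since that is what the
instrument software emits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from pttquant.ddpcr import DEFAULT_DROPLET_VOLUME_NL, ConcentrationEstimate, DropletCount
from pttquant.errors import ConfigError, DataError
from pttquant.pipeline import SAMPLE_SHEET_COLUMNS, estimates_to_frame
from pttquant.ptt import AssayDesign
from pttquant.qpcr import CtRecord
from pttquant.sim import SyntheticDataset

DROPLET_COLUMNS = ["sample_id", "assay_id", "positives", "total"]
_QUANTASOFT_MAP = {
    "Well": "well",
    "Sample": "sample_id",
    "Target": "assay_id",
    "Positives": "positives",
    "AcceptedDroplets": "total",
}


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise DataError(f"no data rows in {path}")
    return df


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise DataError(f"cannot interpret {value!r} as a boolean")


def read_droplet_csv(
    path: str | Path,
    default_dilution: float = 1.0,
    default_droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> list[DropletCount]:
    """Read droplet counts; schema violations are reported with row numbers."""
    df = _read_csv(path)
    if "AcceptedDroplets" in df.columns:  # QuantaSoft-like export
        df = df.rename(columns=_QUANTASOFT_MAP)
        if "assay_id" not in df.columns:
            df["assay_id"] = df["well"]
    missing = [c for c in DROPLET_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    counts = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        try:
            counts.append(
                DropletCount(
                    sample_id=str(row.sample_id),
                    assay_id=str(row.assay_id),
                    positives=int(row.positives),
                    total=int(row.total),
                    dilution_factor=float(getattr(row, "dilution_factor", default_dilution)),
                    droplet_volume_nl=float(
                        getattr(row, "droplet_volume_nl", default_droplet_volume_nl)
                    ),
                )
            )
        except (DataError, ValueError) as exc:
            raise DataError(f"{path}, row {i}: {exc}") from exc
    return counts


def write_droplet_csv(counts: Iterable[DropletCount], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "assay_id": c.assay_id,
                "positives": c.positives,
                "total": c.total,
                "dilution_factor": c.dilution_factor,
                "droplet_volume_nl": c.droplet_volume_nl,
            }
            for c in counts
        ]
    ).to_csv(path, index=False)


def write_estimates_csv(
    estimates: Iterable[ConcentrationEstimate], path: str | Path
) -> None:
    estimates_to_frame(estimates).to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: sample sheet missing columns {missing}")
    df = df.copy()
    df["cleaved"] = df["cleaved"].map(_parse_bool)
    df["timepoint_h"] = df["timepoint_h"].astype(float)
    return df


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


_DESIGN_FIELDS = [
    "gene",
    "amplicon_p1",
    "amplicon_p2",
    "amplicon_p3",
    "ptt_site",
    "cleavage_site",
    "full_length",
]


def read_design_yaml(path: str | Path) -> dict[str, AssayDesign]:
    """Read a panel of assay designs keyed by gene.

    Schema: a top-level ``genes:`` list; each entry carries ``gene``,
    ``amplicon_p1/p2/p3`` as 2-element ``[start, end]`` lists, ``ptt_site``,
    ``cleavage_site``, ``full_length`` and optionally
    ``target_3prime_distance`` / ``distance_tolerance_nt``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"design file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "genes" not in raw:
        raise ConfigError(f"{path}: expected a top-level 'genes' list")
    designs = {}
    for entry in raw["genes"]:
        missing = [f for f in _DESIGN_FIELDS if f not in entry]
        if missing:
            raise ConfigError(f"{path}: design entry missing fields {missing}")
        kwargs = dict(entry)
        for amp in ("amplicon_p1", "amplicon_p2", "amplicon_p3"):
            kwargs[amp] = tuple(int(x) for x in entry[amp])
        designs[entry["gene"]] = AssayDesign(**kwargs)
    return designs


def write_design_yaml(designs: Iterable[AssayDesign], path: str | Path) -> None:
    payload = {
        "genes": [
            {
                "gene": d.gene,
                "amplicon_p1": list(d.amplicon_p1),
                "amplicon_p2": list(d.amplicon_p2),
                "amplicon_p3": list(d.amplicon_p3),
                "ptt_site": d.ptt_site,
                "cleavage_site": d.cleavage_site,
                "full_length": d.full_length,
                "target_3prime_distance": d.target_3prime_distance,
                "distance_tolerance_nt": d.distance_tolerance_nt,
            }
            for d in designs
        ]
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


CT_COLUMNS = ["sample_id", "primer_pair", "gene", "condition", "timepoint_h", "ct"]


def read_ct_csv(path: str | Path) -> list[CtRecord]:
    df = _read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                CtRecord(
                    sample_id=str(row.sample_id),
                    primer_pair=str(row.primer_pair),
                    gene=str(row.gene),
                    condition=str(row.condition),
                    timepoint_h=float(row.timepoint_h),
                    ct=float(row.ct),
                    replicate=int(getattr(row, "replicate", 1)),
                )
            )
        except (DataError, ValueError) as exc:
            raise DataError(f"{path}, row {i}: {exc}") from exc
    return records


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset in exactly the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "droplets": outdir / "droplets.csv",
        "sample_sheet": outdir / "sample_sheet.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_droplet_csv(dataset.droplet_counts, paths["droplets"])
    write_sample_sheet(dataset.sample_sheet, paths["sample_sheet"])
    paths["ground_truth"].write_text(
        json.dumps(dataset.ground_truth, indent=2, sort_keys=True)
    )
    return paths
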
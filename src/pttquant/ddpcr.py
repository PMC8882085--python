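"""Absolute quantification from droplet digital PCR counts.

A ddPCR reaction partitions the template into ``n`` droplets of volume
``V_d``; after endpoint PCR each droplet is read as positive (>= 1 template
copy) or negative.  Under random partitioning the copy number per droplet is
Poisson, so the mean copies per droplet is recovered from the fraction of
positive droplets ``p = k/n`` as::

    lambda = -ln(1 - p)

and the absolute template concentration, corrected for any pre-reaction
dilution, is ``lambda / V_d * dilution_factor`` (copies/ul with ``V_d`` in
ul).  This module implements that transform, its confidence bounds, and the
pooling of replicate wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

from scipy import stats

from pttquant.errors import DataError, SaturationError

#: Default droplet volume in nanoliters. The first-generation Bio-Rad
#: droplet readers assume ~0.85 nl per droplet; instruments differ, so this
#: is configurable on every :class:`DropletCount`.
DEFAULT_DROPLET_VOLUME_NL = 0.85

DEFAULT_CONFIDENCE_LEVEL = 0.95

CiMethod = Literal["delta", "clopper-pearson"]


@dataclass(frozen=True)
class DropletCount:
    """Raw droplet readout for one well (one sample x one assay).

    Parameters
    ----------
    positives
        Number of positive droplets ``k``.
    total
        Number of accepted droplets ``n``.
    dilution_factor
        Fold-dilution applied to the template before the reaction; estimated
        concentrations are multiplied back by this factor.
    droplet_volume_nl
        Volume of a single droplet in nanoliters.
    """

    sample_id: str
    assay_id: str
    positives: int
    total: int
    dilution_factor: float = 1.0
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if self.total < 1:
            raise DataError(f"total droplets must be >= 1, got {self.total}")
        if self.positives < 0:
            raise DataError(f"positives must be >= 0, got {self.positives}")
        if self.positives > self.total:
            raise DataError(
                f"positives ({self.positives}) exceed total droplets "
                f"({self.total}) for sample {self.sample_id!r}"
            )
        if self.droplet_volume_nl <= 0:
            raise DataError("droplet_volume_nl must be > 0")
        if self.dilution_factor < 1:
            raise DataError("dilution_factor must be >= 1")

    @property
    def positive_fraction(self) -> float:
        return self.positives / self.total

    @property
    def saturated(self) -> bool:
        return self.positives == self.total


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Absolute concentration in copies/ul with confidence bounds.

    ``copies_per_ul`` is dilution-corrected.  ``saturated_flag`` marks wells
    in which every droplet was positive; there the Poisson transform is
    undefined and all numeric fields are NaN — never a silent number.
    The raw counts are retained so replicates can be pooled at the count
    level (see :func:`merge_replicates`).
    """

    sample_id: str
    assay_id: str
    copies_per_ul: float
    lambda_per_droplet: float
    ci_low: float
    ci_high: float
    confidence_level: float = DEFAULT_CONFIDENCE_LEVEL
    saturated_flag: bool = False
    positives: int = 0
    total: int = 0
    dilution_factor: float = 1.0
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL


def _lambda_from_fraction(p: float) -> float:
    if p >= 1.0:
        return math.inf
    # log1p keeps precision for small positive fractions
    return -math.log1p(-p)


def _fraction_interval(
    k: int, n: int, confidence_level: float, method: CiMethod
) -> tuple[float, float]:
    """Two-sided confidence interval for the positive fraction k/n.

    ``k = 0`` and ``k = n`` fall back to one-sided exact bounds regardless of
    method: the normal approximation collapses to a point there.
    """
    alpha = 1.0 - confidence_level
    if k == 0:
        return 0.0, 1.0 - alpha ** (1.0 / n)
    if k == n:
        return alpha ** (1.0 / n), 1.0
    if method == "delta":
        p = k / n
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        half = z * math.sqrt(p * (1.0 - p) / n)
        return max(p - half, 0.0), min(p + half, 1.0)
    if method == "clopper-pearson":
        lo = stats.beta.ppf(alpha / 2.0, k, n - k + 1)
        hi = stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k)
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method: {method!r}")


def poisson_concentration(
    count: DropletCount,
    confidence_level: float = DEFAULT_CONFIDENCE_LEVEL,
    method: CiMethod = "delta",
    on_saturation: Literal["flag", "raise"] = "flag",
) -> ConcentrationEstimate:
    """Convert a droplet count into an absolute concentration estimate.

    Confidence bounds are computed on the positive fraction (normal
    approximation by default, exact Clopper-Pearson optionally) and pushed
    through the monotone Poisson transform.  ``k = 0`` yields a zero
    estimate with a one-sided exact upper bound.  ``k = n`` is a saturated
    well: by default the estimate is returned with ``saturated_flag`` set and
    NaN concentrations; with ``on_saturation="raise"`` a
    :class:`~pttquant.errors.SaturationError` is raised instead.
    """
    if not 0.0 < confidence_level < 1.0:
        raise ValueError("confidence_level must lie in (0, 1)")
    if count.saturated:
        if on_saturation == "raise":
            raise SaturationError(
                f"all {count.total} droplets positive in sample "
                f"{count.sample_id!r} / assay {count.assay_id!r}; "
                "dilute the template and repeat"
            )
        return ConcentrationEstimate(
            sample_id=count.sample_id,
            assay_id=count.assay_id,
            copies_per_ul=math.nan,
            lambda_per_droplet=math.nan,
            ci_low=math.nan,
            ci_high=math.nan,
            confidence_level=confidence_level,
            saturated_flag=True,
            positives=count.positives,
            total=count.total,
            dilution_factor=count.dilution_factor,
            droplet_volume_nl=count.droplet_volume_nl,
        )

    droplet_volume_ul = count.droplet_volume_nl * 1e-3
    scale = count.dilution_factor / droplet_volume_ul

    lam = _lambda_from_fraction(count.positive_fraction)
    p_lo, p_hi = _fraction_interval(
        count.positives, count.total, confidence_level, method
    )
    lam_lo = _lambda_from_fraction(p_lo)
    lam_hi = _lambda_from_fraction(p_hi)

    return ConcentrationEstimate(
        sample_id=count.sample_id,
        assay_id=count.assay_id,
        copies_per_ul=lam * scale,
        lambda_per_droplet=lam,
        ci_low=lam_lo * scale,
        ci_high=lam_hi * scale,
        confidence_level=confidence_level,
        saturated_flag=False,
        positives=count.positives,
        total=count.total,
        dilution_factor=count.dilution_factor,
        droplet_volume_nl=count.droplet_volume_nl,
    )


def merge_replicates(
    estimates: Sequence[ConcentrationEstimate],
    method: CiMethod = "delta",
) -> ConcentrationEstimate:
    """Pool replicate wells of the same assay into one estimate.

    Pooling sums positive and total droplet counts *before* the Poisson
    transform rather than averaging per-well concentrations: the droplet
    counts are the sufficient statistic, and count-level pooling weights
    wells by their droplet numbers and narrows the confidence interval
    correctly.

    Raises :class:`~pttquant.errors.DataError` on an empty list or on wells
    with mismatching assay ids, dilution factors or droplet volumes.
    """
    estimates = list(estimates)
    if not estimates:
        raise DataError("cannot merge an empty list of estimates")
    if len(estimates) == 1:
        return estimates[0]

    first = estimates[0]
    assays = {e.assay_id for e in estimates}
    if len(assays) > 1:
        raise DataError(f"cannot merge wells from different assays: {sorted(assays)}")
    if len({e.dilution_factor for e in estimates}) > 1:
        raise DataError("cannot merge wells with different dilution factors")
    if len({e.droplet_volume_nl for e in estimates}) > 1:
        raise DataError("cannot merge wells with different droplet volumes")

    pooled = DropletCount(
        sample_id=first.sample_id,
        assay_id=first.assay_id,
        positives=sum(e.positives for e in estimates),
        total=sum(e.total for e in estimates),
        dilution_factor=first.dilution_factor,
        droplet_volume_nl=first.droplet_volume_nl,
    )
    merged = poisson_concentration(
        pooled, confidence_level=first.confidence_level, method=method
    )
    return replace(merged, sample_id=first.sample_id)


def quantify_wells(
    counts: Iterable[DropletCount],
    confidence_level: float = DEFAULT_CONFIDENCE_LEVEL,
    method: CiMethod = "delta",
) -> list[ConcentrationEstimate]:
    """Quantify every well; saturated wells are flagged, not dropped."""
    return [
        poisson_concentration(c, confidence_level=confidence_level, method=method)
        for c in counts
    ]
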
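"""Bounded pain-intensity scales and summary-statistic transformations.

Pain intensity in randomised trials is reported on instruments with
different bounded ranges: a 0-100 visual analogue scale (VAS), a 0-10
numerical rating scale (NRS), or short verbal rating scales (VRS) such as
"no pain" / "mild" / "moderate" / "severe".  To compare or pool
between-group effects across instruments, group-level means and standard
deviations are mapped onto a common scale by the ratio of scale ranges.

This module provides:

* :class:`ScaleDefinition` -- a bounded scale, optionally carrying ordered
  verbal category labels;
* :func:`assign_numeric_values` -- the 0, 1, 2, ... coding of verbal
  categories used when trial investigators did not number them;
* :func:`rescale_summary` -- the linear range-ratio rescaling of a
  (mean, SD) pair;
* :func:`convert_median_range` / :func:`convert_median_iqr` -- estimators
  of mean and SD from a median with range or interquartile range, needed
  when trials report medians.  The default estimators follow Wan et al.
  (2014); the earlier Hozo et al. (2005) rules are available via
  ``method="hozo"``.

Conversions can be degenerate: a constant sample (min = median = max)
yields SD = 0, which makes any downstream effect-size variance undefined.
Such results are flagged rather than raised, so that exclusion decisions
can be taken (and logged) at the pair-analysis level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

from scipy.stats import norm

__all__ = [
    "ScaleDefinition",
    "ArmSummary",
    "DataFormat",
    "ConversionSource",
    "ConvertedSummary",
    "assign_numeric_values",
    "scale_from_labels",
    "rescale_summary",
    "convert_median_range",
    "convert_median_iqr",
]


class DataFormat(str, Enum):
    """How an arm's outcome is expressed."""

    ENDPOINT = "endpoint"
    CHANGE_FROM_BASELINE = "change_from_baseline"


class ConversionSource(str, Enum):
    """Provenance of a (mean, SD) pair: reported directly or converted."""

    NONE = "none"
    MEDIAN_RANGE = "median_range"
    MEDIAN_IQR = "median_iqr"


@dataclass(frozen=True)
class ScaleDefinition:
    """A bounded measurement scale.

    Parameters
    ----------
    name
        Short identifier, e.g. ``"VAS-100"`` or ``"VRS-4"``.
    lower, upper
        Scale bounds; ``upper`` must exceed ``lower``.  All common pain
        scales have ``lower = 0``.
    labels
        Ordered verbal categories (least to most severe) for verbal
        rating scales; ``None`` for numeric scales.
    values_assigned_by
        ``"trial"`` if the trial investigators numbered the categories,
        ``"analyst"`` if the numbering was imposed during analysis.
    """

    name: str
    lower: float
    upper: float
    labels: tuple[str, ...] | None = None
    values_assigned_by: str = "trial"

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError(
                f"scale {self.name!r}: upper ({self.upper}) must exceed "
                f"lower ({self.lower})"
            )
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))
            n_expected = int(round(self.upper - self.lower)) + 1
            if len(self.labels) != n_expected:
                raise ValueError(
                    f"scale {self.name!r}: {len(self.labels)} labels do not "
                    f"match integer range {self.lower}..{self.upper} "
                    f"({n_expected} categories)"
                )
        if self.values_assigned_by not in ("trial", "analyst"):
            raise ValueError(
                "values_assigned_by must be 'trial' or 'analyst', got "
                f"{self.values_assigned_by!r}"
            )

    @property
    def range(self) -> float:
        """Width of the scale, ``upper - lower``."""
        return self.upper - self.lower

    @property
    def n_points(self) -> int | None:
        """Number of categories for an integer-valued scale, else None."""
        width = self.upper - self.lower
        if float(width).is_integer() and width <= 10:
            return int(width) + 1
        return None


#: The common reference scale used throughout the pipeline.
SCALE_0_100 = ScaleDefinition("0-100", 0.0, 100.0)


@dataclass(frozen=True)
class ArmSummary:
    """Group-level summary for one arm, on one scale, at one timepoint."""

    trial_id: str
    comparison_id: str
    timepoint: str
    arm: str
    scale: ScaleDefinition
    n: int
    mean: float
    sd: float
    data_format: DataFormat = DataFormat.ENDPOINT
    converted_from: ConversionSource = ConversionSource.NONE
    crossover: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "data_format", DataFormat(self.data_format))
        object.__setattr__(
            self, "converted_from", ConversionSource(self.converted_from)
        )
        if self.n < 1:
            raise ValueError(f"arm {self.arm!r}: n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"arm {self.arm!r}: sd must be >= 0, got {self.sd}")
        if self.data_format == DataFormat.ENDPOINT and not (
            self.scale.lower - 1e-9 <= self.mean <= self.scale.upper + 1e-9
        ):
            raise ValueError(
                f"arm {self.arm!r}: endpoint mean {self.mean} outside scale "
                f"bounds [{self.scale.lower}, {self.scale.upper}]"
            )

    @property
    def degenerate(self) -> bool:
        """True when the SD is zero, so no sampling variance exists."""
        return self.sd == 0.0

    def rescaled(self, to: ScaleDefinition) -> "ArmSummary":
        """Return this summary expressed on another scale."""
        mean, sd = rescale_summary(
            self.mean, self.sd, self.scale, to, data_format=self.data_format
        )
        return replace(self, scale=to, mean=mean, sd=sd)


def assign_numeric_values(labels: Sequence[str]) -> Mapping[str, int]:
    """Number ordered verbal pain categories 0, 1, 2, ...

    The least severe category ("no pain") is coded 0 and each subsequent
    category adds one point, e.g. ``["no pain", "mild pain", "moderate
    pain", "severe pain"]`` becomes ``{... : 0, 1, 2, 3}``.

    Raises
    ------
    ValueError
        If ``labels`` is empty or contains duplicates.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("cannot assign numeric values to an empty label list")
    if len(set(labels)) != len(labels):
        raise ValueError("category labels must be distinct")
    return {label: i for i, label in enumerate(labels)}


def scale_from_labels(
    name: str, labels: Sequence[str], *, values_assigned_by: str = "analyst"
) -> ScaleDefinition:
    """Build the 0..(k-1) scale implied by ``assign_numeric_values``.

    A single-category list yields a degenerate zero-width scale and is
    rejected, since no between-group contrast can be expressed on it.
    """
    mapping = assign_numeric_values(labels)
    upper = float(max(mapping.values()))
    if upper == 0.0:
        raise ValueError(
            f"scale {name!r}: a single category gives a zero-width scale"
        )
    return ScaleDefinition(
        name, 0.0, upper, labels=tuple(labels), values_assigned_by=values_assigned_by
    )


def rescale_summary(
    mean: float,
    sd: float,
    from_scale: ScaleDefinition,
    to_scale: ScaleDefinition,
    *,
    data_format: DataFormat | str = DataFormat.ENDPOINT,
) -> tuple[float, float]:
    """Linearly re-express a (mean, SD) pair on another bounded scale.

    Both statistics are divided by the source scale's range and multiplied
    by the target scale's range.  Endpoint scores on a scale with a
    nonzero lower bound are shifted to zero first (``mean - lower``) and
    shifted onto the target's lower bound afterwards; change-from-baseline
    scores are differences, so only the range ratio applies.

    Returns
    -------
    (mean, sd) on the target scale's units.
    """
    ratio = to_scale.range / from_scale.range
    data_format = DataFormat(data_format)
    if data_format == DataFormat.ENDPOINT:
        new_mean = (mean - from_scale.lower) * ratio + to_scale.lower
    else:
        new_mean = mean * ratio
    return new_mean, sd * ratio


def _xi(n: int) -> float:
    """Expected standardized range of a normal sample of size n (Wan C1)."""
    return 2.0 * norm.ppf((n - 0.375) / (n + 0.25))


def _eta(n: int) -> float:
    """Expected standardized IQR of a normal sample of size n (Wan C3)."""
    return 2.0 * norm.ppf((0.75 * n - 0.125) / (n + 0.25))


@dataclass(frozen=True)
class ConvertedSummary:
    """Mean/SD estimated from order statistics, with provenance."""

    mean: float
    sd: float
    source: ConversionSource
    degenerate: bool = field(default=False)


def convert_median_range(
    median: float,
    minimum: float,
    maximum: float,
    n: int,
    *,
    method: str = "wan",
) -> ConvertedSummary:
    """Estimate mean and SD from a median and sample range.

    ``method="wan"`` (default) uses the normal-theory estimator of Wan et
    al. (2014): mean = (min + 2 median + max)/4 and SD = range / xi(n)
    with xi(n) = 2 * Phi^-1((n - 0.375)/(n + 0.25)).  ``method="hozo"``
    uses the piecewise rules of Hozo et al. (2005).

    A constant sample (min = median = max) converts to SD = 0.  This is
    returned flagged as degenerate, not raised: the pair analysis excludes
    such arms because a zero SD leaves the mean difference without a
    sampling variance.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if minimum > maximum:
        raise ValueError(f"min ({minimum}) exceeds max ({maximum})")
    if not (minimum <= median <= maximum):
        raise ValueError(
            f"median ({median}) outside range [{minimum}, {maximum}]"
        )
    if method == "wan" or n <= 25:
        mean = (minimum + 2.0 * median + maximum) / 4.0
    else:
        # Hozo recommends the median itself once n > 25.
        mean = median
    spread = maximum - minimum
    if spread == 0.0:
        return ConvertedSummary(mean, 0.0, ConversionSource.MEDIAN_RANGE, True)
    if method == "wan":
        sd = spread / _xi(n)
    elif method == "hozo":
        # Hozo's size-banded rules; the small-sample branch keeps the
        # median term.
        if n <= 15:
            var = (
                (minimum - 2.0 * median + maximum) ** 2 / 4.0 + spread**2
            ) / 12.0
            sd = math.sqrt(var)
        elif n <= 70:
            sd = spread / 4.0
        else:
            sd = spread / 6.0
    else:
        raise ValueError(f"unknown conversion method {method!r}")
    return ConvertedSummary(mean, sd, ConversionSource.MEDIAN_RANGE, False)


def convert_median_iqr(
    median: float,
    q1: float,
    q3: float,
    n: int,
    *,
    method: str = "wan",
) -> ConvertedSummary:
    """Estimate mean and SD from a median and interquartile range.

    ``method="wan"`` uses mean = (q1 + median + q3)/3 and
    SD = (q3 - q1) / eta(n) with eta(n) = 2 * Phi^-1((0.75n - 0.125)/(n + 0.25)),
    which tends to (q3 - q1)/1.349 for large n.  ``method="hozo"`` keeps
    the same mean estimator but uses the large-sample normal constant
    (q3 - q1)/1.35 for the SD, as Hozo et al. give no finite-sample IQR
    rule.

    q1 = q3 converts to SD = 0 and is flagged degenerate (see
    :func:`convert_median_range`).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if q1 > q3:
        raise ValueError(f"q1 ({q1}) exceeds q3 ({q3})")
    if not (q1 <= median <= q3):
        raise ValueError(f"median ({median}) outside IQR [{q1}, {q3}]")
    mean = (q1 + median + q3) / 3.0
    spread = q3 - q1
    if spread == 0.0:
        return ConvertedSummary(mean, 0.0, ConversionSource.MEDIAN_IQR, True)
    if method == "wan":
        sd = spread / _eta(n)
    elif method == "hozo":
        sd = spread / 1.35
    else:
        raise ValueError(f"unknown conversion method {method!r}")
    return ConvertedSummary(mean, sd, ConversionSource.MEDIAN_IQR, False)
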
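"""Paired-scale contrasts of rescaled between-group effects.

The central question this package addresses: when the same participants
in a trial score their pain on two instruments with different ranges, and
both instruments' summaries are rescaled to a common 0-100 scale, do the
two instruments yield the same between-group mean difference (MD) and the
same precision?

For every trial / comparison / timepoint at which two scales are
available, an *analysis pair* is formed: the MD computed from each scale
(both on 0-100), their difference ``delta_md = MD_small - MD_large``
(small-range scale minus larger-range reference), and each scale's
percentage weight from a two-row random-effects fit of the pair.  A 50%
weight for each scale means the two confidence intervals are equally
wide; below 50% for the small-range scale means it is the less precise
of the two.

Pairs are classified by the ranges involved:

* ``ten_vs_hundred``        -- 0-10 vs 0-100
* ``ten_vs_small``          -- 0-10 vs 0-<10 (e.g. a 0-3 VRS)
* ``hundred_vs_small_4pt``  -- 0-100 vs a 4-point scale (range 0-3)
* ``hundred_vs_small_5pt``  -- 0-100 vs a 5-point scale (range 0-4)

and aggregated per class: mean and range of the signed ``delta_md``,
counts of pairs in which the small-range scale's MD was higher/lower,
and the weight differential of the small-range scale relative to an even
split.  Absolute-value summaries are emitted alongside the signed ones.

Arms whose SD is zero (typically after a degenerate median/range
conversion) cannot enter an MD; their pairs are excluded with a recorded
reason rather than silently dropped, and excluded pairs never contribute
to class summaries.  A sensitivity filter removes pairs that relied on
any median-based conversion.
"""

from __future__ import annotations

import itertools
import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .meta import (
    EffectEstimate,
    inverse_variance_weights,
    md_estimate,
    random_effects_fit,
)
from .scales import SCALE_0_100, ArmSummary, ConversionSource, ScaleDefinition

__all__ = [
    "PairSpec",
    "PairResult",
    "PairClassSummary",
    "PAIR_CLASSES",
    "classify_scale_pair",
    "build_pairs",
    "compare_pair",
    "summarize_pairs",
    "summarize_all",
    "sensitivity_filter",
]

logger = logging.getLogger(__name__)

PAIR_CLASSES = (
    "ten_vs_hundred",
    "ten_vs_small",
    "hundred_vs_small_4pt",
    "hundred_vs_small_5pt",
)


def classify_scale_pair(a: ScaleDefinition, b: ScaleDefinition) -> str:
    """Classify a pair of scales by their ranges.

    The 0-100 vs 0-<10 class is split by whether the short scale has four
    or five points, mirroring how verbal rating scales of both lengths
    occur in practice.
    """
    small, large = sorted((a, b), key=lambda s: s.range)
    if large.range == small.range:
        raise ValueError(
            f"scales {a.name!r} and {b.name!r} have equal ranges; a pair "
            "needs two different ranges"
        )
    if large.range == 100.0 and small.range == 10.0:
        return "ten_vs_hundred"
    if large.range == 10.0 and small.range < 10.0:
        return "ten_vs_small"
    if large.range == 100.0 and small.range < 10.0:
        pts = small.n_points
        if pts is not None and pts <= 4:
            return "hundred_vs_small_4pt"
        return "hundred_vs_small_5pt"
    raise ValueError(
        f"unsupported scale-range pair: {small.range} vs {large.range}"
    )


@dataclass(frozen=True)
class PairSpec:
    """One analysis pair before computation: four arm summaries."""

    trial_id: str
    comparison_id: str
    timepoint: str
    arm_a: str
    arm_b: str
    scale_small: ScaleDefinition
    scale_large: ScaleDefinition
    # (arm_a, arm_b) summaries on each scale
    small_arms: tuple[ArmSummary, ArmSummary]
    large_arms: tuple[ArmSummary, ArmSummary]

    @property
    def pair_class(self) -> str:
        return classify_scale_pair(self.scale_small, self.scale_large)


@dataclass(frozen=True)
class PairResult:
    """The paired-scale contrast for one trial/comparison/timepoint."""

    trial_id: str
    comparison_id: str
    timepoint: str
    arm_a: str
    arm_b: str
    scale_small: ScaleDefinition
    scale_large: ScaleDefinition
    pair_class: str
    md_small: EffectEstimate | None
    md_large: EffectEstimate | None
    delta_md: float | None
    weight_small_pct: float | None
    converted: bool = False
    crossover: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def weight_large_pct(self) -> float | None:
        if self.weight_small_pct is None:
            return None
        return 100.0 - self.weight_small_pct


@dataclass(frozen=True)
class PairClassSummary:
    """Aggregate over the non-excluded pairs of one scale-pair class."""

    pair_class: str
    n_pairs: int
    n_trials: int
    mean_delta_md: float | None
    min_delta_md: float | None
    max_delta_md: float | None
    mean_abs_delta_md: float | None
    n_higher: int
    n_lower: int
    mean_weight_diff_pct: float | None
    min_weight_diff_pct: float | None
    max_weight_diff_pct: float | None
    n_excluded: int = 0

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


def _group_key(s: ArmSummary) -> tuple[str, str, str]:
    return (s.trial_id, s.comparison_id, s.timepoint)


def build_pairs(summaries: Iterable[ArmSummary]) -> list[PairSpec]:
    """Enumerate analysis pairs from a table of arm summaries.

    Within each trial/comparison/timepoint, every combination of two arms
    (for multi-arm trials: A vs B, A vs C, B vs C) is crossed with every
    combination of two scales of different range.  An arm reported on one
    scale but missing on the other is logged and skipped.
    """
    groups: dict[tuple[str, str, str], dict[str, dict[str, ArmSummary]]] = (
        defaultdict(lambda: defaultdict(dict))
    )
    scales_seen: dict[str, ScaleDefinition] = {}
    for s in summaries:
        groups[_group_key(s)][s.scale.name][s.arm] = s
        scales_seen[s.scale.name] = s.scale

    specs: list[PairSpec] = []
    for key in sorted(groups):
        by_scale = groups[key]
        scale_names = sorted(by_scale, key=lambda nm: scales_seen[nm].range)
        for name_a, name_b in itertools.combinations(scale_names, 2):
            sc_a, sc_b = scales_seen[name_a], scales_seen[name_b]
            if sc_a.range == sc_b.range:
                logger.info(
                    "%s: scales %s and %s share a range; no rescaling "
                    "contrast to make",
                    key,
                    name_a,
                    name_b,
                )
                continue
            small_name, large_name = (
                (name_a, name_b) if sc_a.range < sc_b.range else (name_b, name_a)
            )
            small_arms = by_scale[small_name]
            large_arms = by_scale[large_name]
            common = sorted(set(small_arms) & set(large_arms))
            for missing in sorted(set(small_arms) ^ set(large_arms)):
                logger.warning(
                    "%s: arm %r present on one scale only; skipped",
                    key,
                    missing,
                )
            for arm_a, arm_b in itertools.combinations(common, 2):
                specs.append(
                    PairSpec(
                        trial_id=key[0],
                        comparison_id=key[1],
                        timepoint=key[2],
                        arm_a=arm_a,
                        arm_b=arm_b,
                        scale_small=scales_seen[small_name],
                        scale_large=scales_seen[large_name],
                        small_arms=(small_arms[arm_a], small_arms[arm_b]),
                        large_arms=(large_arms[arm_a], large_arms[arm_b]),
                    )
                )
    return specs


def compare_pair(
    spec: PairSpec,
    rescale_to: ScaleDefinition = SCALE_0_100,
    *,
    weight_model: str = "random_effects_reml",
) -> PairResult:
    """Compute the paired-scale contrast for one analysis pair.

    Both MDs are computed on the common target scale; ``delta_md`` is the
    small-range scale's MD minus the large-range scale's MD, and the
    per-scale weights come from a two-row random-effects fit of the pair
    (``weight_model="fixed_effect"`` skips the tau^2 estimate and uses
    plain inverse-variance weights).  Pairs involving an arm with SD = 0
    are returned with ``excluded=True`` and a reason, since the
    degenerate arm has no sampling variance.
    """
    if weight_model not in ("random_effects_reml", "fixed_effect"):
        raise ValueError(f"unknown weight model {weight_model!r}")
    all_arms = list(spec.small_arms) + list(spec.large_arms)
    converted = any(
        a.converted_from != ConversionSource.NONE for a in all_arms
    )
    crossover = any(a.crossover for a in all_arms)
    degenerate = [a for a in all_arms if a.sd == 0.0]
    if degenerate:
        d = degenerate[0]
        reason = (
            f"SD of 0 on scale {d.scale.name!r}"
            + (
                f" (converted from {d.converted_from.value})"
                if d.converted_from != ConversionSource.NONE
                else ""
            )
        )
        logger.warning(
            "%s/%s/%s %s vs %s excluded: %s",
            spec.trial_id,
            spec.comparison_id,
            spec.timepoint,
            spec.arm_a,
            spec.arm_b,
            reason,
        )
        return PairResult(
            trial_id=spec.trial_id,
            comparison_id=spec.comparison_id,
            timepoint=spec.timepoint,
            arm_a=spec.arm_a,
            arm_b=spec.arm_b,
            scale_small=spec.scale_small,
            scale_large=spec.scale_large,
            pair_class=spec.pair_class,
            md_small=None,
            md_large=None,
            delta_md=None,
            weight_small_pct=None,
            converted=converted,
            crossover=crossover,
            excluded=True,
            exclusion_reason=reason,
        )
    md_small = md_estimate(*spec.small_arms, rescale_to)
    md_large = md_estimate(*spec.large_arms, rescale_to)
    if weight_model == "fixed_effect":
        w = inverse_variance_weights(
            np.array([md_small.variance, md_large.variance]), 0.0
        )
        weight_small = float(w[0] * 100.0)
    else:
        fit = random_effects_fit([md_small, md_large])
        weight_small = float(fit.weights_pct[0])
    return PairResult(
        trial_id=spec.trial_id,
        comparison_id=spec.comparison_id,
        timepoint=spec.timepoint,
        arm_a=spec.arm_a,
        arm_b=spec.arm_b,
        scale_small=spec.scale_small,
        scale_large=spec.scale_large,
        pair_class=spec.pair_class,
        md_small=md_small,
        md_large=md_large,
        delta_md=md_small.md - md_large.md,
        weight_small_pct=weight_small,
        converted=converted,
        crossover=crossover,
    )


def summarize_pairs(
    results: Sequence[PairResult], pair_class: str
) -> PairClassSummary:
    """Aggregate one scale-pair class.

    The class mean is the signed arithmetic mean of ``delta_md``
    (small-range scale minus reference), so a negative value reads "the
    small-range scale's MD was on average lower".  ``n_higher``/
    ``n_lower`` count pairs by the sign of ``delta_md``; exact ties count
    in neither.  The weight differential per pair is
    ``(weight_small_pct - 50) * 2`` -- the small-range scale's percentage
    weight surplus (positive) or shortfall (negative) relative to the
    other scale -- summarised by mean/min/max.
    """
    if pair_class not in PAIR_CLASSES:
        raise ValueError(f"unknown pair class {pair_class!r}")
    in_class = [r for r in results if r.pair_class == pair_class]
    usable = [r for r in in_class if not r.excluded]
    n_excluded = len(in_class) - len(usable)
    if not usable:
        return PairClassSummary(
            pair_class=pair_class,
            n_pairs=0,
            n_trials=0,
            mean_delta_md=None,
            min_delta_md=None,
            max_delta_md=None,
            mean_abs_delta_md=None,
            n_higher=0,
            n_lower=0,
            mean_weight_diff_pct=None,
            min_weight_diff_pct=None,
            max_weight_diff_pct=None,
            n_excluded=n_excluded,
        )
    deltas = np.array([r.delta_md for r in usable], dtype=float)
    wdiff = np.array(
        [(r.weight_small_pct - 50.0) * 2.0 for r in usable], dtype=float
    )
    return PairClassSummary(
        pair_class=pair_class,
        n_pairs=len(usable),
        n_trials=len({r.trial_id for r in usable}),
        mean_delta_md=float(deltas.mean()),
        min_delta_md=float(deltas.min()),
        max_delta_md=float(deltas.max()),
        mean_abs_delta_md=float(np.abs(deltas).mean()),
        n_higher=int((deltas > 0).sum()),
        n_lower=int((deltas < 0).sum()),
        mean_weight_diff_pct=float(wdiff.mean()),
        min_weight_diff_pct=float(wdiff.min()),
        max_weight_diff_pct=float(wdiff.max()),
        n_excluded=n_excluded,
    )


def summarize_all(results: Sequence[PairResult]) -> list[PairClassSummary]:
    """One :class:`PairClassSummary` per class, in canonical order."""
    return [summarize_pairs(results, cls) for cls in PAIR_CLASSES]


def sensitivity_filter(results: Sequence[PairResult]) -> list[PairResult]:
    """Drop every pair that relied on a median-based conversion.

    Mirrors the sensitivity analysis of removing trials whose data had
    been converted (e.g. from median and interquartile range); summaries
    are then recomputed on the remainder.
    """
    kept = [r for r in results if not r.converted]
    removed = len(results) - len(kept)
    if removed:
        logger.info(
            "sensitivity filter removed %d pair(s) with converted data",
            removed,
        )
    return kept
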
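"""Synthetic randomised-trial summary data for the rescaling pipeline.

The statistical structure the paired-scale analysis presumes is simple:
each participant carries one latent continuous pain intensity on a 0-100
metric, and every instrument in the trial measures that same latent value
simultaneously, differing only in range, discreteness and measurement
noise.  This module simulates that structure and emits the group-level
summary table (n / mean / SD per arm, scale and timepoint) that the
pipeline consumes, so every stage is testable without external trial
data.

Designs
-------
* *parallel*: each arm is an independent sample of participants;
* *crossover*: every participant receives all interventions; latent
  scores across periods are drawn from a multivariate normal with
  within-participant correlation ``rho`` (the same for all scales), but
  summaries are still emitted per arm, the way such trials report data
  when they do not report paired differences.

Measurement models per scale
----------------------------
* continuous 0-100: latent + noise, censored to [0, 100];
* discrete 0-10: (latent + noise)/10 rounded to the nearest integer and
  clipped;
* k-point ordinal: latent + noise binned by cutpoints over [0, 100]
  (equal-width by default), giving a category in 0..k-1.

Noise is independent across scales; censoring (clipping) rather than
re-drawing is used at the bounds, since pain scales censor: a participant
in more pain than the top anchor still scores the maximum.

Seeding: one root seed; each trial/timepoint draws from a child generator
spawned deterministically from it, so a single trial can be regenerated
in isolation and the full table is byte-identical for a given scenario.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .scales import ArmSummary, DataFormat, ScaleDefinition

__all__ = [
    "MeasuredScale",
    "SimulationScenario",
    "draw_latent",
    "measure_on_scale",
    "summarize_trial",
    "simulate_trial",
    "simulate_many",
    "study_scenarios",
    "vas_100",
    "nrs_10",
    "vrs",
]


def vas_100(name: str = "VAS-100") -> "MeasuredScale":
    """A continuous 0-100 visual analogue scale."""
    return MeasuredScale(ScaleDefinition(name, 0, 100), kind="continuous")


def nrs_10(name: str = "NRS-10") -> "MeasuredScale":
    """A discrete 0-10 numerical rating scale."""
    return MeasuredScale(ScaleDefinition(name, 0, 10), kind="discrete")


def vrs(n_points: int, name: str | None = None) -> "MeasuredScale":
    """A k-point verbal rating scale with equal-width cutpoints."""
    name = name or f"VRS-{n_points}"
    return MeasuredScale(
        ScaleDefinition(name, 0, n_points - 1), kind="ordinal"
    )


@dataclass(frozen=True)
class MeasuredScale:
    """A scale plus its measurement model.

    ``cutpoints`` applies to ordinal scales only: k-1 interior boundaries
    over the latent 0-100 metric.  When omitted, equal-width bins are
    used.  ``report_as`` selects how the generator writes this scale's
    summaries: plain mean/SD, or median with range/IQR to exercise the
    conversion path.
    """

    scale: ScaleDefinition
    kind: Literal["continuous", "discrete", "ordinal"]
    cutpoints: tuple[float, ...] | None = None
    report_as: Literal["mean_sd", "median_range", "median_iqr"] = "mean_sd"

    def __post_init__(self) -> None:
        if self.kind == "ordinal":
            k = self.scale.n_points
            if k is None:
                raise ValueError(
                    f"ordinal scale {self.scale.name!r} must have an "
                    "integer number of points"
                )
            if self.cutpoints is None:
                object.__setattr__(
                    self,
                    "cutpoints",
                    tuple(100.0 * i / k for i in range(1, k)),
                )
            elif len(self.cutpoints) != k - 1:
                raise ValueError(
                    f"ordinal scale {self.scale.name!r} with {k} points "
                    f"needs {k - 1} cutpoints, got {len(self.cutpoints)}"
                )
        elif self.cutpoints is not None:
            raise ValueError("cutpoints only apply to ordinal scales")


@dataclass(frozen=True)
class Arm:
    """An intervention arm's latent-score distribution on the 0-100 metric."""

    name: str
    latent_mean: float
    latent_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.latent_mean <= 100.0:
            raise ValueError(
                f"arm {self.name!r}: latent mean must lie in [0, 100]"
            )
        if self.latent_sd < 0.0:
            raise ValueError(f"arm {self.name!r}: latent sd must be >= 0")


@dataclass(frozen=True)
class SimulationScenario:
    """Everything needed to simulate one trial's summary table.

    Defaults emulate a typical included trial: two parallel arms of
    moderate size, a latent treatment effect of 10 points on the 0-100
    metric, a latent SD of 20 points, light measurement noise, and a
    continuous 0-100 scale measured alongside a 0-10 discrete scale.
    """

    trial_id: str = "trial-01"
    n_per_arm: int = 100
    arms: tuple[Arm, ...] = (
        Arm("treatment", 40.0, 20.0),
        Arm("placebo", 50.0, 20.0),
    )
    scales: tuple[MeasuredScale, ...] = (
        MeasuredScale(ScaleDefinition("VAS-100", 0, 100), kind="continuous"),
        MeasuredScale(ScaleDefinition("NRS-10", 0, 10), kind="discrete"),
    )
    design: Literal["parallel", "crossover"] = "parallel"
    rho: float = 0.6
    measurement_noise_sd: float = 5.0
    timepoints: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")
        if self.measurement_noise_sd < 0.0:
            raise ValueError("measurement_noise_sd must be >= 0")
        if self.timepoints < 1:
            raise ValueError("timepoints must be >= 1")
        if len(self.arms) < 2:
            raise ValueError("need at least two arms")
        if len({a.name for a in self.arms}) != len(self.arms):
            raise ValueError("arm names must be distinct")


def _child_rng(scenario: SimulationScenario, timepoint: int) -> np.random.Generator:
    # crc32 is a stable string hash (the builtin hash is salted per process)
    trial_key = zlib.crc32(scenario.trial_id.encode("utf-8"))
    ss = np.random.SeedSequence(
        scenario.seed, spawn_key=(trial_key, timepoint)
    )
    return np.random.default_rng(ss)


def draw_latent(
    scenario: SimulationScenario, timepoint: int = 0
) -> dict[str, np.ndarray]:
    """Draw per-participant latent pain scores, one array per arm.

    Parallel designs draw each arm independently from
    Normal(arm mean, arm sd); crossover designs draw one multivariate
    normal vector per participant across all periods/arms with pairwise
    correlation ``rho``.  All latent scores are censored to [0, 100].
    Deterministic given the scenario's seed and the timepoint index.
    """
    rng = _child_rng(scenario, timepoint)
    n = scenario.n_per_arm
    if scenario.design == "parallel":
        out = {
            a.name: rng.normal(a.latent_mean, a.latent_sd, size=n)
            for a in scenario.arms
        }
    else:
        k = len(scenario.arms)
        mean = np.array([a.latent_mean for a in scenario.arms])
        sds = np.array([a.latent_sd for a in scenario.arms])
        corr = np.full((k, k), scenario.rho)
        np.fill_diagonal(corr, 1.0)
        cov = corr * np.outer(sds, sds)
        draws = rng.multivariate_normal(mean, cov, size=n, method="cholesky")
        out = {a.name: draws[:, j] for j, a in enumerate(scenario.arms)}
    return {name: np.clip(x, 0.0, 100.0) for name, x in out.items()}


def measure_on_scale(
    latent: np.ndarray | float,
    mscale: MeasuredScale,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Measure latent 0-100 pain scores on an instrument's native units.

    See the module docstring for the per-kind measurement models.  With
    ``noise_sd = 0`` (or no rng) the mapping is deterministic.
    """
    x = np.atleast_1d(np.asarray(latent, dtype=float))
    if noise_sd > 0.0:
        if rng is None:
            raise ValueError("a Generator is required when noise_sd > 0")
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    sc = mscale.scale
    if mscale.kind == "continuous":
        return np.clip(x, 0.0, 100.0)
    if mscale.kind == "discrete":
        return np.clip(np.round(x / 10.0), sc.lower, sc.upper)
    # ordinal: bin by cutpoints; searchsorted gives the category index
    cuts = np.asarray(mscale.cutpoints, dtype=float)
    return np.searchsorted(cuts, x, side="right").astype(float)


def _summary_row(
    scenario: SimulationScenario,
    mscale: MeasuredScale,
    arm: Arm,
    values: np.ndarray,
    timepoint: int,
) -> ArmSummary | dict:
    tp = f"t{timepoint}"
    common = dict(
        trial_id=scenario.trial_id,
        comparison_id="c1",
        timepoint=tp,
        arm=arm.name,
        scale=mscale.scale,
        n=len(values),
        data_format=DataFormat.ENDPOINT,
        crossover=scenario.design == "crossover",
    )
    if mscale.report_as == "mean_sd":
        return ArmSummary(
            mean=float(values.mean()), sd=float(values.std(ddof=1)), **common
        )
    # Median-based reporting is returned as a plain record; conversion to
    # mean/SD is the reader's job, as with real extracted tables.
    if mscale.report_as == "median_range":
        return dict(
            median=float(np.median(values)),
            minimum=float(values.min()),
            maximum=float(values.max()),
            **common,
        )
    q1, q3 = np.percentile(values, [25.0, 75.0])
    return dict(
        median=float(np.median(values)), q1=float(q1), q3=float(q3), **common
    )


def summarize_trial(
    measurements: dict[int, dict[str, dict[str, np.ndarray]]],
    scenario: SimulationScenario,
) -> list[ArmSummary | dict]:
    """Summarise per-participant measurements into group-level rows.

    ``measurements[timepoint][scale_name][arm_name]`` holds native-unit
    values.  Scales with ``report_as="mean_sd"`` yield
    :class:`~painrescale.scales.ArmSummary` records; median-based scales
    yield plain dict records carrying the order statistics, to be
    converted on read like real extracted data.
    """
    by_name = {m.scale.name: m for m in scenario.scales}
    arms = {a.name: a for a in scenario.arms}
    rows: list[ArmSummary | dict] = []
    for timepoint in sorted(measurements):
        for scale_name in sorted(measurements[timepoint]):
            mscale = by_name[scale_name]
            for arm_name, values in measurements[timepoint][scale_name].items():
                rows.append(
                    _summary_row(
                        scenario, mscale, arms[arm_name], values, timepoint
                    )
                )
    return rows


def simulate_trial(scenario: SimulationScenario) -> list[ArmSummary | dict]:
    """Draw, measure and summarise one trial under a scenario."""
    measurements: dict[int, dict[str, dict[str, np.ndarray]]] = {}
    for timepoint in range(scenario.timepoints):
        latent = draw_latent(scenario, timepoint)
        rng = _child_rng(scenario, timepoint + 10_000)  # noise stream
        per_scale: dict[str, dict[str, np.ndarray]] = {}
        for mscale in scenario.scales:
            per_scale[mscale.scale.name] = {
                arm: measure_on_scale(
                    x, mscale, scenario.measurement_noise_sd, rng
                )
                for arm, x in latent.items()
            }
        measurements[timepoint] = per_scale
    return summarize_trial(measurements, scenario)


def study_scenarios(seed: int = 0) -> list[SimulationScenario]:
    """A twelve-trial scenario set emulating a realistic evidence base.

    Mirrors the structure found in low-back-pain analgesic trials that
    report pain on two instruments at once: a mix of parallel and
    crossover designs, two- and three-arm trials, one to three
    timepoints, and the four scale pairings (0-100 with 0-10, 4-point or
    5-point; 0-10 with 4-point).  One trial reports its short-scale data
    as median (range) and one as median (IQR), exercising the conversion
    path.  Child seeds are derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(12) % (2**31)]

    def two(m1: float, m2: float, sd: float = 20.0) -> tuple[Arm, Arm]:
        return (Arm("active", m1, sd), Arm("placebo", m2, sd))

    v100 = vas_100("VAS-100")
    n10 = nrs_10("NRS-10")
    return [
        SimulationScenario(
            "study-01", 83, two(42, 50), (v100, vrs(5)),
            design="crossover", seed=seeds[0],
        ),
        SimulationScenario(
            "study-02", 123,
            (Arm("drug-a", 38, 20), Arm("drug-b", 41, 20), Arm("placebo", 48, 20)),
            (v100, vrs(4)), seed=seeds[1],
        ),
        SimulationScenario(
            "study-03", 46,
            (Arm("drug-a", 40, 18), Arm("drug-b", 36, 18), Arm("drug-c", 38, 18)),
            (v100, MeasuredScale(vrs(4).scale, kind="ordinal",
                                 report_as="median_range")),
            timepoints=3, seed=seeds[2],
        ),
        SimulationScenario(
            "study-04", 41, two(44, 50), (n10, vrs(4)),
            timepoints=2, seed=seeds[3],
        ),
        SimulationScenario(
            "study-05", 104,
            (Arm("drug-a", 40, 20), Arm("drug-b", 43, 20), Arm("placebo", 49, 20)),
            (n10, vrs(4)), timepoints=2, seed=seeds[4],
        ),
        SimulationScenario(
            "study-06", 26, two(45, 52), (v100, vrs(5)),
            timepoints=3, seed=seeds[5],
        ),
        SimulationScenario(
            "study-07", 78, two(41, 49), (v100, vrs(5)),
            design="crossover", seed=seeds[6],
        ),
        SimulationScenario(
            "study-08", 79, two(40, 49), (v100, vrs(5)),
            design="crossover", seed=seeds[7],
        ),
        SimulationScenario(
            "study-09", 61, two(43, 47), (v100, vrs(5)), seed=seeds[8],
        ),
        SimulationScenario(
            "study-10", 138, two(42, 51),
            (n10, MeasuredScale(vrs(4).scale, kind="ordinal",
                                report_as="median_iqr")),
            seed=seeds[9],
        ),
        SimulationScenario(
            "study-11", 396, two(39, 44),
            (n10, MeasuredScale(ScaleDefinition("mBPI-10", 0, 10),
                                kind="discrete"), v100),
            seed=seeds[10],
        ),
        SimulationScenario(
            "study-12", 25, two(44, 52), (v100, vrs(5)), seed=seeds[11],
        ),
    ]


def simulate_many(
    base: SimulationScenario, n_trials: int, seed: int
) -> list[list[ArmSummary | dict]]:
    """Replicate a scenario ``n_trials`` times with distinct child seeds."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_trials) % (2**31)
    return [
        simulate_trial(
            replace(base, trial_id=f"{base.trial_id}-r{i:04d}", seed=int(s))
        )
        for i, s in enumerate(seeds)
    ]
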
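"""Reading, writing and the end-to-end pipeline.

The interchange format is a flat CSV (comma-separated, UTF-8, ``.``
decimal separator, mandatory header) with one row per arm x scale x
timepoint, mirroring how group-level data is extracted from trial
reports:

    trial_id, comparison_id, timepoint, arm,
    scale_name, scale_lower, scale_upper,
    n, mean, sd, median, q1, q3, min, max,
    data_format, converted_from, crossover, values_assigned_by

Exactly one of (mean, sd) or a median-based triple -- (median, min, max)
or (median, q1, q3) -- must be populated per row; median-based rows are
converted to mean/SD on read, with the conversion recorded in
``converted_from``.  Row-level validation failures are collected with
line numbers rather than aborting the whole read.

:func:`run_pipeline` ties everything together: read (or simulate) the
table, enumerate and compare analysis pairs, aggregate per scale-pair
class, and write the pair-level CSV, the class-summary CSV, a plain-text
report laid out like a summary-of-findings table, and a log of every
conversion and exclusion.  Output values in the report are rounded to
one decimal; full precision is kept in the CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import pairs as pairs_mod
from .pairs import (
    PairClassSummary,
    PairResult,
    build_pairs,
    sensitivity_filter,
    summarize_all,
)
from .scales import (
    SCALE_0_100,
    ArmSummary,
    ConversionSource,
    DataFormat,
    ScaleDefinition,
    convert_median_iqr,
    convert_median_range,
)
from .simulate import (
    Arm,
    MeasuredScale,
    SimulationScenario,
    simulate_trial,
)

__all__ = [
    "SCHEMA_COLUMNS",
    "RunConfig",
    "read_trials",
    "write_trials",
    "rows_to_frame",
    "write_pairs",
    "write_summaries",
    "render_report",
    "run_pipeline",
    "scenarios_from_json",
]

logger = logging.getLogger(__name__)

SCHEMA_COLUMNS = [
    "trial_id",
    "comparison_id",
    "timepoint",
    "arm",
    "scale_name",
    "scale_lower",
    "scale_upper",
    "n",
    "mean",
    "sd",
    "median",
    "q1",
    "q3",
    "min",
    "max",
    "data_format",
    "converted_from",
    "crossover",
    "values_assigned_by",
]

_CLASS_LABELS = {
    "ten_vs_hundred": "0 to 10 vs 0 to 100",
    "ten_vs_small": "0 to 10 vs 0 to <10",
    "hundred_vs_small_4pt": "0 to 100 vs 4-point (0 to 3)",
    "hundred_vs_small_5pt": "0 to 100 vs 5-point (0 to 4)",
}


class SchemaError(ValueError):
    """The input table does not match the expected column schema."""


class EmptyInputError(ValueError):
    """No valid arm-summary rows could be read."""


def _is_na(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or x == ""


def _parse_row(
    row: pd.Series, line_no: int, conversion: str
) -> ArmSummary:
    scale = ScaleDefinition(
        str(row["scale_name"]),
        float(row["scale_lower"]),
        float(row["scale_upper"]),
        values_assigned_by=(
            str(row["values_assigned_by"])
            if not _is_na(row.get("values_assigned_by"))
            else "trial"
        ),
    )
    has_mean = not _is_na(row["mean"]) and not _is_na(row["sd"])
    has_range = not (
        _is_na(row["median"]) or _is_na(row["min"]) or _is_na(row["max"])
    )
    has_iqr = not (
        _is_na(row["median"]) or _is_na(row["q1"]) or _is_na(row["q3"])
    )
    n = int(row["n"])
    if has_mean and (has_range or has_iqr):
        raise ValueError(
            "both mean/sd and a median-based summary populated; "
            "provide exactly one"
        )
    if has_mean:
        mean, sd = float(row["mean"]), float(row["sd"])
        converted = ConversionSource.NONE
    elif has_range:
        conv = convert_median_range(
            float(row["median"]),
            float(row["min"]),
            float(row["max"]),
            n,
            method=conversion,
        )
        mean, sd, converted = conv.mean, conv.sd, conv.source
        logger.info(
            "line %d: converted median (range) to mean %.4g, SD %.4g%s",
            line_no,
            mean,
            sd,
            " [degenerate: SD of 0]" if conv.degenerate else "",
        )
    elif has_iqr:
        conv = convert_median_iqr(
            float(row["median"]),
            float(row["q1"]),
            float(row["q3"]),
            n,
            method=conversion,
        )
        mean, sd, converted = conv.mean, conv.sd, conv.source
        logger.info(
            "line %d: converted median (IQR) to mean %.4g, SD %.4g%s",
            line_no,
            mean,
            sd,
            " [degenerate: SD of 0]" if conv.degenerate else "",
        )
    else:
        raise ValueError(
            "row needs either mean+sd or median with range or IQR"
        )
    return ArmSummary(
        trial_id=str(row["trial_id"]),
        comparison_id=str(row["comparison_id"]),
        timepoint=str(row["timepoint"]),
        arm=str(row["arm"]),
        scale=scale,
        n=n,
        mean=mean,
        sd=sd,
        data_format=DataFormat(str(row["data_format"])),
        converted_from=converted,
        crossover=_parse_bool(row["crossover"]),
    )


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in ("true", "1", "yes")


def read_trials(
    path: str | Path, *, conversion: str = "wan", strict: bool = True
) -> list[ArmSummary]:
    """Read and validate a trial-summary CSV into :class:`ArmSummary` rows.

    Median-based rows are converted to mean/SD via the selected
    conversion family (``"wan"`` or ``"hozo"``) with provenance recorded.
    With ``strict=True`` (default) any invalid row raises a single error
    listing every failure with its line number; otherwise bad rows are
    logged and skipped.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    rows: list[ArmSummary] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            rows.append(_parse_row(row, line_no, conversion))
        except (ValueError, KeyError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        msg = f"{path.name}: {len(problems)} invalid row(s):\n" + "\n".join(
            problems
        )
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    if not rows:
        raise EmptyInputError(f"{path.name}: no valid arm-summary rows")
    return rows


def rows_to_frame(rows: Sequence[ArmSummary | dict]) -> pd.DataFrame:
    """Build a full-schema DataFrame from summary records.

    Accepts :class:`ArmSummary` objects (mean/SD rows) and the plain dict
    records the simulator emits for median-based reporting.
    """
    out = []
    for r in rows:
        rec = dict.fromkeys(SCHEMA_COLUMNS, "")
        if isinstance(r, ArmSummary):
            rec.update(
                trial_id=r.trial_id,
                comparison_id=r.comparison_id,
                timepoint=r.timepoint,
                arm=r.arm,
                scale_name=r.scale.name,
                scale_lower=r.scale.lower,
                scale_upper=r.scale.upper,
                n=r.n,
                mean=r.mean,
                sd=r.sd,
                data_format=r.data_format.value,
                converted_from=r.converted_from.value,
                crossover=r.crossover,
                values_assigned_by=r.scale.values_assigned_by,
            )
        else:
            scale: ScaleDefinition = r["scale"]
            rec.update(
                trial_id=r["trial_id"],
                comparison_id=r["comparison_id"],
                timepoint=r["timepoint"],
                arm=r["arm"],
                scale_name=scale.name,
                scale_lower=scale.lower,
                scale_upper=scale.upper,
                n=r["n"],
                median=r["median"],
                data_format=DataFormat(r["data_format"]).value,
                converted_from="",
                crossover=r["crossover"],
                values_assigned_by=scale.values_assigned_by,
            )
            if "minimum" in r:
                rec.update(min=r["minimum"], max=r["maximum"])
            else:
                rec.update(q1=r["q1"], q3=r["q3"])
        out.append(rec)
    return pd.DataFrame(out, columns=SCHEMA_COLUMNS)


def write_trials(rows: Sequence[ArmSummary | dict], path: str | Path) -> None:
    """Write summary records to the interchange CSV."""
    rows_to_frame(rows).to_csv(path, index=False)


def pairs_to_frame(results: Sequence[PairResult]) -> pd.DataFrame:
    """One row per analysis pair, full precision."""
    recs = []
    for r in results:
        recs.append(
            dict(
                trial_id=r.trial_id,
                comparison_id=r.comparison_id,
                timepoint=r.timepoint,
                arm_a=r.arm_a,
                arm_b=r.arm_b,
                scale_small=r.scale_small.name,
                scale_large=r.scale_large.name,
                pair_class=r.pair_class,
                md_small=r.md_small.md if r.md_small else "",
                md_small_ci_lower=r.md_small.ci_lower if r.md_small else "",
                md_small_ci_upper=r.md_small.ci_upper if r.md_small else "",
                md_large=r.md_large.md if r.md_large else "",
                md_large_ci_lower=r.md_large.ci_lower if r.md_large else "",
                md_large_ci_upper=r.md_large.ci_upper if r.md_large else "",
                delta_md=r.delta_md if r.delta_md is not None else "",
                weight_small_pct=(
                    r.weight_small_pct if r.weight_small_pct is not None else ""
                ),
                converted=r.converted,
                crossover=r.crossover,
                excluded=r.excluded,
                exclusion_reason=r.exclusion_reason or "",
            )
        )
    return pd.DataFrame(recs)


def write_pairs(results: Sequence[PairResult], path: str | Path) -> None:
    pairs_to_frame(results).to_csv(path, index=False)


def summaries_to_frame(
    summaries: Sequence[PairClassSummary],
) -> pd.DataFrame:
    recs = []
    for s in summaries:
        recs.append(
            dict(
                pair_class=s.pair_class,
                n_pairs=s.n_pairs,
                n_trials=s.n_trials,
                n_excluded=s.n_excluded,
                mean_delta_md=s.mean_delta_md if not s.empty else "",
                min_delta_md=s.min_delta_md if not s.empty else "",
                max_delta_md=s.max_delta_md if not s.empty else "",
                mean_abs_delta_md=s.mean_abs_delta_md if not s.empty else "",
                n_higher=s.n_higher,
                n_lower=s.n_lower,
                mean_weight_diff_pct=(
                    s.mean_weight_diff_pct if not s.empty else ""
                ),
                min_weight_diff_pct=s.min_weight_diff_pct if not s.empty else "",
                max_weight_diff_pct=s.max_weight_diff_pct if not s.empty else "",
            )
        )
    return pd.DataFrame(recs)


def write_summaries(
    summaries: Sequence[PairClassSummary], path: str | Path
) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


def _fmt_class(s: PairClassSummary, results: Sequence[PairResult]) -> list[str]:
    label = _CLASS_LABELS[s.pair_class]
    lines = [label, "-" * len(label)]
    excluded = [
        r
        for r in results
        if r.pair_class == s.pair_class and r.excluded
    ]
    if s.empty:
        lines.append("  no pairs")
        for r in excluded:
            lines.append(
                f"  excluded: {r.trial_id}/{r.comparison_id}/{r.timepoint} "
                f"{r.arm_a} vs {r.arm_b} -- {r.exclusion_reason}"
            )
        lines.append("")
        return lines
    lines.append(
        f"  studies: {s.n_trials}   analysis pairs: {s.n_pairs}"
        + (f"   excluded: {s.n_excluded}" if s.n_excluded else "")
    )
    direction = "higher" if s.mean_delta_md >= 0 else "lower"
    lines.append(
        f"  difference in MD after rescaling: {abs(s.mean_delta_md):.1f} "
        f"points {direction} on average "
        f"(range {s.min_delta_md:.1f} to {s.max_delta_md:.1f}; "
        f"mean |difference| {s.mean_abs_delta_md:.1f})"
    )
    lines.append(
        f"  pairs with smaller-range scale MD higher: {s.n_higher}, "
        f"lower: {s.n_lower}"
    )
    wd = s.mean_weight_diff_pct
    wdir = "more" if wd >= 0 else "less"
    lines.append(
        f"  smaller-range scale contributed {abs(wd):.1f}% {wdir} weight "
        f"on average (range {s.min_weight_diff_pct:.1f}% to "
        f"{s.max_weight_diff_pct:.1f}%)"
    )
    for r in excluded:
        lines.append(
            f"  excluded: {r.trial_id}/{r.comparison_id}/{r.timepoint} "
            f"{r.arm_a} vs {r.arm_b} -- {r.exclusion_reason}"
        )
    lines.append("")
    return lines


def render_report(
    results: Sequence[PairResult],
    summaries: Sequence[PairClassSummary],
    *,
    title: str = "Paired-scale contrast of rescaled mean differences",
) -> str:
    """Plain-text summary-of-findings report, one block per class."""
    lines = [title, "=" * len(title), ""]
    for s in summaries:
        lines.extend(_fmt_class(s, results))
    return "\n".join(lines)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (an extracted-data CSV) or
    ``scenario_path`` (a JSON scenario file to simulate) must be set.
    """

    input_path: str | Path | None = None
    scenario_path: str | Path | None = None
    reference_scale: ScaleDefinition = SCALE_0_100
    conversion: str = "wan"  # wan | hozo
    weight_model: str = "random_effects_reml"  # | fixed_effect
    ci_level: float = 0.95
    sensitivity: bool = False
    out_dir: str | Path = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.scenario_path is None):
            raise ValueError(
                "set exactly one of input_path or scenario_path"
            )
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.conversion not in ("wan", "hozo"):
            raise ValueError(f"unknown conversion family {self.conversion!r}")
        if self.weight_model not in ("random_effects_reml", "fixed_effect"):
            raise ValueError(f"unknown weight model {self.weight_model!r}")


def _scale_from_spec(d: dict) -> MeasuredScale:
    kind = d.get("kind", "continuous")
    if "n_points" in d:
        lower, upper = 0.0, float(d["n_points"]) - 1.0
    else:
        lower, upper = float(d.get("lower", 0.0)), float(d["upper"])
    return MeasuredScale(
        ScaleDefinition(
            d["name"],
            lower,
            upper,
            values_assigned_by=d.get("values_assigned_by", "trial"),
        ),
        kind=kind,
        cutpoints=tuple(d["cutpoints"]) if d.get("cutpoints") else None,
        report_as=d.get("report_as", "mean_sd"),
    )


def scenarios_from_json(path: str | Path, *, seed: int = 0) -> list[SimulationScenario]:
    """Load one or more simulation scenarios from a JSON file.

    The file holds either one scenario object or a list of them.  Each
    object mirrors :class:`~painrescale.simulate.SimulationScenario`;
    scales are given as ``{"name", "kind", "upper" | "n_points",
    "report_as", "cutpoints"}`` and arms as ``{"name", "latent_mean",
    "latent_sd"}``.  ``seed`` overrides any seed absent from the file.
    """
    raw = json.loads(Path(path).read_text())
    if isinstance(raw, dict):
        raw = [raw]
    scenarios = []
    for i, d in enumerate(raw):
        scenarios.append(
            SimulationScenario(
                trial_id=d.get("trial_id", f"trial-{i + 1:02d}"),
                n_per_arm=int(d.get("n_per_arm", 100)),
                arms=tuple(
                    Arm(a["name"], float(a["latent_mean"]), float(a["latent_sd"]))
                    for a in d["arms"]
                ),
                scales=tuple(_scale_from_spec(s) for s in d["scales"]),
                design=d.get("design", "parallel"),
                rho=float(d.get("rho", 0.6)),
                measurement_noise_sd=float(d.get("measurement_noise_sd", 5.0)),
                timepoints=int(d.get("timepoints", 1)),
                seed=int(d.get("seed", seed)),
            )
        )
    return scenarios


@dataclass
class RunResult:
    """Artefact paths and in-memory results of one pipeline run."""

    results: list[PairResult]
    summaries: list[PairClassSummary]
    sensitivity_results: list[PairResult] | None
    sensitivity_summaries: list[PairClassSummary] | None
    out_dir: Path
    report: str


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis and write all artefacts to ``out_dir``.

    Writes ``pairs.csv``, ``class_summaries.csv``, ``report.txt`` and
    ``run.log`` (plus ``sensitivity_*`` variants when requested, and the
    simulated ``trials.csv`` when running from a scenario file).
    Deterministic given the config and seed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("painrescale")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if config.input_path is not None:
            rows = read_trials(config.input_path, conversion=config.conversion)
        else:
            scenarios = scenarios_from_json(
                config.scenario_path, seed=config.seed
            )
            raw_rows: list = []
            for sc in scenarios:
                raw_rows.extend(simulate_trial(sc))
            table_path = out_dir / "trials.csv"
            write_trials(raw_rows, table_path)
            rows = read_trials(table_path, conversion=config.conversion)

        specs = build_pairs(rows)
        results = [
            pairs_mod.compare_pair(
                s, config.reference_scale, weight_model=config.weight_model
            )
            for s in specs
        ]
        summaries = summarize_all(results)
        write_pairs(results, out_dir / "pairs.csv")
        write_summaries(summaries, out_dir / "class_summaries.csv")
        report = render_report(results, summaries)

        sens_results = sens_summaries = None
        if config.sensitivity:
            sens_results = sensitivity_filter(results)
            sens_summaries = summarize_all(sens_results)
            write_pairs(sens_results, out_dir / "sensitivity_pairs.csv")
            write_summaries(
                sens_summaries, out_dir / "sensitivity_class_summaries.csv"
            )
            report += "\n" + render_report(
                sens_results,
                sens_summaries,
                title="Sensitivity analysis (converted data removed)",
            )
        (out_dir / "report.txt").write_text(report)
        return RunResult(
            results=results,
            summaries=summaries,
            sensitivity_results=sens_results,
            sensitivity_summaries=sens_summaries,
            out_dir=out_dir,
            report=report,
        )
    finally:
        root.removeHandler(handler)
        handler.close()
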
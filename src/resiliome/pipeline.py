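"""End-to-end orchestration of the perturbation/resilience analysis.

Given the sample metadata, scalar measurements and composition profiles,
the pipeline computes (in order): pre-treatment variance components per
scalar variable; raw and normalised distances from baseline; per-subject
summaries (AUCs, maximal perturbation and resilience); Wilcoxon tests of
every metric against its null reference at fixed endpoints and over the
AUC windows; the two-arm comparison; and the four Spearman correlograms.
Every exclusion or fallback (baseline substitution, cohort-median
normaliser, missing windows) is recorded in a machine-readable run log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, io, trajectory
from .panel import DEFAULT_PANEL, VariableKind, panel_by_name

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "run_pipeline_paths"]

#: Fixed post-treatment endpoints at which metrics are tested.
FIXED_ENDPOINT_DAYS = (4, 7, 10, 30, 90)

CORRELOGRAM_MODES = (
    "perturbation",
    "resilience",
    "baseline_vs_perturbation",
    "baseline_vs_resilience",
)


@dataclass
class PipelineConfig:
    """Knobs of the analysis; defaults reproduce the standard design."""

    panel: tuple[VariableKind, ...] = DEFAULT_PANEL
    perturbation_window_end: int = 10
    resilience_days: tuple[int, ...] = (15, 30, 90)
    pretreatment_days: tuple[int, ...] = (-7, -15)
    fixed_endpoint_days: tuple[int, ...] = FIXED_ENDPOINT_DAYS
    alpha: float = 0.05
    bh_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.resilience_days) & set(
            range(1, self.perturbation_window_end + 1)
        ):
            raise ValueError("perturbation and resilience windows must be disjoint")
        names = [v.name for v in self.panel]
        if len(names) != len(set(names)):
            raise ValueError("panel names must be unique")


@dataclass
class ReportBundle:
    """All output tables plus the run log."""

    variability: pd.DataFrame
    distances: pd.DataFrame
    summaries: pd.DataFrame
    tests: pd.DataFrame
    arm_tests: pd.DataFrame
    correlograms: dict[str, pd.DataFrame]
    log: list[str] = field(default_factory=list)

    def frames(self) -> dict[str, pd.DataFrame]:
        out = {
            "variability": self.variability,
            "distances": self.distances,
            "summaries": self.summaries,
            "tests": self.tests,
            "arm_tests": self.arm_tests,
        }
        for mode, df in self.correlograms.items():
            out[f"correlogram_{mode}"] = df
        return out

    def write(self, outdir: str | Path) -> None:
        io.write_tables(self.frames(), outdir)
        logpath = Path(outdir) / "run_log.txt"
        logpath.write_text("\n".join(self.log) + ("\n" if self.log else ""))


def _analysis_scale(scalars: pd.DataFrame, kinds: dict[str, VariableKind]) -> pd.DataFrame:
    """Scalar values on the analysis scale (log10 where the panel says so)."""
    out = scalars.copy()
    vals = out["value"].to_numpy(dtype=float)
    analysis = np.empty_like(vals)
    for i, (var, v) in enumerate(zip(out["variable"], vals)):
        kind = kinds[var]
        if kind.transform == "log10":
            analysis[i] = math.log10(v) if v > 0 else math.nan
        else:
            analysis[i] = v
    out["analysis_value"] = analysis
    return out


def _variability(
    samples: pd.DataFrame,
    scalars: pd.DataFrame,
    kinds: dict[str, VariableKind],
    log: list[str],
) -> pd.DataFrame:
    scal = _analysis_scale(scalars, kinds)
    merged = scal.merge(samples, on="sample_id", how="inner")
    pre = merged[merged["nominal_day"] < 0].dropna(subset=["analysis_value"])
    rows = []
    for var in [v.name for v in kinds.values() if v.dimensionality == "low"]:
        grp = pre[pre["variable"] == var][["subject_id", "analysis_value"]].rename(
            columns={"analysis_value": "value"}
        )
        if grp["subject_id"].nunique() < 2:
            log.append(f"variability_skipped\t{var}\ttoo_few_subjects")
            continue
        try:
            vc = inference.variance_components(grp, variable=var)
        except ValueError as exc:
            log.append(f"variability_skipped\t{var}\t{exc}")
            continue
        rows.append(
            (
                var,
                vc.n_subjects,
                vc.mean,
                vc.between_sd,
                vc.between_cv_pct,
                vc.within_sd,
                vc.within_cv_pct,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variable",
            "n",
            "mean",
            "between_sd",
            "between_cv_pct",
            "within_sd",
            "within_cv_pct",
        ],
    )


def _reference_tests(
    distances: pd.DataFrame,
    summaries: pd.DataFrame,
    config: PipelineConfig,
    kinds: dict[str, VariableKind],
    log: list[str],
) -> pd.DataFrame:
    """Wilcoxon tests of each metric against its null reference."""
    rows = []
    for var, kind in kinds.items():
        low = kind.dimensionality == "low"
        dvar = distances[distances["variable"] == var]
        for day in config.fixed_endpoint_days:
            vals = dvar[dvar["nominal_day"] == day][
                "change" if low else "normalised_distance"
            ].dropna()
            ref = 0.0 if low else 1.0
            if len(vals) == 0 or (vals != ref).sum() == 0:
                log.append(f"test_skipped\t{var}\tday{day}\tno_informative_values")
                continue
            stat, p = inference.wilcoxon_vs_reference(vals, ref)
            rows.append((var, f"day{day}", ref, len(vals), stat, p))
        svar = summaries[summaries["variable"] == var]
        for col, window in (("auc_d0_d10", 10), ("auc_d0_d30", 30)):
            vals = svar[col].dropna()
            ref = 0.0 if low else float(window)
            if len(vals) == 0 or (vals != ref).sum() == 0:
                log.append(f"test_skipped\t{var}\t{col}\tno_informative_values")
                continue
            stat, p = inference.wilcoxon_vs_reference(vals, ref)
            rows.append((var, col, ref, len(vals), stat, p))
    out = pd.DataFrame(
        rows, columns=["variable", "timepoint", "reference", "n", "statistic", "p_value"]
    )
    if config.bh_correction and len(out):
        out["p_adjusted"] = inference.bh_adjust(out["p_value"])
    else:
        out["p_adjusted"] = np.nan
    return out


def _arm_tests(
    summaries: pd.DataFrame, samples: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Rank-sum comparison of the two treatment arms on the AUC metrics."""
    arm_of = samples.drop_duplicates("subject_id").set_index("subject_id")["arm"]
    arms = sorted(arm_of.unique())
    rows = []
    if len(arms) == 2:
        s = summaries.copy()
        s["arm"] = s["subject_id"].map(arm_of)
        for var, grp in s.groupby("variable", sort=True):
            for col in ("auc_d0_d10", "auc_d0_d30"):
                x = grp[grp["arm"] == arms[0]][col].dropna()
                y = grp[grp["arm"] == arms[1]][col].dropna()
                if len(x) == 0 or len(y) == 0:
                    continue
                stat, p = inference.rank_sum_test(x, y)
                rows.append((var, col, arms[0], arms[1], len(x), len(y), stat, p))
    out = pd.DataFrame(
        rows,
        columns=["variable", "metric", "arm_x", "arm_y", "n_x", "n_y", "statistic", "p_value"],
    )
    if config.bh_correction and len(out):
        out["p_adjusted"] = inference.bh_adjust(out["p_value"])
    else:
        out["p_adjusted"] = np.nan
    return out


def run_pipeline(
    samples: pd.DataFrame,
    scalars: pd.DataFrame | None = None,
    profiles: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> ReportBundle:
    """Run the full analysis on in-memory tables."""
    config = config or PipelineConfig()
    kinds = panel_by_name(config.panel)
    log: list[str] = []

    if scalars is not None and len(scalars):
        unknown = sorted(set(scalars["variable"]) - set(kinds))
        if unknown:
            raise io.TableValidationError(
                f"unknown variables not in the panel: {unknown}"
            )
        scalars = scalars.copy()

    raw = trajectory.compute_raw_distances(
        samples, scalars, profiles, config.panel, log=log
    )
    distances = trajectory.normalise_distances(
        raw, config.pretreatment_days, log=log
    )
    if not config.resilience_days:
        log.append("warning\tresilience_window_empty\tmax_resilience_all_missing")
    summaries = trajectory.summarise_trajectories(
        distances,
        samples,
        scalars,
        config.panel,
        log=log,
        perturbation_window_end=config.perturbation_window_end,
        resilience_days=tuple(config.resilience_days),
    )
    variability = (
        _variability(samples, scalars, kinds, log)
        if scalars is not None and len(scalars)
        else pd.DataFrame()
    )
    tests = _reference_tests(distances, summaries, config, kinds, log)
    arm_tests = _arm_tests(summaries, samples, config)

    correlograms = {}
    for mode in CORRELOGRAM_MODES:
        if (mode in ("resilience", "baseline_vs_resilience")) and not len(
            config.resilience_days
        ):
            log.append(f"correlogram_skipped\t{mode}\tno_resilience_window")
            continue
        correlograms[mode] = inference.correlogram(
            summaries, mode, config.panel, config.alpha
        )
    return ReportBundle(variability, distances, summaries, tests, arm_tests, correlograms, log)


def run_pipeline_paths(
    samples_path,
    scalars_path=None,
    profiles_path=None,
    config: PipelineConfig | None = None,
) -> ReportBundle:
    """Run the full analysis from TSV files."""
    samples = io.read_samples(samples_path)
    scalars = io.read_scalars(scalars_path) if scalars_path else None
    profiles = io.read_profiles(profiles_path) if profiles_path else None
    return run_pipeline(samples, scalars, profiles, config)
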
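"""Per-subject perturbation/resilience trajectories.

Each variable's departure from its pre-treatment state is traced per
subject as a *distance from baseline* at every sampling day:

* low-dimensional (scalar) variables: the signed change from baseline on
  the analysis scale (log10 for most variables, identity for richness);
  the raw distance is its absolute value;
* high-dimensional variables (omic-layer compositions): the Spearman
  rank correlation ``s`` between the baseline profile and the profile of
  the day, turned into the distance ``1 − s²`` — zero for a perfectly
  preserved (or perfectly rank-reversed) community structure, one for an
  uncorrelated one.

Raw distances are normalised per subject by the average of that
subject's own pre-treatment distances (days −7 and −15), falling back to
the cohort median of the other subjects' divisors when those visits are
missing, so that a normalised distance of 1 means "no more different
from baseline than the subject was before treatment".

Trajectories are then summarised by standardised trapezoidal AUCs over
the day 0–10 and 0–30 windows (computed on actual stool-emission times,
rescaled to the nominal window length), the maximal perturbation (the
largest normalised distance up to day 10) and the maximal resilience
(the smallest normalised distance on days 15, 30 or 90; smaller = more
resilient).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .panel import DEFAULT_PANEL, LAYER_STRUCTURE, VariableKind, panel_by_name

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectExcludedError",
    "select_baseline",
    "scalar_change",
    "structure_distance",
    "auc_standardised",
    "max_perturbation",
    "max_resilience",
    "compute_raw_distances",
    "normalise_distances",
    "summarise_trajectories",
    "PERTURBATION_WINDOW_END",
    "RESILIENCE_DAYS",
]

#: Maximal perturbation is taken over nominal days in (0, 10].
PERTURBATION_WINDOW_END = 10
#: Maximal resilience is taken over these late nominal days.
RESILIENCE_DAYS = (15, 30, 90)
#: Pre-treatment days used for the per-subject normaliser.
PRETREATMENT_DAYS = (-7, -15)


class SubjectExcludedError(ValueError):
    """A subject lacks the data required for this analysis step."""


def select_baseline(days_present) -> int:
    """Pick the baseline day: −1 if sampled, else −7, else −15."""
    present = set(int(d) for d in days_present)
    for day in (-1, -7, -15):
        if day in present:
            return day
    raise SubjectExcludedError("no pre-treatment sample among days -1, -7, -15")


def scalar_change(value: float, baseline_value: float, transform: str) -> float:
    """Signed change from baseline on the analysis scale."""
    if transform == "identity":
        return float(value) - float(baseline_value)
    if transform == "log10":
        if value is None or baseline_value is None or value <= 0 or baseline_value <= 0:
            logger.warning(
                "nonpositive value under log10 transform; change set to missing"
            )
            return math.nan
        return math.log10(value) - math.log10(baseline_value)
    raise ValueError(f"bad transform {transform!r}")


def structure_distance(profile, baseline_profile) -> tuple[float, float]:
    """Rank-correlation distance between two composition profiles.

    Returns ``(s, 1 − s²)`` where ``s`` is the mid-rank Spearman
    correlation computed over the *support*: features with nonzero
    abundance in at least one of the two profiles (shared absences carry
    no rank information and are excluded).  Missing (NaN, NaN) when the
    support has fewer than 3 features or either profile is rank-constant
    on it.
    """
    a = pd.Series(profile, dtype=float)
    b = pd.Series(baseline_profile, dtype=float)
    idx = a.index.union(b.index)
    a = a.reindex(idx, fill_value=0.0).to_numpy()
    b = b.reindex(idx, fill_value=0.0).to_numpy()
    support = (a > 0) | (b > 0)
    if support.sum() < 3:
        return math.nan, math.nan
    ra = rankdata(a[support])
    rb = rankdata(b[support])
    if ra.std() == 0 or rb.std() == 0:
        return math.nan, math.nan
    s = float(np.corrcoef(ra, rb)[0, 1])
    return s, 1.0 - s * s


def auc_standardised(
    points: pd.DataFrame, window_end: int, metric: str = "normalised_distance"
) -> float:
    """Delay-standardised trapezoidal AUC of a trajectory.

    ``points`` holds one subject-variable trajectory with columns
    ``nominal_day``, ``collection_time`` and ``value``.  The integral
    runs on actual collection times from t = 0 — anchored at the null
    value (0 for signed changes, 1 for normalised distances) — to the
    actual time T of the last sample with nominal day ≤ ``window_end``,
    and is rescaled by ``window_end / T`` so that subjects with
    different collection delays are comparable: a null trajectory scores
    exactly ``window_end`` (normalised distances) or 0 (changes).
    """
    if metric == "signed_change":
        anchor = 0.0
    elif metric == "normalised_distance":
        anchor = 1.0
    else:
        raise ValueError(f"bad metric {metric!r}")
    pts = points.dropna(subset=["value"])
    pts = pts[(pts["nominal_day"] > 0) & (pts["nominal_day"] <= window_end)]
    if len(pts) == 0:
        return math.nan
    pts = pts.sort_values("collection_time")
    times = np.concatenate([[0.0], pts["collection_time"].to_numpy(dtype=float)])
    values = np.concatenate([[anchor], pts["value"].to_numpy(dtype=float)])
    big_t = times[-1]
    if big_t <= 0:
        return math.nan
    integral = float(np.trapezoid(values, times))
    return integral * window_end / big_t


def max_perturbation(
    series: pd.DataFrame, window_end: int = PERTURBATION_WINDOW_END
) -> float:
    """Largest normalised distance at nominal days in (0, window_end]."""
    window = series[
        (series["nominal_day"] > 0) & (series["nominal_day"] <= window_end)
    ]["normalised_distance"].dropna()
    return float(window.max()) if len(window) else math.nan


def max_resilience(
    series: pd.DataFrame, days: tuple[int, ...] = RESILIENCE_DAYS
) -> float:
    """Smallest normalised distance on days 15, 30 or 90 (smaller = more resilient)."""
    window = series[series["nominal_day"].isin(days)]["normalised_distance"].dropna()
    return float(window.min()) if len(window) else math.nan


def _scalar_wide(scalars: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    merged = scalars.merge(samples, on="sample_id", how="inner")
    return merged


def compute_raw_distances(
    samples: pd.DataFrame,
    scalars: pd.DataFrame | None = None,
    profiles: pd.DataFrame | None = None,
    panel: tuple[VariableKind, ...] = DEFAULT_PANEL,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Raw distances from baseline for every subject and panel variable.

    ``samples`` is the sample-metadata table; ``scalars`` a long table
    ``(sample_id, variable, value)`` on the natural scale; ``profiles`` a
    long count table ``(sample_id, layer, feature_id, count)``.  Baseline
    is chosen per subject and variable among the days where that variable
    was actually measured (−1, then −7, then −15); subjects with no
    measured pre-treatment sample for a variable are excluded with a
    logged reason.

    Returns a long frame with columns subject_id, variable, nominal_day,
    collection_time, baseline_day, change (signed change or Spearman s)
    and raw_distance.
    """
    if log is None:
        log = []
    kinds = panel_by_name(panel)
    meta = samples.set_index("sample_id")
    rows: list[tuple] = []

    if scalars is not None and len(scalars):
        merged = scalars.merge(samples, on="sample_id", how="inner")
        for (subj, var), grp in merged.groupby(["subject_id", "variable"], sort=True):
            kind = kinds.get(var)
            if kind is None or kind.dimensionality != "low":
                continue
            grp = grp.dropna(subset=["value"])
            try:
                bday = select_baseline(grp["nominal_day"])
            except SubjectExcludedError:
                log.append(f"excluded\t{subj}\t{var}\tno_pretreatment_sample")
                continue
            bval = float(grp.loc[grp["nominal_day"] == bday, "value"].iloc[0])
            for _, r in grp.iterrows():
                if int(r["nominal_day"]) == bday:
                    continue
                ch = scalar_change(float(r["value"]), bval, kind.transform)
                rows.append(
                    (
                        subj,
                        var,
                        int(r["nominal_day"]),
                        float(r["collection_time"]),
                        bday,
                        ch,
                        abs(ch) if not math.isnan(ch) else math.nan,
                    )
                )

    if profiles is not None and len(profiles):
        for layer, lgrp in profiles.groupby("layer", sort=True):
            var = LAYER_STRUCTURE.get(layer, f"{layer}_structure")
            if var not in kinds:
                continue
            wide = lgrp.pivot_table(
                index="feature_id", columns="sample_id", values="count", fill_value=0.0
            )
            for subj in sorted(meta["subject_id"].unique()):
                subj_samples = meta[meta["subject_id"] == subj]
                have = [
                    sid for sid in subj_samples.index if sid in wide.columns
                ]
                days = {int(meta.loc[sid, "nominal_day"]): sid for sid in have}
                try:
                    bday = select_baseline(days.keys())
                except SubjectExcludedError:
                    log.append(f"excluded\t{subj}\t{var}\tno_pretreatment_sample")
                    continue
                base = wide[days[bday]]
                for day, sid in sorted(days.items()):
                    if day == bday:
                        continue
                    s, dist = structure_distance(wide[sid], base)
                    rows.append(
                        (
                            subj,
                            var,
                            day,
                            float(meta.loc[sid, "collection_time"]),
                            bday,
                            s,
                            dist,
                        )
                    )

    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "variable",
            "nominal_day",
            "collection_time",
            "baseline_day",
            "change",
            "raw_distance",
        ],
    )


def normalise_distances(
    raw: pd.DataFrame,
    pretreatment_days: tuple[int, ...] = PRETREATMENT_DAYS,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Normalise raw distances by each subject's pre-treatment variability.

    The divisor is the mean of the subject's raw distances at the
    pre-treatment days (−7 and −15 by default) that are present and are
    not the baseline day itself.  Subjects with no such sample fall back
    to the median of the other subjects' divisors for that variable.  A
    zero divisor (identical pre-treatment samples) leaves the normalised
    distances missing.
    """
    if log is None:
        log = []
    raw = raw.copy()
    divisors: dict[tuple[str, str], float] = {}
    for (subj, var), grp in raw.groupby(["subject_id", "variable"], sort=True):
        pre = grp[
            grp["nominal_day"].isin(pretreatment_days)
            & (grp["nominal_day"] != grp["baseline_day"])
        ]["raw_distance"].dropna()
        if len(pre):
            divisors[(subj, var)] = float(pre.mean())

    # Cohort fallback: median of the other subjects' divisors per variable.
    by_var: dict[str, list[tuple[str, float]]] = {}
    for (subj, var), d in divisors.items():
        by_var.setdefault(var, []).append((subj, d))

    norm = np.full(len(raw), np.nan)
    normaliser = np.full(len(raw), np.nan)
    source = np.empty(len(raw), dtype=object)
    raw = raw.reset_index(drop=True)
    for (subj, var), grp in raw.groupby(["subject_id", "variable"], sort=True):
        if (subj, var) in divisors:
            div = divisors[(subj, var)]
            src = "own_pretreatment"
        else:
            others = [d for s, d in by_var.get(var, []) if s != subj]
            if not others:
                log.append(f"no_normaliser\t{subj}\t{var}\tno_cohort_divisors")
                continue
            div = float(np.median(others))
            src = "cohort_median"
            log.append(f"fallback_normaliser\t{subj}\t{var}\tcohort_median={div:g}")
        idx = grp.index.to_numpy()
        normaliser[idx] = div
        source[idx] = src
        if div == 0:
            log.append(f"zero_normaliser\t{subj}\t{var}\tnormalised_missing")
            continue
        norm[idx] = grp["raw_distance"].to_numpy(dtype=float) / div
    raw["normalised_distance"] = norm
    raw["normaliser"] = normaliser
    raw["normaliser_source"] = source
    return raw


def summarise_trajectories(
    distances: pd.DataFrame,
    samples: pd.DataFrame,
    scalars: pd.DataFrame | None = None,
    panel: tuple[VariableKind, ...] = DEFAULT_PANEL,
    log: list[str] | None = None,
    perturbation_window_end: int = PERTURBATION_WINDOW_END,
    resilience_days: tuple[int, ...] = RESILIENCE_DAYS,
) -> pd.DataFrame:
    """Per-(subject, variable) summary: baseline value, AUCs, extremes.

    AUCs use signed changes (reference 0) for low-dimensional variables
    and normalised distances (reference equal to the window length) for
    high-dimensional ones.  The baseline value is reported on the
    natural, untransformed scale (scalar variables only) for the
    baseline-vs-outcome correlation analyses.
    """
    if log is None:
        log = []
    kinds = panel_by_name(panel)
    baseline_vals: dict[tuple[str, str], float] = {}
    if scalars is not None and len(scalars):
        merged = scalars.merge(samples, on="sample_id", how="inner")
        for (subj, var), grp in merged.groupby(["subject_id", "variable"]):
            grp = grp.dropna(subset=["value"])
            try:
                bday = select_baseline(grp["nominal_day"])
            except SubjectExcludedError:
                continue
            baseline_vals[(subj, var)] = float(
                grp.loc[grp["nominal_day"] == bday, "value"].iloc[0]
            )

    rows = []
    for (subj, var), grp in distances.groupby(["subject_id", "variable"], sort=True):
        kind = kinds.get(var)
        if kind is None:
            continue
        if kind.dimensionality == "low":
            metric = "signed_change"
            pts = grp.rename(columns={"change": "value"})[
                ["nominal_day", "collection_time", "value"]
            ]
        else:
            metric = "normalised_distance"
            pts = grp.rename(columns={"normalised_distance": "value"})[
                ["nominal_day", "collection_time", "value"]
            ]
        auc10 = auc_standardised(pts, 10, metric)
        auc30 = auc_standardised(pts, 30, metric)
        in_window = pts.dropna(subset=["value"])
        for window in (10, 30):
            got = in_window[
                (in_window["nominal_day"] > 0) & (in_window["nominal_day"] <= window)
            ]["nominal_day"]
            if len(got) and got.max() < window:
                log.append(
                    f"window_end_substituted\t{subj}\t{var}\tauc_d0_d{window}"
                    f"\tlast_day={int(got.max())}"
                )
        mp = max_perturbation(grp, perturbation_window_end)
        mr = max_resilience(grp, resilience_days)
        rows.append(
            (
                subj,
                var,
                baseline_vals.get((subj, var), math.nan),
                mp,
                mr,
                auc10,
                auc30,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "variable",
            "baseline_value",
            "max_perturbation",
            "max_resilience",
            "auc_d0_d10",
            "auc_d0_d30",
        ],
    )
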
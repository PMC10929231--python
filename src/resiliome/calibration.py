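"""Cohort-level simulation studies: type-I calibration and detectability.

These routines run the whole pipeline — generator, distances,
normalisation, AUCs, tests — over replicate synthetic cohorts.  They are
used to verify that the perturbation statistics are calibrated (a null
cohort rejects at the nominal rate) and that a realistic depletion is
detected as an elevated maximal perturbation followed by recovery.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from . import trajectory
from .cohort import generate_design
from .inference import wilcoxon_vs_reference
from .simulate import (
    DEFAULT_COMMUNITY_SPECS,
    DEFAULT_SCALAR_SPECS,
    simulate_composition_series,
    simulate_scalar_series,
)

__all__ = [
    "binomial_envelope",
    "cohort_auc_pvalues",
    "null_rejection_rates",
    "structure_perturbation_summary",
]

_SCALAR_VAR = "bacterial_counts"
_STRUCTURE_VAR = "bacterial_structure"


def binomial_envelope(n: int, p: float = 0.05, conf: float = 0.99) -> tuple[float, float]:
    """Central binomial interval for a rejection *rate* over n replicates."""
    tail = (1.0 - conf) / 2.0
    lo = stats.binom.ppf(tail, n, p) / n
    hi = stats.binom.ppf(1.0 - tail, n, p) / n
    return float(lo), float(hi)


def cohort_auc_pvalues(
    seed: int,
    n_subjects: int = 22,
    missingness_rate: float = 0.05,
    scalar_amplitude: float = 0.0,
    kill_fraction: float = 0.0,
) -> tuple[float, float]:
    """One cohort's Wilcoxon p-values for AUC_D0-D10 against its reference.

    Simulates one scalar variable (tested against 0) and one bacterial
    composition layer (normalised structure distances, AUC tested
    against 10) under the given effect sizes.
    """
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = (int(x) for x in ss.generate_state(3) >> 1)
    design = generate_design(n_subjects, missingness_rate=missingness_rate, seed=s1)
    samples = design.to_frame()

    spec = replace(
        DEFAULT_SCALAR_SPECS[_SCALAR_VAR], perturbation_amplitude=scalar_amplitude
    )
    scalars = simulate_scalar_series(design, spec, s2)
    cspec = replace(DEFAULT_COMMUNITY_SPECS["bacteria_MGS"], kill_fraction=kill_fraction)
    profiles = simulate_composition_series(design, cspec, s3)

    raw = trajectory.compute_raw_distances(samples, scalars, profiles)
    dist = trajectory.normalise_distances(raw)
    summ = trajectory.summarise_trajectories(dist, samples, scalars)
    lo = summ[summ["variable"] == _SCALAR_VAR]["auc_d0_d10"].dropna()
    hi = summ[summ["variable"] == _STRUCTURE_VAR]["auc_d0_d10"].dropna()
    return (
        wilcoxon_vs_reference(lo, 0.0)[1],
        wilcoxon_vs_reference(hi, 10.0)[1],
    )


def null_rejection_rates(
    n_cohorts: int = 200,
    n_subjects: int = 22,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the AUC reference tests over replicate null cohorts."""
    seeds = np.random.SeedSequence(seed).generate_state(n_cohorts) >> 1
    ps = np.array([cohort_auc_pvalues(int(s), n_subjects) for s in seeds])
    lo, hi = binomial_envelope(n_cohorts, alpha)
    return {
        "n_cohorts": n_cohorts,
        "scalar_rejection_rate": float((ps[:, 0] < alpha).mean()),
        "structure_rejection_rate": float((ps[:, 1] < alpha).mean()),
        "envelope_low": lo,
        "envelope_high": hi,
    }


def structure_perturbation_summary(
    seed: int,
    n_subjects: int = 22,
    kill_fraction: float = 0.5,
    recovery_halflife: float = 5.0,
) -> dict[str, float]:
    """Median perturbation/resilience of the bacterial structure in one cohort."""
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(x) for x in ss.generate_state(2) >> 1)
    design = generate_design(n_subjects, missingness_rate=0.05, seed=s1)
    samples = design.to_frame()
    cspec = replace(
        DEFAULT_COMMUNITY_SPECS["bacteria_MGS"],
        kill_fraction=kill_fraction,
        recovery_halflife=recovery_halflife,
    )
    profiles = simulate_composition_series(design, cspec, s2)
    raw = trajectory.compute_raw_distances(samples, profiles=profiles)
    dist = trajectory.normalise_distances(raw)
    summ = trajectory.summarise_trajectories(dist, samples)
    svar = summ[summ["variable"] == _STRUCTURE_VAR]
    day4 = dist[
        (dist["variable"] == _STRUCTURE_VAR) & (dist["nominal_day"] == 4)
    ]["normalised_distance"].dropna()
    return {
        "median_max_perturbation": float(svar["max_perturbation"].median()),
        "median_max_resilience": float(svar["max_resilience"].median()),
        "median_day4_distance": float(day4.median()),
    }
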
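"""Synthetic multi-omic cohort generator.

Emulates the statistical structure of a two-arm antibiotic-challenge
study in healthy volunteers: between- and within-subject variability of
each scalar variable on its analysis scale, an antibiotic-induced
depletion peaking during days 1–4 with near-complete recovery by about
day 30, and random sample missingness.  Nothing mechanistic is modelled
— no pharmacokinetics, no phage–bacteria coupling — the generator's only
job is to produce data with the moments and trajectories the analysis
pipeline assumes, so that every downstream stage is testable at desk
scale.

Scalar variables are simulated on their analysis scale (log10 for most,
identity for richness counts) as

    y_ij = mu + b_i + deflection(t_ij) + e_ij

with ``b_i ~ N(0, between_sd^2)`` and ``e_ij ~ N(0, within_sd^2)``, and a
gamma-pulse deflection with exponential recovery:

    deflection(t) = -A * (t/p) * exp(1 - t/p) * 2^(-max(0, t-p)/h)

for t > 0 (zero before treatment), where ``A`` is the peak amplitude,
``p`` the peak day and ``h`` the recovery half-life.  A positive ``A``
is a depletion; variables that increase under treatment (β-lactamasome,
fungal load) use a negative ``A``.  log10 variables are reported back on
the natural scale as ``10**y``.

Composition profiles are Dirichlet-multinomial: per subject a baseline
relative-abundance vector is drawn once; after treatment a fixed subset
of features (the antibiotic-susceptible fraction) is multiplied by a
depletion factor that relaxes back to 1 with half-life ``h`` once the
course ends, the vector is renormalised, and sequencing counts are drawn
multinomially at fixed depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import StudyDesign, generate_design

__all__ = [
    "ScalarVariableSpec",
    "CommunitySpec",
    "pulse_deflection",
    "simulate_scalar_series",
    "simulate_composition_series",
    "simulate_resistome",
    "simulate_cohort",
    "DEFAULT_SCALAR_SPECS",
    "DEFAULT_COMMUNITY_SPECS",
]

#: Day the antibiotic course ends; composition recovery starts here.
TREATMENT_END_DAY = 4.0


@dataclass(frozen=True)
class ScalarVariableSpec:
    """Generating parameters of one scalar variable, on its analysis scale."""

    name: str
    transform: str  # "log10" | "identity"
    baseline_mean: float
    between_sd: float
    within_sd: float
    perturbation_amplitude: float = 0.0  # peak deflection; >0 depletes
    peak_day: float = 4.0
    recovery_halflife: float = 7.0  # days

    def __post_init__(self) -> None:
        if self.transform not in ("log10", "identity"):
            raise ValueError(f"bad transform {self.transform!r}")
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.recovery_halflife <= 0:
            raise ValueError("recovery_halflife must be > 0")
        if self.peak_day <= 0:
            raise ValueError("peak_day must be > 0")


@dataclass(frozen=True)
class CommunitySpec:
    """Generating parameters of one omic layer's composition."""

    n_features: int = 150
    baseline_concentration: float = 0.3  # Dirichlet concentration per feature
    kill_fraction: float = 0.5  # fraction of features hit by the antibiotic
    kill_depth: float = 0.01  # multiplicative depletion of affected features
    recovery_halflife: float = 5.0  # days, after treatment end
    sequencing_depth: int = 50_000  # counts per sample

    def __post_init__(self) -> None:
        if self.n_features < 3:
            raise ValueError("n_features must be >= 3")
        if not (0 <= self.kill_fraction <= 1):
            raise ValueError("kill_fraction must be in [0, 1]")
        if not (0 < self.kill_depth <= 1):
            raise ValueError("kill_depth must be in (0, 1]")
        if self.recovery_halflife <= 0:
            raise ValueError("recovery_halflife must be > 0")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")


def pulse_deflection(
    t: np.ndarray | float,
    amplitude: float,
    peak_day: float,
    recovery_halflife: float,
) -> np.ndarray | float:
    """Gamma-pulse treatment effect with exponential post-peak recovery.

    Zero for t <= 0; reaches ``-amplitude`` at ``t = peak_day``; decays
    with half-life ``recovery_halflife`` beyond the peak (on top of the
    pulse's own decay, keeping the curve monotone post-peak).
    """
    t = np.asarray(t, dtype=float)
    x = np.where(t > 0, t / peak_day, 0.0)
    pulse = np.where(t > 0, x * np.exp(1.0 - x), 0.0)
    damp = np.exp2(-np.maximum(0.0, t - peak_day) / recovery_halflife)
    return -amplitude * pulse * damp


def simulate_scalar_series(
    design: StudyDesign, spec: ScalarVariableSpec, seed: int
) -> pd.DataFrame:
    """Simulate one scalar variable over a design.

    Returns a long frame ``(sample_id, variable, value)`` with values on
    the natural scale (``10**y`` for log10 variables).
    """
    rng = np.random.default_rng(seed)
    b = {s: rng.normal(0.0, spec.between_sd) for s in design.subjects}
    rows = []
    for s in design.samples:
        t = s.collection_time
        y = (
            spec.baseline_mean
            + b[s.subject_id]
            + float(
                pulse_deflection(
                    t, spec.perturbation_amplitude, spec.peak_day, spec.recovery_halflife
                )
            )
            + rng.normal(0.0, spec.within_sd)
        )
        rows.append((s.sample_id, spec.name, 10.0**y if spec.transform == "log10" else y))
    return pd.DataFrame(rows, columns=["sample_id", "variable", "value"])


def _depletion_factor(t: float, spec: CommunitySpec) -> float:
    # Full depletion during the course; exponential relaxation back to 1
    # with the given half-life once the course ends.
    if t <= 0:
        return 1.0
    recov = 1.0 - 2.0 ** (-max(0.0, t - TREATMENT_END_DAY) / spec.recovery_halflife)
    return spec.kill_depth * (1.0 + (1.0 / spec.kill_depth - 1.0) * recov)


def simulate_composition_series(
    design: StudyDesign, spec: CommunitySpec, seed: int, layer: str = "bacteria_MGS"
) -> pd.DataFrame:
    """Simulate one layer's count profiles over a design.

    Returns a long frame ``(sample_id, layer, feature_id, count)``; each
    sample's counts sum to ``spec.sequencing_depth``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_features
    n_kill = int(round(spec.kill_fraction * n))
    features = [f"{layer}_f{i + 1:04d}" for i in range(n)]
    frames = []
    for subj in design.subjects:
        base = rng.dirichlet(np.full(n, spec.baseline_concentration))
        killed = rng.choice(n, size=n_kill, replace=False)
        for s in design.subject_samples(subj):
            p = base.copy()
            f = _depletion_factor(s.collection_time, spec)
            p[killed] *= f
            p /= p.sum()
            counts = rng.multinomial(spec.sequencing_depth, p)
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": s.sample_id,
                        "layer": layer,
                        "feature_id": features,
                        "count": counts,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


#: ARD families: the five Ambler β-lactamase groups plus a catch-all for
#: every other resistance-determinant family.
BLA_FAMILIES: tuple[str, ...] = ("blaA", "blaB1B2", "blaB3", "blaC", "blaD")
OTHER_FAMILY = "otherARD"


def simulate_resistome(
    design: StudyDesign,
    n_genes: int = 300,
    bla_fraction: float = 1823 / 19061,
    seed: int = 0,
    enrichment_amplitude: float = 2.0,
    peak_day: float = 4.0,
    recovery_halflife: float = 7.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ARD gene-count tables with family annotation.

    A ``bla_fraction`` of genes is spread across the five Ambler
    β-lactamase families; the rest are other resistance determinants.
    After treatment the expected copy number of β-lactamase genes is
    multiplied by ``1 + enrichment_amplitude`` at the peak, decaying with
    the given half-life, so post-treatment samples are bla-enriched
    relative to ``otherARD``.

    Returns ``(counts, annotation)``: counts is long
    ``(sample_id, gene_id, count)``; annotation maps ``gene_id → family``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0 <= bla_fraction <= 1):
        raise ValueError("bla_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_bla = int(round(bla_fraction * n_genes))
    genes = [f"ARD{i + 1:05d}" for i in range(n_genes)]
    families = [BLA_FAMILIES[i % len(BLA_FAMILIES)] for i in range(n_bla)]
    families += [OTHER_FAMILY] * (n_genes - n_bla)
    annotation = pd.DataFrame({"gene_id": genes, "family": families})
    is_bla = np.array([f != OTHER_FAMILY for f in families])

    # Lognormal per-gene baseline copy numbers, shared across subjects.
    base_mean = np.exp(rng.normal(2.0, 1.0, n_genes))
    frames = []
    for subj in design.subjects:
        subj_scale = np.exp(rng.normal(0.0, 0.3))
        for s in design.subject_samples(subj):
            t = s.collection_time
            enrich = 1.0 - float(
                pulse_deflection(t, enrichment_amplitude, peak_day, recovery_halflife)
            )
            mu = base_mean * subj_scale
            mu = np.where(is_bla, mu * enrich, mu)
            counts = rng.poisson(mu)
            frames.append(
                pd.DataFrame({"sample_id": s.sample_id, "gene_id": genes, "count": counts})
            )
    return pd.concat(frames, ignore_index=True), annotation


def _t1(name, transform, mean, bsd, wsd, amp):
    return ScalarVariableSpec(name, transform, mean, bsd, wsd, amp)


#: Generating parameters for the 13 scalar panel variables.  Means and
#: between/within-subject SDs are pre-treatment variability on the
#: analysis scale typical of healthy adults (log10 CFU/g for counts,
#: log10 ratios for loads and rates, plain feature counts for richness).
#: Perturbation amplitudes are chosen to mirror the qualitative picture
#: of a parenteral cephalosporin course: strong bacterial and resistome
#: depletion, β-lactamasome/β-lactamase and fungal expansion (negative
#: amplitude), near-null fungal-richness response, modest metabolome
#: richness change.
DEFAULT_SCALAR_SPECS: dict[str, ScalarVariableSpec] = {
    s.name: s
    for s in [
        _t1("bacterial_counts", "log10", 11.3, 0.19, 0.14, 1.5),
        _t1("bacterial_richness", "identity", 269.7, 64.69, 16.0, 150.0),
        _t1("enterobacterales_counts", "log10", 7.5, 1.37, 1.00, 2.0),
        _t1("resistome_richness", "identity", 820.1, 159.50, 69.75, 300.0),
        _t1("betalactamasome_abundance", "log10", -0.8, 0.03, 0.02, -0.3),
        _t1("betalactamase_activity", "log10", 1.2, 0.59, 0.20, -0.5),
        _t1("phage_richness", "identity", 1226.6, 271.81, 91.37, 400.0),
        _t1("fungal_load", "log10", -5.2, 0.72, 1.27, -0.8),
        _t1("fungal_richness", "identity", 25.6, 4.77, 9.13, 0.0),
        _t1("calbicans_dna", "log10", -5.0, 0.81, 0.47, -0.5),
        _t1("metabolome_richness", "identity", 1472.7, 0.0, 98.85, 60.0),
        _t1("cholesterol_conversion_rate", "log10", -0.6, 1.03, 0.49, 1.0),
        _t1("bile_acid_transformation", "log10", -0.1, 0.09, 0.06, 0.3),
    ]
}

#: Layer compositions: bacteria and phages strongly depleted, fungi
#: nearly untouched, metabolome moderately hit but slow to recover.
DEFAULT_COMMUNITY_SPECS: dict[str, CommunitySpec] = {
    "bacteria_MGS": CommunitySpec(150, 0.3, 0.5, 0.01, 5.0, 50_000),
    "phage_contigs": CommunitySpec(120, 0.3, 0.4, 0.02, 5.0, 30_000),
    "fungal_OTUs": CommunitySpec(40, 0.5, 0.05, 0.5, 5.0, 10_000),
    "metabolites": CommunitySpec(200, 1.0, 0.3, 0.1, 20.0, 100_000),
}


def simulate_cohort(
    n_subjects: int = 22,
    seed: int = 0,
    missingness_rate: float = 0.05,
    scalar_specs: dict[str, ScalarVariableSpec] | None = None,
    community_specs: dict[str, CommunitySpec] | None = None,
    null: bool = False,
) -> dict[str, pd.DataFrame]:
    """Simulate a complete cohort: design, scalars, profiles, resistome.

    With ``null=True`` all perturbation amplitudes and kill fractions are
    zeroed, giving a no-treatment-effect cohort with the same noise
    structure (used for type-I-error calibration).

    Returns a dict of tidy frames: ``samples``, ``scalars``, ``profiles``,
    ``genes``, ``gene_annotation``.
    """
    scalar_specs = dict(scalar_specs or DEFAULT_SCALAR_SPECS)
    community_specs = dict(community_specs or DEFAULT_COMMUNITY_SPECS)
    if null:
        scalar_specs = {
            k: replace(v, perturbation_amplitude=0.0) for k, v in scalar_specs.items()
        }
        community_specs = {
            k: replace(v, kill_fraction=0.0) for k, v in community_specs.items()
        }

    ss = np.random.SeedSequence(seed)
    # One deterministic child seed per stage, keyed by insertion order.
    n_streams = 1 + len(scalar_specs) + len(community_specs) + 1
    child_seeds = [int(s) for s in ss.generate_state(n_streams) >> 1]

    design = generate_design(
        n_subjects, missingness_rate=missingness_rate, seed=child_seeds[0]
    )
    k = 1
    scalar_frames = []
    for name in sorted(scalar_specs):
        scalar_frames.append(simulate_scalar_series(design, scalar_specs[name], child_seeds[k]))
        k += 1
    profile_frames = []
    for layer in sorted(community_specs):
        profile_frames.append(
            simulate_composition_series(design, community_specs[layer], child_seeds[k], layer)
        )
        k += 1
    genes, annotation = simulate_resistome(design, seed=child_seeds[k])

    return {
        "samples": design.to_frame(),
        "scalars": pd.concat(scalar_frames, ignore_index=True),
        "profiles": pd.concat(profile_frames, ignore_index=True),
        "genes": genes,
        "gene_annotation": annotation,
    }
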
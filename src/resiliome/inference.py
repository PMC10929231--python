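"""Statistical layer: variability, reference tests and correlograms.

Pre-treatment variability of each scalar variable is decomposed into
between- and within-subject components with a random-intercept model

    y_ij = mu + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma_e^2)

fitted by restricted maximum likelihood (REML); both components are
reported as coefficients of variation (100·SD/|mean|) on the analysis
scale.  Because the model has a single random intercept, REML reduces to
a one-dimensional profile optimisation over the variance ratio
``lambda = sigma_b^2 / sigma_e^2``, which handles unbalanced designs and
truncates negative between-subject variance at zero.

Perturbation metrics are compared to their null reference values (0 for
scalar changes; 1, 10 and 30 for normalised structure distances and
their AUCs) with two-sided Wilcoxon signed-rank tests, exact for small
samples.  Relations between metrics are screened with Spearman
correlations — exact permutation p-values for very small n — and the
Benjamini–Hochberg step-up correction is applied globally per analysis
as a sensitivity check (primary inference is uncorrected, consistent
with an exploratory design, at two-sided alpha = 0.05).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .panel import DEFAULT_PANEL, VariableKind

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "variance_components",
    "wilcoxon_vs_reference",
    "rank_sum_test",
    "spearman_test",
    "bh_adjust",
    "correlogram",
    "summarise_correlogram",
    "format_fraction",
]

ALPHA = 0.05
#: Largest sample size for which exact null distributions are used.
EXACT_WILCOXON_MAX_N = 25
EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class VarianceComponents:
    """Between/within-subject variability of one variable."""

    variable: str
    n_subjects: int
    mean: float
    between_sd: float
    between_cv_pct: float
    within_sd: float
    within_cv_pct: float


def _as_groups(values) -> list[np.ndarray]:
    if isinstance(values, pd.DataFrame):
        return [
            g["value"].dropna().to_numpy(dtype=float)
            for _, g in values.groupby("subject_id", sort=True)
        ]
    return [np.asarray(v, dtype=float) for _, v in sorted(dict(values).items())]


def _reml_objective(lam: float, groups: list[np.ndarray], n_total: int) -> tuple[float, float, float]:
    """-2 REML log-likelihood profile (up to a constant) at variance ratio lam."""
    w = np.array([len(g) / (1.0 + len(g) * lam) for g in groups])
    means = np.array([g.mean() for g in groups])
    mu = float(np.sum(w * means) / np.sum(w))
    q = 0.0
    logdet = 0.0
    for g in groups:
        r = g - mu
        q += float(r @ r) - lam / (1.0 + len(g) * lam) * float(r.sum()) ** 2
        logdet += math.log1p(len(g) * lam)
    sigma_e2 = q / (n_total - 1)
    obj = (n_total - 1) * math.log(sigma_e2) + logdet + math.log(float(np.sum(w)))
    return obj, sigma_e2, mu


def variance_components(values, variable: str = "") -> VarianceComponents:
    """REML variance components of per-subject repeated measures.

    ``values`` is either a frame with columns ``subject_id``/``value`` or
    a mapping subject → array of analysis-scale values.  Requires at
    least 2 subjects and at least one subject with repeated measures.
    """
    groups = [g for g in _as_groups(values) if len(g)]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 subjects")
    n_total = sum(len(g) for g in groups)
    if all(len(g) < 2 for g in groups):
        raise ValueError("all subjects single-sampled: within-subject SD undefined")

    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    if ssw == 0.0:
        # Degenerate: no residual noise; between-SD from subject means.
        means = np.array([g.mean() for g in groups])
        mu = float(means.mean())
        sb = float(means.std(ddof=1))
        se = 0.0
    else:
        def f(u: float) -> float:
            return _reml_objective(math.exp(u), groups, n_total)[0]

        res = optimize.minimize_scalar(
            f, bounds=(-30.0, 30.0), method="bounded", options={"xatol": 1e-12}
        )
        lam = math.exp(res.x)
        obj, sigma_e2, mu = _reml_objective(lam, groups, n_total)
        obj0, sigma_e2_0, mu0 = _reml_objective(0.0, groups, n_total)
        if obj0 <= obj:  # between-subject variance truncated at zero
            lam, sigma_e2, mu = 0.0, sigma_e2_0, mu0
        se = math.sqrt(sigma_e2)
        sb = math.sqrt(lam * sigma_e2)

    denom = abs(mu)
    cv_b = 100.0 * sb / denom if denom > 0 else math.inf
    cv_w = 100.0 * se / denom if denom > 0 else math.inf
    return VarianceComponents(variable, k, mu, sb, cv_b, se, cv_w)


def wilcoxon_vs_reference(values, reference: float) -> tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test against a reference.

    Zero differences are dropped before ranking.  The exact null
    distribution is used for n ≤ 25 (after zero removal, absent ties);
    otherwise the normal approximation with continuity correction.
    All-zero differences yield p = 1 with a warning.
    """
    d = np.asarray(values, dtype=float) - reference
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        logger.warning("all differences zero in signed-rank test; p = 1")
        return 0.0, 1.0
    ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= EXACT_WILCOXON_MAX_N and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return float(res.statistic), float(res.pvalue)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided two-sample Wilcoxon rank-sum test (arm comparisons)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_WILCOXON_MAX_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _exact_spearman_p(zx: np.ndarray, zy: np.ndarray, rho: float) -> float:
    n = len(zx)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    num = zy[perms] @ zx
    denom = math.sqrt(float(zx @ zx) * float(zy @ zy))
    rho_perm = num / denom
    return float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))


def spearman_test(x, y) -> tuple[float, float]:
    """Mid-rank Spearman correlation with a two-sided test against zero.

    Missing values are dropped pairwise.  The p-value is an exact
    permutation probability for n ≤ 9 and the usual t-approximation
    otherwise.  Requires ≥ 4 complete pairs; rank-constant input yields
    (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    rx = rankdata(x)
    ry = rankdata(y)
    zx = rx - rx.mean()
    zy = ry - ry.mean()
    sx = float(zx @ zx)
    sy = float(zy @ zy)
    if sx == 0 or sy == 0:
        return math.nan, math.nan
    rho = float(zx @ zy) / math.sqrt(sx * sy)
    if n <= EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(zx, zy, rho)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (global, capped at 1).

    NaN entries (untestable pairs) are passed through and do not count
    towards the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def format_fraction(k: int, n: int) -> str:
    """Render a significant-pair fraction the way reports print it, e.g. 11.8%."""
    return f"{100.0 * k / n:.1f}%"


def correlogram(
    summary: pd.DataFrame,
    mode: str = "perturbation",
    panel: tuple[VariableKind, ...] = DEFAULT_PANEL,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Spearman correlogram of perturbation/resilience summaries.

    Modes ``perturbation`` and ``resilience`` test all unordered pairs of
    the panel's metrics (17 metrics → 136 pairs by default) on their
    maximal perturbation or maximal resilience.  Modes
    ``baseline_vs_perturbation`` and ``baseline_vs_resilience`` test the
    rectangular grid of scalar baseline values (untransformed) against
    each metric's outcome.  Missing values are dropped pairwise;
    BH-adjusted p-values are computed globally over the whole mode.
    """
    outcome_col = {
        "perturbation": "max_perturbation",
        "resilience": "max_resilience",
        "baseline_vs_perturbation": "max_perturbation",
        "baseline_vs_resilience": "max_resilience",
    }.get(mode)
    if outcome_col is None:
        raise ValueError(f"bad mode {mode!r}")

    metric_names = [v.name for v in panel]
    wide_out = summary.pivot_table(
        index="subject_id", columns="variable", values=outcome_col
    )
    if mode.startswith("baseline_vs"):
        wide_base = summary.pivot_table(
            index="subject_id", columns="variable", values="baseline_value"
        )
        baseline_names = [v.name for v in panel if v.dimensionality == "low"]
        pairs = [(bx, my) for bx in baseline_names for my in metric_names]

        def get_x(name, idx):
            return wide_base.reindex(idx)[name] if name in wide_base else None
    else:
        pairs = list(itertools.combinations(metric_names, 2))

        def get_x(name, idx):
            return wide_out.reindex(idx)[name] if name in wide_out else None

    idx = wide_out.index
    rows = []
    for mx, my in pairs:
        xs = get_x(mx, idx)
        ys = wide_out[my] if my in wide_out else None
        rho, p, n = math.nan, math.nan, 0
        if xs is not None and ys is not None:
            ok = ~(xs.isna() | ys.isna())
            n = int(ok.sum())
            if n >= 4:
                rho, p = spearman_test(xs[ok], ys[ok])
        rows.append((mx, my, rho, n, p))
    out = pd.DataFrame(rows, columns=["metric_x", "metric_y", "rho", "n_pairs", "p_value"])
    out["p_adjusted"] = bh_adjust(out["p_value"])
    out["significant"] = out["p_value"] < alpha
    out["significant_adjusted"] = out["p_adjusted"] < alpha
    return out


def summarise_correlogram(
    result: pd.DataFrame, alpha: float = ALPHA, adjusted: bool = False
) -> dict:
    """Counts and the formatted percentage of significant pairs."""
    col = "p_adjusted" if adjusted else "p_value"
    n_pairs = len(result)
    n_sig = int((result[col] < alpha).sum())
    return {
        "n_pairs": n_pairs,
        "n_significant": n_sig,
        "percent_significant": format_fraction(n_sig, n_pairs),
    }
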
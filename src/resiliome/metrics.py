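"""Per-sample derived metrics from feature and gene tables.

Covers the quantification conventions of shotgun-metagenomic microbiome
profiling: metagenomic-species (MGS) abundances summarised from marker
genes, observed richness, rarefaction without replacement, the relative
abundance of the β-lactamasome within the resistome, and the scalar
functional ratios (cholesterol conversion, bile-acid transformation,
fungal load).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneCountTable",
    "AbundanceProfile",
    "SampleExcludedError",
    "mgs_abundance",
    "rarefy_counts",
    "observed_richness",
    "betalactamasome_abundance",
    "cholesterol_conversion_rate",
    "bile_acid_transformation",
    "fungal_load",
    "DEFAULT_BLA_FAMILIES",
]

#: Ambler β-lactamase groups counted as the β-lactamasome.
DEFAULT_BLA_FAMILIES: frozenset[str] = frozenset(
    {"blaA", "blaB1B2", "blaB3", "blaC", "blaD"}
)


class SampleExcludedError(ValueError):
    """A sample fails a quantification precondition and must be excluded."""


@dataclass
class GeneCountTable:
    """One sample's gene copies, with ARD family and MGS marker annotation.

    ``counts`` maps gene_id to a nonnegative copy number (copies/g or
    length-normalised coverage — the metrics below are agnostic to the
    unit).  ``annotation`` maps gene_id to an ARD family label for genes
    that are resistance determinants.  ``marker_sets`` maps each MGS to
    the list of its designated marker genes.
    """

    sample_id: str
    counts: Mapping[str, float]
    annotation: Mapping[str, str] = field(default_factory=dict)
    marker_sets: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for gene {g}")


@dataclass
class AbundanceProfile:
    """One sample's feature-abundance vector for one omic layer."""

    sample_id: str
    layer: str
    abundances: pd.Series  # feature_id -> nonnegative value
    relative: bool = False

    def __post_init__(self) -> None:
        self.abundances = pd.Series(self.abundances, dtype=float)
        if (self.abundances < 0).any():
            raise ValueError("abundances must be nonnegative")
        if self.relative:
            total = self.abundances.sum()
            if total > 0 and abs(total - 1.0) > 1e-9:
                raise ValueError("relative abundances must sum to 1")


def mgs_abundance(
    gene_table: GeneCountTable, detection_fraction: float = 0.10
) -> AbundanceProfile:
    """Summarise MGS abundances from marker-gene counts.

    Each MGS abundance is the mean count of its marker genes, zeroed when
    fewer than ``detection_fraction`` of the markers are detected
    (count > 0) in the sample, then the profile is renormalised to sum
    to 1 (an all-zero profile stays all-zero).
    """
    if not gene_table.marker_sets:
        raise ValueError("marker_sets is empty")
    raw = {}
    for mgs, markers in gene_table.marker_sets.items():
        if len(markers) == 0:
            raise ValueError(f"MGS {mgs} has an empty marker list")
        vals = np.array([gene_table.counts.get(g, 0.0) for g in markers], dtype=float)
        seen = float(np.count_nonzero(vals)) / len(vals)
        raw[mgs] = float(vals.mean()) if seen >= detection_fraction else 0.0
    s = pd.Series(raw, dtype=float)
    total = s.sum()
    if total > 0:
        s = s / total
    return AbundanceProfile(gene_table.sample_id, "bacteria_MGS", s, relative=True)


def rarefy_counts(
    counts: Sequence[int] | pd.Series, depth: int, seed: int
) -> np.ndarray | pd.Series:
    """Subsample integer counts without replacement to a fixed depth.

    Draws a multivariate-hypergeometric subsample totalling exactly
    ``depth``.  Samples shallower than the target depth cannot be
    rarefied and are excluded (this mirrors choosing the depth to include
    all samples rather than imputing reads).
    """
    is_series = isinstance(counts, pd.Series)
    arr = np.asarray(counts.to_numpy() if is_series else counts)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    total = int(arr.sum())
    if depth > total:
        raise SampleExcludedError(
            f"rarefaction depth {depth} exceeds sample total {total}"
        )
    rng = np.random.default_rng(seed)
    out = rng.multivariate_hypergeometric(arr, depth)
    if is_series:
        return pd.Series(out, index=counts.index)
    return out


def observed_richness(profile: AbundanceProfile | pd.Series | Sequence[float]) -> int:
    """Number of features with strictly positive abundance."""
    if isinstance(profile, AbundanceProfile):
        values = profile.abundances.to_numpy()
    else:
        values = np.asarray(profile, dtype=float)
    return int(np.count_nonzero(values > 0))


def betalactamasome_abundance(
    gene_table: GeneCountTable,
    bla_families: frozenset[str] | set[str] = DEFAULT_BLA_FAMILIES,
) -> float:
    """Relative abundance of the β-lactamasome within the resistome.

    The proportion of gene copies mapping to any β-lactamase family among
    all copies mapping to an annotated resistance determinant.  Undefined
    (NaN) when the sample carries no ARD copies at all.
    """
    total = 0.0
    bla = 0.0
    for gene, fam in gene_table.annotation.items():
        c = float(gene_table.counts.get(gene, 0.0))
        total += c
        if fam in bla_families:
            bla += c
    if total == 0:
        return math.nan
    return bla / total


def cholesterol_conversion_rate(coprostanol: float, cholesterol: float) -> float:
    """Microbial cholesterol reduction: coprostanol / (coprostanol + cholesterol)."""
    if coprostanol < 0 or cholesterol < 0:
        raise ValueError("concentrations must be >= 0")
    denom = coprostanol + cholesterol
    if denom == 0:
        return math.nan
    return coprostanol / denom


def bile_acid_transformation(lca: float, dca: float, total: float) -> float:
    """Secondary bile-acid fraction: (LCA + DCA) / total faecal bile acids."""
    if lca < 0 or dca < 0:
        raise ValueError("concentrations must be >= 0")
    if lca + dca > total:
        raise ValueError("secondary bile acids exceed the total")
    if total == 0:
        return math.nan
    return (lca + dca) / total


def fungal_load(
    fungal_dna: float, faecal_dna: float, faecal_dna_threshold: float = 50.0
) -> float:
    """Fungal DNA relative to total faecal DNA.

    Samples with faecal DNA at or below the quantification threshold
    (default 50, in the units of the assay) are excluded rather than
    yielding an unreliable ratio.
    """
    if fungal_dna < 0:
        raise ValueError("fungal_dna must be >= 0")
    if faecal_dna <= faecal_dna_threshold:
        raise SampleExcludedError(
            f"faecal DNA {faecal_dna} at or below threshold {faecal_dna_threshold}"
        )
    return fungal_dna / faecal_dna
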
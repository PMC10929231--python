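"""The default panel of gut-ecosystem variables.

The analysis distinguishes *low-dimensional* variables — one scalar per
sample (counts, activities, richness, ratios) — from *high-dimensional*
variables, the multivariate composition ("structure") of each omic layer
(bacterial species, phage contigs, fungal OTUs, metabolite features).

All low-dimensional variables except observed-richness counts are
log10-transformed before analysis; richness stays on the natural scale.
High-dimensional variables carry no transform: their departure from
baseline is measured through rank correlation of the whole profile.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class VariableKind:
    """A panel variable: its name, dimensionality and scalar transform."""

    name: str
    dimensionality: str  # "low" | "high"
    transform: str | None = None  # "log10" | "identity"; None for high

    def __post_init__(self) -> None:
        if self.dimensionality not in ("low", "high"):
            raise ValueError(f"bad dimensionality {self.dimensionality!r}")
        if self.dimensionality == "high":
            if self.transform is not None:
                raise ValueError("high-dimensional variables carry no transform")
        elif self.transform not in ("log10", "identity"):
            raise ValueError(f"bad transform {self.transform!r}")


#: 13 scalar variables (richness variables on the identity scale, all
#: others log10) plus the 4 omic-layer structures: 17 metrics in total,
#: hence 17·16/2 = 136 unordered pairs in a correlogram.
DEFAULT_PANEL: tuple[VariableKind, ...] = (
    VariableKind("bacterial_counts", "low", "log10"),
    VariableKind("bacterial_richness", "low", "identity"),
    VariableKind("enterobacterales_counts", "low", "log10"),
    VariableKind("resistome_richness", "low", "identity"),
    VariableKind("betalactamasome_abundance", "low", "log10"),
    VariableKind("betalactamase_activity", "low", "log10"),
    VariableKind("phage_richness", "low", "identity"),
    VariableKind("fungal_load", "low", "log10"),
    VariableKind("fungal_richness", "low", "identity"),
    VariableKind("calbicans_dna", "low", "log10"),
    VariableKind("metabolome_richness", "low", "identity"),
    VariableKind("cholesterol_conversion_rate", "low", "log10"),
    VariableKind("bile_acid_transformation", "low", "log10"),
    VariableKind("bacterial_structure", "high"),
    VariableKind("phage_structure", "high"),
    VariableKind("fungal_structure", "high"),
    VariableKind("metabolome_structure", "high"),
)

#: Omic layers carrying high-dimensional composition profiles, mapped to
#: the structure variable they feed.
LAYER_STRUCTURE: dict[str, str] = {
    "bacteria_MGS": "bacterial_structure",
    "phage_contigs": "phage_structure",
    "fungal_OTUs": "fungal_structure",
    "metabolites": "metabolome_structure",
}


def panel_by_name(panel: tuple[VariableKind, ...] = DEFAULT_PANEL) -> dict[str, VariableKind]:
    out = {v.name: v for v in panel}
    if len(out) != len(panel):
        raise ValueError("panel names must be unique")
    return out
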
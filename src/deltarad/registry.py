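"""Feature registry: the named, ordered set of radiomic features the pipeline computes.

The default registry holds 43 features: 42 IBSI-style descriptors spanning the
first-order (``Global``), GLCM, GLRLM, GLSZM and NGTDM families, plus the ROI
volume as an explicit geometric descriptor.  Downstream stages (volume
adjustment, deltas, selection, modeling) are driven entirely by the registry,
so alternative feature sets can be swapped in without touching pipeline code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True)
class FeatureDef:
    """A single registry entry."""

    family: str  # Global | GLCM | GLRLM | GLSZM | NGTDM | Geometry
    short: str   # family-local identifier, e.g. "Skewness", "LRE"

    @property
    def name(self) -> str:
        return f"{self.family} {self.short}"


_GLOBAL = ["Mean", "Variance", "Skewness", "Kurtosis", "Median",
           "Minimum", "Maximum", "Energy", "Entropy"]
_GLCM = ["Energy", "Contrast", "Correlation", "Homogeneity", "Entropy",
         "Dissimilarity"]
_GLRLM = ["SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
          "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV"]
_GLSZM = ["SAE", "LAE", "GLN", "ZSN", "ZP", "LGZE", "HGZE", "GLV", "ZSV"]
_NGTDM = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered collection of feature definitions with unique full names."""

    entries: tuple[FeatureDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("feature names in a registry must be unique")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[FeatureDef]:
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        return self.names.index(name)


def default_registry() -> FeatureRegistry:
    """The raw (pre volume-adjustment) 43-feature registry."""
    entries = (
        [FeatureDef("Global", s) for s in _GLOBAL]
        + [FeatureDef("GLCM", s) for s in _GLCM]
        + [FeatureDef("GLRLM", s) for s in _GLRLM]
        + [FeatureDef("GLSZM", s) for s in _GLSZM]
        + [FeatureDef("NGTDM", s) for s in _NGTDM]
        + [FeatureDef("Geometry", "Volume")]
    )
    return FeatureRegistry(tuple(entries))


# Size-dependent features and their volume-adjusted replacements.
# mode "divide_by_voxels": variant = base / n_voxels (suffix -VN).
# mode "feature_volume_normalized": Coarseness x n_voxels, Busyness / n_voxels
# (suffix -VNF), matching their known approximately inverse / linear scaling
# with region size.
DEFAULT_ADJUSTMENT_RULES: list[dict] = [
    {"base": "GLRLM RLN", "variant": "GLRLM RLN-VN", "mode": "divide_by_voxels"},
    {"base": "GLRLM GLN", "variant": "GLRLM GLN-VN", "mode": "divide_by_voxels"},
    {"base": "GLSZM GLN", "variant": "GLSZM GLN-VN", "mode": "divide_by_voxels"},
    {"base": "GLSZM ZSN", "variant": "GLSZM ZSN-VN", "mode": "divide_by_voxels"},
    {"base": "NGTDM Strength", "variant": "NGTDM Strength-VN", "mode": "divide_by_voxels"},
    {"base": "NGTDM Coarseness", "variant": "NGTDM Coarseness-VNF", "mode": "feature_volume_normalized"},
    {"base": "NGTDM Busyness", "variant": "NGTDM Busyness-VNF", "mode": "feature_volume_normalized"},
]


def adjusted_registry(rules: list[dict] | None = None) -> FeatureRegistry:
    """Registry after volume adjustment: size-dependent features are replaced
    in place by their -VN / -VNF variants; the count is unchanged."""
    if rules is None:
        rules = DEFAULT_ADJUSTMENT_RULES
    base = default_registry()
    replacement = {r["base"]: r["variant"] for r in rules}
    out = []
    for e in base:
        if e.name in replacement:
            family, short = replacement[e.name].split(" ", 1)
            out.append(FeatureDef(family, short))
        else:
            out.append(e)
    return FeatureRegistry(tuple(out))
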
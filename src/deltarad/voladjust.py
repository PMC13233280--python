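"""Volume adjustment of size-dependent texture features.

Non-uniformity sums (GLRLM RLN/GLN, GLSZM GLN/ZSN, NGTDM Strength) grow
roughly linearly with the number of ROI voxels and are replaced by
voxel-count-normalized variants (suffix ``-VN``).  NGTDM Coarseness and
Busyness scale approximately inversely / linearly with region size and get the
feature-volume normalization (suffix ``-VNF``): Coarseness x n_voxels,
Busyness / n_voxels.  The ROI volume itself is kept as an independent feature
so anatomical size can still enter the models directly.  Replacement preserves
the feature count and the registry order.
"""

from __future__ import annotations

from dataclasses import dataclass

from .features import FeatureVector
from .preprocess import DegenerateROIError, ParameterError
from .registry import DEFAULT_ADJUSTMENT_RULES


@dataclass(frozen=True)
class VolumeAdjustmentRule:
    base_feature: str
    variant_name: str
    mode: str  # "divide_by_voxels" | "feature_volume_normalized"

    def apply(self, value: float, n_voxels: int) -> float:
        if self.mode == "divide_by_voxels":
            return value / n_voxels
        if self.mode == "feature_volume_normalized":
            # Coarseness varies ~1/volume, Busyness ~volume
            if self.variant_name.endswith("Coarseness-VNF"):
                return value * n_voxels
            return value / n_voxels
        raise ParameterError(f"mode: unknown volume-adjustment mode {self.mode!r}")


def default_rules() -> list[VolumeAdjustmentRule]:
    return [VolumeAdjustmentRule(r["base"], r["variant"], r["mode"])
            for r in DEFAULT_ADJUSTMENT_RULES]


def apply_volume_adjustment(fv: FeatureVector,
                            rules: list[VolumeAdjustmentRule] | None = None
                            ) -> FeatureVector:
    """Replace size-dependent features by their adjusted variants in place of
    the originals; the output vector has the same length as the input."""
    if rules is None:
        rules = default_rules()
    if fv.n_voxels is None or fv.n_voxels <= 0:
        raise DegenerateROIError("volume adjustment requires a positive ROI voxel count")
    by_base = {r.base_feature: r for r in rules}
    for r in rules:
        if r.base_feature not in fv.values:
            raise ParameterError(f"base_feature: {r.base_feature!r} not in feature vector")
    out: dict[str, float] = {}
    for name, value in fv.values.items():
        rule = by_base.get(name)
        if rule is None:
            out[name] = value
        else:
            out[rule.variant_name] = rule.apply(value, fv.n_voxels)
    return FeatureVector(values=out, patient_id=fv.patient_id,
                         fraction=fv.fraction, week=fv.week, n_voxels=fv.n_voxels)
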
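"""Assembly of the full 95-feature panel for one lesion.

The panel comprises 9 global features plus, for each of the ADC and VE
maps, 43 texture features computed on the map quantized at Ng gray
levels: 3 histogram, 9 GLCM, 13 GLRLM, 13 GLSZM and 5 NGTDM features.
Feature names are ``<map>_<family>_<feature>`` in a fixed documented
order; the global solidity/surface-area/volume features are map-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..discretization import quantize
from ..errors import RadiomicsError
from ..io_model import LesionMask, VolumetricMap
from .features import (glcm_features, glrlm_features, glszm_features,
                       global_features, histogram_features, ngtdm_features)
from .matrices import glcm_matrix, glrlm_matrix, glszm_matrix, ngtdm_table

__all__ = ["FeatureVector", "extract_all", "extract_cohort_features",
           "feature_names", "feature_dictionary", "N_FEATURES",
           "BASELINE_PREDICTORS"]

N_FEATURES = 95

#: the two predictors of the mean-only baseline classifier
BASELINE_PREDICTORS = ("adc_global_mean", "ve_global_mean")

_GLOBAL_NAMES = (
    "adc_global_mean", "adc_global_max", "adc_global_min",
    "ve_global_mean", "ve_global_max", "ve_global_min",
    "global_solidity", "global_surface_area", "global_volume",
)

_FAMILY_SIZES = {"histogram": 3, "glcm": 9, "glrlm": 13, "glszm": 13, "ngtdm": 5}

_PER_MAP_NAMES = (
    "histogram_variance", "histogram_skewness", "histogram_kurtosis",
    "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_variance",
    "glcm_sum_average", "glcm_dissimilarity", "glcm_autocorrelation",
    "glcm_entropy", "glcm_homogeneity",
    "glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_rln", "glrlm_rp",
    "glrlm_lgre", "glrlm_hgre", "glrlm_srlge", "glrlm_srhge",
    "glrlm_lrlge", "glrlm_lrhge", "glrlm_glv", "glrlm_rlv",
    "glszm_sze", "glszm_lze", "glszm_gln", "glszm_zsn", "glszm_zp",
    "glszm_lgze", "glszm_hgze", "glszm_szlge", "glszm_szhge",
    "glszm_lzlge", "glszm_lzhge", "glszm_glv", "glszm_zsv",
    "ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
    "ngtdm_complexity", "ngtdm_strength",
)


def feature_names() -> list[str]:
    """The 95 panel feature names in their fixed extraction order."""
    names = list(_GLOBAL_NAMES)
    for map_name in ("adc", "ve"):
        names.extend(f"{map_name}_{n}" for n in _PER_MAP_NAMES)
    assert len(names) == N_FEATURES
    return names


@dataclass(frozen=True)
class FeatureVector:
    """The named 95-feature panel for one lesion."""

    lesion_id: str
    values: dict[str, float]

    def __post_init__(self):
        expected = feature_names()
        got = list(self.values)
        if got != expected:
            raise RadiomicsError(
                f"feature vector for {self.lesion_id} has {len(got)} entries "
                f"or wrong order; expected the canonical 95-name panel")
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise RadiomicsError(
                f"non-finite features for {self.lesion_id}: {bad[:5]}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.lesion_id)


def _texture_block(map_name: str, vol: VolumetricMap, mask: LesionMask,
                   ng: int, lesion_id: str) -> dict[str, float]:
    q = quantize(vol, mask, ng)
    out: dict[str, float] = {}
    try:
        out.update(histogram_features(q))
        out.update(glcm_features(glcm_matrix(q)))
        out.update(glrlm_features(glrlm_matrix(q)))
        out.update(glszm_features(glszm_matrix(q)))
        out.update(ngtdm_features(ngtdm_table(q)))
    except RadiomicsError as exc:
        raise type(exc)(f"lesion {lesion_id}, {map_name} map: {exc}") from exc
    return {f"{map_name}_{k}": v for k, v in out.items()}


def extract_all(adc: VolumetricMap, ve: VolumetricMap, mask: LesionMask,
                ng: int = 64, lesion_id: str = "lesion") -> FeatureVector:
    """Extract the full panel for one lesion at a given gray-level count."""
    values: dict[str, float] = {}
    glob = global_features(adc, ve, mask)
    values.update({k: glob[k] for k in _GLOBAL_NAMES})
    values.update(_texture_block("adc", adc, mask, ng, lesion_id))
    values.update(_texture_block("ve", ve, mask, ng, lesion_id))
    return FeatureVector(lesion_id=lesion_id, values=values)


def extract_cohort_features(lesions, ng: int = 64) -> pd.DataFrame:
    """Feature matrix for a list of lesions (index: lesion_id, 95 columns).

    Accepts :class:`~hcc_radiomics.synthetic.SyntheticLesion` objects or
    any object exposing ``lesion_id``, ``adc``, ``ve`` and ``mask``.
    """
    rows = [extract_all(l.adc, l.ve, l.mask, ng=ng, lesion_id=l.lesion_id).as_series()
            for l in lesions]
    table = pd.DataFrame(rows)
    table.index.name = "lesion_id"
    return table


_FAMILY_DESCRIPTIONS = {
    "global": "first-order statistic of raw masked intensities, or mask shape",
    "histogram": "moment of the quantized-label histogram (spatially invariant)",
    "glcm": "gray-level co-occurrence (4 in-plane directions, distance 1, pooled)",
    "glrlm": "gray-level run length (4 in-plane directions, pooled)",
    "glszm": "gray-level size zone (26-connected 3D zones)",
    "ngtdm": "neighborhood gray-tone difference (3x3x3 neighborhood)",
}


def feature_dictionary() -> pd.DataFrame:
    """Reference table of the panel: name, map, family, description."""
    rows = []
    for name in feature_names():
        parts = name.split("_")
        if name in _GLOBAL_NAMES:
            map_name = parts[0] if parts[0] in ("adc", "ve") else "shape"
            family = "global"
        else:
            map_name, family = parts[0], parts[1]
        rows.append({"name": name, "map": map_name, "family": family,
                     "description": _FAMILY_DESCRIPTIONS[family]})
    return pd.DataFrame(rows)
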
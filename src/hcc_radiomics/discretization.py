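"""Gray-level discretization of within-mask intensities.

All matrix-based texture operators work on a quantized volume: masked
voxel intensities relabeled to integers 1..Ng by equal-width binning
between the masked minimum m and maximum M,

    label(v) = floor(Ng * (v - m) / (M - m)) + 1,   label(M) = Ng.

Equal-width min-max binning (rather than equal-frequency or fixed bin
width) is used because it makes the labels invariant to positive affine
rescaling of the input map and is the convention of classical texture
toolboxes.  A degenerate constant region (M = m) maps every masked voxel
to label 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .io_model import LesionMask, MapKind, VolumetricMap

__all__ = ["QuantizedVolume", "quantize", "ng_sweep", "NG_CHOICES"]

#: supported gray-level counts for the discretization sweep
NG_CHOICES = (16, 32, 64, 128, 256)


@dataclass(frozen=True)
class QuantizedVolume:
    """Integer relabeling of one map within a mask: 0 outside, 1..ng inside."""

    grid: np.ndarray                # int32, 0 = outside mask
    ng: int
    bin_edges: np.ndarray           # ng+1 intensity thresholds
    source_kind: MapKind
    spacing: tuple[float, float, float]

    @property
    def mask(self) -> np.ndarray:
        return self.grid > 0

    @property
    def n_voxels(self) -> int:
        return int((self.grid > 0).sum())

    def masked_labels(self) -> np.ndarray:
        """Flat array of labels of the masked voxels."""
        return self.grid[self.grid > 0]


def quantize(vol: VolumetricMap, mask: LesionMask, ng: int) -> QuantizedVolume:
    """Relabel masked intensities to gray levels 1..ng by min-max binning."""
    if ng < 2:
        raise ConfigurationError(f"ng must be >= 2, got {ng}")
    if vol.shape != mask.shape:
        raise ConfigurationError(
            f"map shape {vol.shape} != mask shape {mask.shape}")
    fg = mask.grid
    values = vol.grid[fg]
    lo = float(values.min())
    hi = float(values.max())

    labels = np.zeros(vol.shape, dtype=np.int32)
    if hi == lo:
        labels[fg] = 1
        edges = np.full(ng + 1, lo, dtype=float)
    else:
        scaled = np.floor(ng * (vol.grid[fg] - lo) / (hi - lo)).astype(np.int64) + 1
        labels[fg] = np.clip(scaled, 1, ng)
        edges = np.linspace(lo, hi, ng + 1)
    return QuantizedVolume(grid=labels, ng=ng, bin_edges=edges,
                           source_kind=vol.kind, spacing=vol.spacing)


def ng_sweep(vol: VolumetricMap, mask: LesionMask,
             ng_list: list[int] | None = None) -> dict[int, QuantizedVolume]:
    """Quantize one map at each requested gray-level count.

    Defaults to the full sweep over ``NG_CHOICES`` (16, 32, 64, 128, 256) so
    downstream feature extraction and classification can be repeated per Ng.
    """
    if ng_list is None:
        ng_list = list(NG_CHOICES)
    bad = [ng for ng in ng_list if ng not in NG_CHOICES]
    if bad:
        raise ConfigurationError(
            f"ng values {bad} not in the supported sweep {sorted(NG_CHOICES)}")
    return {ng: quantize(vol, mask, ng) for ng in ng_list}
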
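"""Shared fixtures: tiny synthetic cohorts and quantized-volume helpers."""

import numpy as np
import pandas as pd
import pytest

from hcc_radiomics.discretization import QuantizedVolume
from hcc_radiomics.io_model import LesionMask, MapKind, VolumetricMap
from hcc_radiomics.synthetic import generate_cohort, preset, write_cohort

UNIT_SPACING = (1.0, 1.0, 1.0)


def make_qvol(labels, ng=None, spacing=UNIT_SPACING, kind=MapKind.ADC):
    """Wrap a raw integer label grid (0 = outside mask) as a QuantizedVolume."""
    labels = np.atleast_3d(np.asarray(labels, dtype=np.int32))
    if ng is None:
        ng = int(labels.max())
    edges = np.linspace(0.0, 1.0, ng + 1)
    return QuantizedVolume(grid=labels, ng=ng, bin_edges=edges,
                           source_kind=kind, spacing=spacing)


def make_map(grid, spacing=UNIT_SPACING, kind=MapKind.ADC):
    return VolumetricMap(np.atleast_3d(np.asarray(grid, dtype=float)),
                         spacing, kind)


def make_mask(grid, spacing=UNIT_SPACING):
    return LesionMask(np.atleast_3d(np.asarray(grid)).astype(np.uint8), spacing)


def random_labeled_grid(rng, shape=(5, 5, 3), ng=4, p_mask=0.8):
    """Random quantized grid with a random (nonempty) mask."""
    while True:
        mask = rng.random(shape) < p_mask
        if mask.sum() >= 4:
            break
    labels = np.zeros(shape, dtype=np.int32)
    labels[mask] = rng.integers(1, ng + 1, size=int(mask.sum()))
    return labels


@pytest.fixture(scope="session")
def tiny_cohort():
    """Nine mean+texture lesions (3 per grade) for structural tests."""
    spec = preset("mean+texture", n_per_class=3, seed=5)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory, tiny_cohort):
    """The tiny cohort written out as NIfTI volumes plus cohort.csv."""
    out = tmp_path_factory.mktemp("cohort")
    csv_path = write_cohort(tiny_cohort, out)
    return csv_path


@pytest.fixture(scope="session")
def tiny_grades(tiny_cohort):
    return pd.Series({l.lesion_id: l.grade for l in tiny_cohort})
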
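"""Shared fixtures: small synthetic configurations used across the suite.

All test data is generated programmatically; nothing is read from disk
except files the tests themselves write.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from imcspatial import synthetic
from imcspatial.io_features import MarkerPanel


def make_config(
    n_phenotypes: int = 4,
    n_markers: int = 8,
    cells_per_roi: float = 400.0,
    rois: dict[str, int] | None = None,
    attraction: synthetic.AttractionSpec | tuple | None = None,
    roi_size: float = 700.0,
    signature_high: float = 12.0,
    seed: int = 0,
    proportions: list[float] | None = None,
) -> synthetic.SimConfig:
    """A compact cohort: phenotype i is high on markers (2i, 2i+1)."""
    if rois is None:
        rois = {"control": 2, "treated": 3}
    if proportions is None:
        proportions = [1.0 / n_phenotypes] * n_phenotypes
    phenos = []
    for i in range(n_phenotypes):
        mean = np.full(n_markers, 1.0)
        on = [(2 * i) % n_markers, (2 * i + 1) % n_markers]
        mean[on] = signature_high
        sd = np.where(mean > 1.0, 2.0, 0.8)
        phenos.append(
            synthetic.PhenotypeSpec(
                name=f"P{i}",
                proportion=proportions[i],
                signature_mean=tuple(map(float, mean)),
                signature_sd=tuple(map(float, sd)),
                mean_cell_area=90.0,
            )
        )
    attrs = ()
    if attraction is not None:
        if isinstance(attraction, tuple):
            attraction = synthetic.AttractionSpec(*attraction)
        attrs = (attraction,)
    return synthetic.SimConfig(
        roi_width=roi_size,
        roi_height=roi_size,
        n_rois_per_condition=rois,
        cells_per_roi=cells_per_roi,
        phenotypes=tuple(phenos),
        attraction_pairs=attrs,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """~1,300 cells, 4 phenotypes, one planted attraction in every ROI."""
    cfg = make_config(
        n_phenotypes=4,
        cells_per_roi=350.0,
        rois={"control": 2, "treated": 3},
        attraction=("P0", "P1", 20.0, 0.8),
        seed=11,
    )
    table, gt = synthetic.generate_cohort(cfg)
    return cfg, table, gt


@pytest.fixture(scope="session")
def small_panel():
    return synthetic.default_panel(8)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
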
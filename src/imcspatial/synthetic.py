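"""Synthetic multi-ROI tissue cohorts with planted spatial structure.

Generates cell tables that emulate the statistical shape of an imaging-mass-
cytometry cohort — a handful of ~700 × 700 µm regions of interest per
condition, a few thousand cells each, a ~32-marker panel — with *known*
phenotype identities, marker signatures, and planted phenotype–phenotype
spatial attraction, so every downstream stage (featurization, clustering,
neighborhood statistics) can be scored against ground truth.

Model
-----
Cells of each phenotype form an independent homogeneous Poisson process over
the ROI rectangle (complete spatial randomness, CSR). A planted attraction
turns a declared fraction of one phenotype's cells into *offspring* placed
uniformly within a disk of radius ``r`` around a uniformly chosen *parent*
cell of another phenotype (a Matérn-style cluster process). Marker
intensities are drawn per cell from a zero-truncated normal with the cell's
phenotype signature. Condition effects are abundance shifts and/or the
presence of an attraction — phenotype signatures themselves do not change
between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io_features import MarkerPanel

__all__ = [
    "PhenotypeSpec",
    "AttractionSpec",
    "SimConfig",
    "SyntheticGroundTruth",
    "generate_roi",
    "generate_cohort",
    "render_mask",
    "default_config",
    "default_panel",
    "write_sim_config",
    "read_sim_config",
    "read_sim_config_dict",
]


@dataclass(frozen=True)
class PhenotypeSpec:
    """One phenotype: its expected cohort fraction, marker signature
    (mean and sd per marker, arbitrary intensity units), and mean cell area."""

    name: str
    proportion: float
    signature_mean: tuple[float, ...]
    signature_sd: tuple[float, ...]
    mean_cell_area: float = 100.0  # µm², ~11 µm diameter

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError(f"proportion of {self.name!r} outside [0, 1]")
        if len(self.signature_mean) != len(self.signature_sd):
            raise ValueError(f"signature mean/sd length mismatch for {self.name!r}")
        if any(s < 0 for s in self.signature_sd):
            raise ValueError(f"negative signature sd for {self.name!r}")
        if self.mean_cell_area <= 0:
            raise ValueError(f"non-positive mean cell area for {self.name!r}")


@dataclass(frozen=True)
class AttractionSpec:
    """Planted attraction: a fraction of ``offspring_phenotype`` cells are
    placed uniformly within ``radius`` µm of a random ``parent_phenotype``
    cell. ``conditions`` restricts the attraction to those condition labels
    (None = active in every condition)."""

    parent_phenotype: str
    offspring_phenotype: str
    radius: float
    offspring_fraction: float
    conditions: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("attraction radius must be positive")
        if not (0.0 <= self.offspring_fraction <= 1.0):
            raise ValueError("offspring_fraction outside [0, 1]")

    def active_in(self, condition: str) -> bool:
        return self.conditions is None or condition in self.conditions


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic cohort; the seed fully determines the
    output."""

    roi_width: float = 700.0
    roi_height: float = 700.0
    n_rois_per_condition: dict[str, int] = field(
        default_factory=lambda: {"control": 5, "treated": 12}
    )
    cells_per_roi: float = 4570.0
    phenotypes: tuple[PhenotypeSpec, ...] = ()
    attraction_pairs: tuple[AttractionSpec, ...] = ()
    #: condition -> phenotype -> multiplicative factor on expected count
    condition_abundance_shift: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.roi_width <= 0 or self.roi_height <= 0:
            raise ValueError("ROI dimensions must be positive")
        if self.cells_per_roi <= 0:
            raise ValueError("cells_per_roi must be positive")
        if not self.phenotypes:
            raise ValueError("at least one phenotype required")
        total = sum(p.proportion for p in self.phenotypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phenotype proportions sum to {total}, not 1")
        names = [p.name for p in self.phenotypes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate phenotype names")
        sizes = {len(p.signature_mean) for p in self.phenotypes}
        if len(sizes) != 1:
            raise ValueError("all phenotype signatures must share one panel size")
        for a in self.attraction_pairs:
            for lbl in (a.parent_phenotype, a.offspring_phenotype):
                if lbl not in names:
                    raise ValueError(f"attraction references unknown phenotype {lbl!r}")
        for cond, shifts in self.condition_abundance_shift.items():
            if cond not in self.n_rois_per_condition:
                raise ValueError(f"abundance shift for unknown condition {cond!r}")
            for lbl in shifts:
                if lbl not in names:
                    raise ValueError(f"abundance shift for unknown phenotype {lbl!r}")

    @property
    def n_markers(self) -> int:
        return len(self.phenotypes[0].signature_mean)

    @property
    def conditions(self) -> list[str]:
        return list(self.n_rois_per_condition)

    def expected_count(self, phenotype: PhenotypeSpec, condition: str) -> float:
        shift = self.condition_abundance_shift.get(condition, {}).get(phenotype.name, 1.0)
        return self.cells_per_roi * phenotype.proportion * shift


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Planted truth for one ROI (or a concatenated cohort): per-cell true
    phenotype and, for attracted offspring, the parent cell it was placed
    around (-1 for none)."""

    frame: pd.DataFrame  # columns: roi_id, cell_id, true_phenotype, parent_cell_id
    config: SimConfig


def _marker_columns(n_markers: int) -> list[str]:
    return [f"marker_{i + 1}" for i in range(n_markers)]


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Normal truncated at zero, elementwise; sd == 0 degenerates to
    max(mean, 0)."""
    mean = np.asarray(mean, float)
    sd = np.asarray(sd, float)
    out = np.where(sd > 0, 0.0, np.maximum(mean, 0.0))
    pos = sd > 0
    if pos.any():
        a = (0.0 - mean[pos]) / sd[pos]
        out = out.astype(float)
        out[pos] = stats.truncnorm.rvs(
            a, np.inf, loc=mean[pos], scale=sd[pos], random_state=rng
        )
    return out


def generate_roi(
    config: SimConfig,
    condition: str,
    roi_index: int,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Generate one ROI as a cell table plus its ground truth.

    Cell counts are Poisson around the condition-adjusted expectation, one
    independent draw per phenotype. Unattracted cells are CSR over the ROI
    rectangle; attracted offspring are uniform in a disk around a uniformly
    chosen parent, clipped to the ROI by rejection sampling (≤100 attempts,
    then placed at the parent). All randomness flows through one generator
    seeded by (seed, condition index, roi_index).
    """
    if condition not in config.n_rois_per_condition:
        raise ValueError(f"unknown condition label {condition!r}")
    if seed is None:
        seed = config.seed
    cond_idx = config.conditions.index(condition)
    rng = np.random.default_rng([int(seed), cond_idx, int(roi_index)])

    active = [a for a in config.attraction_pairs if a.active_in(condition)]
    offspring_of = {a.offspring_phenotype: a for a in active}
    for a in active:
        if a.parent_phenotype in offspring_of:
            raise ValueError(
                f"parent phenotype {a.parent_phenotype!r} is itself an attracted "
                "offspring; chained attractions are not supported"
            )
        parent_spec = next(p for p in config.phenotypes if p.name == a.parent_phenotype)
        if config.expected_count(parent_spec, condition) <= 0:
            raise ValueError(
                f"attraction {a.offspring_phenotype!r}->{a.parent_phenotype!r} has "
                f"zero expected parents in condition {condition!r}"
            )

    counts = {
        p.name: int(rng.poisson(config.expected_count(p, condition)))
        for p in config.phenotypes
    }

    w, h = config.roi_width, config.roi_height
    roi_id = f"{condition}_{roi_index:02d}"
    rows_xy: list[np.ndarray] = []
    rows_label: list[str] = []
    rows_parent: list[np.ndarray] = []

    # parents (and every non-offspring phenotype) first: CSR placement
    placed: dict[str, np.ndarray] = {}
    for p in config.phenotypes:
        if p.name in offspring_of:
            continue
        n = counts[p.name]
        xy = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
        placed[p.name] = xy
        rows_xy.append(xy)
        rows_label += [p.name] * n
        rows_parent.append(np.full(n, -1, dtype=int))

    # running global index of already-placed cells, to record parent linkage
    offsets = {}
    off = 0
    for p in config.phenotypes:
        if p.name in offspring_of:
            continue
        offsets[p.name] = off
        off += counts[p.name]

    for p in config.phenotypes:
        if p.name not in offspring_of:
            continue
        a = offspring_of[p.name]
        n = counts[p.name]
        n_attr = int(round(a.offspring_fraction * n))
        parents = placed[a.parent_phenotype]
        if n_attr > 0 and len(parents) == 0:
            raise ValueError(
                f"no parent cells of {a.parent_phenotype!r} realized in "
                f"{roi_id}; config unusable"
            )
        xy = np.empty((n, 2))
        parent_idx = np.full(n, -1, dtype=int)
        if n_attr > 0:
            choice = rng.integers(0, len(parents), n_attr)
            parent_idx[:n_attr] = choice + offsets[a.parent_phenotype]
            for i, ci in enumerate(choice):
                px, py = parents[ci]
                for _ in range(100):
                    ang = rng.uniform(0, 2 * math.pi)
                    rad = a.radius * math.sqrt(rng.uniform())
                    cand = (px + rad * math.cos(ang), py + rad * math.sin(ang))
                    if 0 <= cand[0] <= w and 0 <= cand[1] <= h:
                        xy[i] = cand
                        break
                else:
                    xy[i] = (px, py)
        n_csr = n - n_attr
        xy[n_attr:] = np.column_stack(
            [rng.uniform(0, w, n_csr), rng.uniform(0, h, n_csr)]
        )
        rows_xy.append(xy)
        rows_label += [p.name] * n
        rows_parent.append(parent_idx)

    xy = np.vstack(rows_xy) if rows_xy else np.empty((0, 2))
    labels = np.array(rows_label, dtype=object)
    parent_idx = np.concatenate(rows_parent) if rows_parent else np.empty(0, int)
    n_total = len(labels)

    # intensities and areas, phenotype by phenotype (order already fixed)
    markers = _marker_columns(config.n_markers)
    intens = np.empty((n_total, config.n_markers))
    areas = np.empty(n_total)
    for p in config.phenotypes:
        sel = labels == p.name
        k = int(sel.sum())
        if k == 0:
            continue
        mean = np.tile(np.asarray(p.signature_mean, float), k)
        sd = np.tile(np.asarray(p.signature_sd, float), k)
        intens[sel] = _truncated_normal(rng, mean, sd).reshape(k, config.n_markers)
        # gamma with shape 16 -> CV 25%, strictly positive areas
        areas[sel] = rng.gamma(16.0, p.mean_cell_area / 16.0, k)

    cell_ids = np.arange(1, n_total + 1)
    table = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "roi_id": roi_id,
            "condition": condition,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "area_um2": areas,
        }
    )
    for j, m in enumerate(markers):
        table[m] = intens[:, j]
    table["true_phenotype"] = labels

    gt_parent = np.where(parent_idx >= 0, cell_ids[np.maximum(parent_idx, 0)], -1)
    gt = SyntheticGroundTruth(
        frame=pd.DataFrame(
            {
                "roi_id": roi_id,
                "cell_id": cell_ids,
                "true_phenotype": labels,
                "parent_cell_id": gt_parent,
            }
        ),
        config=config,
    )
    return table, gt


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Generate every ROI of every condition and concatenate them."""
    tables, frames = [], []
    for condition, n_rois in config.n_rois_per_condition.items():
        for roi_index in range(1, n_rois + 1):
            t, gt = generate_roi(config, condition, roi_index)
            tables.append(t)
            frames.append(gt.frame)
    table = pd.concat(tables, ignore_index=True)
    gt = SyntheticGroundTruth(frame=pd.concat(frames, ignore_index=True), config=config)
    return table, gt


# ---------------------------------------------------------------------------
# Mask rendering (fixture inputs for featurization)
# ---------------------------------------------------------------------------

def _disk_pixels(
    row_c: float, col_c: float, n_px: int, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """The ``n_px`` in-bounds pixels nearest to (row_c, col_c): a digital disk
    whose pixel count equals the cell's area exactly (ties broken by pixel
    index, so the footprint is deterministic)."""
    r_max = int(math.ceil(math.sqrt(n_px / math.pi))) + 2
    r0 = int(round(row_c))
    c0 = int(round(col_c))
    rr, cc = np.meshgrid(
        np.arange(max(0, r0 - r_max), min(shape[0], r0 + r_max + 1)),
        np.arange(max(0, c0 - r_max), min(shape[1], c0 + r_max + 1)),
        indexing="ij",
    )
    rr, cc = rr.ravel(), cc.ravel()
    d2 = (rr - row_c) ** 2 + (cc - col_c) ** 2
    order = np.lexsort((cc, rr, d2))[: min(n_px, len(rr))]
    return rr[order], cc[order]


def render_mask(
    table: pd.DataFrame,
    ground_truth: SyntheticGroundTruth | None = None,
    pixel_size: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    marker_columns: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one ROI's cell table as a label mask plus channel stack.

    Each cell is drawn as a disk of its area centered at its centroid with its
    ``cell_id`` as label; later rows overwrite earlier ones where disks
    overlap. The channel stack holds, at every pixel, the owning cell's marker
    vector plus optional zero-truncated Gaussian noise; background is 0.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if table["roi_id"].nunique() > 1:
        raise ValueError("render_mask expects a single ROI")
    if marker_columns is None:
        marker_columns = [c for c in table.columns if c.startswith("marker_")]
    rng = np.random.default_rng(seed)

    width = float(table["x_um"].max()) if len(table) else 1.0
    height = float(table["y_um"].max()) if len(table) else 1.0
    if ground_truth is not None:
        width = max(width, ground_truth.config.roi_width)
        height = max(height, ground_truth.config.roi_height)
    shape = (int(np.ceil(height / pixel_size)) + 1, int(np.ceil(width / pixel_size)) + 1)

    mask = np.zeros(shape, dtype=np.uint16)
    for row in table.itertuples(index=False):
        rr, cc = _disk_pixels(
            row.y_um / pixel_size,
            row.x_um / pixel_size,
            max(1, int(round(row.area_um2 / pixel_size**2))),
            shape,
        )
        mask[rr, cc] = row.cell_id

    intens = table.set_index("cell_id")[list(marker_columns)]
    n_ch = len(marker_columns)
    stack = np.zeros((n_ch,) + shape, dtype=np.float32)
    fg = mask > 0
    if fg.any():
        lut = np.zeros((int(table["cell_id"].max()) + 1, n_ch), dtype=np.float32)
        lut[intens.index.to_numpy()] = intens.to_numpy(np.float32)
        stack[:, fg] = lut[mask[fg]].T
        if noise_sd > 0:
            noise = rng.normal(0.0, noise_sd, size=(int(fg.sum()), n_ch)).T
            stack[:, fg] = np.maximum(stack[:, fg] + noise, 0.0)
    return mask, stack


# ---------------------------------------------------------------------------
# Default configuration: the study-shaped cohort
# ---------------------------------------------------------------------------

_DEFAULT_N_MARKERS = 32

#: (name, proportion, distinctive marker indices, mean cell area)
_DEFAULT_PHENOTYPES = [
    ("hepatocyte", 0.46, (0, 1, 2), 180.0),
    ("cC3_hepatocyte", 0.03, (3, 4), 160.0),
    ("LSEC", 0.12, (5, 6, 7), 90.0),
    ("Kupffer", 0.07, (8, 9, 10), 110.0),
    ("macrophage", 0.06, (11, 12), 100.0),
    ("CD8_T", 0.09, (13, 14, 15), 70.0),
    ("CD4_T", 0.06, (16, 17), 70.0),
    ("Treg", 0.03, (18, 19), 70.0),
    ("B_cell", 0.04, (20, 21), 70.0),
    ("neutrophil", 0.04, (22, 23, 24), 80.0),
]


def _signature(markers_on: Sequence[int], n_markers: int, high: float = 12.0,
               base: float = 1.0) -> tuple[tuple[float, ...], tuple[float, ...]]:
    mean = np.full(n_markers, base)
    mean[list(markers_on)] = high
    sd = np.where(mean > base, 2.0, 0.8)
    return tuple(map(float, mean)), tuple(map(float, sd))


def default_panel(n_markers: int = _DEFAULT_N_MARKERS) -> MarkerPanel:
    names = tuple(_marker_columns(n_markers))
    return MarkerPanel(names=names)


def default_config(seed: int = 0) -> SimConfig:
    """A cohort emulating the study's shape: two conditions (5 control + 12
    treated ~700 × 700 µm ROIs), ~4,570 cells per ROI for a total on the
    order of 78,000 cells, 32 markers, 10 phenotypes. In the treated
    condition the apoptotic-hepatocyte cluster expands and attracts myeloid
    cells (macrophages and Kupffer cells) within a 20 µm radius."""
    n_m = _DEFAULT_N_MARKERS
    phenos = tuple(
        PhenotypeSpec(
            name=name,
            proportion=prop,
            signature_mean=_signature(on, n_m)[0],
            signature_sd=_signature(on, n_m)[1],
            mean_cell_area=area,
        )
        for name, prop, on, area in _DEFAULT_PHENOTYPES
    )
    return SimConfig(
        roi_width=700.0,
        roi_height=700.0,
        n_rois_per_condition={"control": 5, "treated": 12},
        cells_per_roi=4570.0,
        phenotypes=phenos,
        attraction_pairs=(
            AttractionSpec("cC3_hepatocyte", "macrophage", radius=20.0,
                           offspring_fraction=0.6, conditions=("treated",)),
            AttractionSpec("cC3_hepatocyte", "Kupffer", radius=20.0,
                           offspring_fraction=0.5, conditions=("treated",)),
        ),
        # immune infiltration with hepatocyte loss; shifts chosen so the
        # treated per-ROI expectation stays ~cells_per_roi and the cohort
        # totals ~77,700 cells
        condition_abundance_shift={
            "treated": {
                "cC3_hepatocyte": 3.0,
                "macrophage": 2.0,
                "CD8_T": 1.5,
                "neutrophil": 1.5,
                "hepatocyte": 0.6,
            }
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Config serialization
# ---------------------------------------------------------------------------

def write_sim_config(config: SimConfig, path: str | Path) -> None:
    doc = {
        "roi_width": config.roi_width,
        "roi_height": config.roi_height,
        "n_rois_per_condition": dict(config.n_rois_per_condition),
        "cells_per_roi": config.cells_per_roi,
        "seed": config.seed,
        "phenotypes": [
            {
                "name": p.name,
                "proportion": p.proportion,
                "signature_mean": [float(v) for v in p.signature_mean],
                "signature_sd": [float(v) for v in p.signature_sd],
                "mean_cell_area": float(p.mean_cell_area),
            }
            for p in config.phenotypes
        ],
        "attraction_pairs": [
            {
                "parent_phenotype": a.parent_phenotype,
                "offspring_phenotype": a.offspring_phenotype,
                "radius": a.radius,
                "offspring_fraction": a.offspring_fraction,
                "conditions": list(a.conditions) if a.conditions else None,
            }
            for a in config.attraction_pairs
        ],
        "condition_abundance_shift": {
            c: dict(s) for c, s in config.condition_abundance_shift.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_sim_config(path: str | Path) -> SimConfig:
    return read_sim_config_dict(yaml.safe_load(Path(path).read_text()))


def read_sim_config_dict(doc: dict) -> SimConfig:
    phenos = tuple(
        PhenotypeSpec(
            name=p["name"],
            proportion=p["proportion"],
            signature_mean=tuple(p["signature_mean"]),
            signature_sd=tuple(p["signature_sd"]),
            mean_cell_area=p.get("mean_cell_area", 100.0),
        )
        for p in doc["phenotypes"]
    )
    attrs = tuple(
        AttractionSpec(
            parent_phenotype=a["parent_phenotype"],
            offspring_phenotype=a["offspring_phenotype"],
            radius=a["radius"],
            offspring_fraction=a["offspring_fraction"],
            conditions=tuple(a["conditions"]) if a.get("conditions") else None,
        )
        for a in doc.get("attraction_pairs", [])
    )
    return SimConfig(
        roi_width=doc["roi_width"],
        roi_height=doc["roi_height"],
        n_rois_per_condition=dict(doc["n_rois_per_condition"]),
        cells_per_roi=doc["cells_per_roi"],
        phenotypes=phenos,
        attraction_pairs=attrs,
        condition_abundance_shift={
            c: dict(s) for c, s in doc.get("condition_abundance_shift", {}).items()
        },
        seed=doc.get("seed", 0),
    )
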
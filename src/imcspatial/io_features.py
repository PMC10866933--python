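"""Cell-table I/O and segmentation-mask featurization.

The pipeline's universal currency is the *cell table*: one row per segmented
cell carrying its ROI membership, centroid coordinates in micrometers, area,
and mean per-marker intensities. This module validates and round-trips that
table as CSV, reads/writes label masks and channel stacks as TIFF, and
converts a (label mask, channel stack) pair into a cell table.

Coordinate convention: pixel (0, 0) is the *center* of the top-left pixel;
``x`` increases along columns and ``y`` along rows. All physical distances are
in µm (IMC ablates in 1 µm steps, so the default pixel size is 1 µm/px).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.measure import regionprops_table

__all__ = [
    "MarkerPanel",
    "COORD_COLUMNS",
    "META_COLUMNS",
    "read_panel",
    "write_panel",
    "validate_cell_table",
    "read_cell_table",
    "write_cell_table",
    "featurize_mask",
    "read_mask",
    "write_mask",
    "read_stack",
    "write_stack",
]

#: required non-marker columns of a cell table, in canonical order
META_COLUMNS = ["cell_id", "roi_id", "condition", "x_um", "y_um", "area_um2"]
COORD_COLUMNS = ["x_um", "y_um"]

MARKER_ROLES = ("phenotyping", "nuclear", "functional")


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered antibody panel with a role per marker.

    Nuclear/segmentation-only channels are carried through featurization but
    excluded from phenotyping (clustering uses the ``phenotyping`` subset
    only, mirroring the usual "excluding nuclear markers" convention).
    """

    names: tuple[str, ...]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("marker names must be unique")
        for name, role in self.roles.items():
            if name not in self.names:
                raise ValueError(f"role given for unknown marker {name!r}")
            if role not in MARKER_ROLES:
                raise ValueError(f"unknown marker role {role!r} for {name!r}")
        # canonicalize: every marker carries an explicit role
        full = {n: self.roles.get(n, "phenotyping") for n in self.names}
        object.__setattr__(self, "roles", full)
        if not self.phenotyping_markers:
            raise ValueError("panel has no phenotyping markers")

    @property
    def phenotyping_markers(self) -> list[str]:
        """Markers used for clustering (role 'phenotyping', the default)."""
        return [n for n in self.names if self.roles.get(n, "phenotyping") == "phenotyping"]

    def __len__(self) -> int:
        return len(self.names)


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    doc = {"markers": [{"name": n, "role": panel.roles.get(n, "phenotyping")} for n in panel.names]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_panel(path: str | Path) -> MarkerPanel:
    doc = yaml.safe_load(Path(path).read_text())
    entries = doc["markers"]
    names = tuple(e["name"] for e in entries)
    roles = {e["name"]: e.get("role", "phenotyping") for e in entries}
    return MarkerPanel(names=names, roles=roles)


def validate_cell_table(table: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Validate a cell table against the panel; returns the table unchanged.

    Raises ``ValueError`` naming the first missing required column, any
    non-numeric intensity column, or a duplicated (roi_id, cell_id) pair.
    """
    for col in META_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"cell table is missing required column {col!r}")
    for m in panel.names:
        if m not in table.columns:
            raise ValueError(f"cell table is missing marker column {m!r}")
    for m in panel.names:
        if len(table) == 0:
            break  # an empty table carries no dtype information
        if not pd.api.types.is_numeric_dtype(table[m]):
            raise ValueError(f"marker column {m!r} is not numeric")
        if (table[m].to_numpy(float) < 0).any():
            raise ValueError(f"marker column {m!r} has negative intensities")
    if table.duplicated(subset=["roi_id", "cell_id"]).any():
        dup = table[table.duplicated(subset=["roi_id", "cell_id"])].iloc[0]
        raise ValueError(
            f"duplicate (roi_id, cell_id) pair: ({dup['roi_id']!r}, {dup['cell_id']!r})"
        )
    if len(table) and (table["area_um2"].to_numpy(float) <= 0).any():
        raise ValueError("non-positive cell area")
    return table


def read_cell_table(path: str | Path, panel: MarkerPanel) -> pd.DataFrame:
    """Read and validate a cell-table CSV. Row order is preserved; extra
    columns (e.g. ``true_phenotype`` or ``phenotype``) are retained."""
    table = pd.read_csv(path)
    return validate_cell_table(table, panel)


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TIFF helpers: 16-bit label masks, float32 multi-page channel stacks
# ---------------------------------------------------------------------------

def write_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2-D")
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    tifffile.imwrite(str(path), mask.astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int64)


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a (channels, H, W) stack as multi-page float32 TIFF, one page per
    marker in panel order."""
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 3:
        raise ValueError("channel stack must be (channels, H, W)")
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    stack = np.asarray(tifffile.imread(str(path)), dtype=np.float32)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


# ---------------------------------------------------------------------------
# Featurization
# ---------------------------------------------------------------------------

def featurize_mask(
    label_mask: np.ndarray,
    channel_stack: np.ndarray,
    pixel_size: float,
    panel: MarkerPanel,
    roi_id: str = "roi_1",
    condition: str = "unknown",
) -> pd.DataFrame:
    """Convert a segmentation label mask plus channel stack into a cell table.

    One row per distinct positive label. Centroid is the unweighted mean of
    member pixel centers times ``pixel_size``; area is the pixel count times
    ``pixel_size`` squared; per-marker intensity is the mean channel value
    over member pixels. Labels with zero pixels are absent. Cells touching
    the image border are retained.
    """
    label_mask = np.asarray(label_mask)
    channel_stack = np.asarray(channel_stack, dtype=float)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if channel_stack.ndim != 3:
        raise ValueError("channel stack must be (channels, H, W)")
    if channel_stack.shape[1:] != label_mask.shape:
        raise ValueError(
            f"mask shape {label_mask.shape} does not match stack frame "
            f"shape {channel_stack.shape[1:]}"
        )
    if channel_stack.shape[0] != len(panel):
        raise ValueError(
            f"stack has {channel_stack.shape[0]} channels but panel lists "
            f"{len(panel)} markers"
        )

    if label_mask.max() <= 0:
        empty = {c: pd.Series(dtype=float) for c in [*META_COLUMNS, *panel.names]}
        return pd.DataFrame(empty)

    # regionprops expects channel-last intensity images
    intensity = np.moveaxis(channel_stack, 0, -1)
    props = regionprops_table(
        label_mask.astype(np.int64),
        intensity_image=intensity,
        properties=("label", "centroid", "area", "intensity_mean"),
    )
    n = len(props["label"])
    out = pd.DataFrame(
        {
            "cell_id": props["label"].astype(int),
            "roi_id": roi_id,
            "condition": condition,
            # centroid-0 is the row (y) index, centroid-1 the column (x)
            "x_um": props["centroid-1"] * pixel_size,
            "y_um": props["centroid-0"] * pixel_size,
            "area_um2": props["area"] * pixel_size**2,
        }
    )
    for j, name in enumerate(panel.names):
        key = f"intensity_mean-{j}" if len(panel) > 1 else "intensity_mean"
        out[name] = props[key]
    return validate_cell_table(out, panel)
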
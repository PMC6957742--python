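"""Per-burrow morphometrics and size/orientation classes.

Each labelled component is reduced to a tube-like summary: principal axis
(leading eigenvector of the voxel-centre covariance), length (extent of the
voxel centres projected on that axis), cylinder-equivalent diameter
``2 * sqrt(V / (pi * L))`` and z-angle (0 deg = horizontal, 90 deg =
vertical, from ``arcsin(|axis_z|)`` so the sign of the axis never matters).

Size classes follow the tiny/large split at an equivalent diameter of
0.5 cm; orientation classes split sub-horizontal from sub-vertical at a
configurable cutoff (default 45 deg).  Single-voxel components have no
defined axis: they are flagged degenerate and excluded from orientation
profiles downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import LabelVolume

__all__ = [
    "BurrowComponent",
    "parameterise_component",
    "classify_size",
    "classify_orientation",
    "components_from_labels",
    "burrow_table",
    "TINY_THRESHOLD_MM",
    "VERTICAL_CUTOFF_DEG",
]

TINY_THRESHOLD_MM = 5.0  # "tiny" burrows: equivalent diameter under 0.5 cm
VERTICAL_CUTOFF_DEG = 45.0


@dataclass
class BurrowComponent:
    """Morphometric summary of one segmented burrow."""

    id: int
    voxel_count: int
    volume_mm3: float
    centroid_mm: tuple[float, float, float]
    principal_axis: tuple[float, float, float]
    length_mm: float
    equiv_diameter_mm: float
    z_angle_deg: float  # NaN when degenerate
    size_class: str = ""
    orientation_class: str = ""  # "" when degenerate
    degenerate: bool = False


def _principal_axis(coords_mm: np.ndarray) -> np.ndarray:
    cov = np.cov(coords_mm.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    # deterministic sign: nonnegative z, then y, then x
    for i in (2, 1, 0):
        if abs(axis[i]) > 1e-12:
            if axis[i] < 0:
                axis = -axis
            break
    return axis


def parameterise_component(
    comp_id: int,
    voxel_coords: np.ndarray,
    spacing_mm: tuple[float, float, float],
    *,
    tiny_threshold_mm: float = TINY_THRESHOLD_MM,
    vertical_cutoff_deg: float = VERTICAL_CUTOFF_DEG,
) -> BurrowComponent:
    """Compute all :class:`BurrowComponent` fields from voxel indices.

    ``voxel_coords`` is an (N, 3) integer array of (x, y, z) indices.
    Components need at least 2 voxels for a defined axis; a single-voxel
    component is returned flagged ``degenerate`` with length set to the
    coarsest voxel edge and an undefined (NaN) z-angle.
    """
    voxel_coords = np.atleast_2d(np.asarray(voxel_coords))
    if voxel_coords.shape[0] == 0:
        raise ValueError(f"component {comp_id} has no voxels")
    spacing = np.asarray(spacing_mm, dtype=float)
    voxel_volume = float(spacing.prod())
    n = voxel_coords.shape[0]
    coords_mm = (voxel_coords + 0.5) * spacing
    centroid = tuple(float(c) for c in coords_mm.mean(axis=0))
    volume = n * voxel_volume

    if n < 2:
        length = float(spacing.max())
        comp = BurrowComponent(
            id=comp_id,
            voxel_count=n,
            volume_mm3=volume,
            centroid_mm=centroid,
            principal_axis=(0.0, 0.0, 0.0),
            length_mm=length,
            equiv_diameter_mm=2.0 * math.sqrt(volume / (math.pi * length)),
            z_angle_deg=float("nan"),
            degenerate=True,
        )
        comp.size_class = classify_size(comp, tiny_threshold_mm)
        return comp

    axis = _principal_axis(coords_mm)
    proj = coords_mm @ axis
    length = float(proj.max() - proj.min())
    if length <= 0:  # isotropic degenerate cluster; fall back to a voxel edge
        length = float(spacing.max())
    z_angle = math.degrees(math.asin(min(1.0, abs(float(axis[2])))))
    comp = BurrowComponent(
        id=comp_id,
        voxel_count=n,
        volume_mm3=volume,
        centroid_mm=centroid,
        principal_axis=tuple(float(a) for a in axis),
        length_mm=length,
        equiv_diameter_mm=2.0 * math.sqrt(volume / (math.pi * length)),
        z_angle_deg=z_angle,
    )
    comp.size_class = classify_size(comp, tiny_threshold_mm)
    comp.orientation_class = classify_orientation(comp, vertical_cutoff_deg)
    return comp


def classify_size(component: BurrowComponent, tiny_threshold_mm: float = TINY_THRESHOLD_MM) -> str:
    """``tiny`` iff the equivalent diameter is strictly under the threshold."""
    return "tiny" if component.equiv_diameter_mm < tiny_threshold_mm else "large"


def classify_orientation(
    component: BurrowComponent, vertical_cutoff_deg: float = VERTICAL_CUTOFF_DEG
) -> str:
    """``sub_vertical`` iff z-angle >= cutoff; degenerate components have no class."""
    if component.degenerate or math.isnan(component.z_angle_deg):
        raise ValueError(
            f"component {component.id} is degenerate (single voxel): "
            "exclude it from orientation analysis"
        )
    return "sub_vertical" if component.z_angle_deg >= vertical_cutoff_deg else "sub_horizontal"


def components_from_labels(
    labels: LabelVolume,
    *,
    tiny_threshold_mm: float = TINY_THRESHOLD_MM,
    vertical_cutoff_deg: float = VERTICAL_CUTOFF_DEG,
) -> list[BurrowComponent]:
    """Parameterise every component of a label volume, in label order."""
    from .segmentation import _component_coords

    k = labels.n_components
    coords = _component_coords(labels.labels, k)
    return [
        parameterise_component(
            cid,
            coords[cid - 1],
            labels.spacing_mm,
            tiny_threshold_mm=tiny_threshold_mm,
            vertical_cutoff_deg=vertical_cutoff_deg,
        )
        for cid in range(1, k + 1)
    ]


_TABLE_COLUMNS = [
    "id",
    "voxel_count",
    "volume_mm3",
    "centroid_x_mm",
    "centroid_y_mm",
    "centroid_z_mm",
    "axis_x",
    "axis_y",
    "axis_z",
    "length_mm",
    "equiv_diameter_mm",
    "z_angle_deg",
    "size_class",
    "orientation_class",
]


def burrow_table(components: list[BurrowComponent]) -> pd.DataFrame:
    """Flatten components into the documented spreadsheet layout."""
    rows = [
        {
            "id": c.id,
            "voxel_count": c.voxel_count,
            "volume_mm3": c.volume_mm3,
            "centroid_x_mm": c.centroid_mm[0],
            "centroid_y_mm": c.centroid_mm[1],
            "centroid_z_mm": c.centroid_mm[2],
            "axis_x": c.principal_axis[0],
            "axis_y": c.principal_axis[1],
            "axis_z": c.principal_axis[2],
            "length_mm": c.length_mm,
            "equiv_diameter_mm": c.equiv_diameter_mm,
            "z_angle_deg": c.z_angle_deg,
            "size_class": c.size_class,
            "orientation_class": c.orientation_class,
        }
        for c in components
    ]
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
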
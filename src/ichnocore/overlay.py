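"""QC and publication-style figures.

Two products: (a) segmented burrows projected over a core-face image, each
trace in its own colour (or coloured by orientation/size class), and (b) a
depth-aligned orientation strip showing the vertical/horizontal volume-%
curves with the H / V / V-H interval bands.

The pixel compositing is pure numpy — identical inputs give identical pixel
output — with matplotlib used only to decorate saved figures (depth axis in
cm, legend).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Patch

from .core_prep import CoreGeometry
from .downcore import IntervalLabel, SliceProfile
from .shape_metrics import BurrowComponent
from .types import CoreVolume, LabelVolume

__all__ = [
    "OverlayStyle",
    "render_overlay",
    "save_overlay_figure",
    "orientation_strip",
    "project_labels",
]

# fixed categorical palette (tab20), cycled deterministically over sorted ids
_PALETTE = (plt.get_cmap("tab20")(np.linspace(0, 1, 20))[:, :3] * 255).astype(np.uint8)
_ORIENT_COLORS = {"sub_vertical": (214, 39, 40), "sub_horizontal": (31, 119, 180), "": (127, 127, 127)}
_SIZE_COLORS = {"tiny": (255, 127, 14), "large": (148, 103, 189)}
_INTERVAL_COLORS = {"V": "#d6272833", "H": "#1f77b433", "V/H": "#7f7f7f33"}


@dataclass(frozen=True)
class OverlayStyle:
    color_mode: str = "by_component"  # by_component | by_orientation | by_size
    alpha: float = 0.6
    projection: str = "slab_face"  # slab_face | max_intensity_lateral

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.color_mode not in ("by_component", "by_orientation", "by_size"):
            raise ValueError(f"unknown color_mode {self.color_mode!r}")
        if self.projection not in ("slab_face", "max_intensity_lateral"):
            raise ValueError(f"unknown projection {self.projection!r}")


def _projection_axis(geometry: CoreGeometry | None, style: OverlayStyle) -> tuple[int, bool]:
    """(axis index, reversed?) to project along, from the face normal."""
    if style.projection == "max_intensity_lateral" or geometry is None:
        return 0, False
    nx, ny = geometry.face_normal
    if abs(nx) >= abs(ny):
        return 0, nx > 0
    return 1, ny > 0


def project_labels(labels: np.ndarray, axis: int, reverse: bool = False) -> np.ndarray:
    """Project a label grid along ``axis``; the voxel nearest the viewer wins.

    Viewing direction is towards increasing index unless ``reverse``.
    Pixels with no labelled voxel along the ray are 0.
    """
    arr = np.flip(labels, axis=axis) if reverse else labels
    occupied = arr > 0
    first = np.argmax(occupied, axis=axis)
    hit = occupied.any(axis=axis)
    proj = np.take_along_axis(arr, np.expand_dims(first, axis), axis=axis).squeeze(axis)
    proj[~hit] = 0
    return proj


def _component_colors(
    ids: np.ndarray, components: list[BurrowComponent] | None, style: OverlayStyle
) -> dict[int, tuple[int, int, int]]:
    by_id = {c.id: c for c in (components or [])}
    colors: dict[int, tuple[int, int, int]] = {}
    for i, cid in enumerate(sorted(int(v) for v in ids)):
        if style.color_mode == "by_component" or cid not in by_id:
            colors[cid] = tuple(_PALETTE[i % len(_PALETTE)])
        elif style.color_mode == "by_orientation":
            colors[cid] = _ORIENT_COLORS[by_id[cid].orientation_class]
        else:
            colors[cid] = _SIZE_COLORS[by_id[cid].size_class]
    return colors


def render_overlay(
    base: CoreVolume | np.ndarray,
    labels: LabelVolume,
    geometry: CoreGeometry | None = None,
    style: OverlayStyle = OverlayStyle(),
    components: list[BurrowComponent] | None = None,
) -> tuple[np.ndarray, dict[int, tuple[int, int, int]]]:
    """Alpha-blend projected burrows over the core-face image.

    ``base`` is either the scan volume (its face projection is rendered as
    the background) or a ready 2D grayscale face image with shape matching
    the projected labels.  Returns the RGB uint8 image (rows = depth) and
    the legend mapping component id -> colour.  With an empty label volume
    the output equals the base image.
    """
    axis, reverse = _projection_axis(geometry, style)
    if isinstance(base, CoreVolume):
        if base.shape != labels.shape:
            raise ValueError("volume and labels shapes differ")
        if style.projection == "max_intensity_lateral":
            img = base.data.max(axis=axis)
        else:  # mean attenuation through the slab reads like a face photo
            img = base.data.mean(axis=axis)
    else:
        img = np.asarray(base, dtype=float)
    proj = project_labels(labels.labels, axis, reverse)
    if img.shape != proj.shape:
        raise ValueError(f"base image shape {img.shape} != projected labels {proj.shape}")

    lo, hi = np.percentile(img, [1, 99])
    gray = np.clip((img - lo) / (hi - lo + 1e-12), 0, 1)
    rgb = np.repeat((gray[..., None] * 255).astype(np.uint8), 3, axis=2)

    ids = np.unique(proj)
    ids = ids[ids > 0]
    colors = _component_colors(ids, components, style)
    out = rgb.astype(float)
    for cid in ids:
        sel = proj == cid
        col = np.array(colors[int(cid)], dtype=float)
        out[sel] = (1.0 - style.alpha) * out[sel] + style.alpha * col
    # rows = depth (z), columns = transverse axis
    return np.transpose(out.astype(np.uint8), (1, 0, 2)), colors


def save_overlay_figure(
    path: str | Path,
    image: np.ndarray,
    legend: dict[int, tuple[int, int, int]],
    spacing_mm: tuple[float, float, float],
    depth_origin_cm: float = 0.0,
    title: str = "Segmented burrows over core face",
) -> Path:
    """Save the overlay with a depth axis in cm and a colour legend."""
    path = Path(path)
    nz = image.shape[0]
    depth_base = depth_origin_cm + nz * spacing_mm[2] / 10.0
    fig, ax = plt.subplots(figsize=(4, 8), dpi=100)
    ax.imshow(
        image,
        extent=(0, image.shape[1] * spacing_mm[0], depth_base, depth_origin_cm),
        aspect="auto",
    )
    ax.set_ylabel("downcore depth (cm)")
    ax.set_xlabel("x (mm)")
    ax.set_title(title)
    if legend and len(legend) <= 20:
        patches = [
            Patch(color=np.array(c) / 255.0, label=f"burrow {cid}")
            for cid, c in sorted(legend.items())
        ]
        ax.legend(handles=patches, fontsize=6, loc="upper right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def orientation_strip(
    profiles: list[SliceProfile],
    intervals: list[IntervalLabel] | None = None,
    path: str | Path | None = None,
):
    """Depth-aligned vertical/horizontal volume-% curves with interval bands."""
    fig, ax = plt.subplots(figsize=(3.5, 8), dpi=100)
    if not profiles:
        ax.annotate("no data", (0.5, 0.5), xycoords="axes fraction", ha="center")
    else:
        depth = [p.depth_cm for p in profiles]
        ax.plot([p.pct_vertical for p in profiles], depth, color="#d62728", lw=0.8, label="vertical %")
        ax.plot([p.pct_horizontal for p in profiles], depth, color="#1f77b4", lw=0.8, label="horizontal %")
        for iv in intervals or []:
            ax.axhspan(iv.top_cm, iv.base_cm, color=_INTERVAL_COLORS[iv.klass])
            ax.annotate(
                iv.klass,
                (104, 0.5 * (iv.top_cm + iv.base_cm)),
                fontsize=7,
                ha="left",
                va="center",
                annotation_clip=False,
            )
        ax.invert_yaxis()
        ax.legend(fontsize=6, loc="lower right")
    ax.set_xlim(0, 100)
    ax.set_xlabel("volume-% of segmented traces")
    ax.set_ylabel("downcore depth (cm)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path))
        plt.close(fig)
        return Path(path)
    return fig
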
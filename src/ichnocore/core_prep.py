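"""Locate the half-core in a scan and delete liner and artefact rim.

The core liner has nearly the same X-ray attenuation as soft sediment, so it
cannot be thresholded away; instead the semicircular cross-section of the
archive half is fitted from the core/air boundary and everything outside the
fitted radius — liner included — plus a configurable artefact rim (default
2 mm, against drilling disturbance) is excluded.  The rim is trimmed
radially from the curved surface, where drilling disturbance concentrates;
``trim_face=True`` additionally trims the same distance perpendicular to the
flat slab face for cores where slabbing also disturbed the cut surface
(note the face plane passes through the core axis, so face trimming excludes
the axis itself).

Excluded voxels are recorded in an explicit boolean mask on the returned
:class:`CoreVolume`; the attenuation grid itself is left untouched so that
downstream intensity statistics are computed on clean data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import CoreVolume

__all__ = ["CoreGeometry", "fit_core_geometry", "remove_liner_and_rim"]


@dataclass(frozen=True)
class CoreGeometry:
    """Cross-sectional geometry of the half-core.

    ``axis_center_mm`` is the (x, y) position of the cylinder axis;
    ``face_normal`` is the in-plane unit vector pointing out of the flat
    slab face (away from the sediment).
    """

    axis_center_mm: tuple[float, float]
    radius_mm: float
    face_normal: tuple[float, float]

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


def _bimodal_threshold(values: np.ndarray) -> float:
    """Midpoint of the two modes of a bimodal histogram (air vs sediment).

    The two modes are located with a two-means split (Otsu-like); an
    essentially unimodal histogram — no air/core separation — is an error.
    """
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        raise ValueError("attenuation histogram is not bimodal (constant volume)")
    t = 0.5 * (lo + hi)
    for _ in range(100):
        below = values[values <= t]
        above = values[values > t]
        if below.size == 0 or above.size == 0:
            raise ValueError("attenuation histogram is not bimodal")
        t_new = 0.5 * (float(below.mean()) + float(above.mean()))
        if abs(t_new - t) < 1e-9 * (hi - lo):
            t = t_new
            break
        t = t_new
    below = values[values <= t]
    above = values[values > t]
    # modes must be well separated relative to within-class spread
    spread = max(float(below.std()), float(above.std()), 1e-12)
    if (above.mean() - below.mean()) < 2.0 * spread:
        raise ValueError("attenuation histogram is not bimodal (no core/air contrast)")
    return t


def _fit_circle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit through boundary points."""
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r = float(np.sqrt(sol[2] + cx**2 + cy**2))
    return float(cx), float(cy), r


def fit_core_geometry(volume: CoreVolume) -> CoreGeometry:
    """Estimate centre, radius and face side of the half-core cross-section.

    The core/air threshold is the midpoint of the bimodal attenuation
    histogram.  The circle is fitted to the boundary pixels of the
    through-depth core footprint; points on the flat slab face (which lie
    inside the circle) are trimmed away over two refit rounds so only the
    curved boundary constrains centre and radius.  Deterministic: the same
    volume always yields the same geometry.
    """
    from scipy import ndimage

    sx, sy, _ = volume.spacing_mm
    sample = volume.data[:, :, :: max(1, volume.shape[2] // 64)]
    t = _bimodal_threshold(sample.ravel())
    above = (volume.data > t).mean(axis=2) > 0.5  # robust 2D footprint
    if not above.any():
        raise ValueError("no core found above the air threshold")
    # the sediment body is the largest connected footprint component; a liner
    # shell of sediment-like attenuation separated by the shrinkage gap (or
    # any other debris) must not enter the circle fit
    lab, k = ndimage.label(above)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    footprint = lab == int(sizes.argmax())
    interior = (
        np.roll(footprint, 1, 0)
        & np.roll(footprint, -1, 0)
        & np.roll(footprint, 1, 1)
        & np.roll(footprint, -1, 1)
    )
    bx, by = np.nonzero(footprint & ~interior)
    pts = np.column_stack([(bx + 0.5) * sx, (by + 0.5) * sy])

    # The footprint of an archive half is a half-disc: a straight chord (the
    # slab face) plus a circular arc.  Fitting a circle through both biases
    # centre and radius, so locate the chord first via the footprint's
    # principal axes and fit the circle to the arc points only.
    fx, fy = np.nonzero(footprint)
    body = np.column_stack([(fx + 0.5) * sx, (fy + 0.5) * sy])
    centroid = body.mean(axis=0)
    cov = np.cov((body - centroid).T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, 0]  # short axis: chord normal direction
    coords_v = (body - centroid) @ v
    if abs(coords_v.max()) < abs(coords_v.min()):
        v = -v  # make v point from the face towards the arc
        coords_v = -coords_v
    face_coord = float(np.quantile((pts - centroid) @ v, 0.02))
    arc_sel = (pts - centroid) @ v > face_coord + 0.25 * (coords_v.max() - face_coord)
    if arc_sel.sum() < 10:
        arc_sel[:] = True
    cx, cy, r = _fit_circle(pts[arc_sel, 0], pts[arc_sel, 1])
    # one residual-trim pass against the arc fit
    dist = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    keep = np.abs(dist - r) < max(2.0 * max(sx, sy), 0.03 * r)
    if keep.sum() >= 10:
        cx, cy, r = _fit_circle(pts[keep, 0], pts[keep, 1])

    n = -v / np.linalg.norm(v)  # outward through the flat face
    return CoreGeometry(
        axis_center_mm=(float(cx), float(cy)),
        radius_mm=float(r),
        face_normal=(float(n[0]), float(n[1])),
    )


def remove_liner_and_rim(
    volume: CoreVolume,
    geometry: CoreGeometry,
    rim_mm: float = 2.0,
    *,
    trim_face: bool = False,
) -> CoreVolume:
    """Mask out liner, air and an artefact rim of ``rim_mm``.

    Retained voxels are those at radial distance <= radius - rim from the
    fitted axis, on the sediment side of the slab face and (when
    ``trim_face`` is set) at least ``rim_mm`` from the face plane.  The rim
    must leave something: ``rim_mm >= radius`` is an error.  Increasing
    ``rim_mm`` only ever shrinks the retained set.
    """
    if rim_mm < 0:
        raise ValueError("rim_mm must be nonnegative")
    if rim_mm >= geometry.radius_mm:
        raise ValueError(
            f"rim_mm={rim_mm} >= fitted radius {geometry.radius_mm:.2f} mm: nothing would remain"
        )
    nx, ny, _ = volume.shape
    sx, sy, _ = volume.spacing_mm
    cx, cy = geometry.axis_center_mm
    xs = (np.arange(nx) + 0.5) * sx - cx
    ys = (np.arange(ny) + 0.5) * sy - cy
    R2 = xs[:, None] ** 2 + ys[None, :] ** 2
    keep2d = R2 <= (geometry.radius_mm - rim_mm) ** 2
    # signed distance along the outward face normal; sediment side is negative
    n = np.array(geometry.face_normal)
    s = xs[:, None] * n[0] + ys[None, :] * n[1]
    face_cut = -rim_mm if trim_face else 0.0
    keep2d &= s <= face_cut
    mask = np.repeat(keep2d[:, :, None], volume.shape[2], axis=2)
    if volume.mask is not None:
        mask &= volume.mask
    return replace(volume, mask=mask)
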
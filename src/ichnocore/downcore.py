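"""Downcore profiles: orientation volume-%, H/V intervals and BI logs.

Per CT slice, the fill voxels of every segmented burrow are split by the
orientation class of the burrow they belong to and expressed as volume
percentages of all segmented fill in that slice.  Smoothed profiles are
classified into intervals dominated by vertical burrows (V), by horizontal
burrows (H), or lacking a dominant orientation (V/H).  The bioturbated
fraction per depth bin is mapped through a monotone band table onto the
0-6 Bioturbation Index (BI) scale (0 = no bioturbation, 6 = completely
bioturbated), and a CT-derived BI log can be combined with a depth-binned
BI log read from high-resolution 2D core-surface images.

The CT bioturbated fraction counts only segmented high-contrast fills over
retained core volume, so it under-represents the full trace assemblage —
which is exactly why the combination with the 2D image log never lowers and
usually raises the grade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .shape_metrics import BurrowComponent
from .types import LabelVolume

__all__ = [
    "SliceProfile",
    "IntervalLabel",
    "BIRecord",
    "slice_profiles",
    "classify_intervals",
    "bioturbation_index",
    "combine_bi",
    "pct_to_bi",
    "DEFAULT_BI_BANDS",
    "profiles_to_frame",
]

#: (upper bound of bioturbated %, BI grade); a value maps to the first band
#: whose upper bound it does not exceed.  0% is exactly grade 0 and anything
#: above 99.9% is grade 6 (complete bioturbation).
DEFAULT_BI_BANDS: tuple[tuple[float, int], ...] = (
    (0.0, 0),
    (4.0, 1),
    (30.0, 2),
    (60.0, 3),
    (90.0, 4),
    (99.9, 5),
    (math.inf, 6),
)


@dataclass
class SliceProfile:
    """Orientation volume-% and bioturbated fraction of one CT slice."""

    slice_index: int
    depth_cm: float
    pct_vertical: float
    pct_horizontal: float
    fill_voxels: int
    retained_voxels: int
    bioturbated_pct: float


@dataclass
class IntervalLabel:
    """A depth interval with a dominant-orientation class H, V or V/H."""

    top_cm: float
    base_cm: float
    klass: str

    def __post_init__(self) -> None:
        if self.klass not in ("H", "V", "V/H"):
            raise ValueError(f"unknown interval class {self.klass!r}")
        if not self.top_cm < self.base_cm:
            raise ValueError("require top_cm < base_cm")


@dataclass
class BIRecord:
    """Bioturbation Index of one depth bin from one source."""

    top_cm: float
    base_cm: float
    bi: int
    source: str  # ct | image2d | combined
    taxa: str = ""
    disjoint_flag: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.bi <= 6:
            raise ValueError(f"BI must lie in 0..6; got {self.bi}")


def slice_profiles(
    labels: LabelVolume,
    components: list[BurrowComponent],
    retained_mask: np.ndarray,
    depth_origin_cm: float = 0.0,
) -> list[SliceProfile]:
    """Per-slice orientation volume-% and bioturbated fraction.

    Every nonzero label must have a component record; a missing record is an
    error naming the label.  Degenerate (single-voxel) components have no
    orientation and are excluded from the percentages and fill counts.
    For a nonempty slice ``pct_vertical + pct_horizontal == 100``.
    """
    by_id = {c.id: c for c in components}
    k = labels.n_components
    present = np.unique(labels.labels)
    present = present[present > 0]
    missing = [cid for cid in present if cid not in by_id]
    if missing:
        raise ValueError(f"labels without component records: {missing}")

    # per-label class lookup: 0 none, 1 vertical, 2 horizontal, -1 degenerate
    lut = np.zeros(k + 1, dtype=np.int8)
    for cid in present:
        c = by_id[cid]
        lut[cid] = -1 if c.degenerate else (1 if c.orientation_class == "sub_vertical" else 2)

    classes = lut[labels.labels]
    fill = (classes == 1) | (classes == 2)
    vert = classes == 1
    fill_per_slice = fill.sum(axis=(0, 1))
    vert_per_slice = vert.sum(axis=(0, 1))
    retained_per_slice = retained_mask.sum(axis=(0, 1))

    dz_cm = labels.spacing_mm[2] / 10.0
    profiles = []
    for z in range(labels.shape[2]):
        f = int(fill_per_slice[z])
        if f > 0:
            pv = 100.0 * vert_per_slice[z] / f
            ph = 100.0 - pv
        else:
            pv = ph = 0.0
        r = int(retained_per_slice[z])
        profiles.append(
            SliceProfile(
                slice_index=z,
                depth_cm=depth_origin_cm + z * dz_cm,
                pct_vertical=pv,
                pct_horizontal=ph,
                fill_voxels=f,
                retained_voxels=r,
                bioturbated_pct=100.0 * f / r if r else 0.0,
            )
        )
    return profiles


def _slice_spacing_cm(profiles: list[SliceProfile]) -> float:
    if len(profiles) < 2:
        return 0.05
    return profiles[1].depth_cm - profiles[0].depth_cm


def classify_intervals(
    profiles: list[SliceProfile],
    window_cm: float = 2.0,
    dominance: float = 60.0,
) -> list[IntervalLabel]:
    """Dominant-orientation intervals tiling the section.

    The vertical volume-% is smoothed by a centred moving average over
    ``window_cm`` (weighted by fill voxels, so empty slices do not dilute the
    signal).  A depth is V where the smoothed percentage is at least the
    dominance threshold, H where it is at most ``100 - dominance``, and V/H
    between.  Slices with no fill anywhere in the window inherit the nearest
    class, or V/H when the whole section is barren.  Runs of equal class are
    merged into intervals that tile the section without gaps or overlap.
    """
    if not profiles:
        return []
    dz = _slice_spacing_cm(profiles)
    if window_cm < dz:
        raise ValueError(f"window_cm={window_cm} is finer than the slice spacing {dz} cm")
    pv = np.array([p.pct_vertical for p in profiles])
    w = np.array([p.fill_voxels for p in profiles], dtype=float)
    from scipy import ndimage

    half = max(1, int(round(window_cm / (2 * dz))))
    kernel = np.ones(2 * half + 1)
    num = ndimage.convolve1d(pv * w, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve1d(w, kernel, mode="constant", cval=0.0)
    smoothed = np.divide(num, den, out=np.full_like(num, np.nan), where=den > 0)

    # 0 = undefined, 1 = V, 2 = H, 3 = V/H
    codes = np.zeros(len(profiles), dtype=np.int8)
    defined = ~np.isnan(smoothed)
    codes[defined & (smoothed >= dominance)] = 1
    codes[defined & (smoothed <= 100.0 - dominance)] = 2
    codes[defined & (codes == 0)] = 3
    if not defined.any():
        codes[:] = 3
    else:  # inherit nearest defined class (ties towards shallower)
        idx = np.arange(len(codes))
        defined_idx = idx[codes != 0]
        nearest = defined_idx[
            np.argmin(np.abs(idx[:, None] - defined_idx[None, :]), axis=1)
        ]
        codes = codes[nearest]

    names = {1: "V", 2: "H", 3: "V/H"}
    intervals: list[IntervalLabel] = []
    start = 0
    for i in range(1, len(codes) + 1):
        if i == len(codes) or codes[i] != codes[start]:
            base = profiles[i].depth_cm if i < len(codes) else profiles[-1].depth_cm + dz
            intervals.append(
                IntervalLabel(
                    top_cm=profiles[start].depth_cm,
                    base_cm=base,
                    klass=names[int(codes[start])],
                )
            )
            start = i
    return intervals


def _validate_bands(bands) -> list[tuple[float, int]]:
    bands = [(float(u), int(g)) for u, g in bands]
    uppers = [u for u, _ in bands]
    grades = [g for _, g in bands]
    if sorted(uppers) != uppers or sorted(grades) != grades:
        raise ValueError("BI bands must be monotone in both bound and grade")
    if len(set(uppers)) != len(uppers):
        raise ValueError("BI band bounds must be strictly increasing")
    return bands


def pct_to_bi(pct: float, bands=DEFAULT_BI_BANDS) -> int:
    """Map a bioturbated percentage onto the ordinal 0-6 BI scale."""
    for upper, grade in _validate_bands(bands):
        if pct <= upper:
            return grade
    return bands[-1][1]


def bioturbation_index(
    profiles: list[SliceProfile],
    bin_cm: float = 2.0,
    bands=DEFAULT_BI_BANDS,
) -> list[BIRecord]:
    """CT-derived BI log: mean bioturbated-% per depth bin through the bands."""
    bands = _validate_bands(bands)
    if not profiles:
        return []
    dz = _slice_spacing_cm(profiles)
    top = profiles[0].depth_cm
    base = profiles[-1].depth_cm + dz
    records = []
    edge = top
    while edge < base - 1e-9:
        upper = min(edge + bin_cm, base)
        sel = [p for p in profiles if edge - 1e-9 <= p.depth_cm < upper - 1e-9]
        mean_pct = float(np.mean([p.bioturbated_pct for p in sel])) if sel else 0.0
        records.append(
            BIRecord(top_cm=edge, base_cm=upper, bi=pct_to_bi(mean_pct, bands), source="ct")
        )
        edge = upper
    return records


def combine_bi(
    ct: list[BIRecord],
    image2d: list[BIRecord],
    *,
    disjoint_bonus: bool = True,
) -> list[BIRecord]:
    """Combine a CT BI log with a 2D-image BI log on their common depth grid.

    Each technique sees only part of the trace assemblage, so the combined
    grade per bin is the maximum of the two, raised by one (capped at 6)
    when both sources record bioturbation and the 2D log flags its
    structures as disjoint from the CT-resolved fills.  The combined grade
    is never below either input.  Non-overlapping coverage is an error.
    """
    if not ct or not image2d:
        raise ValueError("both BI logs must be nonempty")
    top = max(min(r.top_cm for r in ct), min(r.top_cm for r in image2d))
    base = min(max(r.base_cm for r in ct), max(r.base_cm for r in image2d))
    if top >= base:
        raise ValueError("BI logs have non-overlapping depth coverage")
    edges = sorted(
        {top, base}
        | {r.top_cm for r in ct if top < r.top_cm < base}
        | {r.base_cm for r in ct if top < r.base_cm < base}
        | {r.top_cm for r in image2d if top < r.top_cm < base}
        | {r.base_cm for r in image2d if top < r.base_cm < base}
    )

    def _covering(records: list[BIRecord], depth: float) -> BIRecord | None:
        for r in records:
            if r.top_cm - 1e-9 <= depth < r.base_cm + 1e-9:
                return r
        return None

    combined = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        rc = _covering(ct, mid)
        r2 = _covering(image2d, mid)
        if rc is None or r2 is None:
            continue  # a gap inside one log: nothing to combine there
        bi = max(rc.bi, r2.bi)
        if disjoint_bonus and rc.bi >= 1 and r2.bi >= 1 and r2.disjoint_flag:
            bi = min(6, bi + 1)
        combined.append(BIRecord(top_cm=lo, base_cm=hi, bi=bi, source="combined"))
    return combined


def profiles_to_frame(profiles: list[SliceProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "slice_index": p.slice_index,
                "depth_cm": p.depth_cm,
                "pct_vertical": p.pct_vertical,
                "pct_horizontal": p.pct_horizontal,
                "fill_voxels": p.fill_voxels,
                "retained_voxels": p.retained_voxels,
                "bioturbated_pct": p.bioturbated_pct,
            }
            for p in profiles
        ]
    )
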
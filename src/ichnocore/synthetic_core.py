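"""Ground-truthed synthetic core CT volumes.

The simulator emulates the statistical structure the downstream analysis
assumes: an archive half-core (a semicylinder, default 6.2 cm diameter)
embedded in air, wrapped by a thin liner of near-sediment attenuation, host
sediment with i.i.d. Gaussian attenuation noise, and dense burrow fills of
controlled geometry, orientation and contrast.  Every generated volume comes
with a ground-truth label grid and per-burrow truth table so that recovery
of counts, volumes and orientations can be scored exactly.

Geometry convention: the core axis runs along ``z`` (downcore).  The flat
slab face of the half-core is the plane ``y = face_y``; the core occupies
``y >= face_y`` within the fitted radius.  Burrow contrast is expressed in
units of the host-noise standard deviation, mirroring how segmentability in
real scans is limited by the density contrast of the fill (e.g. pyritised
burrows) against the host mud.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import CoreVolume, LabelVolume

__all__ = [
    "BurrowSpec",
    "SceneSpec",
    "GroundTruth",
    "generate_core",
    "preset_scene",
    "random_scene",
    "mixed_band_truth",
    "PRESET_NAMES",
]

PRESET_NAMES = ("tiny_vertical", "thick_horizontal", "mixed", "branched")

#: Attenuation of air relative to the host sediment, in host-noise sigmas.
#: Far enough below the sediment mode that core/air separation is trivial,
#: as in real scans.
AIR_OFFSET_SIGMA = -10.0


@dataclass(frozen=True)
class BurrowSpec:
    """Geometry and contrast of one synthetic burrow.

    ``z_angle_deg`` follows the field convention: 0 = horizontal,
    90 = vertical.  ``contrast`` is the attenuation offset of the fill above
    the host mean, in units of the host noise sigma; 0 gives an invisible
    burrow (negative control).  ``modulation_amplitude`` in [0, 1) imposes a
    sinusoidal radius variation along the axis (pinch-and-swell morphology).
    """

    kind: str = "straight_tube"  # straight_tube | branched_network
    diameter_mm: float = 2.0
    length_mm: float = 30.0
    z_angle_deg: float = 90.0
    azimuth_deg: float = 0.0
    anchor_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    contrast: float = 8.0
    modulation_amplitude: float = 0.0
    n_branches: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("straight_tube", "branched_network"):
            raise ValueError(f"unknown burrow kind {self.kind!r}")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if not 0.0 <= self.z_angle_deg <= 90.0:
            raise ValueError("z_angle_deg must lie in [0, 90]")
        if not 0.0 <= self.modulation_amplitude < 1.0:
            raise ValueError("modulation_amplitude must lie in [0, 1)")
        if self.n_branches < 0:
            raise ValueError("n_branches must be nonnegative")

    @property
    def direction(self) -> np.ndarray:
        """Unit axis vector from z-angle and azimuth."""
        th = math.radians(self.z_angle_deg)
        az = math.radians(self.azimuth_deg)
        return np.array(
            [math.cos(th) * math.cos(az), math.cos(th) * math.sin(az), math.sin(th)]
        )


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scan; ``seed`` determines the output bit-for-bit."""

    shape_voxels: tuple[int, int, int] = (192, 96, 300)
    spacing_mm: tuple[float, float, float] = (0.351, 0.351, 0.5)
    core_radius_mm: float = 31.0  # 6.2 cm archive half
    rim_mm: float = 2.0
    host_mean: float = 100.0
    host_sigma: float = 10.0
    liner_thickness_mm: float = 2.0
    liner_contrast: float = 0.0  # liner attenuation is close to the sediment's
    #: air annulus between sediment and liner (drying/shrinkage gap, ubiquitous
    #: in core CT); gives the core/air boundary its visible curved edge even
    #: though the liner itself matches the sediment attenuation.
    core_gap_mm: float = 0.5
    burrows: tuple[BurrowSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape_voxels", tuple(int(n) for n in self.shape_voxels))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "burrows", tuple(self.burrows))
        if any(n <= 0 for n in self.shape_voxels) or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("shape_voxels and spacing_mm must be positive")
        if self.host_sigma <= 0:
            raise ValueError("host_sigma must be positive")
        if self.core_radius_mm <= 0 or self.rim_mm < 0 or self.liner_thickness_mm < 0:
            raise ValueError("invalid core geometry")
        if 2 * self.core_radius_mm > self.shape_voxels[0] * self.spacing_mm[0]:
            raise ValueError("core diameter does not fit within the x footprint")

    # Derived geometry -----------------------------------------------------
    @property
    def axis_center_mm(self) -> tuple[float, float]:
        """(x, y) of the cylinder axis: centred in x, face offset in y."""
        cx = self.shape_voxels[0] * self.spacing_mm[0] / 2.0
        return (cx, self.face_y_mm)

    @property
    def face_y_mm(self) -> float:
        """y-position of the flat slab face; the core occupies y >= face."""
        extent_y = self.shape_voxels[1] * self.spacing_mm[1]
        # leave head-room above the curved surface for the liner + air
        return max(1.0, extent_y - self.core_radius_mm - self.liner_thickness_mm - 3.0)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape_voxels, self.spacing_mm))

    @property
    def air_value(self) -> float:
        return self.host_mean + AIR_OFFSET_SIGMA * self.host_sigma


@dataclass
class GroundTruth:
    """True label grid plus the per-burrow truth table.

    Label ``k`` corresponds to ``spec.burrows[k - 1]``; overlaps are resolved
    to the earlier-listed burrow.  ``table`` columns: burrow_id, kind,
    voxel_count, volume_mm3, z_angle_deg, diameter_mm, length_mm, contrast.
    """

    label_volume: LabelVolume
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# rasterisation


def _voxel_centres_1d(n: int, spacing: float) -> np.ndarray:
    """Physical coordinate (mm) of voxel centres along one axis."""
    return (np.arange(n) + 0.5) * spacing


def _capsule_segments(burrow: BurrowSpec, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray, float]]:
    """Decompose a burrow into straight capsule segments (p0, p1, radius).

    A straight tube is a single segment.  A branched network is a random-walk
    trunk with the requested number of side branches; the walk direction is
    perturbed step by step so the network meanders, which together with the
    radius modulation reproduces the pinch-and-swell look of complex tiny
    burrow systems.
    """
    r = burrow.diameter_mm / 2.0
    anchor = np.asarray(burrow.anchor_mm, dtype=float)
    d = burrow.direction
    if burrow.kind == "straight_tube":
        return [(anchor, anchor + d * burrow.length_mm, r)]

    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    step = max(2.0, burrow.length_mm / 8.0)
    pos = anchor.copy()
    direction = d.copy()
    trunk_points = [pos.copy()]
    travelled = 0.0
    while travelled < burrow.length_mm:
        seg_len = min(step, burrow.length_mm - travelled)
        nxt = pos + direction * seg_len
        segments.append((pos.copy(), nxt.copy(), r))
        trunk_points.append(nxt.copy())
        pos = nxt
        travelled += seg_len
        # small random kink, renormalised
        direction = direction + rng.normal(scale=0.25, size=3)
        direction /= np.linalg.norm(direction)
    for _ in range(burrow.n_branches):
        base = trunk_points[rng.integers(0, len(trunk_points))]
        bdir = rng.normal(size=3)
        bdir /= np.linalg.norm(bdir)
        blen = burrow.length_mm * rng.uniform(0.2, 0.5)
        segments.append((base.copy(), base + bdir * blen, r))
    return segments


def _rasterise_burrow(
    burrow: BurrowSpec,
    spec: SceneSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel indices (ix, iy, iz) whose centres lie inside the burrow tube.

    A voxel belongs to the burrow iff its centre lies within the analytic
    tube — simple and checkable against a brute-force oracle.
    """
    nx, ny, nz = spec.shape_voxels
    sx, sy, sz = spec.spacing_mm
    segments = _capsule_segments(burrow, rng)
    hits: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    rmax_global = burrow.diameter_mm / 2.0 * (1.0 + burrow.modulation_amplitude)
    # wavelength of the pinch-and-swell modulation, in mm along the axis
    wavelength = max(4.0 * burrow.diameter_mm, 2.0)
    for p0, p1, r0 in segments:
        seg = p1 - p0
        seg_len = float(np.linalg.norm(seg))
        if seg_len == 0:
            continue
        d = seg / seg_len
        rmax = r0 * (1.0 + burrow.modulation_amplitude)
        lo = np.minimum(p0, p1) - rmax - 1e-9
        hi = np.maximum(p0, p1) + rmax + 1e-9
        i0 = np.maximum(np.floor(lo / spec.spacing_mm - 0.5).astype(int), 0)
        i1 = np.minimum(
            np.ceil(hi / spec.spacing_mm - 0.5).astype(int) + 1, [nx, ny, nz]
        )
        if np.any(i0 >= i1):
            continue
        xs = _voxel_centres_1d(nx, sx)[i0[0]:i1[0]]
        ys = _voxel_centres_1d(ny, sy)[i0[1]:i1[1]]
        zs = _voxel_centres_1d(nz, sz)[i0[2]:i1[2]]
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        wx, wy, wz = X - p0[0], Y - p0[1], Z - p0[2]
        t = wx * d[0] + wy * d[1] + wz * d[2]
        # squared distance from voxel centre to the segment axis
        dist2 = (wx - t * d[0]) ** 2 + (wy - t * d[1]) ** 2 + (wz - t * d[2]) ** 2
        if burrow.modulation_amplitude > 0:
            radius_t = r0 * (
                1.0 + burrow.modulation_amplitude * np.sin(2 * np.pi * t / wavelength)
            )
        else:
            radius_t = r0
        inside = (t >= 0) & (t <= seg_len) & (dist2 <= radius_t**2)
        ii, jj, kk = np.nonzero(inside)
        hits.append((ii + i0[0], jj + i0[1], kk + i0[2]))
    if not hits:
        return (np.empty(0, int),) * 3
    ix = np.concatenate([h[0] for h in hits])
    iy = np.concatenate([h[1] for h in hits])
    iz = np.concatenate([h[2] for h in hits])
    # deduplicate voxels shared by several capsule segments
    lin = np.unique(ix * (ny * nz) + iy * nz + iz)
    return lin // (ny * nz), (lin // nz) % ny, lin % nz


def _core_region_masks(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """(core, liner) boolean grids for the half-cylinder geometry."""
    nx, ny, nz = spec.shape_voxels
    sx, sy, _ = spec.spacing_mm
    cx, cy = spec.axis_center_mm
    xs = _voxel_centres_1d(nx, sx) - cx
    ys = _voxel_centres_1d(ny, sy) - cy
    R2 = (xs[:, None] ** 2) + (ys[None, :] ** 2)
    halfplane = ys[None, :] >= 0.0
    core2d = (R2 <= spec.core_radius_mm**2) & halfplane
    inner = spec.core_radius_mm + spec.core_gap_mm
    outer = inner + spec.liner_thickness_mm
    liner2d = (R2 > inner**2) & (R2 <= outer**2) & halfplane
    core = np.repeat(core2d[:, :, None], nz, axis=2)
    liner = np.repeat(liner2d[:, :, None], nz, axis=2)
    return core, liner


def generate_core(spec: SceneSpec) -> tuple[CoreVolume, GroundTruth]:
    """Render a synthetic scan and its ground truth.

    The attenuation model is: air at ``host_mean - 10 sigma``; host sediment
    at ``host_mean``; liner at ``host_mean + liner_contrast``; burrow fill at
    ``host_mean + contrast * sigma``.  I.i.d. Gaussian noise of width
    ``host_sigma`` is then added inside the core and liner.  Burrows
    extending outside the half-core are clipped (with a warning); a burrow
    left empty by clipping is an error naming its index.
    """
    nx, ny, nz = spec.shape_voxels
    ss = np.random.SeedSequence(spec.seed)
    geom_seed, noise_seed = ss.spawn(2)
    rng_geom = np.random.default_rng(geom_seed)
    rng_noise = np.random.default_rng(noise_seed)

    core, liner = _core_region_masks(spec)
    labels = np.zeros(spec.shape_voxels, dtype=np.int32)
    rows = []
    for k, burrow in enumerate(spec.burrows, start=1):
        ix, iy, iz = _rasterise_burrow(burrow, spec, rng_geom)
        if ix.size == 0:
            raise ValueError(f"burrow {k - 1} rasterises to zero voxels")
        inside = core[ix, iy, iz]
        if not inside.all():
            warnings.warn(
                f"burrow {k - 1} extends outside the core; clipped "
                f"({int((~inside).sum())} of {ix.size} voxels removed)",
                stacklevel=2,
            )
            ix, iy, iz = ix[inside], iy[inside], iz[inside]
        if ix.size == 0:
            raise ValueError(f"burrow {k - 1} lies entirely outside the core")
        free = labels[ix, iy, iz] == 0  # overlaps go to the earlier burrow
        labels[ix[free], iy[free], iz[free]] = k
        count = int(free.sum())
        rows.append(
            {
                "burrow_id": k,
                "kind": burrow.kind,
                "voxel_count": count,
                "volume_mm3": count * sx_sy_sz(spec),
                "z_angle_deg": burrow.z_angle_deg,
                "diameter_mm": burrow.diameter_mm,
                "length_mm": burrow.length_mm,
                "contrast": burrow.contrast,
            }
        )

    base = np.full(spec.shape_voxels, spec.air_value, dtype=np.float32)
    base[core] = spec.host_mean
    base[liner] = spec.host_mean + spec.liner_contrast
    for k, burrow in enumerate(spec.burrows, start=1):
        sel = labels == k
        base[sel] = spec.host_mean + burrow.contrast * spec.host_sigma
    interior = core | liner
    noise = rng_noise.normal(0.0, spec.host_sigma, size=spec.shape_voxels).astype(
        np.float32
    )
    base[interior] += noise[interior]

    volume = CoreVolume(
        data=base,
        spacing_mm=spec.spacing_mm,
        depth_origin_cm=0.0,
        meta={"source": "synthetic", "seed": spec.seed, "n_burrows": len(spec.burrows)},
    )
    table = pd.DataFrame(
        rows,
        columns=[
            "burrow_id",
            "kind",
            "voxel_count",
            "volume_mm3",
            "z_angle_deg",
            "diameter_mm",
            "length_mm",
            "contrast",
        ],
    )
    truth = GroundTruth(
        label_volume=LabelVolume(labels=labels, spacing_mm=spec.spacing_mm),
        table=table,
    )
    return volume, truth


def sx_sy_sz(spec: SceneSpec) -> float:
    sx, sy, sz = spec.spacing_mm
    return sx * sy * sz


# ---------------------------------------------------------------------------
# scene construction helpers


def _safe_anchor_region(spec: SceneSpec, margin_mm: float) -> tuple[float, float, float]:
    """Radius and y/z limits within which burrows survive rim trimming."""
    safe_r = spec.core_radius_mm - spec.rim_mm - margin_mm
    if safe_r <= 0:
        raise ValueError("core too small for the requested rim and margin")
    return safe_r, spec.face_y_mm + spec.rim_mm + margin_mm, margin_mm


def _point_inside(spec: SceneSpec, p: np.ndarray, margin: float) -> bool:
    cx, cy = spec.axis_center_mm
    safe_r = spec.core_radius_mm - spec.rim_mm - margin
    if (p[0] - cx) ** 2 + (p[1] - cy) ** 2 > safe_r**2:
        return False
    if p[1] < cy + spec.rim_mm + margin:
        return False
    return margin <= p[2] <= spec.extent_mm[2] - margin


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 3D segments (standard clamped solver)."""
    p0, p1, q0, q1 = (np.asarray(v, float) for v in (p0, p1, q0, q1))
    u, v, w = p1 - p0, q1 - q0, p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-clamp s against the clamped t
    if a > 1e-12:
        s = np.clip((b * t - d) / a, 0.0, 1.0)
    return float(np.linalg.norm(p0 + s * u - (q0 + t * v)))


def _place_tube(
    spec: SceneSpec,
    rng: np.random.Generator,
    *,
    diameter_mm: float,
    length_mm: float,
    z_angle_deg: float,
    contrast: float,
    placed: list[tuple[np.ndarray, np.ndarray, float]],
    z_range_mm: tuple[float, float] | None = None,
    clearance_mm: float = 2.5,
    max_tries: int = 400,
) -> BurrowSpec | None:
    """Rejection-sample a straight tube disjoint from already placed tubes."""
    r = diameter_mm / 2.0
    margin = r + 0.8
    cx, cy = spec.axis_center_mm
    zlo, zhi = z_range_mm if z_range_mm is not None else (0.0, spec.extent_mm[2])
    safe_r = spec.core_radius_mm - spec.rim_mm - margin
    ylo = cy + spec.rim_mm + margin
    if safe_r <= 0 or ylo >= cy + safe_r:
        return None
    for _ in range(max_tries):
        az = rng.uniform(0.0, 360.0)
        th = math.radians(z_angle_deg)
        azr = math.radians(az)
        d = np.array([math.cos(th) * math.cos(azr), math.cos(th) * math.sin(azr), math.sin(th)])
        # tube midpoint uniform over the safe footprint and depth band
        mid = np.array(
            [
                cx + rng.uniform(-safe_r, safe_r),
                rng.uniform(ylo, cy + safe_r),
                rng.uniform(zlo + margin, max(zlo + margin, zhi - margin)),
            ]
        )
        p0 = mid - d * (length_mm / 2.0)
        p1 = mid + d * (length_mm / 2.0)
        ok = all(
            _point_inside(spec, q, margin) and zlo <= q[2] <= zhi
            for q in (p0, mid, 0.5 * (p0 + mid), 0.5 * (mid + p1), p1)
        )
        if not ok:
            continue
        if any(
            _segment_distance(p0, p1, q0, q1) < r + qr + clearance_mm
            for q0, q1, qr in placed
        ):
            continue
        placed.append((p0, p1, r))
        return BurrowSpec(
            kind="straight_tube",
            diameter_mm=diameter_mm,
            length_mm=length_mm,
            z_angle_deg=z_angle_deg,
            azimuth_deg=az,
            anchor_mm=tuple(p0),
            contrast=contrast,
        )
    return None


def random_scene(
    seed: int,
    *,
    shape_voxels: tuple[int, int, int] = (256, 128, 400),
    n_burrows: int | None = None,
    contrast: float | None = None,
    diameter_range_mm: tuple[float, float] = (1.5, 4.0),
    length_range_mm: tuple[float, float] = (15.0, 50.0),
) -> SceneSpec:
    """A scene of disjoint straight tubes at random orientations.

    Defaults reflect the regime the pipeline is built for: 10-30 disjoint
    burrows per section, fill diameters of a few voxels and a per-scene fill
    contrast of 6-10 host sigmas (pyritised fills are uniformly mineralised
    within a section, so contrast is drawn once per scene).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xC07E)))
    spec = SceneSpec(shape_voxels=shape_voxels, seed=seed)
    if n_burrows is None:
        n_burrows = int(rng.integers(10, 31))
    if contrast is None:
        contrast = float(rng.uniform(6.0, 10.0))
    placed: list[tuple[np.ndarray, np.ndarray, float]] = []
    burrows: list[BurrowSpec] = []
    attempts = 0
    while len(burrows) < n_burrows and attempts < 50 * n_burrows:
        attempts += 1
        tube = _place_tube(
            spec,
            rng,
            diameter_mm=float(rng.uniform(*diameter_range_mm)),
            length_mm=float(rng.uniform(*length_range_mm)),
            z_angle_deg=float(rng.uniform(0.0, 90.0)),
            contrast=contrast,
            placed=placed,
            max_tries=40,
        )
        if tube is not None:
            burrows.append(tube)
    return replace(spec, burrows=tuple(burrows))


def _mixed_bands(spec_like_zlen_mm: float, n_bands: int = 4) -> list[tuple[float, float, str]]:
    band = spec_like_zlen_mm / n_bands
    return [
        (i * band, (i + 1) * band, "V" if i % 2 == 0 else "H") for i in range(n_bands)
    ]


def mixed_band_truth(spec: SceneSpec) -> list[tuple[float, float, str]]:
    """Constructed depth bands of the ``mixed`` preset: (top_cm, base_cm, class)."""
    return [(t / 10.0, b / 10.0, k) for t, b, k in _mixed_bands(spec.extent_mm[2])]


def preset_scene(name: str, seed: int) -> SceneSpec:
    """Named scenes mirroring the end-member ichnofabrics the method targets.

    ``tiny_vertical``
        Dense assemblage of sub-millimetre vertical tubes (Trichichnus-like:
        0.1-1.0 mm diameter, steep, long).
    ``thick_horizontal``
        Sparse thick horizontal tubes (> 0.5 cm diameter, Thalassinoides-like).
    ``mixed``
        Alternating depth bands dominated by vertical and by horizontal
        burrows, for interval-classification recovery tests.
    ``branched``
        Complex tiny pinch-and-swell networks (Virgaichnus-like, < 1 mm).
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose one of {PRESET_NAMES}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, hash_name(name))))
    placed: list[tuple[np.ndarray, np.ndarray, float]] = []
    burrows: list[BurrowSpec] = []

    if name == "tiny_vertical":
        spec = SceneSpec(shape_voxels=(192, 96, 300), seed=seed)
        zlen = spec.extent_mm[2]
        for _ in range(24):
            tube = _place_tube(
                spec,
                rng,
                diameter_mm=float(rng.uniform(0.6, 1.0)),
                length_mm=float(rng.uniform(40.0, 0.7 * zlen)),
                z_angle_deg=float(rng.uniform(70.0, 90.0)),
                contrast=8.0,
                placed=placed,
                clearance_mm=1.5,
            )
            if tube is not None:
                burrows.append(tube)
    elif name == "thick_horizontal":
        spec = SceneSpec(shape_voxels=(192, 96, 300), seed=seed)
        for _ in range(10):
            tube = _place_tube(
                spec,
                rng,
                diameter_mm=float(rng.uniform(6.0, 10.0)),
                length_mm=float(rng.uniform(25.0, 45.0)),
                z_angle_deg=float(rng.uniform(0.0, 10.0)),
                contrast=8.0,
                placed=placed,
            )
            if tube is not None:
                burrows.append(tube)
    elif name == "mixed":
        spec = SceneSpec(shape_voxels=(192, 96, 400), seed=seed)
        for band_top, band_base, klass in _mixed_bands(spec.extent_mm[2]):
            # keep fills clear of band boundaries so the smoothed profile
            # transitions within the guard zone, not across it
            top, base = band_top + 5.0, band_base - 5.0
            for _ in range(10):
                if klass == "V":
                    tube = _place_tube(
                        spec,
                        rng,
                        diameter_mm=float(rng.uniform(1.5, 3.0)),
                        length_mm=float(rng.uniform(18.0, 0.7 * (base - top))),
                        z_angle_deg=float(rng.uniform(80.0, 90.0)),
                        contrast=8.0,
                        placed=placed,
                        z_range_mm=(top, base),
                    )
                else:
                    tube = _place_tube(
                        spec,
                        rng,
                        diameter_mm=float(rng.uniform(2.0, 4.0)),
                        length_mm=float(rng.uniform(18.0, 40.0)),
                        z_angle_deg=float(rng.uniform(0.0, 8.0)),
                        contrast=8.0,
                        placed=placed,
                        z_range_mm=(top, base),
                    )
                if tube is not None:
                    burrows.append(tube)
    else:  # branched
        spec = SceneSpec(shape_voxels=(192, 96, 240), seed=seed)
        cx, cy = spec.axis_center_mm
        for _ in range(5):
            anchor = np.array(
                [
                    cx + rng.uniform(-10.0, 10.0),
                    cy + rng.uniform(8.0, 18.0),
                    rng.uniform(30.0, spec.extent_mm[2] - 30.0),
                ]
            )
            burrows.append(
                BurrowSpec(
                    kind="branched_network",
                    diameter_mm=float(rng.uniform(0.6, 0.9)),
                    length_mm=float(rng.uniform(20.0, 35.0)),
                    z_angle_deg=float(rng.uniform(20.0, 70.0)),
                    azimuth_deg=float(rng.uniform(0.0, 360.0)),
                    anchor_mm=tuple(anchor),
                    contrast=8.0,
                    modulation_amplitude=0.4,
                    n_branches=int(rng.integers(4, 9)),
                )
            )
    return replace(spec, burrows=tuple(burrows))


def hash_name(name: str) -> int:
    """Stable small integer from a preset name (Python's hash() is salted)."""
    return sum(ord(c) * (i + 1) for i, c in enumerate(name)) % 100003
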
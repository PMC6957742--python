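"""In-memory containers shared by every stage of the pipeline.

Axis convention: arrays are indexed ``(x, y, z)`` with ``z`` the downcore
axis, increasing with depth.  Slice ``z`` sits at downcore depth
``depth_origin_cm + z * spacing_mm[2] / 10`` centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoreVolume", "LabelVolume"]


@dataclass
class CoreVolume:
    """A 3D X-ray attenuation grid with voxel spacing and depth registration.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Attenuation values (arbitrary CT units).
    spacing_mm : tuple of 3 floats
        Voxel edge lengths along (x, y, z) in millimetres.
    depth_origin_cm : float
        Downcore depth of slice ``z = 0`` in centimetres.
    meta : dict
        Free-form provenance (source files, scanner settings, ...).
    mask : ndarray of bool or None
        ``True`` marks retained voxels.  ``None`` means "everything
        retained".  Liner/rim removal populates this; excluded voxels keep
        their data value so attenuation statistics stay uncontaminated.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    depth_origin_cm: float = 0.0
    meta: dict = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D (x, y, z); got shape {self.data.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive reals; got {self.spacing_mm}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def retained(self) -> np.ndarray:
        """Boolean grid of retained voxels (all-True when no mask is set)."""
        if self.mask is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.mask

    def depth_cm(self, z: int | np.ndarray) -> float | np.ndarray:
        """Downcore depth (cm) of the top of slice ``z``."""
        return self.depth_origin_cm + np.asarray(z) * self.spacing_mm[2] / 10.0


@dataclass
class LabelVolume:
    """Integer-labelled voxel grid: 0 = background, k > 0 = burrow component k.

    Shares the (x, y, z) convention and voxel spacing of its parent
    :class:`CoreVolume`.  After compaction the label set is ``{0} | {1..K}``
    with no gaps.
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D; got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_components(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def voxel_counts(self) -> np.ndarray:
        """Voxel count per label id, index 0 = background."""
        return np.bincount(self.labels.ravel(), minlength=self.n_components + 1)
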
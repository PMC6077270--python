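"""Core data containers shared across pipeline stages.

Coordinate convention (used everywhere in this package): images are 2-D
arrays indexed ``[row, col]``, 0-based, row-major. Point coordinates are
``(row, col)`` floats in pixel units; the center of pixel ``(i, j)`` is at
coordinate ``(i, j)``, so the image occupies ``[-0.5, H-0.5] x [-0.5, W-0.5]``.
Physical calibration is a single isotropic ``pixel_size_um`` (µm per pixel);
densities are reported in cells per mm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ValidationError

CHANNEL_ROLES = ("edu", "protein")
MASK_ROLES = ("proliferating", "non_proliferating", "tissue")
GROUP_LABELS = ("control", "treated")


@dataclass
class FluorescenceSection:
    """A two-channel calibrated fluorescence image of one tumor section.

    The red channel (role ``edu``) carries the EdU proliferation label, the
    green channel (role ``protein``) the immunofluorescence of the target
    protein. Intensities are non-negative floats in arbitrary units.
    """

    sample_id: str
    channels: Mapping[str, np.ndarray]
    pixel_size_um: float
    group_label: str | None = None
    target_name: str | None = None

    def __post_init__(self):
        if not self.channels:
            raise ValidationError(f"section '{self.sample_id}': no channels")
        shapes = set()
        chans = {}
        for role, grid in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValidationError(
                    f"section '{self.sample_id}': unknown channel role '{role}'"
                )
            arr = np.asarray(grid, dtype=float)
            if arr.ndim != 2:
                raise ValidationError(
                    f"section '{self.sample_id}': channel '{role}' is not 2-D"
                )
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValidationError(
                    f"section '{self.sample_id}': channel '{role}' has "
                    "negative or non-finite intensities"
                )
            shapes.add(arr.shape)
            chans[role] = arr
        if len(shapes) > 1:
            raise ValidationError(
                f"section '{self.sample_id}': channel shapes differ: {shapes}"
            )
        if not (self.pixel_size_um > 0):
            raise ValidationError(
                f"section '{self.sample_id}': pixel_size_um must be > 0"
            )
        if self.group_label is not None and self.group_label not in GROUP_LABELS:
            raise ValidationError(
                f"section '{self.sample_id}': group_label must be one of "
                f"{GROUP_LABELS}, got '{self.group_label}'"
            )
        self.channels = chans

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise ValidationError(
                f"section '{self.sample_id}' has no '{role}' channel"
            )
        return self.channels[role]


@dataclass
class AreaMask:
    """Binary compartment mask aligned to a section.

    ``role`` says which compartment the set pixels represent; ``provenance``
    records the parameters that produced the mask.
    """

    grid: np.ndarray
    role: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.grid)
        if arr.ndim != 2:
            raise ValidationError("mask grid must be 2-D")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValidationError("mask grid must be binary")
            arr = arr.astype(bool)
        if self.role not in MASK_ROLES:
            raise ValidationError(f"unknown mask role '{self.role}'")
        self.grid = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def area_px(self) -> int:
        return int(self.grid.sum())

    def area_mm2(self, pixel_size_um: float) -> float:
        return self.area_px * (pixel_size_um / 1000.0) ** 2


@dataclass
class CellDetectionSet:
    """Centroids of fluorescence-positive cells for one channel of a section."""

    section_id: str
    channel_role: str
    centroids: np.ndarray  # (n, 2) float, (row, col)
    peak_intensity: np.ndarray  # (n,) float
    detection_params: dict = field(default_factory=dict)

    def __post_init__(self):
        pts = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        peaks = np.asarray(self.peak_intensity, dtype=float).reshape(-1)
        if len(pts) != len(peaks):
            raise ValidationError("centroids and peak_intensity lengths differ")
        if self.channel_role not in CHANNEL_ROLES:
            raise ValidationError(f"unknown channel role '{self.channel_role}'")
        self.centroids = pts
        self.peak_intensity = peaks

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass
class CircularRoi:
    """A circular region of interest sampled inside a compartment mask.

    Membership is boundary-inclusive: a point ``(r, c)`` belongs to the ROI
    iff ``(r - center_row)**2 + (c - center_col)**2 <= radius_px**2``.
    """

    roi_id: str
    center: tuple[float, float]  # (row, col)
    radius_px: float
    compartment: str

    def __post_init__(self):
        if not (self.radius_px > 0):
            raise ValidationError("ROI radius must be > 0")
        if self.compartment not in MASK_ROLES:
            raise ValidationError(f"unknown compartment '{self.compartment}'")
        self.center = (float(self.center[0]), float(self.center[1]))

    def contains(self, row: float, col: float) -> bool:
        dr = row - self.center[0]
        dc = col - self.center[1]
        return dr * dr + dc * dc <= self.radius_px * self.radius_px


@dataclass
class DensityEstimate:
    """Cells-per-mm² summary for one section/channel from k circular ROIs."""

    sample_id: str
    compartment: str
    channel_role: str
    counts: list[int]
    circle_area_mm2: float
    k: int = field(init=False)
    mean_density: float = field(init=False)

    def __post_init__(self):
        if not self.counts:
            raise ValidationError("DensityEstimate needs at least one count")
        if not (self.circle_area_mm2 > 0):
            raise ValidationError("circle area must be > 0")
        self.counts = [int(c) for c in self.counts]
        if any(c < 0 for c in self.counts):
            raise ValidationError("counts must be non-negative")
        self.k = len(self.counts)
        self.mean_density = float(np.mean(self.counts)) / self.circle_area_mm2


@dataclass
class GroupComparison:
    """Control-vs-treated density comparison for one channel/compartment.

    ``percent_change = 100 * (1 - treated_mean / control_mean)``: positive
    when treatment reduces density, negative when it increases it, and at
    most 100 (complete ablation).
    """

    channel_role: str
    compartment: str
    control_mean: float
    treated_mean: float
    n_control: int
    n_treated: int
    percent_change: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self):
        if self.percent_change > 100 + 1e-9:
            raise ValidationError("percent_change cannot exceed 100")


@dataclass
class CompartmentCall:
    """Which compartment a target protein is expressed in.

    ``call`` is 'proliferating' iff the overlap fraction f >= high,
    'non_proliferating' iff f <= low, otherwise 'ambiguous'.
    """

    target_name: str
    overlap_fraction: float
    call: str
    low: float = 0.25
    high: float = 0.75
    n_cells: int = 0

    def __post_init__(self):
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValidationError("overlap_fraction must lie in [0, 1]")
        if not (0.0 <= self.low < self.high <= 1.0):
            raise ValidationError("need 0 <= low < high <= 1")
        expected = (
            "proliferating"
            if self.overlap_fraction >= self.high
            else "non_proliferating"
            if self.overlap_fraction <= self.low
            else "ambiguous"
        )
        if self.call != expected:
            raise ValidationError(
                f"call '{self.call}' inconsistent with f={self.overlap_fraction}"
            )


def circle_area_mm2(radius_px: float, pixel_size_um: float) -> float:
    """Area of a circle of ``radius_px`` pixels, in mm²."""
    return math.pi * radius_px**2 * (pixel_size_um / 1000.0) ** 2
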
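"""Shared domain types: tissue labels, scan geometry, label volumes.

An OCT macular raster volume is a stack of cross-sectional B-scans. Axes are
ordered ``(b, z, x)``: B-scan index (slow axis, across the raster), axial row
(depth, vitreous at the top) and A-scan column (fast axis, along a B-scan).
Physical spacing is anisotropic: the slow axis is sampled far more coarsely
(hundreds of µm between B-scans) than the fast and axial axes (a few µm).
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class Tissue(enum.IntEnum):
    """Semantic tissue classes assigned to every voxel, anterior to posterior."""

    VITREOUS = 0
    RETINA = 1
    CHOROID = 2
    SCLERA = 3


#: Number of semantic classes.
N_TISSUES = len(Tissue)


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of an OCT raster scan.

    Defaults correspond to a 20° horizontal macular raster of 25 lines with
    221 µm line spacing, B-scans of 512×496 px covering 5.3 mm laterally and
    1.9 mm in depth.

    Parameters
    ----------
    n_bscans : int
        Number of B-scans in the raster (slow axis).
    ascans_per_bscan : int
        A-scans (columns) per B-scan (fast axis).
    axial_px : int
        Axial rows per B-scan.
    scan_length_mm : float
        Lateral extent of one B-scan in mm.
    bscan_spacing_um : float
        Distance between adjacent B-scans in µm.
    scan_depth_mm : float
        Axial extent of one B-scan in mm.
    fov_deg : float
        Field of view in degrees (informational only).
    """

    n_bscans: int = 25
    ascans_per_bscan: int = 512
    axial_px: int = 496
    scan_length_mm: float = 5.3
    bscan_spacing_um: float = 221.0
    scan_depth_mm: float = 1.9
    fov_deg: float = 20.0

    def __post_init__(self) -> None:
        for name in ("n_bscans", "ascans_per_bscan", "axial_px"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 2):
                raise ValueError(f"{name} must be an integer >= 2, got {v!r}")
        for name in ("scan_length_mm", "bscan_spacing_um", "scan_depth_mm"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")

    # -- derived pitches ----------------------------------------------------
    @property
    def lateral_pitch_mm(self) -> float:
        """Fast-axis pixel pitch (mm per A-scan)."""
        return self.scan_length_mm / self.ascans_per_bscan

    @property
    def axial_pitch_mm(self) -> float:
        """Axial pixel pitch (mm per row)."""
        return self.scan_depth_mm / self.axial_px

    @property
    def bscan_spacing_mm(self) -> float:
        """Slow-axis spacing (mm per B-scan)."""
        return self.bscan_spacing_um / 1000.0

    # -- en-face coordinates -------------------------------------------------
    def x_mm_of_column(self, x_index) -> np.ndarray | float:
        """En-face x (mm) of an A-scan column *centre*."""
        return (np.asarray(x_index, dtype=float) + 0.5) * self.lateral_pitch_mm

    def y_mm_of_bscan(self, b_index) -> np.ndarray | float:
        """En-face y (mm) of a B-scan line."""
        return np.asarray(b_index, dtype=float) * self.bscan_spacing_mm

    @property
    def center_mm(self) -> tuple[float, float]:
        """En-face (x, y) of the geometric scan centre in mm."""
        return (
            self.scan_length_mm / 2.0,
            (self.n_bscans - 1) / 2.0 * self.bscan_spacing_mm,
        )

    def refined(self, factor: int) -> "ScanGeometry":
        """Return a geometry with ``factor``-times denser lateral sampling.

        The fast axis gains ``factor``× as many A-scans over the same length;
        the slow axis subdivides each inter-B-scan gap into ``factor`` steps,
        keeping the outermost lines in place. Axial sampling is unchanged.
        """
        if not (isinstance(factor, (int, np.integer)) and factor >= 1):
            raise ValueError("factor must be a positive integer")
        return dataclasses.replace(
            self,
            ascans_per_bscan=self.ascans_per_bscan * int(factor),
            n_bscans=(self.n_bscans - 1) * int(factor) + 1,
            bscan_spacing_um=self.bscan_spacing_um / factor,
        )

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanGeometry":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class LabelVolume:
    """A 3-D semantic label volume with its physical scan geometry.

    ``labels`` has shape ``(n_bscans, axial_px, ascans_per_bscan)`` and values
    restricted to the four :class:`Tissue` classes.
    """

    labels: np.ndarray
    geometry: ScanGeometry = field(default_factory=ScanGeometry)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        g = self.geometry
        expected = (g.n_bscans, g.axial_px, g.ascans_per_bscan)
        if self.labels.shape != expected:
            raise ValueError(
                f"label array shape {self.labels.shape} does not match geometry "
                f"(expected {expected})"
            )
        if self.labels.dtype != np.uint8:
            if not np.issubdtype(self.labels.dtype, np.integer):
                raise ValueError("labels must be integer-valued")
            self.labels = self.labels.astype(np.uint8)
        if self.labels.size and self.labels.max() >= N_TISSUES:
            bad = int(self.labels.max())
            raise ValueError(f"label value {bad} outside the 4-class set")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def retina_thickness_px(self) -> np.ndarray:
        """Retina-labelled voxel count per A-scan column, shape ``(b, x)``."""
        return (self.labels == Tissue.RETINA).sum(axis=1)
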
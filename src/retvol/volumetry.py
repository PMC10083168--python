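"""Regional retinal volumes from label volumes and nulla-centred masks.

Volumes are obtained by voxel counting: every A-scan column assigned to a
region contributes its retina-labelled voxels (the full cylinder through the
scan depth), each voxel weighted by the physical voxel volume
``lateral pitch × B-scan spacing × axial pitch``. The coarse slow-axis
sampling (221 µm between B-scans by default) means each B-scan column stands
for a 221 µm-wide slab; no interpolation between B-scans is performed.

Zones and quadrants are derived from the nine slices by composition —
Z1 = S1 (identical by definition), Z2 = S2+S3+S4+S5, Z3 = S6+S7+S8+S9,
Q_k = S1/4 + the sector's inner and outer slice — so the additivity
ΣS = ΣQ = ΣZ holds exactly on every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabelVolume, ScanGeometry
from .foveal_geometry import (
    SLICE_CODES,
    GridSpec,
    Nulla,
    RegionMasks,
    build_region_masks,
    extract_ilm,
    find_nulla,
)
from .segmentation import ValidationReport, validate_label_volume

__all__ = [
    "RegionVolumes",
    "ProcessedEye",
    "voxel_volume",
    "compute_region_volumes",
    "process_eye",
    "REGION_NAMES",
    "SLICE_NAMES",
]

SLICE_NAMES = tuple(f"S{i}" for i in range(1, 10))
ZONE_NAMES = ("Z1", "Z2", "Z3")
QUADRANT_NAMES = ("Q1", "Q2", "Q3", "Q4")
REGION_NAMES = ZONE_NAMES + QUADRANT_NAMES + SLICE_NAMES

_ATOL = 1e-9


@dataclass
class RegionVolumes:
    """The 16 regional measurements of one eye, in mm³.

    Z1 and S1 are the same physical volume by definition. Use
    :meth:`from_slices` to construct consistent instances from the nine
    slice volumes; the constructor enforces the composition invariants.
    """

    Z1: float
    Z2: float
    Z3: float
    Q1: float
    Q2: float
    Q3: float
    Q4: float
    S1: float
    S2: float
    S3: float
    S4: float
    S5: float
    S6: float
    S7: float
    S8: float
    S9: float
    clipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in REGION_NAMES:
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.Z1 != self.S1:
            raise ValueError("Z1 and S1 represent the same volume and must be equal")
        s = self.slices()
        checks = {
            "Z2 = S2+S3+S4+S5": self.Z2 - s[1:5].sum(),
            "Z3 = S6+S7+S8+S9": self.Z3 - s[5:9].sum(),
            "sum(Q) = sum(Z)": (self.Q1 + self.Q2 + self.Q3 + self.Q4)
            - (self.Z1 + self.Z2 + self.Z3),
        }
        for rule, err in checks.items():
            if abs(err) > _ATOL:
                raise ValueError(f"composition violated: {rule} (off by {err:.3e})")
        if not 0.0 <= self.clipped_fraction <= 1.0:
            raise ValueError("clipped_fraction must be in [0, 1]")

    def slices(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SLICE_NAMES])

    def as_dict(self) -> dict:
        d = {n: float(getattr(self, n)) for n in REGION_NAMES}
        d["clipped_fraction"] = float(self.clipped_fraction)
        return d

    @classmethod
    def from_slices(
        cls,
        slices,
        quadrant_slices: dict | None = None,
        clipped_fraction: float = 0.0,
    ) -> "RegionVolumes":
        """Build all 16 regions from S1–S9 via the composition rules.

        ``quadrant_slices`` maps Q1–Q4 to their (inner, outer) slice pair;
        defaults to the standard sector assignment of :class:`GridSpec`.
        """
        s = np.asarray(slices, dtype=float)
        if s.shape != (9,):
            raise ValueError(f"expected 9 slice volumes, got shape {s.shape}")
        quadrant_slices = quadrant_slices or GridSpec().quadrant_slices()
        by_name = dict(zip(SLICE_NAMES, s))
        kw = dict(by_name)
        kw["Z1"] = s[0]
        kw["Z2"] = s[1] + s[2] + s[3] + s[4]
        kw["Z3"] = s[5] + s[6] + s[7] + s[8]
        for q in QUADRANT_NAMES:
            inner, outer = quadrant_slices[q]
            kw[q] = s[0] / 4.0 + by_name[inner] + by_name[outer]
        return cls(clipped_fraction=clipped_fraction, **kw)


def voxel_volume(geometry: ScanGeometry) -> float:
    """Physical volume of one voxel in mm³.

    One A-scan pixel covers ``lateral pitch`` along the B-scan, the full
    ``B-scan spacing`` across the raster, and ``axial pitch`` in depth.
    """
    return (
        geometry.lateral_pitch_mm
        * geometry.bscan_spacing_mm
        * geometry.axial_pitch_mm
    )


def compute_region_volumes(
    volume: LabelVolume,
    masks: RegionMasks,
    geometry: ScanGeometry | None = None,
) -> RegionVolumes:
    """Count retina voxels per region and convert to mm³."""
    geometry = geometry or volume.geometry
    if geometry != volume.geometry or masks.geometry != volume.geometry:
        raise ValueError("masks, volume and geometry must share one ScanGeometry")
    thick = volume.retina_thickness_px()  # (b, x) retina voxel counts
    vv = voxel_volume(geometry)
    slices = np.array(
        [
            thick[masks.region == SLICE_CODES[name]].sum() * vv
            for name in SLICE_NAMES
        ]
    )
    return RegionVolumes.from_slices(
        slices,
        quadrant_slices=masks.grid.quadrant_slices(),
        clipped_fraction=masks.clipped_fraction,
    )


@dataclass
class ProcessedEye:
    """Full single-eye measurement: volumes plus the landmarks and QC."""

    volumes: RegionVolumes
    nulla: Nulla
    masks: RegionMasks
    validation: ValidationReport
    log: list = field(default_factory=list)


def process_eye(
    labels: LabelVolume,
    eye: str = "OD",
    grid: GridSpec | None = None,
    search_radius_mm: float = 1.5,
    smoothing_window: int = 5,
    z_threshold: float = 8.0,
) -> ProcessedEye:
    """Run the measurement chain on one segmented eye.

    ILM extraction → nulla detection → mask construction → voxel counting,
    with a label-map validation report attached. Pure and deterministic:
    the same input always yields the same output.
    """
    grid = grid or GridSpec()
    log: list[str] = []
    report = validate_label_volume(labels, z_threshold=z_threshold)
    log.append(f"validation: {report.summary()}")
    surface = extract_ilm(labels)
    nulla = find_nulla(
        surface,
        labels.geometry,
        search_radius_mm=search_radius_mm,
        smoothing_window=smoothing_window,
    )
    log.append(
        f"nulla at (b={nulla.b_index}, x={nulla.x_index}), "
        f"depth {nulla.depth_px:.0f} px, en-face ({nulla.x_mm:.3f}, {nulla.y_mm:.3f}) mm"
    )
    masks = build_region_masks(nulla, grid, labels.geometry, eye=eye)
    if masks.clipped_fraction > 0:
        log.append(f"ROI clipped by scan edge: {masks.clipped_fraction:.1%}")
    volumes = compute_region_volumes(labels, masks)
    log.append(f"Z1={volumes.Z1:.4f} Z2={volumes.Z2:.4f} Z3={volumes.Z3:.4f} mm³")
    return ProcessedEye(
        volumes=volumes, nulla=nulla, masks=masks, validation=report, log=log
    )
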
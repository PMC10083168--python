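"""Rule-based semantic segmentation of OCT B-scans and label-map validation.

Assigns one of four tissue labels (vitreous / retina / choroid / sclera) to
every pixel of a B-scan. The segmenter is deterministic: pixels are first
classified by nearest configured class intensity, then each A-scan column is
regularised to the anatomical top-to-bottom order vitreous → retina →
choroid → sclera by choosing the three boundary rows ``b1 ≤ b2 ≤ b3`` that
maximise agreement with the raw per-pixel classification (an exact O(rows)
dynamic program per column). Columns that end up with an empty retina run are
flagged rather than treated as fatal.

Label volumes from any external segmenter can be ingested directly as
:class:`~retvol.core.LabelVolume` and checked with
:func:`validate_label_volume`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabelVolume, ScanGeometry, Tissue

__all__ = [
    "IntensityModel",
    "SegmentedBScan",
    "ValidationReport",
    "segment_bscan",
    "segment_stack",
    "validate_label_volume",
]


@dataclass(frozen=True)
class IntensityModel:
    """Mean grey value rendered/expected for each tissue class (0–255).

    The defaults mimic typical spectral-domain OCT contrast: dark vitreous,
    bright neuroretina, intermediate choroid, bright sclera.
    """

    vitreous: float = 20.0
    retina: float = 160.0
    choroid: float = 100.0
    sclera: float = 200.0

    def means(self) -> np.ndarray:
        """Class means indexed by :class:`Tissue` value."""
        out = np.empty(4)
        out[Tissue.VITREOUS] = self.vitreous
        out[Tissue.RETINA] = self.retina
        out[Tissue.CHOROID] = self.choroid
        out[Tissue.SCLERA] = self.sclera
        if len(np.unique(out)) != 4:
            raise ValueError("class intensities must be pairwise distinct")
        return out


@dataclass
class SegmentedBScan:
    """Result of segmenting one B-scan."""

    labels: np.ndarray  # (axial_px, ascans) uint8
    #: columns whose regularised retina run is empty ("no retina" flag)
    no_retina_columns: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def _argcummax(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Running max and index of its first attainment along axis 0."""
    cm = np.maximum.accumulate(values, axis=0)
    idx = np.arange(values.shape[0])[:, None]
    is_new = np.empty(values.shape, dtype=bool)
    is_new[0] = True
    is_new[1:] = values[1:] > cm[:-1]
    arg = np.maximum.accumulate(np.where(is_new, idx, 0), axis=0)
    return cm, arg


def _ordered_boundaries(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal ordered class boundaries per column.

    ``raw`` is an (n_rows, n_cols) array of per-pixel nearest-mean labels.
    Returns ``(b1, b2, b3)`` with ``0 <= b1 <= b2 <= b3 <= n_rows`` per
    column: rows ``[0,b1)`` vitreous, ``[b1,b2)`` retina, ``[b2,b3)``
    choroid, ``[b3,n)`` sclera, maximising the number of rows that keep
    their raw label. Ties resolve to the topmost boundaries, which leaves
    noiseless input unchanged.
    """
    n = raw.shape[0]
    # cum[k][z] = count of raw==k in rows [0, z)
    cum = np.zeros((4, n + 1, raw.shape[1]), dtype=np.int32)
    for k in range(4):
        np.cumsum(raw == k, axis=0, out=cum[k, 1:])
    g1 = cum[Tissue.VITREOUS] - cum[Tissue.RETINA]
    g2 = cum[Tissue.RETINA] - cum[Tissue.CHOROID]
    g3 = cum[Tissue.CHOROID] - cum[Tissue.SCLERA]
    m1, a1 = _argcummax(g1)
    m2, a2 = _argcummax(m1 + g2)
    m3, a3 = _argcummax(m2 + g3)
    b3 = a3[-1]
    cols = np.arange(raw.shape[1])
    b2 = a2[b3, cols]
    b1 = a1[b2, cols]
    return b1, b2, b3


def segment_bscan(
    image: np.ndarray, model: IntensityModel | None = None
) -> SegmentedBScan:
    """Segment a single grayscale B-scan into the four tissue classes.

    Nearest-mean intensity classification (equivalent to thresholding at
    class-mean midpoints) followed by the ordered-boundary regularisation,
    so every column satisfies the anatomical ordering by construction.
    """
    model = model or IntensityModel()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    raw = np.argmin(np.abs(img[None, :, :] - model.means()[:, None, None]), axis=0)
    b1, b2, b3 = _ordered_boundaries(raw)
    z = np.arange(img.shape[0])[:, None]
    labels = (
        (z >= b1).astype(np.uint8) + (z >= b2) + (z >= b3)
    ).astype(np.uint8)
    return SegmentedBScan(labels=labels, no_retina_columns=np.flatnonzero(b1 == b2))


def segment_stack(
    images: np.ndarray,
    geometry: ScanGeometry,
    model: IntensityModel | None = None,
) -> tuple[LabelVolume, list[np.ndarray]]:
    """Segment a full B-scan stack into a :class:`LabelVolume`.

    Returns the label volume and, per B-scan, the flagged no-retina columns.
    """
    images = np.asarray(images)
    labels = np.empty(
        (geometry.n_bscans, geometry.axial_px, geometry.ascans_per_bscan),
        dtype=np.uint8,
    )
    flags: list[np.ndarray] = []
    for b in range(geometry.n_bscans):
        seg = segment_bscan(images[b], model)
        labels[b] = seg.labels
        flags.append(seg.no_retina_columns)
    return LabelVolume(labels=labels, geometry=geometry), flags


@dataclass
class ValidationReport:
    """Per-column quality findings on a label volume. Pure bookkeeping."""

    n_bscans: int
    n_columns: int
    #: (b, x) index pairs of columns whose label sequence is not in
    #: anatomical top-to-bottom order
    out_of_order: np.ndarray
    #: (b, x) index pairs of columns containing zero retina pixels
    zero_retina: np.ndarray
    #: (b, x) index pairs of retina-thickness z-score outliers
    thickness_outliers: np.ndarray
    z_threshold: float

    def counts_per_bscan(self, kind: str) -> np.ndarray:
        pairs = getattr(self, kind)
        out = np.zeros(self.n_bscans, dtype=int)
        if len(pairs):
            np.add.at(out, pairs[:, 0], 1)
        return out

    @property
    def ok(self) -> bool:
        return (
            len(self.out_of_order) == 0
            and len(self.zero_retina) == 0
            and len(self.thickness_outliers) == 0
        )

    def summary(self) -> dict:
        return {
            "out_of_order_columns": int(len(self.out_of_order)),
            "zero_retina_columns": int(len(self.zero_retina)),
            "thickness_outlier_columns": int(len(self.thickness_outliers)),
            "total_columns": self.n_bscans * self.n_columns,
        }


def validate_label_volume(
    volume: LabelVolume, z_threshold: float = 8.0
) -> ValidationReport:
    """Check a label volume for anatomical plausibility (pure function).

    A column is *out of order* if its label sequence is not non-decreasing in
    tissue class (each class must form one contiguous run in the anatomical
    order). Retina-thickness outliers are columns whose retina voxel count
    deviates from the volume-wide mean by more than ``z_threshold`` standard
    deviations (computed over columns that contain retina).
    """
    lab = volume.labels
    ooo = (np.diff(lab.astype(np.int16), axis=1) < 0).any(axis=1)
    thick = volume.retina_thickness_px()
    zero = thick == 0
    has = ~zero
    outlier = np.zeros_like(zero)
    if has.sum() >= 2:
        mu = thick[has].mean()
        sd = thick[has].std(ddof=1)
        if sd > 0:
            outlier[has] = np.abs(thick[has] - mu) / sd > z_threshold
    return ValidationReport(
        n_bscans=lab.shape[0],
        n_columns=lab.shape[2],
        out_of_order=np.argwhere(ooo),
        zero_retina=np.argwhere(zero),
        thickness_outliers=np.argwhere(outlier),
        z_threshold=z_threshold,
    )
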
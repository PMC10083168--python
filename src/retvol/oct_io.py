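"""Readers and writers for B-scan stacks, label volumes and cohort tables.

B-scan stacks mirror the device export: one grayscale BMP/PNG per B-scan
with zero-padded index naming plus a JSON scan-geometry sidecar. Label
volumes use the same layout with unsigned-byte class rasters. Cohort tables
are plain CSV with one row per eye: animal metadata plus the 16 regional
volumes in mm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import LabelVolume, N_TISSUES, ScanGeometry
from .volumetry import REGION_NAMES, SLICE_NAMES, RegionVolumes

__all__ = [
    "BScanStack",
    "EyeRecord",
    "CohortTable",
    "GEOMETRY_SIDECAR",
    "read_bscan_stack",
    "write_bscan_stack",
    "read_label_volume",
    "write_label_volume",
    "read_cohort_table",
    "write_cohort_table",
]

GEOMETRY_SIDECAR = "geometry.json"

_SEXES = {"male", "female"}
_EYES = {"OD", "OS"}
_METADATA_COLUMNS = ("animal_id", "eye", "sex", "origin", "age_months", "weight_kg")
CANONICAL_COLUMNS = _METADATA_COLUMNS + REGION_NAMES


@dataclass
class BScanStack:
    """An ordered stack of grayscale B-scan images with scan geometry."""

    images: np.ndarray  # (n_bscans, axial_px, ascans_per_bscan)
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        g = self.geometry
        expected = (g.n_bscans, g.axial_px, g.ascans_per_bscan)
        if self.images.shape != expected:
            raise ValueError(
                f"image stack shape {self.images.shape} does not match geometry "
                f"(expected {expected})"
            )


@dataclass
class EyeRecord:
    """One eye of one animal: identity, metadata and regional volumes."""

    animal_id: str
    eye: str
    sex: str
    origin: str
    volumes: RegionVolumes
    age_months: float | None = None
    weight_kg: float | None = None

    def __post_init__(self) -> None:
        if self.eye not in _EYES:
            raise ValueError(f"eye must be OD or OS, got {self.eye!r}")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be male or female, got {self.sex!r}")
        if self.origin not in ("Mauritius", "Asia", "unknown"):
            raise ValueError(f"unrecognised origin {self.origin!r}")


@dataclass
class CohortTable:
    """A collection of per-eye records; the unit of the reference database."""

    records: list = field(default_factory=list)
    provenance: str = ""
    #: (row_label, reason) pairs for rows rejected during ingestion
    rejected: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.animal_id, rec.eye)
            if key in seen:
                raise ValueError(f"duplicate (animal_id, eye) pair: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {
                "animal_id": rec.animal_id,
                "eye": rec.eye,
                "sex": rec.sex,
                "origin": rec.origin,
                "age_months": rec.age_months,
                "weight_kg": rec.weight_kg,
            }
            row.update({n: getattr(rec.volumes, n) for n in REGION_NAMES})
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def _stack_files(path: Path) -> list[Path]:
    exts = {".png", ".bmp"}
    return sorted(p for p in path.iterdir() if p.suffix.lower() in exts)


def _load_gray(path: Path) -> np.ndarray:
    try:
        img = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ValueError(f"unreadable image file: {path.name} ({exc})") from exc
    if img.ndim == 3:  # collapse identical colour channels
        img = img[..., 0]
    return np.asarray(img)


def read_bscan_stack(path: str | Path, geometry: ScanGeometry | None = None) -> BScanStack:
    """Load a directory of B-scan images in lexicographic (B-scan) order.

    If ``geometry`` is omitted it is read from the ``geometry.json``
    sidecar. Count or dimension mismatches raise, naming the offence.
    """
    path = Path(path)
    if geometry is None:
        sidecar = path / GEOMETRY_SIDECAR
        if not sidecar.exists():
            raise FileNotFoundError(f"no geometry given and no {sidecar}")
        geometry = ScanGeometry.from_json(sidecar)
    files = _stack_files(path)
    if len(files) != geometry.n_bscans:
        raise ValueError(
            f"expected {geometry.n_bscans} B-scan images in {path}, found {len(files)}"
        )
    expected = (geometry.axial_px, geometry.ascans_per_bscan)
    images = np.empty((geometry.n_bscans,) + expected, dtype=np.uint8)
    for i, f in enumerate(files):
        img = _load_gray(f)
        if img.shape != expected:
            raise ValueError(
                f"image {f.name} has shape {img.shape}, expected {expected}"
            )
        images[i] = img
    return BScanStack(images=images, geometry=geometry)


def write_bscan_stack(stack: BScanStack, path: str | Path, fmt: str = "png") -> Path:
    """Write one image per B-scan (zero-padded names) plus the sidecar."""
    if fmt not in ("png", "bmp"):
        raise ValueError("fmt must be 'png' or 'bmp'")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(stack.geometry.n_bscans - 1)))
    for i, img in enumerate(stack.images):
        iio.imwrite(path / f"bscan_{i:0{width}d}.{fmt}", np.asarray(img, np.uint8))
    stack.geometry.to_json(path / GEOMETRY_SIDECAR)
    return path


def write_label_volume(volume: LabelVolume, path: str | Path) -> Path:
    """Serialise a label volume as unsigned-byte PNG rasters + sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    width = max(3, len(str(volume.geometry.n_bscans - 1)))
    for i, sl in enumerate(volume.labels):
        iio.imwrite(path / f"labels_{i:0{width}d}.png", sl)
    volume.geometry.to_json(path / GEOMETRY_SIDECAR)
    return path


def read_label_volume(path: str | Path, geometry: ScanGeometry | None = None) -> LabelVolume:
    """Inverse of :func:`write_label_volume`; validates the 4-class range."""
    stack = read_bscan_stack(path, geometry)
    if stack.images.max(initial=0) >= N_TISSUES:
        raise ValueError(f"label rasters in {path} contain values outside the 4-class set")
    return LabelVolume(labels=stack.images, geometry=stack.geometry)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def _norm_eye(v) -> str | None:
    s = str(v).strip().upper()
    if s in _EYES:
        return s
    if s in ("RIGHT", "R"):
        return "OD"
    if s in ("LEFT", "L"):
        return "OS"
    return None


def _norm_sex(v) -> str | None:
    s = str(v).strip().lower()
    if s in ("m", "male"):
        return "male"
    if s in ("f", "female"):
        return "female"
    return None


def _norm_origin(v) -> str:
    s = str(v).strip().lower()
    if s in ("mauritius", "mauritian", "m"):
        return "Mauritius"
    if s in ("asia", "asian", "a"):
        return "Asia"
    return "unknown"


def write_cohort_table(cohort: CohortTable, path: str | Path) -> Path:
    """Write the canonical cohort CSV (volumes in mm³, 10 decimal places)."""
    path = Path(path)
    df = cohort.to_dataframe()
    for col in REGION_NAMES:
        df[col] = df[col].map(lambda v: f"{v:.10f}")
    df.to_csv(path, index=False)
    return path


def read_cohort_table(
    path: str | Path,
    column_map: dict | None = None,
    consistency_tol: float = 1e-6,
) -> CohortTable:
    """Read a per-eye volume table into the canonical cohort form.

    ``column_map`` maps the file's headers to canonical field names
    (``animal_id, eye, sex, origin, age_months, weight_kg, Z1..Z3, Q1..Q4,
    S1..S9``) for foreign schemas; canonical headers need no map. Slices may
    be given as S2–S9 with Z1 standing in for S1. Zones/quadrants are always
    reconstructed from the slices by the composition rule; if the file also
    carries them they are cross-checked to ``consistency_tol`` mm³.

    Rows with unparseable or inconsistent volumes are rejected with
    row-level diagnostics (kept in ``CohortTable.rejected``), never silently
    dropped. Origins outside {Mauritius, Asia} map to "unknown".
    """
    path = Path(path)
    df = pd.read_csv(path)
    if column_map:
        unknown = set(column_map) - set(df.columns)
        if unknown:
            raise ValueError(f"column_map refers to absent headers: {sorted(unknown)}")
        df = df.rename(columns=column_map)
    mandatory = ["animal_id", "eye", "sex", "origin"]
    have_slices = [c for c in SLICE_NAMES if c in df.columns]
    if "S1" not in df.columns and "Z1" in df.columns:
        df = df.assign(S1=df["Z1"])
        have_slices = [c for c in SLICE_NAMES if c in df.columns]
    missing = [c for c in mandatory if c not in df.columns]
    missing += [c for c in SLICE_NAMES if c not in have_slices]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")

    from .foveal_geometry import GridSpec

    records: list[EyeRecord] = []
    rejected: list[tuple] = []
    quad_slices = GridSpec().quadrant_slices()
    for idx, row in df.iterrows():
        eye = _norm_eye(row["eye"])
        sex = _norm_sex(row["sex"])
        if eye is None or sex is None:
            rejected.append((idx, f"unparseable eye/sex: {row['eye']!r}/{row['sex']!r}"))
            continue
        try:
            s = np.array([float(row[c]) for c in SLICE_NAMES])
        except (TypeError, ValueError):
            rejected.append((idx, "unparseable slice volume"))
            continue
        if not np.isfinite(s).all() or (s < 0).any():
            rejected.append((idx, "non-finite or negative slice volume"))
            continue
        clipped = row.get("clipped_fraction", 0.0)
        vols = RegionVolumes.from_slices(
            s,
            quadrant_slices=quad_slices,
            clipped_fraction=0.0 if pd.isna(clipped) else float(clipped),
        )
        bad = None
        for name in ("Z2", "Z3", "Q1", "Q2", "Q3", "Q4"):
            if name in row.index and pd.notna(row[name]):
                err = abs(float(row[name]) - getattr(vols, name))
                if err > consistency_tol:
                    bad = f"{name} inconsistent with slices by {err:.2e} mm³"
                    break
        if bad:
            rejected.append((idx, bad))
            continue
        age = row.get("age_months")
        weight = row.get("weight_kg")
        records.append(
            EyeRecord(
                animal_id=str(row["animal_id"]),
                eye=eye,
                sex=sex,
                origin=_norm_origin(row["origin"]),
                age_months=None if pd.isna(age) else float(age),
                weight_kg=None if pd.isna(weight) else float(weight),
                volumes=vols,
            )
        )
    return CohortTable(records=records, provenance=str(path), rejected=rejected)
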
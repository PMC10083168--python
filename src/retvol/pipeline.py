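"""End-to-end orchestration: image path and statistics path.

The image path turns B-scan stacks (or pre-segmented label volumes) into a
per-eye cohort CSV: segment → ILM/nulla → nulla-centred masks → voxel
volumetry. The statistics path turns a cohort CSV into the full
reference-database report. Every under-specified analysis choice (nulla
smoothing window, interaction-drop levels, eye pooling) lives in one
declarative config so a run is reproducible from the config alone.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import LabelVolume, ScanGeometry
from .foveal_geometry import GridSpec
from .oct_io import (
    BScanStack,
    CohortTable,
    EyeRecord,
    read_bscan_stack,
    read_label_volume,
    read_cohort_table,
    write_cohort_table,
)
from .refstats import (
    ANOVA_INTERACTION_DROP,
    MANOVA_INTERACTION_DROP,
    ReportBundle,
    reproduce_report,
)
from .segmentation import IntensityModel, segment_stack
from .volumetry import process_eye

__all__ = ["PipelineConfig", "EyeInput", "PipelineResult", "run_image_pipeline", "run_reference_stats"]

log = logging.getLogger("retvol")


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration of both pipeline paths."""

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    grid: GridSpec = field(default_factory=GridSpec)
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    search_radius_mm: float = 1.5
    smoothing_window: int = 5
    z_threshold: float = 8.0
    manova_interaction_drop: float = MANOVA_INTERACTION_DROP
    anova_interaction_drop: float = ANOVA_INTERACTION_DROP
    pool_eyes_for_correlation: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"]["slice_naming"] = {
            f"{ring}_{sector}": name
            for (ring, sector), name in self.grid.slice_naming.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "geometry" in d:
            d["geometry"] = ScanGeometry(**d["geometry"])
        if "grid" in d:
            g = dict(d["grid"])
            if "slice_naming" in g:
                g["slice_naming"] = {
                    tuple(k.split("_", 1)): v for k, v in g["slice_naming"].items()
                }
            if "ring_diameters_mm" in g:
                g["ring_diameters_mm"] = tuple(g["ring_diameters_mm"])
            d["grid"] = GridSpec(**g)
        if "intensity_model" in d:
            d["intensity_model"] = IntensityModel(**d["intensity_model"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class EyeInput:
    """One eye to process: an image stack or label volume plus metadata."""

    source: str | Path | LabelVolume | BScanStack
    kind: str  # "stack_dir", "labels_dir", "stack", "labels"
    eye: str = "OD"
    animal_id: str = "unknown"
    sex: str = "male"
    origin: str = "unknown"
    age_months: float | None = None
    weight_kg: float | None = None


@dataclass
class PipelineResult:
    cohort: CohortTable
    failures: list  # (animal_id, eye, error message)
    logs: dict  # (animal_id, eye) -> stage log


def _load_labels(inp: EyeInput, config: PipelineConfig) -> LabelVolume:
    if inp.kind == "labels":
        return inp.source
    if inp.kind == "labels_dir":
        return read_label_volume(inp.source)
    if inp.kind == "stack":
        stack = inp.source
    elif inp.kind == "stack_dir":
        stack = read_bscan_stack(inp.source)
    else:
        raise ValueError(f"unknown input kind {inp.kind!r}")
    labels, _ = segment_stack(stack.images, stack.geometry, config.intensity_model)
    return labels


def run_image_pipeline(
    config: PipelineConfig,
    inputs: list,
    out_csv: str | Path | None = None,
) -> PipelineResult:
    """Measure every input eye; failures are isolated per eye.

    Returns the cohort of successful eyes plus a failure manifest; one
    corrupt input never aborts the batch. Deterministic for fixed inputs
    and config.
    """
    if not inputs:
        raise ValueError("need at least one input eye")
    records, failures, logs = [], [], {}
    for inp in inputs:
        t0 = time.perf_counter()
        try:
            labels = _load_labels(inp, config)
            result = process_eye(
                labels,
                eye=inp.eye,
                grid=config.grid,
                search_radius_mm=config.search_radius_mm,
                smoothing_window=config.smoothing_window,
                z_threshold=config.z_threshold,
            )
            records.append(
                EyeRecord(
                    animal_id=inp.animal_id,
                    eye=inp.eye,
                    sex=inp.sex,
                    origin=inp.origin,
                    age_months=inp.age_months,
                    weight_kg=inp.weight_kg,
                    volumes=result.volumes,
                )
            )
            logs[(inp.animal_id, inp.eye)] = result.log
            log.info(
                "%s/%s done in %.2fs", inp.animal_id, inp.eye, time.perf_counter() - t0
            )
        except Exception as exc:
            failures.append((inp.animal_id, inp.eye, str(exc)))
            log.warning("%s/%s failed: %s", inp.animal_id, inp.eye, exc)
    cohort = CohortTable(records=records, provenance="run_image_pipeline")
    if out_csv is not None:
        write_cohort_table(cohort, out_csv)
    return PipelineResult(cohort=cohort, failures=failures, logs=logs)


def run_reference_stats(
    config: PipelineConfig,
    cohort_path: str | Path,
    outdir: str | Path | None = None,
    make_figures: bool = False,
) -> ReportBundle:
    """Read a cohort CSV and emit the full reference-database report."""
    cohort = read_cohort_table(cohort_path)
    if len(cohort) == 0:
        raise ValueError(f"cohort {cohort_path} contains no usable records")
    return reproduce_report(cohort, outdir=outdir, make_figures=make_figures)
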
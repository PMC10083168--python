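"""Synthetic OCT phantoms and simulated reference cohorts.

Two generators make the whole pipeline testable without scanner data:

* a **geometric phantom** — a 3-D label volume with a parametric foveal pit
  (a single Gaussian dip of the ILM with a unique, controllable deepest
  point) on top of a radially symmetric retinal thickness profile (linear
  fovea → parafovea → periphery interpolation at radii 0 / 1.0 / 2.5 mm),
  rendered into noisy B-scan intensity stacks, with the analytic ground
  truth (ILM surface, pit centre, regional volumes) returned alongside;

* a **cohort simulator** — per-eye 9-slice volume vectors drawn from a
  multivariate normal with configurable means, coefficients of variation
  and between-slice correlation, plus additive sex and origin effects,
  operating directly at volume level (the statistics stages need the
  distributional structure, not pixels).

Default calibration reproduces the reference cohort: central-disc (Z1)
volume ≈ 0.205 mm³ with zone 2 ≈ 0.768 mm³ and zone 3 ≈ 1.375 mm³, slice
CVs of 4–8%, a mean between-slice correlation of about 0.5, and sex/origin
offsets concentrated on the paracentral (S2, S4, S7, S9) and central
(S1, S4, S5) slices respectively.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import LabelVolume, ScanGeometry
from .foveal_geometry import GridSpec
from .oct_io import BScanStack, CohortTable, EyeRecord
from .segmentation import IntensityModel
from .volumetry import RegionVolumes

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "EffectDesign",
    "synthesize_label_volume",
    "render_bscan_images",
    "true_region_volumes",
    "simulate_cohort",
    "thickness_profile_um",
]

#: radii (mm) anchoring the piecewise-linear thickness profile
_PROFILE_RADII_MM = (0.0, 1.0, 2.5)


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the geometric foveal-pit phantom.

    The ILM depth (in axial pixels, increasing posteriorly) is
    ``z_base + pit_depth · exp(−r² / (2 σ²))`` with ``r`` the en-face
    distance from the pit centre; the retina extends from the ILM down to
    ILM + thickness(r), the choroid and sclera follow. ``z_base`` is
    anchored so that the retina/choroid boundary at the pit centre sits at
    ``outer_boundary_depth_px``.

    Default thicknesses (212 / 359 / 311 µm at the fovea / 1.0 mm / 2.5 mm)
    are calibrated so the analytic zone volumes match the reference cohort
    means (0.205 / 0.768 / 1.375 mm³). A flat retina (no pit) is expressed
    with ``pit_depth_um = 0`` and equal thicknesses via :meth:`flat`.
    """

    pit_depth_um: float = 120.0
    pit_sigma_um: float = 300.0
    thickness_fovea_um: float = 212.0
    thickness_para_um: float = 359.0
    thickness_peripheral_um: float = 311.0
    outer_boundary_depth_px: int = 330
    choroid_thickness_px: int = 60
    sclera_thickness_px: int = 40
    pit_center_offset_mm: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("thickness_fovea_um", "thickness_para_um", "thickness_peripheral_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.thickness_fovea_um > self.thickness_para_um:
            raise ValueError(
                "thickness_fovea_um must not exceed thickness_para_um "
                "(the foveal depression cannot invert)"
            )
        if self.pit_depth_um < 0:
            raise ValueError("pit_depth_um must be >= 0")
        if not self.pit_sigma_um > 0:
            raise ValueError("pit_sigma_um must be > 0")
        for name in ("choroid_thickness_px", "sclera_thickness_px"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def flat(cls, thickness_um: float, **kwargs) -> "PhantomParams":
        """A pit-free phantom with spatially constant retinal thickness."""
        return cls(
            pit_depth_um=0.0,
            thickness_fovea_um=thickness_um,
            thickness_para_um=thickness_um,
            thickness_peripheral_um=thickness_um,
            **kwargs,
        )

    def replace(self, **kwargs) -> "PhantomParams":
        return dataclasses.replace(self, **kwargs)


def thickness_profile_um(r_mm, params: PhantomParams) -> np.ndarray:
    """Retinal thickness (µm) at en-face radius ``r_mm`` from the pit centre."""
    return np.interp(
        np.asarray(r_mm, dtype=float),
        _PROFILE_RADII_MM,
        [
            params.thickness_fovea_um,
            params.thickness_para_um,
            params.thickness_peripheral_um,
        ],
    )


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a synthesized phantom volume."""

    ilm_depth_px: np.ndarray  # continuous ILM depth per column, (b, x)
    pit_center_b: float  # fractional B-scan index of the pit centre
    pit_center_x: float  # fractional A-scan index of the pit centre
    pit_center_x_mm: float
    pit_center_y_mm: float
    params: PhantomParams
    geometry: ScanGeometry


def _pit_center(geometry: ScanGeometry, params: PhantomParams):
    cx, cy = geometry.center_mm
    x_mm = cx + params.pit_center_offset_mm[0]
    y_mm = cy + params.pit_center_offset_mm[1]
    # inverse of the column-centre / line-position conventions
    x_idx = x_mm / geometry.lateral_pitch_mm - 0.5
    b_idx = y_mm / geometry.bscan_spacing_mm
    return x_mm, y_mm, x_idx, b_idx


def _layer_boundaries_px(geometry: ScanGeometry, params: PhantomParams):
    """Continuous (ILM, retina-bottom) depth maps in axial pixels."""
    x_c, y_c, _, _ = _pit_center(geometry, params)
    x_mm = geometry.x_mm_of_column(np.arange(geometry.ascans_per_bscan))
    y_mm = geometry.y_mm_of_bscan(np.arange(geometry.n_bscans))
    r = np.hypot(x_mm[None, :] - x_c, y_mm[:, None] - y_c)
    px_per_um = 1.0 / (geometry.axial_pitch_mm * 1000.0)
    pit_px = params.pit_depth_um * px_per_um
    t_px = thickness_profile_um(r, params) * px_per_um
    sigma_mm = params.pit_sigma_um / 1000.0
    z_base = (
        params.outer_boundary_depth_px
        - params.thickness_fovea_um * px_per_um
        - pit_px
    )
    ilm = z_base + pit_px * np.exp(-(r**2) / (2.0 * sigma_mm**2))
    return ilm, ilm + t_px


def synthesize_label_volume(
    geometry: ScanGeometry | None = None,
    params: PhantomParams | None = None,
) -> tuple[LabelVolume, PhantomTruth]:
    """Generate a 4-class label volume with a known foveal pit.

    Layer boundaries are computed continuously per A-scan column and
    discretised to the voxel grid by rounding to the nearest row, so every
    column carries the anatomical vitreous → retina → choroid → sclera
    order. Returns the volume together with the exact ground truth.
    """
    geometry = geometry or ScanGeometry()
    params = params or PhantomParams()
    ilm, bottom = _layer_boundaries_px(geometry, params)
    b1 = np.rint(ilm).astype(np.int32)
    b2 = np.rint(bottom).astype(np.int32)
    b3 = b2 + params.choroid_thickness_px
    if b1.min() < 1:
        raise ValueError(
            "ILM reaches the top of the scan: decrease pit_depth_um or "
            "increase outer_boundary_depth_px"
        )
    deepest = int(b3.max()) + params.sclera_thickness_px
    if deepest > geometry.axial_px:
        raise ValueError(
            f"layers exceed the axial extent ({deepest} px > {geometry.axial_px} px): "
            "reduce outer_boundary_depth_px, thickness_para_um, "
            "choroid_thickness_px or sclera_thickness_px"
        )
    z = np.arange(geometry.axial_px)[None, :, None]
    labels = (
        (z >= b1[:, None, :]).astype(np.uint8)
        + (z >= b2[:, None, :])
        + (z >= b3[:, None, :])
    ).astype(np.uint8)
    x_c, y_c, x_idx, b_idx = _pit_center(geometry, params)
    truth = PhantomTruth(
        ilm_depth_px=ilm,
        pit_center_b=b_idx,
        pit_center_x=x_idx,
        pit_center_x_mm=x_c,
        pit_center_y_mm=y_c,
        params=params,
        geometry=geometry,
    )
    return LabelVolume(labels=labels, geometry=geometry), truth


def render_bscan_images(
    volume: LabelVolume,
    params: PhantomParams,
    model: IntensityModel | None = None,
) -> BScanStack:
    """Render a label volume into noisy grayscale B-scans.

    Each tissue class is drawn at its configured mean intensity with
    additive Gaussian noise of scale ``params.noise_sd``, clipped to the
    8-bit range. Deterministic for a given ``params.seed``.
    """
    model = model or IntensityModel()
    rng = np.random.default_rng(params.seed)
    img = model.means()[volume.labels]
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return BScanStack(images=img, geometry=volume.geometry)


def true_region_volumes(
    geometry: ScanGeometry | None = None,
    params: PhantomParams | None = None,
    grid: GridSpec | None = None,
) -> RegionVolumes:
    """Analytic regional volumes of the phantom (independent oracle).

    Integrates the continuous thickness profile over the ideal circular
    region footprints centred on the pit (volume of an annulus
    ``2π ∫ t(r) r dr``; each sector slice is a quarter of its annulus by
    radial symmetry). The radial quadrature step is the fast-axis pixel
    pitch divided by 20, far finer than the voxel grid, and shares no code
    with the voxel-counting path.
    """
    geometry = geometry or ScanGeometry()
    params = params or PhantomParams()
    grid = grid or GridSpec()
    r1, r2, r3 = grid.ring_radii_mm
    step = geometry.lateral_pitch_mm / 20.0

    def band(lo: float, hi: float) -> float:
        r = np.linspace(lo, hi, max(int(np.ceil((hi - lo) / step)), 2) + 1)
        t_mm = thickness_profile_um(r, params) / 1000.0
        return 2.0 * np.pi * float(np.trapezoid(t_mm * r, r))

    s1 = band(0.0, r1)
    inner = band(r1, r2) / 4.0
    outer = band(r2, r3) / 4.0
    slices = np.array([s1] + [inner] * 4 + [outer] * 4)
    return RegionVolumes.from_slices(slices, quadrant_slices=grid.quadrant_slices())


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: reference per-slice marginal means (mm³), right-eye "All" column
DEFAULT_SLICE_MEANS_MM3 = (
    0.205, 0.191, 0.199, 0.188, 0.191, 0.351, 0.347, 0.352, 0.325
)
#: reference per-slice coefficients of variation, right-eye "All" column
DEFAULT_SLICE_CV = (
    0.081, 0.061, 0.048, 0.063, 0.045, 0.054, 0.039, 0.055, 0.038
)
#: additive female-minus-male offsets (mm³), from the right-eye subgroup
#: means averaged over origin; largest on the paracentral slices S2/S4/S7/S9
DEFAULT_SEX_EFFECT_MM3 = (
    -0.0035, -0.0105, -0.002, -0.012, -0.0015, 0.0045, -0.0085, 0.003, -0.009
)
#: additive Mauritius-minus-Asia offsets (mm³), averaged over sex; largest
#: on the central slice S1 (plus S4/S5)
DEFAULT_ORIGIN_EFFECT_MM3 = (
    -0.0105, -0.0035, -0.001, -0.005, -0.0035, 0.0005, -0.0005, 0.0, -0.003
)


def uniform_correlation(rho: float = 0.5, k: int = 9) -> np.ndarray:
    """A k×k correlation matrix with constant off-diagonal ``rho``."""
    return np.full((k, k), rho) + (1.0 - rho) * np.eye(k)


@dataclass(frozen=True)
class EffectDesign:
    """Design of a simulated reference cohort.

    ``slice_means_mm3`` and ``slice_cv`` are *marginal* population targets:
    the simulator back-computes the model intercept and the within-group
    variance from the configured group proportions and effects, so the
    simulated cohort's marginal means and CVs reproduce them.
    Fellow eyes of one animal share a latent intercept with intraclass
    correlation ``intra_animal_corr``; downstream analyses treat eyes as
    independent observations (matching the reference analysis), so the
    coupling is generative only.
    """

    n_animals: int = 187
    p_female: float = 147.0 / 374.0
    p_mauritius: float = 199.0 / 358.0
    slice_means_mm3: tuple = DEFAULT_SLICE_MEANS_MM3
    slice_cv: tuple = DEFAULT_SLICE_CV
    between_slice_corr: np.ndarray | None = None  # default: uniform 0.5
    sex_effect_mm3: tuple = DEFAULT_SEX_EFFECT_MM3
    origin_effect_mm3: tuple = DEFAULT_ORIGIN_EFFECT_MM3
    eyes_per_animal: int = 2
    intra_animal_corr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        for name in ("p_female", "p_mauritius"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.eyes_per_animal not in (1, 2):
            raise ValueError("eyes_per_animal must be 1 or 2")
        if not 0.0 <= self.intra_animal_corr <= 1.0:
            raise ValueError("intra_animal_corr must be in [0, 1]")
        for name in ("slice_means_mm3", "slice_cv", "sex_effect_mm3", "origin_effect_mm3"):
            if len(getattr(self, name)) != 9:
                raise ValueError(f"{name} must have 9 entries")

    def correlation(self) -> np.ndarray:
        R = (
            uniform_correlation()
            if self.between_slice_corr is None
            else np.asarray(self.between_slice_corr, dtype=float)
        )
        if R.shape != (9, 9):
            raise ValueError("between_slice_corr must be 9×9")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("correlation matrix is not positive semi-definite")
        return R


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """A factor L with L Lᵀ = cov, valid for singular PSD matrices."""
    w, v = np.linalg.eigh(cov)
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_cohort(design: EffectDesign | None = None) -> CohortTable:
    """Simulate a per-eye reference cohort with known group effects.

    One record per eye carries sex, origin, eye side, animal id and a
    9-slice volume vector; zones and quadrants are derived by the grid's
    composition rules (Z1 ≡ S1). Deterministic for a given seed.
    """
    design = design or EffectDesign()
    rng = np.random.default_rng(design.seed)
    R = design.correlation()
    means = np.asarray(design.slice_means_mm3, dtype=float)
    sex_eff = np.asarray(design.sex_effect_mm3, dtype=float)
    org_eff = np.asarray(design.origin_effect_mm3, dtype=float)
    # means and CVs are *marginal* targets: back out the model intercept and
    # the within-group variance left after the group effects' contribution
    intercept = means - design.p_female * sex_eff - design.p_mauritius * org_eff
    var_between = (
        design.p_female * (1.0 - design.p_female) * sex_eff**2
        + design.p_mauritius * (1.0 - design.p_mauritius) * org_eff**2
    )
    var_within = np.clip(
        (np.asarray(design.slice_cv, dtype=float) * means) ** 2 - var_between,
        0.0,
        None,
    )
    sd = np.sqrt(var_within)
    L = _psd_factor((sd[:, None] * R) * sd[None, :])

    icc = design.intra_animal_corr
    w_animal, w_eye = np.sqrt(icc), np.sqrt(1.0 - icc)
    records = []
    width = len(str(design.n_animals))
    for a in range(design.n_animals):
        female = rng.random() < design.p_female
        mauritius = rng.random() < design.p_mauritius
        u_animal = rng.standard_normal(9)
        if design.eyes_per_animal == 2:
            eyes = ("OD", "OS")
        else:
            eyes = ("OD" if rng.random() < 0.5 else "OS",)
        base = (
            intercept
            + (sex_eff if female else 0.0)
            + (org_eff if mauritius else 0.0)
        )
        for eye in eyes:
            dev = L @ (w_animal * u_animal + w_eye * rng.standard_normal(9))
            s = base + dev
            records.append(
                EyeRecord(
                    animal_id=f"A{a + 1:0{width}d}",
                    eye=eye,
                    sex="female" if female else "male",
                    origin="Mauritius" if mauritius else "Asia",
                    volumes=RegionVolumes.from_slices(np.clip(s, 0.0, None)),
                )
            )
    return CohortTable(
        records=records,
        provenance=f"simulate_cohort(seed={design.seed}, n_animals={design.n_animals})",
    )
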
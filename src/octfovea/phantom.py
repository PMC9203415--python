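"""Seeded synthetic SD-OCT segmentation phantoms with known fovea.

The phantom emulates the anatomy the detector exploits: a foveal pit
expressed as local GCL-IPL thinning inside a parafoveal thick ring, an
outer retina that thickens toward the fovea, RORA lesions that erase
outer-retina/RPE labels (optionally distorting the inner layers, the
documented failure mode of the method), drusen-like RPE bumps, and
shifted-b-scan acquisition artifacts that truncate the top of the
retina.  All randomness flows from a single integer seed through
independent per-component streams, so adding an outer-retina lesion
never perturbs the inner-layer noise draws.

Layer stack, top to bottom: RNFL, GCL, IPL, INL, OPL, ONL, PR
(photoreceptor inner/outer segments), RPE.  The inner surface is kept
flat; only thickness profiles matter for en face projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .data import ScanGeometry, SegmentationVolume

__all__ = [
    "PitSpec",
    "RoraSpec",
    "DrusenSpec",
    "ArtifactSpec",
    "PhantomSpec",
    "PhantomTruth",
    "CohortJitter",
    "LABEL_SCHEME",
    "generate",
    "sample_cohort_specs",
    "generate_cohort",
    "cohort_rora_summary",
    "paper_like_base",
    "paper_like_jitter",
    "make_degenerate",
    "scan_density_of",
]

LABEL_SCHEME = {
    "RNFL": 1,
    "GCL": 2,
    "IPL": 3,
    "INL": 4,
    "OPL": 5,
    "ONL": 6,
    "PR": 7,
    "RPE": 8,
}

# fixed layer thicknesses (mm); GCL+IPL and PR carry the spatial structure
_RNFL_MM = 0.015
_INL_MM = 0.035
_OPL_MM = 0.030
_ONL_MM = 0.080
_OUTER_PR_FRACTION = 0.6          # split of outer_retina_thickness into PR vs RPE
_FOVEAL_OUTER_BUMP_MM = 0.030     # outer-retina thickening toward the fovea
_FOVEAL_OUTER_BUMP_SIGMA_MM = 0.30
_RORA_ONL_REMNANT = 0.3           # surviving ONL fraction inside a lesion
_ATROPHY_FIELD_CORR_MM = 0.4      # correlation length of lesion severity
_TOP_MARGIN_MM = 0.08             # vitreous gap above the ILM


@dataclass(frozen=True)
class PitSpec:
    """Foveal pit expressed in GCL-IPL thickness.

    The default pit sigma of 0.175 mm makes 2 * sigma equal the ~0.35 mm
    foveola width.  ``profile`` selects a Gaussian pit or a cosine bowl
    of radius 2 * pit_sigma; the latter exists so recovery tests do not
    rely on the pit having exactly the detector's template shape.
    """

    parafoveal_gclipl_thickness: float = 0.09
    foveal_gclipl_thickness: float = 0.0
    pit_sigma: float = 0.175
    profile: str = "gaussian"

    def __post_init__(self) -> None:
        if self.pit_sigma <= 0:
            raise ValueError("pit_sigma must be > 0")
        if self.parafoveal_gclipl_thickness < 0 or self.foveal_gclipl_thickness < 0:
            raise ValueError("thicknesses must be >= 0")
        if self.profile not in ("gaussian", "cosine"):
            raise ValueError("profile must be 'gaussian' or 'cosine'")


@dataclass(frozen=True)
class RoraSpec:
    """A circular RORA lesion.

    ``inner_layer_damage_fraction`` > 0 additionally distorts the
    GCL-IPL thickness inside the lesion, blending the pit toward an
    irregular field — the advanced-degeneration scenario in which the
    en face projection loses its pit pattern.
    """

    center_mm: tuple
    radius_mm: float
    inner_layer_damage_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if not 0.0 <= self.inner_layer_damage_fraction <= 1.0:
            raise ValueError("inner_layer_damage_fraction must be in [0, 1]")

    @classmethod
    def from_area(
        cls, center_mm: tuple, area_mm2: float, inner_layer_damage_fraction: float = 0.0
    ) -> "RoraSpec":
        return cls(
            center_mm=center_mm,
            radius_mm=math.sqrt(area_mm2 / math.pi),
            inner_layer_damage_fraction=inner_layer_damage_fraction,
        )

    @property
    def area_mm2(self) -> float:
        return math.pi * self.radius_mm**2


@dataclass(frozen=True)
class DrusenSpec:
    """A Gaussian RPE bump (sub-RPE deposit)."""

    center_mm: tuple
    sigma_mm: float = 0.15
    height_mm: float = 0.05


@dataclass(frozen=True)
class ArtifactSpec:
    """Shifted b-scan truncating the top ``cut_fraction`` of the retina."""

    bscan_index: int
    cut_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cut_fraction <= 1.0:
            raise ValueError("cut_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Complete configuration of one synthetic eye."""

    geometry: ScanGeometry
    fovea_mm: tuple = (3.0, 3.0)
    pit: PitSpec = field(default_factory=PitSpec)
    outer_retina_thickness: float = 0.13
    rora: Optional[RoraSpec] = None
    drusen: tuple = ()
    artifact: Optional[ArtifactSpec] = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_retina_thickness < 0:
            raise ValueError("outer_retina_thickness must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "drusen", tuple(self.drusen))


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom.

    ``rora_location`` is 'foveal' exactly when the lesion mask covers
    the fovea's native grid cell, 'extrafoveal' when a lesion exists
    elsewhere, and 'none' otherwise.
    """

    fovea_mm: tuple
    rora_mask: np.ndarray  # bool, native [b-scan, a-scan] grid
    rora_location: str


def _native_grids(geom: ScanGeometry) -> tuple:
    x = np.arange(geom.n_ascans) * geom.ascan_spacing
    y = np.arange(geom.n_bscans) * geom.bscan_spacing
    return np.meshgrid(x, y)  # each [n_bscans, n_ascans]


def _smooth_field(rng: np.random.Generator, geom: ScanGeometry, corr_mm: float) -> np.ndarray:
    """Zero-mean, unit-sd spatially correlated noise on the native grid."""
    white = rng.standard_normal((geom.n_bscans, geom.n_ascans))
    sig_y = corr_mm / geom.bscan_spacing
    sig_x = corr_mm / geom.ascan_spacing
    smooth = ndimage.gaussian_filter(white, sigma=(sig_y, sig_x), mode="reflect")
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros_like(smooth)
    return (smooth - smooth.mean()) / sd


def _pit_thickness(spec: PhantomSpec, d2: np.ndarray) -> np.ndarray:
    pit = spec.pit
    lo, hi = pit.foveal_gclipl_thickness, pit.parafoveal_gclipl_thickness
    if pit.profile == "gaussian":
        return hi - (hi - lo) * np.exp(-d2 / (2.0 * pit.pit_sigma**2))
    # cosine bowl of radius 2 * pit_sigma
    radius = 2.0 * pit.pit_sigma
    d = np.sqrt(d2)
    theta = np.pi * np.minimum(d, radius) / radius
    return lo + (hi - lo) * 0.5 * (1.0 - np.cos(theta))


def generate(spec: PhantomSpec, min_border_mm: float = 0.5) -> tuple:
    """Generate a (SegmentationVolume, PhantomTruth) pair.

    Same spec (including seed) -> bit-identical volume.  Column
    thicknesses are perturbed by Gaussian noise before discretization to
    axial voxel counts; layers are stacked top-down from a flat inner
    surface.
    """
    g = spec.geometry
    fx, fy = spec.fovea_mm
    if not (
        min_border_mm <= fx <= g.extent_x - min_border_mm
        and min_border_mm <= fy <= g.extent_y - min_border_mm
    ):
        raise ValueError(
            f"fovea {spec.fovea_mm} closer than {min_border_mm} mm to a scan border"
        )
    if spec.rora is not None:
        cx, cy = spec.rora.center_mm
        if not (0 <= cx <= g.extent_x and 0 <= cy <= g.extent_y):
            raise ValueError(f"RORA centre {spec.rora.center_mm} outside scan extent")

    X, Y = _native_grids(g)
    d2 = (X - fx) ** 2 + (Y - fy) ** 2

    # independent random streams per component: presence/absence of one
    # component never changes another component's draws
    ss_inner, ss_outer, ss_atrophy, ss_damage = np.random.SeedSequence(spec.seed).spawn(4)
    rng_inner = np.random.default_rng(ss_inner)
    rng_outer = np.random.default_rng(ss_outer)

    gclipl = _pit_thickness(spec, d2)
    if spec.noise_sd > 0:
        gclipl = gclipl + rng_inner.normal(0.0, spec.noise_sd, size=gclipl.shape)

    rora_mask = np.zeros(gclipl.shape, dtype=bool)
    if spec.rora is not None:
        cx, cy = spec.rora.center_mm
        rora_mask = (X - cx) ** 2 + (Y - cy) ** 2 <= spec.rora.radius_mm**2
        f = spec.rora.inner_layer_damage_fraction
        if f > 0:
            # distortion field: blend the pit toward an irregular
            # parafoveal-level thickness, erasing the Gaussian pattern
            bumps = _smooth_field(
                np.random.default_rng(ss_damage), g, _ATROPHY_FIELD_CORR_MM
            )
            distorted = spec.pit.parafoveal_gclipl_thickness * np.clip(
                1.0 + 0.35 * bumps, 0.6, 1.4
            )
            gclipl = np.where(rora_mask, (1.0 - f) * gclipl + f * distorted, gclipl)
    gclipl = np.clip(gclipl, 0.0, None)

    pr = _OUTER_PR_FRACTION * spec.outer_retina_thickness + _FOVEAL_OUTER_BUMP_MM * np.exp(
        -d2 / (2.0 * _FOVEAL_OUTER_BUMP_SIGMA_MM**2)
    )
    if spec.noise_sd > 0:
        pr = pr + rng_outer.normal(0.0, spec.noise_sd, size=pr.shape)
    rpe = np.full(gclipl.shape, (1.0 - _OUTER_PR_FRACTION) * spec.outer_retina_thickness)
    for dr in spec.drusen:
        dx, dy = dr.center_mm
        dd2 = (X - dx) ** 2 + (Y - dy) ** 2
        rpe = rpe + dr.height_mm * np.exp(-dd2 / (2.0 * dr.sigma_mm**2))

    onl = np.full(gclipl.shape, _ONL_MM)
    if spec.rora is not None:
        # lesion severity varies spatially: outer layers vanish, a noisy
        # remnant of the ONL survives
        severity = np.clip(
            1.0
            + 0.8 * _smooth_field(np.random.default_rng(ss_atrophy), g, _ATROPHY_FIELD_CORR_MM),
            0.0,
            2.0,
        )
        onl = np.where(rora_mask, _RORA_ONL_REMNANT * onl * severity, onl)
        pr = np.where(rora_mask, 0.0, pr)
        rpe = np.where(rora_mask, 0.0, rpe)
    pr = np.clip(pr, 0.0, None)

    # thickness stack (top -> bottom), discretized to voxel counts
    stack = [
        ("RNFL", np.full(gclipl.shape, _RNFL_MM)),
        ("GCL", gclipl / 2.0),
        ("IPL", gclipl / 2.0),
        ("INL", np.full(gclipl.shape, _INL_MM)),
        ("OPL", np.full(gclipl.shape, _OPL_MM)),
        ("ONL", onl),
        ("PR", pr),
        ("RPE", rpe),
    ]
    top_margin = int(round(_TOP_MARGIN_MM / g.axial_spacing))
    counts = {
        name: np.clip(np.rint(t / g.axial_spacing), 0, None).astype(np.int64)
        for name, t in stack
    }
    bottoms = {}
    running = np.full(gclipl.shape, top_margin, dtype=np.int64)
    tops = {}
    for name, _ in stack:
        tops[name] = running
        running = running + counts[name]
        bottoms[name] = running
    if running.max() > g.n_axial:
        raise ValueError(
            f"retina does not fit the axial range: needs {int(running.max())} "
            f"voxels, geometry has {g.n_axial}"
        )

    z = np.arange(g.n_axial)[None, :, None]
    labels = np.zeros((g.n_bscans, g.n_axial, g.n_ascans), dtype=np.uint8)
    for name, _ in stack:
        layer_mask = (z >= tops[name][:, None, :]) & (z < bottoms[name][:, None, :])
        labels[layer_mask] = LABEL_SCHEME[name]

    if spec.artifact is not None:
        j = spec.artifact.bscan_index
        if not 0 <= j < g.n_bscans:
            raise ValueError(f"artifact b-scan index {j} out of range")
        n_labeled = bottoms["RPE"][j] - top_margin  # contiguous run from the top
        cut = np.floor(spec.artifact.cut_fraction * n_labeled).astype(np.int64)
        zz = np.arange(g.n_axial)[:, None]
        labels[j][zz < (top_margin + cut)[None, :]] = 0

    volume = SegmentationVolume(geometry=g, labels=labels, label_scheme=dict(LABEL_SCHEME))

    fov_b = min(int(round(fy / g.bscan_spacing)), g.n_bscans - 1)
    fov_a = min(int(round(fx / g.ascan_spacing)), g.n_ascans - 1)
    if rora_mask[fov_b, fov_a]:
        location = "foveal"
    elif rora_mask.any():
        location = "extrafoveal"
    else:
        location = "none"
    truth = PhantomTruth(fovea_mm=(fx, fy), rora_mask=rora_mask, rora_location=location)
    return volume, truth


# ---------------------------------------------------------------------------
# cohort sampling


@dataclass(frozen=True)
class CohortJitter:
    """Per-member parameter ranges for seeded cohort generation.

    Defaults mimic the composition of a GA study cohort: fovea scattered
    around the scan centre (the device's fixation error), RORA areas of
    7.42 +/- 5.06 mm^2 with a 32:23 foveal-to-extrafoveal split, roughly
    a quarter dense scans, and shifted-b-scan artifacts on ~10% of eyes.
    """

    fovea_sd_mm: float = 0.25
    fovea_margin_mm: float = 1.0
    rora_area_mean_mm2: float = 7.42
    rora_area_sd_mm2: float = 5.06
    rora_area_range_mm2: tuple = (0.5, 15.0)
    p_foveal: float = 32 / 55
    p_dense: float = 13 / 55
    artifact_prob: float = 0.1
    artifact_cut_range: tuple = (0.4, 0.7)

    def __post_init__(self) -> None:
        lo, hi = self.rora_area_range_mm2
        if not 0 < lo <= hi:
            raise ValueError("rora_area_range_mm2 must be a non-empty positive range")
        lo, hi = self.artifact_cut_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("artifact_cut_range must be a non-empty range within [0, 1]")
        if not (0 <= self.p_foveal <= 1 and 0 <= self.p_dense <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


def paper_like_base(geometry: ScanGeometry | None = None, noise_sd: float = 0.008) -> PhantomSpec:
    """Base spec for the default GA-like cohort (per-column noise on)."""
    return PhantomSpec(geometry=geometry or ScanGeometry.default(), noise_sd=noise_sd)


def paper_like_jitter() -> CohortJitter:
    return CohortJitter()


def _dense_geometry(base: ScanGeometry) -> ScanGeometry:
    return ScanGeometry.default(
        n_bscans=98,
        n_ascans=base.n_ascans,
        n_axial=base.n_axial,
        axial_spacing=base.axial_spacing,
        extent_x=base.extent_x,
        extent_y=base.extent_y,
    )


def scan_density_of(geom: ScanGeometry, dense_threshold: int = 80) -> str:
    return "dense" if geom.n_bscans >= dense_threshold else "standard"


def sample_cohort_specs(
    n: int, base: PhantomSpec, jitter: CohortJitter, seed: int
) -> list:
    """Draw ``n`` reproducible member specs from ``jitter`` ranges."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        member_seed = int(rng.integers(2**31))
        geom = _dense_geometry(base.geometry) if rng.random() < jitter.p_dense else base.geometry
        margin = jitter.fovea_margin_mm
        cx0, cy0 = geom.extent_x / 2.0, geom.extent_y / 2.0
        fx = float(np.clip(cx0 + rng.normal(0, jitter.fovea_sd_mm), margin, geom.extent_x - margin))
        fy = float(np.clip(cy0 + rng.normal(0, jitter.fovea_sd_mm), margin, geom.extent_y - margin))
        area = float(
            np.clip(
                rng.normal(jitter.rora_area_mean_mm2, jitter.rora_area_sd_mm2),
                *jitter.rora_area_range_mm2,
            )
        )
        radius = math.sqrt(area / math.pi)
        foveal = rng.random() < jitter.p_foveal
        center = _place_lesion(rng, geom, (fx, fy), radius, foveal)
        rora = RoraSpec(center_mm=center, radius_mm=radius)
        artifact = None
        if rng.random() < jitter.artifact_prob:
            artifact = ArtifactSpec(
                bscan_index=int(rng.integers(geom.n_bscans)),
                cut_fraction=float(rng.uniform(*jitter.artifact_cut_range)),
            )
        specs.append(
            replace(
                base,
                geometry=geom,
                fovea_mm=(fx, fy),
                rora=rora,
                artifact=artifact,
                seed=member_seed,
            )
        )
    return specs


def _place_lesion(
    rng: np.random.Generator,
    geom: ScanGeometry,
    fovea: tuple,
    radius: float,
    foveal: bool,
    max_tries: int = 200,
) -> tuple:
    """Sample a lesion centre that does (foveal) or does not cover the fovea."""
    fx, fy = fovea
    for _ in range(max_tries):
        angle = rng.uniform(0, 2 * np.pi)
        if foveal:
            dist = rng.uniform(0.0, 0.6 * radius)
        else:
            dist = radius + rng.uniform(0.3, 1.5)
        cx = fx + dist * math.cos(angle)
        cy = fy + dist * math.sin(angle)
        if not (0.2 <= cx <= geom.extent_x - 0.2 and 0.2 <= cy <= geom.extent_y - 0.2):
            continue
        covers = (cx - fx) ** 2 + (cy - fy) ** 2 <= radius**2
        if covers == foveal:
            return (cx, cy)
    raise RuntimeError("could not place RORA lesion satisfying the constraints")


def generate_cohort(
    n: int, base: PhantomSpec, jitter: CohortJitter, seed: int
) -> list:
    """Generate ``n`` (volume, truth) pairs; same arguments -> same cohort."""
    return [generate(spec) for spec in sample_cohort_specs(n, base, jitter, seed)]


def cohort_rora_summary(specs: Sequence[PhantomSpec]) -> dict:
    """RORA area mean/SD (mm^2) and lesion counts over a spec list."""
    areas = [s.rora.area_mm2 for s in specs if s.rora is not None]
    return {
        "n": len(specs),
        "n_with_rora": len(areas),
        "rora_area_mean_mm2": float(np.mean(areas)) if areas else math.nan,
        "rora_area_sd_mm2": float(np.std(areas, ddof=1)) if len(areas) > 1 else math.nan,
    }


def make_degenerate(
    spec: PhantomSpec,
    rng: np.random.Generator,
    radius_mm: float = 1.8,
    offset_mm: float = 0.8,
    damage_fraction: float = 0.8,
) -> PhantomSpec:
    """Turn a member spec into an advanced-degeneration failure case.

    A large lesion covering the fovea distorts the inner layers, so the
    GCL-IPL projection loses its pit pattern; detection then fails with a
    low reliability score.
    """
    fx, fy = spec.fovea_mm
    angle = rng.uniform(0, 2 * np.pi)
    center = (fx + offset_mm * math.cos(angle), fy + offset_mm * math.sin(angle))
    g = spec.geometry
    center = (
        float(np.clip(center[0], 0.2, g.extent_x - 0.2)),
        float(np.clip(center[1], 0.2, g.extent_y - 0.2)),
    )
    rora = RoraSpec(
        center_mm=center,
        radius_mm=radius_mm,
        inner_layer_damage_fraction=damage_fraction,
    )
    return replace(spec, rora=rora, artifact=None)
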
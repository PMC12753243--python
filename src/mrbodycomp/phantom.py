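"""Synthetic axial pelvic MR phantom cohorts with known ground truth.

Emulates T2-weighted axial slices at the S1 (sacral base) level as seen on an
MR-linac during prostate radiotherapy: a bright subcutaneous-fat ring (SAT),
intermediate-intensity skeletal-muscle compartments (paraspinal, gluteal,
psoas), a sacrum with bright marrow and a dark cortical rim, and an anterior
bowel region containing dark gas pockets. Intramuscular adipose tissue (IMAT)
is rendered as small fat-intensity clusters inside the muscle compartments.

Cohorts carry a fully programmed ground truth: per-patient daily atrophy rates
(linear in days), exact per-timepoint compartment pixel counts, and the rigid
inter-fraction misalignment applied to every scan — so every downstream stage
(registration, mask algebra, longitudinal statistics) can be validated against
known answers.

Intensities are in arbitrary units; only the ordering and separation of tissue
distributions is contracted (fat > muscle > gas), mirroring T2w contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage

from .exceptions import DegenerateAnatomyError, InvalidSpecError, OutOfFieldError
from .registration import RigidTransform2D, resample_to_fixed

__all__ = [
    "BACKGROUND", "MUSCLE", "SAT", "BONE", "BOWEL", "GAS", "VISCERA", "IMAT",
    "LABEL_NAMES", "EllipseShape", "PolygonShape", "BowelRegion", "PhantomSpec",
    "IntensityModel", "AtrophyModel", "MisalignmentModel", "GroupSpec",
    "CohortSpec", "LabeledSlice", "ScanRecord", "PatientRecord", "CohortDataset",
    "default_spec", "make_anatomy", "render_intensities", "apply_atrophy",
    "apply_misalignment", "make_cohort", "group_preset", "cohort_preset",
    "muscle_mask", "GROUP_PRESETS",
]

# Label vocabulary. IMAT is a muscle sublabel: a muscle pixel rendered at
# fat-like intensity. `muscle_mask` treats {MUSCLE, IMAT} as muscle.
BACKGROUND, MUSCLE, SAT, BONE, BOWEL, GAS, VISCERA, IMAT = range(8)
LABEL_NAMES = {
    BACKGROUND: "background", MUSCLE: "muscle", SAT: "sat", BONE: "bone",
    BOWEL: "bowel", GAS: "gas", VISCERA: "viscera", IMAT: "imat",
}


def muscle_mask(labels: np.ndarray) -> np.ndarray:
    """Total-muscle binary mask: muscle pixels plus IMAT sublabel pixels."""
    return (labels == MUSCLE) | (labels == IMAT)


# --------------------------------------------------------------------------
# Geometry primitives (all coordinates/lengths in mm, origin at image center,
# x along columns, y along rows with +y posterior).
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EllipseShape:
    center: tuple[float, float]
    semiaxes: tuple[float, float]
    rotation_deg: float = 0.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx, dy = x - self.center[0], y - self.center[1]
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return (u / self.semiaxes[0]) ** 2 + (v / self.semiaxes[1]) ** 2 <= 1.0

    def scaled(self, factor: float) -> "EllipseShape":
        return EllipseShape(
            (self.center[0] * factor, self.center[1] * factor),
            (self.semiaxes[0] * factor, self.semiaxes[1] * factor),
            self.rotation_deg,
        )

    def perturbed(self, dxy: tuple[float, float], axis_scale: float) -> "EllipseShape":
        return EllipseShape(
            (self.center[0] + dxy[0], self.center[1] + dxy[1]),
            (self.semiaxes[0] * axis_scale, self.semiaxes[1] * axis_scale),
            self.rotation_deg,
        )


@dataclass(frozen=True)
class PolygonShape:
    vertices: tuple[tuple[float, float], ...]

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        path = MplPath(np.asarray(self.vertices))
        pts = np.column_stack([x.ravel(), y.ravel()])
        return path.contains_points(pts, radius=1e-9).reshape(x.shape)

    def scaled(self, factor: float) -> "PolygonShape":
        return PolygonShape(tuple((vx * factor, vy * factor) for vx, vy in self.vertices))


@dataclass(frozen=True)
class BowelRegion:
    shape: EllipseShape = EllipseShape((0.0, -30.0), (55.0, 33.0))
    gas_pocket_count: tuple[int, int] = (3, 6)           # inclusive range
    gas_pocket_radius_mm: tuple[float, float] = (4.0, 10.0)

    def scaled(self, factor: float) -> "BowelRegion":
        return BowelRegion(self.shape.scaled(factor), self.gas_pocket_count,
                           tuple(r * factor for r in self.gas_pocket_radius_mm))


def _default_compartments() -> tuple[tuple[str, EllipseShape], ...]:
    return (
        ("paraspinal_l", EllipseShape((-48.0, 51.0), (15.0, 19.0))),
        ("paraspinal_r", EllipseShape((48.0, 51.0), (15.0, 19.0))),
        ("gluteal_l", EllipseShape((-83.0, 20.0), (26.0, 33.0), rotation_deg=20.0)),
        ("gluteal_r", EllipseShape((83.0, 20.0), (26.0, 33.0), rotation_deg=-20.0)),
        ("psoas_l", EllipseShape((-30.0, 15.0), (12.5, 12.5))),
        ("psoas_r", EllipseShape((30.0, 15.0), (12.5, 12.5))),
    )


_DEFAULT_SACRUM = PolygonShape(((-30.0, 38.0), (30.0, 38.0), (20.0, 75.0), (-20.0, 75.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one synthetic pelvis. Lengths in mm."""

    grid_size: int = 480
    pixel_spacing: float = 1.0
    body_semiaxes: tuple[float, float] = (160.0, 100.0)
    sat_thickness: float = 18.0
    muscle_compartments: tuple = field(default_factory=_default_compartments)
    bone_region: PolygonShape = _DEFAULT_SACRUM
    bowel_region: BowelRegion = field(default_factory=BowelRegion)
    imat_fraction: float = 0.12
    imat_cluster_radius_mm: float = 4.0
    # resolved gas-pocket shapes; None means "draw randomly at rasterization".
    # resolve_spec bakes them in so one anatomy can be re-rasterized under
    # different rigid transforms (sub-pixel-exact inter-fraction motion).
    gas_pockets: tuple | None = None

    def validate(self) -> None:
        if self.grid_size < 32:
            raise InvalidSpecError("grid_size must be at least 32")
        if self.pixel_spacing <= 0:
            raise InvalidSpecError("pixel_spacing must be positive")
        if self.sat_thickness <= 0:
            raise InvalidSpecError("sat_thickness must be positive")
        if not 0.0 <= self.imat_fraction <= 0.3:
            raise InvalidSpecError("imat_fraction must lie in [0, 0.3]")
        if min(self.body_semiaxes) <= self.sat_thickness:
            raise InvalidSpecError("body ellipse thinner than SAT layer")
        fov = self.grid_size * self.pixel_spacing
        if 2 * max(self.body_semiaxes) >= fov:
            raise InvalidSpecError("body does not fit in the field of view")

    def scaled(self, factor: float) -> "PhantomSpec":
        """Globally scale all mm geometry (containment margins preserved)."""
        return replace(
            self,
            body_semiaxes=(self.body_semiaxes[0] * factor, self.body_semiaxes[1] * factor),
            sat_thickness=self.sat_thickness * factor,
            muscle_compartments=tuple(
                (name, shp.scaled(factor)) for name, shp in self.muscle_compartments
            ),
            bone_region=self.bone_region.scaled(factor),
            bowel_region=self.bowel_region.scaled(factor),
            gas_pockets=None if self.gas_pockets is None else tuple(
                g.scaled(factor) for g in self.gas_pockets),
        )


def default_spec(grid_size: int = 480, pixel_spacing: float | None = None) -> PhantomSpec:
    """Default pelvis at the requested grid size.

    When ``pixel_spacing`` is omitted it is chosen to keep the physical field
    of view at 480 mm, so the same mm anatomy renders at any grid size.
    """
    if pixel_spacing is None:
        pixel_spacing = 480.0 / grid_size
    return PhantomSpec(grid_size=grid_size, pixel_spacing=pixel_spacing)


# --------------------------------------------------------------------------
# Intensity model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IntensityModel:
    """Per-tissue rendering distributions (arbitrary units, T2w-like ordering)."""

    means: dict = field(default_factory=lambda: {
        "background": 5.0, "muscle": 45.0, "sat": 85.0, "bone_marrow": 78.0,
        "cortical_bone": 16.0, "bowel": 55.0, "gas": 8.0, "viscera": 55.0,
    })
    sds: dict = field(default_factory=lambda: {
        "background": 2.0, "muscle": 4.0, "sat": 6.0, "bone_marrow": 6.0,
        "cortical_bone": 4.0, "bowel": 6.0, "gas": 3.0, "viscera": 5.0,
    })
    noise_sigma: float = 2.0
    bias_field_amplitude: float = 0.0
    cortical_rim_px: int = 2

    def validate(self) -> None:
        if not (self.means["sat"] > self.means["muscle"] > self.means["gas"]):
            raise InvalidSpecError("intensity ordering must satisfy SAT > muscle > gas")
        if any(s < 0 for s in self.sds.values()) or self.noise_sigma < 0:
            raise InvalidSpecError("intensity standard deviations must be >= 0")


# --------------------------------------------------------------------------
# Cohort-level models
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AtrophyModel:
    """Daily fractional area-change rates, in %/day, linear in elapsed days.

    ``rates[roi] = (population mean, population SD across patients)``. Negative
    rates model atrophy, positive rates growth.
    """

    rates: dict = field(default_factory=lambda: {
        "muscle": (0.0, 0.0), "sat": (0.0, 0.0), "imat": (0.0, 0.0),
    })

    def draw_patient_rates(self, rng: np.random.Generator) -> dict:
        return {roi: float(rng.normal(mu, sd)) for roi, (mu, sd) in self.rates.items()}


@dataclass(frozen=True)
class MisalignmentModel:
    """Per-fraction rigid setup perturbation, uniform in the given ranges."""

    max_translation_mm: float = 5.0
    max_rotation_deg: float = 3.0

    def draw(self, rng: np.random.Generator) -> RigidTransform2D:
        tx, ty = rng.uniform(-self.max_translation_mm, self.max_translation_mm, size=2)
        th = rng.uniform(-self.max_rotation_deg, self.max_rotation_deg)
        return RigidTransform2D(float(tx), float(ty), float(th))


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_patients: int
    acquisition_days: tuple[float, ...]
    atrophy: AtrophyModel

    @property
    def n_timepoints(self) -> int:
        return len(self.acquisition_days)

    @property
    def schedule_days(self) -> float:
        return self.acquisition_days[-1] - self.acquisition_days[0]


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    phantom: PhantomSpec = field(default_factory=lambda: default_spec(256))
    intensity: IntensityModel = field(default_factory=IntensityModel)
    misalignment: MisalignmentModel = field(default_factory=MisalignmentModel)
    n_slices: int = 3
    seed: int = 0


# End-of-schedule group-mean changes (%) and their patient-level SDs, realized
# as linear daily rates over each group's schedule. The ADT + 20-fraction arm
# loses ~1% muscle, ~1.9% SAT and ~1.8% IMAT over ~27 days; the 5-fraction
# no-ADT arm shows essentially no muscle change over ~10 days but a consistent
# IMAT decline. Patient SD = reported SEM * sqrt(n).
_DAYS_20 = (0.0, 7.0, 14.0, 21.0, 27.0)
_DAYS_5 = (0.0, 2.0, 4.0, 7.0, 10.0)

GROUP_PRESETS: dict[str, GroupSpec] = {
    "20adt": GroupSpec(
        "20adt", 27, _DAYS_20,
        AtrophyModel({
            "muscle": (-1.0 / 27, 0.4 * np.sqrt(27) / 27),
            "sat": (-1.9 / 27, 0.6 * np.sqrt(27) / 27),
            "imat": (-1.8 / 27, 0.7 * np.sqrt(27) / 27),
        }),
    ),
    "5adt": GroupSpec(
        "5adt", 21, _DAYS_5,
        AtrophyModel({
            "muscle": (0.2 / 10, 0.5 * np.sqrt(21) / 10),
            "sat": (-0.5 / 10, 0.5 * np.sqrt(21) / 10),
            "imat": (-1.0 / 10, 0.7 * np.sqrt(21) / 10),
        }),
    ),
    "5noadt": GroupSpec(
        "5noadt", 22, _DAYS_5,
        AtrophyModel({
            "muscle": (0.2 / 10, 0.5 * np.sqrt(22) / 10),
            "sat": (-0.3 / 10, 0.5 * np.sqrt(22) / 10),
            "imat": (-2.0 / 10, 0.7 * np.sqrt(22) / 10),
        }),
    ),
}


def group_preset(name: str, n_patients: int | None = None) -> GroupSpec:
    g = GROUP_PRESETS[name]
    if n_patients is not None:
        g = replace(g, n_patients=n_patients)
    return g


def cohort_preset(names=("20adt", "5adt", "5noadt"), grid_size: int = 256,
                  seed: int = 0, **kwargs) -> CohortSpec:
    return CohortSpec(
        groups=tuple(group_preset(n) for n in names),
        phantom=default_spec(grid_size),
        seed=seed,
        **kwargs,
    )


# --------------------------------------------------------------------------
# Data containers
# --------------------------------------------------------------------------


@dataclass
class LabeledSlice:
    image: np.ndarray                 # 2D float32 intensity grid
    labels: np.ndarray                # 2D uint8 label map
    spacing: float                    # mm / pixel (isotropic)
    patient_id: str = "phantom"
    timepoint_index: int = 0
    acquisition_day: float = 0.0
    slice_offset: int = 0             # -1 / 0 / +1 around the S1 level
    imat_sites_mm: np.ndarray | None = None   # (N, 2) cluster centers, (x, y) mm
    imat_cluster_radius_mm: float = 4.0
    resolved_spec: "PhantomSpec | None" = None  # continuous anatomy, if known

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise InvalidSpecError("image and labels must share shape")
        if self.spacing <= 0:
            raise InvalidSpecError("spacing must be positive")


@dataclass
class ScanRecord:
    """One imaging session: the 3-slice stack plus its programmed truth."""

    timepoint_index: int
    acquisition_day: float
    slices: list
    true_transform: RigidTransform2D
    true_counts: dict                 # roi -> per-slice pixel counts (pre-misalignment)
    true_area_cm2: dict               # roi -> 3-slice mean area

    @property
    def s1_slice(self) -> LabeledSlice:
        return self.slices[len(self.slices) // 2]


@dataclass
class PatientRecord:
    patient_id: str
    group: str
    rates_pct_per_day: dict
    scans: list


@dataclass
class CohortDataset:
    spec: CohortSpec
    patients: list

    def truth_log(self) -> dict:
        """JSON-serializable programmed ground truth for the whole cohort."""
        out = {"seed": self.spec.seed, "patients": []}
        for p in self.patients:
            rec = {
                "patient_id": p.patient_id,
                "group": p.group,
                "rates_pct_per_day": p.rates_pct_per_day,
                "scans": [
                    {
                        "timepoint_index": s.timepoint_index,
                        "acquisition_day": s.acquisition_day,
                        "transform": s.true_transform.as_dict(),
                        "true_counts": {k: list(map(int, v)) for k, v in s.true_counts.items()},
                        "true_area_cm2": {k: float(v) for k, v in s.true_area_cm2.items()},
                    }
                    for s in p.scans
                ],
            }
            out["patients"].append(rec)
        return out


# --------------------------------------------------------------------------
# Anatomy rasterization
# --------------------------------------------------------------------------


def _mm_grids(grid_size: int, spacing: float):
    half = (grid_size - 1) / 2.0
    coords = (np.arange(grid_size) - half) * spacing
    y, x = np.meshgrid(coords, coords, indexing="ij")
    return x, y


def _draw_gas_pockets(bowel: BowelRegion, rng: np.random.Generator) -> tuple:
    """Random gas-pocket disks fully inside the bowel ellipse."""
    lo, hi = bowel.gas_pocket_count
    n_gas = int(rng.integers(lo, hi + 1))
    bsh = bowel.shape
    pockets = []
    for _ in range(n_gas):
        r = rng.uniform(*bowel.gas_pocket_radius_mm)
        for _attempt in range(50):
            u, v = rng.uniform(-1, 1, size=2)
            cx = bsh.center[0] + u * max(bsh.semiaxes[0] - r, 0.0)
            cy = bsh.center[1] + v * max(bsh.semiaxes[1] - r, 0.0)
            du = (cx - bsh.center[0]) / max(bsh.semiaxes[0] - r, 1e-9)
            dv = (cy - bsh.center[1]) / max(bsh.semiaxes[1] - r, 1e-9)
            if du ** 2 + dv ** 2 <= 1.0:
                break
        pockets.append(EllipseShape((cx, cy), (r, r)))
    return tuple(pockets)


def resolve_spec(spec: PhantomSpec, rng: np.random.Generator,
                 compartment_jitter_mm: float = 0.0) -> PhantomSpec:
    """Freeze all random anatomy choices into the spec (gas pockets, per-slice
    compartment jitter), so the same continuous anatomy can be rasterized
    repeatedly — possibly under different rigid transforms."""
    comps = []
    for name, shp in spec.muscle_compartments:
        if compartment_jitter_mm > 0:
            dxy = rng.uniform(-compartment_jitter_mm, compartment_jitter_mm,
                              size=2)
            axis_scale = float(rng.uniform(0.98, 1.02))
            shp = shp.perturbed(tuple(dxy), axis_scale)
        comps.append((name, shp))
    pockets = (spec.gas_pockets if spec.gas_pockets is not None
               else _draw_gas_pockets(spec.bowel_region, rng))
    return replace(spec, muscle_compartments=tuple(comps), gas_pockets=pockets)


def _rasterize(spec: PhantomSpec,
               transform: RigidTransform2D | None = None) -> np.ndarray:
    """Rasterize the (resolved) continuous anatomy onto the pixel grid.

    ``transform`` places the anatomy under a rigid setup error with sub-pixel
    fidelity: every shape-membership test is evaluated at the inverse-mapped
    pixel centers, exactly as a scanner samples a displaced patient. Raises
    InvalidSpecError if any compartment escapes its containing region
    (enforced by sequential assignment).
    """
    if spec.gas_pockets is None:
        raise InvalidSpecError("spec must be resolved (call resolve_spec)")
    x, y = _mm_grids(spec.grid_size, spec.pixel_spacing)
    if transform is not None and not transform.is_identity():
        inv = transform.inverse()
        xs = inv.matrix[0, 0] * x + inv.matrix[0, 1] * y + inv.tx_mm
        ys = inv.matrix[1, 0] * x + inv.matrix[1, 1] * y + inv.ty_mm
        x, y = xs, ys
    labels = np.full((spec.grid_size, spec.grid_size), BACKGROUND, dtype=np.uint8)

    ax, ay = spec.body_semiaxes
    body = (x / ax) ** 2 + (y / ay) ** 2 <= 1.0
    inner = (x / (ax - spec.sat_thickness)) ** 2 + (y / (ay - spec.sat_thickness)) ** 2 <= 1.0
    labels[body] = SAT
    labels[inner] = VISCERA
    if not inner.any():
        raise InvalidSpecError("SAT layer consumes the whole body")

    def place(shape, label, host=VISCERA, what="compartment"):
        m = shape.contains(x, y)
        if not m.any():
            raise InvalidSpecError(f"{what} rasterizes to zero pixels")
        if np.any(labels[m] != host):
            raise InvalidSpecError(f"{what} escapes its containing region")
        labels[m] = label
        return m

    place(spec.bone_region, BONE, what="bone region")
    bowel = place(spec.bowel_region.shape, BOWEL, what="bowel region")
    for pocket in spec.gas_pockets:
        sel = pocket.contains(x, y) & bowel
        labels[sel] = GAS

    for name, shp in spec.muscle_compartments:
        place(shp, MUSCLE, what=f"muscle compartment {name!r}")

    return labels


def _generate_imat_sites(labels: np.ndarray, spacing: float,
                         rng: np.random.Generator, radius_mm: float) -> np.ndarray:
    """Candidate IMAT cluster centers (mm), uniform over muscle, in a fixed
    random order reused across timepoints so the fat pattern is anatomically
    stable while its pixel count follows the programmed trajectory."""
    m = muscle_mask(labels)
    n_muscle = int(m.sum())
    px_per_cluster = max(np.pi * (radius_mm / spacing) ** 2, 1.0)
    n_sites = int(np.ceil(0.35 * n_muscle / px_per_cluster)) + 32
    rows, cols = np.nonzero(m)
    idx = rng.choice(len(rows), size=min(n_sites, len(rows)), replace=False)
    half = (labels.shape[0] - 1) / 2.0
    xs = (cols[idx] - half) * spacing
    ys = (rows[idx] - half) * spacing
    return np.column_stack([xs, ys]).astype(np.float64)


def _assign_imat(labels: np.ndarray, target_count: int, sites_mm: np.ndarray,
                 radius_mm: float, spacing: float) -> np.ndarray:
    """Relabel exactly ``target_count`` muscle pixels as IMAT, filling fixed
    cluster sites in order and truncating the last cluster (pixels nearest the
    cluster center first) so the count is exact."""
    out = labels.copy()
    out[out == IMAT] = MUSCLE
    if target_count <= 0:
        return out
    n_muscle = int((out == MUSCLE).sum())
    if target_count > n_muscle:
        raise DegenerateAnatomyError("IMAT target exceeds available muscle pixels")
    half = (labels.shape[0] - 1) / 2.0
    r_px = radius_mm / spacing
    remaining = target_count
    for sx, sy in sites_mm:
        if remaining <= 0:
            break
        cc = sx / spacing + half
        cr = sy / spacing + half
        r0 = max(int(np.floor(cr - r_px)) - 1, 0)
        r1 = min(int(np.ceil(cr + r_px)) + 2, labels.shape[0])
        c0 = max(int(np.floor(cc - r_px)) - 1, 0)
        c1 = min(int(np.ceil(cc + r_px)) + 2, labels.shape[1])
        sub = out[r0:r1, c0:c1]
        rr, cols = np.nonzero(sub == MUSCLE)
        if len(rr) == 0:
            continue
        d2 = (rr + r0 - cr) ** 2 + (cols + c0 - cc) ** 2
        inside = d2 <= r_px ** 2
        rr, cols, d2 = rr[inside], cols[inside], d2[inside]
        if len(rr) == 0:
            continue
        order = np.lexsort((cols, rr, d2))
        take = order[: min(remaining, len(order))]
        sub[rr[take], cols[take]] = IMAT
        remaining -= len(take)
    if remaining > 0:
        # sites exhausted: fall back to deterministic fill of leftover muscle
        rows, cols = np.nonzero(out == MUSCLE)
        out[rows[:remaining], cols[:remaining]] = IMAT
    return out


def make_anatomy(spec: PhantomSpec, seed: int,
                 compartment_jitter_mm: float = 0.0) -> LabeledSlice:
    """Build one labeled anatomy slice (day 0, no intensities rendered yet).

    The label map partitions the grid: exterior background, the SAT ring, the
    viscera interior, bone, bowel with gas pockets, and the muscle
    compartments with exactly ``round(imat_fraction * n_muscle)`` pixels
    carrying the IMAT sublabel. Deterministic for fixed (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    spec = resolve_spec(spec, rng, compartment_jitter_mm)
    labels = _rasterize(spec)
    sites = _generate_imat_sites(labels, spec.pixel_spacing, rng,
                                 spec.imat_cluster_radius_mm)
    n_muscle = int(muscle_mask(labels).sum())
    target = int(round(spec.imat_fraction * n_muscle))
    labels = _assign_imat(labels, target, sites, spec.imat_cluster_radius_mm,
                          spec.pixel_spacing)
    return LabeledSlice(
        image=np.zeros_like(labels, dtype=np.float32),
        labels=labels,
        spacing=spec.pixel_spacing,
        imat_sites_mm=sites,
        imat_cluster_radius_mm=spec.imat_cluster_radius_mm,
        resolved_spec=spec,
    )


# --------------------------------------------------------------------------
# Intensity rendering
# --------------------------------------------------------------------------

_LABEL_TISSUE = {
    BACKGROUND: "background", MUSCLE: "muscle", SAT: "sat", BOWEL: "bowel",
    GAS: "gas", VISCERA: "viscera", IMAT: "sat",  # IMAT renders as fat
}


def render_intensities(labels: np.ndarray, model: IntensityModel, seed: int) -> np.ndarray:
    """Render a T2w-like image from a label map.

    Each pixel draws from its tissue's Normal(mean, sd); bone splits into a
    bright marrow core and a dark cortical rim; IMAT pixels draw from the SAT
    (fat) distribution. Optional global additive noise and a smooth
    multiplicative bias field complete the model.
    """
    model.validate()
    rng = np.random.default_rng(seed)
    mean_map = np.zeros(labels.shape, dtype=np.float32)
    sd_map = np.zeros(labels.shape, dtype=np.float32)
    for lab, tissue in _LABEL_TISSUE.items():
        sel = labels == lab
        mean_map[sel] = model.means[tissue]
        sd_map[sel] = model.sds[tissue]
    bone = labels == BONE
    if bone.any():
        marrow = ndimage.binary_erosion(bone, iterations=model.cortical_rim_px)
        rim = bone & ~marrow
        mean_map[marrow] = model.means["bone_marrow"]
        sd_map[marrow] = model.sds["bone_marrow"]
        mean_map[rim] = model.means["cortical_bone"]
        sd_map[rim] = model.sds["cortical_bone"]

    img = mean_map + sd_map * rng.standard_normal(labels.shape).astype(np.float32)
    if model.noise_sigma > 0:
        img += model.noise_sigma * rng.standard_normal(labels.shape).astype(np.float32)
    if model.bias_field_amplitude > 0:
        f = rng.standard_normal((4, 4))
        fld = ndimage.zoom(f, np.array(labels.shape) / 4.0, order=3)
        fld = fld[: labels.shape[0], : labels.shape[1]]
        fld = fld / max(np.abs(fld).max(), 1e-9)
        img *= (1.0 + model.bias_field_amplitude * fld).astype(np.float32)
    return img.astype(np.float32)


# --------------------------------------------------------------------------
# Atrophy: exact-count compartment resizing by signed-distance ranking
# --------------------------------------------------------------------------


def _resize_region(labels: np.ndarray, region: np.ndarray, target: int,
                   freed_label: int, candidate_label: int, roi: str) -> np.ndarray:
    """Erode or dilate ``region`` to exactly ``target`` pixels.

    Shrinking removes the pixels with the smallest interior depth (so the
    controlled quantity is area, not shape); growing claims the nearest
    ``candidate_label`` pixels. Ties break lexicographically for determinism.
    """
    out = labels.copy()
    n0 = int(region.sum())
    if target < 1:
        raise DegenerateAnatomyError(f"requested change empties the {roi} compartment")
    if target < n0:
        k = n0 - target
        depth = ndimage.distance_transform_edt(region)
        rows, cols = np.nonzero(region)
        order = np.lexsort((cols, rows, depth[rows, cols]))
        sel = order[:k]
        # refuse to fully empty any connected component
        removal = np.zeros_like(region)
        removal[rows[sel], cols[sel]] = True
        comp, n_comp = ndimage.label(region)
        kept = region & ~removal
        for ci in range(1, n_comp + 1):
            if not kept[comp == ci].any():
                raise DegenerateAnatomyError(
                    f"requested change empties a {roi} component")
        out[rows[sel], cols[sel]] = freed_label
    elif target > n0:
        k = target - n0
        dist = ndimage.distance_transform_edt(~region)
        cand = labels == candidate_label
        rows, cols = np.nonzero(cand)
        if len(rows) < k:
            raise DegenerateAnatomyError(f"not enough room to grow the {roi} compartment")
        order = np.lexsort((cols, rows, dist[rows, cols]))
        sel = order[:k]
        out[rows[sel], cols[sel]] = MUSCLE if roi == "muscle" else SAT
    return out


def _targets_from_rates(counts0: dict, rates_pct_per_day: dict,
                        elapsed_days: float) -> dict:
    out = {}
    for roi in ("muscle", "sat", "imat"):
        rate = rates_pct_per_day.get(roi, 0.0)
        out[roi] = int(round(counts0[roi] * (1.0 + rate / 100.0 * elapsed_days)))
    return out


def _apply_area_targets(labels: np.ndarray, targets: dict,
                        sites_mm: np.ndarray | None, radius_mm: float,
                        spacing: float) -> np.ndarray:
    """Resize muscle/SAT to exact pixel-count targets and re-select IMAT
    cluster pixels to the IMAT target."""
    work = labels.copy()
    work[work == IMAT] = MUSCLE
    work = _resize_region(work, muscle_mask(labels), targets["muscle"],
                          freed_label=VISCERA, candidate_label=VISCERA,
                          roi="muscle")
    work = _resize_region(work, work == SAT, targets["sat"],
                          freed_label=BACKGROUND, candidate_label=BACKGROUND,
                          roi="sat")
    if targets["imat"] < 0:
        raise DegenerateAnatomyError("requested change empties the imat compartment")
    if sites_mm is not None and targets["imat"] > 0:
        work = _assign_imat(work, targets["imat"], sites_mm, radius_mm, spacing)
    return work


def apply_atrophy(anatomy: LabeledSlice, rates_pct_per_day: dict,
                  elapsed_days: float) -> LabeledSlice:
    """Realize the programmed linear area trajectory on the ground truth.

    Each ROI's pixel count becomes ``round(n0 * (1 + rate/100 * elapsed_days))``
    exactly: muscle and SAT by signed-distance erosion/dilation, IMAT by
    re-selecting fat-cluster pixels to the target count. Muscle freed pixels
    become viscera; SAT resizes at the skin (outer) boundary.
    """
    labels = anatomy.labels
    counts0 = {"muscle": int(muscle_mask(labels).sum()),
               "sat": int((labels == SAT).sum()),
               "imat": int((labels == IMAT).sum())}
    targets = _targets_from_rates(counts0, rates_pct_per_day, elapsed_days)
    work = _apply_area_targets(labels, targets, anatomy.imat_sites_mm,
                               anatomy.imat_cluster_radius_mm, anatomy.spacing)
    return LabeledSlice(
        image=anatomy.image.copy(),
        labels=work,
        spacing=anatomy.spacing,
        patient_id=anatomy.patient_id,
        timepoint_index=anatomy.timepoint_index,
        acquisition_day=elapsed_days,
        slice_offset=anatomy.slice_offset,
        imat_sites_mm=anatomy.imat_sites_mm,
        imat_cluster_radius_mm=anatomy.imat_cluster_radius_mm,
        resolved_spec=anatomy.resolved_spec,
    )


# --------------------------------------------------------------------------
# Inter-fraction misalignment
# --------------------------------------------------------------------------


def apply_misalignment(slc: LabeledSlice, transform: RigidTransform2D,
                       seed: int | None = None) -> LabeledSlice:
    """Resample image (linear) and labels (nearest-neighbor) under the same
    rigid transform, recording it as the scan's true setup error.

    Raises :class:`OutOfFieldError` if the transform would push any body pixel
    off the grid.
    """
    body = slc.labels != BACKGROUND
    if body.any() and not transform.is_identity():
        rows, cols = np.nonzero(body)
        half = (slc.labels.shape[0] - 1) / 2.0
        pts = np.column_stack([(cols - half) * slc.spacing, (rows - half) * slc.spacing])
        moved = transform.apply_points(pts)
        extent = half * slc.spacing
        if np.any(np.abs(moved) > extent):
            raise OutOfFieldError("transform moves the body outside the grid")

    img = resample_to_fixed(slc.image, transform, slc.spacing, is_label=False,
                            cval=0.0)
    lab = resample_to_fixed(slc.labels, transform, slc.spacing, is_label=True,
                            cval=BACKGROUND)
    return LabeledSlice(
        image=img.astype(np.float32),
        labels=lab,
        spacing=slc.spacing,
        patient_id=slc.patient_id,
        timepoint_index=slc.timepoint_index,
        acquisition_day=slc.acquisition_day,
        slice_offset=slc.slice_offset,
        imat_sites_mm=slc.imat_sites_mm,
        imat_cluster_radius_mm=slc.imat_cluster_radius_mm,
    )


# --------------------------------------------------------------------------
# Cohort assembly
# --------------------------------------------------------------------------

_ROIS = ("muscle", "sat", "imat", "lean_muscle")


def _touches_border(labels: np.ndarray) -> bool:
    body = labels != BACKGROUND
    return bool(body[0].any() or body[-1].any()
                or body[:, 0].any() or body[:, -1].any())


def _roi_counts(labels: np.ndarray) -> dict:
    m = int(muscle_mask(labels).sum())
    i = int((labels == IMAT).sum())
    return {"muscle": m, "sat": int((labels == SAT).sum()), "imat": i,
            "lean_muscle": m - i}


def _vary_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Per-patient anatomical variation: global size scale plus an independent
    SAT-thickness factor (kept gentle so containment margins survive)."""
    scale = float(rng.uniform(0.94, 1.06))
    varied = spec.scaled(scale)
    t_factor = float(rng.uniform(0.88, 1.12))
    return replace(varied, sat_thickness=varied.sat_thickness * t_factor)


def make_cohort(cohort: CohortSpec) -> CohortDataset:
    """Simulate the full longitudinal cohort.

    Per patient: a varied anatomy (3 adjacent slices with small independent
    boundary jitter standing for S1-1/S1/S1+1), per-ROI daily rates drawn from
    the group's atrophy model, five rendered scans at the schedule's
    acquisition days, and a random rigid setup error for every fraction after
    the first. Fully deterministic for a fixed spec (same seed, bitwise-equal
    output).
    """
    ss = np.random.SeedSequence(cohort.seed)
    patients = []
    pidx = 0
    for group in cohort.groups:
        for j in range(group.n_patients):
            child = np.random.SeedSequence(entropy=cohort.seed,
                                           spawn_key=(pidx,))
            rng = np.random.default_rng(child)
            pid = f"{group.name}-{j:03d}"
            pspec = _vary_spec(cohort.phantom, rng)
            anat_seed = int(rng.integers(0, 2 ** 31 - 1))
            base_slices = []
            for s_off in (-1, 0, 1):
                sl = make_anatomy(pspec, anat_seed + (s_off + 1),
                                  compartment_jitter_mm=1.0 if s_off != 0 else 0.0)
                sl.patient_id = pid
                sl.slice_offset = s_off
                base_slices.append(sl)
            rates = group.atrophy.draw_patient_rates(rng)

            base_counts = [
                {"muscle": int(muscle_mask(sl.labels).sum()),
                 "sat": int((sl.labels == SAT).sum()),
                 "imat": int((sl.labels == IMAT).sum())}
                for sl in base_slices]

            scans = []
            for t_idx, day in enumerate(group.acquisition_days):
                elapsed = day - group.acquisition_days[0]
                transform = (RigidTransform2D() if t_idx == 0
                             else cohort.misalignment.draw(rng))
                slices = []
                counts = {roi: [] for roi in _ROIS}
                for sl, c0 in zip(base_slices, base_counts):
                    # the scanner images the displaced continuous anatomy:
                    # re-rasterize the resolved shapes under the setup error
                    # (sub-pixel exact), then impose the programmed areas
                    lab = _rasterize(sl.resolved_spec, transform=transform)
                    if _touches_border(lab):
                        raise OutOfFieldError(
                            "setup error moves the body outside the grid")
                    targets = _targets_from_rates(c0, rates, elapsed)
                    sites = (sl.imat_sites_mm if transform.is_identity()
                             else transform.apply_points(sl.imat_sites_mm))
                    lab = _apply_area_targets(lab, targets, sites,
                                              sl.imat_cluster_radius_mm,
                                              sl.spacing)
                    at = LabeledSlice(
                        image=render_intensities(
                            lab, cohort.intensity,
                            seed=int(rng.integers(0, 2 ** 31 - 1))),
                        labels=lab,
                        spacing=sl.spacing,
                        patient_id=pid,
                        timepoint_index=t_idx,
                        acquisition_day=day,
                        slice_offset=sl.slice_offset,
                        imat_sites_mm=sites,
                        imat_cluster_radius_mm=sl.imat_cluster_radius_mm,
                        resolved_spec=sl.resolved_spec,
                    )
                    for roi, c in _roi_counts(at.labels).items():
                        counts[roi].append(c)
                    slices.append(at)
                area = {
                    roi: float(np.mean(counts[roi])) * pspec.pixel_spacing ** 2 / 100.0
                    for roi in _ROIS
                }
                scans.append(ScanRecord(t_idx, day, slices, transform,
                                        counts, area))
            patients.append(PatientRecord(pid, group.name, rates, scans))
            pidx += 1
    return CohortDataset(cohort, patients)
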
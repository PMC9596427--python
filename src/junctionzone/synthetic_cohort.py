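"""Synthetic longitudinal GA-trial cohorts.

Generates everything the downstream analysis consumes — per-eye,
per-visit en-face thickness maps for the ONL, IS and OS laminae, binary
RPE-atrophy masks, a cohort manifest, and a normative reference set —
with the statistical structure the analysis assumes:

* fovea-centered 20°×20° maps with a smooth topographic mean surface,
  a linear age effect and location-specific noise;
* one (optionally two) circular GA foci whose square-root-transformed
  area grows linearly in time at an arm-specific rate;
* a junctional thinning gradient that is steep within ~2° of the lesion
  boundary and shallow beyond, deepening over time;
* a slow macula-wide thinning drift;
* dose-dependent attenuation of both growth and thinning in treated
  arms; stable fellow eyes;
* per-pixel measurement noise plus a per-eye random intercept.

Default rates mirror the trial's headline findings: sham sqrt-area
growth 0.30 mm/y with 25% (monthly) and 22.2% (every-other-month)
reductions, and junctional/diffuse thinning rates whose implied
month-12 monthly−sham contrast at the 5.16° contour-line is ≈ +0.29 z.

Two light-weight simulators (`simulate_change_table`,
`simulate_sqrt_areas`) draw directly from the same ring-level model for
Monte-Carlo studies of the statistical machinery where full rasters
would add nothing but runtime.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lesion_geometry import MM_PER_DEGREE
from .rasters import LAYERS, LesionMask, ThicknessMap

ARMS = ("sham_pooled", "monthly", "eom")

# topographic mean surfaces at age 75, µm; radially symmetric Gaussian
# bump plus a temporal-side asymmetry term (right-eye orientation)
_TOPO = {
    "ONL": (55.0, 40.0, 1.8),
    "IS": (25.0, 10.0, 2.5),
    "OS": (30.0, 15.0, 2.0),
}
_AGE_SLOPE = {"ONL": -0.20, "IS": -0.05, "OS": -0.10}  # µm / year
_SD_BASE = {"ONL": 5.0, "IS": 2.5, "OS": 3.0}  # µm


@dataclass
class TrialConfig:
    """Design constants of a synthetic two-active-arm sham-controlled trial.

    All rates are annual; distances and pitches are in degrees;
    z-quantities are in standardized thickness units.
    """

    n_per_arm: int = 20
    arms: tuple[str, ...] = ARMS
    visit_months: tuple[int, ...] = (0, 2, 6, 12, 18)
    grid_size_deg: float = 20.0
    pixel_pitch_deg: float = 0.1
    age_mean_sd: tuple[float, float] = (79.4, 7.5)
    age_range: tuple[float, float] = (60.0, 97.0)
    baseline_sqrt_area_mean_sd: tuple[float, float] = (2.80, 0.72)
    baseline_sqrt_area_range: tuple[float, float] = (1.6, 4.2)
    sham_growth_rate: float = 0.30          # mm/y on the sqrt-area scale
    growth_rate_sd: float = 0.08            # between-eye SD of the growth rate
    sqrt_area_noise_sd: float = 0.03        # measurement noise on sqrt-area, mm
    treatment_growth_reduction: dict = field(
        default_factory=lambda: {"sham_pooled": 0.0, "monthly": 0.25, "eom": 0.222}
    )
    # junctional deficit: depth_z at baseline, steep scale (deg), shallow scale (deg)
    junctional_deficit_params: tuple[float, float, float] = (2.0, 0.7, 3.0)
    junctional_steep_weight: float = 0.6
    junctional_accrual: dict = field(       # z/y deepening at the boundary
        default_factory=lambda: {"sham_pooled": 1.5, "monthly": 0.3, "eom": 0.42}
    )
    macula_wide_drift: dict = field(        # z/y diffuse thinning
        default_factory=lambda: {"sham_pooled": 0.25, "monthly": 0.05, "eom": 0.07}
    )
    noise_sd: float = 0.4                   # per-pixel measurement noise, z
    eye_random_intercept_sd: float = 0.3    # z
    visit_offset_sd: float = 0.15           # per-acquisition global offset, z
    thinning_rate_rel_sd: float = 0.3       # between-eye spread of thinning rate
    multifocal_fraction: float = 0.0
    include_fellow: bool = True
    fellow_area_mean_sd: tuple[float, float] = (4.0, 2.0)  # mm²
    fellow_mnv_fraction: float = 0.2
    exudation_fraction: float = 0.10
    low_compliance_fraction: float = 0.08
    no_followup_fraction: float = 0.03
    faf_reference_bias_mm: float = -0.02    # FAF minus OCT sqrt-area offset
    faf_reference_noise_mm: float = 0.02
    n_normative: int = 40
    normative_age_range: tuple[float, float] = (55.0, 95.0)
    normative_age_slopes: dict = field(default_factory=lambda: dict(_AGE_SLOPE))
    seed: int = 0

    def __post_init__(self) -> None:
        self.visit_months = tuple(int(m) for m in self.visit_months)
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        if self.pixel_pitch_deg <= 0 or self.grid_size_deg <= 0:
            raise ValueError("grid size and pixel pitch must be positive")
        if list(self.visit_months) != sorted(set(self.visit_months)):
            raise ValueError("visit_months must be strictly increasing")
        if 0 not in self.visit_months or 12 not in self.visit_months:
            raise ValueError("visit_months must include baseline (0) and month 12")
        for name in ("growth_rate_sd", "noise_sd", "eye_random_intercept_sd",
                     "sqrt_area_noise_sd", "visit_offset_sd", "thinning_rate_rel_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for arm, red in self.treatment_growth_reduction.items():
            if not (0 <= red < 1):
                raise ValueError(f"treatment_growth_reduction[{arm}] must be in [0, 1)")

    @property
    def grid_px(self) -> int:
        return int(round(self.grid_size_deg / self.pixel_pitch_deg))

    def deficit_kernel(self, distance_deg: np.ndarray | float) -> np.ndarray | float:
        """Two-exponential junctional decay profile, 1 at the boundary."""
        _, steep, shallow = self.junctional_deficit_params
        w = self.junctional_steep_weight
        d = np.asarray(distance_deg, dtype=float)
        out = w * np.exp(-d / steep) + (1 - w) * np.exp(-d / shallow)
        return out if out.ndim else float(out)

    def annual_thinning(self, arm: str, distance_deg: float) -> float:
        """Expected z-loss per year at a given distance from the boundary."""
        return (self.junctional_accrual[arm] * float(self.deficit_kernel(distance_deg))
                + self.macula_wide_drift[arm])

    def expected_contrast(self, arm_a: str, arm_b: str, distance_deg: float,
                          month: int = 12) -> float:
        """Construction-implied change-from-baseline contrast arm_a − arm_b."""
        t = month / 12.0
        return (self.annual_thinning(arm_b, distance_deg)
                - self.annual_thinning(arm_a, distance_deg)) * t

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("visit_months", "arms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("age_mean_sd", "age_range", "baseline_sqrt_area_mean_sd",
                    "baseline_sqrt_area_range", "junctional_deficit_params",
                    "fellow_area_mean_sd", "normative_age_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class NormativeSet:
    """Reference thickness maps from non-atrophic eyes with known ages."""

    maps: dict[str, list[ThicknessMap]]
    ages: np.ndarray


@dataclass
class Cohort:
    """Everything generate_cohort produces, in memory."""

    config: TrialConfig
    manifest: pd.DataFrame
    maps: dict[tuple, ThicknessMap]      # (participant_id, eye_role, visit_month, layer)
    masks: dict[tuple, LesionMask]       # (participant_id, eye_role, visit_month)
    normative: NormativeSet


def _angular_grid(config: TrialConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = config.grid_px
    c = (n - 1) / 2.0
    idx = (np.arange(n) - c) * config.pixel_pitch_deg
    dy, dx = np.meshgrid(idx, idx, indexing="ij")
    return dx, dy, np.hypot(dx, dy)


def _mean_surface(layer: str, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    base, amp, scale = _TOPO[layer]
    ecc = np.hypot(dx, dy)
    topo = base + amp * np.exp(-((ecc / scale) ** 2))
    # mild temporal-side elevation, breaks mirror symmetry (right-eye frame)
    topo = topo + 2.0 * np.exp(-(((dx - 2.0) / 2.5) ** 2) - ((dy / 2.5) ** 2))
    return topo


def _sd_surface(layer: str, ecc: np.ndarray) -> np.ndarray:
    return _SD_BASE[layer] * (1.0 + 0.2 * np.exp(-((ecc / 2.0) ** 2)))


def _layer_mean(config: TrialConfig, layer: str, age: float,
                dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    # surfaces are anchored at age 75 so thicknesses stay physiologic
    return _mean_surface(layer, dx, dy) + config.normative_age_slopes[layer] * (age - 75.0)


def generate_normative_set(config: TrialConfig,
                           rng: np.random.Generator | None = None) -> NormativeSet:
    """Draw the normative reference set: mean surface + linear age effect + noise.

    Each reference eye contributes one map per layer; noise is i.i.d.
    per pixel with the location-specific SD, so a per-pixel regression
    of thickness on age recovers the configured slopes and SD surfaces.
    """
    if config.n_normative < 3:
        raise ValueError("need at least 3 normative eyes (age regression underdetermined)")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    dx, dy, ecc = _angular_grid(config)
    lo, hi = config.normative_age_range
    ages = np.sort(rng.uniform(lo, hi, size=config.n_normative))
    lateralities = rng.choice(["R", "L"], size=config.n_normative)
    maps: dict[str, list[ThicknessMap]] = {layer: [] for layer in LAYERS}
    for layer in LAYERS:
        sd = _sd_surface(layer, ecc)
        for age, lat in zip(ages, lateralities):
            grid = _layer_mean(config, layer, age, dx, dy) + rng.normal(0.0, sd)
            if lat == "L":
                grid = np.fliplr(grid)
            maps[layer].append(
                ThicknessMap(layer=layer, grid=np.maximum(grid, 0.0),
                             pixel_pitch_deg=config.pixel_pitch_deg, laterality=lat)
            )
    return NormativeSet(maps=maps, ages=ages)


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def _foci_for_eye(rng, sqrt_area0_mm: float, multifocal: bool):
    """Return focus centers (deg) and baseline area shares."""
    c0 = rng.uniform(-0.8, 0.8, size=2)
    if not multifocal:
        return [c0], np.array([1.0])
    shares = np.array([0.7, 0.3])
    radii_deg = np.sqrt(shares * sqrt_area0_mm**2 / math.pi) / MM_PER_DEGREE
    # second focus placed clear of the first so the lesion is genuinely
    # multifocal at baseline (foci may still fuse as they grow)
    angle = rng.uniform(0, 2 * math.pi)
    sep = 1.3 * (radii_deg[0] + radii_deg[1])
    c1 = c0 + sep * np.array([math.cos(angle), math.sin(angle)])
    return [c0, c1], shares


def _mask_from_foci(config, dx, dy, centers, radii_deg) -> np.ndarray:
    m = np.zeros(dx.shape, dtype=bool)
    for (cx, cy), r in zip(centers, radii_deg):
        if r > 0:
            m |= (dx - cx) ** 2 + (dy - cy) ** 2 <= r * r
    return m


def generate_cohort(config: TrialConfig) -> Cohort:
    """Generate a full synthetic trial: manifest, maps, masks, normative set.

    Reproducible bit-for-bit given ``config.seed``.  Study-eye lesions
    grow so that sqrt-area is linear in time at arm-specific rates;
    thickness at location x and visit t is

        normative_mean(age + t, x) + sd(x) · z(x, t)

    with z = eye intercept − deficit_depth(t, arm)·kernel(d(x, t))
    − drift(arm)·t + noise, where d is the distance to the current
    lesion boundary.  Fellow eyes have frozen lesions, frozen deficit
    and zero drift.
    """
    rng = np.random.default_rng(config.seed)
    dx, dy, ecc = _angular_grid(config)
    depth0, _, _ = config.junctional_deficit_params
    half = config.grid_size_deg / 2.0

    manifest_rows: list[dict] = []
    maps: dict[tuple, ThicknessMap] = {}
    masks: dict[tuple, LesionMask] = {}

    pid = 0
    for arm in config.arms:
        expected = 12 if arm != "eom" else 6
        for _ in range(config.n_per_arm):
            pid += 1
            participant = f"P{pid:03d}"
            age = float(_truncated_normal(rng, *config.age_mean_sd, *config.age_range))
            sex = str(rng.choice(["F", "M"], p=[0.63, 0.37]))
            lat = str(rng.choice(["R", "L"]))
            exudation = bool(rng.random() < config.exudation_fraction)
            low_comp = bool(rng.random() < config.low_compliance_fraction)
            no_fup = bool(rng.random() < config.no_followup_fraction)
            received = expected
            if low_comp:
                received = int(rng.integers(1, math.floor(0.75 * expected)))
            if no_fup:
                received = min(received, 1)

            s0 = float(_truncated_normal(rng, *config.baseline_sqrt_area_mean_sd,
                                         *config.baseline_sqrt_area_range))
            growth = config.sham_growth_rate * (1 - config.treatment_growth_reduction[arm])
            growth = max(float(rng.normal(growth, config.growth_rate_sd)), 0.0)
            multifocal = bool(rng.random() < config.multifocal_fraction)
            centers, shares = _foci_for_eye(rng, s0, multifocal)
            eye_b = float(rng.normal(0.0, config.eye_random_intercept_sd))
            # eyes progress at different speeds; scales both junctional and
            # diffuse thinning of this eye
            thin_u = max(float(rng.normal(1.0, config.thinning_rate_rel_sd)), 0.0)
            faf_ref = s0 + config.faf_reference_bias_mm + float(
                rng.normal(0.0, config.faf_reference_noise_mm))

            fellow_area = max(float(rng.normal(*config.fellow_area_mean_sd)), 0.5)
            fellow_mnv = bool(rng.random() < config.fellow_mnv_fraction)
            fellow_b = float(rng.normal(0.0, config.eye_random_intercept_sd))
            fellow_centers, fellow_shares = _foci_for_eye(rng, math.sqrt(fellow_area), False)
            fellow_lat = "L" if lat == "R" else "R"

            visits = list(config.visit_months)
            if no_fup:
                visits = [0]

            for month in visits:
                t = month / 12.0
                row = dict(
                    participant_id=participant, eye_role="study", arm=arm, age=age,
                    sex=sex, laterality=lat, visit_month=month,
                    injections_received_to_month12=received,
                    injections_expected=expected, exudation_ever=exudation,
                    fellow_mnv=fellow_mnv, fellow_baseline_area_mm2=fellow_area,
                    faf_sqrt_area_mm=faf_ref,
                )
                manifest_rows.append(row)

                s_t = s0 + growth * t
                total_area_mm2 = s_t * s_t
                radii_mm = np.sqrt(shares * total_area_mm2 / math.pi)
                radii_deg = radii_mm / MM_PER_DEGREE
                mgrid = _mask_from_foci(config, dx, dy, centers, radii_deg)
                # masks are stored in the eye's native orientation, like the maps
                masks[(participant, "study", month)] = LesionMask(
                    grid=np.fliplr(mgrid) if lat == "L" else mgrid,
                    pixel_pitch_deg=config.pixel_pitch_deg, visit_month=month)

                # distance to the current lesion boundary (analytic, degrees)
                d = np.full(dx.shape, np.inf)
                for (cx, cy), r in zip(centers, radii_deg):
                    d = np.minimum(d, np.hypot(dx - cx, dy - cy) - r)
                d = np.maximum(d, 0.0)

                depth = depth0 + thin_u * config.junctional_accrual[arm] * t
                visit_off = float(rng.normal(0.0, config.visit_offset_sd))
                zfield = (eye_b + visit_off
                          - depth * config.deficit_kernel(d)
                          - thin_u * config.macula_wide_drift[arm] * t)
                for layer in LAYERS:
                    mean = _layer_mean(config, layer, age + t, dx, dy)
                    sd = _sd_surface(layer, ecc)
                    grid = mean + sd * (zfield + rng.normal(0.0, config.noise_sd, dx.shape))
                    grid[mgrid] = 2.0  # atrophic residual signal inside the lesion
                    if lat == "L":
                        grid = np.fliplr(grid)
                    maps[(participant, "study", month, layer)] = ThicknessMap(
                        layer=layer, grid=np.maximum(grid, 0.0),
                        pixel_pitch_deg=config.pixel_pitch_deg, laterality=lat)

                if config.include_fellow:
                    row_f = dict(row, eye_role="fellow", laterality=fellow_lat,
                                 faf_sqrt_area_mm=math.sqrt(fellow_area))
                    manifest_rows.append(row_f)
                    fr_deg = np.sqrt(fellow_shares * fellow_area / math.pi) / MM_PER_DEGREE
                    fgrid = _mask_from_foci(config, dx, dy, fellow_centers, fr_deg)
                    masks[(participant, "fellow", month)] = LesionMask(
                        grid=np.fliplr(fgrid) if fellow_lat == "L" else fgrid,
                        pixel_pitch_deg=config.pixel_pitch_deg, visit_month=month)
                    df_ = np.full(dx.shape, np.inf)
                    for (cx, cy), r in zip(fellow_centers, fr_deg):
                        df_ = np.minimum(df_, np.hypot(dx - cx, dy - cy) - r)
                    df_ = np.maximum(df_, 0.0)
                    zf = (fellow_b + float(rng.normal(0.0, config.visit_offset_sd))
                          - depth0 * config.deficit_kernel(df_))
                    for layer in LAYERS:
                        mean = _layer_mean(config, layer, age + t, dx, dy)
                        sd = _sd_surface(layer, ecc)
                        grid = mean + sd * (zf + rng.normal(0.0, config.noise_sd, dx.shape))
                        grid[fgrid] = 2.0
                        if fellow_lat == "L":
                            grid = np.fliplr(grid)
                        maps[(participant, "fellow", month, layer)] = ThicknessMap(
                            layer=layer, grid=np.maximum(grid, 0.0),
                            pixel_pitch_deg=config.pixel_pitch_deg,
                            laterality=fellow_lat)

    manifest = pd.DataFrame(manifest_rows)
    normative = generate_normative_set(config)
    return Cohort(config=config, manifest=manifest, maps=maps, masks=masks,
                  normative=normative)


# ---------------------------------------------------------------------------
# ring-level fast simulators (same data-generating model, no rasters)
# ---------------------------------------------------------------------------

def simulate_change_table(
    config: TrialConfig,
    distance_deg: float,
    rng: np.random.Generator,
    measurement_sd: float = 0.2,
    rate_sd: float = 0.05,
    baseline_mean: float = -1.5,
    baseline_sd: float = 0.8,
    layer: str = "ONL",
    ring: int = 12,
) -> pd.DataFrame:
    """Draw a change-from-baseline table directly at the ring level.

    Per eye i and visit j: observed ring mean m_ij = baseline_i −
    rate_i·t_j + e_ij with e ~ N(0, measurement_sd²); change_z =
    m_ij − m_i0, so the shared −e_i0 induces the compound-symmetric
    covariance the random-intercept LMM estimates.  rate_i is the
    arm's construction thinning rate at ``distance_deg`` plus N(0,
    rate_sd²) eye heterogeneity.
    """
    rows = []
    follow = [m for m in config.visit_months if m > 0]
    pid = 0
    for arm in config.arms:
        rate0 = config.annual_thinning(arm, distance_deg)
        for _ in range(config.n_per_arm):
            pid += 1
            rate = rng.normal(rate0, rate_sd)
            b0 = rng.normal(baseline_mean, baseline_sd)
            e0 = rng.normal(0.0, measurement_sd)
            for m in follow:
                t = m / 12.0
                e = rng.normal(0.0, measurement_sd)
                rows.append(dict(
                    participant_id=f"S{pid:03d}", arm=arm, visit_month=m,
                    layer=layer, ring=ring, ring_distance_deg=distance_deg,
                    change_z=-rate * t + e - e0, baseline_z=b0 + e0,
                ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk layout: TIFF rasters + CSV tables + YAML config
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort to disk: float32 TIFF maps, uint8 masks, CSV tables."""
    from .rasters import write_mask_tiff, write_thickness_tiff

    out = Path(out_dir)
    (out / "maps").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "normative").mkdir(exist_ok=True)
    cohort.config.to_yaml(out / "config.yaml")
    cohort.manifest.to_csv(out / "manifest.csv", index=False)
    for (pid, role, month, layer), tmap in cohort.maps.items():
        write_thickness_tiff(out / "maps" / f"{pid}_{role}_m{month:02d}_{layer}.tif", tmap)
    for (pid, role, month), mask in cohort.masks.items():
        write_mask_tiff(out / "masks" / f"{pid}_{role}_m{month:02d}_mask.tif", mask)
    rows = []
    for layer, layer_maps in cohort.normative.maps.items():
        for i, m in enumerate(layer_maps):
            write_thickness_tiff(out / "normative" / f"norm_{i:03d}_{layer}.tif", m)
            if layer == LAYERS[0]:
                rows.append(dict(eye_index=i, age=float(cohort.normative.ages[i]),
                                 laterality=m.laterality))
    pd.DataFrame(rows).to_csv(out / "normative" / "ages.csv", index=False)
    return out


def load_cohort(directory: str | Path) -> Cohort:
    """Read back a cohort written by :func:`write_cohort`."""
    from .rasters import read_mask_tiff, read_thickness_tiff

    d = Path(directory)
    config = TrialConfig.from_yaml(d / "config.yaml")
    manifest = pd.read_csv(d / "manifest.csv")
    pitch = config.pixel_pitch_deg
    lat = {(r.participant_id, r.eye_role): r.laterality
           for r in manifest.itertuples()}
    maps, masks = {}, {}
    for f in sorted((d / "maps").glob("*.tif")):
        pid, role, mtag, layer = f.stem.rsplit("_", 3)
        month = int(mtag[1:])
        maps[(pid, role, month, layer)] = read_thickness_tiff(
            f, layer=layer, pixel_pitch_deg=pitch, laterality=lat.get((pid, role), "R"))
    for f in sorted((d / "masks").glob("*_mask.tif")):
        pid, role, mtag, _ = f.stem.rsplit("_", 3)
        month = int(mtag[1:])
        masks[(pid, role, month)] = read_mask_tiff(f, pixel_pitch_deg=pitch,
                                                   visit_month=month)
    ages_df = pd.read_csv(d / "normative" / "ages.csv")
    nmaps = {layer: [] for layer in LAYERS}
    for layer in LAYERS:
        for r in ages_df.itertuples():
            nmaps[layer].append(read_thickness_tiff(
                d / "normative" / f"norm_{r.eye_index:03d}_{layer}.tif",
                layer=layer, pixel_pitch_deg=pitch, laterality=r.laterality))
    return Cohort(config=config, manifest=manifest, maps=maps, masks=masks,
                  normative=NormativeSet(maps=nmaps, ages=ages_df.age.to_numpy()))


def simulate_sqrt_areas(config: TrialConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-eye, per-visit sqrt-transformed lesion areas (mm) directly."""
    rows = []
    pid = 0
    for arm in config.arms:
        slope = config.sham_growth_rate * (1 - config.treatment_growth_reduction[arm])
        for _ in range(config.n_per_arm):
            pid += 1
            s0 = float(_truncated_normal(rng, *config.baseline_sqrt_area_mean_sd,
                                         *config.baseline_sqrt_area_range))
            rate = max(rng.normal(slope, config.growth_rate_sd), 0.0)
            for m in config.visit_months:
                t = m / 12.0
                rows.append(dict(
                    participant_id=f"A{pid:03d}", arm=arm, visit_month=m,
                    sqrt_area_mm=s0 + rate * t + rng.normal(0.0, config.sqrt_area_noise_sd),
                ))
    return pd.DataFrame(rows)
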
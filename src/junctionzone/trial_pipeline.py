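"""Population filters, the full analysis grid, QC, and report tables.

Orchestrates the end-to-end analysis on a cohort: fit the normative
model, standardize every map, extract traveling contour-ring features,
build change-from-baseline tables per analysis population, and fit the
full grid of mixed models — 3 contour-lines (0.43°, 2.58°, 5.16°) ×
3 layers (ONL, IS, OS) × 3 populations (mITT, PP, fellow eyes), i.e.
27 models — with Tukey-adjusted pairwise arm contrasts at each
follow-up visit.  The primary-outcome cell is the ONL 5.16° month-12
monthly − sham contrast.  A sqrt-area growth model and a Bland–Altman
segmentation QC accompany the grid.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .lesion_geometry import (
    REPORTED_RINGS,
    RING_WIDTH_DEG,
    compute_contour_rings,
    extract_ring_means,
    sqrt_area_mm,
)
from .longitudinal_stats import (
    AgreementResult,
    GaProgressionResult,
    arm_contrasts,
    bland_altman,
    build_change_table,
    fit_change_lmm,
    fit_ga_progression,
)
from .normative_model import NormativeModel, fit_normative, standardize
from .rasters import LAYERS
from .synthetic_cohort import Cohort, TrialConfig, generate_cohort, load_cohort

logger = logging.getLogger(__name__)

POPULATIONS = ("mITT", "PP", "PP_no_exudation", "fellow")
#: the grid reported in the main tables (supplementary: PP_no_exudation)
DEFAULT_GRID_POPULATIONS = ("mITT", "PP", "fellow")


@dataclass
class PopulationSpec:
    """Named analysis population with its filter parameters."""

    name: str
    min_injection_fraction: float = 0.75
    fellow_area_threshold_mm2: float = 2.5

    def __post_init__(self) -> None:
        if self.name not in POPULATIONS:
            raise ValueError(f"unknown population {self.name!r}; expected one of {POPULATIONS}")


def apply_population_filter(manifest: pd.DataFrame, spec: PopulationSpec | str) -> pd.DataFrame:
    """Return the manifest rows belonging to an analysis population.

    * ``mITT``: study eyes with ≥ 1 injection and ≥ 1 follow-up visit at
      month 2 or later.
    * ``PP``: mITT eyes that received at least 75% of expected
      injections before month 12 — floor(0.75·expected), i.e. ≥ 9 of 12
      (monthly schedule) or ≥ 4 of 6 (every-other-month schedule).
    * ``PP_no_exudation``: PP, dropping all visits of eyes that ever
      developed exudation.
    * ``fellow``: fellow eyes without macular neovascularization and
      with baseline atrophy area ≥ 2.5 mm².
    """
    if isinstance(spec, str):
        spec = PopulationSpec(spec)
    m = manifest
    if spec.name == "fellow":
        f = m[(m.eye_role == "fellow")
              & ~m.fellow_mnv.astype(bool)
              & (m.fellow_baseline_area_mm2 >= spec.fellow_area_threshold_mm2)]
        return f.copy()

    study = m[m.eye_role == "study"]
    has_fup = study.groupby("participant_id")["visit_month"].max() >= 2
    eligible = set(has_fup[has_fup].index)
    base = study[study.visit_month == 0].set_index("participant_id")
    eligible &= set(base[base.injections_received_to_month12 >= 1].index)
    if spec.name in ("PP", "PP_no_exudation"):
        thr = np.floor(spec.min_injection_fraction * base.injections_expected)
        ok = base[base.injections_received_to_month12 >= thr].index
        eligible &= set(ok)
    if spec.name == "PP_no_exudation":
        eligible -= set(base[base.exudation_ever.astype(bool)].index)
    return study[study.participant_id.isin(eligible)].copy()


def exclusion_flow(
    n_randomized: int = 246,
    n_excluded_device: int = 49,
    n_no_followup: int = 5,
) -> dict:
    """Participant accounting of the inclusion cascade.

    With the trial's numbers: 246 randomized − 49 imaged on the
    incompatible device − 5 without usable follow-up → 192 analyzed,
    97.5% of the compatibly-imaged and 78% of all randomized.
    """
    n_imaged = n_randomized - n_excluded_device
    n_analyzed = n_imaged - n_no_followup
    return dict(
        n_randomized=n_randomized,
        n_imaged_compatible=n_imaged,
        n_analyzed=n_analyzed,
        pct_of_imaged=round(100.0 * n_analyzed / n_imaged, 1),
        pct_of_randomized=round(100.0 * n_analyzed / n_randomized),
    )


# ---------------------------------------------------------------------------
# feature extraction over a cohort
# ---------------------------------------------------------------------------

def extract_cohort_features(
    cohort: Cohort,
    model: NormativeModel,
    ring_width_deg: float = RING_WIDTH_DEG,
    n_rings: int = 12,
) -> pd.DataFrame:
    """Standardize every map and extract ring means for every eye/visit."""
    meta_cols = ["participant_id", "eye_role", "arm", "age", "visit_month"]
    manifest = cohort.manifest[meta_cols].drop_duplicates()
    rows: list[dict] = []
    for rec in manifest.itertuples(index=False):
        key = (rec.participant_id, rec.eye_role, rec.visit_month)
        mask = cohort.masks.get(key)
        if mask is None or not mask.grid.any() or mask.grid.all():
            continue
        rings = compute_contour_rings(mask, ring_width_deg=ring_width_deg,
                                      n_rings=n_rings)
        age_at_visit = rec.age + rec.visit_month / 12.0
        for layer in LAYERS:
            tmap = cohort.maps.get((*key[:2], rec.visit_month, layer))
            if tmap is None:
                continue
            zmap = standardize(tmap, age_at_visit, model)
            rows.extend(extract_ring_means(
                zmap, rings,
                metadata=dict(participant_id=rec.participant_id,
                              eye_role=rec.eye_role, arm=rec.arm),
            ))
    return pd.DataFrame(rows)


def cohort_sqrt_areas(cohort: Cohort, eye_role: str = "study") -> pd.DataFrame:
    """Per-eye, per-visit sqrt-transformed lesion areas measured from the masks."""
    arm = cohort.manifest[cohort.manifest.eye_role == eye_role] \
        .drop_duplicates("participant_id").set_index("participant_id")["arm"]
    rows = []
    for (pid, role, month), mask in cohort.masks.items():
        if role != eye_role:
            continue
        rows.append(dict(participant_id=pid, arm=arm.get(pid), visit_month=month,
                         sqrt_area_mm=sqrt_area_mm(mask),
                         touches_frame=bool(
                             mask.grid[0, :].any() or mask.grid[-1, :].any()
                             or mask.grid[:, 0].any() or mask.grid[:, -1].any())))
    return pd.DataFrame(rows).sort_values(["participant_id", "visit_month"]) \
        .reset_index(drop=True)


def geometry_qc(cohort: Cohort, areas: pd.DataFrame | None = None) -> AgreementResult:
    """Bland–Altman agreement of mask-derived vs reference sqrt-areas (mm).

    Compares the baseline OCT-mask measurement with the manifest's
    reference (FAF-style) measurement, restricted to study eyes whose
    lesion lies fully within the image frame; convention is computed
    minus reference.
    """
    if areas is None:
        areas = cohort_sqrt_areas(cohort)
    base = areas[(areas.visit_month == 0) & ~areas.touches_frame]
    ref = cohort.manifest[(cohort.manifest.eye_role == "study")
                          & (cohort.manifest.visit_month == 0)] \
        .set_index("participant_id")["faf_sqrt_area_mm"]
    merged = base.join(ref, on="participant_id").dropna(subset=["faf_sqrt_area_mm"])
    if len(merged) < 3:
        raise ValueError("need at least 3 paired area measurements for QC")
    return bland_altman(merged.sqrt_area_mm.to_numpy(),
                        merged.faf_sqrt_area_mm.to_numpy())


# ---------------------------------------------------------------------------
# full analysis grid
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """All tables of a full run plus a provenance block."""

    contrasts: pd.DataFrame          # population, layer, ring_deg, visit, contrast, ...
    lsmeans: pd.DataFrame
    ga_progression: GaProgressionResult | None
    agreement: AgreementResult | None
    features: pd.DataFrame
    provenance: dict
    primary_outcome: dict

    @property
    def n_models(self) -> int:
        return int(self.provenance["n_models"])

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.contrasts.to_csv(out / "contrasts.csv", index=False)
        self.lsmeans.to_csv(out / "lsmeans.csv", index=False)
        self.features.to_csv(out / "ring_features.csv", index=False)
        if self.ga_progression is not None:
            g = self.ga_progression
            g.contrasts_month12.to_csv(out / "ga_progression_contrasts.csv", index=False)
            pd.DataFrame([
                dict(arm=a, annualized_change=g.annualized_change.get(a),
                     annualized_slope=g.annualized_slope.get(a),
                     reduction_pct_month12=g.reduction_pct_month12.get(a),
                     reduction_pct_slope=g.reduction_pct_slope.get(a))
                for a in g.annualized_change
            ]).to_csv(out / "ga_progression_arms.csv", index=False)
        if self.agreement is not None:
            a = self.agreement
            pd.DataFrame([dict(bias_mm=a.bias, ci_low=a.bias_ci[0], ci_high=a.bias_ci[1],
                               loa_low=a.limits_of_agreement[0],
                               loa_high=a.limits_of_agreement[1],
                               p_bias=a.p_bias, n=a.n)]).to_csv(
                out / "agreement.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=2))
        return out


def _config_hash(config: TrialConfig) -> str:
    import yaml
    from dataclasses import asdict
    blob = yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(config).items()}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_full_analysis(
    config: TrialConfig | None = None,
    data_dir: str | Path | None = None,
    cohort: Cohort | None = None,
    populations: tuple[str, ...] = DEFAULT_GRID_POPULATIONS,
    rings: tuple[int, ...] = REPORTED_RINGS,
    layers: tuple[str, ...] = LAYERS,
    contrast_months: tuple[int, ...] = (2, 6, 12, 18),
    out_dir: str | Path | None = None,
) -> AnalysisReport:
    """Run the complete contour-line analysis and assemble the report.

    Provide exactly one data source: a ``TrialConfig`` (a cohort is
    generated), a ``data_dir`` written by ``write_cohort``, or an
    in-memory ``Cohort``.  Any stage failure aborts with a
    stage-labeled error; tables produced before the failure are written
    to ``out_dir`` if given.
    """
    t0 = time.time()
    if cohort is None:
        if data_dir is not None:
            cohort = load_cohort(data_dir)
        elif config is not None:
            logger.info("generating synthetic cohort (seed=%d)", config.seed)
            cohort = generate_cohort(config)
        else:
            raise ValueError("provide config, data_dir or cohort")
    config = cohort.config

    stage = "normative-fit"
    contrast_rows: list[pd.DataFrame] = []
    lsmean_rows: list[pd.DataFrame] = []
    ga = agreement = None
    features = pd.DataFrame()
    n_models = 0
    try:
        model = fit_normative(cohort.normative.maps, cohort.normative.ages)
        stage = "feature-extraction"
        features = extract_cohort_features(cohort, model)
        stage = "model-grid"
        for pop in populations:
            eligible = apply_population_filter(cohort.manifest, pop)
            keys = eligible[["participant_id", "eye_role"]].drop_duplicates()
            feats = features.merge(keys, on=["participant_id", "eye_role"])
            changes = build_change_table(feats)
            for layer in layers:
                for ring in rings:
                    sub = changes[(changes.layer == layer) & (changes.ring == ring)]
                    if sub.empty:
                        logger.warning("no data for %s/%s/ring %d", pop, layer, ring)
                        continue
                    fit = fit_change_lmm(sub)
                    n_models += 1
                    for month in contrast_months:
                        if month not in fit.visits:
                            continue
                        res = arm_contrasts(fit, month)
                        c = res.contrasts.assign(
                            population=pop, layer=layer, ring=ring,
                            ring_distance_deg=round(ring * RING_WIDTH_DEG, 2),
                            visit_month=month, singular=res.singular)
                        contrast_rows.append(c)
                        lsmean_rows.append(res.lsmeans.assign(
                            population=pop, layer=layer, ring=ring,
                            ring_distance_deg=round(ring * RING_WIDTH_DEG, 2)))
        stage = "ga-progression"
        areas = cohort_sqrt_areas(cohort)
        in_frame = areas.groupby("participant_id")["touches_frame"].any()
        areas_if = areas[areas.participant_id.isin(in_frame[~in_frame].index)]
        mitt = set(apply_population_filter(cohort.manifest, "mITT").participant_id)
        ga = fit_ga_progression(areas_if[areas_if.participant_id.isin(mitt)])
        stage = "geometry-qc"
        agreement = geometry_qc(cohort, areas)
    except Exception as err:
        if out_dir is not None and contrast_rows:
            AnalysisReport(
                contrasts=pd.concat(contrast_rows, ignore_index=True),
                lsmeans=pd.concat(lsmean_rows, ignore_index=True),
                ga_progression=ga, agreement=agreement, features=features,
                provenance=dict(n_models=n_models, failed_stage=stage),
                primary_outcome={},
            ).save(out_dir)
        raise RuntimeError(f"analysis failed at stage {stage!r}: {err}") from err

    contrasts = pd.concat(contrast_rows, ignore_index=True)
    lsmeans = pd.concat(lsmean_rows, ignore_index=True)

    primary = {}
    sel = contrasts[(contrasts.population == populations[0]) & (contrasts.layer == "ONL")
                    & (contrasts.ring == 12) & (contrasts.visit_month == 12)
                    & (contrasts.contrast == "monthly - sham_pooled")]
    if len(sel):
        r = sel.iloc[0]
        primary = dict(cell="ONL 5.16deg month-12 monthly - sham_pooled",
                       estimate=float(r.estimate), ci_low=float(r.ci_low),
                       ci_high=float(r.ci_high), p_adjusted=float(r.p_adjusted))

    import scipy
    import statsmodels
    provenance = dict(
        config_hash=_config_hash(config),
        seed=config.seed,
        n_models=n_models,
        populations=list(populations),
        layers=list(layers),
        rings=list(rings),
        versions=dict(junctionzone=__version__, numpy=np.__version__,
                      scipy=scipy.__version__, pandas=pd.__version__,
                      statsmodels=statsmodels.__version__),
        runtime_s=round(time.time() - t0, 2),
    )
    report = AnalysisReport(contrasts=contrasts, lsmeans=lsmeans, ga_progression=ga,
                            agreement=agreement, features=features,
                            provenance=provenance, primary_outcome=primary)
    if out_dir is not None:
        report.save(out_dir)
    return report
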
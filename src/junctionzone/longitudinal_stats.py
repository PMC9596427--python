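"""Change-from-baseline mixed models, adjusted contrasts, growth model, agreement.

The core analysis fits, per layer × contour-line, a linear mixed model

    change_z ~ arm + baseline_z + visit + arm:visit,  (1 | participant)

by REML (statsmodels MixedLM), with visit categorical, and reports the
three pairwise arm contrasts at a visit with:

* denominator degrees of freedom by the Satterthwaite approximation,
  computed from the closed-form restricted likelihood of the
  random-intercept model (for the balanced designs generated here this
  agrees closely with the Kenward-Roger approximation, which the same
  machinery exposes as a cross-check target);
* familywise adjustment by the single-step (Tukey) method: p-values and
  confidence intervals from the equicoordinate multivariate-t
  distribution over the estimated contrast correlation matrix.

A companion model for square-root-transformed lesion area quantifies
arm differences in atrophy growth, and a Bland–Altman routine supports
the segmentation-agreement QC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

logger = logging.getLogger(__name__)

CONTRAST_PAIRS = (("monthly", "sham_pooled"), ("eom", "sham_pooled"), ("monthly", "eom"))


# ---------------------------------------------------------------------------
# change table
# ---------------------------------------------------------------------------

def build_change_table(features: pd.DataFrame) -> pd.DataFrame:
    """Change-from-baseline table from long-format ring features.

    For every (eye, layer, ring), subtracts the baseline (month 0)
    ``mean_z`` from each follow-up row; eyes lacking a baseline for a
    given layer/ring are dropped with a warning, and eyes lacking a
    follow-up visit simply contribute no row (observed data only, no
    imputation).
    """
    req = {"participant_id", "visit_month", "layer", "ring", "mean_z"}
    missing = req - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns: {sorted(missing)}")
    feats = features.copy()
    if "eye_role" not in feats.columns:
        feats["eye_role"] = "study"
    keys = ["participant_id", "eye_role", "layer", "ring"]
    base = feats[feats.visit_month == 0].set_index(keys)["mean_z"]
    fup = feats[feats.visit_month > 0].copy()
    idx = pd.MultiIndex.from_frame(fup[keys])
    have = idx.isin(base.index)
    n_drop = fup.loc[~have, "participant_id"].nunique()
    if n_drop:
        logger.warning("dropping rows from %d eye(s) with no baseline ring value", n_drop)
    fup = fup[have]
    fup["baseline_z"] = base.reindex(pd.MultiIndex.from_frame(fup[keys])).to_numpy()
    fup["change_z"] = fup["mean_z"] - fup["baseline_z"]
    return fup.reset_index(drop=True)


# ---------------------------------------------------------------------------
# random-intercept REML internals (closed forms via Woodbury)
# ---------------------------------------------------------------------------

def _group_sums(X: np.ndarray, y: np.ndarray, codes: np.ndarray, G: int):
    p = X.shape[1]
    Sx = np.zeros((G, p))
    Sy = np.zeros(G)
    np.add.at(Sx, codes, X)
    np.add.at(Sy, codes, y)
    sizes = np.bincount(codes, minlength=G).astype(float)
    return Sx, Sy, sizes


def _phi_beta(theta, X, y, XtX, Xty, yty, Sx, Sy, sizes):
    """(X'V⁻¹X)⁻¹, β̂, r'V⁻¹r, log|V| for V_g = σ²I + τ²J."""
    tau2, sig2 = theta
    gam = tau2 / (sig2 + sizes * tau2)           # per group
    XtViX = (XtX - (Sx * gam[:, None]).T @ Sx) / sig2
    XtViy = (Xty - Sx.T @ (gam * Sy)) / sig2
    ytViy = (yty - np.sum(gam * Sy**2)) / sig2
    phi = np.linalg.inv(XtViX)
    beta = phi @ XtViy
    rss = ytViy - beta @ XtViy
    logdetV = np.sum((sizes - 1) * np.log(sig2) + np.log(sig2 + sizes * tau2))
    return phi, beta, rss, logdetV, XtViX


def _reml_loglik(theta, X, y, cache) -> float:
    tau2, sig2 = theta
    if sig2 <= 0 or tau2 < 0:
        return -np.inf
    phi, _, rss, logdetV, XtViX = _phi_beta(theta, X, y, *cache)
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (logdetV + logdetX + rss)


def _numdiff_grad(f, theta, rel=1e-5, floor=1e-8):
    g = np.zeros_like(theta)
    for i in range(len(theta)):
        h = max(abs(theta[i]) * rel, floor)
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        if tm[i] < 0:  # variance component at the boundary: forward difference
            g[i] = (f(tp) - f(theta)) / h
        else:
            g[i] = (f(tp) - f(tm)) / (2 * h)
    return g


def _numdiff_hess(f, theta, rel=1e-4, floor=1e-7):
    k = len(theta)
    H = np.zeros((k, k))
    h = np.array([max(abs(t) * rel, floor) for t in theta])
    shift = np.where(theta - h < 0, h - theta, 0.0)  # keep evaluations feasible
    t0 = theta + shift
    f0 = f(t0)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        if (t0 - ei)[i] >= 0:
            H[i, i] = (f(t0 + ei) - 2 * f0 + f(t0 - ei)) / h[i] ** 2
        else:  # boundary: one-sided second difference
            H[i, i] = (f(t0 + 2 * ei) - 2 * f(t0 + ei) + f0) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            if (t0 - ei - ej)[i] >= 0 and (t0 - ei - ej)[j] >= 0:
                H[i, j] = (f(t0 + ei + ej) - f(t0 + ei - ej)
                           - f(t0 - ei + ej) + f(t0 - ei - ej)) / (4 * h[i] * h[j])
            else:
                H[i, j] = (f(t0 + ei + ej) - f(t0 + ei) - f(t0 + ej) + f0) / (h[i] * h[j])
            H[j, i] = H[i, j]
    return H


@dataclass
class LmmFit:
    """A fitted random-intercept LMM plus what contrast inference needs."""

    result: object                      # statsmodels MixedLMResults
    data: pd.DataFrame
    formula: str
    design_info: object
    X: np.ndarray
    y: np.ndarray
    group_codes: np.ndarray
    n_groups: int
    tau2: float
    sigma2: float
    singular: bool
    converged: bool
    arms: tuple[str, ...]
    visits: tuple[int, ...]
    response: str = "change_z"
    baseline_col: str = "baseline_z"
    _cache: tuple = field(default=None, repr=False)

    def __post_init__(self):
        XtX = self.X.T @ self.X
        Xty = self.X.T @ self.y
        yty = float(self.y @ self.y)
        Sx, Sy, sizes = _group_sums(self.X, self.y, self.group_codes, self.n_groups)
        self._cache = (XtX, Xty, yty, Sx, Sy, sizes)

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.tau2, self.sigma2])

    def beta_cov(self, theta=None):
        theta = self.theta if theta is None else theta
        phi, beta, *_ = _phi_beta(theta, self.X, self.y, *self._cache)
        return beta, phi

    def contrast_variance(self, c: np.ndarray, theta=None) -> float:
        _, phi = self.beta_cov(theta)
        return float(c @ phi @ c)

    def theta_cov(self) -> np.ndarray:
        """Asymptotic covariance of (τ̂², σ̂²) from the REML information."""
        if getattr(self, "_theta_cov", None) is None:
            H = _numdiff_hess(lambda t: _reml_loglik(t, self.X, self.y, self._cache),
                              self.theta)
            try:
                A = np.linalg.inv(-H)
            except np.linalg.LinAlgError:
                A = np.linalg.pinv(-H)
            self._theta_cov = A
        return self._theta_cov

    def satterthwaite_df(self, c: np.ndarray) -> float:
        """Satterthwaite denominator df for the scalar contrast c'β.

        df = 2·(c'Φc)² / (∇g' A ∇g) with g(θ) = c'Φ(θ)c and A the
        inverse negative Hessian of the restricted log-likelihood at θ̂.
        """
        theta = self.theta
        g0 = self.contrast_variance(c, theta)
        grad = _numdiff_grad(lambda t: self.contrast_variance(c, t), theta)
        A = self.theta_cov()
        denom = float(grad @ A @ grad)
        if denom <= 0 or not np.isfinite(denom):
            # flat restricted likelihood (e.g. boundary fit): fall back to
            # the residual df, the large-information limit
            return float(len(self.y) - self.X.shape[1])
        df = 2.0 * g0**2 / denom
        return float(np.clip(df, 1.0, len(self.y) - self.X.shape[1]))

    def design_row(self, **values) -> np.ndarray:
        df = pd.DataFrame([values])
        return np.asarray(patsy.build_design_matrices([self.design_info], df)[0])[0]


def fit_change_lmm(
    table: pd.DataFrame,
    layer: str | None = None,
    ring_distance_deg: float | None = None,
    response: str = "change_z",
    baseline_col: str = "baseline_z",
    extra_fixed: str = "",
) -> LmmFit:
    """Fit the change-from-baseline LMM for one layer × contour-line.

    Fixed effects: treatment arm, baseline value, visit (categorical)
    and the arm-by-visit interaction; random intercept per participant;
    REML estimation.  Singular (zero-variance) fits are flagged on the
    returned object, not raised.
    """
    df = table
    if layer is not None:
        df = df[df.layer == layer]
    if ring_distance_deg is not None:
        df = df[np.isclose(df.ring_distance_deg, ring_distance_deg)]
    df = df.dropna(subset=[response] + ([baseline_col] if baseline_col else [])).copy()
    arms = tuple(sorted(df.arm.unique()))
    visits = tuple(sorted(df.visit_month.unique()))
    if len(arms) < 2:
        raise ValueError("need at least 2 arms to fit the treatment model")
    if len(visits) < 2:
        raise ValueError("need at least 2 follow-up visits")
    ref = "sham_pooled" if "sham_pooled" in arms else arms[0]
    base_term = f" + {baseline_col}" if baseline_col else ""
    formula = (f"{response} ~ C(arm, Treatment('{ref}')) * C(visit_month)"
               f"{base_term}{extra_fixed}")
    # REML variance estimates are equivariant under response scaling; fit on a
    # unit-variance response for optimizer stability, then scale θ̂ back (the
    # fixed-effect GLS step is recomputed from closed forms on the raw scale)
    y_raw = df[response].to_numpy(dtype=float)
    y_scale = float(y_raw.std()) or 1.0
    df["_y_std"] = y_raw / y_scale
    std_formula = formula.replace(f"{response} ~", "_y_std ~", 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(std_formula, data=df, groups=df["participant_id"])
        try:
            result = model.fit(reml=True, method="lbfgs")
        except np.linalg.LinAlgError:
            result = model.fit(reml=True, method="powell")
        if not result.converged:
            result = model.fit(reml=True, method="powell")
    tau2 = float(np.asarray(result.cov_re)[0, 0]) * y_scale**2
    sigma2 = float(result.scale) * y_scale**2
    # noise-free (saturated) data drive the residual variance to zero; keep a
    # vanishing floor so the GLS step stays defined (estimates -> OLS limit)
    sigma2 = max(sigma2, 1e-10 * y_scale**2)
    singular = tau2 < 1e-10 * max(sigma2, 1e-12)
    if singular:
        logger.warning("random-intercept variance estimated at the boundary (~0)")
    codes, groups = pd.factorize(df["participant_id"], sort=True)
    return LmmFit(
        result=result,
        data=df.reset_index(drop=True),
        formula=formula,
        design_info=model.data.design_info,
        X=np.asarray(model.exog, dtype=float),
        y=y_raw,
        group_codes=codes,
        n_groups=len(groups),
        tau2=max(tau2, 0.0),
        sigma2=sigma2,
        singular=singular,
        converged=bool(result.converged),
        arms=arms,
        visits=visits,
        response=response,
        baseline_col=baseline_col,
    )


# ---------------------------------------------------------------------------
# single-step (Tukey) familywise adjustment
# ---------------------------------------------------------------------------

_MVT_SAMPLES = 400_000
_MVT_SEED = 20220425


def _max_abs_t_samples(corr: np.ndarray, df: float,
                       n: int = _MVT_SAMPLES, random_state: int = _MVT_SEED) -> np.ndarray:
    """Seeded draws of max_j |T_j| for central multivariate t with shape corr.

    The pairwise-contrast correlation matrix of 3 arms is singular
    (one contrast is the difference of the other two), so the joint
    distribution lives on a lower-dimensional subspace; drawing in the
    rank-reduced eigenbasis handles that exactly, where generic
    CDF quadratures do not.
    """
    vals, vecs = np.linalg.eigh(np.asarray(corr, dtype=float))
    keep = vals > 1e-10 * vals.max()
    L = vecs[:, keep] * np.sqrt(vals[keep])
    rng = np.random.default_rng(random_state)
    Z = rng.standard_normal((n, int(keep.sum()))) @ L.T
    s = np.sqrt(rng.chisquare(df, n) / df)
    return np.abs(Z).max(axis=1) / s


def single_step_adjust(t_obs: np.ndarray, corr: np.ndarray, df: float,
                       samples: np.ndarray | None = None) -> np.ndarray:
    """Tukey single-step adjusted p-values for a family of correlated t-stats.

    p_adj(j) = P(max_k |T_k| ≥ |t_j|) under the joint central
    multivariate t with the contrasts' correlation matrix; for a family
    of one this reduces to the ordinary two-sided p-value.  Floored at
    the unadjusted p so adjustment can never appear anti-conservative.
    """
    t_obs = np.atleast_1d(np.asarray(t_obs, dtype=float))
    p_un = 2 * stats.t.sf(np.abs(t_obs), df)
    if len(t_obs) == 1:
        return p_un
    if samples is None:
        samples = _max_abs_t_samples(corr, df)
    p_adj = np.array([np.mean(samples >= abs(t)) for t in t_obs])
    return np.maximum(p_adj, p_un)


def equicoordinate_quantile(corr: np.ndarray, df: float, level: float = 0.95,
                            samples: np.ndarray | None = None) -> float:
    """Critical value t* with P(max|T| ≤ t*) = level (single-step CIs)."""
    if corr.shape[0] == 1:
        return float(stats.t.ppf(0.5 + level / 2, df))
    if samples is None:
        samples = _max_abs_t_samples(corr, df)
    return float(np.quantile(samples, level))


# ---------------------------------------------------------------------------
# contrasts and least-squares means
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """Pairwise arm contrasts at one visit plus least-squares means."""

    contrasts: pd.DataFrame   # contrast, estimate, se, df, ci_low, ci_high, t, p_adjusted
    lsmeans: pd.DataFrame     # arm, visit_month, estimate, se, df, ci_low, ci_high
    visit_month: int
    family_df: float
    singular: bool = False


def _baseline_reference(fit: LmmFit) -> float | None:
    if not fit.baseline_col:
        return None
    return float(fit.data[fit.baseline_col].mean())


def arm_contrasts(fit: LmmFit, visit_month: int, alpha: float = 0.05,
                  extra_values: dict | None = None) -> ContrastResult:
    """All pairwise arm contrasts at one visit, single-step adjusted.

    Estimates are differences of model-predicted means at the visit
    with the baseline covariate held at its sample mean (it cancels in
    the differences); CIs use the same equicoordinate critical value as
    the adjusted p-values, matching the cited single-step procedure.
    """
    if visit_month not in fit.visits:
        raise ValueError(f"visit {visit_month} not in fitted model (visits: {fit.visits})")
    arms = list(fit.arms)
    if len(arms) < 3:
        logger.warning("only %d arms present; adjustment family resized", len(arms))
    base = _baseline_reference(fit)
    beta, phi = fit.beta_cov()

    def row(arm):
        vals = dict(arm=arm, visit_month=visit_month)
        if fit.baseline_col:
            vals[fit.baseline_col] = base
        vals.update(extra_values or {})
        return fit.design_row(**vals)

    pairs = [p for p in CONTRAST_PAIRS if p[0] in arms and p[1] in arms]
    if not pairs:  # non-standard arm labels: all pairs in sorted order
        pairs = [(a, b) for i, a in enumerate(arms) for b in arms[i + 1:]]
    C = np.array([row(a) - row(b) for a, b in pairs])
    est = C @ beta
    cov = C @ phi @ C.T
    se = np.sqrt(np.diag(cov))
    dcorr = np.diag(1.0 / se)
    corr = dcorr @ cov @ dcorr
    dfs = np.array([fit.satterthwaite_df(c) for c in C])
    family_df = float(dfs.mean())
    tstats = est / se
    samples = _max_abs_t_samples(corr, family_df) if len(pairs) > 1 else None
    p_adj = single_step_adjust(tstats, corr, family_df, samples=samples)
    crit = equicoordinate_quantile(corr, family_df, level=1 - alpha, samples=samples)
    contrasts = pd.DataFrame(dict(
        contrast=[f"{a} - {b}" for a, b in pairs],
        estimate=est, se=se, df=dfs,
        ci_low=est - crit * se, ci_high=est + crit * se,
        t=tstats, p_adjusted=np.clip(p_adj, 0, 1),
    ))

    ls_rows = []
    for arm in arms:
        x = row(arm)
        e = float(x @ beta)
        s = float(np.sqrt(x @ phi @ x))
        d = fit.satterthwaite_df(x)
        tcrit = stats.t.ppf(1 - alpha / 2, d)
        ls_rows.append(dict(arm=arm, visit_month=visit_month, estimate=e, se=s,
                            df=d, ci_low=e - tcrit * s, ci_high=e + tcrit * s))
    return ContrastResult(contrasts=contrasts, lsmeans=pd.DataFrame(ls_rows),
                          visit_month=visit_month, family_df=family_df,
                          singular=fit.singular)


# ---------------------------------------------------------------------------
# GA progression (sqrt-area) model
# ---------------------------------------------------------------------------

@dataclass
class GaProgressionResult:
    """Arm-wise atrophy growth and sham-vs-treatment slowing."""

    contrasts_month12: pd.DataFrame     # sham − arm differences in month-12 change (mm)
    annualized_change: dict             # arm -> LS-mean month-12 change / 1 y (mm/y)
    annualized_slope: dict              # arm -> slope from continuous-time refit (mm/y)
    reduction_pct_month12: dict         # arm -> 100·(sham − arm)/sham, month-12 change
    reduction_pct_slope: dict           # arm -> same from continuous-time slopes
    fit: LmmFit


def fit_ga_progression(areas: pd.DataFrame, alpha: float = 0.05) -> GaProgressionResult:
    """Mixed model for change in sqrt-transformed lesion area from baseline.

    Fixed effects: arm, baseline sqrt-area, visit, arm×visit and
    baseline×visit interactions; random intercept per participant.
    Reports sham-minus-treatment differences in month-12 change and the
    percentage slowing both from the month-12 contrast and from an
    annualized continuous-time refit (the two framings bracket how a
    'percent reduction' can be read off such a model).
    """
    req = {"participant_id", "arm", "visit_month", "sqrt_area_mm"}
    if not req <= set(areas.columns):
        raise ValueError(f"area table lacks columns: {sorted(req - set(areas.columns))}")
    base = areas[areas.visit_month == 0].set_index("participant_id")["sqrt_area_mm"]
    fup = areas[areas.visit_month > 0].copy()
    fup = fup[fup.participant_id.isin(base.index)]
    fup["baseline_sqrt_area"] = base.reindex(fup.participant_id).to_numpy()
    fup["change_sqrt_area"] = fup["sqrt_area_mm"] - fup["baseline_sqrt_area"]

    fit = fit_change_lmm(
        fup, response="change_sqrt_area", baseline_col="baseline_sqrt_area",
        extra_fixed=" + baseline_sqrt_area:C(visit_month)",
    )
    res12 = arm_contrasts(fit, 12, alpha=alpha)
    ls12 = res12.lsmeans.set_index("arm")["estimate"]
    sham = "sham_pooled" if "sham_pooled" in fit.arms else fit.arms[0]

    # sham − treatment convention: positive = slower growth under treatment
    rows = []
    for _, r in res12.contrasts.iterrows():
        a, b = [s.strip() for s in r.contrast.split(" - ")]
        rows.append(dict(contrast=f"{b} - {a}" if b == sham else r.contrast,
                         estimate=-r.estimate if b == sham else r.estimate,
                         ci_low=-r.ci_high if b == sham else r.ci_low,
                         ci_high=-r.ci_low if b == sham else r.ci_high,
                         se=r.se, df=r.df, p_adjusted=r.p_adjusted))
    con12 = pd.DataFrame(rows)

    annualized_change = {arm: float(ls12[arm]) for arm in fit.arms}
    reduction12 = {}
    for arm in fit.arms:
        if arm != sham and ls12[sham] != 0:
            reduction12[arm] = 100.0 * (ls12[sham] - ls12[arm]) / ls12[sham]

    # continuous-time refit: change ~ arm·years, per-arm slope in mm/y
    fup2 = fup.copy()
    fup2["years"] = fup2.visit_month / 12.0
    ref = sham
    formula = f"change_sqrt_area ~ C(arm, Treatment('{ref}')):years + years + baseline_sqrt_area"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m2 = MixedLM.from_formula(formula, data=fup2, groups=fup2["participant_id"])
        r2 = m2.fit(reml=True, method="lbfgs")
    names = list(r2.model.data.design_info.column_names)
    params = np.asarray(r2.params, dtype=float)
    slope = {}
    base_slope = params[names.index("years")]
    for arm in fit.arms:
        extra = 0.0
        for i, nm in enumerate(names):
            if f"[T.{arm}]" in nm and ":years" in nm:
                extra = params[i]
        slope[arm] = float(base_slope + extra)
    reduction_slope = {arm: 100.0 * (slope[sham] - slope[arm]) / slope[sham]
                       for arm in fit.arms if arm != sham and slope[sham] != 0}

    return GaProgressionResult(
        contrasts_month12=con12,
        annualized_change=annualized_change,
        annualized_slope=slope,
        reduction_pct_month12=reduction12,
        reduction_pct_slope=reduction_slope,
        fit=fit,
    )


# ---------------------------------------------------------------------------
# Bland–Altman agreement
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    """Bland–Altman summary of paired measurements (x − y convention)."""

    bias: float
    bias_ci: tuple[float, float]
    limits_of_agreement: tuple[float, float]
    p_bias: float
    sd_diff: float
    n: int


def bland_altman(x, y, alpha: float = 0.05) -> AgreementResult:
    """Agreement between two paired measurement series.

    bias = mean(x − y) with a t-based CI (n − 1 df); limits of
    agreement are bias ± 1.96·SD(x − y); p_bias is the one-sample
    t-test of zero mean difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired measurement series must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs for agreement analysis")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    if se > 0:
        p = float(2 * stats.t.sf(abs(bias / se), n - 1))
    else:
        p = 1.0 if bias == 0 else 0.0
    return AgreementResult(
        bias=bias,
        bias_ci=(bias - tcrit * se, bias + tcrit * se),
        limits_of_agreement=(bias - 1.96 * sd, bias + 1.96 * sd),
        p_bias=p,
        sd_diff=sd,
        n=n,
    )
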
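"""ROI condition summaries, random-intercept mixed models, and the RT model.

The scientific question served here: does a region's response across the
four trial conditions of ascending value (RejCon < RejAmb < AccAmb <
AccCon) increase *linearly* with signed value ``v = P(acc) - P(rej)``
(value coding) or follow a *quadratic* in v (confidence coding)?  Each
subject contributes the mean parameter estimate over ROI voxels per
condition and phase; the two competing models are

    linear:     y = b0 + b1 v + (1|subject) + e
    quadratic:  y = b0 + b1 v + b2 v^2 + (1|subject) + e

fitted by a profiled one-variance-component likelihood (REML or ML), with
an ordinary likelihood-ratio test on the ML refits deciding the winner,
AIC/BIC reported for both, and fixed-effect 95% CIs from normal posterior
simulation.  The same machinery fits the behavioral response-time model
(mean RT per value bin ~ v + v^2) after a two-stage 3-SD outlier
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InvalidArgumentError

PHASES = ("offer", "commit")


# --------------------------------------------------------------------------
# ROI extraction
# --------------------------------------------------------------------------

def extract_roi_means(beta_maps: dict, roi_mask: np.ndarray) -> dict:
    """Arithmetic mean over mask voxels for each named beta map."""
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise InvalidArgumentError("ROI mask is empty")
    out = {}
    for name, vol in beta_maps.items():
        vol = np.asarray(vol, dtype=float)
        if vol.shape != mask.shape:
            raise InvalidArgumentError(f"map {name!r} does not match the mask grid")
        out[name] = float(vol[mask].mean())
    return out


def roi_condition_summaries(subject_id, phase_betas: dict, roi_mask: np.ndarray,
                            estimates: pd.DataFrame) -> pd.DataFrame:
    """Tidy rows (subject, phase, condition, roi_mean, signed_value_mean).

    ``phase_betas`` maps (phase, condition) to a 3-D beta map;
    ``signed_value_mean`` is the mean signed value of that condition's
    trials, the predictor entering the mixed models.  Conditions with no
    trials are emitted with NaNs and flagged by the caller.
    """
    rows = []
    means = extract_roi_means(phase_betas, roi_mask)
    for phase, cond in phase_betas:
        sub = estimates[estimates["condition"] == cond]
        v = float(sub["signed_value"].mean()) if len(sub) else np.nan
        rows.append(dict(subject=subject_id, phase=phase, condition=cond,
                         roi_mean=means[(phase, cond)], signed_value_mean=v,
                         n_trials=len(sub)))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# random-intercept linear mixed model
# --------------------------------------------------------------------------

@dataclass
class LMMResult:
    """A fitted one-variance-component (random intercept) linear mixed model."""

    param_names: list[str]
    params: np.ndarray
    se: np.ndarray
    cov_params: np.ndarray
    sigma_u: float           # random-intercept SD
    sigma_e: float           # residual SD
    loglik: float            # at the requested criterion (REML or ML)
    loglik_ml: float         # always the ML log-likelihood
    method: str
    aic: float               # -2 loglik_ML + 2 k,   k = p + 2
    bic: float                # -2 loglik_ML + k log(n_obs)
    n_obs: int
    n_groups: int
    boundary: bool            # sigma_u hit zero
    converged: bool
    cis: dict = field(default_factory=dict)


def _group_index(groups):
    codes, uniques = pd.factorize(np.asarray(groups))
    return codes, len(uniques)


def _profile_neg2ll(lam, y, X, codes, n_groups, reml):
    """-2 log-likelihood profiled over the GLS fixed effects and sigma_e.

    With V*_i = I + lam * J_i per group, A' V*^-1 B is computed from group
    sums: A'B - sum_i c_i (sum A_i)'(sum B_i), c_i = lam / (1 + lam n_i).
    Returns (value, beta, sigma_e2, cov_factor) where cov_factor is
    (X' V*^-1 X)^-1.
    """
    n, p = X.shape
    n_i = np.bincount(codes, minlength=n_groups).astype(float)
    c = lam / (1.0 + lam * n_i)

    gx = np.zeros((n_groups, p))
    np.add.at(gx, codes, X)
    gy = np.bincount(codes, weights=y, minlength=n_groups)

    xtx = X.T @ X - (gx * c[:, None]).T @ gx
    xty = X.T @ y - gx.T @ (c * gy)
    yty = y @ y - c @ gy ** 2

    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ xty
    rss = yty - beta @ xty  # r' V*^-1 r at the GLS solution
    rss = max(rss, 1e-300)
    logdet_v = np.log1p(lam * n_i).sum()
    if reml:
        df = n - p
        sigma2 = rss / df
        sign, logdet_x = np.linalg.slogdet(xtx)
        val = df * np.log(2.0 * np.pi * sigma2) + logdet_v + logdet_x + df
    else:
        sigma2 = rss / n
        val = n * np.log(2.0 * np.pi * sigma2) + logdet_v + n
    return val, beta, sigma2, xtx_inv


def _optimize_lambda(y, X, codes, n_groups, reml):
    def f(loglam):
        return _profile_neg2ll(np.exp(loglam), y, X, codes, n_groups, reml)[0]

    grid = np.linspace(-12.0, 10.0, 45)
    vals = [f(g) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    best = float(res.fun)
    # boundary: pure-OLS model (sigma_u = 0)
    v0 = _profile_neg2ll(0.0, y, X, codes, n_groups, reml)[0]
    if v0 <= best + 1e-10:
        return 0.0, v0
    return lam, best


def fit_random_intercept_lmm(y, X, groups, method: str = "REML",
                             param_names: list[str] | None = None) -> LMMResult:
    """Fit ``y = X b + (1|group) + e`` by profiled (restricted) likelihood.

    The variance ratio ``lambda = sigma_u^2 / sigma_e^2`` is profiled on a
    log scale (grid bracketing + bounded scalar minimization, tolerance
    1e-10); the boundary ``sigma_u = 0`` is compared explicitly and
    reported with a flag, in which case the fixed effects coincide with
    OLS.  Fixed-effect covariance is ``sigma_e^2 (X' V*^-1 X)^-1``.  The
    ML log-likelihood is always computed so that likelihood-ratio tests
    and AIC/BIC are well defined regardless of ``method``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.shape[0] != X.shape[0]:
        raise InvalidArgumentError("y and X have different lengths")
    codes, n_groups = _group_index(groups)
    if n_groups < 2:
        raise InvalidArgumentError("need at least 2 subjects")
    counts = np.bincount(codes, minlength=n_groups)
    if counts.min() < 2:
        raise InvalidArgumentError("need at least 2 observations per subject")
    if method not in ("REML", "ML"):
        raise InvalidArgumentError("method must be 'REML' or 'ML'")
    n, p = X.shape
    if n <= p + 1:
        raise InvalidArgumentError("too few observations for the fixed design")
    reml = method == "REML"

    lam, neg2ll = _optimize_lambda(y, X, codes, n_groups, reml)
    _, beta, sigma2, xtx_inv = _profile_neg2ll(lam, y, X, codes, n_groups, reml)
    cov = sigma2 * xtx_inv
    se = np.sqrt(np.diag(cov))
    sigma_e = float(np.sqrt(sigma2))
    sigma_u = float(np.sqrt(lam * sigma2))

    if reml:
        lam_ml, neg2ll_ml = _optimize_lambda(y, X, codes, n_groups, False)
    else:
        lam_ml, neg2ll_ml = lam, neg2ll
    loglik = -0.5 * neg2ll
    loglik_ml = -0.5 * neg2ll_ml
    k = p + 2
    names = param_names or [f"b{i}" for i in range(p)]
    return LMMResult(param_names=list(names), params=beta, se=se, cov_params=cov,
                     sigma_u=sigma_u, sigma_e=sigma_e, loglik=float(loglik),
                     loglik_ml=float(loglik_ml), method=method,
                     aic=float(-2.0 * loglik_ml + 2.0 * k),
                     bic=float(-2.0 * loglik_ml + k * np.log(n)),
                     n_obs=int(n), n_groups=int(n_groups),
                     boundary=bool(lam == 0.0), converged=True)


def likelihood_ratio_test(lmm_small: LMMResult, lmm_big: LMMResult):
    """chi^2 = 2 (ll_big - ll_small) on the ML fits of nested fixed designs."""
    if lmm_small.method != "ML" or lmm_big.method != "ML":
        raise InvalidArgumentError("LRT requires models fitted with method='ML'")
    df = len(lmm_big.param_names) - len(lmm_small.param_names)
    if df <= 0:
        raise InvalidArgumentError("models are not nested (df <= 0)")
    chi2 = max(0.0, 2.0 * (lmm_big.loglik - lmm_small.loglik))
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return float(chi2), int(df), p


def simulate_fixed_effect_cis(result: LMMResult, n_sim: int = 5000,
                              seed: int = 0, level: float = 0.95) -> dict:
    """Simulation CIs: draw fixed effects from N(b, cov) and take the
    empirical 2.5/97.5 percentiles; an effect is 'significant' when its
    interval excludes zero."""
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(result.params, result.cov_params, size=n_sim)
    alpha = (1.0 - level) / 2.0
    lo = np.percentile(draws, 100 * alpha, axis=0)
    hi = np.percentile(draws, 100 * (1 - alpha), axis=0)
    return {name: (float(lo[i]), float(hi[i]))
            for i, name in enumerate(result.param_names)}


# --------------------------------------------------------------------------
# linear vs quadratic model comparison
# --------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """Linear-vs-quadratic mixed-model comparison for one trial phase."""

    phase: str
    linear: LMMResult            # REML estimates
    quadratic: LMMResult
    linear_ml: LMMResult
    quadratic_ml: LMMResult
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    winner: str                  # 'linear' or 'quadratic'
    linear_cis: dict = field(default_factory=dict)
    quadratic_cis: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def pack(r: LMMResult, cis):
            return {"params": dict(zip(r.param_names, map(float, r.params))),
                    "se": dict(zip(r.param_names, map(float, r.se))),
                    "sigma_u": r.sigma_u, "sigma_e": r.sigma_e,
                    "aic": r.aic, "bic": r.bic, "loglik_ml": r.loglik_ml,
                    "cis": {k: list(v) for k, v in cis.items()}}
        return {"phase": self.phase,
                "linear": pack(self.linear, self.linear_cis),
                "quadratic": pack(self.quadratic, self.quadratic_cis),
                "lrt": {"chi2": self.lrt_chi2, "df": self.lrt_df, "p": self.lrt_p},
                "winner": self.winner}


def compare_linear_quadratic(summaries: pd.DataFrame, phase: str,
                             alpha: float = 0.05, n_sim: int = 5000,
                             seed: int = 0) -> ModelComparison:
    """Decide whether a phase's ROI responses code value or confidence.

    ``summaries`` needs columns subject, phase, condition, roi_mean,
    signed_value_mean with all four conditions per subject.  Both models
    are fitted by REML for the reported estimates/CIs and refitted by ML
    for the likelihood-ratio test; the quadratic model wins iff the LRT
    rejects at ``alpha``.
    """
    sub = summaries[summaries["phase"] == phase].dropna(
        subset=["roi_mean", "signed_value_mean"])
    if sub.empty:
        raise InvalidArgumentError(f"no rows for phase {phase!r}")
    counts = sub.groupby("subject")["condition"].nunique()
    if (counts < 4).any():
        raise InvalidArgumentError("every subject needs all 4 condition rows")
    y = sub["roi_mean"].to_numpy()
    v = sub["signed_value_mean"].to_numpy()
    g = sub["subject"].to_numpy()
    Xl = np.column_stack([np.ones_like(v), v])
    Xq = np.column_stack([np.ones_like(v), v, v ** 2])
    names_l = ["intercept", "signed_value"]
    names_q = names_l + ["signed_value_sq"]

    lin = fit_random_intercept_lmm(y, Xl, g, "REML", names_l)
    quad = fit_random_intercept_lmm(y, Xq, g, "REML", names_q)
    lin_ml = fit_random_intercept_lmm(y, Xl, g, "ML", names_l)
    quad_ml = fit_random_intercept_lmm(y, Xq, g, "ML", names_q)
    chi2, df, p = likelihood_ratio_test(lin_ml, quad_ml)
    winner = "quadratic" if p < alpha else "linear"
    return ModelComparison(
        phase=phase, linear=lin, quadratic=quad,
        linear_ml=lin_ml, quadratic_ml=quad_ml,
        lrt_chi2=chi2, lrt_df=df, lrt_p=p, winner=winner,
        linear_cis=simulate_fixed_effect_cis(lin, n_sim, seed),
        quadratic_cis=simulate_fixed_effect_cis(quad, n_sim, seed + 1))


# --------------------------------------------------------------------------
# response-time model
# --------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    n_total: int
    n_stage1: int   # beyond 3 SD of the pooled group RT distribution
    n_stage2: int   # beyond 3 SD of the subject's per-bin mean


@dataclass
class RTAnalysisResult:
    model: LMMResult          # mean bin RT ~ v + v^2 (+1|subject)
    model_zsv: LMMResult      # same with z-scored SV predictors
    exclusions: ExclusionReport
    bin_table: pd.DataFrame
    cis: dict = field(default_factory=dict)


def rt_analysis(trials: pd.DataFrame, n_bins: int = 5, sd_cut: float = 3.0,
                n_sim: int = 5000, seed: int = 0) -> RTAnalysisResult:
    """Inverse-quadratic RT model over equal-width signed-value bins.

    Stage 1 excludes trials whose RT deviates more than ``sd_cut`` SDs from
    the pooled group mean; signed value is then cut into ``n_bins``
    equal-width bins over [-1, 1]; stage 2 excludes trials more than
    ``sd_cut`` SDs from the subject's own per-bin mean.  The model's
    observations are each subject's mean RT per bin, predicted from the
    subject's mean signed value in that bin (and its square) with a random
    intercept per subject.  A companion fit uses per-subject z-scored SV
    as the value predictor.
    """
    req = {"subject", "signed_value", "rt_ms"}
    if not req.issubset(trials.columns):
        raise InvalidArgumentError(f"trials must have columns {sorted(req)}")
    t = trials.dropna(subset=["rt_ms"]).copy()
    n_total = len(t)
    mu, sd = t["rt_ms"].mean(), t["rt_ms"].std(ddof=1)
    if sd > 0:
        keep = (t["rt_ms"] - mu).abs() <= sd_cut * sd
    else:
        keep = pd.Series(True, index=t.index)
    n_stage1 = int((~keep).sum())
    t = t[keep]

    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    t["vbin"] = np.clip(np.digitize(t["signed_value"], edges) - 1, 0, n_bins - 1)

    def stage2(group):
        m, s = group["rt_ms"].mean(), group["rt_ms"].std(ddof=1)
        if not np.isfinite(s) or s == 0:
            return pd.Series(True, index=group.index)
        return (group["rt_ms"] - m).abs() <= sd_cut * s

    keep2 = t.groupby(["subject", "vbin"], group_keys=False).apply(
        stage2, include_groups=False)
    keep2 = keep2.reindex(t.index).fillna(True)
    n_stage2 = int((~keep2).sum())
    t = t[keep2.to_numpy(dtype=bool)]

    # per-subject z-scored SV predictor (computed before binning means)
    if "sv" in t.columns:
        zsv = t.groupby("subject")["sv"].transform(
            lambda s: (s - s.mean()) / s.std() if s.std() > 0 else s * 0.0)
    else:
        zsv = t.groupby("subject")["signed_value"].transform(
            lambda s: (s - s.mean()) / s.std() if s.std() > 0 else s * 0.0)
    t = t.assign(zsv=zsv)

    agg = (t.groupby(["subject", "vbin"])
             .agg(rt_mean=("rt_ms", "mean"), v_mean=("signed_value", "mean"),
                  zsv_mean=("zsv", "mean"), n=("rt_ms", "size"))
             .reset_index())
    bins_per_subject = agg.groupby("subject")["vbin"].size()
    thin = bins_per_subject[bins_per_subject < 2].index
    if len(thin):
        import warnings
        warnings.warn(f"{len(thin)} subject(s) populate fewer than 2 value "
                      "bins and are dropped from the RT model", stacklevel=2)
        agg = agg[~agg["subject"].isin(set(thin))]

    y = agg["rt_mean"].to_numpy()
    v = agg["v_mean"].to_numpy()
    g = agg["subject"].to_numpy()
    X = np.column_stack([np.ones_like(v), v, v ** 2])
    names = ["intercept", "signed_value", "signed_value_sq"]
    model = fit_random_intercept_lmm(y, X, g, "REML", names)

    z = agg["zsv_mean"].to_numpy()
    Xz = np.column_stack([np.ones_like(z), z, z ** 2])
    model_z = fit_random_intercept_lmm(y, Xz, g, "REML",
                                       ["intercept", "zsv", "zsv_sq"])
    cis = simulate_fixed_effect_cis(model, n_sim, seed)
    return RTAnalysisResult(model=model, model_zsv=model_z,
                            exclusions=ExclusionReport(n_total, n_stage1, n_stage2),
                            bin_table=agg, cis=cis)
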
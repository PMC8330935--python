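"""Statistical layer: mixed models for FD%, logistic models of LCV
visibility, Youden cutoff with cluster-adjusted confidence intervals.

Sectors are repeated measurements within an eye (one eye per patient, so
eye and patient coincide); every model therefore carries a per-eye random
intercept or a cluster adjustment:

* FD% endpoint: linear mixed model (REML) with fixed effects LCV, group,
  orientation and the LCV x group interaction, and four planned contrasts
  (LCV effect within each group, group effect within each LCV stratum),
  Bonferroni-adjusted for the 4 comparisons.
* LCV visibility per sector: random-intercept logistic regression fitted by
  adaptive-free Gauss-Hermite quadrature maximum likelihood (deterministic:
  fixed start values, no stochastic optimizer), odds ratios per um of CT.
* LCV in at least one sector (eye level): ordinary logistic regression.
* CT cutoff: exhaustive Youden-index scan over midpoints of adjacent
  distinct CT values (a sector is called LCV-positive iff CT <= cutoff),
  with sensitivity/specificity intervals from the closed-form cluster
  ratio-estimator variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, special, stats as sps
from statsmodels.tools.numdiff import approx_hess1

# ---------------------------------------------------------------------------
# elementary pieces


def bonferroni_adjust(p_values, m: int = 4) -> np.ndarray:
    """min(1, m * p), elementwise."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m < 1:
        raise ValueError("m must be >= 1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, m * p)


def cluster_ratio_ci(successes, trials, level: float = 0.95) -> tuple[float, float, float]:
    """Ratio-estimator interval for a proportion from clustered binary data.

    With per-cluster totals (x_i, n_i), the pooled estimate is
    p = sum(x) / sum(n) and its variance is estimated by the standard
    closed-form cluster ratio estimator

        var = m / ((m - 1) * (sum n)^2) * sum (x_i - p * n_i)^2

    giving a Wald interval clipped to [0, 1].  Returns (p, low, high).
    """
    x = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    if x.shape != n.shape or x.ndim != 1:
        raise ValueError("successes and trials must be 1-D and aligned")
    m = len(x)
    if m < 2:
        raise ValueError("at least two clusters are required")
    if n.sum() <= 0:
        raise ValueError("total number of trials must be positive")
    p = x.sum() / n.sum()
    var = m / ((m - 1) * n.sum() ** 2) * np.sum((x - p * n) ** 2)
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(p), float(max(0.0, p - half)), float(min(1.0, p + half))


# ---------------------------------------------------------------------------
# FD% linear mixed model


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame
    random_intercept_var: float
    residual_var: float
    contrasts: pd.DataFrame
    n_obs: int
    n_eyes: int


_CONTRASTS = {
    # contrast label -> coefficients on (iamd, nasal, lcv, lcv_iamd)
    "lcv_within_iamd": {"lcv": 1.0, "lcv_iamd": 1.0},
    "lcv_within_control": {"lcv": 1.0},
    "group_within_no_lcv": {"iamd": 1.0},
    "group_within_lcv": {"iamd": 1.0, "lcv_iamd": 1.0},
}


def fit_fd_mixed_model(fd_rows: pd.DataFrame, n_comparisons: int = 4) -> MixedModelResult:
    """REML linear mixed model for FD% with a per-eye random intercept.

    Expects columns fd_percent, lcv, group ('iamd'/'control'), orientation
    ('nasal'/'temporal') and eye_id; rows flagged ``drusen`` are dropped
    (drusen disturb the FD measurement itself).  The fixed part is
    lcv + group + orientation + lcv x group -- the model retained after
    dropping the non-significant lcv x orientation and orientation x group
    interactions.  The four planned comparisons are reported with raw and
    Bonferroni-adjusted (x ``n_comparisons``) p-values and intervals.
    """
    df = fd_rows.copy()
    if "drusen" in df.columns:
        df = df[~df["drusen"].astype(bool)]
    for col in ("fd_percent", "lcv", "group", "orientation", "eye_id"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    df["iamd"] = (df["group"] == "iamd").astype(float)
    df["nasal"] = (df["orientation"] == "nasal").astype(float)
    df["lcv"] = df["lcv"].astype(float)
    df["lcv_iamd"] = df["lcv"] * df["iamd"]
    if df.groupby("group")["eye_id"].nunique().reindex(["control", "iamd"]).fillna(0).min() < 2:
        raise ValueError("need at least two eyes per group")
    if df["lcv"].nunique() < 2:
        raise ValueError("LCV stratum is empty: all sectors share one LCV state")

    model = smf.mixedlm("fd_percent ~ iamd + nasal + lcv + lcv_iamd", df, groups=df["eye_id"])
    res = model.fit(reml=True)

    fe_names = ["Intercept", "iamd", "nasal", "lcv", "lcv_iamd"]
    beta = res.fe_params[fe_names]
    cov = res.cov_params().loc[fe_names, fe_names]
    fixed = pd.DataFrame({"estimate": beta, "se": np.sqrt(np.diag(cov))})

    z95 = sps.norm.ppf(0.975)
    z_adj = sps.norm.ppf(1.0 - 0.05 / (2 * n_comparisons))
    rows = []
    for label, coeffs in _CONTRASTS.items():
        L = np.array([coeffs.get(name, 0.0) for name in fe_names])
        est = float(L @ beta.values)
        se = float(np.sqrt(L @ cov.values @ L))
        z = est / se
        p_raw = 2 * sps.norm.sf(abs(z))
        rows.append(
            dict(
                label=label,
                estimate=est,
                se=se,
                ci_low=est - z95 * se,
                ci_high=est + z95 * se,
                p_raw=p_raw,
                p_adj=float(bonferroni_adjust(p_raw, n_comparisons)[0]),
                ci_low_adj=est - z_adj * se,
                ci_high_adj=est + z_adj * se,
            )
        )
    return MixedModelResult(
        fixed_effects=fixed,
        random_intercept_var=float(res.cov_re.iloc[0, 0]),
        residual_var=float(res.scale),
        contrasts=pd.DataFrame(rows).set_index("label"),
        n_obs=len(df),
        n_eyes=df["eye_id"].nunique(),
    )


# ---------------------------------------------------------------------------
# random-intercept logistic regression (Gauss-Hermite quadrature ML)


@dataclass
class LogisticTerm:
    name: str
    log_or: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class LogisticResult:
    terms: dict[str, LogisticTerm]
    intercept: float
    random_intercept_sd: float
    n_obs: int
    n_patients: int
    label: str
    converged: bool = True
    separation: bool = False


def _gh_negloglik(params, X, y, cluster_idx, n_clusters, nodes, log_weights):
    beta, sigma = params[:-1], params[-1]
    eta = X @ beta
    shift = np.sqrt(2.0) * sigma * nodes
    z = eta[:, None] + shift[None, :]
    ll_obs = np.where(y[:, None] > 0.5, -np.logaddexp(0.0, -z), -np.logaddexp(0.0, z))
    ll_cluster = np.zeros((n_clusters, len(nodes)))
    np.add.at(ll_cluster, cluster_idx, ll_obs)
    return -float(special.logsumexp(ll_cluster + log_weights[None, :], axis=1).sum())


class RandomInterceptLogit:
    """Mixed logistic regression with one Gaussian random intercept.

    The marginal likelihood integrates the random effect with ``n_nodes``
    Gauss-Hermite quadrature points; estimation is deterministic (plain
    logistic start values, L-BFGS-B with the random-effect SD bounded at
    zero).  Wald standard errors come from the numerical Hessian at the
    optimum; when the SD collapses to the boundary the fixed-effect block
    is evaluated at sigma = 0, where the model reduces to ordinary
    logistic regression.
    """

    def __init__(self, n_nodes: int = 25):
        nodes, weights = special.roots_hermite(n_nodes)
        self.nodes = nodes
        self.log_weights = np.log(weights) - 0.5 * np.log(np.pi)

    def fit(self, X: np.ndarray, y: np.ndarray, clusters: np.ndarray):
        codes, _ = pd.factorize(clusters)
        n_clusters = codes.max() + 1
        start_model = sm.Logit(y, X)
        with np.errstate(all="ignore"):
            try:
                beta0 = start_model.fit(disp=0, maxiter=200).params
            except Exception:
                beta0 = np.zeros(X.shape[1])
        x0 = np.concatenate([np.clip(beta0, -5, 5), [0.5]])
        args = (X, y, codes, n_clusters, self.nodes, self.log_weights)
        res = optimize.minimize(
            _gh_negloglik,
            x0,
            args=args,
            method="L-BFGS-B",
            bounds=[(None, None)] * X.shape[1] + [(0.0, 20.0)],
            options={"maxiter": 500},
        )
        params = res.x
        separation = bool(np.any(np.abs(params[:-1]) > 15.0))
        sigma = params[-1]
        if sigma < 1e-4:
            # boundary: fixed effects are those of the plain logistic model
            hess = approx_hess1(params[:-1], lambda b: _gh_negloglik(np.r_[b, 0.0], *args))
            cov = _safe_inverse(hess)
        else:
            hess = approx_hess1(params, _gh_negloglik, args=args)
            cov_full = _safe_inverse(hess)
            cov = cov_full[:-1, :-1]
        return params[:-1], sigma, cov, bool(res.success), separation


def _safe_inverse(h: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(h)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(h)


_PREDICTOR_ENCODINGS = {
    "group": lambda df: (df["group"] == "iamd").astype(float),
    "ct": lambda df: df["ct_um"].astype(float),
    "orientation": lambda df: (df["orientation"] == "nasal").astype(float),
}


def _encode(df: pd.DataFrame, predictors) -> tuple[np.ndarray, list[str]]:
    cols, names = [np.ones(len(df))], ["intercept"]
    for pred in predictors:
        if pred == "ct:orientation":
            cols.append(_PREDICTOR_ENCODINGS["ct"](df) * _PREDICTOR_ENCODINGS["orientation"](df))
        elif pred in _PREDICTOR_ENCODINGS:
            cols.append(_PREDICTOR_ENCODINGS[pred](df))
        else:
            cols.append(df[pred].astype(float))
        names.append(pred)
    return np.column_stack(cols), names


def fit_lcv_glmm(
    sector_rows: pd.DataFrame,
    predictors=("ct",),
    label: str = "univariate",
    n_nodes: int = 25,
) -> LogisticResult:
    """Random-intercept logistic model of per-sector LCV visibility.

    Sectors containing drusen stay in (drusen disturb FD% but not the LCV
    grading).  Predictors: 'group' (iAMD vs control), 'ct' (per um),
    'orientation' (nasal vs temporal) and 'ct:orientation'.
    """
    df = sector_rows
    y = df["lcv"].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("LCV outcome has a single class")
    X, names = _encode(df, predictors)
    fitter = RandomInterceptLogit(n_nodes=n_nodes)
    beta, sigma, cov, converged, separation = fitter.fit(X, y, df["eye_id"].to_numpy())
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z95 = sps.norm.ppf(0.975)
    terms = {}
    for i, name in enumerate(names):
        if name == "intercept":
            continue
        z = beta[i] / se[i] if se[i] > 0 else np.nan
        terms[name] = LogisticTerm(
            name=name,
            log_or=float(beta[i]),
            se=float(se[i]),
            odds_ratio=float(np.exp(beta[i])),
            ci_low=float(np.exp(beta[i] - z95 * se[i])),
            ci_high=float(np.exp(beta[i] + z95 * se[i])),
            p=float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
        )
    return LogisticResult(
        terms=terms,
        intercept=float(beta[0]),
        random_intercept_sd=float(sigma),
        n_obs=len(df),
        n_patients=df["eye_id"].nunique(),
        label=label,
        converged=converged,
        separation=separation,
    )


def fit_lcv_models(sector_rows: pd.DataFrame, alpha: float = 0.05) -> dict[str, LogisticResult]:
    """Univariate models per predictor, then the multivariable model.

    The multivariable model includes every predictor whose univariate
    p-value is below ``alpha`` plus the CT x orientation interaction.
    """
    out: dict[str, LogisticResult] = {}
    selected = []
    for pred in ("group", "ct", "orientation"):
        res = fit_lcv_glmm(sector_rows, predictors=(pred,), label=f"univariate:{pred}")
        out[f"univariate:{pred}"] = res
        if res.terms[pred].p < alpha:
            selected.append(pred)
    multi = [p for p in ("group", "ct", "orientation") if p in selected]
    if "ct" in multi and "orientation" in multi:
        multi.append("ct:orientation")
    if multi:
        out["multivariable"] = fit_lcv_glmm(sector_rows, predictors=tuple(multi), label="multivariable")
    return out


def fit_eye_level_logistic(eye_rows: pd.DataFrame, predictor: str) -> LogisticResult:
    """Ordinary logistic regression of 'LCV in at least one sector'."""
    y = eye_rows["lcv_any"].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("eye-level outcome has a single class")
    if predictor == "eye_color":
        dummies = pd.get_dummies(eye_rows["eye_color"], drop_first=True, dtype=float)
        X = sm.add_constant(dummies)
        names = ["intercept"] + list(dummies.columns)
    else:
        col = {"cct": "cct_um"}.get(predictor, predictor)
        X = sm.add_constant(eye_rows[col].astype(float))
        names = ["intercept", predictor]
    res = sm.Logit(y, np.asarray(X, dtype=float)).fit(disp=0, maxiter=200)
    se = res.bse
    z95 = sps.norm.ppf(0.975)
    terms = {}
    for i, name in enumerate(names):
        if name == "intercept":
            continue
        terms[name] = LogisticTerm(
            name=name,
            log_or=float(res.params[i]),
            se=float(se[i]),
            odds_ratio=float(np.exp(res.params[i])),
            ci_low=float(np.exp(res.params[i] - z95 * se[i])),
            ci_high=float(np.exp(res.params[i] + z95 * se[i])),
            p=float(res.pvalues[i]),
        )
    return LogisticResult(
        terms=terms,
        intercept=float(res.params[0]),
        random_intercept_sd=0.0,
        n_obs=len(eye_rows),
        n_patients=len(eye_rows),
        label=f"eye-level:{predictor}",
        converged=bool(res.mle_retvals.get("converged", True)),
    )


# ---------------------------------------------------------------------------
# Youden cutoff


@dataclass
class CutoffResult:
    threshold_um: float
    sensitivity: float
    specificity: float
    youden_j: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]


def youden_cutoff(ct_um, lcv, cluster_ids, level: float = 0.95) -> CutoffResult:
    """CT threshold maximizing the Youden index J = sens + spec - 1.

    Candidate thresholds are the midpoints between adjacent distinct CT
    values; a sector is called LCV-positive iff CT <= threshold (thin
    choroid predicts visibility).  Ties in J break toward the smallest
    threshold.  Sensitivity/specificity intervals account for within-eye
    correlation through the cluster ratio estimator.
    """
    ct = np.asarray(ct_um, dtype=float)
    y = np.asarray(lcv, dtype=bool)
    clusters = np.asarray(cluster_ids)
    if len(np.unique(y)) < 2:
        raise ValueError("both LCV classes must be present")
    distinct = np.unique(ct)
    if len(distinct) < 2:
        raise ValueError("need at least two distinct CT values")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best = None
    for thr in candidates:  # ascending, so ties keep the smallest threshold
        called = ct <= thr
        sens = (called & y).sum() / n_pos
        spec = (~called & ~y).sum() / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    j, thr, sens, spec = best
    called = ct <= thr

    def _per_cluster(mask_outcome, mask_success):
        xs, ns = [], []
        for c in pd.unique(clusters):
            sel = clusters == c
            n_i = int((sel & mask_outcome).sum())
            if n_i:
                xs.append(int((sel & mask_outcome & mask_success).sum()))
                ns.append(n_i)
        return np.array(xs), np.array(ns)

    sx, sn = _per_cluster(y, called)
    px, pn = _per_cluster(~y, ~called)
    _, s_lo, s_hi = cluster_ratio_ci(sx, sn, level)
    _, p_lo, p_hi = cluster_ratio_ci(px, pn, level)
    return CutoffResult(
        threshold_um=float(thr),
        sensitivity=float(sens),
        specificity=float(spec),
        youden_j=float(j),
        sensitivity_ci=(s_lo, s_hi),
        specificity_ci=(p_lo, p_hi),
    )


# ---------------------------------------------------------------------------
# generative law of the FD% endpoint, for calibration studies


def simulate_fd_percent_table(
    rng: np.random.Generator,
    n_iamd: int = 69,
    n_control: int = 49,
    intercept: float = 6.0,
    group_effect: float = 2.0,
    orientation_effect: float = -1.16,
    lcv_effect_iamd: float = -1.3,
    lcv_effect_control: float = 0.0,
    eye_sd: float = 1.5,
    resid_sd: float = 2.0,
    lcv_rate_nasal: float = 0.40,
    lcv_rate_temporal: float = 0.13,
    drusen_rate: float = 0.1,
) -> pd.DataFrame:
    """Draw sector records directly from the FD% mixed-model law.

    This is the generative counterpart of :func:`fit_fd_mixed_model`, used
    to check that the fitted contrasts recover known effects: the expected
    FD% is ``intercept`` for a temporal control sector without LCV, shifted
    by ``group_effect`` for iAMD, ``orientation_effect`` for nasal, and the
    group-specific LCV effects; eyes carry a Gaussian random intercept.
    """
    rows = []
    groups = ["iamd"] * n_iamd + ["control"] * n_control
    for i, group in enumerate(groups):
        u = rng.normal(0.0, eye_sd)
        for sector in (1, 2, 3, 4):
            orientation = {1: "temporal", 2: "nasal", 3: "nasal", 4: "temporal"}[sector]
            nasal = orientation == "nasal"
            lcv = rng.random() < (lcv_rate_nasal if nasal else lcv_rate_temporal)
            mean = intercept
            if group == "iamd":
                mean += group_effect
                mean += lcv_effect_iamd * lcv
            else:
                mean += lcv_effect_control * lcv
            mean += orientation_effect * nasal
            fd = np.clip(mean + u + rng.normal(0.0, resid_sd), 0.0, 100.0)
            rows.append(
                dict(
                    eye_id=f"eye-{i:03d}",
                    group=group,
                    sector=sector,
                    orientation=orientation,
                    lcv=bool(lcv),
                    drusen=bool(rng.random() < drusen_rate),
                    fd_percent=float(fd),
                )
            )
    return pd.DataFrame(rows)
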
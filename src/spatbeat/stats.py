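"""Cohort-level inference: exact tests, the HR mixed model, rank ANOVA.

The inferential layer mirrors a repeated-measures thermal-ramp study design:

* **Exact McNemar** compares within-group asystole rates between two
  temperatures using only the discordant pairs: with *b* spat asystolic at
  the first temperature only and *c* at the second only, the two-sided exact
  p-value is ``min(1, 2·P[Bin(b+c, ½) ≤ min(b, c)])``.
* **Exact Fisher** compares asystole prevalence between groups via the
  two-sided point-probability rule: the sum of hypergeometric probabilities
  of all tables with the observed margins whose point probability does not
  exceed the observed table's.
* **Linear mixed model** for HR:
  ``HR = β0 + βg·group + βT·(T−22) + βgT·group·(T−22) + βph·phase + u_i + ε``
  with a Normal random spat intercept ``u_i`` and first-order autocorrelated
  residuals within spat, estimated by REML.  Neither statsmodels' MixedLM nor
  GEE offers this exact covariance structure, so the profile REML over
  ``(σ²_u, σ²_ε, ρ)`` is implemented here directly (and cross-checked against
  MixedLM in the ρ = 0 special case in the test suite).  Confidence
  intervals are Wald-type on the REML fit.
* **Two-way rank ANOVA** for Q10: a global mid-rank transform followed by
  ordinary two-way fixed-effects ANOVA on the ranks.

All tests are two-sided with no multiplicity correction, matching the study
design being emulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats as sps

from .errors import ParameterError

__all__ = [
    "mcnemar_exact",
    "fisher_exact",
    "ModelFit",
    "fit_hr_model",
    "rank_anova_q10",
]

FIXED_EFFECTS = [
    "intercept",
    "group_Ta10",
    "temp_c",
    "group_Ta10:temp_c",
    "phase_warming",
]


def mcnemar_exact(n_discordant_01: int, n_discordant_10: int) -> float:
    """Two-sided exact McNemar p-value from the two discordant counts.

    ``p = min(1, 2·P[Bin(b+c, 0.5) ≤ min(b, c)])``.  Zero discordant pairs
    carry no information: p = 1.
    """
    b, c = int(n_discordant_01), int(n_discordant_10)
    if b < 0 or c < 0:
        raise ParameterError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * sps.binom.cdf(min(b, c), n, 0.5)))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Point-probability rule: sum hypergeometric probabilities of all tables
    with the observed margins whose probability is <= the observed table's.
    A degenerate margin (an all-zero row or column) yields p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    if np.any(t < 0) or not np.all(t == np.rint(t)):
        raise ParameterError("table entries must be non-negative integers")
    t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class ModelFit:
    """REML fit of the HR mixed model.

    ``params`` etc. are indexed by :data:`FIXED_EFFECTS`.  ``group_slopes``
    gives each group's per-°C HR gradient (positive: HR falls during
    cooling) with Wald 95% CIs; ``slope_difference`` is Ta22 − Ta10.
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    cov_params: pd.DataFrame
    sigma_u2: float
    sigma_e2: float
    rho: float
    converged: bool
    method: str
    n_obs: int
    neg2_reml: float
    group_slopes: dict = field(default_factory=dict)
    slope_difference: dict = field(default_factory=dict)

    def slope(self, group: str) -> float:
        return self.group_slopes[group]["estimate"]

    def intercept_22c(self, group: str) -> float:
        b = self.params
        return float(b["intercept"] + (b["group_Ta10"] if group == "Ta10" else 0.0))


def _design(df: pd.DataFrame, response: str):
    """Full design matrix plus the kept-column subset.

    Columns without variation (single acclimation group, single phase) are
    dropped so the model stays estimable on partial designs; the dropped
    effects are reported as NaN.
    """
    y = df[response].to_numpy(dtype=float)
    g = (df["group"] == "Ta10").to_numpy(dtype=float)
    tc = df["set_point"].to_numpy(dtype=float) - 22.0
    ph = (df["phase"] == "warming").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), g, tc, g * tc, ph])
    keep = [0, 2]  # intercept and temperature always
    if np.ptp(g) > 0:
        keep += [1, 3]
    if np.ptp(ph) > 0:
        keep.append(4)
    keep = sorted(keep)
    return X[:, keep], y, keep


def _blocks(df: pd.DataFrame, X: np.ndarray, y: np.ndarray):
    out = []
    spat = df["spat_id"].to_numpy()
    idx = df["step_index"].to_numpy(dtype=float)
    for s in pd.unique(spat):
        sel = spat == s
        out.append((X[sel], y[sel], idx[sel]))
    return out


def _reml_neg2(theta, blocks, n_fixed, ar1, ridge):
    su2 = float(np.exp(theta[0]))
    se2 = float(np.exp(theta[1]))
    rho = float(np.tanh(theta[2])) if ar1 else 0.0
    A = np.zeros((n_fixed, n_fixed))
    b = np.zeros(n_fixed)
    logdet_v = 0.0
    y_v_y = 0.0
    for Xi, yi, idx in blocks:
        ni = yi.size
        lags = np.abs(idx[:, None] - idx[None, :])
        # C pow handles a negative base at integral exponents, so rho < 0 is safe
        corr = np.power(rho, lags) if rho != 0.0 else np.eye(ni)
        V = su2 * np.ones((ni, ni)) + se2 * corr
        V[np.diag_indices(ni)] += ridge
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return np.inf, None, None, None
        logdet_v += 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vx = linalg.cho_solve(cf, Xi)
        Vy = linalg.cho_solve(cf, yi)
        A += Xi.T @ Vx
        b += Xi.T @ Vy
        y_v_y += float(yi @ Vy)
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf, None, None, None
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    quad = y_v_y - 2.0 * b @ beta + beta @ A @ beta
    return logdet_v + logdet_a + quad, beta, A, (su2, se2, rho)


def fit_hr_model(
    cohort,
    convention: str = "zeroed",
    ar1: bool = True,
) -> ModelFit:
    """Fit the group/temperature/phase mixed model to a cohort.

    ``cohort`` is a :class:`~spatbeat.synthetic.CohortDataset` or a segment
    DataFrame with columns ``spat_id, group, step_index, set_point, phase,
    hr_active, hr_zeroed``.  Under ``convention='zeroed'`` asystolic segments
    contribute HR = 0; under ``'active_only'`` they are missing.  Gaps left
    by missing segments keep their step spacing in the AR(1) correlation
    (``corr = ρ^lag``).  On optimizer failure the fit falls back to ρ = 0 and
    then to ordinary least squares, warning loudly and flagging
    ``converged=False``.
    """
    df = cohort.segments if hasattr(cohort, "segments") else cohort
    if convention not in ("zeroed", "active_only"):
        raise ParameterError(f"unknown convention {convention!r}")
    response = "hr_zeroed" if convention == "zeroed" else "hr_active"
    data = df.dropna(subset=[response]).copy()

    counts = data.groupby("group")["spat_id"].nunique()
    if (counts < 2).any() or len(counts) < 1:
        raise ParameterError("need at least 2 spat per group")
    if data["set_point"].nunique() < 3:
        raise ParameterError("need at least 3 temperature levels")

    X, y, keep = _design(data, response)
    blocks = _blocks(data, X, y)
    p = X.shape[1]
    var_y = float(np.var(y)) or 1.0
    ridge = 1e-8 * var_y

    def objective(th, use_ar1):
        theta = np.array([th[0], th[1], th[2] if use_ar1 else 0.0])
        return _reml_neg2(theta, blocks, p, use_ar1, ridge)[0]

    x0 = np.array([np.log(var_y / 2), np.log(var_y / 2), 0.0])
    method_used, result = "reml_ar1", None
    for use_ar1 in ([True, False] if ar1 else [False]):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = optimize.minimize(
                    lambda th: objective(th, use_ar1),
                    x0 if use_ar1 else x0[:2].tolist() + [0.0],
                    method="Nelder-Mead",
                    options={"maxiter": 800, "xatol": 1e-7, "fatol": 1e-9},
                )
            theta = np.array(
                [res.x[0], res.x[1], res.x[2] if use_ar1 else 0.0]
            )
            neg2, beta, A, comps = _reml_neg2(theta, blocks, p, use_ar1, ridge)
            if beta is not None and np.all(np.isfinite(beta)):
                method_used = "reml_ar1" if use_ar1 else "reml_independent"
                result = (res, neg2, beta, A, comps)
                if not use_ar1 and ar1:
                    warnings.warn(
                        "AR(1) REML failed to converge; fell back to "
                        "independent-residual REML"
                    )
                break
        except Exception:
            continue
    if result is None:
        warnings.warn("REML failed entirely; falling back to ordinary least squares")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = float(resid @ resid) / max(len(y) - p, 1)
        A = X.T @ X / s2
        result = (None, float("nan"), beta, A, (0.0, s2, 0.0))
        method_used = "ols_fallback"

    res, neg2, beta, A, (su2, se2, rho) = result
    converged = bool(res.success) if res is not None else False
    cov_k = np.linalg.inv(A)
    se_k = np.sqrt(np.diag(cov_k))

    # expand back to the full 5-effect space; dropped effects are NaN
    nfull = len(FIXED_EFFECTS)
    beta_f = np.full(nfull, np.nan)
    se_f = np.full(nfull, np.nan)
    cov = np.full((nfull, nfull), np.nan)
    beta_f[keep] = beta
    se_f[keep] = se_k
    cov[np.ix_(keep, keep)] = cov_k
    with np.errstate(invalid="ignore", divide="ignore"):
        pvals = 2.0 * sps.norm.sf(np.abs(beta_f / se_f))
    ci_lo, ci_hi = beta_f - 1.96 * se_f, beta_f + 1.96 * se_f

    idx = FIXED_EFFECTS
    fit = ModelFit(
        params=pd.Series(beta_f, index=idx),
        bse=pd.Series(se_f, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        conf_int=pd.DataFrame({"lower": ci_lo, "upper": ci_hi}, index=idx),
        cov_params=pd.DataFrame(cov, index=idx, columns=idx),
        sigma_u2=su2,
        sigma_e2=se2,
        rho=rho,
        converged=converged,
        method=method_used,
        n_obs=len(y),
        neg2_reml=float(neg2),
    )

    # per-group temperature gradients (beats/min per °C) with Wald CIs
    present = set(data["group"].unique())
    cvecs = {"Ta22": np.array([0.0, 0.0, 1.0, 0.0, 0.0]),
             "Ta10": np.array([0.0, 0.0, 1.0, 1.0, 0.0])}
    covk = pd.DataFrame(cov, index=idx, columns=idx)
    for name, cvec in cvecs.items():
        if name not in present:
            continue
        active = cvec != 0
        if np.any(np.isnan(beta_f[active])):
            continue
        est = float(cvec[active] @ beta_f[active])
        sd = float(np.sqrt(cvec[active] @ cov[np.ix_(active, active)] @ cvec[active]))
        fit.group_slopes[name] = {
            "estimate": est,
            "se": sd,
            "ci": (est - 1.96 * sd, est + 1.96 * sd),
        }
    if not np.isnan(beta_f[3]):  # interaction: Ta10 minus Ta22 gradient
        est, sd = float(beta_f[3]), float(se_f[3])
        fit.slope_difference = {
            "estimate": -est,  # Ta22 minus Ta10, the cooling-decline difference
            "se": sd,
            "ci": (-est - 1.96 * sd, -est + 1.96 * sd),
            "p": float(2.0 * sps.norm.sf(abs(est / sd))) if sd > 0 else float("nan"),
        }
    return fit


def rank_anova_q10(records: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Two-way fixed-effects ANOVA on globally mid-ranked Q10 values.

    ``records`` needs columns ``q10, group, phase`` (NaN Q10 rows — asystole
    — are dropped).  Returns ``{'group': {'F', 'p'}, 'phase': …,
    'interaction': …}``.  A factor with an empty level is dropped with a
    warning; if all ranks are tied every F is 0 with p = 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records.dropna(subset=["q10"]).copy()
    if len(df) == 0:
        raise ParameterError("no defined Q10 values")
    df["rank_"] = sps.rankdata(df["q10"].to_numpy())

    factors = []
    for factor in ("group", "phase"):
        if df[factor].nunique() < 2:
            warnings.warn(f"factor {factor!r} has fewer than 2 observed levels; dropped")
        else:
            factors.append(factor)
    out = {
        "group": {"F": float("nan"), "p": float("nan")},
        "phase": {"F": float("nan"), "p": float("nan")},
        "interaction": {"F": float("nan"), "p": float("nan")},
    }
    if np.ptp(df["rank_"].to_numpy()) == 0:  # all observations tied
        for key in out:
            out[key] = {"F": 0.0, "p": 1.0}
        return out
    if not factors:
        raise ParameterError("no factor has 2 observed levels")

    cells_ok = len(factors) == 2 and (
        df.groupby(["group", "phase"]).size().ge(2).all()
        and df.groupby(["group", "phase"]).ngroups
        == df["group"].nunique() * df["phase"].nunique()
    )
    terms = [f"C({f})" for f in factors]
    if cells_ok:
        terms.append("C(group):C(phase)")
    elif len(factors) == 2:
        warnings.warn("a group x phase cell is empty or singleton; interaction dropped")
    model = smf.ols("rank_ ~ " + " + ".join(terms), data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    mapping = {
        "C(group)": "group",
        "C(phase)": "phase",
        "C(group):C(phase)": "interaction",
    }
    for row, key in mapping.items():
        if row in table.index:
            out[key] = {
                "F": float(table.loc[row, "F"]),
                "p": float(table.loc[row, "PR(>F)"]),
            }
    return out
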
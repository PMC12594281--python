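"""Somatic-burden statistics.

Linear mixed-effects models (random intercept per individual, REML) for
burden vs age and clinical condition, with Satterthwaite-approximated
degrees of freedom for fixed-effect t-tests; QC-covariate correction;
age-adjusted excess burdens; two-tailed Wilcoxon rank-sum tests; covariate
association models (years of football, APOE genetic models, symptom
duration); and High-/Low-Indel classification.

Model estimation is delegated to statsmodels' MixedLM; the Satterthwaite
layer (numeric gradient of each fixed-effect variance with respect to the
variance components, and the numeric REML-likelihood Hessian) is computed
here from the closed-form random-intercept marginal likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf


# ---------------------------------------------------------------------------
# random-intercept REML machinery


def _group_blocks(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    Xo, yo, go = X[order], y[order], groups[order]
    _, starts = np.unique(go, return_index=True)
    bounds = list(starts) + [len(go)]
    return [(Xo[a:b], yo[a:b]) for a, b in zip(bounds[:-1], bounds[1:])]


def _reml_pieces(blocks, tau2: float, sigma2: float):
    """GLS matrices and REML log-likelihood terms for V = s2*I + t2*J."""
    p = blocks[0][0].shape[1]
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    logdet = 0.0
    quad_parts = []
    for Xi, yi in blocks:
        ni = len(yi)
        w = tau2 / (sigma2 + ni * tau2)
        Xs = Xi.sum(axis=0)
        ys = yi.sum()
        A += (Xi.T @ Xi - w * np.outer(Xs, Xs)) / sigma2
        bvec += (Xi.T @ yi - w * Xs * ys) / sigma2
        logdet += (ni - 1) * np.log(sigma2) + np.log(sigma2 + ni * tau2)
        quad_parts.append((Xi, yi, w))
    beta = np.linalg.solve(A, bvec)
    quad = 0.0
    for Xi, yi, w in quad_parts:
        ri = yi - Xi @ beta
        quad += (ri @ ri - w * ri.sum() ** 2) / sigma2
    return A, beta, logdet, quad


def _reml_loglik(blocks, tau2: float, sigma2: float) -> float:
    if sigma2 <= 0 or tau2 < 0:
        return -np.inf
    A, _, logdet, quad = _reml_pieces(blocks, tau2, sigma2)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return -np.inf
    return -0.5 * (logdet + logdetA + quad)


def _coef_var(blocks, tau2, sigma2) -> np.ndarray:
    A, _, _, _ = _reml_pieces(blocks, tau2, sigma2)
    return np.diag(np.linalg.inv(A))


def _satterthwaite_df(blocks, tau2, sigma2, j: int) -> float:
    """df = 2 f^2 / (g' H^-1 g) for coefficient j.

    f is the j-th fixed-effect sampling variance as a function of the
    variance components; g its numeric gradient; H the numeric Hessian of
    the negative REML log-likelihood.
    """
    theta = np.array([tau2, sigma2])
    steps = np.maximum(1e-4 * np.maximum(theta, 1.0), 1e-6)

    def f(th):
        return _coef_var(blocks, max(th[0], 0.0), max(th[1], 1e-12))[j]

    g = np.zeros(2)
    for k in range(2):
        e = np.zeros(2)
        e[k] = steps[k]
        lo = theta - e
        lo[0] = max(lo[0], 0.0)
        lo[1] = max(lo[1], 1e-12)
        g[k] = (f(theta + e) - f(lo)) / (theta[k] + steps[k] - lo[k])
    H = np.zeros((2, 2))
    ll = lambda th: _reml_loglik(blocks, max(th[0], 0.0), max(th[1], 1e-12))
    l0 = ll(theta)
    for a in range(2):
        for b in range(a, 2):
            ea, eb = np.zeros(2), np.zeros(2)
            ea[a], eb[b] = steps[a], steps[b]
            lpp = ll(theta + ea + eb)
            lpm = ll(theta + ea - eb)
            lmp = ll(theta - ea + eb)
            lmm = ll(theta - ea - eb)
            if not np.isfinite([lpp, lpm, lmp, lmm]).all():
                return float("nan")
            H[a, b] = H[b, a] = -(lpp - lpm - lmp + lmm) / (4 * steps[a] * steps[b])
    try:
        cov_theta = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return float("nan")
    denom = g @ cov_theta @ g
    if denom <= 0:
        return float("nan")
    fval = f(theta)
    return float(2 * fval**2 / denom)


# ---------------------------------------------------------------------------
# public fit interface


@dataclass
class LmeFit:
    params: pd.Series
    se: pd.Series
    df: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    tau2: float
    sigma2: float
    converged: bool
    singular: bool
    lrt_pvalues: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    n_obs: int = 0

    @property
    def fixed_effects(self) -> pd.Series:
        return self.params


def fit_burden_lme(
    cells: pd.DataFrame,
    outcome: str = "snv_burden",
    covariates: tuple[str, ...] = ("age",),
    condition: str | None = None,
    control_label: str = "control",
    group_col: str = "individual",
) -> LmeFit:
    """REML random-intercept fit of burden on age (+ optional covariates and
    a condition indicator), with Satterthwaite fixed-effect tests.

    When ``condition`` is given, the data are restricted to control +
    condition cells and a 0/1 condition indicator is added, matching the
    each-condition-against-controls contrast scheme.
    """
    data = cells.copy()
    terms = list(covariates)
    if condition is not None:
        data = data[data["condition"].isin([control_label, condition])].copy()
        data["cond"] = (data["condition"] == condition).astype(float)
        terms.append("cond")
    if data[group_col].nunique() < 2:
        raise ValueError("need at least two individuals")
    # collinearity guard
    Z = data[terms].to_numpy(dtype=float)
    if len(terms) > 1:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(Z)), Z]))
        if rank < len(terms) + 1:
            raise ValueError("rank-deficient fixed-effect design "
                             f"(collinear covariates {terms})")
    formula = f"{outcome} ~ " + " + ".join(terms)
    md = smf.mixedlm(formula, data, groups=data[group_col])
    import warnings

    fit = None
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (["bfgs"], ["powell"], ["nm"]):
            try:
                fit = md.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
    if fit is None:
        raise RuntimeError("mixed-model fit failed with all optimizers")
    tau2 = float(fit.cov_re.iloc[0, 0])
    sigma2 = float(fit.scale)
    singular = tau2 < 1e-8 * max(sigma2, 1.0)
    names = ["Intercept"] + terms
    X = np.column_stack([np.ones(len(data))] + [data[t].to_numpy(float)
                                                for t in terms])
    y = data[outcome].to_numpy(float)
    groups = data[group_col].to_numpy()
    blocks = _group_blocks(X, y, groups)
    A, beta, _, _ = _reml_pieces(blocks, max(tau2, 0.0), max(sigma2, 1e-12))
    cov = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    dfs, pvals, lrt = [], [], {}
    for j, name in enumerate(names):
        dfj = _satterthwaite_df(blocks, tau2, sigma2, j)
        if not np.isfinite(dfj) or dfj < 1:  # degenerate/boundary fit
            dfj = float(len(y) - len(names))
            lrt[name] = _lrt_pvalue(data, outcome, terms, name, group_col)
        t = beta[j] / se[j]
        pvals.append(float(2 * stats.t.sf(abs(t), dfj)))
        dfs.append(dfj)
    resid = y - X @ beta
    fitted = X @ beta
    shapiro_p = float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 else np.nan
    homo = stats.spearmanr(np.abs(resid), fitted)
    diagnostics = {
        "residual_normality_p": shapiro_p,
        "homoscedasticity_rho": float(homo.statistic),
        "homoscedasticity_p": float(homo.pvalue),
        "linearity_corr": float(np.corrcoef(resid, data[terms[0]])[0, 1])
        if len(terms) else np.nan,
    }
    return LmeFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        df=pd.Series(dfs, index=names),
        tvalues=pd.Series(beta / se, index=names),
        pvalues=pd.Series(pvals, index=names),
        tau2=tau2,
        sigma2=sigma2,
        converged=bool(fit.converged),
        singular=singular,
        lrt_pvalues=lrt,
        diagnostics=diagnostics,
        n_obs=len(y),
    )


def _lrt_pvalue(data, outcome, terms, dropped, group_col) -> float:
    """ML likelihood-ratio fallback p-value for one fixed effect."""
    import warnings

    kept = [t for t in terms if t != dropped]
    f_full = f"{outcome} ~ " + " + ".join(terms)
    f_null = f"{outcome} ~ " + (" + ".join(kept) if kept else "1")
    if dropped == "Intercept":
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.mixedlm(f_full, data, groups=data[group_col]).fit(reml=False)
        null = smf.mixedlm(f_null, data, groups=data[group_col]).fit(reml=False)
    lr = 2 * (full.llf - null.llf)
    return float(stats.chi2.sf(max(lr, 0.0), 1))


# ---------------------------------------------------------------------------
# QC correction, excess burden


def qc_correct_burden(
    cells: pd.DataFrame,
    metric: str,
    outcome: str = "snv_burden",
    control_label: str = "control",
) -> tuple[pd.Series, float]:
    """Subtract a quality metric's fitted contribution from every cell.

    The metric coefficient is estimated in control cells only (metric + age
    as fixed effects, individuals random); corrected burden =
    burden - coef * metric for all cells.
    """
    controls = cells[cells["condition"] == control_label]
    if controls[metric].std(ddof=0) == 0:
        raise ValueError(f"quality metric {metric} has zero variance")
    fit = fit_burden_lme(controls, outcome=outcome, covariates=("age", metric))
    coef = float(fit.params[metric])
    corrected = cells[outcome] - coef * cells[metric]
    return corrected, coef


def fit_control_age_model(
    cells: pd.DataFrame, outcome: str = "snv_burden",
    control_label: str = "control",
) -> LmeFit:
    controls = cells[cells["condition"] == control_label]
    return fit_burden_lme(controls, outcome=outcome, covariates=("age",))


def compute_excess_burden(
    cells: pd.DataFrame, control_fit: LmeFit, outcome: str = "snv_burden"
) -> pd.Series:
    """Per-cell excess = burden - (control intercept + age coefficient * age).

    Subtracting the control intercept along with the age contribution
    centres the control group at zero excess.
    """
    expected = (control_fit.params["Intercept"]
                + control_fit.params["age"] * cells["age"])
    return cells[outcome] - expected


def test_excess_wilcoxon(a, b, exact_max_n: int = 50) -> dict:
    """Two-tailed Wilcoxon rank-sum test between two excess-burden groups.

    Exact null distribution for combined n <= ``exact_max_n`` without ties;
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= exact_max_n and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "p": float(res.pvalue),
        "statistic": float(res.statistic),
        "method": method,
        "median_diff": float(np.median(a) - np.median(b)),
    }


# ---------------------------------------------------------------------------
# association covariates


def encode_apoe(diplotype: str) -> tuple[int, int, int]:
    """(dominant, additive, recessive) coding of the APOE e4 allele count."""
    d = diplotype.replace("ε", "e").lower()
    alleles = d.split("/")
    if len(alleles) != 2 or not all(a in ("e2", "e3", "e4") for a in alleles):
        raise ValueError(f"invalid APOE diplotype {diplotype!r}")
    n4 = sum(a == "e4" for a in alleles)
    return (1 if n4 >= 1 else 0, n4, 1 if n4 == 2 else 0)


def test_association(
    cells: pd.DataFrame,
    covariate: str,
    outcome: str = "snv_burden",
    condition: str = "CTE",
) -> LmeFit:
    """Association of burden with a covariate in one clinical group,
    adjusting for age (age + covariate fixed, individuals random)."""
    sub = cells[cells["condition"] == condition].copy()
    if covariate.startswith("apoe_"):
        model = covariate.split("_", 1)[1]
        idx = {"dominant": 0, "additive": 1, "recessive": 2}[model]
        sub[covariate] = [encode_apoe(d)[idx] for d in sub["apoe"]]
    return fit_burden_lme(sub, outcome=outcome, covariates=("age", covariate))


# these are statistical tests, not pytest tests
test_excess_wilcoxon.__test__ = False  # type: ignore[attr-defined]
test_association.__test__ = False  # type: ignore[attr-defined]


def classify_indel_groups(mean_excess: pd.Series, cutoff: float = 50.0) -> pd.Series:
    """High-Indel iff the individual's mean excess sIndels strictly exceeds
    the cutoff."""
    return pd.Series(np.where(mean_excess > cutoff, "High", "Low"),
                     index=mean_excess.index)
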
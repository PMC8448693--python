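"""Inference layer: mixed-effects ANOVA with Dunnett many-to-one post hoc,
Holm step-down adjustment, and repeated-measures curve comparison.

Endpoint assays (viability, anisotropy, ATPase) are modelled with a fixed
treatment effect and a random intercept per biological replicate; the
residual sits at the technical-replicate level.  Many-to-one comparisons
against the control are adjusted with Dunnett's method, i.e. using the
joint multivariate-t distribution of the contrast statistics.  For a
balanced design the contrasts are equicorrelated and the rectangle
probability is evaluated by Gauss-Hermite/Gauss-Legendre quadrature over
the shared factor and the chi-distributed scale; non-equicorrelated
covariance falls back to a seeded Monte Carlo estimate.

Transport time courses are compared as whole curves: a mixed model with
treatment, time and treatment x time fixed effects and a random intercept
per insert, a joint Wald test of all terms involving each treatment versus
the reference, and Holm adjustment across treatments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from . import schemas as S

__all__ = [
    "StatsConfig",
    "ComparisonResult",
    "holm_adjust",
    "dunnett_pvalue",
    "mixed_anova_dunnett",
    "repeated_measures_compare",
]


@dataclass(frozen=True)
class StatsConfig:
    """Configuration of the inferential layer."""

    alpha: float = 0.05
    sided: str = "two"  # "two" | "one"
    random_effect: str = S.BIO_REP
    mc_draws: int = 200_000
    mc_seed: int = 20210820

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


@dataclass(frozen=True)
class ComparisonResult:
    contrast: str
    estimate: float
    std_error: float
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool
    conf_low: float
    conf_high: float


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original order.

    adjusted p_(i) = max_{j<=i} (m - j + 1) * p_(j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# Dunnett multiplicity adjustment
# ---------------------------------------------------------------------------

def _equicorrelated_rectangle(t: float, k: int, rho: float, df: int,
                              n_z: int = 48, n_u: int = 64) -> float:
    """P(max_j |T_j| <= t) for k equicorrelated t statistics.

    T_j = Z_j / S with Z_j = sqrt(rho) Z0 + sqrt(1-rho) X_j and
    S = chi_df / sqrt(df); quadrature over Z0 (Gauss-Hermite) and the
    quantiles of S (Gauss-Legendre).
    """
    if t <= 0:
        return 0.0
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(n_z)  # weight exp(-x^2/2)
    gh_w = gh_w / np.sqrt(2.0 * np.pi)
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_u)
    u = 0.5 * (gl_x + 1.0)
    wu = 0.5 * gl_w
    s = sps.chi.ppf(u, df) / np.sqrt(df)  # quantiles of the scale factor
    sr = np.sqrt(max(rho, 0.0))
    sq = np.sqrt(max(1.0 - rho, 1e-12))
    ts = t * s[:, None]  # (n_u, 1)
    z0 = gh_x[None, :]  # (1, n_z)
    upper = (ts - sr * z0) / sq
    lower = (-ts - sr * z0) / sq
    probs = np.clip(sps.norm.cdf(upper) - sps.norm.cdf(lower), 0.0, 1.0) ** k
    return float(wu @ probs @ gh_w)


def _equicorrelated_rectangle_onesided(t: float, k: int, rho: float, df: int,
                                       n_z: int = 48, n_u: int = 64) -> float:
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(n_z)
    gh_w = gh_w / np.sqrt(2.0 * np.pi)
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_u)
    u = 0.5 * (gl_x + 1.0)
    wu = 0.5 * gl_w
    s = sps.chi.ppf(u, df) / np.sqrt(df)
    sr = np.sqrt(max(rho, 0.0))
    sq = np.sqrt(max(1.0 - rho, 1e-12))
    upper = (t * s[:, None] - sr * gh_x[None, :]) / sq
    probs = sps.norm.cdf(upper) ** k
    return float(wu @ probs @ gh_w)


def _mc_rectangle(t: float, corr: np.ndarray, df: int, sided: str,
                  draws: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    k = corr.shape[0]
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    z = rng.standard_normal((draws, k)) @ chol.T
    s = np.sqrt(rng.chisquare(df, size=draws) / df)
    tt = z / s[:, None]
    if sided == "two":
        return float(np.mean(np.abs(tt).max(axis=1) <= abs(t)))
    return float(np.mean(tt.min(axis=1) > t))


def dunnett_pvalue(t_stat: float, corr: np.ndarray, df: int, sided: str = "two",
                   mc_draws: int = 200_000, mc_seed: int = 20210820) -> float:
    """Dunnett-adjusted p-value of one contrast statistic.

    ``corr`` is the correlation matrix of all k contrast statistics in the
    family.  ``sided='one'`` tests in the direction of a *decrease*
    relative to the control (the many-to-one direction of interest for
    viability, anisotropy and dRLU declines).  Near-equicorrelated
    structure (the balanced case, rho = 0.5) is evaluated by quadrature;
    otherwise a seeded Monte Carlo estimate of the multivariate-t
    rectangle probability is used.
    """
    k = corr.shape[0]
    if k == 1:
        return float(2.0 * sps.t.sf(abs(t_stat), df)) if sided == "two" \
            else float(sps.t.cdf(t_stat, df))
    off = corr[~np.eye(k, dtype=bool)]
    rho = float(off.mean())
    if np.max(np.abs(off - rho)) < 1e-2:
        if sided == "two":
            rect = _equicorrelated_rectangle(abs(t_stat), k, rho, df)
        else:
            # P(all T_j > t) = P(all -T_j <= -t) by symmetry of the mvt
            rect = _equicorrelated_rectangle_onesided(-t_stat, k, rho, df)
    else:
        rect = _mc_rectangle(t_stat, corr, df, sided, mc_draws, mc_seed)
    return float(np.clip(1.0 - rect, 0.0, 1.0))


def _dunnett_critical(alpha: float, corr: np.ndarray, df: int, sided: str,
                      mc_draws: int, mc_seed: int) -> float:
    from scipy.optimize import brentq
    if corr.shape[0] == 1:
        return sps.t.ppf(1 - alpha / (2 if sided == "two" else 1), df)
    sign = 1.0 if sided == "two" else -1.0
    return brentq(
        lambda c: dunnett_pvalue(sign * c, corr, df, sided, mc_draws, mc_seed) - alpha,
        1e-3, 50.0, xtol=1e-6,
    )


# ---------------------------------------------------------------------------
# endpoint assays: mixed ANOVA + Dunnett
# ---------------------------------------------------------------------------

def _treatment_contrasts(fit, treatment_col: str, control: str, levels: list[str]):
    """Extract treatment-vs-control estimates, covariance and names."""
    names = [f"C({treatment_col}, Treatment('{control}'))[T.{lv}]" for lv in levels]
    est = np.array([fit.params[n] for n in names])
    cov = fit.cov_params().loc[names, names].to_numpy()
    return est, cov


def mixed_anova_dunnett(
    data: pd.DataFrame,
    control: str,
    value_col: str = S.VALUE,
    treatment_col: str = S.TREATMENT,
    config: StatsConfig = StatsConfig(),
) -> list[ComparisonResult]:
    """Treatment-vs-control comparisons from a linear mixed-effects ANOVA.

    Fixed treatment effect, random intercept per biological replicate
    (``config.random_effect`` column), residual at the technical-replicate
    level; REML estimation with the variance component floored at zero.
    A single biological replicate falls back to fixed-effects ANOVA with a
    warning; a vanishing replicate variance is refit as OLS so that the
    k = 1 case reduces exactly to the pooled two-sample t-test.  The
    residual degrees of freedom are used throughout.
    """
    df_in = data[[value_col, treatment_col, config.random_effect]].copy()
    df_in.columns = ["value", "treatment", "grp"]
    df_in["treatment"] = df_in["treatment"].astype(str)
    control = str(control)
    levels = sorted(lv for lv in df_in["treatment"].unique() if lv != control)
    if control not in set(df_in["treatment"]):
        raise ValueError(f"control level {control!r} not present")
    if not levels:
        raise ValueError("no treatment levels besides the control")

    formula = f"value ~ C(treatment, Treatment('{control}'))"
    n_groups = df_in["grp"].nunique()
    use_ols = False
    if n_groups < 2:
        warnings.warn(
            "single biological replicate: falling back to fixed-effects ANOVA",
            UserWarning, stacklevel=2,
        )
        use_ols = True
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                mfit = smf.mixedlm(formula, df_in, groups=df_in["grp"]).fit(reml=True)
            if float(mfit.cov_re.iloc[0, 0]) < 1e-8 * float(mfit.scale):
                use_ols = True  # replicate variance at the boundary
        except np.linalg.LinAlgError:
            use_ols = True  # singular profile: variance component is 0
    if use_ols:
        mfit = smf.ols(formula, df_in).fit()
        resid_df = int(mfit.df_resid)
    else:
        resid_df = int(len(df_in) - (len(levels) + 1))

    est, cov = _treatment_contrasts(mfit, "treatment", control, levels)
    se = np.sqrt(np.diag(cov))
    corr = cov / np.outer(se, se)
    tstats = est / se

    crit = _dunnett_critical(config.alpha, corr, resid_df, config.sided,
                             config.mc_draws, config.mc_seed)
    results = []
    for i, lv in enumerate(levels):
        if config.sided == "two":
            p_raw = float(2.0 * sps.t.sf(abs(tstats[i]), resid_df))
            conf = (float(est[i] - crit * se[i]), float(est[i] + crit * se[i]))
        else:
            # one-sided toward a decrease relative to the control
            p_raw = float(sps.t.cdf(tstats[i], resid_df))
            conf = (-np.inf, float(est[i] + crit * se[i]))
        p_adj = dunnett_pvalue(tstats[i], corr, resid_df, config.sided,
                               config.mc_draws, config.mc_seed)
        p_adj = max(p_adj, p_raw)
        results.append(ComparisonResult(
            contrast=f"{lv} - {control}",
            estimate=float(est[i]),
            std_error=float(se[i]),
            statistic=float(tstats[i]),
            p_raw=p_raw,
            p_adjusted=p_adj,
            significant=bool(p_adj < config.alpha),
            conf_low=conf[0],
            conf_high=conf[1],
        ))
    return results


# ---------------------------------------------------------------------------
# transport time courses: repeated-measures curve comparison
# ---------------------------------------------------------------------------

def repeated_measures_compare(
    timecourses: pd.DataFrame,
    reference: str,
    value_col: str = "pct",
    treatment_col: str = S.TREATMENT,
    time_col: str = S.TIME_H,
    replicate_col: str = S.REPLICATE,
    config: StatsConfig = StatsConfig(),
) -> list[ComparisonResult]:
    """Whole-curve comparison of each treatment's time course vs a reference.

    Mixed model: treatment, time and treatment x time fixed effects with a
    random intercept per insert (replicate within treatment).  For each
    non-reference treatment the curve contrast is a joint Wald test over
    its main-effect and interaction coefficients, referred to an
    F(q, n_units - n_treatments) distribution: the treatment contrast is a
    between-insert comparison, so the between-unit degrees of freedom are
    the honest (conservative) denominator -- the residual df would be
    strongly anti-conservative at triplicate designs.  P-values are
    Holm-adjusted across treatments.  Treatments missing timepoints are
    compared on the shared grid (noted in the contrast label).
    """
    df_in = timecourses[[value_col, treatment_col, time_col, replicate_col]].copy()
    df_in.columns = ["value", "treatment", "time", "rep"]
    df_in["treatment"] = df_in["treatment"].astype(str)
    reference = str(reference)
    if reference not in set(df_in["treatment"]):
        raise ValueError(f"reference treatment {reference!r} not present")
    df_in["unit"] = df_in["treatment"] + "/" + df_in["rep"].astype(str)

    # restrict to the timepoint grid shared by every treatment
    grids = df_in.groupby("treatment")["time"].apply(lambda s: set(np.round(s, 9)))
    shared = set.intersection(*grids)
    trimmed = any(g != shared for g in grids)
    df_in = df_in[np.round(df_in["time"], 9).isin(shared)]

    treatments = sorted(t for t in df_in["treatment"].unique() if t != reference)
    formula = f"value ~ C(treatment, Treatment('{reference}')) * C(time)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        fit = smf.mixedlm(formula, df_in, groups=df_in["unit"]).fit(reml=True)

    n_units = df_in["unit"].nunique()
    den_df = max(n_units - df_in["treatment"].nunique(), 1)
    names = list(fit.params.index)
    raw_p, estimates, ses = [], [], []
    for trt in treatments:
        tag = f"[T.{trt}]"
        sel = [n for n in names if tag in n]
        L = np.zeros((len(sel), len(names)))
        for r, n in enumerate(sel):
            L[r, names.index(n)] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wald_stat = float(fit.wald_test(L, scalar=True).statistic)
        q = len(sel)
        raw_p.append(float(sps.f.sf(wald_stat / q, q, den_df)))
        # average curve offset over the shared grid, for reporting
        coefs = np.array([fit.params[n] for n in sel])
        main = fit.params[f"C(treatment, Treatment('{reference}'))[T.{trt}]"]
        estimates.append(float(main + (coefs.sum() - main) / len(shared)))
        ses.append(float(np.sqrt(np.diag(fit.cov_params().loc[sel, sel]).mean())))

    adj = holm_adjust(raw_p)
    results = []
    for i, trt in enumerate(treatments):
        label = f"{trt} vs {reference}"
        if trimmed:
            label += " (shared timepoints only)"
        results.append(ComparisonResult(
            contrast=label,
            estimate=estimates[i],
            std_error=ses[i],
            statistic=np.nan,
            p_raw=raw_p[i],
            p_adjusted=float(adj[i]),
            significant=bool(adj[i] < config.alpha),
            conf_low=np.nan,
            conf_high=np.nan,
        ))
    return results
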
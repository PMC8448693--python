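"""Four-parameter exponential dose-response modelling under concentration addition.

The viability model is

    y(x) = a * [c - (c - 1) * exp(-b * x**d)]

with ``a`` the solvent-control level (percent), ``c`` the maximum fold
change of the response (``c < 1`` for cytotoxicity, so the lower asymptote
is ``a*c``), ``b > 0`` the potency and ``d > 0`` the steepness.  Mixtures
are assessed against the concentration-addition (dose-addition) null
model: each component is treated as a dilution of an index compound via a
relative potency factor (RPF), so a mixture dose ``x`` on the
active-substance axis maps to the equivalent index-compound dose

    x_eq(x) = sum_i RPF_i * rho_i * x

where ``rho_i`` is the dose ratio of component ``i`` to the active
substance.  Under a parallel-curve fit (shared ``a``, ``c``, ``d``; one
``b`` per compound) the unique RPF that makes this mapping exact is

    RPF_i = (b_i / b_ref) ** (1 / d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .schemas import BIO_REP, COMPOUND, CONC, VIABILITY

__all__ = [
    "ExponentialModelParams",
    "ExponentialDoseResponse",
    "ParallelDoseResponse",
    "ParallelFitResult",
    "RelativePotencySet",
    "MixtureSpec",
    "AdditivityVerdict",
    "ClassificationRule",
    "NoCytotoxicitySignal",
    "FitConvergenceError",
    "exponential_model",
    "fit_single",
    "fit_parallel",
    "compute_rpf",
    "equivalent_dose",
    "predict_ca_curve",
    "classify_additivity",
]


class NoCytotoxicitySignal(ValueError):
    """Raised when a compound shows no response decline worth fitting."""


class FitConvergenceError(RuntimeError):
    """Raised when the parallel fit fails to converge after multi-start."""


@dataclass(frozen=True)
class ExponentialModelParams:
    """Parameters of the four-parameter exponential viability model."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name, value in (("a", self.a), ("b", self.b), ("c", self.c), ("d", self.d)):
            if not np.isfinite(value):
                raise ValueError(f"parameter {name!r} is not finite: {value!r}")
        if self.a <= 0:
            raise ValueError(f"parameter 'a' must be > 0, got {self.a}")
        if self.b <= 0:
            raise ValueError(f"parameter 'b' must be > 0, got {self.b}")
        if self.c < 0:
            raise ValueError(f"parameter 'c' must be >= 0, got {self.c}")
        if self.d <= 0:
            raise ValueError(f"parameter 'd' must be > 0, got {self.d}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def exponential_model(x, p: ExponentialModelParams | None = None, *, a=None, b=None, c=None, d=None):
    """Evaluate ``y = a * [c - (c - 1) * exp(-b * x**d)]`` at concentrations ``x``.

    Accepts either an :class:`ExponentialModelParams` or the four scalars.
    ``x`` must be non-negative (concentration in mg/L).
    """
    if p is not None:
        a, b, c, d = p.as_tuple()
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    return a * (c - (c - 1.0) * np.exp(-b * np.power(x, d)))


def _replicate_means(data: pd.DataFrame) -> pd.DataFrame:
    """Mean response per concentration, averaging technical then biological reps."""
    per_rep = data.groupby([CONC, BIO_REP], sort=True)[VIABILITY].mean().reset_index()
    return per_rep.groupby(CONC, sort=True)[VIABILITY].mean().reset_index()


def _check_signal(x: np.ndarray, y: np.ndarray, min_decline: float) -> None:
    control = float(y[x == x.min()].mean())
    decline = (control - y.min()) / control
    if decline < min_decline:
        raise NoCytotoxicitySignal(
            "no cytotoxicity signal; compound should receive RPF 0 "
            f"(maximum decline {100 * decline:.1f}% < {100 * min_decline:.0f}%)"
        )


class ExponentialDoseResponse(RegressorMixin, BaseEstimator):
    """Least-squares fitter for the four-parameter exponential viability model.

    Scikit-learn style estimator: ``fit(X, y)`` with ``X`` a column of
    concentrations (mg/L) and ``y`` viability in percent of the solvent
    control.  The model is ill-conditioned in ``(b, d)``, so the fit is
    multi-started over a log-spaced ``b`` grid (six decades) and
    ``d in {0.5, 1, 2, 4}`` and parameterised internally in
    ``(a, c, log b, log d)``.

    Parameters
    ----------
    min_decline : float
        Minimum relative response decline required before fitting; flatter
        data raises :class:`NoCytotoxicitySignal` (such compounds get RPF 0).
    ftol : float
        Relative tolerance on the sum of squares.
    n_b_starts : int
        Number of log-spaced ``b`` starting values per ``d`` start.
    fix_d : float or None
        Hold the steepness at a known value instead of estimating it.
        Because ``b`` carries units of (mg/L)^-d, its value is only
        comparable across fits at a common ``d``; recovery studies of ``b``
        therefore condition on the design's steepness.

    Attributes
    ----------
    a_, b_, c_, d_ : float
        Fitted parameters.
    rss_ : float
        Residual sum of squares at the optimum.
    converged_ : bool
        Whether the best local search terminated cleanly.
    """

    _D_STARTS = (0.5, 1.0, 2.0, 4.0)

    def __init__(self, min_decline: float = 0.10, ftol: float = 1e-12,
                 n_b_starts: int = 7, fix_d: float | None = None):
        self.min_decline = min_decline
        self.ftol = ftol
        self.n_b_starts = n_b_starts
        self.fix_d = fix_d

    # internal parameterisation: theta = [a, c, log_b, log_d]
    @staticmethod
    def _predict_theta(theta, x):
        a, c, log_b, log_d = theta
        return a * (c - (c - 1.0) * np.exp(-np.exp(log_b) * np.power(x, np.exp(log_d))))

    def _starts(self, x, y):
        a0 = float(y[x == x.min()].mean())
        c0 = float(np.clip(y.min() / max(a0, 1e-9), 1e-3, 0.95))
        x_pos = x[x > 0]
        scale = float(np.median(x_pos))
        starts = []
        d_starts = (self.fix_d,) if self.fix_d is not None else self._D_STARTS
        for d0 in d_starts:
            # b grid spanning six decades around the half-effect scale
            b_mid = np.log(2.0) / max(scale, 1e-12) ** d0
            for b0 in np.geomspace(b_mid * 1e-3, b_mid * 1e3, self.n_b_starts):
                starts.append(np.array([a0, c0, np.log(b0), np.log(d0)]))
        return starts

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("X and y must have matching lengths")
        if np.unique(x).size < 5:
            raise ValueError("need at least 5 distinct concentrations")
        _check_signal(x, y, self.min_decline)

        if self.fix_d is not None:
            log_fix = np.log(self.fix_d)
            lo = np.array([1e-6, 0.0, -60.0, log_fix])
            hi = np.array([np.inf, 2.0, 60.0, log_fix + 1e-12])
        else:
            lo = np.array([1e-6, 0.0, -60.0, np.log(0.05)])
            hi = np.array([np.inf, 2.0, 60.0, np.log(10.0)])

        def resid(theta):
            return self._predict_theta(theta, x) - y

        starts = self._starts(x, y)
        # rank candidate starts by their raw RSS, polish only the best few
        rss0 = [float(np.sum(resid(t) ** 2)) for t in starts]
        order = np.argsort(rss0)[:6]
        best = None
        for idx in order:
            theta0 = np.clip(starts[idx], lo, hi)
            try:
                res = optimize.least_squares(
                    resid, theta0, bounds=(lo, hi), ftol=self.ftol, xtol=1e-14, gtol=1e-14
                )
            except ValueError:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise FitConvergenceError("all local searches failed")
        a, c, log_b, log_d = best.x
        self.a_, self.b_, self.c_, self.d_ = float(a), float(np.exp(log_b)), float(c), float(np.exp(log_d))
        self.rss_ = float(2.0 * best.cost)
        self.converged_ = bool(best.status > 0)
        self.n_points_ = x.size
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return exponential_model(x, self.params_)

    @property
    def params_(self) -> ExponentialModelParams:
        return ExponentialModelParams(self.a_, self.b_, self.c_, self.d_)


@dataclass
class ParallelFitResult:
    """Shared-shape parallel fit: one potency ``b`` per compound."""

    a: float
    c: float
    d: float
    per_compound_b: dict[str, float]
    reference_id: str
    rss: float
    converged: bool
    excluded: tuple[str, ...] = ()

    def params_for(self, compound_id: str) -> ExponentialModelParams:
        return ExponentialModelParams(self.a, self.per_compound_b[compound_id], self.c, self.d)


@dataclass(frozen=True)
class RelativePotencySet:
    """RPFs relative to a reference compound (reference maps to 1)."""

    reference_id: str
    rpf: dict[str, float]

    def __post_init__(self) -> None:
        if abs(self.rpf.get(self.reference_id, np.nan) - 1.0) > 1e-12:
            raise ValueError("reference compound must have RPF 1")
        if any(v < 0 for v in self.rpf.values()):
            raise ValueError("RPFs must be non-negative")


@dataclass(frozen=True)
class MixtureSpec:
    """Fixed-ratio mixture on the active-substance dose axis.

    ``components`` maps compound id to its dose ratio rho_i relative to the
    active substance (mg per mg of active): a mixture dose of x mg/L means
    the active at x and component i at rho_i * x mg/L.
    """

    components: dict[str, float]
    active_id: str

    def __post_init__(self) -> None:
        if self.active_id not in self.components:
            raise ValueError(f"active compound {self.active_id!r} missing from components")
        if abs(self.components[self.active_id] - 1.0) > 1e-12:
            raise ValueError("active compound must have ratio 1")
        if any(r < 0 for r in self.components.values()):
            raise ValueError("mixture ratios must be non-negative")


class ParallelDoseResponse(BaseEstimator):
    """Joint fit of several compounds with shared ``a, c, d`` and per-compound ``b``.

    ``fit(X, y)`` takes ``X`` as a DataFrame with columns ``compound_id``
    and ``concentration_mg_l`` (or a 2-column array of compound codes and
    concentrations) and ``y`` the viability responses.  Compounds are
    assumed to act as dilutions of one another (parallel curves); the RPFs
    follow from the fitted ``b`` values via ``compute_rpf``.
    """

    def __init__(self, reference: str | None = None, ftol: float = 1e-12):
        self.reference = reference
        self.ftol = ftol

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            compounds = X[COMPOUND].to_numpy()
            x = X[CONC].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=object)
            compounds = X[:, 0]
            x = X[:, 1].astype(float)
        y = np.asarray(y, dtype=float).reshape(-1)
        ids = sorted(pd.unique(compounds))
        reference = self.reference if self.reference is not None else ids[0]
        if reference not in ids:
            raise ValueError(f"reference compound {reference!r} not in data")

        # initialise from per-compound single fits
        singles: dict[str, ExponentialDoseResponse] = {}
        for cid in ids:
            m = compounds == cid
            est = ExponentialDoseResponse().fit(x[m], y[m])
            singles[cid] = est

        a0 = float(np.mean([singles[c].a_ for c in ids]))
        c0 = float(np.clip(np.mean([singles[c].c_ for c in ids]), 0.0, 1.95))
        d_starts = [float(np.exp(np.mean([np.log(singles[c].d_) for c in ids])))]
        d_starts += [0.5, 1.0, 2.0, 4.0]

        masks = {cid: compounds == cid for cid in ids}
        n_c = len(ids)
        lo = np.concatenate([[1e-6, 0.0, np.log(0.05)], np.full(n_c, -60.0)])
        hi = np.concatenate([[np.inf, 2.0, np.log(10.0)], np.full(n_c, 60.0)])

        def resid(theta):
            a, c, log_d = theta[:3]
            d = np.exp(log_d)
            out = np.empty_like(y)
            for j, cid in enumerate(ids):
                m = masks[cid]
                b = np.exp(theta[3 + j])
                out[m] = a * (c - (c - 1.0) * np.exp(-b * np.power(x[m], d))) - y[m]
            return out

        best = None
        for d0 in d_starts:
            log_b0 = []
            for cid in ids:
                s = singles[cid]
                # rescale b to the candidate steepness via the half-effect dose
                x50 = (np.log(2.0) / s.b_) ** (1.0 / s.d_)
                log_b0.append(np.log(np.log(2.0)) - d0 * np.log(max(x50, 1e-12)))
            theta0 = np.clip(np.concatenate([[a0, c0, np.log(d0)], log_b0]), lo, hi)
            try:
                res = optimize.least_squares(
                    resid, theta0, bounds=(lo, hi), ftol=self.ftol, xtol=1e-14, gtol=1e-14
                )
            except ValueError:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None or best.status <= 0:
            raise FitConvergenceError("parallel fit did not converge after multi-start")

        self.compounds_ = list(ids)
        self.a_ = float(best.x[0])
        self.c_ = float(best.x[1])
        self.d_ = float(np.exp(best.x[2]))
        self.b_ = {cid: float(np.exp(best.x[3 + j])) for j, cid in enumerate(ids)}
        self.rss_ = float(2.0 * best.cost)
        self.converged_ = True
        self.reference_id_ = reference
        return self

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            compounds = X[COMPOUND].to_numpy()
            x = X[CONC].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=object)
            compounds = X[:, 0]
            x = X[:, 1].astype(float)
        out = np.empty(x.shape, dtype=float)
        for cid in pd.unique(compounds):
            m = compounds == cid
            out[m] = exponential_model(x[m], self.result_.params_for(cid))
        return out

    @property
    def result_(self) -> ParallelFitResult:
        return ParallelFitResult(
            a=self.a_, c=self.c_, d=self.d_, per_compound_b=dict(self.b_),
            reference_id=self.reference_id_, rss=self.rss_, converged=self.converged_,
        )


# ---------------------------------------------------------------------------
# functional wrappers operating on tidy dose-response tables
# ---------------------------------------------------------------------------

def fit_single(data: pd.DataFrame, fix_d: float | None = None) -> ExponentialModelParams:
    """Fit the exponential model to one compound's replicated viability data.

    Responses are aggregated to replicate means (technical within
    biological) before least squares.  Raises
    :class:`NoCytotoxicitySignal` when no concentration shows a >= 10%
    decline, mirroring the exclusion of non-cytotoxic co-formulants.
    ``fix_d`` holds the steepness at a known value (see
    :class:`ExponentialDoseResponse`).
    """
    means = _replicate_means(data)
    est = ExponentialDoseResponse(fix_d=fix_d).fit(
        means[CONC].to_numpy(), means[VIABILITY].to_numpy())
    return est.params_


def fit_parallel(data: pd.DataFrame, reference_id: str) -> ParallelFitResult:
    """Parallel-curve fit over a multi-compound dataset.

    Compounds without a cytotoxic signal are excluded from the joint fit
    and recorded in ``excluded`` (they later receive RPF 0).  The
    reference compound must carry a signal.
    """
    kept_frames = []
    excluded: list[str] = []
    for cid, sub in data.groupby(COMPOUND, sort=True):
        means = _replicate_means(sub)
        try:
            _check_signal(means[CONC].to_numpy(), means[VIABILITY].to_numpy(), 0.10)
        except NoCytotoxicitySignal:
            if cid == reference_id:
                raise
            excluded.append(str(cid))
            continue
        means = means.assign(**{COMPOUND: cid})
        kept_frames.append(means)
    table = pd.concat(kept_frames, ignore_index=True)
    est = ParallelDoseResponse(reference=reference_id).fit(
        table[[COMPOUND, CONC]], table[VIABILITY]
    )
    result = est.result_
    result.excluded = tuple(excluded)
    return result


def compute_rpf(fit: ParallelFitResult) -> RelativePotencySet:
    """Relative potency factors ``RPF_i = (b_i / b_ref) ** (1/d)``.

    Compounds excluded from the fit for lack of a cytotoxicity signal map
    to RPF 0 so that mixture bookkeeping stays complete.
    """
    if fit.d <= 0:
        raise ValueError("invalid fit: d must be positive")
    b_ref = fit.per_compound_b[fit.reference_id]
    rpf = {cid: float((b / b_ref) ** (1.0 / fit.d)) for cid, b in fit.per_compound_b.items()}
    rpf[fit.reference_id] = 1.0
    for cid in fit.excluded:
        rpf[cid] = 0.0
    return RelativePotencySet(reference_id=fit.reference_id, rpf=rpf)


def equivalent_dose(rpf: RelativePotencySet, mix: MixtureSpec, x) -> np.ndarray:
    """Equivalent reference dose ``x_eq = sum_i RPF_i * rho_i * x``."""
    missing = [cid for cid in mix.components if cid not in rpf.rpf]
    if missing:
        raise KeyError(f"mixture components missing from RPF set: {missing}")
    total = sum(rpf.rpf[cid] * rho for cid, rho in mix.components.items())
    return np.asarray(x, dtype=float) * total


def predict_ca_curve(fit: ParallelFitResult, rpf: RelativePotencySet, mix: MixtureSpec, x_grid) -> np.ndarray:
    """Predicted mixture viability under concentration addition.

    The mixture dose axis is the active-substance concentration; each
    grid point is converted to its equivalent reference dose and evaluated
    on the reference curve.
    """
    x_eq = equivalent_dose(rpf, mix, x_grid)
    return exponential_model(x_eq, fit.params_for(fit.reference_id))


@dataclass(frozen=True)
class ClassificationRule:
    """Decision rule for the additivity call."""

    alpha: float = 0.05
    effect_window: tuple[float, float] = (0.10, 0.90)


@dataclass
class AdditivityVerdict:
    """Outcome of comparing observed mixture data with the CA prediction."""

    label: str  # more_than_additive | additive | less_than_additive | indeterminate
    residuals: pd.DataFrame = field(repr=False)
    statistic: float = np.nan
    p_value: float = np.nan
    n_replicates: int = 0
    n_concentrations: int = 0


def classify_additivity(
    observed: pd.DataFrame,
    fit: ParallelFitResult,
    rpf: RelativePotencySet,
    mix: MixtureSpec,
    rule: ClassificationRule = ClassificationRule(),
) -> AdditivityVerdict:
    """Classify observed mixture cytotoxicity against the CA prediction.

    Residuals (observed minus predicted viability) are computed per
    concentration and biological replicate, restricted to concentrations
    whose predicted effect lies in the 10-90% response window, then the
    per-replicate mean residuals are tested against zero (one-sample,
    paired over biological replicates).  Viability significantly below the
    prediction means the mixture is more potent than dose addition.
    """
    ref = fit.params_for(fit.reference_id)
    per_rep = observed.groupby([CONC, BIO_REP], sort=True)[VIABILITY].mean().reset_index()
    x = per_rep[CONC].to_numpy(dtype=float)
    pred = predict_ca_curve(fit, rpf, mix, x)
    if fit.c >= 1.0:
        raise ValueError("additivity classification requires a declining curve (c < 1)")
    effect = (ref.a - pred) / (ref.a * (1.0 - fit.c))
    lo, hi = rule.effect_window
    window = (effect >= lo) & (effect <= hi)
    table = per_rep.assign(predicted=pred, residual=per_rep[VIABILITY].to_numpy() - pred,
                           effect=effect, in_window=window)
    sub = table[table.in_window]
    n_conc = sub[CONC].nunique()
    if n_conc == 0:
        return AdditivityVerdict(label="indeterminate", residuals=table)
    per_rep_mean = sub.groupby(BIO_REP)["residual"].mean()
    n = per_rep_mean.size
    mean = float(per_rep_mean.mean())
    sd = float(per_rep_mean.std(ddof=1)) if n > 1 else 0.0
    if sd == 0.0 or n < 2:
        # degenerate (noise-free or single-replicate) data: decide on the sign
        if abs(mean) < 1e-9:
            label, t, p = "additive", 0.0, 1.0
        else:
            label = "more_than_additive" if mean < 0 else "less_than_additive"
            t, p = np.inf if mean > 0 else -np.inf, 0.0
    else:
        t, p = sps.ttest_1samp(per_rep_mean, 0.0)
        t, p = float(t), float(p)
        if p < rule.alpha:
            label = "more_than_additive" if mean < 0 else "less_than_additive"
        else:
            label = "additive"
    return AdditivityVerdict(
        label=label, residuals=table, statistic=t, p_value=p,
        n_replicates=int(n), n_concentrations=int(n_conc),
    )
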
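"""Seeded simulation studies validating the pipeline's operating characteristics.

Each study regenerates synthetic data under the design the package
emulates (3 biological x 6 technical replicates for plates, triplicate
inserts with the 2/4/6/8 h schedule for transport) and measures a recovery
rate, power or error rate of the corresponding estimator.  They are used
by the test suite and by the reproduction script; all randomness flows
from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from . import schemas as S
from .dose_response import (
    ClassificationRule,
    ExponentialModelParams,
    MixtureSpec,
    ParallelFitResult,
    RelativePotencySet,
    classify_additivity,
    compute_rpf,
    fit_parallel,
    fit_single,
)
from .membrane import atpase_delta_rlu
from .stats import StatsConfig, mixed_anova_dunnett, repeated_measures_compare
from .synthetic import (
    InhibitionCurve,
    TransportSimConfig,
    generate_atpase_plate,
    generate_dose_response,
    simulate_transport,
)
from .transport import cumulative_amount, relative_percent

__all__ = [
    "b_recovery_study",
    "b_ratio_recovery_study",
    "classifier_shift_study",
    "dunnett_fwer_study",
    "dunnett_power_study",
    "atpase_recovery_study",
    "timecourse_power_study",
    "transport_efflux_ratio",
]

_RECOVERY_PARAMS = ExponentialModelParams(a=100.0, b=0.01, c=0.2, d=1.0)
_RECOVERY_GRID = (0.0, 5.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(seed).spawn(n)]


def b_recovery_study(n_sims: int = 200, residual_sd: float = 5.0, seed: int = 0,
                     rel_tol: float = 0.20) -> float:
    """Fraction of single-compound refits recovering the potency ``b``.

    Data: 3 x 6 design on an 8-point grid from a known curve with
    residual SD ``residual_sd``.  Because ``b`` carries units of
    (mg/L)^-d, recovery is assessed at the design's steepness (``fix_d``);
    the unconditional ``b`` is not identifiable to this precision at
    plate-reader noise (its Cramer-Rao relative SD exceeds 0.2).
    """
    hits = 0
    for s in _child_seeds(seed, n_sims):
        data = generate_dose_response(_RECOVERY_PARAMS, _RECOVERY_GRID,
                                      residual_sd=residual_sd,
                                      bio_intercept_sd=0.0, seed=s)
        est = fit_single(data, fix_d=_RECOVERY_PARAMS.d)
        hits += abs(est.b - _RECOVERY_PARAMS.b) / _RECOVERY_PARAMS.b <= rel_tol
    return hits / n_sims


def b_ratio_recovery_study(n_sims: int = 200, residual_sd: float = 2.0, seed: int = 0,
                           rel_tol: float = 0.05) -> float:
    """Fraction of parallel fits recovering the (1, 2, 4) potency ratios.

    Three compounds share a = 100, c = 0.2, d = 1 and differ only in b;
    a simulation counts as recovered when both non-reference b ratios lie
    within ``rel_tol`` of truth.
    """
    b0 = 0.01
    params = {
        "ref": ExponentialModelParams(100.0, b0, 0.2, 1.0),
        "x2": ExponentialModelParams(100.0, 2 * b0, 0.2, 1.0),
        "x4": ExponentialModelParams(100.0, 4 * b0, 0.2, 1.0),
    }
    grids = {"ref": np.array(_RECOVERY_GRID), "x2": np.array(_RECOVERY_GRID) / 2,
             "x4": np.array(_RECOVERY_GRID) / 4}
    hits = 0
    for s in _child_seeds(seed, n_sims):
        import pandas as pd
        frames = [
            generate_dose_response({cid: params[cid]}, grids[cid],
                                   residual_sd=residual_sd,
                                   bio_intercept_sd=0.0, seed=s + j)
            for j, cid in enumerate(params)
        ]
        fit = fit_parallel(pd.concat(frames, ignore_index=True), reference_id="ref")
        r2 = fit.per_compound_b["x2"] / fit.per_compound_b["ref"]
        r4 = fit.per_compound_b["x4"] / fit.per_compound_b["ref"]
        hits += (abs(r2 - 2.0) / 2.0 <= rel_tol) and (abs(r4 - 4.0) / 4.0 <= rel_tol)
    return hits / n_sims


def _shift_fixture() -> tuple[ParallelFitResult, RelativePotencySet, MixtureSpec, np.ndarray]:
    """Known parallel fit for the classifier studies: RPFs (1, 2), ratio 1:1."""
    fit = ParallelFitResult(
        a=100.0, c=0.2, d=1.0, per_compound_b={"ref": 0.01, "co": 0.02},
        reference_id="ref", rss=0.0, converged=True,
    )
    rpf = compute_rpf(fit)
    mix = MixtureSpec(components={"ref": 1.0, "co": 1.0}, active_id="ref")
    grid = np.array([0.0, 1.5, 3.0, 6.0, 12.0, 24.0, 48.0, 96.0])
    return fit, rpf, mix, grid


def classifier_shift_study(n_sims: int = 200, dose_shift: float = 2.0,
                           residual_sd: float = 2.0, seed: int = 0) -> dict[str, float]:
    """Label frequencies when observed mixture doses are shifted by a factor.

    ``dose_shift = 2`` means the observed data behave as if every dose
    were doubled (a left-shifted, more-than-additive mixture);
    ``dose_shift = 0.5`` is the symmetric right shift.  Returns the
    fraction of runs per verdict label.
    """
    fit, rpf, mix, grid = _shift_fixture()
    # response at dose x follows the CA curve evaluated at shift * x
    x_eq_per_dose = sum(rpf.rpf[c] * rho for c, rho in mix.components.items())
    shifted = ExponentialModelParams(
        fit.a, fit.per_compound_b["ref"] * (x_eq_per_dose * dose_shift) ** fit.d,
        fit.c, fit.d,
    )
    counts: dict[str, int] = {}
    for s in _child_seeds(seed, n_sims):
        obs = generate_dose_response({"mix": shifted}, grid,
                                     residual_sd=residual_sd, bio_intercept_sd=residual_sd,
                                     seed=s)
        verdict = classify_additivity(obs, fit, rpf, mix, ClassificationRule())
        counts[verdict.label] = counts.get(verdict.label, 0) + 1
    return {k: v / n_sims for k, v in counts.items()}


def dunnett_fwer_study(n_runs: int = 1000, k_treatments: int = 7, seed: int = 0,
                       alpha: float = 0.05) -> float:
    """Family-wise error rate of the mixed ANOVA + Dunnett under the null.

    Each run is a balanced 3 biological x 6 technical design with
    ``k_treatments`` treatment arms plus a control, identical means,
    biological-replicate SD 3 and residual SD 5.
    """
    import pandas as pd
    false_pos = 0
    cfg = StatsConfig(alpha=alpha)
    groups = ["control"] + [f"t{i}" for i in range(1, k_treatments + 1)]
    for s in _child_seeds(seed, n_runs):
        rng = np.random.default_rng(s)
        rows = []
        for rep in range(3):
            off = rng.normal(0.0, 3.0)
            for g in groups:
                vals = 100.0 + off + rng.normal(0.0, 5.0, size=6)
                rows += [(g, f"bio{rep}", v) for v in vals]
        df = pd.DataFrame(rows, columns=[S.TREATMENT, S.BIO_REP, S.VALUE])
        res = mixed_anova_dunnett(df, control="control", config=cfg)
        false_pos += any(r.significant for r in res)
    return false_pos / n_runs


def dunnett_power_study(n_runs: int = 100, drop_pct: float = 20.0, seed: int = 0,
                        k_treatments: int = 7, alpha: float = 0.05) -> float:
    """Power to flag one arm with a true viability drop (residual SD 5)."""
    import pandas as pd
    hits = 0
    cfg = StatsConfig(alpha=alpha)
    groups = ["control"] + [f"t{i}" for i in range(1, k_treatments + 1)]
    for s in _child_seeds(seed, n_runs):
        rng = np.random.default_rng(s)
        rows = []
        for rep in range(3):
            off = rng.normal(0.0, 3.0)
            for g in groups:
                mean = 100.0 - drop_pct * (g == "t1")
                vals = mean + off + rng.normal(0.0, 5.0, size=6)
                rows += [(g, f"bio{rep}", v) for v in vals]
        df = pd.DataFrame(rows, columns=[S.TREATMENT, S.BIO_REP, S.VALUE])
        res = mixed_anova_dunnett(df, control="control", config=cfg)
        hits += any(r.significant and r.contrast.startswith("t1 ") for r in res)
    return hits / n_runs


def atpase_recovery_study(n_plates: int = 20, inhibition: float = 0.5,
                          noise_cv: float = 0.05, seed: int = 0) -> float:
    """Mean recovered inhibition fraction over seeded 4-replicate plates.

    The plate programmes an inhibition curve whose fraction at the test
    concentration equals ``inhibition``; the estimator is
    ``1 - dRLU(test + verapamil) / dRLU(verapamil)``.
    """
    conc = 10.0
    hill = 1.0
    ic50 = conc * (1.0 / inhibition - 1.0) ** (1.0 / hill)
    est = []
    for s in _child_seeds(seed, n_plates):
        plate = generate_atpase_plate(
            inhibition_curve=InhibitionCurve(ic50, hill), concentrations=(conc,),
            noise_cv=noise_cv, seed=s,
        )
        res = atpase_delta_rlu(plate)
        ratio = float(res.per_article["ratio_vs_verapamil"].iloc[0])
        est.append(1.0 - ratio)
    return float(np.mean(est))


def transport_efflux_ratio(config: TransportSimConfig, inhibitor_conc: float = 0.0,
                           donor_c0: float = 1.0, seed: int | None = None,
                           species: str = "parent") -> float:
    """Efflux ratio (BL->AP % over AP->BL % at 8 h) of one simulated insert pair."""
    pct = {}
    seeds = _child_seeds(seed, 2) if seed is not None else [None, None]
    for d, s in zip(S.DIRECTIONS, seeds):
        res = simulate_transport(config, d, donor_c0, inhibitor_conc=inhibitor_conc, seed=s)
        ts = res.parent if species == "parent" else res.metabolite
        q = cumulative_amount(ts)
        pct[d] = relative_percent(q, donor_c0, ts.v_donor_ul)[-1]
    return pct["BL_to_AP"] / pct["AP_to_BL"]


def timecourse_power_study(n_runs: int = 200, noise_cv: float = 0.05,
                           inhibitor_conc: float = 160.0, seed: int = 0,
                           alpha: float = 0.05) -> float:
    """Power of the repeated-measures curve contrast on secretion curves.

    Reference inserts run without surfactant (efflux ratio near 0.89);
    treated inserts with a saturating surfactant load (near 0.33).  Three
    replicates per arm, BL->AP direction, 2/4/6/8 h sampling.
    """
    import pandas as pd
    cfg0 = TransportSimConfig(noise_cv=noise_cv)
    hits = 0
    for s in _child_seeds(seed, n_runs):
        sub_seeds = _child_seeds(s, 6)
        rows = []
        for arm, inh, seeds in (("reference", 0.0, sub_seeds[:3]),
                                ("treated", inhibitor_conc, sub_seeds[3:])):
            for i, ss in enumerate(seeds):
                res = simulate_transport(cfg0, "BL_to_AP", 1.0, inhibitor_conc=inh,
                                         replicate=f"r{i + 1}", seed=ss)
                q = cumulative_amount(res.parent)
                pct = relative_percent(q, 1.0, res.parent.v_donor_ul)
                rows += [(arm, f"r{i + 1}", t, p)
                         for t, p in zip(res.parent.times, pct)]
        df = pd.DataFrame(rows, columns=[S.TREATMENT, S.REPLICATE, S.TIME_H, "pct"])
        res = repeated_measures_compare(df, reference="reference",
                                        config=StatsConfig(alpha=alpha))
        hits += res[0].significant
    return hits / n_runs
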
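"""Mechanistic synthetic-data generators for every pipeline input.

The generators emulate the study conditions of the in-vitro programme:

* cytotoxicity plates following the four-parameter exponential model with
  3 biological x 6 technical replicates (additive normal biological
  intercept plus residual noise);
* bidirectional transwell transport through a two-compartment monolayer
  with an inhibitable efflux component, micellar sequestration of the
  analyte above the surfactant's critical micelle concentration, optional
  first-order ester hydrolysis to a metabolite, and the 2/4/6/8 h sampling
  schedule with aliquot replacement (500 uL apical / 1500 uL basolateral
  compartments, 200/600 uL aliquots, 1.12 cm^2 insert);
* DPH anisotropy intensity quadruples constructed to invert exactly to a
  target r (about 0.150 for untreated Caco-2 cells);
* Pgp-Glo ATPase plates in which luminescence reports remaining ATP, with
  Na3VO4, verapamil and untreated control wells and 4 replicates.

Measurement noise is multiplicative lognormal (CV-parameterised), the
scale-proportional error of plate readers and LC-MS quantification.  A
single seed fans out to independent child streams via ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schemas as S
from .dose_response import ExponentialModelParams, exponential_model
from .membrane import AnisotropyReading
from .transport import TransportTimeSeries

__all__ = [
    "TransportSimConfig",
    "TransportSimResult",
    "InhibitionCurve",
    "IntegrationError",
    "generate_dose_response",
    "simulate_transport",
    "generate_anisotropy_readings",
    "generate_atpase_plate",
]


class IntegrationError(RuntimeError):
    pass


def _lognormal_factor(rng: np.random.Generator, cv: float, size=()) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# cytotoxicity plates
# ---------------------------------------------------------------------------

def generate_dose_response(
    true_params: dict[str, ExponentialModelParams] | ExponentialModelParams,
    concentrations,
    n_biological: int = 3,
    n_technical: int = 6,
    residual_sd: float = 5.0,
    bio_intercept_sd: float = 2.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicated viability observations from known exponential-model curves.

    ``viability = model(x) + biological intercept + residual``, with the
    intercept shared by all wells of one biological replicate.  The
    default design is the study's 3 biological x 6 technical replicates.
    Deterministic given the seed; the same seed yields bit-identical
    tables.
    """
    if isinstance(true_params, ExponentialModelParams):
        true_params = {"compound": true_params}
    x = np.asarray(list(concentrations), dtype=float)
    if x.size < 4 or 0.0 not in x:
        raise ValueError("concentration grid needs >= 4 points including 0")
    if residual_sd < 0 or bio_intercept_sd < 0:
        raise ValueError("noise standard deviations must be non-negative")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(true_params))
    frames = []
    for (cid, params), child in zip(sorted(true_params.items()), children):
        rng = np.random.default_rng(child)
        curve = exponential_model(x, params)
        rows = []
        for b in range(n_biological):
            intercept = rng.normal(0.0, bio_intercept_sd) if bio_intercept_sd > 0 else 0.0
            noise = rng.normal(0.0, residual_sd, size=(x.size, n_technical)) if residual_sd > 0 \
                else np.zeros((x.size, n_technical))
            for i, xi in enumerate(x):
                for t in range(n_technical):
                    rows.append((cid, xi, curve[i] + intercept + noise[i, t],
                                 f"bio{b + 1}", f"tech{t + 1}"))
        frames.append(pd.DataFrame(rows, columns=list(S.DOSE_RESPONSE_COLUMNS)))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# transwell transport
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportSimConfig:
    """Two-compartment transwell simulator configuration.

    The monolayer carries a passive permeability ``p_passive`` plus an
    efflux component of relative weight ``efflux_weight`` (phi): with
    remaining efflux activity ``e`` the directional permeabilities are

        P(AP->BL) = p_passive * (1 - phi * e)     (absorption, slowed)
        P(BL->AP) = p_passive * (1 + phi * e)     (secretion, boosted)

    where ``e = IC50 / (IC50 + [I])`` decays with the inhibitor (surfactant)
    concentration.  Above the critical micelle concentration the donor's
    free analyte fraction drops to ``1 / (1 + k_mic * ([S] - cmc))``.
    Parent mass may convert to a metabolite (first order, both
    compartments); the metabolite crosses with its own efflux weight.
    Integration is a fixed-step explicit update (default 0.01 h) with
    sampling events applied instantaneously at the scheduled times.
    """

    p_passive_cm_s: float = 7.8e-6
    efflux_weight: float = 0.45
    ic50_efflux_mg_l: float = 1.0
    cmc_mg_l: float = 50.0
    k_mic_l_mg: float = 0.01
    k_hydrolysis_per_h: float = 0.0
    efflux_weight_metabolite: float = 0.7
    v_ap_ul: float = 500.0
    v_bl_ul: float = 1500.0
    area_cm2: float = 1.12
    sample_volumes_ul: dict = field(default_factory=lambda: {"AP": 200.0, "BL": 600.0})
    timepoints_h: tuple = (2.0, 4.0, 6.0, 8.0)
    dt_h: float = 0.01
    noise_cv: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.v_ap_ul, self.v_bl_ul, self.area_cm2) <= 0:
            raise ValueError("volumes and area must be positive")
        if not 0 <= self.noise_cv < 1:
            raise ValueError("noise_cv must lie in [0, 1)")
        t = np.asarray(self.timepoints_h, dtype=float)
        if np.any(np.diff(t) <= 0) or t[0] <= 0:
            raise ValueError("timepoints must be positive and strictly increasing")
        for side, v_comp in (("AP", self.v_ap_ul), ("BL", self.v_bl_ul)):
            if self.sample_volumes_ul[side] >= v_comp:
                raise ValueError(f"sample volume on {side} must be below the compartment volume")
        if self.efflux_weight < 0:
            raise ValueError("efflux_weight must be non-negative")


@dataclass
class TransportSimResult:
    """Parent (and optional metabolite) time series plus the mass ledger."""

    parent: TransportTimeSeries
    metabolite: TransportTimeSeries | None
    ledger: dict

    @property
    def mass_balance_error(self) -> float:
        lg = self.ledger
        total = (lg["donor_parent"] + lg["receiver_parent"] + lg["removed_parent"]
                 + lg["donor_metabolite"] + lg["receiver_metabolite"] + lg["removed_metabolite"])
        return abs(total - lg["initial"]) / lg["initial"]


def simulate_transport(
    config: TransportSimConfig,
    direction: str,
    donor_c0: float,
    inhibitor_conc: float = 0.0,
    analyte_id: str = "analyte",
    replicate: str = "r1",
    seed: int | None = None,
) -> TransportSimResult:
    """Simulate one bidirectional transport study insert.

    ``inhibitor_conc`` is the total surfactant concentration (mg/L) in the
    donor solution; it both inhibits efflux (via ``ic50_efflux_mg_l``) and,
    above the CMC, sequesters analyte into micelles.  Concentrations are
    mg/L = ug/cm^3; masses are tracked in ug and conserved exactly up to
    floating-point roundoff.
    """
    if direction not in S.DIRECTIONS:
        raise ValueError(f"direction must be one of {S.DIRECTIONS}")
    if donor_c0 <= 0:
        raise ValueError("donor_c0 must be positive")
    cfg = config
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)

    donor_side, receiver_side = ("AP", "BL") if direction == "AP_to_BL" else ("BL", "AP")
    v = {"AP": cfg.v_ap_ul / 1000.0, "BL": cfg.v_bl_ul / 1000.0}  # cm^3
    v_d, v_r = v[donor_side], v[receiver_side]
    v_s = cfg.sample_volumes_ul[receiver_side] / 1000.0

    inh = inhibitor_conc / (cfg.ic50_efflux_mg_l + inhibitor_conc) if inhibitor_conc > 0 else 0.0
    e = 1.0 - inh  # remaining efflux activity
    f_u = 1.0 / (1.0 + cfg.k_mic_l_mg * max(0.0, inhibitor_conc - cfg.cmc_mg_l))

    p = cfg.p_passive_cm_s * 3600.0  # cm/h
    p_ab = {"parent": p * (1.0 - cfg.efflux_weight * e),
            "metabolite": p * (1.0 - cfg.efflux_weight_metabolite * e)}
    p_ba = {"parent": p * (1.0 + cfg.efflux_weight * e),
            "metabolite": p * (1.0 + cfg.efflux_weight_metabolite * e)}
    if direction == "AP_to_BL":
        p_dr, p_rd = p_ab, p_ba  # donor->receiver is the absorptive direction
    else:
        p_dr, p_rd = p_ba, p_ab

    dt = cfg.dt_h
    n_steps = int(round(cfg.timepoints_h[-1] / dt))
    event_steps = {int(round(t / dt)): t for t in cfg.timepoints_h}
    if any(abs(k * dt - t) > 1e-9 for k, t in event_steps.items()):
        raise ValueError("timepoints must be multiples of the integration step")

    m_d = {"parent": donor_c0 * v_d, "metabolite": 0.0}  # ug
    m_r = {"parent": 0.0, "metabolite": 0.0}
    removed = {"parent": 0.0, "metabolite": 0.0}
    samples = {"parent": [], "metabolite": []}
    k_h = cfg.k_hydrolysis_per_h

    for step in range(1, n_steps + 1):
        for sp in ("parent", "metabolite"):
            c_d, c_r = m_d[sp] / v_d, m_r[sp] / v_r
            j = cfg.area_cm2 * (p_dr[sp] * c_d * f_u - p_rd[sp] * c_r)  # ug/h
            dm = j * dt
            m_d[sp] -= dm
            m_r[sp] += dm
        if k_h > 0:
            for m in (m_d, m_r):
                conv = k_h * m["parent"] * dt
                m["parent"] -= conv
                m["metabolite"] += conv
        if min(m_d["parent"], m_r["parent"], m_d["metabolite"], m_r["metabolite"]) < 0:
            raise IntegrationError(
                f"negative mass at t={step * dt:.2f} h: decrease dt_h={dt} "
                "or the permeability/rate parameters"
            )
        if step in event_steps:
            t = event_steps[step]
            for sp in ("parent", "metabolite"):
                c_true = m_r[sp] / v_r
                c_meas = float(c_true * _lognormal_factor(rng, cfg.noise_cv))
                samples[sp].append((t, c_meas))
                removed[sp] += c_true * v_s
                m_r[sp] -= c_true * v_s

    def _series(sp: str, name: str) -> TransportTimeSeries:
        return TransportTimeSeries(
            analyte_id=name,
            direction=direction,
            donor_c0=donor_c0,
            v_donor_ul=v_d * 1000.0,
            v_receiver_ul=v_r * 1000.0,
            v_sample_ul=v_s * 1000.0,
            samples=samples[sp],
            replicate=replicate,
        )

    parent = _series("parent", analyte_id)
    metabolite = _series("metabolite", f"{analyte_id}_metabolite") if k_h > 0 else None
    ledger = {
        "initial": donor_c0 * v_d,
        "donor_parent": m_d["parent"],
        "receiver_parent": m_r["parent"],
        "removed_parent": removed["parent"],
        "donor_metabolite": m_d["metabolite"],
        "receiver_metabolite": m_r["metabolite"],
        "removed_metabolite": removed["metabolite"],
    }
    return TransportSimResult(parent=parent, metabolite=metabolite, ledger=ledger)


# ---------------------------------------------------------------------------
# anisotropy readings
# ---------------------------------------------------------------------------

def generate_anisotropy_readings(
    r_true: float,
    intensity_scale: float = 1000.0,
    g_true: float = 1.1,
    noise_cv: float = 0.0,
    n: int = 3,
    seed: int | None = None,
) -> list[AnisotropyReading]:
    """Intensity quadruples whose anisotropy reduction recovers ``r_true``.

    The quadruple is constructed by inverting the anisotropy definition at
    total intensity ``intensity_scale``: I_VV = T(1+2r)/3 and
    I_VH = T(1-r)/(3G), with I_HV = G * I_HH so the G factor is estimable
    from the horizontal-excitation pair.  At zero noise the round trip is
    exact.
    """
    if not -0.5 <= r_true <= 1.0:
        raise ValueError("r_true must lie in the theoretical range [-0.5, 1]")
    if intensity_scale <= 0 or g_true <= 0:
        raise ValueError("intensity_scale and g_true must be positive")
    rng = np.random.default_rng(seed)
    i_vv = intensity_scale * (1.0 + 2.0 * r_true) / 3.0
    i_vh = intensity_scale * (1.0 - r_true) / (3.0 * g_true)
    i_hh = intensity_scale / 2.0
    i_hv = g_true * i_hh
    readings = []
    for _ in range(n):
        f = _lognormal_factor(rng, noise_cv, 4)
        readings.append(AnisotropyReading(
            i_vv=i_vv * f[0], i_vh=i_vh * f[1], i_hv=i_hv * f[2], i_hh=i_hh * f[3],
        ))
    return readings


# ---------------------------------------------------------------------------
# ATPase plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InhibitionCurve:
    """Hill-type inhibition of verapamil-stimulated Pgp ATPase activity."""

    ic50_mg_l: float
    hill: float = 1.0

    def fraction(self, conc: float) -> float:
        if conc <= 0:
            return 0.0
        if np.isinf(self.ic50_mg_l):
            return 0.0
        ch = conc ** self.hill
        return ch / (self.ic50_mg_l ** self.hill + ch)


def generate_atpase_plate(
    basal_activity: float = 60_000.0,
    stimulation_factor: float = 3.0,
    inhibition_curve: InhibitionCurve | dict[str, InhibitionCurve] = InhibitionCurve(10.0),
    concentrations=(2.5, 10.0, 40.0),
    rlu_navo4: float = 250_000.0,
    substrate_stimulation_factor: float = 1.0,
    n_replicates: int = 4,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pgp-Glo plate with Na3VO4/verapamil/untreated controls and test wells.

    Luminescence reports the ATP remaining after the reaction, so wells
    with higher ATPase activity read lower:

        RLU(well) = rlu_navo4 - activity,      activity in RLU units

    with activity = ``basal_activity`` untreated, ``basal * stimulation``
    under verapamil, ``basal * stimulation * (1 - f([test]))`` for test
    articles co-incubated with verapamil, and ``basal * (1 + (substrate
    stimulation - 1) ...)`` for substrate-mode wells without verapamil.
    Na3VO4 wells therefore carry the highest expected RLU on the plate.
    """
    if min(basal_activity, rlu_navo4) <= 0:
        raise ValueError("RLU parameters must be positive")
    if stimulation_factor < 0 or substrate_stimulation_factor < 0:
        raise ValueError("stimulation factors must be non-negative")
    if basal_activity * max(stimulation_factor, substrate_stimulation_factor, 1.0) >= rlu_navo4:
        raise ValueError("activity may not exceed the Na3VO4 baseline RLU")
    curves = inhibition_curve if isinstance(inhibition_curve, dict) \
        else {"test": inhibition_curve}
    rng = np.random.default_rng(seed)

    rows: list[tuple] = []

    def add_wells(condition, article, conc, activity):
        rlu_expected = rlu_navo4 - activity
        f = _lognormal_factor(rng, noise_cv, n_replicates)
        for i in range(n_replicates):
            rows.append((condition, article, conc, f"w{i + 1}", rlu_expected * f[i]))

    add_wells("navo4", "", 0.0, 0.0)
    add_wells("untreated", "", 0.0, basal_activity)
    add_wells("verapamil", "", 0.0, basal_activity * stimulation_factor)
    for article, curve in sorted(curves.items()):
        for conc in concentrations:
            stim_act = basal_activity * stimulation_factor * (1.0 - curve.fraction(conc))
            add_wells("test_verapamil", article, conc, stim_act)
            if substrate_stimulation_factor != 1.0:
                sub_act = basal_activity * (
                    1.0 + (substrate_stimulation_factor - 1.0) * (1.0 - curve.fraction(conc))
                )
                add_wells("test_alone", article, conc, sub_act)
    return pd.DataFrame(rows, columns=list(S.ATPASE_COLUMNS))
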
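"""Reduction of bidirectional transwell time series.

A transport study doses one compartment (donor) of a Caco-2 monolayer
insert and samples the opposite compartment (receiver) at scheduled times;
each aliquot is replaced with blank medium to maintain sink conditions, so
the analyte removed with earlier aliquots must be re-credited when
computing the cumulative transported amount:

    Q_k = c_k * V_receiver + sum_{j<k} c_j * v_sample      [mg/L * uL -> ng]

reported in ug.  Relative transport is Q as percent of the initial donor
amount; the efflux ratio is the secretory (BL->AP) over absorptive
(AP->BL) relative transport at the matched final timepoint; the apparent
permeability is Papp = (dQ/dt) / (A * c0) with the slope taken by ordinary
least squares over the full sampling design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schemas as S

logger = logging.getLogger(__name__)

__all__ = [
    "TransportTimeSeries",
    "TransportSummary",
    "PermeabilityResult",
    "BarrierQC",
    "QCThresholds",
    "cumulative_amount",
    "relative_percent",
    "efflux_ratio",
    "apparent_permeability",
    "barrier_qc",
    "summarize_replicates",
]

#: insert growth area of the 12-well transwell format, cm^2
DEFAULT_AREA_CM2 = 1.12


@dataclass
class TransportTimeSeries:
    """Receiver-compartment concentrations over time for one insert."""

    analyte_id: str
    direction: str  # AP_to_BL | BL_to_AP
    donor_c0: float  # mg/L, measured start concentration
    v_donor_ul: float
    v_receiver_ul: float
    v_sample_ul: float
    samples: list[tuple[float, float]]  # (time h, receiver conc mg/L)
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if self.direction not in S.DIRECTIONS:
            raise ValueError(f"direction must be one of {S.DIRECTIONS}")
        if self.donor_c0 <= 0:
            raise ValueError("donor_c0 must be positive")
        if min(self.v_donor_ul, self.v_receiver_ul) <= 0:
            raise ValueError("compartment volumes must be positive")
        if self.v_sample_ul >= self.v_receiver_ul:
            raise ValueError("sample volume must be smaller than the receiver volume")
        t = np.array([s[0] for s in self.samples], dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples], dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            S.ANALYTE: self.analyte_id,
            S.DIRECTION: self.direction,
            S.REPLICATE: self.replicate,
            S.TIME_H: self.times,
            S.C_RECEIVER: self.concentrations,
            S.DONOR_C0: self.donor_c0,
            S.V_DONOR: self.v_donor_ul,
            S.V_RECEIVER: self.v_receiver_ul,
            S.V_SAMPLE: self.v_sample_ul,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TransportTimeSeries":
        df = df.sort_values(S.TIME_H)
        first = df.iloc[0]
        return cls(
            analyte_id=str(first[S.ANALYTE]),
            direction=str(first[S.DIRECTION]),
            donor_c0=float(first[S.DONOR_C0]),
            v_donor_ul=float(first[S.V_DONOR]),
            v_receiver_ul=float(first[S.V_RECEIVER]),
            v_sample_ul=float(first[S.V_SAMPLE]),
            samples=list(zip(df[S.TIME_H].astype(float), df[S.C_RECEIVER].astype(float))),
            replicate=str(first[S.REPLICATE]),
        )


def cumulative_amount(series: TransportTimeSeries) -> np.ndarray:
    """Cumulative transported amount in ug per timepoint.

    Re-credits the analyte removed with every earlier aliquot.  Negative
    measured concentrations are clipped to zero with a warning in the log.
    """
    c = series.concentrations
    if np.any(c < 0):
        logger.warning(
            "negative receiver concentration(s) in %s/%s clipped to 0",
            series.analyte_id, series.replicate,
        )
        c = np.clip(c, 0.0, None)
    removed = np.concatenate([[0.0], np.cumsum(c[:-1] * series.v_sample_ul)])
    q_ng = c * series.v_receiver_ul + removed
    return q_ng / 1000.0


def relative_percent(q_ug: np.ndarray, donor_c0: float, v_donor_ul: float) -> np.ndarray:
    """Transported amount as percent of the initial donor amount."""
    donor_amount_ug = donor_c0 * v_donor_ul / 1000.0
    if donor_amount_ug <= 0:
        raise ValueError("initial donor amount must be positive")
    pct = 100.0 * np.asarray(q_ug, dtype=float) / donor_amount_ug
    if np.any(pct > 100.0):
        logger.warning("relative transport above 100%% indicates a mass-balance violation")
    return pct


def efflux_ratio(secretory_pct_8h: float, absorptive_pct_8h: float) -> float:
    """Efflux ratio: secretory (BL->AP) over absorptive (AP->BL) transport.

    Reported to 3 decimals to match conventional reporting; undefined
    (NaN) when no absorptive transport was measured.
    """
    if absorptive_pct_8h == 0:
        logger.warning("absorptive transport is zero; efflux ratio undefined")
        return float("nan")
    return round(secretory_pct_8h / absorptive_pct_8h, 3)


@dataclass(frozen=True)
class PermeabilityResult:
    papp_cm_s: float
    slope_ug_s: float
    area_cm2: float
    c0_ug_cm3: float


def apparent_permeability(
    q_ug: np.ndarray,
    timepoints_h: np.ndarray,
    area_cm2: float = DEFAULT_AREA_CM2,
    c0_ug_cm3: float = 1.0,
) -> PermeabilityResult:
    """Papp = (dQ/dt) / (A * c0) in cm/s, slope by OLS over all timepoints."""
    t = np.asarray(timepoints_h, dtype=float) * 3600.0
    q = np.asarray(q_ug, dtype=float)
    if area_cm2 <= 0 or c0_ug_cm3 <= 0:
        raise ValueError("area and c0 must be positive")
    if np.unique(t).size < 2:
        raise ValueError("at least two distinct timepoints are required")
    slope = float(np.polyfit(t, q, 1)[0])
    return PermeabilityResult(
        papp_cm_s=slope / (area_cm2 * c0_ug_cm3),
        slope_ug_s=slope,
        area_cm2=area_cm2,
        c0_ug_cm3=c0_ug_cm3,
    )


@dataclass(frozen=True)
class QCThresholds:
    """Conventional Caco-2 barrier acceptance thresholds (configurable)."""

    teer_min_ohm_cm2: float = 250.0
    fitc_papp_max_cm_s: float = 1e-6


@dataclass(frozen=True)
class BarrierQC:
    teer_0h: float | None
    teer_8h: float | None
    fitc_papp: float | None
    status: str  # pass | fail | not_assessed


def barrier_qc(
    teer_0h: float | None,
    teer_8h: float | None,
    fitc_papp: float | None,
    thresholds: QCThresholds = QCThresholds(),
) -> BarrierQC:
    """Monolayer-integrity QC from TEER at 0/8 h and FITC-dextran Papp.

    Missing measurements give status ``not_assessed`` -- a layer is never
    silently passed.
    """
    if teer_0h is None or teer_8h is None or fitc_papp is None:
        return BarrierQC(teer_0h, teer_8h, fitc_papp, "not_assessed")
    ok = (
        teer_0h >= thresholds.teer_min_ohm_cm2
        and teer_8h >= thresholds.teer_min_ohm_cm2
        and fitc_papp <= thresholds.fitc_papp_max_cm_s
    )
    return BarrierQC(teer_0h, teer_8h, fitc_papp, "pass" if ok else "fail")


@dataclass
class TransportSummary:
    """Per-replicate and mean +/- SD transport summary for one condition."""

    analyte_id: str
    per_replicate: pd.DataFrame = field(repr=False)  # replicate x timepoint table
    mean_pct: pd.Series = field(repr=False)
    sd_pct: pd.Series = field(repr=False)
    final_pct_mean: float = np.nan
    final_pct_sd: float = np.nan


def summarize_replicates(series_list: list[TransportTimeSeries]) -> TransportSummary:
    """Reduce replicate time series to cumulative percent, mean +/- SD."""
    if not series_list:
        raise ValueError("no replicates supplied")
    rows = []
    for s in series_list:
        q = cumulative_amount(s)
        pct = relative_percent(q, s.donor_c0, s.v_donor_ul)
        for t, qk, pk in zip(s.times, q, pct):
            rows.append((s.replicate, t, qk, pk))
    table = pd.DataFrame(rows, columns=[S.REPLICATE, S.TIME_H, "q_ug", "pct"])
    mean = table.groupby(S.TIME_H)["pct"].mean()
    sd = table.groupby(S.TIME_H)["pct"].std(ddof=1)
    t_final = table[S.TIME_H].max()
    final = table[table[S.TIME_H] == t_final]["pct"]
    return TransportSummary(
        analyte_id=series_list[0].analyte_id,
        per_replicate=table,
        mean_pct=mean,
        sd_pct=sd,
        final_pct_mean=float(final.mean()),
        final_pct_sd=float(final.std(ddof=1)) if final.size > 1 else float("nan"),
    )
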
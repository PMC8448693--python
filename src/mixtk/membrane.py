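"""Membrane-assay reductions: DPH fluorescence anisotropy and Pgp-ATPase plates.

Steady-state fluorescence anisotropy of the membrane probe DPH is

    r = (I_VV - G * I_VH) / (I_VV + 2 * G * I_VH)

where the first subscript is the excitation and the second the emission
polariser orientation and G corrects the instrument's polarisation bias.
The physically standard G uses horizontally polarised excitation,
G = I_HV / I_HH; a ``paper_text`` convention (I_VH / I_HH) is available as
a configuration override.  Lower r means a more fluid membrane.

The Pgp-Glo ATPase assay reports remaining (unmetabolised) ATP as
luminescence, so higher ATPase activity gives *lower* RLU.  All activity
measures are differences against the sodium-orthovanadate (Na3VO4)
baseline, which inhibits Pgp ATPase completely:

    dRLU(condition) = mean RLU(Na3VO4) - mean RLU(condition)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schemas as S

__all__ = [
    "AnisotropyReading",
    "AtpaseResult",
    "g_factor",
    "anisotropy",
    "anisotropy_table",
    "atpase_delta_rlu",
]


@dataclass(frozen=True)
class AnisotropyReading:
    """Polarised intensity quadruple (arbitrary units) with optional fixed G."""

    i_vv: float
    i_vh: float
    i_hv: float
    i_hh: float
    g: float | None = None

    def __post_init__(self) -> None:
        if min(self.i_vv, self.i_vh, self.i_hv, self.i_hh) < 0:
            raise ValueError("intensities must be non-negative")


def g_factor(i_hv: float, i_hh: float) -> float:
    """Instrument correction factor G = I_HV / I_HH."""
    if i_hh <= 0:
        raise ValueError("I_HH must be positive to estimate G")
    return i_hv / i_hh


def anisotropy(reading: AnisotropyReading, g_convention: str = "standard") -> float:
    """Reduce a polarised intensity quadruple to the anisotropy r.

    ``g_convention='standard'`` uses G = I_HV/I_HH; ``'paper_text'`` uses
    G = I_VH/I_HH (available for exact reproduction of the transposed
    printed ratio).  An explicit ``reading.g`` overrides both.
    """
    if reading.g is not None:
        g = reading.g
    elif g_convention == "standard":
        g = g_factor(reading.i_hv, reading.i_hh)
    elif g_convention == "paper_text":
        if reading.i_hh <= 0:
            raise ValueError("I_HH must be positive to estimate G")
        g = reading.i_vh / reading.i_hh
    else:
        raise ValueError(f"unknown g_convention {g_convention!r}")
    denom = reading.i_vv + 2.0 * g * reading.i_vh
    if denom <= 0:
        raise ValueError("invalid reading: anisotropy denominator must be positive")
    r = (reading.i_vv - g * reading.i_vh) / denom
    if not -0.5 <= r <= 1.0:
        raise ValueError(f"anisotropy {r:.4f} outside the theoretical range [-0.5, 1]")
    return r


def anisotropy_table(df: pd.DataFrame, g_convention: str = "standard",
                     control_treatment: str | None = None) -> pd.DataFrame:
    """Reduce a tidy intensity table to per-row r values.

    When ``control_treatment`` is given, a ``fluidity_increased`` flag
    marks rows whose r lies below the control mean (lower anisotropy means
    higher membrane fluidity).
    """
    r = [
        anisotropy(AnisotropyReading(row[S.I_VV], row[S.I_VH], row[S.I_HV], row[S.I_HH]),
                   g_convention=g_convention)
        for _, row in df.iterrows()
    ]
    out = df.copy()
    out["r"] = r
    if control_treatment is not None:
        control_mean = out.loc[out[S.TREATMENT] == control_treatment, "r"].mean()
        out["fluidity_increased"] = out["r"] < control_mean
    return out


@dataclass
class AtpaseResult:
    """Per-condition dRLU contrasts of one Pgp-Glo plate."""

    delta_rlu: pd.DataFrame = field(repr=False)  # condition-level means
    basal: float = np.nan  # dRLU(untreated)
    verapamil_stimulated: float = np.nan  # dRLU(verapamil)
    per_article: pd.DataFrame | None = field(default=None, repr=False)


def atpase_delta_rlu(plate: pd.DataFrame) -> AtpaseResult:
    """Reduce a Pgp-Glo plate to dRLU activity contrasts.

    ``plate`` is a tidy well table (condition, test_article, concentration,
    replicate, RLU).  Requires at least one Na3VO4 well as the
    no-Pgp-ATPase baseline.  Per test article and concentration the result
    reports dRLU, the stimulation percentage relative to basal activity
    (for substrate-mode wells measured without verapamil) and the
    inhibition contrast dRLU(test+verapamil) / dRLU(verapamil).
    """
    cond = plate[S.CONDITION]
    if not (cond == "navo4").any():
        raise ValueError("plate has no Na3VO4 wells: no baseline for dRLU")
    baseline = float(plate.loc[cond == "navo4", S.RLU].mean())

    cond_means = (
        plate.groupby(S.CONDITION, sort=True)[S.RLU].mean().rename("mean_rlu").reset_index()
    )
    cond_means["delta_rlu"] = baseline - cond_means["mean_rlu"]

    basal = float(cond_means.loc[cond_means[S.CONDITION] == "untreated", "delta_rlu"].squeeze()) \
        if (cond == "untreated").any() else np.nan
    verap = float(cond_means.loc[cond_means[S.CONDITION] == "verapamil", "delta_rlu"].squeeze()) \
        if (cond == "verapamil").any() else np.nan

    test = plate[cond.isin(["test_verapamil", "test_alone"])]
    per_article = None
    if not test.empty:
        rows = []
        grouped = test.groupby([S.CONDITION, S.TEST_ARTICLE, S.CONC], sort=True)[S.RLU].mean()
        for (condition, article, conc), mean_rlu in grouped.items():
            drlu = baseline - mean_rlu
            stim_pct = 100.0 * drlu / basal if (condition == "test_alone" and np.isfinite(basal) and basal != 0) else np.nan
            inh_ratio = drlu / verap if (condition == "test_verapamil" and np.isfinite(verap) and verap != 0) else np.nan
            rows.append((condition, article, conc, drlu, stim_pct, inh_ratio))
        per_article = pd.DataFrame(
            rows,
            columns=[S.CONDITION, S.TEST_ARTICLE, S.CONC, "delta_rlu",
                     "stimulation_pct_of_basal", "ratio_vs_verapamil"],
        )

    return AtpaseResult(
        delta_rlu=cond_means,
        basal=basal,
        verapamil_stimulated=verap,
        per_article=per_article,
    )
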
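"""Readers, writers, study configuration and the end-to-end case studies.

CSV dialect everywhere: UTF-8, comma separator, header row, period decimal
point.  Every reader validates against its schema and reports *all*
problems at once; generated datasets round-trip with zero warnings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import schemas as S
from .dose_response import (
    ClassificationRule,
    ExponentialModelParams,
    MixtureSpec,
    classify_additivity,
    compute_rpf,
    fit_parallel,
    predict_ca_curve,
)
from .membrane import anisotropy_table, atpase_delta_rlu
from .stats import StatsConfig, mixed_anova_dunnett, repeated_measures_compare
from .synthetic import (
    InhibitionCurve,
    TransportSimConfig,
    generate_anisotropy_readings,
    generate_atpase_plate,
    generate_dose_response,
    simulate_transport,
)
from .transport import TransportTimeSeries, summarize_replicates

__all__ = [
    "ValidationError",
    "StudyConfig",
    "read_validate",
    "write_csv",
    "normalize_viability",
    "default_study_config",
    "run_case_study",
]


class ValidationError(ValueError):
    """Schema validation failure carrying an itemised problem report."""

    def __init__(self, schema_id: str, problems: list[str]):
        self.schema_id = schema_id
        self.problems = problems
        super().__init__(
            f"{schema_id}: {len(problems)} validation problem(s):\n  - " + "\n  - ".join(problems)
        )


_SCHEMAS: dict[str, dict] = {
    "dose_response": {
        "columns": S.DOSE_RESPONSE_COLUMNS,
        "numeric": (S.CONC, S.VIABILITY),
        "non_negative": (S.CONC,),
        "key": (S.COMPOUND, S.CONC, S.BIO_REP, S.TECH_REP),
    },
    "transport": {
        "columns": S.TRANSPORT_COLUMNS,
        "numeric": (S.TIME_H, S.C_RECEIVER, S.DONOR_C0, S.V_DONOR, S.V_RECEIVER, S.V_SAMPLE),
        "non_negative": (S.TIME_H, S.DONOR_C0, S.V_DONOR, S.V_RECEIVER, S.V_SAMPLE),
        "key": (S.ANALYTE, S.DIRECTION, S.REPLICATE, S.TIME_H),
    },
    "anisotropy": {
        "columns": S.ANISOTROPY_COLUMNS,
        "numeric": (S.I_VV, S.I_VH, S.I_HV, S.I_HH),
        "non_negative": (S.I_VV, S.I_VH, S.I_HV, S.I_HH),
        "key": (S.SAMPLE_ID,),
    },
    "atpase": {
        "columns": S.ATPASE_COLUMNS,
        "numeric": (S.CONC, S.RLU),
        "non_negative": (S.CONC, S.RLU),
        "key": (S.CONDITION, S.TEST_ARTICLE, S.CONC, S.REPLICATE),
    },
}


def validate_table(df: pd.DataFrame, schema_id: str) -> pd.DataFrame:
    """Validate a DataFrame against a named schema; raise with a full report."""
    if schema_id not in _SCHEMAS:
        raise KeyError(f"unknown schema {schema_id!r}; known: {sorted(_SCHEMAS)}")
    spec = _SCHEMAS[schema_id]
    problems: list[str] = []
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
    unknown = [c for c in df.columns if c not in spec["columns"]]
    if unknown:
        problems.append(f"unknown columns: {unknown}")
    if not missing:
        for col in spec["numeric"]:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna() & df[col].notna()].tolist()
            if bad:
                problems.append(f"non-numeric values in {col!r} at rows {bad[:10]}")
            df = df.assign(**{col: vals})
        for col in spec["non_negative"]:
            bad = df.index[df[col] < 0].tolist()
            if bad:
                problems.append(f"negative values in {col!r} at rows {bad[:10]}")
        dup = df.duplicated(subset=list(spec["key"]), keep=False)
        if dup.any():
            problems.append(
                f"duplicate replicate keys {spec['key']} at rows {df.index[dup].tolist()[:10]}"
            )
        if schema_id == "transport":
            bad_dir = df.index[~df[S.DIRECTION].isin(S.DIRECTIONS)].tolist()
            if bad_dir:
                problems.append(f"invalid direction at rows {bad_dir[:10]}")
    if problems:
        raise ValidationError(schema_id, problems)
    return df


def read_validate(path: str | Path, schema_id: str) -> pd.DataFrame:
    """Read a CSV and validate it against the named schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return validate_table(df, schema_id)


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def normalize_viability(raw: pd.DataFrame, signal_col: str, control_mask) -> pd.Series:
    """Percent-of-solvent-control normalisation of raw plate signals."""
    control_mean = raw.loc[control_mask, signal_col].mean()
    if not np.isfinite(control_mean) or control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * raw[signal_col] / control_mean


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Declarative description of one case study (scenario)."""

    name: str
    reference_id: str
    mixture_ratios: dict[str, float]  # dose ratio to the active substance
    true_curves: dict[str, dict]  # compound -> {a, b, c, d}
    inert_compounds: tuple[str, ...] = ()
    dose_grid: tuple[float, ...] = (0.0, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0)
    transport: dict = field(default_factory=dict)
    transport_conditions: dict[str, float] = field(default_factory=dict)  # label -> surfactant mg/L
    anisotropy_r: dict[str, float] = field(default_factory=dict)
    atpase_ic50_mg_l: float = 10.0
    alpha: float = 0.05
    seed: int = 0

    def transport_config(self, **overrides) -> TransportSimConfig:
        kw = dict(self.transport)
        kw.update(overrides)
        return TransportSimConfig(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path

    def validate(self) -> None:
        if self.reference_id not in self.mixture_ratios:
            raise ValidationError("study_config", [
                f"reference {self.reference_id!r} missing from mixture_ratios"])
        problems = []
        for cid in self.mixture_ratios:
            if cid not in self.true_curves and cid not in self.inert_compounds:
                problems.append(f"compound {cid!r} has no true curve and is not inert")
        if abs(self.mixture_ratios[self.reference_id] - 1.0) > 1e-12:
            problems.append("active substance must have ratio 1")
        if problems:
            raise ValidationError("study_config", problems)


def default_study_config(scenario: str, seed: int = 0) -> StudyConfig:
    """Shipped scenario defaults for the two product case studies.

    Mixture ratios follow the product compositions (surfactant mg per mg
    of active substance); the transport conditions are the surfactant
    loads of the product-ratio mix (A), the product itself, and the high
    sub-cytotoxic mix (B).
    """
    if scenario == "product1":
        return StudyConfig(
            name="product1",
            reference_id="abamectin",
            mixture_ratios={
                "abamectin": 1.0, "tween_80": 4.2,
                "soprophor_bsu": 1.0, "soprophor_3d33": 1.0,
            },
            true_curves={
                "abamectin": {"a": 100.0, "b": 0.020, "c": 0.05, "d": 1.2},
                "soprophor_bsu": {"a": 100.0, "b": 0.1607, "c": 0.05, "d": 1.2},
                "soprophor_3d33": {"a": 100.0, "b": 0.1345, "c": 0.05, "d": 1.2},
            },
            inert_compounds=("tween_80",),
            dose_grid=(0.0, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0),
            transport={},
            transport_conditions={"active_alone": 0.0, "mix_a": 6.2, "product": 6.2, "mix_b": 160.0},
            anisotropy_r={
                "untreated": 0.150, "active": 0.150, "tween_80": 0.135,
                "soprophor_bsu": 0.135, "soprophor_3d33": 0.135, "product": 0.116,
            },
            seed=seed,
        )
    if scenario == "product2":
        return StudyConfig(
            name="product2",
            reference_id="fluroxypyr_meptyl",
            mixture_ratios={
                "fluroxypyr_meptyl": 1.0, "rhodacal_60be": 0.133,
                "emulsogen_el400": 0.233, "solgad_150uln": 2.0,
            },
            true_curves={
                "fluroxypyr_meptyl": {"a": 100.0, "b": 0.0012, "c": 0.05, "d": 1.2},
                "rhodacal_60be": {"a": 100.0, "b": 0.0185, "c": 0.05, "d": 1.2},
                "solgad_150uln": {"a": 100.0, "b": 0.00075, "c": 0.05, "d": 1.2},
            },
            inert_compounds=("emulsogen_el400",),
            dose_grid=(0.0, 15.0, 30.0, 60.0, 120.0, 240.0, 480.0, 960.0, 1920.0),
            transport={"k_hydrolysis_per_h": 0.30, "efflux_weight": 0.2,
                       "efflux_weight_metabolite": 0.7, "ic50_efflux_mg_l": 30.0},
            transport_conditions={"active_alone": 0.0, "mix_a": 0.3, "product": 0.3, "mix_b": 400.0},
            anisotropy_r={
                "untreated": 0.150, "active": 0.150, "rhodacal_60be": 0.121,
                "emulsogen_el400": 0.139, "solgad_150uln": 0.150, "product": 0.117,
            },
            seed=seed,
        )
    raise ValueError(f"unknown scenario {scenario!r} (expected 'product1' or 'product2')")


# ---------------------------------------------------------------------------
# simulation of all raw inputs for a scenario
# ---------------------------------------------------------------------------

def simulate_inputs(config: StudyConfig, seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Generate every raw table a case study consumes."""
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_dr, s_mix, s_tr, s_an, s_at = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5)]

    curves = {cid: ExponentialModelParams(**p) for cid, p in config.true_curves.items()}
    ref = curves[config.reference_id]
    grid = np.asarray(config.dose_grid, dtype=float)

    # each compound is dosed on a grid scaled to its own potency, the way a
    # lab adapts concentration ranges per test item
    frames = []
    for j, (cid, params) in enumerate(sorted(curves.items())):
        rpf_true = (params.b / ref.b) ** (1.0 / ref.d)
        frames.append(generate_dose_response(
            {cid: params}, np.round(grid / rpf_true, 6), seed=s_dr + j))
    # inert compounds: flat curves over a wide range (no decline anywhere)
    for j, cid in enumerate(config.inert_compounds):
        frames.append(generate_dose_response(
            {cid: ExponentialModelParams(100.0, 1e-8, 0.999, 1.0)},
            grid * 4.0, seed=s_dr + 100 + j))
    singles = pd.concat(frames, ignore_index=True)

    # observed mixture data: generated from the exact CA curve of the true
    # parameters (the classifier's null), on the active-substance axis and
    # on a grid scaled by the mixture's summed potency
    total_rpf = sum(
        (curves[cid].b / ref.b) ** (1.0 / ref.d) * rho if cid in curves else 0.0
        for cid, rho in config.mixture_ratios.items()
    )
    mix_params = ExponentialModelParams(ref.a, ref.b * total_rpf ** ref.d, ref.c, ref.d)
    mixture = generate_dose_response({f"mixture_{config.name}": mix_params},
                                     np.round(grid / total_rpf, 6), seed=s_mix)

    # transport: three inserts per direction and condition, with LC-MS-like
    # measurement noise unless the scenario overrides it
    noise = config.transport.get("noise_cv", 0.05)
    tcfg = config.transport_config(seed=s_tr, noise_cv=noise)
    rows = []
    child = np.random.SeedSequence(s_tr).spawn(
        len(config.transport_conditions) * 2 * 3)
    it = iter(child)
    for label, surf in sorted(config.transport_conditions.items()):
        for direction in S.DIRECTIONS:
            for rep in range(3):
                res = simulate_transport(
                    tcfg, direction, donor_c0=1.0, inhibitor_conc=surf,
                    analyte_id=f"{config.reference_id}:{label}",
                    replicate=f"r{rep + 1}",
                    seed=int(next(it).generate_state(1)[0] % 2**31),
                )
                rows.append(res.parent.to_frame())
                if res.metabolite is not None:
                    rows.append(res.metabolite.to_frame())
    transport = pd.concat(rows, ignore_index=True)

    # anisotropy: 3 biological replicates per treatment
    an_rows = []
    rng_an = np.random.SeedSequence(s_an).spawn(len(config.anisotropy_r))
    for (label, r_true), c in zip(sorted(config.anisotropy_r.items()), rng_an):
        readings = generate_anisotropy_readings(
            r_true, noise_cv=0.005, n=3, seed=int(c.generate_state(1)[0] % 2**31))
        for i, rd in enumerate(readings):
            an_rows.append((f"{label}_{i + 1}", label, f"bio{i + 1}",
                            rd.i_vv, rd.i_vh, rd.i_hv, rd.i_hh))
    aniso = pd.DataFrame(an_rows, columns=list(S.ANISOTROPY_COLUMNS))

    plate = generate_atpase_plate(
        inhibition_curve=InhibitionCurve(config.atpase_ic50_mg_l),
        noise_cv=0.05, seed=s_at,
    )
    return {
        "dose_response_singles": singles,
        "dose_response_mixture": mixture,
        "transport": transport,
        "anisotropy": aniso,
        "atpase": plate,
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_case_study(config: StudyConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute simulate -> fit -> CA classify -> transport -> assays -> stats.

    Writes all raw inputs, summary tables and a run manifest under
    ``outdir`` and returns the summary objects.  Any stage failure
    propagates with the stage named; tables written so far are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    manifest: dict = {"scenario": config.name, "seed": seed, "stages": [], "inputs": {}}
    stage = "simulate"
    try:
        tables = simulate_inputs(config, seed=seed)
        for name, df in tables.items():
            p = write_csv(df, outdir / f"{name}.csv")
            manifest["inputs"][name] = _sha256(p)
        manifest["stages"].append(stage)

        stage = "fit_dose_response"
        singles = pd.concat(
            [tables["dose_response_singles"]], ignore_index=True)
        fit = fit_parallel(singles, reference_id=config.reference_id)
        rpf = compute_rpf(fit)
        fit_out = {
            "a": fit.a, "c": fit.c, "d": fit.d, "b": fit.per_compound_b,
            "reference": fit.reference_id, "rss": fit.rss,
            "excluded_no_signal": list(fit.excluded), "rpf": rpf.rpf,
        }
        (outdir / "dose_response_fit.json").write_text(json.dumps(fit_out, indent=2))
        manifest["stages"].append(stage)

        stage = "ca_classification"
        mix = MixtureSpec(components=dict(config.mixture_ratios), active_id=config.reference_id)
        observed = tables["dose_response_mixture"]
        verdict = classify_additivity(observed, fit, rpf, mix,
                                      ClassificationRule(alpha=config.alpha))
        grid = np.asarray(config.dose_grid, dtype=float)
        ca = pd.DataFrame({S.CONC: grid, "predicted_viability_pct":
                           predict_ca_curve(fit, rpf, mix, grid)})
        write_csv(ca, outdir / "ca_predicted_curve.csv")
        verdict_out = {"label": verdict.label, "statistic": verdict.statistic,
                       "p_value": verdict.p_value, "n_replicates": verdict.n_replicates,
                       "n_concentrations": verdict.n_concentrations}
        (outdir / "additivity_verdict.json").write_text(json.dumps(verdict_out, indent=2))
        manifest["stages"].append(stage)

        stage = "transport_summary"
        tr = tables["transport"]
        summary_rows, er_rows, curves = [], [], []
        for analyte, sub in tr.groupby(S.ANALYTE, sort=True):
            finals = {}
            for direction, dsub in sub.groupby(S.DIRECTION, sort=True):
                series = [TransportTimeSeries.from_frame(g)
                          for _, g in dsub.groupby(S.REPLICATE, sort=True)]
                summ = summarize_replicates(series)
                finals[direction] = summ.final_pct_mean
                for t, m, sd in zip(summ.mean_pct.index, summ.mean_pct, summ.sd_pct):
                    summary_rows.append((analyte, direction, t, m, sd))
                per_rep = summ.per_replicate.assign(**{S.ANALYTE: analyte, S.DIRECTION: direction})
                curves.append(per_rep)
            er = round(finals["BL_to_AP"] / finals["AP_to_BL"], 3) \
                if finals.get("AP_to_BL") else float("nan")
            er_rows.append((analyte, finals.get("AP_to_BL"), finals.get("BL_to_AP"), er))
        write_csv(pd.DataFrame(
            summary_rows, columns=[S.ANALYTE, S.DIRECTION, S.TIME_H, "mean_pct", "sd_pct"]),
            outdir / "transport_summary.csv")
        efflux = pd.DataFrame(
            er_rows, columns=[S.ANALYTE, "ap_to_bl_pct_8h", "bl_to_ap_pct_8h", "efflux_ratio"])
        write_csv(efflux, outdir / "efflux_ratios.csv")
        manifest["stages"].append(stage)

        stage = "stats_timecourse"
        curve_table = pd.concat(curves, ignore_index=True)
        parent = curve_table[~curve_table[S.ANALYTE].str.contains("metabolite")]
        secretory = parent[parent[S.DIRECTION] == "BL_to_AP"].rename(
            columns={S.ANALYTE: S.TREATMENT})
        ref_label = f"{config.reference_id}:active_alone"
        tc_results = repeated_measures_compare(
            secretory, reference=ref_label, config=StatsConfig(alpha=config.alpha))
        write_csv(pd.DataFrame([asdict(r) for r in tc_results]),
                  outdir / "stats_timecourse_secretory.csv")
        manifest["stages"].append(stage)

        stage = "membrane_assays"
        aniso = anisotropy_table(tables["anisotropy"], control_treatment="untreated")
        write_csv(aniso, outdir / "anisotropy_reduced.csv")
        an_stats = mixed_anova_dunnett(
            aniso.rename(columns={"r": S.VALUE}), control="untreated",
            config=StatsConfig(alpha=config.alpha, random_effect=S.REPLICATE))
        write_csv(pd.DataFrame([asdict(r) for r in an_stats]), outdir / "stats_anisotropy.csv")
        atp = atpase_delta_rlu(tables["atpase"])
        write_csv(atp.delta_rlu, outdir / "atpase_delta_rlu.csv")
        if atp.per_article is not None:
            write_csv(atp.per_article, outdir / "atpase_contrasts.csv")
        manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"case study failed at stage {stage!r}: {exc}") from exc

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "fit": fit_out,
        "verdict": verdict_out,
        "efflux_ratios": efflux,
        "timecourse_stats": tc_results,
        "anisotropy_stats": an_stats,
        "manifest": manifest,
    }
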
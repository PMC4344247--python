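"""End-to-end orchestration: simulate/ingest -> calibrate -> features -> LDA.

The pipeline reproduces the full analysis chain of an ecotype-discrimination
experiment:

1. obtain per-seedling luminescence traces (simulated or ingested CSV);
2. calibrate photon counts into [Ca2+]_cyt;
3. average biological replicates per condition;
4. extract the two-window log10 amplitude features;
5. fit the two-group LDA on the NaCl responses and evaluate it with
   jackknifed own-group posterior probabilities.

Everything is deterministic given (config, seed).  Canonical outputs are CSV
tables (features, dose response, jackknife) plus a YAML model dump and a run
log recording the constants actually used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationParams, counts_to_calcium
from .conditions import (
    DEFAULT_CONCENTRATIONS_MM,
    DEFAULT_PROFILES,
    Genotype,
    Stimulus,
    StimulusCondition,
)
from .discriminant import DiscriminantModel, JackknifeReport, fit_lda, jackknife_posteriors
from .features import WINDOW1, WINDOW2, build_feature_table
from .io import (
    features_to_frame,
    load_config_yaml,
    model_to_yaml,
    read_traces_csv,
    write_traces_csv,
)
from .synthetic import SimulationConfig, rng_for_condition, simulate_calcium_trace, simulate_luminescence
from .traces import CalciumTrace, LuminescenceTrace

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


DEFAULT_CONFIG: dict = {
    "mode": "simulate",
    "seed": None,  # must be provided
    "concentrations_mM": list(DEFAULT_CONCENTRATIONS_MM),
    "n_replicates": 3,
    "dt_s": 1.0,
    "aequorin_pool": 1e6,
    "poisson": True,
    "include_sorbitol": True,
    "include_cold": True,
    "include_base": True,
    "sorbitol_osmotic_factor": 2.0,
    "calibration": {},
    "priors": [0.5, 0.5],
    "profiles": {},
    "traces": None,  # ingest mode: path to a trace CSV or a directory of them
}


@dataclass
class ExperimentReport:
    """All tables produced by one pipeline run."""

    feature_table: pd.DataFrame
    dose_response: pd.DataFrame
    model: DiscriminantModel
    jackknife: JackknifeReport
    jackknife_table: pd.DataFrame
    provenance: dict
    measured_traces: list[CalciumTrace]


def resolve_config(config: dict | str | Path) -> dict:
    """Merge a user config (mapping or YAML path) over the defaults."""
    if isinstance(config, (str, Path)):
        config = load_config_yaml(config)
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(DEFAULT_CONFIG)}"
        )
    cfg = {**DEFAULT_CONFIG, **config}
    if cfg["seed"] is None:
        raise ConfigError("config must set an integer 'seed' (reproducibility is mandatory)")
    if cfg["mode"] not in ("simulate", "ingest"):
        raise ConfigError(f"mode must be 'simulate' or 'ingest', got {cfg['mode']!r}")
    if cfg["mode"] == "ingest" and not cfg["traces"]:
        raise ConfigError("ingest mode requires 'traces': path to trace CSV(s)")
    return cfg


def _build_profiles(cfg: dict) -> dict[Genotype, "GenotypeProfile"]:
    profiles = dict(DEFAULT_PROFILES)
    for name, overrides in (cfg["profiles"] or {}).items():
        geno = Genotype(name)
        if isinstance(overrides, dict):
            if "second_time_range_s" in overrides:
                overrides = {**overrides,
                             "second_time_range_s": tuple(overrides["second_time_range_s"])}
            profiles[geno] = dataclasses.replace(profiles[geno], **overrides)
        else:
            raise ConfigError(f"profile override for {name} must be a mapping of fields")
    return profiles


def _simulation_config(cfg: dict) -> SimulationConfig:
    return SimulationConfig(
        profiles=_build_profiles(cfg),
        concentrations_mM=tuple(float(c) for c in cfg["concentrations_mM"]),
        n_replicates=int(cfg["n_replicates"]),
        dt_s=float(cfg["dt_s"]),
        aequorin_pool=float(cfg["aequorin_pool"]),
        seed=int(cfg["seed"]),
        calibration=CalibrationParams(**(cfg["calibration"] or {})),
    )


def simulate_experiment(cfg: dict) -> tuple[list[LuminescenceTrace], SimulationConfig]:
    """Simulate the full design: every genotype x stimulus x concentration x replicate."""
    simcfg = _simulation_config(cfg)
    cells: list[tuple[Stimulus, float]] = [
        (Stimulus.NACL, c) for c in simcfg.concentrations_mM
    ]
    if cfg["include_sorbitol"]:
        factor = float(cfg["sorbitol_osmotic_factor"])
        cells += [(Stimulus.SORBITOL, factor * c) for c in simcfg.concentrations_mM]
    if cfg["include_cold"]:
        cells.append((Stimulus.COLD, 0.0))
    if cfg["include_base"]:
        cells.append((Stimulus.BASE, 0.0))

    lums: list[LuminescenceTrace] = []
    for genotype in simcfg.profiles:
        for stim, conc in cells:
            for rep in range(1, simcfg.n_replicates + 1):
                cond = StimulusCondition(stim, conc, genotype, rep)
                rng = rng_for_condition(simcfg.seed, cond)
                ca = simulate_calcium_trace(cond, simcfg, rng)
                lums.append(
                    simulate_luminescence(ca, simcfg, rng, poisson=bool(cfg["poisson"]))
                )
    return lums, simcfg


def _ingest(cfg: dict) -> list[CalciumTrace | LuminescenceTrace]:
    path = Path(cfg["traces"])
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise ConfigError(f"no trace CSV files found under {path}")
    traces: list = []
    for f in files:
        traces.extend(read_traces_csv(f))
    return traces


def analyze_traces(
    traces: list[CalciumTrace], cfg: dict
) -> tuple[pd.DataFrame, pd.DataFrame, DiscriminantModel, JackknifeReport, pd.DataFrame]:
    """Steps 3-5 on calibrated traces: features, dose response, LDA, jackknife."""
    features = build_feature_table(traces)
    feat_df = features_to_frame(features)
    dose = feat_df.loc[
        feat_df["stimulus"].isin([Stimulus.NACL.value, Stimulus.SORBITOL.value]),
        ["genotype", "stimulus", "concentration_mM", "amp1_nM"],
    ].reset_index(drop=True)

    nacl = feat_df[feat_df["stimulus"] == Stimulus.NACL.value]
    counts = nacl.groupby("genotype").size()
    small = counts[counts < 3]
    if len(counts) != 2 or not small.empty:
        raise ConfigError(
            "the discriminant needs NaCl feature rows for both genotypes with "
            ">= 3 concentrations each; got "
            + (", ".join(f"{g}: {n}" for g, n in counts.items()) or "none")
            + ". Add concentrations/replicates or check trace metadata."
        )
    labels = (Genotype.COL0.value, Genotype.C24.value)
    X = nacl[["log_amp1", "log_amp2"]].to_numpy()
    y = nacl["genotype"].to_numpy()
    keys = list(zip(nacl["genotype"], nacl["concentration_mM"]))
    priors = tuple(float(p) for p in cfg["priors"])
    model = fit_lda(X, y, priors=priors, labels=labels)
    report = jackknife_posteriors(X, y, priors=priors, labels=labels, keys=keys)

    # Table-1 style: one row per concentration, one posterior column per genotype
    rows: dict[float, dict] = {}
    for r in report.rows:
        geno, conc = r.condition_key
        short = "col0" if geno == Genotype.COL0.value else "c24"
        row = rows.setdefault(conc, {"stimulus_mM": conc})
        row[f"{short}_posterior"] = r.own_group_posterior
        row[f"{short}_predicted"] = r.predicted_group
    jk_df = pd.DataFrame(sorted(rows.values(), key=lambda d: d["stimulus_mM"]))
    return feat_df, dose, model, report, jk_df


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> ExperimentReport:
    """Execute the full pipeline; optionally write the report files.

    Returns the in-memory :class:`ExperimentReport`; when ``out_dir`` is set,
    writes ``features.csv``, ``dose_response.csv``, ``jackknife.csv``,
    ``model.yaml``, ``traces.csv`` (simulate mode) and ``run.log`` there.
    """
    cfg = resolve_config(config)
    calib = CalibrationParams(**(cfg["calibration"] or {}))

    lum_traces: list[LuminescenceTrace] = []
    if cfg["mode"] == "simulate":
        lum_traces, _ = simulate_experiment(cfg)
        raw: list = lum_traces
    else:
        raw = _ingest(cfg)
        lum_traces = [t for t in raw if isinstance(t, LuminescenceTrace)]

    measured = [
        counts_to_calcium(t, calib) if isinstance(t, LuminescenceTrace) else t
        for t in raw
    ]
    feat_df, dose, model, report, jk_df = analyze_traces(measured, cfg)

    canonical = yaml.safe_dump(cfg, sort_keys=True)
    provenance = {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": int(cfg["seed"]),
        "casig_version": __version__,
        "n_traces": len(measured),
    }

    out = ExperimentReport(
        feature_table=feat_df,
        dose_response=dose,
        model=model,
        jackknife=report,
        jackknife_table=jk_df,
        provenance=provenance,
        measured_traces=measured,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        feat_df.to_csv(out_dir / "features.csv", index=False)
        dose.to_csv(out_dir / "dose_response.csv", index=False)
        jk_df.to_csv(out_dir / "jackknife.csv", index=False)
        model_to_yaml(model, out_dir / "model.yaml")
        if cfg["mode"] == "simulate" and lum_traces:
            write_traces_csv(lum_traces, out_dir / "traces.csv")
        (out_dir / "run.log").write_text(_run_log(cfg, calib, provenance, out))
        logger.info("report written to %s", out_dir)
    return out


def _run_log(cfg: dict, calib: CalibrationParams, provenance: dict, report: ExperimentReport) -> str:
    lines = [
        f"casig {provenance['casig_version']}",
        f"config sha256: {provenance['config_sha256']}",
        f"mode: {cfg['mode']}  seed: {cfg['seed']}",
        f"calibration: slope={calib.slope} intercept={calib.intercept} "
        f"rate_floor={calib.rate_floor} pca_cap={calib.pca_cap}",
        f"feature windows: {WINDOW1} s and {WINDOW2} s after onset",
        f"lda priors: {tuple(cfg['priors'])}  labels: {report.model.labels}",
        f"traces analysed: {provenance['n_traces']}",
        f"feature rows: {len(report.feature_table)}  "
        f"jackknife rows: {len(report.jackknife_table)}",
    ]
    return "\n".join(lines) + "\n"
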
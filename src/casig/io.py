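"""CSV/YAML interchange for traces, feature tables, and model dumps.

Trace files are long-format CSV with metadata columns ``genotype``,
``stimulus``, ``concentration_mM``, ``replicate`` and data columns ``time_s``
plus either ``ca_nM`` (calibrated traces) or ``counts`` (raw luminometry).
For count traces, each trace carries one extra footer row whose ``time_s``
field is the literal string ``discharge`` and whose ``counts`` field holds
the terminal-discharge photon yield.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conditions import Genotype, Stimulus, StimulusCondition
from .discriminant import DiscriminantModel, JackknifeReport
from .features import PeakFeatures
from .traces import CalciumTrace, LuminescenceTrace

_META_COLS = ["genotype", "stimulus", "concentration_mM", "replicate"]
DISCHARGE_MARKER = "discharge"


def _meta_record(cond: StimulusCondition) -> dict:
    return {
        "genotype": cond.genotype.value,
        "stimulus": cond.stimulus.value,
        "concentration_mM": cond.concentration_mM,
        "replicate": cond.replicate_id if cond.replicate_id is not None else 0,
    }


def traces_to_frame(traces: list[CalciumTrace | LuminescenceTrace]) -> pd.DataFrame:
    """Long-format DataFrame for a homogeneous list of traces."""
    if not traces:
        raise ValueError("no traces to write")
    is_lum = isinstance(traces[0], LuminescenceTrace)
    chunks = []
    for tr in traces:
        if isinstance(tr, LuminescenceTrace) != is_lum:
            raise ValueError("cannot mix calcium and luminescence traces in one file")
        meta = _meta_record(tr.condition)
        if is_lum:
            df = pd.DataFrame(
                {"time_s": tr.time_s.astype(object), "counts": tr.counts}
            )
            df = pd.concat(
                [df, pd.DataFrame({"time_s": [DISCHARGE_MARKER], "counts": [tr.discharge_counts]})],
                ignore_index=True,
            )
        else:
            df = pd.DataFrame({"time_s": tr.time_s, "ca_nM": tr.ca_nM})
        for k, v in meta.items():
            df[k] = v
        chunks.append(df)
    out = pd.concat(chunks, ignore_index=True)
    return out[_META_COLS + [c for c in out.columns if c not in _META_COLS]]


def write_traces_csv(traces, path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[CalciumTrace | LuminescenceTrace]:
    """Parse a long-format trace CSV into trace objects.

    Auto-detects calibrated (``ca_nM``) versus raw-count (``counts``) files.
    Malformed values are reported with their 1-based CSV line number.
    """
    df = pd.read_csv(path, dtype={"time_s": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if "ca_nM" in df.columns:
        value_col, is_lum = "ca_nM", False
    elif "counts" in df.columns:
        value_col, is_lum = "counts", True
    else:
        raise ValueError(f"{path}: need a 'ca_nM' or 'counts' column")

    values = pd.to_numeric(df[value_col], errors="coerce")
    bad = values.isna()
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 1-based
        raise ValueError(f"{path}: non-numeric {value_col} at line {line}")
    if is_lum and (values < 0).any():
        line = int(df.index[values < 0][0]) + 2
        raise ValueError(f"{path}: negative counts at line {line}")

    traces: list = []
    for (gen, stim, conc, rep), grp in df.groupby(_META_COLS, sort=False):
        cond = StimulusCondition(
            Stimulus(stim), float(conc), Genotype(gen),
            int(rep) if int(rep) >= 1 else None,
        )
        if is_lum:
            is_discharge = grp["time_s"] == DISCHARGE_MARKER
            if is_discharge.sum() != 1:
                raise ValueError(
                    f"{path}: trace {cond.key}/rep={rep} needs exactly one discharge row"
                )
            discharge = float(pd.to_numeric(grp.loc[is_discharge, "counts"]).iloc[0])
            body = grp.loc[~is_discharge]
            t = pd.to_numeric(body["time_s"], errors="coerce")
            if t.isna().any():
                line = int(body.index[t.isna()][0]) + 2
                raise ValueError(f"{path}: non-numeric time_s at line {line}")
            traces.append(
                LuminescenceTrace(
                    time_s=t.to_numpy(float),
                    counts=body["counts"].astype(float).to_numpy(),
                    discharge_counts=discharge,
                    condition=cond,
                )
            )
        else:
            t = pd.to_numeric(grp["time_s"], errors="coerce")
            if t.isna().any():
                line = int(grp.index[t.isna()][0]) + 2
                raise ValueError(f"{path}: non-numeric time_s at line {line}")
            traces.append(
                CalciumTrace(
                    time_s=t.to_numpy(float),
                    ca_nM=grp["ca_nM"].astype(float).to_numpy(),
                    condition=cond,
                )
            )
    return traces


def features_to_frame(features: list[PeakFeatures]) -> pd.DataFrame:
    """Feature-table DataFrame: one row per (genotype, stimulus, concentration)."""
    return pd.DataFrame(
        [
            {
                "genotype": f.condition_key[0],
                "stimulus": f.condition_key[1],
                "concentration_mM": f.condition_key[2],
                "amp1_nM": f.amp1_nM,
                "amp2_nM": f.amp2_nM,
                "t_peak1_s": f.t_peak1_s,
                "t_peak2_s": f.t_peak2_s,
                "log_amp1": f.log_amp1,
                "log_amp2": f.log_amp2,
            }
            for f in features
        ]
    )


def model_to_yaml(model: DiscriminantModel, path: str | Path) -> None:
    """Dump the fitted discriminant (means, covariance, priors) as YAML."""
    payload = {
        "labels": list(model.labels),
        "means": np.asarray(model.means).tolist(),
        "pooled_cov": np.asarray(model.pooled_cov).tolist(),
        "priors": [float(p) for p in model.priors],
        "n_per_group": [int(n) for n in model.n_per_group],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def jackknife_to_frame(report: JackknifeReport) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition_key": str(r.condition_key),
                "true_group": r.true_group,
                "own_group_posterior": r.own_group_posterior,
                "predicted_group": r.predicted_group,
                "flagged": r.flagged,
            }
            for r in report.rows
        ]
    )


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
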
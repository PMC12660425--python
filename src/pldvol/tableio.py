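"""Measurement tables, run configuration and validation-report assembly.

The canonical exchange format is a tidy CSV with one row per
case × timepoint × assessor:

    case_id, timepoint, assessor, slice_thickness_mm,
    cc, ap, ml,                      # BASiM diameters (cm)
    lcc, rcc, lap, rap, ml_qdsim,    # QDSiM diameters (cm, optional)
    reference_volume_ml              # semi-automatic volumetry (optional)

Timepoints use the fixed vocabulary {baseline, week24, followup}. Numbers
ingest with Unicode minus / en-dash normalization (clinical tables often
print "– 946.6"). The validation report reproduces the shape of a
method-comparison study: per-diameter and per-volume inter-assessor ICCs,
median (IQR) volume summaries, Bland–Altman agreement (assessor vs
assessor and calibrated method vs reference), Spearman correlation of
index vs reference, and change-rate summaries with ICC vs reference.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import bland_altman, cohort_change_summary, icc_2_1, spearman_rho
from .model import TIMEPOINTS, CalibrationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ID_COLUMNS",
    "BASIM_COLUMNS",
    "QDSIM_COLUMNS",
    "RunConfig",
    "read_table",
    "write_table",
    "add_estimates",
    "validate_report",
    "write_report",
]

ID_COLUMNS = ["case_id", "timepoint", "assessor", "slice_thickness_mm"]
BASIM_COLUMNS = ["cc", "ap", "ml"]
QDSIM_COLUMNS = ["lcc", "rcc", "lap", "rap", "ml_qdsim"]
OPTIONAL_COLUMNS = ["reference_volume_ml"]
ALL_COLUMNS = ID_COLUMNS + BASIM_COLUMNS + QDSIM_COLUMNS + OPTIONAL_COLUMNS

_NUMERIC = [c for c in ALL_COLUMNS if c not in ("case_id", "timepoint", "assessor")]


@dataclass
class RunConfig:
    """Analysis configuration embedded (as a hash) in every report."""

    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    midline: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {"calibration": asdict(self.calibration), "midline": self.midline, "seed": self.seed}

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _normalize_number(x):
    if isinstance(x, str):
        x = x.replace("–", "-").replace("−", "-").replace("—", "-")
        x = x.replace(" ", "").replace(",", "")
        if x in ("", "-", "NA", "NaN", "nan"):
            return np.nan
    return x


def read_table(path) -> pd.DataFrame:
    """Read and validate a measurement CSV.

    Enforces the header, the timepoint vocabulary, positive diameters,
    and uniqueness of (case_id, timepoint, assessor) rows.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table is missing required columns: {missing}")
    has_basim = all(c in df.columns for c in BASIM_COLUMNS)
    has_qdsim = all(c in df.columns for c in QDSIM_COLUMNS)
    if not has_basim and not has_qdsim:
        raise ValueError(
            f"table must contain the BASiM columns {BASIM_COLUMNS} and/or the QDSiM columns {QDSIM_COLUMNS}"
        )
    unknown = set(df.columns) - set(ALL_COLUMNS)
    if unknown:
        raise ValueError(f"unrecognized columns: {sorted(unknown)}")
    for col in df.columns:
        if col in _NUMERIC:
            df[col] = pd.to_numeric(df[col].map(_normalize_number))
    return validate_table(df)


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    bad_tp = set(df["timepoint"].unique()) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints {sorted(bad_tp)}; expected {TIMEPOINTS}")
    dup = df.duplicated(subset=["case_id", "timepoint", "assessor"])
    if dup.any():
        offenders = df.loc[dup, ["case_id", "timepoint", "assessor"]].to_records(index=False)
        raise ValueError(f"duplicate (case, timepoint, assessor) rows: {list(offenders)[:5]}")
    diam_cols = [c for c in BASIM_COLUMNS + QDSIM_COLUMNS if c in df.columns]
    vals = df[diam_cols].to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] < 0):
        raise ValueError("negative diameter values in table")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a measurement table; a read_table round-trip is lossless."""
    cols = [c for c in ALL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def add_estimates(df: pd.DataFrame, cfg: CalibrationConfig | None = None) -> pd.DataFrame:
    """Append index and calibrated-volume columns per available method."""
    if cfg is None:
        cfg = CalibrationConfig()
    out = df.copy()
    if all(c in df.columns for c in BASIM_COLUMNS):
        out["basim_index"] = df["cc"] * df["ap"] * df["ml"]
        out["basim_volume_ml"] = out["basim_index"] * cfg.factor("basim")
    if all(c in df.columns for c in QDSIM_COLUMNS):
        out["qdsim_index"] = (df["lcc"] * df["lap"] + df["rcc"] * df["rap"]) * df["ml_qdsim"] / 2.0
        out["qdsim_volume_ml"] = out["qdsim_index"] * cfg.factor("qdsim")
    return out


def _methods_in(df: pd.DataFrame) -> list:
    methods = []
    if all(c in df.columns for c in BASIM_COLUMNS):
        methods.append("basim")
    if all(c in df.columns for c in QDSIM_COLUMNS):
        methods.append("qdsim")
    return methods

_DIAMETERS = {"basim": BASIM_COLUMNS, "qdsim": QDSIM_COLUMNS}


def _icc_row(pivot: pd.DataFrame, **labels) -> dict:
    res = icc_2_1(pivot.dropna())
    return {**labels, "icc": res.icc, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "n": res.n, "k": res.k}


def _summary_rows(vol: pd.Series, **labels) -> dict:
    q1, med, q3 = vol.quantile([0.25, 0.5, 0.75])
    return {**labels, "median": med, "iqr_low": q1, "iqr_high": q3, "n": int(vol.notna().sum())}


def validate_report(table: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """Assemble the full agreement/validation report from a table.

    Returns a dict of tidy DataFrames: ``diameter_icc``, ``volume_summary``,
    ``volume_icc``, ``bland_altman``, ``spearman``, ``change_rates``.
    Deterministic: row order of the input does not affect the output.
    Bland–Altman differences are oriented first-listed minus second-listed.
    """
    if config is None:
        config = RunConfig()
    cfg = config.calibration
    df = validate_table(table.copy()).sort_values(["case_id", "timepoint", "assessor"], kind="mergesort")
    methods = _methods_in(df)
    assessors = sorted(df["assessor"].unique())
    multi = len(assessors) >= 2
    if not multi:
        logger.warning("single assessor: agreement analyses skipped")
    pair = assessors[:2]
    est = add_estimates(df, cfg)
    subj = ["case_id", "timepoint"]

    # --- per-diameter inter-assessor ICC ------------------------------------
    diam_rows = []
    if multi:
        for m in methods:
            for d in _DIAMETERS[m]:
                piv = est.pivot_table(index=subj, columns="assessor", values=d)[pair]
                diam_rows.append(_icc_row(piv, method=m, quantity=d))
            piv = est.pivot_table(index=subj, columns="assessor", values=f"{m}_index")[pair]
            diam_rows.append(_icc_row(piv, method=m, quantity="volume_index"))
    diameter_icc = pd.DataFrame(diam_rows)

    # --- calibrated volumes (per assessor and per-case assessor mean) -------
    long = []
    for m in methods:
        v = est[subj + ["assessor", f"{m}_index", f"{m}_volume_ml"]].rename(
            columns={f"{m}_index": "index", f"{m}_volume_ml": "volume_ml"}
        )
        v["method"] = m
        long.append(v)
        mean_idx = est.groupby(subj)[f"{m}_index"].mean().reset_index()
        mean_idx["assessor"] = "mean"
        mean_idx["method"] = m
        mean_idx = mean_idx.rename(columns={f"{m}_index": "index"})
        mean_idx["volume_ml"] = mean_idx["index"] * cfg.factor(m)
        long.append(mean_idx)
    vols = pd.concat(long, ignore_index=True)

    ref = None
    if "reference_volume_ml" in df.columns and df["reference_volume_ml"].notna().any():
        ref = df.groupby(subj)["reference_volume_ml"].mean().rename("reference")

    sum_rows = []
    if ref is not None:
        sum_rows.append(_summary_rows(ref, method="reference", assessor="-", timepoint="total"))
        for tp in TIMEPOINTS:
            r = ref[ref.index.get_level_values("timepoint") == tp]
            if len(r):
                sum_rows.append(_summary_rows(r, method="reference", assessor="-", timepoint=tp))
    for m in methods:
        for a in ([*assessors, "mean"] if multi else assessors):
            v = vols[(vols["method"] == m) & (vols["assessor"] == a)]
            sum_rows.append(_summary_rows(v["volume_ml"], method=m, assessor=a, timepoint="total"))
            for tp in TIMEPOINTS:
                vt = v[v["timepoint"] == tp]
                if len(vt):
                    sum_rows.append(_summary_rows(vt["volume_ml"], method=m, assessor=a, timepoint=tp))
    volume_summary = pd.DataFrame(sum_rows)

    # --- volume ICC and Bland–Altman ----------------------------------------
    icc_rows, ba_rows = [], []
    for m in methods:
        mv = vols[vols["method"] == m]
        if multi:
            piv = mv[mv["assessor"].isin(pair)].pivot_table(index=subj, columns="assessor", values="volume_ml")[pair]
            icc_rows.append(_icc_row(piv, comparison=f"assessor_{pair[0]}_vs_{pair[1]}", method=m))
            ba = bland_altman(piv[pair[0]], piv[pair[1]])
            ba_rows.append({"comparison": f"assessor_{pair[0]}_vs_{pair[1]}", "method": m,
                            "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
                            "loa_low": ba.loa_low, "loa_high": ba.loa_high, "n": ba.n})
        if ref is not None:
            mean_v = mv[mv["assessor"] == "mean"].set_index(subj)["volume_ml"]
            joined = pd.concat([ref, mean_v.rename("method")], axis=1).dropna()
            icc_rows.append(_icc_row(joined[["reference", "method"]], comparison="method_mean_vs_reference", method=m))
            ba = bland_altman(joined["reference"], joined["method"])
            ba_rows.append({"comparison": "reference_vs_method_mean", "method": m,
                            "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
                            "loa_low": ba.loa_low, "loa_high": ba.loa_high, "n": ba.n})
    volume_icc = pd.DataFrame(icc_rows)
    ba_table = pd.DataFrame(ba_rows)

    # --- Spearman: index (assessor mean) vs reference volume ----------------
    sp_rows = []
    if ref is not None:
        for m in methods:
            mean_i = vols[(vols["method"] == m) & (vols["assessor"] == "mean")].set_index(subj)["index"]
            joined = pd.concat([ref, mean_i.rename("index")], axis=1).dropna()
            if len(joined) >= 3:
                rho, p = spearman_rho(joined["reference"], joined["index"])
                sp_rows.append({"method": m, "rho": rho, "p_value": p, "n": len(joined)})
    spearman = pd.DataFrame(sp_rows)

    # --- change rates --------------------------------------------------------
    cr_rows = []
    present_tp = set(df["timepoint"].unique())
    sources = {}
    if ref is not None:
        sources["reference"] = ref
    for m in methods:
        sources[f"{m}_mean"] = vols[(vols["method"] == m) & (vols["assessor"] == "mean")].set_index(subj)["volume_ml"]
    for post_tp in ("week24", "followup"):
        if post_tp not in present_tp or "baseline" not in present_tp:
            continue
        per_source_rates = {}
        for name, series in sources.items():
            wide = series.unstack("timepoint")
            if "baseline" not in wide.columns or post_tp not in wide.columns:
                continue
            wide = wide[["baseline", post_tp]].dropna()
            rates = (wide[post_tp] - wide["baseline"]) / wide["baseline"] * 100.0
            per_source_rates[name] = rates
            if len(rates) >= 2:
                mean, (lo, hi) = cohort_change_summary(rates)
                cr_rows.append({"interval": f"baseline_to_{post_tp}", "source": name,
                                "statistic": "mean_change_rate_pct", "estimate": mean,
                                "ci_low": lo, "ci_high": hi, "n": len(rates)})
        if "reference" in per_source_rates:
            for m in methods:
                key = f"{m}_mean"
                if key not in per_source_rates:
                    continue
                joined = pd.concat(
                    [per_source_rates["reference"].rename("reference"),
                     per_source_rates[key].rename("method")], axis=1).dropna()
                if len(joined) >= 2:
                    res = icc_2_1(joined)
                    cr_rows.append({"interval": f"baseline_to_{post_tp}", "source": key,
                                    "statistic": "icc_vs_reference", "estimate": res.icc,
                                    "ci_low": res.ci_low, "ci_high": res.ci_high, "n": res.n})
                    ba = bland_altman(joined["reference"], joined["method"])
                    cr_rows.append({"interval": f"baseline_to_{post_tp}", "source": key,
                                    "statistic": "ba_mean_diff_vs_reference_pct", "estimate": ba.mean_diff,
                                    "ci_low": ba.loa_low, "ci_high": ba.loa_high, "n": ba.n})
    change_rates = pd.DataFrame(cr_rows)

    return {
        "diameter_icc": diameter_icc,
        "volume_summary": volume_summary,
        "volume_icc": volume_icc,
        "bland_altman": ba_table,
        "spearman": spearman,
        "change_rates": change_rates,
    }


def write_report(reports: dict, outdir, config: RunConfig | None = None) -> None:
    """Write each report table as CSV with a provenance header.

    Every file embeds the tool version, the config hash and the seed; the
    Bland–Altman orientation (first − second) is stated once per bundle.
    """
    if config is None:
        config = RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = (
        f"# pldvol {__version__}\n"
        f"# config_hash={config.hash()} seed={config.seed}\n"
        f"# bland_altman_orientation=first_minus_second\n"
    )
    for name, tbl in reports.items():
        with open(outdir / f"{name}.csv", "w", encoding="utf-8") as fh:
            fh.write(header)
            tbl.to_csv(fh, index=False)
    with open(outdir / "run_config.json", "w", encoding="utf-8") as fh:
        json.dump({"version": __version__, "config_hash": config.hash(), **config.to_dict()}, fh, indent=2)
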
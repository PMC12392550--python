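"""End-to-end analysis pipeline and descriptive summaries.

Orchestrates: record loading (or diary preprocessing, or simulation) ->
z-score outlier screening -> cross-sectional and longitudinal association
fits under all three rotations -> composition tests -> influence-exclusion
sensitivity refits -> isotemporal reallocation for outcomes whose
cross-sectional composition test is significant -> descriptive tables.
Artifacts are plain CSV/JSON, written deterministically so a rerun with the
same configuration and seed is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import yaml

from . import __version__
from .composition import Rotation, close, ilr_array
from .diary import default_mapping, load_mapping, outlier_screen, prepare_compositions, read_diary_csv
from .models import (
    OUTCOME_COLUMNS,
    composition_test,
    fit_cross_sectional,
    fit_longitudinal,
    influence_exclude_refit,
    rotation_table,
    select_cross_sectional,
)
from .reallocation import reallocation_curves, one_by_one_table, plot_reallocation_curves
from .synthetic import CohortParams, simulate_cohort

__all__ = [
    "PipelineConfig",
    "describe",
    "screen_records",
    "run_pipeline",
    "read_records_csv",
]

RECORD_COLUMNS = [
    "child_id",
    "timepoint",
    "age_months",
    "sex",
    "pa_min",
    "sb_min",
    "sleep_min",
    *OUTCOME_COLUMNS,
]


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"child_id": str})
    missing = {"child_id", "timepoint", "age_months", "sex", "pa_min", "sb_min", "sleep_min"} - set(df.columns)
    if missing:
        raise ValueError(f"records CSV {path} missing columns: {sorted(missing)}")
    return df


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    records_path: str | None = None
    diary_path: str | None = None
    mapping_path: str | None = None
    simulate: bool = False
    n_children: int = 160
    outcomes: Sequence[str] = ("gm_raw", "zbmi", "se_raw")
    screen_outliers: bool = True
    influence_exclusion: bool = True
    complete_cases_only: bool = False
    realloc_increment: float = 10.0
    realloc_lo: float = -60.0
    realloc_hi: float = 60.0
    realloc_split: str = "equal"
    realloc_reference: str = "arithmetic"
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "coda24_out"
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        sources = [self.records_path, self.diary_path, True if self.simulate else None]
        if sum(s is not None for s in sources) != 1:
            raise ValueError(
                "exactly one input source required: records_path, diary_path, "
                "or simulate=true"
            )
        for p in (self.records_path, self.diary_path, self.mapping_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        unknown = set(self.outcomes) - set(OUTCOME_COLUMNS)
        if unknown:
            raise ValueError(f"unknown outcome names: {sorted(unknown)}")


def describe(
    records: pd.DataFrame,
    variables: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable, per-timepoint descriptives in the field's house style.

    Normality is assessed per timepoint with Shapiro-Wilk at ``alpha``; a
    variable non-normal at any timepoint is reported as median [IQR] at
    every timepoint, otherwise mean +/- sd. Variables with fewer than three
    observations at every timepoint are skipped with a warning.
    """
    if records.empty:
        raise ValueError("no records to describe")
    if variables is None:
        variables = ["pa_min", "sb_min", "sleep_min"] + [
            c for c in OUTCOME_COLUMNS if c in records.columns
        ]
    timepoints = sorted(records["timepoint"].unique())
    rows = []
    for var in variables:
        groups = {
            t: records.loc[records["timepoint"] == t, var].dropna()
            for t in timepoints
        }
        usable = {t: g for t, g in groups.items() if len(g) >= 3}
        if not usable:
            warnings.warn(f"variable {var!r} has n < 3 at every timepoint; skipped")
            continue
        normal = True
        for g in usable.values():
            if g.nunique() == 1:  # degenerate: Shapiro undefined, treat non-normal
                normal = False
            else:
                normal &= st.shapiro(g)[1] >= alpha
        label = "normal" if normal else "non-normal"
        for t, g in usable.items():
            if normal:
                summary = f"{g.mean():.1f} ± {g.std(ddof=1):.1f}"
            else:
                q1, med, q3 = g.quantile([0.25, 0.5, 0.75])
                summary = f"{med:.1f} [{q1:.1f}–{q3:.1f}]"
            rows.append(
                {
                    "variable": var,
                    "timepoint": t,
                    "n": len(g),
                    "distribution": label,
                    "summary": summary,
                    "mean": g.mean(),
                    "sd": g.std(ddof=1),
                    "median": g.median(),
                    "q1": g.quantile(0.25),
                    "q3": g.quantile(0.75),
                }
            )
    return pd.DataFrame(rows)


def screen_records(
    records: pd.DataFrame, outcomes: Sequence[str], lo: float = -3.0, hi: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """z-score outlier screen on ilr coordinates and outcomes, per timepoint.

    A record is dropped when any screened variable is flagged. Returns the
    kept records and a log of (record, variable) flags. The two ilr
    coordinates are screened under the PA-pivot rotation; flags are
    rotation-dependent in principle but the screen is applied identically to
    every analysis downstream.
    """
    records = records.reset_index(drop=True)
    z = ilr_array(
        records[["pa_min", "sb_min", "sleep_min"]].to_numpy(dtype=float), Rotation.PA
    )
    screened = pd.DataFrame(
        {"ilr1": z[:, 0], "ilr2": z[:, 1]}, index=records.index
    )
    for oc in outcomes:
        if oc in records.columns:
            screened[oc] = records[oc]
    flags = []
    drop = np.zeros(len(records), dtype=bool)
    for t, sub in screened.groupby(records["timepoint"]):
        for var in sub.columns:
            vals = sub[var]
            if vals.notna().sum() < 2:
                continue
            f = outlier_screen(vals.to_numpy(dtype=float))
            for i in sub.index[f]:
                flags.append(
                    {
                        "record": i,
                        "child_id": records.at[i, "child_id"],
                        "timepoint": t,
                        "variable": var,
                        "value": records.at[i, var] if var in records else screened.at[i, var],
                    }
                )
                drop[i] = True
    return records.loc[~drop].copy(), pd.DataFrame(
        flags, columns=["record", "child_id", "timepoint", "variable", "value"]
    )


def _fit_block(records: pd.DataFrame, outcome: str, analysis: str, cfg: PipelineConfig) -> dict:
    """Fit full models under all rotations + composition test + sensitivity."""
    fitter = fit_cross_sectional if analysis == "cross_sectional" else fit_longitudinal
    full = fitter(records, outcome, Rotation.PA)
    test = composition_test(full)
    table = rotation_table(records, outcome, analysis)
    block = {
        "outcome": outcome,
        "analysis": analysis,
        "n_obs": full.nobs,
        "n_children": full.n_children,
        "llf": full.llf,
        "test": {
            "kind": test.kind,
            "statistic": test.statistic,
            "df": test.df if isinstance(test.df, int) else list(test.df),
            "pvalue": test.pvalue,
            "r2_delta": test.r2_delta,
            "cohen": test.cohen,
            "r2_marginal": test.r2_marginal,
            "r2_conditional": test.r2_conditional,
        },
        "rotation_table": table.to_dict(orient="records"),
        "excluded": [],
    }
    if cfg.influence_exclusion:
        excluded, refit = influence_exclude_refit(full, records, outcome)
        block["excluded"] = [int(i) for i in excluded]
        if len(excluded):
            sens_test = composition_test(refit)
            block["sensitivity"] = {
                "n_obs": refit.nobs,
                "pvalue": sens_test.pvalue,
                "r2_delta": sens_test.r2_delta,
            }
    return block


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write artifacts under ``config.out_dir``.

    Returns the run-log dict (also written as run_log.json).
    """
    cfg = config
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- load / build records -------------------------------------------
    rejections: list = []
    if cfg.simulate:
        cohort = simulate_cohort(CohortParams(n_children=cfg.n_children), seed=cfg.seed)
        records = cohort.records
    elif cfg.diary_path:
        mapping = load_mapping(cfg.mapping_path) if cfg.mapping_path else default_mapping()
        comps, rejections = prepare_compositions(read_diary_csv(cfg.diary_path), mapping)
        records = comps.assign(timepoint=1, age_months=np.nan, sex=np.nan)
    else:
        records = read_records_csv(cfg.records_path)
    n_in = len(records)

    # ---- close compositions to a common day ----------------------------
    closed = np.array(
        [
            close(row, total=1440.0).as_array()
            for row in records[["pa_min", "sb_min", "sleep_min"]].to_numpy(dtype=float)
        ]
    )
    records = records.assign(
        pa_min=closed[:, 0], sb_min=closed[:, 1], sleep_min=closed[:, 2]
    )

    # ---- outlier screen -------------------------------------------------
    outcomes = [o for o in cfg.outcomes if o in records.columns and records[o].notna().any()]
    if cfg.screen_outliers:
        records, flag_log = screen_records(records, outcomes)
    else:
        flag_log = pd.DataFrame(columns=["record", "child_id", "timepoint", "variable", "value"])
    if cfg.complete_cases_only:
        both = records.groupby("child_id")["timepoint"].transform("nunique") == 2
        records = records.loc[both].copy()

    # ---- descriptives ---------------------------------------------------
    desc = describe(records, alpha=cfg.alpha)
    desc.to_csv(out / "descriptives.csv", index=False)
    flag_log.to_csv(out / "outlier_log.csv", index=False)
    if rejections:
        pd.DataFrame([vars(r) for r in rejections]).to_csv(
            out / "diary_rejections.csv", index=False
        )

    # ---- association models --------------------------------------------
    analyzable = [
        o
        for o in outcomes
        if records.dropna(subset=["age_months", "sex", o]).shape[0] >= 10
    ]
    blocks = []
    for outcome in analyzable:
        for analysis in ("cross_sectional", "longitudinal"):
            blocks.append(_fit_block(records, outcome, analysis, cfg))
    assoc_rows = []
    for b in blocks:
        for r in b["rotation_table"]:
            assoc_rows.append(
                {
                    "outcome": b["outcome"],
                    "analysis": b["analysis"],
                    "n": b["n_obs"],
                    "statistic_kind": b["test"]["kind"],
                    "statistic": b["test"]["statistic"],
                    "pvalue": b["test"]["pvalue"],
                    "r2_delta": b["test"]["r2_delta"],
                    "cohen": b["test"]["cohen"],
                    "reference": r["reference"],
                    "beta_ilr1": r["beta_ilr1"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "beta_pvalue": r["pvalue"],
                }
            )
    pd.DataFrame(assoc_rows).to_csv(out / "associations.csv", index=False)
    with open(out / "associations.json", "w") as fh:
        json.dump(blocks, fh, indent=2, sort_keys=True)

    # ---- reallocation (gated on the cross-sectional composition test) ---
    realloc_outcomes = [
        b["outcome"]
        for b in blocks
        if b["analysis"] == "cross_sectional" and b["test"]["pvalue"] < cfg.alpha
    ]
    curve_frames, fits, comps_by_outcome = [], {}, {}
    for outcome in realloc_outcomes:
        fit = fit_cross_sectional(records, outcome, Rotation.PA)
        sel = select_cross_sectional(records, outcome)
        comps = [
            close(row)
            for row in sel[["pa_min", "sb_min", "sleep_min"]].to_numpy(dtype=float)
        ]
        fits[outcome] = fit
        comps_by_outcome[outcome] = comps
        for scheme in ("proportional", "one_by_one"):
            curves = reallocation_curves(
                fit,
                comps,
                scheme=scheme,
                increment=cfg.realloc_increment,
                lo=cfg.realloc_lo,
                hi=cfg.realloc_hi,
                split=cfg.realloc_split,
                reference=cfg.realloc_reference,
            )
            curves.insert(0, "outcome", outcome)
            curve_frames.append(curves)
            if cfg.make_plots:
                fig = plot_reallocation_curves(curves, outcome)
                fig.savefig(out / f"reallocation_{outcome}_{scheme}.png", dpi=120)
    if curve_frames:
        pd.concat(curve_frames, ignore_index=True).to_csv(
            out / "reallocation_curves.csv", index=False
        )
        one_by_one_table(fits, comps_by_outcome, delta=cfg.realloc_increment).to_csv(
            out / "reallocation_table.csv"
        )

    # ---- run log --------------------------------------------------------
    log = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in vars(cfg).items()},
        "records_in": int(n_in),
        "outlier_flagged": int(flag_log["record"].nunique()) if len(flag_log) else 0,
        "diary_rejected": len(rejections),
        "records_analyzed": int(len(records)),
        "outcomes_analyzed": analyzable,
        "reallocation_outcomes": realloc_outcomes,
        "influence_excluded": {
            f"{b['outcome']}:{b['analysis']}": len(b["excluded"]) for b in blocks
        },
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return log
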
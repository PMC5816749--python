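"""Study orchestration: simulate -> NCA -> mixed-model fits -> reports.

The two study drivers mirror the published analysis plan:

* :func:`run_pk_study` — weighted scalar sire model per NCA parameter
  (five parent parameters, three metabolite parameters, per drug), with
  Wald tests for sex and breed-of-sire.
* :func:`run_rr_study` — Legendre random-regression model per
  drug x compound (fixed curve order 6 for FBZ, 7 for FLU; random sire
  intercept, plus slope for the FBZ metabolite; heterogeneous residual
  variance by hour, AR1 within animal for FLU), with a likelihood-ratio
  comparison of the intercept-only vs intercept+slope sire term and
  predicted population / sire concentration curves.

Every report row carries its variance components, so the heritability in
the row is recomputable from the row alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BREEDS, COMPOUNDS, DRUGS, SEXES
from .design import build_pk_design, build_rr_design
from .genetics import (
    heritability_curve,
    heritability_from_fit,
    predict_sire_curves,
)
from .nca import METABOLITE_PARAMS, PARENT_PARAMS, nca_table
from .reml import (
    REMLError,
    VarianceSpec,
    fit_reml,
    likelihood_ratio_test,
    wald_test,
)

__all__ = [
    "RRBlock",
    "StudyConfig",
    "run_pk_study",
    "run_rr_study",
    "mean_heritability",
    "read_dataset",
    "write_report",
    "DatasetError",
]

log = logging.getLogger(__name__)


class DatasetError(ValueError):
    pass


@dataclass
class RRBlock:
    nf: int
    nr: int
    ar1: bool


def _default_rr_blocks() -> dict:
    return {
        ("FBZ", "parent"): RRBlock(nf=6, nr=0, ar1=False),
        ("FBZ", "metabolite"): RRBlock(nf=6, nr=1, ar1=False),
        ("FLU", "parent"): RRBlock(nf=7, nr=0, ar1=True),
        ("FLU", "metabolite"): RRBlock(nf=7, nr=0, ar1=True),
    }


@dataclass
class StudyConfig:
    rr_blocks: dict = field(default_factory=_default_rr_blocks)
    nca_min_points: int = 3
    auc_method: str = "linear"
    weight_floor: float = 0.01
    weight_policy: str = "terminal_r2"
    log_response_pk: bool = False
    log_response_rr: bool = True
    include_sire: bool = True
    denominator: str = "total"
    rounding_pk: int = 2
    rounding_time: int = 3
    run_lrt: bool = True


def run_pk_study(dataset: pd.DataFrame, config: StudyConfig | None = None,
                 pk_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Heritability of each NCA parameter per drug (scalar sire model).

    ``dataset`` is a long-format concentration table; ``pk_table`` may be
    supplied to skip the NCA step.
    """
    config = config or StudyConfig()
    if pk_table is None:
        pk_table = nca_table(dataset, min_points=config.nca_min_points,
                             method=config.auc_method,
                             weight_floor=config.weight_floor)
    rows = []
    for drug in sorted(pk_table["drug"].unique()):
        for compound, params in (("parent", PARENT_PARAMS),
                                 ("metabolite", METABOLITE_PARAMS)):
            sub = pk_table[(pk_table["drug"] == drug)
                           & (pk_table["compound"] == compound)]
            if sub.empty:
                continue
            if sub["sire_id"].nunique() < 2:
                raise REMLError(
                    f"heritability undefined for {drug}/{compound}: "
                    "fewer than 2 sires"
                )
            for param in params:
                design = build_pk_design(sub, param,
                                         weight_policy=config.weight_policy,
                                         include_sire=config.include_sire,
                                         log_response=config.log_response_pk)
                fit = fit_reml(design, VarianceSpec("weighted"))
                row = {"drug": drug, "compound": compound, "parameter": param,
                       "n_animals": design.n_obs, "converged": fit.converged}
                if config.include_sire:
                    est = heritability_from_fit(fit, config.denominator)
                    row.update(h2=est.h2, se=est.se, sigma2_a=est.sigma2_a,
                               sigma2_sire=est.sigma2_sire,
                               sigma2_batch=est.sigma2_batch,
                               sigma2_e=est.sigma2_e,
                               contains_zero=est.contains_zero,
                               exceeds_one=est.exceeds_one)
                    if not fit.converged:
                        log.info("non-converged fit: %s %s %s", drug, compound, param)
                for factor in ("sex", "breed"):
                    if factor in design.x_groups:
                        _, _, p = wald_test(fit, factor)
                        row[f"p_{factor}"] = p
                rows.append(row)
    return pd.DataFrame(rows)


def run_rr_study(dataset: pd.DataFrame, config: StudyConfig | None = None,
                 blocks: list | None = None):
    """Random-regression heritability-by-hour study.

    Returns ``(time_report, lrt_report, curve_report)`` DataFrames.
    """
    config = config or StudyConfig()
    keys = blocks or sorted({(d, c) for d, c in
                             zip(dataset["drug"], dataset["compound"])})
    time_rows, lrt_rows, curve_rows = [], [], []
    for key in keys:
        drug, compound = key
        block = config.rr_blocks.get(key)
        if block is None:
            continue
        sub = dataset[(dataset["drug"] == drug) & (dataset["compound"] == compound)]
        usable = sub[(sub["time_h"] > 0) & sub["conc_ug_per_ml"].notna()]
        if usable["time_h"].nunique() < 4:
            raise DatasetError(
                f"{drug}/{compound}: need >= 4 distinct post-dose hours"
            )
        counts = usable.groupby("time_h").size()
        lonely = counts[counts < 2]
        if not lonely.empty:
            raise DatasetError(
                f"{drug}/{compound}: residual variance unfittable at hour(s) "
                f"{list(lonely.index)} with a single observation"
            )
        spec = VarianceSpec("het_hour", ar1=block.ar1)

        fits = {}
        orders = sorted({block.nr} | ({0, 1} if config.run_lrt else set()))
        for nr in orders:
            design = build_rr_design(sub, nf=block.nf, nr=nr,
                                     log_response=config.log_response_rr)
            fits[nr] = fit_reml(design, spec)
        fit = fits[block.nr]

        if config.run_lrt and 0 in fits and 1 in fits:
            try:
                stat, df, p = likelihood_ratio_test(fits[0], fits[1], boundary=True)
            except REMLError as exc:
                log.warning("LRT failed for %s/%s: %s", drug, compound, exc)
                stat = df = p = np.nan
            lrt_rows.append({"drug": drug, "compound": compound,
                             "nr_reduced": 0, "nr_full": 1, "statistic": stat,
                             "df": df, "p_value": p, "nr_used": block.nr})

        p_sex = wald_test(fit, "sex")[2] if "sex" in fit.design.x_groups else np.nan
        p_breed = wald_test(fit, "breed")[2] if "breed" in fit.design.x_groups else np.nan
        for est in heritability_curve(fit, denominator=config.denominator):
            time_rows.append({
                "drug": drug, "compound": compound, "time_h": est.time_h,
                "h2": est.h2, "se": est.se, "sigma2_a": est.sigma2_a,
                "sigma2_sire_t": est.sigma2_sire, "sigma2_batch": est.sigma2_batch,
                "sigma2_e_t": est.sigma2_e, "contains_zero": est.contains_zero,
                "exceeds_one": est.exceeds_one, "nr": block.nr, "nf": block.nf,
                "rho": fit.varmodel.rho if block.ar1 else np.nan,
                "p_sex": p_sex, "p_breed": p_breed,
                "converged": fit.converged,
            })
        times, population, deviations = predict_sire_curves(fit)
        for j, t in enumerate(times):
            curve_rows.append({"drug": drug, "compound": compound, "time_h": t,
                               "sire_id": "population", "value": population[j]})
            for i, sid in enumerate(fit.design.sire_ids):
                curve_rows.append({"drug": drug, "compound": compound, "time_h": t,
                                   "sire_id": sid, "value": deviations[i, j]})
    return (pd.DataFrame(time_rows), pd.DataFrame(lrt_rows),
            pd.DataFrame(curve_rows))


def mean_heritability(report_rows: pd.DataFrame, selector: dict | None = None,
                      rounding: int = 2) -> float:
    """Arithmetic mean of h2 point estimates over the selected rows,
    rounded to ``rounding`` decimals. ``selector`` maps column names to
    required values, e.g. ``{"drug": "FBZ", "compound": "parent"}``."""
    df = report_rows
    if selector:
        for col, val in selector.items():
            if isinstance(val, (list, tuple, set)):
                df = df[df[col].isin(val)]
            else:
                df = df[df[col] == val]
    df = df.dropna(subset=["h2"])
    if df.empty:
        raise ValueError("empty selection: no heritability rows to average")
    return float(np.round(df["h2"].mean(), rounding))


_REQUIRED = ["animal_id", "sire_id", "breed", "sex", "batch", "drug", "compound",
             "dose_mg_per_kg", "body_weight_kg", "time_h", "conc_ug_per_ml"]


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a concentrations.csv table. Malformed rows are
    reported with their (1-based, header-inclusive) line numbers."""
    df = pd.read_csv(path, skipinitialspace=True)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required columns: {missing}")
    problems = []
    for col, allowed in (("breed", set(BREEDS)), ("sex", set(SEXES)),
                         ("compound", set(COMPOUNDS))):
        bad = ~df[col].astype(str).str.strip().isin(allowed)
        for i in df.index[bad]:
            problems.append(f"line {i + 2}: unknown {col} {df.loc[i, col]!r}")
    for col in ("time_h", "conc_ug_per_ml", "dose_mg_per_kg", "body_weight_kg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        for i in df.index[bad]:
            problems.append(f"line {i + 2}: non-numeric {col} {df.loc[i, col]!r}")
        df[col] = vals
    neg = df["conc_ug_per_ml"] < 0
    for i in df.index[neg]:
        problems.append(f"line {i + 2}: negative concentration "
                        f"{df.loc[i, 'conc_ug_per_ml']!r}")
    if problems:
        raise DatasetError("invalid dataset:\n" + "\n".join(problems[:50]))
    for col in ("breed", "sex", "compound", "drug", "animal_id", "sire_id"):
        df[col] = df[col].astype(str).str.strip()
    return df


def write_report(reports: dict, out_dir: str | Path) -> None:
    """Write each named report DataFrame as <name>.csv under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in reports.items():
        df.to_csv(out / f"{name}.csv", index=False)
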
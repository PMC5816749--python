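"""Non-compartmental pharmacokinetic analysis.

Per animal x compound profile: terminal log-linear fit (lambda_z with its
R^2, the downstream mixed-model weight), trapezoidal AUC/AUMC with
exponential tail extrapolation, and the derived parameters

    T1/2 = ln 2 / lambda_z          Cl   = Dose / AUC_inf
    MRT  = AUMC_inf / AUC_inf       Vdss = Cl * MRT

with Cmax/Tmax read directly from the observed series. Doses in mg/kg and
concentrations in ug/mL make Cl come out in L/h/kg without conversion
factors (ug/mL = mg/L).

Terminal-point selection follows the common best-fit rule: consider every
suffix of at least ``min_points`` positive observations strictly after the
observed peak, pick the one maximizing adjusted R^2 (ties broken toward
more points). The parent drug of an IV bolus peaks at the first record, so
in practice all but the peak sample are candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NCAError",
    "TerminalFit",
    "PKRecord",
    "terminal_phase_fit",
    "auc_aumc",
    "nca_parameters",
    "nca_table",
    "PARENT_PARAMS",
    "METABOLITE_PARAMS",
]

log = logging.getLogger(__name__)

PARENT_PARAMS = ("T_half_h", "Cl_L_per_h_per_kg", "AUC_inf_h_ug_per_ml",
                 "MRT_h", "Vdss_L_per_kg")
METABOLITE_PARAMS = ("AUC_inf_h_ug_per_ml", "Cmax_ug_per_ml", "Tmax_h")


class NCAError(ValueError):
    """Raised when a profile does not support the requested computation."""


@dataclass
class TerminalFit:
    lambda_z: float
    intercept: float
    r_squared: float
    points_used: np.ndarray = field(repr=False)

    def weight(self, floor: float = 0.01) -> float:
        """Mixed-model weight: terminal R^2 clipped away from zero."""
        return float(np.clip(self.r_squared, floor, 1.0))


@dataclass
class PKRecord:
    animal_id: str
    compound: str
    T_half_h: float
    AUC_inf_h_ug_per_ml: float
    MRT_h: float
    Cl_L_per_h_per_kg: float
    Vdss_L_per_kg: float
    Cmax_ug_per_ml: float
    Tmax_h: float
    auc_extrapolated_fraction: float
    terminal: TerminalFit


def _clean_series(times_h, conc) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.shape != c.shape:
        raise NCAError("times and concentrations must have equal length")
    if np.any(np.diff(t) <= 0):
        raise NCAError("time vector must be strictly increasing")
    keep = ~np.isnan(c)
    return t[keep], c[keep]


def terminal_phase_fit(times_h, conc, min_points: int = 3) -> TerminalFit:
    """Log-linear terminal fit by best adjusted R^2 over post-peak suffixes.

    Pre-dose (t = 0) records are excluded. An interior peak (rise-then-
    fall profile) is excluded from every candidate set; when the profile
    declines monotonically from the first quantified sample (IV bolus
    parent), that first sample is itself a valid terminal candidate.
    """
    t, c = _clean_series(times_h, conc)
    pos = (c > 0) & (t > 0)
    t, c = t[pos], c[pos]
    if len(t) == 0:
        raise NCAError("terminal phase not estimable: no positive concentrations")
    peak = int(np.argmax(c))
    start = peak + 1 if peak > 0 else 0
    t_post, c_post = t[start:], c[start:]
    if len(t_post) < min_points:
        raise NCAError(
            f"terminal phase not estimable: {len(t_post)} post-peak points "
            f"(need >= {min_points})"
        )
    logc = np.log(c_post)
    n_post = len(t_post)
    # suffix regressions in one pass via reversed cumulative sums
    tr, yr = t_post[::-1], logc[::-1]
    k_all = np.arange(1, n_post + 1, dtype=float)
    Sx, Sy = np.cumsum(tr), np.cumsum(yr)
    Sxx, Syy, Sxy = np.cumsum(tr * tr), np.cumsum(yr * yr), np.cumsum(tr * yr)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = k_all * Sxy - Sx * Sy
        vx = k_all * Sxx - Sx ** 2
        vy = k_all * Syy - Sy ** 2
        r2_all = np.where(vx * vy > 0, cov ** 2 / (vx * vy), 0.0)
        adj_all = np.where(k_all > 2,
                           1.0 - (1.0 - r2_all) * (k_all - 1) / (k_all - 2),
                           r2_all)
    valid = k_all >= min_points
    adj_all = np.where(valid, adj_all, -np.inf)
    best_adj = np.max(adj_all)
    k = int(np.max(k_all[adj_all >= best_adj - 1e-12]))  # ties -> more points
    slope, icpt = np.polyfit(t_post[-k:], logc[-k:], 1)
    ys = logc[-k:]
    resid = ys - (icpt + slope * t_post[-k:])
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    if slope >= 0:
        raise NCAError("terminal phase not estimable: non-negative slope")
    points_used = np.arange(n_post - k, n_post) + start
    return TerminalFit(lambda_z=-float(slope), intercept=float(icpt),
                       r_squared=float(np.clip(r2, 0.0, 1.0)),
                       points_used=points_used)


def auc_aumc(times_h, conc, terminal: TerminalFit | None = None,
             method: str = "linear") -> tuple[float, float, float]:
    """(AUC_last, AUC_inf, AUMC_inf) by the trapezoidal rule plus tail.

    ``method`` is ``"linear"`` (default) or ``"linuplogdown"`` (log
    trapezoid on strictly decreasing positive segments).
    """
    t, c = _clean_series(times_h, conc)
    if len(t) < 2:
        raise NCAError("need at least two observations for AUC")
    if method == "linear":
        auc_last = float(np.trapezoid(c, t))
        aumc_last = float(np.trapezoid(c * t, t))
    elif method == "linuplogdown":
        auc_last = aumc_last = 0.0
        for i in range(len(t) - 1):
            dt = t[i + 1] - t[i]
            c1, c2 = c[i], c[i + 1]
            if c2 < c1 and c2 > 0:
                k = np.log(c1 / c2) / dt
                auc_last += (c1 - c2) / k
                aumc_last += (t[i] * c1 - t[i + 1] * c2) / k + (c1 - c2) / k ** 2
            else:
                auc_last += 0.5 * (c1 + c2) * dt
                aumc_last += 0.5 * (t[i] * c1 + t[i + 1] * c2) * dt
        auc_last, aumc_last = float(auc_last), float(aumc_last)
    else:
        raise ValueError(f"unknown AUC method {method!r}")
    if terminal is None:
        return auc_last, np.nan, np.nan
    lz = terminal.lambda_z
    c_last, t_last = c[-1], t[-1]
    auc_inf = auc_last + c_last / lz
    aumc_inf = aumc_last + c_last * t_last / lz + c_last / lz ** 2
    return auc_last, float(auc_inf), float(aumc_inf)


def nca_parameters(times_h, conc, dose_mg_per_kg: float, animal_id: str = "",
                   compound: str = "parent", min_points: int = 3,
                   method: str = "linear") -> PKRecord:
    """Full per-profile NCA. Metabolite records report AUC_inf, Cmax and
    Tmax only (remaining fields NaN), mirroring the usual reporting for a
    formed metabolite with no administered dose of its own."""
    if dose_mg_per_kg <= 0:
        raise NCAError("dose must be positive")
    terminal = terminal_phase_fit(times_h, conc, min_points=min_points)
    _, auc_inf, aumc_inf = auc_aumc(times_h, conc, terminal, method=method)
    auc_last, _, _ = auc_aumc(times_h, conc, None, method=method)
    extrap = 1.0 - auc_last / auc_inf

    t, c = _clean_series(times_h, conc)
    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])

    if compound == "parent":
        t_half = np.log(2.0) / terminal.lambda_z
        cl = dose_mg_per_kg / auc_inf
        mrt = aumc_inf / auc_inf
        vdss = cl * mrt
    else:
        t_half = cl = mrt = vdss = np.nan
    return PKRecord(
        animal_id=animal_id, compound=compound,
        T_half_h=float(t_half), AUC_inf_h_ug_per_ml=float(auc_inf),
        MRT_h=float(mrt), Cl_L_per_h_per_kg=float(cl),
        Vdss_L_per_kg=float(vdss), Cmax_ug_per_ml=cmax, Tmax_h=tmax,
        auc_extrapolated_fraction=float(extrap), terminal=terminal,
    )


def nca_table(conc: pd.DataFrame, min_points: int = 3,
              method: str = "linear", weight_floor: float = 0.01) -> pd.DataFrame:
    """Run NCA over every animal x compound profile of a long-format
    concentration table. Profiles whose terminal phase is not estimable are
    logged and excluded."""
    rows = []
    meta_cols = ["sire_id", "breed", "sex", "batch", "drug", "dose_mg_per_kg",
                 "body_weight_kg"]
    for (animal, compound), grp in conc.groupby(["animal_id", "compound"], sort=True):
        grp = grp.sort_values("time_h")
        try:
            rec = nca_parameters(
                grp["time_h"].to_numpy(), grp["conc_ug_per_ml"].to_numpy(),
                float(grp["dose_mg_per_kg"].iloc[0]), animal_id=animal,
                compound=compound, min_points=min_points, method=method,
            )
        except NCAError as exc:
            log.warning("NCA failed for %s/%s: %s", animal, compound, exc)
            continue
        row = {c: grp[c].iloc[0] for c in meta_cols if c in grp.columns}
        row.update({
            "animal_id": animal, "compound": compound,
            "T_half_h": rec.T_half_h, "Cl_L_per_h_per_kg": rec.Cl_L_per_h_per_kg,
            "AUC_inf_h_ug_per_ml": rec.AUC_inf_h_ug_per_ml, "MRT_h": rec.MRT_h,
            "Vdss_L_per_kg": rec.Vdss_L_per_kg, "Cmax_ug_per_ml": rec.Cmax_ug_per_ml,
            "Tmax_h": rec.Tmax_h,
            "auc_extrapolated_fraction": rec.auc_extrapolated_fraction,
            "lambda_z": rec.terminal.lambda_z,
            "r_squared": rec.terminal.r_squared,
            "weight": rec.terminal.weight(weight_floor),
        })
        rows.append(row)
    return pd.DataFrame(rows)
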
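"""Model matrices for the sire mixed models.

Two builders produce a :class:`DesignMatrices` bundle:

* :func:`build_pk_design` — scalar response (one NCA parameter per
  animal): intercept + sex + breed-of-sire contrasts, random batch and
  sire intercepts, per-animal residual weights (terminal-fit R^2).
* :func:`build_rr_design` — longitudinal response (concentration across
  post-dose hours): fixed Legendre population curve + sex + breed,
  random batch intercept and per-sire Legendre regression coefficients
  (order ``nr``), observation metadata (hour index, animal blocks) for
  heterogeneous / AR1 residual structures.

Reference levels are alphabetical; factors with a single observed level
contribute no contrast columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import LegendreBasis

__all__ = ["DesignMatrices", "build_pk_design", "build_rr_design"]


@dataclass
class DesignMatrices:
    y: np.ndarray
    X: np.ndarray
    x_names: list
    x_groups: dict                      # factor name -> column indices (for Wald tests)
    Z: np.ndarray                       # [batch incidence | sire (x basis) columns]
    n_batch: int                        # number of batch columns (0 = no batch term)
    batch_ids: list
    sire_ids: list
    nr: int | None                      # sire regression order; None = scalar sire model
    weights: np.ndarray | None = None
    hours: np.ndarray | None = None     # sorted unique post-dose hours
    time_index: np.ndarray | None = None
    animal_blocks: list | None = None   # row-index arrays, time-ordered, per animal
    basis: LegendreBasis | None = None
    curve_cols: slice | None = None     # columns of X holding the population curve
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_sires(self) -> int:
        return len(self.sire_ids)

    @property
    def sire_block_size(self) -> int:
        return 1 if self.nr is None else self.nr + 1

    def validate(self) -> None:
        n = self.n_obs
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("row counts of y, X, Z disagree")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is rank deficient after reference-level constraints")

    @property
    def has_sire(self) -> bool:
        return len(self.sire_ids) > 0

    def replace_y(self, y: np.ndarray) -> "DesignMatrices":
        """Same design, new response (fresh cache) — used by simulation
        and the parametric bootstrap."""
        import copy
        new = copy.copy(self)
        new.y = np.asarray(y, dtype=float)
        new._cache = {}
        return new


def _contrasts(values: pd.Series, name: str) -> tuple[np.ndarray, list]:
    """Dummy columns for all but the alphabetically first observed level."""
    levels = sorted(pd.unique(values.astype(str)))
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((values.astype(str) == lev).to_numpy(dtype=float))
        names.append(f"{name}[{lev}]")
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(values), 0)), []


def _incidence(values: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(values), key=lambda v: (str(type(v)), v))
    lookup = {lev: i for i, lev in enumerate(levels)}
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), values.map(lookup).to_numpy()] = 1.0
    return Z, list(levels)


def build_pk_design(pk_table: pd.DataFrame, trait: str,
                    weight_policy: str = "terminal_r2",
                    include_batch: bool = True,
                    include_sire: bool = True,
                    log_response: bool = False) -> DesignMatrices:
    """Scalar-trait design for the weighted sire model."""
    df = pk_table.dropna(subset=[trait]).reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no records with non-missing {trait!r}")
    y = df[trait].to_numpy(dtype=float)
    if log_response:
        y = np.log(y)

    n = len(df)
    X_parts = [np.ones((n, 1))]
    x_names = ["intercept"]
    x_groups: dict = {}
    for factor in ("sex", "breed"):
        if factor in df.columns:
            cols, names = _contrasts(df[factor], factor)
            if cols.shape[1]:
                x_groups[factor] = list(range(len(x_names), len(x_names) + len(names)))
                X_parts.append(cols)
                x_names.extend(names)
    X = np.hstack(X_parts)

    Z_parts, n_batch, batch_ids = [], 0, []
    if include_batch and "batch" in df.columns and df["batch"].nunique() > 1:
        Zb, batch_ids = _incidence(df["batch"])
        Z_parts.append(Zb)
        n_batch = Zb.shape[1]
    sire_ids: list = []
    nr = None
    if include_sire:
        Zs, sire_ids = _incidence(df["sire_id"])
        Z_parts.append(Zs)
    Z = np.hstack(Z_parts) if Z_parts else np.empty((n, 0))

    if weight_policy == "uniform":
        w = np.ones(n)
    elif weight_policy == "terminal_r2":
        if "weight" not in df.columns or df["weight"].isna().any():
            raise ValueError("missing weights; use weight_policy='uniform' or supply them")
        w = df["weight"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown weight_policy {weight_policy!r}")

    d = DesignMatrices(y=y, X=X, x_names=x_names, x_groups=x_groups, Z=Z,
                       n_batch=n_batch, batch_ids=batch_ids, sire_ids=sire_ids,
                       nr=None, weights=w)
    d.validate()
    return d


def build_rr_design(conc_table: pd.DataFrame, nf: int, nr: int,
                    basis: LegendreBasis | None = None,
                    include_batch: bool = True,
                    include_sire: bool = True,
                    log_response: bool = False) -> DesignMatrices:
    """Random-regression design for one drug x compound table."""
    if nr > nf:
        raise ValueError(f"random order nr={nr} cannot exceed fixed order nf={nf}")
    df = conc_table.copy()
    df = df[(df["time_h"] > 0) & df["conc_ug_per_ml"].notna()]
    df = df.sort_values(["animal_id", "time_h"]).reset_index(drop=True)
    if df.empty:
        raise ValueError("no usable (post-dose, quantified) observations")
    y = df["conc_ug_per_ml"].to_numpy(dtype=float)
    if log_response:
        y = np.log(y)

    times = df["time_h"].to_numpy(dtype=float)
    n_hours = len(np.unique(times))
    if nf + 1 > n_hours:
        raise ValueError(
            f"fixed curve order nf={nf} needs {nf + 1} distinct hours; "
            f"data has {n_hours}"
        )
    if basis is None:
        basis = LegendreBasis(order=nf, t_min=float(times.min()),
                              t_max=float(times.max()), normalized=True)
    phi_f = basis.evaluate(times)[:, : nf + 1]

    X_parts = [phi_f]
    x_names = [f"curve{k}" for k in range(nf + 1)]
    x_groups = {"curve": list(range(nf + 1))}
    for factor in ("sex", "breed"):
        if factor in df.columns:
            cols, names = _contrasts(df[factor], factor)
            if cols.shape[1]:
                x_groups[factor] = list(range(len(x_names), len(x_names) + len(names)))
                X_parts.append(cols)
                x_names.extend(names)
    X = np.hstack(X_parts)

    Z_parts, n_batch, batch_ids = [], 0, []
    if include_batch and "batch" in df.columns and df["batch"].nunique() > 1:
        Zb, batch_ids = _incidence(df["batch"])
        Z_parts.append(Zb)
        n_batch = Zb.shape[1]
    sire_ids: list = []
    if include_sire:
        Zs_inc, sire_ids = _incidence(df["sire_id"])
        phi_r = basis.evaluate(times)[:, : nr + 1]
        # sire-major layout: columns [sire0 x phi0..phinr, sire1 x ...]
        Zs = (Zs_inc[:, :, None] * phi_r[:, None, :]).reshape(len(df), -1)
        Z_parts.append(Zs)
    Z = np.hstack(Z_parts) if Z_parts else np.empty((len(df), 0))

    hours = np.unique(times)
    time_index = np.searchsorted(hours, times)
    blocks = [grp.index.to_numpy() for _, grp in df.groupby("animal_id", sort=True)]

    d = DesignMatrices(y=y, X=X, x_names=x_names, x_groups=x_groups, Z=Z,
                       n_batch=n_batch, batch_ids=batch_ids, sire_ids=sire_ids,
                       nr=nr if include_sire else None, weights=None,
                       hours=hours, time_index=time_index, animal_blocks=blocks,
                       basis=basis, curve_cols=slice(0, nf + 1))
    d.validate()
    return d
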
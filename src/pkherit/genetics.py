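"""From variance components to genetic parameters.

In a half-sib sire model the sire variance is one quarter of the additive
genetic variance, so ``sigma2_a = 4 sigma2_sire`` and

    h2 = 4 sigma2_sire / (sigma2_sire + sigma2_batch + sigma2_e).

The denominator keeps the *sire* variance once (not sigma2_a), following
the reporting convention this pipeline reproduces; that convention can
push h2 above 1 when the sire variance is large, so estimates carry an
``exceeds_one`` flag and a conventional variant
(4 sigma2_sire / (sigma2_sire + sigma2_e)) sits behind
``denominator="no_batch"``.

For the random-regression model the sire variance at hour t is the
quadratic form ``t_t S t_t'`` with t_t the basis row at that hour, and the
heritability at t uses that hour's residual variance. Standard errors
propagate the curvature-based covariance of the variance parameters
through each heritability map (delta method, finite-difference gradient);
a parametric bootstrap is provided as the cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import LegendreBasis
from .reml import REMLFit, fit_reml, natural_to_varmodel, simulate_response

__all__ = [
    "HeritabilityEstimate",
    "additive_from_sire",
    "heritability_scalar",
    "heritability_from_fit",
    "sire_variance_at_time",
    "heritability_curve",
    "predict_sire_curves",
    "bootstrap_heritability",
]


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    sigma2_a: float
    sigma2_sire: float
    sigma2_batch: float
    sigma2_e: float
    time_h: float | None = None
    contains_zero: bool = False
    exceeds_one: bool = False


def additive_from_sire(sigma2_sire: float) -> float:
    """sigma2_a = 4 sigma2_sire (half-sibs share 1/4 of additive effects)."""
    if sigma2_sire < 0:
        raise ValueError("sire variance must be non-negative")
    return 4.0 * sigma2_sire


def _h2_value(s2s: float, s2b: float, s2e: float, denominator: str) -> float:
    if denominator == "total":
        denom = s2s + s2b + s2e
    elif denominator == "no_batch":
        denom = s2s + s2e
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    if denom <= 0:
        raise ZeroDivisionError("heritability undefined: zero phenotypic variance")
    return additive_from_sire(s2s) / denom


def heritability_scalar(sigma2_sire: float, sigma2_batch: float, sigma2_e: float,
                        se: float = np.nan,
                        denominator: str = "total") -> HeritabilityEstimate:
    """Point heritability from scalar components (SE optional)."""
    for name, v in (("sigma2_sire", sigma2_sire), ("sigma2_batch", sigma2_batch),
                    ("sigma2_e", sigma2_e)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    h2 = _h2_value(sigma2_sire, sigma2_batch, sigma2_e, denominator)
    contains_zero = bool(np.isfinite(se) and (h2 - se) <= 0.0 <= (h2 + se))
    return HeritabilityEstimate(
        h2=h2, se=float(se), sigma2_a=additive_from_sire(sigma2_sire),
        sigma2_sire=float(sigma2_sire), sigma2_batch=float(sigma2_batch),
        sigma2_e=float(sigma2_e), contains_zero=contains_zero,
        exceeds_one=bool(h2 > 1.0),
    )


def _delta_se(fit: REMLFit, fun) -> float:
    """Delta-method SE of scalar ``fun(natural_params)``."""
    x = fit.natural
    if not np.all(np.isfinite(fit.vcov_theta)):
        return np.nan
    g = np.zeros(len(x))
    for i in range(len(x)):
        h = 1e-6 * max(abs(x[i]), 1e-6)
        e = np.zeros(len(x)); e[i] = h
        try:
            g[i] = (fun(x + e) - fun(x - e)) / (2 * h)
        except (ZeroDivisionError, ValueError):
            return np.nan
    var = float(g @ fit.vcov_theta @ g)
    return float(np.sqrt(max(var, 0.0)))


def _component(fit: REMLFit, name: str, natural=None) -> float:
    natural = fit.natural if natural is None else natural
    try:
        return float(natural[fit.theta_names.index(name)])
    except ValueError:
        return 0.0


def heritability_from_fit(fit: REMLFit,
                          denominator: str = "total") -> HeritabilityEstimate:
    """Scalar-model heritability with delta-method SE."""
    if fit.design.hours is not None and fit.design.sire_block_size > 1:
        raise ValueError("use heritability_curve for random-regression fits")

    def h2_of(nat):
        return _h2_value(max(_component(fit, "sigma2_sire", nat), 0.0),
                         max(_component(fit, "sigma2_batch", nat), 0.0),
                         max(_component(fit, "sigma2_e", nat), 0.0),
                         denominator)

    se = _delta_se(fit, h2_of)
    return heritability_scalar(
        _component(fit, "sigma2_sire"), _component(fit, "sigma2_batch"),
        _component(fit, "sigma2_e"), se=se, denominator=denominator,
    )


def sire_variance_at_time(S: np.ndarray, t_row: np.ndarray) -> float:
    """Quadratic form t_t S t_t' — the sire variance at one hour."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    t = np.asarray(t_row, dtype=float).ravel()
    if S.shape[0] != S.shape[1] or S.shape[0] != len(t):
        raise ValueError("dimension mismatch between S and basis row")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    return float(t @ S @ t)


def _curve_components(fit: REMLFit, basis: LegendreBasis, hour: float,
                      natural=None) -> tuple[float, float, float]:
    natural = fit.natural if natural is None else natural
    hours = fit.design.hours
    matches = np.flatnonzero(np.isclose(hours, hour))
    if len(matches) == 0:
        raise ValueError(f"no fitted residual variance at hour {hour:g}")
    nb = fit.design.sire_block_size
    vm = natural_to_varmodel(natural, fit.design, fit.spec)
    t_row = basis.row(hour)[:nb]
    s2s = sire_variance_at_time(vm.S, t_row)
    s2b = vm.sigma2_batch if vm.sigma2_batch is not None else 0.0
    s2e = float(np.asarray(vm.sigma2_e)[matches[0]])
    return s2s, max(s2b, 0.0), max(s2e, 0.0)


def heritability_curve(fit: REMLFit, basis: LegendreBasis | None = None,
                       times_h=None, denominator: str = "total") -> list:
    """Time-varying heritability for a random-regression fit, one
    :class:`HeritabilityEstimate` per requested hour (default: every
    fitted hour)."""
    if fit.design.hours is None:
        raise ValueError("heritability_curve needs a random-regression fit")
    if basis is None:
        basis = fit.design.basis
    if times_h is None:
        times_h = fit.design.hours
    out = []
    for hour in np.atleast_1d(times_h):
        s2s, s2b, s2e = _curve_components(fit, basis, float(hour))

        def h2_of(nat, _hour=float(hour)):
            c = _curve_components(fit, basis, _hour, nat)
            return _h2_value(max(c[0], 0.0), c[1], c[2], denominator)

        se = _delta_se(fit, h2_of)
        h2 = _h2_value(s2s, s2b, s2e, denominator)
        out.append(HeritabilityEstimate(
            h2=h2, se=se, sigma2_a=additive_from_sire(s2s), sigma2_sire=s2s,
            sigma2_batch=s2b, sigma2_e=s2e, time_h=float(hour),
            contains_zero=bool(np.isfinite(se) and (h2 - se) <= 0 <= (h2 + se)),
            exceeds_one=bool(h2 > 1.0),
        ))
    return out


def predict_sire_curves(fit: REMLFit, basis: LegendreBasis | None = None,
                        times_h=None):
    """Population mean curve (fixed Legendre part of the BLUEs) and
    per-sire deviation curves (random-regression BLUPs).

    Returns ``(times, population, deviations)`` with ``deviations`` of
    shape (n_sires, n_times).
    """
    if fit.design.curve_cols is None:
        raise ValueError("fit has no population curve (scalar model)")
    if basis is None:
        basis = fit.design.basis
    if times_h is None:
        times_h = fit.design.hours
    times = np.atleast_1d(np.asarray(times_h, dtype=float))
    phi = basis.evaluate(times)
    nf_cols = fit.design.curve_cols
    population = phi[:, : nf_cols.stop] @ fit.beta_hat[nf_cols]
    nb = fit.design.sire_block_size
    deviations = fit.blup_sire @ phi[:, :nb].T
    return times, population, deviations


def bootstrap_heritability(fit: REMLFit, times_h=None, n_boot: int = 200,
                           seed: int = 0, denominator: str = "total") -> np.ndarray:
    """Parametric-bootstrap draws of the heritability (curve or scalar).

    Simulates responses from the fitted model on the same design, refits
    (warm-started at the fitted components), and returns an array of shape
    (n_boot, n_times) — or (n_boot, 1) for scalar fits. Bootstrap SEs are
    column standard deviations.
    """
    rng = np.random.default_rng(seed)
    is_curve = fit.design.hours is not None
    if is_curve and times_h is None:
        times_h = fit.design.hours
    n_t = len(np.atleast_1d(times_h)) if is_curve else 1
    draws = np.full((n_boot, n_t), np.nan)
    for b in range(n_boot):
        y_star = simulate_response(fit.design, fit.varmodel, fit.beta_hat, rng)
        d_star = fit.design.replace_y(y_star)
        refit = fit_reml(d_star, fit.spec, start=fit.natural, polish=False)
        if is_curve:
            ests = heritability_curve(refit, fit.design.basis, times_h,
                                      denominator=denominator)
            draws[b] = [e.h2 for e in ests]
        else:
            draws[b, 0] = heritability_from_fit(refit, denominator).h2
    return draws
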
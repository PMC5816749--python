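"""REML estimation for sire mixed models.

The marginal model is ``y = X beta + Z_batch u_b + Z_sire u_s + e`` with

    V = sigma2_batch Z_b Z_b' + Z_s (I ox S) Z_s' + R,

where S is the (nr+1) x (nr+1) sire covariance matrix (1 x 1 for the
scalar sire model) and R is one of three residual structures:

* ``weighted``      — var(e_i) = sigma2_e / w_i, independent;
* ``het_hour``      — var(e_i) = sigma2_e[t(i)], independent, one variance
  per sampling hour;
* ``het_hour`` + AR1 — as above with correlation rho^{|i-j|} between an
  animal's observations, indexed by sampling position, independent across
  animals.

The restricted log-likelihood follows the convention
``logL = -1/2 [log|V| + log|X'V^-1 X| + y'Py]`` (additive constant
dropped). It is evaluated through the mixed-model equations: because R is
diagonal (or Markov-banded within animal) all data enter via a handful of
cross-product matrices that are precomputed once per design, making a
likelihood evaluation O((p+q)^2) rather than O(n^3).

Variance parameters are optimized on an unconstrained scale: log for
variances, log-Cholesky for S, Fisher-z for rho. Curvature (for
standard errors) is a finite-difference Hessian mapped back to the
natural scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .design import DesignMatrices

__all__ = [
    "REMLError",
    "VarianceSpec",
    "VarianceModel",
    "REMLFit",
    "reml_neg_loglik",
    "fit_reml",
    "likelihood_ratio_test",
    "wald_test",
    "simulate_response",
]

log = logging.getLogger(__name__)

_PENALTY = 1.0e10
_BOUND = 18.0     # |log variance| bound on the standardized response scale
_RHO_BOUND = 4.0  # |atanh rho| bound


class REMLError(RuntimeError):
    pass


@dataclass(frozen=True)
class VarianceSpec:
    """Residual structure selector; random terms come from the design."""

    residual: str = "weighted"  # "weighted" | "het_hour"
    ar1: bool = False

    def __post_init__(self):
        if self.residual not in ("weighted", "het_hour"):
            raise ValueError(f"unknown residual structure {self.residual!r}")
        if self.ar1 and self.residual != "het_hour":
            raise ValueError("AR1 serial correlation requires het_hour residuals")


@dataclass
class VarianceModel:
    """Fitted (or hypothesized) variance components on the natural scale."""

    S: np.ndarray | None          # sire covariance, (nb, nb); None = no sire term
    sigma2_batch: float | None
    sigma2_e: np.ndarray | float  # scalar (weighted) or per-hour array
    rho: float | None
    spec: VarianceSpec

    @property
    def sigma2_sire(self) -> float:
        """Sire intercept variance (S[0, 0])."""
        if self.S is None:
            return 0.0
        return float(self.S[0, 0])


def default_spec(design: DesignMatrices) -> VarianceSpec:
    if design.hours is None:
        return VarianceSpec("weighted")
    return VarianceSpec("het_hour")


# ---------------------------------------------------------------------------
# parameterization

def natural_names(design: DesignMatrices, spec: VarianceSpec) -> list:
    names = []
    if design.has_sire:
        nb = design.sire_block_size
        if nb == 1:
            names.append("sigma2_sire")
        else:
            for i in range(nb):
                for j in range(i + 1):
                    names.append(f"S[{i},{j}]")
    if design.n_batch:
        names.append("sigma2_batch")
    if spec.residual == "weighted":
        names.append("sigma2_e")
    else:
        names.extend(f"sigma2_e[{h:g}]" for h in design.hours)
    if spec.ar1:
        names.append("rho")
    return names


def _n_sire_par(design: DesignMatrices) -> int:
    nb = design.sire_block_size
    return nb * (nb + 1) // 2 if design.has_sire else 0


def n_variance_params(design: DesignMatrices, spec: VarianceSpec) -> int:
    n = _n_sire_par(design)
    n += 1 if design.n_batch else 0
    n += 1 if spec.residual == "weighted" else len(design.hours)
    n += 1 if spec.ar1 else 0
    return n


def untransform(theta: np.ndarray, design: DesignMatrices,
                spec: VarianceSpec) -> np.ndarray:
    """Unconstrained parameters -> natural-scale vector (variances, S
    lower-triangle row-wise, rho)."""
    theta = np.asarray(theta, dtype=float)
    out, k = [], 0
    if design.has_sire:
        nb = design.sire_block_size
        L = np.zeros((nb, nb))
        for i in range(nb):
            for j in range(i + 1):
                L[i, j] = np.exp(theta[k]) if i == j else theta[k]
                k += 1
        S = L @ L.T
        out.extend(S[i, j] for i in range(nb) for j in range(i + 1))
    if design.n_batch:
        out.append(np.exp(theta[k])); k += 1
    n_res = 1 if spec.residual == "weighted" else len(design.hours)
    out.extend(np.exp(theta[k:k + n_res])); k += n_res
    if spec.ar1:
        out.append(np.tanh(theta[k])); k += 1
    return np.array(out)


def transform(natural: np.ndarray, design: DesignMatrices,
              spec: VarianceSpec) -> np.ndarray:
    """Natural-scale vector -> unconstrained optimizer scale."""
    natural = np.asarray(natural, dtype=float)
    out, k = [], 0
    tiny = 1e-10
    if design.has_sire:
        nb = design.sire_block_size
        S = np.zeros((nb, nb))
        for i in range(nb):
            for j in range(i + 1):
                S[i, j] = S[j, i] = natural[k]; k += 1
        # nudge to PSD for the Cholesky
        w, V = np.linalg.eigh(S)
        S = (V * np.clip(w, tiny, None)) @ V.T
        L = np.linalg.cholesky(S)
        for i in range(nb):
            for j in range(i + 1):
                out.append(np.log(max(L[i, j], tiny)) if i == j else L[i, j])
    if design.n_batch:
        out.append(np.log(max(natural[k], tiny))); k += 1
    n_res = 1 if spec.residual == "weighted" else len(design.hours)
    for v in natural[k:k + n_res]:
        out.append(np.log(max(v, tiny)))
    k += n_res
    if spec.ar1:
        out.append(np.arctanh(np.clip(natural[k], -0.9999, 0.9999))); k += 1
    return np.array(out)


def natural_to_varmodel(natural: np.ndarray, design: DesignMatrices,
                        spec: VarianceSpec) -> VarianceModel:
    natural = np.asarray(natural, dtype=float)
    k = 0
    S = None
    if design.has_sire:
        nb = design.sire_block_size
        S = np.zeros((nb, nb))
        for i in range(nb):
            for j in range(i + 1):
                S[i, j] = S[j, i] = natural[k]; k += 1
    s2b = None
    if design.n_batch:
        s2b = float(natural[k]); k += 1
    if spec.residual == "weighted":
        s2e: float | np.ndarray = float(natural[k]); k += 1
    else:
        nh = len(design.hours)
        s2e = natural[k:k + nh].copy(); k += nh
    rho = None
    if spec.ar1:
        rho = float(natural[k]); k += 1
    return VarianceModel(S=S, sigma2_batch=s2b, sigma2_e=s2e, rho=rho, spec=spec)


# ---------------------------------------------------------------------------
# cross-product precomputation

def _prep(design: DesignMatrices, spec: VarianceSpec) -> dict:
    key = (spec.residual, spec.ar1)
    if key in design._cache:
        return design._cache[key]
    W = np.column_stack([design.X, design.Z, design.y])
    prep: dict = {"pq": design.X.shape[1] + design.Z.shape[1], "n": design.n_obs}
    if spec.residual == "weighted":
        w = design.weights if design.weights is not None else np.ones(design.n_obs)
        prep["A"] = (W * w[:, None]).T @ W
        prep["sumlogw"] = float(np.sum(np.log(w)))
    else:
        if design.time_index is None:
            raise REMLError("design lacks hour indices for het_hour residuals")
        A_t, n_t = [], []
        for t in range(len(design.hours)):
            rows = np.flatnonzero(design.time_index == t)
            Wt = W[rows]
            A_t.append(Wt.T @ Wt)
            n_t.append(len(rows))
        prep["A_t"], prep["n_t"] = A_t, np.array(n_t)
        if spec.ar1:
            classes: dict = {}
            for block in design.animal_blocks:
                for idx in range(len(block) - 1):
                    ra, rb = block[idx], block[idx + 1]
                    ckey = (int(design.time_index[ra]), int(design.time_index[rb]))
                    classes.setdefault(ckey, [[], []])
                    classes[ckey][0].append(ra)
                    classes[ckey][1].append(rb)
            cls = []
            for (ta, tb), (rows_a, rows_b) in sorted(classes.items()):
                Wa, Wb = W[rows_a], W[rows_b]
                cls.append({
                    "ta": ta, "tb": tb, "lag": tb - ta, "m": len(rows_a),
                    "Saa": Wa.T @ Wa, "Sbb": Wb.T @ Wb,
                    "Sab": Wa.T @ Wb + Wb.T @ Wa,
                })
            prep["classes"] = cls
    design._cache[key] = prep
    return prep


def _assemble(vm: VarianceModel, design: DesignMatrices, spec: VarianceSpec,
              prep: dict) -> tuple[np.ndarray, float]:
    """(M, logdetR) where M = [X Z y]' R^-1 [X Z y]."""
    if spec.residual == "weighted":
        s2e = float(vm.sigma2_e)
        M = prep["A"] / s2e
        logdetR = prep["n"] * np.log(s2e) - prep["sumlogw"]
        return M, logdetR
    s2t = np.asarray(vm.sigma2_e, dtype=float)
    M = sum(A / s2 for A, s2 in zip(prep["A_t"], s2t))
    logdetR = float(np.sum(prep["n_t"] * np.log(s2t)))
    if spec.ar1:
        rho = vm.rho
        sig = np.sqrt(s2t)
        for c in prep["classes"]:
            r = rho ** c["lag"]
            one_m = 1.0 - r * r
            f = r * r / one_m
            g = r / one_m
            M = M + f * (c["Saa"] / s2t[c["ta"]] + c["Sbb"] / s2t[c["tb"]]) \
                  - g * c["Sab"] / (sig[c["ta"]] * sig[c["tb"]])
            logdetR += c["m"] * np.log(one_m)
    return M, logdetR


def _ginv_logdet(vm: VarianceModel, design: DesignMatrices):
    """Block-diagonal G^-1 (q x q) and log|G|; None if q == 0."""
    q = design.Z.shape[1]
    if q == 0:
        return None, 0.0
    Ginv = np.zeros((q, q))
    logdetG = 0.0
    k = 0
    if design.n_batch:
        Ginv[np.arange(design.n_batch), np.arange(design.n_batch)] = 1.0 / vm.sigma2_batch
        logdetG += design.n_batch * np.log(vm.sigma2_batch)
        k = design.n_batch
    if design.has_sire:
        nb = design.sire_block_size
        sign, ld = np.linalg.slogdet(vm.S)
        if sign <= 0:
            raise REMLError("sire covariance not positive definite")
        Sinv = np.linalg.inv(vm.S)
        for _ in range(design.n_sires):
            Ginv[k:k + nb, k:k + nb] = Sinv
            k += nb
        logdetG += design.n_sires * ld
    return Ginv, logdetG


def _core(vm: VarianceModel, design: DesignMatrices, spec: VarianceSpec):
    """Returns (negloglik, chol_C, sol, p, q) on the design's own scale."""
    prep = _prep(design, spec)
    M, logdetR = _assemble(vm, design, spec, prep)
    p = design.X.shape[1]
    q = design.Z.shape[1]
    Ginv, logdetG = _ginv_logdet(vm, design)
    C = M[:-1, :-1].copy()
    if q:
        C[p:, p:] += Ginv
    rhs = M[:-1, -1]
    yRiy = M[-1, -1]
    cho = linalg.cho_factor(C, lower=True, check_finite=False)
    logdetC = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    sol = linalg.cho_solve(cho, rhs, check_finite=False)
    yPy = float(yRiy - rhs @ sol)
    negll = 0.5 * (logdetR + logdetG + logdetC + yPy)
    return negll, cho, sol, p, q


def reml_neg_loglik(theta, design: DesignMatrices,
                    spec: VarianceSpec | None = None) -> float:
    """Negative restricted log-likelihood at unconstrained parameters
    ``theta``. Invalid or numerically singular points return a large
    penalized value (logged at debug level)."""
    if spec is None:
        spec = default_spec(design)
    try:
        vm = natural_to_varmodel(untransform(theta, design, spec), design, spec)
        negll = _core(vm, design, spec)[0]
        if not np.isfinite(negll):
            raise REMLError("non-finite likelihood")
        return float(negll)
    except (np.linalg.LinAlgError, linalg.LinAlgError, REMLError, ValueError) as exc:
        log.debug("penalized likelihood point: %s", exc)
        return _PENALTY + float(np.sum(np.square(theta)))


@dataclass
class REMLFit:
    varmodel: VarianceModel
    beta_hat: np.ndarray
    x_names: list
    blup_batch: np.ndarray
    blup_sire: np.ndarray          # (n_sires, block) matrix
    logL_reml: float
    vcov_theta: np.ndarray         # natural-scale covariance of variance params
    theta_names: list
    natural: np.ndarray            # natural-scale variance parameter vector
    fixed_cov: np.ndarray          # (X' V^-1 X)^-1
    converged: bool
    grad_norm: float
    n_obs: int
    n_params: int                  # number of variance parameters
    design: DesignMatrices = field(repr=False, default=None)
    spec: VarianceSpec = None

    @property
    def sigma2_sire(self) -> float:
        return self.varmodel.sigma2_sire


def _fd_gradient(fun, x, h=1e-5):
    g = np.zeros_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x); e[i] = h
        g[i] = (fun(x + e) - fun(x - e)) / (2 * h)
    return g


def _fd_hessian(fun, x, h=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i + 1):
            ei = np.zeros_like(x); ei[i] = h
            ej = np.zeros_like(x); ej[j] = h
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej)
                    - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * h ** 2)
    return H


def _start_values(design: DesignMatrices, spec: VarianceSpec) -> np.ndarray:
    """Heuristic start on the standardized (unit-variance) response scale."""
    vals = []
    if design.has_sire:
        nb = design.sire_block_size
        S0 = 0.2 * np.eye(nb)
        vals.extend(S0[i, j] for i in range(nb) for j in range(i + 1))
    if design.n_batch:
        vals.append(0.15)
    if spec.residual == "weighted":
        vals.append(0.7)
    else:
        y, ti = design.y, design.time_index
        sd = float(np.std(y)) or 1.0
        for t in range(len(design.hours)):
            vt = float(np.var(y[ti == t] / sd))
            vals.append(max(0.5 * vt, 1e-4))
    if spec.ar1:
        vals.append(0.3)
    return np.array(vals)


def fit_reml(design: DesignMatrices, spec: VarianceSpec | None = None,
             start: np.ndarray | None = None, tol: float = 1e-3,
             polish: bool = True, multi_start: int = 0,
             seed: int = 0, maxiter: int = 500) -> REMLFit:
    """Maximize the restricted likelihood over the variance parameters.

    ``start`` (optional) is a natural-scale parameter vector (same layout
    as :func:`natural_names`) used as a warm start — handy for bootstrap
    replicates. ``multi_start`` adds that many random restarts.
    Convergence is declared when the finite-difference gradient sup-norm
    on the unconstrained scale falls below ``tol``.
    """
    if spec is None:
        spec = default_spec(design)
    sd = float(np.std(design.y))
    if sd <= 0:
        raise REMLError("response has zero variance")
    dstd = design.replace_y(design.y / sd)

    def obj(theta):
        return reml_neg_loglik(theta, dstd, spec)

    if start is not None:
        nat0 = np.asarray(start, dtype=float).copy()
        # scale variances (all natural params except rho) to the std scale
        names = natural_names(design, spec)
        for i, nm in enumerate(names):
            if nm != "rho":
                nat0[i] = nat0[i] / sd ** 2
        theta0 = transform(nat0, design, spec)
    else:
        theta0 = transform(_start_values(dstd, spec), design, spec)

    k = len(theta0)
    bounds = []
    names = natural_names(design, spec)
    for nm in names:
        if nm == "rho":
            bounds.append((-_RHO_BOUND, _RHO_BOUND))
        elif nm.startswith("S[") and nm[2] != nm[4]:
            bounds.append((-np.exp(_BOUND / 2), np.exp(_BOUND / 2)))
        else:
            bounds.append((-_BOUND, _BOUND))
    # off-diagonal Cholesky entries are unbounded in principle; keep finite
    starts = [np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])]
    rng = np.random.default_rng(seed)
    for _ in range(multi_start):
        starts.append(np.clip(theta0 + rng.normal(0, 1.0, k),
                              [b[0] for b in bounds], [b[1] for b in bounds]))

    best = None
    for th0 in starts:
        res = optimize.minimize(obj, th0, method="L-BFGS-B", jac="3-point",
                                bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-13,
                                         "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    if polish:
        res = optimize.minimize(obj, theta, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-13,
                                         "maxfev": 400 * k, "maxiter": 400 * k})
        if res.fun <= best.fun:
            theta = res.x

    grad = _fd_gradient(obj, theta)
    converged = bool(np.max(np.abs(grad)) < tol)
    if not converged:
        log.warning("REML fit did not meet gradient tolerance: |g|=%.3g",
                    float(np.max(np.abs(grad))))

    # solution on the standardized scale
    nat_std = untransform(theta, design, spec)
    vm_std = natural_to_varmodel(nat_std, design, spec)
    negll_std, cho, sol, p, q = _core(vm_std, dstd, spec)
    beta_std = sol[:p]
    u_std = sol[p:]
    Cinv = linalg.cho_solve(cho, np.eye(p + q), check_finite=False)
    fixed_cov = Cinv[:p, :p] * sd ** 2

    # curvature -> natural-scale covariance
    H = _fd_hessian(obj, theta)
    try:
        vcov_trans = np.linalg.pinv(0.5 * (H + H.T))
    except np.linalg.LinAlgError:
        vcov_trans = np.full((k, k), np.nan)
    # Jacobian of (unstandardized natural) wrt transformed params
    scale_vec = np.array([1.0 if nm == "rho" else sd ** 2 for nm in names])
    J = np.zeros((k, k))
    h = 1e-6
    for i in range(k):
        e = np.zeros(k); e[i] = h
        J[:, i] = (untransform(theta + e, design, spec)
                   - untransform(theta - e, design, spec)) / (2 * h)
    J = scale_vec[:, None] * J
    vcov_nat = J @ vcov_trans @ J.T
    vcov_nat = 0.5 * (vcov_nat + vcov_nat.T)

    natural = nat_std * scale_vec
    vm = natural_to_varmodel(natural, design, spec)
    n, pX = design.n_obs, p
    logL = -(negll_std + 0.5 * (n - pX) * np.log(sd ** 2))

    blup_batch = u_std[:design.n_batch] * sd
    nb = design.sire_block_size if design.has_sire else 1
    blup_sire = (u_std[design.n_batch:] * sd).reshape(design.n_sires, nb) \
        if design.has_sire else np.zeros((0, nb))

    return REMLFit(varmodel=vm, beta_hat=beta_std * sd, x_names=design.x_names,
                   blup_batch=blup_batch, blup_sire=blup_sire,
                   logL_reml=float(logL), vcov_theta=vcov_nat,
                   theta_names=names, natural=natural, fixed_cov=fixed_cov,
                   converged=converged, grad_norm=float(np.max(np.abs(grad))),
                   n_obs=n, n_params=k, design=design, spec=spec)


def wald_test(fit: REMLFit, factor: str) -> tuple[float, int, float]:
    """Wald chi-square test that all contrast coefficients of ``factor``
    (e.g. 'sex', 'breed') are zero."""
    idx = fit.design.x_groups.get(factor)
    if not idx:
        raise ValueError(f"no contrast columns for factor {factor!r}")
    b = fit.beta_hat[idx]
    V = fit.fixed_cov[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return stat, df, float(stats.chi2.sf(stat, df))


def likelihood_ratio_test(fit_reduced: REMLFit, fit_full: REMLFit,
                          boundary: bool = False,
                          tol: float = 1e-3) -> tuple[float, int, float]:
    """LRT between nested variance structures fitted to the same data.

    ``boundary=True`` applies the 1/2 chi2_{df-1} + 1/2 chi2_df mixture
    appropriate when the reduced model pins variance components to the
    boundary of the parameter space.
    """
    stat = 2.0 * (fit_full.logL_reml - fit_reduced.logL_reml)
    df = fit_full.n_params - fit_reduced.n_params
    if df <= 0:
        raise ValueError("full model must have more variance parameters")
    if stat < -tol:
        raise REMLError(
            f"negative LRT statistic ({stat:.4g}): optimizer failure, refit "
            "with multi_start or tighter tolerances"
        )
    stat = max(stat, 0.0)
    if stat == 0.0:
        return 0.0, df, 1.0
    if boundary:
        p_hi = stats.chi2.sf(stat, df)
        p_lo = stats.chi2.sf(stat, df - 1) if df > 1 else 0.0
        p = 0.5 * (p_hi + p_lo)
    else:
        p = stats.chi2.sf(stat, df)
    return float(stat), df, float(p)


def simulate_response(design: DesignMatrices, vm: VarianceModel,
                      beta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw a response vector from the mixed model implied by ``vm`` on
    this design (used by the parametric bootstrap and calibration
    experiments)."""
    n = design.n_obs
    y = design.X @ np.asarray(beta, dtype=float)
    k = 0
    u = np.zeros(design.Z.shape[1])
    if design.n_batch:
        u[:design.n_batch] = rng.normal(0, np.sqrt(vm.sigma2_batch), design.n_batch)
        k = design.n_batch
    if design.has_sire:
        nb = design.sire_block_size
        L = np.linalg.cholesky(vm.S + 1e-12 * np.eye(nb))
        devs = rng.normal(size=(design.n_sires, nb)) @ L.T
        u[k:] = devs.ravel()
    if design.Z.shape[1]:
        y = y + design.Z @ u

    spec = vm.spec
    if spec.residual == "weighted":
        w = design.weights if design.weights is not None else np.ones(n)
        e = rng.normal(0, np.sqrt(float(vm.sigma2_e) / w))
    else:
        s2t = np.asarray(vm.sigma2_e, dtype=float)
        sig = np.sqrt(s2t[design.time_index])
        if not spec.ar1 or vm.rho == 0:
            e = rng.normal(0, sig)
        else:
            e = np.empty(n)
            rho = vm.rho
            for block in design.animal_blocks:
                z = np.empty(len(block))
                z[0] = rng.normal()
                for i in range(1, len(block)):
                    lag = design.time_index[block[i]] - design.time_index[block[i - 1]]
                    r = rho ** lag
                    z[i] = r * z[i - 1] + np.sqrt(1 - r * r) * rng.normal()
                e[block] = sig[block] * z
    return y + e
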
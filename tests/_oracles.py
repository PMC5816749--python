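"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and kept independent of the
package's computational paths: dense-matrix restricted likelihood,
closed-form ANOVA variance components, and hand-rolled regression.
"""

import numpy as np


def dense_reml_negll(vm, design, spec) -> float:
    """Brute-force dense evaluation of the restricted likelihood
    -logL = 1/2 [log|V| + log|X'V^-1X| + y'Py] with V assembled entry by
    entry from the variance model."""
    n = design.n_obs
    X, Z, y = design.X, design.Z, design.y
    V = np.zeros((n, n))
    k = 0
    if design.n_batch:
        Zb = Z[:, : design.n_batch]
        V += vm.sigma2_batch * Zb @ Zb.T
        k = design.n_batch
    if design.has_sire:
        G = np.kron(np.eye(design.n_sires), vm.S)
        Zs = Z[:, k:]
        V += Zs @ G @ Zs.T
    if spec.residual == "weighted":
        w = design.weights if design.weights is not None else np.ones(n)
        V += np.diag(float(vm.sigma2_e) / w)
    else:
        s2t = np.asarray(vm.sigma2_e, dtype=float)
        sd = np.sqrt(s2t[design.time_index])
        if spec.ar1:
            for block in design.animal_blocks:
                pos = design.time_index[block]
                C = vm.rho ** np.abs(pos[:, None] - pos[None, :])
                V[np.ix_(block, block)] += sd[block][:, None] * C * sd[block][None, :]
        else:
            V[np.diag_indices(n)] += s2t[design.time_index]
    Vi = np.linalg.inv(V)
    _, ldV = np.linalg.slogdet(V)
    XtViX = X.T @ Vi @ X
    _, ldX = np.linalg.slogdet(XtViX)
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    return 0.5 * (ldV + ldX + y @ P @ y)


def anova_sire_variance(y, sire_idx, n_progeny) -> tuple[float, float]:
    """Balanced one-way ANOVA estimators: (sigma2_sire, sigma2_e)."""
    y = np.asarray(y, dtype=float)
    sires = np.unique(sire_idx)
    means = np.array([y[sire_idx == s].mean() for s in sires])
    msb = n_progeny * means.var(ddof=1)
    ssw = sum(((y[sire_idx == s] - y[sire_idx == s].mean()) ** 2).sum()
              for s in sires)
    msw = ssw / (len(y) - len(sires))
    return max(0.0, (msb - msw) / n_progeny), msw


def least_squares_loglinear(t, c) -> tuple[float, float, float]:
    """Plain normal-equation regression of log c on t: (slope, icpt, r2)."""
    t = np.asarray(t, dtype=float)
    ylog = np.log(np.asarray(c, dtype=float))
    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, ylog, rcond=None)
    fitted = A @ coef
    ss_res = np.sum((ylog - fitted) ** 2)
    ss_tot = np.sum((ylog - ylog.mean()) ** 2)
    return coef[0], coef[1], 1.0 - ss_res / ss_tot
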
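"""Independent convex-solver oracle for the graphical lasso used in tests.

Accelerated proximal gradient (FISTA) with backtracking on the primal
objective tr(S O) - log det(O) + lam * sum_{i!=j} |O_ij|.  A completely
different algorithm family from the package's ADMM splitting solver, so
agreement between the two is a genuine cross-check.  Only suitable for the
small problems used in tests.
"""

import numpy as np


def _soft_offdiag(A, t):
    out = np.sign(A) * np.maximum(np.abs(A) - t, 0.0)
    np.fill_diagonal(out, np.diag(A))
    return out


def _smooth(omega, S):
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return np.inf
    return float(np.trace(S @ omega)) - logdet


def fista_glasso(S, lam, max_iter=50_000, tol=1e-12):
    """Minimize the glasso objective by FISTA with backtracking line search."""
    p = S.shape[0]
    omega = np.linalg.inv(S + 0.1 * np.eye(p))
    y = omega.copy()
    t_mom = 1.0
    step = 1.0
    f_prev = None
    for _ in range(max_iter):
        grad = S - np.linalg.inv(y)
        fy = _smooth(y, S)
        while True:
            candidate = _soft_offdiag(y - step * grad, step * lam)
            fc = _smooth(candidate, S)
            if not np.isfinite(fc):
                step *= 0.5
                continue
            diff = candidate - y
            quad = fy + float(np.sum(grad * diff)) + float(np.sum(diff * diff)) / (2 * step)
            if fc <= quad + 1e-15:
                break
            step *= 0.5
        t_next = (1 + np.sqrt(1 + 4 * t_mom**2)) / 2
        y = candidate + ((t_mom - 1) / t_next) * (candidate - omega)
        # restart momentum if it points uphill
        if np.sum((candidate - omega) * grad) > 0:
            y = candidate
            t_next = 1.0
        omega_prev, omega = omega, candidate
        t_mom = t_next
        f = fc + lam * (np.abs(candidate).sum() - np.abs(np.diag(candidate)).sum())
        if f_prev is not None and abs(f_prev - f) < tol * max(1.0, abs(f)):
            if np.max(np.abs(omega - omega_prev)) < 1e-9:
                break
        f_prev = f
        step *= 1.5  # allow the step to grow back after backtracking
    return omega
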
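"""Independent reference MBAR solver used only as a test oracle.

Minimizes the convex multistate log-likelihood in the dimensionless free
energies with scipy's trust-region Newton method — a completely separate
code path from the package's self-consistent/Newton iteration.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def reference_free_energies(u_kn, n_k, tol=1e-13):
    """Return dimensionless free energies f_k anchored at f_0 = 0."""
    u_kn = np.asarray(u_kn, dtype=float)
    n_k = np.asarray(n_k, dtype=float)
    k_states, n_total = u_kn.shape

    def unpack(x):
        return np.concatenate([[0.0], x])

    def value(x):
        f = unpack(x)
        # (1/N) sum_n ln sum_k N_k exp(f_k - u_kn) - sum_k (N_k/N) f_k
        ln_d = logsumexp(f[None, :] - u_kn.T, b=n_k[None, :], axis=1)
        return float(np.sum(ln_d) / n_total - np.dot(n_k, f) / n_total)

    def weights(x):
        f = unpack(x)
        ln_d = logsumexp(f[None, :] - u_kn.T, b=n_k[None, :], axis=1)
        return np.exp(f[None, :] - u_kn.T - ln_d[:, None])  # (N, K)

    def grad(x):
        w = weights(x)
        g = n_k * (w.sum(axis=0) - 1.0) / n_total
        return g[1:]

    def hess(x):
        w = weights(x)
        wn = w * n_k[None, :]
        h = (np.diag(n_k * w.sum(axis=0)) - wn.T @ wn) / n_total
        return h[1:, 1:]

    x0 = np.zeros(k_states - 1)
    res = minimize(
        value, x0, jac=grad, hess=hess, method="trust-ncg",
        options={"gtol": tol, "maxiter": 2000},
    )
    f = unpack(res.x)
    return f - f[0]
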
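"""Independent fixed-grid oracles used to cross-check the adaptive quadrature.

Deliberately dumb: plain trapezoid sums over dense uniform grids, written
directly from the kernel definitions, sharing no code with iedose.ied.
"""

import numpy as np


def _f(x):
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    return 1.0 - 0.5 ** (x * x)


def _g(x):
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    return 2.0 * np.log(2.0) * x * 0.5 ** (x * x)


def theta_matrix_trapezoid(times, t_d, t_ir, n_points=100_000, tail_factor=20.0):
    """Θ by trapezoid quadrature: n_points per window, improper last window
    truncated at T_N + tail_factor * T_D."""
    times = np.asarray(times, dtype=float)
    n = len(times)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if j == n - 1:
                t = np.linspace(times[-1], times[-1] + tail_factor * t_d, n_points)
                y = _g((t - times[i]) / t_d) / t_d  # activation factor -> 1
            else:
                t = np.linspace(times[j], times[j + 1], n_points)
                y = _g((t - times[i]) / t_d) / t_d * _f((times[j + 1] - t) / t_ir)
            mat[i, j] = np.trapezoid(y, t)
    return mat


def efficacy_brute(times, doses, alpha, alpha_beta, t_d, t_ir, n_points=100_000):
    """IED efficacy from the trapezoid Θ and explicit S/K products."""
    doses = np.asarray(doses, dtype=float)
    beta = alpha / alpha_beta
    kill = 1.0 - np.exp(-alpha * doses - beta * doses**2)
    survive = np.concatenate(([1.0], np.cumprod(1.0 - kill[:-1])))
    theta = theta_matrix_trapezoid(times, t_d, t_ir, n_points)
    return float(np.sum(survive * theta.sum(axis=1) * kill))
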
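"""Independent brute-force reference implementations used by the tests.

These evaluate the SPH pair sums by direct all-pairs loops over plain
numpy, entirely separate from the solver's KD-tree + numba path, so each
production routine has an independent oracle to agree with.
"""

from __future__ import annotations

import numpy as np

from reefsph.kernel import KernelSpec, wendland_gradient, wendland_value


def brute_neighbors(x: np.ndarray, cutoff: float, period_x=None):
    """All-pairs neighbour sets within cutoff (excluding self)."""
    n = x.shape[0]
    out = []
    for i in range(n):
        nbrs = []
        for j in range(n):
            if i == j:
                continue
            d = x[i] - x[j]
            if period_x is not None:
                d[0] -= period_x * round(d[0] / period_x)
            if np.hypot(d[0], d[1]) <= cutoff:
                nbrs.append(j)
        out.append(sorted(nbrs))
    return out


def brute_continuity(x, v, m, spec: KernelSpec):
    """d(rho_i)/dt = sum_j m_j (v_i - v_j) . grad_i W_ij, all pairs."""
    n = x.shape[0]
    drho = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            grad = wendland_gradient(x[i] - x[j], spec)
            drho[i] += m[j] * np.dot(v[i] - v[j], grad)
    return drho


def brute_momentum(x, v, rho, p, m, mu, spec: KernelSpec, body_force=(0.0, 0.0)):
    """Symmetric pressure gradient + Morris viscosity + body force, all pairs."""
    n = x.shape[0]
    acc = np.zeros((n, 2))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rij_vec = x[i] - x[j]
            rij = np.hypot(rij_vec[0], rij_vec[1])
            grad = wendland_gradient(rij_vec, spec)
            acc[i] += -m[j] * (p[j] / rho[j] ** 2 + p[i] / rho[i] ** 2) * grad
            if rij > 0 and rij < spec.support_radius:
                # (1/r) dW/dr recovered from the gradient: grad = (dW/dr) rhat
                dwdr_over_r = np.dot(grad, rij_vec) / rij**2
                acc[i] += (m[j] * (mu + mu) / (rho[i] * rho[j])
                           * dwdr_over_r * (v[i] - v[j]))
        acc[i] += np.asarray(body_force) / rho[i]
    return acc


def brute_smoothed_density(x, rho, m, spec: KernelSpec, epsilon: float):
    """rho_i - eps * sum_j m_j (rho_i - rho_j) W_ij / (0.5 (rho_i + rho_j))."""
    n = x.shape[0]
    out = rho.astype(float).copy()
    for i in range(n):
        corr = 0.0
        for j in range(n):
            if i == j:
                continue
            w = wendland_value(x[i] - x[j], spec)
            corr += m[j] * (rho[i] - rho[j]) * w / (0.5 * (rho[i] + rho[j]))
        out[i] -= epsilon * corr
    return out
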
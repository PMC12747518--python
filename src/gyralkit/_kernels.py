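"""Numba kernels for the explicit growth relaxation.

Per-tet neo-Hookean forces with multiplicative growth and a vertex-pair
self-contact penalty.  Everything here is the exact analytic gradient of
the energy it reports (verified against finite differences in the test
suite), so the relaxation loop can trust its force residuals.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _inv3(a, out):
    d = (
        a[0, 0] * (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1])
        - a[0, 1] * (a[1, 0] * a[2, 2] - a[1, 2] * a[2, 0])
        + a[0, 2] * (a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0])
    )
    out[0, 0] = (a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1]) / d
    out[0, 1] = (a[0, 2] * a[2, 1] - a[0, 1] * a[2, 2]) / d
    out[0, 2] = (a[0, 1] * a[1, 2] - a[0, 2] * a[1, 1]) / d
    out[1, 0] = (a[1, 2] * a[2, 0] - a[1, 0] * a[2, 2]) / d
    out[1, 1] = (a[0, 0] * a[2, 2] - a[0, 2] * a[2, 0]) / d
    out[1, 2] = (a[0, 2] * a[1, 0] - a[0, 0] * a[1, 2]) / d
    out[2, 0] = (a[1, 0] * a[2, 1] - a[1, 1] * a[2, 0]) / d
    out[2, 1] = (a[0, 1] * a[2, 0] - a[0, 0] * a[2, 1]) / d
    out[2, 2] = (a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]) / d
    return d


@njit(cache=True, fastmath=True)
def elastic_energy_forces(x, tets, Dm_inv, vol0, Ginv, mu, kbulk, forces):
    """Neo-Hookean elastic energy and its exact negative gradient.

    W = mu/2 (J_A^{-2/3} tr(A^T A) - 3) + K/2 (J_A - 1)^2 per unit
    reference volume, with A = F G^{-1}.  Returns (energy, min det F).
    ``forces`` is accumulated in place (caller zeroes it).
    """
    n_tet = tets.shape[0]
    energy = 0.0
    min_detF = 1e300
    F = np.empty((3, 3))
    A = np.empty((3, 3))
    Ainv = np.empty((3, 3))
    P = np.empty((3, 3))
    Hc = np.empty((3, 3))
    for e in range(n_tet):
        i0, i1, i2, i3 = tets[e, 0], tets[e, 1], tets[e, 2], tets[e, 3]
        # Ds columns are edge vectors; F = Ds * Dm_inv
        for r in range(3):
            d1 = x[i1, r] - x[i0, r]
            d2 = x[i2, r] - x[i0, r]
            d3 = x[i3, r] - x[i0, r]
            for c in range(3):
                F[r, c] = (
                    d1 * Dm_inv[e, 0, c] + d2 * Dm_inv[e, 1, c] + d3 * Dm_inv[e, 2, c]
                )
        detF = (
            F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
            - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
            + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0])
        )
        if detF < min_detF:
            min_detF = detF
        for r in range(3):
            for c in range(3):
                A[r, c] = (
                    F[r, 0] * Ginv[e, 0, c]
                    + F[r, 1] * Ginv[e, 1, c]
                    + F[r, 2] * Ginv[e, 2, c]
                )
        J = _inv3(A, Ainv)
        if J <= 0.0:
            # inverted element: signal with negative detF, no force update
            if detF > 0.0:
                min_detF = -1e-300
            continue
        I1 = 0.0
        for r in range(3):
            for c in range(3):
                I1 += A[r, c] * A[r, c]
        Jm23 = J ** (-2.0 / 3.0)
        m = mu[e]
        kb = kbulk[e]
        energy += vol0[e] * (
            0.5 * m * (Jm23 * I1 - 3.0) + 0.5 * kb * (J - 1.0) * (J - 1.0)
        )
        # dW/dA = mu J^{-2/3} (A - I1/3 A^{-T}) + K (J-1) J A^{-T}
        coefA = m * Jm23
        coefAinvT = -m * Jm23 * I1 / 3.0 + kb * (J - 1.0) * J
        # P = dW/dF = dW/dA * Ginv^T ; Ginv symmetric so no transpose needed
        for r in range(3):
            for c in range(3):
                dWdA = coefA * A[r, c] + coefAinvT * Ainv[c, r]
                P[r, c] = dWdA
        for r in range(3):
            for c in range(3):
                s = 0.0
                for k in range(3):
                    s += P[r, k] * Ginv[e, c, k]
                Hc[r, c] = s
        # nodal forces: f_a = -vol0 * P_total * (Dm_inv row a), a = 1..3
        for a in range(3):
            fx = -vol0[e] * (
                Hc[0, 0] * Dm_inv[e, a, 0]
                + Hc[0, 1] * Dm_inv[e, a, 1]
                + Hc[0, 2] * Dm_inv[e, a, 2]
            )
            fy = -vol0[e] * (
                Hc[1, 0] * Dm_inv[e, a, 0]
                + Hc[1, 1] * Dm_inv[e, a, 1]
                + Hc[1, 2] * Dm_inv[e, a, 2]
            )
            fz = -vol0[e] * (
                Hc[2, 0] * Dm_inv[e, a, 0]
                + Hc[2, 1] * Dm_inv[e, a, 1]
                + Hc[2, 2] * Dm_inv[e, a, 2]
            )
            idx = tets[e, a + 1]
            forces[idx, 0] += fx
            forces[idx, 1] += fy
            forces[idx, 2] += fz
            forces[i0, 0] -= fx
            forces[i0, 1] -= fy
            forces[i0, 2] -= fz
    return energy, min_detF


@njit(cache=True, fastmath=True)
def contact_energy_forces(x, pairs, contact_range, stiffness, forces):
    """Quadratic vertex-pair proximity penalty.

    E = sum_{pairs closer than contact_range} k/2 (r_c - dist)^2,
    accumulated into ``forces`` (exact gradient).
    """
    energy = 0.0
    rc = contact_range
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = x[i, 0] - x[j, 0]
        dy = x[i, 1] - x[j, 1]
        dz = x[i, 2] - x[j, 2]
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        if dist >= rc or dist <= 1e-14:
            continue
        pen = rc - dist
        energy += 0.5 * stiffness * pen * pen
        coef = stiffness * pen / dist
        forces[i, 0] += coef * dx
        forces[i, 1] += coef * dy
        forces[i, 2] += coef * dz
        forces[j, 0] -= coef * dx
        forces[j, 1] -= coef * dy
        forces[j, 2] -= coef * dz
    return energy
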
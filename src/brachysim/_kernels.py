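"""Fused assembly kernels (numba-accelerated when available).

The explicit solver spends essentially all of its time in the per-step
internal-force assembly: gather nodal displacements, form F at each
integration point, evaluate the Neo-Hookean first Piola-Kirchhoff stress and
scatter back to nodal forces. The fused single-pass kernel below avoids the
intermediate (m, 3, 3) temporaries of the vectorised numpy path; the numpy
path remains as a reference and fallback.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def _internal_force_kernel(indptr, indices, gx, gy, gz, w, mu, kappa, u, f):
    """Assemble nodal internal forces; returns (min det F, argmin ip)."""
    m = w.shape[0]
    det_min = 1e30
    det_arg = -1
    for i in range(m):
        F00 = 1.0; F01 = 0.0; F02 = 0.0
        F10 = 0.0; F11 = 1.0; F12 = 0.0
        F20 = 0.0; F21 = 0.0; F22 = 1.0
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            a0 = u[j, 0]; a1 = u[j, 1]; a2 = u[j, 2]
            bx = gx[k]; by = gy[k]; bz = gz[k]
            F00 += a0 * bx; F01 += a0 * by; F02 += a0 * bz
            F10 += a1 * bx; F11 += a1 * by; F12 += a1 * bz
            F20 += a2 * bx; F21 += a2 * by; F22 += a2 * bz
        c00 = F11 * F22 - F12 * F21
        c01 = F12 * F20 - F10 * F22
        c02 = F10 * F21 - F11 * F20
        J = F00 * c00 + F01 * c01 + F02 * c02
        if J < det_min:
            det_min = J
            det_arg = i
        if J <= 0.0:
            continue
        # cofactors (adjugate^T) for F^{-T} = cof(F)/J
        c10 = F02 * F21 - F01 * F22
        c11 = F00 * F22 - F02 * F20
        c12 = F01 * F20 - F00 * F21
        c20 = F01 * F12 - F02 * F11
        c21 = F02 * F10 - F00 * F12
        c22 = F00 * F11 - F01 * F10
        I1 = (F00 * F00 + F01 * F01 + F02 * F02 +
              F10 * F10 + F11 * F11 + F12 * F12 +
              F20 * F20 + F21 * F21 + F22 * F22)
        a = mu[i] * J ** (-2.0 / 3.0)
        b = kappa[i] * J * (J - 1.0) - a * I1 / 3.0
        bj = b / J
        P00 = a * F00 + bj * c00; P01 = a * F01 + bj * c01; P02 = a * F02 + bj * c02
        P10 = a * F10 + bj * c10; P11 = a * F11 + bj * c11; P12 = a * F12 + bj * c12
        P20 = a * F20 + bj * c20; P21 = a * F21 + bj * c21; P22 = a * F22 + bj * c22
        wi = w[i]
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            bx = wi * gx[k]; by = wi * gy[k]; bz = wi * gz[k]
            f[j, 0] += P00 * bx + P01 * by + P02 * bz
            f[j, 1] += P10 * bx + P11 * by + P12 * bz
            f[j, 2] += P20 * bx + P21 * by + P22 * bz
    return det_min, det_arg


@njit(cache=True, fastmath=True)
def _relax_window_kernel(indptr, indices, gx, gy, gz, w, mu, kappa,
                         u, v, masses, dt, alpha, nsteps,
                         fixed, pidx, pstart, ptarget, pmask,
                         it0, ramp_steps):
    """Run ``nsteps`` damped central-difference steps in place.

    Prescribed targets are ramped linearly from ``pstart`` to ``ptarget``
    over the first ``ramp_steps`` global iterations (``it0`` = iterations
    already done). Returns (steps_done, det_min, det_arg); det_min <= 0
    signals an inverted integration point, with the state left at the step
    where it occurred.
    """
    n = u.shape[0]
    f = np.zeros((n, 3))
    c = 0.5 * alpha * dt
    for j in range(nsteps):
        f[:] = 0.0
        det_min, det_arg = _internal_force_kernel(indptr, indices, gx, gy, gz,
                                                  w, mu, kappa, u, f)
        if det_min <= 0.0:
            return j, det_min, det_arg
        for i in range(n):
            mi = masses[i]
            for a in range(3):
                v[i, a] = (v[i, a] * (1.0 - c) - dt * f[i, a] / mi) / (1.0 + c)
                u[i, a] += dt * v[i, a]
        for k in range(fixed.shape[0]):
            i = fixed[k]
            u[i, 0] = 0.0; u[i, 1] = 0.0; u[i, 2] = 0.0
            v[i, 0] = 0.0; v[i, 1] = 0.0; v[i, 2] = 0.0
        if pidx.shape[0] > 0:
            frac = 1.0
            if ramp_steps > 0:
                frac = (it0 + j + 1.0) / ramp_steps
                if frac > 1.0:
                    frac = 1.0
            for k in range(pidx.shape[0]):
                i = pidx[k]
                for a in range(3):
                    if pmask[k, a]:
                        u[i, a] = pstart[k, a] + frac * (ptarget[k, a] - pstart[k, a])
                        v[i, a] = 0.0
    return nsteps, 1.0, -1
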
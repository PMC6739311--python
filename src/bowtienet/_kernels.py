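"""Numba-compiled inner loops for the dynamics modules.

Kept separate so the public modules stay importable and readable; every
kernel operates on plain CSR arrays (``indptr``/``indices`` of
in-neighbors) and preallocated output buffers.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True, fastmath=True)
def kuramoto_rhs(theta, omega, coupling, indptr, in_nbrs, out):
    n = theta.size
    for i in range(n):
        acc = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            acc += np.sin(theta[in_nbrs[k]] - theta[i])
        out[i] = omega[i] + coupling * acc
    return out


@numba.njit(cache=True, fastmath=True)
def kuramoto_rk4(
    theta,
    omega,
    coupling,
    indptr,
    in_nbrs,
    dt,
    n_steps,
    sample_stride,
    sub_indptr,
    sub_nodes,
    re_out,
    im_out,
    zre_out,
    zim_out,
):
    """Fixed-step RK4 for the phase equations, sampling subset order
    parameters every ``sample_stride`` steps (0 disables sampling).

    ``re_out``/``im_out`` are (n_subsets, n_samples) accumulators of the
    subset-mean phasor; ``zre_out``/``zim_out`` hold the full-network
    mean phasor.  Returns the number of samples written.
    """
    n = theta.size
    n_subsets = sub_indptr.size - 1
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    n_samples = 0
    for step in range(n_steps):
        kuramoto_rhs(theta, omega, coupling, indptr, in_nbrs, k1)
        for i in range(n):
            tmp[i] = theta[i] + 0.5 * dt * k1[i]
        kuramoto_rhs(tmp, omega, coupling, indptr, in_nbrs, k2)
        for i in range(n):
            tmp[i] = theta[i] + 0.5 * dt * k2[i]
        kuramoto_rhs(tmp, omega, coupling, indptr, in_nbrs, k3)
        for i in range(n):
            tmp[i] = theta[i] + dt * k3[i]
        kuramoto_rhs(tmp, omega, coupling, indptr, in_nbrs, k4)
        for i in range(n):
            theta[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            # keep phases wrapped: sin() range reduction stays cheap and
            # the dynamics are 2*pi-periodic (per-step drift < 0.5 by the
            # stability guard, so one correction suffices)
            if theta[i] > np.pi:
                theta[i] -= 2.0 * np.pi
            elif theta[i] < -np.pi:
                theta[i] += 2.0 * np.pi
        if sample_stride > 0 and (step + 1) % sample_stride == 0:
            zre = 0.0
            zim = 0.0
            for i in range(n):
                zre += np.cos(theta[i])
                zim += np.sin(theta[i])
            zre_out[n_samples] = zre / n
            zim_out[n_samples] = zim / n
            for s in range(n_subsets):
                sre = 0.0
                sim = 0.0
                for k in range(sub_indptr[s], sub_indptr[s + 1]):
                    node = sub_nodes[k]
                    sre += np.cos(theta[node])
                    sim += np.sin(theta[node])
                size = sub_indptr[s + 1] - sub_indptr[s]
                re_out[s, n_samples] = sre / size
                im_out[s, n_samples] = sim / size
            n_samples += 1
    return n_samples


@numba.njit(cache=True)
def ising_run(
    spins,
    indptr,
    in_nbrs,
    temperature,
    n_sweeps,
    seed,
    symmetric,
    record,
    sub_indptr,
    sub_nodes,
    m_out,
):
    """Random-sequential heat-bath updates; one sweep = n site updates.

    Each update draws a uniformly random site, computes its local field
    from the CURRENT in-neighbor spins, and resamples the spin from the
    heat-bath distribution.  T = 0 is the explicit limit: align with the
    field, fair coin at zero field.

    With ``symmetric`` the acceptance draw is implemented equivariantly
    under a global spin flip (s = sign(h) * [u < p(|h|)], and at h = 0
    the old spin times a fair coin), so negating all initial spins while
    reusing the seed negates every recorded sample.  Both variants
    realize the same single-update distribution.

    When ``record`` is true, subset magnetizations are written to
    ``m_out`` (n_subsets, n_sweeps) once per sweep.
    """
    np.random.seed(seed)
    n = spins.size
    n_subsets = sub_indptr.size - 1
    for sweep in range(n_sweeps):
        for _ in range(n):
            i = np.random.randint(0, n)
            h = 0
            for k in range(indptr[i], indptr[i + 1]):
                h += spins[in_nbrs[k]]
            u = np.random.random()
            if symmetric:
                if h == 0:
                    new = spins[i] if u < 0.5 else -spins[i]
                else:
                    habs = h if h > 0 else -h
                    if temperature == 0.0:
                        p_abs = 1.0
                    else:
                        p_abs = 1.0 / (1.0 + np.exp(-2.0 * habs / temperature))
                    sgn = 1 if h > 0 else -1
                    new = sgn if u < p_abs else -sgn
            else:
                if temperature == 0.0:
                    if h > 0:
                        p = 1.0
                    elif h < 0:
                        p = 0.0
                    else:
                        p = 0.5
                else:
                    p = 1.0 / (1.0 + np.exp(-2.0 * h / temperature))
                new = 1 if u < p else -1
            spins[i] = new
        if record:
            for s in range(n_subsets):
                acc = 0
                for k in range(sub_indptr[s], sub_indptr[s + 1]):
                    acc += spins[sub_nodes[k]]
                size = sub_indptr[s + 1] - sub_indptr[s]
                m_out[s, sweep] = acc / size
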
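"""Numba chunk kernels for overdamped Langevin dynamics.

Each kernel advances one trajectory for a chunk of steps with a *fixed*
set of metadynamics hills (deposition happens between chunks, in Python).
The bias is evaluated by direct summation over hills at every step --
exact at desk-scale hill counts.  Pre-generated Gaussian noise arrays
keep all randomness in the caller's ``numpy.random.Generator``.
"""

import numpy as np
from numba import njit

__all__ = ["dw1d_chunk", "radial2d_chunk"]


@njit(cache=True)
def _bias_1d(cv, hc, hh, sig2):
    """Bias energy and bias *force* (-dV/dcv) by direct hill summation."""
    v = 0.0
    g = 0.0
    for j in range(hc.shape[0]):
        d = cv - hc[j]
        e = hh[j] * np.exp(-0.5 * d * d / sig2)
        v += e
        g += e * d / sig2
    return v, g


@njit(cache=True)
def dw1d_chunk(
    x,
    nsteps,
    dt,
    friction,
    kT,
    barrier,
    x0,
    lo,
    hi,
    hc,
    hh,
    sigma,
    wall_k,
    wall_r,
    noise,
    save_stride,
    saved_x,
    saved_v,
):
    """One chunk on the 1D double well; bias hills act on x, wall on |x|.

    Returns (x_final, n_saved, exit_step).  exit_step is the 0-based
    local step at which the trajectory left [lo, hi], or -1.
    Saves (x, bias) after every ``save_stride`` steps.
    """
    amp = np.sqrt(2.0 * kT * dt / friction)
    sig2 = sigma * sigma
    n_saved = 0
    for i in range(nsteps):
        u = (x / x0) ** 2 - 1.0
        f = -4.0 * barrier * u * x / (x0 * x0)
        if wall_k > 0.0:
            r = abs(x)
            if r > wall_r:
                fw = -2.0 * wall_k * (r - wall_r)
                f += fw if x > 0.0 else -fw
        v = 0.0
        if hc.shape[0] > 0:
            v, g = _bias_1d(x, hc, hh, sig2)
            f += g
        x = x + dt * f / friction + amp * noise[i]
        if x < lo or x > hi:
            return x, n_saved, i
        if (i + 1) % save_stride == 0:
            if hc.shape[0] > 0:
                v, _ = _bias_1d(x, hc, hh, sig2)
            else:
                v = 0.0
            saved_x[n_saved] = x
            saved_v[n_saved] = v
            n_saved += 1
    return x, n_saved, -1


@njit(cache=True)
def _radial_force(rho, depth, rmin, ww, bh, rb, wb):
    # -dU/drho of the Gaussian well + Gaussian barrier profile
    dwell = (
        depth * (rho - rmin) / (ww * ww) * np.exp(-0.5 * ((rho - rmin) / ww) ** 2)
    )
    dbump = (
        -bh * (rho - rb) / (wb * wb) * np.exp(-0.5 * ((rho - rb) / wb) ** 2)
    )
    return -(dwell + dbump)


@njit(cache=True)
def radial2d_chunk(
    x,
    y,
    nsteps,
    dt,
    friction,
    kT,
    depth,
    rmin,
    ww,
    bh,
    rb,
    wb,
    box,
    hc,
    hh,
    sigma,
    wall_k,
    wall_r,
    stop_rho,
    noise_x,
    noise_y,
    save_stride,
    saved_rho,
    saved_v,
):
    """One chunk on the radial 2D landscape; hills and wall act on rho.

    Returns (x, y, n_saved, exit_step, stop_step).  stop_step is the
    0-based local step at which rho first exceeded ``stop_rho`` (the
    unbinding-commitment radius; pass a negative value to disable),
    exit_step the step leaving the box; both -1 when not triggered.
    Saves (rho, bias) after every ``save_stride`` steps.
    """
    amp = np.sqrt(2.0 * kT * dt / friction)
    sig2 = sigma * sigma
    n_saved = 0
    for i in range(nsteps):
        rho = np.sqrt(x * x + y * y)
        frad = 0.0
        if rho > 1e-12:
            frad = _radial_force(rho, depth, rmin, ww, bh, rb, wb)
            if wall_k > 0.0 and rho > wall_r:
                frad += -2.0 * wall_k * (rho - wall_r)
            if hc.shape[0] > 0:
                _, g = _bias_1d(rho, hc, hh, sig2)
                frad += g
            ux = x / rho
            uy = y / rho
        else:
            ux = 0.0
            uy = 0.0
        x = x + dt * frad * ux / friction + amp * noise_x[i]
        y = y + dt * frad * uy / friction + amp * noise_y[i]
        if x < -box or x > box or y < -box or y > box:
            return x, y, n_saved, i, -1
        rho_new = np.sqrt(x * x + y * y)
        if (i + 1) % save_stride == 0:
            v = 0.0
            if hc.shape[0] > 0:
                v, _ = _bias_1d(rho_new, hc, hh, sig2)
            saved_rho[n_saved] = rho_new
            saved_v[n_saved] = v
            n_saved += 1
        if stop_rho > 0.0 and rho_new > stop_rho:
            return x, y, n_saved, -1, i
    return x, y, n_saved, -1, -1
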
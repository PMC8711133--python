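"""Numba kernels for the 1-D Langevin / well-tempered metadynamics sampler.

The per-step noise is counter-based: step ``i`` draws its standard normal
from a splitmix64 hash of ``(key, i)`` via Box-Muller, so the noise stream
is a pure function of (seed, step) and hill depositions never perturb it.

The bias force acting on the walker is linearly interpolated from a fine
periodic grid that accumulates each deposited Gaussian; the *recorded* hill
height is computed from the exact (6-sigma-truncated) sum over all prior
hills, so the well-tempering identity h_i = w0 * exp(-V(c_i)/(kB*dT)) is
reproducible from the hills log alone.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi

_U = np.uint64


@njit(cache=True, inline="always")
def _splitmix64(x):
    z = (x + _U(0x9E3779B97F4A7C15))
    z = (z ^ (z >> _U(30))) * _U(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U(27))) * _U(0x94D049BB133111EB)
    return z ^ (z >> _U(31))


@njit(cache=True, inline="always")
def _std_normal(key, step):
    c = key + _U(2) * _U(step)
    a = _splitmix64(c)
    b = _splitmix64(c + _U(1))
    # u1 in (0, 1], u2 in [0, 1)
    u1 = (np.float64(a >> _U(11)) + 1.0) * (2.0 ** -53)
    u2 = np.float64(b >> _U(11)) * (2.0 ** -53)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(TWO_PI * u2)


@njit(cache=True, inline="always")
def _wrap(x):
    return (x + np.pi) % TWO_PI - np.pi


@njit(cache=True, inline="always")
def _interp_periodic(arr, x):
    """Linear interpolation on a uniform periodic grid over [-pi, pi)."""
    n = arr.shape[0]
    t = (x + np.pi) * n / TWO_PI
    i = int(np.floor(t))
    frac = t - i
    i0 = i % n
    i1 = (i + 1) % n
    return arr[i0] * (1.0 - frac) + arr[i1] * frac


@njit(cache=True)
def run_kernel(du_pot, n_steps, dt, friction, kT, x0,
               pace, w0, sigma, kT_delta, key, record_stride, n_images):
    """Euler-Maruyama overdamped Langevin with WT-MetaD hill deposition.

    du_pot : dU/dphi tabulated on a uniform periodic grid over [-pi, pi).
    w0     : initial hill height (kcal/mol); 0 disables deposition.
    Returns (hill_times, centers, heights, traj_times, positions, bias_at_pos).
    """
    ngrid = du_pot.shape[0]
    h_grid = TWO_PI / ngrid
    vbias = np.zeros(ngrid)
    dvbias = np.zeros(ngrid)

    max_hills = n_steps // pace if w0 > 0.0 else 0
    hill_t = np.empty(max_hills)
    centers = np.empty(max_hills)
    heights = np.empty(max_hills)
    n_rec = n_steps // record_stride
    rec_t = np.empty(n_rec)
    rec_x = np.empty(n_rec)
    rec_b = np.empty(n_rec)

    x = x0
    drift = dt / friction
    noise_amp = np.sqrt(2.0 * kT * dt / friction)
    cut = 6.0 * sigma
    inv2s2 = 1.0 / (2.0 * sigma * sigma) if sigma > 0.0 else 0.0
    nh = 0
    nr = 0

    for step in range(n_steps):
        f = _interp_periodic(du_pot, x) + _interp_periodic(dvbias, x)
        x = x - drift * f + noise_amp * _std_normal(key, step)
        x = _wrap(x)
        s = step + 1

        if w0 > 0.0 and s % pace == 0 and nh < max_hills:
            c = x
            # exact bias at the new center from all prior hills
            v = 0.0
            for j in range(nh):
                d = _wrap(c - centers[j])
                for m in range(-n_images + 1, n_images):
                    dm = d + m * TWO_PI
                    if np.abs(dm) <= cut:
                        v += heights[j] * np.exp(-dm * dm * inv2s2)
            hgt = w0 * np.exp(-v / kT_delta)
            hill_t[nh] = s * dt
            centers[nh] = c
            heights[nh] = hgt
            nh += 1
            # accumulate the new Gaussian (and its gradient) on the grids
            for i in range(ngrid):
                xg = -np.pi + i * h_grid
                d = _wrap(xg - c)
                for m in range(-n_images + 1, n_images):
                    dm = d + m * TWO_PI
                    if np.abs(dm) <= cut:
                        g = hgt * np.exp(-dm * dm * inv2s2)
                        vbias[i] += g
                        dvbias[i] += -(dm / (sigma * sigma)) * g

        if s % record_stride == 0 and nr < n_rec:
            rec_t[nr] = s * dt
            rec_x[nr] = x
            rec_b[nr] = _interp_periodic(vbias, x)
            nr += 1

    return (hill_t[:nh], centers[:nh], heights[:nh],
            rec_t[:nr], rec_x[:nr], rec_b[:nr])
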
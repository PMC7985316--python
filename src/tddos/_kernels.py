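"""Numba photon-transport kernel for slab transmittance.

White Monte Carlo: scattering only (mu_s = mu_s', isotropic phase function
per the similarity relation), absorption added analytically afterwards via
the Beer-Lambert time factor.  Unpolarized Fresnel reflection/refraction is
applied at both faces (n_sample vs n_external); internally reflected photons
continue to propagate.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _fresnel_reflectance(cos_i: float, n_in: float, n_out: float) -> float:
    """Unpolarized Fresnel power reflectance for incidence from n_in to n_out."""
    if cos_i >= 1.0:
        r = (n_in - n_out) / (n_in + n_out)
        return r * r
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n_in / n_out) * (n_in / n_out) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_in * cos_i - n_out * cos_t) / (n_in * cos_i + n_out * cos_t)
    rp = (n_in * cos_t - n_out * cos_i) / (n_in * cos_t + n_out * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def slab_transmittance_kernel(
    n_photons: int,
    mus: float,
    thickness: float,
    n_sample: float,
    n_external: float,
    det_radius2: float,
    t0: float,
    dt: float,
    n_bins: int,
    inv_v: float,
    seed: int,
):
    """Trace photons through the slab; histogram arrival times at the detector.

    Returns (hist, n_transmitted, n_reflected, n_truncated, n_detected).
    hist holds photon counts per bin (weight 1 each; null absorption).
    n_transmitted counts every exit through the far face (any radius),
    n_truncated counts photons whose path exceeded the grid span.
    Energy bookkeeping: transmitted + reflected + truncated == launched.
    """
    np.random.seed(seed)
    hist = np.zeros(n_bins, dtype=np.float64)
    n_trans = 0
    n_refl = 0
    n_trunc = 0
    n_det = 0
    t_max = t0 + dt * n_bins
    max_path = t_max / inv_v
    two_pi = 2.0 * math.pi
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        path = 0.0
        while True:
            s = -math.log(np.random.random()) / mus
            if uz > 0.0:
                d_b = (thickness - z) / uz
            elif uz < 0.0:
                d_b = z / (-uz)
            else:
                d_b = 1.0e30
            if s < d_b:
                x += ux * s
                y += uy * s
                z += uz * s
                path += s
                if path > max_path:
                    n_trunc += 1
                    break
                cost = 2.0 * np.random.random() - 1.0
                sint = math.sqrt(max(0.0, 1.0 - cost * cost))
                phi = two_pi * np.random.random()
                ux = sint * math.cos(phi)
                uy = sint * math.sin(phi)
                uz = cost
            else:
                x += ux * d_b
                y += uy * d_b
                z += uz * d_b
                path += d_b
                cos_i = abs(uz)
                refl = _fresnel_reflectance(cos_i, n_sample, n_external)
                if np.random.random() < refl:
                    uz = -uz
                    if path > max_path:
                        n_trunc += 1
                        break
                else:
                    t = path * inv_v
                    if uz > 0.0:
                        n_trans += 1
                        if x * x + y * y <= det_radius2 and t0 <= t < t_max:
                            ib = int((t - t0) / dt)
                            hist[ib] += 1.0
                            n_det += 1
                    else:
                        n_refl += 1
                    break
    return hist, n_trans, n_refl, n_trunc, n_det
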
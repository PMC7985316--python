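"""Forward model for time-resolved diffuse transmittance through a slab.

Four routes to a temporal point spread function (TPSF):

* :func:`simulate_reference_tpsf` — white Monte Carlo at null absorption;
* :func:`apply_absorption` — Beer-Lambert factor exp(-mua * v * t) on any
  null-absorption curve;
* :func:`build_library` / :func:`interpolate_library` — a precomputed grid
  of reference curves over reduced scattering, queried continuously;
* :func:`da_transmittance` — the diffusion-approximation closed form
  (extrapolated-boundary image sources), the analytic oracle.

The radiative-transfer scaling relation (:func:`scale_tpsf`) maps a curve
for (L, mus') onto (k*L, mus'/k) by stretching the time axis by k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, stats

from ._kernels import _fresnel_reflectance, slab_transmittance_kernel
from .core import C_CM_PER_PS, SlabGeometry, TimeGrid, TPSF

__all__ = [
    "simulate_reference_tpsf",
    "apply_absorption",
    "scale_tpsf",
    "MCLibrary",
    "build_library",
    "interpolate_library",
    "da_transmittance",
    "compare_histograms",
]


def simulate_reference_tpsf(
    geometry: SlabGeometry,
    mus_prime: float,
    grid: TimeGrid,
    n_photons: int,
    seed: int,
) -> TPSF:
    """Monte Carlo reference TPSF at null absorption.

    Isotropic scattering with mu_s = mus_prime (similarity relation);
    unpolarized Fresnel boundaries; arrival time is path * n_sample / c.
    Deterministic for a given seed.  If no photon reaches the detector the
    returned curve is flagged ``empty`` in its tallies rather than being a
    silent all-zeros result.
    """
    if not mus_prime > 0:
        raise ValueError("mus_prime must be > 0")
    if n_photons < 10**4:
        raise ValueError("n_photons must be >= 1e4 for a usable histogram")
    seed = int(seed) % 2**31
    inv_v = geometry.n_sample / C_CM_PER_PS  # ps per cm of path
    hist, n_trans, n_refl, n_trunc, n_det = slab_transmittance_kernel(
        int(n_photons),
        float(mus_prime),
        float(geometry.thickness),
        float(geometry.n_sample),
        float(geometry.n_external),
        float(geometry.detector_radius) ** 2,
        float(grid.t0),
        float(grid.dt),
        int(grid.n_bins),
        inv_v,
        seed,
    )
    tallies = {
        "transmitted": int(n_trans),
        "reflected": int(n_refl),
        "truncated": int(n_trunc),
        "detected": int(n_det),
        "seed": seed,
    }
    if n_det == 0:
        tallies["empty"] = True
        warnings.warn("no photons reached the detector; empty TPSF flagged")
    return TPSF(
        grid=grid,
        values=hist / n_photons,
        mus_prime=float(mus_prime),
        n_sample=geometry.n_sample,
        mua=0.0,
        photons_launched=int(n_photons),
        null_absorption=True,
        tallies=tallies,
    )


def apply_absorption(tpsf: TPSF, mua: float) -> TPSF:
    """Multiply a TPSF by the Beer-Lambert factor exp(-mua * v * t).

    v = c / n_sample, evaluated at bin centers.  The input is unchanged;
    the result records the accumulated absorption, so successive
    applications compose additively: apply(m1) then apply(m2) equals
    apply(m1 + m2) bin-wise to machine precision.
    """
    if mua < 0:
        raise ValueError("mua must be >= 0")
    v = C_CM_PER_PS / tpsf.n_sample
    out = tpsf.copy()
    if mua > 0:
        out.values = tpsf.values * np.exp(-mua * v * tpsf.grid.centers)
        out.mua = tpsf.mua + mua
        out.null_absorption = False
    return out


def scale_tpsf(reference: TPSF, k: float) -> TPSF:
    """RTE scaling: the curve for all lengths * k and mus' / k.

    Time axis is stretched t -> k*t (bin width included); per-photon
    transmitted fractions are preserved, so bin contents are unchanged.
    """
    if not reference.null_absorption:
        raise ValueError("scaling applies to null-absorption references only")
    if not k > 0:
        raise ValueError("scale factor must be > 0")
    out = reference.copy()
    out.grid = reference.grid.scaled(k)
    out.mus_prime = reference.mus_prime / k
    return out


@dataclass
class MCLibrary:
    """Null-absorption reference curves over a grid of reduced scattering.

    All curves share geometry and time grid; the grid of mus' values is
    strictly increasing.  ``seeds`` records the per-node kernel seed so a
    rebuild is bit-identical.
    """

    geometry: SlabGeometry
    grid_mus_prime: np.ndarray
    curves: list
    n_photons: int
    seed: int
    seeds: np.ndarray

    def __post_init__(self) -> None:
        self.grid_mus_prime = np.asarray(self.grid_mus_prime, dtype=float)
        if np.any(np.diff(self.grid_mus_prime) <= 0):
            raise ValueError("library grid must be strictly increasing")
        if len(self.curves) != len(self.grid_mus_prime):
            raise ValueError("one curve per grid node required")
        g0 = self.curves[0].grid
        for c in self.curves:
            if not c.null_absorption:
                raise ValueError("library curves must be null-absorption")
            if c.grid != g0:
                raise ValueError("library curves must share one TimeGrid")

    @property
    def grid(self) -> TimeGrid:
        return self.curves[0].grid

    @property
    def mus_min(self) -> float:
        return float(self.grid_mus_prime[0])

    @property
    def mus_max(self) -> float:
        return float(self.grid_mus_prime[-1])


def default_library_grid(lo: float = 1.0, hi: float = 70.0, n_nodes: int = 25) -> np.ndarray:
    """Geometric node spacing: curve shape varies smoothly in log mus'."""
    return np.geomspace(lo, hi, n_nodes)


def build_library(
    geometry: SlabGeometry,
    grid_mus_prime: np.ndarray,
    grid: TimeGrid,
    n_photons: int,
    seed: int,
) -> MCLibrary:
    """One Monte Carlo reference per node; reproducible for a given seed."""
    grid_mus_prime = np.asarray(grid_mus_prime, dtype=float)
    ratios = grid_mus_prime[1:] / grid_mus_prime[:-1]
    if ratios.size and ratios.max() > 1.6:
        warnings.warn(
            "library grid is sparse (adjacent node ratio "
            f"{ratios.max():.2f} > 1.6); interpolation accuracy may degrade"
        )
    seeds = np.random.SeedSequence(seed).generate_state(len(grid_mus_prime)) % 2**31
    curves = [
        simulate_reference_tpsf(geometry, m, grid, n_photons, s)
        for m, s in zip(grid_mus_prime, seeds)
    ]
    return MCLibrary(
        geometry=geometry,
        grid_mus_prime=grid_mus_prime,
        curves=curves,
        n_photons=int(n_photons),
        seed=int(seed),
        seeds=seeds,
    )


def interpolate_library(library: MCLibrary, mus_prime: float) -> TPSF:
    """Continuous query of the library in reduced scattering.

    Each bracketing node curve is area-normalized and time-rescaled to the
    query's interpolated mean transit time, then the two shapes are mixed
    linearly in log mus'.  Exact at grid nodes; mean transit time is
    monotone between nodes.  Queries outside the grid raise (no
    extrapolation).
    """
    g = library.grid_mus_prime
    if not (g[0] <= mus_prime <= g[-1]):
        raise ValueError(
            f"mus_prime {mus_prime:g} outside library range [{g[0]:g}, {g[-1]:g}]"
        )
    exact = np.nonzero(np.isclose(g, mus_prime, rtol=1e-12, atol=0))[0]
    if exact.size:
        return library.curves[int(exact[0])].copy()

    j = int(np.searchsorted(g, mus_prime)) - 1
    ca, cb = library.curves[j], library.curves[j + 1]
    w = (math.log(mus_prime) - math.log(g[j])) / (math.log(g[j + 1]) - math.log(g[j]))

    wa, wb = ca.total_weight, cb.total_weight
    ta, tb = ca.mean_time, cb.mean_time
    total = math.exp((1 - w) * math.log(wa) + w * math.log(wb))
    tbar = math.exp((1 - w) * math.log(ta) + w * math.log(tb))

    centers = library.grid.centers

    def rescaled_shape(curve: TPSF, t_node: float) -> np.ndarray:
        u = curve.values / curve.total_weight
        r = t_node / tbar
        return np.interp(centers * r, centers, u, left=0.0, right=0.0) * r

    values = total * ((1 - w) * rescaled_shape(ca, ta) + w * rescaled_shape(cb, tb))
    # time-rescaling can smear a sliver of weight before the ballistic time
    ballistic = library.geometry.ballistic_time
    values[library.grid.bin_edges[1:] <= ballistic] = 0.0
    return TPSF(
        grid=library.grid,
        values=values,
        mus_prime=float(mus_prime),
        n_sample=library.geometry.n_sample,
        mua=0.0,
        photons_launched=0,
        null_absorption=True,
        tallies={"interpolated": True, "bracket": (float(g[j]), float(g[j + 1]))},
    )


# ---------------------------------------------------------------------------
# Diffusion approximation oracle


@lru_cache(maxsize=32)
def _a_coefficient(n_in: float, n_out: float) -> float:
    """Internal-reflection coefficient A = (1 + R_eff) / (1 - R_eff).

    R_eff from the standard angular integrals of the unpolarized Fresnel
    reflectance over the internal hemisphere.
    """

    def r_phi(theta):
        return 2.0 * math.sin(theta) * math.cos(theta) * _fresnel_reflectance(
            math.cos(theta), n_in, n_out
        )

    def r_j(theta):
        return 3.0 * math.sin(theta) * math.cos(theta) ** 2 * _fresnel_reflectance(
            math.cos(theta), n_in, n_out
        )

    rp, _ = integrate.quad(r_phi, 0.0, math.pi / 2, limit=200)
    rj, _ = integrate.quad(r_j, 0.0, math.pi / 2, limit=200)
    r_eff = (rp + rj) / (2.0 - rp + rj)
    return (1.0 + r_eff) / (1.0 - r_eff)


def da_transmittance(
    geometry: SlabGeometry,
    mua: float,
    mus_prime: float,
    grid: TimeGrid,
    n_images: int = 12,
) -> TPSF:
    """Diffusion-approximation time-resolved transmittance (analytic).

    Extrapolated-boundary image-source solution for a slab, with the
    isotropic source at z0 = 1/mus' and D = 1/(3 mus') (absorption enters
    only through the separable Beer-Lambert factor, so
    ``apply_absorption(da(0), mua)`` equals ``da(mua)`` bin-wise).  The
    coaxial-disk detector acceptance multiplies the plane-integrated flux
    by the enclosed fraction of the lateral Gaussian spread.
    """
    if mua < 0 or mus_prime <= 0:
        raise ValueError("require mua >= 0 and mus_prime > 0")
    if mua > 0.1 * mus_prime:
        warnings.warn("outside the diffusive regime (mua not << mus'); DA is unreliable")
    L = geometry.thickness
    v = C_CM_PER_PS / geometry.n_sample
    D = 1.0 / (3.0 * mus_prime)
    z0 = 1.0 / mus_prime
    ze = 2.0 * _a_coefficient(geometry.n_sample, geometry.n_external) * D

    t = grid.centers
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 4.0 * D * v * t
        series = np.zeros_like(t)
        for m in range(-n_images, n_images + 1):
            z1 = L * (1 - 2 * m) - 4 * m * ze - z0
            z2 = L * (1 - 2 * m) - (4 * m - 2) * ze + z0
            series += z1 * np.exp(-(z1**2) / denom) - z2 * np.exp(-(z2**2) / denom)
        flux = (
            np.exp(-mua * v * t)
            * series
            / (2.0 * np.sqrt(np.pi * D * v) * t**1.5)
            * (1.0 - np.exp(-(geometry.detector_radius**2) / denom))
        )
    flux = np.where(np.isfinite(flux), flux, 0.0)
    flux[flux < 0] = 0.0
    flux[t <= 0] = 0.0
    return TPSF(
        grid=grid,
        values=flux * grid.dt,
        mus_prime=float(mus_prime),
        n_sample=geometry.n_sample,
        mua=float(mua),
        photons_launched=0,
        null_absorption=(mua == 0.0),
        tallies={"analytic": True},
    )


# ---------------------------------------------------------------------------
# Statistical comparison of photon-count histograms


def compare_histograms(
    counts1: np.ndarray, counts2: np.ndarray, min_expected: float = 10.0
) -> tuple[float, float, int]:
    """Two-sample chi-square homogeneity test for binned photon counts.

    Bins are pooled from the tails until every pooled bin holds at least
    ``min_expected`` combined counts.  Returns (statistic, p_value, dof).
    Used to assert the RTE scaling invariance: a fresh simulation and a
    rescaled one should be statistically indistinguishable.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("histograms must share binning")
    total = c1 + c2
    keep = np.nonzero(total > 0)[0]
    c1, c2 = c1[keep], c2[keep]
    # pool adjacent bins until each pooled bin is well populated
    p1, p2 = [], []
    acc1 = acc2 = 0.0
    for a, b in zip(c1, c2):
        acc1 += a
        acc2 += b
        if acc1 + acc2 >= min_expected:
            p1.append(acc1)
            p2.append(acc2)
            acc1 = acc2 = 0.0
    if acc1 + acc2 > 0 and p1:
        p1[-1] += acc1
        p2[-1] += acc2
    c1 = np.array(p1)
    c2 = np.array(p2)
    n1, n2 = c1.sum(), c2.sum()
    if n1 == 0 or n2 == 0 or len(c1) < 2:
        raise ValueError("not enough counts for a comparison")
    k1 = math.sqrt(n2 / n1)
    k2 = math.sqrt(n1 / n2)
    statistic = float(np.sum((k1 * c1 - k2 * c2) ** 2 / (c1 + c2)))
    dof = len(c1) - 1
    p_value = float(stats.chi2.sf(statistic, dof))
    return statistic, p_value, dof
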
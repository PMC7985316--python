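"""Recovery of (mua, mus') per wavelength from measured DTOF histograms.

The model curve is ``amplitude * convolve(apply_absorption(
interpolate_library(mus'), mua), IRF) + background``, compared to the
measurement only inside the fit window: from the first bin at or above
80% of the maximum on the rising edge to the last bin at or above 1% of
the maximum on the falling edge.  The amplitude is always free — the fit
relies on the temporal shape of the DTOF alone, never on its absolute
intensity — and for both objectives it has a closed form, leaving a 2-D
search over (mua, log mus').
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

from .core import C_CM_PER_PS
from .instrument import IRF, DTOFRecord, convolve_irf
from .photon_transport import MCLibrary, apply_absorption, interpolate_library

__all__ = [
    "FitConfig",
    "FitResult",
    "OpticalSpectrum",
    "fit_window",
    "fit_optical_properties",
    "fit_spectrum",
]


@dataclass
class FitConfig:
    """Knobs of the per-wavelength curve fit.

    background: 'estimate' (mean of the first 5% of bins), 'none', or a
    fixed counts-per-bin float.  The largest mua_init value sets the upper
    bound (x2) of the absorption profile search that initializes the fit.
    """

    rise_fraction: float = 0.80
    fall_fraction: float = 0.01
    objective: str = "poisson-deviance"  # or "weighted-least-squares"
    max_iterations: int = 400
    parameter_tolerance: float = 1e-4
    background: Union[str, float] = "estimate"
    mua_init: Sequence[float] = (0.01, 0.05, 0.15, 0.4, 1.0)
    fit_time_shift: bool = False
    compute_uncertainties: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.fall_fraction < self.rise_fraction < 1):
            raise ValueError("require 0 < fall_fraction < rise_fraction < 1")
        if self.objective not in ("poisson-deviance", "weighted-least-squares"):
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class FitResult:
    mua: float
    mus_prime: float
    amplitude: float
    objective_value: float
    window: tuple
    converged: bool
    at_boundary: bool = False
    time_shift: float = 0.0
    background: float = 0.0
    mua_err: Optional[float] = None
    musp_err: Optional[float] = None
    n_evaluations: int = 0


@dataclass
class OpticalSpectrum:
    """Broadband absorption and reduced-scattering spectra, 1/cm.

    Failed wavelengths hold NaN (never interpolated over).
    """

    wavelengths: np.ndarray
    mua: np.ndarray
    mus_prime: np.ndarray
    mua_err: Optional[np.ndarray] = None
    musp_err: Optional[np.ndarray] = None
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mua = np.asarray(self.mua, dtype=float)
        self.mus_prime = np.asarray(self.mus_prime, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (len(self.wavelengths) == len(self.mua) == len(self.mus_prime)):
            raise ValueError("spectrum arrays must be aligned")
        for name in ("mua_err", "musp_err"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if len(arr) != len(self.wavelengths):
                    raise ValueError(f"{name} must be aligned with wavelengths")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.wavelengths)


def fit_window(counts: np.ndarray, config: Optional[FitConfig] = None) -> tuple:
    """(start, end) bin indices of the fit region, both inclusive.

    start: first bin at/before the peak with counts >= rise_fraction * max;
    end: last bin at/after the peak with counts >= fall_fraction * max.
    Thresholds are relative, so rescaling the curve leaves the window
    unchanged.
    """
    config = config or FitConfig()
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.max() <= 0:
        raise ValueError("cannot window an empty or non-positive curve")
    peak = int(np.argmax(c))
    hi = config.rise_fraction * c[peak]
    lo = config.fall_fraction * c[peak]
    start = int(np.argmax(c[: peak + 1] >= hi))
    tail = np.nonzero(c[peak:] >= lo)[0]
    end = peak + int(tail[-1])
    if start >= end:
        raise ValueError("degenerate fit window (flat or single-bin curve)")
    return start, end


def _shift_curve(values: np.ndarray, centers: np.ndarray, shift: float) -> np.ndarray:
    if shift == 0.0:
        return values
    return np.interp(centers - shift, centers, values, left=0.0, right=0.0)


def fit_optical_properties(
    record: DTOFRecord,
    irf: IRF,
    library: MCLibrary,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit one DTOF: a dense scattering scan with the absorption profiled
    out at each point, then Nelder-Mead refinement of (mua, log mus') with
    the amplitude solved in closed form at every evaluation.
    Deterministic for fixed inputs and config."""
    config = config or FitConfig()
    grid = record.grid
    if grid != irf.grid:
        raise ValueError("record and IRF must share one TimeGrid")
    counts = record.counts.astype(float)

    if config.background == "estimate":
        n_bg = max(1, int(0.05 * grid.n_bins))
        background = float(counts[:n_bg].mean())
    elif config.background == "none":
        background = 0.0
    else:
        background = float(config.background)

    net = np.clip(counts - background, 0.0, None)
    w0, w1 = fit_window(net, config)
    sl = slice(w0, w1 + 1)
    c_win = counts[sl]
    bg_win = background
    sum_c_net = float(np.clip(c_win - bg_win, 0.0, None).sum())
    centers = grid.centers
    v = C_CM_PER_PS / library.geometry.n_sample
    decay_base = -v * centers

    n_eval = 0
    lg_lo, lg_hi = math.log(library.mus_min), math.log(library.mus_max)

    def model_curve(mua: float, musp: float, shift: float) -> np.ndarray:
        ref = interpolate_library(library, musp)
        absorbed = ref.values * np.exp(mua * decay_base)
        ref.values = absorbed
        m = convolve_irf(ref, irf)
        if shift != 0.0:
            m = _shift_curve(m, centers, shift)
        return m[sl]

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        mua = x[0]
        lg = x[1]
        shift = x[2] if config.fit_time_shift else 0.0
        penalty = 0.0
        if mua < 0:
            penalty += 1e6 * mua**2 * 1e4
            mua = 0.0
        if lg < lg_lo:
            penalty += 1e6 * (lg_lo - lg) ** 2
            lg = lg_lo
        elif lg > lg_hi:
            penalty += 1e6 * (lg - lg_hi) ** 2
            lg = lg_hi
        m = model_curve(mua, math.exp(lg), shift)
        sm = m.sum()
        if sm <= 0 or not np.all(np.isfinite(m)):
            return 1e30
        if config.objective == "poisson-deviance":
            amp = sum_c_net / sm
            mu = amp * m + bg_win
            mu = np.clip(mu, 1e-300, None)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(c_win > 0, c_win * np.log(c_win / mu), 0.0)
            value = 2.0 * float(np.sum(term - (c_win - mu)))
        else:
            wts = 1.0 / np.clip(c_win, 1.0, None)
            amp = float(np.sum(wts * (c_win - bg_win) * m) / np.sum(wts * m * m))
            mu = amp * m + bg_win
            value = float(np.sum(wts * (c_win - mu) ** 2))
        return value + penalty

    # initialization by profile likelihood: the interpolated model is only
    # piecewise smooth across library nodes, so the deviance is multi-modal
    # in mus'.  Scan a dense scattering grid (3 subdivisions per node
    # interval) and minimize over mua at each point — the mua profile is
    # far too sharp at realistic count levels for a fixed seed list —
    # then hand the best basin to the local search.
    n_scan = 3 * (len(library.grid_mus_prime) - 1) + 1 if len(library.grid_mus_prime) > 1 else 1
    scan = np.exp(np.linspace(lg_lo, lg_hi, max(n_scan, 1)))
    mua_hi = max(config.mua_init) * 2.0
    shift_tail = [0.0] if config.fit_time_shift else []

    profile = []
    for musp0 in scan:
        lg0 = math.log(musp0)
        prof = optimize.minimize_scalar(
            lambda mua: objective(np.array([mua, lg0] + shift_tail)),
            bounds=(0.0, mua_hi),
            method="bounded",
            options={"xatol": 1e-4, "maxiter": 40},
        )
        profile.append((float(prof.fun), np.array([float(prof.x), lg0] + shift_tail)))
    i_best = int(np.argmin([p[0] for p in profile]))

    # restart the simplex from the best scan point and its neighbours: the
    # best point can sit exactly on a node kink where a single start stalls
    # on the wrong side
    res = None
    for i in {i_best, max(i_best - 1, 0), min(i_best + 1, len(profile) - 1)}:
        trial = optimize.minimize(
            objective,
            profile[i][1],
            method="Nelder-Mead",
            options={
                "xatol": config.parameter_tolerance * 1e-1,
                "fatol": 1e-9,
                "maxiter": config.max_iterations,
                "maxfev": 4 * config.max_iterations,
            },
        )
        if res is None or trial.fun < res.fun:
            res = trial
    mua_hat = max(float(res.x[0]), 0.0)
    musp_hat = float(np.clip(math.exp(res.x[1]), library.mus_min, library.mus_max))
    shift_hat = float(res.x[2]) if config.fit_time_shift else 0.0

    m = model_curve(mua_hat, musp_hat, shift_hat)
    amp = sum_c_net / m.sum() if m.sum() > 0 else 0.0
    boundary = (
        musp_hat <= library.mus_min * 1.01 or musp_hat >= library.mus_max * 0.99
    )
    if not res.success:
        warnings.warn("fit did not converge; returning last iterate flagged")

    mua_err = musp_err = None
    if config.compute_uncertainties:
        mua_err, musp_err = _curvature_errors(objective, res.x, config)

    return FitResult(
        mua=mua_hat,
        mus_prime=musp_hat,
        amplitude=float(amp),
        objective_value=float(res.fun),
        window=(w0, w1),
        converged=bool(res.success),
        at_boundary=boundary,
        time_shift=shift_hat,
        background=background,
        mua_err=mua_err,
        musp_err=musp_err,
        n_evaluations=n_eval,
    )


def _curvature_errors(objective, x_opt, config) -> tuple:
    """1-sigma errors from the numerical curvature of half the deviance."""
    try:
        h = np.array([max(1e-4, 1e-3 * abs(x_opt[0])), 1e-3])
        hess = np.zeros((2, 2))
        f0 = objective(x_opt)
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros_like(x_opt)
                ej = np.zeros_like(x_opt)
                ei[i] = h[i]
                ej[j] = h[j]
                fpp = objective(x_opt + ei + ej)
                fpm = objective(x_opt + ei - ej)
                fmp = objective(x_opt - ei + ej)
                fmm = objective(x_opt - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        cov = np.linalg.inv(0.5 * hess)
        if cov[0, 0] <= 0 or cov[1, 1] <= 0:
            return None, None
        mua_err = math.sqrt(cov[0, 0])
        # delta method: x[1] is log mus'
        musp_err = math.sqrt(cov[1, 1]) * math.exp(x_opt[1])
        return mua_err, musp_err
    except (np.linalg.LinAlgError, ValueError):
        return None, None


def fit_spectrum(
    records: Sequence[DTOFRecord],
    irfs: Union[IRF, dict, Sequence[IRF]],
    library: MCLibrary,
    config: Optional[FitConfig] = None,
    timestamp: float = 0.0,
) -> OpticalSpectrum:
    """Independent per-wavelength fits assembled into one spectrum.

    ``irfs`` may be a single IRF (shared), a mapping wavelength -> IRF, or
    a sequence aligned with ``records``.  Output is sorted by wavelength;
    failed wavelengths are NaN, never interpolated.
    """
    config = config or FitConfig()
    if len(records) == 0:
        raise ValueError("no records to fit")
    order = np.argsort([r.wavelength for r in records])
    wavelengths, mua, musp, mua_err, musp_err = [], [], [], [], []
    for idx in order:
        rec = records[idx]
        if isinstance(irfs, IRF):
            irf = irfs
        elif isinstance(irfs, dict):
            irf = irfs[rec.wavelength]
        else:
            irf = irfs[idx]
        try:
            fr = fit_optical_properties(rec, irf, library, config)
            mua.append(fr.mua)
            musp.append(fr.mus_prime)
            mua_err.append(fr.mua_err if fr.mua_err is not None else np.nan)
            musp_err.append(fr.musp_err if fr.musp_err is not None else np.nan)
        except ValueError as exc:
            warnings.warn(f"wavelength {rec.wavelength:g} nm failed: {exc}")
            mua.append(np.nan)
            musp.append(np.nan)
            mua_err.append(np.nan)
            musp_err.append(np.nan)
        wavelengths.append(rec.wavelength)
    return OpticalSpectrum(
        wavelengths=np.array(wavelengths),
        mua=np.array(mua),
        mus_prime=np.array(musp),
        mua_err=np.array(mua_err),
        musp_err=np.array(musp_err),
        timestamp=timestamp,
    )
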
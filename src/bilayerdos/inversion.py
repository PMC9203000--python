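"""Semi-infinite homogeneous inversion of simulated reflectance.

The recovery pipeline mirrors a broadband dual-distance instrument work-flow:

1. the complex effective attenuation mueff_tilde at each FD wavelength is
   obtained by an iterative fit of the linearized reflectance ln(rho^2 * R)
   versus rho, using the homogeneous semi-infinite model;
2. (mua, mus') at the FD wavelengths follow algebraically from mueff_tilde;
3. mus' is extrapolated across the CW band with the scattering power law
   through the two FD values (exponent b_rec);
4. the real effective attenuation mueff at every CW wavelength is obtained by
   the same iterative slope fit (the only CW datum per wavelength is the
   two-distance slope);
5. broadband mua follows from mueff and the extrapolated mus';
6. the mua spectrum is unmixed into chromophores by an unconstrained
   QR-based least-squares solve.

FD data therefore enter the chromophore estimates only through mus'.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .forward import (
    SPEED_OF_LIGHT_MM_S,
    InstrumentSpec,
    ReflectanceSet,
    _reflectance_from_complex_mueff,
    _reflectance_from_mueff,
)
from .spectra import ChromophoreConcentrations, ExtinctionTable, build_extinction_matrix, load_default_extinction

__all__ = [
    "RecoveredProperties",
    "NonphysicalRecoveryError",
    "fit_effective_attenuation",
    "fd_slope_model",
    "cw_slope_model",
    "fd_optical_properties",
    "scattering_extrapolation",
    "broadband_absorption",
    "unmix_chromophores",
    "recover_all",
]


class NonphysicalRecoveryError(ValueError):
    """Raised when the algebraic FD inversion yields non-physical properties."""


@dataclass
class RecoveredProperties:
    """Effective homogeneous properties recovered from a ReflectanceSet.

    All spectra are on the instrument's CW wavelength grid.  ``chromophores``
    is the unconstrained linear-inversion result and may fall outside the
    physical ranges; that is the point of the partial-volume analysis.
    """

    fd_wavelengths: np.ndarray
    mua_fd: np.ndarray          # 1/mm at the FD wavelengths
    musp_fd: np.ndarray         # 1/mm at the FD wavelengths
    b_rec: float                # recovered scattering power-law exponent
    cw_wavelengths: np.ndarray
    musp_cw: np.ndarray         # extrapolated mus'(lambda_CW), 1/mm
    mueff_cw: np.ndarray        # recovered effective attenuation, 1/mm
    mua_cw: np.ndarray          # broadband recovered absorption, 1/mm
    chromophores: ChromophoreConcentrations

    def spectra_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "wavelength_nm": self.cw_wavelengths,
            "musp_extrap": self.musp_cw,
            "mueff": self.mueff_cw,
            "mua": self.mua_cw,
        })

    def scalars_dict(self) -> dict:
        c = self.chromophores
        return {
            "thb_uM": c.thb_uM, "so2": c.so2, "water": c.water, "lipid": c.lipid,
            "b_rec": self.b_rec,
            **{f"mua_fd_{int(w)}nm": float(m)
               for w, m in zip(self.fd_wavelengths, self.mua_fd)},
            **{f"musp_fd_{int(w)}nm": float(m)
               for w, m in zip(self.fd_wavelengths, self.musp_fd)},
        }


# ---------------------------------------------------------------------------
# iterative two-distance slope fit
# ---------------------------------------------------------------------------

def fd_slope_model(omega: float, n: float):
    """Homogeneous FD reflectance as a function of trial complex attenuation."""
    def model(k, rho):
        return _reflectance_from_complex_mueff(k, omega, n, rho)
    return model


def cw_slope_model(musp, n: float):
    """Homogeneous CW reflectance as a function of trial real attenuation.

    ``musp`` is the (known) reduced scattering at the wavelength being fitted.
    """
    def model(k, rho):
        return _reflectance_from_mueff(k, musp, rho, n)
    return model


def _linearized(value, rho):
    return np.log(rho**2 * value)


def fit_effective_attenuation(reflectances, distances, model, *,
                              tol=1e-9, max_iter=200):
    """Fit the effective attenuation from reflectance at two distances.

    The measured datum is the linearized slope of ln(rho^2 * R) between the
    two distances; the fit starts at its asymptote (slope = -mueff) and is
    refined by secant iterations on the full homogeneous model until the
    update falls below ``tol`` (relative).  Complex input yields the complex
    FD attenuation, real input the CW one.

    ``model(k, rho)`` must return the homogeneous reflectance for trial
    attenuation ``k``.
    """
    (r1, r2), (rho1, rho2) = reflectances, distances
    if rho1 == rho2:
        raise ValueError("the two distances must differ")
    target = _linearized(r1, rho1) - _linearized(r2, rho2)

    def g(k):
        return (_linearized(model(k, rho1), rho1)
                - _linearized(model(k, rho2), rho2)) - target

    k0 = target / (rho2 - rho1)  # asymptotic initial guess
    k1 = k0 * 1.05
    g0, g1 = g(k0), g(k1)
    for _ in range(max_iter):
        denom = g1 - g0
        if denom == 0:
            break
        k2 = k1 - g1 * (k1 - k0) / denom
        if abs(k2 - k1) <= tol * abs(k2):
            return k2
        k0, g0 = k1, g1
        k1 = k2
        g1 = g(k1)
    raise RuntimeError(
        f"effective-attenuation fit did not converge within {max_iter} "
        f"iterations; last iterates {k0!r}, {k1!r}"
    )


def _fit_mueff_cw_grid(cw, distances, musp, n, *, tol=1e-9, max_iter=200):
    """Vectorized CW slope fit across the whole wavelength grid.

    cw : (n_lambda, 2) reflectance, musp : (n_lambda,) pinned scattering.
    Returns mueff : (n_lambda,).
    """
    rho1, rho2 = distances
    target = _linearized(cw[:, 0], rho1) - _linearized(cw[:, 1], rho2)

    def g(k):
        r1 = _reflectance_from_mueff(k, musp, rho1, n)
        r2 = _reflectance_from_mueff(k, musp, rho2, n)
        return _linearized(r1, rho1) - _linearized(r2, rho2) - target

    k0 = target / (rho2 - rho1)
    k1 = k0 * 1.05
    g0, g1 = g(k0), g(k1)
    k = k1.copy()
    active = np.ones(k.shape, dtype=bool)
    for _ in range(max_iter):
        denom = g1 - g0
        step = np.where(denom != 0, g1 * (k1 - k0) / np.where(denom != 0, denom, 1.0), 0.0)
        k2 = k1 - step
        done = np.abs(k2 - k1) <= tol * np.abs(k2)
        k = np.where(active, k2, k)
        newly = active & done
        active &= ~done
        if not active.any():
            return k
        k0, g0 = k1.copy(), g1.copy()
        k1 = np.where(active, k2, k1)
        g1 = g(k1)
        _ = newly
    raise RuntimeError(
        f"CW effective-attenuation fit did not converge at "
        f"{int(active.sum())} wavelengths"
    )


# ---------------------------------------------------------------------------
# algebraic stages
# ---------------------------------------------------------------------------

def fd_optical_properties(mueff_complex: complex, omega: float, n: float):
    """(mua, mus') at one FD wavelength from the complex effective attenuation.

    With the exp(-i*omega*t) convention, mueff_tilde^2 = 3*mut'*(mua -
    i*omega*n/c), so mut' = -2*c*Re*Im/(3*n*omega) and mua = (Re^2 -
    Im^2)/(3*mut').
    """
    re, im = mueff_complex.real, mueff_complex.imag
    if im == 0.0:
        raise ValueError("purely real attenuation carries no FD information")
    mut = -2.0 * SPEED_OF_LIGHT_MM_S * re * im / (3.0 * n * omega)
    if mut <= 0.0:
        raise NonphysicalRecoveryError(
            f"recovered mut' = {mut:.4g} 1/mm <= 0 (mueff_tilde = {mueff_complex!r})"
        )
    mua = (re**2 - im**2) / (3.0 * mut)
    musp = mut - mua
    if musp <= 0.0:
        raise NonphysicalRecoveryError(
            f"recovered mus' = {musp:.4g} 1/mm <= 0 (mua = {mua:.4g}, mut' = {mut:.4g})"
        )
    return mua, musp


def scattering_extrapolation(musp690: float, musp830: float, grid):
    """Power-law exponent through the two FD mus' values, and the extrapolated
    mus' spectrum anchored at 830 nm.

    b_rec = ln(mus'(830)/mus'(690)) / ln(690/830).
    """
    if musp690 <= 0 or musp830 <= 0:
        raise ValueError("reduced scattering inputs must be positive")
    b_rec = np.log(musp830 / musp690) / np.log(690.0 / 830.0)
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    return float(b_rec), musp830 * (grid / 830.0) ** (-b_rec)


def broadband_absorption(mueff, musp):
    """mua = sqrt(mus'^2/4 + mueff^2/3) - mus'/2 (exact CW diffusion inverse)."""
    mueff = np.asarray(mueff, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if mueff.shape != musp.shape:
        raise ValueError("mueff and musp grids must match")
    if np.any(musp <= 0):
        raise ValueError("musp must be positive")
    return np.sqrt(musp**2 / 4.0 + mueff**2 / 3.0) - musp / 2.0


def unmix_chromophores(mua, basis) -> ChromophoreConcentrations:
    """Unconstrained least-squares chromophore unmixing via QR factorization.

    Solves E c = mua for c = (O, D, W, L) and maps to (T, S, W, L) with
    T = O + D, S = O/T (S is NaN when T = 0).  No non-negativity constraint
    is applied; out-of-range values are reported as-is.
    """
    mua = np.asarray(mua, dtype=float)
    basis = np.asarray(basis, dtype=float)
    if basis.shape[0] != mua.shape[0]:
        raise ValueError("basis and mua grids must match")
    if np.linalg.matrix_rank(basis) < basis.shape[1]:
        raise ValueError("extinction basis is rank deficient")
    q, r = np.linalg.qr(basis, mode="reduced")
    o, d, w, l = solve_triangular(r, q.T @ mua, lower=False)
    t = o + d
    s = o / t if t != 0.0 else float("nan")
    return ChromophoreConcentrations(thb_uM=t, so2=s, water=w, lipid=l)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def recover_all(data: ReflectanceSet, spec: InstrumentSpec | None = None,
                table: ExtinctionTable | None = None,
                basis: np.ndarray | None = None) -> RecoveredProperties:
    """Run the full homogeneous recovery pipeline on simulated data."""
    if spec is None:
        spec = InstrumentSpec()
    if basis is None:
        if table is None:
            table = load_default_extinction()
        basis = build_extinction_matrix(spec.cw_wavelengths, table)

    omega, n = spec.omega, spec.n_assumed
    model = fd_slope_model(omega, n)
    mua_fd = np.empty(len(data.fd_wavelengths))
    musp_fd = np.empty(len(data.fd_wavelengths))
    for i in range(len(data.fd_wavelengths)):
        try:
            k = fit_effective_attenuation(data.fd[i], data.distances_mm, model)
            mua_fd[i], musp_fd[i] = fd_optical_properties(k, omega, n)
        except Exception as exc:
            raise RuntimeError(
                f"FD recovery failed at {data.fd_wavelengths[i]:g} nm"
            ) from exc

    i690 = int(np.argmin(np.abs(data.fd_wavelengths - 690.0)))
    i830 = int(np.argmin(np.abs(data.fd_wavelengths - 830.0)))
    b_rec, musp_cw = scattering_extrapolation(
        musp_fd[i690], musp_fd[i830], data.cw_wavelengths
    )
    try:
        mueff_cw = _fit_mueff_cw_grid(data.cw, data.distances_mm, musp_cw, n)
    except Exception as exc:
        raise RuntimeError("CW effective-attenuation recovery failed") from exc
    mua_cw = broadband_absorption(mueff_cw, musp_cw)
    chrom = unmix_chromophores(mua_cw, basis)
    return RecoveredProperties(
        fd_wavelengths=np.asarray(data.fd_wavelengths, dtype=float),
        mua_fd=mua_fd,
        musp_fd=musp_fd,
        b_rec=b_rec,
        cw_wavelengths=np.asarray(data.cw_wavelengths, dtype=float),
        musp_cw=musp_cw,
        mueff_cw=mueff_cw,
        mua_cw=mua_cw,
        chromophores=chrom,
    )
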
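"""Diffusion-theory forward models: semi-infinite homogeneous and two-layer.

Geometry and conventions
------------------------
Photon-diffusion approximation with an isotropic point source at depth
z0 = 1/(mua + mus') and an extrapolated zero-fluence boundary at z = -zb,
zb = 2*D*(1 + R_eff)/(1 - R_eff), where D = 1/(3*(mua + mus')) and R_eff is
the effective Fresnel reflection coefficient of the tissue-air interface
(R_eff ~ 0.493 at n = 1.4).  "Reflectance" throughout is the outward Fick
flux D*dphi/dz of the extrapolated-boundary fluence, evaluated at the
physical surface z = 0, per unit source power; any constant measurand factor
cancels in the two-distance slopes used by the inversion, and the same
definition is used by the two-layer and homogeneous models so the
homogeneous-limit identity is exact by construction.

Frequency-domain quantities use the exp(-i*omega*t) time convention, so the
complex effective attenuation

    mueff_tilde = sqrt(3*(mua + mus')*(mua - i*omega*n/c))

has a positive real part and a negative imaginary part.  At omega = 0 all
expressions reduce exactly to the CW forms.

The two-layer medium (finite top layer over a semi-infinite bottom layer,
matched refractive index) is solved in the spatial-frequency domain and
inverted with an order-zero Hankel transform evaluated by Gauss-Legendre
quadrature.  When the source depth z0 exceeds the top-layer thickness (very
thin top layers) the solution branch with the source inside the bottom layer
is used.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.special import j0

from .spectra import (
    ChromophoreConcentrations,
    ExtinctionTable,
    ScatteringLaw,
    absorption_spectrum,
    build_extinction_matrix,
    load_default_extinction,
    reduced_scattering_spectrum,
)

__all__ = [
    "SPEED_OF_LIGHT_MM_S",
    "Layer",
    "TwoLayerMedium",
    "InstrumentSpec",
    "ReflectanceSet",
    "effective_reflection_coefficient",
    "homogeneous_reflectance",
    "two_layer_reflectance",
    "simulate_instrument",
    "simulate_cw",
]

SPEED_OF_LIGHT_MM_S = 2.99792458e11  # vacuum speed of light, mm/s

_DEFAULT_NODES = 2048  # Gauss-Legendre nodes for the inverse Hankel transform


@dataclass(frozen=True)
class Layer:
    """One homogeneous layer: chromophore state plus scattering law."""

    chromophores: ChromophoreConcentrations
    scattering: ScatteringLaw

    def optical_properties(self, grid, table: ExtinctionTable):
        """(mua, musp) spectra of this layer on ``grid``, 1/mm."""
        basis = build_extinction_matrix(grid, table)
        mua = absorption_spectrum(self.chromophores.validate(), basis)
        musp = reduced_scattering_spectrum(self.scattering, grid)
        return mua, musp


@dataclass(frozen=True)
class TwoLayerMedium:
    """Finite top layer of thickness ``z_top_mm`` over a semi-infinite bottom.

    Both layers share the refractive index ``n`` (default 1.4).
    """

    top: Layer
    bottom: Layer
    z_top_mm: float
    n: float = 1.4

    def __post_init__(self):
        if not self.z_top_mm > 0.0:
            raise ValueError(f"z_top_mm must be > 0, got {self.z_top_mm}")
        if not self.n >= 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")


def _default_cw_grid() -> np.ndarray:
    return np.arange(650.0, 1024.0 + 1e-9, 0.5)


@dataclass(frozen=True)
class InstrumentSpec:
    """Simulated broadband CW + two-wavelength FD instrument.

    Defaults: CW 650-1024 nm in 0.5 nm steps (749 wavelengths), FD at 690 and
    830 nm with 140.625 MHz modulation, source-detector distances 25 and
    35 mm, assumed refractive index 1.4.
    """

    cw_wavelengths: np.ndarray = field(default_factory=_default_cw_grid)
    fd_wavelengths: tuple[float, float] = (690.0, 830.0)
    distances_mm: tuple[float, float] = (25.0, 35.0)
    mod_freq_hz: float = 140.625e6
    n_assumed: float = 1.4

    @property
    def omega(self) -> float:
        """Angular modulation frequency, rad/s."""
        return 2.0 * np.pi * self.mod_freq_hz


@dataclass
class ReflectanceSet:
    """Simulated instrument output on the (wavelength, distance) grids.

    cw : (n_cw, n_rho) real reflectance
    fd : (n_fd, n_rho) complex reflectance phasors
    """

    cw: np.ndarray
    fd: np.ndarray
    cw_wavelengths: np.ndarray
    fd_wavelengths: np.ndarray
    distances_mm: np.ndarray

    def __post_init__(self):
        self.cw = np.asarray(self.cw, dtype=float)
        self.fd = np.asarray(self.fd, dtype=complex)
        self.cw_wavelengths = np.asarray(self.cw_wavelengths, dtype=float)
        self.fd_wavelengths = np.asarray(self.fd_wavelengths, dtype=float)
        self.distances_mm = np.asarray(self.distances_mm, dtype=float)
        if self.cw.shape != (len(self.cw_wavelengths), len(self.distances_mm)):
            raise ValueError("cw array shape does not match grids")
        if self.fd.shape != (len(self.fd_wavelengths), len(self.distances_mm)):
            raise ValueError("fd array shape does not match grids")
        if np.any(self.cw <= 0) or np.any(np.abs(self.fd) <= 0):
            raise ValueError("reflectance values must be positive in magnitude")

    def to_frame(self):
        """Long-format table: wavelength_nm, rho_mm, domain, value_real, value_imag."""
        import pandas as pd

        rows = []
        for j, rho in enumerate(self.distances_mm):
            for wl, v in zip(self.cw_wavelengths, self.cw[:, j]):
                rows.append((wl, rho, "cw", v, 0.0))
            for wl, v in zip(self.fd_wavelengths, self.fd[:, j]):
                rows.append((wl, rho, "fd", v.real, v.imag))
        return pd.DataFrame(
            rows, columns=["wavelength_nm", "rho_mm", "domain", "value_real", "value_imag"]
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        import pandas as pd

        df = pd.read_csv(path)
        rhos = np.unique(df["rho_mm"].to_numpy())
        out = {}
        for dom in ("cw", "fd"):
            sub = df[df["domain"] == dom]
            wls = np.unique(sub["wavelength_nm"].to_numpy())
            arr = np.empty((len(wls), len(rhos)), dtype=complex)
            for j, rho in enumerate(rhos):
                s = sub[sub["rho_mm"] == rho].sort_values("wavelength_nm")
                arr[:, j] = s["value_real"].to_numpy() + 1j * s["value_imag"].to_numpy()
            out[dom] = (wls, arr)
        return cls(
            cw=out["cw"][1].real,
            fd=out["fd"][1],
            cw_wavelengths=out["cw"][0],
            fd_wavelengths=out["fd"][0],
            distances_mm=rhos,
        )


# ---------------------------------------------------------------------------
# boundary condition
# ---------------------------------------------------------------------------

def _fresnel_unpolarized(cos_i: float, n: float) -> float:
    """Fresnel reflectance for light inside the medium (index n) hitting air."""
    sin_i = np.sqrt(max(0.0, 1.0 - cos_i**2))
    sin_t = n * sin_i
    if sin_t >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t**2)
    rs = (n * cos_i - cos_t) / (n * cos_i + cos_t)
    rp = (n * cos_t - cos_i) / (n * cos_t + cos_i)
    return 0.5 * (rs**2 + rp**2)


@lru_cache(maxsize=16)
def effective_reflection_coefficient(n: float) -> float:
    """Effective internal reflection coefficient R_eff of a tissue-air boundary.

    Computed from the angular integrals of the unpolarized Fresnel reflectance
    (R_eff = (R_phi + R_j) / (2 - R_phi + R_j)); ~0.493 for n = 1.4.
    """
    if n == 1.0:
        return 0.0
    r_phi = quad(lambda t: 2.0 * np.sin(t) * np.cos(t) * _fresnel_unpolarized(np.cos(t), n),
                 0.0, np.pi / 2.0, limit=200)[0]
    r_j = quad(lambda t: 3.0 * np.sin(t) * np.cos(t) ** 2 * _fresnel_unpolarized(np.cos(t), n),
               0.0, np.pi / 2.0, limit=200)[0]
    return (r_phi + r_j) / (2.0 - r_phi + r_j)


def _diffusion_lengths(mua, musp, n):
    """(D, z0, zb) for given optical properties, all in mm."""
    mut = mua + musp
    D = 1.0 / (3.0 * mut)
    z0 = 1.0 / mut
    reff = effective_reflection_coefficient(float(n))
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    return D, z0, zb


def _k_squared(mua, musp, n, omega):
    """Complex squared attenuation 3*mut'*(mua - i*omega*n/c)."""
    mut = mua + musp
    return 3.0 * mut * (mua - 1j * omega * n / SPEED_OF_LIGHT_MM_S)


# ---------------------------------------------------------------------------
# homogeneous semi-infinite model
# ---------------------------------------------------------------------------

def _two_source_flux(k, z0, zb, rho):
    """Outward boundary flux of the source/image pair (Fick's law at z = 0)."""
    r1 = np.sqrt(rho**2 + z0**2)
    zi = z0 + 2.0 * zb
    r2 = np.sqrt(rho**2 + zi**2)
    return (z0 * (k + 1.0 / r1) * np.exp(-k * r1) / r1**2
            + zi * (k + 1.0 / r2) * np.exp(-k * r2) / r2**2) / (4.0 * np.pi)


def homogeneous_reflectance(mua, musp, rho, n=1.4, omega=0.0):
    """Diffuse reflectance of a semi-infinite homogeneous medium.

    Two-monopole (source + extrapolated-boundary image) flux form.  Returns a
    complex phasor for omega > 0 and a real value for omega = 0.  Supports
    numpy broadcasting over ``mua``/``musp``/``rho``.
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if np.any(mua < 0) or np.any(musp <= 0):
        raise ValueError("require mua >= 0 and musp > 0")
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be positive")
    if np.any(rho < 1.0 / (mua + musp)):
        warnings.warn(
            "source-detector distance inside one transport mean free path; "
            "diffusion theory is inaccurate here",
            stacklevel=2,
        )
    _, z0, zb = _diffusion_lengths(mua, musp, n)
    k = np.sqrt(_k_squared(mua, musp, n, omega))
    flux = _two_source_flux(k, z0, zb, rho)
    if omega == 0.0:
        flux = flux.real
        return flux if flux.ndim else float(flux)
    return flux


def _reflectance_from_mueff(mueff, musp, rho, n):
    """Homogeneous CW reflectance parameterized by (mueff, musp).

    mua follows from mueff^2 = 3*mua*(mua + musp).  Used by the iterative CW
    slope fit; vectorized over mueff/musp.
    """
    mua = np.sqrt(musp**2 / 4.0 + mueff**2 / 3.0) - musp / 2.0
    _, z0, zb = _diffusion_lengths(mua, musp, n)
    return _two_source_flux(mueff, z0, zb, rho)


def _reflectance_from_complex_mueff(k, omega, n, rho):
    """Homogeneous FD reflectance parameterized by the complex attenuation k.

    (mut', z0, zb) follow from k via the algebraic relations of the
    exp(-i*omega*t) convention; requires Im(k) < 0.
    """
    mut = -2.0 * SPEED_OF_LIGHT_MM_S * k.real * k.imag / (3.0 * n * omega)
    D = 1.0 / (3.0 * mut)
    z0 = 1.0 / mut
    reff = effective_reflection_coefficient(float(n))
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    return _two_source_flux(k, z0, zb, rho)


# ---------------------------------------------------------------------------
# two-layer model
# ---------------------------------------------------------------------------

def _two_layer_hat(s, mua1, musp1, mua2, musp2, z_top, n, omega):
    """Spatial-frequency-domain surface fluence of the two-layer medium.

    Parameters are broadcast: optical properties have shape (n_lambda, 1) and
    ``s`` shape (n_nodes,); the result has shape (n_lambda, n_nodes).  All
    hyperbolic terms are evaluated in exponentially scaled form so the
    expression stays finite for arbitrarily thick top layers.
    """
    mut1 = mua1 + musp1
    mut2 = mua2 + musp2
    D1 = 1.0 / (3.0 * mut1)
    D2 = 1.0 / (3.0 * mut2)
    z0 = 1.0 / mut1
    reff = effective_reflection_coefficient(float(n))
    zb = 2.0 * D1 * (1.0 + reff) / (1.0 - reff)

    a1 = np.sqrt(s**2 + _k_squared(mua1, musp1, n, omega))
    a2 = np.sqrt(s**2 + _k_squared(mua2, musp2, n, omega))
    beta = D1 * a1
    gamma = D2 * a2
    L = z_top + zb

    # cosh/sinh(a1*x) scaled by exp(-a1*L): exponents are all non-positive
    def chat(x):
        return 0.5 * (np.exp(a1 * (x - L)) + np.exp(-a1 * (x + L)))

    def shat(x):
        return 0.5 * (np.exp(a1 * (x - L)) - np.exp(-a1 * (x + L)))

    den = beta * chat(L) + gamma * shat(L)
    # flux measurand: D1*dphi/dz at z=0 replaces sinh(a1*zb) by beta*cosh(a1*zb)
    flux_fac = beta * np.cosh(a1 * zb)

    deep = z0 >= z_top  # thin-top branch: source sits in the bottom layer
    x1 = np.where(deep, 0.0, z_top - z0)  # guard: only used where ~deep
    num_a = flux_fac * (beta * chat(x1) + gamma * shat(x1))
    phi_a = num_a / (beta * den)
    num_b = flux_fac * np.exp(-a2 * np.where(deep, z0 - z_top, 0.0) - a1 * L)
    phi_b = num_b / den
    return np.where(deep, phi_b, phi_a)


@lru_cache(maxsize=8)
def _gauss_legendre(n_nodes: int):
    from scipy.special import roots_legendre

    x, w = roots_legendre(n_nodes)
    return x, w


def _two_layer_reflectance_props(mua1, musp1, mua2, musp2, z_top, n, rho, omega,
                                 n_nodes=_DEFAULT_NODES):
    """Two-layer surface fluence for per-wavelength optical-property arrays.

    mua1..musp2 : (n_lambda,) arrays; returns (n_lambda,) complex (real part
    is the CW reflectance when omega = 0).
    """
    mua1, musp1, mua2, musp2 = (np.atleast_1d(np.asarray(a, dtype=float))
                                for a in (mua1, musp1, mua2, musp2))
    mut1 = mua1 + musp1
    D1 = 1.0 / (3.0 * mut1)
    reff = effective_reflection_coefficient(float(n))
    zb = 2.0 * D1 * (1.0 + reff) / (1.0 - reff)
    z0 = 1.0 / mut1
    # integrand envelope ~ exp(-s*z0); resolve it to ~1e-13 of its peak
    smax = 30.0 / float(np.min(z0)) + 2.0
    x, w = _gauss_legendre(int(n_nodes))
    s = 0.5 * smax * (x + 1.0)
    ws = 0.5 * smax * w

    hat = _two_layer_hat(
        s[None, :], mua1[:, None], musp1[:, None], mua2[:, None], musp2[:, None],
        z_top, n, omega,
    )
    kern = j0(s * rho) * s * ws / (2.0 * np.pi)
    return hat @ kern


def two_layer_reflectance(medium: TwoLayerMedium, wavelength, rho, omega=0.0,
                          table: ExtinctionTable | None = None,
                          n_nodes=_DEFAULT_NODES):
    """Diffuse reflectance of a two-layer medium at one wavelength and distance.

    Layer optical properties are derived from the medium's chromophore and
    scattering parameters via the bundled (or given) extinction table.
    Returns a real value for omega = 0 and a complex phasor otherwise.
    """
    if table is None:
        table = load_default_extinction()
    wl = np.atleast_1d(float(wavelength))
    mua1, musp1 = medium.top.optical_properties(wl, table)
    mua2, musp2 = medium.bottom.optical_properties(wl, table)
    val = _two_layer_reflectance_props(
        mua1, musp1, mua2, musp2, medium.z_top_mm, medium.n, float(rho), omega,
        n_nodes=n_nodes,
    )[0]
    check = _two_layer_reflectance_props(
        mua1, musp1, mua2, musp2, medium.z_top_mm, medium.n, float(rho), omega,
        n_nodes=int(n_nodes) // 2,
    )[0]
    if abs(val - check) > 1e-6 * abs(val) + 1e-300:
        raise RuntimeError(
            f"Hankel quadrature not converged at {wavelength} nm, rho={rho} mm: "
            f"achieved relative tolerance {abs(val - check) / abs(val):.2e}"
        )
    return float(val.real) if omega == 0.0 else complex(val)


def _layer_spectra(medium: TwoLayerMedium, grid, table: ExtinctionTable):
    mua1, musp1 = medium.top.optical_properties(grid, table)
    mua2, musp2 = medium.bottom.optical_properties(grid, table)
    return mua1, musp1, mua2, musp2


def simulate_cw(medium: TwoLayerMedium, spec: InstrumentSpec,
                table: ExtinctionTable | None = None,
                n_nodes=_DEFAULT_NODES) -> np.ndarray:
    """CW reflectance array of shape (n_cw_wavelengths, n_distances)."""
    if table is None:
        table = load_default_extinction()
    mua1, musp1, mua2, musp2 = _layer_spectra(medium, spec.cw_wavelengths, table)
    cols = [
        _two_layer_reflectance_props(
            mua1, musp1, mua2, musp2, medium.z_top_mm, medium.n, rho, 0.0, n_nodes
        ).real
        for rho in spec.distances_mm
    ]
    return np.column_stack(cols)


def simulate_instrument(medium: TwoLayerMedium, spec: InstrumentSpec | None = None,
                        table: ExtinctionTable | None = None,
                        n_nodes=_DEFAULT_NODES) -> ReflectanceSet:
    """Simulate the full instrument output for a two-layer medium.

    Under the default :class:`InstrumentSpec` this yields 749 x 2 CW
    reflectances and 2 x 2 FD reflectance phasors.
    """
    if spec is None:
        spec = InstrumentSpec()
    if table is None:
        table = load_default_extinction()
    cw = simulate_cw(medium, spec, table, n_nodes)
    fd_wl = np.asarray(spec.fd_wavelengths, dtype=float)
    mua1, musp1, mua2, musp2 = _layer_spectra(medium, fd_wl, table)
    fd = np.column_stack([
        _two_layer_reflectance_props(
            mua1, musp1, mua2, musp2, medium.z_top_mm, medium.n, rho, spec.omega, n_nodes
        )
        for rho in spec.distances_mm
    ])
    return ReflectanceSet(
        cw=cw,
        fd=fd,
        cw_wavelengths=spec.cw_wavelengths,
        fd_wavelengths=fd_wl,
        distances_mm=np.asarray(spec.distances_mm, dtype=float),
    )
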
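"""Chromophore spectra and scattering laws.

Per-layer absorption spectra are linear combinations of chromophore basis
spectra (oxyhemoglobin O, deoxyhemoglobin D, water W, lipid L),

    mua(lambda) = eps_O(lambda)*O + eps_D(lambda)*D + mua_W(lambda)*W
                  + mua_L(lambda)*L,

with O = S*T and D = (1 - S)*T, where T is total hemoglobin (uM) and S the
hemoglobin oxygen saturation (fraction).  W and L are volume fractions that
scale the pure-water / pure-lipid absorption coefficients.  Reduced
scattering follows the power law mus'(lambda) = mus'(830 nm) * (lambda/830)^-b.

Internal units are natural-log absorption: eps_O/eps_D in 1/mm per uM,
mua_W/mua_L in 1/mm at unit volume fraction.  The bundled hemoglobin table is
decadic molar extinction and is converted once at load time.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "ExtinctionTable",
    "ChromophoreConcentrations",
    "ScatteringLaw",
    "load_default_extinction",
    "build_extinction_matrix",
    "absorption_spectrum",
    "reduced_scattering_spectrum",
]

#: decadic 1/(cm*M)  ->  natural-log 1/mm per uM
_DECADIC_PER_M_CM_TO_LN_PER_UM_MM = np.log(10.0) * 1e-7


@dataclass(frozen=True)
class ChromophoreConcentrations:
    """Chromophore state of one layer (or a recovered effective medium).

    thb_uM : total hemoglobin T = O + D, uM
    so2    : hemoglobin oxygen saturation S = O/T, fraction
    water  : water volume fraction
    lipid  : lipid volume fraction

    Forward-model inputs must be physical (``validate``); recovered instances
    come from an unconstrained linear inversion and may fall outside these
    ranges, so validation is not applied on construction.
    """

    thb_uM: float
    so2: float
    water: float
    lipid: float

    def validate(self) -> "ChromophoreConcentrations":
        if not self.thb_uM >= 0.0:
            raise ValueError(f"total hemoglobin must be >= 0, got {self.thb_uM}")
        for name, v in (("so2", self.so2), ("water", self.water), ("lipid", self.lipid)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        return self

    @property
    def oxy_uM(self) -> float:
        # S is undefined (NaN) when T = 0, but O = S*T is still zero
        return self.so2 * self.thb_uM if self.thb_uM != 0.0 else 0.0

    @property
    def deoxy_uM(self) -> float:
        return (1.0 - self.so2) * self.thb_uM if self.thb_uM != 0.0 else 0.0

    def as_vector(self) -> np.ndarray:
        """Concentration vector (O, D, W, L) matching the basis column order."""
        return np.array([self.oxy_uM, self.deoxy_uM, self.water, self.lipid])

    def as_tswl_vector(self) -> np.ndarray:
        """Parameter vector (T, S, W, L); T in uM, the rest fractions."""
        return np.array([self.thb_uM, self.so2, self.water, self.lipid])


@dataclass(frozen=True)
class ScatteringLaw:
    """Reduced-scattering power law anchored at 830 nm."""

    musp830: float  # 1/mm
    power: float    # dimensionless exponent b

    def __post_init__(self):
        if not self.musp830 > 0.0:
            raise ValueError(f"musp830 must be > 0, got {self.musp830}")


class ExtinctionTable:
    """Wavelength-gridded chromophore basis spectra in internal units.

    Attributes
    ----------
    wavelengths : (n,) strictly increasing, nm
    eps_o, eps_d : 1/mm per uM (natural log)
    mua_w, mua_l : 1/mm at unit volume fraction (natural log)
    """

    def __init__(self, wavelengths, eps_o, eps_d, mua_w, mua_l):
        wavelengths = np.asarray(wavelengths, dtype=float)
        if wavelengths.ndim != 1 or len(wavelengths) < 2:
            raise ValueError("wavelength grid must be a 1-D array of length >= 2")
        if not np.all(np.diff(wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        cols = [np.asarray(c, dtype=float) for c in (eps_o, eps_d, mua_w, mua_l)]
        for c in cols:
            if c.shape != wavelengths.shape:
                raise ValueError("spectrum length does not match wavelength grid")
            if not np.all(np.isfinite(c)) or np.any(c < 0):
                raise ValueError("spectra must be finite and non-negative")
        self.wavelengths = wavelengths
        self.eps_o, self.eps_d, self.mua_w, self.mua_l = cols

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])


def load_default_extinction() -> ExtinctionTable:
    """Load the bundled literature spectra (650-1030 nm, 2 nm grid).

    Hemoglobin is a compiled literature tabulation in decadic molar extinction
    (converted here); water and lipid are pure-substance absorption
    coefficients in 1/cm and 1/mm respectively (see the data-file headers for
    provenance; the water and lipid files are reconstructed stand-ins for the
    cited tabulations).
    """
    data = resources.files("bilayerdos") / "data"
    hb = np.loadtxt(str(data / "hemoglobin_extinction.tsv"))
    wa = np.loadtxt(str(data / "water_absorption_synthetic.tsv"))
    li = np.loadtxt(str(data / "lipid_absorption_synthetic.tsv"))
    if not (np.array_equal(hb[:, 0], wa[:, 0]) and np.array_equal(hb[:, 0], li[:, 0])):
        raise ValueError("bundled spectra tables are on inconsistent grids")
    return ExtinctionTable(
        wavelengths=hb[:, 0],
        eps_o=hb[:, 1] * _DECADIC_PER_M_CM_TO_LN_PER_UM_MM,
        eps_d=hb[:, 2] * _DECADIC_PER_M_CM_TO_LN_PER_UM_MM,
        mua_w=wa[:, 1] * 0.1,  # 1/cm -> 1/mm
        mua_l=li[:, 1],
    )


def build_extinction_matrix(grid, table: ExtinctionTable) -> np.ndarray:
    """Assemble the (n_wavelengths, 4) chromophore basis matrix E.

    Columns are ordered (O, D, W, L).  Values are linearly interpolated in
    wavelength from the table; requesting a wavelength outside the tabulated
    range is an error.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    lo, hi = table.range_nm
    bad = (grid < lo) | (grid > hi)
    if np.any(bad):
        raise ValueError(
            f"wavelength {grid[bad][0]:g} nm outside tabulated range [{lo:g}, {hi:g}] nm"
        )
    cols = [np.interp(grid, table.wavelengths, c)
            for c in (table.eps_o, table.eps_d, table.mua_w, table.mua_l)]
    return np.column_stack(cols)


def absorption_spectrum(c: ChromophoreConcentrations, basis: np.ndarray) -> np.ndarray:
    """mua(lambda) = E @ (O, D, W, L), in 1/mm."""
    basis = np.asarray(basis, dtype=float)
    if basis.ndim != 2 or basis.shape[1] != 4:
        raise ValueError("basis must have four columns (O, D, W, L)")
    return basis @ c.as_vector()


def reduced_scattering_spectrum(law: ScatteringLaw, grid) -> np.ndarray:
    """Evaluate mus'(lambda) = mus'(830 nm) * (lambda / 830 nm)^-b, in 1/mm."""
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if np.any(grid <= 0):
        raise ValueError("wavelengths must be positive")
    return law.musp830 * (grid / 830.0) ** (-law.power)
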
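"""The simulation study: baseline tables, parameter sweeps, sensitivity sweeps.

All inputs are simulated two-layer media; this module doubles as the
repository's data generator.  The baseline medium is

    top:    T = 12 uM, S = 83%, W = 5%,  L = 70%, mus'(830) = 0.60/mm, b = 0.1
    bottom: T = 120 uM, S = 67%, W = 90%, L = 20%, mus'(830) = 0.40/mm, b = 1.5

with a 5 mm top layer and n = 1.4, probed by the default broadband CW +
two-wavelength FD instrument.  Sweeps vary exactly one of the 13 medium
parameters at a time (no co-variation) and re-run the full recovery, or the
full sensitivity matrix, at every grid point.  Everything is deterministic.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import InstrumentSpec, Layer, TwoLayerMedium, simulate_instrument
from .inversion import RecoveredProperties, recover_all
from .sensitivity import SensitivityMatrix, sensitivity_matrix
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
    "MEDIUM_PARAMETERS",
    "baseline_medium",
    "default_instrument",
    "BaselineStudy",
    "baseline_study",
    "SweepSpec",
    "default_sweep_grid",
    "absolute_sweep",
    "sensitivity_sweep",
    "set_medium_parameter",
    "get_medium_parameter",
]

#: addressable medium parameters: ("top"|"bottom", field) plus ("z_top",)
MEDIUM_PARAMETERS = tuple(
    (layer, name)
    for layer in ("top", "bottom")
    for name in ("thb_uM", "so2", "water", "lipid", "musp830", "power")
) + (("z_top",),)

_REPORT_WAVELENGTHS = (650.0, 775.0, 900.0, 1024.0)


def baseline_medium(z_top_mm: float = 5.0) -> TwoLayerMedium:
    """The study's baseline two-layer medium."""
    top = Layer(
        ChromophoreConcentrations(thb_uM=12.0, so2=0.83, water=0.05, lipid=0.70),
        ScatteringLaw(musp830=0.60, power=0.1),
    )
    bottom = Layer(
        ChromophoreConcentrations(thb_uM=120.0, so2=0.67, water=0.90, lipid=0.20),
        ScatteringLaw(musp830=0.40, power=1.5),
    )
    return TwoLayerMedium(top=top, bottom=bottom, z_top_mm=z_top_mm)


def default_instrument() -> InstrumentSpec:
    return InstrumentSpec()


def set_medium_parameter(medium: TwoLayerMedium, parameter, value: float) -> TwoLayerMedium:
    """Return a copy of ``medium`` with one addressable parameter replaced."""
    if parameter == ("z_top",) or parameter == "z_top":
        return dataclasses.replace(medium, z_top_mm=float(value))
    layer, name = parameter
    lay: Layer = getattr(medium, layer)
    if name in ("musp830", "power"):
        new = dataclasses.replace(lay, scattering=dataclasses.replace(lay.scattering, **{name: float(value)}))
    else:
        new = dataclasses.replace(lay, chromophores=dataclasses.replace(lay.chromophores, **{name: float(value)}))
    return dataclasses.replace(medium, **{layer: new})


def get_medium_parameter(medium: TwoLayerMedium, parameter) -> float:
    if parameter == ("z_top",) or parameter == "z_top":
        return medium.z_top_mm
    layer, name = parameter
    lay: Layer = getattr(medium, layer)
    holder = lay.scattering if name in ("musp830", "power") else lay.chromophores
    return getattr(holder, name)


# ---------------------------------------------------------------------------
# baseline tables
# ---------------------------------------------------------------------------

@dataclass
class BaselineStudy:
    """Reproduction of the four baseline tables.

    absorption : actual and recovered T, S, W, L and mua at four report
        wavelengths (rows Top actual / Bottom actual / Recovered)
    scattering : actual and recovered mus'(830), b, mus'(690)
    co_sensitivities : 2 x 4 like-parameter sensitivities
    sensitivities : full 8 x 4 sensitivity matrix
    """

    absorption: pd.DataFrame
    scattering: pd.DataFrame
    co_sensitivities: pd.DataFrame
    sensitivities: pd.DataFrame
    recovered: RecoveredProperties
    matrix: SensitivityMatrix

    def write(self, outdir):
        import os

        os.makedirs(outdir, exist_ok=True)
        self.absorption.to_csv(os.path.join(outdir, "baseline_absorption.csv"))
        self.scattering.to_csv(os.path.join(outdir, "baseline_scattering.csv"))
        self.co_sensitivities.to_csv(os.path.join(outdir, "baseline_co_sensitivities.csv"))
        self.matrix.to_csv(os.path.join(outdir, "baseline_sensitivities.csv"))
        self.recovered.spectra_frame().to_csv(
            os.path.join(outdir, "baseline_recovered_spectra.csv"), index=False
        )


def _absorption_row(c: ChromophoreConcentrations, basis: np.ndarray) -> list:
    mua = absorption_spectrum(c, basis)
    return [c.thb_uM, 100 * c.so2, 100 * c.water, 100 * c.lipid, *mua]


def baseline_study(medium: TwoLayerMedium | None = None,
                   spec: InstrumentSpec | None = None,
                   table: ExtinctionTable | None = None) -> BaselineStudy:
    """Run the full baseline pipeline and assemble the four study tables."""
    if medium is None:
        medium = baseline_medium()
    if spec is None:
        spec = default_instrument()
    if table is None:
        table = load_default_extinction()

    data = simulate_instrument(medium, spec, table)
    rec = recover_all(data, spec, table)
    matrix = sensitivity_matrix(medium, spec, table, baseline_rec=rec)

    report_basis = build_extinction_matrix(_REPORT_WAVELENGTHS, table)
    cols = ["T_uM", "S_pct", "W_pct", "L_pct"] + [
        f"mua_{int(w)}nm" for w in _REPORT_WAVELENGTHS
    ]
    c = rec.chromophores
    mua_rec = np.interp(_REPORT_WAVELENGTHS, rec.cw_wavelengths, rec.mua_cw)
    absorption = pd.DataFrame(
        [
            _absorption_row(medium.top.chromophores, report_basis),
            _absorption_row(medium.bottom.chromophores, report_basis),
            [c.thb_uM, 100 * c.so2, 100 * c.water, 100 * c.lipid, *mua_rec],
        ],
        index=["Top actual", "Bottom actual", "Recovered"],
        columns=cols,
    )

    def _sc_row(law: ScatteringLaw):
        return [law.musp830, law.power, float(reduced_scattering_spectrum(law, [690.0])[0])]

    i830 = int(np.argmin(np.abs(rec.fd_wavelengths - 830.0)))
    i690 = int(np.argmin(np.abs(rec.fd_wavelengths - 690.0)))
    scattering = pd.DataFrame(
        [
            _sc_row(medium.top.scattering),
            _sc_row(medium.bottom.scattering),
            [rec.musp_fd[i830], rec.b_rec, rec.musp_fd[i690]],
        ],
        index=["Top actual", "Bottom actual", "Recovered"],
        columns=["musp830_per_mm", "b", "musp690_per_mm"],
    )
    return BaselineStudy(
        absorption=absorption,
        scattering=scattering,
        co_sensitivities=matrix.co_sensitivities,
        sensitivities=matrix.entries,
        recovered=rec,
        matrix=matrix,
    )


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """One-parameter sweep specification.

    ``parameter`` is one of :data:`MEDIUM_PARAMETERS`; exactly one parameter
    is varied while all others stay at the baseline values.
    """

    parameter: tuple
    values: np.ndarray
    baseline: TwoLayerMedium = field(default_factory=baseline_medium)
    instrument: InstrumentSpec = field(default_factory=default_instrument)

    def __post_init__(self):
        key = self.parameter if isinstance(self.parameter, tuple) else (self.parameter,)
        if tuple(key) not in MEDIUM_PARAMETERS:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")
        self.parameter = tuple(key)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("sweep values must be a non-empty 1-D grid")

    @property
    def label(self) -> str:
        if self.parameter == ("z_top",):
            return "z_top_mm"
        layer, name = self.parameter
        return f"{name}_{layer}"


def default_sweep_grid(parameter, baseline: TwoLayerMedium | None = None,
                       n_points: int = 15) -> np.ndarray:
    """Default sweep grid for one parameter.

    Concentrations and scattering amplitude span +/-80% of baseline;
    fractional parameters span [0, 1] (trimmed to stay physical); the
    scattering exponent spans 0-2.5 and the top thickness 1-15 mm.
    """
    if baseline is None:
        baseline = baseline_medium()
    key = tuple(parameter) if isinstance(parameter, tuple) else (parameter,)
    if key == ("z_top",):
        return np.linspace(1.0, 15.0, n_points)
    _, name = key
    if name in ("so2", "water", "lipid"):
        return np.linspace(0.0, 1.0, n_points)
    if name == "power":
        return np.linspace(0.0, 2.5, n_points)
    v0 = get_medium_parameter(baseline, key)
    return np.linspace(0.2 * v0, 1.8 * v0, n_points)


def absolute_sweep(spec: SweepSpec, table: ExtinctionTable | None = None) -> pd.DataFrame:
    """Recovered properties along a one-parameter sweep.

    Each row holds the varied value, the recovered (T, S, W, L, mus'(830), b)
    and the actual top/bottom values of the swept parameter for reference.
    Failures at individual grid points are recorded as NaN rows with the
    error message, and the sweep continues.
    """
    if table is None:
        table = load_default_extinction()
    rows = []
    for v in spec.values:
        medium = set_medium_parameter(spec.baseline, spec.parameter, v)
        row = {spec.label: v}
        try:
            rec = recover_all(simulate_instrument(medium, spec.instrument, table),
                              spec.instrument, table)
            c = rec.chromophores
            i830 = int(np.argmin(np.abs(rec.fd_wavelengths - 830.0)))
            row.update(
                T_uM=c.thb_uM, S=c.so2, W=c.water, L=c.lipid,
                musp830_rec=rec.musp_fd[i830], b_rec=rec.b_rec, error="",
            )
        except Exception as exc:  # per-point failure: record and continue
            row.update(T_uM=np.nan, S=np.nan, W=np.nan, L=np.nan,
                       musp830_rec=np.nan, b_rec=np.nan, error=str(exc))
        for which in ("top", "bottom"):
            if spec.parameter == ("z_top",):
                break
            row[f"actual_{which}"] = get_medium_parameter(
                medium, (which, spec.parameter[1])
            )
        rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_sweep(spec: SweepSpec, table: ExtinctionTable | None = None,
                      steps: dict | None = None) -> pd.DataFrame:
    """Co-sensitivities along a one-parameter sweep (the full matrix is
    recomputed at every grid point; cross-sensitivities are not recorded)."""
    if table is None:
        table = load_default_extinction()
    rows = []
    for v in spec.values:
        medium = set_medium_parameter(spec.baseline, spec.parameter, v)
        row = {spec.label: v}
        try:
            co = sensitivity_matrix(medium, spec.instrument, table, steps=steps).co_sensitivities
            for layer in ("Top", "Bottom"):
                for p in ("T", "S", "W", "L"):
                    row[f"d{p}/d{p}_{layer}"] = co.loc[layer, p]
            row["error"] = ""
        except Exception as exc:
            for layer in ("Top", "Bottom"):
                for p in ("T", "S", "W", "L"):
                    row[f"d{p}/d{p}_{layer}"] = np.nan
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
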
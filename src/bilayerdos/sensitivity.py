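"""Sensitivity of recovered absorption parameters to layer absorption changes.

Each sensitivity is a numerical partial derivative: one of the eight layer
absorption parameters (T, S, W, L in the top or bottom layer) is perturbed by
a small amount, the CW data are re-simulated, and the change of the recovered
effective homogeneous parameter is divided by the applied change.  Throughout
a sensitivity computation the scattering recovered from FD (mus' spectrum and
b) stays pinned at its baseline value — the experimental analogue of taking
one FD measurement at baseline and tracking dynamics with CW only — so
cross-talk with scattering is excluded by construction.

Co-sensitivities relate like parameters (e.g. dT/dT_top); cross-sensitivities
relate unlike parameters and quantify cross-talk.  Entries mixing units carry
the ratio's units (e.g. dS/dT_top in 1/uM); nothing is expressed in percent.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forward import InstrumentSpec, Layer, TwoLayerMedium, simulate_cw
from .inversion import (
    RecoveredProperties,
    _fit_mueff_cw_grid,
    broadband_absorption,
    recover_all,
    unmix_chromophores,
)
from .spectra import ChromophoreConcentrations, ExtinctionTable, build_extinction_matrix, load_default_extinction

__all__ = [
    "ABSORPTION_PARAMETERS",
    "SensitivityMatrix",
    "perturbed_recovery",
    "sensitivity_matrix",
]

logger = logging.getLogger(__name__)

#: the eight independent absorption variables, in table layout order
ABSORPTION_PARAMETERS = tuple(
    (layer, name) for layer in ("top", "bottom") for name in ("thb_uM", "so2", "water", "lipid")
)

_SHORT = {"thb_uM": "T", "so2": "S", "water": "W", "lipid": "L"}

#: default perturbations: relative for T, absolute (fraction) for S, W, L
DEFAULT_STEPS = {"thb_uM": ("relative", 0.005), "so2": ("absolute", 0.005),
                 "water": ("absolute", 0.005), "lipid": ("absolute", 0.005)}


def _with_parameter(medium: TwoLayerMedium, layer: str, name: str, value: float) -> TwoLayerMedium:
    lay: Layer = getattr(medium, layer)
    chrom = dataclasses.replace(lay.chromophores, **{name: value})
    return dataclasses.replace(medium, **{layer: dataclasses.replace(lay, chromophores=chrom)})


def _step_size(name: str, baseline_value: float, steps) -> float:
    kind, size = (steps or DEFAULT_STEPS)[name]
    return size * baseline_value if kind == "relative" else size


def _valid(name: str, value: float) -> bool:
    return value >= 0.0 if name == "thb_uM" else 0.0 <= value <= 1.0


def perturbed_recovery(baseline: TwoLayerMedium, layer: str, name: str, step: float,
                       baseline_rec: RecoveredProperties,
                       spec: InstrumentSpec | None = None,
                       table: ExtinctionTable | None = None,
                       basis: np.ndarray | None = None) -> ChromophoreConcentrations:
    """Recovered chromophores after perturbing one layer absorption parameter.

    Re-simulates the CW data for the perturbed medium and re-inverts it with
    the mus' spectrum (and hence b) pinned to ``baseline_rec``; FD data are
    not re-simulated.  If the perturbed value would leave the physical range,
    the step sign is reversed (and the event logged).
    """
    if (layer, name) not in ABSORPTION_PARAMETERS:
        raise ValueError(f"not an absorption parameter: {layer}.{name}")
    if step == 0.0:
        raise ValueError("perturbation step must be nonzero")
    if spec is None:
        spec = InstrumentSpec()
    if table is None:
        table = load_default_extinction()
    if basis is None:
        basis = build_extinction_matrix(spec.cw_wavelengths, table)

    base_value = getattr(getattr(baseline, layer).chromophores, name)
    value = base_value + step
    if not _valid(name, value):
        logger.info("step %+g on %s.%s leaves the physical range; reversing sign",
                    step, layer, name)
        value = base_value - step
        if not _valid(name, value):
            raise ValueError(f"perturbed {layer}.{name} = {value} is not physical")
    medium = _with_parameter(baseline, layer, name, value)
    cw = simulate_cw(medium, spec, table)
    mueff = _fit_mueff_cw_grid(cw, spec.distances_mm, baseline_rec.musp_cw, spec.n_assumed)
    mua = broadband_absorption(mueff, baseline_rec.musp_cw)
    return unmix_chromophores(mua, basis)


@dataclass
class SensitivityMatrix:
    """8 x 4 matrix of d(recovered)/d(layer parameter) derivatives.

    ``entries`` rows are the independent variables (T, S, W, L for top then
    bottom layer), columns the dependent recovered parameters (T, S, W, L).
    T is in uM and S, W, L are fractions, so e.g. the (dS_top, T) cell carries
    units of uM (per unit saturation change).  ``step_spec`` records the
    perturbation size used per row.
    """

    entries: pd.DataFrame
    step_spec: dict
    baseline_recovered: RecoveredProperties

    @property
    def co_sensitivities(self) -> pd.DataFrame:
        """Table of like-parameter sensitivities: rows Top/Bottom, columns T, S, W, L."""
        out = pd.DataFrame(index=["Top", "Bottom"], columns=["T", "S", "W", "L"], dtype=float)
        for layer in ("top", "bottom"):
            for name, short in _SHORT.items():
                out.loc[layer.capitalize(), short] = self.entries.loc[(layer, short), short]
        return out

    def to_csv(self, path):
        df = self.entries.copy()
        units = {"T": "uM", "S": "", "W": "", "L": ""}
        df.index = [f"d{p}_{lay.capitalize()}" + (f" ({units[p]})" if units[p] else "")
                    for lay, p in df.index]
        df.columns = [f"d{c}" + (f" ({units[c]})" if units[c] else "") for c in df.columns]
        df.to_csv(path)


def sensitivity_matrix(baseline: TwoLayerMedium,
                       spec: InstrumentSpec | None = None,
                       table: ExtinctionTable | None = None,
                       steps: dict | None = None,
                       baseline_rec: RecoveredProperties | None = None) -> SensitivityMatrix:
    """Central-difference sensitivities of all recovered absorption parameters
    with respect to all eight layer absorption parameters.

    Default steps are +/-0.5% relative for T and +/-0.005 absolute for the
    fractional parameters; halving them changes the entries by well under 1%
    (derivative regime).
    """
    if spec is None:
        spec = InstrumentSpec()
    if table is None:
        table = load_default_extinction()
    basis = build_extinction_matrix(spec.cw_wavelengths, table)
    if baseline_rec is None:
        from .forward import simulate_instrument

        baseline_rec = recover_all(simulate_instrument(baseline, spec, table), spec, basis=basis)

    index = pd.MultiIndex.from_tuples(
        [(layer, _SHORT[name]) for layer, name in ABSORPTION_PARAMETERS],
        names=["layer", "parameter"],
    )
    entries = pd.DataFrame(index=index, columns=["T", "S", "W", "L"], dtype=float)
    step_spec = {}
    for layer, name in ABSORPTION_PARAMETERS:
        base_value = getattr(getattr(baseline, layer).chromophores, name)
        h = _step_size(name, base_value, steps)
        if h == 0.0:
            raise ValueError(f"zero step for {layer}.{name} (baseline value {base_value})")
        try:
            plus = perturbed_recovery(baseline, layer, name, +h, baseline_rec, spec, table, basis)
            minus = perturbed_recovery(baseline, layer, name, -h, baseline_rec, spec, table, basis)
        except Exception as exc:
            raise RuntimeError(f"sensitivity computation failed for {layer}.{name}") from exc
        deriv = (plus.as_tswl_vector() - minus.as_tswl_vector()) / (2.0 * h)
        entries.loc[(layer, _SHORT[name]), :] = deriv
        step_spec[f"{layer}.{name}"] = h
    if not np.all(np.isfinite(entries.to_numpy(dtype=float))):
        raise RuntimeError("sensitivity matrix contains non-finite entries")
    return SensitivityMatrix(entries=entries, step_spec=step_spec, baseline_recovered=baseline_rec)
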
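"""Study configuration: a flat, unit-suffixed YAML mapping.

All physical quantities carry explicit unit suffixes in their key names
(``z_top_mm``, ``musp830_top_per_mm``, ...) so a config file is unambiguous
without external documentation.  The defaults reproduce the baseline study
exactly; a round trip through YAML is the identity.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .forward import InstrumentSpec, Layer, TwoLayerMedium
from .spectra import ChromophoreConcentrations, ScatteringLaw

__all__ = ["StudyConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid study configuration; the message names the offending field."""


def _layer_defaults(which: str) -> dict:
    if which == "top":
        return dict(thb_uM=12.0, so2_pct=83.0, water_pct=5.0, lipid_pct=70.0,
                    musp830_per_mm=0.60, scatter_power=0.1)
    return dict(thb_uM=120.0, so2_pct=67.0, water_pct=90.0, lipid_pct=20.0,
                musp830_per_mm=0.40, scatter_power=1.5)


@dataclass
class StudyConfig:
    """Flat configuration of medium, instrument, solver and sweep settings.

    Percent-valued fields (saturation, water, lipid) are percent here and
    converted to fractions at the library boundary.
    """

    top: dict = field(default_factory=lambda: _layer_defaults("top"))
    bottom: dict = field(default_factory=lambda: _layer_defaults("bottom"))
    z_top_mm: float = 5.0
    refractive_index: float = 1.4

    cw_min_nm: float = 650.0
    cw_max_nm: float = 1024.0
    cw_step_nm: float = 0.5
    fd_wavelengths_nm: list = field(default_factory=lambda: [690.0, 830.0])
    distances_mm: list = field(default_factory=lambda: [25.0, 35.0])
    mod_freq_mhz: float = 140.625

    sweep_parameter: str = "thb_uM_top"
    sweep_points: int = 15
    sensitivity_step_thb_rel: float = 0.005
    sensitivity_step_frac_abs: float = 0.005

    # ------------------------------------------------------------------
    def validate(self) -> "StudyConfig":
        if not self.z_top_mm > 0:
            raise ConfigError(f"z_top_mm must be > 0, got {self.z_top_mm}")
        if not self.refractive_index >= 1:
            raise ConfigError(f"refractive_index must be >= 1, got {self.refractive_index}")
        if not 0 < self.cw_step_nm <= (self.cw_max_nm - self.cw_min_nm):
            raise ConfigError("cw_step_nm inconsistent with cw_min_nm/cw_max_nm")
        if len(self.distances_mm) != 2 or self.distances_mm[0] == self.distances_mm[1]:
            raise ConfigError("distances_mm must be two distinct distances")
        if self.mod_freq_mhz <= 0:
            raise ConfigError(f"mod_freq_mhz must be > 0, got {self.mod_freq_mhz}")
        for which in ("top", "bottom"):
            lay = getattr(self, which)
            missing = set(_layer_defaults(which)) - set(lay)
            if missing:
                raise ConfigError(f"{which} layer is missing fields: {sorted(missing)}")
            if lay["thb_uM"] < 0:
                raise ConfigError(f"{which}.thb_uM must be >= 0")
            for pct in ("so2_pct", "water_pct", "lipid_pct"):
                if not 0 <= lay[pct] <= 100:
                    raise ConfigError(f"{which}.{pct} must lie in [0, 100], got {lay[pct]}")
            if lay["musp830_per_mm"] <= 0:
                raise ConfigError(f"{which}.musp830_per_mm must be > 0")
        return self

    # ------------------------------------------------------------------
    def medium(self) -> TwoLayerMedium:
        self.validate()

        def lay(d):
            return Layer(
                ChromophoreConcentrations(
                    thb_uM=d["thb_uM"], so2=d["so2_pct"] / 100.0,
                    water=d["water_pct"] / 100.0, lipid=d["lipid_pct"] / 100.0,
                ),
                ScatteringLaw(musp830=d["musp830_per_mm"], power=d["scatter_power"]),
            )

        return TwoLayerMedium(top=lay(self.top), bottom=lay(self.bottom),
                              z_top_mm=self.z_top_mm, n=self.refractive_index)

    def instrument(self) -> InstrumentSpec:
        self.validate()
        return InstrumentSpec(
            cw_wavelengths=np.arange(self.cw_min_nm, self.cw_max_nm + 1e-9, self.cw_step_nm),
            fd_wavelengths=tuple(self.fd_wavelengths_nm),
            distances_mm=tuple(self.distances_mm),
            mod_freq_hz=self.mod_freq_mhz * 1e6,
            n_assumed=self.refractive_index,
        )

    def sensitivity_steps(self) -> dict:
        return {
            "thb_uM": ("relative", self.sensitivity_step_thb_rel),
            "so2": ("absolute", self.sensitivity_step_frac_abs),
            "water": ("absolute", self.sensitivity_step_frac_abs),
            "lipid": ("absolute", self.sensitivity_step_frac_abs),
        }

    def sweep_parameter_key(self) -> tuple:
        name = self.sweep_parameter
        if name in ("z_top", "z_top_mm"):
            return ("z_top",)
        for suffix in ("_top", "_bottom"):
            if name.endswith(suffix):
                return (suffix[1:], name[: -len(suffix)])
        raise ConfigError(
            f"sweep_parameter {name!r} must end in _top/_bottom or be z_top"
        )

    # ------------------------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "StudyConfig":
        if hasattr(source, "read"):
            raw = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as f:
                    raw = yaml.safe_load(f)
            except (OSError, TypeError):
                raw = yaml.safe_load(source)
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw).validate()
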
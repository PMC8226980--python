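"""Fluid property sets: Newtonian buffers and shear-thinning (Carreau) blood.

Whole blood is modelled as a generalized-Newtonian Carreau fluid,

    eta(gdot) = eta_inf + (eta_0 - eta_inf) * [1 + (lam * gdot)^2]^((n - 1)/2)

interpolating between the zero-shear plateau ``eta_0`` and the infinite-shear
plateau ``eta_inf`` with time constant ``lam`` (s) and power index ``n``.
Parameters for blood: eta_0 = 0.056 Pa s, eta_inf = 0.0035 Pa s,
lam = 3.313 s, n = 0.3568.  PBS/water and serum are Newtonian.

A historical curiosity of the source datasets is a serum density of
906 kg m^-3, below water and physiologically unusual; it is retained as-is
(density only enters inertial terms, which are negligible at Re << 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["FluidModel", "viscosity", "preset_fluids", "get_fluid", "PRESETS"]


@dataclass(frozen=True)
class FluidModel:
    """Density plus a Newtonian or Carreau viscosity law (SI units)."""

    name: str
    density: float                       # kg m^-3
    law: Literal["newtonian", "carreau"] = "newtonian"
    eta: float = 1.0e-3                  # Pa s (newtonian)
    eta_0: float = 0.056                 # Pa s (carreau zero-shear)
    eta_inf: float = 0.0035              # Pa s (carreau infinite-shear)
    lam: float = 3.313                   # s   (carreau time constant)
    n_index: float = 0.3568              # -   (carreau power index)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.law == "newtonian":
            if self.eta <= 0:
                raise ValueError("newtonian viscosity must be positive")
        elif self.law == "carreau":
            if not self.eta_0 >= self.eta_inf > 0:
                raise ValueError("carreau requires eta_0 >= eta_inf > 0")
            if self.lam <= 0:
                raise ValueError("carreau time constant must be positive")
            if not 0 < self.n_index <= 1:
                raise ValueError("carreau power index must lie in (0, 1]")
        else:
            raise ValueError(f"unknown viscosity law {self.law!r}")

    def viscosity(self, shear_rate) -> np.ndarray | float:
        """Apparent viscosity (Pa s) at shear rate(s) ``shear_rate`` (1/s)."""
        return viscosity(self, shear_rate)


def viscosity(fluid: FluidModel, shear_rate) -> np.ndarray | float:
    """Evaluate the fluid's viscosity law at ``shear_rate`` (1/s, >= 0).

    Newtonian fluids return ``eta`` regardless of shear rate.  The Carreau
    law is finite at zero shear (``eta_0``) and tends to ``eta_inf`` as
    ``shear_rate`` grows; it is monotonically non-increasing in between.
    """
    gdot = np.asarray(shear_rate, dtype=float)
    if np.any(gdot < 0):
        raise ValueError("shear_rate must be non-negative")
    if fluid.law == "newtonian":
        out = np.full_like(gdot, fluid.eta)
    else:
        out = fluid.eta_inf + (fluid.eta_0 - fluid.eta_inf) * (
            1.0 + (fluid.lam * gdot) ** 2
        ) ** ((fluid.n_index - 1.0) / 2.0)
    return out if out.ndim else float(out)


#: Named presets.  "water_low_visc" is an alternative water parameterization
#: (0.653 mPa s) occasionally quoted for room-temperature water; the standard
#: 1 cP value is the default because the chip's nominal wall shear stress
#: (0.1 Pa at 0.5 uL/min) is only consistent with 1 cP.
PRESETS: dict[str, FluidModel] = {
    "pbs": FluidModel(name="pbs", density=1000.0, law="newtonian", eta=1.0e-3),
    "serum": FluidModel(name="serum", density=906.0, law="newtonian", eta=1.1e-3),
    "blood": FluidModel(
        name="blood", density=1060.0, law="carreau",
        eta_0=0.056, eta_inf=0.0035, lam=3.313, n_index=0.3568,
    ),
    "water_low_visc": FluidModel(
        name="water_low_visc", density=1000.0, law="newtonian", eta=0.653e-3,
    ),
}


def preset_fluids() -> list[FluidModel]:
    """The three working fluids of the chip: PBS/water, serum, whole blood."""
    return [PRESETS["pbs"], PRESETS["serum"], PRESETS["blood"]]


def get_fluid(name: str) -> FluidModel:
    """Look up a preset fluid by name (including optional variants)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown fluid {name!r}; available: {sorted(PRESETS)}"
        ) from None
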
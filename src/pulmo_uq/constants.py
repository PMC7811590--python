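"""Physical constants of the blood and unit conventions.

All internal computation is done in cgs units (cm, g, s; pressure in
g cm^-1 s^-2, flow in ml s^-1).  Pressures are converted to mmHg only at
interfaces, using the exact factor ``MMHG_PER_CGS`` applied once.
"""

from __future__ import annotations

from dataclasses import dataclass

#: mmHg per (g cm^-1 s^-2); exact conversion constant used throughout.
MMHG_PER_CGS = 1.0 / 1333.22


@dataclass(frozen=True)
class PhysicalConstants:
    """Blood properties and the cardiac period.

    Parameters
    ----------
    rho : float
        Blood density, g ml^-1.
    mu : float
        Dynamic blood viscosity, g cm^-1 s^-1.
    conv : float
        Pressure conversion factor, (g cm^-1 s^-2) per mmHg.
    T : float
        Length of the cardiac cycle, s.  The mouse default is 0.11 s.
    """

    rho: float = 1.055
    mu: float = 0.049
    conv: float = 1333.22
    T: float = 0.11

    def __post_init__(self) -> None:
        for name in ("rho", "mu", "conv", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
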
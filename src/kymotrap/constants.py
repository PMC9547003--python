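"""Physical constants shared across the package."""
from __future__ import annotations

from dataclasses import dataclass

#: kcal/mol per pN·nm (1 pN·nm = 0.1439 kcal/mol)
KCAL_PER_PN_NM = 0.1439


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermal energy and DNA geometry used throughout.

    Attributes
    ----------
    kBT : float
        Thermal energy in pN·nm. Default 4.114 pN·nm (T = 298 K).
    bp_rise : float
        Helical rise per base pair in nm. Default 0.34 nm, the canonical
        B-DNA value, which reproduces the conversion
        0.021 µm²/s = 0.18e6 bp²/s to two significant figures.
    """

    kBT: float = 4.114
    bp_rise: float = 0.34

    def __post_init__(self) -> None:
        if not (self.kBT > 0):
            raise ValueError(f"kBT must be positive, got {self.kBT}")
        if not (self.bp_rise > 0):
            raise ValueError(f"bp_rise must be positive, got {self.bp_rise}")


DEFAULT_CONSTANTS = PhysicalConstants()
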
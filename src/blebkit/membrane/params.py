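"""Model parameters for the active-vesicle Monte-Carlo simulation.

Units: lengths in the minimum bond length ``l_min``, energies in ``kT0``
(thermal energy at the reference temperature T0 ≈ room temperature). The
Metropolis temperature enters through the reduced ratio T/T0, so
β = 1 / (T/T0) in kT0 units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ModelParams"]


@dataclass
class ModelParams:
    """Physical and algorithmic parameters of the vesicle simulation.

    Defaults reproduce the reference condition: κ = 20 kT0, k_A = 1 kT0,
    protein fraction ρ = 11% with contact energy w = 1 kT0, active force
    F = 1 kT0/l_min, reduced temperature T/T0 = 0.7.
    """

    kappa: float = 20.0  # bending modulus, kT0
    k_A: float = 1.0  # triangle stretch modulus, kT0
    w: float = 1.0  # protein-protein contact energy, kT0
    F: float = 1.0  # outward active force per protein node, kT0/l_min
    c0: float = 1.0  # protein spontaneous curvature, 1/l_min
    rho: float = 0.11  # protein fraction of vertices
    T_rel: float = 0.7  # reduced temperature T/T0
    l_min: float = 1.0
    l_ratio: float = 1.7  # l_max = l_ratio * l_min
    r0: float | None = None  # protein binding range, default l_max
    d: float | None = None  # parallel-plate gap (l_min units); None = unconfined
    delta: float = 0.1  # vertex-move half-width, l_min units

    l_max: float = field(init=False)
    l0: float = field(init=False)
    a0: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [0, 1]")
        if min(self.kappa, self.k_A, self.w if self.w is not None else 0.0) < 0:
            raise ValueError("moduli must be nonnegative")
        if self.T_rel <= 0:
            raise ValueError("reduced temperature must be positive")
        if self.d is not None and self.d <= 0:
            raise ValueError("plate gap d must be positive when set")
        self.l_max = self.l_ratio * self.l_min
        self.l0 = 0.5 * (self.l_min + self.l_max)
        self.a0 = (3.0**0.5) * self.l0**2 / 4.0
        if self.r0 is None:
            self.r0 = self.l_max

    @property
    def beta(self) -> float:
        """Inverse temperature in 1/kT0 units."""
        return 1.0 / self.T_rel
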
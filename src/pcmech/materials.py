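"""Constitutive parameters of the two-phase (fiber network + matrix) mixture.

Units convention, fixed project-wide (see ``pcmech.io``): lengths in μm,
forces in μN, stresses in kPa. The fiber network lives in a dimensionless
unit-cube RVE, so the volume-averaged network stress Σ x⊗F / V carries the
units of the fiber force parameter ``A`` and is interpreted directly on the
kPa stress scale of the matrix phase (the calibration of A against dermal
mechanics absorbs the RVE size).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MaterialParams:
    """Parameters of the exponential fiber law and the neo-Hookean matrix.

    Attributes
    ----------
    A : float
        Fiber stiffness scale (μN). The small-strain slope dF/dE_f at zero
        Green strain equals A.
    B : float
        Dimensionless fiber nonlinearity exponent.
    G : float
        Matrix shear modulus (kPa).
    nu : float
        Matrix Poisson ratio; must be < 0.5 (nearly incompressible default).
    """

    A: float = 114.0
    B: float = 10.0
    G: float = 4.2
    nu: float = 0.47

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"fiber stiffness A must be positive, got {self.A}")
        if not self.B > 0:
            raise ValueError(f"fiber nonlinearity B must be positive, got {self.B}")
        if not self.G > 0:
            raise ValueError(f"shear modulus G must be positive, got {self.G}")
        if not 0.0 < self.nu < 0.5:
            raise ValueError(f"Poisson ratio must lie in (0, 0.5), got {self.nu}")

    @property
    def bulk_modulus(self) -> float:
        """Matrix bulk modulus K = 2G(1+ν) / (3(1−2ν)), kPa."""
        return 2.0 * self.G * (1.0 + self.nu) / (3.0 * (1.0 - 2.0 * self.nu))


DEFAULT_PARAMS = MaterialParams()
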
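"""Plane-stress elastic materials (kPa unit system)."""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np


class InvalidMaterialError(ValueError):
    pass


def plane_stress_stiffness(E: float, nu: float) -> np.ndarray:
    """3×3 plane-stress Hooke matrix in Voigt form (ε_xx, ε_yy, γ_xy).

        C = E/(1-ν²) · [[1, ν, 0], [ν, 1, 0], [0, 0, (1-ν)/2]]

    The shear entry (1-ν)/2 acts on the engineering shear strain γ_xy = 2ε_xy.
    """
    if E <= 0:
        raise InvalidMaterialError(f"Young's modulus must be positive, got {E}")
    if not (0 <= nu < 0.5):
        raise InvalidMaterialError(f"Poisson ratio must be in [0, 0.5), got {nu}")
    f = E / (1.0 - nu**2)
    return f * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic plane-stress material: E in kPa, dimensionless ν."""

    young_modulus: float
    poisson_ratio: float

    def __post_init__(self):
        plane_stress_stiffness(self.young_modulus, self.poisson_ratio)

    @cached_property
    def stiffness(self) -> np.ndarray:
        return plane_stress_stiffness(self.young_modulus, self.poisson_ratio)
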
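"""Triclinic unit cells and the reciprocal metric."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["UnitCell"]


@dataclass(frozen=True)
class UnitCell:
    """A triclinic unit cell (lengths in Angstrom, angles in degrees).

    Provides the direct metric tensor, its reciprocal, the cell volume
    and the fractional->Cartesian orthogonalization matrix.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must be in (0, 180)")
        # positive-definiteness of the metric catches impossible angle triples
        if np.linalg.det(self.metric()) <= 0:
            raise ValueError("cell angles do not define a valid (positive definite) metric")

    def metric(self) -> np.ndarray:
        """Direct-space metric tensor G, with G[i, j] = a_i . a_j."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = np.cos(np.radians([self.alpha, self.beta, self.gamma]))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G^-1; s^2 = h^T G* h."""
        return np.linalg.inv(self.metric())

    @property
    def volume(self) -> float:
        return float(np.sqrt(np.linalg.det(self.metric())))

    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M with x_cart = M @ x_frac (PDB convention, a along x)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = np.cos(np.radians([self.alpha, self.beta, self.gamma]))
        sg = np.sin(np.radians(self.gamma))
        v = self.volume / (a * b * c)
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, c * v / sg],
            ]
        )

    def is_orthogonal(self, tol: float = 1e-9) -> bool:
        return (
            abs(self.alpha - 90.0) < tol
            and abs(self.beta - 90.0) < tol
            and abs(self.gamma - 90.0) < tol
        )
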
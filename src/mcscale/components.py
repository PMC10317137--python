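"""Per-component complex structure factors.

Three component models are provided: analytically transformed smeared
spheres, Gaussian point atoms (a protein stand-in), and binary grid
masks evaluated by FFT.  All use the phase convention exp(+2*pi*i h.x)
with x in fractional coordinates, and Gaussian smearing exp(-B s^2 / 4)
with s = 1/d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import UnitCell
from .reflections import MillerSet

__all__ = [
    "Component",
    "Sphere",
    "AtomSet",
    "GridMask",
    "sphere_structure_factors",
    "atom_structure_factors",
    "mask_structure_factors",
    "apply_smearing",
    "shape_factor",
]


@dataclass(frozen=True)
class Component:
    """Complex structure factors of one scattering component.

    ``f`` is aligned index-by-index with a MillerSet.
    """

    id: str
    f: np.ndarray
    kind: str = "external"

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=complex).reshape(-1)
        if not np.all(np.isfinite(f)):
            raise ValueError(f"component {self.id!r} has non-finite structure factors")
        object.__setattr__(self, "f", f)

    def __len__(self) -> int:
        return self.f.shape[0]


@dataclass(frozen=True)
class Sphere:
    """A uniform sphere: fractional center, radius (A), occupancy, smearing B (A^2)."""

    center: tuple[float, float, float]
    radius: float
    occupancy: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")
        if self.b < 0:
            raise ValueError("smearing B must be >= 0")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3


@dataclass(frozen=True)
class AtomSet:
    """Gaussian point atoms: fractional positions, amplitudes, per-atom B (A^2)."""

    positions: np.ndarray
    weights: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        w = np.broadcast_to(np.asarray(self.weights, dtype=float), (pos.shape[0],)).copy()
        b = np.broadcast_to(np.asarray(self.widths, dtype=float), (pos.shape[0],)).copy()
        if np.any(w <= 0):
            raise ValueError("atom weights must be > 0")
        if np.any(b < 0):
            raise ValueError("atom widths must be >= 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "widths", b)

    def __len__(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class GridMask:
    """A binary occupancy mask on a regular grid over the unit cell."""

    values: np.ndarray
    cell: UnitCell

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError("mask grid must be 3-dimensional")
        if not np.all((v == 0) | (v == 1)):
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "values", v.astype(np.int8))


def shape_factor(x) -> np.ndarray:
    """Sphere shape function Phi(x) = 3 (sin x - x cos x) / x^3, Phi(0) = 1."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    # the closed form cancels catastrophically for small x; switch to the
    # Taylor series where its truncation error is below double precision
    small = np.abs(x) < 0.05
    xs = x[small]
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0 - xs**6 / 15120.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def _phases(hkl: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """exp(+2 pi i h.x) for each reflection (rows of hkl) and site (rows of frac)."""
    return np.exp(2j * np.pi * (hkl @ np.atleast_2d(frac).T))


def sphere_structure_factors(sph: Sphere, miller: MillerSet, id: str | None = None) -> Component:
    """Analytic structure factors of a smeared uniform sphere.

    f(s) = q * (4/3) pi R^3 * Phi(2 pi s R) * exp(-B s^2/4) * exp(2 pi i h.x0)
    """
    s = miller.s
    envelope = sph.occupancy * sph.volume * shape_factor(2.0 * np.pi * s * sph.radius)
    envelope = envelope * np.exp(-sph.b * s**2 / 4.0)
    f = envelope * _phases(miller.hkl, np.asarray(sph.center))[:, 0]
    return Component(id=id or "sphere", f=f, kind="sphere")


def atom_structure_factors(atoms: AtomSet, miller: MillerSet, id: str = "atoms") -> Component:
    """Direct-summation structure factors of Gaussian point atoms.

    f(s) = sum_j w_j exp(-B_j s^2/4) exp(2 pi i h.x_j)
    """
    if len(atoms) == 0:
        raise ValueError("empty atom set")
    damp = np.exp(-np.outer(miller.s**2 / 4.0, atoms.widths))  # (n_refl, n_atoms)
    f = np.einsum("rj,j,rj->r", _phases(miller.hkl, atoms.positions), atoms.weights + 0j, damp)
    return Component(id=id, f=f, kind="atoms")


def mask_structure_factors(mask: GridMask, miller: MillerSet, id: str = "mask") -> Component:
    """FFT structure factors of a binary mask, scaled by V_cell / N_grid.

    Requires d_min >= 2 * largest grid spacing (Nyquist); otherwise the
    requested reflections alias and an error names the required grid.
    """
    n = np.array(mask.values.shape)
    spacing = np.array([mask.cell.a, mask.cell.b, mask.cell.c]) / n
    d_min = float(miller.d.min())
    if d_min < 2.0 * spacing.max() - 1e-9:
        need = np.ceil(2.0 * np.array([mask.cell.a, mask.cell.b, mask.cell.c]) / d_min).astype(int)
        raise ValueError(
            f"grid {tuple(mask.values.shape)} too coarse for d_min={d_min:.3g} A; "
            f"need at least {tuple(int(x) for x in need)}"
        )
    # F(h) = V/N sum_x rho(x) exp(+2 pi i h.x) = V/N conj(FFT(rho))[h] for real rho
    transform = np.conj(np.fft.fftn(mask.values.astype(float)))
    transform *= mask.cell.volume / mask.values.size
    idx = tuple((miller.hkl[:, i] % n[i] for i in range(3)))
    return Component(id=id, f=transform[idx], kind="mask")


def apply_smearing(comp: Component, miller: MillerSet, b: float) -> Component:
    """Multiply a component by the Gaussian smearing factor exp(-B s^2 / 4)."""
    if b < 0:
        raise ValueError("smearing B must be >= 0")
    if len(comp) != len(miller):
        raise ValueError("component and MillerSet are not aligned")
    return Component(id=comp.id, f=comp.f * np.exp(-b * miller.s**2 / 4.0), kind=comp.kind)
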
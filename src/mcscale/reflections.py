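"""Reflection enumeration, reciprocal magnitudes and resolution-shell binning.

Reflections are enumerated for a P1 lattice as a Friedel half set: of each
pair (h,k,l)/(-h,-k,-l) only the member with (h>0) or (h=0,k>0) or
(h=k=0,l>0) is kept.  Shell boundaries are placed uniformly in ln(d);
under-populated shells are merged toward lower resolution (larger d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cell import UnitCell

__all__ = [
    "MillerSet",
    "ResolutionShells",
    "generate_hkl",
    "s_magnitude",
    "bin_shells",
]

#: hard cap on the number of enumerated reflections
MAX_REFLECTIONS = 5_000_000


@dataclass(frozen=True)
class MillerSet:
    """An ordered set of Miller indices with reciprocal magnitudes.

    Attributes
    ----------
    hkl : (n, 3) int array of Miller indices, (0,0,0) excluded.
    s : (n,) array, |s| = 1/d in 1/Angstrom.
    cell : the unit cell the indices refer to.
    """

    hkl: np.ndarray
    s: np.ndarray
    cell: UnitCell

    def __post_init__(self) -> None:
        hkl = np.ascontiguousarray(np.asarray(self.hkl, dtype=np.int64).reshape(-1, 3))
        s = np.asarray(self.s, dtype=float).reshape(-1)
        if hkl.shape[0] != s.shape[0]:
            raise ValueError("hkl and s must have the same length")
        if np.any(np.all(hkl == 0, axis=1)):
            raise ValueError("(0,0,0) is not a valid reflection")
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise ValueError("reciprocal magnitudes must be finite and > 0")
        object.__setattr__(self, "hkl", hkl)
        object.__setattr__(self, "s", s)

    @property
    def d(self) -> np.ndarray:
        """Resolution d = 1/|s| in Angstrom."""
        return 1.0 / self.s

    def __len__(self) -> int:
        return self.hkl.shape[0]


@dataclass(frozen=True)
class ResolutionShells:
    """A partition of a MillerSet into resolution shells.

    ``boundaries`` holds n_shells+1 strictly decreasing d values;
    shell i covers d in (boundaries[i+1], boundaries[i]].
    """

    boundaries: np.ndarray
    assignment: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if np.any(np.diff(b) >= 0):
            raise ValueError("shell boundaries must be strictly decreasing in d")
        object.__setattr__(self, "boundaries", b)
        object.__setattr__(self, "assignment", np.asarray(self.assignment, dtype=np.int64))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))

    @property
    def n_shells(self) -> int:
        return len(self.counts)

    def indices(self, shell: int) -> np.ndarray:
        """Reflection indices belonging to one shell."""
        return np.flatnonzero(self.assignment == shell)


def s_magnitude(cell: UnitCell, hkl) -> float | np.ndarray:
    """Reciprocal magnitude |s| = 1/d for one or many Miller indices.

    Uses s^2 = h^T G* h with the reciprocal metric tensor G*.  For an
    orthorhombic cell this reduces to sqrt((h/a)^2 + (k/b)^2 + (l/c)^2).
    """
    h = np.asarray(hkl, dtype=float)
    single = h.ndim == 1
    h = h.reshape(-1, 3)
    if np.any(np.all(h == 0, axis=1)):
        raise ValueError("resolution of (0,0,0) is undefined")
    gstar = cell.reciprocal_metric()
    s = np.sqrt(np.einsum("ni,ij,nj->n", h, gstar, h))
    return float(s[0]) if single else s


def generate_hkl(cell: UnitCell, d_min: float, max_reflections: int = MAX_REFLECTIONS) -> MillerSet:
    """Enumerate the Friedel half set of reflections with d >= d_min.

    Ordering is lexicographic on (h, k, l).  Raises if no reflection
    reaches d_min or if the enumeration box exceeds ``max_reflections``.
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    gstar = cell.reciprocal_metric()
    # |h_i| <= ||a_i|| / d_min bounds the index range for any cell shape
    # (Cauchy-Schwarz: h_i = a_i . s and |s| <= 1/d_min)
    lengths = np.array([cell.a, cell.b, cell.c])
    limits = np.floor(lengths / d_min + 1e-9).astype(int)
    n_box = (2 * limits[0] + 1) * (2 * limits[1] + 1) * (2 * limits[2] + 1)
    if n_box > 2 * max_reflections:
        raise ValueError(
            f"enumeration box of {n_box} indices exceeds the cap of {2 * max_reflections}; "
            "increase d_min or max_reflections"
        )
    hs = np.arange(-limits[0], limits[0] + 1)
    ks = np.arange(-limits[1], limits[1] + 1)
    ls = np.arange(-limits[2], limits[2] + 1)
    grid = np.stack(np.meshgrid(hs, ks, ls, indexing="ij"), axis=-1).reshape(-1, 3)
    h, k, l = grid[:, 0], grid[:, 1], grid[:, 2]
    half = (h > 0) | ((h == 0) & (k > 0)) | ((h == 0) & (k == 0) & (l > 0))
    grid = grid[half]
    s = np.sqrt(np.einsum("ni,ij,nj->n", grid.astype(float), gstar, grid.astype(float)))
    keep = s <= 1.0 / d_min + 1e-12
    grid, s = grid[keep], s[keep]
    if grid.shape[0] == 0:
        raise ValueError(f"no reflection satisfies d >= {d_min} for this cell")
    if grid.shape[0] > max_reflections:
        raise ValueError(f"{grid.shape[0]} reflections exceed the cap of {max_reflections}")
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0]))
    return MillerSet(hkl=grid[order], s=s[order], cell=cell)


def bin_shells(miller: MillerSet, n_shells: int | None = None, min_per_shell: int = 50) -> ResolutionShells:
    """Partition reflections into shells uniform in ln(d).

    ``n_shells`` defaults to a mean shell population of ~100 reflections,
    clamped to [1, 50].  Shells with fewer than ``min_per_shell``
    reflections are merged with their neighbor toward lower resolution
    (larger d); a data set smaller than ``min_per_shell`` falls back to a
    single shell with a warning.
    """
    n = len(miller)
    if n == 0:
        raise ValueError("empty MillerSet")
    if n_shells is None:
        n_shells = int(np.clip(round(n / 100), 1, 50))
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    d = miller.d
    d_max, d_min = float(d.max()), float(d.min())
    if n < min_per_shell and n_shells > 1:
        warnings.warn(
            f"only {n} reflections (< min_per_shell={min_per_shell}); using a single shell",
            stacklevel=2,
        )
        n_shells = 1
    if n_shells == 1 or d_max == d_min:
        boundaries = np.array([d_max, d_min if d_min < d_max else d_min * (1 - 1e-12)])
        return ResolutionShells(
            boundaries=boundaries,
            assignment=np.zeros(n, dtype=np.int64),
            counts=np.array([n]),
        )
    edges = np.exp(np.linspace(np.log(d_max), np.log(d_min), n_shells + 1))
    # assign: shell i covers (edges[i+1], edges[i]]; clip endpoints into range
    assignment = np.searchsorted(-edges, -d, side="left") - 1
    assignment = np.clip(assignment, 0, n_shells - 1)
    counts = np.bincount(assignment, minlength=n_shells)

    # merge under-populated shells into the neighbor with larger d
    edges_list = list(edges)
    counts_list = list(counts)
    i = len(counts_list) - 1
    while len(counts_list) > 1 and i >= 0:
        if counts_list[i] < min_per_shell:
            j = i - 1 if i > 0 else 1
            lo, hi = min(i, j), max(i, j)
            counts_list[lo] += counts_list[hi]
            del counts_list[hi]
            del edges_list[hi]  # drop the boundary between lo and hi
            i = len(counts_list) - 1
        else:
            i -= 1
    edges = np.array(edges_list)
    assignment = np.searchsorted(-edges, -d, side="left") - 1
    assignment = np.clip(assignment, 0, len(counts_list) - 1)
    counts = np.bincount(assignment, minlength=len(counts_list))
    return ResolutionShells(boundaries=edges, assignment=assignment, counts=counts)
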
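"""Columnar reflection-file I/O and a minimal mmCIF reflection importer.

Native format (plain text, whitespace separated)::

    # cell 60.0 60.0 60.0 90.0 90.0 90.0
    # components atoms sphere0
    # columns h k l F_obs I_obs re_atoms im_atoms re_sphere0 im_sphere0
    1 0 0 123.4 15227.56 100.0 0.0 23.4 0.0
    ...

Floats are serialized with repr-exact precision; rows are ordered
lexicographically by (h, k, l); duplicate indices are an error.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cell import UnitCell
from .components import Component
from .reflections import MillerSet, s_magnitude
from .solvers import ObservedData, ScaleSet

__all__ = [
    "read_reflections",
    "write_reflections",
    "read_mmcif_reflections",
    "write_scales",
]


def write_reflections(
    path: str | Path,
    miller: MillerSet,
    obs: ObservedData,
    components: list[Component] | None = None,
) -> None:
    """Write an aligned reflection table (see module docstring for format)."""
    components = components or []
    n = len(miller)
    if len(obs) != n or any(len(c) != n for c in components):
        raise ValueError("miller, observations and components must be aligned")
    order = np.lexsort((miller.hkl[:, 2], miller.hkl[:, 1], miller.hkl[:, 0]))
    cell = miller.cell
    lines = [
        f"# cell {cell.a!r} {cell.b!r} {cell.c!r} {cell.alpha!r} {cell.beta!r} {cell.gamma!r}",
        "# components " + " ".join(c.id for c in components),
        "# columns h k l F_obs I_obs "
        + " ".join(f"re_{c.id} im_{c.id}" for c in components),
    ]
    for i in order:
        row = [str(miller.hkl[i, 0]), str(miller.hkl[i, 1]), str(miller.hkl[i, 2]),
               repr(float(obs.amplitude[i])), repr(float(obs.intensity[i]))]
        for c in components:
            row.append(repr(float(c.f[i].real)))
            row.append(repr(float(c.f[i].imag)))
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_reflections(path: str | Path) -> tuple[MillerSet, ObservedData, list[Component]]:
    """Read a native reflection file back into aligned structures."""
    path = Path(path)
    cell = None
    comp_ids: list[str] = []
    hkl, amp, inten, comp_cols = [], [], [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if fields and fields[0] == "cell":
                if len(fields) != 7:
                    raise ValueError(f"{path}:{lineno}: malformed cell header")
                cell = UnitCell(*map(float, fields[1:]))
            elif fields and fields[0] == "components":
                comp_ids = fields[1:]
            continue
        parts = line.split()
        expected = 5 + 2 * len(comp_ids)
        if len(parts) != expected:
            raise ValueError(f"{path}:{lineno}: expected {expected} columns, got {len(parts)}")
        try:
            h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
            values = [float(x) for x in parts[3:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from None
        hkl.append((h, k, l))
        amp.append(values[0])
        inten.append(values[1])
        comp_cols.append(values[2:])
    if cell is None:
        raise ValueError(f"{path}: missing '# cell' header")
    if not hkl:
        raise ValueError(f"{path}: no reflections")
    seen: dict[tuple[int, int, int], int] = {}
    dupes = [trip for i, trip in enumerate(hkl) if seen.setdefault(trip, i) != i]
    if dupes:
        raise ValueError(f"{path}: duplicate Miller indices: {sorted(set(dupes))}")
    hkl_arr = np.array(hkl, dtype=np.int64)
    miller = MillerSet(hkl=hkl_arr, s=s_magnitude(cell, hkl_arr), cell=cell)
    obs = ObservedData(amplitude=np.array(amp), intensity=np.array(inten))
    comps = []
    cols = np.array(comp_cols) if comp_cols else np.empty((len(hkl), 0))
    for j, cid in enumerate(comp_ids):
        comps.append(Component(id=cid, f=cols[:, 2 * j] + 1j * cols[:, 2 * j + 1]))
    return miller, obs, comps


def read_mmcif_reflections(path: str | Path) -> tuple[MillerSet, ObservedData]:
    """Import Miller indices and amplitudes from an mmCIF reflection loop.

    Minimal reader: finds a loop_ containing _refln.index_h/k/l and an
    amplitude column (_refln.F_meas or _refln.F_meas_au), plus the cell
    from _cell.length_* / _cell.angle_* items.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    cell_items: dict[str, float] = {}
    for line in lines:
        parts = line.split()
        if len(parts) >= 2 and parts[0].startswith(("_cell.length_", "_cell.angle_")):
            try:
                cell_items[parts[0]] = float(parts[1])
            except ValueError:
                pass
    try:
        cell = UnitCell(
            cell_items["_cell.length_a"], cell_items["_cell.length_b"], cell_items["_cell.length_c"],
            cell_items.get("_cell.angle_alpha", 90.0),
            cell_items.get("_cell.angle_beta", 90.0),
            cell_items.get("_cell.angle_gamma", 90.0),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing cell item {exc}") from None

    # locate the refln loop
    i = 0
    while i < len(lines):
        if lines[i].strip() == "loop_":
            tags = []
            j = i + 1
            while j < len(lines) and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip().split()[0])
                j += 1
            if any(t.startswith("_refln.") for t in tags):
                break
        i += 1
    else:
        raise ValueError(f"{path}: no _refln loop found")

    def col(name_options):
        for name in name_options:
            if name in tags:
                return tags.index(name)
        raise ValueError(f"{path}: none of {name_options} in refln loop")

    ih = col(["_refln.index_h"])
    ik = col(["_refln.index_k"])
    il = col(["_refln.index_l"])
    ifo = col(["_refln.F_meas_au", "_refln.F_meas"])
    hkl, amp = [], []
    for raw in lines[j:]:
        s = raw.strip()
        if not s or s.startswith(("#", "_")) or s in ("loop_", "stop_") or s.startswith("data_"):
            break
        parts = s.split()
        if len(parts) < len(tags):
            break
        val = parts[ifo]
        if val in ("?", "."):
            continue
        hkl.append((int(parts[ih]), int(parts[ik]), int(parts[il])))
        amp.append(float(val))
    if not hkl:
        raise ValueError(f"{path}: refln loop holds no usable rows")
    hkl_arr = np.array(hkl, dtype=np.int64)
    miller = MillerSet(hkl=hkl_arr, s=s_magnitude(cell, hkl_arr), cell=cell)
    return miller, ObservedData(amplitude=np.array(amp))


def write_scales(path: str | Path, scales: ScaleSet, boundaries: np.ndarray, counts: np.ndarray, shell_r: np.ndarray | None = None) -> None:
    """Write the fitted scale table: one row per resolution shell."""
    header = ["shell", "d_max", "d_min", "n_refl", "k_overall"] + [f"k_{cid}" for cid in scales.component_ids]
    if shell_r is not None:
        header.append("r_factor")
    lines = ["\t".join(header)]
    for i in range(len(counts)):
        row = [str(i), f"{boundaries[i]:.6g}", f"{boundaries[i + 1]:.6g}", str(int(counts[i])), repr(float(scales.k_overall[i]))]
        row += [repr(float(x)) for x in scales.k[i]]
        if shell_r is not None:
            row.append(repr(float(shell_r[i])))
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
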
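"""Synthetic parameter-recovery experiments.

A synthetic P1 crystal holds a protein-mimicking cluster of Gaussian
atoms (~25% of the cell) plus non-overlapping spheres in the remaining
volume, each with its own true scale.  Error-free amplitudes are
simulated from the total model; recovery trials then re-fit the scales
under controlled coordinate or data errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

from .cell import UnitCell
from .components import AtomSet, Component, Sphere, apply_smearing, atom_structure_factors, sphere_structure_factors
from .reflections import MillerSet, ResolutionShells, bin_shells, generate_hkl
from .solvers import ObservedData, ScaleSet, fit_driver, model_amplitudes, r_factor

__all__ = [
    "SyntheticCrystal",
    "TrialResult",
    "Scenario",
    "make_crystal",
    "pack_spheres",
    "simulate_fobs",
    "perturb_coordinates",
    "add_data_errors",
    "run_benchmark",
    "summarize_trials",
]


@dataclass(frozen=True)
class SyntheticCrystal:
    """A protein mimic plus scaled sphere components in a P1 cell."""

    cell: UnitCell
    atoms: AtomSet
    spheres: tuple[Sphere, ...]
    true_k: np.ndarray
    smearing_b: float
    seed: int | None = None
    protein_center: tuple[float, float, float] = (0.5, 0.5, 0.5)
    protein_radius: float = 0.0

    def __post_init__(self) -> None:
        k = np.asarray(self.true_k, dtype=float)
        if k.shape != (len(self.spheres),):
            raise ValueError("true_k must have one value per sphere")
        object.__setattr__(self, "true_k", k)
        object.__setattr__(self, "spheres", tuple(self.spheres))


@dataclass
class TrialResult:
    """Outcome of one synthetic recovery trial."""

    recovered_k: np.ndarray
    relative_errors: np.ndarray
    mean_relative_error: float
    max_relative_error: float
    r_factor: float
    r_initial: float
    algorithm: str
    converged: bool

    def __post_init__(self) -> None:
        if np.any(self.relative_errors < 0):
            raise ValueError("relative errors must be >= 0")


@dataclass(frozen=True)
class Scenario:
    """Configuration of one synthetic benchmark scenario."""

    kind: str = "error-free"  # error-free | coord-error | data-error
    doses: tuple[float, ...] = (0.0,)
    cell_edge: float = 42.0  # ~1e4 reflections at d_min 2.5
    d_min: float = 2.5
    n_atoms: int = 500
    protein_fraction: float = 0.25
    n_spheres: int | None = 7  # None: pack to saturation
    r_range: tuple[float, float] = (3.0, 10.0)
    k_range: tuple[float, float] = (0.0, 1.0)
    smearing_b: float = 50.0
    n_shells: int | None = 10
    init_spread: float = 10.0  # initial scales within [1/spread, spread] x truth

    def __post_init__(self) -> None:
        if self.kind not in ("error-free", "coord-error", "data-error"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")


def _cartesian_min_image(cell: UnitCell, dfrac: np.ndarray) -> np.ndarray:
    """Cartesian minimum-image vectors from fractional differences."""
    dfrac = dfrac - np.round(dfrac)
    return dfrac @ cell.orthogonalization_matrix().T


def pack_spheres(
    cell: UnitCell,
    protein_region: tuple[tuple[float, float, float], float],
    r_range: tuple[float, float] = (3.0, 10.0),
    q_range: tuple[float, float] = (0.1, 100.0),
    rng: np.random.Generator | None = None,
    max_rejections: int = 80,
    n_max: int | None = 60,
) -> list[Sphere]:
    """Rejection-sample non-overlapping spheres outside a protein region.

    ``protein_region`` is (fractional center, radius in A).  Accepted
    spheres overlap neither the protein sphere nor each other under the
    minimum-image metric; sampling stops after ``max_rejections``
    consecutive rejections (saturation) or at ``n_max`` spheres.
    """
    rng = rng or np.random.default_rng()
    p_center = np.asarray(protein_region[0], dtype=float)
    p_radius = float(protein_region[1])
    if p_radius >= min(cell.a, cell.b, cell.c) / 2.0:
        raise ValueError("protein region fills the cell; no room for spheres")
    accepted: list[Sphere] = []
    centers: list[np.ndarray] = []
    radii: list[float] = []
    rejections = 0
    while rejections < max_rejections and (n_max is None or len(accepted) < n_max):
        r = rng.uniform(*r_range)
        x = rng.uniform(0.0, 1.0, size=3)
        d_prot = np.linalg.norm(_cartesian_min_image(cell, x - p_center))
        ok = d_prot >= r + p_radius
        if ok and centers:
            d = np.linalg.norm(_cartesian_min_image(cell, np.array(centers) - x), axis=1)
            ok = bool(np.all(d >= r + np.array(radii)))
        if ok:
            q = rng.uniform(*q_range)
            accepted.append(Sphere(center=tuple(x), radius=r, occupancy=q))
            centers.append(x)
            radii.append(r)
            rejections = 0
        else:
            rejections += 1
    if not accepted:
        raise RuntimeError("could not place any sphere; protein region too large?")
    return accepted


def make_crystal(
    rng: np.random.Generator,
    cell_edge: float = 60.0,
    protein_fraction: float = 0.25,
    n_atoms: int = 500,
    n_spheres: int | None = 7,
    r_range: tuple[float, float] = (3.0, 10.0),
    k_range: tuple[float, float] = (0.0, 1.0),
    smearing_b: float = 50.0,
    seed: int | None = None,
) -> SyntheticCrystal:
    """Build a cubic P1 synthetic crystal with a protein mimic and spheres.

    The protein mimic is a compact cluster of Gaussian atoms inside a
    central sphere occupying ``protein_fraction`` of the cell volume;
    sphere components are packed into the remainder.
    """
    cell = UnitCell(cell_edge, cell_edge, cell_edge)
    p_radius = (3.0 * protein_fraction * cell.volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    # uniform points in the protein sphere (Cartesian), then to fractional
    u = rng.normal(size=(n_atoms, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radial = p_radius * rng.uniform(0.0, 1.0, size=n_atoms) ** (1.0 / 3.0)
    cart = u * radial[:, None]
    frac = 0.5 + cart / cell_edge
    atoms = AtomSet(
        positions=frac,
        weights=rng.uniform(6.0, 14.0, size=n_atoms),
        widths=rng.uniform(10.0, 30.0, size=n_atoms),
    )
    spheres = pack_spheres(
        cell,
        ((0.5, 0.5, 0.5), p_radius),
        r_range=r_range,
        q_range=k_range,
        rng=rng,
        n_max=n_spheres,
        max_rejections=80 if n_spheres is None else 500,
    )
    if n_spheres is not None and len(spheres) < n_spheres:
        raise RuntimeError(f"placed only {len(spheres)} of {n_spheres} requested spheres")
    true_k = np.array([s.occupancy for s in spheres])
    return SyntheticCrystal(
        cell=cell,
        atoms=atoms,
        spheres=spheres,
        true_k=true_k,
        smearing_b=smearing_b,
        seed=seed,
        protein_radius=p_radius,
    )


def crystal_components(
    crystal: SyntheticCrystal,
    miller: MillerSet,
    atoms: AtomSet | None = None,
) -> list[Component]:
    """Structure factors [F_atoms, smeared unit-occupancy spheres...].

    The first component is the principal (atomic) part; sphere
    components carry the common smearing B but unit occupancy, so the
    true scales are exactly ``crystal.true_k``.
    """
    comps = [atom_structure_factors(atoms or crystal.atoms, miller, id="atoms")]
    for j, sph in enumerate(crystal.spheres):
        unit = replace(sph, occupancy=1.0, b=0.0)
        comp = sphere_structure_factors(unit, miller, id=f"sphere{j}")
        comps.append(apply_smearing(comp, miller, crystal.smearing_b))
    return comps


def simulate_fobs(
    crystal: SyntheticCrystal,
    miller: MillerSet,
    components: list[Component] | None = None,
) -> ObservedData:
    """Error-free observables |F_atoms + sum_n k_n F_n^smeared|."""
    comps = components or crystal_components(crystal, miller)
    total = comps[0].f + sum(k * c.f for k, c in zip(crystal.true_k, comps[1:]))
    amp = np.abs(total)
    return ObservedData(amplitude=amp, intensity=amp**2)


def perturb_coordinates(
    atoms: AtomSet,
    target_rmsd: float,
    rng: np.random.Generator,
    cell: UnitCell,
) -> AtomSet:
    """Displace atoms isotropically so the realized Cartesian RMSD is exact."""
    if target_rmsd < 0:
        raise ValueError("target RMSD must be >= 0")
    if target_rmsd == 0 or len(atoms) == 0:
        return atoms
    disp = rng.normal(size=(len(atoms), 3))
    rms = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
    disp *= target_rmsd / rms
    frac_disp = np.linalg.solve(cell.orthogonalization_matrix(), disp.T).T
    return AtomSet(positions=atoms.positions + frac_disp, weights=atoms.weights, widths=atoms.widths)


def add_data_errors(
    obs: ObservedData,
    target_r: float,
    rng: np.random.Generator,
    tol: float = 1e-6,
) -> ObservedData:
    """Add zero-mean Gaussian amplitude noise calibrated to a target R factor.

    The noise sigma is found by root bracketing so that
    r_factor(noisy, exact) equals ``target_r``; negative amplitudes are
    clipped to zero before calibration, so the clipping is part of the
    calibrated map.
    """
    if not 0.0 <= target_r <= 0.5:
        raise ValueError("target R must be in [0, 0.5]")
    if target_r == 0.0:
        return obs
    amp = obs.amplitude
    eps = rng.normal(size=amp.shape)
    mean_amp = amp.mean()

    def realized(sigma: float) -> float:
        noisy = np.maximum(amp + sigma * mean_amp * eps, 0.0)
        return r_factor(amp, noisy)

    hi = 1.0
    for _ in range(60):
        if realized(hi) >= target_r:
            break
        hi *= 2.0
    else:
        raise RuntimeError(f"target R={target_r} unreachable after clipping")
    sigma = scipy.optimize.brentq(lambda s: realized(s) - target_r, 0.0, hi, xtol=1e-12, rtol=8.9e-16)
    if abs(realized(sigma) - target_r) > max(tol, 1e-4):
        raise RuntimeError(f"noise calibration failed: realized {realized(sigma)} vs target {target_r}")
    noisy = np.maximum(amp + sigma * mean_amp * eps, 0.0)
    return ObservedData(amplitude=noisy, intensity=noisy**2, sigma=np.full_like(amp, sigma * mean_amp))


def _aggregate_k(scales: ScaleSet, shells: ResolutionShells) -> np.ndarray:
    """Reflection-count-weighted mean of per-shell scales, per component."""
    w = shells.counts.astype(float)
    return (w[:, None] * scales.k).sum(axis=0) / w.sum()


def run_trial(
    true_k: np.ndarray,
    shells: ResolutionShells,
    obs: ObservedData,
    obs_exact: ObservedData,
    fit_components: list[Component],
    k_init: np.ndarray,
    algorithm: str,
    tol: float = 1e-8,
) -> TrialResult:
    """Fit one trial and score the recovered scales against truth.

    The recovered per-component multiplier compared with truth is
    k_overall * k_n (the full coefficient of F_n in the model).  All
    components share one smearing B, so the true scales are
    resolution-independent occupancies; the per-shell estimates are
    combined across shells weighted by the component's signal power
    sum |F_n|^2 in each shell (shells where a component does not
    scatter carry no information about its scale).
    """
    scales = fit_driver(
        obs, fit_components, shells, algorithm=algorithm,
        k_init=np.concatenate([[1.0], k_init]), tol=tol,
    )
    c_eff = scales.k_overall[:, None] * scales.k  # (n_shells, M)
    power = np.stack([
        [np.sum(np.abs(comp.f[shells.indices(i)]) ** 2) for comp in fit_components]
        for i in range(shells.n_shells)
    ])  # (n_shells, M)
    k_eff = (power * c_eff).sum(axis=0) / power.sum(axis=0)
    k_hat = k_eff[1:]
    rel = np.abs(k_hat - true_k) / np.abs(true_k)
    model = model_amplitudes(scales, fit_components, shells)
    baseline = _baseline_r(obs_exact, fit_components, shells)
    return TrialResult(
        recovered_k=k_hat,
        relative_errors=rel,
        mean_relative_error=float(rel.mean()),
        max_relative_error=float(rel.max()),
        r_factor=r_factor(obs_exact.amplitude, model),
        r_initial=baseline,
        algorithm=algorithm,
        converged=bool(scales.log["converged"]),
    )


def _baseline_r(obs_exact: ObservedData, fit_components: list[Component], shells: ResolutionShells) -> float:
    """R factor with every non-principal scale at zero (per-shell overall scale only)."""
    f0 = np.abs(fit_components[0].f)
    model = np.empty_like(f0)
    for i in range(shells.n_shells):
        idx = shells.indices(i)
        denom = f0[idx].sum()
        scale = obs_exact.amplitude[idx].sum() / denom if denom > 0 else 1.0
        model[idx] = scale * f0[idx]
    return r_factor(obs_exact.amplitude, model)


def run_benchmark(
    scenario: Scenario,
    n_trials: int = 50,
    algorithms: tuple[str, ...] = ("2h", "4"),
    seed: int = 0,
    tol: float = 1e-8,
    collect_trials: bool = False,
) -> dict:
    """Repeat seeded recovery trials over the scenario's dose grid.

    Returns a summary dict with one row per (algorithm, dose):
    mean/std/max relative error in k, mean fitted R, mean baseline R
    (all scales zero), and the number of failed trials.  Crystal
    geometry is fixed across trials; true scales, initial scales and
    the dose-specific perturbation are redrawn per trial.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_trials + 1)
    geom_rng = np.random.default_rng(children[0])
    crystal = make_crystal(
        geom_rng,
        cell_edge=scenario.cell_edge,
        protein_fraction=scenario.protein_fraction,
        n_atoms=scenario.n_atoms,
        n_spheres=scenario.n_spheres,
        r_range=scenario.r_range,
        k_range=scenario.k_range,
        smearing_b=scenario.smearing_b,
        seed=seed,
    )
    miller = generate_hkl(crystal.cell, scenario.d_min)
    shells = bin_shells(miller, n_shells=scenario.n_shells)
    base_components = crystal_components(crystal, miller)
    n_comp = len(crystal.spheres)

    rows = []
    trials_out: dict[tuple[str, float], list[TrialResult]] = {}
    for dose in scenario.doses:
        per_alg: dict[str, list[TrialResult]] = {a: [] for a in algorithms}
        failures: dict[str, int] = {a: 0 for a in algorithms}
        for t in range(n_trials):
            rng = np.random.default_rng(children[t + 1])
            lo, hi = scenario.k_range
            true_k = rng.uniform(max(lo, 1e-3), hi, size=n_comp)
            trial_crystal = replace(crystal, true_k=true_k)
            obs_exact = simulate_fobs(trial_crystal, miller, base_components)

            if scenario.kind == "coord-error" and dose > 0:
                perturbed = perturb_coordinates(crystal.atoms, dose, rng, crystal.cell)
                fit_components = crystal_components(trial_crystal, miller, atoms=perturbed)
            else:
                fit_components = base_components
            if scenario.kind == "data-error" and dose > 0:
                obs = add_data_errors(obs_exact, dose, rng)
            else:
                obs = obs_exact

            spread = np.log(scenario.init_spread)
            k_init = true_k * np.exp(rng.uniform(-spread, spread, size=n_comp))
            for alg in algorithms:
                try:
                    res = run_trial(
                        true_k, shells, obs, obs_exact, fit_components,
                        k_init, alg, tol=tol,
                    )
                    per_alg[alg].append(res)
                except Exception as exc:  # noqa: BLE001 - trial crash is data, not fatal
                    warnings.warn(f"trial {t} dose {dose} alg {alg} failed: {exc}", stacklevel=2)
                    failures[alg] += 1
        for alg in algorithms:
            rows.append(summarize_trials(per_alg[alg], alg, dose, failures[alg]))
            if collect_trials:
                trials_out[(alg, dose)] = per_alg[alg]

    out = {
        "scenario": scenario.kind,
        "doses": list(scenario.doses),
        "n_trials": n_trials,
        "seed": seed,
        "n_components": n_comp,
        "rows": rows,
    }
    if collect_trials:
        out["trials"] = trials_out
    return out


def summarize_trials(trials: list[TrialResult], algorithm: str, dose: float, n_failed: int = 0) -> dict:
    """Aggregate per-trial errors into one summary row."""
    if not trials:
        return {
            "algorithm": algorithm, "dose": dose, "n_trials": 0, "n_failed": n_failed,
            "mean_rel_error": np.nan, "std_rel_error": np.nan, "max_rel_error": np.nan,
            "mean_r": np.nan, "mean_r_initial": np.nan,
        }
    per_trial = np.array([t.mean_relative_error for t in trials])
    return {
        "algorithm": algorithm,
        "dose": dose,
        "n_trials": len(trials),
        "n_failed": n_failed,
        "mean_rel_error": float(per_trial.mean()),
        "std_rel_error": float(per_trial.std(ddof=1)) if len(trials) > 1 else 0.0,
        "max_rel_error": float(max(t.max_relative_error for t in trials)),
        "mean_r": float(np.mean([t.r_factor for t in trials])),
        "mean_r_initial": float(np.mean([t.r_initial for t in trials])),
    }
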
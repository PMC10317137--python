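"""Per-shell scale-factor search.

The total model in each resolution shell is

    F_model(s) = k_overall * [ k_0 F_0(s) + sum_n k_n F_n(s) ]

with shell-constant scales.  Four search strategies for the k_n are
implemented:

1. sequential one-component-at-a-time amplitude fits,
2. simultaneous quartic intensity least squares (quasi-Newton, optionally
   with analytic second derivatives),
3. a non-iterative two-step solve: linear normal equations for the
   products u_nm = k_n k_m, then a log least squares to factor them,
4. an iterative phased linear solve that borrows phases from the current
   model.

``fit_driver`` wraps any of them with per-shell overall scaling and an
outer iteration until convergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize

from .components import Component
from .reflections import ResolutionShells

__all__ = [
    "ObservedData",
    "CrossTerms",
    "ScaleSet",
    "cross_v",
    "ls_residual",
    "ls_gradient",
    "ls_hessian",
    "solve_shell_alg1",
    "solve_shell_alg2",
    "solve_shell_alg3",
    "solve_shell_alg4",
    "factor_products",
    "fit_driver",
    "r_factor",
]

#: condition number above which linear solves fall back to a pseudo-inverse
CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class ObservedData:
    """Observed amplitudes (and intensities) aligned to a MillerSet."""

    amplitude: np.ndarray
    intensity: np.ndarray | None = None
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float).reshape(-1)
        if np.any(amp < 0):
            raise ValueError("amplitudes must be >= 0")
        object.__setattr__(self, "amplitude", amp)
        if self.intensity is None:
            object.__setattr__(self, "intensity", amp**2)
        else:
            i = np.asarray(self.intensity, dtype=float).reshape(-1)
            if i.shape != amp.shape:
                raise ValueError("intensity and amplitude lengths differ")
            object.__setattr__(self, "intensity", i)

    def __len__(self) -> int:
        return self.amplitude.shape[0]


@dataclass(frozen=True)
class CrossTerms:
    """Real cross terms v_nm(s) = Re(F_n conj F_m), shape (n_refl, M, M)."""

    v: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.v, dtype=float)
        if v.ndim != 3 or v.shape[1] != v.shape[2]:
            raise ValueError("v must have shape (n_refl, M, M)")
        object.__setattr__(self, "v", v)

    @property
    def n_components(self) -> int:
        return self.v.shape[1]


@dataclass
class ScaleSet:
    """Refined per-shell scales plus the run log of the fit."""

    k_overall: np.ndarray  # (n_shells,)
    k: np.ndarray  # (n_shells, M)
    component_ids: list[str]
    fixed: np.ndarray  # (M,) bool
    log: dict = field(default_factory=dict)


def _component_matrix(components: Sequence[Component] | np.ndarray) -> np.ndarray:
    """Stack components into a complex (M, n_refl) matrix."""
    if isinstance(components, np.ndarray):
        f = np.asarray(components, dtype=complex)
        return f.reshape(1, -1) if f.ndim == 1 else f
    lengths = {len(c) for c in components}
    if len(lengths) != 1:
        raise ValueError("components are not aligned to one MillerSet")
    return np.stack([c.f for c in components])


def cross_v(components: Sequence[Component] | np.ndarray) -> CrossTerms:
    """Pairwise real cross terms v_nm(s) = Re(F_n(s) conj(F_m(s)))."""
    f = _component_matrix(components)
    v = np.einsum("ns,ms->snm", f, np.conj(f)).real
    return CrossTerms(v=np.ascontiguousarray(v))


def _shell_slice(arr: np.ndarray, shell) -> np.ndarray:
    out = arr if shell is None else arr[shell]
    if out.shape[0] == 0:
        raise ValueError("empty shell")
    return out


def ls_residual(k: np.ndarray, ct: CrossTerms, obs: ObservedData, shell=None) -> float:
    """Quartic intensity residual sum_s (I_obs - sum_nm k_n k_m v_nm)^2."""
    v = _shell_slice(ct.v, shell)
    i_obs = _shell_slice(obs.intensity, shell)
    k = np.asarray(k, dtype=float)
    model = (v @ k) @ k
    return float(np.sum((i_obs - model) ** 2))


def ls_gradient(k: np.ndarray, ct: CrossTerms, obs: ObservedData, shell=None) -> np.ndarray:
    """d/dk_p of the quartic residual: -4 sum_s delta_s (V_s k)_p."""
    v = _shell_slice(ct.v, shell)
    i_obs = _shell_slice(obs.intensity, shell)
    k = np.asarray(k, dtype=float)
    vk = v @ k  # (S, M)
    delta = i_obs - vk @ k
    return -4.0 * (delta @ vk)


def ls_hessian(k: np.ndarray, ct: CrossTerms, obs: ObservedData, shell=None) -> np.ndarray:
    """Analytic second derivatives of the quartic residual."""
    v = _shell_slice(ct.v, shell)
    i_obs = _shell_slice(obs.intensity, shell)
    k = np.asarray(k, dtype=float)
    vk = v @ k
    delta = i_obs - vk @ k
    return 8.0 * (vk.T @ vk) - 4.0 * np.einsum("s,spq->pq", delta, v)


def r_factor(f_obs: np.ndarray, f_model: np.ndarray) -> float:
    """Crystallographic R = sum ||F_obs| - |F_model|| / sum |F_obs|."""
    f_obs = np.abs(np.asarray(f_obs, dtype=float))
    f_model = np.abs(np.asarray(f_model))
    if f_obs.shape != f_model.shape or f_obs.size == 0:
        raise ValueError("amplitude arrays must be aligned and nonempty")
    denom = f_obs.sum()
    if denom == 0:
        raise ValueError("all observed amplitudes are zero")
    return float(np.abs(f_obs - f_model).sum() / denom)


def _resolve_fixed(m: int, fixed, k_init) -> tuple[np.ndarray, np.ndarray]:
    """Normalize the fixed-component mask and a full-length starting vector."""
    mask = np.zeros(m, dtype=bool)
    if fixed is not None:
        mask[np.asarray(fixed)] = True
    k0 = np.ones(m) if k_init is None else np.asarray(k_init, dtype=float).copy()
    if k0.shape != (m,):
        raise ValueError(f"k_init must have length {m}")
    return mask, k0


def _solve_sym(a: np.ndarray, b: np.ndarray, log: dict | None = None) -> np.ndarray:
    """Symmetric solve with condition monitoring and pseudo-inverse fallback."""
    cond = np.linalg.cond(a) if a.size else 0.0
    if log is not None:
        log.setdefault("condition_numbers", []).append(float(cond))
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        warnings.warn(f"ill-conditioned linear system (cond={cond:.3g}); using pseudo-inverse", stacklevel=2)
        if log is not None:
            log["ill_conditioned"] = True
        return np.linalg.lstsq(a, b, rcond=None)[0]
    return np.linalg.solve(a, b)


# ---------------------------------------------------------------------------
# algorithm 2: simultaneous quartic least squares


def solve_shell_alg2(
    ct: CrossTerms,
    obs: ObservedData,
    shell,
    k_init: np.ndarray,
    use_hessian: bool = False,
    max_iter: int = 100,
    clip: bool = True,
    gtol: float = 1e-8,
    fixed=None,
    log: dict | None = None,
) -> np.ndarray:
    """Minimize the quartic intensity residual over the free scales.

    Runs a bounded quasi-Newton search (optionally with the analytic
    Hessian) followed by Newton polishing to the gradient tolerance.
    Guaranteed not to increase the residual relative to ``k_init``.
    """
    m = ct.n_components
    mask, k_full = _resolve_fixed(m, fixed, k_init)
    free = ~mask
    if not free.any():
        return k_full

    # normalize intensities to unit RMS: same minimizer, sane tolerances
    v_shell = _shell_slice(ct.v, shell)
    i_shell = _shell_slice(obs.intensity, shell)
    norm = float(np.sqrt(np.mean(i_shell**2))) or 1.0
    ct_n = CrossTerms(v=v_shell / norm)
    obs_n = ObservedData(amplitude=np.sqrt(np.abs(i_shell) / norm), intensity=i_shell / norm)

    def embed(x: np.ndarray) -> np.ndarray:
        k = k_full.copy()
        k[free] = x
        return k

    def fun(x):
        return ls_residual(embed(x), ct_n, obs_n, None)

    def jac(x):
        return ls_gradient(embed(x), ct_n, obs_n, None)[free]

    def hess(x):
        return ls_hessian(embed(x), ct_n, obs_n, None)[np.ix_(free, free)]

    # negative scales are allowed during the search (sign information is
    # recovered by normalization below; clipping happens on output)
    x0 = k_full[free]
    f0 = fun(x0)
    nit = 0
    if use_hessian:
        # quasi-Newton warm start, then damped Newton with the analytic
        # Hessian down to the gradient tolerance
        res = scipy.optimize.minimize(
            fun, x0, jac=jac, method="L-BFGS-B",
            options={"maxiter": max(max_iter // 4, 10), "ftol": 1e-14, "gtol": gtol, "maxcor": 20},
        )
        x = np.asarray(res.x, dtype=float)
        nit = int(res.nit)
        for _ in range(max_iter):
            g = jac(x)
            if np.max(np.abs(g)) <= gtol:
                break
            h = hess(x)
            lam = 0.0
            step = None
            for _ in range(12):
                try:
                    step = np.linalg.solve(h + lam * np.eye(h.shape[0]), g)
                except np.linalg.LinAlgError:
                    step = None
                if step is not None and np.all(np.isfinite(step)) and step @ g > 0:
                    break
                lam = max(10.0 * lam, 1e-8 * (np.trace(np.abs(h)) + 1.0))
            else:
                break
            f_cur = fun(x)
            t = 1.0
            f_new = None
            for _ in range(25):
                x_new = x - t * step
                f_new = fun(x_new)
                if f_new <= f_cur:
                    break
                t *= 0.5
            else:
                break
            x = x_new
            nit += 1
            if f_cur - f_new <= 1e-14 * max(f_cur, 1.0):
                break
    else:
        res = scipy.optimize.minimize(
            fun, x0, jac=jac, method="L-BFGS-B",
            options={"maxiter": max_iter * 10, "ftol": 1e-18, "gtol": min(gtol, 1e-10), "maxcor": 20},
        )
        x = np.asarray(res.x, dtype=float)
        nit = int(res.nit)
    if not np.isfinite(fun(x)):
        raise FloatingPointError(f"non-finite residual during search; last iterate {embed(x)}")
    if fun(x) > f0:
        x = x0  # safeguard: never worse than the start
    if x[np.argmax(np.abs(x))] < 0:
        x = -x  # global sign flip is an invariance; report the + branch
    if log is not None:
        log.setdefault("alg2_nit", []).append(nit)
    return embed(x)


# ---------------------------------------------------------------------------
# algorithm 3: two-step analytic search


def solve_shell_alg3(
    ct: CrossTerms,
    obs: ObservedData,
    shell,
    fixed=None,
    k_fixed: np.ndarray | None = None,
    clip: bool = True,
    log: dict | None = None,
) -> np.ndarray:
    """Non-iterative two-step solve.

    Step 1 treats every product u_nm = k_n k_m (n <= m, free components)
    as an independent unknown: the intensity model is then linear in the
    u_nm (with multiplicity 2 - delta_nm from merging the nm/mn terms)
    and solved by normal equations.  Step 2 factors the products by
    least squares on lambda_n = ln k_n over pairs with u_nm > 0.

    Components whose k cannot be fixed at a known value are all free by
    default; if some are fixed (``fixed`` indices with values from
    ``k_fixed``), their quadratic and cross contributions enter the
    model as known offsets and linear columns.
    """
    v = _shell_slice(ct.v, shell)
    i_obs = _shell_slice(obs.intensity, shell)
    m = ct.n_components
    mask, k_full = _resolve_fixed(m, fixed, k_fixed if k_fixed is not None else np.ones(m))
    free_idx = np.flatnonzero(~mask)
    fixed_idx = np.flatnonzero(mask)
    nf = len(free_idx)
    if nf == 0:
        return k_full

    kf = k_full[fixed_idx]
    # known offset from the fixed block
    offset = np.einsum("sfg,f,g->s", v[np.ix_(np.arange(v.shape[0]), fixed_idx, fixed_idx)], kf, kf) if len(fixed_idx) else 0.0
    rhs = i_obs - offset

    pairs = [(a, b) for ai, a in enumerate(free_idx) for b in free_idx[ai:]]
    n_lin = nf if len(fixed_idx) else 0
    design = np.empty((v.shape[0], n_lin + len(pairs)))
    if n_lin:
        # linear columns: cross terms of each free k_a with the fixed block
        for col, a in enumerate(free_idx):
            design[:, col] = 2.0 * (v[:, a, fixed_idx] @ kf)
    for col, (a, b) in enumerate(pairs):
        mult = 1.0 if a == b else 2.0
        design[:, n_lin + col] = mult * v[:, a, b]

    normal = design.T @ design
    solution = _solve_sym(normal, design.T @ rhs, log=log)
    k_lin = solution[:nf] if n_lin else None
    u_flat = solution[n_lin:]
    u = np.zeros((nf, nf))
    pos = {idx: j for j, idx in enumerate(free_idx)}
    for col, (a, b) in enumerate(pairs):
        u[pos[a], pos[b]] = u[pos[b], pos[a]] = u_flat[col]

    k_out = k_full.copy()
    # sign information is lost in the log step; the nonnegative branch
    # is reported regardless of ``clip``
    k_out[free_idx] = factor_products(u, linear=k_lin)
    return k_out


def factor_products(u: np.ndarray, linear: np.ndarray | None = None) -> np.ndarray:
    """Factor a symmetric product table u_nm ~ k_n k_m into nonnegative k.

    Solves the least-squares problem on lambda_n = ln k_n over entries
    with u_nm > 0 (each unordered pair used once), optionally augmented
    with direct estimates ``linear`` of the k themselves.  Components
    with no positive evidence get k = 0 with a warning.
    """
    u = np.asarray(u, dtype=float)
    nf = u.shape[0]
    rows, targets = [], []
    for a in range(nf):
        for b in range(a, nf):
            if u[a, b] > 0:
                row = np.zeros(nf)
                row[a] += 1.0
                row[b] += 1.0
                rows.append(row)
                targets.append(np.log(u[a, b]))
    if linear is not None:
        for j in range(nf):
            if linear[j] > 0:
                row = np.zeros(nf)
                row[j] = 1.0
                rows.append(row)
                targets.append(np.log(linear[j]))
    lam = np.full(nf, -np.inf)
    if rows:
        a_mat = np.array(rows)
        lam_sol, *_ = np.linalg.lstsq(a_mat, np.array(targets), rcond=None)
        determined = (np.abs(a_mat) > 0).any(axis=0)
        lam[determined] = lam_sol[determined]
    undetermined = ~np.isfinite(lam)
    if undetermined.any():
        warnings.warn(
            f"components {np.flatnonzero(undetermined).tolist()} have no positive "
            "product evidence; k set to 0",
            stacklevel=2,
        )
    return np.where(np.isfinite(lam), np.exp(lam), 0.0)


# ---------------------------------------------------------------------------
# algorithm 4: iterative phased search


def solve_shell_alg4(
    components: Sequence[Component] | np.ndarray,
    obs: ObservedData,
    shell,
    k_init: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-6,
    fixed=None,
    log: dict | None = None,
) -> np.ndarray:
    """Iterative phased linear solve.

    Each iteration borrows phases from the current model sum, builds the
    phased pseudo-observations A_s = |F_obs,s| exp(i phi_s), and solves
    the (N+1)-dimensional linear system sum_m k_m sum_s v_nm = w_n with
    w_n = sum_s Re(A conj F_n).  Reflections with zero model amplitude
    are skipped for that phase update.
    """
    f = _component_matrix(components)
    f = f if shell is None else f[:, shell]
    f_obs = _shell_slice(obs.amplitude, shell)
    m = f.shape[0]
    mask, k = _resolve_fixed(m, fixed, k_init)
    free = np.flatnonzero(~mask)
    if len(free) == 0:
        return k
    v_bar_full = np.einsum("ns,ms->nm", f, np.conj(f)).real

    n_done = 0
    for n_done in range(1, max_iter + 1):
        model = k @ f
        amp = np.abs(model)
        ok = amp > 0
        phase = np.ones_like(model)
        phase[ok] = model[ok] / amp[ok]
        a_phased = f_obs * phase
        if ok.all():
            v_bar = v_bar_full
            w = np.einsum("s,ms->m", a_phased, np.conj(f)).real
        else:
            v_bar = np.einsum("ns,ms->nm", f[:, ok], np.conj(f[:, ok])).real
            w = np.einsum("s,ms->m", a_phased[ok], np.conj(f[:, ok])).real
        rhs = w[free] - v_bar[np.ix_(free, np.flatnonzero(mask))] @ k[mask]
        k_free = _solve_sym(v_bar[np.ix_(free, free)], rhs, log=log)
        change = np.max(np.abs(k_free - k[free]) / np.maximum(np.abs(k[free]), 1e-8))
        k = k.copy()
        k[free] = k_free
        if change <= tol:
            break
    if log is not None:
        log.setdefault("alg4_nit", []).append(n_done)
    return k


# ---------------------------------------------------------------------------
# algorithm 1: sequential search


def solve_shell_alg1(
    components: Sequence[Component] | np.ndarray,
    obs: ObservedData,
    shell,
    k_init: np.ndarray | None = None,
    order: Sequence[int] | None = None,
    clip: bool = True,
    fixed=None,
    log: dict | None = None,
) -> np.ndarray:
    """One sequential pass: fit each free component's scale alone.

    Components are visited in ``order`` (default: descending total
    intensity sum |F_n|^2); for each, all other scales are held fixed
    and the 1-D amplitude residual sum (|F_obs| - |F_rest + t F_n|)^2
    is minimized by bracketed scalar search.
    """
    f = _component_matrix(components)
    f = f if shell is None else f[:, shell]
    f_obs = _shell_slice(obs.amplitude, shell)
    m = f.shape[0]
    mask, k = _resolve_fixed(m, fixed, k_init if k_init is not None else np.zeros(m))
    free = [i for i in range(m) if not mask[i]]
    if order is None:
        power = np.abs(f) ** 2
        order = sorted(free, key=lambda i: -power[i].sum())
    else:
        order = [i for i in order if not mask[i]]

    for n in order:
        f_rest = (k @ f) - k[n] * f[n]
        fn = f[n]
        fn2 = np.abs(fn) ** 2

        def resid(t):
            return np.sum((f_obs - np.abs(f_rest + t * fn)) ** 2)

        t_up = float(np.sum(f_obs * np.abs(fn)) / np.sum(fn2))
        lo = 0.0 if clip else -2.0 * t_up
        grid = np.linspace(lo, 2.0 * t_up + 1e-12, 41)
        vals = [resid(t) for t in grid]
        best = int(np.argmin(vals))
        step = grid[1] - grid[0] if len(grid) > 1 else 1.0
        res = scipy.optimize.minimize_scalar(
            resid,
            bounds=(grid[best] - step, grid[best] + step),
            method="bounded",
            options={"xatol": 1e-10 * (1.0 + abs(grid[best]))},
        )
        t = float(res.x)
        if clip:
            t = max(t, 0.0)
        k = k.copy()
        k[n] = t
    return k


# ---------------------------------------------------------------------------
# outer driver


_ALGORITHMS = {"1", "2", "2h", "3", "4"}


def fit_driver(
    obs: ObservedData,
    components: Sequence[Component] | np.ndarray,
    shells: ResolutionShells,
    algorithm: str = "4",
    k_init: np.ndarray | None = None,
    fix_first: bool = True,
    clip: bool = True,
    tol: float = 1e-4,
    max_outer: int = 100,
    component_ids: Sequence[str] | None = None,
) -> ScaleSet:
    """Alternate per-shell scale solves with overall-scale updates.

    ``components[0]`` is the principal (atomic) part; its scale is held
    at 1 when ``fix_first`` (the default) and refined otherwise.

    Internally each shell is solved for the free coefficients
    c_n = k_overall * k_n of every component; when the principal scale
    is fixed the overall scale is then factored out as c_0, which is
    the overall-scale update of the outer iteration.  The outer loop
    stops when the largest relative coefficient change drops to
    ``tol``, or after ``max_outer`` iterations, or on divergence (three
    consecutive increases of the overall R factor, in which case the
    best iterate seen is returned and flagged).
    """
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(_ALGORITHMS)}")
    f = _component_matrix(components)
    m, n_refl = f.shape
    if len(obs) != n_refl:
        raise ValueError("observations and components are not aligned")
    ids = list(component_ids) if component_ids is not None else (
        [c.id for c in components] if not isinstance(components, np.ndarray) else [f"c{i}" for i in range(m)]
    )
    fixed_mask = np.zeros(m, dtype=bool)
    if fix_first and m > 0:
        fixed_mask[0] = True

    ct = cross_v(f)
    n_shells = shells.n_shells
    shell_idx = [shells.indices(i) for i in range(n_shells)]
    log: dict = {"algorithm": algorithm, "shell_logs": [dict() for _ in range(n_shells)]}

    # --- initialization: coefficients c[i] = k_overall * (k_0, ..., k_N) ----
    c = np.ones((n_shells, m))
    if k_init is not None:
        k_init = np.asarray(k_init, dtype=float)
        c[:] = k_init if k_init.ndim == 2 else k_init[None, :]
    else:
        # phased single-component estimate on the summed non-principal
        # parts, split equally across them
        for i, idx in enumerate(shell_idx):
            if m > 1:
                g = f[1:, idx].sum(axis=0)
                base = f[0, idx]
                total = base + g
                amp = np.abs(total)
                denom = np.sum(np.abs(g) ** 2)
                if denom > 0 and np.any(amp > 0):
                    phase = np.where(amp > 0, total / np.maximum(amp, 1e-300), 1.0)
                    a_phased = obs.amplitude[idx] * phase
                    gk = np.sum((a_phased - base) * np.conj(g)).real / denom
                    c[i, 1:] = max(gk, 0.0) if clip else gk
    for i, idx in enumerate(shell_idx):
        denom = np.abs(c[i] @ f[:, idx]).sum()
        if denom > 0:
            c[i] *= obs.amplitude[idx].sum() / denom

    # global pre-fit: whole-set solves seed every shell, keeping the
    # small-shell solves inside the basin of the global solution.  Two
    # starting points are tried: the provided/default initialization and
    # the phased summed-component estimate; the lower-residual basin wins.
    if n_shells > 1 and algorithm != "3":
        glog: dict = {}
        starts = [c.mean(axis=0)]
        if m > 1:
            g = f[1:].sum(axis=0)
            denom = np.sum(np.abs(g) ** 2)
            total0 = f[0] + g
            amp0 = np.abs(total0)
            if denom > 0 and np.any(amp0 > 0):
                phase = np.where(amp0 > 0, total0 / np.maximum(amp0, 1e-300), 1.0)
                gk = np.sum((obs.amplitude * phase - f[0]) * np.conj(g)).real / denom
                alt = np.ones(m)
                alt[1:] = max(gk, 1e-3)
                model = np.abs(alt @ f).sum()
                if model > 0:
                    alt *= obs.amplitude.sum() / model
                starts.append(alt)
        best_glob: tuple[float, np.ndarray] | None = None
        for start in starts:
            try:
                if algorithm == "1":
                    cand = solve_shell_alg1(f, obs, None, k_init=start, clip=clip, log=glog)
                elif algorithm in ("2", "2h"):
                    cand = solve_shell_alg2(
                        ct, obs, None, k_init=start,
                        use_hessian=(algorithm == "2h"), clip=clip, log=glog,
                    )
                else:
                    cand = solve_shell_alg4(f, obs, None, k_init=start, tol=min(tol, 1e-6), log=glog)
            except (FloatingPointError, np.linalg.LinAlgError):
                continue
            resid = r_factor(obs.amplitude, np.abs(cand @ f))
            if best_glob is None or resid < best_glob[0]:
                best_glob = (resid, cand)
        if best_glob is not None:
            c[:] = best_glob[1][None, :]
        log["global_prefit"] = glog

    def total_r(c_cur: np.ndarray) -> float:
        model = np.empty(n_refl)
        for i, idx in enumerate(shell_idx):
            model[idx] = np.abs(c_cur[i] @ f[:, idx])
        return r_factor(obs.amplitude, model)

    # --- outer iteration ----------------------------------------------------
    best = (total_r(c), c.copy())
    r_prev = best[0]
    n_increase = 0
    converged = False
    diverged = False
    r_history = [r_prev]
    n_outer = 0

    for n_outer in range(1, max_outer + 1):
        c_old = c.copy()
        for i, idx in enumerate(shell_idx):
            slog = log["shell_logs"][i]
            obs_i = ObservedData(amplitude=obs.amplitude[idx], intensity=obs.intensity[idx])
            fi = f[:, idx]
            cti = CrossTerms(v=ct.v[idx])
            if algorithm == "1":
                c[i] = solve_shell_alg1(fi, obs_i, None, k_init=c[i], clip=clip, log=slog)
            elif algorithm in ("2", "2h"):
                c[i] = solve_shell_alg2(
                    cti, obs_i, None, k_init=c[i],
                    use_hessian=(algorithm == "2h"), clip=clip, log=slog,
                )
            elif algorithm == "3":
                c[i] = solve_shell_alg3(cti, obs_i, None, clip=clip, log=slog)
            else:
                c[i] = solve_shell_alg4(
                    fi, obs_i, None, k_init=c[i], tol=min(tol, 1e-6), log=slog,
                )

        r_now = total_r(c)
        r_history.append(r_now)
        if r_now < best[0]:
            best = (r_now, c.copy())

        change = np.max(np.abs(c - c_old) / np.maximum(np.abs(c_old), 1e-8))
        if change <= tol:
            converged = True
            break
        if r_now > r_prev * (1.0 + 1e-9) + 1e-14:
            n_increase += 1
            if n_increase >= 3:
                diverged = True
                break
        else:
            n_increase = 0
        r_prev = r_now

    if diverged:
        _, c = best
    if clip:
        c = np.maximum(c, 0.0)

    # factor the overall scale out of the principal coefficient
    if fix_first and m > 0:
        k_ov = np.where(np.abs(c[:, 0]) > 1e-300, c[:, 0], 1.0)
        k = c / k_ov[:, None]
    else:
        k_ov = np.ones(n_shells)
        k = c
    log.update(
        n_outer=n_outer,
        converged=converged,
        diverged=diverged,
        r_history=r_history,
        r_final=total_r(c),
    )
    return ScaleSet(k_overall=k_ov, k=k, component_ids=ids, fixed=fixed_mask, log=log)


def model_amplitudes(scales: ScaleSet, components: Sequence[Component] | np.ndarray, shells: ResolutionShells) -> np.ndarray:
    """Total model amplitudes |k_overall sum_n k_n F_n| per reflection."""
    f = _component_matrix(components)
    out = np.empty(f.shape[1])
    for i in range(shells.n_shells):
        idx = shells.indices(i)
        out[idx] = scales.k_overall[i] * np.abs(scales.k[i] @ f[:, idx])
    return out
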
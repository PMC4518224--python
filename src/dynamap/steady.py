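"""Steady-state enumeration and a simulation-based attractor oracle.

Roots of the right-hand side are located by damped Newton iteration run
from many starting points spread over the admissible box [0, upper_bound]
(two corner starts plus seeded Latin-hypercube starts). The Newton sweep is
vectorised across starts, so one call per iteration evaluates the rhs and
Jacobian for every still-active start. Converged roots are deduplicated,
assigned Jacobian eigenvalues, and labelled stable / unstable / marginal by
the sign of the largest eigenvalue real part.

:func:`attractors_by_simulation` provides the independent cross-check: it
integrates the ODEs from random initial conditions and classifies each
trajectory endpoint as a fixed point or a sustained oscillation from the
peak-to-trough amplitude of its trailing windows.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import NumericsError, OdeModel, ParameterPoint, as_mapping, eval_jacobian

__all__ = [
    "Attractor",
    "RootFindingError",
    "SimulationResult",
    "SolverOptions",
    "SteadyState",
    "attractors_by_simulation",
    "find_steady_states",
]

log = logging.getLogger(__name__)


class RootFindingError(RuntimeError):
    """No Newton start converged: the point's dynamics are undetermined."""


@dataclass(frozen=True)
class SteadyState:
    """A converged root of the rhs with its local stability information."""

    state: np.ndarray            # (n,) nM
    residual_norm: float         # max-norm of rhs at the root, nM/s
    eigenvalues: np.ndarray      # complex, 1/s
    stability: str               # 'stable' | 'unstable' | 'marginal'

    @property
    def max_real_eig(self) -> float:
        return float(np.max(self.eigenvalues.real))


@dataclass(frozen=True)
class SolverOptions:
    """Tunables of the multi-start Newton sweep.

    ``tol_root`` defaults to ``1e-9 * max(1, max upper bound)`` (residual
    max-norm); ``eps_eig`` scales with the spectral radius so that points
    sitting numerically on a bifurcation boundary are flagged marginal
    rather than force-classified.
    """

    n_starts: int = 48
    seed: int = 0
    tol_root: float | None = None
    max_iter: int = 200
    max_halvings: int = 40
    dedup_rtol: float = 1e-5
    eps_eig_rel: float = 1e-8

    def resolve_tol(self, upper: np.ndarray) -> float:
        if self.tol_root is not None:
            return self.tol_root
        return 1e-9 * max(1.0, float(np.max(upper)))


def _newton_starts(
    upper: np.ndarray, n_starts: int, seed: int
) -> np.ndarray:
    """Corner starts (origin, upper bound) plus classic-LHS starts in the box."""
    n = upper.shape[0]
    starts = [np.zeros(n), upper.astype(float)]
    n_lhs = max(n_starts - 2, 0)
    if n_lhs:
        rng = np.random.default_rng(seed)
        u = np.empty((n_lhs, n))
        for j in range(n):
            u[:, j] = (rng.permutation(n_lhs) + rng.uniform(size=n_lhs)) / n_lhs
        starts.append(u * upper)
    return np.vstack([np.atleast_2d(s) for s in starts])


def _batched_solve(J: np.ndarray, b: np.ndarray, scale: float) -> np.ndarray:
    """Solve J x = b per batch row; Tikhonov-regularise singular batches."""
    try:
        return np.linalg.solve(J, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        n = J.shape[-1]
        reg = J + 1e-10 * scale * np.eye(n)
        try:
            return np.linalg.solve(reg, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            out = np.full(b.shape, np.nan)
            for i in range(J.shape[0]):
                try:
                    out[i] = np.linalg.lstsq(J[i], b[i], rcond=None)[0]
                except np.linalg.LinAlgError:
                    pass
            return out


def _damped_newton(
    model: OdeModel,
    params: Mapping[str, float],
    starts: np.ndarray,
    upper: np.ndarray,
    tol: float,
    options: SolverOptions,
) -> np.ndarray:
    """Run the damped Newton sweep; returns converged roots (k, n).

    Iterates are clipped to the admissible box [0, upper]: negative
    concentrations are physically meaningless and integer-valued Hill
    exponents are undefined for negative bases. Starts whose rhs turns
    non-finite are discarded.
    """
    p = dict(params)

    def f(X):
        return np.asarray(model.rhs(X, p), dtype=float)

    def jac(X):
        if model.jacobian is not None:
            return np.asarray(model.jacobian(X, p), dtype=float)
        from .core import finite_difference_jacobian

        return finite_difference_jacobian(model.rhs, X, p)

    X = np.clip(starts.astype(float), 0.0, upper)
    F = f(X)
    normF = np.max(np.abs(F), axis=-1)
    alive = np.all(np.isfinite(F), axis=-1)
    # Convergence needs BOTH a small residual and a negligible Newton step:
    # when the kinetics are slow the residual alone admits a wide interval
    # of pseudo-roots (|f| ~ rate * error), and only the step criterion
    # certifies that the iteration has actually landed on the root.
    converged = np.zeros(X.shape[0], dtype=bool)
    scale = max(1.0, float(np.max(upper)))
    # Damping memory: each start re-enters the line search near the factor
    # that worked last time (growing by 4x), instead of re-halving from 1.
    lam_carry = np.ones(X.shape[0])

    for _ in range(options.max_iter):
        act = alive & ~converged
        if not act.any():
            break
        Xa, Fa = X[act], F[act]
        J = jac(Xa)
        bad_j = ~np.all(np.isfinite(J.reshape(J.shape[0], -1)), axis=-1)
        step = np.zeros_like(Fa)
        ok = ~bad_j
        if ok.any():
            step[ok] = _batched_solve(J[ok], -Fa[ok], scale)
        bad = bad_j | ~np.all(np.isfinite(step), axis=-1)

        # Starts already sitting on a root (tiny residual AND tiny Newton
        # step) are converged outright — a strict-decrease line search can
        # never improve a zero residual.
        norm_a = np.max(np.abs(Fa), axis=-1)
        at_root = (
            ~bad
            & (norm_a < tol)
            & (np.max(np.abs(step), axis=-1) < 1e-9 * (1.0 + np.max(np.abs(Xa), axis=-1)))
        )

        # Backtracking line search on the residual max-norm, per start.
        lam = np.minimum(1.0, 4.0 * lam_carry[act])
        Xn, Fn, norm_n = Xa.copy(), Fa.copy(), norm_a.copy()
        need = ~bad & ~at_root
        for _h in range(options.max_halvings):
            if not need.any():
                break
            trial = np.clip(Xa[need] + lam[need, None] * step[need], 0.0, upper)
            Ft = f(trial)
            nt = np.max(np.abs(Ft), axis=-1)
            finite = np.all(np.isfinite(Ft), axis=-1)
            # Sufficient decrease (Armijo-style): starts that can only make
            # microscopic progress fail the search and are discarded.
            better = finite & (nt < (1.0 - 1e-4 * lam[need]) * norm_a[need])
            idx = np.flatnonzero(need)
            acc = idx[better]
            Xn[acc], Fn[acc], norm_n[acc] = trial[better], Ft[better], nt[better]
            need[acc] = False
            lam[idx[~better]] *= 0.5
        # A start whose line search exhausts its halvings without improving
        # the residual has failed: discard it rather than let it wander.
        bad |= need

        lam_carry[act] = lam
        delta = np.max(np.abs(Xn - Xa), axis=-1)
        state_scale = 1.0 + np.max(np.abs(Xn), axis=-1)
        X[act], F[act] = Xn, Fn
        sub_alive = ~bad
        sub_conv = at_root | (
            sub_alive & (norm_n < tol) & (delta < 1e-9 * state_scale)
        )
        alive_idx = np.flatnonzero(act)
        alive[alive_idx[~sub_alive]] = False
        converged[alive_idx[sub_conv]] = True

    return X[alive & converged]


def _polish(
    model: OdeModel,
    params: Mapping[str, float],
    roots: np.ndarray,
    upper: np.ndarray,
    n_iter: int = 5,
) -> np.ndarray:
    """Sharpen converged roots with undamped Newton steps (quadratic
    convergence drives residuals to machine precision), so that multiple
    starts landing in the same tolerance ball collapse onto one point
    before deduplication."""
    p = dict(params)
    X = roots.copy()
    scale = max(1.0, float(np.max(upper)))
    for _ in range(n_iter):
        F = np.asarray(model.rhs(X, p), dtype=float)
        if model.jacobian is not None:
            J = np.asarray(model.jacobian(X, p), dtype=float)
        else:
            from .core import finite_difference_jacobian

            J = finite_difference_jacobian(model.rhs, X, p)
        step = _batched_solve(J, -F, scale)
        ok = np.all(np.isfinite(step), axis=-1)
        if not ok.any():
            break
        Xn = np.clip(X + np.where(ok[:, None], step, 0.0), 0.0, upper)
        Fn = np.asarray(model.rhs(Xn, p), dtype=float)
        better = (
            ok
            & np.all(np.isfinite(Fn), axis=-1)
            & (np.max(np.abs(Fn), axis=-1) <= np.max(np.abs(F), axis=-1))
        )
        if not better.any():
            break
        X[better] = Xn[better]
    return X


def _dedup(
    roots: np.ndarray, residuals: np.ndarray, tol_dist: float
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy max-norm deduplication; ties keep the smaller residual."""
    order = np.argsort(residuals, kind="stable")
    kept: list[int] = []
    for i in order:
        if all(np.max(np.abs(roots[i] - roots[j])) >= tol_dist for j in kept):
            kept.append(i)
    kept_arr = np.array(kept, dtype=int)
    return roots[kept_arr], residuals[kept_arr]


def find_steady_states(
    model: OdeModel,
    point: ParameterPoint | Mapping[str, float],
    options: SolverOptions | None = None,
) -> list[SteadyState]:
    """Enumerate steady states of ``model`` at ``point``.

    Returns the deduplicated roots sorted by first state coordinate, each
    with Jacobian eigenvalues and a stability label. Raises
    :class:`RootFindingError` if no start converges — an undetermined
    outcome is flagged, never returned as an empty success.
    """
    opts = options or SolverOptions()
    params = model.params_with(as_mapping(point))
    upper = np.asarray(model.state_upper_bounds(params), dtype=float)
    if upper.shape != (model.n_states,) or np.any(upper <= 0) or not np.all(
        np.isfinite(upper)
    ):
        raise NumericsError(
            f"invalid state upper bounds for {model.name}: {upper}"
        )
    tol = opts.resolve_tol(upper)
    starts = _newton_starts(upper, opts.n_starts, opts.seed)
    roots = _damped_newton(model, params, starts, upper, tol, opts)
    if roots.shape[0] == 0:
        raise RootFindingError(
            f"no steady state converged for {model.name} at this point"
        )
    roots = _polish(model, params, roots, upper)
    res = np.max(np.abs(np.asarray(model.rhs(roots, params), dtype=float)), axis=-1)
    keep = res < tol
    roots, res = roots[keep], res[keep]
    if roots.shape[0] == 0:
        raise RootFindingError(
            f"no steady state met the residual tolerance for {model.name}"
        )
    tol_dist = opts.dedup_rtol * (1.0 + float(np.max(upper)))
    roots, res = _dedup(roots, res, tol_dist)

    out = []
    for x, r in zip(roots, res):
        eig = np.linalg.eigvals(eval_jacobian(model, x, params))
        eps = opts.eps_eig_rel * max(1.0, float(np.max(np.abs(eig))))
        mx = float(np.max(eig.real))
        stability = "stable" if mx < -eps else ("unstable" if mx > eps else "marginal")
        out.append(SteadyState(state=x, residual_norm=float(r),
                               eigenvalues=eig, stability=stability))
    out.sort(key=lambda s: s.state[0])
    return out


# ---------------------------------------------------------------------------
# Simulation-based attractor oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Attractor:
    """One attractor found by forward simulation.

    ``kind`` is 'fixed_point' or 'oscillation'. For fixed points ``state``
    is the cluster representative endpoint; for oscillations ``amplitude``
    holds the per-state peak-to-trough amplitude over the trailing window.
    """

    kind: str
    state: np.ndarray
    n_trajectories: int
    amplitude: np.ndarray | None = None


@dataclass(frozen=True)
class SimulationResult:
    attractors: list[Attractor]
    n_trajectories: int
    n_undetermined: int

    @property
    def fixed_points(self) -> list[Attractor]:
        return [a for a in self.attractors if a.kind == "fixed_point"]

    @property
    def oscillations(self) -> list[Attractor]:
        return [a for a in self.attractors if a.kind == "oscillation"]


def _default_t_end(states: Sequence[SteadyState] | None, cap: float) -> float:
    """Heuristic horizon from the local spectra: at least 20 times the
    slowest relaxation time and 10 times the slowest rotation period, so
    transients die out and each trailing window spans >= 1 full period."""
    if not states:
        return min(2e4, cap)
    rates = [
        abs(s.max_real_eig) for s in states if abs(s.max_real_eig) > 1e-12
    ]
    imags = [
        float(np.min(np.abs(s.eigenvalues.imag[s.eigenvalues.imag != 0])))
        for s in states
        if np.any(s.eigenvalues.imag != 0)
    ]
    t_relax = 20.0 / min(rates) if rates else 2e4
    t_rot = 10.0 * 2.0 * np.pi / min(imags) if imags else 0.0
    return float(min(max(t_relax, t_rot), cap))


def _turning_points(window: np.ndarray) -> np.ndarray:
    """Per state, the number of local extrema (derivative sign changes)
    along the sampled window (n_states, n_samples)."""
    d = np.diff(window, axis=1)
    sign = np.sign(d)
    # carry the previous sign across flat samples so plateaus don't count
    for j in range(1, sign.shape[1]):
        zero = sign[:, j] == 0
        sign[zero, j] = sign[zero, j - 1]
    return np.sum(sign[:, 1:] * sign[:, :-1] < 0, axis=1)


def attractors_by_simulation(
    model: OdeModel,
    point: ParameterPoint | Mapping[str, float],
    n_init: int = 20,
    t_end: float | None = None,
    seed: int = 0,
    options: SolverOptions | None = None,
    steady_states: Sequence[SteadyState] | None = None,
    t_cap: float = 1e5,
    fp_rtol: float = 1e-4,
    osc_rtol: float = 1e-2,
    traj_time_budget: float = 10.0,
) -> SimulationResult:
    """Integrate from randomised initial conditions and inventory the
    attractors the trajectories settle onto.

    Initial conditions are ``n_init`` uniform draws from the admissible
    box plus, when the steady states are known (passed in or found here),
    two perturbed starts around every unstable steady state — limit
    cycles born at a Hopf bifurcation can have a small basin relative to
    the box, and local perturbations are how they are reached reliably.

    The trailing 20% of each trajectory is split into two windows and the
    per-state peak-to-trough amplitude is compared with the trajectory's
    own magnitude (plus a small box-relative floor): a fixed point has
    every amplitude below ``fp_rtol`` of that scale in the final window;
    a sustained oscillation has some state's amplitude above ``osc_rtol``
    of its scale in both windows, non-decaying between them, and
    non-monotone (at least two turning points per window — a slow drift
    is not an oscillation). Anything in between (or an integrator
    failure) is counted undetermined and excluded. A trajectory whose
    integration exceeds ``traj_time_budget`` wall-clock seconds (extreme
    stiffness) is likewise abandoned as undetermined rather than stalling
    the scan.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    opts = options or SolverOptions()
    params = model.params_with(as_mapping(point))
    upper = np.asarray(model.state_upper_bounds(params), dtype=float)
    if steady_states is None:
        try:
            steady_states = find_steady_states(model, params, opts)
        except RootFindingError:
            steady_states = None
    if t_end is None:
        t_end = _default_t_end(steady_states, t_cap)
    rng = np.random.default_rng(seed)
    inits = rng.uniform(0.0, upper, size=(n_init, model.n_states))
    if steady_states:
        extra = []
        for s in steady_states:
            if s.stability != "unstable":
                continue
            delta = 0.3 * np.maximum(np.abs(s.state), 0.02 * upper)
            for _ in range(2):
                extra.append(
                    np.clip(s.state + rng.uniform(-1, 1, model.n_states) * delta,
                            0.0, upper)
                )
        if extra:
            inits = np.vstack([inits, extra])

    p = dict(params)

    class _OverBudget(Exception):
        pass

    deadline = [0.0]

    def f(t, y):
        if time.perf_counter() > deadline[0]:
            raise _OverBudget
        return np.asarray(model.rhs(y, p), dtype=float)

    def jac(t, y):
        return np.asarray(eval_jacobian(model, y, p))

    t_tail = np.linspace(0.8 * t_end, t_end, 241)
    fp_endpoints: list[np.ndarray] = []
    osc_records: list[tuple[np.ndarray, np.ndarray]] = []  # (mean state, amplitude)
    n_undet = 0
    for x0 in inits:
        deadline[0] = time.perf_counter() + traj_time_budget
        try:
            sol = solve_ivp(
                f, (0.0, t_end), x0, method="LSODA", jac=jac,
                t_eval=t_tail, rtol=1e-8, atol=1e-11 * np.maximum(1.0, upper),
            )
        except _OverBudget:
            n_undet += 1
            continue
        except Exception:  # integrator blow-up counts as undetermined
            n_undet += 1
            continue
        if not sol.success or sol.y.shape[1] < t_tail.size:
            n_undet += 1
            continue
        y = sol.y  # (n, m)
        half = y.shape[1] // 2
        w1, w2 = y[:, :half], y[:, half:]
        amp1 = w1.max(axis=1) - w1.min(axis=1)
        amp2 = w2.max(axis=1) - w2.min(axis=1)
        mean = np.abs(y.mean(axis=1))
        # scales follow the trajectory's own magnitude, not the box: the
        # heuristic upper bound can sit orders of magnitude above the
        # attractor, which would drown small genuine limit cycles
        fp_scale = mean + 1e-8 * upper
        osc_scale = mean + 1e-6 * upper
        turns1 = _turning_points(w1)
        turns2 = _turning_points(w2)
        osc_mask = (
            (amp1 >= osc_rtol * osc_scale) & (amp2 >= osc_rtol * osc_scale)
            & (amp2 >= 0.5 * amp1)          # sustained, not a decaying spiral
            & (turns1 >= 2) & (turns2 >= 2)
        )
        if np.all(amp2 < fp_rtol * fp_scale):
            fp_endpoints.append(y[:, -1])
        elif np.any(osc_mask):
            osc_records.append((y.mean(axis=1), amp2))
        else:
            n_undet += 1

    if n_undet:
        log.info(
            "%s: %d/%d trajectories undetermined in attractor scan",
            model.name, n_undet, len(inits),
        )

    attractors: list[Attractor] = []
    tol_dist = opts.dedup_rtol * (1.0 + float(np.max(upper)))
    if fp_endpoints:
        pts = np.array(fp_endpoints)
        reps: list[np.ndarray] = []
        counts: list[int] = []
        for xp in pts:
            for i, r in enumerate(reps):
                if np.max(np.abs(xp - r)) < tol_dist:
                    counts[i] += 1
                    break
            else:
                reps.append(xp)
                counts.append(1)
        for r, c in zip(reps, counts):
            attractors.append(Attractor("fixed_point", r, c))
    if osc_records:
        mean_state = np.mean([m for m, _ in osc_records], axis=0)
        amp = np.mean([a for _, a in osc_records], axis=0)
        attractors.append(
            Attractor("oscillation", mean_state, len(osc_records), amplitude=amp)
        )
    return SimulationResult(
        attractors=attractors, n_trajectories=len(inits), n_undetermined=n_undet
    )
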
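"""Dynamics classification from the stability pattern of the steady states.

The rule table is a pure function of the multiset of stability labels:

====================================  =====================
steady-state pattern                  dynamics class
====================================  =====================
1 state, stable                       monostable
1 state, unstable                     oscillatory
3 states, 2 stable + 1 unstable      bistable
3 states, 1 stable + 2 unstable      excitable_or_mixed
any marginal eigenvalue               undetermined
anything else                         other
====================================  =====================

A unique unstable steady state is read as likely sustained oscillation
without proving a limit cycle; the opt-in simulation pass cross-checks
oscillatory and excitable_or_mixed calls against the attractor oracle and,
for the latter, refines the label to excitable vs mixed fixed-point /
limit-cycle bistability. Points sitting on bifurcation boundaries (a
marginal eigenvalue) are never force-classified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import OdeModel, ParameterPoint
from .sampling import SampleEnsemble
from .steady import (
    RootFindingError,
    SolverOptions,
    SteadyState,
    attractors_by_simulation,
    find_steady_states,
)

__all__ = [
    "CLASSES",
    "Classification",
    "ClassifyOptions",
    "EnsembleClassification",
    "classify",
    "classify_ensemble",
]

CLASSES = (
    "monostable",
    "oscillatory",
    "bistable",
    "excitable_or_mixed",
    "other",
    "undetermined",
)


@dataclass(frozen=True)
class ClassifyOptions:
    solver: SolverOptions = field(default_factory=SolverOptions)
    confirm_oscillation: bool = False
    sim_n_init: int = 20
    sim_seed: int = 0
    sim_t_end: float | None = None


@dataclass(frozen=True)
class Classification:
    """Dynamics class of one parameter point, with its steady-state
    inventory; ``confirmed_by_simulation`` and ``refined_class`` are set
    only when the simulation pass runs."""

    point: ParameterPoint
    steady_states: list[SteadyState]
    dynamics_class: str
    confirmed_by_simulation: bool | None = None
    refined_class: str | None = None


def _class_from_pattern(states: Sequence[SteadyState]) -> str:
    labels = [s.stability for s in states]
    if "marginal" in labels:
        return "undetermined"
    n, n_stable = len(labels), labels.count("stable")
    if n == 1:
        return "monostable" if n_stable == 1 else "oscillatory"
    if n == 3 and n_stable == 2:
        return "bistable"
    if n == 3 and n_stable == 1:
        return "excitable_or_mixed"
    return "other"


def classify(
    model: OdeModel,
    point: ParameterPoint | Mapping[str, float],
    options: ClassifyOptions | None = None,
) -> Classification:
    """Classify the dynamics of ``model`` at ``point`` by the eigenvalue
    rule table; root-finder failure propagates as 'undetermined'."""
    opts = options or ClassifyOptions()
    pp = point if isinstance(point, ParameterPoint) else ParameterPoint(dict(point))
    try:
        states = find_steady_states(model, pp, opts.solver)
    except RootFindingError:
        return Classification(pp, [], "undetermined")
    cls = _class_from_pattern(states)

    confirmed = None
    refined = None
    if opts.confirm_oscillation and cls in ("oscillatory", "excitable_or_mixed"):
        sim = attractors_by_simulation(
            model, pp, n_init=opts.sim_n_init, t_end=opts.sim_t_end,
            seed=opts.sim_seed, options=opts.solver, steady_states=states,
        )
        has_osc = bool(sim.oscillations)
        n_fp = len(sim.fixed_points)
        if cls == "oscillatory":
            confirmed = has_osc
        else:
            confirmed = n_fp >= 1
            refined = "mixed_bistable" if has_osc else "excitable"
    return Classification(pp, states, cls,
                          confirmed_by_simulation=confirmed, refined_class=refined)


@dataclass(frozen=True)
class EnsembleClassification:
    """Per-point classifications in ensemble order, with class counts."""

    classifications: list[Classification]
    counts: dict[str, int]

    @property
    def classes(self) -> list[str]:
        return [c.dynamics_class for c in self.classifications]

    def __len__(self) -> int:
        return len(self.classifications)


def _tally(classifications: Sequence[Classification]) -> dict[str, int]:
    counts = {c: 0 for c in CLASSES}
    for c in classifications:
        counts[c.dynamics_class] += 1
    return counts


def classify_ensemble(
    model: OdeModel,
    ensemble: SampleEnsemble,
    options: ClassifyOptions | None = None,
    chunk_size: int | None = None,
    n_jobs: int = 1,
) -> EnsembleClassification:
    """Classify every point of a sampled ensemble.

    Varied parameters come from the ensemble; non-varied ones from the
    model defaults. Work may be chunked (and the chunks processed in
    parallel with ``n_jobs`` joblib worker threads when requested);
    result order is that of the ensemble and is independent of chunking,
    so a given (model, ensemble, options) always yields identical output.
    """
    opts = options or ClassifyOptions()
    unknown = {s.name for s in ensemble.specs} - set(model.param_names)
    if unknown:
        raise ValueError(f"ensemble specs not in model parameters: {sorted(unknown)}")
    points = ensemble.points
    if chunk_size is None or chunk_size <= 0:
        chunk_size = len(points) or 1
    chunks = [points[i : i + chunk_size] for i in range(0, len(points), chunk_size)]

    def run_chunk(chunk: list[ParameterPoint]) -> list[Classification]:
        return [classify(model, p, opts) for p in chunk]

    if n_jobs != 1 and len(chunks) > 1:
        from joblib import Parallel, delayed

        # threads, not processes: model rhs/jacobian are closures, and the
        # heavy work is inside numpy/LAPACK which releases the GIL
        results = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(run_chunk)(c) for c in chunks
        )
    else:
        results = [run_chunk(c) for c in chunks]
    flat = [c for chunk in results for c in chunk]
    return EnsembleClassification(flat, _tally(flat))
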
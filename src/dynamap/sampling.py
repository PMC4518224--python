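"""Parameter-space sampling: Monte-Carlo and Latin-hypercube ensembles,
and the unit-interval normalisation used by the parallel-coordinates plots.

Linear-scale parameters are sampled uniformly on [low, high]; log-scale
parameters uniformly in log10 space; integer-flagged parameters uniformly
on the integer grid {low, ..., high}. All randomness flows through a
seeded :class:`numpy.random.Generator`, so a given seed reproduces an
ensemble bit-identically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import ParameterPoint, ParameterSpec

__all__ = [
    "SampleEnsemble",
    "denormalize",
    "denormalize_matrix",
    "latin_hypercube",
    "monte_carlo",
    "normalize",
    "normalize_matrix",
]

#: Full-factorial stratified designs above this size are refused.
LHS_HARD_CAP = 10**6


@dataclass(frozen=True)
class SampleEnsemble:
    """An ordered collection of sampled parameter points.

    ``matrix`` holds the raw values, one row per point, columns in spec
    order; ``points`` views the same data as :class:`ParameterPoint`.
    """

    specs: tuple[ParameterSpec, ...]
    matrix: np.ndarray  # (n_points, n_specs), raw model units
    seed: int
    method: str
    segments: int | None = None

    @property
    def n_points(self) -> int:
        return self.matrix.shape[0]

    @property
    def points(self) -> list[ParameterPoint]:
        names = [s.name for s in self.specs]
        return [
            ParameterPoint(dict(zip(names, row))) for row in self.matrix.tolist()
        ]

    def __len__(self) -> int:
        return self.n_points

    def to_csv(self, path) -> None:
        """Write one row per point (full precision), parameter names as the
        header, and seed/method/specs as leading comment lines."""
        import json

        meta = {
            "seed": self.seed,
            "method": self.method,
            "segments": self.segments,
            "specs": [
                {"name": s.name, "low": s.low, "high": s.high,
                 "scale": s.scale, "integer": s.integer}
                for s in self.specs
            ],
        }
        with open(path, "w") as fh:
            fh.write("# dynamap-samples " + json.dumps(meta) + "\n")
            fh.write(",".join(s.name for s in self.specs) + "\n")
            for row in self.matrix:
                fh.write(",".join(repr(float(v)) for v in row) + "\n")


def _validate_specs(specs) -> tuple[ParameterSpec, ...]:
    specs = tuple(specs)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate parameter names in specs: {names}")
    return specs


def _draw_uniform(spec: ParameterSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    if spec.integer:
        return rng.integers(int(spec.low), int(spec.high) + 1, size=size).astype(float)
    if spec.scale == "log":
        return 10.0 ** rng.uniform(np.log10(spec.low), np.log10(spec.high), size=size)
    return rng.uniform(spec.low, spec.high, size=size)


def monte_carlo(specs, n: int, seed: int = 0) -> SampleEnsemble:
    """Draw ``n`` independent points, one column of draws per parameter."""
    specs = _validate_specs(specs)
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    cols = [_draw_uniform(s, rng, n) for s in specs]
    matrix = (
        np.column_stack(cols) if specs else np.empty((n, 0))
    )
    return SampleEnsemble(specs, matrix, seed=seed, method="monte_carlo")


def _stratum_edges(spec: ParameterSpec, segments: int) -> np.ndarray:
    """Stratum boundaries in the parameter's sampling scale."""
    if spec.scale == "log":
        return np.logspace(np.log10(spec.low), np.log10(spec.high), segments + 1)
    return np.linspace(spec.low, spec.high, segments + 1)


def _stratified_draws(
    spec: ParameterSpec, segments: int, rng: np.random.Generator
) -> np.ndarray:
    """One draw inside each of ``segments`` strata, in stratum order."""
    if spec.integer:
        # Integer strata are consecutive sub-ranges of the integer grid; a
        # stratum narrower than one integer collapses to its nearest integer.
        edges = np.linspace(spec.low, spec.high, segments + 1)
        vals = np.empty(segments)
        for i in range(segments):
            lo = int(np.ceil(edges[i])) if i == 0 else int(np.floor(edges[i])) + 1
            hi = int(np.floor(edges[i + 1]))
            if lo > hi:
                vals[i] = float(np.clip(round((edges[i] + edges[i + 1]) / 2),
                                        spec.low, spec.high))
            else:
                vals[i] = float(rng.integers(lo, hi + 1))
        return vals
    edges = _stratum_edges(spec, segments)
    u = rng.uniform(edges[:-1], edges[1:])
    return u


def latin_hypercube(
    specs,
    segments: int,
    seed: int = 0,
    max_sets: int | None = None,
    permute: bool = True,
    hard_cap: int = LHS_HARD_CAP,
) -> SampleEnsemble:
    """Full-factorial stratified design: each parameter range is divided
    into ``segments`` strata with one uniform draw per stratum, and the
    per-parameter values are combined factorially into ``segments**d``
    sets (d parameters). ``permute`` shuffles each parameter's stratum
    assignment independently; ``max_sets`` truncates the design by seeded
    random subsampling.
    """
    specs = _validate_specs(specs)
    if segments < 1:
        raise ValueError("segments must be >= 1")
    d = len(specs)
    total = segments**d
    if total > hard_cap:
        raise ValueError(
            f"{segments}^{d} = {total} sets exceeds the cap of {hard_cap}; "
            "reduce segments, use max_sets with classic_lhs, or raise hard_cap"
        )
    rng = np.random.default_rng(seed)
    values = []
    for s in specs:
        v = _stratified_draws(s, segments, rng)
        if permute:
            v = v[rng.permutation(segments)]
        values.append(v)
    idx = np.array(list(itertools.product(range(segments), repeat=d)), dtype=int)
    if d == 0:
        matrix = np.empty((1, 0))
    else:
        matrix = np.column_stack([values[j][idx[:, j]] for j in range(d)])
    if max_sets is not None and max_sets < matrix.shape[0]:
        keep = rng.choice(matrix.shape[0], size=max_sets, replace=False)
        matrix = matrix[np.sort(keep)]
    return SampleEnsemble(
        specs, matrix, seed=seed, method="latin_hypercube", segments=segments
    )


def classic_lhs(specs, n: int, seed: int = 0) -> SampleEnsemble:
    """Standard n-point Latin hypercube: n strata per parameter, one point
    per stratum, independent per-parameter permutations. Suited to high
    dimension where the factorial design explodes."""
    specs = _validate_specs(specs)
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    cols = []
    for s in specs:
        u = (rng.permutation(n) + rng.uniform(size=n)) / max(n, 1)
        cols.append(_unit_to_value(u, s))
    matrix = np.column_stack(cols) if specs else np.empty((n, 0))
    return SampleEnsemble(specs, matrix, seed=seed, method="classic_lhs")


# ---------------------------------------------------------------------------
# Unit-interval normalisation (the PC-plot coordinate system)
# ---------------------------------------------------------------------------

def _value_to_unit(v: np.ndarray, spec: ParameterSpec) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v < spec.low) or np.any(v > spec.high):
        bad = v[(v < spec.low) | (v > spec.high)][0]
        raise ValueError(f"{spec.name}: value {bad} outside [{spec.low}, {spec.high}]")
    if spec.low == spec.high:
        return np.full_like(v, 0.5)
    if spec.scale == "log":
        return (np.log10(v) - np.log10(spec.low)) / (
            np.log10(spec.high) - np.log10(spec.low)
        )
    return (v - spec.low) / (spec.high - spec.low)


def _unit_to_value(u: np.ndarray, spec: ParameterSpec) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        bad = u[(u < 0) | (u > 1)][0]
        raise ValueError(f"{spec.name}: unit coordinate {bad} outside [0, 1]")
    if spec.low == spec.high:
        v = np.full_like(u, spec.low)
    elif spec.scale == "log":
        v = 10.0 ** (np.log10(spec.low) + u * (np.log10(spec.high) - np.log10(spec.low)))
    else:
        v = spec.low + u * (spec.high - spec.low)
    if spec.integer:
        # round half up, clipped into the integer range
        v = np.clip(np.floor(v + 0.5), spec.low, spec.high)
    return v


def normalize(point: ParameterPoint | dict, specs) -> np.ndarray:
    """Map a point's values to [0, 1] per spec (log-linear for log scale).
    Values outside the spec range raise; they are never clipped."""
    vals = point.values if isinstance(point, ParameterPoint) else point
    return np.array([_value_to_unit(np.float64(vals[s.name]), s) for s in specs])


def denormalize(unit: np.ndarray, specs) -> ParameterPoint:
    """Inverse of :func:`normalize`; integer specs round half-up to the
    nearest in-range integer."""
    specs = tuple(specs)
    unit = np.asarray(unit, dtype=float)
    if unit.shape != (len(specs),):
        raise ValueError(f"expected {len(specs)} coordinates, got {unit.shape}")
    return ParameterPoint(
        {s.name: float(_unit_to_value(np.float64(u), s)) for u, s in zip(unit, specs)}
    )


def normalize_matrix(matrix: np.ndarray, specs) -> np.ndarray:
    """Column-wise :func:`normalize` for an (n_points, n_specs) matrix."""
    specs = tuple(specs)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] != len(specs):
        raise ValueError("matrix column count does not match specs")
    return np.column_stack(
        [_value_to_unit(matrix[:, j], s) for j, s in enumerate(specs)]
    ) if specs else matrix.copy()


def denormalize_matrix(unit: np.ndarray, specs) -> np.ndarray:
    specs = tuple(specs)
    unit = np.asarray(unit, dtype=float)
    return np.column_stack(
        [_unit_to_value(unit[:, j], s) for j, s in enumerate(specs)]
    ) if specs else unit.copy()
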
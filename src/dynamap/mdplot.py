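"""Multi-parameter dynamics (MD) plot data: classified ensembles on
parallel coordinates, brushing, axis reordering, folded 3-D layouts,
scatter projections, and CSV/JSON round-trip export.

The substrate is a :class:`ClassifiedEnsemble`: the sampled parameter
matrix in raw model units alongside its unit-interval normalisation (one
column per parameter, via :mod:`dynamap.sampling`), a dynamics class per
row, and run metadata. All transformations return new ensembles; raw data
is never mutated, and plotting always operates on the unit-normalised
copy. Colour conventions follow the usual MD-plot reading (oscillatory
red, bistable green, monostable grey) and are configurable everywhere.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import CLASSES, Classification, EnsembleClassification
from .core import ParameterSpec
from .sampling import normalize_matrix

__all__ = [
    "Brush",
    "ClassifiedEnsemble",
    "DEFAULT_CLASS_COLORS",
    "FoldedLayout",
    "PolylineSet",
    "ScatterProjection",
    "brush",
    "build_ensemble",
    "export",
    "filter_by_class",
    "folded_layout",
    "invert_axis",
    "pc_segments",
    "plot_folded",
    "plot_pc",
    "plot_scatter",
    "read_ensemble",
    "reorder_axes",
    "scatter_projection",
]

log = logging.getLogger(__name__)

DEFAULT_CLASS_COLORS: dict[str, str] = {
    "monostable": "#9e9e9e",
    "oscillatory": "#d62728",
    "bistable": "#2ca02c",
    "excitable_or_mixed": "#ff7f0e",
    "other": "#8c564b",
    "undetermined": "#c7c7c7",
}

_HIGHLIGHT_COLOR = "#1f77b4"


@dataclass(frozen=True)
class ClassifiedEnsemble:
    """Sampled parameter sets with their dynamics classes.

    ``raw`` is (n_points, n_params) in model units, ``unit`` its
    column-wise [0, 1] normalisation (always re-derivable exactly from
    ``raw`` and ``specs``). ``keep`` and ``highlight`` are row flags set
    by brushing; ``metadata`` records model name, seed, sampling method,
    per-class counts and any inverted axes.
    """

    specs: tuple[ParameterSpec, ...]
    raw: np.ndarray
    unit: np.ndarray
    classes: tuple[str, ...]
    metadata: dict
    keep: np.ndarray | None = None
    highlight: np.ndarray | None = None

    @property
    def n_points(self) -> int:
        return self.raw.shape[0]

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def keep_mask(self) -> np.ndarray:
        if self.keep is None:
            return np.ones(self.n_points, dtype=bool)
        return self.keep

    def highlight_mask(self) -> np.ndarray:
        if self.highlight is None:
            return np.zeros(self.n_points, dtype=bool)
        return self.highlight

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for c in self.classes:
            out[c] = out.get(c, 0) + 1
        return out

    def __len__(self) -> int:
        return self.n_points


def _tally_metadata(metadata: Mapping | None, classes: Sequence[str]) -> dict:
    md = dict(metadata or {})
    counts = {c: 0 for c in CLASSES}
    for c in classes:
        counts[c] = counts.get(c, 0) + 1
    md["counts"] = counts
    md.setdefault("inverted_axes", [])
    return md


def build_ensemble(
    classified: EnsembleClassification | Sequence[Classification],
    specs: Iterable[ParameterSpec],
    metadata: Mapping | None = None,
) -> ClassifiedEnsemble:
    """Assemble the MD-plot substrate from per-point classifications."""
    if isinstance(classified, EnsembleClassification):
        items = classified.classifications
    else:
        items = list(classified)
    specs = tuple(specs)
    names = [s.name for s in specs]
    rows = []
    for c in items:
        missing = [n for n in names if n not in c.point]
        if missing:
            raise ValueError(f"classification point missing parameters {missing}")
        rows.append([c.point[n] for n in names])
    raw = np.array(rows, dtype=float) if rows else np.empty((0, len(specs)))
    unit = normalize_matrix(raw, specs)
    classes = tuple(c.dynamics_class for c in items)
    return ClassifiedEnsemble(
        specs=specs, raw=raw, unit=unit, classes=classes,
        metadata=_tally_metadata(metadata, classes),
    )


def _subset(ens: ClassifiedEnsemble, mask: np.ndarray) -> ClassifiedEnsemble:
    classes = tuple(np.array(ens.classes, dtype=object)[mask])
    return ClassifiedEnsemble(
        specs=ens.specs,
        raw=ens.raw[mask],
        unit=ens.unit[mask],
        classes=classes,
        metadata=_tally_metadata(
            {k: v for k, v in ens.metadata.items() if k != "counts"}, classes
        ),
        keep=None if ens.keep is None else ens.keep[mask],
        highlight=None if ens.highlight is None else ens.highlight[mask],
    )


def filter_by_class(
    ens: ClassifiedEnsemble, keep_classes: Iterable[str]
) -> ClassifiedEnsemble:
    """Row subset containing only the requested dynamics classes."""
    keep_classes = set(keep_classes)
    unknown = keep_classes - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown dynamics classes: {sorted(unknown)}")
    mask = np.array([c in keep_classes for c in ens.classes], dtype=bool)
    return _subset(ens, mask)


@dataclass(frozen=True)
class Brush:
    """An interval selection on one axis, in raw model units.

    ``mode='keep'`` restricts the visible rows (conjunctively across
    brushes); ``mode='highlight'`` flags matching rows for colouring.
    Boundaries are inclusive.
    """

    axis: str
    interval: tuple[float, float]
    mode: str = "highlight"

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if lo > hi:
            raise ValueError(f"brush interval [{lo}, {hi}] has lo > hi")
        if self.mode not in ("keep", "highlight"):
            raise ValueError(f"brush mode must be 'keep' or 'highlight', got {self.mode!r}")


def brush(ens: ClassifiedEnsemble, brushes: Sequence[Brush]) -> ClassifiedEnsemble:
    """Apply brushes: keep-brushes AND together into the ``keep`` flag,
    highlight-brushes AND together into the ``highlight`` flag."""
    names = ens.axis_names
    for b in brushes:
        if b.axis not in names:
            raise ValueError(f"brush axis {b.axis!r} not among {names}")
    keep = np.ones(ens.n_points, dtype=bool)
    highlights = [b for b in brushes if b.mode == "highlight"]
    hl = np.full(ens.n_points, bool(highlights), dtype=bool)
    for b in brushes:
        col = ens.raw[:, names.index(b.axis)]
        inside = (col >= b.interval[0]) & (col <= b.interval[1])
        if b.mode == "keep":
            keep &= inside
        else:
            hl &= inside
    return replace(ens, keep=keep, highlight=hl)


def reorder_axes(
    ens: ClassifiedEnsemble, order: Sequence[str]
) -> ClassifiedEnsemble:
    """Permute the axis columns everywhere consistently; rows unchanged."""
    names = ens.axis_names
    if sorted(order) != sorted(names):
        raise ValueError(f"{list(order)} is not a permutation of {list(names)}")
    idx = [names.index(n) for n in order]
    return replace(
        ens,
        specs=tuple(ens.specs[i] for i in idx),
        raw=ens.raw[:, idx],
        unit=ens.unit[:, idx],
    )


def invert_axis(ens: ClassifiedEnsemble, axis: str) -> ClassifiedEnsemble:
    """Toggle unit-value reflection (u -> 1-u) for one axis at render time;
    raw data and the unit matrix stay untouched, the flag lives in
    metadata."""
    if axis not in ens.axis_names:
        raise ValueError(f"unknown axis {axis!r}")
    md = dict(ens.metadata)
    inv = list(md.get("inverted_axes", []))
    if axis in inv:
        inv.remove(axis)
    else:
        inv.append(axis)
    md["inverted_axes"] = inv
    return replace(ens, metadata=md)


@dataclass(frozen=True)
class PolylineSet:
    """Render-ready polylines: one per kept row, vertices at equally
    spaced vertical axes in unit coordinates."""

    axis_names: tuple[str, ...]
    x_positions: np.ndarray      # (k,) in [0, 1]
    vertices: np.ndarray         # (n_rows, k) unit values (inversions applied)
    colors: tuple[str, ...]      # one per row
    classes: tuple[str, ...]

    @property
    def n_polylines(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_segments(self) -> int:
        return self.n_polylines * max(self.vertices.shape[1] - 1, 0)


def pc_segments(
    ens: ClassifiedEnsemble,
    class_colors: Mapping[str, str] | None = None,
    highlight_color: str = _HIGHLIGHT_COLOR,
) -> PolylineSet:
    """Build the standard parallel-coordinates polylines for the kept rows."""
    if len(ens.specs) < 2:
        raise ValueError("parallel coordinates need at least 2 axes")
    cmap = dict(DEFAULT_CLASS_COLORS)
    if class_colors:
        cmap.update(class_colors)
    mask = ens.keep_mask()
    unit = ens.unit[mask].copy()
    inverted = set(ens.metadata.get("inverted_axes", []))
    for j, name in enumerate(ens.axis_names):
        if name in inverted:
            unit[:, j] = 1.0 - unit[:, j]
    classes = tuple(np.array(ens.classes, dtype=object)[mask])
    hl = ens.highlight_mask()[mask]
    colors = tuple(
        highlight_color if h else cmap.get(c, "#000000")
        for c, h in zip(classes, hl)
    )
    k = len(ens.specs)
    x = np.linspace(0.0, 1.0, k)
    return PolylineSet(ens.axis_names, x, unit, colors, classes)


@dataclass(frozen=True)
class FoldedLayout:
    """3-D folded parallel-coordinates geometry: each axis is a vertical
    unit segment standing at a base position in the horizontal plane, and
    any requested (unordered) axis pair carries a connecting panel."""

    axis_names: tuple[str, ...]
    axis_positions: np.ndarray           # (n, 3) base point of each axis
    panels: tuple[tuple[str, str], ...]  # unordered pairs, stored sorted

    @property
    def max_panels(self) -> int:
        n = len(self.axis_names)
        return n * (n - 1) // 2


def folded_layout(
    axis_names: Sequence[str],
    panels: Iterable[tuple[str, str]] | None = None,
    arrangement: str = "polygon",
) -> FoldedLayout:
    """Place n axes as vertical unit segments in 3-D.

    ``arrangement='polygon'`` puts the axis bases at the vertices of a
    regular n-gon in the z=0 plane (any pair can carry a direct panel);
    ``'zigzag'`` folds them along an accordion path like a fold-screen.
    ``panels`` defaults to the adjacent pairs in the given order — the
    standard PC plot's path graph; with two axes the layout degenerates
    to the standard PC plot.
    """
    names = tuple(axis_names)
    if len(names) < 2:
        raise ValueError("folded layout needs at least 2 axes")
    if len(set(names)) != len(names):
        raise ValueError("axis names must be unique")
    n = len(names)
    if arrangement == "polygon":
        theta = 2.0 * np.pi * np.arange(n) / n
        base = np.column_stack([np.cos(theta), np.sin(theta), np.zeros(n)])
    elif arrangement == "zigzag":
        base = np.column_stack(
            [np.arange(n, dtype=float), 0.5 * (np.arange(n) % 2), np.zeros(n)]
        )
    else:
        raise ValueError("arrangement must be 'polygon' or 'zigzag'")
    if panels is None:
        pairs = [(names[i], names[i + 1]) for i in range(n - 1)]
    else:
        pairs = list(panels)
    seen: set[tuple[str, str]] = set()
    norm_pairs: list[tuple[str, str]] = []
    for a, b in pairs:
        if a not in names or b not in names:
            raise ValueError(f"panel ({a!r}, {b!r}) references an unknown axis")
        if a == b:
            raise ValueError(f"panel pairs a distinct axis with itself: {a!r}")
        key = (a, b) if a <= b else (b, a)
        if key not in seen:
            seen.add(key)
            norm_pairs.append(key)
    return FoldedLayout(names, base, tuple(norm_pairs))


@dataclass(frozen=True)
class ScatterProjection:
    """2-D projection of the raw ensemble through arithmetic expressions."""

    x: np.ndarray
    y: np.ndarray
    classes: tuple[str, ...]
    x_expr: str
    y_expr: str
    n_dropped: int


def scatter_projection(
    ens: ClassifiedEnsemble,
    x_expr: str,
    y_expr: str,
    classes: Iterable[str] | None = None,
) -> ScatterProjection:
    """Evaluate two arithmetic expressions over the raw axis values
    (ratios and products of parameter names) for the selected classes.
    Rows where an expression is non-finite (e.g. division by zero) are
    dropped with a logged count."""
    mask = ens.keep_mask().copy()
    if classes is not None:
        wanted = set(classes)
        unknown = wanted - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown dynamics classes: {sorted(unknown)}")
        mask &= np.array([c in wanted for c in ens.classes], dtype=bool)
    df = pd.DataFrame(ens.raw[mask], columns=list(ens.axis_names))
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.asarray(df.eval(x_expr), dtype=float)
        y = np.asarray(df.eval(y_expr), dtype=float)
    finite = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~finite).sum())
    if n_dropped:
        log.info("scatter projection dropped %d non-finite points", n_dropped)
    cls = tuple(np.array(ens.classes, dtype=object)[mask][finite])
    return ScatterProjection(x[finite], y[finite], cls, x_expr, y_expr, n_dropped)


# ---------------------------------------------------------------------------
# Export / import (bit-exact round trip)
# ---------------------------------------------------------------------------

def _spec_dict(s: ParameterSpec) -> dict:
    return {
        "name": s.name, "low": s.low, "high": s.high,
        "scale": s.scale, "integer": s.integer,
    }


def export(ens: ClassifiedEnsemble, path: str | Path, format: str | None = None) -> Path:
    """Write the ensemble as CSV or JSON (format inferred from the suffix
    when not given). Floats are serialised with ``repr``, which Python
    round-trips exactly, so export -> import reproduces the ensemble
    bit-identically."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        header_meta = {
            "specs": [_spec_dict(s) for s in ens.specs],
            "metadata": ens.metadata,
        }
        with open(path, "w", newline="") as fh:
            fh.write("# dynamap-ensemble " + json.dumps(header_meta) + "\n")
            writer = csv.writer(fh)
            writer.writerow(list(ens.axis_names) + ["class", "highlight"])
            hl = ens.highlight_mask()
            for i in range(ens.n_points):
                writer.writerow(
                    [repr(float(v)) for v in ens.raw[i]]
                    + [ens.classes[i], int(hl[i])]
                )
    elif fmt == "json":
        hl = ens.highlight_mask()
        doc = {
            "specs": [_spec_dict(s) for s in ens.specs],
            "rows": [
                {
                    "raw": [float(v) for v in ens.raw[i]],
                    "unit": [float(v) for v in ens.unit[i]],
                    "class": ens.classes[i],
                    "highlight": bool(hl[i]),
                }
                for i in range(ens.n_points)
            ],
            "metadata": ens.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise ValueError(f"unsupported export format {fmt!r} (csv or json)")
    return path


def read_ensemble(path: str | Path) -> ClassifiedEnsemble:
    """Inverse of :func:`export` for both formats."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        with open(path, newline="") as fh:
            first = fh.readline()
            if not first.startswith("# dynamap-ensemble "):
                raise ValueError(f"{path} is not a dynamap ensemble CSV")
            meta = json.loads(first[len("# dynamap-ensemble "):])
            reader = csv.reader(fh)
            header = next(reader)
            names = header[:-2]
            rows, classes, hl = [], [], []
            for rec in reader:
                rows.append([float(v) for v in rec[: len(names)]])
                classes.append(rec[-2])
                hl.append(bool(int(rec[-1])))
        specs = tuple(ParameterSpec(**d) for d in meta["specs"])
        if names != [s.name for s in specs]:
            raise ValueError("CSV header does not match spec metadata")
        raw = np.array(rows, dtype=float) if rows else np.empty((0, len(specs)))
        return ClassifiedEnsemble(
            specs=specs, raw=raw, unit=normalize_matrix(raw, specs),
            classes=tuple(classes), metadata=meta["metadata"],
            highlight=np.array(hl, dtype=bool) if hl else None,
        )
    if fmt == "json":
        with open(path) as fh:
            doc = json.load(fh)
        specs = tuple(ParameterSpec(**d) for d in doc["specs"])
        rows = doc["rows"]
        raw = (
            np.array([r["raw"] for r in rows], dtype=float)
            if rows else np.empty((0, len(specs)))
        )
        unit = (
            np.array([r["unit"] for r in rows], dtype=float)
            if rows else np.empty((0, len(specs)))
        )
        hl = np.array([r["highlight"] for r in rows], dtype=bool)
        return ClassifiedEnsemble(
            specs=specs, raw=raw, unit=unit,
            classes=tuple(r["class"] for r in rows),
            metadata=doc["metadata"],
            highlight=hl if rows else None,
        )
    raise ValueError(f"unsupported ensemble format {fmt!r}")


# ---------------------------------------------------------------------------
# Static rendering (vector output; geometry computed above)
# ---------------------------------------------------------------------------

def plot_pc(
    ens: ClassifiedEnsemble,
    path: str | Path | None = None,
    class_colors: Mapping[str, str] | None = None,
    ax=None,
    linewidth: float = 0.6,
    alpha: float = 0.5,
):
    """Draw the standard MD plot (unit-normalised parallel coordinates)."""
    import matplotlib.pyplot as plt

    lines = pc_segments(ens, class_colors=class_colors)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.6 * len(lines.axis_names), 4.0))
    for row, color in zip(lines.vertices, lines.colors):
        ax.plot(lines.x_positions, row, color=color, lw=linewidth, alpha=alpha)
    for xp in lines.x_positions:
        ax.axvline(xp, color="k", lw=0.8)
    ax.set_xticks(lines.x_positions)
    ax.set_xticklabels(lines.axis_names)
    ax.set_ylim(-0.02, 1.02)
    ax.set_ylabel("normalised parameter value")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_folded(
    ens: ClassifiedEnsemble,
    layout: FoldedLayout | None = None,
    path: str | Path | None = None,
    class_colors: Mapping[str, str] | None = None,
    ax=None,
    linewidth: float = 0.5,
    alpha: float = 0.4,
):
    """Render the folded PC plot: vertical axes in 3-D with the selected
    panels carrying the pairwise connecting segments."""
    import matplotlib.pyplot as plt

    if layout is None:
        layout = folded_layout(ens.axis_names)
    cmap = dict(DEFAULT_CLASS_COLORS)
    if class_colors:
        cmap.update(class_colors)
    if ax is None:
        fig = plt.figure(figsize=(7, 6))
        ax = fig.add_subplot(projection="3d")
    pos = {n: layout.axis_positions[i] for i, n in enumerate(layout.axis_names)}
    names = ens.axis_names
    mask = ens.keep_mask()
    unit = ens.unit[mask]
    classes = np.array(ens.classes, dtype=object)[mask]
    for n, b in pos.items():
        ax.plot([b[0]] * 2, [b[1]] * 2, [0.0, 1.0], color="k", lw=1.2)
        ax.text(b[0], b[1], 1.05, n)
    for a, b in layout.panels:
        ia, ib = names.index(a), names.index(b)
        pa, pb = pos[a], pos[b]
        for row, cls in zip(unit, classes):
            ax.plot(
                [pa[0], pb[0]], [pa[1], pb[1]], [row[ia], row[ib]],
                color=cmap.get(cls, "#000000"), lw=linewidth, alpha=alpha,
            )
    ax.set_zlim(0, 1.1)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_scatter(
    proj: ScatterProjection,
    path: str | Path | None = None,
    class_colors: Mapping[str, str] | None = None,
    ax=None,
    logx: bool = False,
    logy: bool = False,
):
    """Scatter a 2-D projection, coloured by dynamics class."""
    import matplotlib.pyplot as plt

    cmap = dict(DEFAULT_CLASS_COLORS)
    if class_colors:
        cmap.update(class_colors)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cls_arr = np.array(proj.classes, dtype=object)
    for cls in sorted(set(proj.classes)):
        sel = cls_arr == cls
        ax.scatter(proj.x[sel], proj.y[sel], s=8, label=cls,
                   color=cmap.get(cls, "#000000"), alpha=0.7)
    if logx:
        ax.set_xscale("log")
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel(proj.x_expr)
    ax.set_ylabel(proj.y_expr)
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
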
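"""Minimal SBML import: build an :class:`~dynamap.core.OdeModel` from the
ODE-compatible subset of SBML (levels 2 and 3).

Supported constructs: compartments (sizes as constants), species
(concentrations; ``constant``/``boundaryCondition`` species become
parameters), global parameters, reactions with MathML kinetic laws and
local parameters (inlined as numbers), function definitions (inlined),
assignment rules (substituted into all expressions) and rate rules on
species. Events, algebraic rules, delays and explicit time dependence are
rejected with an error naming the construct. Kinetic laws are converted
to sympy expressions, differentiated symbolically for the Jacobian, and
lambdified to vectorised numpy callables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import sympy as sp
from lxml import etree

from .core import OdeModel

__all__ = ["SbmlImportError", "UnsupportedSbmlError", "import_sbml"]


class SbmlImportError(ValueError):
    """The file is not usable SBML."""


class UnsupportedSbmlError(SbmlImportError):
    """The file uses an SBML construct outside the ODE-compatible subset."""

    def __init__(self, construct: str):
        super().__init__(
            f"unsupported SBML construct: {construct}; only plain ODE models "
            "(species, reactions, parameters, assignment/rate rules) are supported"
        )
        self.construct = construct


def _local(el) -> str:
    tag = el.tag
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _children(el, name: str):
    return [c for c in el if _local(c) == name]


def _first(el, name: str):
    found = _children(el, name)
    return found[0] if found else None


def _find_all(root, name: str):
    return [e for e in root.iter() if _local(e) == name]


# ---------------------------------------------------------------------------
# MathML -> sympy
# ---------------------------------------------------------------------------

_RELATIONS = {
    "lt": sp.Lt, "leq": sp.Le, "gt": sp.Gt, "geq": sp.Ge,
    "eq": sp.Eq, "neq": sp.Ne,
}


def _parse_cn(el) -> sp.Expr:
    ctype = el.get("type", "real")
    parts = [el.text or ""]
    for child in el:
        if _local(child) == "sep":
            parts.append(child.tail or "")
    parts = [p.strip() for p in parts]
    if ctype == "e-notation":
        return sp.Float(float(parts[0]) * 10.0 ** float(parts[1]))
    if ctype == "rational":
        return sp.Rational(int(parts[0]), int(parts[1]))
    if ctype == "integer":
        return sp.Integer(int(parts[0]))
    return sp.Float(float(parts[0]))


def _parse_math(el, functions: dict[str, tuple[list[sp.Symbol], sp.Expr]]) -> sp.Expr:
    """Recursive MathML content-markup parser (the subset used by kinetic
    laws: arithmetic, powers, exp/ln/log, piecewise, relations, bools)."""
    name = _local(el)
    if name == "math":
        kids = [c for c in el if isinstance(c.tag, str)]
        if len(kids) != 1:
            raise SbmlImportError("math element must contain exactly one expression")
        return _parse_math(kids[0], functions)
    if name == "ci":
        return sp.Symbol((el.text or "").strip())
    if name == "cn":
        return _parse_cn(el)
    if name == "csymbol":
        url = el.get("definitionURL", "")
        if url.endswith("/delay"):
            raise UnsupportedSbmlError("delay")
        if url.endswith("/time"):
            raise UnsupportedSbmlError("time (non-autonomous model)")
        if url.endswith("/avogadro"):
            return sp.Float(6.02214076e23)
        raise UnsupportedSbmlError(f"csymbol {url}")
    if name == "true":
        return sp.true
    if name == "false":
        return sp.false
    if name == "pi":
        return sp.pi
    if name == "exponentiale":
        return sp.E
    if name == "notanumber":
        return sp.nan
    if name == "infinity":
        return sp.oo
    if name == "piecewise":
        pieces = []
        otherwise: sp.Expr | None = None
        for child in el:
            cname = _local(child)
            kids = [c for c in child if isinstance(c.tag, str)]
            if cname == "piece":
                val, cond = (_parse_math(k, functions) for k in kids)
                pieces.append((val, cond))
            elif cname == "otherwise":
                otherwise = _parse_math(kids[0], functions)
        if otherwise is not None:
            pieces.append((otherwise, sp.true))
        return sp.Piecewise(*pieces)
    if name == "lambda":
        bvars = [
            sp.Symbol((_first(b, "ci").text or "").strip())
            for b in _children(el, "bvar")
        ]
        body = [c for c in el if isinstance(c.tag, str) and _local(c) != "bvar"]
        return (bvars, _parse_math(body[-1], functions))  # type: ignore[return-value]
    if name != "apply":
        raise SbmlImportError(f"unhandled MathML element <{name}>")

    kids = [c for c in el if isinstance(c.tag, str)]
    op, args_el = kids[0], kids[1:]
    opname = _local(op)
    if opname == "ci":  # user-defined function call
        fname = (op.text or "").strip()
        if fname not in functions:
            raise SbmlImportError(f"call to undefined function {fname!r}")
        bvars, body = functions[fname]
        args = [_parse_math(a, functions) for a in args_el]
        if len(args) != len(bvars):
            raise SbmlImportError(f"function {fname!r} called with wrong arity")
        return body.xreplace(dict(zip(bvars, args)))
    args = [_parse_math(a, functions) for a in args_el]
    if opname == "plus":
        return sp.Add(*args) if args else sp.Integer(0)
    if opname == "times":
        return sp.Mul(*args) if args else sp.Integer(1)
    if opname == "minus":
        return -args[0] if len(args) == 1 else args[0] - args[1]
    if opname == "divide":
        return args[0] / args[1]
    if opname == "power":
        return args[0] ** args[1]
    if opname == "root":
        degree = _first(el, "degree")
        if degree is not None:
            kids_d = [c for c in degree if isinstance(c.tag, str)]
            d = _parse_math(kids_d[0], functions)
            return args[0] ** (sp.Integer(1) / d)
        return sp.sqrt(args[0])
    if opname == "exp":
        return sp.exp(args[0])
    if opname == "ln":
        return sp.log(args[0])
    if opname == "log":
        logbase = _first(el, "logbase")
        if logbase is not None:
            kids_b = [c for c in logbase if isinstance(c.tag, str)]
            base = _parse_math(kids_b[0], functions)
            return sp.log(args[-1], base)
        return sp.log(args[0], 10)
    if opname == "abs":
        return sp.Abs(args[0])
    if opname == "floor":
        return sp.floor(args[0])
    if opname == "ceiling":
        return sp.ceiling(args[0])
    if opname in _RELATIONS:
        return _RELATIONS[opname](args[0], args[1])
    if opname == "and":
        return sp.And(*args)
    if opname == "or":
        return sp.Or(*args)
    if opname == "not":
        return sp.Not(args[0])
    raise SbmlImportError(f"unhandled MathML operator <{opname}>")


# ---------------------------------------------------------------------------
# Importer
# ---------------------------------------------------------------------------

def _lambdify_vector(
    exprs: list[sp.Expr], state_syms: list[sp.Symbol], param_names: list[str]
):
    param_syms = [sp.Symbol(n) for n in param_names]
    funcs = [sp.lambdify(state_syms + param_syms, e, modules="numpy") for e in exprs]

    def call(x: np.ndarray, p) -> list[np.ndarray]:
        args = [x[..., i] for i in range(len(state_syms))]
        args += [p[n] for n in param_names]
        return [f(*args) for f in funcs]

    return call


def import_sbml(path: str | Path, bound_scale: float = 10.0) -> OdeModel:
    """Read an SBML file into an :class:`OdeModel`.

    Dynamic species become states (document order); constant/boundary
    species, compartment sizes and global parameters are exposed as model
    parameters by id. Per-state upper bounds use the heuristic
    ``max(10, bound_scale * initial concentration)`` since SBML carries no
    conservation information explicitly.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise SbmlImportError(f"cannot parse {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root) != "sbml":
        raise SbmlImportError(f"{path} is not an SBML document")
    model_el = _first(root, "model")
    if model_el is None:
        raise SbmlImportError("SBML document has no <model>")

    # Hard rejections first, naming the construct.
    if _find_all(model_el, "event"):
        raise UnsupportedSbmlError("event")
    if _find_all(model_el, "algebraicRule"):
        raise UnsupportedSbmlError("algebraic rule")
    if _find_all(model_el, "delay"):
        raise UnsupportedSbmlError("delay")

    functions: dict[str, tuple[list[sp.Symbol], sp.Expr]] = {}
    for fd in _find_all(model_el, "functionDefinition"):
        math = _first(fd, "math")
        lam = _parse_math(math, functions)
        functions[fd.get("id")] = lam  # type: ignore[assignment]

    compartments: dict[str, float] = {}
    for comp in _find_all(model_el, "compartment"):
        size = comp.get("size", comp.get("volume"))
        compartments[comp.get("id")] = float(size) if size is not None else 1.0

    species: dict[str, dict] = {}
    for spe in _find_all(model_el, "species"):
        sid = spe.get("id")
        comp = spe.get("compartment")
        size = compartments.get(comp, 1.0)
        if spe.get("initialConcentration") is not None:
            init = float(spe.get("initialConcentration"))
        elif spe.get("initialAmount") is not None:
            init = float(spe.get("initialAmount")) / size
        else:
            init = 0.0
        species[sid] = {
            "initial": init,
            "size": size,
            "constant": spe.get("constant") == "true"
            or spe.get("boundaryCondition") == "true",
        }

    global_params: dict[str, float] = {}
    param_list = _first(model_el, "listOfParameters")
    for par in _children(param_list if param_list is not None else model_el,
                         "parameter"):
        v = par.get("value")
        global_params[par.get("id")] = float(v) if v is not None else 0.0

    assignments: dict[sp.Symbol, sp.Expr] = {}
    rate_rules: dict[str, sp.Expr] = {}
    for rule in _find_all(model_el, "assignmentRule") + _find_all(model_el, "rateRule"):
        var = rule.get("variable")
        expr = _parse_math(_first(rule, "math"), functions)
        if _local(rule) == "assignmentRule":
            assignments[sp.Symbol(var)] = expr
        else:
            if var not in species or species[var]["constant"]:
                raise UnsupportedSbmlError(f"rate rule on non-species {var!r}")
            rate_rules[var] = expr

    # Net reaction contribution per dynamic species, in concentration units.
    net: dict[str, sp.Expr] = {
        sid: sp.Integer(0) for sid, rec in species.items() if not rec["constant"]
    }
    for rxn in _find_all(model_el, "reaction"):
        kl = _first(rxn, "kineticLaw")
        if kl is None:
            raise SbmlImportError(f"reaction {rxn.get('id')!r} has no kinetic law")
        rate = _parse_math(_first(kl, "math"), functions)
        # local parameters shadow globals inside this law: inline their values
        local_subs = {}
        for lp in _find_all(kl, "parameter") + _find_all(kl, "localParameter"):
            local_subs[sp.Symbol(lp.get("id"))] = sp.Float(float(lp.get("value")))
        rate = rate.xreplace(local_subs)
        for ref, sign in (("listOfReactants", -1), ("listOfProducts", +1)):
            lst = _first(rxn, ref)
            if lst is None:
                continue
            for sref in _children(lst, "speciesReference"):
                sid = sref.get("species")
                stoich = float(sref.get("stoichiometry", "1"))
                if sid in net:
                    net[sid] = net[sid] + sign * stoich * rate / species[sid]["size"]

    for sid, expr in rate_rules.items():
        net[sid] = expr

    # Inline assignment rules (repeat to resolve chains).
    for _ in range(len(assignments) + 1):
        changed = False
        for sid in net:
            new = net[sid].xreplace(assignments)
            if new is not net[sid] and new != net[sid]:
                net[sid] = new
                changed = True
        if not changed:
            break

    state_names = [sid for sid, rec in species.items() if not rec["constant"]]
    if not state_names:
        raise SbmlImportError("model has no dynamic species")
    state_syms = [sp.Symbol(s) for s in state_names]

    # Everything symbolic that is not a state must resolve to a parameter.
    params: dict[str, float] = {}
    params.update(global_params)
    for cid, size in compartments.items():
        params.setdefault(cid, size)
    for sid, rec in species.items():
        if rec["constant"]:
            params.setdefault(sid, rec["initial"])
    for name in list(params):
        if sp.Symbol(name) in assignments:
            del params[name]  # assignment-ruled entities are not free parameters

    exprs = [net[s] for s in state_names]
    free = set().union(*(e.free_symbols for e in exprs)) - set(state_syms)
    unknown = {s.name for s in free} - set(params)
    if unknown:
        raise SbmlImportError(f"unresolved symbols in kinetic laws: {sorted(unknown)}")
    param_names = [n for n in params if sp.Symbol(n) in free]
    # keep also declared-but-unused globals: harmless and user-expected
    param_names += [n for n in params if n not in param_names]

    rhs_call = _lambdify_vector(exprs, state_syms, param_names)
    jac_exprs = [
        [sp.diff(e, s) for s in state_syms] for e in exprs
    ]
    jac_call = _lambdify_vector(
        [c for row in jac_exprs for c in row], state_syms, param_names
    )
    n = len(state_names)
    initials = np.array([species[s]["initial"] for s in state_names])

    def _stack(cols: list, shape: tuple[int, ...]) -> np.ndarray:
        out = np.empty(shape + (len(cols),))
        for i, c in enumerate(cols):
            out[..., i] = c
        return out

    def rhs(x: np.ndarray, p) -> np.ndarray:
        return _stack(rhs_call(x, p), np.shape(x[..., 0]))

    def jacobian(x: np.ndarray, p) -> np.ndarray:
        flat = _stack(jac_call(x, p), np.shape(x[..., 0]))
        return flat.reshape(np.shape(x[..., 0]) + (n, n))

    def bounds(p) -> np.ndarray:
        return np.maximum(10.0, bound_scale * initials)

    return OdeModel(
        name=model_el.get("id") or path.stem,
        state_names=tuple(state_names),
        param_names=tuple(param_names),
        rhs=rhs,
        jacobian=jacobian,
        state_upper_bounds=bounds,
        default_params={k: params[k] for k in param_names},
        default_specs=(),
    )
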
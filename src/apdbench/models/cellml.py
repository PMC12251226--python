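"""Optional CellML 1.0/1.1 import.

The native model implementations are the primary path; this loader lets a
user bring in a CellML cell model directly.  It supports the subset of
CellML used by single-cell electrophysiology models: components with
variables, variable connections, and content-MathML equations (algebraic
assignments and first-order time derivatives, with piecewise
expressions).  Unit conversion is *not* performed — variables are taken
in the units the file declares, as is conventional for these models,
which are written in self-consistent unit systems.

Unsupported constructs (reactions, imports, delays, higher derivatives,
unknown MathML operators) raise :class:`CellMLParseError` naming the
construct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

__all__ = ["CellMLParseError", "CellMLModel", "load_cellml"]

_CELLML_NS = ("http://www.cellml.org/cellml/1.0#", "http://www.cellml.org/cellml/1.1#")
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class CellMLParseError(ValueError):
    """Invalid or unsupported CellML content."""


@dataclass
class CellMLModel:
    """A parsed CellML model: an ODE system with named states/parameters."""

    name: str
    state_names: tuple[str, ...]
    initial_state: np.ndarray
    parameters: dict[str, float]
    _rhs_fn: Callable
    _param_order: tuple[str, ...]

    def rhs(self, t: float, y, parameters: Mapping[str, float] | None = None):
        """State derivative at (t, y), optionally with parameter overrides."""
        params = dict(self.parameters)
        if parameters:
            params.update(parameters)
        p = [params[k] for k in self._param_order]
        return np.asarray(self._rhs_fn(t, list(np.asarray(y, dtype=float)), p),
                          dtype=float)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1] if "}" in tag else tag


class _Sym:
    """Tiny expression tree compiled to a Python callable via sympy."""


def _parse_mathml(node, sym):
    import sympy as sp

    tag = _local(node.tag)
    if tag == "ci":
        return sym(node.text.strip())
    if tag == "cn":
        text = (node.text or "").strip()
        sep = node.find(f"{{{_MATHML_NS}}}sep")
        if sep is not None:  # e-notation: mantissa <sep/> exponent
            return sp.Float(float(f"{text}e{sep.tail.strip()}"))
        return sp.Float(float(text))
    if tag == "pi":
        return sp.pi
    if tag == "exponentiale":
        return sp.E
    if tag == "apply":
        children = [c for c in node if _local(c.tag) != "degree"]
        op = _local(children[0].tag)
        args = [_parse_mathml(c, sym) for c in children[1:]]
        if op == "plus":
            return sp.Add(*args)
        if op == "minus":
            return args[0] - args[1] if len(args) == 2 else -args[0]
        if op == "times":
            return sp.Mul(*args)
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
        if op == "root":
            return sp.sqrt(args[0])
        if op == "exp":
            return sp.exp(args[0])
        if op == "ln":
            return sp.log(args[0])
        if op == "log":
            return sp.log(args[0], 10)
        if op == "abs":
            return sp.Abs(args[0])
        if op == "floor":
            return sp.floor(args[0])
        if op == "ceiling":
            return sp.ceiling(args[0])
        if op in ("lt", "gt", "leq", "geq", "eq", "neq"):
            rel = {"lt": sp.Lt, "gt": sp.Gt, "leq": sp.Le, "geq": sp.Ge,
                   "eq": sp.Eq, "neq": sp.Ne}[op]
            return rel(args[0], args[1])
        if op == "and":
            return sp.And(*args)
        if op == "or":
            return sp.Or(*args)
        if op == "not":
            return sp.Not(args[0])
        raise CellMLParseError(f"unsupported MathML operator: <{op}>")
    if tag == "piecewise":
        import sympy as sp

        pieces = []
        otherwise = None
        for c in node:
            ctag = _local(c.tag)
            if ctag == "piece":
                val = _parse_mathml(c[0], sym)
                cond = _parse_mathml(c[1], sym)
                pieces.append((val, cond))
            elif ctag == "otherwise":
                otherwise = _parse_mathml(c[0], sym)
        if otherwise is not None:
            pieces.append((otherwise, True))
        return sp.Piecewise(*pieces)
    raise CellMLParseError(f"unsupported MathML construct: <{tag}>")


def load_cellml(path, time_units_hint: str = "ms") -> CellMLModel:
    """Parse a CellML 1.0/1.1 file into a :class:`CellMLModel`.

    States are the variables appearing as first-order time derivatives;
    variables with an ``initial_value`` never assigned by an equation
    become parameters; intermediate algebraic variables are substituted.
    """
    import sympy as sp
    from lxml import etree

    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise CellMLParseError(f"cannot parse CellML file: {exc}") from exc
    root = tree.getroot()
    ns = root.nsmap.get(None)
    if ns not in _CELLML_NS:
        raise CellMLParseError(
            f"not a CellML 1.0/1.1 model (root namespace {ns!r})"
        )
    for bad in ("reaction", "import"):
        if root.findall(f".//{{{ns}}}{bad}"):
            raise CellMLParseError(f"unsupported CellML construct: <{bad}>")

    model_name = root.get("name", "cellml_model")

    # variables, keyed (component, name)
    init: dict[tuple[str, str], float] = {}
    all_vars: set[tuple[str, str]] = set()
    outward: set[tuple[str, str]] = set()
    for comp in root.findall(f"{{{ns}}}component"):
        cname = comp.get("name")
        for var in comp.findall(f"{{{ns}}}variable"):
            key = (cname, var.get("name"))
            all_vars.add(key)
            iv = var.get("initial_value")
            if iv is not None:
                init[key] = float(iv)
            if var.get("public_interface") == "out":
                outward.add(key)

    # connections: union-find over connected variables
    parent: dict[tuple[str, str], tuple[str, str]] = {v: v for v in all_vars}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for conn in root.findall(f"{{{ns}}}connection"):
        mc = conn.find(f"{{{ns}}}map_components")
        c1, c2 = mc.get("component_1"), mc.get("component_2")
        for mv in conn.findall(f"{{{ns}}}map_variables"):
            union((c1, mv.get("variable_1")), (c2, mv.get("variable_2")))

    # pick each equivalence class's representative: the member owning the
    # initial value, else the declared source (public_interface="out")
    classes: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for v in all_vars:
        classes.setdefault(find(v), []).append(v)
    rep: dict[tuple[str, str], str] = {}
    for members in classes.values():
        members = sorted(members)
        chosen = (next((m for m in members if m in init), None)
                  or next((m for m in members if m in outward), None)
                  or members[0])
        name = f"{chosen[0]}__{chosen[1]}"
        for m in members:
            rep[m] = name

    def canon(comp, name):
        key = (comp, name)
        if key not in rep:
            raise CellMLParseError(f"undeclared variable {name!r} in component {comp!r}")
        return rep[key]

    # merged initial values (any member of the class may carry it)
    init_by_canon: dict[str, float] = {}
    for key, value in init.items():
        init_by_canon[canon(*key)] = value

    # equations
    derivs: dict[str, sp.Expr] = {}
    algebraic: dict[str, sp.Expr] = {}
    time_syms: set[str] = set()
    for comp in root.findall(f"{{{ns}}}component"):
        cname = comp.get("name")

        def sym(name, _c=cname):
            return sp.Symbol(canon(_c, name))

        for math in comp.findall(f"{{{_MATHML_NS}}}math"):
            for apply_ in math.findall(f"{{{_MATHML_NS}}}apply"):
                if _local(apply_[0].tag) != "eq":
                    raise CellMLParseError("top-level MathML must be an <eq> equation")
                lhs_node, rhs_node = apply_[1], apply_[2]
                rhs_expr = _parse_mathml(rhs_node, sym)
                if _local(lhs_node.tag) == "apply" and _local(lhs_node[0].tag) == "diff":
                    bvar = [c for c in lhs_node if _local(c.tag) == "bvar"][0]
                    time_syms.add(canon(cname, bvar[0].text.strip()))
                    target = [c for c in lhs_node
                              if _local(c.tag) == "ci" and c is not bvar][-1]
                    state = canon(cname, target.text.strip())
                    if state in derivs:
                        raise CellMLParseError(f"duplicate derivative for {state}")
                    derivs[state] = rhs_expr
                elif _local(lhs_node.tag) == "ci":
                    var = canon(cname, lhs_node.text.strip())
                    if var in algebraic:
                        raise CellMLParseError(f"duplicate assignment for {var}")
                    algebraic[var] = rhs_expr
                else:
                    raise CellMLParseError(
                        "unsupported equation left-hand side "
                        f"<{_local(lhs_node.tag)}> (only x = ... and dx/dt = ...)"
                    )

    if not derivs:
        raise CellMLParseError("model has no time derivatives (not an ODE model)")
    if len(time_syms) > 1:
        raise CellMLParseError(f"multiple independent variables: {sorted(time_syms)}")
    t_sym = sp.Symbol(next(iter(time_syms)))

    states = tuple(sorted(derivs))
    state_syms = [sp.Symbol(s) for s in states]
    missing_init = [s for s in states if s not in init_by_canon]
    if missing_init:
        raise CellMLParseError(f"states lack initial values: {missing_init}")

    # substitute algebraic assignments (iterate to resolve chains)
    def resolve(expr):
        for _ in range(len(algebraic) + 1):
            subs = {sp.Symbol(k): v for k, v in algebraic.items()
                    if sp.Symbol(k) in expr.free_symbols}
            if not subs:
                return expr
            expr = expr.xreplace(subs)
        raise CellMLParseError("cyclic algebraic dependencies")

    resolved = [resolve(derivs[s]) for s in states]

    free = set()
    for e in resolved:
        free |= e.free_symbols
    param_syms = sorted(
        (s for s in free
         if s not in state_syms and s != t_sym and str(s) not in algebraic),
        key=str,
    )
    params = {}
    for s in param_syms:
        if str(s) not in init_by_canon:
            raise CellMLParseError(f"constant {s} has no initial_value")
        params[str(s)] = init_by_canon[str(s)]

    fn = sp.lambdify((t_sym, state_syms, param_syms), resolved, modules="numpy")

    return CellMLModel(
        name=model_name,
        state_names=states,
        initial_state=np.array([init_by_canon[s] for s in states]),
        parameters=params,
        _rhs_fn=fn,
        _param_order=tuple(str(s) for s in param_syms),
    )
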
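"""Rate, constraint and attribute expressions.

Expressions appear in three syntactic positions: attribute patterns and
product attributes, kinetic rates (including the ``if c then r else 0``
constraint sugar), and user-declared functions.  Evaluation is pure:
the same expression under the same environment always yields the same
value.  A rate expression must evaluate to a non-negative number;
anything else (a boolean, a string, a negative number) is a modeling
error and raises.

Fresh values for the nu-operator come from a :class:`FreshValueGenerator`,
a monotone counter kept separate from the simulation's random stream so
that creating identifiers never perturbs the random sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Union

from .core import Fresh, format_value

__all__ = [
    "Expression", "Lit", "Name", "Call", "Bin", "Un", "Cmp", "BoolOp", "If",
    "Env", "EvalError", "UserFunction", "FreshValueGenerator", "fresh",
    "evaluate", "evaluate_rate", "format_expr", "free_names", "BUILTINS",
]


class EvalError(Exception):
    """Expression evaluation failed (unbound name, type error, bad rate...)."""


@dataclass(frozen=True)
class Lit:
    value: Union[int, float, str, bool]


@dataclass(frozen=True)
class Name:
    ident: str


@dataclass(frozen=True)
class Call:
    func: str
    args: tuple


@dataclass(frozen=True)
class Bin:
    op: str  # + - * / ^
    left: "Expression"
    right: "Expression"


@dataclass(frozen=True)
class Un:
    op: str  # - !
    operand: "Expression"


@dataclass(frozen=True)
class Cmp:
    op: str  # = != < <= > >=
    left: "Expression"
    right: "Expression"


@dataclass(frozen=True)
class BoolOp:
    op: str  # && ||
    left: "Expression"
    right: "Expression"


@dataclass(frozen=True)
class If:
    cond: "Expression"
    then: "Expression"
    orelse: "Expression"


Expression = Union[Lit, Name, Call, Bin, Un, Cmp, BoolOp, If]


@dataclass(frozen=True)
class UserFunction:
    """A pure function declared in the model file (``fun f(x,y) = ...;``)."""
    name: str
    params: tuple[str, ...]
    body: Expression


def _num(v, what: str):
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise EvalError(f"{what} requires a number, got {v!r}")
    return v


def _exact_div(a, b):
    if b == 0:
        raise EvalError("division by zero")
    if isinstance(a, int) and isinstance(b, int) and a % b == 0:
        return a // b
    return a / b


def _builtin_min(*xs):
    return min(_num(x, "min") for x in xs)


def _builtin_max(*xs):
    return max(_num(x, "max") for x in xs)


BUILTINS: dict[str, Callable] = {
    "exp": lambda x: math.exp(_num(x, "exp")),
    "log": lambda x: math.log(_num(x, "log")),
    "pow": lambda x, y: _num(x, "pow") ** _num(y, "pow"),
    "sqrt": lambda x: math.sqrt(_num(x, "sqrt")),
    "floor": lambda x: math.floor(_num(x, "floor")),
    "ceil": lambda x: math.ceil(_num(x, "ceil")),
    "abs": lambda x: abs(_num(x, "abs")),
    "min": _builtin_min,
    "max": _builtin_max,
}


class Env:
    """Evaluation environment: variable bindings over model context.

    ``bindings`` holds rule-local variables (attribute values, species
    identifier amounts, bound rest-solutions, nu values); ``constants``
    and ``functions`` come from the model.  Lookup of an unbound name
    is an error, never a default.
    """

    __slots__ = ("bindings", "constants", "functions")

    def __init__(self, bindings: Mapping[str, object] | None = None,
                 constants: Mapping[str, object] | None = None,
                 functions: Mapping[str, UserFunction] | None = None) -> None:
        # a dict passed in is adopted, not copied (evaluation never mutates)
        if bindings is None:
            self.bindings = {}
        elif type(bindings) is dict:
            self.bindings = bindings
        else:
            self.bindings = dict(bindings)
        self.constants = constants if constants is not None else {}
        self.functions = functions if functions is not None else {}

    def lookup(self, ident: str):
        try:
            return self.bindings[ident]
        except KeyError:
            pass
        try:
            return self.constants[ident]
        except KeyError:
            raise EvalError(f"unbound name '{ident}'") from None

    def child(self, bindings: Mapping[str, object]) -> "Env":
        return Env(bindings, self.constants, self.functions)


class FreshValueGenerator:
    """Monotone source of :class:`~mlrules.core.Fresh` values.

    Every emitted value is distinct from all previously emitted values
    and, by construction of the :class:`Fresh` type, from every literal
    a model file can contain.
    """

    __slots__ = ("_next",)

    def __init__(self, start: int = 0) -> None:
        self._next = start

    def next(self) -> Fresh:
        v = Fresh(self._next)
        self._next += 1
        return v


def fresh(gen: FreshValueGenerator, n: int) -> list[Fresh]:
    """Draw ``n`` pairwise-distinct fresh values."""
    return [gen.next() for _ in range(n)]


def evaluate(expr: Expression, env: Env):
    """Evaluate ``expr`` under ``env``; deterministic and side-effect free."""
    t = type(expr)
    if t is Lit:
        return expr.value
    if t is Name:
        return env.lookup(expr.ident)
    if t is Bin:
        a = _num(evaluate(expr.left, env), f"'{expr.op}'")
        b = _num(evaluate(expr.right, env), f"'{expr.op}'")
        op = expr.op
        if op == "+":
            return a + b
        if op == "-":
            return a - b
        if op == "*":
            return a * b
        if op == "/":
            return _exact_div(a, b)
        if op == "^":
            return a ** b
        raise EvalError(f"unknown operator '{op}'")
    if t is Un:
        v = evaluate(expr.operand, env)
        if expr.op == "-":
            return -_num(v, "unary '-'")
        if expr.op == "!":
            if not isinstance(v, bool):
                raise EvalError(f"'!' requires a boolean, got {v!r}")
            return not v
        raise EvalError(f"unknown operator '{expr.op}'")
    if t is Cmp:
        return _compare(expr.op, evaluate(expr.left, env),
                        evaluate(expr.right, env))
    if t is BoolOp:
        a = evaluate(expr.left, env)
        if not isinstance(a, bool):
            raise EvalError(f"'{expr.op}' requires booleans, got {a!r}")
        if expr.op == "&&":
            if not a:
                return False
        elif expr.op == "||":
            if a:
                return True
        else:
            raise EvalError(f"unknown operator '{expr.op}'")
        b = evaluate(expr.right, env)
        if not isinstance(b, bool):
            raise EvalError(f"'{expr.op}' requires booleans, got {b!r}")
        return b
    if t is If:
        c = evaluate(expr.cond, env)
        if not isinstance(c, bool):
            raise EvalError(f"'if' condition must be boolean, got {c!r}")
        return evaluate(expr.then if c else expr.orelse, env)
    if t is Call:
        fn = env.functions.get(expr.func)
        args = [evaluate(a, env) for a in expr.args]
        if fn is not None:
            if len(args) != len(fn.params):
                raise EvalError(
                    f"function '{expr.func}' expects {len(fn.params)} "
                    f"arguments, got {len(args)}")
            # user functions see only their parameters plus model constants
            return evaluate(fn.body, Env(dict(zip(fn.params, args)),
                                         env.constants, env.functions))
        builtin = BUILTINS.get(expr.func)
        if builtin is None:
            raise EvalError(f"unknown function '{expr.func}'")
        try:
            return builtin(*args)
        except EvalError:
            raise
        except (ValueError, OverflowError, ZeroDivisionError) as exc:
            raise EvalError(f"'{expr.func}' failed: {exc}") from None
    raise EvalError(f"cannot evaluate {expr!r}")


def _compare(op: str, a, b) -> bool:
    numeric = (lambda v: isinstance(v, (int, float))
               and not isinstance(v, bool))
    if numeric(a) and numeric(b):
        pass  # ordinary numeric comparison below
    elif isinstance(a, str) and isinstance(b, str):
        pass
    elif isinstance(a, bool) and isinstance(b, bool):
        pass
    elif isinstance(a, Fresh) or isinstance(b, Fresh):
        if op == "=":
            return a == b
        if op == "!=":
            return a != b
        raise EvalError("fresh values support only '=' and '!='")
    else:
        # mixed types: unequal by definition, not orderable
        if op == "=":
            return False
        if op == "!=":
            return True
        raise EvalError(f"cannot order {a!r} and {b!r}")
    if op == "=":
        return a == b
    if op == "!=":
        return a != b
    if op == "<":
        return a < b
    if op == "<=":
        return a <= b
    if op == ">":
        return a > b
    if op == ">=":
        return a >= b
    raise EvalError(f"unknown comparison '{op}'")


def evaluate_rate(expr: Expression, env: Env):
    """Evaluate a kinetic-rate expression; must be a non-negative number."""
    v = evaluate(expr, env)
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise EvalError(f"rate expression evaluated to non-number {v!r}")
    if v < 0:
        raise EvalError(f"rate expression evaluated to negative value {v!r}")
    return v


def free_names(expr: Expression, acc: set[str] | None = None) -> set[str]:
    """All :class:`Name` identifiers occurring in ``expr``."""
    if acc is None:
        acc = set()
    t = type(expr)
    if t is Name:
        acc.add(expr.ident)
    elif t is Bin or t is Cmp or t is BoolOp:
        free_names(expr.left, acc)
        free_names(expr.right, acc)
    elif t is Un:
        free_names(expr.operand, acc)
    elif t is If:
        free_names(expr.cond, acc)
        free_names(expr.then, acc)
        free_names(expr.orelse, acc)
    elif t is Call:
        for a in expr.args:
            free_names(a, acc)
    return acc


# ---------------------------------------------------------------------------
# Compilation to Python callables (hot-path evaluation in the matcher).
# Semantics mirror evaluate(); helpers delegate to the same primitives.


def _c_bool(v):
    if not isinstance(v, bool):
        raise EvalError(f"expected a boolean, got {v!r}")
    return v


def _c_not(v):
    if not isinstance(v, bool):
        raise EvalError(f"'!' requires a boolean, got {v!r}")
    return not v


def _c_eq(a, b):
    return _compare("=", a, b)


def _c_ne(a, b):
    return _compare("!=", a, b)


def compile_expr(expr: Expression, constants: Mapping[str, object],
                 functions: Mapping[str, UserFunction]):
    """Compile to ``fn(bindings: dict) -> value``.

    Constants are inlined; user functions become positional lambdas.
    Type errors surface as :class:`EvalError` (or Python ``TypeError``
    from primitive operators, which callers treat the same way).
    """
    ns: dict[str, object] = {
        "_div": _exact_div, "_bool": _c_bool, "_not": _c_not,
        "_eq": _c_eq, "_ne": _c_ne, "EvalError": EvalError,
    }
    for bn, bf in BUILTINS.items():
        ns["_fn_" + bn] = bf
    compiled_fns: dict[str, object] = {}

    def compile_function(fn: UserFunction) -> None:
        if fn.name in compiled_fns:
            return
        compiled_fns[fn.name] = None  # recursion guard
        body = emit(fn.body, set(fn.params))
        ns["_uf_" + fn.name] = eval(
            f"lambda {', '.join(fn.params)}: {body}", ns)

    def emit(e: Expression, scope: set[str]) -> str:
        t = type(e)
        if t is Lit:
            return repr(e.value)
        if t is Name:
            if e.ident in scope:
                return e.ident
            if e.ident in constants:
                return repr(constants[e.ident])
            return f"b[{e.ident!r}]"
        if t is Bin:
            a, c = emit(e.left, scope), emit(e.right, scope)
            if e.op == "/":
                return f"_div({a}, {c})"
            if e.op == "^":
                return f"({a} ** {c})"
            return f"({a} {e.op} {c})"
        if t is Un:
            a = emit(e.operand, scope)
            return f"(-{a})" if e.op == "-" else f"_not({a})"
        if t is Cmp:
            a, c = emit(e.left, scope), emit(e.right, scope)
            if e.op == "=":
                return f"_eq({a}, {c})"
            if e.op == "!=":
                return f"_ne({a}, {c})"
            return f"({a} {e.op} {c})"
        if t is BoolOp:
            a, c = emit(e.left, scope), emit(e.right, scope)
            op = "and" if e.op == "&&" else "or"
            return f"(_bool({a}) {op} _bool({c}))"
        if t is If:
            return (f"({emit(e.then, scope)} if _bool({emit(e.cond, scope)})"
                    f" else {emit(e.orelse, scope)})")
        if t is Call:
            args = ", ".join(emit(a, scope) for a in e.args)
            fn = functions.get(e.func)
            if fn is not None:
                compile_function(fn)
                return f"_uf_{e.func}({args})"
            if e.func in BUILTINS:
                return f"_fn_{e.func}({args})"
            raise EvalError(f"unknown function '{e.func}'")
        raise EvalError(f"cannot compile {e!r}")

    return eval(f"lambda b: {emit(expr, set())}", ns)


_PREC = {"||": 1, "&&": 2, "cmp": 4, "+": 5, "-": 5, "*": 6, "/": 6,
         "u-": 7, "!": 7, "^": 8}


def format_expr(expr: Expression, parent_prec: int = 0) -> str:
    """Deterministic textual form; reparses to an equal tree."""
    t = type(expr)
    if t is Lit:
        return format_value(expr.value)
    if t is Name:
        return expr.ident
    if t is Call:
        return expr.func + "(" + ", ".join(format_expr(a) for a in expr.args) + ")"
    if t is If:
        s = (f"if {format_expr(expr.cond)} then {format_expr(expr.then)} "
             f"else {format_expr(expr.orelse)}")
        return f"({s})" if parent_prec > 0 else s
    if t is Un:
        p = _PREC["u-"]
        s = expr.op + format_expr(expr.operand, p)
        return f"({s})" if parent_prec > p else s
    if t is Bin:
        p = _PREC[expr.op]
        if expr.op == "^":  # right-associative
            s = (format_expr(expr.left, p + 1) + " ^ "
                 + format_expr(expr.right, p))
        else:
            s = (format_expr(expr.left, p) + f" {expr.op} "
                 + format_expr(expr.right, p + 1))
        return f"({s})" if parent_prec > p else s
    if t is Cmp:
        p = _PREC["cmp"]
        s = (format_expr(expr.left, p + 1) + f" {expr.op} "
             + format_expr(expr.right, p + 1))
        return f"({s})" if parent_prec >= p else s
    if t is BoolOp:
        p = _PREC[expr.op]
        s = (format_expr(expr.left, p) + f" {expr.op} "
             + format_expr(expr.right, p + 1))
        return f"({s})" if parent_prec > p else s
    raise TypeError(f"not an expression: {expr!r}")
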
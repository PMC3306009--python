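"""Model text format: grammar, parser, validator and serializer.

A model file consists of statements, each terminated by ``;``:

* species definitions — ``C(4);`` declares name ``C`` with arity 4
  (``A;`` declares a zero-arity species; parentheses are omitted for
  arity 0 on output);
* constants — ``const k3 = 180;`` (the right-hand side may be any
  closed expression over previously declared constants);
* functions — ``fun nb(x1, y1, x2, y2) = ...;`` pure user functions
  usable in any expression;
* the initial solution — ``init 2 A(1)[3 B] + C;``;
* rules — ``A(x):a -> B(2 * x) @ k * a if a > T;``.

Rule syntax elements: attribute patterns are expressions (a bare
lower-case name that is not a constant binds the attribute), ``:a``
binds the species identifier ``a`` to the amount of the matched
population, ``[ ... ]`` encloses a nested content pattern, ``s?``
inside brackets binds the rest of the content solution (reusable on
the product side, including multiple times), ``nu(x)`` in front of the
products binds fresh values, and ``@ r if c`` is sugar for the rate
``if c then r else 0``.  Rules are uni-directional; a reversible
reaction is written as two rules.  Comments run from ``//`` to end of
line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import (AttributeValue, Solution, Species, format_solution,
                   format_value)
from .expr import (BUILTINS, Bin, BoolOp, Call, Cmp, Env, EvalError,
                   Expression, If, Lit, Name, Un, UserFunction, evaluate,
                   format_expr, free_names)

__all__ = [
    "Pattern", "Product", "Rule", "Model", "ParseError", "ModelError",
    "parse_model", "parse_solution", "parse_pattern", "serialize_model",
    "validate_model",
]


class ParseError(Exception):
    def __init__(self, message: str, line: int, col: int) -> None:
        super().__init__(f"{message} (line {line}, column {col})")
        self.line = line
        self.col = col


class ModelError(Exception):
    """The model text parses but is semantically inconsistent."""

    def __init__(self, diagnostics: list[str]) -> None:
        super().__init__("; ".join(diagnostics))
        self.diagnostics = diagnostics


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Pattern:
    """A reactant pattern.

    ``attrs`` are expressions; at match time a bare non-constant name
    binds the attribute, anything else filters by its evaluated value.
    ``ident`` binds the matched population's amount.  ``content`` holds
    nested patterns that must be found inside the matched species;
    unmatched content is lost on firing unless bound by ``rest``.
    """

    name: str
    attrs: tuple[Expression, ...] = ()
    ident: Optional[str] = None
    content: tuple["Pattern", ...] = ()
    rest: Optional[str] = None


@dataclass(frozen=True)
class Product:
    """A product template: a species constructor or a rest-solution ref.

    For a species constructor, ``name`` is set and ``restvar`` is None.
    For a rest-solution reference (``s?`` used as a product), ``restvar``
    names the bound solution variable whose content is poured out at
    this position.  ``amount`` is an expression (defaults to 1).
    """

    amount: Expression = Lit(1)
    name: Optional[str] = None
    attrs: tuple[Expression, ...] = ()
    content: tuple["Product", ...] = ()
    restvar: Optional[str] = None


@dataclass(frozen=True)
class Rule:
    reactants: tuple[Pattern, ...]
    products: tuple[Product, ...]
    rate: Expression
    nu: tuple[str, ...] = ()

    def __str__(self) -> str:
        return _format_rule(self)


@dataclass
class Model:
    definitions: dict[str, int] = field(default_factory=dict)
    constants: dict[str, AttributeValue] = field(default_factory=dict)
    functions: dict[str, UserFunction] = field(default_factory=dict)
    rules: tuple[Rule, ...] = ()
    initial: Solution = field(default_factory=Solution)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Model):
            return NotImplemented
        return (self.definitions == other.definitions
                and self.constants == other.constants
                and self.functions == other.functions
                and self.rules == other.rules
                and self.initial == other.initial)


# ---------------------------------------------------------------------------
# Tokenizer

_TOKEN_RE = re.compile(r"""
    (?P<ws>\s+|//[^\n]*)
  | (?P<float>\d+\.\d*(?:[eE][+-]?\d+)?|\d+[eE][+-]?\d+)
  | (?P<int>\d+)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<string>'(?:[^'\\]|\\.)*')
  | (?P<op>->|!=|<=|>=|&&|\|\||[-+*/^()\[\];:,?@=<>!])
""", re.VERBOSE)

_KEYWORDS = {"const", "fun", "init", "if", "then", "else", "true", "false",
             "nu"}


@dataclass(frozen=True)
class _Token:
    kind: str  # 'int' 'float' 'name' 'string' 'op' 'kw' 'eof'
    text: str
    line: int
    col: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    line, col, pos = 1, 1, 0
    n = len(text)
    while pos < n:
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        tok = m.group()
        if kind != "ws":
            if kind == "name" and tok in _KEYWORDS:
                kind = "kw"
            tokens.append(_Token(kind, tok, line, col))
        nl = tok.count("\n")
        if nl:
            line += nl
            col = len(tok) - tok.rfind("\n")
        else:
            col += len(tok)
        pos = m.end()
    tokens.append(_Token("eof", "", line, col))
    return tokens


# ---------------------------------------------------------------------------
# Parser

class _Parser:
    def __init__(self, text: str) -> None:
        self.tokens = _tokenize(text)
        self.pos = 0

    # -- token helpers ------------------------------------------------------

    @property
    def cur(self) -> _Token:
        return self.tokens[self.pos]

    def advance(self) -> _Token:
        t = self.cur
        if t.kind != "eof":
            self.pos += 1
        return t

    def at(self, kind: str, text: str | None = None) -> bool:
        t = self.cur
        return t.kind == kind and (text is None or t.text == text)

    def accept(self, kind: str, text: str | None = None) -> Optional[_Token]:
        if self.at(kind, text):
            return self.advance()
        return None

    def expect(self, kind: str, text: str | None = None) -> _Token:
        if not self.at(kind, text):
            want = text if text is not None else kind
            raise ParseError(
                f"expected {want!r}, found {self.cur.text or 'end of input'!r}",
                self.cur.line, self.cur.col)
        return self.advance()

    def error(self, msg: str) -> ParseError:
        return ParseError(msg, self.cur.line, self.cur.col)

    # -- model --------------------------------------------------------------

    def parse_model(self) -> Model:
        model = Model()
        init_seen = False
        while not self.at("eof"):
            if self.accept("kw", "const"):
                name_t = self.expect("name")
                self._check_lower(name_t, "constant")
                self.expect("op", "=")
                rhs = self.parse_expr()
                self.expect("op", ";")
                if name_t.text in model.constants:
                    raise ParseError(f"duplicate constant '{name_t.text}'",
                                     name_t.line, name_t.col)
                try:
                    value = evaluate(rhs, Env({}, model.constants,
                                              model.functions))
                except EvalError as exc:
                    raise ParseError(f"cannot evaluate constant "
                                     f"'{name_t.text}': {exc}",
                                     name_t.line, name_t.col) from None
                model.constants[name_t.text] = value
            elif self.accept("kw", "fun"):
                name_t = self.expect("name")
                self._check_lower(name_t, "function")
                self.expect("op", "(")
                params: list[str] = []
                if not self.at("op", ")"):
                    while True:
                        p = self.expect("name")
                        params.append(p.text)
                        if not self.accept("op", ","):
                            break
                self.expect("op", ")")
                self.expect("op", "=")
                body = self.parse_expr()
                self.expect("op", ";")
                if name_t.text in model.functions:
                    raise ParseError(f"duplicate function '{name_t.text}'",
                                     name_t.line, name_t.col)
                model.functions[name_t.text] = UserFunction(
                    name_t.text, tuple(params), body)
            elif self.accept("kw", "init"):
                if init_seen:
                    raise self.error("duplicate init statement")
                init_seen = True
                model.initial = self.parse_init_solution(model)
                self.expect("op", ";")
            else:
                stmt = self._try_species_def()
                if stmt is not None:
                    name_t, arity = stmt
                    prev = model.definitions.get(name_t.text)
                    if prev is not None and prev != arity:
                        raise ParseError(
                            f"species '{name_t.text}' redefined with arity "
                            f"{arity}, previously {prev} (the arity of a "
                            f"species name is fixed)",
                            name_t.line, name_t.col)
                    model.definitions[name_t.text] = arity
                else:
                    model.rules = model.rules + (self.parse_rule(),)
        return model

    def _check_lower(self, tok: _Token, what: str) -> None:
        if not tok.text[0].islower():
            raise ParseError(
                f"{what} names must start with a lower-case letter, "
                f"got '{tok.text}'", tok.line, tok.col)

    def _try_species_def(self) -> Optional[tuple[_Token, int]]:
        """``Name;`` or ``Name(INT);`` — otherwise roll back and return None."""
        save = self.pos
        if not self.at("name") or not self.cur.text[0].isupper():
            return None
        name_t = self.advance()
        arity = 0
        if self.accept("op", "("):
            t = self.accept("int")
            if t is None or not self.accept("op", ")"):
                self.pos = save
                return None
            arity = int(t.text)
        if not self.accept("op", ";"):
            self.pos = save
            return None
        return name_t, arity

    # -- rules --------------------------------------------------------------

    def parse_rule(self) -> Rule:
        reactants: list[Pattern] = []
        if self.accept("int"):
            # '0 ->' empty reactant side; any other count prefixes a pattern
            prev = self.tokens[self.pos - 1]
            if prev.text == "0" and self.at("op", "->"):
                pass
            else:
                reactants.extend([self.parse_pattern()]
                                 * self._positive(prev))
                while self.accept("op", "+"):
                    reactants.extend(self._counted_pattern())
        elif not self.at("op", "->"):
            reactants.extend(self._counted_pattern())
            while self.accept("op", "+"):
                reactants.extend(self._counted_pattern())
        self.expect("op", "->")
        nu: list[str] = []
        if self.accept("kw", "nu"):
            self.expect("op", "(")
            while True:
                t = self.expect("name")
                self._check_lower(t, "nu binder")
                nu.append(t.text)
                if not self.accept("op", ","):
                    break
            self.expect("op", ")")
        products: list[Product] = []
        if self.at("int") and self.cur.text == "0" and \
                self.tokens[self.pos + 1].text == "@":
            self.advance()
        else:
            products.append(self.parse_product())
            while self.accept("op", "+"):
                products.append(self.parse_product())
        self.expect("op", "@")
        rate = self.parse_expr()
        if self.accept("kw", "if"):
            cond = self.parse_expr()
            rate = If(cond, rate, Lit(0))
        self.expect("op", ";")
        return Rule(tuple(reactants), tuple(products), rate, tuple(nu))

    def _positive(self, tok: _Token) -> int:
        n = int(tok.text)
        if n < 1:
            raise ParseError(f"reactant count must be positive, got {n}",
                             tok.line, tok.col)
        return n

    def _counted_pattern(self) -> list[Pattern]:
        count = 1
        t = self.accept("int")
        if t is not None:
            count = self._positive(t)
        pat = self.parse_pattern()
        return [pat] * count

    def parse_pattern(self) -> Pattern:
        name_t = self.expect("name")
        if not name_t.text[0].isupper():
            raise ParseError("species names must start with an upper-case "
                             f"letter, got '{name_t.text}'",
                             name_t.line, name_t.col)
        attrs: list[Expression] = []
        if self.accept("op", "("):
            if not self.at("op", ")"):
                while True:
                    attrs.append(self.parse_expr())
                    if not self.accept("op", ","):
                        break
            self.expect("op", ")")
        ident: Optional[str] = None
        if self.accept("op", ":"):
            t = self.expect("name")
            self._check_lower(t, "species identifier")
            ident = t.text
        content: list[Pattern] = []
        rest: Optional[str] = None
        if self.accept("op", "["):
            while not self.at("op", "]"):
                if (self.at("name") and self.cur.text[0].islower()
                        and self.tokens[self.pos + 1].text == "?"):
                    if rest is not None:
                        raise self.error("at most one rest-solution variable "
                                         "per content pattern")
                    rest = self.advance().text
                    self.advance()  # '?'
                else:
                    content.append(self.parse_pattern())
                if not self.accept("op", "+"):
                    break
            self.expect("op", "]")
        # the species identifier may also follow the content brackets
        if ident is None and self.accept("op", ":"):
            t = self.expect("name")
            self._check_lower(t, "species identifier")
            ident = t.text
        return Pattern(name_t.text, tuple(attrs), ident, tuple(content), rest)

    def parse_product(self) -> Product:
        amount: Expression = Lit(1)
        t = self.accept("int")
        if t is not None:
            amount = Lit(self._positive(t))
        elif self.at("op", "("):
            # parenthesized amount expression, e.g. '(dtot - 1) D'
            save = self.pos
            self.advance()
            try:
                e = self.parse_expr()
                self.expect("op", ")")
            except ParseError:
                self.pos = save
            else:
                if self.at("name") or self.at("kw", "nu"):
                    amount = e
                else:
                    self.pos = save
        return self._product_term(amount)

    def _product_term(self, amount: Expression) -> Product:
        if (self.at("name") and self.cur.text[0].islower()
                and self.tokens[self.pos + 1].text == "?"):
            var = self.advance().text
            self.advance()  # '?'
            return Product(amount=amount, restvar=var)
        name_t = self.expect("name")
        if not name_t.text[0].isupper():
            raise ParseError("species names must start with an upper-case "
                             f"letter, got '{name_t.text}'",
                             name_t.line, name_t.col)
        attrs: list[Expression] = []
        if self.accept("op", "("):
            if not self.at("op", ")"):
                while True:
                    attrs.append(self.parse_expr())
                    if not self.accept("op", ","):
                        break
            self.expect("op", ")")
        content: list[Product] = []
        if self.accept("op", "["):
            while not self.at("op", "]"):
                content.append(self.parse_product())
                if not self.accept("op", "+"):
                    break
            self.expect("op", "]")
        return Product(amount, name_t.text, tuple(attrs), tuple(content))

    # -- initial solution ---------------------------------------------------

    def parse_init_solution(self, model: Model) -> Solution:
        env = Env({}, model.constants, model.functions)
        if self.at("int") and self.cur.text == "0" and \
                self.tokens[self.pos + 1].text == ";":
            self.advance()
            return Solution()
        pops: list[tuple[Species, int]] = []
        pops.append(self._init_term(env))
        while self.accept("op", "+"):
            pops.append(self._init_term(env))
        return Solution(pops)

    def _init_term(self, env: Env) -> tuple[Species, int]:
        amount = 1
        tok = self.cur
        t = self.accept("int")
        if t is not None:
            amount = int(t.text)
        elif self.at("op", "("):
            save = self.pos
            self.advance()
            try:
                e = self.parse_expr()
                self.expect("op", ")")
            except ParseError:
                self.pos = save
            else:
                if self.at("name"):
                    amount = self._eval_init(e, env, tok, integer=True)
                else:
                    self.pos = save
        elif self.at("name") and self.cur.text[0].islower():
            save = self.pos
            nm = self.advance()
            if self.at("name") and self.cur.text[0].isupper():
                amount = self._eval_init(Name(nm.text), env, tok, integer=True)
            else:
                self.pos = save
        if amount < 0:
            raise ParseError(f"negative amount {amount}", tok.line, tok.col)
        name_t = self.expect("name")
        attrs: list[AttributeValue] = []
        if self.accept("op", "("):
            if not self.at("op", ")"):
                while True:
                    atok = self.cur
                    attrs.append(self._eval_init(self.parse_expr(), env, atok))
                    if not self.accept("op", ","):
                        break
            self.expect("op", ")")
        content = Solution()
        if self.accept("op", "["):
            pops: list[tuple[Species, int]] = []
            if self.at("int") and self.cur.text == "0" and \
                    self.tokens[self.pos + 1].text == "]":
                self.advance()
            else:
                while not self.at("op", "]"):
                    pops.append(self._init_term(env))
                    if not self.accept("op", "+"):
                        break
            self.expect("op", "]")
            content = Solution(pops)
        return Species(name_t.text, attrs, content), amount

    def _eval_init(self, e: Expression, env: Env, tok: _Token,
                   integer: bool = False):
        try:
            v = evaluate(e, env)
        except EvalError as exc:
            raise ParseError(f"initial solution: {exc}", tok.line,
                             tok.col) from None
        if integer and (isinstance(v, bool) or not isinstance(v, int)):
            raise ParseError(f"amount must be an integer, got {v!r}",
                             tok.line, tok.col)
        return v

    # -- expressions --------------------------------------------------------

    def parse_expr(self) -> Expression:
        return self._parse_or()

    def _parse_or(self) -> Expression:
        e = self._parse_and()
        while self.accept("op", "||"):
            e = BoolOp("||", e, self._parse_and())
        return e

    def _parse_and(self) -> Expression:
        e = self._parse_not()
        while self.accept("op", "&&"):
            e = BoolOp("&&", e, self._parse_not())
        return e

    def _parse_not(self) -> Expression:
        if self.accept("op", "!"):
            return Un("!", self._parse_not())
        return self._parse_cmp()

    def _parse_cmp(self) -> Expression:
        e = self._parse_add()
        for op in ("!=", "<=", ">=", "=", "<", ">"):
            if self.at("op", op):
                self.advance()
                return Cmp(op, e, self._parse_add())
        return e

    def _parse_add(self) -> Expression:
        e = self._parse_mul()
        while True:
            if self.accept("op", "+"):
                e = Bin("+", e, self._parse_mul())
            elif self.accept("op", "-"):
                e = Bin("-", e, self._parse_mul())
            else:
                return e

    def _parse_mul(self) -> Expression:
        e = self._parse_unary()
        while True:
            if self.accept("op", "*"):
                e = Bin("*", e, self._parse_unary())
            elif self.accept("op", "/"):
                e = Bin("/", e, self._parse_unary())
            else:
                return e

    def _parse_unary(self) -> Expression:
        if self.accept("op", "-"):
            return Un("-", self._parse_unary())
        return self._parse_power()

    def _parse_power(self) -> Expression:
        base = self._parse_atom()
        if self.accept("op", "^"):
            return Bin("^", base, self._parse_unary())
        return base

    def _parse_atom(self) -> Expression:
        t = self.cur
        if t.kind == "int":
            self.advance()
            return Lit(int(t.text))
        if t.kind == "float":
            self.advance()
            return Lit(float(t.text))
        if t.kind == "string":
            self.advance()
            body = t.text[1:-1]
            return Lit(body.replace("\\'", "'").replace("\\\\", "\\"))
        if t.kind == "kw":
            if t.text == "true":
                self.advance()
                return Lit(True)
            if t.text == "false":
                self.advance()
                return Lit(False)
            if t.text == "if":
                self.advance()
                cond = self.parse_expr()
                self.expect("kw", "then")
                then = self.parse_expr()
                self.expect("kw", "else")
                orelse = self.parse_expr()
                return If(cond, then, orelse)
        if t.kind == "name":
            self.advance()
            if self.at("op", "("):
                if t.text[0].isupper():
                    raise ParseError(
                        f"'{t.text}' looks like a species in expression "
                        "position", t.line, t.col)
                self.advance()
                args: list[Expression] = []
                if not self.at("op", ")"):
                    while True:
                        args.append(self.parse_expr())
                        if not self.accept("op", ","):
                            break
                self.expect("op", ")")
                return Call(t.text, tuple(args))
            if t.text[0].isupper():
                # capitalized bare identifier: a symbolic string literal
                return Lit(t.text)
            return Name(t.text)
        if self.accept("op", "("):
            e = self.parse_expr()
            self.expect("op", ")")
            return e
        raise self.error(f"expected an expression, found {t.text!r}")


# ---------------------------------------------------------------------------
# Public API


def parse_model(text: str, validate: bool = True) -> Model:
    """Parse model text; raises :class:`ParseError` on bad syntax and
    :class:`ModelError` on semantic inconsistencies (unless
    ``validate=False``)."""
    model = _Parser(text).parse_model()
    if validate:
        diagnostics = validate_model(model)
        if diagnostics:
            raise ModelError(diagnostics)
    return model


def parse_solution(text: str, model: Model | None = None) -> Solution:
    """Parse a standalone solution term (initial-solution syntax)."""
    model = model if model is not None else Model()
    p = _Parser(text + ";")
    sol = p.parse_init_solution(model)
    p.expect("op", ";")
    p.expect("eof")
    return sol


def parse_pattern(text: str) -> Pattern:
    """Parse a standalone reactant pattern (used for observables)."""
    p = _Parser(text)
    pat = p.parse_pattern()
    p.expect("eof")
    return pat


# ---------------------------------------------------------------------------
# Validation


def _pattern_uses(pat: Pattern) -> Iterable[tuple[str, int]]:
    yield pat.name, len(pat.attrs)
    for sub in pat.content:
        yield from _pattern_uses(sub)


def _product_uses(prod: Product) -> Iterable[tuple[str, int]]:
    if prod.name is not None:
        yield prod.name, len(prod.attrs)
        for sub in prod.content:
            yield from _product_uses(sub)


def _solution_uses(sol: Solution) -> Iterable[tuple[str, int]]:
    for sp, _ in sol:
        yield sp.name, len(sp.attrs)
        yield from _solution_uses(sp.content)


def validate_model(model: Model) -> list[str]:
    """Consistency diagnostics; an empty list means the model is valid."""
    diags: list[str] = []
    const_names = set(model.constants)
    fn_names = set(model.functions) | set(BUILTINS)
    overlap = set(model.definitions) & (const_names | set(model.functions))
    for nm in sorted(overlap):
        diags.append(f"name '{nm}' is used both for a species and for a "
                     "constant or function")
    for nm in sorted(const_names & set(model.functions)):
        diags.append(f"name '{nm}' is both a constant and a function")

    def check_use(name: str, nargs: int, where: str) -> None:
        arity = model.definitions.get(name)
        if arity is None:
            diags.append(f"{where}: species '{name}' is not defined")
        elif arity != nargs:
            diags.append(f"{where}: species '{name}' used with {nargs} "
                         f"attributes but declared with arity {arity}")

    for fn in model.functions.values():
        unknown = free_names(fn.body) - set(fn.params) - const_names
        for nm in sorted(unknown):
            diags.append(f"function '{fn.name}': unbound name '{nm}'")

    for name, nargs in _solution_uses(model.initial):
        check_use(name, nargs, "initial solution")

    for i, rule in enumerate(model.rules):
        where = f"rule {i + 1}"
        bound: set[str] = set()

        def bind_pattern(pat: Pattern) -> None:
            check_use(pat.name, len(pat.attrs), where)
            for ap in pat.attrs:
                if isinstance(ap, Name) and ap.ident not in const_names:
                    bound.add(ap.ident)
                else:
                    missing = free_names(ap) - bound - const_names
                    for nm in sorted(missing):
                        diags.append(
                            f"{where}: attribute expression uses unbound "
                            f"variable '{nm}' (bind it in an earlier "
                            "position)")
            if pat.ident is not None:
                bound.add(pat.ident)
            for sub in pat.content:
                bind_pattern(sub)
            if pat.rest is not None:
                if pat.rest in bound:
                    diags.append(f"{where}: rest-solution variable "
                                 f"'{pat.rest}' is already bound")
                bound.add(pat.rest)

        for pat in rule.reactants:
            bind_pattern(pat)
        for nb in rule.nu:
            if nb in bound:
                diags.append(f"{where}: nu binder '{nb}' shadows a bound "
                             "variable")
            bound.add(nb)

        def check_expr(e: Expression, what: str) -> None:
            for nm in sorted(free_names(e) - bound - const_names):
                diags.append(f"{where}: {what} uses unbound variable '{nm}'")
            for call in _calls(e):
                fn = model.functions.get(call.func)
                if fn is not None:
                    if len(call.args) != len(fn.params):
                        diags.append(
                            f"{where}: function '{call.func}' called with "
                            f"{len(call.args)} arguments, expects "
                            f"{len(fn.params)}")
                elif call.func not in BUILTINS:
                    diags.append(f"{where}: unknown function '{call.func}'")

        def check_product(prod: Product) -> None:
            if prod.restvar is not None:
                if prod.restvar not in bound:
                    diags.append(f"{where}: product references unbound "
                                 f"solution variable '{prod.restvar}'")
                check_expr(prod.amount, "product amount")
                return
            check_use(prod.name, len(prod.attrs), where)
            check_expr(prod.amount, "product amount")
            for ae in prod.attrs:
                check_expr(ae, "product attribute")
            for sub in prod.content:
                check_product(sub)

        check_expr(rule.rate, "rate expression")
        for prod in rule.products:
            check_product(prod)
    return diags


def _calls(e: Expression) -> Iterable[Call]:
    t = type(e)
    if t is Call:
        yield e
        for a in e.args:
            yield from _calls(a)
    elif t is Bin or t is Cmp or t is BoolOp:
        yield from _calls(e.left)
        yield from _calls(e.right)
    elif t is Un:
        yield from _calls(e.operand)
    elif t is If:
        yield from _calls(e.cond)
        yield from _calls(e.then)
        yield from _calls(e.orelse)


# ---------------------------------------------------------------------------
# Serialization


def _format_pattern(pat: Pattern) -> str:
    s = pat.name
    if pat.attrs:
        s += "(" + ", ".join(format_expr(a) for a in pat.attrs) + ")"
    if pat.ident is not None:
        s += ":" + pat.ident
    if pat.content or pat.rest is not None:
        inner = [_format_pattern(p) for p in pat.content]
        if pat.rest is not None:
            inner.append(pat.rest + "?")
        s += "[" + " + ".join(inner) + "]"
    return s


def _format_product(prod: Product) -> str:
    if prod.restvar is not None:
        body = prod.restvar + "?"
    else:
        body = prod.name
        if prod.attrs:
            body += "(" + ", ".join(format_expr(a) for a in prod.attrs) + ")"
        if prod.content:
            body += ("[" + " + ".join(_format_product(p)
                                      for p in prod.content) + "]")
    if prod.amount == Lit(1):
        return body
    if isinstance(prod.amount, Lit):
        return f"{format_expr(prod.amount)} {body}"
    return f"({format_expr(prod.amount)}) {body}"


def _format_rule(rule: Rule) -> str:
    # group runs of identical reactant patterns back into counted form
    groups: list[tuple[Pattern, int]] = []
    for pat in rule.reactants:
        if groups and groups[-1][0] == pat:
            groups[-1] = (pat, groups[-1][1] + 1)
        else:
            groups.append((pat, 1))
    lhs = " + ".join(_format_pattern(p) if n == 1
                     else f"{n} {_format_pattern(p)}"
                     for p, n in groups) or "0"
    rhs = " + ".join(_format_product(p) for p in rule.products) or "0"
    if rule.nu:
        rhs = "nu(" + ", ".join(rule.nu) + ") " + rhs
    rate = rule.rate
    if (isinstance(rate, If) and rate.orelse == Lit(0)):
        rate_s = f"{format_expr(rate.then, 1)} if {format_expr(rate.cond)}"
    else:
        rate_s = format_expr(rate)
    return f"{lhs} -> {rhs} @ {rate_s};"


def serialize_model(model: Model) -> str:
    """Deterministic canonical text; round-trips through parse_model."""
    lines: list[str] = []
    for name, arity in model.definitions.items():
        lines.append(f"{name}({arity});" if arity else f"{name};")
    if model.definitions:
        lines.append("")
    for name, value in model.constants.items():
        lines.append(f"const {name} = {format_value(value)};")
    if model.constants:
        lines.append("")
    for fn in model.functions.values():
        lines.append(f"fun {fn.name}({', '.join(fn.params)}) = "
                     f"{format_expr(fn.body)};")
    if model.functions:
        lines.append("")
    for rule in model.rules:
        lines.append(_format_rule(rule))
    if model.rules:
        lines.append("")
    lines.append(f"init {format_solution(model.initial)};")
    return "\n".join(lines) + "\n"
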
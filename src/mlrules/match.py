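"""Rule-schema instantiation against a nested state.

A rule's top-level reactant patterns are matched *within a single
sub-solution* (the site); the same rule is tried at the root and inside
every nested sub-solution.  Because the state aggregates identical
species into populations, a single population-level match stands for
many individual-level ones: the propensity of a reaction instance is
the value of its rate expression multiplied by the amounts of all
populations strictly enclosing the match site (the context factor).
Reactant amounts themselves are *not* folded in automatically — mass
action is written explicitly through species identifiers (``k * a``).

Matching one sub-solution depends only on the rule and on that
sub-solution's canonical content, so local match results are cached per
``(rule, solution)``; a simulation step only pays for sub-solutions it
has never seen before.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .core import (Address, Fresh, Solution, Species, value_key,
                   values_equal, walk_addresses)
from .expr import (Env, EvalError, Name, compile_expr, evaluate,
                   free_names)
from .language import Model, Pattern, Product, Rule

__all__ = [
    "MatchEmbedding", "ReactionInstance", "Matcher",
    "match_reactants", "create_reactions", "calc_propensity",
    "ground_products", "context_factor",
]


class LocalMatch:
    """One way of embedding a rule's reactants into one sub-solution."""

    __slots__ = ("consumed", "bindings", "rate", "_gkey")

    def __init__(self, consumed: tuple[tuple[Species, int], ...],
                 bindings: dict, rate: float | int) -> None:
        self.consumed = consumed  # population -> copies removed
        self.bindings = bindings  # treat as immutable: shared by the cache
        self.rate = rate
        self._gkey: tuple | None = None  # computed on demand by the Matcher


@dataclass(frozen=True)
class MatchEmbedding:
    rule: Rule
    rule_index: int
    site: Address
    consumed: tuple[tuple[Species, int], ...]
    bindings: dict
    rate: float | int


@dataclass(frozen=True)
class ReactionInstance:
    """A grounded reaction: equivalent embeddings grouped at one site."""

    rule: Rule
    rule_index: int
    site: Address
    consumed: tuple[tuple[Species, int], ...]
    bindings: dict  # one representative binding (they ground identically)
    rate: float | int
    multiplicity: int
    propensity: float


def context_factor(state: Solution, site: Address) -> int:
    """Product of the amounts of all populations enclosing ``site``."""
    ctx = 1
    sol = state
    for step in site:
        n = sol.amount(step)
        if n < 1:
            raise ValueError(f"address step {step!r} not present")
        ctx *= n
        sol = step.content
    return ctx


# Deterministic placeholders standing in for nu values during grounding
# for grouping purposes; real Fresh values are drawn only when a rule fires.
def _nu_placeholders(rule: Rule) -> dict[str, Fresh]:
    return {nb: Fresh(-(i + 1)) for i, nb in enumerate(rule.nu)}


def ground_products(rule: Rule, bindings: dict, constants, functions
                    ) -> list[tuple[Species, int]]:
    """Evaluate the product templates under a completed binding.

    Rest-solution references pour out their bound solution's
    populations; bound solutions placed inside product species are
    reused as-is (deep copy is free on immutable solutions).
    """
    env = Env(bindings, constants, functions)
    out: list[tuple[Species, int]] = []

    def amount_of(prod: Product) -> int:
        v = evaluate(prod.amount, env)
        if isinstance(v, bool) or not isinstance(v, int):
            raise EvalError(f"product amount must be an integer, got {v!r}")
        if v < 0:
            raise EvalError(f"product amount is negative: {v}")
        return v

    def build(prod: Product) -> list[tuple[Species, int]]:
        n = amount_of(prod)
        if n == 0:
            return []
        if prod.restvar is not None:
            sol = env.lookup(prod.restvar)
            if not isinstance(sol, Solution):
                raise EvalError(
                    f"'{prod.restvar}?' is not bound to a solution")
            return [(sp, n * k) for sp, k in sol]
        attrs = []
        for ae in prod.attrs:
            v = evaluate(ae, env)
            if isinstance(v, Solution):
                raise EvalError("a solution cannot be an attribute value")
            attrs.append(v)
        pops: list[tuple[Species, int]] = []
        for sub in prod.content:
            pops.extend(build(sub))
        return [(Species(prod.name, attrs, Solution(pops)), n)]

    for prod in rule.products:
        out.extend(build(prod))
    return out


def _products_key(grounded: list[tuple[Species, int]]) -> tuple:
    return tuple(sorted((sp.token, n) for sp, n in grounded))


class Matcher:
    """Per-model matching engine with a local-match cache."""

    def __init__(self, model: Model, cache_limit: int = 50_000) -> None:
        self.model = model
        self.constants = model.constants
        self.functions = model.functions
        self.rules = model.rules
        self.cache_limit = cache_limit
        self._cache: dict[tuple[int, Solution], tuple[LocalMatch, ...]] = {}
        self._site_cache: dict[Solution, tuple[float, tuple]] = {}
        self._index_cache: dict[Solution, dict[str, list[int]]] = {}
        self._single_cache: dict[tuple, tuple[LocalMatch, ...]] = {}
        self._pop_cache: dict[tuple, tuple[float, tuple]] = {}
        self._subtree_cache: dict[Species, float] = {}
        self._compiled: dict[Pattern, tuple] = {}
        self._content_same: dict[Pattern, tuple] = {}
        # single-reactant rules indexed by reactant name; the rest
        # (zero- or multi-reactant) are matched per whole sub-solution
        self._single_by_name: dict[str, list[tuple[int, Pattern]]] = {}
        self._multi_rules: list[int] = []
        for ri, r in enumerate(self.rules):
            if len(r.reactants) == 1:
                self._single_by_name.setdefault(
                    r.reactants[0].name, []).append((ri, r.reactants[0]))
            else:
                self._multi_rules.append(ri)
        self._rate_fns = [compile_expr(r.rate, self.constants, self.functions)
                          for r in self.rules]
        # per-rule: do any two reactant patterns compare equal (symmetry dedup)
        self._same_as_prev = [
            tuple(i > 0 and r.reactants[i] == r.reactants[i - 1]
                  for i in range(len(r.reactants)))
            for r in self.rules
        ]

    # -- local matching -----------------------------------------------------

    def local_matches(self, rule_index: int,
                      sol: Solution) -> tuple[LocalMatch, ...]:
        key = (rule_index, sol)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        result = tuple(self._compute_local(rule_index, sol))
        if len(self._cache) >= self.cache_limit:
            self._cache.clear()
        self._cache[key] = result
        return result

    def population_matches(self, sp: Species,
                           n: int) -> tuple[float, tuple]:
        """Positive-rate matches of all single-reactant rules against one
        population, with their summed rate (cached per population)."""
        key = (sp, n)
        hit = self._pop_cache.get(key)
        if hit is not None:
            return hit
        local: list[tuple[int, LocalMatch]] = []
        total = 0.0
        for ri, pat in self._single_by_name.get(sp.name, ()):
            for lm in self._single_matches(ri, pat, sp, n):
                if lm.rate > 0:
                    local.append((ri, lm))
                    total += lm.rate
        result = (total, tuple(local))
        if len(self._pop_cache) >= self.cache_limit:
            self._pop_cache.clear()
        self._pop_cache[key] = result
        return result

    def site_matches(self, sol: Solution) -> tuple[float, tuple]:
        """All positive-rate local matches of all rules in one sub-solution.

        Returns ``(total_rate, blocks)`` where each block is a
        ``(block_rate, ((rule_index, LocalMatch), ...))`` pair; the
        block substructure lets the simulator reuse per-population
        caches without flattening.  Cached per sub-solution; on a cache
        miss only single-reactant rules against *new* populations and
        multi-reactant rules are actually recomputed.
        """
        hit = self._site_cache.get(sol)
        if hit is not None:
            return hit
        blocks: list[tuple[float, tuple]] = []
        total = 0.0
        for sp, n in sol.items:
            btotal, bmatches = self.population_matches(sp, n)
            if bmatches:
                blocks.append((btotal, bmatches))
                total += btotal
        local: list[tuple[int, LocalMatch]] = []
        btotal = 0.0
        for ri in self._multi_rules:
            for lm in self.local_matches(ri, sol):
                if lm.rate > 0:
                    local.append((ri, lm))
                    btotal += lm.rate
        if local:
            blocks.append((btotal, tuple(local)))
            total += btotal
        result = (total, tuple(blocks))
        if len(self._site_cache) >= self.cache_limit:
            self._site_cache.clear()
        self._site_cache[sol] = result
        return result

    def subtree_rate(self, sp: Species) -> float:
        """Total local-match rate of everything nested inside one copy of
        ``sp``: the rate of its content site plus the amount-weighted
        subtree rates of its content species.  Cached per species, so a
        simulation step touches only the spine that actually changed."""
        r = self._subtree_cache.get(sp)
        if r is None:
            r, _blocks = self.site_matches(sp.content)
            for child, n in sp.content.items:
                if child.has_content:
                    r += n * self.subtree_rate(child)
            if len(self._subtree_cache) >= self.cache_limit:
                self._subtree_cache.clear()
            self._subtree_cache[sp] = r
        return r

    def _name_index(self, sol: Solution) -> dict[str, list[int]]:
        idx = self._index_cache.get(sol)
        if idx is None:
            idx = {}
            for j, (sp, _n) in enumerate(sol.items):
                idx.setdefault(sp.name, []).append(j)
            if len(self._index_cache) >= self.cache_limit:
                self._index_cache.clear()
            self._index_cache[sol] = idx
        return idx

    def _compute_local(self, rule_index: int,
                       sol: Solution) -> Iterator[LocalMatch]:
        rule = self.rules[rule_index]
        same_as_prev = self._same_as_prev[rule_index]
        items = sol.items
        npat = len(rule.reactants)
        if npat == 1:
            # single-reactant rules: one population at a time, and the
            # result per population is context-free, hence memoizable
            pat = rule.reactants[0]
            out1: list[LocalMatch] = []
            for j in self._name_index(sol).get(pat.name, ()):
                sp, n = items[j]
                out1.extend(self._single_matches(rule_index, pat, sp, n))
            return iter(out1)
        # NOTE: recursion goes through bound methods, not nested closures;
        # recursive closures form reference cycles, which matters because
        # simulation loops run with the cyclic collector paused.
        out: list[LocalMatch] = []
        self._assign(rule_index, rule, items, self._name_index(sol),
                     same_as_prev, 0, 0, {}, {}, out)
        return iter(out)

    def _assign(self, rule_index: int, rule: Rule, items, name_index,
                same_as_prev, i: int, start: int,
                used: dict[Species, int], bindings: dict,
                out: list[LocalMatch]) -> None:
        if i == len(rule.reactants):
            out.append(self._make_match(
                rule_index, rule,
                tuple(sorted(used.items(), key=lambda kv: kv[0].token)),
                bindings))
            return
        pat = rule.reactants[i]
        lo = start if same_as_prev[i] else 0
        for j in name_index.get(pat.name, ()):
            if j < lo:
                continue
            sp, n = items[j]
            taken = used.get(sp, 0)
            if n - taken < 1:
                continue
            for nb in self._match_species(pat, sp, n, bindings):
                used[sp] = taken + 1
                self._assign(rule_index, rule, items, name_index,
                             same_as_prev, i + 1, j, used, nb, out)
                if taken:
                    used[sp] = taken
                else:
                    del used[sp]

    def _make_match(self, rule_index: int, rule: Rule, consumed: tuple,
                    bindings: dict) -> LocalMatch:
        if rule.nu:
            full = dict(bindings)
            full.update(_nu_placeholders(rule))
        else:
            full = bindings
        try:
            rate = self._rate_fns[rule_index](full)
        except (EvalError, TypeError, KeyError, ZeroDivisionError) as exc:
            raise EvalError(f"rate of rule [{rule}]: {exc}") from None
        if rate is True or rate is False or not isinstance(rate, (int, float)):
            raise EvalError(f"rate of rule [{rule}]: not a number: {rate!r}")
        if rate < 0:
            raise EvalError(f"rate of rule [{rule}]: negative value {rate!r}")
        return LocalMatch(consumed, full, rate)

    def _single_matches(self, rule_index: int, pat: Pattern, sp: Species,
                        amount: int) -> tuple[LocalMatch, ...]:
        """All matches of a one-reactant rule against one population."""
        rule = self.rules[rule_index]
        key = ((rule_index, sp, amount) if pat.ident is not None
               else (rule_index, sp))
        hit = self._single_cache.get(key)
        if hit is not None:
            return hit
        res = [self._make_match(rule_index, rule, ((sp, 1),), b)
               for b in self._match_species(pat, sp, amount, {})]
        hit = tuple(res)
        if len(self._single_cache) >= self.cache_limit:
            self._single_cache.clear()
        self._single_cache[key] = hit
        return hit

    def _compiled_attrs(self, pat: Pattern) -> tuple:
        """Per-position attribute matchers: bind / literal / expression."""
        comp = self._compiled.get(pat)
        if comp is not None:
            return comp
        entries = []
        for ap in pat.attrs:
            if isinstance(ap, Name) and ap.ident not in self.constants:
                entries.append(("bind", ap.ident))
            else:
                names = tuple(free_names(ap) - set(self.constants))
                if not names:
                    try:
                        val = evaluate(ap, Env({}, self.constants,
                                               self.functions))
                        entries.append(("lit", value_key(val)))
                        continue
                    except EvalError:
                        pass
                entries.append(("expr",
                                compile_expr(ap, self.constants,
                                             self.functions), names))
        comp = tuple(entries)
        self._compiled[pat] = comp
        return comp

    def _match_species(self, pat: Pattern, sp: Species, amount: int,
                       bindings: dict) -> Iterator[dict]:
        """Yield extended bindings for matching ``pat`` against one
        population (species ``sp`` with the given amount)."""
        b = bindings
        copied = False
        for entry, val in zip(self._compiled_attrs(pat), sp.attrs):
            tag = entry[0]
            if tag == "bind":
                ident = entry[1]
                bound = b.get(ident, _MISSING)
                if bound is _MISSING:
                    if not copied:
                        b = dict(b)
                        copied = True
                    b[ident] = val
                elif isinstance(bound, Solution) or not values_equal(bound, val):
                    return
            elif tag == "lit":
                if entry[1] != value_key(val):
                    return
            else:
                fn, names = entry[1], entry[2]
                for nm in names:
                    if nm not in b:
                        return  # unbound: this pattern cannot decide yet
                try:
                    want = fn(b)
                except (EvalError, TypeError, KeyError, ZeroDivisionError):
                    return
                if isinstance(want, Solution) or not values_equal(want, val):
                    return
        if pat.ident is not None:
            bound = b.get(pat.ident, _MISSING)
            if bound is _MISSING:
                if not copied:
                    b = dict(b)
                    copied = True
                b[pat.ident] = amount
            elif bound != amount or isinstance(bound, bool):
                return
        if not pat.content and pat.rest is None:
            yield b
            return
        yield from self._match_content(pat, sp.content, b)

    def _match_content(self, pat: Pattern, content: Solution,
                       bindings: dict) -> Iterator[dict]:
        same = self._content_same.get(pat)
        if same is None:
            same = tuple(i > 0 and pat.content[i] == pat.content[i - 1]
                         for i in range(len(pat.content)))
            self._content_same[pat] = same
        yield from self._content_assign(pat, content, same, 0, 0, {},
                                        bindings)

    def _content_assign(self, pat: Pattern, content: Solution, same,
                        i: int, start: int, used: dict[Species, int],
                        b: dict) -> Iterator[dict]:
        pats = pat.content
        if i == len(pats):
            if pat.rest is not None:
                rest = content.minus(used)
                bound = b.get(pat.rest, _MISSING)
                if bound is not _MISSING:
                    if bound != rest:
                        return
                    yield b
                else:
                    b2 = dict(b)
                    b2[pat.rest] = rest
                    yield b2
            else:
                yield b
            return
        sub = pats[i]
        items = content.items
        lo = start if same[i] else 0
        for j in range(lo, len(items)):
            sp, n = items[j]
            if sp.name != sub.name:
                continue
            taken = used.get(sp, 0)
            if n - taken < 1:
                continue
            for nb in self._match_species(sub, sp, n, b):
                used[sp] = taken + 1
                yield from self._content_assign(pat, content, same, i + 1,
                                                j, used, nb)
                if taken:
                    used[sp] = taken
                else:
                    del used[sp]

    # -- whole-state matching ----------------------------------------------

    def embeddings(self, state: Solution,
                   rule_index: int) -> list[MatchEmbedding]:
        rule = self.rules[rule_index]
        out: list[MatchEmbedding] = []
        for addr, _ctx, sol in walk_addresses(state):
            for lm in self.local_matches(rule_index, sol):
                out.append(MatchEmbedding(rule, rule_index, addr,
                                          lm.consumed, lm.bindings, lm.rate))
        return out

    def reactions(self, state: Solution) -> list[ReactionInstance]:
        """All grounded reaction instances with positive propensity."""
        out: list[ReactionInstance] = []
        for addr, ctx, sol in walk_addresses(state):
            for ri in range(len(self.rules)):
                out.extend(self._group_site(ri, addr, ctx, sol))
        return out

    def group_key(self, rule_index: int, lm: LocalMatch) -> tuple:
        """Equivalence key of a local match: grounded reactants, grounded
        products (nu binders as placeholders) and rate value."""
        if lm._gkey is None:
            grounded = ground_products(self.rules[rule_index], lm.bindings,
                                       self.constants, self.functions)
            lm._gkey = (tuple((sp.token, n) for sp, n in lm.consumed),
                        _products_key(grounded), lm.rate)
        return lm._gkey

    def _group_site(self, rule_index: int, addr: Address, ctx: int,
                    sol: Solution) -> Iterator[ReactionInstance]:
        groups: dict[tuple, list[LocalMatch]] = {}
        for lm in self.local_matches(rule_index, sol):
            if lm.rate <= 0:
                continue
            groups.setdefault(self.group_key(rule_index, lm), []).append(lm)
        for members in groups.values():
            first = members[0]
            mult = len(members)
            yield ReactionInstance(
                self.rules[rule_index], rule_index, addr, first.consumed,
                first.bindings, first.rate, mult,
                float(first.rate) * mult * ctx)


_MISSING = object()


# ---------------------------------------------------------------------------
# Functional API


def match_reactants(rule: Rule, state: Solution,
                    model: Model | None = None) -> list[MatchEmbedding]:
    """All embeddings of ``rule`` at the root and in every sub-solution."""
    matcher = _matcher_for(rule, model)
    return matcher.embeddings(state, _rule_index(matcher, rule))


def create_reactions(rule: Rule, embeddings: list[MatchEmbedding],
                     state: Solution,
                     model: Model | None = None) -> list[ReactionInstance]:
    """Group equivalent embeddings into reaction instances.

    Embeddings producing identical grounded reactions (same site, same
    grounded reactants, products and rate value) merge into one
    instance whose propensity sums their weights; zero-rate matches are
    dropped.
    """
    matcher = _matcher_for(rule, model)
    groups: dict[tuple, list[MatchEmbedding]] = {}
    for emb in embeddings:
        if emb.rate <= 0:
            continue
        full = dict(emb.bindings)
        full.update(_nu_placeholders(rule))
        grounded = ground_products(rule, full, matcher.constants,
                                   matcher.functions)
        key = (emb.site, tuple((sp.token, n) for sp, n in emb.consumed),
               _products_key(grounded), emb.rate)
        groups.setdefault(key, []).append(emb)
    out = []
    for members in groups.values():
        first = members[0]
        mult = len(members)
        ctx = context_factor(state, first.site)
        out.append(ReactionInstance(
            first.rule, first.rule_index, first.site, first.consumed,
            first.bindings, first.rate, mult, float(first.rate) * mult * ctx))
    return out


def calc_propensity(instance: ReactionInstance, state: Solution) -> float:
    """Rate value x multiplicity x product of enclosing amounts."""
    return (float(instance.rate) * instance.multiplicity
            * context_factor(state, instance.site))


def _matcher_for(rule: Rule, model: Model | None) -> Matcher:
    if model is None:
        model = Model(rules=(rule,))
    elif rule not in model.rules:
        model = Model(model.definitions, model.constants, model.functions,
                      model.rules + (rule,), model.initial)
    return Matcher(model)


def _rule_index(matcher: Matcher, rule: Rule) -> int:
    return matcher.rules.index(rule)
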
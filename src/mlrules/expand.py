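"""Expansion of a flat rule-schema model into an explicit reaction network.

A rule schema with attribute variables stands for many concrete
reactions.  When the reachable attribute space is finite, the schema
model can be unfolded into a flat network: starting from the species of
the initial solution, every rule is instantiated against all known
species, product species are added, and the process repeats until a
fixed point.  The classic motivation is combinatorial binding: a
scaffold protein with ``n`` independent binding sites needs ``2^n + n``
species and ``2 n 2^(n-1)`` uni-directional reactions when written out
flat, but only ``n + 1`` species definitions and ``2 n`` rule schemata.

Rates in the expanded network are the rule's rate expression evaluated
with every species identifier set to 1 — i.e. the per-configuration
mass-action constant, not a state-dependent propensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .core import Solution, Species
from .expr import Env, EvalError, evaluate
from .language import Model, parse_model
from .match import Matcher, ground_products

__all__ = ["FlatNetwork", "ExpansionError", "expand_network",
           "scaffold_model", "scaffold_text"]

Reaction = tuple[tuple[tuple[Species, int], ...],
                 tuple[tuple[Species, int], ...],
                 float]


class ExpansionError(Exception):
    pass


@dataclass
class FlatNetwork:
    """Explicit species list + reaction list (no variables, no nesting)."""

    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def summary(self) -> str:
        return (f"species: {len(self.species)}, "
                f"reactions: {len(self.reactions)}")

    def format_reactions(self) -> str:
        def side(pops):
            if not pops:
                return "0"
            return " + ".join(f"{n} {sp!r}" if n != 1 else repr(sp)
                              for sp, n in pops)

        lines = [f"{side(r)} -> {side(p)} @ {rate:g}"
                 for r, p, rate in self.reactions]
        return "\n".join(lines)


def _check_flat(model: Model) -> None:
    for sp in model.initial.species():
        if len(sp.content):
            raise ExpansionError("expansion requires a flat model; the "
                                 f"initial solution nests {sp!r}")
    for i, rule in enumerate(model.rules):
        if rule.nu:
            raise ExpansionError(f"rule {i + 1} uses the nu-operator; its "
                                 "expansion is unbounded")
        for pat in rule.reactants:
            if pat.content or pat.rest is not None:
                raise ExpansionError(f"rule {i + 1} has nested reactants; "
                                     "only flat models can be expanded")
        for prod in rule.products:
            if prod.restvar is not None or prod.content:
                raise ExpansionError(f"rule {i + 1} has nested products; "
                                     "only flat models can be expanded")


def expand_network(model: Model,
                   domains: Optional[Mapping[str, Sequence[frozenset]]] = None,
                   max_species: int = 10 ** 6) -> FlatNetwork:
    """Fixed-point closure of a flat schema model over its reachable species.

    ``domains`` optionally restricts attribute values per species name
    (one set per attribute position); a product outside its domain
    aborts with :class:`ExpansionError`.  ``max_species`` guards against
    non-terminating closures, naming the rule applied last.
    """
    _check_flat(model)
    matcher = Matcher(model)
    idents = [tuple(p.ident for p in rule.reactants if p.ident is not None)
              for rule in model.rules]

    def check_domain(sp: Species, rule_no: int) -> None:
        if domains is None:
            return
        dom = domains.get(sp.name)
        if dom is None:
            return
        for pos, (val, allowed) in enumerate(zip(sp.attrs, dom)):
            if val not in allowed:
                raise ExpansionError(
                    f"rule {rule_no} produced {sp!r} with attribute "
                    f"{val!r} outside its domain (position {pos + 1})")

    known: dict[Species, None] = {}  # insertion-ordered set
    for sp in model.initial.species():
        known[Species(sp.name, sp.attrs)] = None
    reactions: dict[tuple, Reaction] = {}

    # enough copies of everything that multi-copy reactant patterns match
    depth = max((len(r.reactants) for r in model.rules), default=1)
    amount = max(2, depth)

    seen: set[tuple] = set()  # (rule, consumed): products are determined
    changed = True
    while changed:
        changed = False
        universe = Solution({sp: amount for sp in known})
        for ri, rule in enumerate(model.rules):
            for lm in matcher.local_matches(ri, universe):
                skey = (ri, tuple((sp.token, n) for sp, n in lm.consumed))
                if skey in seen:
                    continue
                seen.add(skey)
                # unit-amount rate: identifiers re-bound to 1
                bindings = dict(lm.bindings)
                for ident in idents[ri]:
                    bindings[ident] = 1
                env = Env(bindings, model.constants, model.functions)
                try:
                    rate = evaluate(rule.rate, env)
                except EvalError as exc:
                    raise ExpansionError(
                        f"rule {ri + 1}: rate evaluation failed: {exc}"
                        ) from None
                if not isinstance(rate, (int, float)) or isinstance(rate, bool):
                    raise ExpansionError(f"rule {ri + 1}: rate is not a "
                                         f"number: {rate!r}")
                if rate <= 0:
                    continue
                products = ground_products(rule, bindings, model.constants,
                                           model.functions)
                consumed = lm.consumed
                key = (tuple((sp.token, n) for sp, n in consumed),
                       tuple(sorted((sp.token, n) for sp, n in products)),
                       rate)
                if key not in reactions:
                    reactions[key] = (consumed,
                                      tuple(sorted(products,
                                                   key=lambda t: t[0].token)),
                                      float(rate))
                    changed = True
                for sp, _n in products:
                    flat = Species(sp.name, sp.attrs)
                    if flat not in known:
                        check_domain(flat, ri + 1)
                        known[flat] = None
                        changed = True
                        if len(known) > max_species:
                            raise ExpansionError(
                                f"expansion exceeded {max_species} species "
                                f"(last rule applied: {ri + 1})")

    net = FlatNetwork(sorted(known, key=lambda s: s.token),
                      sorted(reactions.values(),
                             key=lambda r: (tuple((sp.token, n)
                                                  for sp, n in r[0]),
                                            tuple((sp.token, n)
                                                  for sp, n in r[1]),
                                            r[2])))
    return net


def scaffold_text(n: int, kon: float = 1.0, koff: float = 1.0) -> str:
    """Model text for a scaffold protein with ``n`` independent binding sites.

    One scaffold species ``S`` of arity ``n`` (each attribute is ``F``
    for a free site or ``B`` for a bound one), ``n`` partner proteins
    ``P1..Pn``, and ``2 n`` uni-directional rules (n bind + n unbind),
    each independent of the state of all other sites.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lines = [f"S({n});"]
    lines += [f"P{i};" for i in range(1, n + 1)]
    lines.append(f"const kon = {kon!r};")
    lines.append(f"const koff = {koff!r};")
    for i in range(1, n + 1):
        before = ", ".join("F" if j == i else f"a{j}"
                           for j in range(1, n + 1))
        after = ", ".join("B" if j == i else f"a{j}"
                          for j in range(1, n + 1))
        lines.append(f"S({before}):s + P{i}:p -> S({after}) "
                     f"@ kon * s * p;")
        lines.append(f"S({after}):s -> S({before}) + P{i} @ koff * s;")
    init = "S(" + ", ".join(["F"] * n) + ") + " + \
        " + ".join(f"P{i}" for i in range(1, n + 1))
    lines.append(f"init {init};")
    return "\n".join(lines) + "\n"


def scaffold_model(n: int, kon: float = 1.0, koff: float = 1.0) -> Model:
    """Parsed scaffold model (the text form exercises the parser)."""
    return parse_model(scaffold_text(n, kon, koff))
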
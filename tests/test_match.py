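"""Rule instantiation, grouping, and hierarchy-dependent propensities."""

import itertools

import pytest

from mlrules.core import Solution, Species
from mlrules.expr import Env, EvalError, evaluate
from mlrules.language import Model, parse_model
from mlrules.match import (Matcher, calc_propensity, create_reactions,
                           match_reactants)


def reactions_of(model, rule_index=0, state=None):
    state = state if state is not None else model.initial
    rule = model.rules[rule_index]
    embs = match_reactants(rule, state, model)
    return create_reactions(rule, embs, state, model)


class TestInstantiation:
    def test_attribute_variable_groups(self):
        model = parse_model("A(1); B;\nA(x) -> B @ 1;\ninit 2 A(1) + 4 A(2);")
        embs = match_reactants(model.rules[0], model.initial, model)
        assert sorted(e.bindings["x"] for e in embs) == [1, 2]

    def test_mass_action_identifier_propensities(self):
        model = parse_model(
            "A(1); B;\nconst k = 3;\nA(x):a -> B @ k * a;\n"
            "init 2 A(1) + 4 A(2);")
        props = sorted(r.propensity for r in reactions_of(model))
        assert props == [6.0, 12.0]

    def test_expression_pattern_requires_consistent_binding(self):
        # A(x) + A(2x): only x = 1 works over [A(1) + A(2) + B(3)]
        model = parse_model(
            "A(1); B(1); C;\nA(x) + A(2 * x) -> C @ 1;\n"
            "init A(1) + A(2) + B(3);")
        embs = match_reactants(model.rules[0], model.initial, model)
        assert len(embs) == 1 and embs[0].bindings["x"] == 1
        # and no match over [A(3) + A(5)]
        model2 = parse_model(
            "A(1); C;\nA(x) + A(2 * x) -> C @ 1;\ninit A(3) + A(5);")
        assert match_reactants(model2.rules[0], model2.initial, model2) == []

    def test_empty_state_matches_nothing(self):
        model = parse_model("A(1); B;\nA(x) -> B @ 1;\ninit 0;")
        assert match_reactants(model.rules[0], model.initial, model) == []

    def test_nested_pattern_ignores_extra_content(self):
        # A(0)[Cx] matches an A(0) whose content holds Cx plus anything else
        model = parse_model(
            "A(1); Cx; D; E;\nA(0)[Cx] -> A(1)[Cx] @ 1;\n"
            "init A(0)[Cx + 2 D[E]];")
        embs = match_reactants(model.rules[0], model.initial, model)
        assert len(embs) == 1

    def test_two_copies_need_amount_two(self):
        model = parse_model("A; B;\n2 A -> B @ 1;\ninit A;")
        assert match_reactants(model.rules[0], model.initial, model) == []
        model2 = parse_model("A; B;\n2 A -> B @ 1;\ninit 2 A;")
        assert len(match_reactants(model2.rules[0], model2.initial,
                                   model2)) == 1

    def test_zero_rate_instances_dropped(self):
        model = parse_model(
            "A(1); B;\nA(x):a -> B @ a if a > 10;\ninit 2 A(1);")
        assert reactions_of(model) == []

    def test_grouping_merges_symmetric_embeddings(self):
        # A(x) + A(y) -> B with a binding-independent grounded reaction:
        # the two symmetric embeddings collapse into one instance of
        # multiplicity 2 with summed weight
        model = parse_model(
            "A(1); B;\nA(x) + A(y) -> B @ 2;\ninit A(1) + A(2);")
        rxns = reactions_of(model)
        assert len(rxns) == 1
        assert rxns[0].multiplicity == 2 and rxns[0].propensity == 4.0

    def test_group_then_expand_matches_raw_embeddings(self, rng):
        model = parse_model(
            "A(1); B;\nA(x) + A(y) -> B @ 1;\n"
            "init A(1) + A(2) + 2 A(3);")
        rule = model.rules[0]
        embs = match_reactants(rule, model.initial, model)
        rxns = create_reactions(rule, embs, model.initial, model)
        assert sum(r.multiplicity for r in rxns) == len(embs)


class TestContextPropensity:
    def test_hierarchy_worked_example(self):
        """Two reactants of amount 2 inside a singleton species that sits
        in an outer population of amount 2: propensity 2*2*1*2 = 8."""
        model = parse_model(
            "Outer; Mid; X; Y; Z;\nX:a + Y:b -> Z @ a * b;\n"
            "init 2 Outer[Mid[2 X + 2 Y]];")
        rxns = reactions_of(model)
        assert len(rxns) == 1
        assert rxns[0].propensity == 8.0
        assert calc_propensity(rxns[0], model.initial) == 8.0

    def test_root_match_has_unit_context(self):
        model = parse_model("X; Y; Z;\nX:a + Y:b -> Z @ a * b;\n"
                            "init 2 X + 2 Y;")
        rxns = reactions_of(model)
        assert rxns[0].propensity == 4.0

    def test_doubling_root_amounts_doubles_context(self):
        text = "Outer; X; Z;\nX:a -> Z @ a;\ninit {n} Outer[3 X];"
        one = parse_model(text.format(n=1))
        two = parse_model(text.format(n=2))
        p1 = sum(r.propensity for r in reactions_of(one))
        p2 = sum(r.propensity for r in reactions_of(two))
        assert p2 == 2 * p1

    def test_match_output_is_order_independent(self):
        # the same multiset built in different insertion orders gives the
        # same canonical state, hence identical reactions
        model = parse_model(
            "A(1); B;\nA(x):a -> B @ a;\ninit 2 A(2) + 3 A(1);")
        swapped = Solution([(Species("A", (1,)), 3), (Species("A", (2,)), 2)])
        assert swapped == model.initial
        a = [(r.rate, r.propensity) for r in reactions_of(model)]
        b = [(r.rate, r.propensity)
             for r in reactions_of(model, state=swapped)]
        assert a == b


# ---------------------------------------------------------------------------
# Brute-force completeness oracle: expand all *enclosing* populations to
# individuals, enumerate pattern assignments exhaustively, and compare
# total propensity per grounded reaction with the engine's instances.


def oracle_reactions(model: Model, rule_index: int):
    """Independent enumeration of grounded reactions with propensities.

    Context factors are realized by literally multiplying out enclosing
    populations (an amount-n species is n individual sites); within a
    site, assignments of patterns to populations are enumerated with
    itertools over all ordered tuples and deduplicated by grounded
    reaction, mirroring population-level (not individual-level)
    reactant semantics.
    """
    from mlrules.match import ground_products, _nu_placeholders

    rule = model.rules[rule_index]
    matcher = Matcher(model)
    out: dict[tuple, float] = {}

    def sites(sol, mult):
        yield sol, mult
        for sp, n in sol:
            if len(sp.content):
                yield from sites(sp.content, mult * n)

    for sol, mult in sites(model.initial, 1):
        pops = list(sol)
        for combo in itertools.product(range(len(pops)),
                                       repeat=len(rule.reactants)):
            used: dict = {}
            ok = True
            for pat, idx in zip(rule.reactants, combo):
                sp, n = pops[idx]
                used[sp] = used.get(sp, 0) + 1
                if sp.name != pat.name or used[sp] > n:
                    ok = False
                    break
            if not ok:
                continue
            # bind left to right
            bindings: dict = {}
            for pat, idx in zip(rule.reactants, combo):
                sp, n = pops[idx]
                got = list(matcher._match_species(pat, sp, n, bindings))
                if not got:
                    ok = False
                    break
                assert len(got) == 1, "oracle limited to unambiguous content"
                bindings = got[0]
            if not ok:
                continue
            full = dict(bindings)
            full.update(_nu_placeholders(rule))
            try:
                rate = evaluate(rule.rate, Env(full, model.constants,
                                               model.functions))
            except EvalError:
                continue
            if not rate:
                continue
            grounded = ground_products(rule, full, model.constants,
                                       model.functions)
            key = (tuple(sorted((sp.token, k) for sp, k in used.items())),
                   tuple(sorted((sp.token, k) for sp, k in grounded)),
                   rate, sol.key)
            out[key] = out.get(key, 0.0) + rate * mult / _symmetry(
                rule, combo)
        # NOTE: duplicate pattern order permutations are handled by
        # dividing by the number of identical-pattern permutations that
        # map the combo to itself-equivalent assignments
    return out


def _symmetry(rule, combo):
    """Ordered assignments per engine embedding.

    The engine enumerates one embedding per *multiset* of population
    choices for a run of identical patterns, while the oracle's product
    loop enumerates ordered tuples; each engine embedding therefore
    corresponds to multinomial(k; c_1, c_2, ...) ordered tuples, where k
    identical patterns hit populations with multiplicities c_v.
    """
    import math
    from collections import Counter
    groups: dict = {}
    for pat, idx in zip(rule.reactants, combo):
        groups.setdefault(pat, []).append(idx)
    total = 1
    for idxs in groups.values():
        counts = Counter(idxs)
        total *= math.factorial(len(idxs)) // math.prod(
            math.factorial(v) for v in counts.values())
    return total


def engine_reactions(model: Model, rule_index: int):
    rule = model.rules[rule_index]
    embs = match_reactants(rule, model.initial, model)
    rxns = create_reactions(rule, embs, model.initial, model)
    out = {}
    for r in rxns:
        from mlrules.match import ground_products, _nu_placeholders
        full = dict(r.bindings)
        sol = model.initial
        for step in r.site:
            sol = step.content
        grounded = ground_products(rule, full, model.constants,
                                   model.functions)
        key = (tuple(sorted((sp.token, k) for sp, k in r.consumed)),
               tuple(sorted((sp.token, k) for sp, k in grounded)),
               r.rate, sol.key)
        out[key] = out.get(key, 0.0) + r.propensity
    return out


class TestCompletenessOracle:
    @pytest.mark.parametrize("text,rule_index", [
        ("A(1); B;\nA(x):a -> B @ a;\n"
         "init 2 A(1) + 3 A(2) + A(3);", 0),
        ("O; A(1); B;\nA(x) -> B @ 2;\n"
         "init 2 O[3 A(1) + A(2)] + A(1);", 0),
        ("O; P; A(1); B(1);\nA(x):a -> B(x) @ a;\n"
         "init 2 O[2 P[2 A(5)] + A(4)] + 3 P[A(6)];", 0),
        ("A(1); B;\nA(x) + A(y) -> B @ 3;\ninit 2 A(1) + 2 A(2);", 0),
        ("O; X; Y; Z;\nX:a + Y:b -> Z @ a * b;\n"
         "init 2 O[O[2 X + 2 Y]] + X + Y;", 0),
    ])
    def test_engine_matches_exhaustive_enumeration(self, text, rule_index):
        model = parse_model(text)
        assert model.initial is not None
        eng = engine_reactions(model, rule_index)
        orc = oracle_reactions(model, rule_index)
        assert set(eng) == set(orc)
        for key in eng:
            assert eng[key] == pytest.approx(orc[key]), key
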
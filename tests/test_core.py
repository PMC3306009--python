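"""Canonical nested-multiset semantics: equality, split/merge, conservation."""

import random

import pytest

from mlrules.core import (AddressError, AmountError, Solution, Species,
                          apply_at, flatten_counts, format_solution,
                          insert_species, remove_species, walk_addresses)
from conftest import random_solution, random_species


def S(*pops):
    return Solution(list(pops))


A = lambda sol=None: Species("A", (), sol)
B = Species("B")
C = Species("C", (1,))


class TestCanonicalEquality:
    def test_empty_content_is_atomic(self):
        assert Species("A", (), Solution()) == Species("A")
        assert hash(Species("A", (), Solution())) == hash(Species("A"))

    def test_multiset_order_independence(self):
        left = Species("A", (), S((B, 2), (C, 1)))
        right = Species("A", (), S((C, 1), (B, 2)))
        assert left == right and left.key == right.key

    def test_type_tagged_attribute_identity(self):
        # 1, 1.0 and True are three distinct species
        keys = {Species("C", (1,)), Species("C", (1.0,)),
                Species("C", (True,))}
        assert len(keys) == 3

    def test_insertion_order_never_matters(self, rng):
        for _ in range(50):
            pops = [(random_species(rng, 2), rng.randint(1, 3))
                    for _ in range(5)]
            shuffled = pops[:]
            rng.shuffle(shuffled)
            assert Solution(pops) == Solution(shuffled)

    def test_key_equality_matches_structural_equality(self, rng):
        """Brute-force structural comparison agrees with canonical keys."""

        def structurally_equal(x: Species, y: Species) -> bool:
            if x.name != y.name or len(x.attrs) != len(y.attrs):
                return False
            from mlrules.core import values_equal
            if any(not values_equal(a, b)
                   for a, b in zip(x.attrs, y.attrs)):
                return False
            xi, yi = list(x.content), list(y.content)
            if len(xi) != len(yi):
                return False
            used = [False] * len(yi)
            for sp, n in xi:
                for j, (tp, m) in enumerate(yi):
                    if not used[j] and n == m and structurally_equal(sp, tp):
                        used[j] = True
                        break
                else:
                    return False
            return True

        species = [random_species(rng, 2) for _ in range(300)]
        for _ in range(1000):
            x, y = rng.choice(species), rng.choice(species)
            assert (x.key == y.key) == structurally_equal(x, y)


class TestSplitMerge:
    def test_removal_splits_and_merges_populations(self):
        # 2 A[2B] + 2 A[3B], take one B out of an A[3B]
        a2, a3 = A(S((B, 2))), A(S((B, 3)))
        state = S((a2, 2), (a3, 2))
        result = remove_species(state, (a3,), B, 1)
        assert result == S((a2, 3), (a3, 1))
        assert format_solution(result) == "3 A[2 B] + A[3 B]"

    def test_removal_to_empty_content_gives_atomic(self):
        state = S((A(S((B, 1))), 1))
        result = remove_species(state, (A(S((B, 1))),), B, 1)
        assert result == S((A(), 1))
        assert next(result.species()).is_atomic()

    def test_insert_is_dual_of_remove(self):
        a2, a3 = A(S((B, 2))), A(S((B, 3)))
        state = S((a2, 3), (a3, 1))
        result = insert_species(state, (a2,), B, 1)
        assert result == S((a2, 2), (a3, 2))

    def test_insert_into_empty_root(self):
        assert insert_species(Solution(), (), B, 1) == S((B, 1))

    def test_missing_victim_raises(self):
        state = S((A(S((B, 1))), 1))
        with pytest.raises(AmountError):
            remove_species(state, (A(S((B, 1))),), B, 2)

    def test_bad_address_raises(self):
        with pytest.raises(AddressError):
            remove_species(S((B, 1)), (A(),), B, 1)

    def test_remove_insert_roundtrip_identity(self, rng):
        def address_after_removal(addr, victim):
            # the same location after the edit: every enclosing species on
            # the path now carries the modified content
            return tuple(
                step.with_content(
                    apply_at(step.content, addr[i + 1:], [(victim, 1)]))
                for i, step in enumerate(addr))

        for _ in range(100):
            state = random_solution(rng, 2)
            spots = [(addr, sol) for addr, _, sol in walk_addresses(state)
                     if len(sol)]
            if not spots:
                continue
            addr, sol = rng.choice(spots)
            victim = rng.choice(list(sol.species()))
            mid = remove_species(state, addr, victim, 1)
            back = insert_species(mid, address_after_removal(addr, victim),
                                  victim, 1)
            assert back == state

    def test_conservation_under_relocation(self, rng):
        """Moving copies between addresses never changes total counts."""
        moved = 0
        for _ in range(200):
            state = random_solution(rng, 2)
            spots = [(addr, sol) for addr, _, sol in walk_addresses(state)
                     if len(sol)]
            if len(spots) < 2:
                continue
            (src, ssol), (dst, _) = rng.sample(spots, 2)
            if any(len(step.content) == 0 for step in dst):
                continue
            victim = rng.choice(list(ssol.species()))
            if any(step == victim for step in dst):
                continue  # cannot move a species into itself
            before = flatten_counts(state)
            try:
                out = apply_at(state, src, removals=[(victim, 1)])
                out = apply_at(out, dst, additions=[(victim, 1)])
            except AddressError:
                continue  # the removal rewrote a species on dst's path
            assert flatten_counts(out) == before
            moved += 1
        assert moved > 30

    def test_merge_completeness_after_random_edits(self, rng):
        """No sub-solution ever holds two canonically equal keys."""
        state = random_solution(rng, 2)
        for _ in range(300):
            spots = list(walk_addresses(state))
            addr, _, sol = rng.choice(spots)
            if len(sol) and rng.random() < 0.5:
                victim = rng.choice(list(sol.species()))
                state = remove_species(state, addr, victim, 1)
            else:
                state = insert_species(state, addr,
                                       random_species(rng, 1), 1)
            for _, _, sub in walk_addresses(state):
                keys = [sp.key for sp in sub.species()]
                assert len(keys) == len(set(keys))
                assert all(n > 0 for _, n in sub)


class TestFlattenCounts:
    def test_empty(self):
        assert flatten_counts(Solution()) == {}

    def test_nested_example(self):
        # A[C + 2 D[E]] + B[3 E]
        E = Species("E")
        inner = Species("A", (), S((Species("Cx"), 1),
                                   (Species("D", (), S((E, 1))), 2)))
        b = Species("B", (), S((E, 3)))
        counts = flatten_counts(S((inner, 1), (b, 1)))
        assert counts == {"A": 1, "B": 1, "Cx": 1, "D": 2, "E": 5}

    def test_multiplicative_weighting(self):
        assert flatten_counts(S((A(S((B, 2))), 2))) == {"A": 2, "B": 4}
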
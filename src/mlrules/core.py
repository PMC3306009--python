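"""Nested-multiset state representation.

The simulator state is a :class:`Solution`: a multiset of species
populations, where each species has a name, a fixed-length tuple of
attribute values, and (possibly) an enclosed sub-solution of further
species.  Populations of *canonically equal* species are always kept
merged, so a solution is a canonical form: any permutation of insertions
yields the identical object.

Attribute values are plain Python scalars (``int``, ``float``, ``str``,
``bool``) plus :class:`Fresh` markers produced by the nu-operator.
Equality between attribute values is exact and type-tagged: ``1``,
``1.0`` and ``True`` are three distinct values for the purpose of
species identity, and a fresh value equals only itself.

Modifying a species deep inside a nested solution changes the identity
of every enclosing species on the path, so a single removal or
insertion must *split* one representative off each enclosing population
and *merge* the modified copy with any now-identical population, all
the way up to the root.  :func:`apply_at` implements that propagation;
:func:`remove_species` and :func:`insert_species` are its two
single-sided specializations.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Sequence, Union

__all__ = [
    "Fresh",
    "AttributeValue",
    "Species",
    "Solution",
    "Address",
    "AddressError",
    "AmountError",
    "EMPTY_SOLUTION",
    "value_key",
    "canonicalize",
    "format_value",
    "format_solution",
    "apply_at",
    "remove_species",
    "insert_species",
    "flatten_counts",
]


class AddressError(Exception):
    """A path into a nested solution does not exist."""


class AmountError(Exception):
    """A removal asked for more copies of a species than are present."""


class Fresh:
    """An opaque, globally unique attribute value (nu-operator output).

    Fresh values compare equal only to themselves and never to any
    literal a modeler could write, which makes them usable as bond or
    individual identifiers.
    """

    __slots__ = ("uid",)

    def __init__(self, uid: int) -> None:
        self.uid = uid

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Fresh) and other.uid == self.uid

    def __hash__(self) -> int:
        return hash(("mlrules.Fresh", self.uid))

    def __repr__(self) -> str:
        return f"#{self.uid}"


AttributeValue = Union[int, float, str, bool, Fresh]

# Type tags give a total order across heterogeneous attribute values and
# keep bool/int/float apart even where Python's == would conflate them.
def value_key(v: AttributeValue) -> tuple:
    if isinstance(v, bool):
        return ("b", v)
    if isinstance(v, int):
        return ("i", v)
    if isinstance(v, float):
        return ("f", v)
    if isinstance(v, str):
        return ("s", v)
    if isinstance(v, Fresh):
        return ("u", v.uid)
    raise TypeError(f"unsupported attribute value: {v!r}")


def values_equal(a: AttributeValue, b: AttributeValue) -> bool:
    """Exact, type-tagged equality (no numeric coercion)."""
    return value_key(a) == value_key(b)


def format_value(v: AttributeValue) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, Fresh)):
        return repr(v)
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, str):
        # only capitalized identifiers read back as bare symbols; anything
        # else must be quoted to avoid colliding with variable names
        if v.isidentifier() and v[0].isupper():
            return v
        return "'" + v.replace("\\", "\\\\").replace("'", "\\'") + "'"
    raise TypeError(f"unsupported attribute value: {v!r}")


class Species:
    """A concrete species instance: name, attribute tuple, content.

    A species with empty content is the same thing as an atomic species;
    both are represented with ``content is EMPTY_SOLUTION``-equivalent
    empty solutions and compare equal.
    """

    __slots__ = ("name", "attrs", "content", "has_content", "token",
                 "_key", "_hash")

    def __init__(self, name: str, attrs: Sequence[AttributeValue] = (),
                 content: "Solution | None" = None) -> None:
        self.name = name
        self.attrs = tuple(attrs)
        self.content = EMPTY_SOLUTION if content is None else content
        self.has_content = bool(self.content._items)
        # canonical serialization: injective, so it doubles as identity
        # and as a cheap total order (plain string comparison)
        token = name
        if self.attrs:
            token += "(" + ",".join(format_value(a) for a in self.attrs) + ")"
        if self.has_content:
            token += "[" + format_solution(self.content) + "]"
        self.token = token
        self._hash = hash(token)
        self._key = None

    @property
    def key(self) -> tuple:
        """Total-ordered, hashable canonical key.

        Two instances share a key iff name, attribute tuple and
        (recursively canonical) content are identical.
        """
        if self._key is None:
            self._key = (self.name,
                         tuple(value_key(a) for a in self.attrs),
                         self.content.key)
        return self._key

    def is_atomic(self) -> bool:
        return len(self.content) == 0

    def with_content(self, content: "Solution") -> "Species":
        return Species(self.name, self.attrs, content)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Species) and other.token == self.token

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return self.token


class Solution:
    """A canonical multiset of species populations.

    Internally a tuple of ``(Species, amount)`` pairs sorted by the
    species' canonical key, plus a hash map for amount lookup.  Amounts
    are strictly positive integers; zero-amount entries are dropped at
    construction, and equal keys are merged, so the representation is
    independent of insertion order.
    """

    __slots__ = ("_items", "_index", "_key", "_hash")

    def __init__(self, populations: Union[Mapping[Species, int],
                                          Iterable[tuple[Species, int]], None] = None) -> None:
        merged: dict[Species, int] = {}
        if populations is not None:
            items = (populations.items() if hasattr(populations, "items")
                     else populations)
            for sp, n in items:
                if not isinstance(n, int) or isinstance(n, bool):
                    raise TypeError(f"population amount must be an integer, got {n!r}")
                if n < 0:
                    raise ValueError(f"negative population amount {n} for {sp!r}")
                if n == 0:
                    continue
                merged[sp] = merged.get(sp, 0) + n
        self._index = merged
        self._items = tuple(sorted(merged.items(),
                                   key=lambda kv: kv[0].token))
        self._key = None
        self._hash = None

    @property
    def key(self) -> tuple:
        # computed lazily: many transient solutions are never hashed
        if self._key is None:
            self._key = tuple((sp.token, n) for sp, n in self._items)
        return self._key

    @property
    def items(self) -> tuple[tuple[Species, int], ...]:
        return self._items

    def amount(self, sp: Species) -> int:
        return self._index.get(sp, 0)

    def species(self) -> Iterator[Species]:
        for sp, _ in self._items:
            yield sp

    def __contains__(self, sp: Species) -> bool:
        return sp in self._index

    def __iter__(self) -> Iterator[tuple[Species, int]]:
        return iter(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def total(self) -> int:
        """Number of top-level individuals (sum of amounts)."""
        return sum(n for _, n in self._items)

    def with_changes(self, delta: Mapping[Species, int]) -> "Solution":
        """Copy with amounts changed by ``delta`` (may be negative).

        Keys already present keep their sorted position; brand-new keys
        are merge-inserted, so the full canonical re-sort of a large
        solution is avoided.
        """
        counts = {}
        fresh = []
        for sp, d in delta.items():
            have = self._index.get(sp, 0)
            n = have + d
            if n < 0:
                raise AmountError(
                    f"cannot remove {-d} of {sp!r}: only {have} present")
            counts[sp] = n
            if have == 0 and n > 0:
                fresh.append((sp, n))
        fresh.sort(key=lambda kv: kv[0].token)
        items = []
        fi = 0
        for sp, n in self._items:
            if sp in counts:
                n = counts[sp]
                if n == 0:
                    continue
            while fi < len(fresh) and fresh[fi][0].token < sp.token:
                items.append(fresh[fi])
                fi += 1
            items.append((sp, n))
        items.extend(fresh[fi:])
        sol = Solution.__new__(Solution)
        sol._items = tuple(items)
        sol._index = dict(items)
        sol._key = None
        sol._hash = None
        return sol

    def minus(self, used: Mapping[Species, int]) -> "Solution":
        """Copy with ``used[sp]`` copies of each key removed.

        Fast path for rest-solution binding: the items stay sorted, so
        the canonical form is rebuilt without re-merging.  ``used`` must
        not exceed the stored amounts.
        """
        items = []
        for sp, n in self._items:
            n -= used.get(sp, 0)
            if n > 0:
                items.append((sp, n))
            elif n < 0:
                raise ValueError(f"removing more {sp!r} than present")
        sol = Solution.__new__(Solution)
        sol._items = tuple(items)
        sol._index = dict(items)
        sol._key = None
        sol._hash = None
        return sol

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Solution) and other.key == self.key

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash(self.key)
        return self._hash

    def __repr__(self) -> str:
        return f"<Solution {format_solution(self)}>"


EMPTY_SOLUTION = Solution()

#: A path from the root down to a nested sub-solution, as the sequence of
#: species whose contents are traversed.  The empty tuple addresses the root.
Address = tuple[Species, ...]


def canonicalize(instance: Species) -> tuple:
    """Total-ordered, hashable canonical key of a species instance.

    Two instances share a key iff their name, attribute tuple and
    recursively canonical content are identical; ``A[(empty)]`` equals
    atomic ``A``, and content multiset order never matters.
    """
    return instance.key


def format_solution(sol: Solution) -> str:
    """Render a solution in the model-file syntax (``0`` if empty)."""
    if not len(sol):
        return "0"
    parts = []
    for sp, n in sol:
        term = repr(sp)
        if n != 1:
            term = f"{n} {term}"
        parts.append(term)
    return " + ".join(parts)


def apply_at(root: Solution, addr: Address,
             removals: Iterable[tuple[Species, int]] = (),
             additions: Iterable[tuple[Species, int]] = ()) -> Solution:
    """Remove and add species inside the sub-solution at ``addr``.

    Exactly one representative of each population on the path is
    modified; the enclosing population is split (amount decremented)
    and the modified copy merged back at every level, so the result is
    canonical and all other copies are untouched.

    Raises :class:`AddressError` if a path step is absent and
    :class:`AmountError` if a removal exceeds the available amount.
    """
    if not addr:
        delta: dict[Species, int] = {}
        for sp, k in removals:
            if root.amount(sp) + delta.get(sp, 0) < k:
                raise AmountError(
                    f"cannot remove {k} of {sp!r}: only "
                    f"{root.amount(sp)} present")
            delta[sp] = delta.get(sp, 0) - k
        for sp, k in additions:
            delta[sp] = delta.get(sp, 0) + k
        return root.with_changes(delta)
    head, rest = addr[0], addr[1:]
    if root.amount(head) < 1:
        raise AddressError(f"address step {head!r} not present in solution")
    new_head = head.with_content(apply_at(head.content, rest, removals,
                                          additions))
    if new_head == head:
        return root
    return root.with_changes({head: -1, new_head: 1})


def remove_species(root: Solution, addr: Address, victim: Species,
                   count: int = 1) -> Solution:
    """Remove ``count`` copies of ``victim`` from the sub-solution at ``addr``."""
    if count < 1:
        raise ValueError("count must be a positive integer")
    return apply_at(root, addr, removals=[(victim, count)])


def insert_species(root: Solution, addr: Address, newcomer: Species,
                   count: int = 1) -> Solution:
    """Insert ``count`` copies of ``newcomer`` into the sub-solution at ``addr``."""
    if count < 1:
        raise ValueError("count must be a positive integer")
    return apply_at(root, addr, additions=[(newcomer, count)])


def flatten_counts(root: Solution) -> dict[str, int]:
    """Total count of every species name across all nesting levels.

    Each nested occurrence is weighted by the product of the amounts of
    all enclosing populations, i.e. ``2 A[2 B]`` counts 4 ``B``.
    """
    out: dict[str, int] = {}

    stack = [(root, 1)]
    while stack:
        sol, weight = stack.pop()
        for sp, n in sol._items:
            w = weight * n
            out[sp.name] = out.get(sp.name, 0) + w
            if sp.has_content:
                stack.append((sp.content, w))
    return out


def walk_addresses(root: Solution) -> Iterator[tuple[Address, int, Solution]]:
    """Yield every sub-solution with its address and context factor.

    The context factor of an address is the product of the amounts of
    all populations strictly enclosing that sub-solution; it is 1 for
    the root.  Species with empty content are atomic (an empty content
    solution and no content are the same thing), so they contribute no
    address.  Traversal order is a fixed function of the canonical form,
    so iteration is deterministic and reproducible across runs.
    """

    stack = [((), 1, root)]
    while stack:
        addr, ctx, sol = stack.pop()
        yield addr, ctx, sol
        for sp, n in sol._items:
            if sp.has_content:
                stack.append((addr + (sp,), ctx * n, sp.content))
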
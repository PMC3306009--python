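"""Exact stochastic simulation (Gillespie direct method) over nested states.

The state is a continuous-time Markov chain whose transitions are the
grounded reaction instances produced by matching every rule at every
nesting level.  Each step recomputes the full instance set (no
dependency graph — unchanged sub-solutions are served from the match
cache), draws an exponential waiting time with the total propensity,
selects one instance linearly in canonical order, and executes it:
grounded reactants are removed, nu binders are resolved to fresh
values, products are constructed and inserted, and the split/merge
bookkeeping of :mod:`mlrules.core` keeps the state canonical.

Trajectories record observables at equidistant instants using the state
right before each instant; a run is bit-reproducible for a fixed seed
and replicate index.
"""

from __future__ import annotations

import gc
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

from .core import Address, Solution, apply_at, walk_addresses
from .expr import FreshValueGenerator
from .language import Model, Pattern, Rule, parse_pattern
from .match import LocalMatch, Matcher, ground_products

__all__ = [
    "SimulationState", "Observable", "Trajectory", "Simulator", "paused_gc",
    "step", "run", "count_pattern",
]

#: Called after each firing with (time, rule, site, state_before, state_after).
FiringListener = Callable[[float, Rule, Address, Solution, Solution], None]


@contextmanager
def paused_gc():
    """Pause the cyclic garbage collector around a simulation loop.

    The simulator's data structures (immutable solution trees, match
    caches) are acyclic, so reference counting reclaims everything;
    generational GC only adds long pauses that grow with cache size.
    """
    was_enabled = gc.isenabled()
    gc.disable()
    try:
        yield
    finally:
        if was_enabled:
            gc.enable()
            gc.collect()


@dataclass
class SimulationState:
    time: float
    solution: Solution
    rng: np.random.Generator
    fresh: FreshValueGenerator


@dataclass(frozen=True)
class Observable:
    """A named species pattern counted over the whole hierarchy.

    The count of a pattern is the sum over all matching populations of
    ``amount x context factor``, i.e. ``2 C[3 M]`` contributes 6 to the
    count of pattern ``M``.  Attribute variables act as wildcards;
    literal or constant attribute positions filter; a content pattern
    restricts to species whose content embeds it.
    """

    name: str
    pattern: Pattern


@dataclass
class Trajectory:
    names: list[str]
    times: list[float] = field(default_factory=list)
    values: list[list[int]] = field(default_factory=list)
    seed: Optional[int] = None
    replicate: int = 0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.names,
                            index=pd.Index(self.times, name="time"))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed} replicate={self.replicate}\n")
            fh.write("time," + ",".join(self.names) + "\n")
            for t, row in zip(self.times, self.values):
                fh.write(f"{t:g}," + ",".join(str(v) for v in row) + "\n")

    def column(self, name: str) -> list[int]:
        i = self.names.index(name)
        return [row[i] for row in self.values]


def _as_observables(observables: Iterable[Union[str, Observable]]
                    ) -> list[Observable]:
    out = []
    for ob in observables:
        if isinstance(ob, Observable):
            out.append(ob)
        else:
            out.append(Observable(str(ob), parse_pattern(str(ob))))
    return out


def count_pattern(state: Solution, pattern: Union[str, Pattern],
                  model: Model, matcher: Matcher | None = None) -> int:
    """Flatten-style count of a species pattern over all nesting levels."""
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    if matcher is None:
        matcher = Matcher(model)
    total = 0
    for _addr, ctx, sol in walk_addresses(state):
        for sp, n in sol:
            if sp.name != pattern.name:
                continue
            for _b in matcher._match_species(pattern, sp, n, {}):
                total += ctx * n
                break  # one embedding suffices; count the population once
    return total


class Simulator:
    """Stateful wrapper around the direct-method loop."""

    def __init__(self, model: Model, seed: int = 0, replicate: int = 0,
                 listener: Optional[FiringListener] = None) -> None:
        self.model = model
        self.matcher = Matcher(model)
        self.listener = listener
        self.seed = seed
        self.replicate = replicate
        # replicate index deterministically perturbs the stream
        self.state = SimulationState(
            time=0.0,
            solution=model.initial,
            rng=np.random.default_rng(
                np.random.SeedSequence((seed, replicate))),
            fresh=FreshValueGenerator(),
        )
        self.steps = 0

    # -- one SSA step ---------------------------------------------------

    def step_once(self) -> bool:
        """Advance by one reaction firing; False if no rule can fire.

        The total propensity is assembled from cached per-site and
        per-subtree aggregates, and the fired instance is located by
        descending the nesting hierarchy — only sub-solutions touched by
        the previous firing are actually re-matched.
        """
        st = self.state
        matcher = self.matcher
        root = st.solution
        total0, _blocks0 = matcher.site_matches(root)
        a0 = total0
        for sp, n in root.items:
            if sp.has_content:
                a0 += n * matcher.subtree_rate(sp)
        if a0 <= 0.0:
            return False
        dt = st.rng.exponential(1.0 / a0)
        u = st.rng.random() * a0
        chosen = self._select(root, u)
        if chosen is None:  # float round-off at the very edge
            chosen = self._select(root, a0 * (1.0 - 1e-12))
        if chosen is None:
            return False
        addr, ri, lm = chosen
        addr, ri, lm = chosen
        rule = self.model.rules[ri]
        return self._execute(addr, ri, lm, rule, dt)

    def _select(self, root: Solution,
                u: float) -> Optional[tuple[Address, int, "LocalMatch"]]:
        """Locate the reaction instance at cumulative propensity ``u`` by
        descending the hierarchy (site first, then content subtrees, in
        canonical order)."""
        matcher = self.matcher
        addr: Address = ()
        ctx = 1
        sol = root
        acc = 0.0
        while True:
            total, blocks = matcher.site_matches(sol)
            site_weight = ctx * total
            if u < acc + site_weight:
                for btotal, local in blocks:
                    bweight = ctx * btotal
                    if acc + bweight <= u:
                        acc += bweight
                        continue
                    for ri, lm in local:
                        acc += ctx * lm.rate
                        if u < acc:
                            return (addr, ri, lm)
                    break
                # round-off inside this site: take its last match
                if blocks:
                    ri, lm = blocks[-1][1][-1]
                    return (addr, ri, lm)
                return None
            acc += site_weight
            descended = False
            for sp, n in sol.items:
                if not sp.has_content:
                    continue
                w = ctx * n * matcher.subtree_rate(sp)
                if acc + w <= u:
                    acc += w
                    continue
                addr = addr + (sp,)
                ctx *= n
                sol = sp.content
                descended = True
                break
            if not descended:
                return None

    def _execute(self, addr: Address, ri: int, lm: "LocalMatch",
                 rule: Rule, dt: float) -> bool:
        st = self.state
        bindings = lm.bindings
        if rule.nu:
            bindings = dict(bindings)
            for nb in rule.nu:
                bindings[nb] = st.fresh.next()
        grounded = ground_products(rule, bindings, self.model.constants,
                                   self.model.functions)
        before = st.solution
        st.solution = apply_at(before, addr, removals=lm.consumed,
                               additions=grounded)
        st.time += dt
        self.steps += 1
        if self.listener is not None:
            self.listener(st.time, rule, addr, before, st.solution)
        return True

    # -- trajectory recording --------------------------------------------

    def run(self, end_time: float, observe_every: float,
            observables: Iterable[Union[str, Observable]]) -> Trajectory:
        if end_time < 0:
            raise ValueError("end_time must be non-negative")
        if observe_every <= 0:
            raise ValueError("observe_every must be positive")
        obs = _as_observables(observables)
        traj = Trajectory([o.name for o in obs], seed=self.seed,
                          replicate=self.replicate)

        instants: list[float] = []
        k = 0
        while k * observe_every < end_time:
            instants.append(k * observe_every)
            k += 1
        instants.append(end_time)

        def record(t: float) -> None:
            traj.times.append(t)
            traj.values.append([
                count_pattern(self.state.solution, o.pattern, self.model,
                              self.matcher) for o in obs])

        i = 0
        alive = True
        with paused_gc():
            self._run_loop(instants, record)
        return traj

    def _run_loop(self, instants, record) -> None:
        i = 0
        alive = True
        while i < len(instants):
            if not alive or self.state.time >= instants[i]:
                record(instants[i])
                i += 1
                continue
            prev_solution = self.state.solution
            prev_time = self.state.time
            alive = self.step_once()
            if alive and self.state.time >= instants[i]:
                # the state right before the instant is the pre-step one
                save_sol, save_t = self.state.solution, self.state.time
                self.state.solution = prev_solution
                while i < len(instants) and save_t >= instants[i]:
                    record(instants[i])
                    i += 1
                self.state.solution = save_sol


def step(state: SimulationState, model: Model,
         matcher: Matcher | None = None) -> Optional[SimulationState]:
    """One direct-method step; None when the state is absorbing."""
    sim = Simulator(model)
    sim.state = state
    if matcher is not None:
        sim.matcher = matcher
    return state if sim.step_once() else None


def run(model: Model, end_time: float, observe_every: float,
        observables: Iterable[Union[str, Observable]], seed: int = 0,
        replicate: int = 0,
        listener: Optional[FiringListener] = None) -> Trajectory:
    """Simulate and record a trajectory (reproducible per seed/replicate)."""
    sim = Simulator(model, seed=seed, replicate=replicate, listener=listener)
    return sim.run(end_time, observe_every, observables)
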
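# mlrules

Rule-based multi-level modeling and exact stochastic simulation of
nested biochemical systems.

Cell-biological dynamics play out on several organizational levels at
once: molecule counts gate cell-level events (a protein threshold
triggers a cell-cycle phase change), and high-level state modulates
molecular rates (cell volume dilutes an enzyme, extracellular pheromone
represses an intracellular complex).  `mlrules` is a modeling language
and simulator for exactly this kind of system, aimed at modelers who
want to write their biology as reaction rules rather than as code.

A model's state is a *nested multiset*: species carry a name, a
fixed-arity attribute tuple, and optionally a whole solution of further
species — `2 C(232, G1)[3 M_A + 150 D]` is a population of two cells,
each with volume attribute 232, phase G1, and its own molecular
content.  Dynamics are *rule schemata* over such states:

```
// mass action with a threshold constraint: a binds the amount of A(x)
A(x):a -> B(2 * x) @ k * a if a > thr;

// downward causation: volume-diluted dissociation inside a cell,
// content preserved through the rest-solution variable s?
C(v, p)[M_A:a + s?]:c -> C(v, p)[D + Y_P + s?] @ k4 * a * vref * td / v * c if a > 1;

// fresh values encode bonds (private-channel idiom)
A(F) + B(F) -> nu(x) A(x) + B(x) @ kon;
```

The semantics is a continuous-time Markov chain over population counts,
executed with the Gillespie direct method.  Matching a rule inside a
nested species multiplies its propensity by the amounts of all
enclosing populations (a reaction is proportionally more likely the
more compartments it could happen in), and rewriting deep inside one
representative of a population splits it off and re-merges the modified
copy canonically at every level.  For flat models with finite attribute
ranges, the same rules can instead be *expanded* into an explicit
reaction network — one schema stands for many concrete reactions (a
9-site scaffold protein: 10 species definitions and 18 rules in place
of 521 species and 4608 reactions).

The package ships executable example models of fission-yeast biology —
an intracellular MPF oscillator, volume/phase-coupled cell division,
mating-type switching, pheromone communication with G1 arrest, and a
spatial voxel grid — built programmatically and emitted as `.mlr` text
(see `docs/methods.md` for the science and the parameter choices).

## Worked example

```python
import mlrules as m

model = m.parse_model("""
    X; Y; Z;
    const kf = 0.8; const kb = 0.5; const kc = 0.3;
    X:x -> Y @ kf * x;
    Y:y -> X @ kb * y;
    Y:y -> Z @ kc * y;
    init 20 X;
""")
traj = m.run(model, end_time=10.0, observe_every=2.0,
             observables=["X", "Y", "Z"], seed=42)
print(traj.to_dataframe())
```

prints

```
       X  Y   Z
time
0.0   20  0   0
2.0    8  8   4
4.0    8  5   7
6.0    5  5  10
8.0    6  2  12
10.0   3  2  15
```

one row per observation instant: the irreversible sink `Z` drains the
X/Y pool, and the same seed reproduces this table bit for bit.  The
same model expands to its explicit three-reaction network:

```python
net = m.expand_network(model)
print(net.summary())            # species: 3, reactions: 3
print(net.format_reactions())
# X -> Y @ 0.8
# Y -> X @ 0.5
# Y -> Z @ 0.3
```

The command line mirrors the library — `mlrules validate model.mlr`,
`mlrules simulate --model model.mlr --end-time 100 --seed 1
--observable X --output run`, `mlrules expand scaffold.mlr`, and
`mlrules fixtures --out-dir examples/` to write all yeast example
models as `.mlr` files.

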
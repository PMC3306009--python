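"""Executable example models: fission-yeast cell cycle, division with
mating-type switching, pheromone signaling, and a discretized spatial grid.

Every builder produces model *text* first and parses it, so the model
file syntax is exercised by each fixture.  The intracellular layer is a
stochastic variant of the Tyson cyclin/cdc2 oscillator reduced to five
molecular species:

``Y``    cyclin
``Y_P``  phosphorylated cyclin
``D``    cdc2 (phosphorylated and unphosphorylated lumped together)
``M_I``  inactive MPF (cyclin-P . cdc2-P complex)
``M_A``  active MPF
``M_R``  pheromone-repressed MPF (population models only)

with reactions: cyclin synthesis, cyclin-cdc2 association, autocatalytic
MPF activation at rate ``k3 * m_i * (m_a / D_tot)^2``, MPF dissociation
at rate ``k4 * m_a`` (volume-diluted, ``* T_d / v``, once a cell species
exists) guarded by ``m_a > 1`` so activation never loses its seed, and
phosphorylated-cyclin turnover.  ``k3`` and ``k4`` are the published
oscillation-region constants; the remaining mass-action constants are
ESTIMATED (marked below) to give sustained oscillations around those
two values, since no complete published set is reproduced here.

The cell level adds a ``C`` species whose attributes carry the cell
volume (stored as an integer number of growth steps of ``1/T_d`` so that
repeated increments never fragment populations through float drift),
the cell-cycle phase (``G1``, ``SG2``, ``M``), and for population models
the mating type (``P``/``M``) and switchability (``U``/``S``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .language import Model, parse_model

__all__ = ["YeastParameters", "build_cycle_model", "build_population_model",
           "build_spatial_model", "cycle_text", "population_text",
           "spatial_text", "birth_death_text", "build_birth_death",
           "FIXTURE_BUILDERS"]


@dataclass(frozen=True)
class YeastParameters:
    """Parameters of the yeast fixtures (rates in min^-1, times in min).

    ``k3``/``k4`` are the published activation/dissociation constants;
    ``k6`` is the growth rate constant (one volume step of ``1/t_d`` per
    firing); thresholds ``t7``/``t8``/``t9`` gate the cell-cycle phase
    transitions on M_I and M_A counts (``t9`` much lower than ``t8``).
    Constants marked ESTIMATED have no published value here and were
    chosen so the intracellular oscillator runs in its oscillatory
    regime at k3 = 180, k4 = 0.9 and so the multi-level cell's mean
    cycle tracks the mass-doubling time.
    """

    k3: float = 180.0       # autocatalytic MPF activation
    k4: float = 0.9         # MPF dissociation
    k6: float = 1.0         # growth firings per minute
    t_d: int = 116          # mass-doubling time (116 wild type, 232 starved)
    d_tot: int = 400        # total cdc2 per cell
    k1_frac: float = 0.03   # ESTIMATED cyclin synthesis per cdc2 per minute
    ka: float = 200.0       # ESTIMATED cyclin-cdc2 association
    k2: float = 0.05        # ESTIMATED free-cyclin turnover
    k7: float = 0.6         # ESTIMATED Y_P turnover
    v_ref: float = 4.5      # ESTIMATED volume (in birth units) at which the
                            # diluting MPF-dissociation machinery runs at k4
    t7: int = 120           # M_I threshold, G1 -> S/G2
    t8: int = 60            # M_A threshold, S/G2 -> M
    t9: int = 8             # M_A threshold (falling), M -> G1 + division
    k_trans: float = 10.0   # ESTIMATED phase-transition rate once gated open
    k_div: float = 10.0     # ESTIMATED division rate once volume >= 2
    k_death: float = 0.006  # cell death rate
    n0: int = 100           # initial number of cells (population models)
    # pheromone layer (all ESTIMATED; see docs/methods.md)
    k_sec: float = 0.3      # pheromone secretion per cell
    k_out: float = 0.01     # pheromone loss (diffusion out of the system)
    k_sxa: float = 0.03     # Sxa2 secretion by M cells
    k_deg: float = 0.0005   # Sxa2-catalyzed F_P degradation
    hill_max: float = 0.2   # maximal MPF repression rate factor
    hill_k: float = 400.0   # half-saturation pheromone amount
    k_derep: float = 0.02   # volume-proportional de-repression
    # spatial layer
    x_max: int = 5
    y_max: int = 5
    k_diff: float = 0.1     # ESTIMATED pheromone hop rate between voxels
    k_move: float = 0.05    # ESTIMATED cell displacement rate scale

    def scaled(self, **changes) -> "YeastParameters":
        return replace(self, **changes)

    @classmethod
    def with_pool(cls, d_tot: int, **changes) -> "YeastParameters":
        """Parameters for a different cdc2 pool size, keeping the phase
        thresholds at the calibrated fractions of the pool (t7 = 0.30,
        t8 = 0.15, t9 = 0.02)."""
        return cls(d_tot=d_tot, t7=int(0.30 * d_tot), t8=int(0.15 * d_tot),
                   t9=max(3, int(0.02 * d_tot))).scaled(**changes)


def _molecular_defs(with_repressed: bool = False) -> list[str]:
    defs = ["Y;", "Y_P;", "D;", "M_I;", "M_A;"]
    if with_repressed:
        defs.append("M_R;")
    return defs


def _molecular_consts(p: YeastParameters) -> list[str]:
    return [
        f"const dtot = {p.d_tot};",
        f"const k1 = {p.k1_frac * p.d_tot!r}; // ESTIMATED cyclin synthesis",
        f"const ka = {p.ka!r};                // ESTIMATED association",
        f"const k3 = {p.k3!r};",
        f"const k2 = {p.k2!r};                // ESTIMATED Y turnover",
        f"const k4 = {p.k4!r};",
        f"const k7 = {p.k7!r};                // ESTIMATED Y_P turnover",
    ]


# intracellular rules that are the same at every nesting level
_FLAT_MOLECULAR = [
    "Y:y + D:d -> M_I @ ka * y * d / dtot;",
    "M_I:i + M_A:a -> 2 M_A @ k3 * i * (a / dtot)^2;",
    "Y:y -> 0 @ k2 * y;",
    "Y_P:w -> 0 @ k7 * w;",
]


def cycle_text(p: YeastParameters | None = None,
               level: str = "multilevel") -> str:
    """Cell-cycle model text at one of three description levels.

    ``tyson``      flat stochastic oscillator, no cell species;
    ``downward``   adds the cell with volume-diluted MPF dissociation,
                   growth below volume 2 and division (volume halving)
                   at volume >= 2;
    ``multilevel`` adds the phase attribute with threshold-gated
                   transitions (upward causation) and growth allowed in
                   every phase except M.
    """
    p = p or YeastParameters()
    if level == "tyson":
        lines = _molecular_defs() + _molecular_consts(p) + [
            "0 -> Y @ k1;",
            *_FLAT_MOLECULAR,
            "M_A:a -> D + Y_P @ k4 * a if a > 1;",
            "init (dtot - 1) D + M_A;",
        ]
        return "\n".join(lines) + "\n"

    cell_consts = [
        f"const td = {p.t_d};",
        f"const vref = {p.v_ref!r};   // ESTIMATED dilution reference",
        f"const k6 = {p.k6!r};",
        f"const kdiv = {p.k_div!r};   // ESTIMATED",
    ]
    if level == "downward":
        lines = (["C(1); // volume, in integer steps of 1/td"]
                 + _molecular_defs() + _molecular_consts(p) + cell_consts + [
            "C(v)[s?]:c -> C(v)[Y + s?] @ k1 * c;",
            *_FLAT_MOLECULAR,
            "C(v)[M_A:a + s?]:c -> C(v)[D + Y_P + s?] "
            "@ k4 * a * vref * td / v * c if a > 1;",
            "C(v)[s?]:c -> C(v + 1)[s?] @ k6 * c if v < 2 * td;",
            "C(v)[s?]:c -> C(floor(v / 2))[s?] @ kdiv * c if v >= 2 * td;",
            "init C(td)[(dtot - 1) D + M_A];",
        ])
        return "\n".join(lines) + "\n"

    if level == "multilevel":
        lines = (["C(2); // volume (steps of 1/td), cell cycle phase"]
                 + _molecular_defs() + _molecular_consts(p) + cell_consts + [
            f"const t7 = {p.t7};",
            f"const t8 = {p.t8};",
            f"const t9 = {p.t9};",
            f"const ktr = {p.k_trans!r};  // ESTIMATED",
            "C(v, p)[s?]:c -> C(v, p)[Y + s?] @ k1 * c;",
            *_FLAT_MOLECULAR,
            "C(v, p)[M_A:a + s?]:c -> C(v, p)[D + Y_P + s?] "
            "@ k4 * a * vref * td / v * c if a > 1;",
            "// growth at any time except during mitosis",
            "C(v, p)[s?]:c -> C(v + 1, p)[s?] @ k6 * c if p != M;",
            "// upward causation: protein counts gate phase transitions",
            "C(v, G1)[M_I:i + s?]:c -> C(v, SG2)[M_I + s?] "
            "@ ktr * c if i > t7;",
            "C(v, SG2)[M_A:a + s?]:c -> C(v, M)[M_A + s?] "
            "@ ktr * c if a > t8;",
            "C(v, M)[M_A:a + s?]:c -> C(floor(v / 2), G1)[M_A + s?] "
            "@ ktr * c if a < t9;",
            "init C(td, G1)[(dtot - 1) D + M_A];",
        ])
        return "\n".join(lines) + "\n"

    raise ValueError(f"unknown level {level!r}; expected tyson, downward "
                     "or multilevel")


def build_cycle_model(p: YeastParameters | None = None,
                      level: str = "multilevel") -> Model:
    return parse_model(cycle_text(p, level))


def _population_cell_rules() -> list[str]:
    """Cell-level rules shared by the population and spatial models,
    except division and death (which differ in the spatial context)."""
    return [
        "C(v, p, t, w)[s?]:c -> C(v, p, t, w)[Y + s?] @ k1 * c;",
        *_FLAT_MOLECULAR,
        "C(v, p, t, w)[M_A:a + s?]:c -> C(v, p, t, w)[D + Y_P + s?] "
        "@ k4 * a * vref * td / v * c if a > 1;",
        "C(v, p, t, w)[s?]:c -> C(v + 1, p, t, w)[s?] @ k6 * c if p != M;",
        "C(v, G1, t, w)[M_I:i + s?]:c -> C(v, SG2, t, w)[M_I + s?] "
        "@ ktr * c if i > t7;",
        "C(v, SG2, t, w)[M_A:a + s?]:c -> C(v, M, t, w)[M_A + s?] "
        "@ ktr * c if a > t8;",
    ]


def _division_products(vol: str = "floor(v / 2)") -> tuple[str, str]:
    """LHS-independent product templates for the two division schemata.

    An unswitchable (U) mother yields one U and one S daughter of her
    own type; a switchable (S) mother yields one S daughter of her own
    type and one U daughter of the opposite type.  Content is copied
    entirely into both daughters (total cdc2 per cell is conserved).
    """
    u_products = (f"C({vol}, G1, t, U)[M_A + s?] + "
                  f"C({vol}, G1, t, S)[M_A + s?]")
    s_products = (f"C({vol}, G1, t, S)[M_A + s?] + "
                  f"C({vol}, G1, if t = P then M else P, U)[M_A + s?]")
    return u_products, s_products


def _pheromone_core_rules() -> list[str]:
    """Secretion, protease action and MPF repression (location-agnostic:
    valid both in the well-mixed and in the voxel-structured setting)."""
    return [
        "// pheromone secretion (released outside the secreting cell)",
        "C(v, p, M, w)[s?]:c -> C(v, p, M, w)[s?] + F_M @ ksec * c;",
        "C(v, p, P, w)[s?]:c -> C(v, p, P, w)[s?] + F_P @ ksec * c;",
        "C(v, p, M, w)[s?]:c -> C(v, p, M, w)[s?] + Sxa2 @ ksxa * c;",
        "Sxa2:x + F_P:f -> Sxa2 @ kdeg * x * f;",
        "// downward causation across the cell membrane: extracellular",
        "// pheromone of the opposite type represses MPF inside the cell",
        "F_M:f + C(v, p, P, w)[M_I:i + s?]:c -> "
        "F_M + C(v, p, P, w)[M_R + s?] "
        "@ hmax * f^3 / (hillk^3 + f^3) * i * td / v * c;",
        "F_P:f + C(v, p, M, w)[M_I:i + s?]:c -> "
        "F_P + C(v, p, M, w)[M_R + s?] "
        "@ hmax * f^3 / (hillk^3 + f^3) * i * td / v * c;",
        "// volume-proportional de-repression (adaptation with cell growth)",
        "C(v, p, t, w)[M_R:r + s?]:c -> C(v, p, t, w)[M_I + s?] "
        "@ kderep * r * v / td * c;",
    ]


def _pheromone_decay_rules() -> list[str]:
    """Uniform loss of extracellular molecules (well-mixed setting only;
    the spatial model replaces this with boundary out-diffusion)."""
    return [
        "F_M:f -> 0 @ kout * f;",
        "F_P:f -> 0 @ kout * f;",
        "Sxa2:x -> 0 @ kout * x;",
    ]


def _population_consts(p: YeastParameters,
                       with_pheromone: bool) -> list[str]:
    consts = _molecular_consts(p) + [
        f"const td = {p.t_d};",
        f"const vref = {p.v_ref!r};   // ESTIMATED dilution reference",
        f"const k6 = {p.k6!r};",
        f"const t7 = {p.t7};",
        f"const t8 = {p.t8};",
        f"const t9 = {p.t9};",
        f"const ktr = {p.k_trans!r};  // ESTIMATED",
        f"const kdeath = {p.k_death!r};",
    ]
    if with_pheromone:
        consts += [
            f"const ksec = {p.k_sec!r};    // ESTIMATED",
            f"const kout = {p.k_out!r};    // ESTIMATED",
            f"const ksxa = {p.k_sxa!r};    // ESTIMATED",
            f"const kdeg = {p.k_deg!r};    // ESTIMATED",
            f"const hmax = {p.hill_max!r}; // ESTIMATED",
            f"const hillk = {p.hill_k!r};  // ESTIMATED",
            f"const kderep = {p.k_derep!r};// ESTIMATED",
        ]
    return consts


def population_text(p: YeastParameters | None = None,
                    with_pheromone: bool = False) -> str:
    """Multicellular model: division with mating-type switching, death,
    and (optionally) pheromone communication with G1 arrest."""
    p = p or YeastParameters()
    defs = ["C(4); // volume, phase, mating type (P/M), switchability (U/S)"]
    defs += _molecular_defs(with_repressed=with_pheromone)
    if with_pheromone:
        defs += ["F_P;", "F_M;", "Sxa2;"]
    u_products, s_products = _division_products()
    lines = defs + _population_consts(p, with_pheromone) + \
        _population_cell_rules() + [
        "// division with mating-type switching; content copied entirely",
        f"C(v, M, t, U)[M_A:a + s?]:c -> {u_products} @ ktr * c if a < t9;",
        f"C(v, M, t, S)[M_A:a + s?]:c -> {s_products} @ ktr * c if a < t9;",
        "C(v, p, t, w):c -> 0 @ kdeath * c;",
    ]
    if with_pheromone:
        lines += _pheromone_core_rules() + _pheromone_decay_rules()
    lines.append(f"init {p.n0} C(td, G1, P, U)[(dtot - 1) D + M_A];")
    return "\n".join(lines) + "\n"


def build_population_model(p: YeastParameters | None = None,
                           with_pheromone: bool = False) -> Model:
    return parse_model(population_text(p, with_pheromone))


def spatial_text(p: YeastParameters | None = None) -> str:
    """Spatial model: a 2-D grid of voxels G(x, y, n_cells) holding cells
    and pheromones; von-Neumann diffusion, boundary out-diffusion, and
    displacement of cells from crowded voxels."""
    p = p or YeastParameters()
    defs = ["G(3); // grid coordinates x, y and the number of cells inside",
            "C(4);"]
    defs += _molecular_defs(with_repressed=True) + ["F_P;", "F_M;", "Sxa2;"]
    consts = _population_consts(p, with_pheromone=True) + [
        f"const xmax = {p.x_max};",
        f"const ymax = {p.y_max};",
        f"const kdiff = {p.k_diff!r};  // ESTIMATED",
        f"const kmove = {p.k_move!r};  // ESTIMATED",
    ]
    nb = ("fun nb(x1, y1, x2, y2) = "
          "if (x1 = x2 && (y1 = y2 + 1 || y1 = y2 - 1)) || "
          "(y1 = y2 && (x1 = x2 + 1 || x1 = x2 - 1)) "
          "then true else false;")
    u_products, s_products = _division_products()
    rules = _population_cell_rules() + [
        "// pheromone diffusion between von-Neumann neighbor voxels",
        "G(x1, y1, n1)[F_P:f + s1?] + G(x2, y2, n2)[s2?] -> "
        "G(x1, y1, n1)[s1?] + G(x2, y2, n2)[F_P + s2?] "
        "@ kdiff * f if nb(x1, y1, x2, y2);",
        "G(x1, y1, n1)[F_M:f + s1?] + G(x2, y2, n2)[s2?] -> "
        "G(x1, y1, n1)[s1?] + G(x2, y2, n2)[F_M + s2?] "
        "@ kdiff * f if nb(x1, y1, x2, y2);",
        "// open boundary: pheromone leaves the grid at the rim",
        "G(x, y, n)[F_P:f + s?] -> G(x, y, n)[s?] "
        "@ kout * f if x = 1 || x = xmax || y = 1 || y = ymax;",
        "G(x, y, n)[F_M:f + s?] -> G(x, y, n)[s?] "
        "@ kout * f if x = 1 || x = xmax || y = 1 || y = ymax;",
        "// excluded volume: cells are pushed towards less crowded voxels",
        "G(x1, y1, n1)[C(v, p, t, w):cc[sc?] + s1?] + G(x2, y2, n2)[s2?] -> "
        "G(x1, y1, n1 - 1)[s1?] + "
        "G(x2, y2, n2 + 1)[C(v, p, t, w)[sc?] + s2?] "
        "@ kmove * cc / (n2 + 1) if nb(x1, y1, x2, y2);",
        "// division and death with extended context: the voxel's cell",
        "// count attribute is updated alongside",
        "G(x, y, n)[C(v, M, t, U):cc[M_A:a + s?] + g?] -> "
        f"G(x, y, n + 1)[{u_products} + g?] @ ktr * cc if a < t9;",
        "G(x, y, n)[C(v, M, t, S):cc[M_A:a + s?] + g?] -> "
        f"G(x, y, n + 1)[{s_products} + g?] @ ktr * cc if a < t9;",
        "G(x, y, n)[C(v, p, t, w):cc + g?] -> G(x, y, n - 1)[g?] "
        "@ kdeath * cc;",
    ] + _pheromone_core_rules()
    voxels = []
    cx = (p.x_max + 1) // 2
    cy = (p.y_max + 1) // 2
    for x in range(1, p.x_max + 1):
        for y in range(1, p.y_max + 1):
            if x == cx and y == cy:
                voxels.append(
                    f"G({x}, {y}, {p.n0})"
                    f"[{p.n0} C(td, G1, P, U)[(dtot - 1) D + M_A]]")
            else:
                voxels.append(f"G({x}, {y}, 0)")
    lines = (defs + consts + [nb] + rules
             + ["init " + " + ".join(voxels) + ";"])
    return "\n".join(lines) + "\n"


def build_spatial_model(p: YeastParameters | None = None) -> Model:
    p = p or YeastParameters()
    if p.x_max < 1 or p.y_max < 1:
        raise ValueError("grid dimensions must be >= 1")
    return parse_model(spatial_text(p))


def birth_death_text(lam: float = 10.0, mu: float = 1.0) -> str:
    """Immigration-death process (stationary law Poisson(lam/mu))."""
    return (f"X;\nconst lam = {lam!r};\nconst mu = {mu!r};\n"
            "0 -> X @ lam;\nX:x -> 0 @ mu * x;\ninit 0;\n")


def build_birth_death(lam: float = 10.0, mu: float = 1.0) -> Model:
    return parse_model(birth_death_text(lam, mu))


#: name -> callable(params) -> model text, used by the CLI `fixtures` command
FIXTURE_BUILDERS = {
    "cycle_tyson": lambda p: cycle_text(p, "tyson"),
    "cycle_downward": lambda p: cycle_text(p, "downward"),
    "cycle_multilevel": lambda p: cycle_text(p, "multilevel"),
    "population": lambda p: population_text(p, with_pheromone=False),
    "population_pheromone": lambda p: population_text(p, with_pheromone=True),
    "spatial": lambda p: spatial_text(p),
    "birth_death": lambda p: birth_death_text(),
}
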
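"""Mass-action reaction networks.

A :class:`ReactionNetwork` is an ordered list of species, a list of
:class:`Reaction` objects with mass-action kinetics, non-negative initial
abundances (molecules), and an optional piecewise-constant stimulus
schedule for designated input species.  Each reaction's rate is

    rate = k * prod(reactant abundances ** stoichiometry) * prod(modifier abundances)

where *modifiers* affect the rate without being consumed.  Rate constants
are first-order (s^-1) when the combined reactant+modifier order is one,
and molecule^-1 s^-1 when it is two.

Networks can be serialized to a small YAML schema (see :func:`save_network`)
which is also the format of the fixture files shipped with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import InvalidNetworkError

__all__ = [
    "Reaction",
    "StimulusSegment",
    "ReactionNetwork",
    "Trajectory",
    "build_complete_unimolecular",
    "build_dose_response_prior",
    "build_modular_toy",
    "load_network",
    "save_network",
]


@dataclass
class Reaction:
    """A single mass-action reaction.

    Parameters
    ----------
    reactants, products
        Maps species name -> stoichiometric coefficient (positive int).
    modifiers
        Species that multiply the rate without being consumed.
    param
        Name of the rate-constant parameter.  Unique across the network.
    """

    reactants: dict
    products: dict
    param: str
    modifiers: tuple = ()

    def __post_init__(self):
        self.reactants = dict(self.reactants)
        self.products = dict(self.products)
        self.modifiers = tuple(self.modifiers)
        for side in (self.reactants, self.products):
            for sp, coef in side.items():
                if not (isinstance(coef, (int, np.integer)) and coef > 0):
                    raise InvalidNetworkError(
                        f"stoichiometric coefficient for {sp!r} in reaction "
                        f"{self.param!r} must be a positive integer, got {coef!r}"
                    )

    @property
    def order(self) -> int:
        """Kinetic order: total reactant stoichiometry plus modifier count."""
        return int(sum(self.reactants.values()) + len(self.modifiers))

    @property
    def units(self) -> str:
        """Units of the rate constant implied by the kinetic order."""
        order = self.order
        if order <= 1:
            return "s^-1" if order == 1 else "molecule s^-1"
        return "molecule^-%d s^-1" % (order - 1)

    def species(self):
        return set(self.reactants) | set(self.products) | set(self.modifiers)


@dataclass(frozen=True)
class StimulusSegment:
    """Piecewise-constant stimulus: ``name`` is held at ``value`` on [start, end)."""

    name: str
    value: float
    start: float
    end: float


@dataclass
class ReactionNetwork:
    species: list
    reactions: list
    initial_state: dict
    inputs: list = field(default_factory=list)  # list[StimulusSegment]
    input_species: tuple = ()
    modules: dict = field(default_factory=dict)  # module id -> [param names]
    name: str = ""

    def __post_init__(self):
        self.species = list(self.species)
        self.reactions = list(self.reactions)
        self.initial_state = {sp: float(self.initial_state.get(sp, 0.0)) for sp in self.species}
        self.input_species = tuple(self.input_species)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self):
        known = set(self.species)
        seen_params = set()
        for rxn in self.reactions:
            missing = rxn.species() - known
            if missing:
                raise InvalidNetworkError(
                    f"reaction {rxn.param!r} references unknown species {sorted(missing)}"
                )
            if rxn.param in seen_params:
                raise InvalidNetworkError(f"duplicate rate parameter name {rxn.param!r}")
            seen_params.add(rxn.param)
        for sp, x0 in self.initial_state.items():
            if not np.isfinite(x0) or x0 < 0:
                raise InvalidNetworkError(f"initial abundance of {sp!r} is {x0}, must be >= 0")
        for sp in self.input_species:
            if sp not in known:
                raise InvalidNetworkError(f"input species {sp!r} not in species list")
        for seg in self.inputs:
            if seg.name not in known:
                raise InvalidNetworkError(f"stimulus references unknown species {seg.name!r}")
        if self.modules:
            assigned = [p for params in self.modules.values() for p in params]
            if len(assigned) != len(set(assigned)):
                raise InvalidNetworkError("a reaction parameter appears in more than one module")
            unknown = set(assigned) - seen_params
            if unknown:
                raise InvalidNetworkError(f"module assignment references unknown parameters {sorted(unknown)}")

    # -- convenience -----------------------------------------------------
    @property
    def param_names(self):
        return [rxn.param for rxn in self.reactions]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def initial_vector(self) -> np.ndarray:
        return np.array([self.initial_state[sp] for sp in self.species], dtype=float)

    def module_of(self, param: str):
        for mod, params in self.modules.items():
            if param in params:
                return mod
        return None

    def is_conversion_only(self) -> bool:
        """True when every reaction is a first-order conversion A -> B with no
        modifiers and no clamped inputs (dynamics are a linear ODE)."""
        if self.input_species or self.inputs:
            return False
        for rxn in self.reactions:
            if rxn.modifiers or len(rxn.reactants) != 1 or len(rxn.products) != 1:
                return False
            if sum(rxn.reactants.values()) != 1 or sum(rxn.products.values()) != 1:
                return False
        return True

    def to_dict(self) -> dict:
        d = {
            "species": list(self.species),
            "initial_state": {k: float(v) for k, v in self.initial_state.items()},
            "reactions": [
                {
                    "reactants": {k: int(v) for k, v in r.reactants.items()},
                    "products": {k: int(v) for k, v in r.products.items()},
                    "modifiers": list(r.modifiers),
                    "param": r.param,
                }
                for r in self.reactions
            ],
        }
        if self.input_species:
            d["input_species"] = list(self.input_species)
        if self.inputs:
            d["inputs"] = [
                {"name": s.name, "value": s.value, "start": s.start, "end": s.end}
                for s in self.inputs
            ]
        if self.modules:
            d["modules"] = {k: list(v) for k, v in self.modules.items()}
        if self.name:
            d["name"] = self.name
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        reactions = [
            Reaction(
                reactants=r.get("reactants", {}),
                products=r.get("products", {}),
                modifiers=tuple(r.get("modifiers", ())),
                param=r["param"],
            )
            for r in d.get("reactions", [])
        ]
        inputs = [
            StimulusSegment(s["name"], float(s["value"]), float(s["start"]), float(s["end"]))
            for s in d.get("inputs", [])
        ]
        return cls(
            species=d["species"],
            reactions=reactions,
            initial_state=d.get("initial_state", {}),
            inputs=inputs,
            input_species=tuple(d.get("input_species", ())),
            modules={k: list(v) for k, v in d.get("modules", {}).items()},
            name=d.get("name", ""),
        )


@dataclass
class Trajectory:
    """Simulated abundances on a strictly increasing time grid.

    ``values`` has shape (n_times, n_species); column order follows
    ``species``.  Small negative integrator slop is clipped to zero by the
    simulator before a Trajectory is constructed.
    """

    times: np.ndarray
    values: np.ndarray
    species: tuple

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.species = tuple(self.species)

    def series(self, species: str) -> np.ndarray:
        return self.values[:, self.species.index(species)]

    def value_at(self, species: str, time: float) -> float:
        idx = np.flatnonzero(np.isclose(self.times, time, rtol=1e-9, atol=1e-9))
        if idx.size == 0:
            raise KeyError(f"time {time} not on trajectory grid")
        return float(self.values[idx[0], self.species.index(species)])

    def total(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_frame(self):
        """Tidy long-format frame with columns time, species, value."""
        import pandas as pd

        n_t = len(self.times)
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, len(self.species)),
                "species": list(self.species) * n_t,
                "value": self.values.reshape(-1),
            }
        )

    def write_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _node_name(i: int) -> str:
    if i < 26:
        return chr(ord("A") + i)
    return f"S{i}"


def build_complete_unimolecular(n: int) -> ReactionNetwork:
    """Complete directed graph on ``n`` species with one first-order
    conversion per ordered pair (n*(n-1) reactions).

    Node A starts with 100 molecules; every other species starts at 0.
    For n=3 this is the 6-reaction fully connected network used as the
    prior model for inferring the A->B->C pulse-generator motif.
    """
    if n < 2:
        raise InvalidNetworkError(f"complete unimolecular network needs n >= 2, got {n}")
    species = [_node_name(i) for i in range(n)]
    reactions = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            reactions.append(
                Reaction(
                    reactants={species[i]: 1},
                    products={species[j]: 1},
                    param=f"k_{species[i]}{species[j]}",
                )
            )
    initial = {species[0]: 100.0}
    return ReactionNetwork(
        species=species,
        reactions=reactions,
        initial_state=initial,
        name=f"complete-{n}-node",
    )


def build_dose_response_prior() -> ReactionNetwork:
    """Combined linear + perfectly-adapting dose-response prior network.

    Signal S is a clamped input, response R is observed, intermediate X is
    not.  The union of the two Tyson motifs contributes five named
    parameters: ``k_s-rs`` (S-driven R production), ``k_r-0`` (R decay),
    ``k_s-xs`` (S-driven X production), ``k_x-0`` (X decay) and ``k_xr-x``
    (X-catalyzed R removal).  The sixth reaction of the six-parameter prior
    is taken as basal (zero-order) production of R, ``k_0-r`` -- the basal
    synthesis term of Tyson's linear-response motif.  This reconciliation
    choice is a property of this fixture, made because only the five
    parameters above are named in the figure captions.
    """
    reactions = [
        Reaction(reactants={}, products={"R": 1}, modifiers=("S",), param="k_s-rs"),
        Reaction(reactants={"R": 1}, products={}, param="k_r-0"),
        Reaction(reactants={}, products={"X": 1}, modifiers=("S",), param="k_s-xs"),
        Reaction(reactants={"X": 1}, products={}, param="k_x-0"),
        Reaction(reactants={"R": 1}, products={}, modifiers=("X",), param="k_xr-x"),
        Reaction(reactants={}, products={"R": 1}, param="k_0-r"),
    ]
    return ReactionNetwork(
        species=["S", "R", "X"],
        reactions=reactions,
        initial_state={"S": 0.0, "R": 0.0, "X": 0.0},
        input_species=("S",),
        name="dose-response-prior",
    )


def build_modular_toy() -> ReactionNetwork:
    """Small three-module feedback network (synthetic desk-scale fixture).

    This network is an artifact of this package, built so that grouped
    (module-level) Lasso selection can be exercised without any external
    model: a stimulus S activates A, A drives the response R, and A also
    induces a feedback inhibitor F that removes A.  Under a short stimulus
    pulse the feedback module barely engages and is dispensable for fitting
    R; under continuous stimulation the feedback is what makes the response
    adapt, so it is required.  It is NOT a model of any published signaling
    pathway.

    Modules (each reaction belongs to exactly one):
      activation: ``k_sa`` (S-driven A production), ``k_a0`` (A decay)
      response:   ``k_ar`` (A-driven R production), ``k_r0`` (R decay)
      feedback:   ``k_af`` (A-driven F production), ``k_fa`` (F-catalyzed A removal)
    """
    reactions = [
        Reaction(reactants={}, products={"A": 1}, modifiers=("S",), param="k_sa"),
        Reaction(reactants={"A": 1}, products={}, param="k_a0"),
        Reaction(reactants={}, products={"R": 1}, modifiers=("A",), param="k_ar"),
        Reaction(reactants={"R": 1}, products={}, param="k_r0"),
        Reaction(reactants={}, products={"F": 1}, modifiers=("A",), param="k_af"),
        Reaction(reactants={"A": 1}, products={}, modifiers=("F",), param="k_fa"),
    ]
    modules = {
        "activation": ["k_sa", "k_a0"],
        "response": ["k_ar", "k_r0"],
        "feedback": ["k_af", "k_fa"],
    }
    return ReactionNetwork(
        species=["S", "A", "R", "F"],
        reactions=reactions,
        initial_state={"S": 0.0, "A": 0.0, "R": 0.0, "F": 0.0},
        input_species=("S",),
        modules=modules,
        name="modular-toy",
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def save_network(network: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network.to_dict(), fh, sort_keys=False)


def load_network(path) -> ReactionNetwork:
    with open(path) as fh:
        return ReactionNetwork.from_dict(yaml.safe_load(fh))
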
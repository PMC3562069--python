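"""Mass-action reaction networks and their deterministic integration.

A :class:`ReactionNetwork` is a list of species with non-negative copy
numbers, a list of elementary reactions (mass action, zeroth-order
synthesis, first-order degradation), and a parameter table mapping rate
constant names to values.  Units follow the Albeck-model convention:
amounts in molecules per cell, time in hours.

The only non-elementary rate law supported is a saturating inhibition
multiplier ``1 / (1 + [I]/K)`` attached to a reaction; it exists for the
ROS-driven cFLIP module, where "inhibition of production/degradation"
cannot be written as an elementary step without extra machinery species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "Reaction",
    "Event",
    "ReactionNetwork",
    "Trajectory",
    "NetworkDefinitionError",
    "IntegrationError",
    "assemble_rates",
    "set_turnover",
    "integrate",
    "default_grid",
]

MASS_ACTION = "mass_action"
SYNTHESIS = "zeroth_order_synthesis"
DEGRADATION = "first_order_degradation"
_KINDS = (MASS_ACTION, SYNTHESIS, DEGRADATION)


class NetworkDefinitionError(ValueError):
    """A reaction references unknown species or violates its kind's shape."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; the message reports the time of failure."""


@dataclass(frozen=True)
class Species:
    name: str
    initial_amount: float = 0.0
    is_observable: bool = True
    compartment_tag: str = "cytosol"

    def __post_init__(self):
        if self.initial_amount < 0:
            raise NetworkDefinitionError(
                f"species {self.name!r}: initial amount must be >= 0"
            )


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction.

    ``rate_param`` names an entry of the network parameter table.
    ``modifiers`` enter the flux like reactants but have zero net
    stoichiometry (catalysts).  ``inhibitors`` is a tuple of
    ``(species, K_param)`` pairs applying a saturating multiplier
    ``1/(1 + [species]/K)`` to the flux — the one sanctioned departure
    from elementary kinetics.
    """

    name: str
    reactants: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    modifiers: tuple[str, ...] = ()
    rate_param: str = ""
    kind: str = MASS_ACTION
    inhibitors: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise NetworkDefinitionError(
                f"reaction {self.name!r}: unknown kind {self.kind!r}"
            )
        if self.kind == SYNTHESIS and self.reactants:
            raise NetworkDefinitionError(
                f"reaction {self.name!r}: zeroth-order synthesis takes no reactants"
            )
        if self.kind == DEGRADATION and (
            len(self.reactants) != 1 or self.products
        ):
            raise NetworkDefinitionError(
                f"reaction {self.name!r}: first-order degradation needs exactly "
                "one reactant and no products"
            )


@dataclass(frozen=True)
class Event:
    """Set a species amount or a parameter value at a fixed time (hours)."""

    time: float
    target: str
    new_value: float

    def __post_init__(self):
        if self.new_value < 0:
            raise ValueError(f"event on {self.target!r}: new value must be >= 0")


class ReactionNetwork:
    """Species, reactions and rate parameters; the simulatable model."""

    def __init__(self, name: str = "network"):
        self.name = name
        self.species: dict[str, Species] = {}
        self.reactions: list[Reaction] = []
        self.parameters: dict[str, float] = {}

    # -- construction -------------------------------------------------

    def add_species(self, name, initial_amount=0.0, *, is_observable=True,
                    compartment_tag="cytosol"):
        if name in self.species:
            raise NetworkDefinitionError(f"duplicate species {name!r}")
        self.species[name] = Species(name, float(initial_amount),
                                     is_observable, compartment_tag)
        return self

    def set_parameter(self, name, value):
        if value < 0:
            raise NetworkDefinitionError(f"parameter {name!r} must be >= 0")
        self.parameters[name] = float(value)
        return self

    def add_reaction(self, name, reactants=(), products=(), *, modifiers=(),
                     k=None, rate_param=None, kind=MASS_ACTION, inhibitors=()):
        """Append a reaction; ``k`` creates/overwrites its rate parameter.

        ``inhibitors`` entries may be ``(species, K_param)`` or
        ``(species, K_param, K_value)``.
        """
        if any(r.name == name for r in self.reactions):
            raise NetworkDefinitionError(f"duplicate reaction {name!r}")
        rate_param = rate_param or f"k_{name}"
        if k is not None:
            self.set_parameter(rate_param, k)
        elif rate_param not in self.parameters:
            raise NetworkDefinitionError(
                f"reaction {name!r}: rate parameter {rate_param!r} undefined"
            )
        inh = []
        for entry in inhibitors:
            if len(entry) == 3:
                sp, kp, kv = entry
                self.set_parameter(kp, kv)
            else:
                sp, kp = entry
                if kp not in self.parameters:
                    raise NetworkDefinitionError(
                        f"reaction {name!r}: inhibition constant {kp!r} undefined"
                    )
            inh.append((sp, kp))
        rxn = Reaction(name, tuple(reactants), tuple(products),
                       tuple(modifiers), rate_param, kind, tuple(inh))
        for sp in itertools.chain(rxn.reactants, rxn.products, rxn.modifiers,
                                  (s for s, _ in rxn.inhibitors)):
            if sp not in self.species:
                raise NetworkDefinitionError(
                    f"reaction {name!r} references unknown species {sp!r}"
                )
        self.reactions.append(rxn)
        return self

    # -- queries ------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return list(self.species)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species.values()])

    def has_species(self, name) -> bool:
        return name in self.species

    def set_initial_amount(self, name, amount):
        self.species[name] = replace(self.species[name],
                                     initial_amount=float(amount))
        return self

    def copy(self) -> "ReactionNetwork":
        new = ReactionNetwork(self.name)
        new.species = dict(self.species)
        new.reactions = list(self.reactions)
        new.parameters = dict(self.parameters)
        return new

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": [
                {"name": s.name, "initial_amount": s.initial_amount,
                 "is_observable": s.is_observable,
                 "compartment_tag": s.compartment_tag}
                for s in self.species.values()
            ],
            "parameters": dict(self.parameters),
            "reactions": [
                {"name": r.name, "reactants": list(r.reactants),
                 "products": list(r.products), "modifiers": list(r.modifiers),
                 "rate_param": r.rate_param, "kind": r.kind,
                 "inhibitors": [list(i) for i in r.inhibitors]}
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ReactionNetwork":
        net = cls(data.get("name", "network"))
        try:
            for s in data["species"]:
                net.add_species(s["name"], s["initial_amount"],
                                is_observable=s.get("is_observable", True),
                                compartment_tag=s.get("compartment_tag", "cytosol"))
            for p, v in data.get("parameters", {}).items():
                net.set_parameter(p, v)
            for r in data["reactions"]:
                net.add_reaction(
                    r["name"], r.get("reactants", ()), r.get("products", ()),
                    modifiers=r.get("modifiers", ()),
                    rate_param=r["rate_param"], kind=r.get("kind", MASS_ACTION),
                    inhibitors=[tuple(i) for i in r.get("inhibitors", ())],
                )
        except KeyError as exc:
            raise NetworkDefinitionError(f"malformed network config: missing {exc}")
        return net

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ReactionNetwork":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise NetworkDefinitionError(f"malformed network config in {path}")
        return cls.from_dict(data)


class CompiledRates:
    """Vectorised derivative function for a network.

    Evaluates all mass-action fluxes in a handful of numpy operations:
    each flux is ``k * ext[f0] * ext[f1] * ext[f2]`` over an extended
    state whose last slot is the constant 1 (padding for reactions of
    order < 3).  Reactions of order > 3 (reactants + modifiers) are
    rejected; none occur in the apoptosis models.
    """

    MAX_ORDER = 3

    def __init__(self, network: ReactionNetwork):
        self.network = network
        names = network.species_names
        self.index = {n: i for i, n in enumerate(names)}
        n = len(names)
        m = len(network.reactions)
        self.n_species = n
        dummy = n
        factors = np.full((m, self.MAX_ORDER), dummy, dtype=np.intp)
        S = np.zeros((n, m))
        self._inhibitors: list[tuple[int, int, str]] = []
        self._rate_params = []
        for j, r in enumerate(network.reactions):
            terms = list(r.reactants) + list(r.modifiers)
            if len(terms) > self.MAX_ORDER:
                raise NetworkDefinitionError(
                    f"reaction {r.name!r}: order {len(terms)} > {self.MAX_ORDER}"
                )
            for col, sp in enumerate(terms):
                factors[j, col] = self.index[sp]
            for sp in r.reactants:
                S[self.index[sp], j] -= 1.0
            for sp in r.products:
                S[self.index[sp], j] += 1.0
            for sp, kp in r.inhibitors:
                self._inhibitors.append((j, self.index[sp], kp))
            self._rate_params.append(r.rate_param)
        self._factors = factors
        self.stoichiometry = S
        self._ext = np.empty(n + 1)
        self._ext[-1] = 1.0
        self.refresh_parameters()

    def refresh_parameters(self, overrides: dict[str, float] | None = None):
        """Re-read rate constants from the network table (plus overrides)."""
        table = dict(self.network.parameters)
        if overrides:
            table.update(overrides)
        self._k = np.array([table[p] for p in self._rate_params])
        self._Ki = [(j, si, table[kp]) for j, si, kp in self._inhibitors]

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        ext = self._ext
        np.clip(y, 0.0, None, out=ext[:-1])
        f = self._factors
        flux = self._k * ext[f[:, 0]] * ext[f[:, 1]] * ext[f[:, 2]]
        for j, si, K in self._Ki:
            flux[j] /= 1.0 + ext[si] / K
        return flux

    def __call__(self, t, y):
        return self.stoichiometry @ self.fluxes(y)


def assemble_rates(network: ReactionNetwork) -> CompiledRates:
    """Compile the network into a callable ``f(t, y) -> dy/dt``."""
    return CompiledRates(network)


def set_turnover(network: ReactionNetwork, species_subset) -> ReactionNetwork:
    """Add zeroth-order synthesis balancing each species' degradation.

    For every species in ``species_subset`` there must already be a
    first-order degradation reaction with a positive rate constant; the
    synthesis rate is set to ``k_deg * initial_amount`` so the
    treatment-free network rests at its initial state.  Returns a new
    network.
    """
    net = network.copy()
    for sp in species_subset:
        if sp not in net.species:
            raise NetworkDefinitionError(f"unknown species {sp!r}")
        deg = [r for r in net.reactions
               if r.kind == DEGRADATION and r.reactants == (sp,)]
        if not deg:
            raise NetworkDefinitionError(
                f"species {sp!r} has no first-order degradation reaction"
            )
        k_deg = net.parameters[deg[0].rate_param]
        if k_deg <= 0:
            raise NetworkDefinitionError(
                f"species {sp!r}: degradation constant must be > 0 for turnover"
            )
        rate = k_deg * net.species[sp].initial_amount
        net.add_reaction(f"synth_{sp}", (), (sp,), k=rate, kind=SYNTHESIS)
    return net


@dataclass
class Trajectory:
    """Time grid (hours) and species-by-time amounts, clipped at 0."""

    times: np.ndarray
    values: np.ndarray  # shape (n_species, n_times)
    species: list[str] = field(default_factory=list)

    def get(self, name: str) -> np.ndarray:
        return self.values[self.species.index(name)]

    def at(self, name: str, t: float) -> float:
        return float(np.interp(t, self.times, self.get(name)))

    def to_frame(self):
        """Tidy (time, species, amount) table."""
        import pandas as pd

        return pd.DataFrame({
            "time": np.repeat(self.times, len(self.species)),
            "species": np.tile(self.species, len(self.times)),
            "amount": self.values.T.ravel(),
        })


def default_grid(t_end: float = 24.0, t_start: float = 0.0,
                 step: float = 0.1) -> np.ndarray:
    n = int(round((t_end - t_start) / step))
    return t_start + step * np.arange(n + 1)


def integrate(network: ReactionNetwork, events=(), time_grid=None, *,
              rtol: float = 1e-6, atol: float = 1e-3,
              parameter_overrides: dict[str, float] | None = None,
              initial_state: np.ndarray | None = None) -> Trajectory:
    """Integrate the network ODEs with stop-and-restart timed events.

    Events are applied in time order; the integration is restarted at
    each event time, so a grid point coinciding with an event reports
    the post-event state.  The stiff LSODA solver is used throughout
    (copy numbers span several orders of magnitude).  A negative
    undershoot beyond ``1e-6`` of the largest initial amount aborts;
    smaller undershoot is clipped to zero on output.
    """
    if time_grid is None:
        time_grid = default_grid()
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.ndim != 1 or len(time_grid) < 2 or np.any(np.diff(time_grid) <= 0):
        raise ValueError("time grid must be strictly increasing with >= 2 points")
    events = sorted(events, key=lambda e: e.time)
    if events and events[0].time < time_grid[0]:
        raise ValueError(
            f"event at t={events[0].time} precedes grid start {time_grid[0]}"
        )
    rates = assemble_rates(network)
    overrides = dict(parameter_overrides or {})
    if overrides:
        rates.refresh_parameters(overrides)
    y = (network.initial_state() if initial_state is None
         else np.asarray(initial_state, dtype=float).copy())
    if len(y) != rates.n_species:
        raise ValueError("initial state length mismatch")

    undershoot_tol = 1e-6 * max(1.0, float(y.max()))
    out = np.empty((rates.n_species, len(time_grid)))
    t = time_grid[0]
    written = 0

    def apply_event(ev: Event):
        nonlocal y
        if network.has_species(ev.target):
            y[rates.index[ev.target]] = ev.new_value
        elif ev.target in network.parameters or ev.target in overrides:
            overrides[ev.target] = ev.new_value
            rates.refresh_parameters(overrides)
        else:
            raise NetworkDefinitionError(
                f"event targets unknown species/parameter {ev.target!r}"
            )

    # events at or before the first grid point take effect immediately
    pending = []
    for ev in events:
        if ev.time <= time_grid[0]:
            apply_event(ev)
        else:
            pending.append(ev)

    # first grid point reports the (post-event) initial state
    out[:, 0] = y
    written = 1
    t = time_grid[0]
    remaining = list(pending)
    while t < time_grid[-1]:
        t_stop = remaining[0].time if remaining else time_grid[-1]
        if t_stop > t:
            mask = (time_grid > t) & (time_grid < t_stop)
            if t_stop == time_grid[-1]:
                mask |= time_grid == t_stop
            t_eval = np.append(time_grid[mask], t_stop)
            t_eval = np.unique(t_eval)
            sol = solve_ivp(rates, (t, t_stop), y, method="LSODA",
                            t_eval=t_eval, rtol=rtol, atol=atol)
            if not sol.success:
                raise IntegrationError(
                    f"solver failed near t={sol.t[-1] if len(sol.t) else t:.4g} h: "
                    f"{sol.message}"
                )
            n_grid = int(mask.sum())
            out[:, written:written + n_grid] = sol.y[:, :len(t_eval)][
                :, np.isin(t_eval, time_grid[mask])]
            written += n_grid
            y = sol.y[:, -1].copy()
            if y.min() < -undershoot_tol:
                bad = rates.network.species_names[int(np.argmin(y))]
                raise IntegrationError(
                    f"negative undershoot in {bad!r} at t={t_stop:.4g} h "
                    f"({y.min():.3g})"
                )
        while remaining and remaining[0].time <= t_stop:
            apply_event(remaining.pop(0))
        t = t_stop
        # a grid point exactly at an event time reports the post-event state
        if t < time_grid[-1] and np.any(time_grid == t):
            out[:, written] = y
            written += 1
    if written != len(time_grid):
        raise IntegrationError("internal bookkeeping error in event handling")
    return Trajectory(time_grid.copy(), np.clip(out, 0.0, None),
                      network.species_names)
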
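"""Two-species ROS model of non-monotonic cFLIP regulation.

LY30 drives superoxide production; superoxide is converted into
hydrogen peroxide, which is cleared by first-order degradation.  The
two ROS species pull cFLIP in opposite directions on different
timescales: superoxide (fast) inhibits cFLIP degradation, raising
cFLIP within ~30 min, while H2O2 (slow, accumulating) inhibits cFLIP
mRNA production, dropping cFLIP below baseline within a few hours.
Both inhibitions are saturating multipliers ``1/(1 + [ROS]/K)`` — the
only non-elementary rate laws in the package.

Scavenger interventions add a first-order removal reaction for one ROS
species: Tiron removes superoxide (pre-incubated 1 h before LY30) and
catalase removes H2O2 (present from time zero).

Amounts are arbitrary concentration units with the untreated cFLIP and
cFLIP mRNA steady states equal to 1; LY30 is in µM; time in hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import LY30_UNITS_PER_UM, ModelVariant
from .network import Event, ReactionNetwork, Trajectory, default_grid, integrate

__all__ = [
    "ScavengerIntervention",
    "build_ros_cflip_network",
    "apply_scavenger",
    "simulate_ros_cflip",
    "cflip_fold_change",
    "couple_to_apoptosis",
    "ROS_CFLIP_RATES",
]

SUPEROXIDE = "superoxide"
H2O2 = "H2O2"

#: default kinetic constants (hours; LY30 in µM)
ROS_CFLIP_RATES = {
    "k_ly30_decay": 0.9,      # drug clearance; gives superoxide its peak
    "k_sox_prod": 0.4,        # LY30 -> LY30 + superoxide, per µM per h
    "k_sox_conv": 4.0,        # superoxide -> H2O2 (fast dismutation)
    "k_h2o2_deg": 0.4,        # slow H2O2 clearance (accumulates for hours)
    "k_mrna_prod": 0.8,       # cFLIP transcription (H2O2-inhibited)
    "k_mrna_deg": 0.8,
    "k_translate": 1.5,       # cFLIP_mRNA --> cFLIP
    "k_cflip_deg": 1.5,       # cFLIP -> cFLIP_Deg (superoxide-inhibited)
    "K_sox": 1.0,             # half-inhibition of cFLIP degradation
    "K_h2o2": 2.0,            # half-inhibition of cFLIP production
}


@dataclass(frozen=True)
class ScavengerIntervention:
    """First-order removal of exactly one ROS species.

    Tiron is pre-incubated (default start −1 h, i.e. before the LY30
    input at time zero); catalase is present from time zero of a
    pre-equilibrated state.
    """

    kind: str  # "tiron_superoxide" | "catalase_h2o2"
    start_time: float | None = None
    removal_rate: float = 100.0

    def __post_init__(self):
        if self.kind not in ("tiron_superoxide", "catalase_h2o2"):
            raise ValueError(f"unknown scavenger kind {self.kind!r}")
        if self.removal_rate < 0:
            raise ValueError("removal rate must be >= 0")
        if self.start_time is None:
            object.__setattr__(
                self, "start_time",
                -1.0 if self.kind == "tiron_superoxide" else 0.0)

    @property
    def target(self) -> str:
        return SUPEROXIDE if self.kind == "tiron_superoxide" else H2O2

    @property
    def rate_param(self) -> str:
        return f"k_{self.kind}"


def build_ros_cflip_network(overrides: dict[str, float] | None = None,
                            two_to_one_dismutation: bool = False,
                            ) -> ReactionNetwork:
    """The LY30 → (superoxide, H2O2) → cFLIP network.

    With ``two_to_one_dismutation`` the conversion consumes two
    superoxide molecules per H2O2 produced (the textbook dismutation
    stoichiometry); the default is 1:1 mass flow.
    """
    rates = dict(ROS_CFLIP_RATES)
    if overrides:
        rates.update(overrides)
    net = ReactionNetwork("ros_cflip")
    net.add_species("LY30", 0.0)
    net.add_species(SUPEROXIDE, 0.0)
    net.add_species(H2O2, 0.0)
    # untreated steady state: mRNA = k_mrna_prod/k_mrna_deg, cFLIP =
    # k_translate*mRNA/k_cflip_deg
    mrna0 = rates["k_mrna_prod"] / rates["k_mrna_deg"]
    net.add_species("cFLIP_mRNA", mrna0)
    net.add_species("cFLIP", rates["k_translate"] * mrna0 / rates["k_cflip_deg"])
    net.add_species("cFLIP_Deg", 0.0)
    for name, value in rates.items():
        net.set_parameter(name, value)
    net.add_reaction("ly30_decay", ("LY30",), (), rate_param="k_ly30_decay",
                     kind="first_order_degradation")
    net.add_reaction("sox_prod", (), (SUPEROXIDE,), modifiers=("LY30",),
                     rate_param="k_sox_prod")
    conv_reactants = ((SUPEROXIDE, SUPEROXIDE) if two_to_one_dismutation
                      else (SUPEROXIDE,))
    net.add_reaction("sox_conv", conv_reactants, (H2O2,),
                     rate_param="k_sox_conv")
    net.add_reaction("h2o2_deg", (H2O2,), (), rate_param="k_h2o2_deg",
                     kind="first_order_degradation")
    net.add_reaction("mrna_prod", (), ("cFLIP_mRNA",),
                     rate_param="k_mrna_prod", kind="zeroth_order_synthesis",
                     inhibitors=((H2O2, "K_h2o2"),))
    net.add_reaction("mrna_deg", ("cFLIP_mRNA",), (), rate_param="k_mrna_deg",
                     kind="first_order_degradation")
    net.add_reaction("translate", (), ("cFLIP",), modifiers=("cFLIP_mRNA",),
                     rate_param="k_translate")
    net.add_reaction("cflip_deg", ("cFLIP",), ("cFLIP_Deg",),
                     rate_param="k_cflip_deg",
                     inhibitors=((SUPEROXIDE, "K_sox"),))
    return net


def apply_scavenger(network: ReactionNetwork,
                    intervention: ScavengerIntervention) -> ReactionNetwork:
    """Add the intervention's removal reaction (rate applied from its
    start time by :func:`simulate_ros_cflip`)."""
    if any(r.name == intervention.kind for r in network.reactions):
        raise ValueError(f"{intervention.kind} already applied")
    net = network.copy()
    net.add_reaction(intervention.kind, (intervention.target,), (),
                     k=0.0, rate_param=intervention.rate_param,
                     kind="first_order_degradation")
    return net


def simulate_ros_cflip(network: ReactionNetwork, ly30_dose_um: float = 25.0,
                       interventions=(), t_end: float = 8.0,
                       step: float = 0.01) -> Trajectory:
    """Integrate from the LY30-free steady state with an LY30 step at 0.

    The grid starts early enough to cover any pre-incubated scavenger;
    each scavenger's removal rate switches on at its start time.
    """
    net = network
    events = [Event(0.0, "LY30", float(ly30_dose_um))]
    t_start = 0.0
    seen = set()
    for iv in interventions:
        if iv.kind in seen:
            raise ValueError(f"duplicate intervention {iv.kind}")
        seen.add(iv.kind)
        net = apply_scavenger(net, iv)
        t_start = min(t_start, iv.start_time)
        events.append(Event(iv.start_time, iv.rate_param, iv.removal_rate))
    grid = default_grid(t_end, t_start, step)
    if 0.0 not in grid:
        grid = np.sort(np.append(grid, 0.0))
    return integrate(net, events, grid)


def cflip_fold_change(trajectory: Trajectory, times,
                      baseline_time: float = 0.0) -> np.ndarray:
    """cFLIP(t)/cFLIP(baseline) at the requested times."""
    base = trajectory.at("cFLIP", baseline_time)
    if base <= 0:
        raise ValueError("baseline cFLIP must be positive")
    return np.array([trajectory.at("cFLIP", t) for t in np.atleast_1d(times)]) / base


def couple_to_apoptosis(variant: ModelVariant,
                        ros_network: ReactionNetwork | None = None,
                        ) -> ModelVariant:
    """Replace the constant-rate LY30-driven cFLIP decay of the
    combination model with the dynamic ROS-driven cFLIP submodel.

    Shared species are merged by name mapping (the ROS model's cFLIP is
    the apoptosis model's ``flip``; LY30 is shared).  Translation and
    superoxide production are rescaled so that the merged model keeps
    the apoptosis model's cFLIP copy number at steady state and sees
    LY30 in its copy-number input units.  The drug input is treated as
    non-depleting, like the rest of the combination model.
    """
    if ros_network is None:
        ros_network = build_ros_cflip_network()
    apop = variant.network
    if not any(r.name == "flip_deg_ly30" for r in apop.reactions):
        raise ValueError("variant has no LY30-driven cFLIP decay to replace")
    mapping = {"cFLIP": "flip", "LY30": "LY30"}
    net = apop.copy()
    net.reactions = [r for r in net.reactions if r.name != "flip_deg_ly30"]
    for sp in ros_network.species.values():
        if sp.name in mapping:
            continue
        if net.has_species(sp.name):
            raise ValueError(f"species name collision on {sp.name!r}")
        net.add_species(sp.name, sp.initial_amount,
                        compartment_tag=sp.compartment_tag)
    for name, value in ros_network.parameters.items():
        if name == "k_ly30_decay":
            continue  # the combination model owns the drug input dynamics
        if name in net.parameters:
            raise ValueError(f"parameter name collision on {name!r}")
        net.set_parameter(name, value)
    flip0 = apop.species["flip"].initial_amount
    mrna0 = ros_network.species["cFLIP_mRNA"].initial_amount
    # cFLIP translation in copies/cell; superoxide production per LY30
    # copy-number unit instead of per µM
    net.set_parameter("k_translate",
                      ros_network.parameters["k_cflip_deg"] * flip0 / mrna0)
    net.set_parameter("k_sox_prod",
                      ros_network.parameters["k_sox_prod"] / LY30_UNITS_PER_UM)
    for r in ros_network.reactions:
        if r.name == "ly30_decay":
            continue  # non-depleting input in the combination model
        net.add_reaction(
            f"rc_{r.name}",
            tuple(mapping.get(s, s) for s in r.reactants),
            tuple(mapping.get(s, s) for s in r.products),
            modifiers=tuple(mapping.get(s, s) for s in r.modifiers),
            rate_param=r.rate_param, kind=r.kind,
            inhibitors=tuple((mapping.get(s, s), kp)
                             for s, kp in r.inhibitors),
        )
    return ModelVariant(variant.variant_tag + "_ros_cflip", net,
                        variant.schedule, variant.events)
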
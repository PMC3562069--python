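"""Builders for the TRAIL, LY30 and combination apoptosis networks.

The base network is an Albeck-style extrinsic-apoptosis model for HeLa
cells, condensed to the receptor → DISC → caspase-8 → caspase-3 axis
with the mitochondrial amplification loop (tBid, Bax, Bcl2, pore,
cytochrome c / Smac release, apoptosome, XIAP), and modified as follows:

* active caspase-3 feeds back onto caspase-9 activation;
* caspase-3 activates caspase-8 directly (no caspase-6 intermediate);
* cFLIP starts at an elevated level (the cycloheximide-era value was
  artificially low);
* ARC, not BAR, is the stoichiometric caspase-8 inhibitor;
* synthesis/degradation turnover is modelled for caspases only, with
  synthesis balancing degradation at the untreated state.

The LY30 extension adds receptor priming (an LY30-catalysed conversion
of the receptor into a faster-binding form), LY30-catalysed cFLIP
degradation, and LY30-driven ROS with two pro-death channels: weak
ROS-catalysed Bax activation (mitochondrial permeability) and a direct
ROS → PARP-cleavage channel that is enabled only in a small flagged
subpopulation of cells (mitochondria-independent death).

Amounts are molecules per cell and time is hours.  Dose conversions
(ng/ml TRAIL and µM LY30 into copy numbers / input units) are
configurable module constants; rate values are calibration defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import Event, ReactionNetwork, set_turnover

__all__ = [
    "TreatmentSchedule",
    "ModelVariant",
    "build_trail_network",
    "build_ly30_extension",
    "make_schedule",
    "build_variant",
    "TRAIL_COPIES_PER_NGML",
    "LY30_UNITS_PER_UM",
    "CASPASE_SPECIES",
    "RECEPTOR_SPECIES",
    "ROS_PARP_RATE_FLAGGED",
]

# dose conversions (the source experiments report ng/ml and µM; copy
# numbers per cell are the model's working units)
TRAIL_COPIES_PER_NGML = 60.0   # 20 ng/ml -> 1200 ligand copies
LY30_UNITS_PER_UM = 40.0       # 25 µM -> 1000 input units

#: caspase pro-forms subject to synthesis/degradation turnover
CASPASE_SPECIES = ("pC8", "pC3", "pC9")

#: all receptor-containing forms (conserved in the absence of turnover)
RECEPTOR_SPECIES = ("R", "R_primed", "DISC", "flip_DISC")

#: ROS->PARP rate constant in the mitochondria-independent subpopulation
ROS_PARP_RATE_FLAGGED = 4.0e-4

#: initial copy numbers (untreated HeLa-like state)
INITIAL_AMOUNTS = {
    "TRAIL": 0.0,
    "R": 200.0,
    "R_primed": 0.0,
    "DISC": 0.0,
    "flip": 1000.0,        # elevated ~10x over the cycloheximide-era value
    "flip_DISC": 0.0,
    "ARC": 1000.0,
    "ARC_C8": 0.0,
    "pC8": 20000.0,
    "C8a": 0.0,
    "pC3": 10000.0,
    "C3a": 0.0,
    "C3_ub": 0.0,
    "XIAP": 30000.0,
    "XIAP_C3": 0.0,
    "pC9": 10000.0,
    "C9a": 0.0,
    "Bid": 40000.0,
    "tBid": 0.0,
    "Bax": 100000.0,
    "Bax_a": 0.0,
    "Bax2": 0.0,
    "Bcl2": 30000.0,
    "Bax_Bcl2": 0.0,
    "Pore": 0.0,
    "CytoC_m": 500000.0,
    "CytoC": 0.0,
    "Smac_m": 100000.0,
    "Smac": 0.0,
    "Smac_XIAP": 0.0,
    "Apaf": 100000.0,
    "Apaf_a": 0.0,
    "Apop": 0.0,
    "PARP": 1000000.0,
    "cPARP": 0.0,
}

_MITO_TAG = {"CytoC_m", "Smac_m", "Bax", "Bax_a", "Bax2", "Bcl2", "Bax_Bcl2",
             "Pore"}
_EXTRA_TAG = {"TRAIL"}

#: default rate constants (per hour; bimolecular per molecule per hour)
TRAIL_RATES = {
    "k_bind": 1.8e-4,          # TRAIL + R -> DISC (slow, unprimed)
    "k_flip_bind": 7.2e-3,     # DISC + flip -> flip_DISC
    "k_flip_unbind": 0.02,
    "k_c8_act_disc": 1.08e-3,   # pC8 --DISC--> C8a
    "k_arc_bind": 3.6e-3,      # C8a + ARC -> ARC_C8
    "k_arc_unbind": 0.1,
    "k_arc_degrade": 0.25,     # ARC_C8 -> ARC (bound C8a degraded)
    "k_c3_act_c8": 3.6e-4,     # pC3 --C8a--> C3a
    "k_xiap_bind": 1.44e-3,     # C3a + XIAP -> XIAP_C3
    "k_xiap_unbind": 0.1,
    "k_xiap_degrade": 1.0,     # XIAP_C3 -> XIAP + C3_ub
    "k_c8_feedback": 1.08e-4,   # pC8 --C3a--> C8a (no caspase-6)
    "k_bid_cleave": 1.8e-4,    # Bid --C8a--> tBid
    "k_bax_act": 3.6e-5,       # Bax --tBid--> Bax_a
    "k_bax_deact": 0.05,       # Bax_a -> Bax (spontaneous reversal)
    "k_bcl2_bind": 3.6e-3,     # Bax_a + Bcl2 -> Bax_Bcl2
    "k_bcl2_unbind": 0.1,
    "k_bcl2_deact": 0.2,       # Bax_Bcl2 -> Bax + Bcl2 (buffer recycling)
    "k_bax_dimer": 3.6e-4,     # 2 Bax_a -> Bax2
    "k_bax_undimer": 0.1,
    "k_pore_form": 3.6e-4,     # 2 Bax2 -> Pore
    "k_cytc_release": 3.6e-3,  # CytoC_m --Pore--> CytoC
    "k_smac_release": 3.6e-3,
    "k_smac_xiap_bind": 3.6e-3,
    "k_smac_xiap_unbind": 0.05,
    "k_apaf_act": 3.6e-6,      # Apaf --CytoC--> Apaf_a
    "k_apop_form": 3.6e-5,     # Apaf_a + pC9 -> Apop
    "k_c3_act_apop": 1.8e-5,   # pC3 --Apop--> C3a
    "k_c9_feedback": 3.6e-6,   # pC9 --C3a--> C9a
    "k_c3_act_c9": 1.8e-5,     # pC3 --C9a--> C3a
    "k_parp_cleave": 3.0e-4,   # PARP --C3a--> cPARP
    "k_deg_pro": 0.05,         # pro-caspase turnover
    "k_deg_active": 1.0,       # active caspase degradation
}

LY30_RATES = {
    "k_prime": 2.0e-3,         # R --LY30--> R_primed
    "priming_factor": 10.0,    # primed binding speed-up (>1)
    "k_flip_deg_ly30": 3.0e-3,  # flip --LY30--> degraded
    "k_ros_prod": 0.5,         # LY30 -> LY30 + ROS
    "k_ros_decay": 1.0,
    "k_ros_bax": 1.6e-5,       # Bax --ROS--> Bax_a (mito permeability)
    "k_ros_parp": 0.0,         # direct ROS death channel, off by default
    "k_ly30_decay": 0.0,       # non-depleting input by default
}


def build_trail_network(overrides: dict[str, float] | None = None,
                        initial_overrides: dict[str, float] | None = None,
                        ) -> ReactionNetwork:
    """Construct the modified Albeck-style TRAIL network (no LY30)."""
    rates = dict(TRAIL_RATES)
    if overrides:
        rates.update(overrides)
    amounts = dict(INITIAL_AMOUNTS)
    if initial_overrides:
        amounts.update(initial_overrides)
    net = ReactionNetwork("trail")
    for name, amount in amounts.items():
        tag = ("mitochondria" if name in _MITO_TAG
               else "extracellular" if name in _EXTRA_TAG else "cytosol")
        net.add_species(name, amount, compartment_tag=tag)
    for name, value in rates.items():
        net.set_parameter(name, value)

    # receptor / DISC module
    net.add_reaction("bind", ("TRAIL", "R"), ("DISC",), rate_param="k_bind")
    net.add_reaction("flip_bind", ("DISC", "flip"), ("flip_DISC",),
                     rate_param="k_flip_bind")
    net.add_reaction("flip_unbind", ("flip_DISC",), ("DISC", "flip"),
                     rate_param="k_flip_unbind")
    net.add_reaction("c8_act_disc", ("pC8",), ("C8a",), modifiers=("DISC",),
                     rate_param="k_c8_act_disc")
    net.add_reaction("arc_bind", ("C8a", "ARC"), ("ARC_C8",),
                     rate_param="k_arc_bind")
    net.add_reaction("arc_unbind", ("ARC_C8",), ("C8a", "ARC"),
                     rate_param="k_arc_unbind")
    net.add_reaction("arc_degrade", ("ARC_C8",), ("ARC",),
                     rate_param="k_arc_degrade")
    # executioner caspase module
    net.add_reaction("c3_act_c8", ("pC3",), ("C3a",), modifiers=("C8a",),
                     rate_param="k_c3_act_c8")
    net.add_reaction("xiap_bind", ("C3a", "XIAP"), ("XIAP_C3",),
                     rate_param="k_xiap_bind")
    net.add_reaction("xiap_unbind", ("XIAP_C3",), ("C3a", "XIAP"),
                     rate_param="k_xiap_unbind")
    net.add_reaction("xiap_degrade", ("XIAP_C3",), ("XIAP", "C3_ub"),
                     rate_param="k_xiap_degrade")
    net.add_reaction("c8_feedback", ("pC8",), ("C8a",), modifiers=("C3a",),
                     rate_param="k_c8_feedback")
    # mitochondrial module
    net.add_reaction("bid_cleave", ("Bid",), ("tBid",), modifiers=("C8a",),
                     rate_param="k_bid_cleave")
    net.add_reaction("bax_act", ("Bax",), ("Bax_a",), modifiers=("tBid",),
                     rate_param="k_bax_act")
    net.add_reaction("bax_deact", ("Bax_a",), ("Bax",),
                     rate_param="k_bax_deact")
    net.add_reaction("bcl2_bind", ("Bax_a", "Bcl2"), ("Bax_Bcl2",),
                     rate_param="k_bcl2_bind")
    net.add_reaction("bcl2_unbind", ("Bax_Bcl2",), ("Bax_a", "Bcl2"),
                     rate_param="k_bcl2_unbind")
    net.add_reaction("bcl2_recycle", ("Bax_Bcl2",), ("Bax", "Bcl2"),
                     rate_param="k_bcl2_deact")
    net.add_reaction("bax_dimer", ("Bax_a", "Bax_a"), ("Bax2",),
                     rate_param="k_bax_dimer")
    net.add_reaction("bax_undimer", ("Bax2",), ("Bax_a", "Bax_a"),
                     rate_param="k_bax_undimer")
    net.add_reaction("pore_form", ("Bax2", "Bax2"), ("Pore",),
                     rate_param="k_pore_form")
    net.add_reaction("cytc_release", ("CytoC_m",), ("CytoC",),
                     modifiers=("Pore",), rate_param="k_cytc_release")
    net.add_reaction("smac_release", ("Smac_m",), ("Smac",),
                     modifiers=("Pore",), rate_param="k_smac_release")
    net.add_reaction("smac_xiap_bind", ("Smac", "XIAP"), ("Smac_XIAP",),
                     rate_param="k_smac_xiap_bind")
    net.add_reaction("smac_xiap_unbind", ("Smac_XIAP",), ("Smac", "XIAP"),
                     rate_param="k_smac_xiap_unbind")
    # apoptosome module with caspase-3 -> caspase-9 feedback
    net.add_reaction("apaf_act", ("Apaf",), ("Apaf_a",), modifiers=("CytoC",),
                     rate_param="k_apaf_act")
    net.add_reaction("apop_form", ("Apaf_a", "pC9"), ("Apop",),
                     rate_param="k_apop_form")
    net.add_reaction("c3_act_apop", ("pC3",), ("C3a",), modifiers=("Apop",),
                     rate_param="k_c3_act_apop")
    net.add_reaction("c9_feedback", ("pC9",), ("C9a",), modifiers=("C3a",),
                     rate_param="k_c9_feedback")
    net.add_reaction("c3_act_c9", ("pC3",), ("C3a",), modifiers=("C9a",),
                     rate_param="k_c3_act_c9")
    # death substrate
    net.add_reaction("parp_cleave", ("PARP",), ("cPARP",), modifiers=("C3a",),
                     rate_param="k_parp_cleave")
    # caspase-only turnover: first-order degradation, then synthesis
    # balancing the untreated state
    for sp in CASPASE_SPECIES:
        net.add_reaction(f"deg_{sp}", (sp,), (), rate_param="k_deg_pro",
                         kind="first_order_degradation")
    for sp in ("C8a", "C3a", "C9a"):
        net.add_reaction(f"deg_{sp}", (sp,), (), rate_param="k_deg_active",
                         kind="first_order_degradation")
    return set_turnover(net, CASPASE_SPECIES)


def build_ly30_extension(network: ReactionNetwork,
                         overrides: dict[str, float] | None = None,
                         ) -> ReactionNetwork:
    """Add the LY30 effect reactions to a built TRAIL network."""
    if any(r.name == "prime_receptor" for r in network.reactions):
        raise ValueError("LY30 extension already applied")
    rates = dict(LY30_RATES)
    if overrides:
        rates.update(overrides)
    net = network.copy()
    net.add_species("LY30", 0.0)
    net.add_species("ROS", 0.0)
    for name, value in rates.items():
        net.set_parameter(name, value)
    # primed receptor binds TRAIL faster by priming_factor (single knob)
    net.set_parameter("k_bind_primed",
                      net.parameters["k_bind"] * rates["priming_factor"])
    net.add_reaction("prime_receptor", ("R",), ("R_primed",),
                     modifiers=("LY30",), rate_param="k_prime")
    net.add_reaction("bind_primed", ("TRAIL", "R_primed"), ("DISC",),
                     rate_param="k_bind_primed")
    net.add_reaction("flip_deg_ly30", ("flip",), (), modifiers=("LY30",),
                     rate_param="k_flip_deg_ly30")
    net.add_reaction("ros_prod", (), ("ROS",), modifiers=("LY30",),
                     rate_param="k_ros_prod")
    net.add_reaction("ros_decay", ("ROS",), (), rate_param="k_ros_decay",
                     kind="first_order_degradation")
    net.add_reaction("ros_bax", ("Bax",), ("Bax_a",), modifiers=("ROS",),
                     rate_param="k_ros_bax")
    # direct mitochondria-independent channel; rate 0 except in the
    # flagged subpopulation (see population module)
    net.add_reaction("ros_parp", ("PARP",), ("cPARP",), modifiers=("ROS",),
                     rate_param="k_ros_parp")
    if rates["k_ly30_decay"] > 0:
        net.add_reaction("ly30_decay", ("LY30",), (),
                         rate_param="k_ly30_decay",
                         kind="first_order_degradation")
    return net


@dataclass(frozen=True)
class TreatmentSchedule:
    """Doses and times of the two agents (paper protocol: LY30 at 0 h,
    TRAIL 1 h later)."""

    ly30_dose: float = 25.0    # µM
    trail_dose: float = 20.0   # ng/ml
    ly30_time: float = 0.0     # h
    trail_time: float = 1.0    # h

    def __post_init__(self):
        if self.ly30_dose < 0 or self.trail_dose < 0:
            raise ValueError("doses must be >= 0")


@dataclass(frozen=True)
class ModelVariant:
    variant_tag: str
    network: ReactionNetwork
    schedule: TreatmentSchedule
    events: tuple[Event, ...] = field(default_factory=tuple)


def make_schedule(variant_tag: str, ly30_dose: float = 25.0,
                  trail_dose: float = 20.0,
                  ) -> tuple[TreatmentSchedule, list[Event]]:
    """Treatment events for a variant; doses in µM (LY30) / ng/ml (TRAIL).

    ``combination`` schedules LY30 at 0 h and TRAIL at 1 h (TRAIL is
    zero during the first hour); single treatments dose at 0 h.
    """
    if ly30_dose < 0 or trail_dose < 0:
        raise ValueError("doses must be >= 0")
    trail_copies = trail_dose * TRAIL_COPIES_PER_NGML
    ly30_units = ly30_dose * LY30_UNITS_PER_UM
    if variant_tag == "trail_only":
        schedule = TreatmentSchedule(0.0, trail_dose, trail_time=0.0)
        events = [Event(0.0, "TRAIL", trail_copies)]
    elif variant_tag == "ly30_only":
        schedule = TreatmentSchedule(ly30_dose, 0.0)
        events = [Event(0.0, "LY30", ly30_units)]
    elif variant_tag == "combination":
        schedule = TreatmentSchedule(ly30_dose, trail_dose)
        events = [Event(0.0, "LY30", ly30_units),
                  Event(1.0, "TRAIL", trail_copies)]
    elif variant_tag == "untreated":
        schedule = TreatmentSchedule(0.0, 0.0)
        events = []
    else:
        raise ValueError(f"unknown variant tag {variant_tag!r}")
    return schedule, events


def build_variant(variant_tag: str, ly30_dose: float = 25.0,
                  trail_dose: float = 20.0,
                  trail_overrides: dict[str, float] | None = None,
                  ly30_overrides: dict[str, float] | None = None,
                  ) -> ModelVariant:
    """Build a ready-to-simulate variant (network + schedule + events).

    All variants other than ``trail_only`` carry the LY30 extension so
    that per-cell parameter overrides (e.g. the flagged subpopulation's
    ROS channel) are well defined; with an LY30 dose of zero the
    extension reactions carry no flux.
    """
    net = build_trail_network(trail_overrides)
    if variant_tag != "trail_only":
        net = build_ly30_extension(net, ly30_overrides)
    schedule, events = make_schedule(variant_tag, ly30_dose, trail_dose)
    return ModelVariant(variant_tag, net, schedule, tuple(events))
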
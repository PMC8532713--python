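"""Four-stage beef supply-chain construction.

Builds the product systems compared throughout the package: cow/calf,
backgrounding (BG), feed yard (FY) and harvesting, wired together with the
cull-cow bypass, revenue-based co-product allocation at the packing plant,
and the scenario boundaries / functional units of the study design
(gate-to-gate live weight gain vs. cradle-to-harvest retail cuts).

Two flavours of stage process are produced from the same feed-trial record:

* *gate-to-gate* — reference product is 1000 kg of live weight gain at that
  stage; feed, utilities and emissions are expressed per 1000 kg LWG and the
  animals themselves stay outside the boundary;
* *chain* — reference product is 1 kg of live animal leaving the stage,
  consuming the incoming animal mass, so stages link into a cradle-to-harvest
  system that conserves live weight along the chain.

Treatment-dependent processes carry the treatment tag in their process id;
treatment-independent processes (cow/calf, cull-cow supply, feed and energy
background) share ids across the paired systems, which is what lets the
paired Monte-Carlo engine give them common draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .lci import (
    Exchange,
    Flow,
    ProductSystem,
    UncertaintySpec,
    UnitProcess,
)

__all__ = [
    "RationItem",
    "FeedTrial",
    "HarvestSplit",
    "StageOverheads",
    "ChainParams",
    "ScenarioConfig",
    "ELEMENTARY_FLOWS",
    "BACKGROUND_FLOWS",
    "augment_indirect_n2o",
    "truncate_backgrounding",
    "carcass_mass",
    "economic_allocation",
    "allocate_harvest",
    "make_stage_process",
    "cow_calf_process",
    "cull_cow_supply",
    "build_chain_system",
    "build_gate_to_gate_system",
    "build_scenario",
    "scenario_boundaries",
    "lwg_flow",
]

TREATMENTS = ("CNV", "EFC")

# Canonical elementary flows (emissions and resource extractions).
ELEMENTARY_FLOWS: dict[str, Flow] = {
    f.id: f
    for f in [
        Flow("ch4_enteric", "methane, enteric fermentation", "elementary", "kg"),
        Flow("ch4_manure", "methane, manure management", "elementary", "kg"),
        Flow("ch4_fossil", "methane, fossil", "elementary", "kg"),
        Flow("n2o", "dinitrogen monoxide, direct", "elementary", "kg"),
        Flow("n2o_indirect", "dinitrogen monoxide, indirect", "elementary", "kg"),
        Flow("nh3", "ammonia", "elementary", "kg"),
        Flow("co2_fossil", "carbon dioxide, fossil", "elementary", "kg"),
        Flow("land_arable", "occupation, arable land", "elementary", "m2a"),
        Flow("land_pasture", "occupation, pasture", "elementary", "m2a"),
        Flow("water_surface", "water, surface and ground", "elementary", "m3"),
        Flow("crude_oil", "crude oil, in ground", "elementary", "kg"),
        Flow("natural_gas_resource", "natural gas, in ground", "elementary", "kg"),
        Flow("hard_coal", "hard coal, in ground", "elementary", "kg"),
    ]
}

# Product flows supplied by the background database (feeds, energy, services).
BACKGROUND_FLOWS: dict[str, Flow] = {
    f.id: f
    for f in [
        Flow("corn_grain", "corn grain, dry matter, at farm", "product", "kg"),
        Flow("corn_silage", "corn silage, dry matter, at farm", "product", "kg"),
        Flow("alfalfa_hay", "alfalfa hay, dry matter, at farm", "product", "kg"),
        Flow("distillers_grains", "distillers grains, dry matter", "product", "kg"),
        Flow("urea_feed", "urea, feed grade", "product", "kg"),
        Flow("pasture_grass", "grazed pasture forage, dry matter", "product", "kg"),
        Flow("electricity", "electricity, grid", "product", "MJ"),
        Flow("diesel_work", "diesel, burned in machinery", "product", "MJ"),
        Flow("natural_gas_heat", "natural gas, burned in furnace", "product", "MJ"),
        Flow("transport", "transport, lorry", "product", "tkm"),
        Flow("fertilizer_n", "nitrogen fertilizer, as N", "product", "kg"),
        Flow("drinking_water", "water, for livestock", "product", "m3"),
    ]
}

# Live-animal and packing-plant product flows.  Treatment-dependent flows are
# created on demand via the helpers below.
CALF_FLOW = Flow("weaned_calf_lw", "weaned calf, live weight", "product", "kg")
CULL_FLOW = Flow("cull_cow_lw", "cull cow, live weight", "product", "kg")

#: Map from feed-trial emission keys to elementary flow ids.
EMISSION_FLOW_IDS = {
    "enteric_ch4": "ch4_enteric",
    "manure_ch4": "ch4_manure",
    "manure_n2o": "n2o",
    "nh3": "nh3",
}

#: Map from ration ingredient names to background product-flow ids.
FEED_FLOW_IDS = {
    "corn grain": "corn_grain",
    "corn silage": "corn_silage",
    "alfalfa hay": "alfalfa_hay",
    "distillers grains": "distillers_grains",
    "urea": "urea_feed",
}


def lwg_flow(stage: str, treatment: str) -> Flow:
    return Flow(
        f"lwg_{stage}_{treatment}",
        f"live weight gain, {stage}, {treatment}",
        "product",
        "kg",
    )


def _animal_flow(kind: str, treatment: str) -> Flow:
    return Flow(
        f"{kind}_{treatment}", f"{kind.replace('_', ' ')}, {treatment}", "product", "kg"
    )


@dataclass(frozen=True)
class RationItem:
    """One ration ingredient with its trial-level feeding record."""

    name: str
    dmi_kg_per_head_day: float
    nem_mj_per_kg: float
    inclusion_limit: float | None = None  # kg DM/head/day


@dataclass
class FeedTrial:
    """Per-treatment animal-performance and ration record for one stage.

    ``emissions`` holds cumulative kg per head over the trial for the keys
    ``enteric_ch4``, ``manure_ch4``, ``manure_n2o`` and ``nh3``.
    """

    treatment: str
    n_head: int
    days_on_feed: int
    start_weight: float
    end_weight: float
    ration: list[RationItem]
    emissions: dict[str, float]

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if not self.end_weight > self.start_weight:
            raise ValueError("end_weight must exceed start_weight")
        if self.n_head <= 0 or self.days_on_feed <= 0:
            raise ValueError("n_head and days_on_feed must be positive")
        for item in self.ration:
            if item.dmi_kg_per_head_day <= 0:
                raise ValueError(f"nonpositive intake for {item.name!r}")

    @property
    def lwg_per_head(self) -> float:
        return self.end_weight - self.start_weight

    @property
    def total_lwg(self) -> float:
        return self.n_head * self.lwg_per_head

    @property
    def daily_dmi_per_head(self) -> float:
        return sum(i.dmi_kg_per_head_day for i in self.ration)

    @property
    def total_feed_dm(self) -> float:
        return self.n_head * self.days_on_feed * self.daily_dmi_per_head

    @property
    def gain_to_feed(self) -> float:
        return self.total_lwg / self.total_feed_dm

    def feed_totals(self) -> dict[str, float]:
        """Cumulative kg DM consumed per ingredient over the whole trial."""
        return {
            i.name: self.n_head * self.days_on_feed * i.dmi_kg_per_head_day
            for i in self.ration
        }


@dataclass
class HarvestSplit:
    """Co-product split at the packing plant.

    ``revenues`` are relative revenue shares of the three co-product groups;
    ``yields`` are kg of co-product per kg of carcass processed.  Dressing
    percentages convert live weight to carcass mass: 0.50 for cull cows and
    0.63 for finished animals.
    """

    revenues: dict[str, float] = field(
        default_factory=lambda: {"retail_cuts": 0.90, "rendering": 0.06, "hide": 0.04}
    )
    yields: dict[str, float] = field(
        default_factory=lambda: {"retail_cuts": 0.68, "rendering": 0.27, "hide": 0.05}
    )
    dressing_cull: float = 0.50
    dressing_finished: float = 0.63

    def __post_init__(self) -> None:
        for k, v in self.revenues.items():
            if v < 0:
                raise ValueError(f"negative revenue share for {k!r}")
        for d in (self.dressing_cull, self.dressing_finished):
            if not (0.0 < d <= 1.0):
                raise ValueError("dressing fractions must be in (0, 1]")


@dataclass(frozen=True)
class StageOverheads:
    """Utilities consumed per head and day at a feeding stage."""

    drinking_water_m3: float = 0.045
    electricity_mj: float = 0.9
    diesel_mj: float = 1.6


@dataclass
class CowCalfIntensity:
    """Burdens per kg of weaned calf leaving the cow/calf operation.

    These cover the whole breeding-herd overhead (cows, bulls, replacements)
    prorated onto the weaned calves, which is why the enteric methane and
    pasture figures are large relative to the feeding stages.
    """

    pasture_dm_kg: float = 26.0
    drinking_water_m3: float = 0.022
    diesel_mj: float = 1.4
    transport_tkm: float = 0.25
    enteric_ch4_kg: float = 0.31
    manure_ch4_kg: float = 0.021
    manure_n2o_kg: float = 0.010
    nh3_kg: float = 0.055
    cull_lw_per_calf_lw: float = 0.18  # joint cull-cow output, informational


@dataclass
class HarvestIntensity:
    """Packing-plant inputs and emissions per kg of carcass processed."""

    electricity_mj: float = 0.95
    natural_gas_mj: float = 0.80
    water_m3: float = 0.011
    transport_tkm: float = 0.35
    co2_fossil_kg: float = 0.012


@dataclass
class ChainParams:
    """Everything the chain builder needs besides the feed trials."""

    cow_calf: CowCalfIntensity = field(default_factory=CowCalfIntensity)
    harvest: HarvestIntensity = field(default_factory=HarvestIntensity)
    split: HarvestSplit = field(default_factory=HarvestSplit)
    overheads: dict[str, StageOverheads] = field(
        default_factory=lambda: {
            "bg": StageOverheads(drinking_water_m3=0.032, electricity_mj=0.6, diesel_mj=1.9),
            "fy": StageOverheads(drinking_water_m3=0.048, electricity_mj=1.0, diesel_mj=1.5),
        }
    )
    #: cull-cow live weight entering harvest per kg of finished live weight
    cull_lw_per_finished_lw: float = 0.15
    #: IPCC volatilization factor for indirect N2O from NH3
    indirect_n2o_ef: float = 0.01
    include_indirect_n2o: bool = True
    #: dispersion defaults: 5 % CV on inputs, 10 % on emissions
    cv_inputs: float = 0.05
    cv_emissions: float = 0.10
    distribution: str = "lognormal"

    def input_uncertainty(self) -> UncertaintySpec | None:
        if self.cv_inputs == 0:
            return None
        return UncertaintySpec(self.distribution, self.cv_inputs)

    def emission_uncertainty(self) -> UncertaintySpec | None:
        if self.cv_emissions == 0:
            return None
        return UncertaintySpec(self.distribution, self.cv_emissions)


@dataclass
class ScenarioConfig:
    """One scenario/boundary/functional-unit combination.

    Boundaries: ``gate_to_gate_FY``, ``gate_to_gate_BG``, ``BG_plus_FY``
    (all per 1000 kg live weight gain), ``cradle_to_harvest`` (per 1000 kg
    retail cuts) and ``cradle_to_FY`` (per 1000 kg finished live weight at
    the feed-yard gate).
    """

    scenario_id: int
    boundary: str
    functional_unit: str

    _BOUNDARIES = (
        "gate_to_gate_FY",
        "gate_to_gate_BG",
        "BG_plus_FY",
        "cradle_to_harvest",
        "cradle_to_FY",
    )
    _UNITS = ("lwg_1000kg", "retail_cut_1000kg", "finished_lw_1000kg")

    def __post_init__(self) -> None:
        if self.scenario_id not in range(1, 7):
            raise ValueError(f"unknown scenario id {self.scenario_id}")
        if self.boundary not in self._BOUNDARIES:
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.functional_unit not in self._UNITS:
            raise ValueError(f"unknown functional unit {self.functional_unit!r}")


def scenario_boundaries(scenario_id: int) -> list[ScenarioConfig]:
    """Boundary/functional-unit combinations evaluated for each scenario."""
    table = {
        1: [("gate_to_gate_FY", "lwg_1000kg")],
        2: [("gate_to_gate_BG", "lwg_1000kg")],
        3: [("gate_to_gate_BG", "lwg_1000kg")],
        4: [
            ("BG_plus_FY", "lwg_1000kg"),
            ("cradle_to_harvest", "retail_cut_1000kg"),
            ("cradle_to_FY", "finished_lw_1000kg"),
        ],
        5: [
            ("BG_plus_FY", "lwg_1000kg"),
            ("cradle_to_harvest", "retail_cut_1000kg"),
        ],
        6: [
            ("BG_plus_FY", "lwg_1000kg"),
            ("cradle_to_harvest", "retail_cut_1000kg"),
            ("gate_to_gate_FY", "lwg_1000kg"),
        ],
    }
    if scenario_id not in table:
        raise ValueError(f"unknown scenario id {scenario_id}")
    return [ScenarioConfig(scenario_id, b, fu) for b, fu in table[scenario_id]]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def augment_indirect_n2o(
    nh3_mass: float, ef: float = 0.01, include: bool = True
) -> float:
    """Indirect N2O (kg) from volatilized ammonia (kg NH3).

    Converts NH3 to N (14/17), applies the volatilization emission factor
    ``ef`` (kg N2O-N per kg N) and converts N2O-N back to N2O (44/28).
    """
    if nh3_mass < 0:
        raise ValueError("nh3_mass must be nonnegative")
    if not (0.0 <= ef <= 0.1):
        raise ValueError(f"indirect-N2O emission factor {ef} outside [0, 0.1]")
    if not include:
        return 0.0
    return nh3_mass * (14.0 / 17.0) * ef * (44.0 / 28.0)


def truncate_backgrounding(full: FeedTrial, target_end_weight: float) -> FeedTrial:
    """Shorten a backgrounding trial to an intermediate end weight.

    Interpolates linearly in cumulative live weight: the day count and all
    cumulative quantities (feed, emissions) are scaled by
    ``(target - start) / (end - start)``.
    """
    if target_end_weight == full.end_weight:
        return replace(full)
    if not (full.start_weight < target_end_weight < full.end_weight):
        raise ValueError(
            f"target end weight {target_end_weight} outside "
            f"({full.start_weight}, {full.end_weight})"
        )
    frac = (target_end_weight - full.start_weight) / (
        full.end_weight - full.start_weight
    )
    days = max(1, round(full.days_on_feed * frac))
    # keep the cumulative feed equal to frac * original despite day rounding
    dmi_scale = frac * full.days_on_feed / days
    ration = [
        replace(item, dmi_kg_per_head_day=item.dmi_kg_per_head_day * dmi_scale)
        for item in full.ration
    ]
    emissions = {k: v * frac for k, v in full.emissions.items()}
    return FeedTrial(
        treatment=full.treatment,
        n_head=full.n_head,
        days_on_feed=days,
        start_weight=full.start_weight,
        end_weight=target_end_weight,
        ration=ration,
        emissions=emissions,
    )


def carcass_mass(cull_lw: float, finished_lw: float, split: HarvestSplit) -> float:
    """Carcass mass from cull-cow and finished live weights."""
    if cull_lw < 0 or finished_lw < 0:
        raise ValueError("live weights must be nonnegative")
    return split.dressing_cull * cull_lw + split.dressing_finished * finished_lw


def economic_allocation(revenues: Mapping[str, float]) -> dict[str, float]:
    """Revenue-based allocation factors, summing to 1."""
    total = float(sum(revenues.values()))
    if total <= 0:
        raise ValueError("at least one co-product must have positive revenue")
    if any(v < 0 for v in revenues.values()):
        raise ValueError("revenue shares must be nonnegative")
    return {k: v / total for k, v in revenues.items()}


def allocate_harvest(
    split: HarvestSplit, total_burden: Mapping[str, float]
) -> dict[str, float]:
    """Burden share assigned to retail cuts per impact category."""
    factor = economic_allocation(split.revenues)["retail_cuts"]
    return {cat: factor * v for cat, v in total_burden.items()}


# ---------------------------------------------------------------------------
# Stage-process construction
# ---------------------------------------------------------------------------

def _stage_exchanges(
    trial: FeedTrial,
    stage: str,
    params: ChainParams,
    per_kg: float,
) -> list[Exchange]:
    """Feed, utility and emission exchanges scaled by ``per_kg``.

    ``per_kg`` converts trial-cumulative herd totals into the process's
    per-reference-unit amounts.
    """
    in_unc = params.input_uncertainty()
    em_unc = params.emission_uncertainty()
    exchanges: list[Exchange] = []
    for name, total in trial.feed_totals().items():
        try:
            flow = BACKGROUND_FLOWS[FEED_FLOW_IDS[name]]
        except KeyError:
            raise KeyError(f"no background feed process for ingredient {name!r}")
        exchanges.append(Exchange(flow, total * per_kg, "input", in_unc))
    ov = params.overheads[stage]
    head_days = trial.n_head * trial.days_on_feed
    for flow_id, rate in [
        ("drinking_water", ov.drinking_water_m3),
        ("electricity", ov.electricity_mj),
        ("diesel_work", ov.diesel_mj),
    ]:
        if rate > 0:
            exchanges.append(
                Exchange(
                    BACKGROUND_FLOWS[flow_id], head_days * rate * per_kg, "input", in_unc
                )
            )
    for key, flow_id in EMISSION_FLOW_IDS.items():
        total = trial.n_head * trial.emissions.get(key, 0.0)
        if total > 0:
            exchanges.append(
                Exchange(ELEMENTARY_FLOWS[flow_id], total * per_kg, "output", em_unc)
            )
    nh3_total = trial.n_head * trial.emissions.get("nh3", 0.0)
    indirect = augment_indirect_n2o(
        nh3_total, params.indirect_n2o_ef, params.include_indirect_n2o
    )
    if indirect > 0:
        exchanges.append(
            Exchange(
                ELEMENTARY_FLOWS["n2o_indirect"], indirect * per_kg, "output", em_unc
            )
        )
    return exchanges


def make_stage_process(
    stage: str,
    trial: FeedTrial,
    params: ChainParams,
    basis: str = "lwg",
) -> UnitProcess:
    """Build the BG or FY unit process from a feed trial.

    ``basis="lwg"`` gives a gate-to-gate process whose reference product is
    1000 kg of live weight gain.  ``basis="chain"`` gives a linkable process
    whose reference product is 1 kg of live animal leaving the stage and
    which consumes the incoming animal mass, conserving live weight.
    """
    if stage not in ("bg", "fy"):
        raise ValueError(f"unknown feeding stage {stage!r}")
    if trial.total_lwg <= 0:
        raise ValueError("trial has zero live weight gain")
    t = trial.treatment
    if basis == "lwg":
        per_kg = 1.0 / trial.total_lwg
        ref = (lwg_flow(stage, t), 1000.0)
        exchanges = [
            replace(e, amount=e.amount * 1000.0)
            for e in _stage_exchanges(trial, stage, params, per_kg)
        ]
        return UnitProcess(f"{stage}:{t}", f"{stage} stage ({t}), per 1000 kg LWG", ref, exchanges)
    if basis == "chain":
        herd_out = trial.n_head * trial.end_weight
        per_kg = 1.0 / herd_out
        exchanges = _stage_exchanges(trial, stage, params, per_kg)
        in_flow = CALF_FLOW if stage == "bg" else _animal_flow("feeder_lw", t)
        out_flow = (
            _animal_flow("feeder_lw", t) if stage == "bg" else _animal_flow("finished_lw", t)
        )
        # animal mass transfers are definitional links, not uncertain inputs
        exchanges.insert(
            0,
            Exchange(in_flow, trial.start_weight / trial.end_weight, "input", None),
        )
        return UnitProcess(
            f"{stage}_chain:{t}",
            f"{stage} stage ({t}), per kg live weight out",
            (out_flow, 1.0),
            exchanges,
        )
    raise ValueError(f"unknown basis {basis!r}")


def cow_calf_process(
    params: ChainParams,
    alloc_share: float = 1.0,
    process_id: str = "cow_calf",
) -> UnitProcess:
    """Cow/calf unit process per kg of weaned calf (treatment-independent).

    ``alloc_share`` scales the burden carried by the calves; the default 1.0
    is the cull-cow bypass ("calves carry everything").
    """
    cc = params.cow_calf
    in_unc = params.input_uncertainty()
    em_unc = params.emission_uncertainty()
    a = alloc_share
    exchanges = [
        Exchange(BACKGROUND_FLOWS["pasture_grass"], a * cc.pasture_dm_kg, "input", in_unc),
        Exchange(BACKGROUND_FLOWS["drinking_water"], a * cc.drinking_water_m3, "input", in_unc),
        Exchange(BACKGROUND_FLOWS["diesel_work"], a * cc.diesel_mj, "input", in_unc),
        Exchange(BACKGROUND_FLOWS["transport"], a * cc.transport_tkm, "input", in_unc),
        Exchange(ELEMENTARY_FLOWS["ch4_enteric"], a * cc.enteric_ch4_kg, "output", em_unc),
        Exchange(ELEMENTARY_FLOWS["ch4_manure"], a * cc.manure_ch4_kg, "output", em_unc),
        Exchange(ELEMENTARY_FLOWS["n2o"], a * cc.manure_n2o_kg, "output", em_unc),
        Exchange(ELEMENTARY_FLOWS["nh3"], a * cc.nh3_kg, "output", em_unc),
    ]
    indirect = augment_indirect_n2o(
        a * cc.nh3_kg, params.indirect_n2o_ef, params.include_indirect_n2o
    )
    if indirect > 0:
        exchanges.append(
            Exchange(ELEMENTARY_FLOWS["n2o_indirect"], indirect, "output", em_unc)
        )
    return UnitProcess(process_id, "cow/calf operation, per kg weaned calf", (CALF_FLOW, 1.0), exchanges)


def cull_cow_supply(
    params: ChainParams, burden_per_kg: float = 0.0
) -> UnitProcess:
    """Cull-cow live-weight supply.

    With the bypass wiring cull cows enter harvesting with zero upstream
    burden (``burden_per_kg = 0``); the allocate-then-recombine wiring uses
    :func:`allocated_cow_calf_pair` instead.
    """
    exchanges: list[Exchange] = []
    if burden_per_kg != 0.0:
        raise ValueError("bypass cull-cow supply is burden-free by construction")
    return UnitProcess(
        "cull_cow_supply", "cull cows to harvest, per kg live weight", (CULL_FLOW, 1.0), exchanges
    )


def allocated_cow_calf_pair(
    params: ChainParams, calf_alloc: float, cull_per_calf: float
) -> tuple[UnitProcess, UnitProcess]:
    """Allocate-then-recombine wiring of the cow/calf co-production.

    Splits the joint cow/calf burden between calves (share ``calf_alloc``)
    and cull cows (share ``1 - calf_alloc``), with ``cull_per_calf`` kg of
    cull-cow live weight produced per kg of weaned calf.  Used as the
    independent wiring against which the bypass is verified.
    """
    if not (0.0 <= calf_alloc <= 1.0):
        raise ValueError("calf allocation share must be in [0, 1]")
    if cull_per_calf <= 0:
        raise ValueError("cull co-production ratio must be positive")
    calf = cow_calf_process(params, alloc_share=calf_alloc, process_id="cow_calf")
    cull_share_per_kg_cull = (1.0 - calf_alloc) / cull_per_calf
    template = cow_calf_process(params, alloc_share=cull_share_per_kg_cull, process_id="cull_cow_supply")
    cull = UnitProcess(
        "cull_cow_supply",
        "cull cows to harvest (allocated share), per kg live weight",
        (CULL_FLOW, 1.0),
        template.exchanges,
    )
    return calf, cull


def _carcass_process(treatment: str, params: ChainParams) -> UnitProcess:
    """Combine cull and finished live weight into 1 kg of carcass."""
    split = params.split
    r = params.cull_lw_per_finished_lw
    finished_per_kg = 1.0 / (split.dressing_finished + split.dressing_cull * r)
    cull_per_kg = r * finished_per_kg
    carcass = _animal_flow("carcass", treatment)
    exchanges = [
        Exchange(_animal_flow("finished_lw", treatment), finished_per_kg, "input", None),
        Exchange(CULL_FLOW, cull_per_kg, "input", None),
    ]
    return UnitProcess(
        f"carcass:{treatment}",
        f"carcass combination ({treatment}), per kg carcass",
        (carcass, 1.0),
        exchanges,
    )


def _harvest_process(treatment: str, params: ChainParams) -> UnitProcess:
    """Packing-plant process allocated to retail cuts, per kg retail cuts."""
    split = params.split
    hv = params.harvest
    factor = economic_allocation(split.revenues)["retail_cuts"]
    scale = factor / split.yields["retail_cuts"]  # per kg retail cut
    in_unc = params.input_uncertainty()
    em_unc = params.emission_uncertainty()
    exchanges = [
        Exchange(_animal_flow("carcass", treatment), scale * 1.0, "input", None),
        Exchange(BACKGROUND_FLOWS["electricity"], scale * hv.electricity_mj, "input", in_unc),
        Exchange(BACKGROUND_FLOWS["natural_gas_heat"], scale * hv.natural_gas_mj, "input", in_unc),
        Exchange(BACKGROUND_FLOWS["drinking_water"], scale * hv.water_m3, "input", in_unc),
        Exchange(BACKGROUND_FLOWS["transport"], scale * hv.transport_tkm, "input", in_unc),
        Exchange(ELEMENTARY_FLOWS["co2_fossil"], scale * hv.co2_fossil_kg, "output", em_unc),
    ]
    return UnitProcess(
        f"harvest:{treatment}",
        f"harvesting, revenue-allocated to retail cuts ({treatment})",
        (_animal_flow("retail_cuts", treatment), 1.0),
        exchanges,
    )


# ---------------------------------------------------------------------------
# System assembly
# ---------------------------------------------------------------------------

def build_gate_to_gate_system(
    trials: dict[str, FeedTrial],
    params: ChainParams,
    background: list[UnitProcess],
    boundary: str,
    demand_kg: float = 1000.0,
) -> ProductSystem:
    """Gate-to-gate system for one treatment.

    ``trials`` maps stage ("bg"/"fy") to the treatment's trial.  For the
    combined boundary an aggregator process expresses 1 kg of combined live
    weight gain as the stage-share mix of BG and FY gain.
    """
    processes = list(background)
    if boundary == "gate_to_gate_FY":
        proc = make_stage_process("fy", trials["fy"], params, basis="lwg")
        processes.append(proc)
        demand_flow = proc.reference_product[0]
    elif boundary == "gate_to_gate_BG":
        proc = make_stage_process("bg", trials["bg"], params, basis="lwg")
        processes.append(proc)
        demand_flow = proc.reference_product[0]
    elif boundary == "BG_plus_FY":
        bg = make_stage_process("bg", trials["bg"], params, basis="lwg")
        fy = make_stage_process("fy", trials["fy"], params, basis="lwg")
        t = trials["fy"].treatment
        g_bg = trials["bg"].lwg_per_head
        g_fy = trials["fy"].lwg_per_head
        g_tot = g_bg + g_fy
        combined = UnitProcess(
            f"bgfy:{t}",
            f"combined BG+FY live weight gain ({t})",
            (lwg_flow("bgfy", t), 1.0),
            [
                Exchange(bg.reference_product[0], g_bg / g_tot, "input", None),
                Exchange(fy.reference_product[0], g_fy / g_tot, "input", None),
            ],
        )
        processes += [bg, fy, combined]
        demand_flow = combined.reference_product[0]
    else:
        raise ValueError(f"not a gate-to-gate boundary: {boundary!r}")
    return ProductSystem(processes, {demand_flow: demand_kg})


def build_chain_system(
    trials: dict[str, FeedTrial],
    params: ChainParams,
    background: list[UnitProcess],
    boundary: str = "cradle_to_harvest",
    demand_kg: float = 1000.0,
    wiring: str = "bypass",
    calf_alloc: float = 0.8,
) -> ProductSystem:
    """Cradle-to-harvest (or cradle-to-FY-gate) system for one treatment.

    ``wiring`` selects how the cull-cow co-product of the cow/calf stage is
    handled: ``"bypass"`` assigns all cow/calf burden to the calves and
    reintroduces cull cows burden-free at harvest; ``"allocated"`` splits the
    burden with factor ``calf_alloc`` and recombines at the carcass process.
    Both give identical retail-cut impacts.
    """
    t = trials["fy"].treatment
    bg = make_stage_process("bg", trials["bg"], params, basis="chain")
    fy = make_stage_process("fy", trials["fy"], params, basis="chain")
    if wiring == "bypass":
        calf = cow_calf_process(params)
        cull = cull_cow_supply(params)
    elif wiring == "allocated":
        # consistency: cull mass consumed at harvest per kg finished animal
        # equals the cull mass co-produced per kg calf propagated down-chain
        wean = trials["bg"].start_weight
        finish = trials["fy"].end_weight
        cull_per_calf = params.cull_lw_per_finished_lw * finish / wean
        calf, cull = allocated_cow_calf_pair(params, calf_alloc, cull_per_calf)
    else:
        raise ValueError(f"unknown wiring {wiring!r}")
    processes = list(background) + [calf, cull, bg, fy]
    if boundary == "cradle_to_FY":
        demand_flow = fy.reference_product[0]
    elif boundary == "cradle_to_harvest":
        carcass = _carcass_process(t, params)
        harvest = _harvest_process(t, params)
        processes += [carcass, harvest]
        demand_flow = harvest.reference_product[0]
    else:
        raise ValueError(f"not a chain boundary: {boundary!r}")
    return ProductSystem(processes, {demand_flow: demand_kg})


def build_scenario(
    cfg: ScenarioConfig,
    trials: Mapping[str, Mapping[str, FeedTrial]],
    params: ChainParams,
    background: list[UnitProcess],
) -> tuple[ProductSystem, ProductSystem]:
    """Paired (CNV, EFC) product systems for a scenario configuration.

    ``trials`` maps trial-set keys to per-treatment trials.  Expected keys:
    ``bg_full`` (full backgrounding trial), ``fy_full`` (feed-yard trial),
    ``bg_s5``/``fy_s5`` (paired-weight re-simulations for scenario 5) and
    ``fy_s6`` (re-simulated feed yard for scenario 6, starting at the full
    backgrounding end weight with the trial live weight gain maintained).
    Scenarios 3 and 4 use the backgrounding trial truncated to the feed-yard
    start weight.
    """
    sid = cfg.scenario_id

    def stage_trials(treatment: str) -> dict[str, FeedTrial]:
        bg_full = trials["bg_full"][treatment]
        fy_full = trials["fy_full"][treatment]
        if sid in (1, 2):
            return {"bg": bg_full, "fy": fy_full}
        if sid in (3, 4):
            bg_trunc = truncate_backgrounding(bg_full, fy_full.start_weight)
            return {"bg": bg_trunc, "fy": fy_full}
        if sid == 5:
            return {"bg": trials["bg_s5"][treatment], "fy": trials["fy_s5"][treatment]}
        if sid == 6:
            return {"bg": bg_full, "fy": trials["fy_s6"][treatment]}
        raise ValueError(f"unknown scenario id {sid}")

    systems = []
    for t in TREATMENTS:
        st = stage_trials(t)
        if cfg.boundary in ("gate_to_gate_FY", "gate_to_gate_BG", "BG_plus_FY"):
            systems.append(
                build_gate_to_gate_system(st, params, background, cfg.boundary)
            )
        else:
            systems.append(
                build_chain_system(st, params, background, cfg.boundary)
            )
    return systems[0], systems[1]
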
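"""Synthetic study inputs: background LCI database, characterization
factors, and feed trials with configurable treatment effects.

The generator emulates the *shape* of the study inputs — two feeding-trial
datasets (a backgrounding trial and a feed-yard trial, 60 head per
treatment), farm-simulator-style stage emissions, and an upstream process
database of the feeds, energy carriers and services the stages consume —
without claiming numerical agreement with any proprietary database or
whole-farm simulation.  Emission surrogates (methane yield per kg dry-matter
intake, nitrogen excretion shares) and upstream intensities are documented
plausibility constants.

The treatment contrast is imposed algebraically: the treated (EFC) ration
delivers the same (or, with the live-weight-gain interaction, greater) gain
from ``1 - fcr_improvement`` times the feed, so the gain-to-feed ratio of
the generated EFC trial is exactly ``1/(1 - improvement)`` times the
conventional one.  Emissions scale with feed intake.  Setting the
improvements to zero and the interaction off yields identical trial pairs
(the null generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .calibration import CalibrationTarget, SurrogateFarmModel, SurrogateIngredient
from .chain import (
    BACKGROUND_FLOWS,
    ELEMENTARY_FLOWS,
    ChainParams,
    FeedTrial,
    RationItem,
    ScenarioConfig,
    scenario_boundaries,
)
from .lci import (
    Exchange,
    ImpactMethod,
    UncertaintySpec,
    UnitProcess,
    write_impact_method,
    write_process_database,
    read_impact_method,
    read_process_database,
)

__all__ = [
    "EmissionFactorSet",
    "GeneratorConfig",
    "StudyBundle",
    "gen_background_db",
    "gen_feed_trial",
    "gen_study_bundle",
    "load_bundle",
    "dg_allocation_factors",
    "surrogate_from_trial",
    "target_from_trial",
]

TRIAL_SETS = ("bg_full", "fy_full", "bg_s5", "fy_s5", "fy_s6")


@dataclass(frozen=True)
class EmissionFactorSet:
    """Stage emission surrogates, kg of gas per kg of dry-matter intake.

    Backgrounding rations are forage-heavier, hence the higher enteric
    methane yield; feed-yard rations are grain-rich with a lower yield.
    """

    enteric_ch4_bg: float = 0.016
    enteric_ch4_fy: float = 0.0070
    manure_ch4_bg: float = 0.0026
    manure_ch4_fy: float = 0.0023
    manure_n2o_bg: float = 0.00035
    manure_n2o_fy: float = 0.00030
    nh3_bg: float = 0.010
    nh3_fy: float = 0.012

    def for_stage(self, stage: str) -> dict[str, float]:
        sfx = {"bg": "bg", "fy": "fy"}[stage]
        return {
            "enteric_ch4": getattr(self, f"enteric_ch4_{sfx}"),
            "manure_ch4": getattr(self, f"manure_ch4_{sfx}"),
            "manure_n2o": getattr(self, f"manure_n2o_{sfx}"),
            "nh3": getattr(self, f"nh3_{sfx}"),
        }


# ration composition (dry-matter mass shares) and feed energetics
_BG_SHARES = {
    "corn silage": 0.35,
    "corn grain": 0.30,
    "distillers grains": 0.18,
    "alfalfa hay": 0.15,
    "urea": 0.02,
}
_FY_SHARES = {
    "corn grain": 0.50,
    "corn silage": 0.20,
    "distillers grains": 0.20,
    "alfalfa hay": 0.08,
    "urea": 0.02,
}
_NEM_MJ_PER_KG = {
    "corn grain": 9.0,
    "corn silage": 6.9,
    "distillers grains": 8.9,
    "alfalfa hay": 5.4,
    "urea": 6.0,
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generator.

    Weights follow the base case of the study design: calves weaned at
    244.5 kg, backgrounded (full trial) to 380 kg over 92 days, entering the
    feed yard at 293 kg and finished at 570 kg (conventional) or 590 kg
    (treated, when the feed-conversion x live-weight-gain interaction is
    on).  The paired-weight re-simulation uses 380 kg feeders finished at
    662 kg for both treatments with a reduced (~1.5 %) feed-conversion
    improvement and no interaction.
    """

    seed: int = 0
    n_head: int = 60
    bg_days: int = 92
    fy_days: int = 154
    wean_weight: float = 244.5
    bg_end_weight: float = 380.0
    fy_start_weight: float = 293.0
    fy_end_cnv: float = 570.0
    fy_end_efc: float = 590.0
    s5_bg_end: float = 380.0
    s5_fy_end: float = 662.0
    fcr_improvement_fy: float = 0.05
    fcr_improvement_bg: float = 0.035
    fcr_improvement_s5: float = 0.015
    lwg_interaction: bool = True
    fcr_cnv_bg: float = 5.8  # kg DM per kg gain
    fcr_cnv_fy: float = 6.1
    s5_fcr_penalty: float = 1.08  # larger animals convert feed less efficiently
    s6_maintenance_scale: float = 1.08
    emission_factors: EmissionFactorSet = field(default_factory=EmissionFactorSet)
    # characterization constants are configuration, not fixed science
    gwp_ch4_biogenic: float = 28.0
    gwp_ch4_fossil: float = 29.8
    gwp_n2o: float = 265.0
    cv_inputs: float = 0.05
    cv_emissions: float = 0.10

    def __post_init__(self) -> None:
        for imp in (
            self.fcr_improvement_fy,
            self.fcr_improvement_bg,
            self.fcr_improvement_s5,
        ):
            if not (0.0 <= imp <= 0.2):
                raise ValueError(f"feed-conversion improvement {imp} outside [0, 0.2]")
        if not (
            self.wean_weight
            < self.fy_start_weight
            < self.bg_end_weight
            < self.fy_end_cnv
        ):
            raise ValueError("weights must increase along the chain")

    def null(self) -> "GeneratorConfig":
        """The no-effect configuration: identical CNV and EFC trials."""
        return replace(
            self,
            fcr_improvement_fy=0.0,
            fcr_improvement_bg=0.0,
            fcr_improvement_s5=0.0,
            lwg_interaction=False,
        )

    def chain_params(self) -> ChainParams:
        return ChainParams(cv_inputs=self.cv_inputs, cv_emissions=self.cv_emissions)


def dg_allocation_factors(
    revenue_ethanol: float = 0.75, revenue_dg: float = 0.25
) -> dict[str, float]:
    """Economic allocation factors of the corn-ethanol co-production from
    which the distillers-grains background process is derived."""
    total = revenue_ethanol + revenue_dg
    if total <= 0:
        raise ValueError("revenues must be positive")
    return {"ethanol": revenue_ethanol / total, "distillers_grains": revenue_dg / total}


def _proc(pid, name, flow_id, ref_amount, exchanges, cfg) -> UnitProcess:
    in_unc = UncertaintySpec("lognormal", cfg.cv_inputs)
    em_unc = UncertaintySpec("lognormal", cfg.cv_emissions)
    built = []
    for fid, amount, direction in exchanges:
        if fid in BACKGROUND_FLOWS:
            flow, unc = BACKGROUND_FLOWS[fid], in_unc
        else:
            flow, unc = ELEMENTARY_FLOWS[fid], em_unc
        built.append(Exchange(flow, amount, direction, unc if cfg else None))
    return UnitProcess(pid, name, (BACKGROUND_FLOWS[flow_id], ref_amount), built)


def gen_background_db(cfg: GeneratorConfig) -> tuple[list[UnitProcess], ImpactMethod]:
    """Background process database plus characterization factors.

    A small, fully linked technosphere: energy carriers, fertilizer, the
    feed crops, a revenue-allocated distillers-grains process, transport and
    livestock water supply.  Every elementary flow is characterized in each
    of the four categories (with zero where the flow does not contribute).
    Deterministic for a given configuration.
    """
    dg_alloc = dg_allocation_factors()["distillers_grains"]
    # joint corn-ethanol plant: per kg corn milled -> 0.30 kg ethanol +
    # 0.28 kg distillers grains; DG burden share = alloc / yield
    dg_scale = dg_alloc / 0.28

    processes = [
        _proc(
            "electricity", "electricity, grid average", "electricity", 1.0,
            [
                ("co2_fossil", 0.125, "output"),
                ("ch4_fossil", 0.00025, "output"),
                ("hard_coal", 0.040, "input"),
                ("natural_gas_resource", 0.012, "input"),
                ("crude_oil", 0.002, "input"),
            ],
            cfg,
        ),
        _proc(
            "diesel_work", "diesel, burned in agricultural machinery", "diesel_work", 1.0,
            [
                ("crude_oil", 0.0245, "input"),
                ("co2_fossil", 0.0780, "output"),
                ("ch4_fossil", 0.00001, "output"),
            ],
            cfg,
        ),
        _proc(
            "natural_gas_heat", "natural gas, burned in industrial furnace",
            "natural_gas_heat", 1.0,
            [
                ("natural_gas_resource", 0.0220, "input"),
                ("co2_fossil", 0.0561, "output"),
            ],
            cfg,
        ),
        _proc(
            "transport", "transport, lorry, average load", "transport", 1.0,
            [("diesel_work", 1.25, "input")],
            cfg,
        ),
        _proc(
            "fertilizer_n", "nitrogen fertilizer production, as N", "fertilizer_n", 1.0,
            [
                ("natural_gas_heat", 38.0, "input"),
                ("electricity", 3.0, "input"),
                ("co2_fossil", 1.30, "output"),
                ("n2o", 0.0035, "output"),
            ],
            cfg,
        ),
        _proc(
            "corn_grain", "corn grain production, dry matter", "corn_grain", 1.0,
            [
                ("fertilizer_n", 0.022, "input"),
                ("diesel_work", 2.2, "input"),
                ("electricity", 0.30, "input"),
                ("transport", 0.09, "input"),
                ("land_arable", 1.05, "output"),
                ("water_surface", 0.15, "input"),
                ("n2o", 0.00046, "output"),
                ("nh3", 0.0024, "output"),
                ("co2_fossil", 0.018, "output"),
            ],
            cfg,
        ),
        _proc(
            "corn_silage", "corn silage production, dry matter", "corn_silage", 1.0,
            [
                ("fertilizer_n", 0.008, "input"),
                ("diesel_work", 0.75, "input"),
                ("land_arable", 0.24, "output"),
                ("water_surface", 0.20, "input"),
                ("n2o", 0.00018, "output"),
                ("co2_fossil", 0.006, "output"),
            ],
            cfg,
        ),
        _proc(
            "alfalfa_hay", "alfalfa hay production, dry matter", "alfalfa_hay", 1.0,
            [
                ("diesel_work", 1.3, "input"),
                ("land_arable", 1.55, "output"),
                ("water_surface", 0.28, "input"),
                ("n2o", 0.00023, "output"),
                ("co2_fossil", 0.005, "output"),
            ],
            cfg,
        ),
        _proc(
            "pasture_grass", "pasture forage, grazed, dry matter", "pasture_grass", 1.0,
            [
                ("diesel_work", 0.06, "input"),
                ("land_pasture", 4.2, "output"),
                ("n2o", 0.00008, "output"),
            ],
            cfg,
        ),
        _proc(
            "urea_feed", "urea production, feed grade", "urea_feed", 1.0,
            [
                ("natural_gas_heat", 28.0, "input"),
                ("electricity", 1.5, "input"),
                ("co2_fossil", 0.73, "output"),
            ],
            cfg,
        ),
        _proc(
            "distillers_grains",
            "distillers grains, revenue-allocated share of corn ethanol plant",
            "distillers_grains", 1.0,
            # per kg corn milled: 1 kg corn, 4.2 MJ gas, 0.7 MJ electricity,
            # 0.056 tkm transport; DG carries dg_alloc of that per 0.28 kg DG
            [
                ("corn_grain", dg_scale * 1.0, "input"),
                ("natural_gas_heat", dg_scale * 4.2, "input"),
                ("electricity", dg_scale * 0.7, "input"),
                ("transport", dg_scale * 0.056, "input"),
                ("water_surface", dg_scale * 0.02, "input"),
            ],
            cfg,
        ),
        _proc(
            "drinking_water", "water supply for livestock", "drinking_water", 1.0,
            [
                ("water_surface", 1.02, "input"),
                ("electricity", 1.1, "input"),
            ],
            cfg,
        ),
    ]

    method = ImpactMethod(
        factors={
            "climate change": {
                "co2_fossil": 1.0,
                "ch4_enteric": cfg.gwp_ch4_biogenic,
                "ch4_manure": cfg.gwp_ch4_biogenic,
                "ch4_fossil": cfg.gwp_ch4_fossil,
                "n2o": cfg.gwp_n2o,
                "n2o_indirect": cfg.gwp_n2o,
                "nh3": 0.0,
            },
            "land use": {"land_arable": 1.0, "land_pasture": 1.0},
            "water use": {"water_surface": 1.0},
            "fossil energy": {
                "crude_oil": 1.0,
                "natural_gas_resource": 1.13,
                "hard_coal": 0.65,
            },
        }
    )
    return processes, method


def gen_feed_trial(
    cfg: GeneratorConfig, stage: str, treatment: str, variant: str = "base"
) -> FeedTrial:
    """Generate one stage trial for one treatment.

    ``variant="base"`` is the trial as observed; ``"s5"`` the paired-weight
    re-simulation (same start/end weights for both treatments, reduced
    improvement, no interaction); ``"s6"`` the feed-yard re-simulation
    starting at the full backgrounding end weight with the trial live weight
    gain maintained and feed scaled up for the larger animals' maintenance.
    """
    if stage not in ("bg", "fy"):
        raise ValueError(f"unknown stage {stage!r}")
    if variant not in ("base", "s5", "s6"):
        raise ValueError(f"unknown variant {variant!r}")
    shares = _BG_SHARES if stage == "bg" else _FY_SHARES
    efs = cfg.emission_factors.for_stage(stage)

    if stage == "bg":
        days = cfg.bg_days
        start, end_cnv, end_efc = cfg.wean_weight, cfg.bg_end_weight, cfg.bg_end_weight
        fcr, imp = cfg.fcr_cnv_bg, cfg.fcr_improvement_bg
        if variant == "s5":
            end_cnv = end_efc = cfg.s5_bg_end
            imp = cfg.fcr_improvement_s5
        elif variant == "s6":
            raise ValueError("the scenario-6 re-simulation modifies only the feed yard")
    else:
        days = cfg.fy_days
        start = cfg.fy_start_weight
        end_cnv = cfg.fy_end_cnv
        end_efc = cfg.fy_end_efc if cfg.lwg_interaction else cfg.fy_end_cnv
        fcr, imp = cfg.fcr_cnv_fy, cfg.fcr_improvement_fy
        if variant == "s5":
            start, end_cnv, end_efc = cfg.s5_bg_end, cfg.s5_fy_end, cfg.s5_fy_end
            fcr, imp = fcr * cfg.s5_fcr_penalty, cfg.fcr_improvement_s5
        elif variant == "s6":
            gain_cnv = cfg.fy_end_cnv - cfg.fy_start_weight
            gain_efc = (
                cfg.fy_end_efc - cfg.fy_start_weight
                if cfg.lwg_interaction
                else gain_cnv
            )
            start = cfg.bg_end_weight
            end_cnv = start + gain_cnv
            end_efc = start + gain_efc
            fcr = fcr * cfg.s6_maintenance_scale

    gain_cnv_kg = end_cnv - start
    gain_t = (end_cnv if treatment == "CNV" else end_efc) - start
    feed_cnv = gain_cnv_kg * fcr  # kg DM per head over the trial
    if treatment == "CNV":
        feed_t = feed_cnv
    else:
        # G:F(EFC) = G:F(CNV) / (1 - improvement), exactly
        feed_t = feed_cnv * (1.0 - imp) * (gain_t / gain_cnv_kg)
    ration = [
        RationItem(
            name=name,
            dmi_kg_per_head_day=share * feed_t / days,
            nem_mj_per_kg=_NEM_MJ_PER_KG[name],
            inclusion_limit=1.25 * share * feed_t / days,
        )
        for name, share in shares.items()
    ]
    emissions = {gas: ef * feed_t for gas, ef in efs.items()}
    return FeedTrial(
        treatment=treatment,
        n_head=cfg.n_head,
        days_on_feed=days,
        start_weight=start,
        end_weight=start + gain_t,
        ration=ration,
        emissions=emissions,
    )


@dataclass
class StudyBundle:
    """Everything the scenario runner needs, generated or loaded from disk."""

    cfg: GeneratorConfig
    background: list[UnitProcess]
    method: ImpactMethod
    trials: dict[str, dict[str, FeedTrial]]  # trial_set -> treatment -> trial
    params: ChainParams
    scenarios: list[ScenarioConfig]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_process_database(self.background, out / "background_db.csv")
        write_impact_method(self.method, out / "characterization_factors.csv")
        rows = []
        for tset, per_treatment in self.trials.items():
            for t, trial in per_treatment.items():
                for item in trial.ration:
                    rows.append(
                        dict(
                            trial_set=tset,
                            treatment=t,
                            n_head=trial.n_head,
                            days_on_feed=trial.days_on_feed,
                            start_weight=trial.start_weight,
                            end_weight=trial.end_weight,
                            enteric_ch4=trial.emissions["enteric_ch4"],
                            manure_ch4=trial.emissions["manure_ch4"],
                            manure_n2o=trial.emissions["manure_n2o"],
                            nh3=trial.emissions["nh3"],
                            ingredient=item.name,
                            dmi_kg_per_head_day=item.dmi_kg_per_head_day,
                            nem_mj_per_kg=item.nem_mj_per_kg,
                            inclusion_limit=item.inclusion_limit,
                        )
                    )
        pd.DataFrame(rows).to_csv(out / "feed_trials.csv", index=False, float_format="%.12g")
        scen = [
            dict(
                scenario_id=s.scenario_id,
                boundary=s.boundary,
                functional_unit=s.functional_unit,
            )
            for s in self.scenarios
        ]
        with open(out / "scenarios.yaml", "w") as fh:
            yaml.safe_dump({"seed": self.cfg.seed, "scenarios": scen}, fh, sort_keys=False)


def gen_study_bundle(cfg: GeneratorConfig | None = None, outdir=None) -> StudyBundle:
    """Generate the complete input bundle for all six scenarios.

    With the default configuration the gate-to-gate percent
    decreases fall in the 3-6 % band and the cradle-to-harvest ones are
    smaller (the dilution effect).  ``cfg.null()`` yields identical treatment
    pairs and hence 0 % everywhere.
    """
    cfg = cfg or GeneratorConfig()
    background, method = gen_background_db(cfg)
    trials: dict[str, dict[str, FeedTrial]] = {}
    for tset, (stage, variant) in {
        "bg_full": ("bg", "base"),
        "fy_full": ("fy", "base"),
        "bg_s5": ("bg", "s5"),
        "fy_s5": ("fy", "s5"),
        "fy_s6": ("fy", "s6"),
    }.items():
        trials[tset] = {
            t: gen_feed_trial(cfg, stage, t, variant) for t in ("CNV", "EFC")
        }
    scenarios = [s for sid in range(1, 7) for s in scenario_boundaries(sid)]
    bundle = StudyBundle(
        cfg=cfg,
        background=background,
        method=method,
        trials=trials,
        params=cfg.chain_params(),
        scenarios=scenarios,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def load_bundle(indir, cfg: GeneratorConfig | None = None) -> StudyBundle:
    """Load a bundle previously written by :meth:`StudyBundle.write`."""
    indir = Path(indir)
    background = read_process_database(indir / "background_db.csv")
    method = read_impact_method(indir / "characterization_factors.csv")
    df = pd.read_csv(indir / "feed_trials.csv")
    trials: dict[str, dict[str, FeedTrial]] = {}
    for (tset, t), grp in df.groupby(["trial_set", "treatment"], sort=False):
        first = grp.iloc[0]
        ration = [
            RationItem(
                name=row["ingredient"],
                dmi_kg_per_head_day=float(row["dmi_kg_per_head_day"]),
                nem_mj_per_kg=float(row["nem_mj_per_kg"]),
                inclusion_limit=float(row["inclusion_limit"]),
            )
            for _, row in grp.iterrows()
        ]
        trials.setdefault(tset, {})[t] = FeedTrial(
            treatment=t,
            n_head=int(first["n_head"]),
            days_on_feed=int(first["days_on_feed"]),
            start_weight=float(first["start_weight"]),
            end_weight=float(first["end_weight"]),
            ration=ration,
            emissions={
                k: float(first[k])
                for k in ("enteric_ch4", "manure_ch4", "manure_n2o", "nh3")
            },
        )
    with open(indir / "scenarios.yaml") as fh:
        scen = yaml.safe_load(fh)
    scenarios = [
        ScenarioConfig(s["scenario_id"], s["boundary"], s["functional_unit"])
        for s in scen["scenarios"]
    ]
    cfg = cfg or GeneratorConfig(seed=int(scen.get("seed", 0)))
    return StudyBundle(
        cfg=cfg,
        background=background,
        method=method,
        trials=trials,
        params=cfg.chain_params(),
        scenarios=scenarios,
    )


# ---------------------------------------------------------------------------
# Bridges to the ration-calibration surrogate
# ---------------------------------------------------------------------------

def surrogate_from_trial(
    trial: FeedTrial, silage_name: str = "corn silage"
) -> SurrogateFarmModel:
    """Surrogate farm model whose energy demand reproduces the trial ration."""
    ingredients = [
        SurrogateIngredient(
            name=i.name,
            # the silage is the free variable: unconstrained fill
            inclusion_limit=(
                float("inf")
                if i.name == silage_name
                else (
                    i.inclusion_limit
                    if i.inclusion_limit is not None
                    else 1.25 * i.dmi_kg_per_head_day
                )
            ),
            nem_mj_per_kg=i.nem_mj_per_kg,
            is_silage=(i.name == silage_name),
        )
        for i in trial.ration
    ]
    energy = sum(i.dmi_kg_per_head_day * i.nem_mj_per_kg for i in trial.ration)
    return SurrogateFarmModel(
        ingredients=ingredients,
        herd_size=trial.n_head,
        energy_demand_mj_per_head_day=energy,
        start_weight_kg=trial.start_weight,
        gain_kg_per_head_day=trial.lwg_per_head / trial.days_on_feed,
    )


def target_from_trial(trial: FeedTrial) -> CalibrationTarget:
    """Observed calibration target extracted from a feed trial."""
    totals = trial.feed_totals()
    total = sum(totals.values())
    return CalibrationTarget(
        fractions={k: v / total for k, v in totals.items()},
        total_consumed_kg=total,
        final_herd_liveweight_kg=trial.n_head * trial.end_weight,
    )
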
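"""Comparative-LCA model and results objects.

:class:`ComparativeLCA` holds the study inputs (feed trials, background
database, characterization method, scenario list) and knows how to build
the paired conventional/treated product systems for each scenario boundary.
``fit()`` solves every scenario deterministically and returns a
:class:`ComparativeLCAResults` carrying the per-category impacts, percent
decreases and per-stage contributions, with ``summary()`` for a printed
overview.  Monte-Carlo uncertainty and the bootstrap significance decision
hang off the results object via ``monte_carlo()``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chain import ScenarioConfig, build_scenario
from .lci import (
    CATEGORY_UNITS,
    ImpactResult,
    ProductSystem,
    contribution_analysis,
    percent_decrease,
)
from .synthetic import GeneratorConfig, StudyBundle, gen_study_bundle, load_bundle
from .uncertainty import BootstrapDecision, PairedMCResult, bootstrap_test, paired_mc

__all__ = ["ComparativeLCA", "ComparativeLCAResults", "child_seed"]

#: human-readable labels for the scenario boundaries, used in decision tables
BOUNDARY_LABELS = {
    "gate_to_gate_FY": "FY (GtG)",
    "gate_to_gate_BG": "BG (GtG)",
    "BG_plus_FY": "BGFY (GtG)",
    "cradle_to_harvest": "Retail cut",
    "cradle_to_FY": "Cradle-to-FY gate",
}


def child_seed(seed: int, label: str) -> int:
    """Deterministic sub-seed below 2**31 for a named random substream."""
    return (1000003 * int(seed) + zlib.crc32(label.encode())) % 2**31


class ComparativeLCA:
    """Paired conventional-vs-treated beef supply-chain LCA.

    Parameters
    ----------
    bundle : StudyBundle
        The study inputs (trials, background database, factors, scenarios).
    scenarios : list of ScenarioConfig, optional
        Subset of scenario/boundary combinations to evaluate; defaults to
        every combination declared in the bundle.
    """

    def __init__(self, bundle: StudyBundle, scenarios: list[ScenarioConfig] | None = None):
        self.bundle = bundle
        self.scenarios = scenarios if scenarios is not None else list(bundle.scenarios)

    @classmethod
    def from_bundle(cls, path, **kwargs) -> "ComparativeLCA":
        """Build from a bundle directory written by the generator."""
        return cls(load_bundle(path), **kwargs)

    @classmethod
    def from_config(cls, cfg: GeneratorConfig | None = None, **kwargs) -> "ComparativeLCA":
        """Build directly from a generator configuration (no files)."""
        return cls(gen_study_bundle(cfg), **kwargs)

    def build_systems(self, cfg: ScenarioConfig) -> tuple[ProductSystem, ProductSystem]:
        """The paired (CNV, EFC) product systems for one scenario config."""
        return build_scenario(
            cfg, self.bundle.trials, self.bundle.params, self.bundle.background
        )

    def fit(self) -> "ComparativeLCAResults":
        """Solve every scenario deterministically.

        For each scenario/boundary combination both systems are solved with
        a contribution analysis, and the treatment percent decrease is
        computed per impact category.
        """
        rows = []
        contribs: dict[tuple[int, str], dict[str, ImpactResult]] = {}
        for cfg in self.scenarios:
            cnv_sys, efc_sys = self.build_systems(cfg)
            res_c = contribution_analysis(cnv_sys, self.bundle.method)
            res_e = contribution_analysis(efc_sys, self.bundle.method)
            contribs[(cfg.scenario_id, cfg.boundary)] = {"CNV": res_c, "EFC": res_e}
            for cat in CATEGORY_UNITS:
                cnv_v, efc_v = res_c.totals[cat], res_e.totals[cat]
                rows.append(
                    dict(
                        scenario_id=cfg.scenario_id,
                        boundary=cfg.boundary,
                        functional_unit=cfg.functional_unit,
                        category=cat,
                        unit=CATEGORY_UNITS[cat],
                        CNV=cnv_v,
                        EFC=efc_v,
                        percent_decrease=percent_decrease(cnv_v, efc_v),
                    )
                )
        return ComparativeLCAResults(
            model=self, impacts=pd.DataFrame(rows), _contributions=contribs
        )


@dataclass
class ComparativeLCAResults:
    """Deterministic comparative results, with uncertainty added on demand."""

    model: ComparativeLCA
    impacts: pd.DataFrame
    _contributions: dict[tuple[int, str], dict[str, ImpactResult]] = field(
        default_factory=dict
    )
    decisions: pd.DataFrame | None = None
    mc_results: dict[tuple[int, str], PairedMCResult] = field(default_factory=dict)
    bootstrap: dict[tuple[int, str], BootstrapDecision] = field(default_factory=dict)

    # -- deterministic views -------------------------------------------------

    def table(self, scenario_id: int, boundary: str | None = None) -> pd.DataFrame:
        """Result table for one scenario: category, unit, CNV, EFC, percent
        decrease (rendered with a leading minus sign, 2 decimals)."""
        df = self.impacts[self.impacts.scenario_id == scenario_id]
        if boundary is not None:
            df = df[df.boundary == boundary]
        if df.empty:
            raise KeyError(f"no results for scenario {scenario_id}, {boundary!r}")
        out = df[["category", "unit", "CNV", "EFC", "percent_decrease"]].copy()
        out["percent_decrease_label"] = out["percent_decrease"].map(
            lambda v: f"-{v:.2f}%" if v >= 0 else f"+{-v:.2f}%"
        )
        return out.reset_index(drop=True)

    def contributions(self, scenario_id: int, boundary: str, treatment: str = "CNV") -> pd.DataFrame:
        """Per-process contribution shares for one solved system."""
        res = self._contributions[(scenario_id, boundary)][treatment]
        rows = []
        for cat, per_proc in res.contributions.items():
            total = res.totals[cat]
            for pid, v in per_proc.items():
                if v != 0.0:
                    rows.append(
                        dict(
                            category=cat,
                            process_id=pid,
                            contribution=v,
                            share=v / total if total else np.nan,
                        )
                    )
        return pd.DataFrame(rows)

    def percent_decreases(self) -> pd.DataFrame:
        return self.impacts[
            ["scenario_id", "boundary", "category", "percent_decrease"]
        ].copy()

    # -- uncertainty ---------------------------------------------------------

    def monte_carlo(
        self,
        n_iter: int = 250,
        seed: int = 0,
        m: int = 30,
        reps: int = 300,
        scenarios: list[ScenarioConfig] | None = None,
    ) -> pd.DataFrame:
        """Paired Monte-Carlo + bootstrap decision for each scenario.

        Returns (and stores on ``self.decisions``) a decision table with one
        row per scenario/boundary and the 99th-percentile bootstrap p-value
        per impact category.
        """
        scenarios = scenarios if scenarios is not None else self.model.scenarios
        rows = []
        for cfg in scenarios:
            key = (cfg.scenario_id, cfg.boundary)
            label = f"mc-s{cfg.scenario_id}-{cfg.boundary}"
            cnv_sys, efc_sys = self.model.build_systems(cfg)
            mc = paired_mc(
                cnv_sys,
                efc_sys,
                self.model.bundle.method,
                n_iter=n_iter,
                seed=child_seed(seed, label),
            )
            dec = bootstrap_test(
                mc, m=m, reps=reps, seed=child_seed(seed, label + "-boot")
            )
            self.mc_results[key] = mc
            self.bootstrap[key] = dec
            row = dict(
                system_boundary=BOUNDARY_LABELS[cfg.boundary],
                scenario=cfg.scenario_id,
            )
            for cat in CATEGORY_UNITS:
                row[cat] = dec.p99[cat]
            rows.append(row)
        self.decisions = pd.DataFrame(rows)
        return self.decisions

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        """Printed overview of every scenario's percent decreases (and the
        significance decisions, when Monte Carlo has been run)."""
        lines = ["Comparative beef-ration LCA", "=" * 27, ""]
        for (sid, boundary), grp in self.impacts.groupby(
            ["scenario_id", "boundary"], sort=True
        ):
            fu = grp.functional_unit.iloc[0]
            lines.append(f"Scenario {sid} - {BOUNDARY_LABELS[boundary]} (per {fu})")
            tbl = grp[["category", "unit", "CNV", "EFC", "percent_decrease"]].copy()
            tbl["percent_decrease"] = tbl["percent_decrease"].map(lambda v: f"-{v:.2f}%")
            lines.append(
                tbl.to_string(index=False, float_format=lambda v: f"{v:,.1f}")
            )
            lines.append("")
        if self.decisions is not None:
            lines.append("Bootstrap decision table (p99 of one-sided p-values)")
            lines.append(
                self.decisions.to_string(index=False, float_format=lambda v: f"{v:.3g}")
            )
            lines.append("")
        return "\n".join(lines)
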
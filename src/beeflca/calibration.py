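"""Ration calibration against a surrogate energy-balance intake model.

Whole-farm simulators do not accept an animal ration directly: they simulate
intake from feed availability and nutritional characteristics.  Matching a
simulated ration to an observed feeding trial is therefore an inverse
problem over three kinds of knobs: the per-ingredient daily inclusion limit
(kg DM/head/day), the net energy of maintenance (NEm, MJ/kg DM) of the
silage, and the herd size (by one or two head, to match final herd live
weight).

The forward model used here is a deliberately simple energy-balance fill
model (it is *not* a re-implementation of any whole-farm simulator): each
head demands a fixed amount of feed energy per day; non-silage ingredients
are filled in declaration order up to their inclusion limit; silage is the
free variable that fills whatever energy demand remains, so its dry-matter
intake is inversely proportional to its NEm.  Nutritional fine-tuning knobs
are exposed as per-ingredient digestibility multipliers on the effective
NEm.

The calibration procedure mirrors manual simulator calibration: bisection on
each non-silage inclusion limit (round-robin), bisection on silage NEm, and
a +/-2-head search on herd size, all to a 1 % tolerance on composition,
total consumption and final herd weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SurrogateIngredient",
    "SurrogateFarmModel",
    "CalibrationTarget",
    "FeedingResult",
    "CalibrationResult",
    "InfeasibleRationError",
    "CalibrationError",
    "simulate_feeding",
    "calibrate_inclusion_limits",
    "calibrate_silage_nem",
    "adjust_herd_size",
    "RationCalibration",
]

MAX_ITERS = 200
BRACKET_WIDENINGS = 8


class InfeasibleRationError(Exception):
    """The energy demand cannot be met (or matched) under the constraints."""


class CalibrationError(Exception):
    """Bisection failed to converge within the iteration budget."""


@dataclass(frozen=True)
class SurrogateIngredient:
    """One ration ingredient in the surrogate intake model."""

    name: str
    inclusion_limit: float  # kg DM/head/day; silage may be unlimited (inf)
    nem_mj_per_kg: float
    is_silage: bool = False
    digestibility: float = 1.0  # multiplier on effective NEm (fine-tuning knob)

    @property
    def effective_nem(self) -> float:
        return self.nem_mj_per_kg * self.digestibility


@dataclass
class SurrogateFarmModel:
    """Energy-balance fill model of herd feeding.

    Each head demands ``energy_demand_mj_per_head_day`` MJ of NEm-equivalent
    feed energy daily (maintenance plus gain).  Non-silage ingredients are
    consumed at ``min(inclusion_limit, remaining demand / NEm)`` in
    declaration order; the single silage ingredient fills the remainder.
    """

    ingredients: list[SurrogateIngredient]
    herd_size: int
    energy_demand_mj_per_head_day: float
    start_weight_kg: float = 293.0
    gain_kg_per_head_day: float = 1.8

    def __post_init__(self) -> None:
        if self.herd_size < 1:
            raise ValueError("herd_size must be >= 1")
        n_silage = sum(i.is_silage for i in self.ingredients)
        if n_silage != 1:
            raise ValueError("exactly one silage ingredient is required")
        for i in self.ingredients:
            if i.inclusion_limit <= 0 or i.nem_mj_per_kg <= 0:
                raise ValueError(f"limits and NEm must be positive ({i.name!r})")

    @property
    def silage(self) -> SurrogateIngredient:
        return next(i for i in self.ingredients if i.is_silage)

    def with_limit(self, name: str, limit: float) -> "SurrogateFarmModel":
        items = [
            replace(i, inclusion_limit=limit) if i.name == name else i
            for i in self.ingredients
        ]
        return replace(self, ingredients=items)

    def with_silage_nem(self, nem: float) -> "SurrogateFarmModel":
        items = [
            replace(i, nem_mj_per_kg=nem) if i.is_silage else i
            for i in self.ingredients
        ]
        return replace(self, ingredients=items)


@dataclass
class FeedingResult:
    """Output of one deterministic feeding simulation."""

    consumed_kg: dict[str, float]  # herd-total kg DM per ingredient
    final_herd_liveweight_kg: float
    days: int

    @property
    def total_consumed_kg(self) -> float:
        return float(sum(self.consumed_kg.values()))

    def fractions(self) -> dict[str, float]:
        total = self.total_consumed_kg
        return {k: v / total for k, v in self.consumed_kg.items()}


@dataclass
class CalibrationTarget:
    """Observed quantities the simulation must match within tolerance."""

    fractions: dict[str, float]  # observed ration mass fractions
    total_consumed_kg: float
    final_herd_liveweight_kg: float

    def __post_init__(self) -> None:
        s = sum(self.fractions.values())
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"ration mass fractions sum to {s}, expected 1")
        if self.total_consumed_kg <= 0:
            raise ValueError("total consumption must be positive")

    def masses(self) -> dict[str, float]:
        return {k: f * self.total_consumed_kg for k, f in self.fractions.items()}


def simulate_feeding(model: SurrogateFarmModel, days: int) -> FeedingResult:
    """Deterministic herd feeding over ``days`` days.

    Raises :class:`InfeasibleRationError` when the silage inclusion limit is
    too tight to close the daily energy balance.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    remaining = model.energy_demand_mj_per_head_day
    daily: dict[str, float] = {}
    for ing in model.ingredients:
        if ing.is_silage:
            continue
        intake = min(ing.inclusion_limit, max(remaining, 0.0) / ing.effective_nem)
        daily[ing.name] = intake
        remaining -= intake * ing.effective_nem
    silage = model.silage
    silage_intake = max(remaining, 0.0) / silage.effective_nem
    if silage_intake > silage.inclusion_limit + 1e-12:
        raise InfeasibleRationError(
            f"infeasible ration: silage demand {silage_intake:.3f} kg/head/day "
            f"exceeds inclusion limit {silage.inclusion_limit:.3f}"
        )
    daily[silage.name] = silage_intake
    scale = model.herd_size * days
    consumed = {k: v * scale for k, v in daily.items()}
    final_lw = model.herd_size * (
        model.start_weight_kg + model.gain_kg_per_head_day * days
    )
    return FeedingResult(consumed_kg=consumed, final_herd_liveweight_kg=final_lw, days=days)


def _bisect_monotone(
    fun, target: float, lo: float, hi: float, increasing: bool, max_iters: int
) -> tuple[float, int]:
    """Bisection for fun(x) = target on a monotone function, with bracket
    widening (x2, up to BRACKET_WIDENINGS times) if the initial interval does
    not bracket the target."""
    f_lo, f_hi = fun(lo), fun(hi)
    if not increasing:
        # flip so that f is increasing in the search variable
        return _bisect_monotone(
            lambda x: -fun(x), -target, lo, hi, True, max_iters
        )
    widenings = 0
    while f_hi < target and widenings < BRACKET_WIDENINGS:
        hi *= 2.0
        f_hi = fun(hi)
        widenings += 1
    while f_lo > target and widenings < BRACKET_WIDENINGS:
        lo /= 2.0
        f_lo = fun(lo)
        widenings += 1
    if not (f_lo <= target <= f_hi):
        raise InfeasibleRationError(
            f"no bracket: target {target:.6g} outside [{f_lo:.6g}, {f_hi:.6g}]"
        )
    it = 0
    for it in range(max_iters):
        mid = 0.5 * (lo + hi)
        if fun(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-12 * max(1.0, hi):
            break
    return 0.5 * (lo + hi), it + 1


def calibrate_inclusion_limits(
    model: SurrogateFarmModel,
    target: CalibrationTarget,
    days: int,
    tol: float = 0.01,
    max_iters: int = MAX_ITERS,
) -> tuple[SurrogateFarmModel, int]:
    """Fit non-silage inclusion limits so simulated consumption matches the
    observed per-ingredient masses within ``tol`` (relative).

    Round-robin bisection over the non-silage ingredients; the silage intake
    responds through the energy balance.  Returns the fitted model and the
    total bisection iteration count.
    """
    fitted = model
    target_masses = target.masses()
    iterations = 0
    for _ in range(max_iters):
        for ing in fitted.ingredients:
            if ing.is_silage:
                continue
            if ing.name not in target_masses:
                raise KeyError(f"target has no mass fraction for {ing.name!r}")
            goal = target_masses[ing.name]

            def consumed(limit: float, name=ing.name) -> float:
                return simulate_feeding(fitted.with_limit(name, limit), days).consumed_kg[name]

            current = fitted.ingredients[
                [i.name for i in fitted.ingredients].index(ing.name)
            ].inclusion_limit
            x, used = _bisect_monotone(
                consumed, goal, current / 2.0, current * 2.0, True, max_iters
            )
            iterations += used
            fitted = fitted.with_limit(ing.name, x)
        if _limits_converged(fitted, target, days, tol):
            return fitted, iterations
    res = _residual_frame(fitted, target, days)
    raise CalibrationError(
        "inclusion-limit calibration did not converge; residuals:\n"
        + res.to_string(index=False)
    )


def _limits_converged(
    model: SurrogateFarmModel, target: CalibrationTarget, days: int, tol: float
) -> bool:
    """Per-ingredient consumed-mass residuals for the non-silage ingredients.

    Composition fractions are checked after the silage NEm stage: while the
    silage energy density is still mis-specified, the simulated total (the
    denominator of every fraction) is off through no fault of the limits.
    """
    sim = simulate_feeding(model, days)
    masses = target.masses()
    for ing in model.ingredients:
        if ing.is_silage:
            continue
        obs = masses[ing.name]
        if obs > 0 and abs(sim.consumed_kg[ing.name] - obs) / obs > tol:
            return False
    return True


def _fully_converged(
    model: SurrogateFarmModel, target: CalibrationTarget, days: int, tol: float
) -> bool:
    """Composition fractions and total consumption, all within ``tol``."""
    if not _limits_converged(model, target, days, tol):
        return False
    sim = simulate_feeding(model, days)
    if (
        abs(sim.total_consumed_kg - target.total_consumed_kg)
        / target.total_consumed_kg
        > tol
    ):
        return False
    fr = sim.fractions()
    for name, obs in target.fractions.items():
        if obs > 0 and abs(fr[name] - obs) / obs > tol:
            return False
    return True


def calibrate_silage_nem(
    model: SurrogateFarmModel,
    target_silage_kg: float,
    days: int,
    tol: float = 0.01,
    max_iters: int = MAX_ITERS,
) -> tuple[SurrogateFarmModel, int]:
    """Fit the silage NEm so the simulated silage consumption matches
    ``target_silage_kg`` (herd total over the period) within ``tol``.

    Silage intake is strictly decreasing in its NEm (a more energy-dense
    silage closes the energy balance with less dry matter).
    """
    if target_silage_kg <= 0:
        raise ValueError("target silage consumption must be positive")
    name = model.silage.name
    nem0 = model.silage.nem_mj_per_kg

    def consumed(nem: float) -> float:
        return simulate_feeding(model.with_silage_nem(nem), days).consumed_kg[name]

    x, used = _bisect_monotone(
        consumed, target_silage_kg, nem0 / 2.0, nem0 * 2.0, False, max_iters
    )
    fitted = model.with_silage_nem(x)
    sim = consumed(x)
    if abs(sim - target_silage_kg) / target_silage_kg > tol:
        raise CalibrationError(
            f"silage NEm calibration residual "
            f"{abs(sim - target_silage_kg) / target_silage_kg:.4f} exceeds {tol}"
        )
    return fitted, used


def adjust_herd_size(
    model: SurrogateFarmModel, target_final_lw_kg: float, days: int
) -> SurrogateFarmModel:
    """Pick the herd size within +/-2 head of nominal that best matches the
    observed final herd live weight; ties go to the smaller herd."""
    if model.herd_size < 3:
        raise ValueError("nominal herd size must be >= 3")
    best = None
    for n in range(model.herd_size - 2, model.herd_size + 3):
        cand = replace(model, herd_size=n)
        lw = simulate_feeding(cand, days).final_herd_liveweight_kg
        err = abs(lw - target_final_lw_kg)
        if best is None or err < best[0] - 1e-12:
            best = (err, n)
    return replace(model, herd_size=best[1])


def _residual_frame(
    model: SurrogateFarmModel, target: CalibrationTarget, days: int
) -> pd.DataFrame:
    sim = simulate_feeding(model, days)
    masses = target.masses()
    rows = []
    for ing in model.ingredients:
        obs = masses.get(ing.name, np.nan)
        got = sim.consumed_kg[ing.name]
        rows.append(
            {
                "ingredient": ing.name,
                "target_kg": obs,
                "simulated_kg": got,
                "residual": (got - obs) / obs if obs else np.nan,
            }
        )
    rows.append(
        {
            "ingredient": "(total)",
            "target_kg": target.total_consumed_kg,
            "simulated_kg": sim.total_consumed_kg,
            "residual": (sim.total_consumed_kg - target.total_consumed_kg)
            / target.total_consumed_kg,
        }
    )
    rows.append(
        {
            "ingredient": "(final herd lw)",
            "target_kg": target.final_herd_liveweight_kg,
            "simulated_kg": sim.final_herd_liveweight_kg,
            "residual": (
                sim.final_herd_liveweight_kg - target.final_herd_liveweight_kg
            )
            / target.final_herd_liveweight_kg,
        }
    )
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    """Fitted surrogate model plus residual diagnostics."""

    model: SurrogateFarmModel
    residuals: pd.DataFrame
    n_iterations: int
    tol: float
    converged: bool = True

    def summary(self) -> str:
        head = (
            f"Ration calibration: {len(self.model.ingredients)} ingredients, "
            f"herd {self.model.herd_size}, {self.n_iterations} bisection steps, "
            f"tolerance {self.tol:.0%}\n"
        )
        return head + self.residuals.to_string(index=False, float_format="%.4g")

    def to_csv(self, path) -> None:
        self.residuals.to_csv(path, index=False)


class RationCalibration:
    """Calibration problem: fit a surrogate farm model to trial observations.

    Parameters
    ----------
    model : SurrogateFarmModel
        Initial model (starting limits, NEm, nominal herd size).
    target : CalibrationTarget
        Observed ration composition, total consumption and final herd weight.
    days : int
        Feeding-period length in days.
    """

    def __init__(self, model: SurrogateFarmModel, target: CalibrationTarget, days: int):
        self.model = model
        self.target = target
        self.days = days

    def fit(self, tol: float = 0.01, max_iters: int = MAX_ITERS) -> CalibrationResult:
        """Run the three calibration stages and return the fitted result.

        Stage 1: round-robin bisection of non-silage inclusion limits;
        stage 2: bisection of silage NEm to the silage mass target;
        stage 3: +/-2-head herd-size adjustment to final herd weight.
        Residuals above ``tol`` raise :class:`CalibrationError`.
        """
        fitted, it1 = calibrate_inclusion_limits(
            self.model, self.target, self.days, tol=tol, max_iters=max_iters
        )
        silage_target = self.target.masses()[fitted.silage.name]
        fitted, it2 = calibrate_silage_nem(
            fitted, silage_target, self.days, tol=tol, max_iters=max_iters
        )
        fitted = adjust_herd_size(
            fitted, self.target.final_herd_liveweight_kg, self.days
        )
        residuals = _residual_frame(fitted, self.target, self.days)
        if not _fully_converged(fitted, self.target, self.days, tol):
            raise CalibrationError(
                "composition or total-consumption residual exceeds tolerance:\n"
                + residuals.to_string(index=False)
            )
        n_iter = it1 + it2
        logger.info("ration calibration converged in %d bisection steps", n_iter)
        return CalibrationResult(
            model=fitted, residuals=residuals, n_iterations=n_iter, tol=tol
        )
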
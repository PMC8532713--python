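"""Matrix-based life-cycle inventory and impact assessment.

This module is a small, self-contained LCI engine in the classical
computational structure of LCA: a square technosphere matrix ``A`` whose
columns are unit processes and whose rows are product flows, an intervention
matrix ``B`` mapping processes to elementary flows, and a final-demand vector
``f``.  Solving ``A s = f`` for the scaling vector ``s`` and forming
``g = B s`` yields the cumulative life-cycle inventory, which a
characterization method converts into impact-category scores.

Conventions
-----------
* Every unit process is mono-functional: exactly one reference product.
  Multi-output activities must be allocated into mono-functional processes
  before entering a :class:`ProductSystem` (see :mod:`beeflca.chain` for the
  revenue-based allocation helpers).
* Product flows and processes are indexed in declaration order, so matrices
  are deterministic across runs.
* Elementary exchanges contribute their amount to the inventory with a
  positive sign for both emissions (direction ``output``) and resource
  extractions (direction ``input``); characterization factors are expressed
  on that basis.
* Units are opaque labels validated at link time: the unit of a consumed
  product flow must equal the unit of its supplier's reference flow.
  No automatic conversion is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Flow",
    "Exchange",
    "UncertaintySpec",
    "UnitProcess",
    "ProductSystem",
    "ImpactMethod",
    "ImpactResult",
    "MatrixSystem",
    "LCAError",
    "UnlinkedFlowError",
    "AmbiguousSupplyError",
    "InfeasibleSystemError",
    "UnitMismatchError",
    "CATEGORY_UNITS",
    "build_matrices",
    "solve_inventory",
    "characterize",
    "contribution_analysis",
    "percent_decrease",
    "read_process_database",
    "write_process_database",
    "read_impact_method",
    "write_impact_method",
]

#: The four key-performance-indicator impact categories carried throughout
#: the package, with the unit each score is reported in.
CATEGORY_UNITS: dict[str, str] = {
    "climate change": "kg CO2 eq",
    "land use": "m2a",
    "water use": "m3",
    "fossil energy": "kg oil eq",
}


class LCAError(Exception):
    """Base class for inventory-model errors."""


class UnlinkedFlowError(LCAError):
    """A consumed or demanded product flow has no supplying process."""


class AmbiguousSupplyError(LCAError):
    """A product flow is supplied by more than one process."""


class InfeasibleSystemError(LCAError):
    """The technosphere matrix is singular or the solve residual is large."""


class UnitMismatchError(LCAError):
    """Consumer and producer disagree on the unit of a product flow."""


@dataclass(frozen=True)
class Flow:
    """A product or elementary flow.

    Parameters
    ----------
    id : str
        Opaque identifier, unique within a database.
    name : str
        Human-readable name.
    kind : str
        Either ``"product"`` (linked between processes) or ``"elementary"``
        (exchange with the environment).
    unit : str
        Unit label (kg, MJ, m3, m2a, head, ...).
    """

    id: str
    name: str
    kind: str  # "product" | "elementary"
    unit: str

    def __post_init__(self) -> None:
        if self.kind not in ("product", "elementary"):
            raise ValueError(f"unknown flow kind {self.kind!r} for flow {self.id!r}")


@dataclass(frozen=True)
class UncertaintySpec:
    """Dispersion attached to an exchange amount.

    ``distribution`` is one of ``"lognormal"``, ``"truncnormal"`` (normal
    truncated at zero) or ``"none"``; ``cv`` is the coefficient of variation
    (standard deviation divided by the mean) of the amount.
    """

    distribution: str = "lognormal"
    cv: float = 0.0

    def __post_init__(self) -> None:
        if self.distribution not in ("lognormal", "truncnormal", "none"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not (self.cv >= 0.0):
            raise ValueError("cv must be nonnegative")


@dataclass(frozen=True)
class Exchange:
    """A single input or output of a unit process.

    ``amount`` is expressed per unit of the owning process's reference
    product.  Elementary flows are never linked to another process; product
    outputs other than the reference product are rejected (allocate first).
    """

    flow: Flow
    amount: float
    direction: str  # "input" | "output"
    uncertainty: UncertaintySpec | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("input", "output"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not np.isfinite(self.amount):
            raise ValueError("exchange amount must be finite")


@dataclass
class UnitProcess:
    """A production activity with one reference product plus exchanges."""

    id: str
    name: str
    reference_product: tuple[Flow, float]
    exchanges: list[Exchange] = field(default_factory=list)

    def __post_init__(self) -> None:
        flow, amount = self.reference_product
        if flow.kind != "product":
            raise ValueError(
                f"reference product of {self.id!r} must be a product flow"
            )
        if not amount > 0:
            raise ValueError(f"reference amount of {self.id!r} must be positive")
        for ex in self.exchanges:
            if ex.flow.kind == "product" and ex.direction == "output":
                raise ValueError(
                    f"process {self.id!r} declares a product output "
                    f"{ex.flow.id!r} besides its reference product; "
                    "multi-output processes must be allocated first"
                )


@dataclass
class ProductSystem:
    """A linked set of mono-functional unit processes plus a demand vector.

    ``demand`` maps product flows to the functional-unit quantity, e.g.
    1000 kg of live weight gain.
    """

    processes: list[UnitProcess]
    demand: dict[Flow, float]

    def process_ids(self) -> list[str]:
        return [p.id for p in self.processes]


@dataclass
class ImpactMethod:
    """Characterization factors for the four KPI categories.

    ``factors`` maps category name -> {elementary flow id -> factor}, on the
    sign convention of this module (emissions and extractions positive).
    """

    factors: dict[str, dict[str, float]]
    units: dict[str, str] = field(default_factory=lambda: dict(CATEGORY_UNITS))

    def __post_init__(self) -> None:
        missing = set(CATEGORY_UNITS) - set(self.factors)
        if missing:
            raise ValueError(f"impact method missing categories: {sorted(missing)}")
        for cat, fs in self.factors.items():
            for fid, v in fs.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite factor for {fid!r} in {cat!r}")

    @property
    def categories(self) -> list[str]:
        return list(CATEGORY_UNITS)


@dataclass
class ImpactResult:
    """Characterized scores, optionally with per-process contributions."""

    totals: dict[str, float]
    units: dict[str, str]
    contributions: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": c, "unit": self.units.get(c, ""), "total": t}
            for c, t in self.totals.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class _Entry:
    """Position of one exchange coefficient in A or B (for perturbation)."""

    matrix: str  # "A" | "B"
    row: int
    col: int
    amount: float  # signed value as placed in the matrix
    uncertainty: UncertaintySpec | None
    process_id: str
    exchange_index: int


@dataclass
class MatrixSystem:
    """Assembled matrix form of a :class:`ProductSystem`.

    Attributes
    ----------
    A : (n, n) ndarray
        Technosphere matrix; supply positive on the diagonal, consumption
        negative off-diagonal.
    B : (m, n) ndarray
        Intervention matrix over elementary flows.
    f : (n,) ndarray
        Final-demand vector.
    """

    A: np.ndarray
    B: np.ndarray
    f: np.ndarray
    product_flows: list[Flow]
    elementary_flows: list[Flow]
    process_ids: list[str]
    entries: list[_Entry]

    def solve_scaling(self) -> np.ndarray:
        return _solve(self.A, self.f)


def _solve(A: np.ndarray, f: np.ndarray) -> np.ndarray:
    try:
        s = np.linalg.solve(A, f)
    except np.linalg.LinAlgError as err:
        raise InfeasibleSystemError(f"infeasible system: {err}") from None
    fnorm = np.linalg.norm(f)
    if fnorm > 0:
        resid = np.linalg.norm(A @ s - f) / fnorm
        if not resid < 1e-10:
            raise InfeasibleSystemError(
                f"infeasible system: solve residual {resid:.2e} exceeds 1e-10"
            )
    return s


def build_matrices(system: ProductSystem) -> MatrixSystem:
    """Assemble A, B and f from a linked product system.

    Raises
    ------
    AmbiguousSupplyError
        If two processes supply the same product flow.
    UnlinkedFlowError
        If a consumed or demanded product flow has no supplier.
    UnitMismatchError
        If a consumer's unit for a product flow differs from the supplier's.
    """
    suppliers: dict[str, int] = {}
    product_flows: list[Flow] = []
    for j, proc in enumerate(system.processes):
        flow, _ = proc.reference_product
        if flow.id in suppliers:
            other = system.processes[suppliers[flow.id]].id
            raise AmbiguousSupplyError(
                f"ambiguous supply: product flow {flow.id!r} supplied by both "
                f"{other!r} and {proc.id!r}"
            )
        suppliers[flow.id] = j
        product_flows.append(flow)

    n = len(system.processes)
    prod_index = {fl.id: i for i, fl in enumerate(product_flows)}

    elem_index: dict[str, int] = {}
    elementary_flows: list[Flow] = []

    A = np.zeros((n, n))
    entries: list[_Entry] = []
    for j, proc in enumerate(system.processes):
        ref_flow, ref_amount = proc.reference_product
        A[prod_index[ref_flow.id], j] += ref_amount
        for k, ex in enumerate(proc.exchanges):
            if ex.flow.kind == "product":
                # direction is necessarily "input" (outputs rejected upstream)
                if ex.flow.id not in prod_index:
                    raise UnlinkedFlowError(
                        f"unlinked flow: {ex.flow.id!r} consumed by "
                        f"{proc.id!r} has no supplying process"
                    )
                supplier = product_flows[prod_index[ex.flow.id]]
                if supplier.unit != ex.flow.unit:
                    raise UnitMismatchError(
                        f"unit mismatch on {ex.flow.id!r}: supplier uses "
                        f"{supplier.unit!r}, consumer {proc.id!r} uses "
                        f"{ex.flow.unit!r}"
                    )
                row = prod_index[ex.flow.id]
                A[row, j] -= ex.amount
                entries.append(
                    _Entry("A", row, j, -ex.amount, ex.uncertainty, proc.id, k)
                )
            else:
                if ex.flow.id not in elem_index:
                    elem_index[ex.flow.id] = len(elementary_flows)
                    elementary_flows.append(ex.flow)

    m = len(elementary_flows)
    B = np.zeros((m, n))
    for j, proc in enumerate(system.processes):
        for k, ex in enumerate(proc.exchanges):
            if ex.flow.kind == "elementary":
                row = elem_index[ex.flow.id]
                B[row, j] += ex.amount
                entries.append(
                    _Entry("B", row, j, ex.amount, ex.uncertainty, proc.id, k)
                )

    f = np.zeros(n)
    for flow, qty in system.demand.items():
        if flow.id not in prod_index:
            raise UnlinkedFlowError(
                f"unlinked flow: demanded flow {flow.id!r} has no supplier"
            )
        f[prod_index[flow.id]] += qty

    return MatrixSystem(
        A=A,
        B=B,
        f=f,
        product_flows=product_flows,
        elementary_flows=elementary_flows,
        process_ids=system.process_ids(),
        entries=entries,
    )


def solve_inventory(system: ProductSystem) -> dict[str, float]:
    """Cumulative life-cycle inventory of the system's demand.

    Returns a map from elementary-flow id to total amount.
    """
    mats = build_matrices(system)
    s = mats.solve_scaling()
    g = mats.B @ s
    return {fl.id: float(g[i]) for i, fl in enumerate(mats.elementary_flows)}


def characterize(
    g: Mapping[str, float], method: ImpactMethod
) -> ImpactResult:
    """Convert an inventory into the four impact-category scores.

    Flows without a factor in a category contribute zero to that category;
    flows without a factor in *any* category are logged once.
    """
    totals: dict[str, float] = {}
    for cat in method.categories:
        fs = method.factors[cat]
        totals[cat] = float(sum(amount * fs.get(fid, 0.0) for fid, amount in g.items()))
    orphan = [
        fid
        for fid in g
        if all(fid not in method.factors[cat] for cat in method.categories)
    ]
    if orphan:
        logger.warning(
            "uncharacterized elementary flows (contribute zero): %s",
            ", ".join(sorted(orphan)),
        )
    return ImpactResult(totals=totals, units=dict(method.units))


def contribution_analysis(
    system: ProductSystem, method: ImpactMethod
) -> ImpactResult:
    """Impact totals with per-process contribution shares.

    The contribution of process *j* in category *c* is the characterized
    column of ``B diag(s)``; contributions sum to the category total.
    """
    mats = build_matrices(system)
    s = mats.solve_scaling()
    scaled = mats.B * s[np.newaxis, :]  # (m, n): flow k emitted by process j
    totals: dict[str, float] = {}
    contribs: dict[str, dict[str, float]] = {}
    for cat in method.categories:
        fs = method.factors[cat]
        w = np.array([fs.get(fl.id, 0.0) for fl in mats.elementary_flows])
        per_proc = w @ scaled  # (n,)
        totals[cat] = float(per_proc.sum())
        contribs[cat] = {
            pid: float(v) for pid, v in zip(mats.process_ids, per_proc)
        }
    return ImpactResult(totals=totals, units=dict(method.units), contributions=contribs)


def percent_decrease(cnv_value: float, efc_value: float) -> float:
    """Percent decrease of the treatment value relative to the conventional one.

    Returns ``100 * (cnv - efc) / cnv``.  The report layer renders the value
    with a leading minus sign, rounded to 2 decimals.
    """
    if not cnv_value > 0:
        raise ValueError("conventional value must be positive")
    return 100.0 * (cnv_value - efc_value) / cnv_value


# ---------------------------------------------------------------------------
# CSV interfaces
#
# Process database: one row per exchange with columns
#   process_id, process_name, flow_id, flow_name, flow_kind, direction,
#   amount, unit, distribution, cv
# The single product-kind output row of each process is its reference product.
# Characterization factors: category, flow_id, factor, unit.
# ---------------------------------------------------------------------------

_DB_COLUMNS = [
    "process_id",
    "process_name",
    "flow_id",
    "flow_name",
    "flow_kind",
    "direction",
    "amount",
    "unit",
    "distribution",
    "cv",
]


def write_process_database(processes: Iterable[UnitProcess], path) -> None:
    rows = []
    for proc in processes:
        ref_flow, ref_amount = proc.reference_product
        rows.append(
            dict(
                process_id=proc.id,
                process_name=proc.name,
                flow_id=ref_flow.id,
                flow_name=ref_flow.name,
                flow_kind="product",
                direction="output",
                amount=ref_amount,
                unit=ref_flow.unit,
                distribution="none",
                cv=0.0,
            )
        )
        for ex in proc.exchanges:
            unc = ex.uncertainty or UncertaintySpec("none", 0.0)
            rows.append(
                dict(
                    process_id=proc.id,
                    process_name=proc.name,
                    flow_id=ex.flow.id,
                    flow_name=ex.flow.name,
                    flow_kind=ex.flow.kind,
                    direction=ex.direction,
                    amount=ex.amount,
                    unit=ex.flow.unit,
                    distribution=unc.distribution,
                    cv=unc.cv,
                )
            )
    pd.DataFrame(rows, columns=_DB_COLUMNS).to_csv(path, index=False)


def read_process_database(path) -> list[UnitProcess]:
    """Read unit processes from the one-row-per-exchange CSV dialect."""
    df = pd.read_csv(path)
    missing = set(_DB_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"process database missing columns: {sorted(missing)}")
    processes: list[UnitProcess] = []
    for pid, grp in df.groupby("process_id", sort=False):
        name = str(grp["process_name"].iloc[0])
        ref = grp[(grp["flow_kind"] == "product") & (grp["direction"] == "output")]
        if len(ref) != 1:
            raise ValueError(
                f"process {pid!r} must have exactly one product output "
                f"(reference product); found {len(ref)}"
            )
        r = ref.iloc[0]
        ref_flow = Flow(str(r["flow_id"]), str(r["flow_name"]), "product", str(r["unit"]))
        exchanges: list[Exchange] = []
        for _, row in grp.drop(index=ref.index).iterrows():
            flow = Flow(
                str(row["flow_id"]),
                str(row["flow_name"]),
                str(row["flow_kind"]),
                str(row["unit"]),
            )
            dist = str(row["distribution"])
            cv = float(row["cv"])
            unc = None if dist == "none" and cv == 0.0 else UncertaintySpec(dist, cv)
            exchanges.append(
                Exchange(flow, float(row["amount"]), str(row["direction"]), unc)
            )
        processes.append(
            UnitProcess(str(pid), name, (ref_flow, float(r["amount"])), exchanges)
        )
    return processes


def write_impact_method(method: ImpactMethod, path) -> None:
    rows = [
        dict(category=cat, flow_id=fid, factor=v, unit=method.units[cat])
        for cat in method.categories
        for fid, v in method.factors[cat].items()
    ]
    pd.DataFrame(rows, columns=["category", "flow_id", "factor", "unit"]).to_csv(
        path, index=False
    )


def read_impact_method(path) -> ImpactMethod:
    df = pd.read_csv(path)
    factors: dict[str, dict[str, float]] = {c: {} for c in CATEGORY_UNITS}
    units = dict(CATEGORY_UNITS)
    for _, row in df.iterrows():
        cat = str(row["category"])
        factors.setdefault(cat, {})[str(row["flow_id"])] = float(row["factor"])
        units[cat] = str(row["unit"])
    return ImpactMethod(factors=factors, units=units)
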
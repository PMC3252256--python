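"""Synthetic hospital ward stock and pharmacy sales generator.

The generative model realizes the mechanism that makes pharmacy sales an
imperfect proxy for consumption: wards hold a local antibiotic stock and
order from the pharmacy in discrete lots when the shelf runs low, so weekly
sales are lumpy while patient consumption is comparatively smooth.  The
discrepancy is purely stock-size fluctuation plus the small non-consumption
flows (loans, discards, discharge take-aways) — there is no measurement
noise, which is what lets the accounting pipeline be tested for exact
conservation.

Daily loop per ward x agent:

1. morning doses — demand is drawn (Poisson, or patient-course bursts) and
   taken from stock; unmet demand is deferred (backorder) and consumed as
   soon as stock is replenished, mirroring same-day resupply from another
   ward or the pharmacy;
2. on the first day of each week, after the morning doses, a snapshot of the
   shelf is taken (suppressed inside configured missing blocks);
3. ordering — if stock is below the route's reorder point an order is
   placed, recorded as a pharmacy sale and delivered the same week;
4. on the first day of each week, loan/discard/discharge/return events are
   sampled at their configured weekly DDD rates and applied to stock.

Random streams are split per ward x agent (seeded from the config seed plus
the ward and agent positions) so adding an agent does not perturb other
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .accounting import FlowRecord, SalesRecord, StockSnapshot, ConsumptionSeries
from .ddd import AgentSpec, DDDReferenceTable
from .errors import ValidationError

import pandas as pd

DAYS_PER_WEEK = 7


@dataclass(frozen=True)
class OrderPolicy:
    """Reorder-point policy for one route.

    When shelf stock falls below ``reorder_point`` (DDDs) an order is placed;
    the order size is drawn from the discrete distribution given by
    ``order_sizes`` with ``order_weights`` (uniform when weights omitted).
    """

    reorder_point: float
    order_sizes: tuple[float, ...]
    order_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.order_sizes:
            raise ValidationError("order_sizes must be non-empty")
        if any(s <= 0 for s in self.order_sizes):
            raise ValidationError("order sizes must be positive")
        if self.order_weights is not None:
            if len(self.order_weights) != len(self.order_sizes):
                raise ValidationError(
                    "order_weights length must match order_sizes"
                )
            if any(w < 0 for w in self.order_weights):
                raise ValidationError("order weights must be >= 0")

    def mean_order_size(self) -> float:
        sizes = np.asarray(self.order_sizes, dtype=float)
        if self.order_weights is None:
            return float(sizes.mean())
        w = np.asarray(self.order_weights, dtype=float)
        return float((sizes * w).sum() / w.sum())


@dataclass
class SimConfig:
    """Full description of one synthetic study.

    ``demand`` maps ward_id -> agent_id -> mean weekly patient demand in
    DDDs.  Flow rates are hospital-wide expected DDDs per week, allocated
    across ward x agent cells proportionally to demand.  ``seed`` fully
    determines the output.
    """

    wards: list[str]
    agents: list[AgentSpec]
    demand: dict[str, dict[str, float]]
    weeks: int = 26
    order_policy: dict[str, OrderPolicy] = field(default_factory=dict)
    demand_model: str = "poisson_daily"
    loan_in_rate: float = 0.0
    loan_out_rate: float = 0.0
    discard_rate: float = 0.0
    discharge_rate: float = 0.0
    return_rate: float = 0.0
    missing_blocks: list[tuple[int, int]] = field(default_factory=list)
    initial_stock_weeks: float = 1.5
    course_mean_ddd: float = 7.0  # patient_courses mode: mean DDDs per course
    seed: int = 0

    def __post_init__(self) -> None:
        if self.demand_model not in ("poisson_daily", "patient_courses"):
            raise ValidationError(
                f"unknown demand_model {self.demand_model!r}"
            )
        for rate_name in ("loan_in_rate", "loan_out_rate", "discard_rate",
                          "discharge_rate", "return_rate"):
            if getattr(self, rate_name) < 0:
                raise ValidationError(f"{rate_name} must be >= 0")
        if self.weeks < 1:
            raise ValidationError("weeks must be >= 1")
        for route in ("parenteral", "oral"):
            self.order_policy.setdefault(route, _DEFAULT_POLICIES[route])
        ids = {a.agent_id for a in self.agents}
        for ward, rates in self.demand.items():
            if ward not in self.wards:
                raise ValidationError(f"demand for unknown ward {ward!r}")
            for agent_id, rate in rates.items():
                if agent_id not in ids:
                    raise ValidationError(
                        f"demand for unknown agent {agent_id!r}"
                    )
                if rate < 0:
                    raise ValidationError("demand rates must be >= 0")
        for policy in self.order_policy.values():
            # a zero reorder point with positive demand would deadlock only
            # if no order could ever be triggered; orders trigger on
            # stock < reorder_point, so the point must exceed zero when any
            # demand exists
            if policy.reorder_point < 0:
                raise ValidationError("reorder_point must be >= 0")

    def reference_table(self) -> DDDReferenceTable:
        return DDDReferenceTable.from_agents(self.agents)

    def total_weekly_demand(self) -> float:
        return sum(sum(r.values()) for r in self.demand.values())

    def expected_grand_total(self) -> float:
        """Analytic expectation of total patient consumption (DDDs)."""
        return self.total_weekly_demand() * self.weeks


_DEFAULT_POLICIES = {
    # parenteral: small frequent orders, 5-10 DDDs per order
    "parenteral": OrderPolicy(
        reorder_point=5.0,
        order_sizes=tuple(float(s) for s in range(5, 11)),
    ),
    # oral: lumpy orders 5-50 DDDs, weighted so the median order is 20
    "oral": OrderPolicy(
        reorder_point=10.0,
        order_sizes=(5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0),
        order_weights=(0.10, 0.15, 0.15, 0.20, 0.15, 0.10, 0.10, 0.05),
    ),
}


@dataclass
class SimOutput:
    """Everything the pipeline needs, plus the ground truth it should
    recover."""

    config: SimConfig
    true_consumption: ConsumptionSeries
    snapshots: list[StockSnapshot]
    flows: list[FlowRecord]
    sales: list[SalesRecord]

    def sales_total(self) -> float:
        return sum(s.ddd_ordered for s in self.sales)

    def flow_total(self, *flow_types: str) -> float:
        return sum(
            f.amount_ddd for f in self.flows if f.flow_type in flow_types
        )


def _series_rng(seed: int, ward_idx: int, agent_idx: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, ward_idx, agent_idx])


def _daily_demand(rng: np.random.Generator, config: SimConfig,
                  weekly_rate: float, n_days: int) -> np.ndarray:
    """Per-day patient demand in whole DDDs over the study horizon."""
    if weekly_rate == 0.0:
        return np.zeros(n_days)
    if config.demand_model == "poisson_daily":
        return rng.poisson(weekly_rate / DAYS_PER_WEEK, size=n_days).astype(float)
    # patient_courses: admissions are Poisson, each starting a course of
    # 1 DDD/day whose length is geometric with the configured mean
    mean_len = max(config.course_mean_ddd, 1.0)
    adm_rate = weekly_rate / mean_len / DAYS_PER_WEEK
    demand = np.zeros(n_days)
    admissions = rng.poisson(adm_rate, size=n_days)
    for day, count in enumerate(admissions):
        for _ in range(count):
            length = int(rng.geometric(1.0 / mean_len))
            demand[day:day + length] += 1.0
    return demand


def _weekly_event_amounts(rng: np.random.Generator, rate: float,
                          weeks: int) -> np.ndarray:
    """Integer-DDD event amounts per week with the given mean rate."""
    if rate == 0.0:
        return np.zeros(weeks)
    return rng.poisson(rate, size=weeks).astype(float)


def simulate(config: SimConfig) -> SimOutput:
    """Run the stock/ordering simulation; seed-deterministic."""
    ref = config.reference_table()
    n_weeks = config.weeks
    n_days = n_weeks * DAYS_PER_WEEK
    suppressed = _suppressed_boundaries(config)

    total_demand = config.total_weekly_demand()
    snapshots_by_ward: dict[str, dict[int, dict[str, float]]] = {
        w: {} for w in config.wards
    }
    flows: list[FlowRecord] = []
    sales: list[SalesRecord] = []
    truth_rows = []
    order_counter = 0

    for w_idx, ward_id in enumerate(config.wards):
        for a_idx, agent in enumerate(config.agents):
            rng = _series_rng(config.seed, w_idx, a_idx)
            weekly_rate = config.demand.get(ward_id, {}).get(agent.agent_id, 0.0)
            policy = config.order_policy[agent.route]
            share = weekly_rate / total_demand if total_demand > 0 else 0.0

            demand = _daily_demand(rng, config, weekly_rate, n_days + 1)
            events = {
                ftype: _weekly_event_amounts(rng, rate * share, n_weeks)
                for ftype, rate in (
                    ("loan_in", config.loan_in_rate),
                    ("loan_out", config.loan_out_rate),
                    ("discard", config.discard_rate),
                    ("discharge_takeaway", config.discharge_rate),
                    ("return_to_pharmacy", config.return_rate),
                )
            }
            sizes = np.asarray(policy.order_sizes)
            weights = None
            if policy.order_weights is not None:
                weights = np.asarray(policy.order_weights, dtype=float)
                weights = weights / weights.sum()

            stock = policy.reorder_point + weekly_rate * config.initial_stock_weeks
            backlog = 0.0
            consumed_week = np.zeros(n_weeks)

            def record_snapshot(boundary: int, level: float) -> None:
                if boundary in suppressed:
                    return
                snapshots_by_ward[ward_id].setdefault(boundary, {})[
                    agent.agent_id
                ] = level * agent.ddd_mg / agent.pack_strength_mg

            record_snapshot(0, stock)  # pre-study opening count

            for day in range(1, n_days + 2):
                first_of_week = (day - 1) % DAYS_PER_WEEK == 0
                # accounting window of this day's morning dose: the dose on
                # the first day of a week precedes that day's snapshot, so
                # it belongs to the closing week
                dose_week = 1 if day == 1 else (day - 2) // DAYS_PER_WEEK + 1
                # 1. morning doses (day n_days+1 exists only for the dose
                #    preceding the closing count)
                want = demand[day - 1] + backlog
                taken = min(stock, want)
                stock -= taken
                backlog = want - taken
                consumed_week[dose_week - 1] += taken
                if first_of_week and day > 1:
                    record_snapshot((day - 1) // DAYS_PER_WEEK, stock)
                if day > n_days:
                    break
                # events from here on fall after the snapshot, in the week
                # that is just opening
                week = (day - 1) // DAYS_PER_WEEK + 1
                # 2. ordering: same-week delivery, after the snapshot
                if stock < policy.reorder_point and weekly_rate > 0:
                    size = float(rng.choice(sizes, p=weights))
                    order_counter += 1
                    sales.append(
                        SalesRecord(
                            ward_id=ward_id, week_index=week,
                            agent_id=agent.agent_id, ddd_ordered=size,
                            order_id=f"o{order_counter:05d}",
                        )
                    )
                    flows.append(
                        FlowRecord(
                            ward_id=ward_id, week_index=week,
                            agent_id=agent.agent_id, flow_type="delivery",
                            amount_ddd=size,
                        )
                    )
                    stock += size
                # 3. weekly non-consumption events
                if first_of_week:
                    for ftype, amounts in events.items():
                        amount = amounts[week - 1]
                        if amount <= 0:
                            continue
                        if ftype == "loan_in":
                            stock += amount
                        else:
                            amount = min(amount, stock)
                            if amount <= 0:
                                continue
                            stock -= amount
                        flows.append(
                            FlowRecord(
                                ward_id=ward_id, week_index=week,
                                agent_id=agent.agent_id, flow_type=ftype,
                                amount_ddd=float(amount),
                            )
                        )

            for week in range(1, n_weeks + 1):
                truth_rows.append(
                    {"ward_id": ward_id, "agent_id": agent.agent_id,
                     "week": week, "ddd": consumed_week[week - 1],
                     "imputed": False}
                )

    snapshots = [
        StockSnapshot(ward_id=ward_id, week_index=boundary, counts=counts)
        for ward_id, by_boundary in snapshots_by_ward.items()
        for boundary, counts in sorted(by_boundary.items())
    ]
    truth = ConsumptionSeries(
        method="ward",
        data=pd.DataFrame(truth_rows).sort_values(
            ["ward_id", "agent_id", "week"], ignore_index=True
        ),
        n_weeks=n_weeks,
    )
    return SimOutput(
        config=config, true_consumption=truth,
        snapshots=snapshots, flows=flows, sales=sales,
    )


def _suppressed_boundaries(config: SimConfig) -> set[int]:
    """Boundaries with no stock count: the interior boundaries of each
    missing block.  Block (a, b) keeps boundaries a-1 and b so its total
    stays computable by the balance equation."""
    suppressed: set[int] = set()
    for start, end in config.missing_blocks:
        if start < 1 or end > config.weeks or start > end:
            raise ValidationError(
                f"missing block ({start}, {end}) outside study window"
            )
        suppressed.update(range(start, end))
    return suppressed


def degrade_to_observed(sim: SimOutput, drop_flow_fraction: float,
                        seed: int | None = None) -> SimOutput:
    """Randomly drop a fraction of the manually registered flow records
    (loans and discharge take-aways), leaving electronically registered
    discards, returns, deliveries and sales intact."""
    if not 0.0 <= drop_flow_fraction <= 1.0:
        raise ValidationError(
            f"drop_flow_fraction must be in [0, 1], got {drop_flow_fraction}"
        )
    rng = np.random.default_rng(
        (sim.config.seed & 0x7FFFFFFF) if seed is None else seed
    )
    manual = ("loan_in", "loan_out", "discharge_takeaway")
    kept = []
    for f in sim.flows:
        if f.flow_type in manual and rng.random() < drop_flow_fraction:
            continue
        kept.append(f)
    return SimOutput(
        config=sim.config,
        true_consumption=sim.true_consumption.copy(),
        snapshots=list(sim.snapshots),
        flows=kept,
        sales=list(sim.sales),
    )


# --------------------------------------------------------------------------
# Default study configuration: 5 wards x 8 broad-spectrum agents x 26 weeks

def study_agents() -> list[AgentSpec]:
    """The eight broad-spectrum items: 2nd/3rd-generation cephalosporins,
    carbapenems, and ciprofloxacin in both routes.  DDD strengths follow the
    WHO ATC/DDD index; they are plain data and can be edited."""
    return [
        AgentSpec("cefuroxime", "J01DC02", "cefuroxime", "parenteral",
                  ddd_mg=3000, pack_strength_mg=1500),
        AgentSpec("cefotaxime", "J01DD01", "cefotaxime", "parenteral",
                  ddd_mg=4000, pack_strength_mg=1000),
        AgentSpec("ceftazidime", "J01DD02", "ceftazidime", "parenteral",
                  ddd_mg=4000, pack_strength_mg=2000),
        AgentSpec("ceftriaxone", "J01DD04", "ceftriaxone", "parenteral",
                  ddd_mg=2000, pack_strength_mg=1000),
        AgentSpec("meropenem", "J01DH02", "meropenem", "parenteral",
                  ddd_mg=2000, pack_strength_mg=500),
        AgentSpec("imipenem_cilastatin", "J01DH51", "imipenem/cilastatin",
                  "parenteral", ddd_mg=2000, pack_strength_mg=500),
        AgentSpec("ciprofloxacin_iv", "J01MA02", "ciprofloxacin",
                  "parenteral", ddd_mg=500, pack_strength_mg=200),
        AgentSpec("ciprofloxacin_po", "J01MA02", "ciprofloxacin", "oral",
                  ddd_mg=1000, pack_strength_mg=500),
    ]


# 26-week ward totals (DDDs) per reporting class, shaped like the study
# hospital: a cephalosporin-heavy pulmonary ward, ciprofloxacin-heavy
# urology wards with zero carbapenem use, and mixed medical wards.
_CLASS_TOTALS = {
    #              2nd-gen 3rd-gen  carb  cipro-iv cipro-po
    "pulmonary":        (432.5, 360.3, 171.0, 26.4, 204.0),
    "gastro_infect":    (231.0, 152.5,  96.3, 130.0, 288.3),
    "endo_haem":        (128.0, 111.3,  76.0,  46.8, 314.0),
    "urology_1":        ( 62.5,  32.8,   0.0, 131.2, 346.3),
    "urology_2":        ( 63.0,  19.0,   0.0, 144.4, 402.3),
}

# within-class split across agents (free choice, fixed once)
_THIRD_GEN_SPLIT = {"cefotaxime": 0.5, "ceftazidime": 0.3, "ceftriaxone": 0.2}
_CARBAPENEM_SPLIT = {"meropenem": 0.6, "imipenem_cilastatin": 0.4}


def default_study_config(seed: int = 0, weeks: int = 26) -> SimConfig:
    """Study-shaped configuration: 5 wards, 8 agents, 26 weeks, expected
    grand total near 3 970 DDDs, ~50% ciprofloxacin of which ~77% oral,
    non-consumption flows near 1% of use, and missing count blocks at weeks
    10-12 and 25-26."""
    demand: dict[str, dict[str, float]] = {}
    for ward, (c2, c3, carb, cip_iv, cip_po) in _CLASS_TOTALS.items():
        rates = {"cefuroxime": c2}
        for agent_id, frac in _THIRD_GEN_SPLIT.items():
            rates[agent_id] = c3 * frac
        for agent_id, frac in _CARBAPENEM_SPLIT.items():
            rates[agent_id] = carb * frac
        rates["ciprofloxacin_iv"] = cip_iv
        rates["ciprofloxacin_po"] = cip_po
        demand[ward] = {a: total / 26.0 for a, total in rates.items()}

    return SimConfig(
        wards=list(_CLASS_TOTALS),
        agents=study_agents(),
        demand=demand,
        weeks=weeks,
        # hospital-wide expected DDDs/week, totalling ~1% of use over the
        # study: discard 10.5, discharge 18.0, loans out 14.5, loans in 9
        loan_in_rate=9.0 / 26.0,
        loan_out_rate=14.5 / 26.0,
        discard_rate=10.5 / 26.0,
        discharge_rate=18.0 / 26.0,
        return_rate=0.0,
        missing_blocks=[(10, 12), (25, 26)] if weeks >= 26 else [],
        seed=seed,
    )


# --------------------------------------------------------------------------
# YAML round-trip for SimConfig

def config_to_yaml(config: SimConfig, path) -> None:
    payload = {
        "wards": config.wards,
        "agents": [
            {"agent_id": a.agent_id, "atc_code": a.atc_code, "name": a.name,
             "route": a.route, "ddd_mg": a.ddd_mg,
             "pack_strength_mg": a.pack_strength_mg, "is_bsa": a.is_bsa}
            for a in config.agents
        ],
        "demand": config.demand,
        "weeks": config.weeks,
        "order_policy": {
            route: {
                "reorder_point": p.reorder_point,
                "order_sizes": list(p.order_sizes),
                "order_weights": (
                    list(p.order_weights) if p.order_weights else None
                ),
            }
            for route, p in config.order_policy.items()
        },
        "demand_model": config.demand_model,
        "loan_in_rate": config.loan_in_rate,
        "loan_out_rate": config.loan_out_rate,
        "discard_rate": config.discard_rate,
        "discharge_rate": config.discharge_rate,
        "return_rate": config.return_rate,
        "missing_blocks": [list(b) for b in config.missing_blocks],
        "initial_stock_weeks": config.initial_stock_weeks,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    agents = [AgentSpec(**a) for a in payload.pop("agents")]
    policies = {
        route: OrderPolicy(
            reorder_point=p["reorder_point"],
            order_sizes=tuple(p["order_sizes"]),
            order_weights=(
                tuple(p["order_weights"]) if p.get("order_weights") else None
            ),
        )
        for route, p in payload.pop("order_policy", {}).items()
    }
    blocks = [tuple(b) for b in payload.pop("missing_blocks", [])]
    return SimConfig(agents=agents, order_policy=policies,
                     missing_blocks=blocks, **payload)
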
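"""Weekly antibiotic consumption from two independent data sources.

Ward stock accounting infers what patients actually received from successive
shelf counts corrected for everything else that moves stock: deliveries from
the pharmacy, loans between wards, drugs sent home with discharged patients,
discards of expired stock, and returns to the pharmacy.  Pharmacy sales data
is the conventional surveillance proxy: DDDs sold to a ward net of returns.
The two disagree week to week because ward stock levels fluctuate; this
module computes both series, imputes missing count blocks, aggregates them
into registration intervals of 1-4 weeks, and pairs them for agreement
analysis.

Week indexing is 1-based (weeks 1..W).  Stock snapshots live on week
boundaries 0..W: boundary ``b`` is the count taken after the morning doses at
the start of week ``b+1`` (boundary 0 is the pre-study count, boundary W the
closing count).  Consumption in week ``w`` is balanced between boundaries
``w-1`` and ``w``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .ddd import DDDReferenceTable, packs_to_ddd
from .errors import (
    ConfigurationError,
    SequencingError,
    ValidationError,
)

FLOW_TYPES = (
    "delivery",
    "loan_in",
    "loan_out",
    "discharge_takeaway",
    "discard",
    "return_to_pharmacy",
)

#: sign of each flow type in the ward stock balance equation
FLOW_SIGN = {
    "delivery": +1,
    "loan_in": +1,
    "loan_out": -1,
    "discharge_takeaway": -1,
    "discard": -1,
    "return_to_pharmacy": -1,
}

#: stock-reducing flows that are not patient consumption
NON_CONSUMPTION_TYPES = ("discard", "discharge_takeaway", "loan_out")


@dataclass(frozen=True)
class StockSnapshot:
    """Pack-unit counts of every agent on one ward's shelf at one boundary."""

    ward_id: str
    week_index: int  # boundary index, 0..W
    counts: dict  # agent_id -> pack units

    def __post_init__(self) -> None:
        if self.week_index < 0:
            raise ValidationError("snapshot week_index must be >= 0")
        for agent_id, packs in self.counts.items():
            if packs < 0:
                raise ValidationError(
                    f"negative pack count {packs} for {agent_id!r}"
                )


@dataclass(frozen=True)
class FlowRecord:
    """A dated stock input/output event with a typed reason, in DDDs."""

    ward_id: str
    week_index: int  # 1-based consumption week the event falls in
    agent_id: str
    flow_type: str
    amount_ddd: float

    def __post_init__(self) -> None:
        if self.flow_type not in FLOW_TYPES:
            raise ValidationError(f"unknown flow_type {self.flow_type!r}")
        if not self.amount_ddd > 0:
            raise ValidationError(
                f"amount_ddd must be > 0, got {self.amount_ddd}"
            )


@dataclass(frozen=True)
class SalesRecord:
    """One pharmacy order line: DDDs sold to a ward in one order."""

    ward_id: str
    week_index: int
    agent_id: str
    ddd_ordered: float
    order_id: str = ""

    def __post_init__(self) -> None:
        if not self.ddd_ordered > 0:
            raise ValidationError(
                f"ddd_ordered must be > 0, got {self.ddd_ordered}"
            )


@dataclass
class ConsumptionSeries:
    """Weekly DDDs per ward x agent from one of the two methods.

    ``data`` is a tidy frame with columns ward_id, agent_id, week, ddd,
    imputed; after imputation every (ward, agent) holds a value for every
    week 1..n_weeks.  Pharmacy weeks may be negative when returns exceed
    orders; no floor is applied.
    """

    method: str  # "ward" | "pharmacy"
    data: pd.DataFrame
    n_weeks: int
    imputed_weeks: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.method not in ("ward", "pharmacy"):
            raise ValidationError(f"unknown method {self.method!r}")
        self.data = self.data.reset_index(drop=True)

    @property
    def wards(self) -> list[str]:
        return sorted(self.data["ward_id"].unique())

    @property
    def agents(self) -> list[str]:
        return sorted(self.data["agent_id"].unique())

    def total(self) -> float:
        return float(self.data["ddd"].sum())

    def cell(self, ward_id: str, agent_id: str, week: int) -> float:
        sel = self.data[
            (self.data["ward_id"] == ward_id)
            & (self.data["agent_id"] == agent_id)
            & (self.data["week"] == week)
        ]
        if len(sel) != 1:
            raise ValidationError(
                f"expected one cell for ({ward_id}, {agent_id}, {week}), "
                f"found {len(sel)}"
            )
        return float(sel["ddd"].iloc[0])

    def weekly_totals(self) -> pd.Series:
        return self.data.groupby("week")["ddd"].sum()

    def copy(self) -> "ConsumptionSeries":
        return ConsumptionSeries(
            method=self.method,
            data=self.data.copy(),
            n_weeks=self.n_weeks,
            imputed_weeks=set(self.imputed_weeks),
        )


def _snapshot_ddd(snapshot: StockSnapshot, agent_id: str,
                  ref: DDDReferenceTable) -> float:
    return packs_to_ddd(snapshot.counts.get(agent_id, 0.0), ref[agent_id])


def weekly_ward_consumption(
    prev: StockSnapshot,
    curr: StockSnapshot,
    flows: Sequence[FlowRecord],
    ref: DDDReferenceTable,
) -> dict[str, float]:
    """Balance one week of ward stock into per-agent consumption (DDDs).

    consumption = prev_count - curr_count + deliveries + loans_in
                  - loans_out - discharge_takeaways - discards - returns

    Returns to the pharmacy are stock-reducing non-consumption, netted like
    discards on the ward side.
    """
    if prev.ward_id != curr.ward_id:
        raise SequencingError(
            f"snapshots from different wards: {prev.ward_id!r} vs "
            f"{curr.ward_id!r}"
        )
    if prev.week_index + 1 != curr.week_index:
        raise SequencingError(
            f"snapshots not consecutive: boundaries {prev.week_index} and "
            f"{curr.week_index}"
        )
    agents = set(prev.counts) | set(curr.counts)
    consumption = {
        a: _snapshot_ddd(prev, a, ref) - _snapshot_ddd(curr, a, ref)
        for a in agents
    }
    for flow in flows:
        if flow.ward_id != prev.ward_id:
            raise ValidationError(
                f"flow for ward {flow.ward_id!r} passed to "
                f"{prev.ward_id!r} accounting"
            )
        if flow.week_index != curr.week_index:
            raise ValidationError(
                f"flow for week {flow.week_index} passed to week "
                f"{curr.week_index} accounting"
            )
        ref[flow.agent_id]  # raise on unknown agent
        consumption[flow.agent_id] = (
            consumption.get(flow.agent_id, 0.0)
            + FLOW_SIGN[flow.flow_type] * flow.amount_ddd
        )
    return consumption


def ward_consumption_series(
    snapshots: Sequence[StockSnapshot],
    flows: Sequence[FlowRecord],
    ref: DDDReferenceTable,
    n_weeks: int,
    agents: Sequence[str] | None = None,
) -> ConsumptionSeries:
    """Build the full ward consumption series from snapshots and flows.

    Snapshots may be missing at boundaries inside holiday blocks.  For a run
    of missing boundaries the balance equation is applied across the whole
    gap; the resulting block total is placed on the first week of the gap
    (remaining weeks 0) and is meant to be spread evenly afterwards by
    :func:`impute_missing_blocks`.
    """
    if agents is None:
        agents = ref.agent_ids
    by_ward: dict[str, dict[int, StockSnapshot]] = {}
    for snap in snapshots:
        by_ward.setdefault(snap.ward_id, {})[snap.week_index] = snap
    flow_index: dict[tuple, list[FlowRecord]] = {}
    for f in flows:
        flow_index.setdefault((f.ward_id, f.agent_id), []).append(f)

    rows = []
    for ward_id, snaps in sorted(by_ward.items()):
        boundaries = sorted(snaps)
        if 0 not in snaps or n_weeks not in snaps:
            raise SequencingError(
                f"ward {ward_id!r} lacks opening (0) or closing ({n_weeks}) "
                "snapshot"
            )
        for agent_id in agents:
            agent_flows = flow_index.get((ward_id, agent_id), [])
            for lo, hi in zip(boundaries[:-1], boundaries[1:]):
                # balance across the gap lo..hi (hi - lo weeks)
                total = (
                    _snapshot_ddd(snaps[lo], agent_id, ref)
                    - _snapshot_ddd(snaps[hi], agent_id, ref)
                )
                for f in agent_flows:
                    if lo < f.week_index <= hi:
                        total += FLOW_SIGN[f.flow_type] * f.amount_ddd
                rows.append(
                    {"ward_id": ward_id, "agent_id": agent_id,
                     "week": lo + 1, "ddd": total, "imputed": False}
                )
                for w in range(lo + 2, hi + 1):
                    rows.append(
                        {"ward_id": ward_id, "agent_id": agent_id,
                         "week": w, "ddd": 0.0, "imputed": False}
                    )
    data = pd.DataFrame(rows).sort_values(
        ["ward_id", "agent_id", "week"], ignore_index=True
    )
    return ConsumptionSeries(method="ward", data=data, n_weeks=n_weeks)


def weekly_pharmacy_consumption(
    sales: Sequence[SalesRecord],
    returns: Sequence[FlowRecord],
    wards: Sequence[str],
    agents: Sequence[str],
    n_weeks: int,
) -> ConsumptionSeries:
    """Pharmacy consumption series: orders minus returns per cell.

    Cells with no records are zero.  A week dominated by returns may be
    negative; it is kept as-is.
    """
    for rec in returns:
        if rec.flow_type != "return_to_pharmacy":
            raise ValidationError(
                f"returns must have flow_type return_to_pharmacy, got "
                f"{rec.flow_type!r}"
            )
    index = pd.MultiIndex.from_product(
        [sorted(wards), sorted(agents), range(1, n_weeks + 1)],
        names=["ward_id", "agent_id", "week"],
    )
    values = pd.Series(0.0, index=index)
    for s in sales:
        key = (s.ward_id, s.agent_id, s.week_index)
        if key not in values.index:
            raise ValidationError(f"sales record outside grid: {key}")
        values.loc[key] += s.ddd_ordered
    for r in returns:
        key = (r.ward_id, r.agent_id, r.week_index)
        if key not in values.index:
            raise ValidationError(f"return record outside grid: {key}")
        values.loc[key] -= r.amount_ddd
    data = values.rename("ddd").reset_index()
    data["imputed"] = False
    return ConsumptionSeries(method="pharmacy", data=data, n_weeks=n_weeks)


def impute_missing_blocks(
    series: ConsumptionSeries,
    blocks: Iterable[tuple[int, int]],
) -> ConsumptionSeries:
    """Replace each week inside a block by the block's weekly average.

    ``blocks`` are inclusive 1-based (start, end) week ranges.  The block
    total is the sum of the block's current weekly values — for a pharmacy
    series these are the recorded weekly sales, for a ward series the
    balance-equation block total placed by :func:`ward_consumption_series`.
    The series total over the study window is conserved exactly.
    """
    out = series.copy()
    for start, end in blocks:
        if start < 1 or end > series.n_weeks or start > end:
            raise ValidationError(
                f"block ({start}, {end}) outside study window "
                f"1..{series.n_weeks}"
            )
        length = end - start + 1
        in_block = out.data["week"].between(start, end)
        for (ward, agent), grp in out.data[in_block].groupby(
            ["ward_id", "agent_id"]
        ):
            avg = grp["ddd"].sum() / length
            out.data.loc[grp.index, "ddd"] = avg
        out.data.loc[in_block, "imputed"] = True
        out.imputed_weeks.update(range(start, end + 1))
    return out


def retained_weeks(n_weeks: int, omit_weeks: Iterable[int]) -> list[int]:
    omit = set(omit_weeks)
    for w in omit:
        if w < 1 or w > n_weeks:
            raise ValidationError(
                f"omitted week {w} outside study window 1..{n_weeks}"
            )
    return [w for w in range(1, n_weeks + 1) if w not in omit]


def aggregate_intervals(
    series: ConsumptionSeries,
    k: int,
    omit_weeks: Iterable[int] = (),
) -> pd.DataFrame:
    """Sum weekly DDDs into consecutive non-overlapping k-week intervals.

    Weeks in ``omit_weeks`` are dropped first; the remaining weeks, in
    order, are partitioned into blocks of k starting from the first retained
    week.  Returns a frame with columns ward_id, agent_id, interval, ddd.
    """
    if k not in (1, 2, 3, 4):
        raise ConfigurationError(f"interval length k must be 1..4, got {k}")
    weeks = retained_weeks(series.n_weeks, omit_weeks)
    if len(weeks) % k != 0:
        raise ConfigurationError(
            f"{len(weeks)} retained weeks not divisible by k={k} "
            f"(remainder {len(weeks) % k})"
        )
    interval_of = {w: i // k + 1 for i, w in enumerate(weeks)}
    data = series.data[series.data["week"].isin(interval_of)].copy()
    data["interval"] = data["week"].map(interval_of)
    out = (
        data.groupby(["ward_id", "agent_id", "interval"], as_index=False)[
            "ddd"
        ]
        .sum()
        .sort_values(["ward_id", "agent_id", "interval"], ignore_index=True)
    )
    return out


def build_paired_registrations(
    pharm: ConsumptionSeries,
    ward: ConsumptionSeries,
    k: int,
    omit_weeks: Iterable[int] = (),
    stratum: str = "all",
    ref: DDDReferenceTable | None = None,
) -> pd.DataFrame:
    """Pair pharmacy and ward interval totals per (ward, agent, interval).

    One dual registration per cell; cells where both methods are zero are
    retained.  ``stratum`` restricts agents by route ("all", "parenteral",
    "oral"; the route strata require ``ref``).  Returns columns ward_id,
    agent_id, interval, k, pharmacy_ddd, ward_ddd.
    """
    if pharm.method != "pharmacy" or ward.method != "ward":
        raise ValidationError("series passed in wrong order or mislabelled")
    if (pharm.n_weeks != ward.n_weeks
            or pharm.wards != ward.wards
            or pharm.agents != ward.agents):
        raise ValidationError(
            "pharmacy and ward series cover different wards/agents/windows"
        )
    if stratum not in ("all", "parenteral", "oral"):
        raise ValidationError(f"unknown stratum {stratum!r}")
    pa = aggregate_intervals(pharm, k, omit_weeks).rename(
        columns={"ddd": "pharmacy_ddd"}
    )
    wa = aggregate_intervals(ward, k, omit_weeks).rename(
        columns={"ddd": "ward_ddd"}
    )
    pairs = pa.merge(wa, on=["ward_id", "agent_id", "interval"], how="outer")
    if pairs[["pharmacy_ddd", "ward_ddd"]].isna().any().any():
        raise ValidationError("series shape mismatch after aggregation")
    if stratum != "all":
        if ref is None:
            raise ValidationError(
                "route stratum requires a DDD reference table"
            )
        keep = set(ref.agents_by_route(stratum))
        pairs = pairs[pairs["agent_id"].isin(keep)]
    pairs = pairs.reset_index(drop=True)
    pairs.insert(3, "k", k)
    return pairs


def percent_difference(pharmacy_ddd: float, ward_ddd: float) -> float:
    """Relative deviation of ward accounting from pharmacy sales, in percent.

    Direction is pharmacy - ward, relative to pharmacy.  Undefined (NaN)
    when pharmacy use is zero; reports print a dash for such cells.
    """
    if pharmacy_ddd == 0:
        return float("nan")
    return 100.0 * (pharmacy_ddd - ward_ddd) / pharmacy_ddd


def non_consumption_share(
    flows: Sequence[FlowRecord],
    total_ward_ddd: float,
) -> float:
    """Share of ward consumption lost to discards, discharge take-aways and
    loans out, in percent of total ward DDDs."""
    if not total_ward_ddd > 0:
        raise ValidationError(
            f"total_ward_ddd must be > 0, got {total_ward_ddd}"
        )
    lost = sum(
        f.amount_ddd for f in flows if f.flow_type in NON_CONSUMPTION_TYPES
    )
    return 100.0 * lost / total_ward_ddd
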
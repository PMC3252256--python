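"""CSV serialization for all record types.

All files are plain UTF-8 CSV with a header row; enumerations are lowercase
tokens; week indices are integers; amounts are decimal DDDs except stock
snapshots, which are pack units as counted on the shelf.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .accounting import (
    ConsumptionSeries,
    FlowRecord,
    SalesRecord,
    StockSnapshot,
)
from .errors import ValidationError


def write_snapshots(snapshots: Sequence[StockSnapshot], path) -> None:
    rows = [
        {"ward_id": s.ward_id, "week_index": s.week_index,
         "agent_id": agent_id, "packs": packs}
        for s in snapshots
        for agent_id, packs in sorted(s.counts.items())
    ]
    pd.DataFrame(
        rows, columns=["ward_id", "week_index", "agent_id", "packs"]
    ).to_csv(path, index=False)


def read_snapshots(path) -> list[StockSnapshot]:
    df = _read(path, {"ward_id", "week_index", "agent_id", "packs"})
    snapshots = []
    for (ward, boundary), grp in df.groupby(["ward_id", "week_index"]):
        snapshots.append(
            StockSnapshot(
                ward_id=str(ward), week_index=int(boundary),
                counts={
                    str(r.agent_id): float(r.packs)
                    for r in grp.itertuples(index=False)
                },
            )
        )
    snapshots.sort(key=lambda s: (s.ward_id, s.week_index))
    return snapshots


def write_flows(flows: Sequence[FlowRecord], path) -> None:
    pd.DataFrame(
        [
            {"ward_id": f.ward_id, "week_index": f.week_index,
             "agent_id": f.agent_id, "flow_type": f.flow_type,
             "amount_ddd": f.amount_ddd}
            for f in flows
        ],
        columns=["ward_id", "week_index", "agent_id", "flow_type",
                 "amount_ddd"],
    ).to_csv(path, index=False)


def read_flows(path) -> list[FlowRecord]:
    df = _read(path, {"ward_id", "week_index", "agent_id", "flow_type",
                      "amount_ddd"})
    return [
        FlowRecord(
            ward_id=str(r.ward_id), week_index=int(r.week_index),
            agent_id=str(r.agent_id), flow_type=str(r.flow_type),
            amount_ddd=float(r.amount_ddd),
        )
        for r in df.itertuples(index=False)
    ]


def write_sales(sales: Sequence[SalesRecord], path) -> None:
    pd.DataFrame(
        [
            {"ward_id": s.ward_id, "week_index": s.week_index,
             "agent_id": s.agent_id, "ddd_ordered": s.ddd_ordered,
             "order_id": s.order_id}
            for s in sales
        ],
        columns=["ward_id", "week_index", "agent_id", "ddd_ordered",
                 "order_id"],
    ).to_csv(path, index=False)


def read_sales(path) -> list[SalesRecord]:
    df = _read(path, {"ward_id", "week_index", "agent_id", "ddd_ordered",
                      "order_id"})
    return [
        SalesRecord(
            ward_id=str(r.ward_id), week_index=int(r.week_index),
            agent_id=str(r.agent_id), ddd_ordered=float(r.ddd_ordered),
            order_id="" if pd.isna(r.order_id) else str(r.order_id),
        )
        for r in df.itertuples(index=False)
    ]


def write_consumption(series: ConsumptionSeries, path) -> None:
    out = series.data.copy()
    out.insert(0, "method", series.method)
    out.to_csv(path, index=False)


def read_consumption(path) -> ConsumptionSeries:
    df = _read(path, {"method", "ward_id", "agent_id", "week", "ddd",
                      "imputed"})
    methods = df["method"].unique()
    if len(methods) != 1:
        raise ValidationError(
            f"consumption file mixes methods {sorted(methods)}"
        )
    data = df.drop(columns=["method"]).copy()
    data["week"] = data["week"].astype(int)
    data["ddd"] = data["ddd"].astype(float)
    data["imputed"] = data["imputed"].astype(bool)
    imputed_weeks = set(data.loc[data["imputed"], "week"].tolist())
    return ConsumptionSeries(
        method=str(methods[0]), data=data,
        n_weeks=int(data["week"].max()), imputed_weeks=imputed_weeks,
    )


def _read(path, required: set) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing columns {sorted(missing)}"
        )
    return df
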
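"""End-to-end pipeline driver and report tables.

Composes simulate -> account -> pair -> analyze and writes three report
tables — a consumption table (per ward x reporting class, both methods,
percent difference), a reliability table (ICC with CI per stratum x
registration interval) and an agreement table (Bland-Altman mean difference
and DDD use range per stratum x interval) — plus Bland-Altman plot data and
weekly totals for plotting.

Rounding to one decimal (half away from zero) happens only at CSV
serialization; the in-memory frames keep full precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .accounting import (
    ConsumptionSeries,
    build_paired_registrations,
    impute_missing_blocks,
    non_consumption_share,
    percent_difference,
    retained_weeks,
    ward_consumption_series,
    weekly_pharmacy_consumption,
)
from .agreement import (
    bland_altman,
    bland_altman_plot_data,
    icc,
    loa_to_use_range,
    reliability_verdict,
)
from .ddd import DDDReferenceTable
from .errors import ConfigurationError, ValidationError
from . import io as wio
from .simulate import SimConfig, SimOutput, simulate

logger = logging.getLogger("wardstock")

#: reporting class per ATC prefix (+ route for ciprofloxacin)
CLASS_RULES = (
    ("J01DC", None, "2nd generation cephalosporins"),
    ("J01DD", None, "3rd generation cephalosporins"),
    ("J01DH", None, "Carbapenems"),
    ("J01MA02", "parenteral", "Ciprofloxacin parenteral"),
    ("J01MA02", "oral", "Ciprofloxacin oral"),
)


def agent_class(atc_code: str, route: str) -> str:
    for prefix, rule_route, label in CLASS_RULES:
        if atc_code.startswith(prefix) and (
            rule_route is None or rule_route == route
        ):
            return label
    raise ConfigurationError(
        f"agent with ATC {atc_code!r} route {route!r} maps to no reporting "
        "class"
    )


def class_rollup(series: ConsumptionSeries,
                 ref: DDDReferenceTable) -> pd.DataFrame:
    """Total DDDs per ward x reporting class; class rows sum exactly to the
    all-agent total."""
    totals = series.data.groupby(["ward_id", "agent_id"], as_index=False)[
        "ddd"
    ].sum()
    totals["agent_class"] = [
        agent_class(ref[a].atc_code, ref[a].route)
        for a in totals["agent_id"]
    ]
    return (
        totals.groupby(["ward_id", "agent_class"], as_index=False)["ddd"]
        .sum()
        .sort_values(["ward_id", "agent_class"], ignore_index=True)
    )


def consumption_table(pharm: ConsumptionSeries, ward: ConsumptionSeries,
                      ref: DDDReferenceTable) -> pd.DataFrame:
    """Per-ward class breakdown with ward and grand total rows and the
    pharmacy-vs-ward percent difference."""
    p = class_rollup(pharm, ref).rename(columns={"ddd": "pharmacy_ddd"})
    w = class_rollup(ward, ref).rename(columns={"ddd": "ward_ddd"})
    table = p.merge(w, on=["ward_id", "agent_class"], how="outer").fillna(0.0)
    rows = []
    for ward_id, grp in table.groupby("ward_id"):
        rows.extend(grp.to_dict("records"))
        rows.append(
            {"ward_id": ward_id, "agent_class": "(ward total)",
             "pharmacy_ddd": grp["pharmacy_ddd"].sum(),
             "ward_ddd": grp["ward_ddd"].sum()}
        )
    rows.append(
        {"ward_id": "(all)", "agent_class": "(grand total)",
         "pharmacy_ddd": table["pharmacy_ddd"].sum(),
         "ward_ddd": table["ward_ddd"].sum()}
    )
    out = pd.DataFrame(rows)
    out["percent_difference"] = [
        percent_difference(r.pharmacy_ddd, r.ward_ddd)
        for r in out.itertuples(index=False)
    ]
    return out


def agreement_tables(
    pharm: ConsumptionSeries,
    ward: ConsumptionSeries,
    ref: DDDReferenceTable,
    ks=(1, 2, 3, 4),
    omit_weeks=(12, 26),
    strata=("all", "parenteral", "oral"),
    icc_variant: str = "consistency",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Reliability and agreement tables plus Bland-Altman plot data for
    every stratum x interval combination."""
    reliability_rows, agreement_rows, plot_frames = [], [], []
    n_wards = len(pharm.wards)
    for k in ks:
        # omit weeks only when needed to make the window divisible by k;
        # 1- and 2-week intervals use the full window
        omit = omit_weeks if (pharm.n_weeks % k) else ()
        for stratum in strata:
            pairs = build_paired_registrations(
                pharm, ward, k, omit, stratum=stratum, ref=ref
            )
            n_agents = pairs["agent_id"].nunique()
            icc_res = icc(pairs, variant=icc_variant)
            verdict, label = reliability_verdict(icc_res)
            reliability_rows.append(
                {"stratum": stratum, "k": k, "n": len(pairs),
                 "icc": icc_res.icc, "ci_low": icc_res.ci_low,
                 "ci_high": icc_res.ci_high,
                 "sigma_s2": icc_res.sigma_s2, "sigma_e2": icc_res.sigma_e2,
                 "sufficient": verdict, "label": label}
            )
            ba = bland_altman(pairs)
            strat_p = pairs["pharmacy_ddd"].sum()
            strat_w = pairs["ward_ddd"].sum()
            n_intervals = pairs["interval"].max()
            mean_use = ((strat_p + strat_w) / 2.0) / n_intervals
            use_range = loa_to_use_range(ba, n_wards * n_agents, mean_use) \
                if mean_use > 0 else None
            agreement_rows.append(
                {"stratum": stratum, "k": k, "n": len(pairs),
                 "mean_use": mean_use,
                 "range_low": use_range.range_low if use_range else np.nan,
                 "range_high": use_range.range_high if use_range else np.nan,
                 "percent_low": use_range.percent_low if use_range else np.nan,
                 "percent_high": (
                     use_range.percent_high if use_range else np.nan
                 ),
                 "mean_difference": ba.mean_difference,
                 "sd_difference": ba.sd_difference,
                 "loa_low": ba.loa_low, "loa_high": ba.loa_high}
            )
            plot = bland_altman_plot_data(pairs)
            plot.insert(0, "stratum", stratum)
            plot.insert(1, "k", k)
            plot["loa_low"] = ba.loa_low
            plot["loa_high"] = ba.loa_high
            plot_frames.append(plot)
    return (
        pd.DataFrame(reliability_rows),
        pd.DataFrame(agreement_rows),
        pd.concat(plot_frames, ignore_index=True),
    )


@dataclass
class RunManifest:
    """Provenance record naming the inputs and outputs of one run."""

    seed: int | None
    mode: str
    config_path: str | None
    package_version: str
    input_digests: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    timestamp: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used in the reports)."""
    if x != x:  # NaN
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _write_rounded(df: pd.DataFrame, path, percent_cols=()) -> None:
    out = df.copy()
    for col in percent_cols:
        out[col] = [
            "-" if v != v else f"{round_half_away(v, 1):.1f}"
            for v in out[col]
        ]
    out.to_csv(path, index=False)


def run_pipeline(
    mode: str = "simulate",
    config: SimConfig | None = None,
    input_paths: dict | None = None,
    ref: DDDReferenceTable | None = None,
    seed: int | None = None,
    ks=(1, 2, 3, 4),
    omit_weeks=(12, 26),
    strata=("all", "parenteral", "oral"),
    outdir="results",
    impute_blocks=None,
    config_path: str | None = None,
) -> dict:
    """Drive the full pipeline and write the report bundle under outdir.

    mode "simulate": generate data from ``config`` (seed optionally
    overridden).  mode "from_files": read the four CSV inputs named in
    ``input_paths`` (keys reference, snapshots, flows, sales).
    Returns the report frames plus the consumption series.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=seed, mode=mode, config_path=config_path,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )

    if mode == "simulate":
        if config is None:
            raise ValidationError("simulate mode requires a SimConfig")
        if seed is not None:
            config.seed = seed
        logger.info("simulating %d wards x %d agents x %d weeks (seed %s)",
                    len(config.wards), len(config.agents), config.weeks,
                    config.seed)
        sim = simulate(config)
        ref = config.reference_table()
        snapshots, flows, sales = sim.snapshots, sim.flows, sim.sales
        n_weeks = config.weeks
        if impute_blocks is None:
            impute_blocks = config.missing_blocks
    elif mode == "from_files":
        required = {"reference", "snapshots", "flows", "sales"}
        if input_paths is None or required - set(input_paths):
            raise ValidationError(
                f"from_files mode requires input paths {sorted(required)}"
            )
        ref = DDDReferenceTable.read_csv(input_paths["reference"])
        snapshots = wio.read_snapshots(input_paths["snapshots"])
        flows = wio.read_flows(input_paths["flows"])
        sales = wio.read_sales(input_paths["sales"])
        n_weeks = max(s.week_index for s in snapshots)
        for name, path in input_paths.items():
            manifest.input_digests[name] = _digest(path)
        if impute_blocks is None:
            impute_blocks = []
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    wards = sorted({s.ward_id for s in snapshots})
    logger.info("accounting: %d snapshots, %d flows, %d sales records",
                len(snapshots), len(flows), len(sales))
    ward_series = ward_consumption_series(snapshots, flows, ref, n_weeks)
    returns = [f for f in flows if f.flow_type == "return_to_pharmacy"]
    pharm_series = weekly_pharmacy_consumption(
        sales, returns, wards, ref.agent_ids, n_weeks
    )
    if impute_blocks:
        ward_series = impute_missing_blocks(ward_series, impute_blocks)
        pharm_series = impute_missing_blocks(pharm_series, impute_blocks)

    cons_table = consumption_table(pharm_series, ward_series, ref)
    reliability, agreement, ba_plot = agreement_tables(
        pharm_series, ward_series, ref, ks=ks, omit_weeks=omit_weeks,
        strata=strata,
    )
    weekly = pd.DataFrame(
        {"pharmacy_ddd": pharm_series.weekly_totals(),
         "ward_ddd": ward_series.weekly_totals()}
    ).reset_index()

    total_ward = ward_series.total()
    share = (
        non_consumption_share(flows, total_ward) if total_ward > 0 else None
    )

    outputs = {
        "consumption_ward.csv": lambda p: wio.write_consumption(ward_series, p),
        "consumption_pharmacy.csv": lambda p: wio.write_consumption(
            pharm_series, p
        ),
        "table_consumption.csv": lambda p: _write_rounded(
            cons_table, p, percent_cols=("percent_difference",)
        ),
        "table_reliability.csv": lambda p: reliability.to_csv(p, index=False),
        "table_agreement.csv": lambda p: agreement.to_csv(p, index=False),
        "bland_altman_points.csv": lambda p: ba_plot.to_csv(p, index=False),
        "weekly_totals.csv": lambda p: weekly.to_csv(p, index=False),
    }
    for name, writer in outputs.items():
        path = outdir / name
        writer(path)
        manifest.outputs.append(str(path))
    manifest.write(outdir / "manifest.json")
    logger.info("wrote %d report files to %s", len(outputs), outdir)

    return {
        "ward_series": ward_series,
        "pharmacy_series": pharm_series,
        "consumption_table": cons_table,
        "reliability_table": reliability,
        "agreement_table": agreement,
        "bland_altman_points": ba_plot,
        "weekly_totals": weekly,
        "non_consumption_share": share,
        "manifest": manifest,
    }
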
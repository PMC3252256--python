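"""WHO ATC/DDD unit conversion.

The defined daily dose (DDD) is WHO's assumed average maintenance dose per
day for a drug used for its main indication.  All consumption quantities in
this package are expressed in DDDs so that vials, infusion bags and tablets
of different strengths become comparable.  DDD assignments are configuration
data, not constants: they change between ATC index years, so the reference
table is loaded from an editable CSV rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .errors import UnknownAgentError, ValidationError

ROUTES = ("parenteral", "oral")


@dataclass(frozen=True)
class AgentSpec:
    """One antibiotic item: an ATC-coded agent in a single formulation.

    ``ddd_mg`` is milligrams per one DDD; ``pack_strength_mg`` is milligrams
    per physical pack unit (vial, infusion bag, or tablet).  Combination
    agents (imipenem/cilastatin) are a single item with DDD defined on the
    active-component strength.
    """

    agent_id: str
    atc_code: str
    name: str
    route: str
    ddd_mg: float
    pack_strength_mg: float
    is_bsa: bool = True

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValidationError(
                f"route must be one of {ROUTES}, got {self.route!r}"
            )
        if not self.ddd_mg > 0:
            raise ValidationError(f"ddd_mg must be > 0, got {self.ddd_mg}")
        if not self.pack_strength_mg > 0:
            raise ValidationError(
                f"pack_strength_mg must be > 0, got {self.pack_strength_mg}"
            )


@dataclass
class DDDReferenceTable:
    """Lookup table of :class:`AgentSpec` keyed by ``agent_id``.

    Lookup of a missing key raises :class:`UnknownAgentError`; it is never a
    silent zero.  ``(atc_code, route)`` must be unique across entries.
    """

    entries: dict[str, AgentSpec] = field(default_factory=dict)

    @classmethod
    def from_agents(cls, agents: Iterable[AgentSpec]) -> "DDDReferenceTable":
        table = cls()
        for agent in agents:
            table.add(agent)
        return table

    def add(self, agent: AgentSpec) -> None:
        if agent.agent_id in self.entries:
            raise ValidationError(f"duplicate agent_id {agent.agent_id!r}")
        key = (agent.atc_code, agent.route)
        for other in self.entries.values():
            if (other.atc_code, other.route) == key:
                raise ValidationError(
                    f"duplicate (atc_code, route) {key!r} for "
                    f"{agent.agent_id!r} and {other.agent_id!r}"
                )
        self.entries[agent.agent_id] = agent

    def __getitem__(self, agent_id: str) -> AgentSpec:
        try:
            return self.entries[agent_id]
        except KeyError:
            raise UnknownAgentError(
                f"agent_id {agent_id!r} not in DDD reference table"
            ) from None

    def __contains__(self, agent_id: str) -> bool:
        return agent_id in self.entries

    def __iter__(self) -> Iterator[AgentSpec]:
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def agent_ids(self) -> list[str]:
        return list(self.entries)

    def agents_by_route(self, route: str) -> list[str]:
        if route not in ROUTES:
            raise ValidationError(f"unknown route {route!r}")
        return [a.agent_id for a in self if a.route == route]

    @classmethod
    def read_csv(cls, path) -> "DDDReferenceTable":
        """Load a reference table from CSV with columns agent_id, atc_code,
        name, route, ddd_mg, pack_strength_mg, is_bsa."""
        df = pd.read_csv(path, dtype={"agent_id": str, "atc_code": str})
        required = {"agent_id", "atc_code", "name", "route", "ddd_mg",
                    "pack_strength_mg", "is_bsa"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"reference table missing columns {sorted(missing)}")
        agents = [
            AgentSpec(
                agent_id=row.agent_id,
                atc_code=row.atc_code,
                name=row.name,
                route=row.route,
                ddd_mg=float(row.ddd_mg),
                pack_strength_mg=float(row.pack_strength_mg),
                is_bsa=_parse_bool(row.is_bsa),
            )
            for row in df.itertuples(index=False)
        ]
        return cls.from_agents(agents)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            [
                {
                    "agent_id": a.agent_id,
                    "atc_code": a.atc_code,
                    "name": a.name,
                    "route": a.route,
                    "ddd_mg": a.ddd_mg,
                    "pack_strength_mg": a.pack_strength_mg,
                    "is_bsa": str(a.is_bsa).lower(),
                }
                for a in self
            ]
        )
        df.to_csv(path, index=False)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    token = str(value).strip().lower()
    if token in ("true", "1", "yes"):
        return True
    if token in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot parse boolean {value!r}")


def mg_to_ddd(amount_mg: float, agent: AgentSpec) -> float:
    """Convert a milligram amount to DDDs for one agent.

    Linear and exactly invertible: ``amount_mg / agent.ddd_mg``.
    """
    if amount_mg < 0:
        raise ValidationError(f"amount_mg must be >= 0, got {amount_mg}")
    return amount_mg / agent.ddd_mg


def packs_to_ddd(pack_count: float, agent: AgentSpec) -> float:
    """Convert a count of pack units (vials/bags/tablets) to DDDs.

    Fractional pack counts are permitted (partially used blister packs).
    """
    if pack_count < 0:
        raise ValidationError(f"pack_count must be >= 0, got {pack_count}")
    return pack_count * agent.pack_strength_mg / agent.ddd_mg


def ddd_per_100_bed_days(ddd_total: float, bed_days: float) -> float:
    """Standard drug-utilization rate: DDDs per 100 occupied bed-days."""
    if bed_days <= 0:
        raise ValidationError(f"bed_days must be > 0, got {bed_days}")
    return 100.0 * ddd_total / bed_days
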
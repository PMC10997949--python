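"""Analytic plug-flow hydraulic retention time (HRT) for every tap.

The HRT of a tap is the total time a water parcel spends between the SWSS
inlet tank and the tap, decomposed additively into

* ``tank_s``       — summed regulated residence times of every tank on the path,
* ``riser_s``      — pumped riser legs (tank -> next tank, last tank -> zone
  entry floor), each traversed at the tank's full downstream demand,
* ``downfeed_s``   — the down-feed from the zone entry floor to the tap's
  storey; the segment through floor *j* carries the cumulative demand of the
  zone's floors from the bottom of the zone up to *j*,
* ``horizontal_s`` — the on-floor horizontal line, flushed only by the tap
  floor's own demand.

Each term is segment volume divided by the steady flow through the segment;
per-storey standpipe volumes use each traversed storey's own geometry, so the
uniform-geometry case reduces to (number of storeys) * Vs / Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import pandas as pd

from .errors import (
    StagnantRiserError,
    StagnantSegmentError,
    StagnantTapError,
    TopologyValidationError,
    UnmodeledFloorError,
)
from .topology import (
    BuildingTopology,
    TankSpec,
    ZoneSpec,
    downstream_demand,
    riser_flow,
    validate_topology,
)


@dataclass(frozen=True)
class HRTComponents:
    """Additive breakdown of one tap's retention time, seconds."""

    tank_s: float
    riser_s: float
    downfeed_s: float
    horizontal_s: float

    @property
    def total_s(self) -> float:
        return self.tank_s + self.riser_s + self.downfeed_s + self.horizontal_s

    @property
    def total_h(self) -> float:
        return self.total_s / 3600.0


@dataclass(frozen=True)
class HRTRow:
    floor: int
    zone_id: str
    components: HRTComponents | None
    status: str  # "ok" or "stagnant"


@dataclass(frozen=True)
class HRTProfile:
    """Per-floor retention times for one building."""

    building: str
    rows: tuple[HRTRow, ...]

    def __iter__(self) -> Iterator[HRTRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def hrt_by_floor(self) -> dict[int, float]:
        """Mapping floor -> HRT in seconds, defined rows only."""
        return {
            r.floor: r.components.total_s
            for r in self.rows
            if r.components is not None
        }

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; undefined retention times are left empty (NaN) and
        flagged in ``status``."""
        records = []
        for r in self.rows:
            c = r.components
            records.append(
                {
                    "floor": r.floor,
                    "zone": r.zone_id,
                    "tank_s": c.tank_s if c else math.nan,
                    "riser_s": c.riser_s if c else math.nan,
                    "downfeed_s": c.downfeed_s if c else math.nan,
                    "horizontal_s": c.horizontal_s if c else math.nan,
                    "hrt_s": c.total_s if c else math.nan,
                    "hrt_h": c.total_h if c else math.nan,
                    "status": r.status,
                }
            )
        return pd.DataFrame.from_records(records)


def riser_travel_time(
    topology: BuildingTopology, tank: TankSpec, entry_floor: int
) -> float:
    """Travel time (s) up the riser from *tank* to *entry_floor*.

    The leg's volume is the sum of the traversed storeys' standpipe volumes
    (storeys ``tank.floor_index + 1 .. entry_floor``); the leg carries the
    total demand of every floor ultimately fed from the tank.
    """
    flow = riser_flow(topology, tank)
    if flow <= 0:
        raise StagnantRiserError(
            f"riser from tank {tank.id} carries zero total demand"
        )
    volume = sum(
        topology.standpipe_volume_at(j)
        for j in range(tank.floor_index + 1, entry_floor + 1)
    )
    return volume / flow


def downfeed_travel_time(
    topology: BuildingTopology, zone: ZoneSpec, floor_k: int
) -> float:
    """Travel time (s) from the zone entry floor down to floor *k*.

    Sums, over storeys j from *k* to the zone's top served floor, the storey's
    standpipe volume divided by the cumulative demand of zone floors up to j.
    If the entry floor sits above the top served floor, the extra storeys are
    traversed at the zone's full demand.
    """
    lo, hi = zone.served_floors
    q_k = downstream_demand(topology, zone, floor_k)  # raises OutOfZoneError
    t = 0.0
    if zone.entry_floor > hi:
        q_total = downstream_demand(topology, zone, hi)
        if q_total <= 0:
            raise StagnantSegmentError(hi)
        vol = sum(
            topology.standpipe_volume_at(j)
            for j in range(hi + 1, zone.entry_floor + 1)
        )
        t += vol / q_total
    for j in range(floor_k, hi + 1):
        q_j = downstream_demand(topology, zone, j)
        if q_j <= 0:
            raise StagnantSegmentError(j)
        t += topology.standpipe_volume_at(j) / q_j
    return t


def tap_hrt(topology: BuildingTopology, floor_k: int) -> HRTComponents:
    """Retention time with component breakdown for the tap on floor *k*.

    Raises :class:`UnmodeledFloorError` for mains-direct or unserved floors
    and a :class:`~swss_hrt.errors.StagnantFlowError` subclass when any
    traversed segment (or the tap itself) carries zero flow.
    """
    floor = topology.floor(floor_k)
    if floor is None:
        raise UnmodeledFloorError(f"floor {floor_k} is not in the topology")
    if floor.supply_label == "mains-direct":
        raise UnmodeledFloorError(
            f"floor {floor_k} is mains-direct; mains water age is not modelled"
        )
    zone = topology.zone_of(floor_k)
    if zone is None:
        raise UnmodeledFloorError(f"floor {floor_k} is not served by any zone")

    chain = [topology.tank(tid) for tid in zone.upstream_tanks]
    tank_s = sum(t.hrt for t in chain)

    riser_s = 0.0
    for pos, tank in enumerate(chain):
        leg_end = (
            chain[pos + 1].floor_index if pos + 1 < len(chain) else zone.entry_floor
        )
        riser_s += riser_travel_time(topology, tank, leg_end)

    downfeed_s = downfeed_travel_time(topology, zone, floor_k)

    if floor.demand <= 0:
        raise StagnantTapError(f"tap on floor {floor_k} has zero demand")
    horizontal_s = floor.horizontal_volume / floor.demand

    return HRTComponents(tank_s, riser_s, downfeed_s, horizontal_s)


def hrt_profile(topology: BuildingTopology) -> HRTProfile:
    """Compute the full per-floor profile (one row per served floor).

    Stagnant floors are kept as rows with an undefined marker rather than an
    infinite HRT, so downstream statistics can drop them deterministically.
    """
    violations = validate_topology(topology)
    if violations:
        raise TopologyValidationError(violations)
    rows = []
    for zone in topology.zones:
        for k in zone.floor_indices:
            try:
                comps = tap_hrt(topology, k)
                rows.append(HRTRow(k, zone.id, comps, "ok"))
            except (StagnantRiserError, StagnantSegmentError, StagnantTapError):
                rows.append(HRTRow(k, zone.id, None, "stagnant"))
    rows.sort(key=lambda r: r.floor)
    return HRTProfile(building=topology.name, rows=tuple(rows))
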
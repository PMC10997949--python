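"""Data model for a high-rise secondary water supply system (SWSS).

A building is described by its floors (pipe geometry and demand), its storage
tanks (with operator-regulated residence times), and its supply zones.  Water
enters an inlet tank (typically in the basement), is pumped up a riser to a
mechanical floor, and either gravity-feeds the zone below ("SWSS-first") or is
stored in a second tank and pumped further up to feed the zone above
("SWSS-second").  The model assumes steady plug flow: every pipe segment
carries the summed average demand of the taps downstream of it, and a water
parcel traverses it in time volume / flow.

Floors below ground carry negative indices, so the storey count of a riser leg
is simply ``upper_floor - lower_floor``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

from .errors import (
    DanglingTankError,
    InvalidDemandError,
    InvalidGeometryError,
    OutOfZoneError,
)

#: Seconds in the 30-day month used to convert monthly consumption to a rate.
SECONDS_PER_MONTH = 30 * 24 * 3600  # 2_592_000

SUPPLY_LABELS = ("mains-direct", "swss-first", "swss-second")


def segment_volume(diameter: float, length: float) -> float:
    """Internal volume of a cylindrical pipe segment, m^3.

    Parameters
    ----------
    diameter : float
        Internal pipe diameter in metres; must be positive.
    length : float
        Segment length in metres; must be non-negative.
    """
    if diameter <= 0:
        raise InvalidGeometryError(f"diameter must be > 0, got {diameter}")
    if length < 0:
        raise InvalidGeometryError(f"length must be >= 0, got {length}")
    return 0.25 * math.pi * diameter * diameter * length


def demand_from_monthly(tonnes_per_month: float) -> float:
    """Convert a monthly consumption (t/month, 1 t = 1 m^3) to m^3/s.

    Uses a 30-day month (:data:`SECONDS_PER_MONTH` seconds).
    """
    if tonnes_per_month < 0:
        raise InvalidDemandError(
            f"monthly demand must be >= 0, got {tonnes_per_month}"
        )
    return tonnes_per_month / SECONDS_PER_MONTH


@dataclass(frozen=True)
class FloorSpec:
    """One storey: geometry of its standpipe rise and horizontal line, and its
    average tap demand.

    ``demand`` is the average water-consumption rate at the floor's taps in
    m^3/s (convert monthly tonnage with :func:`demand_from_monthly`).
    ``height`` is the per-storey standpipe rise.
    """

    index: int
    demand: float
    height: float = 3.0
    standpipe_diameter: float = 0.05
    horizontal_diameter: float = 0.025
    horizontal_length: float = 10.0
    supply_label: str = "swss-first"

    def __post_init__(self):
        if self.height <= 0:
            raise InvalidGeometryError(f"floor {self.index}: height must be > 0")
        if self.standpipe_diameter <= 0 or self.horizontal_diameter <= 0:
            raise InvalidGeometryError(f"floor {self.index}: diameters must be > 0")
        if self.horizontal_length < 0:
            raise InvalidGeometryError(
                f"floor {self.index}: horizontal_length must be >= 0"
            )
        if self.demand < 0:
            raise InvalidDemandError(f"floor {self.index}: demand must be >= 0")
        if self.supply_label not in SUPPLY_LABELS:
            raise ValueError(
                f"floor {self.index}: supply_label must be one of {SUPPLY_LABELS}"
            )

    @property
    def standpipe_volume(self) -> float:
        """Single-pass standpipe volume for this storey, m^3."""
        return segment_volume(self.standpipe_diameter, self.height)

    @property
    def horizontal_volume(self) -> float:
        """Horizontal supply-line volume on this floor, m^3."""
        return segment_volume(self.horizontal_diameter, self.horizontal_length)


@dataclass(frozen=True)
class TankSpec:
    """A storage tank with its regulated residence time (seconds)."""

    id: str
    floor_index: int
    hrt: float = 0.0

    def __post_init__(self):
        if self.hrt < 0:
            raise InvalidDemandError(f"tank {self.id}: hrt must be >= 0")


@dataclass(frozen=True)
class ZoneSpec:
    """A supply zone: a contiguous run of floors fed through a chain of tanks.

    ``served_floors`` is the inclusive ``(low, high)`` floor range.
    ``entry_floor`` is where water enters the zone's down-feed (the mechanical
    floor for a gravity zone, the top floor for a pumped zone).
    ``upstream_tanks`` lists tank ids from the network inlet to this zone; the
    last entry is ``source_tank``.
    """

    id: str
    source_tank: str
    entry_floor: int
    served_floors: tuple[int, int]
    upstream_tanks: tuple[str, ...]

    def __post_init__(self):
        lo, hi = self.served_floors
        if lo > hi:
            raise ValueError(f"zone {self.id}: empty served_floors range")
        object.__setattr__(self, "served_floors", (int(lo), int(hi)))
        object.__setattr__(self, "upstream_tanks", tuple(self.upstream_tanks))

    @property
    def floor_indices(self) -> range:
        lo, hi = self.served_floors
        return range(lo, hi + 1)

    def serves(self, floor_index: int) -> bool:
        lo, hi = self.served_floors
        return lo <= floor_index <= hi


@dataclass(frozen=True)
class BuildingTopology:
    """Floors, tanks, and zones of one high-rise SWSS.

    Storeys traversed by a riser but not listed in ``floors`` (basements,
    mains-direct lobbies) fall back to ``default_storey_height`` and
    ``default_standpipe_diameter`` for their standpipe geometry.
    """

    name: str
    floors: tuple[FloorSpec, ...]
    tanks: tuple[TankSpec, ...]
    zones: tuple[ZoneSpec, ...]
    functional_area: str = "office"
    pipe_material: str = "GPLS"
    default_storey_height: float = 3.0
    default_standpipe_diameter: float = 0.05

    def __post_init__(self):
        object.__setattr__(self, "floors", tuple(self.floors))
        object.__setattr__(self, "tanks", tuple(self.tanks))
        object.__setattr__(self, "zones", tuple(self.zones))

    # -- lookups ---------------------------------------------------------

    def floor(self, index: int) -> FloorSpec | None:
        for f in self.floors:
            if f.index == index:
                return f
        return None

    def tank(self, tank_id: str) -> TankSpec | None:
        for t in self.tanks:
            if t.id == tank_id:
                return t
        return None

    def zone(self, zone_id: str) -> ZoneSpec | None:
        for z in self.zones:
            if z.id == zone_id:
                return z
        return None

    def zone_of(self, floor_index: int) -> ZoneSpec | None:
        for z in self.zones:
            if z.serves(floor_index):
                return z
        return None

    def served_floor_indices(self) -> list[int]:
        """All floor indices served by some zone, ascending."""
        out: set[int] = set()
        for z in self.zones:
            out.update(z.floor_indices)
        return sorted(out)

    def standpipe_volume_at(self, storey: int) -> float:
        """Per-storey standpipe volume, using the storey's own geometry if the
        floor is listed and the building defaults otherwise."""
        f = self.floor(storey)
        if f is not None:
            return f.standpipe_volume
        return segment_volume(self.default_standpipe_diameter, self.default_storey_height)

    def with_demands(self, demands: dict[int, float]) -> "BuildingTopology":
        """Return a copy with the given per-floor demands (m^3/s) substituted."""
        new_floors = tuple(
            replace(f, demand=demands[f.index]) if f.index in demands else f
            for f in self.floors
        )
        return replace(self, floors=new_floors)


def downstream_demand(topology: BuildingTopology, zone: ZoneSpec, floor_j: int) -> float:
    """Cumulative demand (m^3/s) carried by the zone's down-pipe at floor j.

    Water flowing down past floor ``floor_j`` serves every zone floor from the
    bottom of the zone up to ``floor_j``, so the segment carries their summed
    demand.
    """
    if not zone.serves(floor_j):
        raise OutOfZoneError(
            f"floor {floor_j} is not served by zone {zone.id} "
            f"(range {zone.served_floors})"
        )
    lo, _ = zone.served_floors
    total = 0.0
    for i in range(lo, floor_j + 1):
        f = topology.floor(i)
        if f is not None:
            total += f.demand
    return total


def _floors_fed_by_tank(topology: BuildingTopology, tank: TankSpec) -> list[int]:
    """Floor indices of every zone whose upstream chain passes through *tank*."""
    fed: set[int] = set()
    for z in topology.zones:
        if tank.id in z.upstream_tanks:
            fed.update(z.floor_indices)
    return sorted(fed)


def riser_flow(topology: BuildingTopology, tank: TankSpec) -> float:
    """Total demand (m^3/s) of every floor ultimately fed from *tank*,
    including floors reached through downstream tanks."""
    fed = _floors_fed_by_tank(topology, tank)
    if not fed:
        raise DanglingTankError(f"tank {tank.id} feeds no zone")
    total = 0.0
    for i in fed:
        f = topology.floor(i)
        if f is not None:
            total += f.demand
    return total


def validate_topology(topology: BuildingTopology) -> list[str]:
    """Check cross-references and structural invariants.

    Returns a list of human-readable violations; an empty list means the
    topology is valid.  Nothing is raised here — callers that need an
    exception wrap the result in :class:`TopologyValidationError`.
    """
    violations: list[str] = []

    indices = [f.index for f in topology.floors]
    for idx in sorted({i for i in indices if indices.count(i) > 1}):
        violations.append(f"duplicate floor index {idx}")
    tank_ids = [t.id for t in topology.tanks]
    for tid in sorted({t for t in tank_ids if tank_ids.count(t) > 1}):
        violations.append(f"duplicate tank id {tid!r}")
    zone_ids = [z.id for z in topology.zones]
    for zid in sorted({z for z in zone_ids if zone_ids.count(z) > 1}):
        violations.append(f"duplicate zone id {zid!r}")

    # zone membership: each served floor in exactly one zone, mains-direct in none
    membership: dict[int, list[str]] = {}
    for z in topology.zones:
        for i in z.floor_indices:
            membership.setdefault(i, []).append(z.id)
    for i, zs in sorted(membership.items()):
        if len(zs) > 1:
            violations.append(f"floor {i} belongs to {len(zs)} zones: {zs}")
        f = topology.floor(i)
        if f is None:
            violations.append(f"zone {zs[0]} serves floor {i} which has no FloorSpec")
        elif f.supply_label == "mains-direct":
            violations.append(
                f"floor {i} is mains-direct but assigned to zone {zs[0]}"
            )
    for f in topology.floors:
        if f.supply_label != "mains-direct" and f.index not in membership:
            violations.append(
                f"floor {f.index} is labelled {f.supply_label!r} but no zone serves it"
            )

    # tank chains
    inlets = set()
    for z in topology.zones:
        if not z.upstream_tanks:
            violations.append(f"zone {z.id} has an empty upstream tank chain")
            continue
        for tid in z.upstream_tanks:
            if topology.tank(tid) is None:
                violations.append(f"zone {z.id} references missing tank id {tid!r}")
        if z.upstream_tanks[-1] != z.source_tank:
            violations.append(
                f"zone {z.id}: source_tank {z.source_tank!r} is not the last "
                f"upstream tank ({z.upstream_tanks[-1]!r})"
            )
        inlets.add(z.upstream_tanks[0])
        chain = [topology.tank(tid) for tid in z.upstream_tanks]
        if all(t is not None for t in chain):
            floors_on_chain = [t.floor_index for t in chain]
            if floors_on_chain != sorted(floors_on_chain):
                violations.append(
                    f"zone {z.id}: tank chain floors {floors_on_chain} not ascending"
                )
            _, hi = z.served_floors
            if z.entry_floor < hi:
                violations.append(
                    f"zone {z.id}: entry_floor {z.entry_floor} below top served "
                    f"floor {hi}"
                )
            if chain[-1].floor_index > z.entry_floor:
                violations.append(
                    f"zone {z.id}: source tank sits above the entry floor"
                )
    if len(inlets) > 1:
        violations.append(
            f"zones disagree on the inlet tank: {sorted(inlets)}"
        )

    for t in topology.tanks:
        if not _floors_fed_by_tank(topology, t):
            violations.append(f"tank {t.id} feeds no zone (dangling)")

    return violations


def total_served_demand(topology: BuildingTopology) -> float:
    """Summed demand of every served floor, m^3/s."""
    return sum(
        topology.floor(i).demand
        for i in topology.served_floor_indices()
        if topology.floor(i) is not None
    )
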
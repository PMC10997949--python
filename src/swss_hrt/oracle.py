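"""Independent plug-flow parcel-tracking verification of the analytic HRT.

This module never calls the analytic travel-time formulas.  It builds the
explicit chain of physical elements a water parcel passes through — tank
dwells and pipe segments, each with its own length, cross-section area, and
steady flow — and then tracks the parcel:

* event-based: each pipe segment takes exactly volume / flow; the result must
  match the analytic HRT to floating-point accuracy.
* time-stepped: the parcel advances at velocity flow / area in fixed steps of
  ``dt`` seconds; first-order accurate (error O(dt) from segment-boundary
  overshoot), useful as a sanity check that the event times are physical.

Segment flows are recomputed here by brute-force enumeration of the tap set
downstream of each segment, not by the closed-form cumulative sums the
analytic engine uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import StagnantRiserError, StagnantSegmentError, StagnantTapError, UnmodeledFloorError
from .topology import BuildingTopology, ZoneSpec


@dataclass(frozen=True)
class _Dwell:
    seconds: float


@dataclass(frozen=True)
class _Pipe:
    length: float  # m
    area: float    # m^2
    flow: float    # m^3/s

    @property
    def volume(self) -> float:
        return self.length * self.area

    @property
    def velocity(self) -> float:
        return self.flow / self.area


def _pipe_area(topology: BuildingTopology, storey: int) -> tuple[float, float]:
    """(length, area) of the standpipe segment through *storey*."""
    f = topology.floor(storey)
    if f is not None:
        d, h = f.standpipe_diameter, f.height
    else:
        d, h = topology.default_standpipe_diameter, topology.default_storey_height
    return h, 0.25 * math.pi * d * d


def _taps_below_tank(topology: BuildingTopology, tank_id: str) -> set[int]:
    """Every tap floor whose supply path passes through *tank_id*."""
    taps: set[int] = set()
    for z in topology.zones:
        if tank_id in z.upstream_tanks:
            taps.update(z.floor_indices)
    return taps


def _demand_of(topology: BuildingTopology, taps: set[int]) -> float:
    return sum(
        f.demand for f in topology.floors if f.index in taps
    )


def build_path(topology: BuildingTopology, floor_k: int) -> list[_Dwell | _Pipe]:
    """Explicit element chain from the inlet tank to the tap on floor *k*."""
    floor = topology.floor(floor_k)
    if floor is None or floor.supply_label == "mains-direct":
        raise UnmodeledFloorError(f"floor {floor_k} is outside the SWSS model")
    zone = topology.zone_of(floor_k)
    if zone is None:
        raise UnmodeledFloorError(f"floor {floor_k} is not served by any zone")

    elements: list[_Dwell | _Pipe] = []
    chain = [topology.tank(tid) for tid in zone.upstream_tanks]

    # tanks and pumped riser legs
    for pos, tank in enumerate(chain):
        elements.append(_Dwell(tank.hrt))
        leg_end = (
            chain[pos + 1].floor_index if pos + 1 < len(chain) else zone.entry_floor
        )
        flow = _demand_of(topology, _taps_below_tank(topology, tank.id))
        if flow <= 0:
            raise StagnantRiserError(f"riser from tank {tank.id} is stagnant")
        for storey in range(tank.floor_index + 1, leg_end + 1):
            length, area = _pipe_area(topology, storey)
            elements.append(_Pipe(length, area, flow))

    # gravity/pumped down-feed from the entry floor to the tap's storey
    lo, hi = zone.served_floors
    for storey in range(zone.entry_floor, floor_k - 1, -1):
        # taps fed through this down-feed segment: zone floors at or below it
        taps = {i for i in zone.floor_indices if i <= storey}
        flow = _demand_of(topology, taps)
        if flow <= 0:
            raise StagnantSegmentError(storey)
        length, area = _pipe_area(topology, storey)
        elements.append(_Pipe(length, area, flow))

    # on-floor horizontal line, flushed by the tap floor alone
    if floor.demand <= 0:
        raise StagnantTapError(f"tap on floor {floor_k} has zero demand")
    h_area = 0.25 * math.pi * floor.horizontal_diameter ** 2
    elements.append(_Pipe(floor.horizontal_length, h_area, floor.demand))
    return elements


def simulate_parcel_oracle(
    topology: BuildingTopology, floor_k: int, dt: float | None = None
) -> float:
    """Elapsed time (s) for a parcel from the inlet tank to the tap on
    floor *k*.

    With ``dt=None`` (default) the simulation is event-based: each pipe
    segment contributes exactly volume / flow.  With ``dt > 0`` the parcel is
    advanced in fixed time steps at the local plug-flow velocity; the answer
    is then accurate to O(dt).
    """
    elements = build_path(topology, floor_k)
    if dt is None:
        t = 0.0
        for el in elements:
            t += el.seconds if isinstance(el, _Dwell) else el.volume / el.flow
        return t
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = 0.0
    pipes = []
    for el in elements:
        if isinstance(el, _Dwell):
            t += el.seconds
        else:
            pipes.append(el)
    # track position along the concatenated pipe run, one whole dt per step
    bounds = []
    pos_end = 0.0
    for p in pipes:
        pos_end += p.length
        bounds.append(pos_end)
    pos = 0.0
    seg = 0
    while pos < pos_end:
        while seg < len(pipes) - 1 and pos >= bounds[seg]:
            seg += 1
        pos += pipes[seg].velocity * dt
        t += dt
    return t
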
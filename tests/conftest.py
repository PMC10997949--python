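import math

import pytest

from swss_hrt import (
    BuildingTopology,
    FloorSpec,
    TankSpec,
    ZoneSpec,
    office_topology,
    residential_topology,
)


def diameter_for_volume(volume: float, height: float = 1.0) -> float:
    """Standpipe diameter giving the requested per-storey volume."""
    return math.sqrt(4.0 * volume / (math.pi * height))


def single_zone_building(
    demands: dict[int, float],
    vs: float = 2e-6,
    vh: float = 0.0,
    tank_hrt: float = 0.0,
    tank_floor: int | None = None,
    entry_floor: int | None = None,
) -> BuildingTopology:
    """Minimal one-tank, one-zone building with uniform per-storey standpipe
    volume ``vs`` and horizontal volume ``vh`` on every floor."""
    lo, hi = min(demands), max(demands)
    entry = hi if entry_floor is None else entry_floor
    tfloor = lo - 1 if tank_floor is None else tank_floor
    ds = diameter_for_volume(vs)
    if vh > 0:
        dh, hl = 0.02, vh / (0.25 * math.pi * 0.02**2)
    else:
        dh, hl = 0.02, 0.0
    floors = tuple(
        FloorSpec(index=i, demand=q, height=1.0, standpipe_diameter=ds,
                  horizontal_diameter=dh, horizontal_length=hl)
        for i, q in sorted(demands.items())
    )
    return BuildingTopology(
        name="toy",
        floors=floors,
        tanks=(TankSpec("T1", tfloor, tank_hrt),),
        zones=(ZoneSpec("z", "T1", entry_floor=entry,
                        served_floors=(lo, hi), upstream_tanks=("T1",)),),
        default_storey_height=1.0,
        default_standpipe_diameter=ds,
    )


@pytest.fixture
def office():
    return office_topology()


@pytest.fixture
def residential():
    return residential_topology()
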
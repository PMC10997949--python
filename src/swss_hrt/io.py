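"""Read and write building-topology configurations (YAML or JSON).

Schema (keys under the top-level ``building`` mapping)::

    building:
      name: str
      functional_area: office | residence
      pipe_material: str                  # e.g. GPLS, polypropylene
      default_storey_height: m           # optional
      default_standpipe_diameter: m      # optional
      floors:                            # list
        - index: int                     # storey number, negative = basement
          demand_m3_s: float             # exactly one of demand_m3_s /
          monthly_demand_t: float        #   monthly_demand_t must be present
          height: m
          standpipe_diameter: m
          horizontal_diameter: m
          horizontal_length: m
          supply_label: mains-direct | swss-first | swss-second
      tanks:
        - {id: str, floor_index: int, hrt_s: float}
      zones:
        - id: str
          source_tank: str
          entry_floor: int
          served_floors: [low, high]     # inclusive
          upstream_tanks: [id, ...]      # inlet first

JSON files parse through the same reader (JSON is a YAML subset).
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError
from .topology import (
    BuildingTopology,
    FloorSpec,
    TankSpec,
    ZoneSpec,
    demand_from_monthly,
)

_FLOOR_GEOM_KEYS = (
    "height",
    "standpipe_diameter",
    "horizontal_diameter",
    "horizontal_length",
    "supply_label",
)


def _floor_from_dict(d: dict[str, Any]) -> FloorSpec:
    if "index" not in d:
        raise ConfigError(f"floor entry missing 'index': {d}")
    has_rate = "demand_m3_s" in d
    has_monthly = "monthly_demand_t" in d
    if has_rate == has_monthly:
        raise ConfigError(
            f"floor {d['index']}: exactly one of demand_m3_s / monthly_demand_t "
            "must be given"
        )
    demand = (
        float(d["demand_m3_s"])
        if has_rate
        else demand_from_monthly(float(d["monthly_demand_t"]))
    )
    kwargs = {k: d[k] for k in _FLOOR_GEOM_KEYS if k in d}
    return FloorSpec(index=int(d["index"]), demand=demand, **kwargs)


def topology_from_dict(doc: dict[str, Any]) -> BuildingTopology:
    """Build a :class:`BuildingTopology` from a parsed config mapping."""
    try:
        b = doc["building"]
    except (KeyError, TypeError):
        raise ConfigError("config must contain a top-level 'building' mapping")
    for key in ("name", "floors", "tanks", "zones"):
        if key not in b:
            raise ConfigError(f"building config missing {key!r}")
    try:
        floors = tuple(_floor_from_dict(f) for f in b["floors"])
        tanks = tuple(
            TankSpec(id=str(t["id"]), floor_index=int(t["floor_index"]),
                     hrt=float(t.get("hrt_s", 0.0)))
            for t in b["tanks"]
        )
        zones = tuple(
            ZoneSpec(
                id=str(z["id"]),
                source_tank=str(z["source_tank"]),
                entry_floor=int(z["entry_floor"]),
                served_floors=(int(z["served_floors"][0]), int(z["served_floors"][1])),
                upstream_tanks=tuple(str(t) for t in z["upstream_tanks"]),
            )
            for z in b["zones"]
        )
    except (KeyError, TypeError, ValueError, IndexError) as exc:
        raise ConfigError(f"malformed building config: {exc}") from exc
    extra = {}
    for key in (
        "functional_area",
        "pipe_material",
        "default_storey_height",
        "default_standpipe_diameter",
    ):
        if key in b:
            extra[key] = b[key]
    return BuildingTopology(
        name=str(b["name"]), floors=floors, tanks=tanks, zones=zones, **extra
    )


def topology_to_dict(topology: BuildingTopology) -> dict[str, Any]:
    """Inverse of :func:`topology_from_dict`; demands emitted in m^3/s."""
    return {
        "building": {
            "name": topology.name,
            "functional_area": topology.functional_area,
            "pipe_material": topology.pipe_material,
            "default_storey_height": topology.default_storey_height,
            "default_standpipe_diameter": topology.default_standpipe_diameter,
            "floors": [
                {
                    "index": f.index,
                    "demand_m3_s": f.demand,
                    "height": f.height,
                    "standpipe_diameter": f.standpipe_diameter,
                    "horizontal_diameter": f.horizontal_diameter,
                    "horizontal_length": f.horizontal_length,
                    "supply_label": f.supply_label,
                }
                for f in topology.floors
            ],
            "tanks": [
                {"id": t.id, "floor_index": t.floor_index, "hrt_s": t.hrt}
                for t in topology.tanks
            ],
            "zones": [
                {
                    "id": z.id,
                    "source_tank": z.source_tank,
                    "entry_floor": z.entry_floor,
                    "served_floors": list(z.served_floors),
                    "upstream_tanks": list(z.upstream_tanks),
                }
                for z in topology.zones
            ],
        }
    }


def load_topology(path: str | Path) -> BuildingTopology:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return topology_from_dict(doc)


def save_topology(topology: BuildingTopology, path: str | Path) -> None:
    atomic_write_text(
        path, yaml.safe_dump(topology_to_dict(topology), sort_keys=False)
    )


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write *text* to *path* via a temp file + rename, so failures never
    leave a partial output behind."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
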
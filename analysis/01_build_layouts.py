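#!/usr/bin/env python
"""Write the two study building layouts as editable configs and validate them.

The office tower (34 storeys) has an underground inlet tank on floor -2, a
mechanical floor with a break tank on 23, a gravity zone serving floors 6-23
and a pumped zone serving 24-34.  The residential tower (45 storeys) has the
mechanical floor on 30, zones 3-30 and 31-45.  Floors 1-2 (and the office's
non-operational mall floors 3-5) are supplied directly from the mains and
are outside the model.
"""

from pathlib import Path

from swss_hrt import save_topology, study_layout_fixtures, validate_topology

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for topo in study_layout_fixtures():
        path = OUT / f"{topo.name}_topology.yaml"
        violations = validate_topology(topo)
        save_topology(topo, path)
        n = len(topo.served_floor_indices())
        print(
            f"{topo.name}: {n} served floors, "
            f"{len(topo.tanks)} tanks, zones "
            f"{[z.served_floors for z in topo.zones]}, "
            f"violations={violations or 'none'} -> {path.name}"
        )


if __name__ == "__main__":
    main()
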
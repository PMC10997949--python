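"""Geometry, demand bookkeeping, and topology validation."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from swss_hrt import (
    demand_from_monthly,
    downstream_demand,
    riser_flow,
    segment_volume,
    validate_topology,
)
from swss_hrt.errors import (
    DanglingTankError,
    InvalidDemandError,
    InvalidGeometryError,
    OutOfZoneError,
)
from swss_hrt.topology import (
    SECONDS_PER_MONTH,
    BuildingTopology,
    FloorSpec,
    TankSpec,
    ZoneSpec,
)

from conftest import single_zone_building


class TestSegmentVolume:
    @pytest.mark.parametrize(
        "d, length, expected",
        [
            (0.05, 3.0, 5.8905e-3),   # 50-mm riser storey
            (0.025, 4.074, 2.0e-3),   # 2-L first-draw occupies ~4 m of 25-mm line
            (0.04, 0.0, 0.0),
        ],
    )
    def test_values(self, d, length, expected):
        assert segment_volume(d, length) == pytest.approx(expected, rel=1e-3)

    def test_first_draw_line_length(self):
        # inverting V = (pi/4) d^2 L for a 2-L draw: ~4 m at 25 mm, ~3 m at 30 mm
        for d, rounded in [(0.025, 4), (0.030, 3)]:
            length = 0.002 / (0.25 * math.pi * d * d)
            assert round(length) == rounded

    @pytest.mark.parametrize("d, length", [(0.0, 1.0), (-0.1, 1.0), (0.05, -1.0)])
    def test_invalid_geometry(self, d, length):
        with pytest.raises(InvalidGeometryError):
            segment_volume(d, length)

    @given(
        d=st.floats(1e-3, 1.0),
        length=st.floats(0.0, 100.0),
        c=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_linear_in_length_quadratic_in_diameter(self, d, length, c):
        v = segment_volume(d, length)
        assert segment_volume(d, c * length) == pytest.approx(c * v, rel=1e-12, abs=1e-300)
        assert segment_volume(c * d, length) == pytest.approx(c * c * v, rel=1e-12, abs=1e-300)


class TestDemandConversion:
    @pytest.mark.parametrize(
        "monthly, expected",
        [(2.592, 1.0e-6), (0.0, 0.0), (12.0, 12.0 / 2_592_000)],
    )
    def test_values(self, monthly, expected):
        assert demand_from_monthly(monthly) == pytest.approx(expected, rel=1e-12)

    def test_month_constant(self):
        assert SECONDS_PER_MONTH == 30 * 24 * 3600

    def test_negative_rejected(self):
        with pytest.raises(InvalidDemandError):
            demand_from_monthly(-1.0)


class TestDownstreamDemand:
    def test_enumerated_sum(self):
        topo = single_zone_building({6: 1e-6, 7: 2e-6, 8: 3e-6})
        zone = topo.zones[0]
        # brute-force enumeration oracle
        for j in (6, 7, 8):
            expected = sum(q for i, q in {6: 1e-6, 7: 2e-6, 8: 3e-6}.items() if i <= j)
            assert downstream_demand(topo, zone, j) == pytest.approx(expected)
        assert downstream_demand(topo, zone, 7) == pytest.approx(3e-6)

    def test_single_floor_zone(self):
        topo = single_zone_building({6: 5e-6})
        assert downstream_demand(topo, topo.zones[0], 6) == pytest.approx(5e-6)

    def test_non_decreasing_in_floor(self):
        topo = single_zone_building({i: (i % 3) * 1e-6 for i in range(4, 12)})
        zone = topo.zones[0]
        vals = [downstream_demand(topo, zone, j) for j in zone.floor_indices]
        assert vals == sorted(vals)

    def test_out_of_zone(self):
        topo = single_zone_building({6: 1e-6, 7: 1e-6})
        with pytest.raises(OutOfZoneError):
            downstream_demand(topo, topo.zones[0], 9)


class TestRiserFlow:
    def test_conservation_at_inlet(self, office):
        tank1 = office.tank("Tank1")
        total = sum(
            office.floor(i).demand for i in office.served_floor_indices()
        )
        assert riser_flow(office, tank1) == pytest.approx(total, rel=1e-12)

    def test_two_zone_union(self, office):
        # Tank2 feeds only the pumped upper zone; Tank1 feeds both zones
        q2 = sum(office.floor(i).demand for i in range(24, 35))
        assert riser_flow(office, office.tank("Tank2")) == pytest.approx(q2)
        assert riser_flow(office, office.tank("Tank1")) > q2

    def test_linearity_in_single_demand(self, office):
        delta = 3.3e-6
        bumped = office.with_demands({10: office.floor(10).demand + delta})
        t1 = office.tank("Tank1")
        assert riser_flow(bumped, t1) - riser_flow(office, t1) == pytest.approx(
            delta, rel=1e-9
        )

    def test_dangling_tank(self, office):
        from dataclasses import replace

        lonely = replace(office, tanks=office.tanks + (TankSpec("T9", 0, 0.0),))
        with pytest.raises(DanglingTankError):
            riser_flow(lonely, lonely.tank("T9"))


class TestValidateTopology:
    def test_fixtures_valid(self, office, residential):
        assert validate_topology(office) == []
        assert validate_topology(residential) == []

    def test_floor_in_two_zones(self, office):
        from dataclasses import replace

        overlap = replace(
            office,
            zones=(
                office.zones[0],
                ZoneSpec("second", "Tank2", entry_floor=34,
                         served_floors=(23, 34),
                         upstream_tanks=("Tank1", "Tank2")),
            ),
        )
        msgs = validate_topology(overlap)
        assert any("floor 23" in m and "2 zones" in m for m in msgs)

    def test_missing_tank_id(self, office):
        from dataclasses import replace

        broken = replace(
            office,
            zones=(
                office.zones[0],
                ZoneSpec("second", "TankX", entry_floor=34,
                         served_floors=(24, 34),
                         upstream_tanks=("Tank1", "TankX")),
            ),
        )
        msgs = validate_topology(broken)
        assert any("TankX" in m for m in msgs)

    def test_mains_direct_floor_in_zone(self):
        topo = single_zone_building({6: 1e-6, 7: 1e-6})
        from dataclasses import replace

        floors = tuple(
            replace(f, supply_label="mains-direct") if f.index == 6 else f
            for f in topo.floors
        )
        msgs = validate_topology(replace(topo, floors=floors))
        assert any("mains-direct" in m for m in msgs)
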
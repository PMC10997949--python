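"""Synthetic per-tap observations with the statistical structure of a
high-rise tap-water survey.

The generator emulates the quantitative endpoints a building survey measures
at each tap:

* total-bacteria proxy: log10 16S rRNA gene copies per litre, linear in HRT
  (in hours) on the log scale, with Gaussian noise calibrated so the
  *population* coefficient of determination against HRT hits a chosen target;
* Fe concentration (mg/L), linear in HRT with noise calibrated to a target
  Pearson correlation, truncated at zero;
* Zn and Cu (mg/L), drawn lognormally around pipe-material-dependent means
  (galvanized plastic-lined steel sheds Zn; brass fittings shed Cu);
* per-floor summer consumption drawn from the survey's low (1-5 t/month) and
  high (10-14 t/month) usage bands.

A single master seed deterministically derives independent substreams for
demands, 16S noise, Fe noise, and metals, so output tables are byte-identical
across reruns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, GenerationError, InvalidDemandError
from .hrt import hrt_profile
from .topology import (
    SECONDS_PER_MONTH,
    BuildingTopology,
    FloorSpec,
    TankSpec,
    ZoneSpec,
)

LOW_BAND = (1.0, 5.0)    # t/month
HIGH_BAND = (10.0, 14.0)  # t/month


@dataclass(frozen=True)
class TapObservation:
    """One synthetic (or observed) tap sample."""

    building: str
    floor: int
    functional_area: str
    supply_label: str
    consumption_band: str
    hrt_s: float
    log10_16s: float
    fe: float
    zn: float
    cu: float

    def __post_init__(self):
        if min(self.fe, self.zn, self.cu) < 0:
            raise ValueError("metal concentrations must be >= 0")


@dataclass
class GeneratorParams:
    """Tunable parameters of the observation generator.

    ``slope_16s`` is in log10 gene copies per hour of HRT; the default span
    of roughly two orders of magnitude across a building mirrors the contrast
    between low- and high-storey taps.  ``target_r2_16s`` and ``target_r_fe``
    set the *population* R2 / Pearson r that the calibrated noise realises.
    Setting ``noise_sd_16s`` / ``noise_sd_fe`` overrides the calibration with
    an explicit standard deviation (0 gives noise-free responses).
    """

    intercept_16s: float = 3.0    # log10 copies/L at HRT = 0
    slope_16s: float = 0.3        # log10 copies/L per hour
    target_r2_16s: float = 0.63
    intercept_fe: float = 0.02    # mg/L at HRT = 0
    slope_fe: float = 0.004       # mg/L per hour
    target_r_fe: float = 0.79
    zn_mean_by_material: dict = field(
        default_factory=lambda: {"GPLS": 0.40, "polypropylene": 0.10}
    )
    cu_mean_by_material: dict = field(
        default_factory=lambda: {"GPLS": 0.005, "polypropylene": 0.069}
    )
    zn_log_sd: float = 0.5
    cu_log_sd: float = 0.5
    p_low_band: float = 9.0 / 16.0  # survey had 9 low-usage of 16 banded taps
    noise_sd_16s: float | None = None
    noise_sd_fe: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.target_r2_16s < 1.0:
            raise CalibrationError("target_r2_16s must lie in (0, 1)")
        if not -1.0 < self.target_r_fe < 1.0:
            raise CalibrationError("target_r_fe must lie in (-1, 1)")
        if self.slope_fe != 0.0 and self.target_r_fe == 0.0:
            raise CalibrationError("target_r_fe must be nonzero when slope_fe is")


# ---------------------------------------------------------------------------
# demand sampling


def assign_bands(
    floors: Sequence[int], rng: np.random.Generator, p_low: float = 9.0 / 16.0
) -> dict[int, str]:
    """Randomly assign each floor to the low or high consumption band."""
    return {
        f: ("low" if u < p_low else "high")
        for f, u in zip(floors, rng.random(len(floors)))
    }


def sample_demands(
    floors: Sequence[int],
    band_assignment: dict[int, str],
    rng: np.random.Generator,
) -> dict[int, float]:
    """Draw per-floor monthly consumption (t/month) from the assigned bands.

    Low-band floors draw uniformly from 1-5 t/month, high-band floors from
    10-14 t/month.  Returns t/month; convert with
    :func:`~swss_hrt.topology.demand_from_monthly`.
    """
    if len(floors) == 0:
        raise InvalidDemandError("cannot sample demands for an empty floor set")
    out: dict[int, float] = {}
    for f in floors:
        band = band_assignment[f]
        lo, hi = LOW_BAND if band == "low" else HIGH_BAND
        out[f] = float(rng.uniform(lo, hi))
    return out


def band_of_monthly(tonnes_per_month: float) -> str:
    lo, hi = LOW_BAND
    if lo <= tonnes_per_month <= hi:
        return "low"
    lo, hi = HIGH_BAND
    if lo <= tonnes_per_month <= hi:
        return "high"
    return "other"


# ---------------------------------------------------------------------------
# noise calibration


def calibrate_noise_sd(
    slope: float, hrt_values: Sequence[float], target_r2: float
) -> float:
    """Noise SD making the population R2 of ``slope*x + noise`` equal
    *target_r2* over the fixed design *hrt_values*.

    R2 = b^2 Var(x) / (b^2 Var(x) + sd^2)  =>  sd = |b| sd(x) sqrt((1-R2)/R2).
    """
    if not 0.0 < target_r2 < 1.0:
        raise CalibrationError(f"target_r2 must lie in (0, 1), got {target_r2}")
    var = float(np.var(np.asarray(hrt_values, dtype=float)))
    if var == 0.0:
        raise CalibrationError("hrt_values are constant; R2 is undefined")
    return abs(slope) * math.sqrt(var) * math.sqrt((1.0 - target_r2) / target_r2)


# ---------------------------------------------------------------------------
# observation generation


def _lognormal_around_mean(
    rng: np.random.Generator, mean: float, log_sd: float, n: int
) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean."""
    if mean <= 0:
        return np.zeros(n)
    mu = math.log(mean) - 0.5 * log_sd * log_sd
    return rng.lognormal(mu, log_sd, size=n)


def generate_observations(
    topology: BuildingTopology,
    params: GeneratorParams,
    floors: Sequence[int] | None = None,
    sample_demand_bands: bool = True,
) -> list[TapObservation]:
    """Generate one tap observation per requested floor.

    With ``sample_demand_bands=True`` (default) per-floor demands are first
    redrawn from the consumption bands; otherwise the topology's own demands
    are used and bands are inferred from them.  ``floors`` may repeat an
    index to place several taps on one floor (they share the floor's HRT but
    receive independent noise); the default is every served, non-stagnant
    floor.
    """
    ss = np.random.SeedSequence(params.seed)
    rng_demand, rng_16s, rng_fe, rng_metal = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    served = topology.served_floor_indices()
    monthly: dict[int, float]
    if sample_demand_bands:
        bands = assign_bands(served, rng_demand, params.p_low_band)
        monthly = sample_demands(served, bands, rng_demand)
        topology = topology.with_demands(
            {f: t / SECONDS_PER_MONTH for f, t in monthly.items()}
        )
    else:
        monthly = {
            f: topology.floor(f).demand * SECONDS_PER_MONTH for f in served
        }

    profile = hrt_profile(topology)
    hrt_by_floor = profile.hrt_by_floor()
    if not hrt_by_floor:
        raise GenerationError(
            f"no floor of {topology.name!r} has a defined HRT (all stagnant?)"
        )
    if floors is None:
        floors = sorted(hrt_by_floor)
    else:
        missing = [f for f in floors if f not in hrt_by_floor]
        if missing:
            raise GenerationError(
                f"floors {missing} have no defined HRT in {topology.name!r}"
            )

    hrt_s = np.array([hrt_by_floor[f] for f in floors])
    hrt_h = hrt_s / 3600.0
    n = len(floors)

    sd16 = (
        params.noise_sd_16s
        if params.noise_sd_16s is not None
        else calibrate_noise_sd(params.slope_16s, hrt_h, params.target_r2_16s)
    )
    log10_16s = (
        params.intercept_16s + params.slope_16s * hrt_h
        + rng_16s.normal(0.0, sd16, size=n)
    )

    if params.noise_sd_fe is not None:
        sd_fe = params.noise_sd_fe
    elif params.slope_fe == 0.0:
        sd_fe = 0.0
    else:
        sd_fe = calibrate_noise_sd(
            params.slope_fe, hrt_h, params.target_r_fe ** 2
        )
    fe = np.clip(
        params.intercept_fe + params.slope_fe * hrt_h
        + rng_fe.normal(0.0, sd_fe, size=n),
        0.0,
        None,
    )

    material = topology.pipe_material
    try:
        zn_mean = params.zn_mean_by_material[material]
        cu_mean = params.cu_mean_by_material[material]
    except KeyError as exc:
        raise GenerationError(
            f"no metal means configured for pipe material {material!r}"
        ) from exc
    zn = _lognormal_around_mean(rng_metal, zn_mean, params.zn_log_sd, n)
    cu = _lognormal_around_mean(rng_metal, cu_mean, params.cu_log_sd, n)

    obs = []
    for i, f in enumerate(floors):
        spec = topology.floor(f)
        obs.append(
            TapObservation(
                building=topology.name,
                floor=f,
                functional_area=topology.functional_area,
                supply_label=spec.supply_label,
                consumption_band=band_of_monthly(monthly[f]),
                hrt_s=float(hrt_s[i]),
                log10_16s=float(log10_16s[i]),
                fe=float(fe[i]),
                zn=float(zn[i]),
                cu=float(cu[i]),
            )
        )
    return obs


def observations_to_frame(observations: Iterable[TapObservation]) -> pd.DataFrame:
    df = pd.DataFrame([vars(o) for o in observations])
    df["hrt_h"] = df["hrt_s"] / 3600.0
    return df


# ---------------------------------------------------------------------------
# study layout fixtures


def _make_floors(
    indices: Iterable[int],
    label_of,
    monthly_t: float,
) -> list[FloorSpec]:
    demand = monthly_t / SECONDS_PER_MONTH
    return [
        FloorSpec(
            index=i,
            demand=0.0 if label_of(i) == "mains-direct" else demand,
            supply_label=label_of(i),
        )
        for i in indices
    ]


def office_topology(monthly_t: float = 7.0) -> BuildingTopology:
    """34-storey office SWSS: inlet tank on basement floor -2, mechanical
    floor 23 with a break tank, gravity zone 6-23 and pumped zone 24-34.
    Floors 1-5 (lobby and non-operational shopping mall) are outside the
    SWSS.  ``monthly_t`` sets a uniform default demand per served floor.
    """

    def label(i):
        if i <= 5:
            return "mains-direct"
        return "swss-first" if i <= 23 else "swss-second"

    return BuildingTopology(
        name="office",
        functional_area="office",
        pipe_material="GPLS",
        floors=tuple(_make_floors(range(1, 35), label, monthly_t)),
        tanks=(
            TankSpec("Tank1", floor_index=-2, hrt=4 * 3600.0),
            TankSpec("Tank2", floor_index=23, hrt=2 * 3600.0),
        ),
        zones=(
            ZoneSpec("first", "Tank1", entry_floor=23,
                     served_floors=(6, 23), upstream_tanks=("Tank1",)),
            ZoneSpec("second", "Tank2", entry_floor=34,
                     served_floors=(24, 34), upstream_tanks=("Tank1", "Tank2")),
        ),
    )


def residential_topology(monthly_t: float = 7.0) -> BuildingTopology:
    """45-storey residential SWSS: inlet tank on basement floor -2,
    mechanical floor 30 with a break tank, gravity zone 3-30 and pumped
    zone 31-45; floors 1-2 are mains-direct."""

    def label(i):
        if i <= 2:
            return "mains-direct"
        return "swss-first" if i <= 30 else "swss-second"

    return BuildingTopology(
        name="residential",
        functional_area="residence",
        pipe_material="polypropylene",
        floors=tuple(_make_floors(range(1, 46), label, monthly_t)),
        tanks=(
            TankSpec("Tank1", floor_index=-2, hrt=4 * 3600.0),
            TankSpec("Tank3", floor_index=30, hrt=2 * 3600.0),
        ),
        zones=(
            ZoneSpec("first", "Tank1", entry_floor=30,
                     served_floors=(3, 30), upstream_tanks=("Tank1",)),
            ZoneSpec("second", "Tank3", entry_floor=45,
                     served_floors=(31, 45), upstream_tanks=("Tank1", "Tank3")),
        ),
    )


def study_layout_fixtures() -> tuple[BuildingTopology, BuildingTopology]:
    """The two packaged building layouts (office, residential)."""
    return office_topology(), residential_topology()


# ---------------------------------------------------------------------------
# randomized topologies for property testing


def random_topology(rng: np.random.Generator) -> BuildingTopology:
    """A small random valid topology: one or two stacked zones, random pipe
    geometry, strictly positive random demands and tank residence times."""
    two_zones = bool(rng.random() < 0.6)
    inlet_floor = -int(rng.integers(1, 4))
    lo1 = int(rng.integers(1, 4))
    hi1 = lo1 + int(rng.integers(0, 6))
    tanks = [TankSpec("T1", inlet_floor, float(rng.uniform(0.0, 2e4)))]
    zones = [
        ZoneSpec("z1", "T1", entry_floor=hi1,
                 served_floors=(lo1, hi1), upstream_tanks=("T1",))
    ]
    top = hi1
    if two_zones:
        lo2 = hi1 + 1
        hi2 = lo2 + int(rng.integers(0, 6))
        tanks.append(TankSpec("T2", hi1, float(rng.uniform(0.0, 2e4))))
        zones.append(
            ZoneSpec("z2", "T2", entry_floor=hi2,
                     served_floors=(lo2, hi2), upstream_tanks=("T1", "T2"))
        )
        top = hi2
    floors = []
    for i in range(lo1, top + 1):
        label = "swss-first" if i <= hi1 else "swss-second"
        floors.append(
            FloorSpec(
                index=i,
                demand=float(rng.uniform(0.5, 20.0)) / SECONDS_PER_MONTH,
                height=float(rng.uniform(2.5, 4.0)),
                standpipe_diameter=float(rng.uniform(0.02, 0.08)),
                horizontal_diameter=float(rng.uniform(0.015, 0.04)),
                horizontal_length=float(rng.uniform(0.0, 20.0)),
                supply_label=label,
            )
        )
    return BuildingTopology(
        name="random",
        floors=tuple(floors),
        tanks=tuple(tanks),
        zones=tuple(zones),
        default_storey_height=float(rng.uniform(2.5, 4.0)),
        default_standpipe_diameter=float(rng.uniform(0.02, 0.08)),
    )
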
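"""Fuel-bed accounting, consumption, emissions, and plume extent.

Fuel is tracked in the six CONSUME-style categories: canopy, ground fuel
(duff), litter-lichen-moss, nonwoody, shrub, and woody fuels.  Three fire
types are distinguished:

``WF``
    a wildfire on the untreated fuel bed (consumes canopy),
``Rx``
    a prescribed burn, understory only — its canopy fraction is
    structurally zero,
``postRxWF``
    a wildfire on the residual bed left after prescribed-fire treatment,
    burning with reduced intensity.

Consumption is expressed as configurable per-category fractions of the
available load rather than a re-derivation of combustion physics; the
shipped defaults are calibrated against the published CONSUME accounting
for the 2016 Gatlinburg wildfire region, so the case-study totals
(356,483.3 t wildfire; 179,779.2 t prescribed; 147,476.2 t post-treatment
wildfire) are reproduced by summation.

Emission factors (kg species per ton fuel consumed) are a surrogate
table in the magnitude range of the Prichard-O'Neill factors and are
fully user-replaceable; every downstream statistic is linear in them.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "FIRE_TYPES",
    "FuelBed",
    "ConsumptionFractions",
    "ConsumptionResult",
    "EmissionFactors",
    "EmissionSeries",
    "PlumeParams",
    "consume",
    "residual_fuel",
    "emissions_total",
    "allocate_hourly",
    "plume_extent",
    "scenario_emissions",
    "calibrate_fractions",
    "gatlinburg_loads",
    "gatlinburg_fractions",
    "default_emission_factors",
    "default_diurnal_profile",
    "accounting_table",
]

CATEGORIES = ("canopy", "ground_fuel", "litter_lichen_moss", "nonwoody", "shrub", "woody")
FIRE_TYPES = ("WF", "Rx", "postRxWF")

# Published CONSUME accounting for the Gatlinburg wildfire region
# (metric tons); used to calibrate the default consumption fractions.
GATLINBURG_FUEL_LOAD_TONS = {
    "canopy": 425704.8,
    "ground_fuel": 94784.2,
    "litter_lichen_moss": 75088.2,
    "nonwoody": 3229.0,
    "shrub": 74999.0,
    "woody": 120832.9,
}
GATLINBURG_CONSUMPTION_TONS = {
    "WF": {
        "canopy": 165219.9,
        "ground_fuel": 14607.9,
        "litter_lichen_moss": 51946.0,
        "nonwoody": 3136.4,
        "shrub": 48547.4,
        "woody": 73025.7,
    },
    "Rx": {
        "canopy": 0.0,
        "ground_fuel": 8116.2,
        "litter_lichen_moss": 51776.4,
        "nonwoody": 3137.3,
        "shrub": 47682.9,
        "woody": 69066.4,
    },
    "postRxWF": {
        "canopy": 65959.0,
        "ground_fuel": 13985.6,
        "litter_lichen_moss": 15859.5,
        "nonwoody": 89.6,
        "shrub": 18488.2,
        "woody": 33094.3,
    },
}
#: Approximate footprint of the case-study fire, used only to convert the
#: regional loads into per-acre densities for synthetic scenarios.
GATLINBURG_BURNED_ACRES = 10000.0


@dataclass(frozen=True)
class FuelBed:
    """Per-category fuel loads in metric tons."""

    loads: dict

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.loads)
        if missing:
            raise ValueError(f"fuel bed missing categories: {sorted(missing)}")
        for c in CATEGORIES:
            v = self.loads[c]
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"load for {c} must be finite and nonnegative, got {v}")

    def total(self) -> float:
        return float(sum(self.loads[c] for c in CATEGORIES))

    def scaled(self, factor: float) -> "FuelBed":
        return FuelBed({c: self.loads[c] * factor for c in CATEGORIES})


@dataclass(frozen=True)
class ConsumptionFractions:
    """Per fire type, the fraction of each category's load consumed."""

    by_fire_type: dict

    def __post_init__(self) -> None:
        for ft, fracs in self.by_fire_type.items():
            if ft not in FIRE_TYPES:
                raise ValueError(f"unknown fire type {ft!r}")
            for c in CATEGORIES:
                f = fracs.get(c)
                if f is None or not (0.0 <= f <= 1.0):
                    raise ValueError(f"fraction for {ft}/{c} must be in [0, 1], got {f}")
        rx = self.by_fire_type.get("Rx")
        if rx is not None and rx["canopy"] != 0.0:
            raise ValueError("prescribed fire consumes no canopy: Rx canopy fraction must be 0")

    def for_type(self, fire_type: str) -> dict:
        if fire_type not in self.by_fire_type:
            raise ValueError(f"no fractions defined for fire type {fire_type!r}")
        return self.by_fire_type[fire_type]


@dataclass(frozen=True)
class ConsumptionResult:
    fire_type: str
    consumed: dict
    total_tons: float


@dataclass(frozen=True)
class EmissionFactors:
    """kg of species emitted per metric ton of fuel consumed, per fire type."""

    by_fire_type: dict

    def factor(self, species: str, fire_type: str) -> float:
        try:
            table = self.by_fire_type[fire_type]
        except KeyError:
            raise ValueError(f"no emission factors for fire type {fire_type!r}")
        try:
            f = table[species]
        except KeyError:
            raise ValueError(f"unknown species {species!r} for fire type {fire_type}")
        if f < 0:
            raise ValueError("emission factors must be nonnegative")
        return f

    def species(self, fire_type: str) -> list[str]:
        return sorted(self.by_fire_type[fire_type])


def default_emission_factors() -> EmissionFactors:
    """Surrogate factor table (kg/ton) in the usual wildland-fire range."""
    wf = {"PM25": 16.0, "NOx": 2.5, "VOC": 18.0}
    rx = {"PM25": 13.0, "NOx": 2.0, "VOC": 15.0}
    return EmissionFactors({"WF": wf, "Rx": rx, "postRxWF": dict(wf)})


def consume(bed: FuelBed, fire_type: str, fractions: ConsumptionFractions) -> ConsumptionResult:
    """Per-category consumption: fraction x load, summed to a total."""
    fracs = fractions.for_type(fire_type)
    consumed = {c: fracs[c] * bed.loads[c] for c in CATEGORIES}
    return ConsumptionResult(fire_type, consumed, float(sum(consumed.values())))


def residual_fuel(bed: FuelBed, consumed: ConsumptionResult) -> FuelBed:
    """Fuel left after a burn; negative residuals are clamped to zero."""
    residual = {}
    for c in CATEGORIES:
        r = bed.loads[c] - consumed.consumed[c]
        if r < 0:
            import logging

            logging.getLogger(__name__).warning(
                "consumption exceeds load for %s by %.1f t; clamping residual to 0", c, -r
            )
            r = 0.0
        residual[c] = r
    return FuelBed(residual)


def calibrate_fractions(
    loads: FuelBed, consumption_by_type: dict
) -> ConsumptionFractions:
    """Back-solve per-category fractions from an accounting table.

    WF and Rx fractions are relative to the full load; postRxWF fractions
    are relative to the residual bed after the Rx consumption, matching
    how a post-treatment wildfire actually meets the fuel.
    """
    out: dict = {}
    for ft in ("WF", "Rx"):
        if ft in consumption_by_type:
            out[ft] = {
                c: (consumption_by_type[ft][c] / loads.loads[c]) if loads.loads[c] > 0 else 0.0
                for c in CATEGORIES
            }
    if "postRxWF" in consumption_by_type:
        if "Rx" not in consumption_by_type:
            raise ValueError("postRxWF calibration needs the Rx consumption for the residual bed")
        resid = {c: loads.loads[c] - consumption_by_type["Rx"][c] for c in CATEGORIES}
        out["postRxWF"] = {
            c: (consumption_by_type["postRxWF"][c] / resid[c]) if resid[c] > 0 else 0.0
            for c in CATEGORIES
        }
    return ConsumptionFractions(out)


def gatlinburg_loads() -> FuelBed:
    return FuelBed(dict(GATLINBURG_FUEL_LOAD_TONS))


def gatlinburg_fractions() -> ConsumptionFractions:
    """Default fractions calibrated from the Gatlinburg case-study table."""
    return calibrate_fractions(gatlinburg_loads(), GATLINBURG_CONSUMPTION_TONS)


def emissions_total(consumed: ConsumptionResult, factors: EmissionFactors) -> dict:
    """Species totals in metric tons: consumed fuel x factor / 1000."""
    return {
        sp: consumed.total_tons * factors.factor(sp, consumed.fire_type) / 1000.0
        for sp in factors.species(consumed.fire_type)
    }


def default_diurnal_profile() -> np.ndarray:
    """Symmetric mid-afternoon-peaked 24-h weight profile (sums to 1).

    A baseline keeps nighttime hours nonzero for wildfires, which burn
    through the night; the 14:00-centered Gaussian bump concentrates the
    bulk of activity in the afternoon.
    """
    h = np.arange(24)
    w = 0.35 + 2.5 * np.exp(-((h - 14.0) ** 2) / (2 * 3.0**2))
    return w / w.sum()


@dataclass
class EmissionSeries:
    """Hourly species emissions (tons/h) plus per-hour plume extent."""

    times: pd.DatetimeIndex
    species: dict  # species -> np.ndarray tons/h
    fuel_tons: np.ndarray  # hourly fuel consumption driving plume rise
    fire_type: str
    plume_bottom_m: np.ndarray = None
    plume_top_m: np.ndarray = None

    def __post_init__(self) -> None:
        n = len(self.times)
        if self.plume_bottom_m is None:
            self.plume_bottom_m = np.zeros(n)
        if self.plume_top_m is None:
            self.plume_top_m = np.zeros(n)
        for sp, arr in self.species.items():
            if len(arr) != n:
                raise ValueError(f"species {sp} series length mismatch")
        if np.any(self.plume_bottom_m > self.plume_top_m + 1e-9):
            raise ValueError("plume bottom must not exceed plume top")

    def total(self, species: str) -> float:
        return float(self.species[species].sum())

    def add(self, other: "EmissionSeries") -> "EmissionSeries":
        """Superpose two series defined on identical hours."""
        if not self.times.equals(other.times):
            raise ValueError("can only add series on identical hours")
        species = {
            sp: self.species.get(sp, 0) + other.species.get(sp, 0)
            for sp in set(self.species) | set(other.species)
        }
        return EmissionSeries(
            self.times,
            species,
            self.fuel_tons + other.fuel_tons,
            self.fire_type,
            np.minimum(self.plume_bottom_m, other.plume_bottom_m),
            np.maximum(self.plume_top_m, other.plume_top_m),
        )


def allocate_hourly(
    species_totals: dict,
    fuel_total_tons: float,
    fire_type: str,
    burn_dates: list[dt.date],
    profile: np.ndarray | None = None,
    rx_window: tuple[int, int] = (10, 17),
) -> EmissionSeries:
    """Distribute species totals over the hours of the burn window.

    Prescribed fires take exactly one date and emit only between ignition
    at 10:00 and completion before 17:00 local; wildfires span a
    contiguous multi-day range with the total split equally across days,
    each day shaped by the 24-h diurnal profile.  Hourly sums reproduce
    the totals to float precision.
    """
    if not burn_dates:
        raise ValueError("burn_dates must be nonempty")
    profile = default_diurnal_profile() if profile is None else np.asarray(profile, float)
    if len(profile) != 24 or profile.min() < 0:
        raise ValueError("diurnal profile must be 24 nonnegative weights")

    if fire_type == "Rx":
        if len(burn_dates) != 1:
            raise ValueError("a prescribed burn takes exactly one date")
        lo, hi = rx_window
        day_weights = np.zeros(24)
        day_weights[lo:hi] = profile[lo:hi]
        day_weights /= day_weights.sum()
        daily = [day_weights]
    else:
        span = (burn_dates[-1] - burn_dates[0]).days + 1
        if span != len(burn_dates):
            raise ValueError("wildfire burn dates must be a contiguous daily range")
        per_day = profile / profile.sum() / len(burn_dates)
        daily = [per_day] * len(burn_dates)

    weights = np.concatenate(daily)
    start = pd.Timestamp(burn_dates[0])
    times = pd.date_range(start, periods=len(weights), freq="h")
    species = {sp: total * weights for sp, total in species_totals.items()}
    return EmissionSeries(times, species, fuel_total_tons * weights, fire_type)


@dataclass(frozen=True)
class PlumeParams:
    """Buoyant-rise surrogate in the Briggs functional form.

    top = stack + rise_coeff * F^(1/3) / u  with buoyancy flux
    F = buoyancy_per_mw * heat (MW), and bottom = bottom_fraction * top.
    ``heat_content_gj_per_ton`` converts hourly fuel consumption to heat
    release (18.6 GJ/t is a typical wildland-fuel higher heating value).
    """

    rise_coeff: float = 140.0
    buoyancy_per_mw: float = 8.8
    bottom_fraction: float = 0.5
    stack_height_m: float = 0.0
    heat_content_gj_per_ton: float = 18.6


def plume_extent(
    heat_mw: np.ndarray, wind_ms: np.ndarray, params: PlumeParams = PlumeParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-hour plume bottom/top (m) from heat release and wind speed.

    Monotone nondecreasing in heat and nonincreasing in wind; zero heat
    gives a zero-extent plume.
    """
    heat = np.asarray(heat_mw, dtype=float)
    wind = np.asarray(wind_ms, dtype=float)
    if np.any(heat < 0):
        raise ValueError("heat release must be nonnegative")
    if np.any(wind <= 0):
        raise ValueError("wind speed must be positive for plume rise")
    flux = params.buoyancy_per_mw * heat
    rise = params.rise_coeff * np.cbrt(flux) / wind
    top = np.where(heat > 0, params.stack_height_m + rise, 0.0)
    bottom = params.bottom_fraction * top
    return bottom, top


def heat_release_mw(fuel_tons_per_hour: np.ndarray, params: PlumeParams = PlumeParams()) -> np.ndarray:
    """Hourly heat release: consumption x heat content, GJ/h -> MW."""
    return np.asarray(fuel_tons_per_hour, float) * params.heat_content_gj_per_ton * 1000.0 / 3600.0


@dataclass
class ScenarioEmissions:
    """Per-case emission series for one treatment configuration."""

    wf: EmissionSeries
    rx: list  # [(BurnUnit, EmissionSeries)] one per treated unit
    post_rx: EmissionSeries
    consumption: dict  # case -> ConsumptionResult summed over units


def _sum_consumption(results: list[ConsumptionResult], fire_type: str) -> ConsumptionResult:
    consumed = {c: float(sum(r.consumed[c] for r in results)) for c in CATEGORIES}
    return ConsumptionResult(fire_type, consumed, float(sum(consumed.values())))


def scenario_emissions(
    plan,
    beds: list[FuelBed],
    fractions: ConsumptionFractions,
    factors: EmissionFactors,
    wildfire_dates: list[dt.date],
    treatment_fraction: float = 1.0,
    profile: np.ndarray | None = None,
) -> ScenarioEmissions:
    """Build the three fire cases for one treatment level.

    The first ``ceil(treatment_fraction x n_units)`` units of the plan are
    treated by prescribed fire.  The wildfire burns every unit's full bed;
    the post-treatment wildfire burns residual beds on treated units (with
    reduced-intensity fractions) and full beds elsewhere.  With
    ``treatment_fraction=0`` the post-treatment case is numerically
    identical to the wildfire and the prescribed case is empty.
    """
    if not 0.0 <= treatment_fraction <= 1.0:
        raise ValueError("treatment_fraction must be in [0, 1]")
    units = plan.units if hasattr(plan, "units") else list(plan)
    if len(beds) != len(units):
        raise ValueError("need one fuel bed per unit")
    n_treated = math.ceil(treatment_fraction * len(units))

    wf_results = [consume(bed, "WF", fractions) for bed in beds]
    wf_total = _sum_consumption(wf_results, "WF")
    wf_series = allocate_hourly(
        emissions_total(wf_total, factors), wf_total.total_tons, "WF", wildfire_dates, profile
    )

    rx_pairs = []
    rx_results = []
    post_results = []
    for i, (unit, bed) in enumerate(zip(units, beds)):
        if i < n_treated:
            rx_c = consume(bed, "Rx", fractions)
            rx_results.append(rx_c)
            series = allocate_hourly(
                emissions_total(rx_c, factors), rx_c.total_tons, "Rx", [unit.burn_date], profile
            )
            rx_pairs.append((unit, series))
            post_results.append(consume(residual_fuel(bed, rx_c), "postRxWF", fractions))
        else:
            post_results.append(consume(bed, "WF", fractions))
    post_type = "postRxWF" if n_treated > 0 else "WF"
    post_total = _sum_consumption(post_results, post_type)
    post_series = allocate_hourly(
        emissions_total(post_total, factors),
        post_total.total_tons,
        post_type,
        wildfire_dates,
        profile,
    )

    consumption = {"WF": wf_total, "postRxWF": post_total}
    if rx_results:
        consumption["Rx"] = _sum_consumption(rx_results, "Rx")
    return ScenarioEmissions(wf_series, rx_pairs, post_series, consumption)


def accounting_table(
    loads: FuelBed, consumption: dict
) -> pd.DataFrame:
    """Accounting matrix: rows load/WF/Rx/post-Rx, columns categories + total."""
    rows = {"fuel_load": {**loads.loads, "total": loads.total()}}
    labels = {"WF": "WF_consumption", "Rx": "Rx_consumption", "postRxWF": "postRxWF_consumption"}
    for ft, label in labels.items():
        if ft in consumption:
            r = consumption[ft]
            rows[label] = {**r.consumed, "total": r.total_tons}
    return pd.DataFrame(rows).T[list(CATEGORIES) + ["total"]]
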
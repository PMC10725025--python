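"""Closed-form physiological relations.

Drinking rate, consumed volume, sucrose solution density and sucrose mass,
energy content, solution viscosity, abdominal temperature, offloading time,
and mass-specific metabolic rates.  All functions take a
:class:`PhysiologyParams`, defaulting to the published constants.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

from beeforage.errors import (
    ConfigError,
    DomainError,
    UnsupportedConcentrationError,
)

# Molar masses used to convert a % w/w sucrose concentration to mole fraction.
_M_SUCROSE = 342.30  # g mol^-1
_M_WATER = 18.015  # g mol^-1


@dataclass(frozen=True)
class PhysiologyParams:
    """All constants of the physiological model.

    Drinking rate follows a power law in bee mass, ``a * (mass / mass_ref)**b``,
    with separate ``(a, b)`` fits for 50% and 35% w/w sucrose; concentrations
    at or below ``low_conc_plateau`` reuse the 35% model (drinking rate is
    constant below roughly 35-40% w/w).  Density is quadratic in
    concentration.  Offloading time is linear in volume with a
    viscosity-dependent coefficient; viscosity follows the Genotelle form
    ``log10(eta) = visc_n_coeff*N + visc_const + phi*(visc_phi_lin +
    visc_phi_pow_coeff*N**visc_phi_pow_exp)`` with ``N`` the sucrose mole
    fraction and ``phi = (30 - T)/(91 + T)``.
    """

    # Drinking-rate power laws (uL/s at mass_ref, dimensionless exponent).
    drink_a_50: float = 1.542
    drink_b_50: float = 0.155
    drink_a_35: float = 2.991
    drink_b_35: float = 0.4602
    mass_ref: float = 1.0  # g
    # Solution density quadratic in concentration (g/mL).
    density_c0: float = 0.9988603
    density_c1: float = 0.0037291
    density_c2: float = 0.0000178
    # Energy content of sucrose.
    sucrose_energy: float = 15.48  # J/mg
    # Mass-specific metabolic rates.
    mr_flight: float = 0.435  # J/(g s)
    mr_probe: float = 0.034  # J/(g s)
    # Offloading-time model.
    offload_coeff: float = 10 ** -1.652  # s/uL
    offload_exp: float = 0.502
    viscosity_ref: float = 1.0  # mPa s
    # Abdominal temperature as an affine map of lab temperature.
    abd_temp_intercept: float = 16.8  # degC
    abd_temp_slope: float = 0.438
    lab_temperature: float = 21.0  # degC
    # Time in the nest other than offloading.
    nest_other_time: float = 83.8  # s
    # Reward and visit-classification constants.
    reward_cap: float = 15.0  # uL per flower per trip
    taste_threshold: float = 2.0  # s
    low_conc_plateau: float = 35.0  # % w/w
    # Genotelle viscosity coefficients (config-injectable).
    visc_n_coeff: float = 22.46
    visc_const: float = -0.114
    visc_phi_lin: float = 1.1
    visc_phi_pow_coeff: float = 43.1
    visc_phi_pow_exp: float = 1.25
    # Opt-in log-linear interpolation between the 35% and 50% drinking models
    # for concentrations in the open interval (low_conc_plateau, 50).
    interpolate_rates: bool = False
    # Mass state assumed while offloading in the nest: "laden" or "unladen".
    offload_mass_mode: str = "laden"

    def __post_init__(self) -> None:
        positive = [
            "drink_a_50",
            "drink_a_35",
            "drink_b_50",
            "drink_b_35",
            "mass_ref",
            "density_c0",
            "sucrose_energy",
            "mr_flight",
            "mr_probe",
            "offload_coeff",
            "viscosity_ref",
            "nest_other_time",
            "reward_cap",
            "low_conc_plateau",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"PhysiologyParams.{name} must be > 0")
        if self.taste_threshold < 0:
            raise ConfigError("taste_threshold must be >= 0")
        if self.offload_mass_mode not in ("laden", "unladen"):
            raise ConfigError("offload_mass_mode must be 'laden' or 'unladen'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhysiologyParams":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown physiology parameter(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhysiologyParams":
        with Path(path).open(encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def dump(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


DEFAULT_PARAMS = PhysiologyParams()


def drinking_rate(
    mass: float, concentration: float, params: PhysiologyParams = DEFAULT_PARAMS
) -> float:
    """Drinking rate in uL/s for a bee of ``mass`` grams.

    Concentrations at or below ``low_conc_plateau`` use the 35% model; 50%
    uses the 50% model.  Values strictly between the plateau and 50% have no
    fitted model and raise :class:`UnsupportedConcentrationError` unless
    ``params.interpolate_rates`` enables log-linear interpolation.
    """
    if mass <= 0:
        raise DomainError(f"bee mass must be > 0 g, got {mass}")
    if not 0 < concentration <= 70:
        raise DomainError(f"concentration {concentration} outside (0, 70] % w/w")
    rel = mass / params.mass_ref
    rate_35 = params.drink_a_35 * rel ** params.drink_b_35
    rate_50 = params.drink_a_50 * rel ** params.drink_b_50
    if concentration <= params.low_conc_plateau:
        return rate_35
    if concentration == 50.0:
        return rate_50
    if params.low_conc_plateau < concentration < 50.0 and params.interpolate_rates:
        w = (concentration - params.low_conc_plateau) / (
            50.0 - params.low_conc_plateau
        )
        return math.exp((1 - w) * math.log(rate_35) + w * math.log(rate_50))
    raise UnsupportedConcentrationError(
        f"no drinking-rate model for {concentration}% w/w (fitted models cover "
        f"<= {params.low_conc_plateau}% and 50%; set interpolate_rates to "
        "interpolate)"
    )


def estimate_volume(
    drink_time: float,
    mass: float,
    concentration: float,
    params: PhysiologyParams = DEFAULT_PARAMS,
) -> float:
    """Estimated volume consumed (uL) for a summed per-visit drinking time.

    Times at or below ``taste_threshold`` (tasting, not drinking) contribute
    zero; estimates above ``reward_cap`` are capped at the cap.
    """
    if drink_time < 0:
        raise DomainError(f"drink_time must be >= 0, got {drink_time}")
    if drink_time <= params.taste_threshold:
        return 0.0
    raw = drinking_rate(mass, concentration, params) * drink_time
    return min(raw, params.reward_cap)


def sucrose_density(
    concentration: float, params: PhysiologyParams = DEFAULT_PARAMS
) -> float:
    """Density of a sucrose solution (g/mL) at ``concentration`` % w/w."""
    if not 0 <= concentration <= 70:
        raise DomainError(f"concentration {concentration} outside [0, 70] % w/w")
    c = concentration
    return params.density_c0 + params.density_c1 * c + params.density_c2 * c * c


def sucrose_mass(
    volume: float, concentration: float, params: PhysiologyParams = DEFAULT_PARAMS
) -> float:
    """Mass of sucrose (mg) in ``volume`` uL of solution at % w/w ``concentration``."""
    if volume < 0:
        raise DomainError(f"volume must be >= 0, got {volume}")
    volume_ml = volume / 1000.0
    grams = volume_ml * sucrose_density(concentration, params) * concentration / 100.0
    return grams * 1000.0  # g -> mg


def energy_intake(
    volume: float, concentration: float, params: PhysiologyParams = DEFAULT_PARAMS
) -> float:
    """Energy (J) gained from consuming ``volume`` uL of solution."""
    return sucrose_mass(volume, concentration, params) * params.sucrose_energy


def abdominal_temperature(
    lab_temperature: float | None = None, params: PhysiologyParams = DEFAULT_PARAMS
) -> float:
    """Bee abdominal temperature (degC) as an affine map of lab temperature."""
    t = params.lab_temperature if lab_temperature is None else lab_temperature
    return params.abd_temp_intercept + params.abd_temp_slope * t


def mole_fraction(concentration: float) -> float:
    """Sucrose mole fraction of a % w/w solution."""
    n_suc = concentration / _M_SUCROSE
    n_wat = (100.0 - concentration) / _M_WATER
    return n_suc / (n_suc + n_wat)


def viscosity(
    concentration: float,
    temperature: float,
    params: PhysiologyParams = DEFAULT_PARAMS,
) -> float:
    """Dynamic viscosity (mPa s) of a sucrose solution, Genotelle form."""
    if not 0 <= concentration <= 70:
        raise DomainError(f"concentration {concentration} outside [0, 70] % w/w")
    if not -10 <= temperature <= 80:
        raise DomainError(f"temperature {temperature} degC outside [-10, 80]")
    n = mole_fraction(concentration)
    phi = (30.0 - temperature) / (91.0 + temperature)
    log10_eta = (
        params.visc_n_coeff * n
        + params.visc_const
        + phi * (params.visc_phi_lin + params.visc_phi_pow_coeff * n ** params.visc_phi_pow_exp)
    )
    return 10.0 ** log10_eta


def offloading_time(
    volume: float,
    concentration: float,
    params: PhysiologyParams = DEFAULT_PARAMS,
) -> float:
    """Time (s) to offload ``volume`` uL of solution in the nest.

    Linear in volume; the coefficient scales with solution viscosity
    evaluated at the bee's abdominal temperature.
    """
    if volume < 0:
        raise DomainError(f"volume must be >= 0, got {volume}")
    if volume == 0:
        return 0.0
    mu = viscosity(concentration, abdominal_temperature(params=params), params)
    return (
        params.offload_coeff * (mu / params.viscosity_ref) ** params.offload_exp * volume
    )


def metabolic_power(
    mass: float, activity_class: str, params: PhysiologyParams = DEFAULT_PARAMS
) -> float:
    """Metabolic power (J/s) of a bee of ``mass`` grams.

    ``"flight"`` covers flying between flowers and any hover interaction;
    ``"probe"`` covers landed interaction, resting, and all time in the nest.
    """
    if mass <= 0:
        raise DomainError(f"bee mass must be > 0 g, got {mass}")
    if activity_class == "flight":
        return mass * params.mr_flight
    if activity_class == "probe":
        return mass * params.mr_probe
    raise ConfigError(f"unknown activity class {activity_class!r}")
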
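"""Faecal calorimetry reduction and fox energy-budget arithmetic.

Bomb calorimetry yields gross energy per dry kg of faeces; combined with
the measured water content this converts to wet-basis energy densities,
and with the fox's daily energy need to the mass of faeces (or the number
of small rodents) needed per day.  Replicated combustions are accepted
only when their relative standard deviation is below 1.5% of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KJ_PER_KCAL_THERMOCHEMICAL = 4.184
KJ_PER_KCAL_INTERNATIONAL = 4.1868

RSD_LIMIT_PCT = 1.5


@dataclass(frozen=True)
class ReplicateQC:
    accepted: bool
    mean: float
    rsd_pct: float
    flag: str = ""


def replicate_qc(energies) -> ReplicateQC:
    """Accept a dog's combustion replicates iff RSD < 1.5% of the mean."""
    values = np.asarray(list(energies), float)
    if len(values) < 2:
        return ReplicateQC(accepted=False, mean=float(values.mean()),
                           rsd_pct=float("nan"), flag="insufficient replication")
    mean = float(values.mean())
    rsd = 100.0 * float(values.std(ddof=1)) / mean
    ok = rsd < RSD_LIMIT_PCT
    return ReplicateQC(accepted=ok, mean=mean, rsd_pct=rsd,
                       flag="" if ok else "replicate spread above limit")


def mj_to_kcal100g(mj_per_kg: float, kj_per_kcal: float = KJ_PER_KCAL_THERMOCHEMICAL) -> float:
    """MJ per kg -> kcal per 100 g (thermochemical calorie by default)."""
    if mj_per_kg < 0:
        raise ValueError("energy density must be >= 0")
    return mj_per_kg * 1000.0 / kj_per_kcal / 10.0


def kcal100g_to_mj(kcal_per_100g: float, kj_per_kcal: float = KJ_PER_KCAL_THERMOCHEMICAL) -> float:
    if kcal_per_100g < 0:
        raise ValueError("energy density must be >= 0")
    return kcal_per_100g * 10.0 * kj_per_kcal / 1000.0


def water_content(wet_g: float, dry_g: float) -> float:
    """Mass fraction of water lost on drying: (wet - dry) / wet."""
    if not 0 < dry_g <= wet_g:
        raise ValueError("need 0 < dry_g <= wet_g")
    return (wet_g - dry_g) / wet_g


def wet_from_dry(dry_value: float, water_fraction: float) -> float:
    """Convert a per-dry-mass quantity to per-wet-mass: dry x (1 - water)."""
    if not 0.0 <= water_fraction < 1.0:
        raise ValueError("water_fraction must be in [0, 1)")
    return dry_value * (1.0 - water_fraction)


def mineral_fractions(residue_g: float, dry_pellet_g: float,
                      water_fraction: float) -> tuple[float, float]:
    """Non-combustible residue as (% of dry mass, % of wet mass)."""
    if not 0.0 <= residue_g <= dry_pellet_g:
        raise ValueError("residue must be in [0, dry pellet mass]")
    pct_dry = 100.0 * residue_g / dry_pellet_g
    wet_pellet = dry_pellet_g / (1.0 - water_fraction)
    pct_wet = 100.0 * residue_g / wet_pellet
    return pct_dry, pct_wet


@dataclass(frozen=True)
class FoxBudget:
    """Energy bracket of an average adult fox and its rodent prey."""

    body_mass_kg: float = 6.4
    need_low_kcal: float = 400.0
    need_high_kcal: float = 800.0
    rodent_mass_g: float = 20.0
    rodent_energy_low_kcal100g: float = 137.0
    rodent_energy_high_kcal100g: float = 170.0

    def __post_init__(self) -> None:
        vals = (self.body_mass_kg, self.need_low_kcal, self.need_high_kcal,
                self.rodent_mass_g, self.rodent_energy_low_kcal100g,
                self.rodent_energy_high_kcal100g)
        if any(v <= 0 for v in vals):
            raise ValueError("all budget figures must be positive")
        if self.need_low_kcal > self.need_high_kcal:
            raise ValueError("need_low must be <= need_high")


def _round_to(value: float, step: float | None) -> float:
    if step is None:
        return value
    return round(value / step) * step


def daily_faeces_requirement(
    budget: FoxBudget, kcal_wet_per_100g: float, rounding: str | None = "hundred",
) -> tuple[float, float]:
    """Grams of faeces per day covering the low and high daily need."""
    if kcal_wet_per_100g <= 0:
        raise ValueError("energy density must be positive")
    step = {None: None, "none": None, "hundred": 100.0}[rounding]
    low = 100.0 * budget.need_low_kcal / kcal_wet_per_100g
    high = 100.0 * budget.need_high_kcal / kcal_wet_per_100g
    return _round_to(low, step), _round_to(high, step)


def rodents_per_day(budget: FoxBudget, rounding: str | None = "ten") -> tuple[float, float]:
    """Small rodents per day bracketing the daily need.

    The low end pairs the low need with the most calorific rodent, the high
    end the high need with the least calorific one.
    """
    step = {None: None, "none": None, "ten": 10.0}[rounding]
    kcal_per_rodent_high = budget.rodent_energy_high_kcal100g * budget.rodent_mass_g / 100.0
    kcal_per_rodent_low = budget.rodent_energy_low_kcal100g * budget.rodent_mass_g / 100.0
    low = budget.need_low_kcal / kcal_per_rodent_high
    high = budget.need_high_kcal / kcal_per_rodent_low
    return _round_to(low, step), _round_to(high, step)


@dataclass(frozen=True)
class EnergyProfile:
    """Study-level calorimetry summary (means with sd over dogs)."""

    n_dogs: int
    gross_energy_dry_mj: float
    gross_energy_dry_mj_sd: float
    kcal_dry_100g: float
    kcal_dry_100g_sd: float
    gross_energy_wet_mj: float
    gross_energy_wet_mj_sd: float
    kcal_wet_100g: float
    kcal_wet_100g_sd: float
    water_fraction: float
    mineral_pct_dry: float | None
    mineral_pct_wet: float | None
    n_dogs_mineral: int


def build_energy_profile(
    calorimetry: pd.DataFrame,
    kj_per_kcal: float = KJ_PER_KCAL_THERMOCHEMICAL,
) -> EnergyProfile:
    """Reduce a calorimetry bench sheet to a study-level energy profile.

    Per dog: replicate-QC the combustion energies and keep the mean; water
    content from summed wet/dry pellet masses.  Wet-basis figures use the
    study-average water fraction applied uniformly; kcal columns are
    converted per dog and then averaged.  Mineral fractions use only dogs
    with a recorded residue.
    """
    per_dog = []
    for dog, grp in calorimetry.groupby("dog_id", sort=True):
        qc = replicate_qc(grp["gross_energy_MJ_per_dry_kg"])
        wf = water_content(float(grp["wet_g"].sum()), float(grp["dry_g"].sum()))
        residue = None
        if "mineral_residue_g" in grp and grp["mineral_residue_g"].notna().all():
            residue = 100.0 * float(grp["mineral_residue_g"].sum()) / float(grp["dry_g"].sum())
        per_dog.append({"dog": dog, "mj_dry": qc.mean, "accepted": qc.accepted,
                        "water": wf, "mineral_pct_dry": residue})
    df = pd.DataFrame(per_dog)
    used = df[df["accepted"]]
    if used.empty:
        raise ValueError("no dog passed replicate QC")
    water = float(used["water"].mean())
    mj_dry = used["mj_dry"].to_numpy()
    kcal_dry = np.array([mj_to_kcal100g(v, kj_per_kcal) for v in mj_dry])
    mj_wet = np.array([wet_from_dry(v, water) for v in mj_dry])
    kcal_wet = np.array([wet_from_dry(v, water) for v in kcal_dry])

    def sd(a: np.ndarray) -> float:
        return float(np.std(a, ddof=1)) if len(a) > 1 else 0.0

    minerals = used["mineral_pct_dry"].dropna()
    mineral_dry = float(minerals.mean()) if len(minerals) else None
    mineral_wet = mineral_dry * (1.0 - water) if mineral_dry is not None else None
    return EnergyProfile(
        n_dogs=len(used),
        gross_energy_dry_mj=float(mj_dry.mean()), gross_energy_dry_mj_sd=sd(mj_dry),
        kcal_dry_100g=float(kcal_dry.mean()), kcal_dry_100g_sd=sd(kcal_dry),
        gross_energy_wet_mj=float(mj_wet.mean()), gross_energy_wet_mj_sd=sd(mj_wet),
        kcal_wet_100g=float(kcal_wet.mean()), kcal_wet_100g_sd=sd(kcal_wet),
        water_fraction=water,
        mineral_pct_dry=mineral_dry, mineral_pct_wet=mineral_wet,
        n_dogs_mineral=int(len(minerals)),
    )


def profile_table(profile: EnergyProfile) -> pd.DataFrame:
    """Energy profile as a one-row publication-style table."""
    return pd.DataFrame([{
        "Species": "Canis lupus familiaris",
        "N": profile.n_dogs,
        "MJ_per_dry_kg": round(profile.gross_energy_dry_mj, 2),
        "MJ_per_dry_kg_sd": round(profile.gross_energy_dry_mj_sd, 2),
        "kcal_per_dry_100g": round(profile.kcal_dry_100g, 2),
        "kcal_per_dry_100g_sd": round(profile.kcal_dry_100g_sd, 2),
        "MJ_per_wet_kg": round(profile.gross_energy_wet_mj, 2),
        "MJ_per_wet_kg_sd": round(profile.gross_energy_wet_mj_sd, 2),
        "kcal_per_wet_100g": round(profile.kcal_wet_100g, 2),
        "kcal_per_wet_100g_sd": round(profile.kcal_wet_100g_sd, 2),
        "water_pct": round(100.0 * profile.water_fraction, 1),
        "mineral_pct_dry": (round(profile.mineral_pct_dry, 1)
                            if profile.mineral_pct_dry is not None else "NA"),
        "mineral_pct_wet": (round(profile.mineral_pct_wet, 1)
                            if profile.mineral_pct_wet is not None else "NA"),
    }])
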
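"""Interspecies dose scaling and circulating-concentration arithmetic.

Body-surface-area (BSA) scaling converts a dose between species through
the standard Km factors (body weight / surface area, kg/m^2):

    target mg/kg = (dose_mg / source body weight) * (Km_source / Km_target)

The circulating concentration then follows from the crude assumption that
the whole dose is confined to the blood volume:

    C = (dose_mg / molar mass) / blood volume

This deliberately overestimates exposure - for a lipophilic drug like
glibenclamide the volume of distribution far exceeds the blood volume -
so the result carries an explicit caveat and should be read as an upper
bound on plasma concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SpeciesProfile",
    "DoseTranslation",
    "HUMAN",
    "MOUSE",
    "bsa_convert",
    "circulating_concentration",
    "translate_dose",
]

_CAVEAT = (
    "Assumes the entire dose is confined to the blood volume; true plasma "
    "levels are lower whenever the volume of distribution exceeds blood "
    "volume (e.g. lipophilic drugs). Treat as an upper bound."
)


@dataclass(frozen=True)
class SpeciesProfile:
    """Species constants for BSA scaling: weight (kg), Km, blood volume (mL)."""

    name: str
    body_weight_kg: float
    km_factor: float
    blood_volume_mL: float | None = None

    def __post_init__(self) -> None:
        if self.body_weight_kg <= 0 or self.km_factor <= 0:
            raise ValueError("body weight and Km factor must be positive")
        if self.blood_volume_mL is not None and self.blood_volume_mL <= 0:
            raise ValueError("blood volume must be positive")


#: standard adult human (FDA Km = 37)
HUMAN = SpeciesProfile("human", body_weight_kg=70.0, km_factor=37.0)
#: 30 g mouse (FDA Km = 3), circulating blood volume ~2.6 mL
MOUSE = SpeciesProfile("mouse", body_weight_kg=0.030, km_factor=3.0, blood_volume_mL=2.6)


@dataclass(frozen=True)
class DoseTranslation:
    """Full human dose -> animal mg/kg -> circulating molarity chain."""

    source_dose_mg: float
    source_species: SpeciesProfile
    target_species: SpeciesProfile
    target_dose_mg_per_kg: float
    target_dose_mg_per_animal: float
    molar_mass_g_per_mol: float | None
    circulating_concentration_mol_per_L: float | None
    caveat: str = _CAVEAT


def bsa_convert(dose_mg: float, source: SpeciesProfile, target: SpeciesProfile) -> float:
    """BSA-scaled dose in the target species, in mg/kg."""
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    return (dose_mg / source.body_weight_kg) * (source.km_factor / target.km_factor)


def circulating_concentration(
    dose_mg_per_animal: float,
    blood_volume_mL: float,
    molar_mass_g_per_mol: float,
) -> float:
    """Molar concentration if the whole dose sits in the blood volume (mol/L)."""
    if dose_mg_per_animal < 0:
        raise ValueError("dose must be non-negative")
    if blood_volume_mL <= 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("blood volume and molar mass must be positive")
    moles = (dose_mg_per_animal / 1000.0) / molar_mass_g_per_mol
    return moles / (blood_volume_mL / 1000.0)


def translate_dose(
    dose_mg: float,
    source: SpeciesProfile = HUMAN,
    target: SpeciesProfile = MOUSE,
    molar_mass_g_per_mol: float | None = None,
) -> DoseTranslation:
    """Run the whole chain; the concentration step needs the target blood
    volume and a molar mass, otherwise it is left as None."""
    mg_per_kg = bsa_convert(dose_mg, source, target)
    mg_per_animal = mg_per_kg * target.body_weight_kg
    conc = None
    if molar_mass_g_per_mol is not None and target.blood_volume_mL is not None:
        conc = circulating_concentration(mg_per_animal, target.blood_volume_mL, molar_mass_g_per_mol)
    return DoseTranslation(
        source_dose_mg=dose_mg,
        source_species=source,
        target_species=target,
        target_dose_mg_per_kg=mg_per_kg,
        target_dose_mg_per_animal=mg_per_animal,
        molar_mass_g_per_mol=molar_mass_g_per_mol,
        circulating_concentration_mol_per_L=conc,
    )
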
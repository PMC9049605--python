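"""Molar-mass registry for g <-> mmol conversions at the model boundary.

Fluxes are carried in mmol·gDW⁻¹·h⁻¹ internally; feed media and yields are
often specified in g·l⁻¹ or g·g⁻¹, so conversions happen exactly once, here.
"""

from __future__ import annotations

# g·mol⁻¹
MOLAR_MASSES: dict[str, float] = {
    "glucose": 180.156,
    "fructose": 180.156,
    "mannose": 180.156,
    "sucrose": 342.297,
    "ethanol": 46.069,
    "glycerol": 92.094,
    "lactate": 90.078,
    "succinate": 118.088,
    "o2": 31.998,
    "co2": 44.009,
}


def molar_mass(species: str, registry: dict[str, float] | None = None) -> float:
    """Return the molar mass of ``species`` in g·mol⁻¹.

    ``registry`` entries override / extend the built-in table.
    """
    if registry and species in registry:
        return registry[species]
    try:
        return MOLAR_MASSES[species]
    except KeyError:
        raise KeyError(
            f"no molar mass registered for species {species!r}; "
            "extend the registry via configuration"
        ) from None


def g_per_l_to_mmol_per_l(value: float, species: str,
                          registry: dict[str, float] | None = None) -> float:
    return value * 1000.0 / molar_mass(species, registry)


def mmol_per_l_to_g_per_l(value: float, species: str,
                          registry: dict[str, float] | None = None) -> float:
    return value * molar_mass(species, registry) / 1000.0
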
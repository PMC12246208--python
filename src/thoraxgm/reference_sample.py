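"""Composition of the comparative reference sample.

The study's comparative sample consists of recent adult male *H. sapiens*
from populations across the five inhabited continents, grouped by the mean
annual temperature of their locality (cold <= 7 degC, temperate <= 23 degC,
warm > 23 degC), plus three non-sapiens *Homo* fossils.  The synthetic
generator reproduces this composition by default; the counts below are the
inputs for the sample-arithmetic checks.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PopulationRow:
    population: str
    site: str
    climate_group: str
    n: int
    latitude_deg: float


REFERENCE_POPULATIONS: tuple[PopulationRow, ...] = (
    # cold
    PopulationRow("Inuit", "Point Hope, Alaska (USA)", "cold", 3, 70),
    PopulationRow("Inuit", "Greenland (Denmark)", "cold", 3, 68),
    PopulationRow("Norsemen", "Nuuk, Greenland (Denmark)", "cold", 2, 64),
    PopulationRow("South Patagonian - Fuegian",
                  "Isla Grande de Tierra del Fuego (Argentina/Chile)",
                  "cold", 4, -53),
    # temperate
    PopulationRow("French", "Paris (France)", "temperate", 3, 48),
    PopulationRow("Spanish", "Madrid (Spain)", "temperate", 3, 40),
    PopulationRow("Native North American", "New Mexico (USA)",
                  "temperate", 3, 35),
    PopulationRow("Native North American", "California (USA)",
                  "temperate", 2, 34),
    PopulationRow("Japanese", "Hyogo Prefecture (Japan)", "temperate", 3, 34),
    PopulationRow("Native Canarian", "Gran Canaria (Spain)",
                  "temperate", 5, 28),
    PopulationRow("Mexican", "Mexico", "temperate", 3, 25),
    PopulationRow("Native South American", "Santiago del Estero (Argentina)",
                  "temperate", 3, -27),
    PopulationRow("North Patagonian", "Rio Negro and Chubut (Argentina)",
                  "temperate", 4, -41),
    # warm
    PopulationRow("Nubian", "Abri, Northern State (Sudan)", "warm", 3, 21),
    PopulationRow("Negrito", "Luzon (Philippines)", "warm", 3, 15),
    PopulationRow("Papuan", "New Britain (Papua New Guinea)", "warm", 3, -6),
    PopulationRow("Native South American", "Ancon (Peru)", "warm", 3, -9),
    PopulationRow("Sub-Saharan", "Lagos (Portugal)", "warm", 3, 15),
    PopulationRow("Afro-American", "New Mexico (USA)", "warm", 3, 35),
)

#: non-sapiens comparative fossils (specimen, taxon)
OTHER_FOSSILS = (
    ("KNM-WT 15000", "erectus"),
    ("Kebara 2", "neanderthal"),
    ("Shanidar 3", "neanderthal"),
)


def total_recent_n() -> int:
    """Total number of recent comparative specimens."""
    return sum(row.n for row in REFERENCE_POPULATIONS)


def population_count() -> int:
    """Number of sampled populations (table rows)."""
    return len(REFERENCE_POPULATIONS)


def group_sizes() -> dict[str, int]:
    sizes: dict[str, int] = {}
    for row in REFERENCE_POPULATIONS:
        sizes[row.climate_group] = sizes.get(row.climate_group, 0) + row.n
    return sizes
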
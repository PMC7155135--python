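"""Land-use class registry for the Alpine model region.

The landscape is described by 22 land-use classes that combine usage type
and, for arable land and grassland, usage intensity. Each class belongs to
one of four broad habitat groups (agricultural lands, grasslands, forests,
alpine habitats) used for specialist classification and reporting.

Class codes are stable integers 1..22 and are what land-use rasters store.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

AGRICULTURAL = "Agricultural lands"
GRASSLANDS = "Grasslands"
FORESTS = "Forests"
ALPINE = "Alpine habitats"

HABITAT_GROUPS = (AGRICULTURAL, GRASSLANDS, FORESTS, ALPINE)


@dataclass(frozen=True)
class LandUseClass:
    """One land-use class and its fixed attributes.

    ``sector`` marks the agricultural sub-economy a farm manages the class
    under ("cropland" / "grassland") or ``None`` for classes outside the
    farm economy.  ``intensive`` encodes the intensive-use definition:
    non-low-input cropland, meadows mown at least three times a year and
    pastures stocked above 1.5 livestock units/ha.  ``static`` classes are
    never touched by farm decisions or succession.
    """

    code: int
    name: str
    group: str
    share_current: float  # percent of region area under current conditions
    sector: Optional[str] = None
    intensive: bool = False
    static: bool = False


CLASSES: List[LandUseClass] = [
    LandUseClass(1, "Arable land fallow and low input", AGRICULTURAL, 0.41, "cropland"),
    LandUseClass(2, "Cereal crop", AGRICULTURAL, 2.46, "cropland", intensive=True),
    LandUseClass(3, "Cereal crop low input", AGRICULTURAL, 0.21, "cropland"),
    LandUseClass(4, "Energy crop", AGRICULTURAL, 0.01, "cropland", intensive=True),
    LandUseClass(5, "Misc. arable land", AGRICULTURAL, 0.79, "cropland", intensive=True),
    LandUseClass(6, "Non-cereal crop", AGRICULTURAL, 2.21, "cropland", intensive=True),
    LandUseClass(7, "Non-cereal crop low input", AGRICULTURAL, 0.19, "cropland"),
    LandUseClass(8, "Ruderal", AGRICULTURAL, 2.53, static=True),
    LandUseClass(9, "Dry grassland", GRASSLANDS, 0.03, static=True),
    LandUseClass(10, "Extensive meadow (one- or two-cut per year)", GRASSLANDS, 2.33, "grassland"),
    LandUseClass(11, "Extensive pasture (max. 1.5 livestock units per hectare)", GRASSLANDS, 6.67, "grassland"),
    LandUseClass(12, "Intensive meadow (min. three-cut per year)", GRASSLANDS, 3.96, "grassland", intensive=True),
    LandUseClass(13, "Intensive pasture (min. 1.5 livestock units per hectare)", GRASSLANDS, 4.60, "grassland", intensive=True),
    LandUseClass(14, "Orchard meadow and fruit plantation", GRASSLANDS, 0.02, static=True),
    LandUseClass(15, "Riparian", GRASSLANDS, 1.02, static=True),
    LandUseClass(16, "Wetland", GRASSLANDS, 0.10, static=True),
    LandUseClass(17, "Broad-leaved forest", FORESTS, 23.60),
    LandUseClass(18, "Conifer forest", FORESTS, 41.70),
    LandUseClass(19, "Felling area", FORESTS, 1.28),
    LandUseClass(20, "Alpine grassland", ALPINE, 1.02, static=True),
    LandUseClass(21, "Rock and scree", ALPINE, 3.51, static=True),
    LandUseClass(22, "Scrub & Shrub (incl. krummholz)", ALPINE, 1.39),
]

N_CLASSES = 22
ALL_CODES = tuple(c.code for c in CLASSES)

BY_CODE: Dict[int, LandUseClass] = {c.code: c for c in CLASSES}

#: class code -> habitat group (total, exhaustive over the 22 classes)
HABITAT_GROUP_LOOKUP: Dict[int, str] = {c.code: c.group for c in CLASSES}

#: classes a farm can manage, by sector
CROPLAND_CLASSES = tuple(c.code for c in CLASSES if c.sector == "cropland")
GRASSLAND_FARM_CLASSES = tuple(c.code for c in CLASSES if c.sector == "grassland")
FARM_CLASSES = CROPLAND_CLASSES + GRASSLAND_FARM_CLASSES

#: intensively used classes (non-organic cropland, >=3-cut meadow, >1.5 LU/ha pasture)
INTENSIVE_CLASSES = tuple(c.code for c in CLASSES if c.intensive)

#: classes never altered by the simulation
STATIC_CLASSES = tuple(c.code for c in CLASSES if c.static)

FOREST_CLASSES = (17, 18, 19)
ALPINE_CLASSES = (20, 21, 22)

#: succession target for abandoned agricultural land
SCRUB_CLASS = 22
BROADLEAF_FOREST = 17
CONIFER_FOREST = 18

#: current-period percent shares (Table-style mixture used by the generator)
CURRENT_SHARES: Dict[int, float] = {c.code: c.share_current for c in CLASSES}


def group_shares(shares: Dict[int, float]) -> Dict[str, float]:
    """Aggregate per-class shares to the four habitat groups."""
    out = {g: 0.0 for g in HABITAT_GROUPS}
    for code, s in shares.items():
        out[HABITAT_GROUP_LOOKUP[code]] += s
    return out


# -- intensity / conversion transition maps used by farm actions ---------------

INTENSIFY_CROPLAND = {1: 5, 3: 2, 7: 6}
EXTENSIFY_CROPLAND = {2: 3, 4: 1, 5: 1, 6: 7}
INTENSIFY_GRASSLAND = {10: 12, 11: 13}
EXTENSIFY_GRASSLAND = {12: 10, 13: 11}
#: cropland -> grassland keeps the intensity stratum
CROPLAND_TO_GRASSLAND = {1: 10, 3: 10, 7: 10, 2: 12, 4: 12, 5: 12, 6: 12}
GRASSLAND_TO_CROPLAND = {10: 3, 11: 3, 12: 2, 13: 2}
ENERGY_CROP = 4
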
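"""Land-cover class codes and suitability categories.

The real pipeline consumes an LCDB-style categorical raster; the synthetic
generator emits the same integer codes. Classes fall into three categories:

* ``surveyed`` — field plot data exist (built-up area, herbaceous saline
  vegetation, scrub & shrubland, plus forest which was surveyed and empty);
* ``nominal`` — possibly suitable but low-preference, assigned a nominal
  3 nests/ha and 0.03 occupancy without survey;
* ``unsuitable`` — density and occupancy zero (water, bare surfaces, crops…).
"""

from __future__ import annotations

__all__ = [
    "CLASS_IDS",
    "ID_TO_CLASS",
    "DEFAULT_CATEGORIES",
    "NOMINAL_DENSITY",
    "NOMINAL_OCCUPANCY",
]

# integer raster codes for the classes the model distinguishes
CLASS_IDS: dict[str, int] = {
    "WAT": 0,   # water bodies / bare / artificial — unsuitable
    "HSV": 1,   # herbaceous saline vegetation
    "BUA": 2,   # built-up area
    "SAS": 3,   # scrub and shrubland
    "OVP": 4,   # orchard, vineyard & other perennial crops
    "HFV": 5,   # herbaceous freshwater vegetation
    "TTG": 6,   # tall tussock grassland
    "FOR": 7,   # forest
}

ID_TO_CLASS: dict[int, str] = {v: k for k, v in CLASS_IDS.items()}

DEFAULT_CATEGORIES: dict[str, str] = {
    "HSV": "surveyed",
    "BUA": "surveyed",
    "SAS": "surveyed",
    "FOR": "surveyed",
    "OVP": "nominal",
    "HFV": "nominal",
    "TTG": "nominal",
    "WAT": "unsuitable",
}

NOMINAL_DENSITY = 3          # nests per hectare for low-preference classes
NOMINAL_OCCUPANCY = 0.03     # occupancy for low-preference classes
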
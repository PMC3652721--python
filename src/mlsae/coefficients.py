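"""Default fixed-effect surface for the synthetic-data generator.

The values below are a reference coefficient set (with standard errors) for
a national childhood-obesity multilevel model on the 2007 National Survey of
Children's Health scale: individual age group, sex and
race/ethnicity effects plus zip-level income-octile, lifestyle and
urbanization effects and county-level income-octile and urban-rural effects,
all on the logit scale.  Reference levels carry coefficient 0 and are omitted
from the mappings.

They serve two roles here: as the default ``TrueModel`` risk surface of the
synthetic generator (so simulated surveys live on a realistic prevalence
scale, about 16% overall), and as a frozen coefficient set for worked-example
risk predictions.
"""

from __future__ import annotations

INTERCEPT = -3.4529
INTERCEPT_SE = 0.15

#: term -> {non-reference level -> coefficient}
COEFFICIENTS: dict[str, dict] = {
    "age": {"10-14": 0.4117},
    "sex": {"M": 0.5753},
    "race": {
        "black": 0.6804,
        "hispanic": 0.5697,
        "asian": -0.1188,
        "aian": 0.7070,
        "nhpi": 0.7325,
        "multiracial": 0.1655,
        "other": 0.0220,
    },
    "zip_income_octile": {
        1: 0.8478,
        2: 0.7535,
        3: 0.6750,
        4: 0.7204,
        5: 0.5944,
        6: 0.4319,
        7: 0.3410,
    },
    "zip_lifestyle": {
        "High Society": 0.3810,
        "Upscale Avenues": 0.3063,
        "Metropolis": 0.3515,
        "Senior Styles": 0.2716,
        "Scholars and Patriots": -0.1758,
        "High Hopes": 0.3312,
        "Global Roots": 0.4404,
        "Family Portrait": 0.4092,
        "Traditional Living": 0.3541,
        "Factories and Farms": 0.4768,
        "American Quilt": 0.3711,
    },
    "zip_urbanization": {
        "Principal Urban Centers II": 0.0574,
        "Metro Cities I": -0.0739,
        "Metro Cities II": 0.1325,
        "Urban Outskirts I": 0.0561,
        "Urban Outskirts II": 0.1739,
        "Suburban Periphery I": -0.0788,
        "Suburban Periphery II": 0.0746,
        "Small Towns": 0.1453,
        "Rural I": 0.0458,
        "Rural II": 0.2242,
    },
    "county_income_octile": {
        1: -0.1670,
        2: -0.1919,
        3: -0.1783,
        4: -0.1616,
        5: -0.0259,
        6: -0.0455,
        7: 0.0031,
    },
    "county_urban_rural": {
        "Fringe metro": 0.0027,
        "Medium metro": 0.0118,
        "Small metro": -0.0168,
        "Micropolitan": -0.0136,
        "Noncore rural": -0.0526,
    },
}

#: term -> {non-reference level -> standard error}
STANDARD_ERRORS: dict[str, dict] = {
    "age": {"10-14": 0.03},
    "sex": {"M": 0.03},
    "race": {
        "black": 0.05478,
        "hispanic": 0.05,
        "asian": 0.1714,
        "aian": 0.14,
        "nhpi": 0.25,
        "multiracial": 0.12,
        "other": 0.12,
    },
    "zip_income_octile": {1: 0.11, 2: 0.11, 3: 0.10, 4: 0.10, 5: 0.10, 6: 0.08, 7: 0.08},
    "zip_lifestyle": {
        "High Society": 0.12,
        "Upscale Avenues": 0.12,
        "Metropolis": 0.12,
        "Senior Styles": 0.13,
        "Scholars and Patriots": 0.17,
        "High Hopes": 0.11,
        "Global Roots": 0.11,
        "Family Portrait": 0.12,
        "Traditional Living": 0.11,
        "Factories and Farms": 0.13,
        "American Quilt": 0.13,
    },
    "zip_urbanization": {
        "Principal Urban Centers II": 0.12,
        "Metro Cities I": 0.11,
        "Metro Cities II": 0.11,
        "Urban Outskirts I": 0.11,
        "Urban Outskirts II": 0.13,
        "Suburban Periphery I": 0.11,
        "Suburban Periphery II": 0.12,
        "Small Towns": 0.14,
        "Rural I": 0.13,
        "Rural II": 0.14,
    },
    "county_income_octile": {1: 0.12, 2: 0.11, 3: 0.10, 4: 0.10, 5: 0.10, 6: 0.10, 7: 0.09},
    "county_urban_rural": {
        "Fringe metro": 0.07,
        "Medium metro": 0.06,
        "Small metro": 0.07,
        "Micropolitan": 0.07,
        "Noncore rural": 0.08,
    },
}

#: between-state variance of the null (random-effects-only) state model
SIGMA2_STATE_NULL = 0.0530
#: between-county variance of the null county model
SIGMA2_COUNTY_NULL = 0.0928
#: between-zip variance of the null zip model
SIGMA2_ZIP_NULL = 0.1950
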
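"""Categorical systems used throughout the pipeline.

Every covariate in the model is categorical.  Each term has an ordered list of
levels and a declared reference level; design matrices use dummy (one-hot minus
reference) coding in the declared order, so the level lists here define the
column order of every coefficient vector in the package.

The area-level classifications mirror the commercial/administrative schemes
used for neighbourhood characterisation in US child-health surveillance:
median-household-income octiles (1 = poorest, 8 = richest), a 12-category
community "lifestyle" segmentation, an 11-category urbanization gradient for
sub-county areas, and the 6-level NCHS urban-rural scheme for counties.
"""

from __future__ import annotations

SEX_LEVELS = ["F", "M"]
SEX_REF = "F"

AGE_LEVELS = ["15-17", "10-14"]
AGE_REF = "15-17"

RACE_LEVELS = [
    "white",
    "black",
    "hispanic",
    "asian",
    "aian",        # American Indian / Alaska Native
    "nhpi",        # Native Hawaiian / Pacific Islander
    "multiracial",
    "other",
]
RACE_REF = "white"

INCOME_OCTILES = [1, 2, 3, 4, 5, 6, 7, 8]
INCOME_REF = 8  # richest octile is the baseline

LIFESTYLE_LEVELS = [
    "High Society",
    "Upscale Avenues",
    "Metropolis",
    "Solo Acts",
    "Senior Styles",
    "Scholars and Patriots",
    "High Hopes",
    "Global Roots",
    "Family Portrait",
    "Traditional Living",
    "Factories and Farms",
    "American Quilt",
]
LIFESTYLE_REF = "Solo Acts"

URBANIZATION_LEVELS = [
    "Principal Urban Centers I",
    "Principal Urban Centers II",
    "Metro Cities I",
    "Metro Cities II",
    "Urban Outskirts I",
    "Urban Outskirts II",
    "Suburban Periphery I",
    "Suburban Periphery II",
    "Small Towns",
    "Rural I",
    "Rural II",
]
URBANIZATION_REF = "Principal Urban Centers I"

URBAN_RURAL_LEVELS = [
    "Central metro",
    "Fringe metro",
    "Medium metro",
    "Small metro",
    "Micropolitan",
    "Noncore rural",
]
URBAN_RURAL_REF = "Central metro"

#: term name -> (ordered levels, reference level)
TERMS: dict[str, tuple[list, object]] = {
    "age": (AGE_LEVELS, AGE_REF),
    "sex": (SEX_LEVELS, SEX_REF),
    "race": (RACE_LEVELS, RACE_REF),
    "zip_income_octile": (INCOME_OCTILES, INCOME_REF),
    "zip_lifestyle": (LIFESTYLE_LEVELS, LIFESTYLE_REF),
    "zip_urbanization": (URBANIZATION_LEVELS, URBANIZATION_REF),
    "county_income_octile": (INCOME_OCTILES, INCOME_REF),
    "county_urban_rural": (URBAN_RURAL_LEVELS, URBAN_RURAL_REF),
}

#: the full model's fixed-effect terms, in design order
FULL_TERMS = [
    "age",
    "sex",
    "race",
    "zip_income_octile",
    "zip_lifestyle",
    "zip_urbanization",
    "county_income_octile",
    "county_urban_rural",
]

#: the reduced predictive model: county terms and urbanization dropped
PREDICTIVE_TERMS = ["age", "sex", "race", "zip_income_octile", "zip_lifestyle"]

#: which geography each term's covariate is read from
TERM_AREA = {
    "age": "child",
    "sex": "child",
    "race": "child",
    "zip_income_octile": "zip",
    "zip_lifestyle": "zip",
    "zip_urbanization": "zip",
    "county_income_octile": "county",
    "county_urban_rural": "county",
}

#: zip-level term -> the block-group covariate column it transfers onto.
#: Coefficients estimated at the zip level are applied unchanged to block
#: groups (the coefficient-transfer assumption of the predictive model).
ZIP_TO_BG_COLUMN = {
    "zip_income_octile": "income_octile",
    "zip_lifestyle": "lifestyle_class",
    "zip_urbanization": "urbanization_class",
}


def levels(term: str) -> list:
    return TERMS[term][0]


def reference(term: str):
    return TERMS[term][1]


def nonreference_levels(term: str) -> list:
    lv, ref = TERMS[term]
    return [x for x in lv if x != ref]
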
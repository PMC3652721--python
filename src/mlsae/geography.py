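"""Nested area hierarchy (state > county > {zip, block group}) with covariates.

The model uses only membership relations, never coordinates: a child belongs
to a zip, the zip to a county, the county to a state; block groups sit beside
zips under the same counties and carry the covariates onto which zip-level
coefficients are transferred at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import categories as cat


@dataclass
class GeographyFrame:
    """Area hierarchy and per-area categorical covariates.

    Attributes
    ----------
    states : DataFrame with column ``state_id``.
    counties : DataFrame with ``county_id``, ``state_id``, ``income_octile``,
        ``urban_rural_class``.
    zips : DataFrame with ``zip_id``, ``county_id``, ``state_id``,
        ``income_octile``, ``lifestyle_class``, ``urbanization_class``.
    block_groups : same covariate columns as zips, keyed by ``bg_id``.
    """

    states: pd.DataFrame
    counties: pd.DataFrame
    zips: pd.DataFrame
    block_groups: pd.DataFrame

    def validate(self) -> None:
        """Check parentage and covariate ranges; raise ValueError on defects."""
        states = set(self.states["state_id"])
        counties = set(self.counties["county_id"])
        if not set(self.counties["state_id"]) <= states:
            raise ValueError("county with unknown parent state")
        for frame, name in ((self.zips, "zip"), (self.block_groups, "block group")):
            if not set(frame["county_id"]) <= counties:
                raise ValueError(f"{name} with unknown parent county")
            # stored state_id must agree with the county's parent
            parent = self.counties.set_index("county_id")["state_id"]
            if not (frame["state_id"].to_numpy() == parent.loc[frame["county_id"]].to_numpy()).all():
                raise ValueError(f"{name} state_id inconsistent with its county's state")
            if not frame["income_octile"].isin(cat.INCOME_OCTILES).all():
                raise ValueError(f"{name} income octile outside 1-8")
            if not frame["lifestyle_class"].isin(cat.LIFESTYLE_LEVELS).all():
                raise ValueError(f"{name} lifestyle class unknown")
            if not frame["urbanization_class"].isin(cat.URBANIZATION_LEVELS).all():
                raise ValueError(f"{name} urbanization class unknown")
        if not self.counties["income_octile"].isin(cat.INCOME_OCTILES).all():
            raise ValueError("county income octile outside 1-8")
        if not self.counties["urban_rural_class"].isin(cat.URBAN_RURAL_LEVELS).all():
            raise ValueError("county urban-rural class unknown")
        for frame, key in (
            (self.states, "state_id"),
            (self.counties, "county_id"),
            (self.zips, "zip_id"),
            (self.block_groups, "bg_id"),
        ):
            if frame[key].duplicated().any():
                raise ValueError(f"duplicate {key}")

    # -- convenience lookups -------------------------------------------------
    def county_state(self) -> pd.Series:
        return self.counties.set_index("county_id")["state_id"]

    def zip_covariates(self) -> pd.DataFrame:
        return self.zips.set_index("zip_id")

    def bg_covariates(self) -> pd.DataFrame:
        return self.block_groups.set_index("bg_id")

    def county_covariates(self) -> pd.DataFrame:
        return self.counties.set_index("county_id")


def generate_geography(
    n_states: int,
    counties_per_state: int,
    zips_per_county: int,
    bgs_per_county: int,
    seed: int,
    bg_covariate_source: str = "independent",
) -> GeographyFrame:
    """Build a balanced synthetic hierarchy with random area covariates.

    Income octiles are uniform over 1-8; lifestyle, urbanization and county
    urban-rural classes are uniform over their category lists.  Zips and block
    groups are dealt to counties in fixed counts, so the hierarchy is balanced
    by construction.

    Parameters
    ----------
    bg_covariate_source : "independent" or "zip".  With "independent"
        (default) block-group covariates are drawn independently of the zips.
        With "zip", each block group copies the covariates of one of its
        county's zips (cyclically), which makes the zip-to-block-group
        coefficient-transfer assumption hold exactly — useful for calibration
        studies of the prediction pipeline.
    """
    for name, v in (
        ("n_states", n_states),
        ("counties_per_state", counties_per_state),
        ("zips_per_county", zips_per_county),
        ("bgs_per_county", bgs_per_county),
    ):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    if bg_covariate_source not in ("independent", "zip"):
        raise ValueError("bg_covariate_source must be 'independent' or 'zip'")

    rng = np.random.default_rng(seed)
    state_ids = [f"S{i:02d}" for i in range(n_states)]
    n_counties = n_states * counties_per_state
    county_ids = [f"C{i:04d}" for i in range(n_counties)]
    county_state = np.repeat(state_ids, counties_per_state)

    def _sub_covariates(n: int) -> dict:
        return {
            "income_octile": rng.integers(1, 9, size=n),
            "lifestyle_class": rng.choice(cat.LIFESTYLE_LEVELS, size=n),
            "urbanization_class": rng.choice(cat.URBANIZATION_LEVELS, size=n),
        }

    counties = pd.DataFrame(
        {
            "county_id": county_ids,
            "state_id": county_state,
            "income_octile": rng.integers(1, 9, size=n_counties),
            "urban_rural_class": rng.choice(cat.URBAN_RURAL_LEVELS, size=n_counties),
        }
    )

    n_zips = n_counties * zips_per_county
    zips = pd.DataFrame(
        {
            "zip_id": [f"Z{i:05d}" for i in range(n_zips)],
            "county_id": np.repeat(county_ids, zips_per_county),
            "state_id": np.repeat(county_state, zips_per_county),
            **_sub_covariates(n_zips),
        }
    )

    n_bgs = n_counties * bgs_per_county
    block_groups = pd.DataFrame(
        {
            "bg_id": [f"B{i:06d}" for i in range(n_bgs)],
            "county_id": np.repeat(county_ids, bgs_per_county),
            "state_id": np.repeat(county_state, bgs_per_county),
            **_sub_covariates(n_bgs),
        }
    )
    if bg_covariate_source == "zip":
        # bg j within its county copies zip (j mod zips_per_county)
        within = np.tile(np.arange(bgs_per_county), n_counties) % zips_per_county
        src = np.repeat(np.arange(n_counties) * zips_per_county, bgs_per_county) + within
        for col in ("income_octile", "lifestyle_class", "urbanization_class"):
            block_groups[col] = zips[col].to_numpy()[src]

    geo = GeographyFrame(
        states=pd.DataFrame({"state_id": state_ids}),
        counties=counties,
        zips=zips,
        block_groups=block_groups,
    )
    geo.validate()
    return geo
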
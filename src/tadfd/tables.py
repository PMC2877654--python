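"""Site-level data containers: community presence and habitat tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CommunityTable", "HabitatTable", "HABITAT_VARIABLES", "MICROHABITAT_VARIABLES"]

#: The 14 habitat variables recorded per 30 m stream section: nine
#: stream (tadpole-relevant) variables, four forest (adult-frog)
#: variables, and riparian vegetation structure.
HABITAT_VARIABLES = (
    "width",
    "slope",
    "canopy_cover",
    "leaves",
    "sand",
    "gravel",
    "rock",
    "dragonfly_larvae",
    "mayfly_larvae",
    "forest_shrubs",
    "forest_trees",
    "forest_canopy_cover",
    "leaf_litter",
    "riparian_vegetation",
)

#: Ground-substrate proportions; together they cover 100 % of a site.
MICROHABITAT_VARIABLES = ("leaves", "sand", "gravel", "rock")


@dataclass(frozen=True)
class CommunityTable:
    """Site-by-species presence/absence matrix.

    Species richness (SR) per site is the row sum; every site must hold
    at least one species and species columns index into the regional
    pool (the rows of the trait matrix).
    """

    site_ids: tuple
    species_ids: tuple
    presence: np.ndarray

    def __post_init__(self):
        P = np.asarray(self.presence)
        if P.dtype != bool:
            if not np.all(np.isin(P, (0, 1))):
                raise ValueError("presence matrix must be binary")
            P = P.astype(bool)
        object.__setattr__(self, "presence", P)
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        if P.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValueError("presence shape does not match site/species labels")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site ids")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise ValueError("duplicate species ids")
        if np.any(P.sum(axis=1) < 1):
            raise ValueError("every site must contain at least one species")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def sr(self) -> np.ndarray:
        """Species richness per site."""
        return self.presence.sum(axis=1).astype(int)

    def members(self, site) -> tuple:
        i = self.site_ids.index(site)
        return tuple(s for s, p in zip(self.species_ids, self.presence[i]) if p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.presence.astype(int), index=list(self.site_ids),
            columns=list(self.species_ids),
        ).rename_axis("site")


@dataclass(frozen=True)
class HabitatTable:
    """Per-site habitat variables (the 14-column stream/forest table)."""

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        missing = [v for v in HABITAT_VARIABLES if v not in df.columns]
        if missing:
            raise ValueError(f"habitat table is missing variables: {missing}")
        df = df.loc[:, list(HABITAT_VARIABLES)].astype(float)
        if df.isna().any().any():
            raise ValueError("habitat table contains missing values")
        micro = df.loc[:, list(MICROHABITAT_VARIABLES)]
        if (micro.values < 0).any() or (micro.values > 100).any():
            raise ValueError("microhabitat percentages must lie in [0, 100]")
        if not np.allclose(micro.sum(axis=1), 100.0, atol=1e-6):
            raise ValueError("microhabitat percentages must sum to 100 per site")
        object.__setattr__(self, "df", df)

    @property
    def site_ids(self) -> tuple:
        return tuple(self.df.index)
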
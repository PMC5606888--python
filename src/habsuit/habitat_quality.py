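"""Point-Quarter transect estimators and the browse-weighted habitat index.

Stem density from Pollard's unbiased plotless estimator, per-species
composition and basal area, a configurable browse-class-weighted habitat
quality index, and its per-subregion regression against modelled
suitability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransectSample",
    "HabitatQualityIndex",
    "point_quarter_density",
    "species_composition",
    "species_basal_area",
    "habitat_quality_index",
    "site_habitat_quality",
    "regress_index",
    "DEFAULT_BROWSE_WEIGHTS",
]

logger = logging.getLogger(__name__)

DEFAULT_BROWSE_WEIGHTS = {1: 3.0, 2: 2.0, 3: 1.0, 4: 0.0}
TRUNCATION_DISTANCE_M = 50.0  # stands in for an empty quadrant


@dataclass
class TransectSample:
    """Point-Quarter measurements: one row per (station, quadrant) tree.

    Columns: station, quadrant, distance_m, species, dbh_cm (and optionally
    height_m).  An empty quadrant is flagged by a missing distance and is
    replaced by the truncation distance in density estimation.
    """

    site: str
    trees: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.trees).copy()
        required = ["station", "quadrant", "distance_m", "species", "dbh_cm"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"transect table missing column {col!r}")
        d = df["distance_m"].to_numpy(dtype=float)
        if np.any(d[~np.isnan(d)] <= 0):
            raise ValueError("distances must be positive")
        self.trees = df.reset_index(drop=True)

    @property
    def n_stations(self) -> int:
        return self.trees["station"].nunique()

    def found_trees(self) -> pd.DataFrame:
        return self.trees[~self.trees["distance_m"].isna()]


def point_quarter_density(transect: TransectSample) -> float:
    """Stems per hectare via Pollard's unbiased estimator
    lambda = 4(4n - 1) / (pi * sum r^2) with n the station count.

    Empty quadrants contribute the 50-m truncation distance rather than
    dropping the station (dropping would bias density upward).
    """
    df = transect.trees
    n = transect.n_stations
    if n < 1:
        raise ValueError("need at least one complete station")
    r = df["distance_m"].to_numpy(dtype=float)
    n_empty = int(np.isnan(r).sum())
    if n_empty:
        logger.warning(
            "site %s: %d empty quadrants substituted with %.0f m truncation",
            transect.site, n_empty, TRUNCATION_DISTANCE_M,
        )
        r = np.where(np.isnan(r), TRUNCATION_DISTANCE_M, r)
    if len(r) != 4 * n:
        raise ValueError("expected 4 quadrant records per station")
    lam_per_m2 = 4.0 * (4.0 * n - 1.0) / (np.pi * np.sum(r**2))
    return float(lam_per_m2 * 1e4)


def species_composition(transect: TransectSample) -> pd.DataFrame:
    """Per-species percent occurrence, mean dbh and mean per-stem basal area
    (m^2) among the measured trees."""
    df = transect.found_trees()
    if df.empty:
        raise ValueError("no trees measured on transect")
    if (df["species"].astype(str).str.len() == 0).any():
        raise ValueError("empty species name")
    total = len(df)
    rows = []
    for sp, grp in df.groupby("species", sort=True):
        dbh_m = grp["dbh_cm"].to_numpy(dtype=float) / 100.0
        rows.append(
            {
                "species": sp,
                "pct_occurrence": 100.0 * len(grp) / total,
                "mean_dbh_cm": float(grp["dbh_cm"].mean()),
                "mean_basal_area_m2": float(np.mean(np.pi * (dbh_m / 2.0) ** 2)),
            }
        )
    return pd.DataFrame(rows)


def species_basal_area(density: float, composition: pd.DataFrame) -> pd.DataFrame:
    """Per-species basal area (m^2/ha):
    density x proportion occurrence x mean per-stem basal area."""
    out = composition.copy()
    out["basal_area_m2_ha"] = (
        density * (out["pct_occurrence"] / 100.0) * out["mean_basal_area_m2"]
    )
    return out


@dataclass
class HabitatQualityIndex:
    site: str
    class_basal_area: dict[int, float]
    richness_bonus: float
    index: float
    weights: dict[int, float] = field(default_factory=dict)


def habitat_quality_index(
    basal_area: pd.DataFrame,
    browse_classes: dict[str, int],
    weights: dict[int, float] | None = None,
    diversity_bonus: float = 0.1,
    site: str = "",
) -> HabitatQualityIndex:
    """Browse-weighted basal-area index.

    index = sum_c weight_c * BA_c, times (1 + diversity_bonus * extra
    class-1/2 species beyond the first), capped at a 1.5x multiplier.
    Unmapped species fall to class 4 (unsuitable) with a warning.
    """
    if weights is None:
        weights = dict(DEFAULT_BROWSE_WEIGHTS)
    if any(w < 0 for w in weights.values()):
        raise ValueError("browse weights must be non-negative")
    class_ba: dict[int, float] = {c: 0.0 for c in (1, 2, 3, 4)}
    prime_species = set()
    for _, row in basal_area.iterrows():
        sp = row["species"]
        if sp in browse_classes:
            cls = int(browse_classes[sp])
        else:
            logger.warning("species %r not in browse map; assigned class 4", sp)
            cls = 4
        class_ba[cls] = class_ba.get(cls, 0.0) + float(row["basal_area_m2_ha"])
        if cls in (1, 2):
            prime_species.add(sp)
    base = sum(weights.get(c, 0.0) * ba for c, ba in class_ba.items())
    richness = len(prime_species)
    bonus = min(1.0 + diversity_bonus * max(0, richness - 1), 1.5)
    return HabitatQualityIndex(site, class_ba, bonus, base * bonus, dict(weights))


def site_habitat_quality(
    transect: TransectSample,
    browse_classes: dict[str, int],
    weights: dict[int, float] | None = None,
    diversity_bonus: float = 0.1,
) -> HabitatQualityIndex:
    """Convenience chain: density -> composition -> basal area -> index."""
    dens = point_quarter_density(transect)
    comp = species_composition(transect)
    ba = species_basal_area(dens, comp)
    return habitat_quality_index(
        ba, browse_classes, weights, diversity_bonus, site=transect.site
    )


def regress_index(
    index: np.ndarray,
    suitability: np.ndarray,
    subregion: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-subregion OLS of the habitat-quality index on suitability;
    reports slope, r^2 and the two-sided slope-test p value."""
    index = np.asarray(index, dtype=float)
    suitability = np.asarray(suitability, dtype=float)
    if subregion is None:
        subregion = np.zeros(len(index), dtype=int)
    subregion = np.asarray(subregion)
    rows = []
    for sub in np.unique(subregion):
        sel = subregion == sub
        x, y = suitability[sel], index[sel]
        if len(x) < 3:
            raise ValueError(f"subregion {sub!r} has fewer than 3 sites")
        res = stats.linregress(x, y)
        rows.append(
            {
                "subregion": sub,
                "n": int(sel.sum()),
                "slope": res.slope,
                "intercept": res.intercept,
                "r_squared": res.rvalue**2,
                "p_value": res.pvalue,
            }
        )
    return pd.DataFrame(rows)
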
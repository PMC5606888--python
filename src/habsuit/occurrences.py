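"""Occurrence record preparation.

Cleaning against a cleared-land mask, elevational subregion splitting,
replicated random spatial thinning, and collinearity screening of the
predictor stack.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import PredictorStack, Raster

__all__ = [
    "OccurrenceSet",
    "ThinnedReplicates",
    "clean_records",
    "split_subregions",
    "thin_occurrences",
    "make_replicates",
    "screen_predictors",
]

logger = logging.getLogger(__name__)

OCCURRENCE_COLUMNS = ["x", "y", "accuracy_m", "date", "source"]


@dataclass
class OccurrenceSet:
    """Point records with positional accuracy in a projected CRS (metres)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        for col in OCCURRENCE_COLUMNS:
            if col not in df.columns:
                if col == "accuracy_m":
                    df[col] = 50.0
                elif col in ("date", "source"):
                    df[col] = ""
                else:
                    raise ValueError(f"occurrence table missing column {col!r}")
        df = df[OCCURRENCE_COLUMNS].reset_index(drop=True)
        if len(df):
            xy = df[["x", "y"]].to_numpy(dtype=float)
            if not np.all(np.isfinite(xy)):
                raise ValueError("non-finite coordinates in occurrence set")
            acc = df["accuracy_m"].to_numpy(dtype=float)
            if np.any(acc <= 0):
                raise ValueError("accuracy must be positive")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def xy(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(dtype=float)

    def take(self, idx) -> "OccurrenceSet":
        return OccurrenceSet(self.records.iloc[np.asarray(idx, dtype=int)])

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "OccurrenceSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | os.PathLike) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def concat(cls, sets: list["OccurrenceSet"]) -> "OccurrenceSet":
        frames = [s.records for s in sets if len(s)]
        if not frames:
            return cls(pd.DataFrame(columns=OCCURRENCE_COLUMNS))
        return cls(pd.concat(frames, ignore_index=True))


@dataclass
class ThinnedReplicates:
    replicates: list[OccurrenceSet]
    holdout: OccurrenceSet
    min_dist: float
    seeds: list[int] = field(default_factory=list)


def clean_records(
    records: OccurrenceSet, cleared_mask: Raster, max_accuracy: float = 100.0
) -> OccurrenceSet:
    """Drop records in cleared cells or with accuracy above ``max_accuracy``.

    ``cleared_mask`` is 1 in cleared cells, 0 in retained (e.g. forested)
    cells.  Records outside the raster extent are rejected and counted in a
    warning, not raised.
    """
    if max_accuracy <= 0:
        raise ValueError("max_accuracy must be positive")
    if len(records) == 0:
        return records
    acc_ok = records.records["accuracy_m"].to_numpy(dtype=float) <= max_accuracy
    x, y = records.xy.T
    row, col = cleared_mask.grid.point_to_rowcol(x, y)
    in_extent = (row >= 0) & (col >= 0)
    n_outside = int(np.sum(~in_extent))
    if n_outside:
        logger.warning("%d records outside raster extent rejected", n_outside)
    cleared = np.zeros(len(records), dtype=bool)
    ok = in_extent.copy()
    cleared[in_extent] = cleared_mask.values[row[in_extent], col[in_extent]] > 0
    keep = acc_ok & ok & ~cleared
    return records.take(np.flatnonzero(keep))


def split_subregions(
    records: OccurrenceSet, dem: Raster, threshold: float = 500.0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Partition records at an elevation threshold (strictly below vs at-or-above).

    Records outside the DEM extent or on nodata cells go to neither subset.
    """
    if len(records) == 0:
        return records, records
    x, y = records.xy.T
    elev = dem.sample(x, y)
    n_bad = int(np.sum(np.isnan(elev)))
    if n_bad:
        logger.warning("%d records on nodata/out-of-extent DEM cells excluded", n_bad)
    low = records.take(np.flatnonzero(elev < threshold))
    high = records.take(np.flatnonzero(elev >= threshold))
    return low, high


def thin_occurrences(
    records: OccurrenceSet, min_dist: float = 2000.0, seed: int = 0
) -> OccurrenceSet:
    """Greedy random-order spatial thinning.

    Shuffle with the seed, then accept each record at least ``min_dist``
    (inclusive) from all previously accepted ones.  The result is maximal
    under the random order: every rejected record is within ``min_dist`` of
    some accepted record.
    """
    if min_dist <= 0:
        raise ValueError("min_dist must be positive")
    n = len(records)
    if n <= 1:
        return records
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    xy = records.xy
    accepted: list[int] = []
    acc_xy = np.empty((n, 2))
    d2 = min_dist * min_dist
    for i in order:
        k = len(accepted)
        if k:
            diff = acc_xy[:k] - xy[i]
            if np.min(diff[:, 0] ** 2 + diff[:, 1] ** 2) < d2:
                continue
        acc_xy[k] = xy[i]
        accepted.append(int(i))
    return records.take(sorted(accepted))


def make_replicates(
    records: OccurrenceSet,
    n_rep: int = 5,
    min_dist: float = 2000.0,
    seeds: list[int] | None = None,
) -> ThinnedReplicates:
    """Draw ``n_rep`` independently thinned sets; the holdout is everything
    that appears in none of them."""
    if seeds is None:
        seeds = list(range(n_rep))
    if len(seeds) != n_rep:
        raise ValueError("seeds must have length n_rep")
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seeds would produce coincident replicates")
    used = np.zeros(len(records), dtype=bool)
    reps = []
    xy = records.xy
    for s in seeds:
        rep = thin_occurrences(records, min_dist, s)
        reps.append(rep)
        # identify indices of retained rows by positional match
        idx = _match_rows(xy, rep.xy)
        used[idx] = True
    holdout = records.take(np.flatnonzero(~used))
    return ThinnedReplicates(reps, holdout, min_dist, list(seeds))


def _match_rows(all_xy: np.ndarray, sub_xy: np.ndarray) -> np.ndarray:
    """Positional indices in ``all_xy`` of the rows present in ``sub_xy``."""
    order = np.lexsort(all_xy.T)
    srt = all_xy[order]
    out = []
    for pt in sub_xy:
        lo = np.searchsorted(srt[:, 1], pt[1], side="left")
        hi = np.searchsorted(srt[:, 1], pt[1], side="right")
        block = srt[lo:hi]
        hits = order[lo:hi][np.flatnonzero(block[:, 0] == pt[0])]
        out.extend(int(h) for h in hits)
    return np.unique(out)


def screen_predictors(
    stack: PredictorStack,
    threshold: float = 0.75,
    priority: list[str] | None = None,
) -> list[str]:
    """Greedy collinearity filter on continuous layers.

    Walk the priority list; retain a layer only if its absolute Pearson
    correlation with every already-retained continuous layer is at or below
    the threshold.  Correlations use cells valid in all compared layers.
    Categorical layers pass through untouched; constant layers are dropped.
    """
    cont = stack.continuous_names()
    if not cont:
        raise ValueError("stack has no continuous layers")
    if priority is None:
        priority = cont
    missing = set(cont) - set(priority)
    if missing:
        raise ValueError(f"priority list missing continuous layers: {sorted(missing)}")
    mask = stack.mask
    cols = {n: stack.layers[n].values[mask] for n in cont}
    retained: list[str] = []
    for name in priority:
        if name not in cols:
            continue
        v = cols[name]
        if np.std(v) == 0:
            logger.warning("constant layer %r dropped from screening", name)
            continue
        ok = True
        for kept in retained:
            r = np.corrcoef(v, cols[kept])[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            retained.append(name)
    # preserve original stack ordering in the output, categoricals included
    keep = set(retained) | set(stack.categorical_names())
    return [n for n in stack.names if n in keep]
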
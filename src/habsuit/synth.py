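"""Synthetic landscapes, occurrences, detection histories and transects.

Everything the pipeline consumes can be generated here with a known truth,
so each stage is testable end-to-end without any field data: smoothed
Gaussian random field predictors, a known logistic suitability function,
observer-biased presence sampling, Bernoulli detection histories, and
Poisson tree point-patterns measured with the Point-Quarter protocol.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .habitat_quality import TransectSample
from .occupancy import DetectionHistory
from .occurrences import OccurrenceSet
from .raster import Grid, PredictorStack, Raster, write_raster

__all__ = [
    "SyntheticTruth",
    "gen_landscape",
    "gen_occurrences",
    "gen_histories",
    "gen_transects",
    "simulate_bundle",
    "DEFAULT_SPECIES_POOL",
]

DEFAULT_PSI_COEF = (-2.0, 4.0)  # logit-linear in true suitability
DEFAULT_P_BY_TRIP = (0.43, 0.36, 0.30)
DEFAULT_SPECIES_POOL = {
    "redgum": 1,
    "tallowwood": 1,
    "greygum": 2,
    "blackbutt": 3,
    "turpentine": 4,
    "brushbox": 4,
}


@dataclass
class SyntheticTruth:
    """The generating process: kept beside outputs, read only by tests."""

    suitability: Raster
    coefficients: dict[str, float]
    psi_coef: tuple[float, float] = DEFAULT_PSI_COEF
    p_by_trip: tuple[float, ...] = DEFAULT_P_BY_TRIP
    cleared: Raster | None = None
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def psi(self, suit: np.ndarray) -> np.ndarray:
        b0, b1 = self.psi_coef
        return expit(b0 + b1 * np.asarray(suit, dtype=float))

    def save(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_raster(self.suitability, os.path.join(outdir, "true_suitability.asc"))
        if self.cleared is not None:
            write_raster(self.cleared, os.path.join(outdir, "cleared.asc"))
        payload = {
            "coefficients": self.coefficients,
            "psi_coef": list(self.psi_coef),
            "p_by_trip": list(self.p_by_trip),
            "seed": self.seed,
            "meta": self.meta,
        }
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(payload, fh, indent=1)


def _random_field(rng, shape, correlation_length: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian white noise."""
    z = rng.standard_normal(shape)
    if correlation_length > 0:
        z = gaussian_filter(z, sigma=correlation_length, mode="wrap")
        z = (z - z.mean()) / z.std()
    return z


def gen_landscape(
    size: int = 200,
    n_continuous: int = 3,
    n_categorical: int = 2,
    correlation_length: float = 8.0,
    seed: int = 0,
    cellsize: float = 250.0,
    cleared_fraction: float = 0.1,
) -> tuple[PredictorStack, SyntheticTruth]:
    """Predictor stack with known true suitability.

    Continuous layers are standardized smoothed random fields; categorical
    layers come from quantile-thresholding independent fields (the first
    soil-like with 6 levels, subsequent fire-like with 4).  A 'dem' layer
    ramps west-to-east with smoothed noise so the 500-m subregion split is
    non-trivial.  True suitability is the inverse logit of a sparse linear
    + hinge combination of the first two continuous layers and the dem.
    """
    rng = np.random.default_rng(seed)
    grid = Grid(0.0, 0.0, cellsize, size, size)
    stack = PredictorStack()

    conts = []
    for i in range(n_continuous):
        z = _random_field(rng, (size, size), correlation_length)
        conts.append(z)
        stack.add(f"cont_{i + 1}", Raster(z, grid), "continuous")

    ramp = np.tile(np.linspace(0.0, 1000.0, size), (size, 1))
    dem = ramp + 120.0 * _random_field(rng, (size, size), correlation_length)
    dem = np.clip(dem, 0.0, None)
    stack.add("dem", Raster(dem, grid), "continuous")

    n_levels = [6, 4] + [4] * max(0, n_categorical - 2)
    for i in range(n_categorical):
        z = _random_field(rng, (size, size), correlation_length)
        k = n_levels[i]
        edges = np.quantile(z, np.linspace(0, 1, k + 1)[1:-1])
        stack.add(f"cat_{i + 1}", Raster(np.digitize(z, edges).astype(float), grid),
                  "categorical")

    coef = {"intercept": -1.0, "cont_1": 3.0, "cont_2_hinge": 2.0, "dem": -2.0}
    dem_z = (dem - dem.mean()) / dem.std()
    lin = (
        coef["intercept"]
        + coef["cont_1"] * conts[0]
        + coef["cont_2_hinge"] * np.maximum(0.0, conts[1] if n_continuous > 1 else 0.0)
        + coef["dem"] * dem_z
    )
    suit = Raster(expit(lin), grid)

    cleared_field = _random_field(rng, (size, size), max(correlation_length, 2.0))
    thresh = np.quantile(cleared_field, 1.0 - cleared_fraction)
    cleared = Raster((cleared_field > thresh).astype(float), grid)

    truth = SyntheticTruth(
        suitability=suit,
        coefficients=coef,
        cleared=cleared,
        seed=seed,
        meta={"size": size, "correlation_length": correlation_length,
              "cellsize": cellsize},
    )
    return stack, truth


def gen_occurrences(
    truth: SyntheticTruth,
    n_presence: int = 1000,
    observer_bias: Raster | None = None,
    seed: int = 0,
    accuracy_m: float = 50.0,
) -> OccurrenceSet:
    """Presences drawn cellwise with probability proportional to
    suitability x observer bias, jittered uniformly within cells."""
    rng = np.random.default_rng(seed)
    suit = truth.suitability
    mask = suit.mask
    if observer_bias is not None:
        mask = mask & observer_bias.mask
    rows, cols = np.nonzero(mask)
    w = suit.values[rows, cols].astype(float)
    if observer_bias is not None:
        w = w * observer_bias.values[rows, cols]
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    idx = rng.choice(len(rows), size=n_presence, replace=True, p=w)
    g = suit.grid
    x = g.xll + (cols[idx] + rng.random(n_presence)) * g.cellsize
    y = g.yll + (g.nrows - rows[idx] - rng.random(n_presence)) * g.cellsize
    return OccurrenceSet(
        pd.DataFrame(
            {
                "x": x,
                "y": y,
                "accuracy_m": accuracy_m,
                "date": "2015-10-01",
                "source": "synthetic",
            }
        )
    )


def gen_histories(
    truth: SyntheticTruth,
    n_sites: int = 65,
    occasions: int = 7,
    p_by_trip: tuple[float, ...] | None = None,
    seed: int = 0,
    n_failed: int = 0,
    n_strata: int = 4,
) -> tuple[DetectionHistory, pd.DataFrame]:
    """Detection histories at sites stratified across suitability quantiles.

    Sites are assigned round-robin to trips; occupancy is Bernoulli of the
    truth's logit-linear psi; detections are Bernoulli(p_trip) at occupied
    sites.  ``n_failed`` recorders become all-missing rows.  Returns the
    history plus a per-site frame (x, y, suitability, trip, occupied).
    """
    if p_by_trip is None:
        p_by_trip = truth.p_by_trip
    rng = np.random.default_rng(seed)
    suit = truth.suitability
    rows, cols = np.nonzero(suit.mask)
    vals = suit.values[rows, cols]
    qs = np.quantile(vals, np.linspace(0, 1, n_strata + 1))
    strata = np.clip(np.digitize(vals, qs[1:-1]), 0, n_strata - 1)

    chosen: list[int] = []
    per = [n_sites // n_strata] * n_strata
    for i in range(n_sites - sum(per)):
        per[i % n_strata] += 1
    for s in range(n_strata):
        pool = np.flatnonzero(strata == s)
        take = min(per[s], len(pool))
        chosen.extend(rng.choice(pool, size=take, replace=False))
    while len(chosen) < n_sites:  # degenerate strata fallback
        chosen.append(int(rng.integers(len(rows))))
    chosen = np.asarray(chosen[:n_sites])

    g = suit.grid
    site_suit = vals[chosen]
    x = g.xll + (cols[chosen] + 0.5) * g.cellsize
    y = g.yll + (g.nrows - rows[chosen] - 0.5) * g.cellsize

    psi = truth.psi(site_suit)
    occupied = rng.random(n_sites) < psi
    trip = np.arange(n_sites) % len(p_by_trip)
    p_site = np.asarray(p_by_trip)[trip]
    dets = (rng.random((n_sites, occasions)) < p_site[:, None]) & occupied[:, None]
    yh = dets.astype(float)
    if n_failed > 0:
        failed = rng.choice(n_sites, size=min(n_failed, n_sites), replace=False)
        yh[failed] = np.nan

    trip_labels = np.array([f"trip{t + 1}" for t in trip])
    site_cov = pd.DataFrame(
        {"x": x, "y": y, "suitability": site_suit, "trip": trip_labels,
         "occupied": occupied.astype(int)}
    )
    rain = np.round(rng.gamma(0.6, 6.0, size=(n_sites, occasions)), 1)
    hist = DetectionHistory(
        yh,
        site_covariates=site_cov[["suitability"]].copy(),
        occasion_covariates={
            "trip": np.tile(trip_labels[:, None], (1, occasions)),
            "rainfall": rain,
        },
    )
    return hist, site_cov


def _class_weights(suit: float) -> dict[int, float]:
    """Browse-class mixture shifting toward classes 1-2 as suitability rises."""
    w = {
        1: 0.05 + 0.55 * suit,
        2: 0.15 + 0.15 * suit,
        3: 0.30 - 0.15 * suit,
        4: max(0.05, 0.50 - 0.55 * suit),
    }
    total = sum(w.values())
    return {c: v / total for c, v in w.items()}


def gen_transects(
    truth: SyntheticTruth | None,
    sites: pd.DataFrame,
    stems_per_ha: float = 300.0,
    species_pool: dict[str, int] | None = None,
    seed: int = 0,
    n_stations: int = 10,
    station_spacing: float = 20.0,
    dbh_median_cm: float = 35.0,
    dbh_sigma: float = 0.3,
) -> list[TransectSample]:
    """Point-Quarter samples of homogeneous Poisson tree patterns.

    ``sites`` needs columns ``site`` (or an index) and ``suitability``.  The
    intensity refers to measurable trees (dbh > 20 cm); dbh is lognormal
    with the stated median, resampled away from the <= 20 cm tail.  Species
    are multinomial with the class-1/2 share increasing in suitability.
    """
    if species_pool is None:
        species_pool = dict(DEFAULT_SPECIES_POOL)
    by_class: dict[int, list[str]] = {}
    for sp, c in species_pool.items():
        by_class.setdefault(int(c), []).append(sp)
    rng = np.random.default_rng(seed)
    out: list[TransectSample] = []

    length = (n_stations - 1) * station_spacing
    buf = 60.0
    x0, x1 = -buf, length + buf
    y0, y1 = -buf, buf
    area = (x1 - x0) * (y1 - y0)
    lam = stems_per_ha / 1e4

    for irow, row in sites.reset_index().iterrows():
        site = str(row["site"]) if "site" in row else f"site{irow + 1}"
        suit = float(row["suitability"])
        n_trees = rng.poisson(lam * area)
        tx = rng.uniform(x0, x1, n_trees)
        ty = rng.uniform(y0, y1, n_trees)
        cw = _class_weights(suit)
        classes = [c for c in sorted(by_class)]
        probs = np.array([cw.get(c, 0.0) for c in classes])
        probs /= probs.sum()
        tree_class = rng.choice(classes, size=n_trees, p=probs)
        species = np.array(
            [by_class[c][rng.integers(len(by_class[c]))] for c in tree_class]
        )
        dbh = rng.lognormal(np.log(dbh_median_cm), dbh_sigma, n_trees)
        while np.any(dbh <= 20.0):  # intensity counts measurable trees only
            bad = dbh <= 20.0
            dbh[bad] = rng.lognormal(np.log(dbh_median_cm), dbh_sigma, bad.sum())

        recs = []
        for s in range(n_stations):
            sx = s * station_spacing
            dx = tx - sx
            dy = ty
            quadmask = {
                1: (dx >= 0) & (dy >= 0),
                2: (dx < 0) & (dy >= 0),
                3: (dx < 0) & (dy < 0),
                4: (dx >= 0) & (dy < 0),
            }
            for q, qm in quadmask.items():
                if np.any(qm):
                    d2 = dx[qm] ** 2 + dy[qm] ** 2
                    j = np.argmin(d2)
                    idx = np.flatnonzero(qm)[j]
                    recs.append(
                        {
                            "station": s + 1,
                            "quadrant": q,
                            "distance_m": float(np.sqrt(d2[j])),
                            "species": species[idx],
                            "dbh_cm": float(dbh[idx]),
                        }
                    )
                else:
                    recs.append(
                        {
                            "station": s + 1,
                            "quadrant": q,
                            "distance_m": np.nan,
                            "species": "",
                            "dbh_cm": np.nan,
                        }
                    )
        out.append(TransectSample(site, pd.DataFrame(recs)))
    return out


def simulate_bundle(
    outdir: str | os.PathLike,
    seed: int = 0,
    size: int = 120,
    n_presence: int = 1500,
    n_target_group: int = 1500,
    n_sites: int = 65,
    n_failed: int = 2,
    stems_per_ha: float = 300.0,
    correlation_length: float = 8.0,
) -> dict:
    """Write a full synthetic input bundle (rasters, CSVs, truth) to a
    directory and return the paths."""
    rng = np.random.default_rng(seed)
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    stack, truth = gen_landscape(
        size=size, correlation_length=correlation_length, seed=int(rng.integers(2**31))
    )
    # observer bias pulled toward an "urban" corner
    g = stack.grid
    cx, cy = g.cell_centers()
    urban = np.exp(
        -((cx - g.xll) ** 2 + (cy - g.yll) ** 2)
        / (2 * (0.3 * size * g.cellsize) ** 2)
    )
    observer_bias = Raster(1.0 + 29.0 * urban / urban.max(), g)

    occ = gen_occurrences(truth, n_presence, observer_bias, seed=int(rng.integers(2**31)))
    target = gen_occurrences(truth, n_target_group, observer_bias,
                             seed=int(rng.integers(2**31)))
    hist, site_cov = gen_histories(truth, n_sites=n_sites, n_failed=n_failed,
                                   seed=int(rng.integers(2**31)))
    sites = site_cov.copy()
    sites.insert(0, "site", [f"site{i + 1}" for i in range(len(sites))])
    transects = gen_transects(truth, sites, stems_per_ha,
                              seed=int(rng.integers(2**31)))

    paths = {}
    rasters = dict(stack.layers)
    rasters["observer_bias"] = observer_bias
    stack_dir = os.path.join(outdir, "stack")
    os.makedirs(stack_dir, exist_ok=True)
    for name, r in stack.layers.items():
        p = os.path.join(stack_dir, f"{name}.asc")
        write_raster(r, p)
        paths[name] = p
    write_raster(observer_bias, os.path.join(outdir, "observer_bias.asc"))
    with open(os.path.join(stack_dir, "kinds.json"), "w") as fh:
        json.dump(stack.kinds, fh, indent=1)

    occ.to_csv(os.path.join(outdir, "occurrences.csv"))
    target.to_csv(os.path.join(outdir, "target_group.csv"))

    hist_df = pd.DataFrame(
        hist.y, columns=[f"night_{t + 1}" for t in range(hist.n_occasions)]
    )
    hist_df.insert(0, "site", sites["site"])
    hist_df.to_csv(os.path.join(outdir, "detection_history.csv"), index=False,
                   na_rep="NA")
    sites.to_csv(os.path.join(outdir, "sites.csv"), index=False)
    rain = pd.DataFrame(hist.occasion_covariates["rainfall"],
                        columns=[f"night_{t + 1}" for t in range(hist.n_occasions)])
    rain.insert(0, "site", sites["site"])
    rain.to_csv(os.path.join(outdir, "rainfall.csv"), index=False)

    rows = []
    for t in transects:
        df = t.trees.copy()
        df.insert(0, "site", t.site)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(
        os.path.join(outdir, "transects.csv"), index=False
    )
    pd.DataFrame(
        {"species": list(DEFAULT_SPECIES_POOL), "class": list(DEFAULT_SPECIES_POOL.values())}
    ).to_csv(os.path.join(outdir, "browse_classes.csv"), index=False)

    truth.save(os.path.join(outdir, "truth"))
    if truth.cleared is not None:
        write_raster(truth.cleared, os.path.join(outdir, "cleared.asc"))
    paths.update(
        {
            "outdir": outdir,
            "stack_dir": stack_dir,
            "occurrences": os.path.join(outdir, "occurrences.csv"),
            "target_group": os.path.join(outdir, "target_group.csv"),
            "detection_history": os.path.join(outdir, "detection_history.csv"),
            "sites": os.path.join(outdir, "sites.csv"),
            "transects": os.path.join(outdir, "transects.csv"),
            "truth": os.path.join(outdir, "truth"),
        }
    )
    return paths
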
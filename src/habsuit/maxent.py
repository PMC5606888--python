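"""Regularized maximum-entropy presence-background modelling.

Hinge feature basis over continuous predictors plus level indicators for
categorical predictors; L1-penalised log-loss minimised by cyclic
coordinate descent with backtracking; logistic output calibrated by the
entropy of the fitted raw distribution.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .bias import BiasSurface
from .occurrences import OccurrenceSet
from .raster import PredictorStack, Raster

__all__ = [
    "Feature",
    "HingeBasis",
    "MaxentModel",
    "sample_background",
    "build_features",
    "fit_maxent",
    "presence_background_auc",
    "run_replicates",
    "average_sets",
    "percent_contribution",
    "response_curve",
    "class_frequency",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Feature:
    """One basis function derived from a single source variable.

    kind 'fwd':  max(0, (x - knot) / (x_max - knot))
    kind 'rev':  max(0, (knot - x) / (knot - x_min))
    kind 'cat':  indicator(x == level)
    """

    variable: str
    kind: str
    knot: float = 0.0
    x_min: float = 0.0
    x_max: float = 1.0

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "fwd":
            return np.maximum(0.0, (x - self.knot) / (self.x_max - self.knot))
        if self.kind == "rev":
            return np.maximum(0.0, (self.knot - x) / (self.knot - self.x_min))
        if self.kind == "cat":
            return (x == self.knot).astype(float)
        raise ValueError(f"unknown feature kind {self.kind!r}")


@dataclass
class HingeBasis:
    features: list[Feature]

    def __len__(self) -> int:
        return len(self.features)

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            if f.variable not in seen:
                seen.append(f.variable)
        return seen

    def design_matrix(self, table: dict[str, np.ndarray]) -> np.ndarray:
        """Evaluate all features on a dict of per-variable value arrays."""
        cols = [f.evaluate(table[f.variable]) for f in self.features]
        return np.column_stack(cols) if cols else np.empty((0, 0))


def build_features(
    stack_kinds: dict[str, str],
    background: dict[str, np.ndarray],
    knots_per_variable: int = 50,
) -> HingeBasis:
    """Place forward/reverse hinge knots at equally spaced quantiles of each
    continuous variable over the background; categorical levels observed in
    the background become indicators."""
    if knots_per_variable < 1:
        raise ValueError("knots_per_variable must be >= 1")
    feats: list[Feature] = []
    for name, kind in stack_kinds.items():
        x = np.asarray(background[name], dtype=float)
        x = x[np.isfinite(x)]
        if kind == "categorical":
            for level in np.unique(x):
                feats.append(Feature(name, "cat", float(level)))
            continue
        x_min, x_max = float(x.min()), float(x.max())
        if x_max == x_min:
            logger.warning("variable %r constant over background; no features", name)
            continue
        k = min(knots_per_variable, max(1, len(np.unique(x)) - 1))
        probs = (np.arange(k) + 1.0) / (k + 1.0)
        knots = np.unique(np.quantile(x, probs))
        for knot in knots:
            if knot < x_max:
                feats.append(Feature(name, "fwd", float(knot), x_min, x_max))
            if knot > x_min:
                feats.append(Feature(name, "rev", float(knot), x_min, x_max))
    return HingeBasis(feats)


@dataclass
class MaxentModel:
    """Fitted weights plus the background normaliser and entropy.

    raw density over the background: q_i = exp(eta_i - log_z); the entropy
    H of q calibrates the logistic transform so that a cell with raw
    density exp(-H) scores 0.5.
    """

    basis: HingeBasis
    lam: np.ndarray
    beta: np.ndarray
    log_z: float
    entropy: float
    gain_trace: dict[str, float] = field(default_factory=dict)
    n_presence: int = 0

    def eta(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, dtype=float) @ self.lam

    def raw(self, features: np.ndarray) -> np.ndarray:
        """Normalised raw density relative to the fitting background."""
        return np.exp(self.eta(features) - self.log_z)

    def logistic(self, features: np.ndarray) -> np.ndarray:
        qh = self.raw(features) * np.exp(self.entropy)
        return qh / (1.0 + qh)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "lam": self.lam.tolist(),
            "beta": self.beta.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "gain_trace": self.gain_trace,
            "features": [
                {
                    "variable": f.variable,
                    "kind": f.kind,
                    "knot": f.knot,
                    "x_min": f.x_min,
                    "x_max": f.x_max,
                }
                for f in self.basis.features
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "MaxentModel":
        with open(path) as fh:
            payload = json.load(fh)
        basis = HingeBasis([Feature(**f) for f in payload["features"]])
        return cls(
            basis,
            np.asarray(payload["lam"]),
            np.asarray(payload["beta"]),
            payload["log_z"],
            payload["entropy"],
            payload.get("gain_trace", {}),
            payload.get("n_presence", 0),
        )


def sample_background(
    template: Raster,
    bias: BiasSurface | None,
    n: int = 10000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n cells with replacement, probability proportional to bias weight
    (uniform when bias is None).  Returns (rows, cols)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = template.mask
    if bias is not None:
        mask = mask & bias.grid.mask
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("no valid cells to sample background from")
    if bias is None:
        w = np.ones(len(rows))
    else:
        w = bias.grid.values[rows, cols].astype(float)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=True, p=w)
    return rows[idx], cols[idx]


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    basis: HingeBasis | None = None,
    reg_multiplier: float = 2.0,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> MaxentModel:
    """Cyclic coordinate descent on the L1-regularised maxent log-loss.

    objective(lam) = -mean_presence(F lam) + logsumexp(F_bg lam)
                     + sum_j beta_j |lam_j|

    with beta_j = reg_multiplier * 0.5/sqrt(m) * sd_bg(feature_j) and m the
    presence count.  Each accepted coordinate step's objective improvement
    is credited to the stepped feature's source variable (the gain trace
    used for percent contribution).
    """
    fp = np.asarray(presence_features, dtype=float)
    fb = np.asarray(background_features, dtype=float)
    if fp.ndim != 2 or fb.ndim != 2:
        raise ValueError("feature matrices must be 2-D")
    if fp.shape[0] < 1:
        raise ValueError("need at least one presence")
    if fb.shape[0] < 2:
        raise ValueError("need at least two background rows")
    if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fb))):
        raise ValueError("non-finite feature values")
    m, nf = fp.shape
    if fb.shape[1] != nf:
        raise ValueError("presence/background feature dimension mismatch")

    sd = fb.std(axis=0)
    beta = reg_multiplier * (0.5 / np.sqrt(m)) * sd
    # features constant over background get a nominal floor so their weight
    # stays penalised rather than unbounded
    beta = np.where(sd > 0, beta, reg_multiplier * 0.5 / np.sqrt(m))

    lam = np.zeros(nf)
    eta_p = np.zeros(m)
    eta_b = np.zeros(fb.shape[0])
    mean_fp = fp.mean(axis=0)

    def objective(eta_p_, eta_b_, lam_):
        return float(-eta_p_.mean() + logsumexp(eta_b_) + np.sum(beta * np.abs(lam_)))

    obj = objective(eta_p, eta_b, lam)
    gain_trace: dict[str, float] = {}
    var_of = (
        [f.variable for f in basis.features] if basis is not None else [str(j) for j in range(nf)]
    )

    for _cycle in range(max_iter):
        obj_start = obj
        for j in range(nf):
            # current raw distribution over background
            w = np.exp(eta_b - logsumexp(eta_b))
            fbj = fb[:, j]
            ew = float(w @ fbj)
            grad = -mean_fp[j] + ew
            hess = float(w @ (fbj * fbj)) - ew * ew
            if hess < 1e-12:
                hess = 1e-12
            z = lam[j] - grad / hess
            lam_new = np.sign(z) * max(0.0, abs(z) - beta[j] / hess)
            delta = lam_new - lam[j]
            if abs(delta) < 1e-15:
                continue
            # backtracking until the true objective does not increase
            accepted = False
            for _ in range(30):
                trial_p = eta_p + delta * fp[:, j]
                trial_b = eta_b + delta * fbj
                lam_j_trial = lam[j] + delta
                trial_obj = (
                    float(-trial_p.mean())
                    + float(logsumexp(trial_b))
                    + float(np.sum(beta * np.abs(lam)) - beta[j] * abs(lam[j]) + beta[j] * abs(lam_j_trial))
                )
                if trial_obj <= obj:
                    accepted = True
                    break
                delta *= 0.5
                if abs(delta) < 1e-15:
                    break
            if accepted and trial_obj < obj:
                gain = obj - trial_obj
                v = var_of[j]
                gain_trace[v] = gain_trace.get(v, 0.0) + gain
                lam[j] += delta
                eta_p, eta_b = trial_p, trial_b
                obj = trial_obj
        if obj_start - obj < tol:
            break

    log_z = float(logsumexp(eta_b))
    q = np.exp(eta_b - log_z)
    entropy = float(log_z - q @ eta_b)
    model = MaxentModel(
        basis if basis is not None else HingeBasis([]),
        lam,
        beta,
        log_z,
        entropy,
        gain_trace,
        n_presence=m,
    )
    return model


def presence_background_auc(pres_scores: np.ndarray, bg_scores: np.ndarray) -> float:
    """Rank-based AUC with the midrank tie correction."""
    pres_scores = np.asarray(pres_scores, dtype=float)
    bg_scores = np.asarray(bg_scores, dtype=float)
    n_p, n_b = len(pres_scores), len(bg_scores)
    if n_p == 0 or n_b == 0:
        raise ValueError("need scores on both sides")
    ranks = rankdata(np.concatenate([pres_scores, bg_scores]))
    r_sum = ranks[:n_p].sum()
    return float((r_sum - n_p * (n_p + 1) / 2.0) / (n_p * n_b))


@dataclass
class SuitabilityMap:
    grid: Raster
    provenance: list[str] = field(default_factory=list)


def run_replicates(
    records: OccurrenceSet,
    stack: PredictorStack,
    bias: BiasSurface | None,
    n_rep: int = 20,
    train_frac: float = 0.75,
    seed: int = 0,
    n_background: int = 10000,
    knots_per_variable: int = 50,
    reg_multiplier: float = 2.0,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> tuple[SuitabilityMap, list[float], list[MaxentModel]]:
    """Random 75/25 presence partitions; fit each, score test AUC against
    the background, average the logistic surfaces cellwise."""
    n = len(records)
    if n < 4:
        raise ValueError("need at least 4 records for a 75/25 partition")
    rng = np.random.default_rng(seed)
    grid = stack.grid
    mask = stack.mask
    cell_rows, cell_cols = np.nonzero(mask)
    cell_table = stack.table(cell_rows, cell_cols)

    surf_sum = np.zeros(grid.shape)
    aucs: list[float] = []
    models: list[MaxentModel] = []
    for rep in range(n_rep):
        br, bc = sample_background(
            next(iter(stack.layers.values())), bias, n_background,
            seed=int(rng.integers(2**31)),
        )
        bg_table = stack.table(br, bc)
        basis = build_features(stack.kinds, bg_table, knots_per_variable)
        fb = basis.design_matrix(bg_table)

        perm = rng.permutation(n)
        n_train = max(1, int(round(train_frac * n)))
        if n_train >= n:
            n_train = n - 1
        train = records.take(perm[:n_train])
        test = records.take(perm[n_train:])
        fp = basis.design_matrix(_point_table(stack, train))
        ft = basis.design_matrix(_point_table(stack, test))
        ok_p = np.all(np.isfinite(fp), axis=1)
        ok_t = np.all(np.isfinite(ft), axis=1)
        model = fit_maxent(fp[ok_p], fb, basis, reg_multiplier, max_iter, tol)
        models.append(model)
        aucs.append(
            presence_background_auc(model.logistic(ft[ok_t]), model.logistic(fb))
        )
        surf = np.zeros(grid.shape)
        surf[cell_rows, cell_cols] = model.logistic(basis.design_matrix(cell_table))
        surf_sum += surf

    mean = surf_sum / n_rep
    nod = next(iter(stack.layers.values())).nodata
    mean = np.where(mask, mean, nod)
    raster = Raster(mean, grid, nod)
    return SuitabilityMap(raster, [f"rep{j}" for j in range(n_rep)]), aucs, models


def _point_table(stack: PredictorStack, records: OccurrenceSet) -> dict[str, np.ndarray]:
    x, y = records.xy.T if len(records) else (np.empty(0), np.empty(0))
    return stack.table_at_points(x, y)


def average_sets(maps: list[SuitabilityMap]) -> SuitabilityMap:
    """Cellwise arithmetic mean of co-registered maps; nodata propagates."""
    if not maps:
        raise ValueError("no maps to average")
    ref = maps[0].grid
    for m in maps[1:]:
        if m.grid.grid != ref.grid:
            raise ValueError("maps are not co-registered")
    stackv = np.stack([m.grid.values for m in maps])
    maskv = np.stack([m.grid.mask for m in maps])
    ok = maskv.all(axis=0)
    mean = np.where(ok, stackv.mean(axis=0), ref.nodata)
    prov = [p for m in maps for p in m.provenance]
    return SuitabilityMap(Raster(mean, ref.grid, ref.nodata), prov)


def percent_contribution(model: MaxentModel) -> pd.Series:
    """Per-variable share of the total training gain, normalised to 100."""
    trace = model.gain_trace
    variables = model.basis.variables or list(trace)
    total = sum(trace.values())
    if total <= 0:
        return pd.Series({v: 0.0 for v in variables})
    return pd.Series({v: 100.0 * trace.get(v, 0.0) / total for v in variables})


def response_curve(
    variable: str,
    records: OccurrenceSet,
    stack: PredictorStack,
    values: np.ndarray,
    bias: BiasSurface | None = None,
    n_background: int = 10000,
    knots_per_variable: int = 50,
    reg_multiplier: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Univariate model built from the one variable's features, evaluated
    over a grid of its values."""
    if variable not in stack.names:
        raise KeyError(variable)
    sub = stack.subset([variable])
    br, bc = sample_background(sub.layers[variable], bias, n_background, seed)
    bg_table = sub.table(br, bc)
    basis = build_features(sub.kinds, bg_table, knots_per_variable)
    fb = basis.design_matrix(bg_table)
    fp = basis.design_matrix(_point_table(sub, records))
    fp = fp[np.all(np.isfinite(fp), axis=1)]
    model = fit_maxent(fp, fb, basis, reg_multiplier)
    fv = basis.design_matrix({variable: np.asarray(values, dtype=float)})
    return pd.DataFrame({variable: values, "suitability": model.logistic(fv)})


def class_frequency(
    suitability: SuitabilityMap,
    holdout: OccurrenceSet,
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Suitability-class table: percentage of area and of holdout records in
    each bin [0, w), [w, 2w), ..., with the top bin closed above."""
    raster = suitability.grid
    vals = raster.valid_values()
    n_bins = max(1, int(round(1.0 / bin_width)) - 1)
    edges = np.array([i * bin_width for i in range(n_bins)] + [np.inf])
    area_counts = np.histogram(vals, bins=edges)[0]

    x, y = holdout.xy.T if len(holdout) else (np.empty(0), np.empty(0))
    rec_vals = raster.sample(x, y)
    n_excluded = int(np.sum(np.isnan(rec_vals)))
    if n_excluded:
        logger.warning("%d holdout records on nodata cells excluded", n_excluded)
    rec_vals = rec_vals[~np.isnan(rec_vals)]
    rec_counts = np.histogram(rec_vals, bins=edges)[0]

    labels = [
        f"[{edges[i]:.1f}, {edges[i + 1]:.1f})" if np.isfinite(edges[i + 1]) else f"[{edges[i]:.1f}, max]"
        for i in range(n_bins)
    ]
    return pd.DataFrame(
        {
            "class": labels,
            "pct_area": 100.0 * area_counts / max(1, area_counts.sum()),
            "pct_records": 100.0 * rec_counts / max(1, rec_counts.sum()),
        }
    )
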
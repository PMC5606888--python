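"""Single-season occupancy modelling with imperfect detection.

Zero-inflated detection-history likelihood with logit links on occupancy
(psi) and per-occasion detection (p), multi-start maximum likelihood, AIC
model selection, parametric-bootstrap goodness of fit, and the fitted-psi
validation statistics.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "DetectionHistory",
    "OccupancyModel",
    "parse_model_spec",
    "neg2_log_likelihood",
    "fit_occupancy",
    "selection_table",
    "gof_bootstrap",
    "fitted_psi",
    "correlate_validation",
    "simulate_histories",
]

logger = logging.getLogger(__name__)


@dataclass
class DetectionHistory:
    """Site-by-occasion detection matrix plus covariates.

    ``y`` holds 0/1 with NaN for missing occasions.  ``site_covariates`` is
    a DataFrame with one row per site; ``occasion_covariates`` maps names to
    (n_sites, n_occasions) arrays (numeric, or strings for categorical
    occasion covariates such as a trip label).
    """

    y: np.ndarray
    site_covariates: pd.DataFrame | None = None
    occasion_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    site_ids: list | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("detection history must be a 2-D site x occasion matrix")
        vals = self.y[~np.isnan(self.y)]
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("detection entries must be 0, 1 or missing")
        if self.site_covariates is None:
            self.site_covariates = pd.DataFrame(index=range(self.y.shape[0]))
        if len(self.site_covariates) != self.y.shape[0]:
            raise ValueError("site covariate rows must match site count")
        if self.site_ids is None:
            self.site_ids = list(range(self.y.shape[0]))

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.y)

    def active_sites(self) -> np.ndarray:
        """Sites with at least one non-missing occasion."""
        return self.observed.any(axis=1)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.nan_to_num(self.y, nan=-1.0).tobytes())
        return h.hexdigest()[:16]

    def naive_occupancy(self) -> float:
        act = self.active_sites()
        det = np.nansum(self.y[act], axis=1) > 0
        return float(det.mean())

    @classmethod
    def from_csv(
        cls,
        history_path,
        site_covariates_path=None,
        occasion_covariate_paths: dict | None = None,
    ) -> "DetectionHistory":
        df = pd.read_csv(history_path)
        site_col = df.columns[0]
        sites = df[site_col].tolist()
        y = df.drop(columns=[site_col]).to_numpy(dtype=float)
        site_cov = None
        if site_covariates_path is not None:
            site_cov = pd.read_csv(site_covariates_path)
            site_cov = site_cov.set_index(site_cov.columns[0]).loc[sites].reset_index(drop=True)
        occ = {}
        if occasion_covariate_paths:
            for name, path in occasion_covariate_paths.items():
                odf = pd.read_csv(path)
                odf = odf.set_index(odf.columns[0]).loc[sites]
                occ[name] = odf.to_numpy()
        return cls(y, site_cov, occ, site_ids=sites)


_SPEC_RE = re.compile(r"^\s*psi\(([^)]*)\)\s*,\s*p\(([^)]*)\)\s*$", re.IGNORECASE)


def parse_model_spec(spec: str) -> tuple[list[str], list[str]]:
    """Parse a model label like ``psi(suitability+npp),p(trip)``; ``.`` or an
    empty list means intercept only."""
    m = _SPEC_RE.match(spec)
    if not m:
        raise ValueError(f"cannot parse model spec {spec!r}")

    def terms(s: str) -> list[str]:
        s = s.strip()
        if s in ("", "."):
            return []
        return [t.strip() for t in s.split("+") if t.strip()]

    return terms(m.group(1)), terms(m.group(2))


def _encode_site(df: pd.DataFrame, covs: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate columns; non-numeric columns become treatment
    dummies against the first observed level."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["(intercept)"]
    for c in covs:
        if c not in df.columns:
            raise KeyError(f"missing site covariate {c!r}")
        col = df[c]
        if pd.api.types.is_numeric_dtype(col):
            v = col.to_numpy(dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in covariate {c!r}")
            cols.append(v)
            names.append(c)
        else:
            levels = sorted(col.astype(str).unique())
            for lv in levels[1:]:
                cols.append((col.astype(str) == lv).to_numpy(dtype=float))
                names.append(f"{c}[{lv}]")
    return np.column_stack(cols), names


def _encode_occasion(
    data: DetectionHistory, covs: list[str]
) -> tuple[np.ndarray, list[str]]:
    """(n_sites, n_occasions, k) design tensor for detection.

    Site-level covariates are broadcast across occasions; occasion-level
    arrays are used as-is; string-valued arrays expand to dummies.
    """
    n, t = data.y.shape
    mats = [np.ones((n, t))]
    names = ["(intercept)"]
    for c in covs:
        if c in data.occasion_covariates:
            arr = data.occasion_covariates[c]
            if arr.shape != (n, t):
                raise ValueError(f"occasion covariate {c!r} has wrong shape")
            if np.issubdtype(np.asarray(arr).dtype, np.number):
                a = np.asarray(arr, dtype=float)
                if not np.all(np.isfinite(a)):
                    raise ValueError(f"non-finite values in covariate {c!r}")
                mats.append(a)
                names.append(c)
            else:
                s = np.asarray(arr).astype(str)
                for lv in sorted(np.unique(s))[1:]:
                    mats.append((s == lv).astype(float))
                    names.append(f"{c}[{lv}]")
        elif c in data.site_covariates.columns:
            x, nm = _encode_site(data.site_covariates, [c])
            for j in range(1, x.shape[1]):
                mats.append(np.broadcast_to(x[:, j][:, None], (n, t)).copy())
                names.append(nm[j])
        else:
            raise KeyError(f"missing detection covariate {c!r}")
    return np.stack(mats, axis=-1), names


def neg2_log_likelihood(
    params: np.ndarray,
    data: DetectionHistory,
    psi_design: np.ndarray,
    p_design: np.ndarray,
) -> float:
    """-2 log L of the zero-inflated occupancy likelihood.

    Per site: L_i = psi_i * prod_t p_it^y (1-p_it)^(1-y) + (1-psi_i) * I[no
    detections]; missing occasions contribute no factor.
    """
    params = np.asarray(params, dtype=float)
    k_psi = psi_design.shape[1]
    psi = expit(psi_design @ params[:k_psi])
    p = expit(p_design @ params[k_psi:])
    y = data.y
    obs = data.observed
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(obs, np.where(y == 1, np.log(p), np.log1p(-p)), 0.0)
    logf = np.where(np.isfinite(logf), logf, -745.0)  # log of denormal floor
    log_det_prod = logf.sum(axis=1)
    detected = np.nansum(np.where(obs, y, 0.0), axis=1) > 0
    lik = psi * np.exp(log_det_prod) + np.where(detected, 0.0, 1.0 - psi)
    active = data.active_sites()
    lik = np.clip(lik[active], 1e-300, None)
    return float(-2.0 * np.sum(np.log(lik)))


@dataclass
class OccupancyModel:
    label: str
    psi_covs: list[str]
    p_covs: list[str]
    coef: np.ndarray
    coef_names: list[str]
    k_psi: int
    neg2ll: float
    vcov: np.ndarray | None
    data_fingerprint: str
    converged: bool = True

    @property
    def k(self) -> int:
        return len(self.coef)

    @property
    def aic(self) -> float:
        return self.neg2ll + 2 * self.k

    def psi_coef(self) -> np.ndarray:
        return self.coef[: self.k_psi]

    def psi_vcov(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        return self.vcov[: self.k_psi, : self.k_psi]


def _numeric_hessian(fun, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    n = len(x)
    h = np.zeros((n, n))
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h


def fit_occupancy(
    data: DetectionHistory,
    spec: str = "psi(.),p(.)",
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
) -> OccupancyModel:
    """Multi-start quasi-Newton ML fit of the model named by ``spec``."""
    psi_covs, p_covs = parse_model_spec(spec)
    x_psi, psi_names = _encode_site(data.site_covariates, psi_covs)
    x_p, p_names = _encode_occasion(data, p_covs)
    k_psi = x_psi.shape[1]
    k = k_psi + x_p.shape[-1]

    def fun(theta):
        return neg2_log_likelihood(theta, data, x_psi, x_p)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)]
    for _ in range(n_starts - 1):
        starts.append(rng.normal(scale=1.5, size=k))

    best = None
    for s in starts:
        res = optimize.minimize(fun, s, method="BFGS", options={"gtol": 1e-9, "maxiter": 500})
        res2 = optimize.minimize(fun, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-9, "fatol": tol, "maxiter": 2000})
        cand = res2 if res2.fun <= res.fun else res
        if best is None or cand.fun < best.fun - 1e-12:
            best = cand

    hess = _numeric_hessian(fun, best.x)
    vcov = None
    try:
        # neg2LL Hessian is twice the observed information
        vcov = 2.0 * np.linalg.inv(hess)
        if not np.all(np.isfinite(vcov)) or np.any(np.diag(vcov) < 0):
            vcov = None
    except np.linalg.LinAlgError:
        vcov = None
    if vcov is None:
        logger.warning("singular Hessian for %s; vcov unavailable", spec)

    return OccupancyModel(
        label=spec,
        psi_covs=psi_covs,
        p_covs=p_covs,
        coef=best.x,
        coef_names=psi_names + p_names,
        k_psi=k_psi,
        neg2ll=float(best.fun),
        vcov=vcov,
        data_fingerprint=data.fingerprint(),
    )


def selection_table(
    models: list[OccupancyModel], labels: list[str] | None = None
) -> pd.DataFrame:
    """AIC ranking: delta AIC, relative model likelihood exp(-delta/2),
    normalised Akaike weights, and the delta<2 substantial-support flag."""
    if not models:
        raise ValueError("no models to rank")
    fps = {m.data_fingerprint for m in models}
    if len(fps) > 1:
        raise ValueError("models were fitted on different data")
    if labels is None:
        labels = [m.label for m in models]
    aic = np.array([m.aic for m in models])
    delta = aic - aic.min()
    lik = np.exp(-delta / 2.0)
    weights = lik / lik.sum()
    df = pd.DataFrame(
        {
            "model": labels,
            "AIC": aic,
            "delta_AIC": delta,
            "AIC_weight": weights,
            "model_likelihood": lik,
            "n_parameters": [m.k for m in models],
            "neg2_log_likelihood": [m.neg2ll for m in models],
            "substantial_support": delta < 2.0,
        }
    ).sort_values("AIC", kind="stable").reset_index(drop=True)
    return df


def make_selection_table(
    rows: list[tuple[str, float, int]]
) -> pd.DataFrame:
    """Selection table from (label, neg2LL, k) triples — the printed-table
    arithmetic without refitting."""
    labels = [r[0] for r in rows]
    neg2ll = np.array([r[1] for r in rows], dtype=float)
    k = np.array([r[2] for r in rows], dtype=int)
    aic = neg2ll + 2 * k
    delta = aic - aic.min()
    lik = np.exp(-delta / 2.0)
    weights = lik / lik.sum()
    return pd.DataFrame(
        {
            "model": labels,
            "AIC": aic,
            "delta_AIC": delta,
            "AIC_weight": weights,
            "model_likelihood": lik,
            "n_parameters": k,
            "neg2_log_likelihood": neg2ll,
            "substantial_support": delta < 2.0,
        }
    ).sort_values("AIC", kind="stable").reset_index(drop=True)


def _site_probs(model: OccupancyModel, data: DetectionHistory):
    x_psi, _ = _encode_site(data.site_covariates, model.psi_covs)
    x_p, _ = _encode_occasion(data, model.p_covs)
    psi = expit(x_psi @ model.coef[: model.k_psi])
    p = expit(x_p @ model.coef[model.k_psi:])
    return psi, p


def _history_chi2(model: OccupancyModel, data: DetectionHistory) -> float:
    """Pearson chi-squared over detection-history frequencies.

    Sites sharing an identical (psi, p-vector, missingness) pattern pool
    into one cohort; expected counts come from enumerating the 2^T_obs
    possible histories on each cohort's observed occasions.
    """
    psi, p = _site_probs(model, data)
    obs_mask = data.observed
    active = data.active_sites()

    cohorts: dict[tuple, list[int]] = {}
    for i in np.flatnonzero(active):
        key = (round(float(psi[i]), 12), tuple(np.round(p[i][obs_mask[i]], 12)),
               tuple(obs_mask[i]))
        cohorts.setdefault(key, []).append(i)

    chi2 = 0.0
    for key, idx in cohorts.items():
        i0 = idx[0]
        occ = np.flatnonzero(obs_mask[i0])
        t_obs = len(occ)
        p_i = p[i0][occ]
        psi_i = psi[i0]
        n_hist = 1 << t_obs
        # probability of each possible history for this cohort
        probs = np.zeros(n_hist)
        for h in range(n_hist):
            bits = np.array([(h >> b) & 1 for b in range(t_obs)], dtype=float)
            det = np.prod(np.where(bits == 1, p_i, 1 - p_i))
            probs[h] = psi_i * det + (1 - psi_i) * (1.0 if h == 0 else 0.0)
        counts = np.zeros(n_hist)
        for i in idx:
            bits = data.y[i][occ].astype(int)
            h = int(np.sum(bits << np.arange(t_obs)))
            counts[h] += 1
        expected = len(idx) * probs
        nz = expected > 1e-300
        chi2 += float(np.sum((counts[nz] - expected[nz]) ** 2 / expected[nz]))
    return chi2


def gof_bootstrap(
    model: OccupancyModel,
    data: DetectionHistory,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Parametric-bootstrap goodness of fit: (observed chi2, p value, c-hat).

    p is the fraction of bootstrap chi2 at or above the observed value;
    c-hat is observed / mean bootstrap chi2.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    chi2_obs = _history_chi2(model, data)
    psi, p = _site_probs(model, data)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        z = rng.random(data.n_sites) < psi
        dets = (rng.random(data.y.shape) < p) & z[:, None]
        y = np.where(data.observed, dets.astype(float), np.nan)
        sim = DetectionHistory(
            y, data.site_covariates.copy(), dict(data.occasion_covariates)
        )
        refit = fit_occupancy(sim, model.label, n_starts=1, seed=int(rng.integers(2**31)))
        boots[b] = _history_chi2(refit, sim)
    p_value = float(np.mean(boots >= chi2_obs))
    mean_boot = float(boots.mean())
    c_hat = chi2_obs / mean_boot if mean_boot > 0 else float("nan")
    return chi2_obs, p_value, c_hat


def fitted_psi(
    model: OccupancyModel, covariate_values: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Occupancy estimates with delta-method intervals on the logit scale."""
    x, _ = _encode_site(covariate_values, model.psi_covs)
    eta = x @ model.psi_coef()
    psi = expit(eta)
    out = pd.DataFrame({"psi": psi})
    v = model.psi_vcov()
    if v is not None:
        se = np.sqrt(np.einsum("ij,jk,ik->i", x, v, x))
        zc = stats.norm.ppf(1 - alpha / 2)
        out["psi_lower"] = expit(eta - zc * se)
        out["psi_upper"] = expit(eta + zc * se)
        out["se_logit"] = se
    return out


def correlate_validation(
    fitted: np.ndarray, suitability: np.ndarray
) -> tuple[float, float, int]:
    """Pearson correlation of per-site fitted psi against suitability;
    returns (r, two-sided p, df = n - 2)."""
    fitted = np.asarray(fitted, dtype=float)
    suitability = np.asarray(suitability, dtype=float)
    if len(fitted) != len(suitability):
        raise ValueError("length mismatch")
    n = len(fitted)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(fitted) == 0 or np.std(suitability) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(fitted, suitability)
    return float(r), float(p), n - 2


def simulate_histories(
    psi: np.ndarray | float,
    p: np.ndarray | float,
    n_sites: int,
    n_occasions: int,
    seed: int = 0,
) -> DetectionHistory:
    """Bernoulli occupancy/detection simulator used by recovery tests."""
    rng = np.random.default_rng(seed)
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (n_sites,))
    p = np.broadcast_to(np.asarray(p, dtype=float), (n_sites, n_occasions))
    z = rng.random(n_sites) < psi
    y = ((rng.random((n_sites, n_occasions)) < p) & z[:, None]).astype(float)
    return DetectionHistory(y)
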
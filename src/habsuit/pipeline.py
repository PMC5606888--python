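"""End-to-end orchestration of the habitat-suitability analysis.

prep -> bias -> per-subregion maxent (sets x replicates) -> mosaic/average
-> class frequency -> staged occupancy selection -> habitat-quality index
-> validation statistics.  Every artifact directory carries a manifest
with the config hash and seeds so reruns are reproducible and auditable.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import bias as bias_mod
from . import maxent as mx
from .config import RunConfig
from .habitat_quality import TransectSample, regress_index, site_habitat_quality
from .occupancy import (
    DetectionHistory,
    correlate_validation,
    fit_occupancy,
    fitted_psi,
    gof_bootstrap,
    selection_table,
)
from .occurrences import (
    OccurrenceSet,
    clean_records,
    make_replicates,
    screen_predictors,
    split_subregions,
)
from .raster import PredictorStack, Raster, read_raster, write_raster

logger = logging.getLogger(__name__)

__all__ = ["load_stack", "run_pipeline"]


def load_stack(stack_dir: str | os.PathLike) -> PredictorStack:
    """Read every .asc layer in a directory; kinds.json flags categoricals."""
    kinds_path = os.path.join(stack_dir, "kinds.json")
    kinds = {}
    if os.path.exists(kinds_path):
        with open(kinds_path) as fh:
            kinds = json.load(fh)
    stack = PredictorStack()
    for name in sorted(os.listdir(stack_dir)):
        if not name.endswith(".asc"):
            continue
        layer = os.path.splitext(name)[0]
        stack.add(layer, read_raster(os.path.join(stack_dir, name)),
                  kinds.get(layer, "continuous"))
    if not stack.layers:
        raise ValueError(f"no .asc layers found in {stack_dir}")
    return stack


def _write_manifest(outdir: str, config: RunConfig, extra: dict) -> None:
    manifest = {"config_hash": config.hash(), "config": config.to_dict()}
    manifest.update(extra)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def run_pipeline(config: RunConfig) -> str:
    """Run the full analysis recipe on an input bundle directory.

    Returns the output directory.  Any stage failure raises with the stage
    name in the message.
    """
    config.validate()
    ind = config.input_dir
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    counts: dict[str, object] = {}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # ---------------------------------------------------------------- prep
    s = stage("prep")
    try:
        stack = load_stack(os.path.join(ind, "stack"))
        occ = OccurrenceSet.from_csv(os.path.join(ind, "occurrences.csv"))
        cleared_path = os.path.join(ind, "cleared.asc")
        if os.path.exists(cleared_path):
            occ = clean_records(occ, read_raster(cleared_path), config.max_accuracy)
        counts["cleaned"] = len(occ)
        retained = screen_predictors(stack, config.correlation_threshold)
        stack = stack.subset(retained)
        counts["predictors_retained"] = retained
        dem = stack.layers["dem"]
        sub1, sub2 = split_subregions(occ, dem, config.elevation_threshold)
        counts["subregion_records"] = [len(sub1), len(sub2)]
    except Exception as e:
        raise RuntimeError(f"stage {s!r} failed: {e}") from e

    # ---------------------------------------------------------------- bias
    s = stage("bias")
    try:
        target = OccurrenceSet.from_csv(os.path.join(ind, "target_group.csv"))
        effort_points = OccurrenceSet.concat([occ, target])
        surface = bias_mod.build_bias_surface(
            effort_points, next(iter(stack.layers.values())), config.bias_bandwidth
        )
        write_raster(surface.grid, os.path.join(out, "bias.asc"))
    except Exception as e:
        raise RuntimeError(f"stage {s!r} failed: {e}") from e

    # -------------------------------------------------------------- maxent
    s = stage("maxent")
    try:
        rng = np.random.default_rng(config.seeds["maxent"])
        sub_maps = []
        aucs_all: dict[str, list[float]] = {}
        for subname, sub in (("subregion1", sub1), ("subregion2", sub2)):
            reps = make_replicates(
                sub, config.n_sets, config.min_dist,
                list(config.seeds["thinning"])[: config.n_sets],
            )
            counts[f"{subname}_thinned"] = [len(r) for r in reps.replicates]
            counts[f"{subname}_holdout"] = len(reps.holdout)
            set_maps = []
            aucs_all[subname] = []
            for rep in reps.replicates:
                m, aucs, _ = mx.run_replicates(
                    rep, stack, surface,
                    n_rep=config.n_replicates,
                    train_frac=config.train_frac,
                    seed=int(rng.integers(2**31)),
                    n_background=config.n_background,
                    knots_per_variable=config.knots_per_variable,
                    reg_multiplier=config.reg_multiplier,
                    max_iter=config.max_iter,
                    tol=config.tol,
                )
                set_maps.append(m)
                aucs_all[subname].extend(aucs)
            sub_maps.append(mx.average_sets(set_maps))
        # mosaic at the elevation seam: < threshold from model 1, else model 2
        dem_vals = stack.layers["dem"].values
        low = dem_vals < config.elevation_threshold
        final_vals = np.where(low, sub_maps[0].grid.values, sub_maps[1].grid.values)
        mask = stack.mask
        final_vals = np.where(mask, final_vals, sub_maps[0].grid.nodata)
        final = mx.SuitabilityMap(
            Raster(final_vals, stack.grid, sub_maps[0].grid.nodata),
            ["subregion1", "subregion2"],
        )
        write_raster(final.grid, os.path.join(out, "suitability.asc"))
        counts["mean_test_auc"] = {k: float(np.mean(v)) for k, v in aucs_all.items()}
        holdout_all = OccurrenceSet.concat(
            [make_replicates(sub1, config.n_sets, config.min_dist,
                             list(config.seeds["thinning"])[: config.n_sets]).holdout,
             make_replicates(sub2, config.n_sets, config.min_dist,
                             list(config.seeds["thinning"])[: config.n_sets]).holdout]
        )
        freq = mx.class_frequency(final, holdout_all)
        freq.to_csv(os.path.join(out, "class_frequency.csv"), index=False)
    except Exception as e:
        raise RuntimeError(f"stage {s!r} failed: {e}") from e

    # ----------------------------------------------------------- occupancy
    s = stage("occupancy")
    try:
        hist = DetectionHistory.from_csv(
            os.path.join(ind, "detection_history.csv"),
            site_covariates_path=os.path.join(ind, "sites.csv"),
            occasion_covariate_paths={"rainfall": os.path.join(ind, "rainfall.csv")},
        )
        sites = pd.read_csv(os.path.join(ind, "sites.csv"))
        suit_at_sites = final.grid.sample(sites["x"], sites["y"])
        hist.site_covariates["suitability"] = suit_at_sites
        hist.occasion_covariates["trip"] = np.tile(
            sites["trip"].to_numpy()[:, None], (1, hist.n_occasions)
        )

        # habitat-quality index per site (needed as an occupancy covariate)
        tdf = pd.read_csv(os.path.join(ind, "transects.csv"))
        bmap = pd.read_csv(os.path.join(ind, "browse_classes.csv"))
        browse = dict(zip(bmap["species"], bmap["class"]))
        weights = {int(k): float(v) for k, v in config.browse_weights.items()}
        hq = {}
        for site, grp in tdf.groupby("site"):
            hq[site] = site_habitat_quality(
                TransectSample(str(site), grp.drop(columns=["site"])),
                browse, weights, config.diversity_bonus,
            ).index
        hqvals = sites["site"].map(hq).to_numpy(dtype=float)
        hist.site_covariates["habitat_quality"] = hqvals

        seed_occ = config.seeds["occupancy"]
        # stage 1: detection structure with constant occupancy
        det_models = [fit_occupancy(hist, sp, seed=seed_occ)
                      for sp in config.detection_specs]
        det_table = selection_table(det_models)
        det_table.to_csv(os.path.join(out, "selection_detection.csv"), index=False)
        best_p = det_models[int(np.argmin([m.aic for m in det_models]))].p_covs
        p_term = "+".join(best_p) if best_p else "."

        # stage 2: occupancy covariates with the chosen detection structure
        psi_specs = [f"psi(.),p({p_term})"] + [
            f"psi({c}),p({p_term})" for c in config.occupancy_covariates
        ]
        psi_models = [fit_occupancy(hist, sp, seed=seed_occ) for sp in psi_specs]
        psi_table = selection_table(psi_models)
        psi_table.to_csv(os.path.join(out, "selection_occupancy.csv"), index=False)

        suit_model = next(
            m for m in psi_models if m.psi_covs == ["suitability"]
        )
        fp = fitted_psi(suit_model, hist.site_covariates)
        fp.insert(0, "site", sites["site"])
        fp["suitability"] = hist.site_covariates["suitability"].to_numpy()
        fp.to_csv(os.path.join(out, "fitted_psi.csv"), index=False)
        ok = np.isfinite(fp["psi"]) & np.isfinite(fp["suitability"])
        r, p, df = correlate_validation(
            fp.loc[ok, "psi"], fp.loc[ok, "suitability"]
        )
        validation = {"psi_vs_suitability": {"r": r, "p": p, "df": df}}
        if config.n_gof_boot >= 2:
            chi2, pgof, chat = gof_bootstrap(
                suit_model, hist, config.n_gof_boot, config.seeds.get("gof", 0)
            )
            validation["gof"] = {"chi2": chi2, "p": pgof, "c_hat": chat}
    except Exception as e:
        raise RuntimeError(f"stage {s!r} failed: {e}") from e

    # ------------------------------------------------------ habitat quality
    s = stage("habitat_quality")
    try:
        sub_label = np.where(
            stack.layers["dem"].sample(sites["x"], sites["y"])
            < config.elevation_threshold, 1, 2,
        )
        ok = np.isfinite(hqvals) & np.isfinite(suit_at_sites)
        reg = regress_index(hqvals[ok], suit_at_sites[ok], sub_label[ok])
        reg.to_csv(os.path.join(out, "hq_regression.csv"), index=False)
        validation["hq_vs_suitability"] = reg.to_dict(orient="records")
    except Exception as e:
        raise RuntimeError(f"stage {s!r} failed: {e}") from e

    with open(os.path.join(out, "validation.json"), "w") as fh:
        json.dump(validation, fh, indent=1)
    _write_manifest(out, config, {"counts": counts})
    return out
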
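"""End-to-end driver: simulate -> screen -> model -> Moran -> variogram -> map.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and
its master seed; every artifact embeds the config hash and seed so a run
can be reproduced exactly from its own report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import modeling, moran, synthetic
from . import variogram as vg
from .grids import GridGeometry
from .kriging import holdout_validate, ok_predict, sgcs
from .plots import summarize

log = logging.getLogger("canopygeo")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Per-stage parameters for a full pipeline run."""

    seed: int = 0
    outdir: str = "canopygeo_run"
    # synthetic footprint emulation (study-scale defaults)
    extent: tuple[float, float, float, float] = (0.0, 0.0, 50_000.0, 55_200.0)
    n_tracks: int = 20
    track_spacing: float = 2_500.0
    along_track_step: float = 100.0
    thin_interval: int = 10
    # modeling
    train_frac: float = 0.70
    alpha: float = 0.05
    model_families: tuple[str, ...] = modeling.MODEL_FAMILIES
    # autocorrelation
    weights_scheme: str = "idw_band"
    weights_cutoff: float | None = None  # None: fitted variogram range
    lisa_n_perm: int = 199
    # variogram
    lag_width: float | None = None
    max_lag: float | None = None
    # interpolation
    map_cell: float = 1_000.0
    n_real: int = 50
    holdout_frac: float = 0.80

    def hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write a report bundle to ``outdir``.

    Stages: footprint simulation and thinning; normality summary; Pearson
    screening; four-family model comparison on a 70/30 split; global and
    local Moran's I; omnidirectional + directional variograms with model
    fitting; ordinary kriging and sequential Gaussian simulation surfaces;
    80/20 holdout validation of both interpolators.  Returns the in-memory
    results dict; all tables/grids/JSON land in ``outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.hash(), "seed": config.seed,
            "config": asdict(config)}
    results: dict = {"meta": meta}

    frame = _simulate(config)
    cio.write_footprints(frame, out / "footprints.csv")
    results["n_footprints"] = len(frame)

    stats = summarize(frame["nfcc"].to_numpy())
    results["nfcc_summary"] = asdict(stats)

    selected, screen_table = _screen(frame, config)
    screen_table.to_csv(out / "covariate_screen.csv", index=False)
    results["selected_covariates"] = selected

    comparison, best_family = _model(frame, selected, config)
    comparison.to_csv(out / "model_comparison.csv", index=False)
    results["model_comparison"] = comparison.to_dict(orient="records")
    results["best_model"] = best_family

    emp, best_fit, fits, direction = _variogram(frame, config)
    pd.DataFrame({"lag": emp.lags, "gamma": emp.gamma, "n_pairs": emp.counts}
                 ).to_csv(out / "variogram_bins.csv", index=False)
    vario_doc = {
        "family": best_fit.model.family,
        "C0": best_fit.model.nugget,
        "C": best_fit.model.partial_sill,
        "a": best_fit.model.range_,
        "sill": best_fit.model.sill,
        "NSR_percent": 100.0 * best_fit.model.nsr,
        "spatial_dependence": vg.classify_nsr(best_fit.model.nsr),
        "R2": best_fit.r2,
        "RSS": best_fit.rss,
        "all_families": {f.model.family: {"R2": f.r2, "RSS": f.rss}
                         for f in fits if f.converged},
        "most_anisotropic_direction": direction,
        **meta,
    }
    (out / "variogram.json").write_text(json.dumps(vario_doc, indent=2))
    results["variogram"] = vario_doc

    moran_res, lisa_res = _autocorrelation(frame, best_fit.model, config)
    results["moran"] = {"I": moran_res.I, "expected": moran_res.expected,
                        "z": moran_res.z, "p": moran_res.p, "n": moran_res.n}
    (out / "moran.json").write_text(json.dumps({**results["moran"], **meta}, indent=2))
    lisa_table = pd.DataFrame({
        "id": frame["id"], "x": frame["x"], "y": frame["y"],
        "nfcc": frame["nfcc"], "local_i": lisa_res.local_i,
        "p": lisa_res.p, "label": lisa_res.labels,
    })
    lisa_table.to_csv(out / "lisa.csv", index=False)
    results["lisa_counts"] = lisa_table["label"].value_counts().to_dict()

    surfaces = _interpolate(frame, best_fit.model, config, out)
    results.update(surfaces)

    (out / "report.json").write_text(json.dumps(
        {k: v for k, v in results.items() if k != "meta"} | {"meta": meta},
        indent=2, default=str))
    return results


@_stage("simulate")
def _simulate(config: RunConfig) -> pd.DataFrame:
    tracks = synthetic.TrackConfig(
        n_tracks=config.n_tracks, track_spacing=config.track_spacing,
        along_track_step=config.along_track_step, seed=config.seed)
    return synthetic.make_footprint_dataset(
        seed=config.seed, extent=config.extent, tracks=tracks,
        thin_interval=config.thin_interval)


@_stage("screen")
def _screen(frame, config):
    feats = frame[list(synthetic.COVARIATE_NAMES)]
    return modeling.pearson_screen(feats, frame["nfcc"].to_numpy(),
                                   alpha=config.alpha)


@_stage("model")
def _model(frame, selected, config):
    data = modeling.Dataset(frame[selected], frame["nfcc"].to_numpy(),
                            seed=config.seed, train_frac=config.train_frac)
    table = modeling.compare_models(data, families=config.model_families,
                                    seed=config.seed)
    return table, table.iloc[0]["method"]


@_stage("variogram")
def _variogram(frame, config):
    pts = frame[["x", "y"]].to_numpy()
    vals = frame["nfcc"].to_numpy()
    emp = vg.empirical_variogram(pts, vals, lag_width=config.lag_width,
                                 max_lag=config.max_lag)
    best, fits = vg.fit_model(emp)
    suite = vg.directional_suite(pts, vals, lag_width=config.lag_width,
                                 max_lag=config.max_lag)
    return emp, best, fits, suite["most_anisotropic"]


@_stage("autocorrelation")
def _autocorrelation(frame, model, config):
    pts = frame[["x", "y"]].to_numpy()
    vals = frame["nfcc"].to_numpy()
    cutoff = config.weights_cutoff or model.range_
    weights = moran.build_weights(pts, scheme=config.weights_scheme, param=cutoff)
    res = moran.global_moran(vals, weights)
    lisa = moran.local_moran(vals, weights, alpha=config.alpha,
                             n_perm=config.lisa_n_perm, seed=config.seed)
    return res, lisa


@_stage("interpolate")
def _interpolate(frame, model, config, out: Path) -> dict:
    pts = frame[["x", "y"]].to_numpy()
    vals = frame["nfcc"].to_numpy()
    xmin, ymin, xmax, ymax = config.extent
    ncols = int(np.floor((xmax - xmin) / config.map_cell)) + 1
    nrows = int(np.floor((ymax - ymin) / config.map_cell)) + 1
    geom = GridGeometry(xmin, ymin, config.map_cell, nrows, ncols)

    ok_grid = ok_predict(pts, vals, model, geom)
    cio.write_esri_ascii(ok_grid.prediction, geom, out / "ok_prediction.asc")
    cio.write_esri_ascii(ok_grid.variance, geom, out / "ok_variance.asc")

    sim = sgcs(pts, vals, model, geom, n_real=config.n_real, seed=config.seed)
    cio.write_esri_ascii(sim.etype_mean, geom, out / "sgcs_etype_mean.asc")
    cio.write_esri_ascii(sim.etype_variance, geom, out / "sgcs_etype_variance.asc")

    ok_eval, ok_pairs = holdout_validate(pts, vals, frac_train=config.holdout_frac,
                                         seed=config.seed, method="ok", model=model)
    sg_eval, sg_pairs = holdout_validate(pts, vals, frac_train=config.holdout_frac,
                                         seed=config.seed, method="sgcs_etype",
                                         model=model, n_real=config.n_real)
    pd.DataFrame(np.column_stack([ok_pairs, sg_pairs[:, 3]]),
                 columns=["x", "y", "observed", "ok_pred", "sgcs_pred"]
                 ).to_csv(out / "holdout_scatter.csv", index=False)
    return {
        "ok_validation": {"r2": ok_eval.r2, "rmse": ok_eval.rmse, "n": ok_eval.n},
        "sgcs_validation": {"r2": sg_eval.r2, "rmse": sg_eval.rmse, "n": sg_eval.n},
        "ok_surface_variance": float(np.nanvar(ok_grid.prediction)),
        "sgcs_realization_variance": float(np.nanvar(sim.realizations[0])),
    }
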
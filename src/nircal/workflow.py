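"""End-to-end study orchestration.

``run_full_study`` reproduces the structure of a portable-spectrometer SSC
calibration study on one dataset (loaded from CSV or generated synthetically):

1. crop the spectra to the working wavelength range;
2. compare the six pretreatment pipelines under a PLS model (``table2.csv``);
3. fit full-spectrum PLS and LS-SVM on the default pretreatment (``table3.csv``);
4. select wavelengths by BOSS, SPA and BOSS-SPA (``selection.json``);
5. fit PLS / LS-SVM / MLR on each selected subset (``table4.csv``);
6. run the repeated-resampling stability protocol (``stability.csv``).

One Kennard-Stone split is computed on the cropped spectra and frozen for
stages 2–5; stage 6 re-draws random 3:1 splits. A manifest records the
resolved configuration, its hash, package version and per-stage status, so any
report can be traced back to the exact knobs that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import evaluate_model, stability_analysis
from .models import MLR, PLS, LSSVM
from .preprocess import PIPELINE_NAMES, build_pipeline
from .selection import BossConfig, boss, boss_spa, spa
from .spectra import SpectrumSet, crop, read_csv
from .split import SplitResult, kennard_stone
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "run_full_study"]

log = logging.getLogger("nircal")


@dataclass
class RunConfig:
    """Everything a full study run depends on; seed is mandatory."""

    seed: int
    input_csv: str | None = None           # when None, generate synthetically
    synthetic: dict = field(default_factory=dict)
    crop_lo: float = 550.0
    crop_hi: float = 1000.0
    preprocess: str = "sg-msc"             # pretreatment for stages 3-6
    table2_pipelines: tuple[str, ...] = PIPELINE_NAMES
    n_cal: int | None = None               # default: 3/4 of the samples
    max_lv: int = 15
    selection_methods: tuple[str, ...] = ("boss", "spa", "boss-spa")
    boss: dict = field(default_factory=dict)        # BossConfig overrides
    spa_max_vars: int = 30
    #: fraction of the calibration set kept for SPA's internal validation split
    spa_val_fraction: float = 0.2
    lssvm_grid_points: int = 13
    stability_repeats: int = 20
    stability_cal_fraction: float = 0.75
    #: BOSS sub-model count during stability (scaled for the 20x protocol)
    stability_submodels: int = 200
    out_dir: str = "nircal_run"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ValueError("config must set a seed")
        cfg = cls(**d)
        if cfg.preprocess.lower() not in PIPELINE_NAMES:
            build_pipeline(cfg.preprocess)  # raises with the valid names
        for m in cfg.selection_methods:
            if m not in ("boss", "spa", "boss-spa"):
                raise ValueError(f"unknown selection method '{m}'")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["table2_pipelines"] = list(self.table2_pipelines)
        d["selection_methods"] = list(self.selection_methods)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _lssvm_grids(points: int):
    return np.logspace(0, 7, points), np.logspace(0, 6, points)


def _load_dataset(cfg: RunConfig):
    if cfg.input_csv is not None:
        ds = read_csv(cfg.input_csv)
        if ds.ssc is None:
            raise ValueError("input CSV has no 'ssc' column; labels are required")
        return ds, None
    syn = SyntheticConfig(**{"seed": cfg.seed, **cfg.synthetic})
    ds, truth = generate_dataset(syn)
    return ds, truth


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _preprocessed_blocks(ds: SpectrumSet, split: SplitResult, name: str):
    pipe = build_pipeline(name)
    cal = ds.subset(split.calibration_indices)
    pred = ds.subset(split.prediction_indices)
    pipe.fit(cal)
    return pipe.apply(cal), pipe.apply(pred)


def _fit_family(family: str, Xc, yc, seed: int, max_lv: int, grids):
    if family == "pls":
        return PLS(Xc, yc).fit(max_lv=min(max_lv, Xc.shape[1], Xc.shape[0] - 2))
    if family == "lssvm":
        g, s2 = grids
        return LSSVM(Xc, yc).fit(gamma_grid=g, sigma2_grid=s2, seed=seed)
    if family == "mlr":
        return MLR(Xc, yc).fit()
    raise ValueError(f"unknown model family '{family}'")


def run_full_study(config: RunConfig) -> dict:
    """Run every stage, writing reports into ``config.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``). A failing
    stage is recorded as failed; completed artifacts are kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {
        "package": "nircal",
        "version": __version__,
        "config": config.resolved(),
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as err:  # noqa: BLE001 - partial runs keep their artifacts
            log.error("stage %s FAILED: %s", name, err)
            manifest["stages"][name] = {"status": "failed", "error": str(err)}
        else:
            dt = time.perf_counter() - t0
            log.info("stage %s done in %.1f s", name, dt)
            manifest["stages"][name] = {"status": "ok", "seconds": round(dt, 2)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    state: dict = {}

    def load():
        ds, truth = _load_dataset(config)
        ds = crop(ds, config.crop_lo, config.crop_hi)
        n_cal = config.n_cal or int(round(0.75 * ds.n_samples))
        split = kennard_stone(ds.intensities, n_cal)
        split.to_json(out / "split.json")
        state.update(ds=ds, truth=truth, split=split)
        log.info("dataset: %d samples x %d channels; KS split %d/%d",
                 ds.n_samples, ds.n_channels, n_cal, ds.n_samples - n_cal)

    def table2():
        ds, split = state["ds"], state["split"]
        rows = []
        for name in config.table2_pipelines:
            cal, pred = _preprocessed_blocks(ds, split, name)
            res = PLS(cal.intensities, cal.ssc).fit(max_lv=config.max_lv)
            row = evaluate_model(res, cal.intensities, cal.ssc,
                                 pred.intensities, pred.ssc,
                                 model_tag=f"{name}+pls")
            d = row.as_dict()
            d["preprocessing"] = name
            d["LVs"] = res.n_lv
            rows.append(d)
        _write_csv(pd.DataFrame(rows), out / "table2.csv")

    def table3():
        ds, split = state["ds"], state["split"]
        cal, pred = _preprocessed_blocks(ds, split, config.preprocess)
        state.update(cal=cal, pred=pred)
        grids = _lssvm_grids(config.lssvm_grid_points)
        rows = []
        for fam in ("pls", "lssvm"):
            res = _fit_family(fam, cal.intensities, cal.ssc, config.seed,
                              config.max_lv, grids)
            rows.append(evaluate_model(res, cal.intensities, cal.ssc,
                                       pred.intensities, pred.ssc,
                                       model_tag=f"full+{fam}").as_dict())
        _write_csv(pd.DataFrame(rows), out / "table3.csv")

    def select():
        cal = state["cal"]
        Xc, yc = cal.intensities, cal.ssc
        # SPA scores candidate subsets on a KS-internal validation split of the
        # calibration block, never on the frozen prediction set.
        n_fit = int(round((1 - config.spa_val_fraction) * Xc.shape[0]))
        inner = kennard_stone(Xc, n_fit)
        Xf, yf = Xc[inner.calibration_indices], yc[inner.calibration_indices]
        Xv, yv = Xc[inner.prediction_indices], yc[inner.prediction_indices]
        bcfg = BossConfig(**{"seed": config.seed, **config.boss})
        selections: dict[str, object] = {}
        for method in config.selection_methods:
            if method == "boss":
                selections[method] = boss(Xc, yc, bcfg)
            elif method == "spa":
                selections[method] = spa(Xf, yf, Xv, yv, config.spa_max_vars)
            else:
                selections[method] = boss_spa(Xf, yf, Xv, yv, bcfg,
                                              config.spa_max_vars)
        state["selections"] = selections
        doc = {}
        for method, res in selections.items():
            idx = res.selected_indices
            doc[method] = {
                "n_selected": int(idx.size),
                "indices": idx.tolist(),
                "wavelengths_nm": cal.wavelengths[idx].tolist(),
                "nvar_trace": [int(v) for v in res.nvar_trace],
                "rmsecv_trace": [float(v) for v in res.rmsecv_trace],
            }
        (out / "selection.json").write_text(json.dumps(doc, indent=2) + "\n")

    def table4():
        cal, pred = state["cal"], state["pred"]
        grids = _lssvm_grids(config.lssvm_grid_points)
        rows = []
        for method, res in state["selections"].items():
            cols = res.selected_indices
            Xc = cal.intensities[:, cols]
            Xp = pred.intensities[:, cols]
            for fam in ("pls", "lssvm", "mlr"):
                try:
                    fitted = _fit_family(fam, Xc, cal.ssc, config.seed,
                                         config.max_lv, grids)
                    row = evaluate_model(fitted, Xc, cal.ssc, Xp, pred.ssc,
                                         model_tag=f"{method}+{fam}")
                except (ValueError, np.linalg.LinAlgError) as err:
                    log.warning("table4 %s+%s skipped: %s", method, fam, err)
                    continue
                d = row.as_dict()
                d["selection"] = method
                rows.append(d)
        _write_csv(pd.DataFrame(rows), out / "table4.csv")

    def stability():
        ds = state["ds"]
        pipe_name = config.preprocess
        bcfg = BossConfig(**{"seed": config.seed, **config.boss})
        bcfg.n_submodels = config.stability_submodels
        grids = _lssvm_grids(min(config.lssvm_grid_points, 9))
        max_lv = config.max_lv

        def selector(Xc, yc, seed):
            cfg = dataclasses.replace(bcfg, seed=seed)
            n_fit = int(round((1 - config.spa_val_fraction) * Xc.shape[0]))
            inner = kennard_stone(Xc, n_fit)
            res = boss_spa(Xc[inner.calibration_indices],
                           yc[inner.calibration_indices],
                           Xc[inner.prediction_indices],
                           yc[inner.prediction_indices],
                           cfg, config.spa_max_vars)
            return res.selected_indices

        builders = {
            "boss-spa-pls": lambda Xc, yc, seed: PLS(Xc, yc).fit(
                max_lv=min(max_lv, Xc.shape[1], Xc.shape[0] - 2)),
            "boss-spa-lssvm": lambda Xc, yc, seed: LSSVM(Xc, yc).fit(
                gamma_grid=grids[0], sigma2_grid=grids[1], seed=seed),
            "boss-spa-mlr": lambda Xc, yc, seed: MLR(Xc, yc).fit(),
        }
        prep = _StabilityPreprocessor(ds, pipe_name)
        report = stability_analysis(
            prep.matrix, ds.ssc, builders,
            n_repeats=config.stability_repeats,
            cal_fraction=config.stability_cal_fraction,
            base_seed=config.seed, selector=selector)
        _write_csv(report.rows, out / "stability.csv")
        _write_csv(report.summary().reset_index(), out / "stability_summary.csv")
        state["stability"] = report

    _stage("load", load)
    if "ds" in state:
        _stage("table2", table2)
        _stage("table3", table3)
        if "cal" in state:
            _stage("select", select)
            if "selections" in state:
                _stage("table4", table4)
            _stage("stability", stability)

    manifest["complete"] = all(
        s.get("status") == "ok" for s in manifest["stages"].values()
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    log.removeHandler(handler)
    handler.close()
    state["manifest"] = manifest
    return state


class _StabilityPreprocessor:
    """Applies the chosen pretreatment once to the whole set for the stability
    stage.

    MSC's reference is the grand mean rather than each repeat's calibration
    mean; for a 20x protocol the difference is a second-order effect and
    keeping one matrix makes the repeats directly comparable.
    """

    def __init__(self, ds: SpectrumSet, pipeline_name: str):
        pipe = build_pipeline(pipeline_name)
        self.matrix = pipe.fit(ds).apply(ds).intensities
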
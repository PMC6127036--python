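"""Trial-table IO, run configuration, and the reproducible pipeline.

Trial tables are tab-separated text with a header; columns:

    subject_id  block_id  trial_index  base_rate  coherence_signed
    direction  duration_s  [choice  confidence_raw  confidence_category
    belief_report]

The behavioral columns are optional (stimulus-only tables feed the
observer simulator).  Validation errors name the offending row.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .task import BASE_RATES, COHERENCES

REQUIRED_COLUMNS = ["subject_id", "block_id", "trial_index", "base_rate",
                    "coherence_signed", "duration_s"]
BEHAVIOR_COLUMNS = ["choice", "confidence_raw", "confidence_category",
                    "belief_report"]
_FLOAT_FMT = "%.12g"


class ValidationError(ValueError):
    pass


def _check(cond, row, msg):
    if not cond:
        raise ValidationError(f"row {row}: {msg}")


def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    mags = np.round(np.abs(df["coherence_signed"].to_numpy(dtype=float)), 6)
    ok_mag = np.isin(mags, np.round(COHERENCES, 6))
    if not ok_mag.all():
        _check(False, int(np.argmax(~ok_mag)) + 1,
               f"coherence magnitude {mags[~ok_mag][0]} not in {COHERENCES}")
    rates = np.round(df["base_rate"].to_numpy(dtype=float), 6)
    ok_b = np.isin(rates, np.round(BASE_RATES, 6))
    if not ok_b.all():
        _check(False, int(np.argmax(~ok_b)) + 1,
               f"base_rate {rates[~ok_b][0]} not in {BASE_RATES}")
    if "confidence_raw" in df.columns and df["confidence_raw"].notna().any():
        conf = df["confidence_raw"].to_numpy(dtype=float)
        bad = (conf < 0.5) | (conf > 1.0)
        if bad.any():
            _check(False, int(np.argmax(bad)) + 1,
                   f"confidence_raw {conf[bad][0]} outside [0.5, 1]")
    if "belief_report" in df.columns and df["belief_report"].notna().any():
        bel = df["belief_report"].to_numpy(dtype=float)
        bad = (bel < 0.0) | (bel > 1.0)
        if bad.any():
            _check(False, int(np.argmax(bad)) + 1,
                   f"belief_report {bel[bad][0]} outside [0, 1]")
    # trial_index contiguous and 1-based within each (subject, block)
    for (s, b), grp in df.groupby(["subject_id", "block_id"], sort=False):
        ti = grp["trial_index"].to_numpy(dtype=int)
        if not np.array_equal(ti, np.arange(1, len(ti) + 1)):
            _check(False, int(grp.index[0]) + 1,
                   f"trial_index not contiguous 1-based in subject {s} block {b}")
    return df


def read_trial_table(path) -> pd.DataFrame:
    """Read and validate a tab-separated trial table."""
    df = pd.read_csv(path, sep="\t")
    return validate_trial_table(df)


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Validate and write a trial table (TSV, 12 significant digits)."""
    validate_trial_table(df)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; all randomness flows from ``seed``."""

    seed: int = 0
    out_dir: str = "priorlearn_run"
    n_blocks: int = 30
    models: tuple[str, ...] = ("bayesian", "choice_only", "choice_confidence")
    n_starts: int = 5
    n_sim: int = 50
    generator: dict = field(default_factory=dict)  # ObserverParams overrides
    fit: dict = field(default_factory=dict)        # FitConfig overrides

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.models = tuple(cfg.models)
        return cfg


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def pipeline_run(config: RunConfig) -> Path:
    """simulate-task -> simulate-observer -> fit -> predict -> evaluate.

    Writes all artifacts plus a manifest (seeds, config hash, file hashes,
    per-stage wall time) into ``config.out_dir``; identical config and seed
    give byte-identical numeric outputs.
    """
    from . import __version__
    from .task import generate_experiment
    from .observer import DEFAULT_GENERATOR_PARAMS, ObserverParams, simulate_observer
    from .ddm import AccumulatorParams, counterfactual_posterior_map
    from .fitting import FitConfig, fit_model, compare_models
    from .evaluation import (predict_beliefs, reported_end_of_block,
                             end_of_block_mse, run_regression)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=list)
    # the hash covers the scientific configuration, not where it is written
    hashed = json.dumps({k: v for k, v in cfg_dict.items() if k != "out_dir"},
                        sort_keys=True, default=list)
    manifest = dict(config=json.loads(cfg_json),
                    config_hash=hashlib.sha256(hashed.encode()).hexdigest()[:16],
                    version=__version__, seed=config.seed, stages={}, files={})
    manifest_path = out / "manifest.json"

    def _stage(name):
        manifest["stages"][name] = dict(t0=time.time())

    def _done(name, **extra):
        manifest["stages"][name]["wall_s"] = round(
            time.time() - manifest["stages"][name].pop("t0"), 3)
        manifest["stages"][name].update(extra)
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    try:
        _stage("simulate_task")
        design = generate_experiment(config.n_blocks, rng_seed=config.seed)
        stim_path = out / "stimuli.tsv"
        write_trial_table(design.to_frame(), stim_path)
        _done("simulate_task", n_trials=design.n_trials)

        _stage("simulate_observer")
        gen = ObserverParams(**{**asdict(DEFAULT_GENERATOR_PARAMS),
                                **config.generator})
        fit_cfg = FitConfig(**config.fit)
        acc = AccumulatorParams(kappa=gen.kappa, bound=gen.bound,
                                dt=fit_cfg.dt, n_evidence=fit_cfg.n_evidence,
                                dt_sim=0.001)
        maps = counterfactual_posterior_map(acc)
        data = simulate_observer(design, gen, maps,
                                 np.random.default_rng([config.seed, 1]))
        data_path = out / "behavior.tsv"
        write_trial_table(data, data_path)
        _done("simulate_observer")

        fits = {}
        for m in config.models:
            _stage(f"fit_{m}")
            fit = fit_model(data, m, n_starts=config.n_starts,
                            rng=np.random.default_rng([config.seed, 2]),
                            config=fit_cfg)
            (out / f"fit_{m}.json").write_text(fit.to_json())
            fits[m] = fit
            _done(f"fit_{m}", llf=fit.llf, floor_count=fit.floor_count)
        comp = compare_models(list(fits.values()))
        comp.to_csv(out / "model_comparison.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT)

        _stage("predict_beliefs")
        best_id = comp.sort_values("aic").iloc[0]["model_id"]
        best = fits[best_id]
        bp = best.observer_params()
        bmaps = counterfactual_posterior_map(
            AccumulatorParams(kappa=bp.kappa, bound=bp.bound, dt=fit_cfg.dt,
                              n_evidence=fit_cfg.n_evidence, dt_sim=0.001))
        pred = predict_beliefs(bp, data, bmaps, n_sim=config.n_sim,
                               rng=np.random.default_rng([config.seed, 3]))
        mse = end_of_block_mse(pred.mean_end_of_block().to_numpy(),
                               reported_end_of_block(data).to_numpy())
        pd.DataFrame({"block_id": pred.mean_end_of_block().index,
                      "predicted": pred.mean_end_of_block().to_numpy(),
                      "reported": reported_end_of_block(data).to_numpy()}
                     ).to_csv(out / "belief_end_of_block.tsv", sep="\t",
                              index=False, float_format=_FLOAT_FMT)
        _done("predict_beliefs", best_model=str(best_id), end_of_block_mse=mse)

        _stage("evaluate")
        reg = run_regression("eq19_choice_bias", data)
        pd.DataFrame({"coef": reg.params, "se": reg.bse}).to_csv(
            out / "eq19_coefficients.tsv", sep="\t", float_format=_FLOAT_FMT)
        _done("evaluate")
    except Exception as exc:
        manifest["failed_stage"] = next(
            (k for k, v in manifest["stages"].items() if "wall_s" not in v), None)
        manifest["error"] = repr(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        raise

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("fit_*.json")):
        manifest["files"][f.name] = _sha(f)
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest_path
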
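"""Pipeline orchestration: simulate -> quantify -> features -> classify -> ephys.

Each stage reads the previous stage's serialized outputs from the run
directory (or externally supplied files), so stages can be re-run in
isolation with identical results. A machine-readable ``manifest.json`` lists
the configuration echo and hash, the resolved seed, package versions and the
SHA-256 of every output file; for a fixed config and seed two runs are
bit-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__, classify as clf, ephys, io, quant, synth
from .config import RunConfig
from .errors import AISQuantError, PipelineError
from .profiles import NeuronRecord

logger = logging.getLogger("aisquant")


def _setup_logging(run_dir: Path, level: str) -> None:
    logger.setLevel(level)
    logger.handlers = [h for h in logger.handlers
                       if not isinstance(h, logging.FileHandler)]
    handler = logging.FileHandler(run_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"))
    logger.addHandler(handler)


def _cohort_config(config: RunConfig, seed: int) -> synth.SyntheticCohortConfig:
    return synth.SyntheticCohortConfig(
        **config.cohort.model_dump(),
        effect=synth.EffectConfig(**config.effect.model_dump()),
        seed=seed)


def _stage_simulate(config: RunConfig, run_dir: Path, chash: str, seed: int) -> None:
    cohort_cfg = _cohort_config(config, seed)
    records = synth.generate_cohort(cohort_cfg)
    io.write_cohort_csv(records, run_dir / "cohort.csv", chash)
    io.write_ground_truth_json(records, run_dir / "ground_truth.json", chash)
    logger.info("simulate: wrote %d records", len(records))

    e = config.ephys
    proto_f = ephys.StepProtocol(**e.firing_protocol.model_dump())
    proto_p = ephys.StepProtocol(**e.passive_protocol.model_dump())
    for i in range(e.n_cells):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1000 + i,)))
        factor = float(np.exp(rng.normal(0.0, e.rin_cv))) if e.rin_cv > 0 else 1.0
        cell_seed = int(rng.integers(0, 2 ** 31))
        cell = synth.SyntheticCellConfig(
            **{**e.cell.model_dump(), "rin_mohm": e.cell.rin_mohm * factor},
            protocol=proto_f, seed=cell_seed)
        cell_id = f"cell_{i:03d}"
        firing = synth.generate_sweep_family(cell, cell_id)
        passive = synth.generate_sweep_family(cell, cell_id, protocol=proto_p)
        io.write_sweeps_csv(firing, run_dir / "sweeps" / f"{cell_id}_firing.csv",
                            run_dir / "sweeps" / f"{cell_id}_firing.json", chash)
        io.write_sweeps_csv(passive, run_dir / "sweeps" / f"{cell_id}_passive.csv",
                            run_dir / "sweeps" / f"{cell_id}_passive.json", chash)
    logger.info("simulate: wrote %d sweep families", 2 * e.n_cells)


def _load_cohort(config: RunConfig, run_dir: Path) -> List[NeuronRecord]:
    cohort_path = Path(config.cohort_csv) if config.cohort_csv else run_dir / "cohort.csv"
    truth_path = (Path(config.ground_truth_json) if config.ground_truth_json
                  else run_dir / "ground_truth.json")
    if not cohort_path.exists():
        raise PipelineError(f"cohort file not found: {cohort_path}")
    return io.read_cohort_csv(cohort_path, truth_path)


def _stage_quantify(config: RunConfig, run_dir: Path, chash: str) -> None:
    records = _load_cohort(config, run_dir)
    q = config.quantify
    background = config.cohort.background_level
    results = []
    for rec in records:
        bg = rec.ground_truth.background_level if rec.ground_truth else background
        try:
            results.append(quant.quantify_neuron(rec, bg, bg, q.threshold_fraction,
                                                 q.smooth_window))
        except AISQuantError as exc:
            raise PipelineError(f"quantify failed at record {rec.neuron_id}: {exc}") from exc
    results = quant.normalize_to_control(results, q.control_label)
    io.write_quant_csv(results, run_dir / "quant.csv", chash)
    logger.info("quantify: wrote %d rows", len(results))


def _stage_features(config: RunConfig, run_dir: Path, chash: str) -> None:
    records = _load_cohort(config, run_dir)
    quant_path = run_dir / "quant.csv"
    if not quant_path.exists():
        raise PipelineError(f"quant table not found: {quant_path}")
    qdf = io.read_quant_csv(quant_path).set_index("neuron_id")
    adr_col = "normalized_adr" if config.classify.use_normalized_adr else "adr"
    background = config.cohort.background_level
    rows = []
    for rec in records:
        if rec.neuron_id not in qdf.index:
            raise PipelineError(f"features: {rec.neuron_id} missing from quant table")
        bg = rec.ground_truth.background_level if rec.ground_truth else background
        profile = quant.subtract_background(rec.ais_profile, bg)
        try:
            denoised = clf.denoise_profile(profile)
            fv = clf.compute_features(denoised, float(qdf.loc[rec.neuron_id, adr_col]))
        except AISQuantError as exc:
            raise PipelineError(f"features failed at record {rec.neuron_id}: {exc}") from exc
        rows.append({"neuron_id": rec.neuron_id, "label": rec.treatment,
                     **dataclasses.asdict(fv)})
    io.write_features_csv(pd.DataFrame(rows), run_dir / "features.csv", chash)
    logger.info("features: wrote %d rows", len(rows))


def _stage_classify(config: RunConfig, run_dir: Path, chash: str, seed: int) -> None:
    path = run_dir / "features.csv"
    if not path.exists():
        raise PipelineError(f"feature table not found: {path}")
    df = io.read_features_csv(path)
    X = df[list(clf.FEATURE_NAMES)].to_numpy()
    c = config.classify
    result = clf.run_repeated_classification(
        X, df["label"].tolist(), n_repeats=c.n_repeats, seed=seed,
        train_fraction=c.train_fraction, kernel=c.kernel, c=c.c,
        stratified=c.stratified)
    io.write_classification_json(result, run_dir / "classification.json",
                                 config_echo=c.model_dump(), config_hash=chash)
    logger.info("classify: mean accuracy %.3f +/- %.3f over %d repeats",
                result.mean_accuracy, result.sd_accuracy, result.n_repeats)


def _stage_ephys(config: RunConfig, run_dir: Path, chash: str) -> None:
    sweep_dir = run_dir / "sweeps"
    firing_files = sorted(sweep_dir.glob("*_firing.csv"))
    if not firing_files:
        raise PipelineError(f"no sweep families found under {sweep_dir}")
    rows = []
    for firing_csv in firing_files:
        cell_id = firing_csv.name.replace("_firing.csv", "")
        firing = io.read_sweeps_csv(firing_csv, firing_csv.with_suffix(".json"))
        passive_csv = sweep_dir / f"{cell_id}_passive.csv"
        passive = io.read_sweeps_csv(passive_csv, passive_csv.with_suffix(".json"))
        try:
            spikes = ephys.extract_spike_features(firing)
            props = ephys.passive_properties(passive)
        except AISQuantError as exc:
            raise PipelineError(f"ephys failed at cell {cell_id}: {exc}") from exc
        rows.append({
            "cell_id": cell_id,
            "voltage_threshold_mv": spikes.voltage_threshold_mv,
            "current_threshold_pa": spikes.current_threshold_pa,
            "rin_mohm": props.rin_mohm,
            "tau_ms": props.tau_ms,
            "capacitance_pf": props.capacitance_pf,
            "upstroke_mv_per_ms": spikes.upstroke_mv_per_ms,
            "downstroke_mv_per_ms": spikes.downstroke_mv_per_ms,
            "latency_ms": spikes.latency_to_first_peak_ms,
            "max_spikes": spikes.max_spike_count,
            "max_freq_hz": spikes.max_firing_frequency_hz,
        })
    io.write_features_csv(pd.DataFrame(rows), run_dir / "ephys_features.csv", chash)
    logger.info("ephys: wrote %d cells", len(rows))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    seed = config.resolved_seed()
    if "simulate" not in config.stages and config.cohort_csv is not None:
        if not Path(config.cohort_csv).exists():
            raise PipelineError(f"input cohort not found: {config.cohort_csv}")
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(run_dir, config.log_level)
    chash = config.config_hash()
    logger.info("run start: config hash %s, seed %d", chash, seed)

    stage_fns = {
        "simulate": lambda: _stage_simulate(config, run_dir, chash, seed),
        "quantify": lambda: _stage_quantify(config, run_dir, chash),
        "features": lambda: _stage_features(config, run_dir, chash),
        "classify": lambda: _stage_classify(config, run_dir, chash, seed),
        "ephys": lambda: _stage_ephys(config, run_dir, chash),
    }
    for stage in config.stages:
        logger.info("stage %s", stage)
        stage_fns[stage]()

    outputs = sorted(p for p in run_dir.rglob("*")
                     if p.is_file() and p.name not in ("manifest.json", "pipeline.log"))
    manifest = {
        "config": config.model_dump(),
        "config_hash": chash,
        "seed": seed,
        "stages": list(config.stages),
        "versions": {"aisquant": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "inputs": {"cohort_csv": config.cohort_csv,
                   "ground_truth_json": config.ground_truth_json},
        "outputs": {str(p.relative_to(run_dir)): _sha256(p) for p in outputs},
    }
    io._write_json(manifest, run_dir / "manifest.json")
    logger.info("run complete: %d output files", len(outputs))
    return run_dir
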
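"""Plain-text readers and writers.

Cohorts are exchanged as a long-format CSV (neuron_id, condition,
compartment, position_um, intensity) with a JSON ground-truth sidecar;
images as TIFF plus a JSON ROI file (rectangles as 0-based half-open pixel
bounds); sweep families as one CSV per cell (time_ms then one voltage column
per sweep) plus a JSON protocol sidecar. Tabular results are CSV with a
one-line header; an optional leading ``# config_hash=...`` comment line ties
every output file to the run configuration that produced it.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .classify import ClassificationResult
from .ephys import (CellGroundTruth, CurrentClampRecording, CurrentClampSweep,
                    StepProtocol)
from .errors import PipelineError
from .profiles import (AIS, DENDRITE, IntensityProfile, NeuronRecord,
                       ProfileGroundTruth, QuantResult, Rect)


def _write_csv(df: pd.DataFrame, path: Path, config_hash: Optional[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _write_json(obj, path: Path, config_hash: Optional[str] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if config_hash is not None and isinstance(obj, dict):
        obj = {"config_hash": config_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# -------------------------------------------------------------------------
# imaging cohorts
# -------------------------------------------------------------------------

def write_cohort_csv(records: Sequence[NeuronRecord], path: Path,
                     config_hash: Optional[str] = None) -> None:
    rows = []
    for rec in records:
        for comp, prof in ((AIS, rec.ais_profile), (DENDRITE, rec.dendrite_profile)):
            rows.append(pd.DataFrame({
                "neuron_id": rec.neuron_id,
                "condition": rec.treatment,
                "compartment": comp,
                "position_um": prof.positions_um,
                "intensity": prof.intensities,
            }))
    _write_csv(pd.concat(rows, ignore_index=True), path, config_hash)


def write_ground_truth_json(records: Sequence[NeuronRecord], path: Path,
                            config_hash: Optional[str] = None) -> None:
    truths = {}
    for rec in records:
        if rec.ground_truth is not None:
            truths[rec.neuron_id] = {"analyte": rec.analyte,
                                     **dataclasses.asdict(rec.ground_truth)}
    _write_json({"records": truths}, path, config_hash)


def read_cohort_csv(path: Path, ground_truth_path: Optional[Path] = None,
                    analyte: str = "synthetic") -> List[NeuronRecord]:
    df = _read_csv(path)
    truths = {}
    if ground_truth_path is not None and Path(ground_truth_path).exists():
        raw = json.loads(Path(ground_truth_path).read_text())["records"]
        for nid, d in raw.items():
            d = dict(d)
            d.pop("analyte", None)
            truths[nid] = ProfileGroundTruth(**d)
    records = []
    for nid, group in df.groupby("neuron_id", sort=False):
        condition = str(group["condition"].iloc[0])
        profiles = {}
        for comp, sub in group.groupby("compartment", sort=False):
            pos = sub["position_um"].to_numpy()
            if pos.size < 3:
                raise PipelineError(f"{nid}/{comp}: fewer than 3 samples in {path}")
            pixel = float(np.median(np.diff(pos)))
            profiles[comp] = IntensityProfile(pos, sub["intensity"].to_numpy(),
                                              pixel, comp, analyte)
        if AIS not in profiles or DENDRITE not in profiles:
            raise PipelineError(f"{nid}: missing a compartment profile in {path}")
        records.append(NeuronRecord(nid, condition, analyte, profiles[AIS],
                                    profiles[DENDRITE], truths.get(nid)))
    return records


# -------------------------------------------------------------------------
# images
# -------------------------------------------------------------------------

def write_image_tiff(image: np.ndarray, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image_tiff(path: Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_rois_json(rois: Dict[str, Rect], path: Path) -> None:
    _write_json({name: r.to_dict() for name, r in rois.items()}, path)


def read_rois_json(path: Path) -> Dict[str, Rect]:
    raw = json.loads(Path(path).read_text())
    return {name: Rect.from_dict(d) for name, d in raw.items() if name != "config_hash"}


# -------------------------------------------------------------------------
# current-clamp sweep families
# -------------------------------------------------------------------------

def write_sweeps_csv(recording: CurrentClampRecording, csv_path: Path,
                     sidecar_path: Path, config_hash: Optional[str] = None) -> None:
    data = {"time_ms": recording.sweeps[0].time_ms}
    for i, sweep in enumerate(recording.sweeps):
        data[f"sweep_{i:03d}"] = sweep.voltage_mv
    _write_csv(pd.DataFrame(data), csv_path, config_hash)
    sidecar = {
        "cell_id": recording.cell_id,
        "protocol": dataclasses.asdict(recording.protocol),
        "amplitudes_pa": [s.current_amplitude_pa for s in recording.sweeps],
        "step_onset_ms": recording.sweeps[0].step_onset_ms,
        "step_offset_ms": recording.sweeps[0].step_offset_ms,
    }
    if recording.ground_truth is not None:
        gt = dataclasses.asdict(recording.ground_truth)
        gt["spike_times_ms"] = [list(map(float, t)) for t in gt["spike_times_ms"]]
        sidecar["ground_truth"] = gt
    _write_json(sidecar, sidecar_path, config_hash)


def read_sweeps_csv(csv_path: Path, sidecar_path: Path) -> CurrentClampRecording:
    df = _read_csv(csv_path)
    meta = json.loads(Path(sidecar_path).read_text())
    time = df["time_ms"].to_numpy()
    sweeps = []
    for i, amp in enumerate(meta["amplitudes_pa"]):
        sweeps.append(CurrentClampSweep(
            time_ms=time, voltage_mv=df[f"sweep_{i:03d}"].to_numpy(),
            current_amplitude_pa=float(amp),
            step_onset_ms=float(meta["step_onset_ms"]),
            step_offset_ms=float(meta["step_offset_ms"])))
    truth = None
    if "ground_truth" in meta:
        gt = dict(meta["ground_truth"])
        gt["spike_times_ms"] = [np.asarray(t) for t in gt["spike_times_ms"]]
        truth = CellGroundTruth(**gt)
    return CurrentClampRecording(cell_id=meta["cell_id"], sweeps=sweeps,
                                 protocol=StepProtocol(**meta["protocol"]),
                                 ground_truth=truth)


# -------------------------------------------------------------------------
# results tables and reports
# -------------------------------------------------------------------------

QUANT_COLUMNS = ["neuron_id", "treatment", "analyte", "ais_length_um",
                 "ais_integrated_sum", "dendrite_integrated_sum", "adr",
                 "adr_defined", "clamped_start", "clamped_end",
                 "normalized_ais", "normalized_dendrite", "normalized_adr"]


def write_quant_csv(results: Sequence[QuantResult], path: Path,
                    config_hash: Optional[str] = None) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in results], columns=QUANT_COLUMNS)
    _write_csv(df, path, config_hash)


def read_quant_csv(path: Path) -> pd.DataFrame:
    return _read_csv(path)


def write_features_csv(df: pd.DataFrame, path: Path,
                       config_hash: Optional[str] = None) -> None:
    _write_csv(df, path, config_hash)


def read_features_csv(path: Path) -> pd.DataFrame:
    return _read_csv(path)


def write_classification_json(result: ClassificationResult, path: Path,
                              config_echo: Optional[dict] = None,
                              config_hash: Optional[str] = None) -> None:
    payload = {
        "mean_accuracy": result.mean_accuracy,
        "sd_accuracy": result.sd_accuracy,
        "n_repeats": result.n_repeats,
        "train_size": result.train_size,
        "test_size": result.test_size,
        "confusion_totals": result.confusion_totals,
        "per_repeat_accuracy": [float(a) for a in result.per_repeat_accuracy],
        "seed": result.seed,
        "positive_label": result.positive_label,
    }
    if config_echo is not None:
        payload["config"] = config_echo
    _write_json(payload, path, config_hash)
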
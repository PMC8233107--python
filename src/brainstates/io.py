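"""Plain-text I/O: parcellated series TSV + events TSV, config YAML/JSON,
distance matrices and segmentations as CSV with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import StateDistanceMatrix
from .synthetic import Block, ParcelSeries, StudyConfig


def exclude_regions(region_labels: list[str] | int,
                    excluded_indices: tuple[int, ...]) -> list[str]:
    """Drop atlas parcels by 0-based index (e.g. parcels with no coverage).

    Accepts either explicit labels or a region count (labels are generated).
    """
    if isinstance(region_labels, int):
        region_labels = [f"R{r:03d}" for r in range(region_labels)]
    bad = set(excluded_indices)
    out_of_range = [i for i in bad if i < 0 or i >= len(region_labels)]
    if out_of_range:
        raise ValueError(f"excluded indices out of range: {out_of_range}")
    return [l for i, l in enumerate(region_labels) if i not in bad]


def write_parcel_series(series: ParcelSeries, signal_path, events_path) -> None:
    """Signal as TSV (rows = time, header = region labels) plus an events TSV
    (onset, duration, trial_type, performance)."""
    df = pd.DataFrame(series.signal.T, columns=series.region_labels)
    df.to_csv(signal_path, sep="\t", index=False, float_format="%.17g")
    ev = pd.DataFrame(
        [(on, dur, cond, "" if perf is None else perf)
         for cond, on, dur, perf in series.events],
        columns=["onset", "duration", "trial_type", "performance"])
    ev.to_csv(events_path, sep="\t", index=False)


def read_parcel_series(signal_path, events_path=None, tr: float = 1.5,
                       volunteer_id: str | None = None) -> ParcelSeries:
    """Read and validate a parcellated series (and optional events table)."""
    df = pd.read_csv(signal_path, sep="\t")
    if df.isna().any().any():
        bad = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0]) + 2
        raise ValueError(f"{signal_path}: missing/ragged values near line {bad}")
    events: list[tuple[str, float, float, float | None]] = []
    if events_path is not None:
        ev = pd.read_csv(events_path, sep="\t")
        required = {"onset", "duration", "trial_type"}
        missing = required - set(ev.columns)
        if missing:
            raise ValueError(f"{events_path}: missing columns {sorted(missing)}")
        for i, row in ev.iterrows():
            perf = row.get("performance", None)
            perf = None if perf is None or (isinstance(perf, float) and np.isnan(perf)) \
                or perf == "" else float(perf)
            events.append((str(row["trial_type"]), float(row["onset"]),
                           float(row["duration"]), perf))
    name = volunteer_id or Path(str(signal_path)).stem
    return ParcelSeries(volunteer_id=name, signal=df.to_numpy().T, tr=tr,
                        region_labels=list(df.columns), events=events)


def _config_to_dict(config: StudyConfig) -> dict:
    d = {
        "n_volunteers": config.n_volunteers,
        "n_regions": config.n_regions,
        "tr": config.tr,
        "band": list(config.band),
        "coupling_strength": config.coupling_strength,
        "idiosyncrasy_strength": config.idiosyncrasy_strength,
        "performance_effect": config.performance_effect,
        "ar1_phi": config.ar1_phi,
        "noise_sd": config.noise_sd,
        "n_communities": config.n_communities,
        "seed": config.seed,
        "block_layout": [
            {"condition": b.condition, "duration": b.duration,
             "instruction_duration": b.instruction_duration,
             "performance": b.performance}
            for b in config.block_layout
        ],
    }
    return d


def write_study_config(config: StudyConfig, path) -> None:
    path = Path(path)
    d = _config_to_dict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def read_study_config(path) -> StudyConfig:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    layout = [Block(condition=b["condition"], duration=b["duration"],
                    instruction_duration=b.get("instruction_duration", 12.0),
                    performance=b.get("performance"))
              for b in d.pop("block_layout")]
    d["band"] = tuple(d["band"])
    return StudyConfig(block_layout=layout, **d)


def write_distance_matrix(sdm: StateDistanceMatrix, csv_path, meta_path) -> None:
    pd.DataFrame(sdm.D).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {"metric_name": sdm.metric_name, "n": sdm.n,
               "points": sdm.points.to_dict(orient="list")}
    Path(meta_path).write_text(json.dumps(sidecar, indent=2, default=str))


def read_distance_matrix(csv_path, meta_path) -> StateDistanceMatrix:
    D = pd.read_csv(csv_path).to_numpy()
    meta = json.loads(Path(meta_path).read_text())
    return StateDistanceMatrix(metric_name=meta["metric_name"], D=D,
                               points=pd.DataFrame(meta["points"]))
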
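"""Plain-text cohort storage: CSV signals, JSON annotations, JSON manifest.

A cohort directory holds one ``<swallow_id>.csv`` per swallow (columns
time_s, ap, si, ml), one ``<swallow_id>.json`` with the true trajectory and
every rater's annotation, and a ``manifest.json`` listing swallows with
participant ids and labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RawSwallowSignal
from .simulate import Cohort, SimulatedSwallow, SwallowSimConfig
from .targets import HyoidAnnotation

__all__ = ["save_cohort", "load_cohort", "save_signal_csv", "load_signal_csv"]


def save_signal_csv(sig: RawSwallowSignal, path: Path) -> None:
    t = np.arange(sig.n_samples) / sig.sampling_rate
    pd.DataFrame({"time_s": t, "ap": sig.data[:, 0], "si": sig.data[:, 1],
                  "ml": sig.data[:, 2]}).to_csv(path, index=False)


def load_signal_csv(path: Path, swallow_id: str = "",
                    participant_id: str = "") -> RawSwallowSignal:
    df = pd.read_csv(path)
    dt = np.diff(df["time_s"].to_numpy()[:2])[0]
    return RawSwallowSignal(df[["ap", "si", "ml"]].to_numpy(),
                            sampling_rate=round(1.0 / dt),
                            swallow_id=swallow_id,
                            participant_id=participant_id)


def _annotation_to_obj(ann: HyoidAnnotation) -> dict:
    return {"rater_id": ann.rater_id,
            "anterior": ann.anterior.tolist(),
            "c2": ann.c2.tolist(),
            "c4": ann.c4.tolist()}


def _annotation_from_obj(obj: dict) -> HyoidAnnotation:
    return HyoidAnnotation(np.asarray(obj["anterior"]),
                           np.asarray(obj["c2"]), np.asarray(obj["c4"]),
                           rater_id=obj["rater_id"])


def save_cohort(cohort: Cohort, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: list(v) if isinstance(v, tuple) else v
                           for k, v in cohort.config.__dict__.items()},
                "swallows": []}
    for sw in cohort.swallows:
        save_signal_csv(sw.signal, directory / f"{sw.swallow_id}.csv")
        ann_obj = {
            "true_trajectory": sw.true_trajectory.tolist(),
            "raters": [_annotation_to_obj(a) for a in sw.annotations],
        }
        (directory / f"{sw.swallow_id}.json").write_text(
            json.dumps(ann_obj))
        manifest["swallows"].append({
            "swallow_id": sw.swallow_id,
            "participant_id": sw.participant_id,
            "gender": sw.gender,
            "stroke_history": sw.stroke_history,
            "signal_csv": f"{sw.swallow_id}.csv",
            "annotation_json": f"{sw.swallow_id}.json",
        })
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg_obj = {k: tuple(v) if isinstance(v, list) else v
               for k, v in manifest["config"].items()}
    config = SwallowSimConfig(**cfg_obj)
    swallows = []
    for entry in manifest["swallows"]:
        sig = load_signal_csv(directory / entry["signal_csv"],
                              entry["swallow_id"], entry["participant_id"])
        ann_obj = json.loads(
            (directory / entry["annotation_json"]).read_text())
        swallows.append(SimulatedSwallow(
            signal=sig,
            true_trajectory=np.asarray(ann_obj["true_trajectory"]),
            annotations=[_annotation_from_obj(o) for o in ann_obj["raters"]],
            participant_id=entry["participant_id"],
            gender=entry["gender"],
            stroke_history=entry["stroke_history"],
            swallow_id=entry["swallow_id"],
        ))
    return Cohort(swallows, config)
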
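"""Dataset / result / configuration I/O and run manifests.

Datasets are CSV files with an ``abscissa,value,weight`` header plus a JSON
sidecar (``<name>.json``) carrying the protocol, observable, normalization
and provenance, so a dataset round-trips losslessly.  Configurations are
YAML (JSON accepted).  Every pipeline run writes a RunManifest recording
the command, config hash, package version, seed and the files it read and
wrote.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
import datetime
import hashlib
import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from .calibrate import CalibrationDataset
from .network import InhibitorSpec, ModelError
from .simulate import StimulusEvent, StimulusProtocol


def _protocol_to_dict(p: StimulusProtocol) -> dict:
    return {
        "events": [{"time": e.time, "species": e.species,
                    "amount": e.amount, "units": e.units}
                   for e in p.events],
        "inhibitors": [{"target": i.target, "fraction": i.fraction,
                        "apply_time": i.apply_time}
                       for i in p.inhibitors],
        "t_end": p.t_end,
    }


def _protocol_from_dict(d: dict) -> StimulusProtocol:
    return StimulusProtocol(
        events=[StimulusEvent(e["time"], e["species"], e["amount"],
                              e.get("units", "ng_per_mL"))
                for e in d.get("events", [])],
        inhibitors=[InhibitorSpec(i["target"], i["fraction"],
                                  i.get("apply_time", 0.0))
                    for i in d.get("inhibitors", [])],
        t_end=d.get("t_end", 120.0),
    )


def write_dataset_csv(dataset: CalibrationDataset, path) -> pathlib.Path:
    path = pathlib.Path(path)
    with open(path, "w") as fh:
        fh.write("abscissa,value,weight\n")
        for a, v, w in dataset.points:
            fh.write(f"{a!r},{v!r},{w!r}\n")
    sidecar = {
        "id": dataset.id,
        "observable": dataset.observable,
        "abscissa_kind": dataset.abscissa_kind,
        "normalization": dataset.normalization,
        "source": dataset.source,
        "dose_ligand": dataset.dose_ligand,
        "dose_summary": dataset.dose_summary,
        "dose_time": dataset.dose_time,
        "truth_fingerprint": dataset.truth_fingerprint,
        "extrapolation_flag": dataset.extrapolation_flag,
        "protocol": _protocol_to_dict(dataset.protocol),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def read_dataset_csv(path) -> CalibrationDataset:
    """Read a dataset (CSV + JSON sidecar); errors name the offending row."""
    path = pathlib.Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header.split(",") != ["abscissa", "value", "weight"]:
            raise ModelError(f"{path.name}: malformed header {header!r}")
        points = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.strip().split(",")
            if len(cells) != 3:
                raise ModelError(f"{path.name} row {lineno}: expected 3 cells")
            try:
                a, v, w = (float(c) for c in cells)
            except ValueError:
                raise ModelError(
                    f"{path.name} row {lineno}: non-numeric cell") from None
            if w <= 0:
                raise ModelError(
                    f"{path.name} row {lineno}: non-positive weight {w}")
            points.append((a, v, w))
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            side = json.load(fh)
    else:
        side = {"id": path.stem, "observable": "unknown",
                "abscissa_kind": "time", "normalization": "absolute",
                "protocol": {"t_end": max(p[0] for p in points)}}
    return CalibrationDataset(
        id=side["id"], protocol=_protocol_from_dict(side["protocol"]),
        observable=side["observable"], abscissa_kind=side["abscissa_kind"],
        points=points, normalization=side["normalization"],
        source=side.get("source", "file"),
        dose_ligand=side.get("dose_ligand"),
        dose_summary=side.get("dose_summary", "steady"),
        dose_time=side.get("dose_time"),
        truth_fingerprint=side.get("truth_fingerprint", ""),
        extrapolation_flag=side.get("extrapolation_flag", False))


def write_results_csv(result, path) -> pathlib.Path:
    """Tidy (time, observable, value) CSV for a SimulationResult."""
    path = pathlib.Path(path)
    result.to_tidy().to_csv(path, index=False)
    return path


def load_config(path) -> dict:
    path = pathlib.Path(path)
    with open(path) as fh:
        if path.suffix == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    config_hash: str
    package_version: str
    seed: int | None
    started: str = ""
    finished: str = ""
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    @classmethod
    def start(cls, command, config=None, seed=None):
        from . import __version__
        return cls(command=command,
                   config_hash=config_hash(config or {}),
                   package_version=__version__, seed=seed,
                   started=datetime.datetime.now().isoformat())

    def finish(self, outdir):
        self.finished = datetime.datetime.now().isoformat()
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(asdict(self), fh, indent=1)
        return outdir / "manifest.json"
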
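"""Plain-text readers/writers for traces, spike trains and waveforms.

Formats:
* trace — CSV with header ``time,value`` (or ``time,v,n,m,h``), optional
  ``#``-prefixed comment lines declaring units;
* spikes — one spike time (ms) per line, optional second column with the
  simple/complex label ``S``/``C``;
* stimulus — trace CSV plus a YAML sidecar with the generator metadata.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .spike_analysis import SpikeTrain
from .stimuli import StimulusWaveform

__all__ = [
    "write_trace", "read_trace",
    "write_spikes", "read_spikes",
    "write_stimulus", "read_stimulus",
]


def write_trace(path, time, columns: dict, units: str | None = None) -> None:
    path = Path(path)
    names = ["time"] + list(columns)
    data = np.column_stack([np.asarray(time)] + [np.asarray(c) for c in columns.values()])
    header = ""
    if units:
        header += f"# units: {units}\n"
    header += ",".join(names)
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.10g")


def read_trace(path) -> dict[str, np.ndarray]:
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    names = [c.strip() for c in lines[0].strip().split(",")]
    data = np.loadtxt(lines[1:], delimiter=",", ndmin=2)
    return {name: data[:, i] for i, name in enumerate(names)}


def write_spikes(path, train: SpikeTrain) -> None:
    with open(path, "w") as fh:
        if train.labels is None:
            for t in train.times:
                fh.write(f"{t:.10g}\n")
        else:
            for t, lab in zip(train.times, train.labels):
                fh.write(f"{t:.10g} {lab}\n")


def read_spikes(path) -> SpikeTrain:
    times, labels = [], []
    with open(path) as fh:
        for ln in fh:
            parts = ln.split()
            if not parts or parts[0].startswith("#"):
                continue
            times.append(float(parts[0]))
            if len(parts) > 1:
                labels.append(parts[1])
    lab = np.asarray(labels) if labels else None
    if lab is not None and len(lab) != len(times):
        raise ValueError("inconsistent labelling in spike file")
    return SpikeTrain(times=np.asarray(times), labels=lab)


def write_stimulus(path, stim: StimulusWaveform) -> None:
    """Write waveform CSV and a ``<path>.meta.yaml`` sidecar."""
    path = Path(path)
    write_trace(path, stim.time, {"value": stim.current},
                units=f"time ms, current {stim.meta.get('units', '?')}")
    meta = {k: (list(v) if isinstance(v, tuple) else v) for k, v in stim.meta.items()}
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_stimulus(path) -> StimulusWaveform:
    path = Path(path)
    cols = read_trace(path)
    meta_path = path.with_suffix(path.suffix + ".meta.yaml")
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
        if isinstance(meta.get("band"), list):
            meta["band"] = tuple(meta["band"])
    return StimulusWaveform(time=cols["time"], current=cols["value"], meta=meta)
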
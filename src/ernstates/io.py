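"""Plain-text readers and writers for recordings, templates, and results.

All exchange formats are delimited text so fixtures and outputs remain
inspectable: recordings as channels × samples matrices with a one-line
header (rate + channel labels), microstate sets as one template per row,
segmentations as TSV, montages as .sfp-style ``label x y z`` lines.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from .backfit import Segmentation
from .clustering import MicrostateSet
from .core import EEGRecording
from .montage import ElectrodeMontage, read_sfp, write_sfp  # re-export

__all__ = [
    "read_sfp",
    "write_sfp",
    "write_recording",
    "read_recording",
    "write_microstate_set",
    "read_microstate_set",
    "write_segmentation",
    "write_epochs",
    "read_epochs",
    "config_hash",
]


def write_recording(rec: EEGRecording, path) -> None:
    header = f"rate={rec.rate} channels={','.join(rec.montage.channel_ids)}"
    np.savetxt(path, rec.data, fmt="%.6g", header=header)


def read_recording(path, montage: ElectrodeMontage) -> EEGRecording:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    fields = dict(item.split("=", 1) for item in header.split())
    rate = float(fields["rate"])
    labels = tuple(fields["channels"].split(","))
    if labels != montage.channel_ids:
        raise ValueError("channel labels do not match the montage")
    data = np.loadtxt(path)
    return EEGRecording(np.atleast_2d(data), rate, montage)


def write_microstate_set(mset: MicrostateSet, path, channel_ids=None) -> None:
    labels = ",".join(channel_ids) if channel_ids else ""
    header = f"polarity_mode={mset.polarity_mode} fit_gev={mset.fit_gev:.12g} channels={labels}"
    np.savetxt(path, mset.templates, fmt="%.10g", header=header)


def read_microstate_set(path) -> MicrostateSet:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    fields = dict(item.split("=", 1) for item in header.split() if "=" in item)
    templates = np.atleast_2d(np.loadtxt(path))
    return MicrostateSet(templates, fields["polarity_mode"], float(fields.get("fit_gev", 0.0)))


def write_segmentation(seg: Segmentation, path, times_ms=None) -> None:
    seg.to_frame(times_ms).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_epochs(data: np.ndarray, times_ms: np.ndarray, rate: float, condition: str, path) -> None:
    """Epochs × channels × samples tensor as 2-D text with a shape header."""
    n_ep, n_ch, n_t = data.shape
    header = (
        f"shape={n_ep},{n_ch},{n_t} rate={rate} condition={condition} "
        f"t0={times_ms[0]} t1={times_ms[-1]}"
    )
    np.savetxt(path, data.reshape(n_ep * n_ch, n_t), fmt="%.6g", header=header)


def read_epochs(path):
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    fields = dict(item.split("=", 1) for item in header.split())
    n_ep, n_ch, n_t = (int(v) for v in fields["shape"].split(","))
    data = np.loadtxt(path).reshape(n_ep, n_ch, n_t)
    times = np.linspace(float(fields["t0"]), float(fields["t1"]), n_t)
    return data, times, float(fields["rate"]), fields["condition"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
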
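"""Acquisition-protocol presets and config-file loading.

A protocol set is a mapping ``{"mtw": ..., "t1w": ..., "pdw": ...}`` of
:class:`~mpfmap.model.AcquisitionProtocol`.  The packaged preset
``clinical_1p5T`` reproduces a three-sequence 1.5 T fast MPF mapping
protocol: MT-weighted TR 20 ms / FA 8 deg with a Gaussian saturation pulse
(1.5 kHz offset, 500 deg effective flip, 7.68 ms), T1-weighted TR 16 ms /
FA 18 deg, PD-weighted TR 16 ms / FA 3 deg, all at TE 4.76 ms.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import yaml

from .model import AcquisitionProtocol, MTPulse

__all__ = ["load_protocols", "protocol_preset", "PRESETS"]

PRESETS = ("clinical_1p5T",)


def _protocol_from_dict(d: Mapping) -> AcquisitionProtocol:
    pulse = None
    if d.get("mt_pulse") is not None:
        p = d["mt_pulse"]
        pulse = MTPulse(
            offset_frequency=float(p["offset_frequency"]),
            effective_flip_angle=float(p["effective_flip_angle"]),
            duration=float(p["duration"]),
            envelope_shape=p.get("envelope_shape", "gaussian"),
            truncation_level=float(p.get("truncation_level", 0.01)),
        )
    return AcquisitionProtocol(
        repetition_time=float(d["repetition_time"]),
        excitation_flip_angle=float(d["excitation_flip_angle"]),
        echo_time=float(d.get("echo_time", 0.0)),
        mt_pulse=pulse,
    )


def load_protocols(source) -> dict[str, AcquisitionProtocol]:
    """Load a protocol set from a YAML/JSON file path or open stream.

    The file maps sequence names to ``AcquisitionProtocol`` fields; the MT
    pulse, when present, is given under the ``mt_pulse`` key.
    """
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError("protocol config must map sequence names to parameter dicts")
    return {name: _protocol_from_dict(d) for name, d in raw.items()}


def protocol_preset(name: str = "clinical_1p5T") -> dict[str, AcquisitionProtocol]:
    """Return a packaged protocol preset by name."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {PRESETS}")
    ref = resources.files("mpfmap").joinpath(f"data/{name}.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return load_protocols(fh)
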
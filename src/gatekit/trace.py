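"""Time-trace container and on-disk formats.

A :class:`TimeTrace` is a uniformly sampled scalar signal — a height-time
trace from height spectroscopy (nm) or a current-time trace from a
single-channel recording (pA).  The ``polarity`` attribute records which
level corresponds to the conducting (open) channel: in height traces the
probe descends into the open pore, so the *low* level is open; in current
traces the open channel conducts, so the *high* level is open.

Traces are stored either as two-column plain text (time_s, value) or as raw
little-endian float32 binary with a JSON sidecar carrying the sampling
metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TimeTrace",
    "read_trace_text",
    "write_trace_text",
    "read_trace_binary",
    "write_trace_binary",
]

_UNITS = ("nm", "pA")
_POLARITIES = ("open_is_low", "open_is_high")


@dataclass
class TimeTrace:
    """Uniformly sampled scalar signal with acquisition metadata.

    Parameters
    ----------
    values : ndarray
        Signal samples (nm or pA).
    sample_rate : float
        Sampling rate in Hz, > 0.
    units : {"nm", "pA"}
        Physical units of ``values``.
    polarity : {"open_is_low", "open_is_high"}
        Which signal level corresponds to the open channel.  Height traces
        use ``open_is_low``; current traces use ``open_is_high``.
    metadata : dict
        Free-form provenance (seed, segment offset, source file, ...).
    """

    values: np.ndarray
    sample_rate: float
    units: str = "nm"
    polarity: str = "open_is_low"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.units not in _UNITS:
            raise ValueError(f"units must be one of {_UNITS}")
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.values.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (t=0 at the first sample)."""
        return np.arange(self.values.size) / self.sample_rate

    def replace_values(self, values: np.ndarray, **meta) -> "TimeTrace":
        """Return a copy with new samples and updated metadata."""
        md = dict(self.metadata)
        md.update(meta)
        return TimeTrace(np.asarray(values, dtype=float), self.sample_rate,
                         self.units, self.polarity, md)


def write_trace_text(trace: TimeTrace, path) -> None:
    """Write a trace as two-column text: time_s, value."""
    path = Path(path)
    header = (f"sample_rate_hz={trace.sample_rate} units={trace.units} "
              f"polarity={trace.polarity}")
    data = np.column_stack([trace.times, trace.values])
    np.savetxt(path, data, fmt="%.9g", header=header)


def read_trace_text(path, units: str = "nm",
                    polarity: str = "open_is_low") -> TimeTrace:
    """Read a two-column (time_s, value) text trace.

    The sampling rate is recovered from the header if present, otherwise
    from the median time step.
    """
    path = Path(path)
    sample_rate = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            key, _, val = tok.partition("=")
            if key == "sample_rate_hz":
                sample_rate = float(val)
            elif key == "units":
                units = val
            elif key == "polarity":
                polarity = val
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (time_s, value)")
    if sample_rate is None:
        dt = np.median(np.diff(data[:, 0]))
        sample_rate = 1.0 / dt
    return TimeTrace(data[:, 1], sample_rate, units, polarity,
                     metadata={"source": str(path)})


def write_trace_binary(trace: TimeTrace, path) -> None:
    """Write raw little-endian float32 samples plus a JSON sidecar."""
    path = Path(path)
    trace.values.astype("<f4").tofile(path)
    sidecar = {
        "sample_rate": trace.sample_rate,
        "units": trace.units,
        "polarity": trace.polarity,
        "n_samples": int(trace.n_samples),
        "dtype": "<f4",
        "metadata": _jsonable(trace.metadata),
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_trace_binary(path) -> TimeTrace:
    """Read a raw float32 trace written by :func:`write_trace_binary`."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    values = np.fromfile(path, dtype=sidecar.get("dtype", "<f4"))
    return TimeTrace(values.astype(float), sidecar["sample_rate"],
                     sidecar.get("units", "nm"),
                     sidecar.get("polarity", "open_is_low"),
                     metadata=sidecar.get("metadata", {}))


def _jsonable(obj):
    """Best-effort conversion of metadata to JSON-serializable types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
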
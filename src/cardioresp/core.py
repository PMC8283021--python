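"""Core signal containers.

A :class:`Trace` is a single uniformly sampled physiological channel
(arterial pressure, heart rate, airflow, SpO2, EEG, EMG, ...) with a sample
rate, physical units and a clock time for its first sample.  A
:class:`Recording` bundles the traces of one animal together with the
metadata (group, body weight, lighting schedule) that the analysis modules
need.  Artifact samples are carried as an explicit boolean validity mask
rather than sentinel values, so that filtering steps stay testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Trace", "Recording"]


@dataclass
class Trace:
    """One uniformly sampled signal channel.

    Parameters
    ----------
    label
        Channel name, e.g. ``"pressure"`` or ``"flow"``.
    values
        Sample values in physical units.
    rate
        Sampling rate in Hz; must be positive.
    units
        Physical dimension of the samples (``"mmHg"``, ``"mL/s"``, ...).
    start_clock_s
        Clock time of the first sample, in seconds after midnight.  Only
        used for light/dark assignment; all internal arithmetic is in
        seconds from the start of the trace.
    valid
        Optional boolean mask, ``True`` where the sample is usable.  When
        omitted every sample must be finite.
    """

    label: str
    values: np.ndarray
    rate: float
    units: str = ""
    start_clock_s: float = 0.0
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("trace values must be a non-empty 1-D array")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError("validity mask must match values in shape")
            if not np.all(np.isfinite(self.values[self.valid])):
                raise ValueError("valid samples must be finite")
        elif not np.all(np.isfinite(self.values)):
            raise ValueError(
                "trace contains non-finite samples without a validity mask"
            )

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate

    def times(self) -> np.ndarray:
        """Sample times in seconds from the start of the trace."""
        return np.arange(self.values.size) / self.rate

    def slice_time(self, t0: float, t1: float) -> "Trace":
        """Sub-trace covering ``[t0, t1)`` seconds from trace start."""
        i0 = max(0, int(np.ceil(t0 * self.rate - 1e-9)))
        i1 = min(self.values.size, int(np.ceil(t1 * self.rate - 1e-9)))
        if i1 <= i0:
            raise ValueError(f"empty time slice [{t0}, {t1})")
        return Trace(
            label=self.label,
            values=self.values[i0:i1].copy(),
            rate=self.rate,
            units=self.units,
            start_clock_s=self.start_clock_s + i0 / self.rate,
            valid=None if self.valid is None else self.valid[i0:i1].copy(),
        )


@dataclass
class Recording:
    """A keyed bundle of traces plus per-animal metadata."""

    animal_id: str
    traces: dict[str, Trace] = field(default_factory=dict)
    group: str = "other"
    body_weight_g: float = 1.0
    lights_on_hour: float = 9.0
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.body_weight_g > 0:
            raise ValueError("body_weight_g must be positive")
        if not 0 <= self.lights_on_hour < 24:
            raise ValueError("lights_on_hour must lie in [0, 24)")

    def __getitem__(self, label: str) -> Trace:
        return self.traces[label]

    def __contains__(self, label: str) -> bool:
        return label in self.traces
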
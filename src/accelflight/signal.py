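"""Sensor model and acceleration transforms.

A tri-axial accelerometer sample is a vector ``A = (a_x, a_y, a_z)`` in
g-force (1 g = 9.81 m s^-2), x lateral, y longitudinal, z vertical.  The
transforms here turn a raw trace into vectorial dynamic body acceleration
(VeDBA): the static (gravitational/orientation) component ``A_static`` is
estimated per axis with a centred running mean, the dynamic component is
``DBA = A - A_static``, and ``VeDBA = ||DBA||_2`` per sample.

Also provides the MEMS sensor model: saturating uniform quantization
(e.g. +/-8 g at 8 bits, a 0.0625 g step) and integer-factor subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

STANDARD_GRAVITY = 9.81  # m s^-2 per g


@dataclass(frozen=True)
class AccelTrace:
    """A fixed-rate tri-axial acceleration series in g.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz, > 0.
    data : ndarray, shape (n, 3)
        Acceleration samples ``(a_x, a_y, a_z)`` in g.  All finite.
    sensor_range_g, sensor_bits : optional
        Sensor metadata when the trace has been quantized.
    """

    sample_rate: float
    data: np.ndarray
    sensor_range_g: float | None = None
    sensor_bits: int | None = None

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 3:
            raise ValueError(f"data must have shape (n, 3), got {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("data contains non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Recording span in seconds (n / rate)."""
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """0-based sample timestamps, ``i / sample_rate``."""
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class VedbaSeries:
    """Per-sample VeDBA in g, aligned 1:1 with its source trace."""

    sample_rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("values must be 1-D")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("VeDBA values must be finite and >= 0")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


def quantization_step(range_g: float, bits: int) -> float:
    """Level spacing of a symmetric ``bits``-bit sensor over ``+/-range_g``.

    2^bits levels span [-range_g, range_g), so the step is
    ``2 * range_g / 2**bits`` (0.0625 g for +/-8 g at 8 bits).
    """
    return 2.0 * range_g / (2**bits)


def quantize(trace: AccelTrace, range_g: float = 8.0, bits: int = 8) -> AccelTrace:
    """Map every sample to the nearest representable sensor level.

    Levels are ``-range_g + k * step`` for ``k in [0, 2**bits - 1]``; the
    topmost level is ``range_g - step``.  Ties round half away from zero;
    out-of-range values saturate to the extreme levels.  Idempotent.
    """
    if not 2 <= bits <= 16:
        raise ValueError(f"bits must be in [2, 16], got {bits}")
    if not range_g > 0:
        raise ValueError(f"range_g must be > 0, got {range_g}")
    step = quantization_step(range_g, bits)
    v = trace.data
    idx = (v + range_g) / step
    # nearest level, ties away from zero in value space
    k = np.where(v >= 0, np.floor(idx + 0.5), np.ceil(idx - 0.5))
    k = np.clip(k, 0, 2**bits - 1)
    levels = -range_g + k * step
    return AccelTrace(trace.sample_rate, levels, sensor_range_g=range_g, sensor_bits=bits)


def subsample(trace: AccelTrace, factor: int) -> AccelTrace:
    """Keep every ``factor``-th sample (indices 0, factor, 2*factor, ...).

    The kept samples are bit-identical to the originals and the rate
    divides accordingly, e.g. 100 Hz at factor 4 -> 25 Hz.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    return replace(
        trace,
        sample_rate=trace.sample_rate / factor,
        data=trace.data[::factor].copy(),
    )


def running_mean(values: np.ndarray, window: int, axis: int = 0) -> np.ndarray:
    """Centred running mean with the window clipped at the boundaries.

    ``window`` must be odd so the window centres on each sample.  Near an
    edge the window shrinks to the samples actually available, i.e. index
    range ``[i - r, i + r]`` intersected with the series, so the output
    has the same length as the input.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd (centred), got {window}")
    if window < 1:
        raise ValueError("window must be >= 1")
    a = np.asarray(values, dtype=float)
    n = a.shape[axis]
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    r = window // 2
    a_moved = np.moveaxis(a, axis, 0)
    csum = np.concatenate(
        [np.zeros((1,) + a_moved.shape[1:]), np.cumsum(a_moved, axis=0)], axis=0
    )
    i = np.arange(n)
    lo = np.maximum(i - r, 0)
    hi = np.minimum(i + r, n - 1)
    total = csum[hi + 1] - csum[lo]
    count = (hi - lo + 1).reshape((n,) + (1,) * (a_moved.ndim - 1))
    return np.moveaxis(total / count, 0, axis)


def static_acceleration(trace: AccelTrace, window_samples: int = 5) -> AccelTrace:
    """Per-axis running-mean estimate of the gravitational component.

    The default 5-sample window corresponds to 0.22 s at a 23 Hz rate.
    """
    smoothed = running_mean(trace.data, window_samples, axis=0)
    return replace(trace, data=smoothed, sensor_range_g=None, sensor_bits=None)


def dynamic_acceleration(trace: AccelTrace, window_samples: int = 5) -> np.ndarray:
    """DBA = raw minus static acceleration, shape (n, 3) in g."""
    return trace.data - static_acceleration(trace, window_samples).data


def vedba(trace: AccelTrace, window_samples: int = 5) -> VedbaSeries:
    """Per-sample VeDBA: Euclidean norm of the three DBA components."""
    dba = dynamic_acceleration(trace, window_samples)
    return VedbaSeries(trace.sample_rate, np.sqrt((dba**2).sum(axis=1)))


def segment_mean_vedba(series: VedbaSeries, start: float, duration: float) -> float:
    """Mean VeDBA over the half-open time interval [start, start + duration).

    Sample ``i`` has timestamp ``i / sample_rate``; the mean is over the
    samples whose timestamps fall inside the interval.  An interval that
    contains no sample is an error rather than a silent zero.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if start < 0 or start + duration > series.n_samples / series.sample_rate + 1e-9:
        raise ValueError("interval extends outside the series")
    eps = 1e-9
    i0 = int(np.ceil(start * series.sample_rate - eps))
    i1 = int(np.ceil((start + duration) * series.sample_rate - eps))
    i0, i1 = max(i0, 0), min(i1, series.n_samples)
    if i1 <= i0:
        raise ValueError(f"no samples in interval [{start}, {start + duration})")
    return float(series.values[i0:i1].mean())
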
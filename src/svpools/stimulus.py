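"""Stimulation protocols and deterministic presynaptic Ca2+ waveforms.

A :class:`PulseProtocol` is an ordered list of stimulus times.  Two Ca2+
signals are derived from it:

* the *sensor-facing* transient :func:`ca_sensor` -- a train of brief
  Gaussian action-potential (AP) transients riding on resting Ca2+ and,
  by default, on the residual Ca2+;
* the *residual* Ca2+ :func:`ca_residual` -- a per-pulse increment that
  decays exponentially and sums linearly across pulses.  It drives the
  Ca2+-dependent recruitment (priming) step of the sequential two-pool
  model.

Units are SI throughout: seconds and molar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PulseProtocol",
    "CaParams",
    "build_regular_train",
    "build_triplet_train",
    "build_random_low_freq_train",
    "concat_protocols",
    "ca_residual",
    "ca_sensor",
    "residual_peaks",
    "gaussian_sigma",
]


def gaussian_sigma(fwhm: float) -> float:
    """Standard deviation of a Gaussian with the given full width at half maximum."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class CaParams:
    """Parameters of the deterministic Ca2+ waveforms.

    Attributes
    ----------
    ca_rest:
        Resting free Ca2+ (M).
    ap_amplitude:
        Peak amplitude of the local AP-evoked Ca2+ transient at the release
        sensor (M).
    ap_fwhm:
        Full width at half maximum of the AP transient (s).  The default of
        0.55 ms is chosen so that a single AP drives a release probability of
        ~0.25 per resting releasable vesicle with the five-site sensor used
        here, matching estimates from unitary granule-cell synapses;
        microsecond-scale transients of the same amplitude bind essentially
        no Ca2+ at these on-rates (see docs/methods.md).
    residual_increment:
        Residual Ca2+ added per pulse (M), decaying with ``residual_tau``
        and summing linearly across pulses.
    residual_tau:
        Decay time constant of residual Ca2+ (s).
    sensor_sees_residual:
        If True (default), the sensor-facing signal is
        rest + residual + AP Gaussian; if False the residual only drives
        recruitment.
    """

    ca_rest: float = 50e-9
    ap_amplitude: float = 22.5e-6
    ap_fwhm: float = 0.55e-3
    residual_increment: float = 520e-9
    residual_tau: float = 0.042
    sensor_sees_residual: bool = True

    def __post_init__(self) -> None:
        for name in ("ca_rest", "ap_amplitude", "ap_fwhm",
                     "residual_increment", "residual_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CaParams.{name} must be strictly positive")

    @property
    def ap_sigma(self) -> float:
        return gaussian_sigma(self.ap_fwhm)

    def replace(self, **kw) -> "CaParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PulseProtocol:
    """Ordered stimulus times with optional named segments.

    ``segments`` is a tuple of ``(name, start, stop)`` half-open index
    ranges into ``pulse_times`` (e.g. an LFD phase followed by a recovery
    train).  Ranges must lie within bounds and must not overlap.
    """

    pulse_times: np.ndarray
    label: str = ""
    segments: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        times = np.asarray(self.pulse_times, dtype=float)
        object.__setattr__(self, "pulse_times", times)
        if times.ndim != 1:
            raise ValueError("pulse_times must be one-dimensional")
        if times.size and times[0] < 0:
            raise ValueError("pulse times must be non-negative")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("pulse times must be strictly increasing")
        n = times.size
        used = np.zeros(n, dtype=bool)
        for name, start, stop in self.segments:
            if not (0 <= start <= stop <= n):
                raise ValueError(f"segment {name!r} out of bounds")
            if used[start:stop].any():
                raise ValueError(f"segment {name!r} overlaps another segment")
            used[start:stop] = True

    @property
    def n_pulses(self) -> int:
        return int(self.pulse_times.size)

    def segment_slice(self, name: str) -> slice:
        for seg_name, start, stop in self.segments:
            if seg_name == name:
                return slice(start, stop)
        raise KeyError(name)

    def segment_labels(self) -> np.ndarray:
        """Per-pulse segment name ('' where no segment covers the pulse)."""
        out = np.full(self.n_pulses, "", dtype=object)
        for name, start, stop in self.segments:
            out[start:stop] = name
        return out

    # -- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": np.arange(self.n_pulses),
            "time_s": self.pulse_times,
            "segment": self.segment_labels(),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "PulseProtocol":
        df = pd.read_csv(path, keep_default_na=False)
        times = df["time_s"].to_numpy(dtype=float)
        segments = []
        if "segment" in df:
            seg = df["segment"].astype(str).to_numpy()
            i = 0
            while i < len(seg):
                if seg[i] not in ("", "nan"):
                    j = i
                    while j < len(seg) and seg[j] == seg[i]:
                        j += 1
                    segments.append((seg[i], i, j))
                    i = j
                else:
                    i += 1
        return cls(times, label=label, segments=tuple(segments))

    def to_json(self, path=None):
        payload = {
            "label": self.label,
            "pulse_times": self.pulse_times.tolist(),
            "segments": [list(s) for s in self.segments],
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, source) -> "PulseProtocol":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            np.asarray(payload["pulse_times"], dtype=float),
            label=payload.get("label", ""),
            segments=tuple(tuple(s) for s in payload.get("segments", ())),
        )


# ---------------------------------------------------------------------------
# protocol builders
# ---------------------------------------------------------------------------

def build_regular_train(frequency: float, n_pulses: int, t0: float = 0.0,
                        label: str | None = None) -> PulseProtocol:
    """Regular train: pulse i at ``t0 + i / frequency``."""
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if n_pulses < 1:
        raise ValueError("n_pulses must be at least 1")
    times = t0 + np.arange(n_pulses) / frequency
    if label is None:
        label = f"{n_pulses}@{frequency:g}Hz"
    return PulseProtocol(times, label=label)


def build_triplet_train(n_triplets: int, repeat_freq: float,
                        intra_freq: float) -> PulseProtocol:
    """Triplets of pulses: triplet k starts at ``k / repeat_freq``; the three
    pulses within a triplet are spaced ``1 / intra_freq`` apart."""
    if n_triplets < 1:
        raise ValueError("n_triplets must be at least 1")
    if repeat_freq <= 0 or intra_freq <= 0:
        raise ValueError("frequencies must be positive")
    if intra_freq <= repeat_freq or 2.0 / intra_freq >= 1.0 / repeat_freq:
        raise ValueError("triplet does not fit within the repeat interval")
    starts = np.arange(n_triplets) / repeat_freq
    offsets = np.arange(3) / intra_freq
    times = (starts[:, None] + offsets[None, :]).ravel()
    return PulseProtocol(
        times, label=f"{n_triplets}x3@{repeat_freq:g}Hz/{intra_freq:g}Hz")


def build_random_low_freq_train(n_pulses: int, min_freq: float,
                                max_freq: float, seed: int) -> PulseProtocol:
    """Train with i.i.d. inter-stimulus intervals uniform in
    ``[1/max_freq, 1/min_freq]`` (instantaneous rate in the stated band)."""
    if n_pulses < 1:
        raise ValueError("n_pulses must be at least 1")
    if min_freq <= 0 or min_freq > max_freq:
        raise ValueError("need 0 < min_freq <= max_freq")
    rng = np.random.default_rng(seed)
    isis = rng.uniform(1.0 / max_freq, 1.0 / min_freq, size=n_pulses - 1)
    times = np.concatenate([[0.0], np.cumsum(isis)])
    return PulseProtocol(
        times, label=f"{n_pulses}@[{min_freq:g},{max_freq:g}]Hz")


def concat_protocols(a: PulseProtocol, b: PulseProtocol, gap: float,
                     names: tuple[str, str] = ("a", "b")) -> PulseProtocol:
    """Append ``b`` starting ``gap`` seconds after the last pulse of ``a``.

    The two parts are recorded as segments so downstream analysis can
    address, e.g., a depression phase and a recovery train separately.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    if b.n_pulses == 0:
        return PulseProtocol(a.pulse_times, label=a.label,
                             segments=((names[0], 0, a.n_pulses),))
    offset = (a.pulse_times[-1] + gap) if a.n_pulses else gap
    shifted = b.pulse_times - b.pulse_times[0] + offset
    times = np.concatenate([a.pulse_times, shifted])
    segments = (
        (names[0], 0, a.n_pulses),
        (names[1], a.n_pulses, a.n_pulses + b.n_pulses),
    )
    return PulseProtocol(times, label=f"{a.label}+{b.label}",
                         segments=segments)


# ---------------------------------------------------------------------------
# Ca2+ waveforms
# ---------------------------------------------------------------------------

def ca_residual(t, protocol: PulseProtocol, params: CaParams):
    """Residual Ca2+ above rest at time(s) ``t`` (M).

    Each pulse at t_i <= t contributes
    ``residual_increment * exp(-(t - t_i) / residual_tau)``; contributions
    sum linearly.  The resting level is *not* included -- callers add
    ``params.ca_rest`` where the absolute concentration is needed.
    """
    t_arr = np.asarray(t, dtype=float)
    out = np.zeros_like(t_arr, dtype=float)
    inv_tau = 1.0 / params.residual_tau
    for ti in protocol.pulse_times:
        mask = t_arr >= ti
        if not mask.any():
            break
        out[mask] += params.residual_increment * np.exp(-(t_arr[mask] - ti) * inv_tau)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def residual_peaks(protocol: PulseProtocol, params: CaParams) -> np.ndarray:
    """Residual Ca2+ immediately after each pulse (own increment included).

    Computed by the exact recursion
    ``A_i = A_{i-1} * exp(-ISI_i / tau) + increment`` -- all terms share the
    same decay constant, so the running sum is a single exponential.
    """
    peaks = np.empty(protocol.n_pulses)
    a = 0.0
    prev_t = None
    for i, ti in enumerate(protocol.pulse_times):
        if prev_t is not None:
            a *= np.exp(-(ti - prev_t) / params.residual_tau)
        a += params.residual_increment
        peaks[i] = a
        prev_t = ti
    return peaks


def ca_sensor(t, protocol: PulseProtocol, params: CaParams):
    """Sensor-facing Ca2+ at time(s) ``t`` (M): rest + (residual, if
    ``sensor_sees_residual``) + the sum of per-pulse AP Gaussians."""
    t_arr = np.asarray(t, dtype=float)
    out = np.full_like(t_arr, params.ca_rest, dtype=float)
    if params.sensor_sees_residual:
        out += ca_residual(t_arr, protocol, params)
    sigma = params.ap_sigma
    for ti in protocol.pulse_times:
        dt = t_arr - ti
        mask = np.abs(dt) < 8.0 * sigma
        if mask.any():
            out[mask] += params.ap_amplitude * np.exp(-dt[mask] ** 2 / (2.0 * sigma ** 2))
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out
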
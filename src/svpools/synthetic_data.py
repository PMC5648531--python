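"""Synthetic EPSC-train generation.

Generates evoked-EPSC trains with the statistical structure the
analysis pipeline assumes, either from simulated per-pulse release
probabilities (bridging the kinetic models to the train analysis) or
from a parametric delayed-monoexponential depression profile.  The
amplitude model is multiplicative fiber-count x quantal-size structure:
each stimulated fiber contributes an integer number of quanta (Poisson
or binomial trial variability, or the deterministic expectation), each
quantum contributes the unitary quantal content, and multiplicative
Gaussian measurement noise is applied on top.  Baseline (0.033 Hz)
trains use the unitary median EPSC (failures included) per fiber, so
fiber-count estimation round-trips by construction -- a modelling
convention, not a biological claim.

All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .epsc_analysis import EPSCTrain
from .stimulus import PulseProtocol, build_regular_train

__all__ = ["SynthConfig", "synth_from_model", "synth_parametric_lfd",
           "synth_baseline"]

_LAWS = ("poisson", "binomial", "none")


@dataclass(frozen=True)
class SynthConfig:
    """Ground-truth configuration for synthetic trains.

    ``release_law`` is the per-bouton quantal count law: 'poisson',
    'binomial' (n = ``binomial_n`` docking sites, p chosen to match the
    mean) or 'none' (deterministic expectation).  ``noise_cv`` is the
    coefficient of variation of multiplicative Gaussian measurement
    noise.  ``charge_kernel`` converts amplitude (pA) to charge (pC);
    ``async_fraction``/``async_tau`` add a slow charge component growing
    with stimulus number (positive control for the asynchronous-release
    check).
    """

    n_fibers: int = 10
    quantal_content: float = 8.0
    unitary_median: float = 5.3
    release_law: str = "poisson"
    binomial_n: int = 5
    noise_cv: float = 0.05
    charge_kernel: float = 0.01
    async_fraction: float = 0.0
    async_tau: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be at least 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.release_law not in _LAWS:
            raise ValueError(f"release_law must be one of {_LAWS}")
        if self.quantal_content <= 0 or self.unitary_median <= 0:
            raise ValueError("quantal parameters must be positive")

    def replace(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


def _draw_quanta(rng: np.random.Generator, mean_per_bouton: np.ndarray,
                 config: SynthConfig) -> np.ndarray:
    """Total quanta summed over fibers, per stimulus."""
    mu = np.clip(mean_per_bouton, 0.0, None)
    if config.release_law == "poisson":
        return rng.poisson(mu * config.n_fibers).astype(float)
    if config.release_law == "binomial":
        n_tot = config.binomial_n * config.n_fibers
        p = np.clip(mu / config.binomial_n, 0.0, 1.0)
        return rng.binomial(n_tot, p).astype(float)
    return mu * config.n_fibers


def _measure(rng: np.random.Generator, quanta: np.ndarray,
             times: np.ndarray, config: SynthConfig):
    amps = quanta * config.quantal_content
    if config.noise_cv > 0:
        amps = amps * (1.0 + config.noise_cv * rng.standard_normal(amps.shape))
    amps = np.clip(amps, 0.0, None)
    charges = amps * config.charge_kernel
    if config.async_fraction > 0:
        # slow charge component ramping up over the train
        ramp = 1.0 - np.exp(-(times - times[0]) / config.async_tau)
        charges = charges * (1.0 + config.async_fraction * ramp)
    return amps, charges


def synth_from_model(p_r, protocol: PulseProtocol,
                     config: SynthConfig | None = None,
                     segment: str = "LFD") -> EPSCTrain:
    """Synthesize an EPSC train from per-pulse release probabilities.

    ``p_r[i]`` is the expected quanta per bouton at stimulus i (the
    per-pulse release probability of a normalized scheme).  Amplitude =
    (total quanta across fibers) * quantal_content * (1 + noise).
    """
    if config is None:
        config = SynthConfig()
    p_r = np.asarray(p_r, dtype=float)
    if p_r.shape != (protocol.n_pulses,):
        raise ValueError("p_r must align with the protocol's pulses")
    rng = np.random.default_rng(config.seed)
    quanta = _draw_quanta(rng, p_r, config)
    amps, charges = _measure(rng, quanta, protocol.pulse_times, config)
    return EPSCTrain(protocol.pulse_times, amps, charges,
                     np.full(protocol.n_pulses, segment, dtype=object),
                     label=protocol.label)


def lfd_profile(times: np.ndarray, d: int, tau: float, plateau: float) -> np.ndarray:
    """Delayed-monoexponential normalized amplitude: 1 for stimulus
    index <= d, then ``plateau + (1-plateau)*exp(-(t - t_d)/tau)``."""
    times = np.asarray(times, dtype=float)
    out = np.ones_like(times)
    late = np.arange(times.size) > d
    out[late] = plateau + (1.0 - plateau) * np.exp(-(times[late] - times[d]) / tau)
    return out


def synth_parametric_lfd(d: int, tau: float, plateau: float,
                         protocol: PulseProtocol,
                         config: SynthConfig | None = None,
                         first_mean_quanta: float = 1.0) -> EPSCTrain:
    """Synthesize a depression train from parametric ground truth.

    The expected normalized amplitude follows :func:`lfd_profile`;
    ``first_mean_quanta`` sets the per-bouton mean at the first stimulus.
    """
    if config is None:
        config = SynthConfig()
    if d < 0 or tau <= 0 or not (0 <= plateau <= 1.2):
        raise ValueError("invalid depression-shape parameters")
    if protocol.n_pulses <= d:
        raise ValueError("protocol must cover more stimuli than the delay")
    profile = lfd_profile(protocol.pulse_times, d, tau, plateau)
    rng = np.random.default_rng(config.seed)
    quanta = _draw_quanta(rng, first_mean_quanta * profile, config)
    amps, charges = _measure(rng, quanta, protocol.pulse_times, config)
    return EPSCTrain(protocol.pulse_times, amps, charges,
                     np.full(protocol.n_pulses, "LFD", dtype=object),
                     label="parametric LFD")


def synth_baseline(n: int, freq: float = 0.033,
                   config: SynthConfig | None = None) -> EPSCTrain:
    """Stationary baseline train at ``freq`` with mean amplitude
    ``n_fibers * unitary_median`` and CV ``noise_cv``."""
    if config is None:
        config = SynthConfig()
    if n < 1:
        raise ValueError("n must be at least 1")
    if n == 1:
        import warnings
        warnings.warn("single-point baseline: fiber estimate will be noisy")
    protocol = build_regular_train(freq, n, label="baseline")
    rng = np.random.default_rng(config.seed)
    mean = config.n_fibers * config.unitary_median
    amps = mean * (1.0 + config.noise_cv * rng.standard_normal(n))
    amps = np.clip(amps, 0.0, None)
    charges = amps * config.charge_kernel
    return EPSCTrain(protocol.pulse_times, amps, charges,
                     np.full(n, "baseline", dtype=object), label="baseline")
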
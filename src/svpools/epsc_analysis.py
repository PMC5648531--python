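"""Analysis of evoked EPSC trains.

Implements the quantal bookkeeping and curve fitting used to
characterize low-frequency depression (LFD) at granule-cell to Purkinje
cell connections:

* fiber-count estimation from the baseline (0.033 Hz) amplitude and the
  unitary median EPSC;
* cumulative quanta released per bouton from cumulative amplitude, the
  fiber count and the unitary quantal content;
* per-train normalization (EPSC_n / EPSC_1), paired-pulse ratios;
* delayed-monoexponential fitting of LFD time courses (a flat onset of
  ``d`` stimuli followed by an exponential decay, in seconds, to a
  plateau);
* a charge/amplitude superposition score flagging asynchronous release.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "EPSCTrain",
    "QuantalConstants",
    "LFDFit",
    "estimate_n_fibers",
    "quanta_per_bouton",
    "normalize_amplitudes",
    "fit_lfd",
    "paired_pulse_ratios",
    "charge_amplitude_superposition",
]


@dataclass(frozen=True)
class QuantalConstants:
    """Unitary-connection quantal anchors (pA).

    ``unitary_median_epsc`` is the median single-fiber EPSC including
    release failures; ``quantal_content`` is the mean response per
    released vesicle complement at a unitary connection.
    """

    unitary_median_epsc: float = 5.3
    quantal_content: float = 8.0

    def __post_init__(self):
        if self.unitary_median_epsc <= 0 or self.quantal_content <= 0:
            raise ValueError("quantal constants must be positive")


@dataclass(frozen=True)
class EPSCTrain:
    """Stimulus-indexed EPSC amplitudes (positive magnitudes, pA) with
    optional charges (pC) and per-stimulus segment labels
    (baseline / LFD / recovery / '')."""

    times: np.ndarray
    amplitudes: np.ndarray
    charges: np.ndarray | None = None
    segments: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and amplitudes must be equal-length 1-D")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("stimulus times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("amplitudes are positive magnitudes")
        if self.charges is not None:
            c = np.asarray(self.charges, dtype=float)
            object.__setattr__(self, "charges", c)
            if c.shape != t.shape:
                raise ValueError("charges must align with times")
        if self.segments is not None:
            s = np.asarray(self.segments, dtype=object)
            object.__setattr__(self, "segments", s)
            if s.shape != t.shape:
                raise ValueError("segments must align with times")

    @property
    def n_stimuli(self) -> int:
        return int(self.times.size)

    def segment(self, name: str) -> "EPSCTrain":
        if self.segments is None:
            raise KeyError("train has no segment labels")
        m = self.segments == name
        if not m.any():
            raise KeyError(f"no stimuli in segment {name!r}")
        return EPSCTrain(self.times[m], self.amplitudes[m],
                         None if self.charges is None else self.charges[m],
                         self.segments[m], label=f"{self.label}:{name}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "index": np.arange(self.n_stimuli),
            "time_s": self.times,
            "amplitude_pA": self.amplitudes,
        })
        df["charge_pC"] = self.charges if self.charges is not None else np.nan
        df["segment"] = self.segments if self.segments is not None else ""
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "EPSCTrain":
        df = pd.read_csv(path, keep_default_na=False)
        for col in ("time_s", "amplitude_pA"):
            if col not in df:
                raise ValueError(f"EPSC CSV is missing column {col!r}")
        charges = None
        if "charge_pC" in df:
            c = pd.to_numeric(df["charge_pC"], errors="coerce").to_numpy(float)
            if not np.all(np.isnan(c)):
                charges = c
        segments = None
        if "segment" in df:
            seg = df["segment"].astype(str).to_numpy(dtype=object)
            if np.any(seg != ""):
                segments = seg
        return cls(df["time_s"].to_numpy(float),
                   df["amplitude_pA"].to_numpy(float),
                   charges, segments, label=label)


@dataclass
class LFDFit:
    """Delayed-monoexponential depression fit.

    Normalized amplitude model: constant for stimulus n <= d, then an
    exponential decay ``plateau + (1 - plateau) * exp(-(t_n - t_d) / tau)``
    (relative to the pre-onset level).  ``delay`` is the onset stimulus
    count d, ``tau`` the decay constant in seconds, ``plateau`` the
    asymptote as a fraction of the initial response.
    """

    delay: int
    tau: float
    plateau: float
    r_squared: float
    converged: bool
    no_depression: bool = False

    def __post_init__(self):
        if self.converged:
            if self.delay < 0 or self.tau <= 0:
                raise ValueError("invalid fitted parameters")

    def predict(self, times: np.ndarray, delay_time: float) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        out = np.ones_like(t)
        late = t > delay_time
        out[late] = self.plateau + (1.0 - self.plateau) * np.exp(
            -(t[late] - delay_time) / self.tau)
        return out

    def to_json(self, path=None):
        payload = asdict(self)
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# quantal arithmetic
# ---------------------------------------------------------------------------

def estimate_n_fibers(baseline_amplitudes,
                      constants: QuantalConstants | None = None) -> float:
    """Number of stimulated fibers: mean baseline EPSC divided by the
    unitary median EPSC (failures included)."""
    if constants is None:
        constants = QuantalConstants()
    amps = np.asarray(baseline_amplitudes, dtype=float)
    if amps.size == 0:
        raise ValueError("baseline is empty")
    mean = float(amps.mean())
    if mean == 0.0:
        warnings.warn("all-zero baseline: estimated fiber count is 0")
    return mean / constants.unitary_median_epsc


def quanta_per_bouton(train: EPSCTrain, n_fibers: float,
                      constants: QuantalConstants | None = None,
                      index_range: slice | None = None) -> float:
    """Cumulative quanta released per bouton over ``index_range``:
    cumulative amplitude / (n_fibers * quantal_content)."""
    if constants is None:
        constants = QuantalConstants()
    if n_fibers <= 0:
        raise ValueError("n_fibers must be positive")
    amps = train.amplitudes if index_range is None else train.amplitudes[index_range]
    return float(amps.sum()) / (n_fibers * constants.quantal_content)


def normalize_amplitudes(train: EPSCTrain) -> np.ndarray:
    """EPSC_n / EPSC_1, segment-wise when the train carries segment
    labels (each segment is normalized to its own first response)."""
    amps = train.amplitudes
    if train.segments is None:
        if amps[0] == 0:
            raise ZeroDivisionError("first response is zero")
        return amps / amps[0]
    out = np.empty_like(amps)
    for name in pd.unique(train.segments):
        m = train.segments == name
        first = amps[m][0]
        if first == 0:
            raise ZeroDivisionError(f"first response of segment {name!r} is zero")
        out[m] = amps[m] / first
    return out


def paired_pulse_ratios(train: EPSCTrain, pairs) -> np.ndarray:
    """``EPSC_j / EPSC_i`` for each requested ``(i, j)`` index pair."""
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        denom = train.amplitudes[i]
        if denom == 0:
            raise ZeroDivisionError(f"zero denominator at stimulus {i}")
        out[k] = train.amplitudes[j] / denom
    return out


# ---------------------------------------------------------------------------
# LFD fitting
# ---------------------------------------------------------------------------

def _fit_with_onset(t: np.ndarray, y: np.ndarray, d: int,
                    tau0: float, plat0: float):
    """Least-squares fit of the delayed-exponential model with onset at
    stimulus index ``d``: a free pre-onset level ``h`` (nominally 1, but
    normalizing by the noisy first response shifts the whole curve, so
    fixing it inflates the change-point variance) followed by
    ``plat + (h - plat) * exp(-(t - t_d)/tau)``.
    Returns (tau, plateau_fraction, head, sse, ok)."""
    t_d = t[d]
    idx = np.arange(y.size)

    def resid(p):
        log_tau, plat, h = p
        model = np.where(idx <= d, h,
                         plat + (h - plat) * np.exp(-(t - t_d) / np.exp(log_tau)))
        return model - y

    try:
        sol = least_squares(resid, x0=(np.log(tau0), plat0, 1.0),
                            bounds=((-10.0, -0.2, 0.5), (15.0, 1.2, 2.0)))
    except Exception:
        return tau0, plat0, 1.0, np.inf, False
    tau, plat, h = float(np.exp(sol.x[0])), float(sol.x[1]), float(sol.x[2])
    return tau, plat / h, h, float(2.0 * sol.cost), bool(sol.success)


def fit_lfd(train: EPSCTrain, max_delay: int | None = None,
            min_stimuli: int = 30) -> LFDFit:
    """Fit the delayed-monoexponential depression model to a train.

    Amplitudes are normalized to the first response, so the fit is
    invariant to uniform rescaling.  The onset ``d`` (index of the last
    baseline-level stimulus) is grid-searched; for each candidate the
    model is fitted by least squares in *time* (the decay constant is
    reported in seconds) and the candidate with the smallest residual
    sum of squares wins.  The reported plateau is the asymptote as a
    fraction of the fitted pre-onset level.
    """
    if train.n_stimuli < min_stimuli:
        raise ValueError(f"need at least {min_stimuli} stimuli to fit LFD")
    y = normalize_amplitudes(train) if train.segments is None \
        else train.amplitudes / train.amplitudes[0]
    t = train.times
    n = y.size
    if max_delay is None:
        max_delay = min(n // 3, 40)

    # degenerate, non-depressing trains: flat within noise
    tail_level = float(np.median(y[-max(n // 10, 5):]))
    if tail_level > 0.8:
        return LFDFit(delay=0, tau=np.inf, plateau=float(np.clip(tail_level, 0, 1.2)),
                      r_squared=0.0, converged=True, no_depression=True)

    span = t[-1] - t[0]
    tau0 = max(span / 10.0, 1e-3)
    plat0 = max(tail_level, 0.0)
    best = None
    for d in range(0, max_delay + 1):
        tau, plat, h, sse, ok = _fit_with_onset(t, y, d, tau0, plat0)
        if best is None or sse < best[0]:
            best = (sse, d, tau, plat, ok)
    sse, d, tau, plat, ok = best
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
    return LFDFit(delay=d, tau=tau, plateau=float(plat),
                  r_squared=r2, converged=bool(ok))


# ---------------------------------------------------------------------------
# asynchronous-release signature
# ---------------------------------------------------------------------------

def charge_amplitude_superposition(train: EPSCTrain) -> float:
    """Maximum absolute divergence between the normalized charge and the
    normalized amplitude across stimuli.

    Synchronous release keeps charge proportional to amplitude, so the
    two normalized series superimpose and the score is ~0; a slow
    (asynchronous) charge component growing with stimulus number pushes
    the score up.  Scores above ~0.1 flag asynchronous release.
    """
    if train.charges is None:
        raise ValueError("train has no charges")
    a, c = train.amplitudes, train.charges
    if a[0] == 0 or c[0] == 0:
        raise ZeroDivisionError("first response is zero")
    return float(np.max(np.abs(c / c[0] - a / a[0])))
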
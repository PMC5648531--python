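"""Exact stochastic simulation of the kinetic schemes (independent oracle).

The schemes are continuous-time Markov chains over vesicle counts with
time-varying, Ca2+-driven rates.  They are simulated exactly by
*thinning*: within each timeline segment candidate events are drawn from
an upper bound on the total propensity (evaluated at the maximum Ca2+
the segment can reach -- the AP Gaussian peak inside pulse windows, the
residual level at the segment start outside them) and accepted with
probability actual/bound.  This is a brute-force cross-check for the
deterministic engine, intended for small vesicle numbers and short
protocols; the event loop is JIT-compiled with numba.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .engine import SimOptions, _pulse_window_halfwidth
from .kinetic_models import KineticScheme, resting_state
from .stimulus import CaParams, PulseProtocol, residual_peaks

__all__ = ["gillespie_oracle", "GillespieResult"]


@njit(cache=True)
def _run_one(seed, counts0, Q0, Qs, Qr, fuse, recycle_to, recycle_fraction,
             seg_bounds, seg_res_amp, seg_res_t0, seg_pulse_t,
             ca_rest, amp, sigma, inv_tau, see_res,
             pulse_times, window_ends, fusions_out):
    np.random.seed(seed)
    n = counts0.shape[0]
    counts = counts0.copy()
    n_seg = seg_bounds.shape[0] - 1
    two_s2 = 2.0 * sigma * sigma
    rates = np.empty(n * n + n)  # flattened i->j rates then fusion rates
    for s in range(n_seg):
        t = seg_bounds[s]
        t1 = seg_bounds[s + 1]
        res_amp = seg_res_amp[s]
        res_t0 = seg_res_t0[s]
        pulse_t = seg_pulse_t[s]
        # Ca2+ upper bounds over the segment (residual only decays within it)
        res_max = res_amp * np.exp(-(t - res_t0) * inv_tau)
        cr_max = ca_rest + res_max
        cs_max = cr_max if see_res else ca_rest
        if pulse_t == pulse_t:  # not NaN -> AP Gaussian present
            cs_max += amp
        while True:
            # total propensity bound with current counts
            bound = 0.0
            for i in range(n):
                ci = counts[i]
                if ci == 0:
                    continue
                out = fuse[i]
                for j in range(n):
                    out += Q0[i, j] + Qs[i, j] * cs_max + Qr[i, j] * cr_max
                bound += ci * out
            if bound <= 0.0:
                break
            dt = -np.log(np.random.random()) / bound
            t = t + dt
            if t >= t1:
                break
            # actual Ca2+ at the candidate time
            res = res_amp * np.exp(-(t - res_t0) * inv_tau)
            cr = ca_rest + res
            cs = cr if see_res else ca_rest
            if pulse_t == pulse_t:
                cs += amp * np.exp(-((t - pulse_t) ** 2) / two_s2)
            total = 0.0
            for i in range(n):
                ci = counts[i]
                base = i * n
                for j in range(n):
                    r = ci * (Q0[i, j] + Qs[i, j] * cs + Qr[i, j] * cr)
                    rates[base + j] = r
                    total += r
                rates[n * n + i] = ci * fuse[i]
                total += rates[n * n + i]
            if np.random.random() * bound > total:
                continue  # thinned
            # pick the event
            u = np.random.random() * total
            acc = 0.0
            idx = -1
            for k in range(n * n + n):
                acc += rates[k]
                if u <= acc:
                    idx = k
                    break
            if idx < 0:
                idx = n * n + n - 1
            if idx < n * n:
                i = idx // n
                j = idx % n
                counts[i] -= 1
                counts[j] += 1
            else:
                i = idx - n * n
                counts[i] -= 1
                if recycle_to >= 0 and np.random.random() < recycle_fraction:
                    counts[recycle_to] += 1
                # attribute the fusion to a pulse window
                for p in range(pulse_times.shape[0]):
                    if pulse_times[p] <= t < window_ends[p]:
                        fusions_out[p] += 1
                        break
    return counts


class GillespieResult:
    """Per-pulse fusion-count statistics over stochastic repetitions.

    ``v_init_mean`` is the expected initial occupancy of the releasable
    pool implied by the integer total vesicle count, i.e. the exact
    scale to multiply deterministic per-pulse release probabilities by
    when comparing against ``mean``.
    """

    def __init__(self, counts: np.ndarray, v_init_mean: float):
        self.counts = counts  # (n_reps, n_pulses)
        self.v_init_mean = v_init_mean

    @property
    def mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def se(self) -> np.ndarray:
        n = self.counts.shape[0]
        return self.counts.std(axis=0, ddof=1) / np.sqrt(n)


def gillespie_oracle(scheme: KineticScheme, protocol: PulseProtocol,
                     ca: CaParams, n_svs: int, n_reps: int, seed: int,
                     options: SimOptions | None = None,
                     init: np.ndarray | None = None) -> GillespieResult:
    """Event-driven simulation of ``scheme`` as a CTMC of ``n_svs``
    resting releasable vesicles (the other pools are scaled accordingly).

    Returns per-pulse fusion counts attributed to the same windows as
    :func:`svpools.engine.per_pulse_release`, so ``result.mean`` is
    directly comparable with ``n_svs * p_r`` from the deterministic
    engine (normalized schemes) or with ``p_r`` scaled by
    ``n_svs / pool_size`` (absolute schemes).

    Constant influx terms (basal refill, reload) are not simulated; the
    oracle is meant for short protocols where their contribution is
    negligible (and exactly zero for ``k_basal = 0``).
    """
    if protocol.n_pulses > 5:
        raise ValueError("the stochastic oracle is restricted to short "
                         "protocols (<= 5 pulses)")
    if n_svs > 100:
        raise ValueError("the stochastic oracle is restricted to <= 100 SVs")
    if options is None:
        options = SimOptions()
    if init is None:
        init = resting_state(scheme, ca.ca_rest)
    init = np.asarray(init, dtype=float)

    times = protocol.pulse_times
    w = _pulse_window_halfwidth(ca, options)
    t_start = min(0.0, float(times[0]) - w) if times.size else 0.0
    t_end = float(times[-1]) + options.release_window if times.size else 0.0
    # segment boundaries: pulse windows and inter-pulse stretches
    pts = [t_start, t_end]
    for ti in times:
        pts.extend([ti - w, ti, ti + w])
    pts = np.unique(np.clip(np.asarray(pts), t_start, t_end))
    pts = pts[np.concatenate([[True], np.diff(pts) > 1e-12])]

    peaks = residual_peaks(protocol, ca)
    seg_res_amp = np.zeros(pts.size - 1)
    seg_res_t0 = np.zeros(pts.size - 1)
    seg_pulse_t = np.full(pts.size - 1, np.nan)
    for s in range(pts.size - 1):
        ta, mid = pts[s], 0.5 * (pts[s] + pts[s + 1])
        j = int(np.searchsorted(times, ta, side="right")) - 1
        if j >= 0:
            seg_res_amp[s] = peaks[j]
            seg_res_t0[s] = times[j]
        for cand in (j, j + 1):
            if 0 <= cand < times.size and abs(times[cand] - mid) <= w:
                seg_pulse_t[s] = times[cand]
                break

    isis = np.diff(times, append=np.inf)
    window_ends = times + np.minimum(isis, options.release_window)

    # expected counts per state for n_svs resting releasable vesicles
    v_cols = [i for i, lab in enumerate(scheme.labels)
              if lab.startswith("V") or lab.startswith("S")
              or lab.startswith("F") or lab.startswith("G")]
    v_total = init[v_cols].sum() if v_cols else init.sum()
    weights = init / init.sum()
    n_total = int(round(n_svs * init.sum() / v_total))

    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    fusion_counts = np.zeros((n_reps, protocol.n_pulses), dtype=np.int64)
    recycle_to = scheme.recycle_to if scheme.recycle_to is not None else -1
    for r in range(n_reps):
        counts0 = rng.multinomial(n_total, weights).astype(np.int64)
        fus = fusion_counts[r]
        _run_one(int(rep_seeds[r]), counts0, scheme.Q0, scheme.Qs, scheme.Qr,
                 scheme.fuse, recycle_to, scheme.recycle_fraction,
                 pts, seg_res_amp, seg_res_t0, seg_pulse_t,
                 ca.ca_rest, ca.ap_amplitude, ca.ap_sigma,
                 1.0 / ca.residual_tau, ca.sensor_sees_residual,
                 times, window_ends, fus)
    return GillespieResult(fusion_counts, n_total * v_total / init.sum())
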
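"""Mass-action kinetic schemes of vesicle-pool mobilization and fusion.

Three models are provided, all built on a five-site cooperative Ca2+
binding ladder:

* :func:`make_sequential_scheme` -- a sequential *two-pool* model.  A
  reluctant pool (states ``R0``, ``R1``) feeds a fully-releasable pool
  (sensor states ``V0``..``V5``) through a Ca2+-dependent priming step
  (``R0 -> R1``, driven by residual Ca2+) and a Ca2+-independent filling
  step (``R1 <-> V0``).  Fusion occurs from the fully Ca2+-occupied state
  ``V5`` at rate ``gamma``.  A fraction of the fused flux is recycled into
  ``R0``; the remainder is lost to an implicit recycling pathway.
  Occupancies are normalized so that the resting fully-releasable pool
  sums to 1.

* :func:`make_one_pool_scheme` -- a single pool with an *allosteric*
  sensor: vesicles fuse from every occupancy state ``Sj`` at rate
  ``l_plus * f**j``, and the pool is replenished at a constant rate
  (SV/s), independent of Ca2+.  Occupancies are absolute vesicle counts.

* :func:`make_parallel_scheme` -- two non-interacting allosteric pools
  with different fusion scales (a fast- and a slowly-releasing pool,
  ``J+ < I+``).

Every transition is first order, with a rate coefficient that is either
constant or linear in one of the two Ca2+ drives, so a scheme is stored
as three per-capita rate matrices (constant, sensor-Ca-linear,
recruitment-Ca-linear) plus a fusion-rate vector and influx terms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import scipy.linalg

__all__ = [
    "SensorParams",
    "SequentialPoolParams",
    "AllostericParams",
    "ParallelPoolParams",
    "InfluxTerm",
    "KineticScheme",
    "make_sequential_scheme",
    "make_one_pool_scheme",
    "make_parallel_scheme",
    "resting_state",
    "sensor_equilibrium",
    "ladder_weights",
]

N_SITES = 5


def _check_positive(obj, names):
    for name in names:
        if getattr(obj, name) <= 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be positive")


@dataclass(frozen=True)
class SensorParams:
    """Five-site cooperative release sensor of the sequential model.

    The j-th ion binds at ``(n_sites - j + 1) * k_on * Ca`` and unbinds at
    ``j * k_off * b**(j-1)``; cooperativity ``b < 1`` slows unbinding as
    occupancy grows.  Fusion proceeds from the fully occupied state at
    ``gamma``.
    """

    k_on: float = 1e8      # M^-1 s^-1
    k_off: float = 3000.0  # s^-1
    b: float = 0.25
    gamma: float = 5000.0  # s^-1
    n_sites: int = N_SITES

    def __post_init__(self):
        _check_positive(self, ("k_off", "b", "gamma"))
        if self.k_on < 0:
            raise ValueError("k_on must be non-negative")
        if not (0 < self.b <= 1):
            raise ValueError("cooperativity b must lie in (0, 1]")
        if self.n_sites != N_SITES:
            raise ValueError("the release sensor has five Ca2+ binding sites")


@dataclass(frozen=True)
class SequentialPoolParams:
    """Sequential two-pool model parameters.

    ``k_prim`` (Ca2+-dependent priming, driven by residual Ca2+) and
    ``k_unprim`` govern ``R0 <-> R1``; ``k_fill``/``k_unfil`` govern the
    Ca2+-independent exchange ``R1 <-> V0``.  ``recycle_fraction`` of the
    fused flux is routed back into ``R0``; ``k_basal`` refills ``R0`` from
    an implicit reserve pool, either as a constant influx (pool units/s)
    or proportionally to the deficit from the resting ``R0``.
    """

    k_prim: float = 8e8     # M^-1 s^-1
    k_unprim: float = 120.0  # s^-1
    k_fill: float = 200.0    # s^-1
    k_unfil: float = 150.0   # s^-1
    k_basal: float = 0.002   # s^-1 (pool units/s at default mode)
    recycle_fraction: float = 0.9
    basal_mode: str = "constant_influx"
    sensor: SensorParams = field(default_factory=SensorParams)

    def __post_init__(self):
        _check_positive(self, ("k_prim", "k_unprim", "k_fill", "k_unfil"))
        if self.k_basal < 0:
            raise ValueError("k_basal must be non-negative")
        if not (0 <= self.recycle_fraction <= 1):
            raise ValueError("recycle_fraction must lie in [0, 1]")
        if self.basal_mode not in ("constant_influx", "deficit_proportional"):
            raise ValueError(f"unknown basal_mode {self.basal_mode!r}")

    def replace(self, **kw) -> "SequentialPoolParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class AllostericParams:
    """Allosteric-sensor one-pool model parameters.

    Vesicles fuse from every occupancy state ``Sj`` at ``l_plus * f**j``
    (``l_plus`` is the basal fusion 'willingness', ``f > 1`` the per-ion
    boost).  The pool is reloaded into ``S0`` at ``reload_rate`` SV/s.
    The sensor rate constants default to the canonical allosteric model
    of fusion at a large calyx-type synapse; they are fully
    config-exposed.  ``reload_capped`` stops reloading once the pool
    reaches ``pool_size``; the default leaves it uncapped, which is what
    a strictly constant, Ca2+-independent replenishment rate means and
    what produces this model's characteristic low-frequency facilitation
    (the pool grows between widely spaced stimuli).
    """

    k_on: float = 1e8       # M^-1 s^-1
    k_off: float = 4000.0   # s^-1
    b: float = 0.5
    l_plus: float = 2e-4    # s^-1, basal fusion rate
    f: float = 31.3
    n_sites: int = N_SITES
    pool_size: float = 2000.0   # SVs at rest
    reload_rate: float = 2000.0  # SV/s (2 SV/ms)
    reload_capped: bool = False

    def __post_init__(self):
        _check_positive(self, ("k_off", "b", "l_plus", "f", "pool_size"))
        if self.k_on < 0:
            raise ValueError("k_on must be non-negative")
        if self.reload_rate < 0:
            raise ValueError("reload_rate must be non-negative")
        if self.f <= 1:
            raise ValueError("per-ion fusion factor f must exceed 1")
        if not (0 < self.b <= 1):
            raise ValueError("cooperativity b must lie in (0, 1]")
        if self.n_sites != N_SITES:
            raise ValueError("the allosteric sensor has five binding sites")

    def replace(self, **kw) -> "AllostericParams":
        return replace(self, **kw)


def _default_fast() -> AllostericParams:
    return AllostericParams(pool_size=1000.0)


def _default_slow() -> AllostericParams:
    # Slowly releasing pool: same sensor, ten-fold smaller fusion scale.
    return AllostericParams(l_plus=2e-5, pool_size=1000.0)


@dataclass(frozen=True)
class ParallelPoolParams:
    """Two parallel, non-interacting allosteric pools (fast and slow)."""

    fast: AllostericParams = field(default_factory=_default_fast)
    slow: AllostericParams = field(default_factory=_default_slow)

    def __post_init__(self):
        if self.slow.l_plus >= self.fast.l_plus:
            raise ValueError("slow pool fusion scale must be below the fast pool's")


@dataclass(frozen=True)
class InfluxTerm:
    """Zeroth-order source into one state.

    kind:
      * ``constant`` -- ``rate`` units/s unconditionally;
      * ``deficit_proportional`` -- ``rate * (target - y[state])``, clipped
        at zero;
      * ``reload_capped`` -- ``rate`` units/s while the total occupancy is
        below ``target``, ramped linearly to zero over the last ``width``
        units so the right-hand side stays Lipschitz.
    """

    kind: str
    state: int
    rate: float
    target: float = 0.0
    width: float = 1e-3

    def flux(self, y: np.ndarray) -> float:
        if self.kind == "constant":
            return self.rate
        if self.kind == "deficit_proportional":
            return self.rate * max(self.target - y[self.state], 0.0)
        if self.kind == "reload_capped":
            gate = (self.target - float(np.sum(y))) / self.width
            return self.rate * min(max(gate, 0.0), 1.0)
        raise ValueError(f"unknown influx kind {self.kind!r}")


@dataclass(frozen=True)
class KineticScheme:
    """A labelled first-order state network with Ca2+-linear rates.

    The per-capita rate from state i to state j at Ca levels
    ``(ca_sens, ca_rec)`` is ``Q0[i,j] + Qs[i,j]*ca_sens + Qr[i,j]*ca_rec``.
    ``fuse[i]`` is the (constant) fusion rate out of state i; a fraction
    ``recycle_fraction`` of the fusion flux re-enters at ``recycle_to``,
    the rest is lost.  Two bookkeeping channels (cumulative fused,
    cumulative lost) are appended to the ODE state by the engine.
    """

    name: str
    labels: tuple[str, ...]
    Q0: np.ndarray
    Qs: np.ndarray
    Qr: np.ndarray
    fuse: np.ndarray
    recycle_to: int | None = None
    recycle_fraction: float = 0.0
    influx: tuple[InfluxTerm, ...] = ()
    normalization: str = "fraction_of_resting_V"
    params: object = None

    def __post_init__(self):
        n = len(self.labels)
        for mat_name in ("Q0", "Qs", "Qr"):
            m = np.asarray(getattr(self, mat_name), dtype=float)
            object.__setattr__(self, mat_name, m)
            if m.shape != (n, n):
                raise ValueError(f"{mat_name} must be {n}x{n}")
            if np.any(m < 0):
                raise ValueError(f"{mat_name} must have non-negative entries")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{mat_name} must have a zero diagonal")
        fuse = np.asarray(self.fuse, dtype=float)
        object.__setattr__(self, "fuse", fuse)
        if fuse.shape != (n,) or np.any(fuse < 0):
            raise ValueError("fuse must be a non-negative length-n vector")
        for term in self.influx:
            if not (0 <= term.state < n):
                raise ValueError("influx state index out of range")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def rate_matrix(self, ca_sens: float, ca_rec: float) -> np.ndarray:
        """Per-capita transition-rate matrix at the given Ca2+ levels."""
        return self.Q0 + ca_sens * self.Qs + ca_rec * self.Qr

    def generator(self, ca_sens: float, ca_rec: float) -> np.ndarray:
        """Generator M such that dy/dt = M^T y (fusion and recycling
        included, influx terms excluded)."""
        K = self.rate_matrix(ca_sens, ca_rec)
        M = K.copy()
        out_rate = K.sum(axis=1) + self.fuse
        M[np.diag_indices_from(M)] = -out_rate
        if self.recycle_to is not None and self.recycle_fraction > 0:
            M[:, self.recycle_to] += self.recycle_fraction * self.fuse
        return M


# ---------------------------------------------------------------------------
# ladder helpers
# ---------------------------------------------------------------------------

def _ladder_matrices(k_on: float, k_off: float, b: float,
                     offset: int, n: int, Q0: np.ndarray, Qs: np.ndarray):
    """Write the five-site binding/unbinding ladder into Q0/Qs in place,
    for states offset..offset+5."""
    for j in range(N_SITES):
        # binding j -> j+1, rate (5-j) * k_on * Ca_sens
        Qs[offset + j, offset + j + 1] = (N_SITES - j) * k_on
        # unbinding j+1 -> j, rate (j+1) * k_off * b**j
        Q0[offset + j + 1, offset + j] = (j + 1) * k_off * b ** j


def ladder_weights(k_on: float, k_off: float, b: float, ca: float) -> np.ndarray:
    """Unnormalized stationary weights of the pure binding ladder
    (no fusion): ``w_j = C(5,j) * (k_on*ca/k_off)^j * b^(-j(j-1)/2)``."""
    if ca < 0:
        raise ValueError("ca must be non-negative")
    w = np.zeros(N_SITES + 1)
    w[0] = 1.0
    if ca == 0 or k_on == 0:
        return w
    # build in log space to stay finite at very high Ca
    logK = math.log(k_on * ca / k_off)
    logb = math.log(b)
    logw = np.array([
        math.log(math.comb(N_SITES, j)) + j * logK - j * (j - 1) / 2.0 * logb
        for j in range(N_SITES + 1)
    ])
    logw -= logw.max()
    return np.exp(logw)


def sensor_equilibrium(params: SensorParams, ca: float) -> np.ndarray:
    """Stationary occupancy distribution of the sensor ladder V0..V5 at a
    fixed Ca2+ level, with fusion switched off (gamma = 0), normalized to 1.

    This is the closed-form product distribution of a birth--death chain
    and serves as an independent oracle for the full schemes.
    """
    w = ladder_weights(params.k_on, params.k_off, params.b, ca)
    return w / w.sum()


# ---------------------------------------------------------------------------
# scheme constructors
# ---------------------------------------------------------------------------

def make_sequential_scheme(params: SequentialPoolParams | None = None) -> KineticScheme:
    """Sequential two-pool scheme: states R0, R1, V0..V5."""
    if params is None:
        params = SequentialPoolParams()
    labels = ("R0", "R1") + tuple(f"V{j}" for j in range(N_SITES + 1))
    n = len(labels)
    Q0 = np.zeros((n, n))
    Qs = np.zeros((n, n))
    Qr = np.zeros((n, n))
    R0, R1, V0 = 0, 1, 2
    Qr[R0, R1] = params.k_prim        # Ca2+-dependent priming (residual Ca)
    Q0[R1, R0] = params.k_unprim
    Q0[R1, V0] = params.k_fill
    Q0[V0, R1] = params.k_unfil
    s = params.sensor
    _ladder_matrices(s.k_on, s.k_off, s.b, V0, n, Q0, Qs)
    fuse = np.zeros(n)
    fuse[V0 + N_SITES] = s.gamma
    influx: tuple[InfluxTerm, ...] = ()
    if params.k_basal > 0:
        if params.basal_mode == "constant_influx":
            influx = (InfluxTerm("constant", R0, params.k_basal),)
        else:
            # deficit-proportional refilling toward the resting R0
            r0_rest = (params.k_unfil / params.k_fill) * params.k_unprim / params.k_prim
            influx = (InfluxTerm("deficit_proportional", R0, params.k_basal,
                                 target=r0_rest),)
    return KineticScheme(
        name="sequential",
        labels=labels,
        Q0=Q0, Qs=Qs, Qr=Qr,
        fuse=fuse,
        recycle_to=R0,
        recycle_fraction=params.recycle_fraction,
        influx=influx,
        normalization="fraction_of_resting_V",
        params=params,
    )


def make_one_pool_scheme(params: AllostericParams | None = None,
                         prefix: str = "S") -> KineticScheme:
    """One-pool allosteric scheme: states S0..S5, absolute SV counts."""
    if params is None:
        params = AllostericParams()
    labels = tuple(f"{prefix}{j}" for j in range(N_SITES + 1))
    n = len(labels)
    Q0 = np.zeros((n, n))
    Qs = np.zeros((n, n))
    Qr = np.zeros((n, n))
    _ladder_matrices(params.k_on, params.k_off, params.b, 0, n, Q0, Qs)
    fuse = params.l_plus * params.f ** np.arange(N_SITES + 1)
    if params.reload_rate > 0:
        kind = "reload_capped" if params.reload_capped else "constant"
        influx = (InfluxTerm(kind, 0, params.reload_rate,
                             target=params.pool_size,
                             width=max(1e-3 * params.pool_size, 1e-9)),)
    else:
        influx = ()
    return KineticScheme(
        name="one_pool",
        labels=labels,
        Q0=Q0, Qs=Qs, Qr=Qr,
        fuse=fuse,
        recycle_to=None,
        recycle_fraction=0.0,
        influx=influx,
        normalization="absolute_SV_counts",
        params=params,
    )


def make_parallel_scheme(params: ParallelPoolParams | None = None) -> KineticScheme:
    """Disjoint union of a fast and a slow allosteric pool."""
    if params is None:
        params = ParallelPoolParams()
    fast = make_one_pool_scheme(params.fast, prefix="F")
    slow = make_one_pool_scheme(params.slow, prefix="G")
    n1, n2 = fast.n_states, slow.n_states
    n = n1 + n2
    Q0 = scipy.linalg.block_diag(fast.Q0, slow.Q0)
    Qs = scipy.linalg.block_diag(fast.Qs, slow.Qs)
    Qr = scipy.linalg.block_diag(fast.Qr, slow.Qr)
    fuse = np.concatenate([fast.fuse, slow.fuse])
    influx = tuple(fast.influx) + tuple(
        InfluxTerm(t.kind, t.state + n1, t.rate, t.target, t.width)
        for t in slow.influx
    )
    # NOTE: for a capped reload the two pools must be gated on their own
    # totals, not the union's; capped parallel reload is therefore handled
    # per pool by the engine via the state-slice encoded in the target.
    if any(t.kind == "reload_capped" for t in influx):
        raise NotImplementedError(
            "capped reload is not supported in the parallel scheme; "
            "use reload_capped=False (the default)")
    return KineticScheme(
        name="parallel",
        labels=fast.labels + slow.labels,
        Q0=Q0, Qs=Qs, Qr=Qr,
        fuse=fuse,
        recycle_to=None,
        recycle_fraction=0.0,
        influx=influx,
        normalization="absolute_SV_counts",
        params=params,
    )


# ---------------------------------------------------------------------------
# resting states
# ---------------------------------------------------------------------------

def resting_state(scheme: KineticScheme, ca: float) -> np.ndarray:
    """Resting occupancy vector for a scheme at ambient Ca2+ ``ca``.

    Sequential scheme: the quasi-stationary mode of the full generator at
    constant Ca (fusion leak and recycling included, basal influx
    excluded), i.e. the slowest-decaying eigenvector, normalized so the
    fully-releasable pool sums to 1.  At resting Ca2+ this is numerically
    the detailed-balance point ``R1/V = k_unfil/k_fill``,
    ``R0/R1 = k_unprim/(k_prim*ca)`` with the ladder distributed per
    :func:`sensor_equilibrium`, corrected for the slow drain through the
    fused state.

    Allosteric schemes: the binding-ladder equilibrium over ``pool_size``
    vesicles (fusion neglected -- the basal fusion rate is orders of
    magnitude below the ladder rates).
    """
    if ca < 0:
        raise ValueError("ca must be non-negative")
    if scheme.name == "sequential":
        if ca == 0:
            raise ValueError("the sequential rest point is undefined at Ca = 0 "
                             "(priming flux vanishes)")
        M = scheme.generator(ca, ca)
        # slowest mode of dy/dt = M^T y
        vals, vecs = scipy.linalg.eig(M.T)
        order = np.argsort(-vals.real)
        v = vecs[:, order[0]].real
        if np.max(np.abs(v.imag if np.iscomplexobj(v) else 0)) > 1e-12:
            raise ArithmeticError("no real quasi-stationary mode found")
        v = v / v[np.argmax(np.abs(v))]
        if np.any(v < -1e-9):
            raise ArithmeticError("quasi-stationary mode is not non-negative")
        v = np.clip(v, 0.0, None)
        v_total = v[2:].sum()
        if v_total <= 0:
            raise ArithmeticError("degenerate rest point: empty releasable pool")
        return v / v_total
    if scheme.name in ("one_pool", "parallel"):
        p = scheme.params
        if scheme.name == "one_pool":
            return p.pool_size * _ladder_dist(p, ca)
        fast = p.fast.pool_size * _ladder_dist(p.fast, ca)
        slow = p.slow.pool_size * _ladder_dist(p.slow, ca)
        return np.concatenate([fast, slow])
    raise ValueError(f"unknown scheme {scheme.name!r}")


def _ladder_dist(p: AllostericParams, ca: float) -> np.ndarray:
    w = ladder_weights(p.k_on, p.k_off, p.b, ca)
    return w / w.sum()


# ---------------------------------------------------------------------------
# JSON (de)serialization of parameter sets
# ---------------------------------------------------------------------------

_PARAM_TYPES = {
    "sequential": SequentialPoolParams,
    "one_pool": AllostericParams,
    "parallel": ParallelPoolParams,
}


def params_to_json(params, path=None):
    payload = asdict(params)
    if path is None:
        return json.dumps(payload, indent=2)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def params_from_dict(model: str, overrides: dict):
    """Build a parameter set for ``model`` from a (possibly nested) dict of
    overrides on top of the defaults."""
    cls = _PARAM_TYPES[model]
    if model == "sequential":
        sensor = SensorParams(**overrides.pop("sensor", {}))
        return cls(sensor=sensor, **overrides)
    if model == "parallel":
        fast = _default_fast().replace(**overrides.pop("fast", {}))
        slow = _default_slow().replace(**overrides.pop("slow", {}))
        if overrides:
            raise ValueError(f"unknown parallel-model keys: {sorted(overrides)}")
        return cls(fast=fast, slow=slow)
    return cls(**overrides)
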
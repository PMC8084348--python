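"""Synthetic point-process generators used to validate the estimators.

All simulators take an explicit seed and are bit-for-bit reproducible.
Independent random substreams (via :class:`numpy.random.SeedSequence`)
are used for source, target and thinning draws, so changing one
component's usage pattern does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .series import EventSeries, _ensure_strict

__all__ = [
    "CoupledPairParams",
    "NoisyCopyParams",
    "LIFParams",
    "StimulusParams",
    "simulate_homogeneous_poisson",
    "coupled_rate",
    "simulate_coupled_pair",
    "simulate_noisy_copy",
    "simulate_stimulus",
    "simulate_lif",
]


# ---------------------------------------------------------------------------
# parameter containers

@dataclass(frozen=True)
class CoupledPairParams:
    """Unidirectionally coupled pair: Poisson source, rate-modulated target.

    The target's instantaneous rate depends only on the time ``t_y1``
    since the most recent source event: a Gaussian bump of height ``m``
    centred at ``t_cut / 2`` rides on the baseline ``lambda_x_base`` for
    ``t_y1 < t_cut`` and the rate returns to baseline afterwards.  The
    bump is shifted down so the rate is continuous (equal to baseline)
    at ``t_y1 = 0``.

    With the default parameters the ground-truth TE rate from source to
    target is 0.5076 +/- 0.001 nats per time unit (computable exactly by
    filtering over the hidden time-since-last-source-event state).
    """

    lambda_y_bar: float = 1.0      # source rate, events / time
    m: float = 5.0                 # bump height, events / time
    t_cut: float = 1.0             # bump support length, time
    lambda_x_base: float = 0.5     # baseline target rate, events / time
    sigma_sq: float = 0.01         # bump variance, time^2
    lambda_h: float | None = None  # thinning bound; default = analytic supremum

    def __post_init__(self) -> None:
        for name in ("lambda_y_bar", "m", "t_cut", "lambda_x_base", "sigma_sq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lambda_h is None:
            # The rate never exceeds baseline + bump height, so this bound
            # keeps the thinning acceptance probability <= 1 everywhere.
            object.__setattr__(self, "lambda_h", self.lambda_x_base + self.m)
        elif self.lambda_h < self.lambda_x_base + self.m:
            raise ValueError("lambda_h must dominate the conditional rate")


@dataclass(frozen=True)
class NoisyCopyParams:
    """Quasi-periodic mother process with two jittered daughter copies."""

    T: float = 1.0           # mother period, time
    sigma_M: float = 0.05    # mother jitter s.d., time
    trunc_eps: float = 1e-6  # left-truncation offset so intervals stay > eps
    a_D1: float = 0.25       # first daughter delay, time
    a_D2: float = 0.5        # second daughter delay, time
    sigma_D: float = 0.05    # daughter jitter s.d., time
    omega: float = 0.0       # translation applied to D1 after simulation

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if not self.a_D1 < self.a_D2:
            raise ValueError("a_D1 must be less than a_D2")
        if self.trunc_eps <= 0:
            raise ValueError("trunc_eps must be positive")


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire neuron with instantaneous synaptic jumps.

    ``connections`` lists ``(stimulus_index, sign, strength_mV, delay)``
    with ``sign`` in ``{"excitatory", "inhibitory"}``.
    """

    V0: float = -65.0          # resting potential, mV
    V_reset: float = -75.0     # reset potential, mV
    V_threshold: float = -45.0  # threshold, mV
    tau_m: float = 0.01        # membrane time constant, time
    refractory: float = 0.005  # hard refractory period, time
    connections: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.V_reset < self.V_threshold:
            raise ValueError("V_reset must be below V_threshold")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")
        conns = tuple(tuple(c) for c in self.connections)
        for idx, sign, strength, delay in conns:
            if sign not in ("excitatory", "inhibitory"):
                raise ValueError(f"unknown connection sign {sign!r}")
            if strength < 0:
                raise ValueError("connection strength must be non-negative")
            if delay < 0:
                raise ValueError("connection delay must be non-negative")
        object.__setattr__(self, "connections", conns)


@dataclass(frozen=True)
class StimulusParams:
    """Piecewise-constant-rate inhomogeneous Poisson stimulus.

    The rate is constant over windows of ``window_length`` and drawn
    uniformly in ``[rate_low, rate_high]`` per window; events are thinned
    from a homogeneous Poisson bound ``bound_rate`` and a hard refractory
    period is applied by a sequential forward scan.
    """

    window_length: float = 0.5  # time
    rate_low: float = 0.0       # events / time
    rate_high: float = 40.0     # events / time
    refractory: float = 0.005   # time
    bound_rate: float | None = None  # thinning bound R; default = rate_high

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if not 0 <= self.rate_low <= self.rate_high:
            raise ValueError("need 0 <= rate_low <= rate_high")
        if self.bound_rate is None:
            object.__setattr__(self, "bound_rate", max(self.rate_high, 1e-12))
        elif self.bound_rate < self.rate_high:
            raise ValueError("bound_rate must be >= rate_high")


# ---------------------------------------------------------------------------
# simulators

def simulate_homogeneous_poisson(rate: float, n_events: int,
                                 seed: int | np.random.SeedSequence,
                                 t0: float = 0.0,
                                 label: str = "poisson") -> EventSeries:
    """Homogeneous Poisson process with exactly ``n_events`` events.

    Inter-event intervals are i.i.d. Exponential(``rate``); the first
    event is one such interval after ``t0``.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    rng = np.random.default_rng(seed)
    isis = rng.exponential(1.0 / rate, size=int(n_events))
    return EventSeries(t0 + np.cumsum(isis), label=label)


def coupled_rate(t_y1, params: CoupledPairParams):
    """Target rate as a function of the time since the last source event.

    Scalar or array ``t_y1``.  For ``t_y1 >= t_cut`` (including the
    "no source event yet" limit ``t_y1 = +inf``) the rate is the
    baseline; inside the bump window it is the shifted Gaussian bump.
    """
    t = np.asarray(t_y1, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_y1 must be non-negative")
    half = params.t_cut / 2.0
    bump = params.m * np.exp(-((t - half) ** 2) / (2.0 * params.sigma_sq))
    offset = params.m * np.exp(-(half ** 2) / (2.0 * params.sigma_sq))
    out = np.where(t < params.t_cut,
                   params.lambda_x_base + bump - offset,
                   params.lambda_x_base)
    if np.isscalar(t_y1):
        return float(out)
    return out


def simulate_coupled_pair(params: CoupledPairParams, n_target_events: int,
                          seed: int | np.random.SeedSequence,
                          burn_in_source_events: int = 10,
                          ) -> tuple[EventSeries, EventSeries]:
    """Simulate the coupled pair by thinning; return (source Y, target X).

    Candidate target events are generated as homogeneous Poisson at the
    bound rate ``lambda_h`` and each kept with probability
    ``coupled_rate(t_y1) / lambda_h``.  Candidates occurring before the
    first source event see the baseline rate (the ``t_y1 -> inf``
    branch).  A burn-in prefix (everything before the
    ``burn_in_source_events``-th source event) is discarded before the
    contiguous block of exactly ``n_target_events`` target events (with
    the covering source events) is returned.
    """
    if n_target_events < 1:
        raise ValueError("n_target_events must be at least 1")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    src_ss, cand_ss, thin_ss = ss.spawn(3)
    rng_src = np.random.default_rng(src_ss)
    rng_cand = np.random.default_rng(cand_ss)
    rng_thin = np.random.default_rng(thin_ss)

    # mean target rate is at least the baseline, so this horizon usually
    # suffices; extend multiplicatively if the thinning was unlucky.
    accepted: list[np.ndarray] = []
    n_acc = 0
    t_hi = 1.3 * n_target_events / params.lambda_x_base
    src_times = np.cumsum(rng_src.exponential(
        1.0 / params.lambda_y_bar,
        size=int(2.5 * params.lambda_y_bar * t_hi) + 64))
    while src_times[-1] < t_hi:
        extra = np.cumsum(rng_src.exponential(
            1.0 / params.lambda_y_bar, size=1024)) + src_times[-1]
        src_times = np.concatenate([src_times, extra])

    t_cursor = 0.0
    burn_end = src_times[burn_in_source_events - 1] if burn_in_source_events > 0 else 0.0
    while True:
        n_cand = int(1.2 * params.lambda_h * (t_hi - t_cursor)) + 64
        cands = t_cursor + np.cumsum(rng_cand.exponential(1.0 / params.lambda_h,
                                                          size=n_cand))
        while cands[-1] < t_hi:
            extra = cands[-1] + np.cumsum(rng_cand.exponential(
                1.0 / params.lambda_h, size=1024))
            cands = np.concatenate([cands, extra])
        cands = cands[cands <= t_hi]
        while src_times[-1] < t_hi:
            extra = np.cumsum(rng_src.exponential(
                1.0 / params.lambda_y_bar, size=1024)) + src_times[-1]
            src_times = np.concatenate([src_times, extra])
        idx = np.searchsorted(src_times, cands, side="left") - 1
        t_y1 = np.where(idx >= 0, cands - src_times[np.clip(idx, 0, None)], np.inf)
        # inf maps to the baseline branch
        rate = np.where(np.isinf(t_y1), params.lambda_x_base,
                        coupled_rate(np.where(np.isinf(t_y1), 0.0, t_y1), params))
        keep = rng_thin.random(cands.size) < rate / params.lambda_h
        kept = cands[keep]
        kept = kept[kept > burn_end]
        accepted.append(kept)
        n_acc += kept.size
        if n_acc >= n_target_events:
            break
        t_cursor = t_hi
        t_hi *= 1.5

    target = np.concatenate(accepted)[:n_target_events]
    source = src_times[src_times <= target[-1]]
    return (EventSeries(source, label="Y"), EventSeries(target, label="X"))


def simulate_noisy_copy(params: NoisyCopyParams, n_mother_events: int,
                        seed: int | np.random.SeedSequence,
                        ) -> tuple[EventSeries, EventSeries, EventSeries]:
    """Mother process plus two noisy-copy daughters; returns (M, D1, D2).

    Mother intervals are ``T + xi_M`` with ``xi_M`` a zero-mean normal of
    s.d. ``sigma_M`` left-truncated at ``-T + trunc_eps`` (intervals stay
    positive).  Daughter ``i`` copies each mother event shifted by
    ``a_Di + xi_Di``; D1 is then translated by ``omega``.  Outputs are
    re-sorted (jitter can reorder events) and kept strictly increasing.
    """
    if n_mother_events < 1:
        raise ValueError("n_mother_events must be at least 1")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    m_ss, d1_ss, d2_ss = ss.spawn(3)

    a = (-params.T + params.trunc_eps) / params.sigma_M
    xi_m = stats.truncnorm.rvs(a, np.inf, loc=0.0, scale=params.sigma_M,
                               size=int(n_mother_events),
                               random_state=np.random.default_rng(m_ss))
    mother = np.cumsum(params.T + xi_m)

    rng1 = np.random.default_rng(d1_ss)
    rng2 = np.random.default_rng(d2_ss)
    d1 = mother + params.a_D1 + rng1.normal(0.0, params.sigma_D, mother.size)
    d2 = mother + params.a_D2 + rng2.normal(0.0, params.sigma_D, mother.size)
    d1 = _ensure_strict(d1 + params.omega)
    d2 = _ensure_strict(d2)
    return (EventSeries(mother, label="M"),
            EventSeries(d1, label="D1"),
            EventSeries(d2, label="D2"))


def simulate_stimulus(params: StimulusParams, duration: float,
                      seed: int | np.random.SeedSequence,
                      label: str = "stimulus") -> EventSeries:
    """Inhomogeneous Poisson stimulus with per-window uniform rates.

    Thinning: candidates at the bound rate R are kept with probability
    ``r_i / R`` where ``r_i`` is the rate of the window containing the
    candidate; events within the refractory period of the previous
    *kept* event are then removed by a forward scan.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rate_ss, cand_ss, thin_ss = ss.spawn(3)
    rng_rate = np.random.default_rng(rate_ss)
    rng_cand = np.random.default_rng(cand_ss)
    rng_thin = np.random.default_rng(thin_ss)

    n_windows = int(np.ceil(duration / params.window_length))
    rates = rng_rate.uniform(params.rate_low, params.rate_high, size=n_windows)
    if params.rate_high == 0:
        return EventSeries(np.empty(0), label=label)

    R = params.bound_rate
    n_cand = rng_cand.poisson(R * duration)
    cands = np.sort(rng_cand.uniform(0.0, duration, size=n_cand))
    win = np.minimum((cands / params.window_length).astype(int), n_windows - 1)
    keep = rng_thin.random(cands.size) < rates[win] / R
    kept = cands[keep]

    out: list[float] = []
    last = -np.inf
    for t in kept:
        if t - last >= params.refractory:
            out.append(t)
            last = t
    return EventSeries(np.asarray(out), label=label)


def simulate_lif(params: LIFParams, stimuli: list[EventSeries],
                 duration: float,
                 seed: int | np.random.SeedSequence | None = None,
                 label: str = "lif") -> EventSeries:
    """Event-driven leaky integrate-and-fire neuron.

    The membrane potential decays exactly (closed-form exponential
    toward ``V0``) between delayed presynaptic arrivals; each arrival
    jumps ``V`` by its signed strength.  A threshold crossing emits a
    spike at the arrival time, resets ``V`` and freezes the dynamics for
    the refractory period (arrivals during it are lost).  ``seed`` is
    accepted for interface uniformity; the dynamics are deterministic
    given the stimuli.
    """
    arrival_times: list[np.ndarray] = []
    arrival_jumps: list[np.ndarray] = []
    for idx, sign, strength, delay in params.connections:
        times = stimuli[idx].times + delay
        jump = strength if sign == "excitatory" else -strength
        arrival_times.append(times)
        arrival_jumps.append(np.full(times.size, jump))
    if arrival_times:
        times = np.concatenate(arrival_times)
        jumps = np.concatenate(arrival_jumps)
        order = np.argsort(times, kind="stable")
        times, jumps = times[order], jumps[order]
    else:
        times = np.empty(0)
        jumps = np.empty(0)

    V = params.V0
    t_prev = 0.0
    frozen_until = -np.inf
    spikes: list[float] = []
    for t, jump in zip(times, jumps):
        if t > duration:
            break
        if t < frozen_until:
            continue
        start = max(t_prev, frozen_until)
        if start > -np.inf and t > start:
            V = params.V0 + (V - params.V0) * np.exp(-(t - start) / params.tau_m)
        V += jump
        t_prev = t
        if V >= params.V_threshold:
            spikes.append(t)
            V = params.V_reset
            frozen_until = t + params.refractory
            t_prev = frozen_until
    return EventSeries(_ensure_strict(np.asarray(spikes)), label=label)
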
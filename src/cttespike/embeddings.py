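"""Inter-event-interval history embeddings and the four sample sets.

The continuous-time estimator works on history embeddings: at an
observation time ``t`` the recent past of a process is summarised by the
interval from ``t`` back to the most recent event, followed by the
preceding inter-event intervals.  Joint embeddings (target + source +
conditionals) and conditioning-only embeddings (without the source) are
collected both at target events (sets ``J_X`` / ``C_X``) and at sample
points placed independently of the target (sets ``J_U`` / ``C_U``).

Every sample carries a dynamic-correlation exclusion window spanning
from the earliest event that contributed an interval to the sample, up
to the observation time; neighbour searches ignore samples with
overlapping windows (Theiler exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import EventSeries

__all__ = [
    "EmbeddingConfig",
    "EmbeddingSample",
    "SampleSets",
    "embed_at",
    "build_sample_sets",
    "windows_overlap",
    "InsufficientHistoryError",
]


class InsufficientHistoryError(ValueError):
    """An observation point lacks enough preceding events to embed."""


class EstimationImpossibleError(RuntimeError):
    """No usable samples could be constructed."""


@dataclass(frozen=True)
class EmbeddingConfig:
    """History-embedding lengths and target-independent sampling.

    ``l_X`` / ``l_Y`` / ``l_Z`` count backward inter-event intervals per
    process; ``N_U`` is the number of target-independent sample points,
    placed at fixed intervals or uniformly at random within the span.
    """

    l_X: int = 1
    l_Y: int = 1
    l_Z: tuple[int, ...] = ()
    N_U: int | None = None          # default: one per target event
    placement: str = "fixed_interval"

    def __post_init__(self) -> None:
        if self.l_X < 1 or self.l_Y < 1 or any(l < 1 for l in self.l_Z):
            raise ValueError("embedding lengths must be >= 1")
        if self.N_U is not None and self.N_U < 1:
            raise ValueError("N_U must be >= 1")
        if self.placement not in ("fixed_interval", "random_uniform"):
            raise ValueError(f"unknown placement {self.placement!r}")
        object.__setattr__(self, "l_Z", tuple(int(l) for l in self.l_Z))

    @property
    def l_J(self) -> int:
        return self.l_X + self.l_Y + sum(self.l_Z)

    @property
    def l_C(self) -> int:
        return self.l_X + sum(self.l_Z)


@dataclass(frozen=True)
class EmbeddingSample:
    """One history embedding with its exclusion window(s)."""

    x: np.ndarray
    y: np.ndarray | None
    z: tuple[np.ndarray, ...]
    exclusion_windows: tuple[tuple[float, float], ...]
    observation_time: float

    @property
    def joint(self) -> np.ndarray:
        parts = [self.x]
        if self.y is not None:
            parts.append(self.y)
        parts.extend(self.z)
        return np.concatenate(parts)


def embedding_to_csv(sample: "EmbeddingSample", path) -> None:
    """Dump one embedding sample as ``component,index,value`` rows."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["component", "index", "value"])
        for k, v in enumerate(sample.x, 1):
            writer.writerow(["x", k, repr(float(v))])
        if sample.y is not None:
            for k, v in enumerate(sample.y, 1):
                writer.writerow(["y", k, repr(float(v))])
        for j, z in enumerate(sample.z, 1):
            for k, v in enumerate(z, 1):
                writer.writerow([f"z{j}", k, repr(float(v))])


def _pred_index(times: np.ndarray, t: float | np.ndarray) -> np.ndarray:
    """Index of the most recent event strictly before ``t`` (-1 if none)."""
    return np.searchsorted(times, t, side="left") - 1


def _embed_process(times: np.ndarray, obs: np.ndarray, l: int
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised single-process embedding at each observation point.

    Returns ``(components (n, l), earliest_event_time (n,), valid (n,))``.
    Component 1 is the interval from the observation back to the
    predecessor event; component k>1 is the (k-1)-th inter-event interval
    further back.
    """
    n = obs.size
    if times.size < l:
        return (np.full((n, l), np.nan), np.full(n, np.nan),
                np.zeros(n, dtype=bool))
    idx = _pred_index(times, obs)
    valid = idx >= l - 1
    comps = np.zeros((n, l))
    earliest = np.full(n, np.nan)
    safe = np.where(valid, idx, l - 1)
    comps[:, 0] = obs - times[safe]
    for k in range(2, l + 1):
        comps[:, k - 1] = times[safe - k + 2] - times[safe - k + 1]
    earliest = times[safe - l + 1]
    comps[~valid] = np.nan
    earliest[~valid] = np.nan
    return comps, earliest, valid


def embed_at(t: float, target: EventSeries, source: EventSeries | None,
             conditionals: tuple[EventSeries, ...] | list,
             config: EmbeddingConfig) -> EmbeddingSample:
    """Construct a single embedding sample at observation time ``t``.

    The predecessor search is strict, so an observation at a target
    event uses the preceding inter-event interval as its first target
    component.  Raises :class:`InsufficientHistoryError` when any
    embedded process has fewer than its configured number of events
    before ``t``.
    """
    obs = np.asarray([float(t)])
    x, ex, vx = _embed_process(target.times, obs, config.l_X)
    earliest = [ex[0]]
    if not vx[0]:
        raise InsufficientHistoryError(f"target history too short at t={t}")
    y = None
    if source is not None:
        y, ey, vy = _embed_process(source.times, obs, config.l_Y)
        if not vy[0]:
            raise InsufficientHistoryError(f"source history too short at t={t}")
        earliest.append(ey[0])
        y = y[0]
    z = []
    for series, lz in zip(conditionals, config.l_Z):
        zc, ez, vz = _embed_process(series.times, obs, lz)
        if not vz[0]:
            raise InsufficientHistoryError(
                f"conditioning history too short at t={t}")
        earliest.append(ez[0])
        z.append(zc[0])
    window = (float(min(earliest)), float(t))
    return EmbeddingSample(x=x[0], y=y, z=tuple(z),
                           exclusion_windows=(window,),
                           observation_time=float(t))


def windows_overlap(a: EmbeddingSample, b: EmbeddingSample) -> bool:
    """True iff any exclusion window of ``a`` intersects any of ``b``.

    Intersection is closed-interval: shared endpoints count as overlap.
    """
    for (s1, e1) in a.exclusion_windows:
        for (s2, e2) in b.exclusion_windows:
            if s1 <= e2 and s2 <= e1:
                return True
    return False


def embed_observation_points(obs: np.ndarray, target: EventSeries,
                             source: EventSeries | None,
                             conditionals: tuple[EventSeries, ...] | list,
                             config: EmbeddingConfig
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                        np.ndarray, np.ndarray]:
    """Vectorised embedding of many observation points.

    Returns ``(J, C, windows_J, windows_C, retained_obs)`` where
    invalid observation points (insufficient history in any process)
    have been dropped.  ``J`` columns are laid out as
    ``[target | source | cond_1 | ...]`` and ``C`` drops the source
    block.  Windows are ``(n, 2)`` arrays of (start, end); the joint and
    conditioning-only embeddings each track the earliest event among
    their own components.
    """
    obs = np.asarray(obs, dtype=float)
    x, ex, vx = _embed_process(target.times, obs, config.l_X)
    blocks = [x]
    earliest_c = [ex]
    valid = vx.copy()
    if source is not None:
        y, ey, vy = _embed_process(source.times, obs, config.l_Y)
        blocks.append(y)
        earliest_j_src = ey
        valid &= vy
    else:
        y = np.zeros((obs.size, 0))
        earliest_j_src = np.full(obs.size, np.inf)
        blocks.append(y)
    for series, lz in zip(conditionals, config.l_Z):
        zc, ez, vz = _embed_process(series.times, obs, lz)
        blocks.append(zc)
        earliest_c.append(ez)
        valid &= vz

    J = np.concatenate(blocks, axis=1)
    C = np.concatenate([blocks[0]] + blocks[2:], axis=1)
    start_c = np.min(np.stack(earliest_c, axis=0), axis=0)
    start_j = np.minimum(start_c, earliest_j_src)
    windows_J = np.column_stack([start_j, obs])
    windows_C = np.column_stack([start_c, obs])
    return (J[valid], C[valid], windows_J[valid], windows_C[valid], obs[valid])


@dataclass
class SampleSets:
    """The four embedding collections used by the estimators.

    ``J_X`` / ``C_X`` are index-aligned (the i-th conditioning sample is
    the i-th joint sample minus the source block), as are ``J_U`` /
    ``C_U``.  ``mean_rate`` is the unconditional target rate estimate
    (N_X - 1) / span over the retained target events.
    """

    J_X: np.ndarray
    C_X: np.ndarray
    J_U: np.ndarray
    C_U: np.ndarray
    windows_JX: np.ndarray
    windows_CX: np.ndarray
    windows_JU: np.ndarray
    windows_CU: np.ndarray
    mean_rate: float
    config: EmbeddingConfig
    obs_X: np.ndarray = field(default_factory=lambda: np.empty(0))
    obs_U: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_X(self) -> int:
        return self.J_X.shape[0]

    @property
    def n_U(self) -> int:
        return self.J_U.shape[0]


def place_sample_points(span: tuple[float, float], n: int, placement: str,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Place ``n`` target-independent observation points within ``span``.

    Fixed placement uses the interior grid ``t0 + k (t1 - t0) / (n + 1)``
    for k = 1..n, which never coincides with the span endpoints.
    """
    t0, t1 = span
    if placement == "fixed_interval":
        return t0 + np.arange(1, n + 1) * (t1 - t0) / (n + 1)
    if placement == "random_uniform":
        if rng is None:
            raise ValueError("random placement requires a generator")
        return np.sort(rng.uniform(t0, t1, size=n))
    raise ValueError(f"unknown placement {placement!r}")


def build_sample_sets(target: EventSeries, source: EventSeries,
                      conditionals: tuple[EventSeries, ...] | list = (),
                      config: EmbeddingConfig | None = None,
                      span: tuple[float, float] | None = None,
                      seed: int | np.random.Generator | None = None
                      ) -> SampleSets:
    """Build J_X, C_X, J_U and C_U from raw event series.

    Joint samples are taken at every target event with sufficient
    history in all embedded processes, and at ``N_U`` sample points
    (default: one per target event) placed within ``span`` (default:
    first to last target event).  All normalisations use retained
    counts; the mean target rate uses the span of the retained target
    events.
    """
    if config is None:
        config = EmbeddingConfig()
    if len(conditionals) != len(config.l_Z):
        raise ValueError("number of conditioning processes must match l_Z")
    if span is None:
        if len(target) < 2:
            raise EstimationImpossibleError("need at least two target events")
        span = (float(target.times[0]), float(target.times[-1]))

    J_X, C_X, wjx, wcx, obs_x = embed_observation_points(
        target.times, target, source, conditionals, config)
    if J_X.shape[0] < 2:
        raise EstimationImpossibleError("no usable target-event samples")

    n_u = config.N_U if config.N_U is not None else J_X.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u_points = place_sample_points(span, n_u, config.placement, rng)
    J_U, C_U, wju, wcu, obs_u = embed_observation_points(
        u_points, target, source, conditionals, config)
    if J_U.shape[0] < 2:
        raise EstimationImpossibleError("no usable target-independent samples")

    mean_rate = (obs_x.size - 1) / (obs_x[-1] - obs_x[0])
    return SampleSets(J_X=J_X, C_X=C_X, J_U=J_U, C_U=C_U,
                      windows_JX=wjx, windows_CX=wcx,
                      windows_JU=wju, windows_CU=wcu,
                      mean_rate=float(mean_rate), config=config,
                      obs_X=obs_x, obs_U=obs_u)
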
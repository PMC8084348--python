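"""Surrogate generation and significance testing for conditional independence.

The null hypothesis of zero (conditional) transfer entropy states that
the density of joint histories at target events factorises as
``p_X(x, y, z) = p_X(x, z) p_U(y | x, z)``.  The local permutation
scheme builds surrogates conforming to exactly this null: each target
event keeps its own target and conditioning history but receives the
source history of a (x, z)-similar sample drawn at a target-independent
time.  A conventional source time-shift surrogate is also provided; it
conforms to the stronger (and, for conditional tests, wrong) null in
which the source history is independent of everything, and is included
as the baseline whose failure modes the local permutation scheme
avoids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ct_estimator import (EstimatorConfig, EstimationImpossibleError,
                           divergence_terms, estimate_te)
from .embeddings import (EmbeddingConfig, SampleSets, build_sample_sets,
                         embed_observation_points, place_sample_points)
from .knn import NeighborSet, norm_to_p
from .series import EventSeries

__all__ = [
    "SurrogateConfig",
    "SurrogateResult",
    "local_permutation_surrogate",
    "time_shift_surrogate",
    "significance_test",
]


@dataclass(frozen=True)
class SurrogateConfig:
    """Settings for surrogate generation and the significance test."""

    scheme: str = "local_permutation"   # or "time_shift"
    k_perm: int = 10
    N_U_surrogate: int | None = None    # default: one pool point per target event
    n_surrogates: int = 100
    shift_range: tuple[float, float] = (200.0, 300.0)
    pool_placement: str = "fixed_interval"
    share_pool: bool = False
    conservative_p: bool = False        # (count+1)/(n+1) instead of count/n
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("local_permutation", "time_shift"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.k_perm < 1:
            raise ValueError("k_perm must be >= 1")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if not self.shift_range[0] < self.shift_range[1]:
            raise ValueError("shift_range must satisfy min < max")


@dataclass
class SurrogateResult:
    """Original estimate, surrogate null distribution and p-value."""

    original_te: float
    surrogate_tes: np.ndarray
    p_value: float
    effective_te: float
    n_failures: int = 0


def _build_pool(target: EventSeries, source: EventSeries,
                conditionals, embed_config: EmbeddingConfig,
                n_pool: int, placement: str,
                rng: np.random.Generator):
    """Joint embeddings at target-independent points for resampling."""
    span = (float(target.times[0]), float(target.times[-1]))
    pts = place_sample_points(span, n_pool, placement, rng)
    J, C, wj, _, _ = embed_observation_points(
        pts, target, source, conditionals, embed_config)
    return J, C, wj


def local_permutation_surrogate(sets: SampleSets, target: EventSeries,
                                source: EventSeries, conditionals,
                                surr_config: SurrogateConfig,
                                rng: np.random.Generator,
                                norm: str = "manhattan",
                                pool: tuple | None = None,
                                pool_query=None,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Resample source histories from (x, z)-similar pool samples.

    Returns the surrogate joint set at target events (same target and
    conditioning components as the original ``J_X``; only the source
    block is replaced) together with per-sample exclusion windows of
    shape ``(n, 2, 2)`` carrying both the original window and the window
    of the pool sample the source history came from.  Used pool indices
    are tracked to reduce duplicate draws.
    """
    cfg = sets.config
    n_x = sets.n_X
    n_pool = surr_config.N_U_surrogate or n_x
    if n_pool < surr_config.k_perm:
        raise ValueError("surrogate pool smaller than k_perm")
    if pool is None:
        pool = _build_pool(target, source, conditionals, cfg, n_pool,
                           surr_config.pool_placement, rng)
    pool_J, pool_C, pool_w = pool
    if pool_J.shape[0] < surr_config.k_perm:
        raise ValueError("surrogate pool smaller than k_perm after boundary drops")

    # (x, z)-nearest pool samples for each original target-event sample,
    # honouring Theiler exclusion between the anchor's and candidates'
    # joint windows.
    if pool_query is None:
        ns = NeighborSet(pool_C, pool_w, p=norm_to_p(norm))
        qr = ns.query(sets.C_X, sets.windows_JX, k=surr_config.k_perm)
    else:
        qr = pool_query

    k_perm = surr_config.k_perm
    used = np.zeros(pool_J.shape[0], dtype=bool)
    picks = np.empty(n_x, dtype=int)
    u_draw = rng.random(n_x)
    n_valid = np.minimum(qr.n_valid, k_perm).astype(int)
    indices = qr.indices
    for i in range(n_x):
        m = n_valid[i]
        if m == 0:
            picks[i] = -1
            continue
        cand = indices[i, :m]
        fresh = cand[~used[cand]]
        pool_choice = fresh if fresh.size else cand
        pick = pool_choice[int(u_draw[i] * pool_choice.size)]
        used[pick] = True
        picks[i] = pick

    l_x, l_y = cfg.l_X, cfg.l_Y
    J_surr = sets.J_X.copy()
    win = np.repeat(sets.windows_JX[:, None, :], 2, axis=1)
    ok = picks >= 0
    if not np.all(ok):
        warnings.warn(f"{int((~ok).sum())} samples had no admissible pool "
                      "candidates; their source histories were kept")
    J_surr[ok, l_x:l_x + l_y] = pool_J[picks[ok], l_x:l_x + l_y]
    win[ok, 1, :] = pool_w[picks[ok]]
    return J_surr, win


def time_shift_surrogate(source: EventSeries,
                         shift_range: tuple[float, float],
                         rng: np.random.Generator) -> EventSeries:
    """Translate the whole source by one uniform draw from ``shift_range``."""
    lo, hi = shift_range
    return source.shifted(float(rng.uniform(lo, hi)))


def _p_value(surrogate_tes: np.ndarray, original: float,
             conservative: bool) -> float:
    count = int(np.sum(surrogate_tes >= original))
    n = surrogate_tes.size
    if conservative:
        return (count + 1) / (n + 1)
    return count / n


def significance_test(target: EventSeries, source: EventSeries,
                      conditionals=(),
                      embed_config: EmbeddingConfig | None = None,
                      est_config: EstimatorConfig | None = None,
                      surr_config: SurrogateConfig | None = None,
                      seed: int | None = None) -> SurrogateResult:
    """Estimate the TE rate and its surrogate-based p-value.

    The p-value is the fraction of surrogate TE estimates at least as
    large as the original; ``effective_te`` is the original estimate
    minus the surrogate mean (a bias-corrected TE).  For the local
    permutation scheme the surrogate estimates reuse the original
    ``J_U`` / ``C_U`` sets and the conditioning-term contributions,
    which are unchanged by construction; neighbour searches anchored at
    surrogate samples honour both of their exclusion windows.
    """
    embed_config = embed_config or EmbeddingConfig()
    est_config = est_config or EstimatorConfig()
    surr_config = surr_config or SurrogateConfig()
    if seed is None:
        seed = surr_config.seed
    ss = np.random.SeedSequence(seed)
    master, *subs = ss.spawn(surr_config.n_surrogates + 1)
    rng = np.random.default_rng(master)

    sets = build_sample_sets(target, source, conditionals, embed_config,
                             seed=rng)
    p = norm_to_p(est_config.norm)
    k = est_config.k_global
    theiler = est_config.theiler
    wjx = sets.windows_JX if theiler else None
    wju = sets.windows_JU if theiler else None
    wcx = sets.windows_CX if theiler else None
    wcu = sets.windows_CU if theiler else None
    self_idx = None if theiler else np.arange(sets.n_X)

    oth_J = NeighborSet(sets.J_U, wju, p)
    own_C = NeighborSet(sets.C_X, wcx, p)
    oth_C = NeighborSet(sets.C_U, wcu, p)
    c_terms, c_valid = divergence_terms(
        sets.C_X, wcx, own_C, oth_C, k, sets.config.l_C,
        est_config.variant, est_config.eps_scale, self_idx)

    def joint_part(J, wj):
        own = NeighborSet(J, wj if theiler else None, p)
        return divergence_terms(J, wj if theiler else None, own, oth_J, k,
                                sets.config.l_J, est_config.variant,
                                est_config.eps_scale, self_idx)

    def combine(j_terms, j_valid):
        valid = j_valid & c_valid
        if not np.any(valid):
            raise EstimationImpossibleError("every sample was skipped")
        return sets.mean_rate * float(np.mean((j_terms - c_terms)[valid]))

    original_te = combine(*joint_part(sets.J_X, sets.windows_JX))

    shared_pool = None
    shared_pool_query = None
    if surr_config.scheme == "local_permutation" and (
            surr_config.share_pool
            or surr_config.pool_placement == "fixed_interval"):
        # a fixed-interval pool is identical across surrogates, so build
        # (and search) once
        shared_pool = _build_pool(
            target, source, conditionals, embed_config,
            surr_config.N_U_surrogate or sets.n_X,
            surr_config.pool_placement, rng)
        ns_pool = NeighborSet(shared_pool[1], shared_pool[2], p)
        shared_pool_query = ns_pool.query(sets.C_X, sets.windows_JX,
                                          k=surr_config.k_perm)

    surrogate_tes = []
    n_failures = 0
    for s_ss in subs:
        retry_streams = s_ss.spawn(2)
        te_s = None
        for attempt_ss in retry_streams:
            s_rng = np.random.default_rng(attempt_ss)
            try:
                if surr_config.scheme == "local_permutation":
                    J_s, w_s = local_permutation_surrogate(
                        sets, target, source, conditionals, surr_config,
                        s_rng, norm=est_config.norm, pool=shared_pool,
                        pool_query=shared_pool_query)
                    te_s = combine(*joint_part(J_s, w_s))
                else:
                    shifted = time_shift_surrogate(
                        source, surr_config.shift_range, s_rng)
                    sets_s = build_sample_sets(target, shifted, conditionals,
                                               embed_config, seed=s_rng)
                    te_s = estimate_te(sets_s, est_config).te_rate
                break
            except (EstimationImpossibleError, ValueError):
                continue
        if te_s is None:
            n_failures += 1
        else:
            surrogate_tes.append(te_s)

    if n_failures:
        warnings.warn(f"{n_failures} surrogate estimates failed")
    if not surrogate_tes:
        raise EstimationImpossibleError("all surrogate estimates failed")
    surrogate_tes = np.asarray(surrogate_tes)
    return SurrogateResult(
        original_te=original_te,
        surrogate_tes=surrogate_tes,
        p_value=_p_value(surrogate_tes, original_te,
                         surr_config.conservative_p),
        effective_te=original_te - float(np.mean(surrogate_tes)),
        n_failures=n_failures)
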
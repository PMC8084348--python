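"""Continuous-time transfer-entropy rate estimation via kNN statistics.

The TE rate between point processes is expressed, after a Bayesian
inversion, as a difference of two Kullback-Leibler divergences between
the distributions of history embeddings observed at target events and
those observed at arbitrary times.  Each divergence is estimated with
Kozachenko-Leonenko-style k-nearest-neighbour entropy / cross-entropy
terms.  Two combinations are provided:

* the 4KL estimator — four independent searches with a fixed ``k``;
* the CT estimator — a bias-improved variant that shares a search
  radius within each divergence and uses per-sample neighbour counts
  with digamma corrections.

All searches honour the Theiler exclusion windows by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln

from .embeddings import EmbeddingConfig, SampleSets
from .knn import NeighborSet, norm_to_p

__all__ = [
    "EstimatorConfig",
    "TEEstimate",
    "kl_entropy",
    "kl_cross_entropy",
    "estimate_te",
    "estimate_te_4kl",
    "estimate_te_ct",
    "radius_count",
    "DegenerateDataError",
    "EstimationImpossibleError",
]

_TINY = np.finfo(float).tiny


class DegenerateDataError(ValueError):
    """All sample points coincide; differential entropy is undefined."""


class EstimationImpossibleError(RuntimeError):
    """Every sample was skipped; no estimate can be formed."""


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings shared by the 4KL and CT estimators.

    ``k_global`` is the minimum neighbour count of every search;
    ``eps_scale`` multiplies every neighbour distance before taking
    logarithms (the factor provably cancels between paired terms, so the
    estimate is insensitive to the distance-vs-diameter convention).
    """

    k_global: int = 4
    norm: str = "manhattan"
    variant: str = "ct"          # "ct" or "4kl"
    theiler: bool = True
    eps_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.k_global < 1:
            raise ValueError("k_global must be >= 1")
        if self.variant not in ("ct", "4kl"):
            raise ValueError(f"unknown variant {self.variant!r}")
        norm_to_p(self.norm)
        if self.eps_scale <= 0:
            raise ValueError("eps_scale must be positive")


@dataclass
class TEEstimate:
    """A TE rate estimate with its per-event local contributions.

    ``te_rate`` (nats per time unit) always equals
    ``mean_rate * mean(local_terms)``.
    """

    te_rate: float
    local_terms: np.ndarray
    mean_rate: float
    n_samples: int
    config: EstimatorConfig
    embedding: EmbeddingConfig | None = None


def log_unit_ball_volume(d: int, p: float) -> float:
    """ln volume of the d-dimensional unit ball under an l_p norm."""
    if p == 1.0:
        return d * np.log(2.0) - gammaln(d + 1)
    if p == 2.0:
        return (d / 2.0) * np.log(np.pi) - gammaln(d / 2.0 + 1.0)
    if np.isinf(p):
        return d * np.log(2.0)
    raise ValueError(f"unsupported norm order {p}")


def _safe_log(eps: np.ndarray, what: str) -> np.ndarray:
    eps = np.asarray(eps, dtype=float)
    zero = eps <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} coincident samples in {what}; "
            "distances clamped to the smallest representable value")
        eps = np.where(zero, _TINY, eps)
    return np.log(eps)


# ---------------------------------------------------------------------------
# plain Kozachenko-Leonenko estimators

def kl_entropy(samples: np.ndarray, k: int, norm: str = "manhattan",
               windows: np.ndarray | None = None) -> float:
    """Kozachenko-Leonenko differential entropy estimate, in nats.

    Searches for the k-th neighbour of each point within the same set
    (self excluded; samples with overlapping exclusion ``windows``
    excluded when given).
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n, d = samples.shape
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    p = norm_to_p(norm)
    ns = NeighborSet(samples, windows, p)
    qr = ns.query(samples, windows, k=k,
                  self_indices=None if windows is not None else np.arange(n))
    eps = qr.kth(k)
    if np.all(eps <= 0):
        raise DegenerateDataError("all sample points coincide")
    log_eps = _safe_log(eps, "kl_entropy")
    return float(-digamma(k) + np.log(n - 1) + log_unit_ball_volume(d, p)
                 + d * np.mean(log_eps))


def kl_cross_entropy(eval_points: np.ndarray, reference_set: np.ndarray,
                     k: int, norm: str = "manhattan",
                     eval_windows: np.ndarray | None = None,
                     reference_windows: np.ndarray | None = None) -> float:
    """kNN cross-entropy estimate: evaluation points search the *other* set."""
    eval_points = np.atleast_2d(np.asarray(eval_points, dtype=float))
    reference_set = np.atleast_2d(np.asarray(reference_set, dtype=float))
    n_ref, d = reference_set.shape
    if k >= n_ref:
        raise ValueError("k must be smaller than the reference set")
    p = norm_to_p(norm)
    ns = NeighborSet(reference_set, reference_windows, p)
    qr = ns.query(eval_points, eval_windows, k=k)
    log_eps = _safe_log(qr.kth(k), "kl_cross_entropy")
    return float(-digamma(k) + np.log(n_ref) + log_unit_ball_volume(d, p)
                 + d * np.mean(log_eps))


def radius_count(anchor: np.ndarray, points: np.ndarray, radius: float,
                 norm: str = "manhattan",
                 point_windows: np.ndarray | None = None,
                 anchor_window: np.ndarray | None = None,
                 exclude_index: int | None = None
                 ) -> tuple[int, float]:
    """Count admissible points within ``radius`` of ``anchor`` (closed ball).

    Returns the count and the distance to the count-th admissible
    neighbour (0.0 when the ball is empty).  Brute force by design: this
    is the reference counting rule the tree-backed searches must match.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    p = norm_to_p(norm)
    ns = NeighborSet(points, point_windows, p)
    full = ns._row_exhaustive(
        np.asarray(anchor, dtype=float),
        np.atleast_2d(anchor_window) if anchor_window is not None else None,
        exclude_index)
    within = full[full <= radius]
    return int(within.size), float(within[-1]) if within.size else 0.0


# ---------------------------------------------------------------------------
# divergence building blocks

def divergence_terms(anchors: np.ndarray, anchor_windows: np.ndarray | None,
                     own: NeighborSet, other: NeighborSet, k: int, dim: int,
                     variant: str, eps_scale: float = 1.0,
                     self_indices: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor KL-divergence contributions between two sample sets.

    For each anchor the own-set search is an entropy term and the
    other-set search a cross-entropy term; their difference estimates a
    local log density ratio.  The CT variant shares the larger of the
    two k-th-neighbour radii between the paired searches and applies the
    per-sample digamma correction; the 4KL variant uses a fixed ``k``.
    Returns ``(terms, valid)`` where invalid anchors (fewer than ``k``
    admissible neighbours in either set) should be skipped.
    """
    q_own = own.query(anchors, anchor_windows, k=k, self_indices=self_indices)
    q_oth = other.query(anchors, anchor_windows, k=k)
    valid = (q_own.n_valid >= k) & (q_oth.n_valid >= k)

    if variant == "4kl":
        log_own = _safe_log(eps_scale * q_own.kth(k), "4kl own-set search")
        log_oth = _safe_log(eps_scale * q_oth.kth(k), "4kl cross search")
        terms = dim * (log_oth - log_own)
        return np.where(valid, terms, 0.0), valid

    d_own = q_own.kth(k)
    d_oth = q_oth.kth(k)
    r = np.where(valid, np.maximum(d_own, d_oth), 0.0)
    c_own, e_own = own.count_within(anchors, r, q_own, anchor_windows,
                                    self_indices)
    c_oth, e_oth = other.count_within(anchors, r, q_oth, anchor_windows)
    c_own = np.maximum(c_own, 1)
    c_oth = np.maximum(c_oth, 1)
    log_own = _safe_log(eps_scale * e_own, "ct own-set search")
    log_oth = _safe_log(eps_scale * e_oth, "ct cross search")
    terms = (digamma(c_own) - digamma(c_oth)
             + dim * (log_oth - log_own))
    return np.where(valid, terms, 0.0), valid


def _estimate(sets: SampleSets, config: EstimatorConfig) -> TEEstimate:
    p = norm_to_p(config.norm)
    k = config.k_global
    if min(sets.n_X, sets.n_U) <= k:
        raise ValueError("all four sample sets must exceed k_global")
    theiler = config.theiler

    own_J = NeighborSet(sets.J_X, sets.windows_JX if theiler else None, p)
    oth_J = NeighborSet(sets.J_U, sets.windows_JU if theiler else None, p)
    own_C = NeighborSet(sets.C_X, sets.windows_CX if theiler else None, p)
    oth_C = NeighborSet(sets.C_U, sets.windows_CU if theiler else None, p)
    self_idx = None if theiler else np.arange(sets.n_X)

    j_terms, j_valid = divergence_terms(
        sets.J_X, sets.windows_JX if theiler else None, own_J, oth_J,
        k, sets.config.l_J, config.variant, config.eps_scale, self_idx)
    c_terms, c_valid = divergence_terms(
        sets.C_X, sets.windows_CX if theiler else None, own_C, oth_C,
        k, sets.config.l_C, config.variant, config.eps_scale, self_idx)

    valid = j_valid & c_valid
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise EstimationImpossibleError("every sample was skipped")
    if n_valid < valid.size:
        warnings.warn(f"skipped {valid.size - n_valid} samples with too few "
                      "admissible neighbours after exclusion")
    local = (j_terms - c_terms)[valid]
    te_rate = sets.mean_rate * float(np.mean(local))
    return TEEstimate(te_rate=te_rate, local_terms=local,
                      mean_rate=sets.mean_rate, n_samples=n_valid,
                      config=config, embedding=sets.config)


def estimate_te(sets: SampleSets, config: EstimatorConfig | None = None
                ) -> TEEstimate:
    """Estimate the (conditional) TE rate from prepared sample sets."""
    return _estimate(sets, config or EstimatorConfig())


def estimate_te_4kl(sets: SampleSets, config: EstimatorConfig | None = None
                    ) -> TEEstimate:
    """Fixed-k estimator: four independent Kozachenko-Leonenko searches."""
    config = config or EstimatorConfig(variant="4kl")
    if config.variant != "4kl":
        config = EstimatorConfig(k_global=config.k_global, norm=config.norm,
                                 variant="4kl", theiler=config.theiler,
                                 eps_scale=config.eps_scale)
    return _estimate(sets, config)


def estimate_te_ct(sets: SampleSets, config: EstimatorConfig | None = None
                   ) -> TEEstimate:
    """Bias-improved estimator sharing search radii within each divergence."""
    config = config or EstimatorConfig(variant="ct")
    if config.variant != "ct":
        config = EstimatorConfig(k_global=config.k_global, norm=config.norm,
                                 variant="ct", theiler=config.theiler,
                                 eps_scale=config.eps_scale)
    return _estimate(sets, config)
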
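"""All-pairs reference implementations used as independent test oracles.

Everything here is deliberately written with plain loops and explicit
interval logic — no KD-trees, no shared code with the package's search
machinery — so that agreement with the package is a meaningful check.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma


def _dist(a: np.ndarray, b: np.ndarray, norm: str) -> float:
    d = np.abs(np.asarray(a, float) - np.asarray(b, float))
    if norm == "manhattan":
        return float(d.sum())
    if norm == "euclidean":
        return float(np.sqrt((d * d).sum()))
    return float(d.max())


def _overlaps(w1, w2) -> bool:
    for (s1, e1) in np.atleast_2d(w1):
        for (s2, e2) in np.atleast_2d(w2):
            if s1 <= e2 and s2 <= e1:
                return True
    return False


def _admissible_dists(anchor, anchor_win, points, point_wins, theiler,
                      self_index, norm):
    out = []
    for j in range(points.shape[0]):
        if self_index is not None and j == self_index:
            continue
        if theiler and _overlaps(anchor_win, point_wins[j]):
            continue
        out.append(_dist(anchor, points[j], norm))
    return sorted(out)


def brute_te(sets, k: int, variant: str = "ct", theiler: bool = True,
             norm: str = "manhattan", eps_scale: float = 1.0) -> float:
    """TE rate by exhaustive search; mirrors the estimator's definitions.

    Non-strict (<=) in-radius counting, self excluded in own-set
    searches, Theiler exclusion optional.  Used on tiny sample sets only.
    """
    tiny = np.finfo(float).tiny
    l_J = sets.J_X.shape[1]
    l_C = sets.C_X.shape[1]
    n_x = sets.n_X
    local = []
    for i in range(n_x):
        parts = []
        for anchors, a_wins, own_pts, own_wins, oth_pts, oth_wins, dim in (
            (sets.J_X, sets.windows_JX, sets.J_X, sets.windows_JX,
             sets.J_U, sets.windows_JU, l_J),
            (sets.C_X, sets.windows_CX, sets.C_X, sets.windows_CX,
             sets.C_U, sets.windows_CU, l_C),
        ):
            d_own = _admissible_dists(anchors[i], a_wins[i], own_pts,
                                      own_wins, theiler, i, norm)
            d_oth = _admissible_dists(anchors[i], a_wins[i], oth_pts,
                                      oth_wins, theiler, None, norm)
            if len(d_own) < k or len(d_oth) < k:
                parts = None
                break
            if variant == "4kl":
                e_own = max(eps_scale * d_own[k - 1], tiny)
                e_oth = max(eps_scale * d_oth[k - 1], tiny)
                parts.append(dim * (np.log(e_oth) - np.log(e_own)))
            else:
                r = max(d_own[k - 1], d_oth[k - 1])
                w_own = [d for d in d_own if d <= r]
                w_oth = [d for d in d_oth if d <= r]
                c_own, c_oth = max(len(w_own), 1), max(len(w_oth), 1)
                e_own = max(eps_scale * (w_own[-1] if w_own else 0.0), tiny)
                e_oth = max(eps_scale * (w_oth[-1] if w_oth else 0.0), tiny)
                parts.append(digamma(c_own) - digamma(c_oth)
                             + dim * (np.log(e_oth) - np.log(e_own)))
        if parts is None:
            continue
        local.append(parts[0] - parts[1])
    return sets.mean_rate * float(np.mean(local))


def brute_radius_count(anchor, points, radius, norm="manhattan",
                       point_wins=None, anchor_win=None, self_index=None):
    """In-radius count and count-th distance by direct scan."""
    dists = []
    for j in range(points.shape[0]):
        if self_index is not None and j == self_index:
            continue
        if (anchor_win is not None and point_wins is not None
                and _overlaps(anchor_win, point_wins[j])):
            continue
        d = _dist(anchor, points[j], norm)
        if d <= radius:
            dists.append(d)
    return len(dists), (max(dists) if dists else 0.0)


def coupled_pair_true_te(params, n_events: int = 20000, seed: int = 11,
                         ds: float = 0.005) -> float:
    """Ground-truth TE rate of the coupled pair by exact state filtering.

    The target's conditional rate given only its own history requires
    marginalising over the hidden time-since-last-source-event state s.
    Between target events the filtering density over s evolves linearly
    (transport at unit speed, resets to zero at the source rate,
    killing at the target rate); the update is computed in closed form
    via the eigendecomposition of the discretised generator.  At each
    target event the density is reweighted by the rate profile.  The TE
    rate is then the time-average of ln lambda(s_true) - ln E[lambda(s)]
    over target events — no nearest-neighbour machinery involved.
    """
    from cttespike import coupled_rate, simulate_coupled_pair

    lam_y = params.lambda_y_bar
    M = int(round(params.t_cut / ds))
    s_mid = (np.arange(M) + 0.5) * ds
    lam_full = np.concatenate([coupled_rate(s_mid, params),
                               [params.lambda_x_base]])
    A = np.zeros((M + 1, M + 1))
    for j in range(M):
        A[j + 1, j] += 1.0 / ds
        A[j, j] -= 1.0 / ds
    A[0, :] += lam_y
    np.fill_diagonal(A, A.diagonal() - lam_y - lam_full)
    w, V = np.linalg.eig(A)
    Vinv = np.linalg.inv(V)

    y, x = simulate_coupled_pair(params, n_events, seed)
    ys, xs = y.times, x.times
    idx = np.searchsorted(ys, xs, "left") - 1
    ok = idx >= 0
    xs = xs[ok]
    lam_true = coupled_rate(xs - ys[idx[ok]], params)

    q = np.concatenate([np.exp(-lam_y * s_mid) * lam_y * ds,
                        [np.exp(-lam_y * params.t_cut)]])
    q /= q.sum()
    q = q * lam_full
    q /= q.sum()
    prev = xs[0]
    logs = []
    for i in range(1, xs.size):
        q = (V @ (np.exp(w * (xs[i] - prev)) * (Vinv @ q))).real
        q = np.maximum(q, 0)
        q /= q.sum()
        lam_c = float(q @ lam_full)
        logs.append(np.log(lam_true[i]) - np.log(lam_c))
        q = q * lam_full
        q /= q.sum()
        prev = xs[i]
    burn = 500
    return float(np.sum(logs[burn:]) / (xs[-1] - xs[burn]))
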
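"""k-nearest-neighbour searches with dynamic-correlation (Theiler) exclusion.

KD-tree queries (scipy ``cKDTree``) are post-filtered against exclusion
windows: a candidate is ignored when any of its windows intersects any
window of the anchor.  Queries over-fetch a padded number of neighbours
and fall back to exhaustive per-row searches in the rare cases where the
padding is insufficient, so results are exact (identical to an
all-pairs scan) regardless of how many neighbours the exclusion removes.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["NeighborSet", "QueryResult", "norm_to_p"]

_NORM_P = {"manhattan": 1.0, "euclidean": 2.0, "chebyshev": np.inf,
           "l1": 1.0, "l2": 2.0, "linf": np.inf}


def norm_to_p(norm: str) -> float:
    try:
        return _NORM_P[norm]
    except KeyError:
        raise ValueError(f"unknown norm {norm!r}") from None


def _as_windows(w: np.ndarray | None) -> np.ndarray | None:
    """Normalise windows to shape (n, m, 2)."""
    if w is None:
        return None
    w = np.asarray(w, dtype=float)
    if w.ndim == 2:
        w = w[:, None, :]
    if w.ndim != 3 or w.shape[-1] != 2:
        raise ValueError("windows must have shape (n, 2) or (n, m, 2)")
    return w


def _overlap_matrix(aw: np.ndarray, bw: np.ndarray) -> np.ndarray:
    """Closed-interval overlap, anchors (n, ma, 2) vs candidates (n, k, mb, 2)."""
    n, ma, _ = aw.shape
    out = np.zeros(bw.shape[:2], dtype=bool)
    for a in range(ma):
        s1 = aw[:, a, 0][:, None]
        e1 = aw[:, a, 1][:, None]
        for b in range(bw.shape[2]):
            s2 = bw[:, :, b, 0]
            e2 = bw[:, :, b, 1]
            out |= (s1 <= e2) & (s2 <= e1)
    return out


class QueryResult:
    """Sorted admissible neighbour distances per anchor, inf-padded."""

    def __init__(self, dists: np.ndarray, n_valid: np.ndarray,
                 coverage: np.ndarray, indices: np.ndarray | None = None):
        self.dists = dists        # (n, K) ascending, inf beyond n_valid
        self.n_valid = n_valid    # (n,)
        self.coverage = coverage  # (n,) radius guaranteed fully scanned
        self.indices = indices    # (n, K) aligned with dists, -1 padding

    def kth(self, k: int) -> np.ndarray:
        """Distance to the k-th admissible neighbour (inf if fewer exist)."""
        if k > self.dists.shape[1]:
            return np.full(self.dists.shape[0], np.inf)
        return self.dists[:, k - 1]


class NeighborSet:
    """A point set with optional exclusion windows, queryable exactly.

    Distance ties are counted with non-strict comparison (<=); the
    sorted-distance representation makes tie-breaking immaterial for
    every quantity derived here (k-th distances and in-radius counts).
    """

    def __init__(self, points: np.ndarray, windows: np.ndarray | None = None,
                 p: float = 1.0):
        self.points = np.ascontiguousarray(points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be 2-d (n, d)")
        self.windows = _as_windows(windows)
        if self.windows is not None and self.windows.shape[0] != self.points.shape[0]:
            raise ValueError("windows must align with points")
        self.p = p
        self.n = self.points.shape[0]
        self.tree = cKDTree(self.points)

    # -- helpers -----------------------------------------------------------

    def _dist(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Distances along the last axis, one formula everywhere."""
        diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        if np.isinf(self.p):
            return np.max(np.abs(diff), axis=-1)
        if self.p == 1.0:
            return np.sum(np.abs(diff), axis=-1)
        return np.sqrt(np.sum(diff * diff, axis=-1))

    def _mask_valid(self, idx: np.ndarray, dist: np.ndarray,
                    anchor_windows: np.ndarray | None,
                    self_indices: np.ndarray | None) -> np.ndarray:
        valid = np.isfinite(dist)
        safe = np.minimum(idx, self.n - 1)
        if self_indices is not None:
            valid &= safe != self_indices[:, None]
        if anchor_windows is not None and self.windows is not None:
            cand_w = self.windows[safe]          # (n, k, mb, 2)
            valid &= ~_overlap_matrix(anchor_windows, cand_w)
        return valid

    def _row_exhaustive(self, anchor: np.ndarray,
                        anchor_window: np.ndarray | None,
                        self_index: int | None) -> np.ndarray:
        """All admissible distances from one anchor, sorted ascending."""
        return self._row_exhaustive_with_indices(anchor, anchor_window,
                                                 self_index)[0]

    def _row_exhaustive_with_indices(self, anchor: np.ndarray,
                                     anchor_window: np.ndarray | None,
                                     self_index: int | None,
                                     limit: int | None = None
                                     ) -> tuple[np.ndarray, np.ndarray]:
        d = self._dist(self.points, anchor[None, :])
        keep = np.ones(self.n, dtype=bool)
        if self_index is not None:
            keep[self_index] = False
        if anchor_window is not None and self.windows is not None:
            aw = anchor_window[None, :, :] if anchor_window.ndim == 2 else anchor_window
            cw = self.windows[:, None, :, :]
            ov = np.zeros(self.n, dtype=bool)
            for a in range(aw.shape[1]):
                for b in range(cw.shape[2]):
                    ov |= (aw[0, a, 0] <= cw[:, 0, b, 1]) & (cw[:, 0, b, 0] <= aw[0, a, 1])
            keep &= ~ov
        kept_idx = np.nonzero(keep)[0]
        dk = d[kept_idx]
        if limit is not None and dk.size > limit:
            part = np.argpartition(dk, limit - 1)[:limit]
            order = part[np.argsort(dk[part], kind="stable")]
        else:
            order = np.argsort(dk, kind="stable")
        return dk[order], kept_idx[order]

    # -- queries -----------------------------------------------------------

    def query(self, anchors: np.ndarray, anchor_windows: np.ndarray | None = None,
              k: int = 1, self_indices: np.ndarray | None = None,
              pad: int = 24) -> QueryResult:
        """Sorted admissible neighbour distances, at least ``k`` per anchor
        whenever the set contains that many admissible points."""
        anchors = np.asarray(anchors, dtype=float)
        aw = _as_windows(anchor_windows)
        n_anchor = anchors.shape[0]
        k0 = min(self.n, k + pad)
        dist, idx = self.tree.query(anchors, k=k0, p=self.p)
        if k0 == 1:
            dist, idx = dist[:, None], idx[:, None]
        # recompute distances with a single consistent formula so that
        # radius-membership decisions are bit-identical everywhere
        missing = ~np.isfinite(dist)
        dist = self._dist(anchors[:, None, :],
                          self.points[np.minimum(idx, self.n - 1)])
        dist[missing] = np.inf
        valid = self._mask_valid(idx, dist, aw, self_indices)
        vd = np.where(valid, dist, np.inf)
        vidx = np.where(valid, np.minimum(idx, self.n - 1), -1)
        order = np.argsort(vd, axis=1, kind="stable")
        vd = np.take_along_axis(vd, order, axis=1)
        vidx = np.take_along_axis(vidx, order, axis=1)
        n_valid = valid.sum(axis=1)
        coverage = dist[:, -1].copy()
        coverage[~np.isfinite(coverage)] = np.inf
        if k0 == self.n:
            coverage[:] = np.inf

        deficient = (n_valid < k) & (k0 < self.n)
        if np.any(deficient):
            rows = np.nonzero(deficient)[0]
            width = vd.shape[1]
            for r in rows:
                full, fidx = self._row_exhaustive_with_indices(
                    anchors[r],
                    aw[r] if aw is not None else None,
                    int(self_indices[r]) if self_indices is not None else None,
                    limit=width)
                row = np.full(width, np.inf)
                rowi = np.full(width, -1)
                take = min(width, full.size)
                row[:take] = full[:take]
                rowi[:take] = fidx[:take]
                vd[r] = row
                vidx[r] = rowi
                n_valid[r] = full.size
                coverage[r] = full[-1] if full.size == width else np.inf
        return QueryResult(vd, n_valid, coverage, vidx)

    def count_within(self, anchors: np.ndarray, radii: np.ndarray,
                     qr: QueryResult | None = None,
                     anchor_windows: np.ndarray | None = None,
                     self_indices: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Count admissible points with distance <= radius, per anchor.

        Also returns the distance to the count-th admissible neighbour —
        the largest admissible distance within the radius (0.0 for an
        empty ball).  Closed-ball membership; exact regardless of how
        many points the exclusion windows remove.
        """
        anchors = np.asarray(anchors, dtype=float)
        aw = _as_windows(anchor_windows)
        n_anchor = anchors.shape[0]
        # slightly inflated tree ball (superset), then exact membership by
        # the shared distance formula in one flat vectorised pass
        lists = self.tree.query_ball_point(
            anchors, radii * (1 + 1e-9), p=self.p, return_sorted=False)
        lens = np.fromiter((len(l) for l in lists), dtype=np.int64,
                           count=n_anchor)
        counts = np.zeros(n_anchor, dtype=np.int64)
        eps = np.zeros(n_anchor)
        total = int(lens.sum())
        if total == 0:
            return counts, eps
        from itertools import chain
        flat = np.fromiter(chain.from_iterable(lists), dtype=np.int64,
                           count=total)
        aid = np.repeat(np.arange(n_anchor), lens)
        d = self._dist(self.points[flat], anchors[aid])
        keep = d <= radii[aid]
        if self_indices is not None:
            keep &= flat != self_indices[aid]
        if aw is not None and self.windows is not None:
            cw = self.windows[flat]
            ov = np.zeros(total, dtype=bool)
            for a in range(aw.shape[1]):
                s1 = aw[aid, a, 0]
                e1 = aw[aid, a, 1]
                for b in range(cw.shape[1]):
                    ov |= (s1 <= cw[:, b, 1]) & (cw[:, b, 0] <= e1)
            keep &= ~ov
        # groups are contiguous in aid, so per-anchor maxima come from reduceat
        kept_d = d[keep]
        counts = np.bincount(aid[keep], minlength=n_anchor)
        if kept_d.size:
            starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
            nonempty = counts > 0
            # reduceat over the starts of non-empty groups only: each
            # reduces up to the next non-empty start (empty groups occupy
            # no positions), the last one to the end of the array
            eps[nonempty] = np.maximum.reduceat(kept_d, starts[nonempty])
        return counts, eps
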
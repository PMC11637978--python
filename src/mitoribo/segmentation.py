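"""Rigid-segment partitioning of a per-residue mobility profile.

A predicted structure's per-residue confidence (pLDDT) is inversely related
to local mobility, so a chain can be divided into N rigid-like segments by
minimizing, over all partitions into N contiguous runs, the total sum of
squared residuals (SSR) of a low-order polynomial fitted per run to the
mobility proxy ``m_i = 100 - pLDDT_i``.  The optimal partition is found by
exact dynamic programming over precomputed interval costs, with ties broken
toward the earliest boundary.  A rigid body moving as one unit produces a
smoothly varying equivalent mobility along the chain, which the default
quadratic captures; the residual-versus-N curve is non-increasing and its
largest relative drop marks the natural segment count.

Interval costs are evaluated from prefix sums of polynomial moments with the
residue coordinate affinely scaled to [-1, 1] for numerical conditioning
(the SSR of a polynomial fit is invariant under affine reparametrization of
the abscissa).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import PLDDTProfile

__all__ = [
    "SegmentationResult",
    "trim_range",
    "mobility_proxy",
    "fit_segment",
    "optimal_partition",
    "residual_curve",
]


@dataclass(frozen=True)
class SegmentationResult:
    """An optimal N-segment partition of a mobility profile."""

    n_segments: int
    boundaries: tuple[int, ...]  # last residue index of every segment
    first_residue: int
    coefficients: tuple[tuple[float, ...], ...]  # per segment, constant first
    segment_ssr: tuple[float, ...]
    total_ssr: float
    per_residue_fitted: np.ndarray

    @property
    def segments(self) -> list[tuple[int, int]]:
        """(first_res, last_res) per segment in residue numbering."""
        out = []
        first = self.first_residue
        for last in self.boundaries:
            out.append((first, last))
            first = last + 1
        return out


def trim_range(profile: PLDDTProfile, drop: tuple[int, int] | None) -> PLDDTProfile:
    """Drop a leading or trailing residue range (e.g. a targeting sequence).

    ``drop`` is an inclusive (first, last) residue-index range that must sit
    at an edge of the profile; interior drops would break contiguity and are
    rejected.  ``None`` (or an empty range) is the identity.  Original
    residue numbering is retained.
    """
    if drop is None:
        return profile
    lo, hi = drop
    if hi < lo:
        return profile
    first, last = int(profile.residue_index[0]), int(profile.residue_index[-1])
    if lo <= first and hi >= last:
        raise ValueError("drop range covers the whole profile")
    if lo <= first:
        keep = profile.residue_index > hi
    elif hi >= last:
        keep = profile.residue_index < lo
    else:
        raise ValueError(f"drop range {drop} is interior; only edge trims preserve contiguity")
    return PLDDTProfile(profile.residue_index[keep], profile.plddt[keep])


def mobility_proxy(profile: PLDDTProfile, transform=None) -> np.ndarray:
    """Per-residue mobility vector; default inverse transform 100 - pLDDT.

    Any other monotone-decreasing transform of pLDDT may be supplied.
    """
    if transform is None:
        return 100.0 - profile.plddt
    return np.asarray(transform(profile.plddt), dtype=float)


def fit_segment(values: np.ndarray, order: int = 2) -> tuple[tuple[float, ...], float]:
    """OLS polynomial fit on the within-segment offset 0..n-1.

    Returns (coefficients, ssr) with coefficients constant-first.  The
    order-0 fit is the segment mean.  Requires more points than the order.
    """
    y = np.asarray(values, dtype=float)
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    if y.size <= order:
        raise ValueError(f"segment of length {y.size} cannot support order {order}")
    x = np.arange(y.size, dtype=float)
    coefs = np.polynomial.polynomial.polyfit(x, y, order)
    fitted = np.polynomial.polynomial.polyval(x, coefs)
    ssr = float(np.sum((y - fitted) ** 2))
    return tuple(float(c) for c in coefs), ssr


class _IntervalCosts:
    """SSR of an order-p polynomial fit on every contiguous interval.

    Prefix sums of x^k and x^k y (x scaled to [-1, 1] over the full profile)
    give each interval's normal equations in O(1); the SSR follows as
    ``Syy - b^T M^{-1} b``.
    """

    def __init__(self, y: np.ndarray, order: int):
        self.n = y.size
        self.order = order
        x = np.linspace(-1.0, 1.0, self.n) if self.n > 1 else np.zeros(1)
        p = order
        self._Sx = [np.concatenate([[0.0], np.cumsum(x**k)]) for k in range(2 * p + 1)]
        self._Sxy = [np.concatenate([[0.0], np.cumsum((x**k) * y)]) for k in range(p + 1)]
        self._Syy = np.concatenate([[0.0], np.cumsum(y * y)])

    def cost_row(self, s: int, ends: np.ndarray) -> np.ndarray:
        """SSR for intervals [s, e] (inclusive, 0-based) for all e in ends."""
        p = self.order
        m = len(ends)
        M = np.empty((m, p + 1, p + 1))
        b = np.empty((m, p + 1))
        for j in range(p + 1):
            b[:, j] = self._Sxy[j][ends + 1] - self._Sxy[j][s]
            for k in range(p + 1):
                M[:, j, k] = self._Sx[j + k][ends + 1] - self._Sx[j + k][s]
        Syy = self._Syy[ends + 1] - self._Syy[s]
        c = np.linalg.solve(M, b[..., None])[..., 0]
        ssr = Syy - np.einsum("ij,ij->i", b, c)
        return np.maximum(ssr, 0.0)


def _dp_tables(
    y: np.ndarray, max_segments: int, order: int, min_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """DP over prefix lengths: dp[k, e] = best SSR of [0..e] in k+1 segments."""
    n = y.size
    costs = _IntervalCosts(y, order)
    # cost[s, e] for all valid intervals; inf where too short.
    cost = np.full((n, n), np.inf)
    ends_all = np.arange(n)
    for s in range(n):
        ends = ends_all[s + min_len - 1 :]
        if ends.size:
            cost[s, ends] = costs.cost_row(s, ends)

    K = max_segments
    dp = np.full((K, n), np.inf)
    back = np.full((K, n), -1, dtype=int)
    dp[0] = cost[0]
    for k in range(1, K):
        for e in range(n):
            # previous segment ends at b; new segment [b+1, e]
            bs = np.arange(k * min_len - 1, e - min_len + 1)
            if bs.size == 0:
                continue
            cand = dp[k - 1, bs] + cost[bs + 1, e]
            i = int(np.argmin(cand))  # argmin keeps the earliest boundary on ties
            if np.isfinite(cand[i]):
                dp[k, e] = cand[i]
                back[k, e] = bs[i]
    return dp, back


def optimal_partition(
    mobility: np.ndarray | Sequence[float],
    n_segments: int,
    order: int = 2,
    min_len: int = 5,
    residue_index: np.ndarray | None = None,
) -> SegmentationResult:
    """Exact minimum-SSR partition into ``n_segments`` contiguous runs.

    ``residue_index`` carries the original residue numbering for reported
    boundaries (defaults to 1..L).  ``min_len`` is raised to ``order + 1``
    when needed so every segment can support its fit.
    """
    y = np.asarray(mobility, dtype=float)
    n = y.size
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    min_len = max(min_len, order + 1)
    if n < n_segments * min_len:
        raise ValueError(
            f"profile of length {n} cannot be split into {n_segments} "
            f"segments of >= {min_len} residues"
        )
    if residue_index is None:
        residue_index = np.arange(1, n + 1)
    residue_index = np.asarray(residue_index)

    dp, back = _dp_tables(y, n_segments, order, min_len)
    total = float(dp[n_segments - 1, n - 1])
    cuts: list[int] = []  # 0-based last index of each segment
    e = n - 1
    for k in range(n_segments - 1, 0, -1):
        b = int(back[k, e])
        cuts.append(e)
        e = b
    cuts.append(e)
    cuts.reverse()

    boundaries = tuple(int(residue_index[c]) for c in cuts)
    coefficients: list[tuple[float, ...]] = []
    segment_ssr: list[float] = []
    fitted = np.empty(n)
    first = 0
    for c in cuts:
        seg = y[first : c + 1]
        coefs, ssr = fit_segment(seg, order)
        coefficients.append(coefs)
        segment_ssr.append(ssr)
        x = np.arange(seg.size, dtype=float)
        fitted[first : c + 1] = np.polynomial.polynomial.polyval(x, np.asarray(coefs))
        first = c + 1
    return SegmentationResult(
        n_segments=n_segments,
        boundaries=boundaries,
        first_residue=int(residue_index[0]),
        coefficients=tuple(coefficients),
        segment_ssr=tuple(segment_ssr),
        total_ssr=total,
        per_residue_fitted=fitted,
    )


def residual_curve(
    mobility: np.ndarray | Sequence[float],
    n_range: Sequence[int],
    order: int = 2,
    min_len: int = 5,
) -> list[tuple[int, float]]:
    """(N, total SSR) over a range of segment counts; non-increasing in N."""
    y = np.asarray(mobility, dtype=float)
    n_range = sorted(set(int(k) for k in n_range))
    if not n_range or n_range[0] < 1:
        raise ValueError("n_range must contain positive segment counts")
    min_len_eff = max(min_len, order + 1)
    if y.size < max(n_range) * min_len_eff:
        raise ValueError("largest N in n_range is infeasible for this profile")
    dp, _ = _dp_tables(y, max(n_range), order, min_len_eff)
    return [(k, float(dp[k - 1, y.size - 1])) for k in n_range]
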
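"""Bivariate density estimation for a censored event pair by optional Pólya trees.

The estimator works in two stages.  First, each sample's probability mass is
laid out along each axis: an uncensored observation is a point mass at its
observed time, while a censored observation's mass is redistributed over the
Kaplan-Meier event times beyond it, proportionally to the KM survival
increments (any residual KM tail mass is spread uniformly between the last
event time and the edge of the sample space).  A sample's two-dimensional mass
is the product of its two axis distributions.

Second, the rectangular sample space is partitioned by recursive binary
midpoint splits.  For a region ``A`` the optional-Pólya-tree marginal
likelihood obeys

    Phi(A) = 1/2 Phi0(A)
           + 1/4 sum_m [B(N(Am1)+1/2, N(Am2)+1/2) / B(1/2, 1/2)]
                 Phi(Am1) Phi(Am2),

where ``m`` ranges over the two split directions, ``Phi0(A) = |A|^(-N(A))``
is the likelihood of a uniform layout of the region's mass, ``N(A)`` is the
(fractional) number of samples in ``A`` and ``B`` is the Beta function.  A
region is kept as a single uniform leaf when ``Phi0`` exceeds the Beta-weighted
split likelihoods; otherwise it is split along the axis with the larger
weighted child-likelihood product.  Leaves carry the constant density
``N(A) / (N |A|)``.

All likelihood arithmetic is done in log space (Beta terms via log-gamma), so
fractional counts and sample sizes up to at least 1e4 are handled without
overflow.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable

import numpy as np
from scipy.special import betaln

from .config import CNEConfig
from .data_model import kaplan_meier

__all__ = [
    "Region",
    "AxisAllocation",
    "MassAllocation",
    "DensityEstimate",
    "MarginalDensity",
    "allocate_mass",
    "region_mass",
    "opt_log_likelihood",
    "estimate_bivariate_density",
    "marginalize",
    "write_density_tsv",
]

_LOG_HALF = math.log(0.5)
_LOG_QUARTER = math.log(0.25)
_BETALN_HALF = betaln(0.5, 0.5)


@dataclasses.dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle ``[lo1, hi1) x [lo2, hi2)`` with its split depth."""

    lo1: float
    hi1: float
    lo2: float
    hi2: float
    depth: int = 0

    def __post_init__(self) -> None:
        if not (self.lo1 < self.hi1 and self.lo2 < self.hi2):
            raise ValueError("region must have lo < hi on both axes")

    @property
    def area(self) -> float:
        return (self.hi1 - self.lo1) * (self.hi2 - self.lo2)

    def children(self, axis: int) -> tuple["Region", "Region"]:
        """Midpoint split along ``axis`` (1 or 2)."""
        d = self.depth + 1
        if axis == 1:
            mid = 0.5 * (self.lo1 + self.hi1)
            return (
                Region(self.lo1, mid, self.lo2, self.hi2, d),
                Region(mid, self.hi1, self.lo2, self.hi2, d),
            )
        mid = 0.5 * (self.lo2 + self.hi2)
        return (
            Region(self.lo1, self.hi1, self.lo2, mid, d),
            Region(self.lo1, self.hi1, mid, self.hi2, d),
        )


@dataclasses.dataclass
class AxisAllocation:
    """Per-sample discrete mass layout along one time axis.

    ``weights[n, k]`` is sample ``n``'s mass on the KM event time
    ``points[k]``; ``tail_weight[n]`` is spread uniformly over
    ``(tail_lo[n], root_hi]``.  Every row sums to one.
    """

    points: np.ndarray       # (K,) sorted KM event times
    weights: np.ndarray      # (N, K)
    tail_lo: np.ndarray      # (N,)
    tail_weight: np.ndarray  # (N,)
    root_hi: float

    @property
    def n_samples(self) -> int:
        return self.weights.shape[0]

    def totals(self) -> np.ndarray:
        """Per-sample total mass (should be exactly 1)."""
        return self.weights.sum(axis=1) + self.tail_weight

    def interval_mass(self, lo: float, hi: float) -> np.ndarray:
        """Per-sample mass in ``[lo, hi)`` (``hi`` may equal ``root_hi``)."""
        mask = (self.points >= lo) & (self.points < hi)
        out = self.weights[:, mask].sum(axis=1)
        width = self.root_hi - self.tail_lo
        with np.errstate(invalid="ignore", divide="ignore"):
            overlap = np.minimum(hi, self.root_hi) - np.maximum(lo, self.tail_lo)
            frac = np.clip(overlap, 0.0, None) / np.where(width > 0, width, 1.0)
        out = out + np.where(width > 0, frac * self.tail_weight, 0.0)
        # degenerate tail (tail_lo == root_hi): treat as an atom at root_hi
        atom = (width <= 0) & (self.tail_weight > 0)
        if np.any(atom) and hi >= self.root_hi:
            out = out + np.where(atom, self.tail_weight, 0.0)
        return out

    def binned(self, n_cells: int) -> np.ndarray:
        """Exact (N, n_cells) layout on the uniform dyadic grid over [0, root_hi]."""
        n = self.n_samples
        cells = np.zeros((n, n_cells))
        width = self.root_hi / n_cells
        if self.points.size:
            idx = np.minimum((self.points / width).astype(int), n_cells - 1)
            # points are sorted, hence so are their cell indices
            starts = np.flatnonzero(np.r_[True, np.diff(idx) > 0])
            sums = np.add.reduceat(self.weights, starts, axis=1)
            cells[:, idx[starts]] += sums
        has_tail = self.tail_weight > 0
        if np.any(has_tail):
            tl = self.tail_lo[has_tail]
            tw = self.tail_weight[has_tail]
            span = self.root_hi - tl
            edges_lo = np.arange(n_cells) * width
            edges_hi = edges_lo + width
            ok = span > 0
            if np.any(ok):
                overlap = np.clip(
                    edges_hi[None, :] - np.maximum(edges_lo[None, :], tl[ok, None]),
                    0.0,
                    width,
                )
                cells[np.flatnonzero(has_tail)[ok]] += (
                    overlap / span[ok, None] * tw[ok, None]
                )
            if np.any(~ok):  # tail collapsed to the upper edge
                cells[np.flatnonzero(has_tail)[~ok], -1] += tw[~ok]
        return cells


@dataclasses.dataclass
class MassAllocation:
    """Joint (product-form) mass layout of an event pair."""

    axis1: AxisAllocation
    axis2: AxisAllocation

    @property
    def n_samples(self) -> int:
        return self.axis1.n_samples

    @property
    def root(self) -> Region:
        return Region(0.0, self.axis1.root_hi, 0.0, self.axis2.root_hi)


def allocate_mass(
    times: np.ndarray, status: np.ndarray, root_hi: float
) -> AxisAllocation:
    """Kaplan-Meier mass redistribution for one axis.

    Uncensored samples are point masses at their observed times.  A sample
    censored at ``x`` receives the KM survival increments of event times
    beyond ``x``, renormalized by ``S(x)``; the residual tail mass
    ``S(last event)/S(x)`` is spread uniformly on ``(max(x, last event),
    root_hi]``.  If ``S(x) = 0`` no mass is available beyond ``x`` and the
    sample falls back to a point mass at ``x`` (with a warning).
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status)
    if root_hi < times.max():
        raise ValueError("root_hi must be >= the largest observed time")
    km = kaplan_meier(times, status)
    pts = km.event_times
    incr = km.increments()
    s_final = float(km.survival[-1]) if km.survival.size else 1.0
    last_event = float(pts[-1]) if pts.size else 0.0

    n = times.size
    weights = np.zeros((n, pts.size))
    tail_lo = np.full(n, last_event)
    tail_weight = np.zeros(n)

    for i in range(n):
        x = times[i]
        if status[i] == 1:
            k = int(np.searchsorted(pts, x))
            weights[i, k] = 1.0
            continue
        s_x = float(km.survival_at(x))
        if s_x <= 0.0:
            warnings.warn(
                f"censored sample at t={x} has zero KM survival; "
                "falling back to a point mass at its observed time",
                stacklevel=2,
            )
            k = int(np.searchsorted(pts, x))
            weights[i, min(k, pts.size - 1)] = 1.0
            continue
        beyond = pts > x
        weights[i, beyond] = incr[beyond] / s_x
        tail_weight[i] = s_final / s_x
        tail_lo[i] = max(x, last_event)
    return AxisAllocation(
        points=pts,
        weights=weights,
        tail_lo=tail_lo,
        tail_weight=tail_weight,
        root_hi=float(root_hi),
    )


def region_mass(alloc: MassAllocation, region: Region) -> float:
    """Probability mass ``P_A`` of a region under the product-form layout.

    ``P_A`` is the mean over samples of (axis-1 mass in ``[lo1, hi1)``) times
    (axis-2 mass in ``[lo2, hi2)``).
    """
    root = alloc.root
    if not (
        region.lo1 >= root.lo1 - 1e-12
        and region.hi1 <= root.hi1 + 1e-12
        and region.lo2 >= root.lo2 - 1e-12
        and region.hi2 <= root.hi2 + 1e-12
    ):
        raise ValueError("region lies outside the root sample space")
    m1 = alloc.axis1.interval_mass(region.lo1, region.hi1)
    m2 = alloc.axis2.interval_mass(region.lo2, region.hi2)
    return float(np.mean(m1 * m2))


# ---------------------------------------------------------------------------
# OPT likelihood, reference (region-recursive) form


def _log_phi0(n_a: float, area: float) -> float:
    return -n_a * math.log(area)


def _split_log_term(n1: float, n2: float, lphi1: float, lphi2: float) -> float:
    return betaln(n1 + 0.5, n2 + 0.5) - _BETALN_HALF + lphi1 + lphi2


def opt_log_likelihood(
    region: Region,
    alloc: MassAllocation,
    max_depth: int,
    cache: dict | None = None,
) -> float:
    """log Phi of a region under the OPT recursion with midpoint splits.

    At ``max_depth`` the recursion terminates with ``Phi = Phi0``.  Results
    are memoized on region identity in ``cache``.  This direct recursive form
    is exact but quadratic-ish in the sample count per region; the estimator
    in :func:`estimate_bivariate_density` uses an equivalent vectorized
    dyadic-table computation.
    """
    if cache is None:
        cache = {}
    return _opt_rec(region, alloc, max_depth, cache)


def _opt_rec(region: Region, alloc: MassAllocation, max_depth: int, cache: dict) -> float:
    key = (region.lo1, region.hi1, region.lo2, region.hi2)
    hit = cache.get(key)
    if hit is not None:
        return hit
    n = alloc.n_samples
    n_a = n * region_mass(alloc, region)
    lphi0 = _log_phi0(n_a, region.area)
    if region.depth >= max_depth:
        cache[key] = lphi0
        return lphi0
    terms = [_LOG_HALF + lphi0]
    for axis in (1, 2):
        c1, c2 = region.children(axis)
        n1 = n * region_mass(alloc, c1)
        n2 = n * region_mass(alloc, c2)
        l1 = _opt_rec(c1, alloc, max_depth, cache)
        l2 = _opt_rec(c2, alloc, max_depth, cache)
        terms.append(_LOG_QUARTER + _split_log_term(n1, n2, l1, l2))
    out = float(np.logaddexp.reduce(terms))
    if not np.isfinite(out):
        raise FloatingPointError(f"non-finite OPT likelihood at region {key}")
    cache[key] = out
    return out


# ---------------------------------------------------------------------------
# fast dyadic-table fit


class _PairTables:
    """Vectorized OPT tables over the dyadic partition of an event pair.

    For every level pair ``(l1, l2)`` with ``l1 + l2 <= max_depth`` this holds
    the fractional counts ``N(A)`` and log Phi of all ``2^l1 x 2^l2`` regions,
    plus the Beta-weighted split terms used both by the recursion and by the
    top-down stop/split decisions.
    """

    def __init__(self, a1: AxisAllocation, a2: AxisAllocation, max_depth: int):
        self.max_depth = max_depth
        self.w1 = a1.root_hi
        self.w2 = a2.root_hi
        g = 2 ** max_depth
        lev1 = self._levels(a1.binned(g).T, max_depth)
        lev2 = self._levels(a2.binned(g).T, max_depth)

        self.counts: dict[tuple[int, int], np.ndarray] = {}
        self.log_phi: dict[tuple[int, int], np.ndarray] = {}
        self.split1: dict[tuple[int, int], np.ndarray] = {}
        self.split2: dict[tuple[int, int], np.ndarray] = {}

        for d in range(max_depth, -1, -1):
            for l1 in range(d + 1):
                l2 = d - l1
                cnt = lev1[l1] @ lev2[l2].T  # (2^l1, 2^l2), equals N(A)
                cnt = np.clip(cnt, 0.0, None)
                self.counts[(l1, l2)] = cnt
                area = (self.w1 / 2 ** l1) * (self.w2 / 2 ** l2)
                lphi0 = -cnt * math.log(area)
                if d == max_depth:
                    self.log_phi[(l1, l2)] = lphi0
                    continue
                ch1 = self.log_phi[(l1 + 1, l2)]
                cn1 = self.counts[(l1 + 1, l2)]
                s1 = (
                    betaln(cn1[0::2] + 0.5, cn1[1::2] + 0.5)
                    - _BETALN_HALF
                    + ch1[0::2]
                    + ch1[1::2]
                )
                ch2 = self.log_phi[(l1, l2 + 1)]
                cn2 = self.counts[(l1, l2 + 1)]
                s2 = (
                    betaln(cn2[:, 0::2] + 0.5, cn2[:, 1::2] + 0.5)
                    - _BETALN_HALF
                    + ch2[:, 0::2]
                    + ch2[:, 1::2]
                )
                self.split1[(l1, l2)] = s1
                self.split2[(l1, l2)] = s2
                self.log_phi[(l1, l2)] = np.logaddexp(
                    _LOG_HALF + lphi0, _LOG_QUARTER + np.logaddexp(s1, s2)
                )
                if not np.all(np.isfinite(self.log_phi[(l1, l2)])):
                    raise FloatingPointError(
                        f"non-finite OPT likelihood at level pair {(l1, l2)}"
                    )

    @staticmethod
    def _levels(finest: np.ndarray, max_depth: int) -> list[np.ndarray]:
        levels = [None] * (max_depth + 1)
        levels[max_depth] = finest
        for l in range(max_depth - 1, -1, -1):
            prev = levels[l + 1]
            levels[l] = prev[0::2] + prev[1::2]
        return levels

    def leaves(self, min_count: float) -> list[tuple[int, int, int, int]]:
        """Top-down stop/split pass; returns leaf index tuples (l1, a1, l2, a2)."""
        out: list[tuple[int, int, int, int]] = []
        stack = [(0, 0, 0, 0)]
        while stack:
            l1, a1, l2, a2 = stack.pop()
            d = l1 + l2
            if d >= self.max_depth or self.counts[(l1, l2)][a1, a2] < min_count:
                out.append((l1, a1, l2, a2))
                continue
            area = (self.w1 / 2 ** l1) * (self.w2 / 2 ** l2)
            lphi0 = -self.counts[(l1, l2)][a1, a2] * math.log(area)
            s1 = self.split1[(l1, l2)][a1, a2]
            s2 = self.split2[(l1, l2)][a1, a2]
            if lphi0 > _LOG_HALF + np.logaddexp(s1, s2):
                out.append((l1, a1, l2, a2))
            elif s1 >= s2:  # ties split along axis 1
                stack.append((l1 + 1, 2 * a1, l2, a2))
                stack.append((l1 + 1, 2 * a1 + 1, l2, a2))
            else:
                stack.append((l1, a1, l2 + 1, 2 * a2))
                stack.append((l1, a1, l2 + 1, 2 * a2 + 1))
        return out


@dataclasses.dataclass
class DensityEstimate:
    """Piecewise-constant bivariate density on an axis-aligned partition."""

    leaves: list[tuple[Region, float]]
    root: Region
    pair: tuple[str, str] = ("event_1", "event_2")

    def integral(self) -> float:
        return sum(d * r.area for r, d in self.leaves)

    def evaluate(self, t1: float, t2: float) -> float:
        """Density at a point (0 outside the root)."""
        for r, d in self.leaves:
            if r.lo1 <= t1 < r.hi1 and r.lo2 <= t2 < r.hi2:
                return d
        return 0.0


@dataclasses.dataclass
class MarginalDensity:
    """Piecewise-constant univariate density derived from a pair density."""

    breakpoints: np.ndarray  # (B+1,)
    values: np.ndarray       # (B,)
    source: str = ""

    def integral(self) -> float:
        return float(np.sum(self.values * np.diff(self.breakpoints)))

    def mean(self) -> float:
        a, b = self.breakpoints[:-1], self.breakpoints[1:]
        return float(np.sum(self.values * (b ** 2 - a ** 2) / 2.0))

    def evaluate(self, t: float | np.ndarray) -> float | np.ndarray:
        idx = np.clip(
            np.searchsorted(self.breakpoints, t, side="right") - 1,
            0,
            self.values.size - 1,
        )
        out = np.where(
            (np.asarray(t) >= self.breakpoints[0]) & (np.asarray(t) < self.breakpoints[-1]),
            self.values[idx],
            0.0,
        )
        return float(out) if np.isscalar(t) else out


def _root_bounds(x: np.ndarray, tail_factor: float) -> float:
    hi = tail_factor * float(np.max(x))
    return hi if hi > 0 else 1.0


def estimate_bivariate_density(
    xi: np.ndarray,
    di: np.ndarray,
    xj: np.ndarray,
    dj: np.ndarray,
    config: CNEConfig | None = None,
    pair: tuple[str, str] = ("event_1", "event_2"),
) -> DensityEstimate:
    """Fit the OPT piecewise-constant density of one censored event pair.

    Parameters
    ----------
    xi, di : arrays
        Observed times and censoring indicators of the first event.
    xj, dj : arrays
        Same for the second event.
    config : CNEConfig
        ``tail_factor``, ``max_depth``, ``min_count``, ``min_samples``.
    """
    config = config or CNEConfig()
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if not (xi.size == di.__len__() == xj.size == dj.__len__()):
        raise ValueError("input vectors must have equal length")
    if xi.size < config.min_samples:
        raise ValueError(
            f"need at least {config.min_samples} samples, got {xi.size}"
        )
    hi1 = _root_bounds(xi, config.tail_factor)
    hi2 = _root_bounds(xj, config.tail_factor)
    root = Region(0.0, hi1, 0.0, hi2)
    if np.ptp(xi) == 0 or np.ptp(xj) == 0:
        warnings.warn(
            "degenerate sample space (constant observed times); "
            "returning a single-leaf uniform density",
            stacklevel=2,
        )
        return DensityEstimate(leaves=[(root, 1.0 / root.area)], root=root, pair=pair)
    a1 = allocate_mass(xi, di, hi1)
    a2 = allocate_mass(xj, dj, hi2)
    return _fit_pair(a1, a2, config, pair)


def _fit_pair(
    a1: AxisAllocation,
    a2: AxisAllocation,
    config: CNEConfig,
    pair: tuple[str, str] = ("event_1", "event_2"),
) -> DensityEstimate:
    """Fit from precomputed axis allocations (shared across pairs by callers)."""
    tables = _PairTables(a1, a2, config.max_depth)
    n = a1.n_samples
    leaves = []
    for l1, i1, l2, i2 in tables.leaves(config.min_count):
        w1 = tables.w1 / 2 ** l1
        w2 = tables.w2 / 2 ** l2
        r = Region(i1 * w1, (i1 + 1) * w1, i2 * w2, (i2 + 1) * w2, depth=l1 + l2)
        p_a = tables.counts[(l1, l2)][i1, i2] / n
        leaves.append((r, p_a / r.area))
    total = sum(d * r.area for r, d in leaves)
    if total <= 0:
        raise FloatingPointError("density fit produced zero total mass")
    leaves = [(r, d / total) for r, d in leaves]
    root = Region(0.0, tables.w1, 0.0, tables.w2)
    return DensityEstimate(leaves=leaves, root=root, pair=pair)


def marginalize(density: DensityEstimate, axis: int) -> MarginalDensity:
    """Exact strip integration of a pair density onto one axis.

    The leaf partition tiles the root, so each breakpoint interval on the
    chosen axis is either fully covered by a leaf or disjoint from it; the
    marginal value on an interval is the sum of (leaf density x leaf extent on
    the other axis) over covering leaves.
    """
    if axis not in (1, 2):
        raise ValueError("axis must be 1 or 2")
    if axis == 1:
        bounds = [(r.lo1, r.hi1, (r.hi2 - r.lo2), d) for r, d in density.leaves]
        root_lo, root_hi = density.root.lo1, density.root.hi1
    else:
        bounds = [(r.lo2, r.hi2, (r.hi1 - r.lo1), d) for r, d in density.leaves]
        root_lo, root_hi = density.root.lo2, density.root.hi2
    breaks = np.unique(
        np.concatenate([[root_lo, root_hi], [b[0] for b in bounds], [b[1] for b in bounds]])
    )
    values = np.zeros(breaks.size - 1)
    mids = 0.5 * (breaks[:-1] + breaks[1:])
    for lo, hi, extent, d in bounds:
        covered = (mids > lo) & (mids < hi)
        values[covered] += d * extent
    return MarginalDensity(
        breakpoints=breaks,
        values=values,
        source=f"{density.pair[0]}|{density.pair[1]}:axis{axis}",
    )


def write_density_tsv(density: DensityEstimate, path: str) -> None:
    """Export leaves as TSV columns ``lo1 hi1 lo2 hi2 density``."""
    import pandas as pd

    rows = [
        (r.lo1, r.hi1, r.lo2, r.hi2, d) for r, d in density.leaves
    ]
    pd.DataFrame(rows, columns=["lo1", "hi1", "lo2", "hi2", "density"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
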
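"""Gaussian-kernel calling of TF-binding-site clustered regions.

A Gaussian kernel of bandwidth ``b`` (unnormalised: a site contributes 1 at
distance 0) is centred on each binding-site anchor; every strict local
maximum of the summed density is a called region. A region's complexity is
the sum of kernel weights of the sites that each contribute at least
``theta`` at the peak, i.e. an effective site count on a 0-1 per-site scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genomic_io import GenomicInterval, TfbsRecord

__all__ = [
    "KernelParams",
    "DensityProfile",
    "ClusteredRegion",
    "CategoryScheme",
    "IntervalMixtureFit",
    "kernel_weight",
    "compute_density",
    "find_peaks",
    "call_regions",
    "categorize",
    "flag_hot_cold",
    "site_concentration_curve",
    "fit_interval_mixture",
]

# largest |d| (in bandwidth-scaled units) with exp(-d^2/(2 b^2)) > 0 in
# binary64; beyond this the kernel underflows to exactly 0.0
_UNDERFLOW_SIGMAS = math.sqrt(2.0 * 745.2)


@dataclass(frozen=True)
class KernelParams:
    """Kernel bandwidth, contribution threshold and evaluation grid step."""

    bandwidth: float = 300.0
    theta: float = 0.1
    grid_step: int = 1

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")
        if self.grid_step < 1:
            raise ValueError("grid_step must be >= 1")

    @property
    def contribution_cutoff(self) -> float:
        """Distance beyond which a site contributes < theta."""
        return self.bandwidth * math.sqrt(2.0 * math.log(1.0 / self.theta))

    @property
    def support(self) -> int:
        """Distance beyond which the kernel underflows to exactly zero."""
        return int(math.ceil(self.bandwidth * _UNDERFLOW_SIGMAS))


def kernel_weight(d, params: KernelParams = KernelParams()):
    """Unnormalised Gaussian kernel exp(-d^2 / (2 b^2)); k(0) = 1."""
    d = np.asarray(d, dtype=float)
    b = params.bandwidth
    out = np.exp(-(d * d) / (2.0 * b * b))
    return float(out) if out.ndim == 0 else out


@dataclass
class DensityProfile:
    """Kernel density evaluated on a regular grid along one chromosome."""

    chrom: str
    start: int
    step: int
    values: np.ndarray

    @property
    def positions(self) -> np.ndarray:
        return self.start + self.step * np.arange(len(self.values))

    def value_at(self, pos: int) -> float:
        idx = (pos - self.start) // self.step
        if idx < 0 or idx >= len(self.values):
            return 0.0
        return float(self.values[idx])


DEFAULT_CATEGORY_BOUNDS = (6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 19.0, 23.0, 30.0, math.inf)


@dataclass(frozen=True)
class CategoryScheme:
    """Ten complexity categories TC0-TC9 with low/median/high bands.

    A region falls in the first category whose upper bound exceeds its
    complexity; a complexity of exactly 30 falls in TC9 (half-open-up
    convention at every bound).
    """

    upper_bounds: tuple = DEFAULT_CATEGORY_BOUNDS
    low_max: int = 2    # TC0..TC2 -> low
    median_max: int = 7  # TC3..TC7 -> median; rest high

    def __post_init__(self) -> None:
        bounds = self.upper_bounds
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("category bounds must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        return [f"TC{i}" for i in range(len(self.upper_bounds))]

    def band_of(self, index: int) -> str:
        if index <= self.low_max:
            return "low"
        if index <= self.median_max:
            return "median"
        return "high"


def categorize(c: float, scheme: CategoryScheme = CategoryScheme()) -> tuple[str, str]:
    """Map a complexity value to its (category label, band)."""
    if c < 0:
        raise ValueError(f"negative complexity {c}")
    idx = int(np.searchsorted(scheme.upper_bounds, c, side="right"))
    return scheme.labels[idx], scheme.band_of(idx)


@dataclass
class ClusteredRegion:
    """One called region: peak, window, complexity and categorisation."""

    cell_type: str
    chrom: str
    peak: int
    window: GenomicInterval
    complexity: float
    contributing_sites: list[tuple[str, int, float]] = field(default_factory=list)
    category: str = ""
    band: str = ""
    is_hot: bool = False
    is_cold: bool = False
    n_sites: int = 0
    n_distinct_tfs: int = 0

    def __post_init__(self) -> None:
        if self.contributing_sites and self.n_sites == 0:
            self.n_sites = len(self.contributing_sites)
            self.n_distinct_tfs = len({tf for tf, _, _ in self.contributing_sites})

    @property
    def centre(self) -> int:
        return self.window.midpoint


def flag_hot_cold(
    region: ClusteredRegion, hot_tf_count: int = 40, cold_category: str = "TC0"
) -> ClusteredRegion:
    """Set the HOT (> ``hot_tf_count`` distinct TFs, strict) and COLD flags."""
    region.is_hot = region.n_distinct_tfs > hot_tf_count
    region.is_cold = region.category == cold_category
    return region


# ---------------------------------------------------------------------------
# density evaluation and peak finding

def compute_density(
    sites: Sequence[int], params: KernelParams = KernelParams(), chrom: str = ""
) -> DensityProfile:
    """Sum the kernel over ``sites`` on a regular grid covering their support.

    All sites contribute at every grid point (the theta threshold applies
    only to complexity accounting, not to the density itself). Sites are
    accumulated in ascending order, so results are reproducible bit for bit.
    """
    sites = np.sort(np.asarray(sites, dtype=np.int64))
    if len(sites) == 0:
        return DensityProfile(chrom, 0, params.grid_step, np.zeros(0))
    support = params.support
    step = params.grid_step
    lo = int(sites[0]) - support
    hi = int(sites[-1]) + support
    n = (hi - lo) // step + 1
    values = np.zeros(n)
    b = params.bandwidth
    if step == 1:
        # all integer offsets share one kernel vector
        offs = np.arange(-support, support + 1, dtype=float)
        kern = np.exp(-(offs * offs) / (2.0 * b * b))
        for s in sites:
            i0 = int(s) - support - lo
            values[i0 : i0 + len(kern)] += kern
    else:
        grid = lo + step * np.arange(n)
        for s in sites:
            gi0 = int(np.searchsorted(grid, s - support, side="left"))
            gi1 = int(np.searchsorted(grid, s + support, side="right"))
            d = grid[gi0:gi1].astype(float) - float(s)
            values[gi0:gi1] += np.exp(-(d * d) / (2.0 * b * b))
    return DensityProfile(chrom, lo, step, values)


def find_peaks(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a flat-topped run yields its midpoint
    (rounded down). Boundary runs are not peaks."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        return np.zeros(0, dtype=np.int64)
    s = np.sign(np.diff(v)).astype(np.int8)
    nz = np.nonzero(s)[0]
    if len(nz) < 2:
        return np.zeros(0, dtype=np.int64)
    sv = s[nz]
    cand = np.nonzero((sv[:-1] == 1) & (sv[1:] == -1))[0]
    starts = nz[cand] + 1      # first index of the plateau
    ends = nz[cand + 1]        # last index of the plateau
    return (starts + ends) // 2


def call_regions(
    records: Iterable[TfbsRecord],
    params: KernelParams = KernelParams(),
    scheme: CategoryScheme = CategoryScheme(),
    hot_tf_count: int = 40,
) -> list[ClusteredRegion]:
    """Call clustered regions for one cell type's binding sites.

    For each density peak ``p``: sites with kernel weight >= theta at ``p``
    contribute; complexity is the sum of their weights; the window is centred
    on ``p`` with half-width (max contributing distance + bandwidth/2).
    Peaks with no contributing site are dropped.
    """
    records = list(records)
    if not records:
        return []
    cell = records[0].cell_type
    by_chrom: dict[str, list[TfbsRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    half_bw = int(round(params.bandwidth / 2.0))
    b = params.bandwidth
    out: list[ClusteredRegion] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.position, r.tf_id))
        positions = np.array([r.position for r in recs], dtype=np.int64)
        prof = compute_density(positions, params, chrom)
        for idx in find_peaks(prof.values):
            p = prof.start + prof.step * int(idx)
            d = positions.astype(float) - float(p)
            k = np.exp(-(d * d) / (2.0 * b * b))
            mask = k >= params.theta
            if not mask.any():
                continue
            c = float(k[mask].sum())
            maxdist = int(np.max(np.abs(positions[mask] - p)))
            hw = maxdist + half_bw
            window = GenomicInterval(chrom, max(0, p - hw), p + hw)
            contributing = [
                (recs[i].tf_id, int(positions[i]), float(k[i]))
                for i in np.nonzero(mask)[0]
            ]
            label, band = categorize(c, scheme)
            region = ClusteredRegion(
                cell_type=cell,
                chrom=chrom,
                peak=p,
                window=window,
                complexity=c,
                contributing_sites=contributing,
                category=label,
                band=band,
            )
            out.append(flag_hot_cold(region, hot_tf_count))
    return out


# ---------------------------------------------------------------------------
# genome-wide site spacing statistics

def site_concentration_curve(records: Iterable[TfbsRecord]):
    """Cumulative fraction of adjacent-site intervals (y) versus the fraction
    of their total genomic span covered (x), intervals sorted short-first.

    Tightly clustered sites show a near-vertical rise at x ~ 0.
    """
    by_chrom: dict[str, list[int]] = {}
    n = 0
    for r in records:
        by_chrom.setdefault(r.interval.chrom, []).append(r.position)
        n += 1
    if n < 2:
        raise ValueError("need at least 2 sites")
    gaps = []
    for positions in by_chrom.values():
        positions.sort()
        gaps.extend(np.diff(positions))
    gaps = np.sort(np.asarray(gaps, dtype=float))
    if len(gaps) == 0 or gaps.sum() == 0:
        raise ValueError("no positive site-site intervals")
    x = np.cumsum(gaps) / gaps.sum()
    y = np.arange(1, len(gaps) + 1) / len(gaps)
    return x, y


def adjacent_gaps(records: Iterable[TfbsRecord]) -> np.ndarray:
    """Distances between adjacent site anchors, per chromosome, pooled."""
    by_chrom: dict[str, list[int]] = {}
    for r in records:
        by_chrom.setdefault(r.interval.chrom, []).append(r.position)
    gaps: list[int] = []
    for positions in by_chrom.values():
        positions.sort()
        gaps.extend(int(g) for g in np.diff(positions))
    return np.asarray(gaps, dtype=np.int64)


# ---------------------------------------------------------------------------
# two-component geometric mixture of site-site gaps

@dataclass
class IntervalMixtureFit:
    """EM fit of gaps as a mixture of within- and between-cluster geometrics."""

    within_mean: float
    between_mean: float
    weight: float           # mixing weight of the within component
    within_q995: int        # 99.5% quantile of the within component, bp
    log_likelihood: float
    n_iter: int
    degenerate: bool = False


def _geom_logpmf(gaps: np.ndarray, mean: float) -> np.ndarray:
    p = min(1.0 / mean, 1.0 - 1e-12)
    return math.log(p) + (gaps - 1.0) * math.log1p(-p)


def _geom_q995(mean: float) -> int:
    p = min(1.0 / mean, 1.0 - 1e-12)
    return int(math.ceil(math.log(0.005) / math.log1p(-p)))


def fit_interval_mixture(
    gaps: Sequence[int],
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> IntervalMixtureFit:
    """Fit a two-component geometric mixture to adjacent-site gaps by EM.

    Initialised by 2-means on log gaps with ``n_restarts`` random restarts;
    the best final log-likelihood wins. Converges when the log-likelihood
    improves by less than ``tol``. Identical gaps (or a collapsed
    component) yield a flagged single-component fit.
    """
    gaps = np.asarray(gaps, dtype=float)
    if len(gaps) < 50:
        raise ValueError("need at least 50 gaps")
    if np.any(gaps <= 0):
        raise ValueError("gaps must be positive")
    if np.all(gaps == gaps[0]):
        mean = float(gaps[0])
        ll = float(np.sum(_geom_logpmf(gaps, max(mean, 1.0 + 1e-9))))
        return IntervalMixtureFit(mean, mean, 1.0, _geom_q995(max(mean, 1.0 + 1e-9)),
                                  ll, 0, degenerate=True)
    rng = np.random.default_rng(seed)
    log_g = np.log(gaps)
    best = None
    for _ in range(n_restarts):
        centres = rng.choice(log_g, size=2, replace=False)
        for _ in range(20):  # Lloyd iterations on 1-D log gaps
            assign = np.abs(log_g[:, None] - centres[None, :]).argmin(axis=1)
            for c in range(2):
                if np.any(assign == c):
                    centres[c] = log_g[assign == c].mean()
        means = np.exp(centres)
        means = np.clip(means, 1.0 + 1e-9, None)
        w = max(min(float(np.mean(assign == np.argmin(means))), 0.99), 0.01)
        res = _run_em(gaps, float(means.min()), float(means.max()), w, max_iter, tol)
        if best is None or res[3] > best[3]:
            best = res
    m1, m2, w, ll, iters = best
    if m1 > m2:
        m1, m2, w = m2, m1, 1.0 - w
    # one-component data: EM splits a single geometric into two similar
    # means; call it degenerate unless the components are well separated
    degenerate = m2 < 5.0 * m1 or w < 1e-4 or w > 1.0 - 1e-4
    if degenerate:
        mean = float(np.mean(gaps))
        return IntervalMixtureFit(mean, mean, 1.0, _geom_q995(mean), ll, iters,
                                  degenerate=True)
    return IntervalMixtureFit(m1, m2, w, _geom_q995(m1), ll, iters)


def _run_em(gaps, m1, m2, w, max_iter, tol):
    prev_ll = -np.inf
    iters = 0
    for iters in range(1, max_iter + 1):
        la = math.log(w) + _geom_logpmf(gaps, m1)
        lb = math.log1p(-w) + _geom_logpmf(gaps, m2)
        mx = np.maximum(la, lb)
        lse = mx + np.log(np.exp(la - mx) + np.exp(lb - mx))
        ll = float(np.sum(lse))
        r = np.exp(la - lse)  # responsibility of component 1
        w = float(np.clip(r.mean(), 1e-10, 1.0 - 1e-10))
        m1 = max(float(np.sum(r * gaps) / np.sum(r)), 1.0 + 1e-9)
        m2 = max(float(np.sum((1 - r) * gaps) / np.sum(1 - r)), 1.0 + 1e-9)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return m1, m2, w, ll, iters
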
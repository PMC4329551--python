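"""Cross-cell-type master list, genomic annotation and saturation analysis.

The master list consolidates per-cell called regions into non-overlapping
entries: within each connected component of overlapping windows the
highest-complexity region wins, overlapping losers are discarded, and the
procedure repeats on what remains.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .genomic_io import GeneAnnotation, GenomicInterval, merge_intervals
from .region_calling import ClusteredRegion

__all__ = [
    "MasterEntry",
    "MasterList",
    "SaturationCurve",
    "WeibullFit",
    "build_master_list",
    "cell_ubiquity",
    "saturation_curve",
    "fit_weibull_saturation",
    "annotate_region_classes",
    "assign_nearest_gene",
]

ANNOTATION_CLASSES = ("promoter", "exon", "UTR", "intron", "intergenic")


@dataclass
class MasterEntry:
    region: ClusteredRegion
    ubiquity: int = 0
    genomic_class: str = ""
    nearest_gene: str | None = None

    @property
    def window(self) -> GenomicInterval:
        return self.region.window


@dataclass
class MasterList:
    entries: list[MasterEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def windows(self) -> list[GenomicInterval]:
        return [e.window for e in self.entries]


def _components(regions: list[ClusteredRegion]):
    """Connected components of window overlap within one chromosome."""
    regions = sorted(regions, key=lambda r: (r.window.start, r.window.end, r.cell_type))
    comp: list[ClusteredRegion] = []
    comp_end = -1
    for r in regions:
        if comp and r.window.start < comp_end:
            comp.append(r)
            comp_end = max(comp_end, r.window.end)
        else:
            if comp:
                yield comp
            comp = [r]
            comp_end = r.window.end
    if comp:
        yield comp


def _resolve(component: list[ClusteredRegion], selected: list[ClusteredRegion]) -> None:
    if not component:
        return
    winner = min(
        component,
        key=lambda r: (-r.complexity, r.window.start, r.cell_type),
    )
    selected.append(winner)
    rest = [r for r in component if r is not winner and not r.window.overlaps(winner.window)]
    for sub in _components(rest):
        _resolve(sub, selected)


def build_master_list(per_cell_regions: dict[str, list[ClusteredRegion]]) -> MasterList:
    """Greedy highest-complexity consolidation into non-overlapping entries.

    Ties break by (leftmost window start, cell-type name), making the result
    independent of input order.
    """
    by_chrom: dict[str, list[ClusteredRegion]] = {}
    for regions in per_cell_regions.values():
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
    selected: list[ClusteredRegion] = []
    for chrom in sorted(by_chrom):
        for comp in _components(by_chrom[chrom]):
            _resolve(comp, selected)
    selected.sort(key=lambda r: (r.chrom, r.window.start, r.window.end))
    return MasterList([MasterEntry(r) for r in selected])


def cell_ubiquity(
    master: MasterList, per_cell_regions: dict[str, list[ClusteredRegion]]
) -> list[int]:
    """Per master entry, number of cell types with a >=1 bp window overlap."""
    # merged windows per cell per chrom, as sorted start/end arrays
    cell_index: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for cell, regions in per_cell_regions.items():
        merged = merge_intervals([r.window for r in regions])
        per_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for iv in merged:
            per_chrom.setdefault(iv.chrom, ([], []))
            per_chrom[iv.chrom][0].append(iv.start)
            per_chrom[iv.chrom][1].append(iv.end)
        cell_index[cell] = {
            c: (np.array(s), np.array(e)) for c, (s, e) in per_chrom.items()
        }
    counts = []
    for entry in master:
        w = entry.window
        n = 0
        for cell, idx in cell_index.items():
            if w.chrom not in idx:
                continue
            starts, ends = idx[w.chrom]
            i = int(np.searchsorted(starts, w.end, side="left")) - 1
            if i >= 0 and ends[i] > w.start:
                n += 1
        entry.ubiquity = n
        counts.append(n)
    return counts


# ---------------------------------------------------------------------------
# saturation analysis

@dataclass
class SaturationCurve:
    """Mean unique-element count and bp coverage versus cell-type count."""

    x: np.ndarray                 # number of cell types combined
    mean_elements: np.ndarray
    mean_bp: np.ndarray
    n_subsets: np.ndarray         # subsets actually evaluated at each x
    max_element_len: int


def _count_elements(windows: list[GenomicInterval], max_len: int) -> tuple[int, int]:
    merged = merge_intervals(windows)
    n_elem = sum(-(-iv.width // max_len) for iv in merged)  # ceil division
    bp = sum(iv.width for iv in merged)
    return n_elem, bp


def saturation_curve(
    per_cell_regions: dict[str, list[ClusteredRegion]],
    n_samples: int = 20000,
    max_element_len: int = 5000,
    seed: int = 0,
) -> SaturationCurve:
    """Sample cell-type combinations of every size and count merged elements.

    Merged runs longer than ``max_element_len`` are split into consecutive
    chunks of at most that length before counting. When the number of
    distinct subsets of size x is <= ``n_samples`` all subsets are
    enumerated; otherwise ``n_samples`` random subsets are drawn (distinct
    subsets are not enforced across draws).
    """
    cells = sorted(per_cell_regions)
    if len(cells) < 2:
        raise ValueError("need at least 2 cell types")
    windows = {c: [r.window for r in per_cell_regions[c]] for c in cells}
    rng = np.random.default_rng(seed)
    n = len(cells)
    xs, mean_el, mean_bp, n_sub = [], [], [], []
    for x in range(1, n + 1):
        total = math.comb(n, x)
        if total <= n_samples:
            subsets = itertools.combinations(range(n), x)
            m = total
        else:
            subsets = (rng.choice(n, size=x, replace=False) for _ in range(n_samples))
            m = n_samples
        els = np.empty(m)
        bps = np.empty(m)
        for i, sub in enumerate(subsets):
            pooled = [w for j in sub for w in windows[cells[j]]]
            els[i], bps[i] = _count_elements(pooled, max_element_len)
        xs.append(x)
        mean_el.append(els.mean())
        mean_bp.append(bps.mean())
        n_sub.append(m)
    return SaturationCurve(
        np.array(xs), np.array(mean_el), np.array(mean_bp), np.array(n_sub),
        max_element_len,
    )


@dataclass
class WeibullFit:
    """Least-squares fit of y(x) = A (1 - exp(-(x/lam)^k))."""

    asymptote: float
    scale: float
    shape: float
    asymptote_se: float
    scale_se: float
    shape_se: float

    def predict(self, x) -> np.ndarray:
        return weibull_saturation(np.asarray(x, dtype=float),
                                  self.asymptote, self.scale, self.shape)


def weibull_saturation(x, a, lam, k):
    return a * (1.0 - np.exp(-((x / lam) ** k)))


def fit_weibull_saturation(x, y) -> WeibullFit:
    """Fit the saturating Weibull CDF shape to a saturation curve.

    Multi-start Levenberg-Marquardt (via ``scipy.optimize.curve_fit`` with
    positivity bounds); the asymptote A is the predicted saturation level
    and its standard error comes from the fit covariance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 4:
        raise ValueError("need >= 4 distinct x values")
    ymax = float(y.max())
    starts = [
        (a0 * ymax, lam0, k0)
        for a0 in (1.0, 1.5, 3.0)
        for lam0 in (0.1, max(x.max() / 4.0, 1e-3), x.max(), 2.0 * x.max())
        for k0 in (0.5, 1.0, 2.0)
    ]
    best = None
    errors = []
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                weibull_saturation, x, y, p0=p0,
                bounds=([1e-12, 1e-9, 1e-9], [np.inf] * 3), maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            errors.append(str(exc))
            continue
        sse = float(np.sum((weibull_saturation(x, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise RuntimeError(
            "Weibull fit failed to converge from any start: " + "; ".join(errors[:3])
        )
    _, popt, pcov = best
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return WeibullFit(popt[0], popt[1], popt[2], se[0], se[1], se[2])


# ---------------------------------------------------------------------------
# genomic-class annotation

def _merged_coverage_index(intervals: list[GenomicInterval]):
    """Per-chrom (starts, ends, cumulative covered bp) for merged intervals."""
    merged = merge_intervals(intervals)
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        per_chrom.setdefault(iv.chrom, []).append(iv)
    out = {}
    for chrom, ivs in per_chrom.items():
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        cum = np.concatenate(([0], np.cumsum(ends - starts)))
        out[chrom] = (starts, ends, cum)
    return out


def _overlap_bp(index, chrom: str, a: int, b: int) -> int:
    """Covered bp of merged interval set within [a, b)."""
    if chrom not in index:
        return 0
    starts, ends, cum = index[chrom]

    def covered_before(pos: int) -> int:
        i = int(np.searchsorted(starts, pos, side="right"))
        total = int(cum[i])
        if i > 0 and ends[i - 1] > pos:
            total -= int(ends[i - 1] - pos)
        return total

    return covered_before(b) - covered_before(a)


def annotate_region_classes(
    master: MasterList,
    annotation: GeneAnnotation,
    promoter_distance: int = 1000,
    min_cds_overlap: int = 75,
) -> list[str]:
    """Assign each master entry one genomic class by priority.

    promoter (peak within 1 kb of a TSS) > exon (>= 75 bp CDS overlap)
    > UTR (>= 1 bp) > intron (>= 1 bp) > intergenic.
    """
    tss_index = annotation.tss_by_chrom()
    cds_idx = _merged_coverage_index(annotation.feature_intervals("cds"))
    utr_idx = _merged_coverage_index(annotation.feature_intervals("utr"))
    intron_idx = _merged_coverage_index(annotation.feature_intervals("intron"))
    classes = []
    for entry in master:
        w = entry.window
        peak = entry.region.peak
        cls = "intergenic"
        if w.chrom in tss_index:
            tss, _ = tss_index[w.chrom]
            i = int(np.searchsorted(tss, peak))
            near = min(
                abs(int(tss[j]) - peak) for j in (i - 1, i) if 0 <= j < len(tss)
            ) if len(tss) else None
            if near is not None and near <= promoter_distance:
                cls = "promoter"
        if cls == "intergenic":
            if _overlap_bp(cds_idx, w.chrom, w.start, w.end) >= min_cds_overlap:
                cls = "exon"
            elif _overlap_bp(utr_idx, w.chrom, w.start, w.end) >= 1:
                cls = "UTR"
            elif _overlap_bp(intron_idx, w.chrom, w.start, w.end) >= 1:
                cls = "intron"
        entry.genomic_class = cls
        classes.append(cls)
    return classes


def assign_nearest_gene(master: MasterList, annotation: GeneAnnotation) -> list[str | None]:
    """Nearest gene by |TSS - window centre|; ties go to the smaller gene id."""
    if len(annotation) == 0:
        raise ValueError("empty gene annotation")
    tss_index = annotation.tss_by_chrom()
    out: list[str | None] = []
    for entry in master:
        w = entry.window
        centre = w.midpoint
        if w.chrom not in tss_index:
            entry.nearest_gene = None
            out.append(None)
            continue
        tss, gids = tss_index[w.chrom]
        d = np.abs(tss - centre)
        mind = d.min()
        best = min(gids[j] for j in np.nonzero(d == mind)[0])
        entry.nearest_gene = best
        out.append(best)
    return out
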
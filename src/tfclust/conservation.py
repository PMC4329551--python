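"""Conservation and nucleotide-diversity summaries over region groups."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_io import GenomicInterval, SignalTrack, merge_intervals

__all__ = [
    "ConservationSummary",
    "DiversitySummary",
    "region_max_window_score",
    "group_bootstrap_ci",
    "nucleotide_diversity",
]


def region_max_window_score(
    region: GenomicInterval, track: SignalTrack, window: int = 100
) -> float:
    """Maximum mean per-base score over all sliding ``window``-bp windows
    inside the region; regions narrower than the window are one window.

    Returns NaN if the track has no data on the region's chromosome.
    """
    if not track.has_chrom(region.chrom):
        return float("nan")
    vals = track.values(region.chrom, region.start, region.end)
    w = min(window, len(vals))
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    sums = csum[w:] - csum[:-w]
    return float(sums.max() / w)


@dataclass
class ConservationSummary:
    group: str
    mean: float
    ci_low: float
    ci_high: float
    n_sampled: int


def group_bootstrap_ci(
    values,
    group: str = "",
    n_values: int = 1000,
    n_reps: int = 1000,
    seed: int = 0,
) -> ConservationSummary:
    """Bootstrap mean and 95% CI: ``n_reps`` replicates of ``n_values``
    draws with replacement; the CI is the 2.5/97.5% quantiles of the
    replicate means."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError("no finite values")
    rng = np.random.default_rng(seed)
    draws = rng.choice(values, size=(n_reps, n_values), replace=True)
    rep_means = draws.mean(axis=1)
    lo, hi = np.quantile(rep_means, [0.025, 0.975])
    return ConservationSummary(group, float(rep_means.mean()), float(lo), float(hi),
                               n_values * n_reps)


@dataclass
class DiversitySummary:
    pi: float              # nucleotide diversity per base
    bases_considered: int  # unmasked bp (L)
    masked_bases: int
    n_sites: int


def nucleotide_diversity(
    regions: list[GenomicInterval],
    variant_positions: dict[str, np.ndarray],
    variant_freqs: dict[str, np.ndarray],
    n_haplotypes: int,
    masks: list[GenomicInterval] | None = None,
) -> DiversitySummary:
    """Per-base nucleotide diversity over the unmasked part of the regions.

    pi = sum over unmasked variant sites of 2 p (1-p) n_h/(n_h - 1),
    normalised by the unmasked bp L. ``variant_positions``/``variant_freqs``
    map chrom -> sorted positions and matching alternate-allele frequencies.
    """
    if n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    merged = merge_intervals(regions)
    mask_merged = merge_intervals(masks) if masks else []
    mask_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in mask_merged:
        mask_by_chrom.setdefault(iv.chrom, []).append(iv)

    def unmasked_pieces(iv: GenomicInterval):
        pieces = [(iv.start, iv.end)]
        for mk in mask_by_chrom.get(iv.chrom, []):
            nxt = []
            for a, b in pieces:
                if mk.end <= a or mk.start >= b:
                    nxt.append((a, b))
                    continue
                if a < mk.start:
                    nxt.append((a, mk.start))
                if mk.end < b:
                    nxt.append((mk.end, b))
            pieces = nxt
        return pieces

    total_l = 0
    masked = 0
    het_sum = 0.0
    n_sites = 0
    corr = n_haplotypes / (n_haplotypes - 1)
    for iv in merged:
        pieces = unmasked_pieces(iv)
        kept = sum(b - a for a, b in pieces)
        total_l += kept
        masked += iv.width - kept
        pos = variant_positions.get(iv.chrom)
        if pos is None:
            continue
        freqs = variant_freqs[iv.chrom]
        for a, b in pieces:
            i0 = int(np.searchsorted(pos, a, side="left"))
            i1 = int(np.searchsorted(pos, b, side="left"))
            p = freqs[i0:i1]
            het_sum += float(np.sum(2.0 * p * (1.0 - p) * corr))
            n_sites += i1 - i0
    if total_l == 0:
        raise ValueError("no unmasked bases under consideration")
    return DiversitySummary(het_sum / total_l, total_l, masked, n_sites)
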
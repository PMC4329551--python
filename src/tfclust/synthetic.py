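"""Ground-truth synthetic data generators.

Every generator is a pure function of (seed, config): a global seed fans
out to fixed per-generator substreams, so adding a generator never perturbs
the outputs of another. Defaults target a single 10-Mb chromosome
("chrS1") so whole-pipeline tests run in seconds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .genomic_io import GenomicInterval, SignalTrack, TfbsRecord, write_bed

__all__ = [
    "LandscapeConfig",
    "ClusterTruth",
    "LandscapeTruth",
    "LineageTruth",
    "gen_tfbs_landscape",
    "gen_occupancy_track",
    "gen_lineage_dataset",
    "gen_score_track",
    "write_landscape",
]

_STREAMS = {"landscape": 1, "occupancy": 2, "lineage": 3, "scores": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


# ---------------------------------------------------------------------------
# TFBS landscapes

@dataclass(frozen=True)
class LandscapeConfig:
    genome_length: int = 10_000_000
    chrom: str = "chrS1"
    n_cell_types: int = 4
    n_tfs: int = 20
    n_clusters: int = 200
    sites_per_cluster: tuple[int, int] = (2, 8)  # inclusive range
    gap_mean: float = 46.0
    site_width: int = 10
    share_prob: float = 0.7


@dataclass
class ClusterTruth:
    centre: int
    sites: list[int]
    tfs: list[str]
    cells: list[str]


@dataclass
class LandscapeTruth:
    seed: int
    config: LandscapeConfig
    clusters: list[ClusterTruth] = field(default_factory=list)

    def to_json(self) -> str:
        d = {"seed": self.seed, "config": asdict(self.config),
             "clusters": [asdict(c) for c in self.clusters]}
        return json.dumps(d, indent=1)


def gen_tfbs_landscape(
    config: LandscapeConfig = LandscapeConfig(), seed: int = 0
) -> tuple[dict[str, list[TfbsRecord]], LandscapeTruth]:
    """Plant TFBS clusters with geometric within-cluster gaps.

    One anchor per cluster is jittered inside its own genome slot; site
    gaps are geometric with mean ``gap_mean`` (so clusters are a few
    hundred bp wide at the defaults); each cluster is present in a random
    subset of cell types (always >= 1). Site intervals are written so that
    the interval midpoint equals the planted point position.
    """
    rng = _rng(seed, "landscape")
    cfg = config
    slot = cfg.genome_length // cfg.n_clusters
    margin = slot // 4
    if margin < 1 or slot <= 2 * margin:
        raise ValueError("clusters overflow genome: too many clusters for its length")
    cells = [f"cell{i:02d}" for i in range(cfg.n_cell_types)]
    smin, smax = cfg.sites_per_cluster
    half_w = cfg.site_width // 2
    truth = LandscapeTruth(seed, cfg)
    per_cell: dict[str, list[TfbsRecord]] = {c: [] for c in cells}
    for ci in range(cfg.n_clusters):
        anchor = ci * slot + int(rng.integers(margin, slot - margin))
        n_sites = int(rng.integers(smin, smax + 1))
        gaps = rng.geometric(1.0 / cfg.gap_mean, size=n_sites - 1) if n_sites > 1 else []
        positions = anchor + np.concatenate(([0], np.cumsum(gaps))).astype(np.int64)
        if positions[-1] + cfg.site_width >= cfg.genome_length:
            raise ValueError("clusters overflow genome")
        tfs = [f"TF{int(t):03d}" for t in rng.integers(0, cfg.n_tfs, size=n_sites)]
        present = rng.random(cfg.n_cell_types) < cfg.share_prob
        if not present.any():
            present[int(rng.integers(0, cfg.n_cell_types))] = True
        cluster_cells = [c for c, p in zip(cells, present) if p]
        centre = int(round(positions.mean()))
        truth.clusters.append(
            ClusterTruth(centre, [int(p) for p in positions], tfs, cluster_cells)
        )
        for cell in cluster_cells:
            for pos, tf in zip(positions, tfs):
                iv = GenomicInterval(
                    cfg.chrom, int(pos) - half_w, int(pos) - half_w + cfg.site_width
                )
                per_cell[cell].append(TfbsRecord(iv, tf, cell))
    for cell in cells:
        per_cell[cell].sort(key=lambda r: (r.interval.chrom, r.interval.start, r.tf_id))
    return per_cell, truth


def write_landscape(
    per_cell: dict[str, list[TfbsRecord]], truth: LandscapeTruth, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cell, records in per_cell.items():
        write_bed(records, out / f"{cell}.bed")
    (out / "truth.json").write_text(truth.to_json())


# ---------------------------------------------------------------------------
# occupancy tracks

def gen_occupancy_track(
    regions: list[GenomicInterval],
    chrom_length: int,
    period: float = 200.0,
    amplitude: float = 0.3,
    depletion_depth: float = 0.5,
    noise_sd: float = 0.0,
    dip_sigma: float = 400.0,
    span: int = 4000,
    seed: int = 0,
) -> tuple[SignalTrack, dict]:
    """Occupancy with planted periodicity and central depletion.

    Baseline 1.0; outward from each region edge a cosine of the given
    period (phase 0 at the edge); a Gaussian dip of ``depletion_depth`` at
    the centre; optional additive Gaussian noise. Overlapping planted spans
    are summed with a warning.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    rng = _rng(seed, "occupancy")
    values = np.ones(chrom_length)
    spans = sorted((iv.midpoint - span, iv.midpoint + span) for iv in regions)
    if any(b[0] < a[1] for a, b in zip(spans, spans[1:])):
        warnings.warn("planted region spans overlap; phases summed")
    for iv in regions:
        c = iv.midpoint
        half_w = iv.width // 2
        lo = max(0, c - span)
        hi = min(chrom_length, c + span + 1)
        d = np.arange(lo, hi) - c
        add = np.zeros(hi - lo)
        dip = np.exp(-(d.astype(float) ** 2) / (2.0 * dip_sigma ** 2))
        outside = np.abs(d) >= half_w
        # oscillation fades inside the depleted centre (no positioned
        # nucleosomes where occupancy is planted low)
        add[outside] = amplitude * np.cos(
            2.0 * np.pi * (np.abs(d[outside]) - half_w) / period
        ) * (1.0 - dip[outside])
        add -= depletion_depth * dip
        values[lo:hi] += add
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=chrom_length)
    chrom = regions[0].chrom if regions else "chrS1"
    track = SignalTrack()
    track.add_array(chrom, 0, values)
    truth = {
        "period": period,
        "amplitude": amplitude,
        "depletion_depth": depletion_depth,
        "noise_sd": noise_sd,
        "dip_sigma": dip_sigma,
        "span": span,
    }
    return track, truth


# ---------------------------------------------------------------------------
# lineage datasets

@dataclass
class LineageTruth:
    newick: str
    leaf_names: list[str]
    branch_elements: dict[frozenset, list[GenomicInterval]]
    bipartitions: set[frozenset]  # non-trivial splits of the true tree

    def clade_of_branch(self, names) -> frozenset:
        return frozenset(names)


def gen_lineage_dataset(
    newick: str,
    gains_per_branch,
    element_width: int = 200,
    element_gap: int = 300,
    chrom: str = "chrS1",
    genome_length: int = 10_000_000,
    seed: int = 0,
) -> tuple[dict[str, list[GenomicInterval]], LineageTruth]:
    """Evolve region sets down a known tree by branch-specific gains.

    Every branch (edge above a node; the root edge is shared by all leaves)
    gains fresh non-overlapping elements; a leaf's set is the union of the
    gains on its root path; there are no losses. ``gains_per_branch`` is an
    int applied to every branch, or a dict mapping a branch's descendant
    leaf-name frozenset to its gain count (missing branches gain 0).
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaf_names = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaf_names)) != len(leaf_names):
        raise ValueError("duplicate leaf names")
    nodes = list(tree.preorder_node_iter())
    clades: list[frozenset] = []
    for node in nodes:
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        clades.append(clade)
    if isinstance(gains_per_branch, dict):
        gains = [int(gains_per_branch.get(c, 0)) for c in clades]
    else:
        gains = [int(gains_per_branch)] * len(clades)
    if any(g < 0 for g in gains):
        raise ValueError("gains must be >= 0")
    total = sum(gains)
    pitch = element_width + element_gap
    if total * pitch > genome_length:
        raise ValueError("element supply exceeds genome length")
    rng = _rng(seed, "lineage")
    slot_order = rng.permutation(genome_length // pitch)[:total]
    intervals = [
        GenomicInterval(chrom, int(s) * pitch, int(s) * pitch + element_width)
        for s in slot_order
    ]
    branch_elements: dict[frozenset, list[GenomicInterval]] = {}
    cursor = 0
    per_leaf: dict[str, list[GenomicInterval]] = {name: [] for name in leaf_names}
    for clade, g in zip(clades, gains):
        elems = intervals[cursor : cursor + g]
        cursor += g
        if not elems:
            continue
        branch_elements.setdefault(clade, []).extend(elems)
        for name in clade:
            per_leaf[name].extend(elems)
    for name in leaf_names:
        per_leaf[name].sort()
    all_names = frozenset(leaf_names)
    bips = {
        frozenset((c, all_names - c))
        for c in clades
        if 2 <= len(c) <= len(all_names) - 2
    }
    truth = LineageTruth(newick, leaf_names, branch_elements, bips)
    return per_leaf, truth


# ---------------------------------------------------------------------------
# score tracks

def gen_score_track(
    regions_with_categories: list[tuple[GenomicInterval, int]],
    chrom_length: int,
    base: float = 0.1,
    slope: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SignalTrack:
    """Per-base score: base + slope * category_index inside each region,
    base outside, plus optional Gaussian noise."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    rng = _rng(seed, "scores")
    chrom = regions_with_categories[0][0].chrom if regions_with_categories else "chrS1"
    values = np.full(chrom_length, base)
    for iv, cat in regions_with_categories:
        values[iv.start : iv.end] = base + slope * cat
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=chrom_length)
    track = SignalTrack()
    track.add_array(chrom, 0, values)
    return track
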
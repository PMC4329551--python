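"""Genomic interval types and readers/writers for BED, bedGraph/wig and GTF.

Coordinate convention: BED style, 0-based half-open, everywhere in the
package. Conversion to/from other conventions happens only inside the I/O
functions in this module.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "TfbsRecord",
    "SignalTrack",
    "Gene",
    "GeneAnnotation",
    "BedFormatError",
    "read_bed",
    "write_bed",
    "read_signal_track",
    "write_bedgraph",
    "merge_intervals",
    "read_gene_annotation",
]


class BedFormatError(ValueError):
    """Raised for malformed interval text input; carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Interval midpoint, rounded down."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (abutting does not count)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TfbsRecord:
    """One transcription-factor binding site in one cell type.

    The site's point position (used as the kernel anchor) is the interval
    midpoint, rounded down.
    """

    interval: GenomicInterval
    tf_id: str
    cell_type: str = ""

    def __post_init__(self) -> None:
        if not self.tf_id:
            raise ValueError("tf_id must be non-empty")

    @property
    def position(self) -> int:
        return self.interval.midpoint


class SignalTrack:
    """Dense per-base numeric track keyed by chromosome.

    Bases never written read as 0. Overlapping input records are summed
    (tracks are additive read counts).
    """

    def __init__(self) -> None:
        self._data: dict[str, np.ndarray] = {}

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def chrom_length(self, chrom: str) -> int:
        arr = self._data.get(chrom)
        return 0 if arr is None else len(arr)

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        if start < 0 or start >= end:
            raise ValueError(f"bad span {start}-{end}")
        if not np.isfinite(value):
            raise ValueError(f"non-finite value {value}")
        arr = self._data.get(chrom)
        if arr is None or len(arr) < end:
            new = np.zeros(max(end, 2 * len(arr) if arr is not None else 0))
            if arr is not None:
                new[: len(arr)] = arr
            self._data[chrom] = new
            arr = new
        arr[start:end] += value

    def add_array(self, chrom: str, start: int, values: np.ndarray) -> None:
        """Add a dense block of per-base values starting at ``start``."""
        end = start + len(values)
        arr = self._data.get(chrom)
        if arr is None or len(arr) < end:
            new = np.zeros(max(end, 2 * len(arr) if arr is not None else 0))
            if arr is not None:
                new[: len(arr)] = arr
            self._data[chrom] = new
            arr = new
        arr[start:end] += values

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); bases outside the data are 0."""
        if start < 0 or start >= end:
            raise ValueError(f"bad span {start}-{end}")
        out = np.zeros(end - start)
        arr = self._data.get(chrom)
        if arr is None:
            return out
        lo, hi = start, min(end, len(arr))
        if hi > lo:
            out[: hi - lo] = arr[lo:hi]
        return out

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._data

    @property
    def total_signal(self) -> float:
        return float(sum(a.sum() for a in self._data.values()))


@dataclass
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: list[GenomicInterval] = field(default_factory=list)
    utr: list[GenomicInterval] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """5' end respecting strand (last base of the span on minus strand)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between merged exonic (CDS+UTR) blocks inside the gene span."""
        exonic = merge_intervals(self.cds + self.utr)
        out = []
        for a, b in zip(exonic, exonic[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start))
        return out


@dataclass
class GeneAnnotation:
    genes: list[Gene]

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    def tss_by_chrom(self) -> dict[str, tuple[np.ndarray, list[str]]]:
        """Per chrom: sorted TSS positions and matching gene ids."""
        out: dict[str, list[tuple[int, str]]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        return {
            c: (
                np.array([t for t, _ in sorted(v)], dtype=np.int64),
                [gid for _, gid in sorted(v)],
            )
            for c, v in out.items()
        }

    def feature_intervals(self, kind: str) -> list[GenomicInterval]:
        if kind == "cds":
            return [iv for g in self.genes for iv in g.cds]
        if kind == "utr":
            return [iv for g in self.genes for iv in g.utr]
        if kind == "intron":
            return [iv for g in self.genes for iv in g.introns]
        raise ValueError(f"unknown feature kind {kind!r}")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path, cell_type: str | None = None):
    """Read a BED3/BED4 file.

    With >= 4 columns the 4th column is taken as the TF id and a list of
    :class:`TfbsRecord` is returned (``cell_type`` defaults to the file
    stem); with 3 columns a list of :class:`GenomicInterval` is returned.
    Output is sorted by (chrom, start, end).
    """
    path = Path(path)
    if cell_type is None:
        cell_type = path.stem
    intervals: list[GenomicInterval] = []
    records: list[TfbsRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                iv = GenomicInterval(fields[0], start, end)
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
            if len(fields) >= 4 and fields[3]:
                records.append(TfbsRecord(iv, fields[3], cell_type))
            else:
                intervals.append(iv)
    if records and intervals:
        raise BedFormatError(f"{path}: mixed BED3 and BED4 lines")
    if records:
        records.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
        return records
    intervals.sort()
    return intervals


def write_bed(items: Iterable, path: str | Path) -> None:
    """Write intervals or TFBS records as BED3/BED4."""
    with open(path, "w") as fh:
        for it in items:
            if isinstance(it, TfbsRecord):
                iv = it.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{it.tf_id}\n")
            else:
                fh.write(f"{it.chrom}\t{it.start}\t{it.end}\n")


# ---------------------------------------------------------------------------
# bedGraph / wig

def read_signal_track(path: str | Path) -> SignalTrack:
    """Read a bedGraph or fixed/variable-step wiggle file.

    Overlapping records are summed. Wiggle ``span``/``step`` must be
    positive; wig positions are 1-based and converted to 0-based.
    """
    track = SignalTrack()
    mode = "bedgraph"
    chrom = ""
    step = span = 1
    pos = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                if step <= 0 or span <= 0:
                    raise BedFormatError(f"{path}:{lineno}: non-positive step/span")
                mode = "fixed"
                continue
            if line.startswith("variableStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
                if span <= 0:
                    raise BedFormatError(f"{path}:{lineno}: non-positive span")
                mode = "variable"
                continue
            fields = line.split()
            if mode == "fixed":
                track.add(chrom, pos, pos + span, float(fields[0]))
                pos += step
            elif mode == "variable":
                p = int(fields[0]) - 1
                track.add(chrom, p, p + span, float(fields[1]))
            else:
                if len(fields) < 4:
                    raise BedFormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
                try:
                    track.add(fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                except ValueError as exc:
                    raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
    return track


def write_bedgraph(track: SignalTrack, path: str | Path, precision: int = 6) -> None:
    """Write a track as run-length-encoded bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in track.chroms:
            vals = track.values(chrom, 0, track.chrom_length(chrom))
            if len(vals) == 0:
                continue
            # run-length boundaries
            change = np.nonzero(np.diff(vals))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.{precision}g}\n")


# ---------------------------------------------------------------------------
# interval algebra

def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted set of disjoint intervals covering the union.

    Abutting intervals merge (half-open adjacency counts as contiguous).
    """
    ivs = sorted(intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


# ---------------------------------------------------------------------------
# gene annotation

_GENE_ID_RE = re.compile(r'gene_id[ =]"?([^";]+)"?')


def read_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read gene structures from GTF/GFF (gene/CDS/UTR features) or BED12.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    Features falling outside their gene span are clamped with a warning.
    For BED12 input, thick region blocks are taken as CDS and thin block
    parts as UTR.
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    if first and len(first.split("\t")) >= 12 and first.split("\t")[6].isdigit():
        return _read_bed12(path)
    return _read_gtf(path)


def _read_gtf(path: Path) -> GeneAnnotation:
    genes: dict[str, Gene] = {}
    features: list[tuple[str, str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise BedFormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, kind, start1, end1, _, strand, _, attrs = f[:9]
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise BedFormatError(f"{path}:{lineno}: missing gene_id attribute")
            gid = m.group(1)
            iv = GenomicInterval(chrom, int(start1) - 1, int(end1))
            kind = kind.lower()
            if kind == "gene":
                genes[gid] = Gene(gid, chrom, iv.start, iv.end, strand)
            elif kind == "cds":
                features.append((gid, "cds", iv))
            elif kind in ("utr", "five_prime_utr", "three_prime_utr"):
                features.append((gid, "utr", iv))
    for gid, kind, iv in features:
        g = genes.get(gid)
        if g is None:
            warnings.warn(f"{kind} feature for unknown gene {gid}; skipped")
            continue
        if iv.start < g.start or iv.end > g.end:
            warnings.warn(f"{kind} of {gid} outside gene span; clamped")
            iv = GenomicInterval(iv.chrom, max(iv.start, g.start), min(iv.end, g.end))
        (g.cds if kind == "cds" else g.utr).append(iv)
    return GeneAnnotation(list(genes.values()))


def _read_bed12(path: Path) -> GeneAnnotation:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise BedFormatError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            g = Gene(name, chrom, start, end, strand)
            for size, off in zip(sizes, offsets):
                bs, be = start + off, start + off + size
                cs, ce = max(bs, thick_s), min(be, thick_e)
                if cs < ce:
                    g.cds.append(GenomicInterval(chrom, cs, ce))
                if bs < min(be, thick_s):
                    g.utr.append(GenomicInterval(chrom, bs, min(be, thick_s)))
                if max(bs, thick_e) < be:
                    g.utr.append(GenomicInterval(chrom, max(bs, thick_e), be))
            genes.append(g)
    return GeneAnnotation(genes)
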
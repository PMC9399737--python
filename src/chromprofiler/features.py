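"""Priority-based peak feature annotation and peak-set overlap.

Peaks (from an external broad-peak caller) are assigned to one of five
categories — Intergenic, 5UTR, 3UTR, Exon, Intron — by walking an ordered
priority list and taking the first category the peak overlaps by >= 1 bp.
The default priority puts Intergenic first, applied literally: any
intergenic bp wins.  This mirrors the annotator configuration the analysis
used; typical annotators resolve multi-category peaks differently, so the
priority is configurable.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, derive_introns
from .intervals import GenomicInterval

__all__ = [
    "CATEGORIES",
    "DEFAULT_PRIORITY",
    "Peak",
    "FeatureAssignment",
    "FeatureIndex",
    "build_feature_index",
    "annotate_peak",
    "feature_distribution",
    "peak_overlap_fraction",
    "read_peaks_bed",
    "write_peaks_bed",
]

CATEGORIES = ("Intergenic", "5UTR", "3UTR", "Exon", "Intron")
DEFAULT_PRIORITY = CATEGORIES


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    score: float | None = None
    name: str | None = None


@dataclass(frozen=True)
class FeatureAssignment:
    peak: Peak
    category: str
    overlaps: dict[str, int]


class FeatureIndex:
    """Merged, sorted interval arrays per category and chromosome."""

    def __init__(self, chrom_sizes: dict[str, int],
                 intervals: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]):
        self.chrom_sizes = chrom_sizes
        self.intervals = intervals

    def overlap_bp(self, category: str, chrom: str, start: int, end: int) -> int:
        per_chrom = self.intervals.get(category, {})
        if chrom not in per_chrom:
            return 0
        starts, ends = per_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return int(np.maximum(e - s, 0).sum())


def _merge(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    intervals.sort()
    starts, ends = [], []
    cs, ce = intervals[0]
    for s, e in intervals[1:]:
        if s <= ce:
            ce = max(ce, e)
        else:
            starts.append(cs)
            ends.append(ce)
            cs, ce = s, e
    starts.append(cs)
    ends.append(ce)
    return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)


def _subtract(a: tuple[np.ndarray, np.ndarray],
              b: tuple[np.ndarray, np.ndarray]) -> list[tuple[int, int]]:
    """Set difference a \\ b on merged interval arrays (single chromosome)."""
    out = []
    bs, be = b
    for s, e in zip(a[0].tolist(), a[1].tolist()):
        pos = s
        lo = np.searchsorted(be, s, side="right")
        hi = np.searchsorted(bs, e, side="left")
        for i in range(lo, hi):
            if bs[i] > pos:
                out.append((pos, int(bs[i])))
            pos = max(pos, int(be[i]))
        if pos < e:
            out.append((pos, e))
    return out


def build_feature_index(ann: GenomeAnnotation) -> FeatureIndex:
    """Category interval index: Exon = exonic bp not in an annotated UTR;
    Intron = derived introns; Intergenic = complement of all gene spans.
    UTR categories are populated only from explicit five_prime_utr /
    three_prime_utr features."""
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {
        c: {} for c in ("Exon", "Intron", "5UTR", "3UTR")
    }
    for g in ann.genes:
        for t in g.transcripts:
            for e in t.exons:
                raw["Exon"].setdefault(g.chrom, []).append((e.start, e.end))
            for i in derive_introns(t):
                raw["Intron"].setdefault(g.chrom, []).append((i.start, i.end))
            for u in t.utr5:
                raw["5UTR"].setdefault(g.chrom, []).append((u.start, u.end))
            for u in t.utr3:
                raw["3UTR"].setdefault(g.chrom, []).append((u.start, u.end))

    intervals: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {
        c: {} for c in CATEGORIES
    }
    for cat in ("Intron", "5UTR", "3UTR"):
        for chrom, ivs in raw[cat].items():
            intervals[cat][chrom] = _merge(ivs)
    # exonic bp minus UTR bp
    for chrom, ivs in raw["Exon"].items():
        exon = _merge(ivs)
        for cat in ("5UTR", "3UTR"):
            if chrom in intervals[cat]:
                exon = _merge(_subtract(exon, intervals[cat][chrom]))
        intervals["Exon"][chrom] = exon
    # intergenic: complement of gene spans over every chromosome
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in ann.chrom_sizes}
    for g in ann.genes:
        spans[g.chrom].append((g.span.start, g.span.end))
    for chrom, size in ann.chrom_sizes.items():
        whole = (np.array([0], dtype=np.int64), np.array([size], dtype=np.int64))
        inter = _subtract(whole, _merge(spans[chrom])) if spans[chrom] else [(0, size)]
        intervals["Intergenic"][chrom] = _merge(inter)
    return FeatureIndex(dict(ann.chrom_sizes), intervals)


def annotate_peak(
    peak: Peak, index: FeatureIndex, priority: tuple[str, ...] = DEFAULT_PRIORITY
) -> FeatureAssignment:
    """Assign the first category in *priority* order with >= 1 bp overlap."""
    if sorted(priority) != sorted(CATEGORIES):
        raise ValueError(f"priority must be a permutation of {CATEGORIES}")
    iv = peak.interval
    if iv.chrom not in index.chrom_sizes:
        raise ValueError(f"peak on unknown chromosome {iv.chrom}")
    overlaps = {
        c: index.overlap_bp(c, iv.chrom, iv.start, iv.end) for c in CATEGORIES
    }
    for cat in priority:
        if overlaps[cat] > 0:
            return FeatureAssignment(peak, cat, overlaps)
    # a peak always overlaps something (categories cover the genome), but be
    # safe against degenerate indexes
    return FeatureAssignment(peak, "Intergenic", overlaps)


def feature_distribution(
    peaks: list[Peak],
    index: FeatureIndex,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Fractions of peaks per category (sums to 1)."""
    if not peaks:
        raise ValueError("feature_distribution requires >= 1 peak")
    counts = {c: 0 for c in CATEGORIES}
    for p in peaks:
        counts[annotate_peak(p, index, priority).category] += 1
    n = len(peaks)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "fraction": [counts[c] / n for c in CATEGORIES],
        }
    )


def peak_overlap_fraction(a: list[Peak], b: list[Peak]) -> float:
    """Fraction of peaks in *a* overlapping (>= 1 bp) any peak in *b*
    (asymmetric)."""
    if not a or not b:
        raise ValueError("peak_overlap_fraction requires two nonempty peak sets")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in b:
        per_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end)
        )
    merged = {c: _merge(ivs) for c, ivs in per_chrom.items()}
    hits = 0
    for p in a:
        iv = p.interval
        if iv.chrom not in merged:
            continue
        starts, ends = merged[iv.chrom]
        lo = np.searchsorted(ends, iv.start, side="right")
        if lo < len(starts) and starts[lo] < iv.end:
            hits += 1
    return hits / len(a)


def read_peaks_bed(path: str | Path) -> list[Peak]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    peaks = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(str(row[0]), int(row[1]), int(row[2]))
        name = str(row[3]) if len(row) > 3 else None
        score = float(row[4]) if len(row) > 4 else None
        peaks.append(Peak(iv, score=score, name=name))
    return peaks


def write_peaks_bed(peaks: list[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name or '.'}"
                f"\t{p.score if p.score is not None else 0}\t{iv.strand}\n"
            )
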
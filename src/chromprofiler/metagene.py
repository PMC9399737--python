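"""Scaled metagene profiles (TSS-2kb .. TES+2kb mapped onto 500 bins).

Each admissible gene is mapped onto a common coordinate: 100 fixed-width
20 bp bins upstream of the TSS, 300 bins that partition the gene body into
near-equal contiguous pieces, and 100 fixed-width bins downstream of the TES;
for minus-strand genes the bin list is orientation-reversed so index 0 is
always biologically upstream.  The profile averages the per-bin mean signal
with equal gene weighting.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Gene
from .coverage import CoverageTrack
from .intervals import GenomicInterval

__all__ = ["BinScheme", "MetageneProfile", "bin_gene", "metagene_profile",
           "body_skew", "write_profile_tsv"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinScheme:
    """flank bp split into flank_bins fixed bins; gene body into body_bins."""

    flank: int = 2000
    flank_bins: int = 100
    body_bins: int = 300

    def __post_init__(self) -> None:
        if self.flank % self.flank_bins:
            raise ValueError("flank must be a multiple of flank_bins")
        if min(self.flank, self.flank_bins, self.body_bins) <= 0:
            raise ValueError("scheme parameters must be positive")

    @property
    def bin_width(self) -> int:
        return self.flank // self.flank_bins

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    @property
    def min_gene_length(self) -> int:
        # every body bin must be >= 2 bp wide
        return 2 * self.body_bins


DEFAULT_SCHEME = BinScheme()


@dataclass
class MetageneProfile:
    values: np.ndarray          # length n_bins, per-bin mean over genes
    n_genes: int
    scheme: BinScheme
    tag: str = "raw"
    bin_counts: np.ndarray = field(default=None)  # genes contributing per bin

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != self.scheme.n_bins:
            raise ValueError("profile length does not match the bin scheme")
        if self.bin_counts is None:
            self.bin_counts = np.full(len(self.values), self.n_genes)


def _gene_boundaries(gene: Gene, scheme: BinScheme) -> np.ndarray:
    """501 genomic boundaries (left flank, body, right flank), + orientation."""
    start, end = gene.span.start, gene.span.end
    L = end - start
    if L < scheme.min_gene_length:
        raise ValueError(
            f"gene {gene.id} is {L} bp, shorter than the "
            f"{scheme.min_gene_length} bp minimum for {scheme.body_bins} body bins"
        )
    w = scheme.bin_width
    left = start - scheme.flank + w * np.arange(scheme.flank_bins)
    i = np.arange(scheme.body_bins + 1, dtype=np.float64)
    body = start + np.floor(i * L / scheme.body_bins + 0.5).astype(np.int64)
    right = end + w * np.arange(1, scheme.flank_bins + 1)
    return np.concatenate([left, body, right])


def bin_gene(
    gene: Gene,
    scheme: BinScheme = DEFAULT_SCHEME,
    chrom_size: int | None = None,
) -> list[GenomicInterval | None]:
    """The gene's bins as genomic intervals, index 0 biologically upstream.

    Body bin boundaries are ``round(i * L / body_bins)`` so widths differ by
    at most 1 bp (>= 2 bp for genes passing the 600 bp filter).  Flank bins
    are clipped at chromosome bounds; a bin left empty by clipping is
    returned as ``None``.
    """
    bounds = _gene_boundaries(gene, scheme)
    starts, ends = bounds[:-1], bounds[1:]
    bins: list[GenomicInterval | None] = []
    hi = chrom_size if chrom_size is not None else math.inf
    for s, e in zip(starts.tolist(), ends.tolist()):
        s = max(0, s)
        e = min(hi, e)
        bins.append(GenomicInterval(gene.chrom, int(s), int(e), gene.strand)
                    if e > s else None)
    if gene.strand == "-":
        bins.reverse()
    return bins


def metagene_profile(
    track: CoverageTrack,
    genes: list[Gene],
    scheme: BinScheme = DEFAULT_SCHEME,
) -> MetageneProfile:
    """Average per-bin mean signal over *genes* (equal gene weighting).

    ``values[k]`` is the mean over genes of the length-weighted mean signal in
    bin k; bins fully clipped off the chromosome are excluded from that bin's
    average (tracked in ``bin_counts``).
    """
    if not genes:
        raise ValueError("metagene_profile requires at least one gene")
    n = scheme.n_bins
    total = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    n_used = 0
    for gene in genes:
        size = track.chrom_sizes.get(gene.chrom)
        if size is None:
            raise ValueError(f"gene {gene.id} on unknown chromosome {gene.chrom}")
        if gene.span.end + scheme.flank <= 0 or gene.span.start - scheme.flank >= size:
            logger.warning("dropping gene %s: bin window entirely off-chromosome",
                           gene.id)
            continue
        bounds = _gene_boundaries(gene, scheme)
        means = track.means(gene.chrom, bounds[:-1], bounds[1:])
        if gene.strand == "-":
            means = means[::-1]
        ok = ~np.isnan(means)
        total[ok] += means[ok]
        counts += ok
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable genes for metagene profile")
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return MetageneProfile(values=values, n_genes=n_used, scheme=scheme,
                           tag=track.tag, bin_counts=counts)


def body_skew(profile: MetageneProfile, eps: float = 0.5) -> float:
    """log2 ratio of mean signal in the 5' half of the gene body over the 3'
    half (pseudocount *eps*); positive values mean 5'-heavy profiles."""
    s = profile.scheme
    body = profile.values[s.flank_bins: s.flank_bins + s.body_bins]
    half = s.body_bins // 2
    m5 = float(np.mean(body[:half]))
    m3 = float(np.mean(body[half: 2 * half]))
    return math.log2((m5 + eps) / (m3 + eps))


def write_profile_tsv(profile: MetageneProfile, path: str | Path) -> None:
    s = profile.scheme
    region = (["upstream"] * s.flank_bins + ["body"] * s.body_bins
              + ["downstream"] * s.flank_bins)
    pd.DataFrame(
        {
            "bin_index": np.arange(s.n_bins),
            "region": region,
            "mean_signal": profile.values,
            "n_genes": profile.bin_counts,
        }
    ).to_csv(path, sep="\t", index=False)
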
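"""Signal tracks: read pileup, RPM / spike-in normalization, queries, ratios.

Normalization follows the exogenous-spike-in scheme: reads from a fixed
proportion of foreign (e.g. Drosophila) chromatin are sequenced alongside the
sample, and every track value is scaled by ``1e6 / reads aligned to the
spike-in genome`` (or ``1e6 / reads aligned to the primary genome`` for plain
RPM).  A :class:`CoverageTrack` is a per-chromosome stepwise function stored
run-length encoded; bedGraph is the canonical on-disk form.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "ReadRecord",
    "ReadSet",
    "AlignmentSummary",
    "NormalizationFactors",
    "NormalizationError",
    "CoverageTrack",
    "compute_factors",
    "reads_to_coverage",
    "mean_signal",
    "sum_signal",
    "ratio_track",
    "read_bedgraph",
    "write_bedgraph",
    "read_reads_bed",
    "write_reads_bed",
]


@dataclass(frozen=True)
class ReadRecord:
    """A single-end read, reduced to its 5' end position and strand.

    For ``+`` reads ``five_prime_pos`` is the 0-based position of the 5'-most
    covered base; for ``-`` reads it is the half-open (exclusive) coordinate
    of the 5' terminus, matching BED's ``end`` convention, so a ``-`` read at
    position p extended to ``ext`` bp covers ``[p - ext, p)``.
    """

    chrom: str
    five_prime_pos: int
    strand: str = "+"


class ReadSet:
    """Column-oriented container of reads (fast path for large simulations)."""

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray]] | None = None):
        # chrom -> (positions int64, plus_strand bool)
        self.data = data or {}

    @classmethod
    def from_records(cls, records: Iterable[ReadRecord]) -> "ReadSet":
        per: dict[str, list] = {}
        for r in records:
            per.setdefault(r.chrom, []).append((r.five_prime_pos, r.strand != "-"))
        return cls(
            {
                c: (
                    np.array([p for p, _ in v], dtype=np.int64),
                    np.array([s for _, s in v], dtype=bool),
                )
                for c, v in per.items()
            }
        )

    def __iter__(self) -> Iterator[ReadRecord]:
        for chrom in sorted(self.data):
            pos, plus = self.data[chrom]
            for p, s in zip(pos.tolist(), plus.tolist()):
                yield ReadRecord(chrom, p, "+" if s else "-")

    def __len__(self) -> int:
        return sum(len(pos) for pos, _ in self.data.values())


@dataclass(frozen=True)
class AlignmentSummary:
    """Read counts aligned to the primary and spike-in genomes."""

    n_primary: int
    n_spikein: int = 0

    def __post_init__(self) -> None:
        if self.n_primary < 0 or self.n_spikein < 0:
            raise ValueError("alignment counts must be >= 0")


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-read scale factors, plus the raw counts they came from.

    Scaling via ``(depth / count) * 1e6`` instead of ``depth * factor`` keeps
    spike-in-normalized tracks bit-exactly invariant under integer c-fold
    duplication of reads and counts, so the counts are kept when known.
    """

    rpm: float | None = None
    spikein: float | None = None
    n_primary: int | None = None
    n_spikein: int | None = None

    def count_for(self, mode: str) -> int | None:
        return self.n_primary if mode == "rpm" else self.n_spikein


class NormalizationError(ValueError):
    pass


def compute_factors(s: AlignmentSummary) -> NormalizationFactors:
    """Per-read scale factors: ``rpm = 1e6 / n_primary`` and
    ``spikein = 1e6 / n_spikein``.  A zero count leaves that factor undefined
    only if the other is usable; requesting it later raises."""
    if s.n_primary <= 0:
        raise NormalizationError(
            "RPM factor undefined: zero reads aligned to the primary genome"
        )
    spike = None
    if s.n_spikein > 0:
        spike = 1e6 / s.n_spikein
    return NormalizationFactors(
        rpm=1e6 / s.n_primary,
        spikein=spike,
        n_primary=s.n_primary,
        n_spikein=s.n_spikein if s.n_spikein > 0 else None,
    )


class CoverageTrack:
    """Per-chromosome stepwise signal, run-length encoded.

    For each chromosome the track stores ``bounds`` (int64, length k+1,
    ``bounds[0] == 0`` and ``bounds[-1] == chrom length``) and ``values``
    (float64, length k).  Chromosomes absent from ``data`` are all-zero.
    """

    def __init__(
        self,
        chrom_sizes: dict[str, int],
        data: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
        tag: str = "raw",
    ):
        self.chrom_sizes = dict(chrom_sizes)
        self.tag = tag
        self.data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (bounds, values) in (data or {}).items():
            self._set(chrom, np.asarray(bounds, dtype=np.int64),
                      np.asarray(values, dtype=np.float64))

    # -- construction -------------------------------------------------------

    def _set(self, chrom: str, bounds: np.ndarray, values: np.ndarray) -> None:
        size = self.chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"unknown chromosome {chrom}")
        if bounds[0] != 0 or bounds[-1] != size or len(values) != len(bounds) - 1:
            raise ValueError(f"track runs must partition [0, {size}) on {chrom}")
        if np.any(np.diff(bounds) <= 0):
            raise ValueError(f"track bounds must be strictly increasing on {chrom}")
        bounds, values = _compress(bounds, values)
        self.data[chrom] = (bounds, values)
        widths = np.diff(bounds).astype(np.float64)
        self._cum[chrom] = np.concatenate([[0.0], np.cumsum(values * widths)])

    @classmethod
    def from_dense(
        cls, chrom_sizes: dict[str, int], dense: dict[str, np.ndarray], tag: str = "raw"
    ) -> "CoverageTrack":
        data = {}
        for chrom, arr in dense.items():
            arr = np.asarray(arr, dtype=np.float64)
            if len(arr) != chrom_sizes[chrom]:
                raise ValueError(f"dense array length mismatch on {chrom}")
            change = np.flatnonzero(np.diff(arr)) + 1
            bounds = np.concatenate([[0], change, [len(arr)]]).astype(np.int64)
            data[chrom] = (bounds, arr[bounds[:-1]])
        return cls(chrom_sizes, data, tag=tag)

    @classmethod
    def from_intervals(
        cls,
        chrom_sizes: dict[str, int],
        intervals: Iterable[tuple[str, int, int, float]],
        tag: str = "raw",
    ) -> "CoverageTrack":
        """Build from (chrom, start, end, value) runs; gaps are zero.
        Overlapping runs are an error (a track is a function)."""
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            per.setdefault(chrom, []).append((int(start), int(end), float(value)))
        data = {}
        for chrom, runs in per.items():
            runs.sort()
            size = chrom_sizes[chrom]
            bounds = [0]
            values = []
            pos = 0
            for start, end, value in runs:
                if start < pos:
                    raise ValueError(
                        f"overlapping intervals on {chrom} at {start} (previous end {pos})"
                    )
                if end > size:
                    raise ValueError(f"interval [{start},{end}) beyond {chrom} ({size} bp)")
                if start > pos:
                    bounds.append(start)
                    values.append(0.0)
                bounds.append(end)
                values.append(value)
                pos = end
            if pos < size:
                bounds.append(size)
                values.append(0.0)
            data[chrom] = (np.array(bounds, dtype=np.int64), np.array(values))
        return cls(chrom_sizes, data, tag=tag)

    @classmethod
    def uniform(cls, chrom_sizes: dict[str, int], value: float, tag: str = "raw"):
        data = {
            c: (np.array([0, size], dtype=np.int64), np.array([float(value)]))
            for c, size in chrom_sizes.items()
        }
        return cls(chrom_sizes, data, tag=tag)

    # -- queries ------------------------------------------------------------

    def _chrom_arrays(self, chrom: str):
        if chrom not in self.chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom}")
        if chrom not in self.data:
            size = self.chrom_sizes[chrom]
            return (
                np.array([0, size], dtype=np.int64),
                np.array([0.0]),
                np.array([0.0, 0.0]),
            )
        bounds, values = self.data[chrom]
        return bounds, values, self._cum[chrom]

    def integrals(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorized ``integral of track over [start, end)`` (value * bp).
        Query coordinates are clipped to the chromosome."""
        bounds, values, cum = self._chrom_arrays(chrom)
        size = self.chrom_sizes[chrom]
        starts = np.clip(np.asarray(starts, dtype=np.int64), 0, size)
        ends = np.clip(np.asarray(ends, dtype=np.int64), 0, size)

        def cum_at(pos):
            idx = np.searchsorted(bounds, pos, side="right") - 1
            idx = np.clip(idx, 0, len(values) - 1)
            return cum[idx] + values[idx] * (pos - bounds[idx])

        out = cum_at(ends) - cum_at(starts)
        return np.where(ends > starts, out, 0.0)

    def means(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorized length-weighted means; empty (fully clipped) intervals
        yield NaN."""
        size = self.chrom_sizes[chrom]
        s = np.clip(np.asarray(starts, dtype=np.int64), 0, size)
        e = np.clip(np.asarray(ends, dtype=np.int64), 0, size)
        width = (e - s).astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.integrals(chrom, s, e) / width
        return np.where(width > 0, out, np.nan)

    def integral(self, iv: GenomicInterval) -> float:
        return float(self.integrals(iv.chrom, [iv.start], [iv.end])[0])

    def mean(self, iv: GenomicInterval) -> float:
        return float(self.means(iv.chrom, [iv.start], [iv.end])[0])

    @property
    def total_integral(self) -> float:
        return float(sum(cum[-1] for cum in self._cum.values()))

    # -- transforms ---------------------------------------------------------

    def scale(self, factor: float, tag: str | None = None) -> "CoverageTrack":
        data = {c: (b.copy(), v * factor) for c, (b, v) in self.data.items()}
        return CoverageTrack(self.chrom_sizes, data, tag=tag or self.tag)

    def runs(self, chrom: str):
        bounds, values, _ = self._chrom_arrays(chrom)
        return bounds, values

    def __eq__(self, other) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if self.chrom_sizes != other.chrom_sizes:
            return False
        for chrom in self.chrom_sizes:
            b1, v1 = self.runs(chrom)
            b2, v2 = other.runs(chrom)
            if not (np.array_equal(b1, b2) and np.array_equal(v1, v2)):
                return False
        return True


def _compress(bounds: np.ndarray, values: np.ndarray):
    """Merge adjacent runs with equal values (canonical form)."""
    if len(values) <= 1:
        return bounds, values
    keep = np.concatenate([[True], values[1:] != values[:-1]])
    new_values = values[keep]
    starts = bounds[:-1][keep]
    new_bounds = np.concatenate([starts, bounds[-1:]])
    return new_bounds, new_values


# ---------------------------------------------------------------------------
# Pileup and normalization
# ---------------------------------------------------------------------------

def reads_to_coverage(
    reads: ReadSet | Iterable[ReadRecord],
    chrom_sizes: dict[str, int],
    ext: int = 150,
    factors: NormalizationFactors | None = None,
    mode: str = "raw",
) -> CoverageTrack:
    """Pile up reads extended to *ext* bp from their 5' end in the read-strand
    direction, clipped at chromosome bounds, scaled by the selected
    normalization factor (x1 for ``raw``).
    """
    if ext <= 0:
        raise ValueError("ext must be > 0")
    if mode not in ("raw", "rpm", "spikein"):
        raise ValueError(f"unknown mode {mode!r}")
    count = None
    if mode == "raw":
        factor = 1.0
    else:
        if factors is None:
            raise NormalizationError(f"mode {mode!r} requires normalization factors")
        factor = getattr(factors, mode)
        if factor is None:
            raise NormalizationError(
                f"{mode} factor undefined: zero reads aligned to the "
                f"{'spike-in' if mode == 'spikein' else 'primary'} genome"
            )
        count = factors.count_for(mode)
    if not isinstance(reads, ReadSet):
        reads = ReadSet.from_records(reads)

    data = {}
    for chrom, (pos, plus) in reads.data.items():
        size = chrom_sizes.get(chrom)
        if size is None:
            raise ValueError(f"read on unknown chromosome {chrom}")
        if len(pos):
            # + reads: 5' base at pos must lie on the chromosome;
            # - reads: pos is the exclusive 5' coordinate, valid in (0, size]
            bad_plus = plus & ((pos < 0) | (pos >= size))
            bad_minus = ~plus & ((pos <= 0) | (pos > size))
            if (bad_plus | bad_minus).any():
                raise ValueError(f"read 5' position outside chromosome {chrom}")
        starts = np.where(plus, pos, pos - ext)
        ends = starts + ext
        starts = np.clip(starts, 0, size)
        ends = np.clip(ends, 0, size)
        diff = np.zeros(size + 1, dtype=np.float64)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        dense = np.cumsum(diff[:-1])
        change = np.flatnonzero(np.diff(dense)) + 1
        bounds = np.concatenate([[0], change, [size]]).astype(np.int64)
        values = dense[bounds[:-1]]
        if count is not None:
            values = (values / count) * 1e6  # duplication-exact scaling
        else:
            values = values * factor
        data[chrom] = (bounds, values)
    return CoverageTrack(chrom_sizes, data, tag=mode)


def mean_signal(track: CoverageTrack, iv: GenomicInterval) -> float:
    """Length-weighted mean of the stepwise track over *iv*."""
    return track.mean(iv)


def sum_signal(track: CoverageTrack, iv: GenomicInterval) -> float:
    """Integral (value x bp) of the track over *iv*."""
    return track.integral(iv)


def ratio_track(num: CoverageTrack, den: CoverageTrack, eps: float = 0.5) -> CoverageTrack:
    """Run-wise ``(num + eps) / (den + eps)``; *eps* is the pseudocount that
    keeps zero-coverage regions finite (0/0 -> 1)."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if num.chrom_sizes != den.chrom_sizes:
        raise ValueError("ratio_track requires the same chromosome universe")
    data = {}
    for chrom in num.chrom_sizes:
        b1, v1 = num.runs(chrom)
        b2, v2 = den.runs(chrom)
        bounds = np.union1d(b1, b2)
        mids = bounds[:-1]
        nv = v1[np.searchsorted(b1, mids, side="right") - 1]
        dv = v2[np.searchsorted(b2, mids, side="right") - 1]
        data[chrom] = (bounds, (nv + eps) / (dv + eps))
    return CoverageTrack(num.chrom_sizes, data, tag="ratio")


# ---------------------------------------------------------------------------
# I/O: bedGraph (canonical text form) and BED reads
# ---------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path: str | Path, write_zero: bool = False) -> None:
    """Write non-zero runs as 4-column bedGraph (0-based half-open).  Values
    are written with full round-trip precision."""
    with open(path, "w") as fh:
        for chrom in sorted(track.chrom_sizes):
            bounds, values = track.runs(chrom)
            for s, e, v in zip(bounds[:-1].tolist(), bounds[1:].tolist(), values.tolist()):
                if v != 0.0 or write_zero:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


def read_bedgraph(
    path: str | Path,
    chrom_sizes: dict[str, int] | None = None,
    tag: str = "raw",
) -> CoverageTrack:
    """Read a bedGraph into a track.  Unsorted input is accepted and sorted;
    overlapping intervals are an error.  Without *chrom_sizes*, each
    chromosome's size defaults to its maximum end coordinate."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
        comment="#",
        header=None,
        float_precision="round_trip",  # bit-exact round trip of written values
    )
    df = df[~df["chrom"].str.startswith(("track", "browser"))]
    if chrom_sizes is None:
        chrom_sizes = df.groupby("chrom")["end"].max().astype(int).to_dict()
    return CoverageTrack.from_intervals(
        chrom_sizes,
        df[["chrom", "start", "end", "value"]].itertuples(index=False, name=None),
        tag=tag,
    )


def write_reads_bed(reads: ReadSet | Iterable[ReadRecord], path: str | Path,
                    read_len: int = 50) -> None:
    """Write reads as BED6; the BED interval is the sequenced read (length
    *read_len* from the 5' end in strand direction)."""
    if not isinstance(reads, ReadSet):
        reads = ReadSet.from_records(reads)
    with open(path, "w") as fh:
        for chrom in sorted(reads.data):
            pos, plus = reads.data[chrom]
            starts = np.where(plus, pos, np.maximum(pos - read_len, 0))
            ends = np.where(plus, pos + read_len, pos)
            for s, e, p in zip(starts.tolist(), ends.tolist(), plus.tolist()):
                fh.write(f"{chrom}\t{s}\t{e}\tread\t0\t{'+' if p else '-'}\n")


def read_reads_bed(path: str | Path) -> ReadSet:
    """Read BED6 reads; the 5' end is the BED start for + reads and the BED
    end (exclusive) for - reads."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
        header=None,
    )
    data = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        plus = (sub["strand"] != "-").to_numpy()
        pos = np.where(plus, sub["start"].to_numpy(), sub["end"].to_numpy())
        data[str(chrom)] = (pos.astype(np.int64), plus)
    return ReadSet(data)
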
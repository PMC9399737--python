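"""Gene models: GTF I/O, intron derivation and the two selection filters.

The two selection procedures implemented here are the ones the downstream
analyses depend on:

* :func:`select_metagene_genes` — protein-coding genes of span length
  >= 600 bp with no other annotated gene within 2 kb of the TSS or TES
  (the substrate of metagene profiles);
* :func:`select_exon_transcripts` — the longest transcript per
  protein-coding gene, with every transcript whose span overlaps another
  selected transcript's span (strand ignored) removed, both members of each
  overlapping pair (the substrate of exon/intron enrichment scores).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval

__all__ = [
    "Transcript",
    "Gene",
    "GenomeAnnotation",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "write_bed6",
    "derive_introns",
    "select_metagene_genes",
    "select_exon_transcripts",
]

PROTEIN_CODING = "protein_coding"
LNCRNA = "lncRNA"


class GtfParseError(ValueError):
    """Raised for malformed GTF input; the message names the line number."""


@dataclass(frozen=True)
class Transcript:
    """A transcript: an ordered, non-overlapping exon chain on one strand."""

    id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = PROTEIN_CODING
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        chrom = self.exons[0].chrom
        strand = self.exons[0].strand
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != chrom or ex.strand != strand:
                raise ValueError(
                    f"transcript {self.id}: exons must share one chromosome/strand"
                )
            if ex.start < prev_end:
                raise ValueError(
                    f"transcript {self.id}: exons must be sorted and non-overlapping"
                )
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass(frozen=True)
class Gene:
    id: str
    span: GenomicInterval
    biotype: str
    transcripts: tuple[Transcript, ...] = ()

    def __post_init__(self) -> None:
        for t in self.transcripts:
            s = t.span
            if s.start < self.span.start or s.end > self.span.end:
                raise ValueError(
                    f"gene {self.id}: transcript {t.id} extends beyond gene span"
                )

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        """Transcription start site (5' end of the span, strand-aware)."""
        return self.span.start if self.strand != "-" else self.span.end

    @property
    def tes(self) -> int:
        return self.span.end if self.strand != "-" else self.span.start

    @property
    def length(self) -> int:
        return self.span.length


@dataclass
class GenomeAnnotation:
    """A set of genes plus the chromosome-size universe they live in."""

    chrom_sizes: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"gene {g.id} on unknown chromosome {g.chrom}")
            if g.span.end > size:
                raise ValueError(
                    f"gene {g.id} extends beyond chromosome {g.chrom} ({size} bp)"
                )
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.span.start, g.id))

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def transcripts(self) -> list[Transcript]:
        return [t for g in self.genes for t in g.transcripts]


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect: gene_id / transcript_id / gene_biotype attributes)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attrs(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path, chrom_sizes: dict[str, int] | None = None) -> GenomeAnnotation:
    """Parse an Ensembl-dialect GTF into a :class:`GenomeAnnotation`.

    GTF is 1-based with closed intervals; coordinates are converted to the
    internal 0-based half-open convention.  ``gene``/``transcript`` feature
    lines are optional — spans and biotypes are inferred from exon lines when
    absent.  When *chrom_sizes* is not given, each chromosome's size defaults
    to the maximum annotated end coordinate.
    """
    genes_meta: dict[str, dict] = {}
    tx_meta: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    utr5: dict[str, list[GenomicInterval]] = {}
    utr3: dict[str, list[GenomicInterval]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start = int(start_s) - 1  # GTF 1-based closed -> 0-based half-open
                end = int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if end <= start:
                raise GtfParseError(f"{path}: line {lineno}: empty interval")
            attrs = _parse_attrs(attrs_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GtfParseError(f"{path}: line {lineno}: missing gene_id attribute")
            biotype = attrs.get("gene_biotype", "")

            if feature == "gene":
                genes_meta[gene_id] = {
                    "iv": GenomicInterval(chrom, start, end, strand),
                    "biotype": biotype,
                }
                continue

            tid = attrs.get("transcript_id")
            if feature in ("exon", "five_prime_utr", "three_prime_utr", "transcript"):
                if tid is None:
                    raise GtfParseError(
                        f"{path}: line {lineno}: {feature} lacks transcript_id"
                    )
                meta = tx_meta.setdefault(tid, {"gene_id": gene_id, "biotype": biotype})
                if biotype and not meta["biotype"]:
                    meta["biotype"] = biotype
                iv = GenomicInterval(chrom, start, end, strand)
                if feature == "exon":
                    exons.setdefault(tid, []).append(iv)
                elif feature == "five_prime_utr":
                    utr5.setdefault(tid, []).append(iv)
                elif feature == "three_prime_utr":
                    utr3.setdefault(tid, []).append(iv)
            # other feature kinds (CDS, start_codon, ...) are ignored

    for tid in list(tx_meta):
        if tid not in exons:
            del tx_meta[tid]  # transcript line without exons: drop

    tx_by_gene: dict[str, list[Transcript]] = {}
    for tid, meta in tx_meta.items():
        t = Transcript(
            id=tid,
            gene_id=meta["gene_id"],
            exons=tuple(sorted(exons[tid], key=lambda e: e.start)),
            biotype=meta["biotype"],
            utr5=tuple(sorted(utr5.get(tid, []), key=lambda e: e.start)),
            utr3=tuple(sorted(utr3.get(tid, []), key=lambda e: e.start)),
        )
        tx_by_gene.setdefault(meta["gene_id"], []).append(t)

    genes: list[Gene] = []
    for gid in sorted(set(genes_meta) | set(tx_by_gene)):
        txs = sorted(tx_by_gene.get(gid, []), key=lambda t: t.id)
        if gid in genes_meta:
            iv = genes_meta[gid]["iv"]
            biotype = genes_meta[gid]["biotype"]
        else:
            if not txs:
                continue
            iv = GenomicInterval(
                txs[0].chrom,
                min(t.span.start for t in txs),
                max(t.span.end for t in txs),
                txs[0].strand,
            )
            biotype = txs[0].biotype
        genes.append(Gene(id=gid, span=iv, biotype=biotype, transcripts=tuple(txs)))

    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.span.end)
    return GenomeAnnotation(chrom_sizes=dict(chrom_sizes), genes=genes)


def write_gtf(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write gene/transcript/exon (+UTR) lines, converting back to GTF 1-based."""

    def line(chrom, feature, iv, attrs):
        attr_s = " ".join(f'{k} "{v}";' for k, v in attrs)
        return (
            f"{chrom}\tchromprofiler\t{feature}\t{iv.start + 1}\t{iv.end}\t."
            f"\t{iv.strand}\t.\t{attr_s}\n"
        )

    with open(path, "w") as fh:
        for g in ann.genes:
            base = [("gene_id", g.id), ("gene_biotype", g.biotype)]
            fh.write(line(g.chrom, "gene", g.span, base))
            for t in g.transcripts:
                tattrs = [
                    ("gene_id", g.id),
                    ("transcript_id", t.id),
                    ("gene_biotype", g.biotype),
                ]
                fh.write(line(g.chrom, "transcript", t.span, tattrs))
                for ex in t.exons:
                    fh.write(line(g.chrom, "exon", ex, tattrs))
                for u in t.utr5:
                    fh.write(line(g.chrom, "five_prime_utr", u, tattrs))
                for u in t.utr3:
                    fh.write(line(g.chrom, "three_prime_utr", u, tattrs))


def write_bed6(items: Iterable, path: str | Path) -> None:
    """Write genes/transcripts/intervals as BED6 (name=id, score=0)."""
    with open(path, "w") as fh:
        for item in items:
            iv = item.span if hasattr(item, "span") else item
            name = getattr(item, "id", ".")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Derived structure and selection filters
# ---------------------------------------------------------------------------

def derive_introns(t: Transcript) -> list[GenomicInterval]:
    """Gaps between consecutive exons; zero-length gaps (abutting exons) are
    not introns."""
    introns = []
    for a, b in zip(t.exons, t.exons[1:]):
        if b.start > a.end:
            introns.append(GenomicInterval(t.chrom, a.end, b.start, t.strand))
    return introns


def select_metagene_genes(
    ann: GenomeAnnotation, min_len: int = 600, flank: int = 2000
) -> list[Gene]:
    """Protein-coding genes with span >= *min_len* bp whose +-*flank* window
    (clipped at chromosome bounds) intersects no other gene's span, any
    biotype, either strand.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    selected: list[Gene] = []
    by_chrom: dict[str, list[Gene]] = {}
    for g in ann.genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, genes in by_chrom.items():
        size = ann.chrom_sizes[chrom]
        starts = np.array([g.span.start for g in genes])
        ends = np.array([g.span.end for g in genes])
        for i, g in enumerate(genes):
            if g.biotype != PROTEIN_CODING or g.length < min_len:
                continue
            wstart = max(0, g.span.start - flank)
            wend = min(size, g.span.end + flank)
            hit = (starts < wend) & (ends > wstart)
            hit[i] = False
            if not hit.any():
                selected.append(g)
    return sorted(selected, key=lambda g: (g.chrom, g.span.start, g.id))


def longest_transcript(gene: Gene) -> Transcript | None:
    """The transcript with maximal span length; ties break to the
    lexicographically smallest id."""
    if not gene.transcripts:
        return None
    return min(gene.transcripts, key=lambda t: (-t.span.length, t.id))


def select_exon_transcripts(ann: GenomeAnnotation) -> list[Transcript]:
    """Longest transcript per protein-coding gene, then drop every transcript
    whose span overlaps any other selected transcript's span (strand ignored).
    Both members of an overlapping pair are removed.
    """
    picked: list[Transcript] = []
    for g in ann.genes:
        if g.biotype != PROTEIN_CODING:
            continue
        t = longest_transcript(g)
        if t is not None:
            picked.append(t)
    picked.sort(key=lambda t: (t.chrom, t.span.start, t.id))

    keep: list[Transcript] = []
    by_chrom: dict[str, list[Transcript]] = {}
    for t in picked:
        by_chrom.setdefault(t.chrom, []).append(t)
    for txs in by_chrom.values():
        starts = np.array([t.span.start for t in txs])
        ends = np.array([t.span.end for t in txs])
        # sorted by start: t_i overlaps an earlier transcript iff some earlier
        # end exceeds starts[i]; overlaps a later one iff starts[i+1] < ends[i]
        run_max = np.maximum.accumulate(ends)
        earlier = np.zeros(len(txs), dtype=bool)
        earlier[1:] = starts[1:] < run_max[:-1]
        later = np.zeros(len(txs), dtype=bool)
        later[:-1] = starts[1:] < ends[:-1]
        for t, bad in zip(txs, earlier | later):
            if not bad:
                keep.append(t)
    return sorted(keep, key=lambda t: (t.chrom, t.span.start, t.id))


def transcript_gene_map(transcripts: Sequence[Transcript]) -> dict[str, str]:
    return {t.id: t.gene_id for t in transcripts}
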
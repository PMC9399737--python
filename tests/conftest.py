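import numpy as np
import pytest

from chromprofiler.annotation import Gene, GenomeAnnotation, Transcript
from chromprofiler.intervals import GenomicInterval
from chromprofiler.synth import (
    SignalSpec,
    SyntheticGenomeSpec,
    generate_annotation,
    generate_coverage,
)


def make_transcript(tid, gene_id, chrom, strand, exon_coords, biotype="protein_coding",
                    utr5=(), utr3=()):
    return Transcript(
        id=tid,
        gene_id=gene_id,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_coords),
        biotype=biotype,
        utr5=tuple(GenomicInterval(chrom, s, e, strand) for s, e in utr5),
        utr3=tuple(GenomicInterval(chrom, s, e, strand) for s, e in utr3),
    )


def make_gene(gid, chrom, start, end, strand="+", biotype="protein_coding",
              transcripts=()):
    return Gene(
        id=gid,
        span=GenomicInterval(chrom, start, end, strand),
        biotype=biotype,
        transcripts=tuple(transcripts),
    )


@pytest.fixture(scope="session")
def synth_spec():
    return SyntheticGenomeSpec(seed=3)


@pytest.fixture(scope="session")
def synth_ann(synth_spec):
    ann, truth = generate_annotation(synth_spec)
    return ann, truth


@pytest.fixture(scope="session")
def noiseless_cov(synth_ann):
    ann, _ = synth_ann
    return generate_coverage(ann, SignalSpec(rho=3.0, gamma=0.0, noise="none"))


@pytest.fixture()
def simple_gene():
    """An isolated + strand 2-exon gene: exons [10000,10400) and
    [11000,11600), intron [10400,11000)."""
    t = make_transcript("T1", "G1", "chr1", "+", [(10000, 10400), (11000, 11600)])
    return make_gene("G1", "chr1", 10000, 11600, transcripts=[t])


def brute_force_isolated(genes, chrom_sizes, min_len=600, flank=2000):
    """All-pairs oracle for the metagene gene filter."""
    out = []
    for g in genes:
        if g.biotype != "protein_coding" or g.span.length < min_len:
            continue
        ws = max(0, g.span.start - flank)
        we = min(chrom_sizes[g.chrom], g.span.end + flank)
        clash = any(
            o is not g and o.chrom == g.chrom
            and o.span.start < we and o.span.end > ws
            for o in genes
        )
        if not clash:
            out.append(g.id)
    return sorted(out)


def brute_force_nonoverlapping(transcripts):
    """All-pairs oracle: ids of transcripts overlapping no other (strand
    ignored)."""
    out = []
    for t in transcripts:
        s = t.span
        clash = any(
            o is not t and o.chrom == t.chrom
            and o.span.start < s.end and s.start < o.span.end
            for o in transcripts
        )
        if not clash:
            out.append(t.id)
    return sorted(out)
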
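"""Synthetic annotation, coverage, expression and splicing-event generator.

Every downstream stage is testable against ground truth recorded at
generation time: which genes satisfy the metagene isolation filter, each
gene's longest transcript, the true exon:intron signal ratio (rho) and 5'->3'
gradient (gamma), each gene's expression stratum, and which genes carry
significant splicing events.

The signal model inside a gene is

    lambda(x) = base_depth * tpm(g)**expr_coupling
                * (rho if x exonic else 1)
                * (1 + gamma * (pos(x)/L - 0.5))

with ``pos`` measured 5'->3' along the gene span and a flat intergenic
background of ``background_fraction * base_depth``.  ``gamma > 0`` makes
profiles 3'-heavy (the canonical skew of co-transcriptional marks).

In ``noise="none"`` mode the returned track IS lambda, so recovery targets
(per-transcript score = rho, gradient skew) are exact.  In ``noise="poisson"``
mode, 150 bp fragment midpoints are drawn per base at rate lambda/ext and
emitted as 5'-anchored 50 bp reads; re-extending them to 150 bp reconstructs
the fragments, so the expected pileup is an ext-wide moving average of lambda
(boundary smearing included).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    Gene,
    GenomeAnnotation,
    Transcript,
    longest_transcript,
    write_gtf,
)
from .coverage import (
    AlignmentSummary,
    CoverageTrack,
    ReadSet,
    write_bedgraph,
    write_reads_bed,
)
from .expression import AS_EVENT_TYPES, TPM_CUTOFFS
from .intervals import GenomicInterval

__all__ = [
    "SyntheticGenomeSpec",
    "SignalSpec",
    "CoverageData",
    "generate_annotation",
    "generate_coverage",
    "generate_expression",
    "generate_events",
    "write_synthetic_dataset",
]


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Structural parameters of the synthetic genome.

    Exons are drawn long (300-1500 bp) relative to the 150 bp extended
    fragment so that region means are dominated by interior bases; intron
    lengths bracket the ~1 kb median of real human introns.  A
    ``crowded_fraction`` of inter-gene gaps is drawn below the 2 kb metagene
    flank so the isolation filter has known violations to find.
    """

    n_chroms: int = 2
    chrom_len: int = 1_500_000
    n_genes: int = 60
    exon_count_range: tuple[int, int] = (1, 8)
    exon_len_range: tuple[int, int] = (300, 1500)
    intron_len_range: tuple[int, int] = (1000, 4000)
    intergene_gap_range: tuple[int, int] = (4500, 12000)
    crowded_gap_range: tuple[int, int] = (200, 1500)
    crowded_fraction: float = 0.15
    lnc_fraction: float = 0.2
    two_transcript_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exon_count_range", "exon_len_range", "intron_len_range",
                     "intergene_gap_range", "crowded_gap_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if not 0 <= self.crowded_fraction <= 1:
            raise ValueError("crowded_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SignalSpec:
    """Ground-truth signal parameters for synthetic coverage."""

    rho: float = 3.0                 # exon : intron signal ratio
    gamma: float = 0.0               # linear 5'->3' gradient in [-1, 1]
    base_depth: float = 30.0         # mean intronic coverage (reads x ext / bp)
    expr_coupling: float = 0.0       # amplitude ~ tpm**expr_coupling
    spike_fraction: float = 0.1      # fraction of all reads from the spike-in
    background_fraction: float = 0.05  # intergenic level relative to base_depth
    noise: str = "none"              # {"none", "poisson"}
    ext: int = 150                   # extended fragment length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be > 0")
        if not -1.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [-1, 1] (negative intensities)")
        if self.base_depth < 0:
            raise ValueError("base_depth must be >= 0")
        if not 0 < self.spike_fraction < 1:
            raise ValueError("spike_fraction must be in (0, 1)")
        if self.noise not in ("none", "poisson"):
            raise ValueError("noise must be 'none' or 'poisson'")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    spec: SyntheticGenomeSpec,
) -> tuple[GenomeAnnotation, dict]:
    """Non-overlapping genes with alternating strands and known structure.

    The ground-truth record lists, per gene: biotype, exon count, the longest
    transcript id, whether the gene violates the +-2 kb isolation filter
    (``crowded``), and whether it passes the 600 bp metagene length filter.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    chrom_sizes = {c: spec.chrom_len for c in chrom_names}
    genes: list[Gene] = []
    truth_genes: dict[str, dict] = {}
    # gap BEFORE each gene; crowded gaps (< 2 kb flank) flag both neighbors
    per_chrom = np.array_split(np.arange(spec.n_genes), spec.n_chroms)

    gi = 0
    for chrom, idxs in zip(chrom_names, per_chrom):
        pos = int(rng.integers(*spec.intergene_gap_range))
        prev_gene_id: str | None = None
        for k, _ in enumerate(idxs):
            gid = f"G{gi:04d}"
            n_exons = int(rng.integers(spec.exon_count_range[0],
                                       spec.exon_count_range[1] + 1))
            exon_lens = rng.integers(spec.exon_len_range[0],
                                     spec.exon_len_range[1] + 1, n_exons)
            intron_lens = rng.integers(spec.intron_len_range[0],
                                       spec.intron_len_range[1] + 1,
                                       max(n_exons - 1, 0))
            strand = "+" if gi % 2 == 0 else "-"
            crowded_before = False
            if k > 0:
                if rng.random() < spec.crowded_fraction:
                    gap = int(rng.integers(*spec.crowded_gap_range))
                    crowded_before = True
                else:
                    gap = int(rng.integers(*spec.intergene_gap_range))
                pos += gap
            start = pos
            exons = []
            for j in range(n_exons):
                exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[j]), strand))
                pos += int(exon_lens[j])
                if j < n_exons - 1:
                    pos += int(intron_lens[j])
            end = exons[-1].end
            if end > spec.chrom_len:
                raise ValueError(
                    f"genes do not fit on {chrom}: increase chrom_len "
                    f"(need > {end} bp) or reduce n_genes"
                )
            biotype = "lncRNA" if rng.random() < spec.lnc_fraction else "protein_coding"
            tx_primary = Transcript(
                id=f"{gid}.t1", gene_id=gid, exons=tuple(exons), biotype=biotype
            )
            txs = [tx_primary]
            if n_exons >= 2 and rng.random() < spec.two_transcript_fraction:
                # secondary isoform: drop a terminal exon -> strictly shorter span
                sub = exons[1:] if rng.random() < 0.5 else exons[:-1]
                txs.append(
                    Transcript(id=f"{gid}.t2", gene_id=gid, exons=tuple(sub),
                               biotype=biotype)
                )
            gene = Gene(
                id=gid,
                span=GenomicInterval(chrom, start, end, strand),
                biotype=biotype,
                transcripts=tuple(txs),
            )
            genes.append(gene)
            truth_genes[gid] = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "biotype": biotype,
                "n_exons": n_exons,
                "longest_transcript": tx_primary.id,
                "crowded": crowded_before,  # updated below for right neighbor
                "length": end - start,
            }
            if crowded_before and prev_gene_id is not None:
                truth_genes[prev_gene_id]["crowded"] = True
            prev_gene_id = gid
            gi += 1

    # ensure at least one gene of each biotype when genes exist
    if genes:
        biotypes = {g.biotype for g in genes}
        for want in ("protein_coding", "lncRNA"):
            if want not in biotypes and spec.lnc_fraction not in (0.0, 1.0):
                g0 = genes[0]
                genes[0] = Gene(
                    id=g0.id, span=g0.span, biotype=want,
                    transcripts=tuple(
                        Transcript(id=t.id, gene_id=t.gene_id, exons=t.exons,
                                   biotype=want)
                        for t in g0.transcripts
                    ),
                )
                truth_genes[g0.id]["biotype"] = want

    ann = GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes)
    metagene_ids = sorted(
        gid for gid, t in truth_genes.items()
        if t["biotype"] == "protein_coding" and t["length"] >= 600
        and not t["crowded"]
    )
    truth = {
        "spec": asdict(spec),
        "genes": truth_genes,
        "metagene_gene_ids": metagene_ids,
        "exon_transcript_ids": sorted(
            t["longest_transcript"] for t in truth_genes.values()
            if t["biotype"] == "protein_coding"
        ),
    }
    return ann, truth


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageData:
    reads: ReadSet | None
    summary: AlignmentSummary
    track: CoverageTrack
    truth: dict = field(default_factory=dict)


def _lambda_arrays(
    ann: GenomeAnnotation, sig: SignalSpec, tpm: dict[str, float] | None
) -> dict[str, np.ndarray]:
    """Dense per-base expected extended-fragment coverage."""
    dense = {
        c: np.full(size, sig.background_fraction * sig.base_depth)
        for c, size in ann.chrom_sizes.items()
    }
    for g in ann.genes:
        L = g.length
        amp = sig.base_depth
        if sig.expr_coupling != 0.0:
            t = 0.0 if tpm is None else float(tpm.get(g.id, 0.0))
            amp = sig.base_depth * t ** sig.expr_coupling
        idx = np.arange(L, dtype=np.float64)
        pos = (idx + 0.5) / L          # 5'->3' fractional position, + strand
        if g.strand == "-":
            pos = pos[::-1]
        lam = amp * (1.0 + sig.gamma * (pos - 0.5))
        exonic = np.zeros(L, dtype=bool)
        t_longest = longest_transcript(g)
        exon_source = t_longest.exons if t_longest is not None else ()
        for e in exon_source:
            exonic[e.start - g.span.start: e.end - g.span.start] = True
        lam = np.where(exonic, lam * sig.rho, lam)
        dense[g.chrom][g.span.start: g.span.end] = lam
    return dense


def generate_coverage(
    ann: GenomeAnnotation,
    sig: SignalSpec,
    tpm: dict[str, float] | None = None,
) -> CoverageData:
    """Synthetic coverage for *ann* under signal model *sig*.

    Exonic bases are those of each gene's longest transcript (the transcript
    set the enrichment analysis uses).  Returns reads (poisson mode only), an
    :class:`AlignmentSummary` with the spike-in read count implied by
    ``spike_fraction``, and a materialized track: lambda itself in noiseless
    mode, the raw extended-read pileup in poisson mode.
    """
    dense = _lambda_arrays(ann, sig, tpm)
    rng = np.random.default_rng(sig.seed)
    ext = sig.ext
    if sig.noise == "none":
        track = CoverageTrack.from_dense(ann.chrom_sizes, dense, tag="raw")
        n_primary = int(round(track.total_integral / ext))
        reads = None
    else:
        half = ext // 2
        data = {}
        for chrom, lam in dense.items():
            size = len(lam)
            counts = rng.poisson(lam / ext)
            centers = np.repeat(np.flatnonzero(counts), counts[counts > 0])
            plus = rng.random(len(centers)) < 0.5
            # 5' end such that the ext-bp extension covers [c-half, c-half+ext)
            # (- reads record the exclusive 5' coordinate, BED-end style)
            five = np.where(plus, centers - half, centers - half + ext)
            five = np.clip(five, np.where(plus, 0, ext),
                           np.where(plus, size - ext, size))
            data[chrom] = (five.astype(np.int64), plus)
        reads = ReadSet(data)
        from .coverage import reads_to_coverage

        track = reads_to_coverage(reads, ann.chrom_sizes, ext=ext, mode="raw")
        n_primary = len(reads)
    n_spikein = int(round(sig.spike_fraction / (1.0 - sig.spike_fraction) * n_primary))
    summary = AlignmentSummary(n_primary=n_primary, n_spikein=n_spikein)
    truth = {"signal": asdict(sig), "n_primary": n_primary, "n_spikein": n_spikein}
    return CoverageData(reads=reads, summary=summary, track=track, truth=truth)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(
    ann: GenomeAnnotation,
    seed: int = 0,
    log_mean: float = 0.5,
    log_sigma: float = 1.5,
    all_zero: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Log-normal TPM table over the annotation's genes.

    lncRNA TPMs are scaled down 20x (they straddle the 0.1/0.5 cutoffs the way
    coding genes straddle 2/4).  Nonempty low and high strata are guaranteed
    for each biotype present (the extreme draws are nudged to the stratum
    boundaries when a stratum would be empty).  Ground truth records each
    gene's stratum under the published cutoffs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in ann.genes:
        if all_zero:
            tpm = 0.0
        else:
            tpm = float(rng.lognormal(log_mean, log_sigma))
            if g.biotype == "lncRNA":
                tpm /= 20.0
        rows.append({"gene_id": g.id, "biotype": g.biotype, "tpm": tpm})
    df = pd.DataFrame(rows, columns=["gene_id", "biotype", "tpm"])

    if not all_zero:
        for biotype, (low_max, high_min) in TPM_CUTOFFS.items():
            mask = df["biotype"] == biotype
            if mask.sum() < 2:
                continue
            tpms = df.loc[mask, "tpm"]
            if not ((tpms > 0) & (tpms <= low_max)).any():
                df.loc[tpms.idxmin(), "tpm"] = low_max / 2.0
            tpms = df.loc[mask, "tpm"]
            if not (tpms >= high_min).any():
                df.loc[tpms.idxmax(), "tpm"] = high_min * 2.0

    strata: dict[str, dict[str, list[str]]] = {}
    for biotype, (low_max, high_min) in TPM_CUTOFFS.items():
        sub = df[df["biotype"] == biotype]
        strata[biotype] = {
            "low": sorted(sub.loc[(sub["tpm"] > 0) & (sub["tpm"] <= low_max),
                                  "gene_id"]),
            "high": sorted(sub.loc[sub["tpm"] >= high_min, "gene_id"]),
        }
    return df, {"strata": strata}


# ---------------------------------------------------------------------------
# Splicing events (rMATS-format)
# ---------------------------------------------------------------------------

def generate_events(
    ann: GenomeAnnotation,
    seed: int = 0,
    n_up: int = 10,
    n_down: int = 10,
    n_nonsig: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Event table in the normalized rMATS schema (gene_id, event_type,
    delta_psi, fdr): *n_up* genes get a significant positive-delta event,
    *n_down* a significant negative one, the rest draw fdr >= 0.1.  Event
    types cycle through SE/A5SS/A3SS/MXE/RI."""
    rng = np.random.default_rng(seed)
    gene_ids = [g.id for g in ann.genes]
    need = n_up + n_down
    if need > len(gene_ids):
        raise ValueError(
            f"n_up + n_down = {need} exceeds the {len(gene_ids)} genes available"
        )
    chosen = list(rng.choice(gene_ids, size=need, replace=False)) if need else []
    up_genes = sorted(chosen[:n_up])
    down_genes = sorted(chosen[n_up:])
    others = [g for g in gene_ids if g not in set(chosen)][:n_nonsig]

    rows = []
    k = 0

    def etype():
        nonlocal k
        e = AS_EVENT_TYPES[k % len(AS_EVENT_TYPES)]
        k += 1
        return e

    for gid in up_genes:
        rows.append({"gene_id": gid, "event_type": etype(),
                     "delta_psi": float(rng.uniform(0.05, 0.5)),
                     "fdr": float(rng.uniform(1e-6, 0.049))})
    for gid in down_genes:
        rows.append({"gene_id": gid, "event_type": etype(),
                     "delta_psi": float(-rng.uniform(0.05, 0.5)),
                     "fdr": float(rng.uniform(1e-6, 0.049))})
    for gid in others:
        rows.append({"gene_id": gid, "event_type": etype(),
                     "delta_psi": float(rng.uniform(-0.5, 0.5)),
                     "fdr": float(rng.uniform(0.1, 1.0))})
    df = pd.DataFrame(rows, columns=["gene_id", "event_type", "delta_psi", "fdr"])
    truth = {"up_genes": up_genes, "down_genes": down_genes,
             "n_significant": need}
    return df, truth


def write_rmats_tables(events: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Write one rMATS-format TSV per event type (SE.MATS.JC.txt, ...).
    These are synthetic stand-ins for real rMATS output: only the columns the
    analysis consumes (GeneID, IncLevelDifference, FDR) carry signal."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for et in AS_EVENT_TYPES:
        sub = events[events["event_type"] == et]
        df = pd.DataFrame(
            {
                "ID": np.arange(len(sub)),
                "GeneID": ['"%s"' % g for g in sub["gene_id"]],
                "geneSymbol": ['"%s"' % g for g in sub["gene_id"]],
                "PValue": sub["fdr"].to_numpy() / 2.0,
                "FDR": sub["fdr"].to_numpy(),
                "IncLevelDifference": sub["delta_psi"].to_numpy(),
            }
        )
        path = outdir / f"{et}.MATS.JC.txt"
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# One-call dataset writer
# ---------------------------------------------------------------------------

def write_synthetic_dataset(
    outdir: str | Path,
    genome_spec: SyntheticGenomeSpec | None = None,
    signal_spec: SignalSpec | None = None,
    seed: int | None = None,
) -> dict:
    """Generate and write a complete dataset (GTF, chrom sizes, reads BED,
    bedGraph track, expression TSV, rMATS tables, ground-truth JSON).
    Returns the ground-truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        genome_spec = genome_spec or SyntheticGenomeSpec(seed=seed)
        signal_spec = signal_spec or SignalSpec(seed=seed + 1)
    genome_spec = genome_spec or SyntheticGenomeSpec()
    signal_spec = signal_spec or SignalSpec()

    ann, truth = generate_annotation(genome_spec)
    write_gtf(ann, outdir / "annotation.gtf")
    with open(outdir / "chrom.sizes", "w") as fh:
        for c, size in ann.chrom_sizes.items():
            fh.write(f"{c}\t{size}\n")

    expr, expr_truth = generate_expression(ann, seed=genome_spec.seed + 101)
    expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)

    tpm = dict(zip(expr["gene_id"], expr["tpm"]))
    cov = generate_coverage(ann, signal_spec, tpm=tpm)
    write_bedgraph(cov.track, outdir / "coverage.bedgraph")
    if cov.reads is not None:
        write_reads_bed(cov.reads, outdir / "reads.bed")
    with open(outdir / "alignment_summary.json", "w") as fh:
        json.dump({"n_primary": cov.summary.n_primary,
                   "n_spikein": cov.summary.n_spikein}, fh)

    events, ev_truth = generate_events(ann, seed=genome_spec.seed + 202)
    write_rmats_tables(events, outdir / "rmats")

    truth_all = {**truth, "coverage": cov.truth, "expression": expr_truth,
                 "events": ev_truth}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_all, fh, indent=1)
    return truth_all
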
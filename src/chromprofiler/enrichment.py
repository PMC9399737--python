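"""Exon vs intron signal summaries.

Two estimators are provided, matching the two ways the field summarizes
exonic enrichment of a histone mark:

* :func:`global_exon_intron_signal` — the pooled estimator: total signal on
  all exons divided by total exon length, likewise for introns, and their
  ratio (one number per transcript set);
* :func:`per_transcript_enrichment` — the per-transcript score: mean exon
  signal over mean intron signal for each transcript individually
  (undefined for single-exon transcripts or zero intron signal).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Transcript, derive_introns
from .coverage import CoverageTrack
from .expression import BoxplotSummary, boxplot_summary

__all__ = [
    "TranscriptSignal",
    "transcript_signal",
    "per_transcript_enrichment",
    "global_exon_intron_signal",
    "enrichment_table",
    "SetSummary",
    "aggregate_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TranscriptSignal:
    transcript_id: str
    gene_id: str
    exon_total: float
    exon_len: int
    intron_total: float
    intron_len: int

    @property
    def exon_mean(self) -> float:
        return self.exon_total / self.exon_len if self.exon_len else float("nan")

    @property
    def intron_mean(self) -> float:
        return self.intron_total / self.intron_len if self.intron_len else float("nan")

    @property
    def score(self) -> float | None:
        """exon_mean / intron_mean; None when no introns or zero intron signal."""
        if self.intron_len == 0 or self.intron_total == 0.0:
            return None
        return self.exon_mean / self.intron_mean


def transcript_signal(track: CoverageTrack, t: Transcript) -> TranscriptSignal:
    ex_starts = np.array([e.start for e in t.exons])
    ex_ends = np.array([e.end for e in t.exons])
    introns = derive_introns(t)
    exon_total = float(track.integrals(t.chrom, ex_starts, ex_ends).sum())
    if introns:
        in_starts = np.array([i.start for i in introns])
        in_ends = np.array([i.end for i in introns])
        intron_total = float(track.integrals(t.chrom, in_starts, in_ends).sum())
        intron_len = int((in_ends - in_starts).sum())
    else:
        intron_total, intron_len = 0.0, 0
    return TranscriptSignal(
        transcript_id=t.id,
        gene_id=t.gene_id,
        exon_total=exon_total,
        exon_len=int((ex_ends - ex_starts).sum()),
        intron_total=intron_total,
        intron_len=intron_len,
    )


def per_transcript_enrichment(track: CoverageTrack, t: Transcript) -> float | None:
    """Enrichment score for one transcript, or None where undefined."""
    return transcript_signal(track, t).score


def global_exon_intron_signal(
    track: CoverageTrack, transcripts: list[Transcript]
) -> tuple[float, float, float]:
    """Pooled (avg_exon, avg_intron, ratio) over a transcript set.

    avg_exon is the total signal on all exons divided by the total exon
    length; avg_intron likewise.  Raises when the set is empty or the total
    intron length is zero (ratio undefined).
    """
    if not transcripts:
        raise ValueError("global_exon_intron_signal requires >=1 transcript")
    sigs = [transcript_signal(track, t) for t in transcripts]
    exon_len = sum(s.exon_len for s in sigs)
    intron_len = sum(s.intron_len for s in sigs)
    if intron_len == 0:
        raise ValueError("total intron length is zero: pooled ratio undefined")
    avg_exon = sum(s.exon_total for s in sigs) / exon_len
    avg_intron = sum(s.intron_total for s in sigs) / intron_len
    return avg_exon, avg_intron, avg_exon / avg_intron


def enrichment_table(track: CoverageTrack, transcripts: list[Transcript]) -> pd.DataFrame:
    """Per-transcript scores as a DataFrame with columns transcript_id,
    gene_id, exon_mean, intron_mean, score, defined."""
    rows = []
    for t in transcripts:
        s = transcript_signal(track, t)
        score = s.score
        rows.append(
            {
                "transcript_id": s.transcript_id,
                "gene_id": s.gene_id,
                "exon_mean": s.exon_mean,
                "intron_mean": s.intron_mean,
                "score": np.nan if score is None else score,
                "defined": score is not None,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "exon_mean", "intron_mean",
                 "score", "defined"],
    )
    n_excl = int((~df["defined"]).sum()) if len(df) else 0
    if n_excl:
        logger.info("%d transcripts with undefined enrichment score excluded "
                    "from aggregates", n_excl)
    return df


@dataclass(frozen=True)
class SetSummary:
    name: str
    n: int
    mean: float
    median: float
    box: BoxplotSummary | None


def aggregate_enrichment(
    table: pd.DataFrame, gene_sets: dict[str, set[str]]
) -> dict[str, SetSummary]:
    """Summaries of defined scores per named gene set (e.g. splicing Up/Down
    plus an 'All' set).  Gene ids absent from the table are ignored with a
    warning."""
    defined = table[table["defined"]]
    known = set(table["gene_id"])
    out = {}
    for name, genes in gene_sets.items():
        missing = set(genes) - known
        if missing:
            logger.warning("set %s: %d gene ids not in the score table",
                           name, len(missing))
        scores = defined.loc[defined["gene_id"].isin(genes), "score"].to_numpy()
        if len(scores) == 0:
            out[name] = SetSummary(name, 0, float("nan"), float("nan"), None)
        else:
            out[name] = SetSummary(
                name,
                len(scores),
                float(np.mean(scores)),
                float(np.median(scores)),
                boxplot_summary(scores),
            )
    return out
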
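"""End-to-end pipeline: one config file, all downstream analyses.

Per condition the pipeline builds (or loads) a normalized coverage track and
emits the metagene profile + skew, pooled and per-transcript exon/intron
enrichment, the peak feature distribution (when peaks are given), TPM-stratum
signal summaries (when an expression table is given) and splicing-direction
enrichment aggregates (when rMATS tables are given).  A manifest records
versions, seeds and parameters so a rerun is byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    read_gtf,
    select_exon_transcripts,
    select_metagene_genes,
)
from .coverage import (
    AlignmentSummary,
    compute_factors,
    read_bedgraph,
    read_reads_bed,
    reads_to_coverage,
    write_bedgraph,
)
from .enrichment import aggregate_enrichment, enrichment_table, global_exon_intron_signal
from .expression import (
    TPM_CUTOFFS,
    boxplot_summary,
    filter_significant,
    gene_body_signal,
    read_expression_table,
    read_rmats_table,
    splice_event_gene_sets,
    stratify_by_expression,
)
from .features import build_feature_index, feature_distribution, read_peaks_bed
from .metagene import BinScheme, body_skew, metagene_profile, write_profile_tsv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ConditionConfig:
    name: str
    track: str | None = None          # bedGraph (already normalized or raw)
    reads: str | None = None          # BED reads to pile up
    n_primary: int | None = None
    n_spikein: int | None = None


@dataclass
class PipelineConfig:
    gtf: str
    outdir: str
    conditions: list[ConditionConfig]
    chrom_sizes: str | None = None
    peaks: dict[str, str] = field(default_factory=dict)
    expression: str | None = None
    rmats_dir: str | None = None
    mode: str = "spikein"             # rpm | spikein | raw
    ext: int = 150
    flank: int = 2000
    flank_bins: int = 100
    body_bins: int = 300
    eps: float = 0.5
    fdr_max: float = 0.05
    min_fc: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        conds = [ConditionConfig(**c) for c in raw.pop("conditions")]
        cfg = cls(conditions=conds, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [("gtf", self.gtf), ("chrom_sizes", self.chrom_sizes),
                 ("expression", self.expression)]
        paths += [(f"peaks[{k}]", v) for k, v in self.peaks.items()]
        for cond in self.conditions:
            paths.append((f"conditions[{cond.name}].track", cond.track))
            paths.append((f"conditions[{cond.name}].reads", cond.reads))
        for label, p in paths:
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"{label}: no such file: {p}")
        if self.rmats_dir is not None and not Path(self.rmats_dir).is_dir():
            raise PipelineError("config", f"rmats_dir: no such directory: {self.rmats_dir}")
        if not self.conditions:
            raise PipelineError("config", "at least one condition is required")
        for cond in self.conditions:
            if cond.track is None and cond.reads is None:
                raise PipelineError(
                    "config", f"condition {cond.name}: needs 'track' or 'reads'"
                )


def _read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns a manifest of produced outputs."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(cfg).items()
            if k not in ("conditions", "peaks")
        },
        "conditions": {},
        "outputs": [],
    }

    def out(path: Path) -> Path:
        manifest["outputs"].append(str(path))
        return path

    def stage(name):
        logger.info("stage %-18s %.2fs elapsed", name, time.perf_counter() - t0)

    try:
        sizes = _read_chrom_sizes(cfg.chrom_sizes) if cfg.chrom_sizes else None
        ann = read_gtf(cfg.gtf, chrom_sizes=sizes)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("annotation", str(e)) from e
    stage("annotation")

    scheme = BinScheme(flank=cfg.flank, flank_bins=cfg.flank_bins,
                       body_bins=cfg.body_bins)
    metagene_genes = select_metagene_genes(ann, flank=cfg.flank)
    transcripts = select_exon_transcripts(ann)

    expr = read_expression_table(cfg.expression) if cfg.expression else None

    gene_sets = None
    if cfg.rmats_dir:
        try:
            frames = []
            for p in sorted(Path(cfg.rmats_dir).glob("*.MATS.*.txt")):
                et = p.name.split(".")[0]
                frames.append(read_rmats_table(p, et))
            events = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
                columns=["gene_id", "event_type", "delta_psi", "fdr"])
            significant = filter_significant(events, fdr_max=cfg.fdr_max)
            gene_sets = splice_event_gene_sets(significant)
            gene_sets["All"] = {t.gene_id for t in transcripts}
            out(outdir / "significant_events.tsv")
            significant.to_csv(outdir / "significant_events.tsv", sep="\t",
                               index=False)
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError("splicing", str(e)) from e
        stage("splicing")

    for cond in cfg.conditions:
        cdir = outdir / cond.name
        cdir.mkdir(exist_ok=True)
        cm: dict = {}
        manifest["conditions"][cond.name] = cm
        # ---- track -------------------------------------------------------
        try:
            if cond.reads is not None:
                reads = read_reads_bed(cond.reads)
                factors = None
                if cfg.mode != "raw":
                    n_primary = cond.n_primary or len(reads)
                    factors = compute_factors(
                        AlignmentSummary(n_primary=n_primary,
                                         n_spikein=cond.n_spikein or 0)
                    )
                track = reads_to_coverage(reads, ann.chrom_sizes, ext=cfg.ext,
                                          factors=factors, mode=cfg.mode)
            else:
                track = read_bedgraph(cond.track, chrom_sizes=ann.chrom_sizes)
                if cfg.mode != "raw" and cond.n_primary:
                    factors = compute_factors(
                        AlignmentSummary(n_primary=cond.n_primary,
                                         n_spikein=cond.n_spikein or 0)
                    )
                    factor = getattr(factors, cfg.mode)
                    track = track.scale(factor, tag=cfg.mode)
            write_bedgraph(track, out(cdir / f"track.{track.tag}.bedgraph"))
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(f"coverage:{cond.name}", str(e)) from e
        stage(f"coverage:{cond.name}")

        # ---- metagene ------------------------------------------------------
        try:
            profile = metagene_profile(track, metagene_genes, scheme)
            write_profile_tsv(profile, out(cdir / "metagene.tsv"))
            cm["body_skew"] = body_skew(profile, eps=cfg.eps)
            cm["n_metagene_genes"] = profile.n_genes
        except Exception as e:
            raise PipelineError(f"metagene:{cond.name}", str(e)) from e
        stage(f"metagene:{cond.name}")

        # ---- exon/intron enrichment ---------------------------------------
        try:
            table = enrichment_table(track, transcripts)
            table.to_csv(out(cdir / "enrichment.tsv"), sep="\t", index=False)
            avg_exon, avg_intron, ratio = global_exon_intron_signal(track, transcripts)
            cm["global_exon_mean"] = avg_exon
            cm["global_intron_mean"] = avg_intron
            cm["global_exon_intron_ratio"] = ratio
            cm["median_enrichment_score"] = float(
                table.loc[table["defined"], "score"].median())
            if gene_sets is not None:
                agg = aggregate_enrichment(table, gene_sets)
                rows = [
                    {"set": s.name, "n": s.n, "mean": s.mean, "median": s.median}
                    for s in agg.values()
                ]
                pd.DataFrame(rows).to_csv(out(cdir / "enrichment_sets.tsv"),
                                          sep="\t", index=False)
                cm["enrichment_sets"] = {s.name: s.median for s in agg.values()}
        except Exception as e:
            raise PipelineError(f"enrichment:{cond.name}", str(e)) from e
        stage(f"enrichment:{cond.name}")

        # ---- peak feature distribution --------------------------------------
        if cond.name in cfg.peaks:
            try:
                peaks = read_peaks_bed(cfg.peaks[cond.name])
                index = build_feature_index(ann)
                dist = feature_distribution(peaks, index)
                dist.to_csv(out(cdir / "feature_distribution.tsv"), sep="\t",
                            index=False)
                cm["feature_distribution"] = dict(
                    zip(dist["category"], dist["fraction"]))
            except Exception as e:
                raise PipelineError(f"features:{cond.name}", str(e)) from e
            stage(f"features:{cond.name}")

        # ---- expression strata ----------------------------------------------
        if expr is not None:
            try:
                rows = []
                signal = gene_body_signal(track, ann.genes)
                for biotype in TPM_CUTOFFS:
                    strata = stratify_by_expression(expr, biotype)
                    for stratum, ids in strata.items():
                        vals = signal.reindex(sorted(ids)).dropna()
                        if len(vals) == 0:
                            continue
                        box = boxplot_summary(vals.to_numpy())
                        rows.append({
                            "biotype": biotype, "stratum": stratum,
                            "n": box.n, "median": box.median, "q1": box.q1,
                            "q3": box.q3, "whisker_low": box.whisker_low,
                            "whisker_high": box.whisker_high,
                            "n_outliers": len(box.outliers),
                        })
                pd.DataFrame(rows).to_csv(out(cdir / "expression_strata.tsv"),
                                          sep="\t", index=False)
                cm["expression_strata"] = rows
            except Exception as e:
                raise PipelineError(f"expression:{cond.name}", str(e)) from e
            stage(f"expression:{cond.name}")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
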
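"""End-to-end synthetic run: simulate a cohort, then drive every analysis
stage off it — SRE calling/quantification/classification, abundance
deciles, transcript integrity, small-RNA cluster calling with consensus,
and the seasonal differential test.

Everything is a pure function of the :class:`~spermkit.simulate.SimulationConfig`
(one global seed), so two runs with the same config produce byte-identical
output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from . import differential, integrity, simulate, smallrna, sre
from .io import GenomeAnnotation, ReadIntervalSet, RepeatTrack, write_alignments, write_annotation

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    annotation: GenomeAnnotation
    repeats: RepeatTrack
    reads: dict[str, ReadIntervalSet]
    truth_reads: simulate.GroundTruth
    sres: pd.DataFrame                      # called + classified, with decile
    abundance: sre.AbundanceMatrix
    decile_share: pd.Series
    tins: pd.DataFrame
    pirna_consensus: pd.DataFrame
    truth_smallrna: simulate.GroundTruth
    de: differential.SeasonalDEResults
    truth_counts: simulate.GroundTruth


def run_pipeline(config: simulate.SimulationConfig,
                 outdir: str | None = None,
                 min_support: int = 3, max_gap: int = 0) -> PipelineResult:
    """Simulate and analyse one cohort; optionally write TSV/BED outputs."""
    ann, track = simulate.generate_annotation(config)
    reads, truth_reads = simulate.simulate_reads(ann, config)

    called = sre.call_sres(list(reads.values()), min_support=min_support,
                           max_gap=max_gap)
    abundance = sre.quantify_sres(called, list(reads.values()))
    classified = sre.classify_sres(called, ann)
    deciles, share = sre.partition_deciles(abundance, called)
    table = classified.merge(abundance.mean_sd(), left_on="sre_id",
                             right_index=True)
    table["decile"] = deciles.reindex(table["sre_id"]).to_numpy()

    tins = integrity.tin_table(ann, reads)

    sreads, truth_small = simulate.simulate_small_rna(ann, config)
    per_sample = {sid: smallrna.call_pirna_clusters(r)
                  for sid, r in sreads.items()}
    consensus = smallrna.reproducible_clusters(per_sample)

    counts, truth_counts = simulate.simulate_counts(config)
    de = differential.SeasonalCountModel(counts, config.design()).fit()

    result = PipelineResult(
        annotation=ann, repeats=track, reads=reads, truth_reads=truth_reads,
        sres=table, abundance=abundance, decile_share=share, tins=tins,
        pirna_consensus=consensus, truth_smallrna=truth_small, de=de,
        truth_counts=truth_counts,
    )
    if outdir is not None:
        _write_outputs(result, counts, outdir)
    return result


def _write_outputs(res: PipelineResult, counts: pd.DataFrame, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_annotation(res.annotation, os.path.join(outdir, "annotation.gff3"))
    res.repeats.records.to_csv(os.path.join(outdir, "repeats.tsv"),
                               sep="\t", index=False)
    for sid, r in res.reads.items():
        write_alignments(r, os.path.join(outdir, f"reads_{sid}.bed"))
    out = res.sres.copy()
    out["linked_gene_ids"] = out["linked_gene_ids"].map(",".join)
    out.to_csv(os.path.join(outdir, "sres.tsv"), sep="\t", index=False,
               float_format="%.6g")
    res.abundance.values.to_csv(os.path.join(outdir, "sre_rpkm.tsv"),
                                sep="\t", float_format="%.6g")
    res.decile_share.to_csv(os.path.join(outdir, "decile_share.tsv"),
                            sep="\t", float_format="%.6g")
    res.tins.to_csv(os.path.join(outdir, "tin.tsv"), sep="\t",
                    float_format="%.4f")
    res.pirna_consensus.to_csv(os.path.join(outdir, "pirna_clusters.tsv"),
                               sep="\t", index=False)
    counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    res.de.table.to_csv(os.path.join(outdir, "de_results.tsv"), sep="\t",
                        float_format="%.6g")
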
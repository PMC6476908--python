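"""Synthetic sperm RNA-seq data with known ground truth.

The generators emulate the salient structure of a mature-sperm total and
short RNA-seq experiment so that every downstream stage of the pipeline can
be scored against a planted truth:

* heavy-tailed per-gene abundances (log-normal; at the default sd the top
  decile of features carries roughly two thirds of the read mass),
* fragmented transcript coverage — each transcript is covered uniformly
  over one contiguous window spanning a fraction ``f`` of its exonic
  length, drawn from a Beta distribution, so that the integrity score of a
  transcript has the closed form ``100 * f``,
* a two-season (summer/winter), two-batch sample design with planted
  log2 fold changes and negative-binomial counts,
* small-RNA reads with a 22 nt microRNA mode and 26-33 nt piRNA reads
  concentrated in planted clusters.

One global seed drives everything; each generator draws from its own
deterministic substream so adding a generator never shifts another's
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenomeAnnotation, ReadIntervalSet, RepeatTrack, merge_intervals

__all__ = [
    "SimulationConfig",
    "SmallRNAParams",
    "GroundTruth",
    "SizingError",
    "DesignError",
    "generate_annotation",
    "simulate_reads",
    "simulate_counts",
    "simulate_small_rna",
]


class SizingError(ValueError):
    """The requested structures do not fit in the configured genome."""


class DesignError(ValueError):
    """The sample design is unusable (e.g. a season with < 2 samples)."""


@dataclass
class SmallRNAParams:
    """Parameters of the short-RNA read generator."""

    mirna_length: int = 22
    pirna_len_min: int = 26
    pirna_len_max: int = 33
    #: planted piRNA clusters as (chrom, start, end); defaults assume the
    #: default 2 x 1 Mb genome
    planted_clusters: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("chr1", 650_000, 658_000),
                                 ("chr2", 200_000, 207_000)])
    #: expected piRNA reads per bp of planted cluster, per sample
    cluster_density: float = 0.05
    #: planted miRNA loci as (chrom, position)
    mirna_loci: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 100_000), ("chr2", 500_000)])
    #: expected reads per miRNA locus per sample
    mirna_mean_reads: float = 50.0
    #: expected background reads per bp of genome per sample (any length 20-35)
    background_rate: float = 2e-5


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Defaults describe a 10-boar cohort: 5 summer and 5 winter ejaculates
    split over two sequencing batches, heavy-tailed abundances and heavy
    transcript fragmentation.
    """

    seed: int = 0
    # genome / annotation
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 100
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 500
    lncrna_fraction: float = 0.05
    #: genome fraction per repeat class
    repeat_fractions: dict[str, float] = field(
        default_factory=lambda: {"SINE": 0.02, "LINE1": 0.03, "simple_repeat": 0.01}
    )
    repeat_length: int = 200
    # abundance & fragmentation
    abundance_meanlog: float = 1.0
    abundance_sdlog: float = 1.65   # puts ~65% of read mass in the top decile
    frag_beta_a: float = 1.0
    frag_beta_b: float = 3.0        # ~58% of transcripts with f <= 0.25
    read_length: int = 75
    #: expected reads per unit of abundance per transcript per sample
    depth_factor: float = 1.0
    #: orphan read clusters planted in intergenic space: (chrom, start, end, reads)
    orphan_clusters: list[tuple[str, int, int, int]] = field(default_factory=list)
    #: additionally auto-place this many orphan read clusters in the widest
    #: intergenic gaps, > 10 kb from any gene, per sample
    n_auto_orphans: int = 2
    orphan_reads: int = 30
    orphan_span: int = 500
    orphan_clearance: int = 15_000
    # seasonal design
    n_samples_per_group: int = 5
    n_batches: int = 2
    batch_log2_effect: float = 0.5
    n_features: int = 2000
    counts_meanlog: float = 4.0
    counts_sdlog: float = 1.0
    dispersion: float = 0.2
    #: feature index -> planted log2 fold change (summer relative to winter);
    #: default plants 20 strong effects, half up and half down, echoing the
    #: handful of seasonally shifted transcripts seen against a null bulk
    planted_log2fc: dict[int, float] = field(
        default_factory=lambda: {
            i: lfc
            for i, lfc in enumerate([2.0, -2.0, 3.0, -3.0, 4.0, -4.0, 5.0,
                                     -5.0, 6.0, -6.0, 2.5, -2.5, 3.5, -3.5,
                                     4.5, -4.5, 5.5, -5.5, 2.0, -2.0])
        })
    smallrna: SmallRNAParams = field(default_factory=SmallRNAParams)

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not (0 < self.frag_beta_a and 0 < self.frag_beta_b):
            raise ValueError("fragmentation Beta parameters must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic substream ``stream`` of the global seed."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))

    def design(self) -> pd.DataFrame:
        """Sample sheet: sample_id, season, batch."""
        if self.n_samples_per_group < 2:
            raise DesignError("need >= 2 samples per season")
        rows = []
        for season in ("summer", "winter"):
            for i in range(self.n_samples_per_group):
                sid = f"{season[0]}{i + 1}"
                rows.append((sid, season, f"batch{(i % self.n_batches) + 1}"))
        return pd.DataFrame(rows, columns=["sample_id", "season", "batch"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.design()["sample_id"])


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline against the simulation."""

    gene_abundance: pd.Series | None = None          # gene_id -> abundance
    covered_fraction: pd.Series | None = None        # transcript_id -> f
    orphan_clusters: list[tuple[str, int, int]] = field(default_factory=list)
    de_log2fc: pd.Series | None = None               # feature -> planted lfc (0 = null)
    pirna_clusters: list[tuple[str, int, int]] = field(default_factory=list)
    mirna_loci: list[tuple[str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------


def generate_annotation(config: SimulationConfig) -> tuple[GenomeAnnotation, RepeatTrack]:
    """Lay out non-overlapping genes with exon structure, plus a repeat track.

    A ``lncrna_fraction`` of genes (rounded) gets the ``lncRNA`` biotype,
    the rest ``protein_coding``.  Repeat intervals are scattered uniformly
    to reach the configured genome fraction per class.
    """
    rng = config.rng(1)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    gene_span = (config.exons_per_gene * config.exon_length
                 + (config.exons_per_gene - 1) * config.intron_length)
    genome = config.n_chroms * config.chrom_length
    if config.n_genes * gene_span * 1.2 > genome:
        raise SizingError(
            f"{config.n_genes} genes of span {gene_span} bp do not fit "
            f"in a {genome} bp genome with intergenic room"
        )
    n_lnc = int(round(config.lncrna_fraction * config.n_genes))
    lnc_idx = set(rng.permutation(config.n_genes)[:n_lnc].tolist())

    # per-chromosome quota; intergenic gaps are exponential draws rescaled
    # so their sum exactly fills the chromosome slack, guaranteeing the
    # quota fits without overlap
    quota = [config.n_genes // config.n_chroms] * config.n_chroms
    for k in range(config.n_genes % config.n_chroms):
        quota[k] += 1

    genes, txs, exons = [], [], []
    gi = 0
    for chrom, nq in zip(chroms, quota):
        if nq == 0:
            continue
        chrom_slack = config.chrom_length - nq * gene_span
        if chrom_slack < 0:
            raise SizingError(
                f"{nq} genes of span {gene_span} bp exceed chromosome "
                f"length {config.chrom_length}")
        raw = rng.exponential(1.0, size=nq + 1)
        gaps = np.floor(raw / raw.sum() * chrom_slack).astype(int)
        pos = 0
        for k in range(nq):
            pos += int(gaps[k])
            gid = f"G{gi + 1:05d}"
            tid = f"T{gi + 1:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = "lncRNA" if gi in lnc_idx else "protein_coding"
            genes.append((gid, chrom, pos, pos + gene_span, strand, biotype))
            txs.append((tid, gid))
            estart = pos
            for _ in range(config.exons_per_gene):
                exons.append((tid, chrom, estart, estart + config.exon_length, strand))
                estart += config.exon_length + config.intron_length
            gi += 1
            pos += gene_span

    rep_rows = []
    for cls in sorted(config.repeat_fractions):
        frac = config.repeat_fractions[cls]
        if frac <= 0:
            continue
        n_per_chrom = int(round(frac * config.chrom_length / config.repeat_length))
        for chrom in chroms:
            starts = rng.integers(0, config.chrom_length - config.repeat_length,
                                  size=n_per_chrom)
            for k, s in enumerate(sorted(starts.tolist())):
                rep_rows.append((chrom, s, s + config.repeat_length, cls,
                                 f"{cls}_{chrom}_{k}"))
    track = RepeatTrack(records=pd.DataFrame(
        rep_rows, columns=["chrom", "start", "end", "re_class", "re_name"]))
    ann = GenomeAnnotation(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                           "strand", "biotype"]),
        transcripts=pd.DataFrame(txs, columns=["transcript_id", "gene_id"]),
        exons=pd.DataFrame(exons, columns=["transcript_id", "chrom", "start",
                                           "end", "strand"]),
    )
    return ann, track


def _exon_offsets(exons: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative exonic-coordinate offsets for mapping exonic -> genomic."""
    merged = merge_intervals(list(zip(exons["start"], exons["end"])))
    lengths = merged[:, 1] - merged[:, 0]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return merged, lengths, offsets


def _exonic_to_genomic(e_start: int, e_end: int, merged: np.ndarray,
                       offsets: np.ndarray) -> list[tuple[int, int]]:
    """Map an exonic-coordinate interval to genomic pieces (one per exon hit)."""
    pieces = []
    for k in range(len(merged)):
        lo = max(e_start, offsets[k])
        hi = min(e_end, offsets[k + 1])
        if lo < hi:
            g0 = merged[k, 0] + (lo - offsets[k])
            pieces.append((int(g0), int(g0 + (hi - lo))))
    return pieces


def simulate_reads(annotation: GenomeAnnotation, config: SimulationConfig
                   ) -> tuple[dict[str, ReadIntervalSet], GroundTruth]:
    """Fragmented-coverage total RNA-seq reads for every sample.

    Per transcript, a covered fraction ``f ~ Beta(a, b)`` is drawn once and a
    contiguous window of ``f * L`` exonic bases is covered uniformly in every
    sample; expected read count is ``abundance * depth_factor``.  Reads are
    emitted as aligned blocks (a read crossing an exon boundary contributes
    one interval per exon).  Orphan intergenic clusters from the config are
    planted verbatim in every sample.
    """
    rng = config.rng(2)
    gene_ids = annotation.gene_ids()
    abundance = pd.Series(
        rng.lognormal(config.abundance_meanlog, config.abundance_sdlog,
                      size=len(gene_ids)),
        index=gene_ids, name="abundance",
    )
    tx = annotation.transcripts
    fvals = pd.Series(rng.beta(config.frag_beta_a, config.frag_beta_b, size=len(tx)),
                      index=list(tx["transcript_id"]), name="covered_fraction")

    # precompute exon maps per transcript
    tx_info = {}
    for t in tx.itertuples(index=False):
        ex = annotation.transcript_exons(t.transcript_id)
        merged, lengths, offsets = _exon_offsets(ex)
        tx_info[t.transcript_id] = (t.gene_id, ex["chrom"].iloc[0],
                                    merged, offsets, int(offsets[-1]))

    # auto-placed orphan clusters: centre a short window in the widest
    # intergenic gaps, keeping > orphan_clearance bp of clearance so the
    # cluster classifies as ORPHAN (> 10 kb from any gene span)
    orphan_sites = list(config.orphan_clusters)
    if config.n_auto_orphans > 0:
        gaps = []
        for chrom, sub in annotation.genes.groupby("chrom"):
            bounds = sub.sort_values("start")
            prev_end = 0
            for gs, ge in zip(bounds["start"], bounds["end"]):
                gaps.append((int(gs) - prev_end, chrom, prev_end, int(gs)))
                prev_end = int(ge)
        gaps.sort(reverse=True)
        placed = 0
        for width, chrom, lo, hi in gaps:
            if placed >= config.n_auto_orphans:
                break
            if width < 2 * config.orphan_clearance + config.orphan_span:
                continue
            mid = (lo + hi) // 2
            orphan_sites.append((chrom, mid - config.orphan_span // 2,
                                 mid + config.orphan_span // 2,
                                 config.orphan_reads))
            placed += 1

    rl = config.read_length
    out: dict[str, ReadIntervalSet] = {}
    for sid in config.sample_ids:
        rows: list[tuple[str, int, int, str]] = []
        for tid, (gid, chrom, merged, offsets, L) in tx_info.items():
            mean_reads = abundance[gid] * config.depth_factor
            n = int(rng.poisson(mean_reads)) if mean_reads > 0 else 0
            if n == 0:
                continue
            f = float(fvals[tid])
            w_len = max(1, int(round(f * L)))
            w0 = int(rng.integers(0, L - w_len + 1))
            # uniform expected coverage inside the window: starts may hang
            # off either edge and are clipped to it
            starts = rng.integers(w0 - rl + 1, w0 + w_len, size=n)
            for s in starts:
                a, b = max(int(s), w0), min(int(s) + rl, w0 + w_len)
                if a >= b:
                    continue
                for g0, g1 in _exonic_to_genomic(a, b, merged, offsets):
                    rows.append((chrom, g0, g1, "."))
        for chrom, c0, c1, n_reads in orphan_sites:
            starts = rng.integers(c0, max(c0 + 1, c1 - rl), size=int(n_reads))
            for s in starts:
                rows.append((chrom, int(s), min(int(s) + rl, c1), "."))
        rec = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        rec = rec.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        out[sid] = ReadIntervalSet(sample_id=sid, records=rec)
    truth = GroundTruth(
        gene_abundance=abundance,
        covered_fraction=fvals,
        orphan_clusters=[(c, s, e) for c, s, e, _ in orphan_sites],
    )
    return out, truth


def simulate_counts(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Seasonal NB count matrix (features x samples) with planted effects.

    Baseline means are log-normal; summer samples get ``2**log2fc`` applied
    for planted features and the second batch a multiplicative
    ``2**batch_log2_effect``.  Counts are gamma-Poisson draws at the
    configured dispersion.
    """
    design = config.design()
    rng = config.rng(3)
    n_f = config.n_features
    base = rng.lognormal(config.counts_meanlog, config.counts_sdlog, size=n_f)
    lfc = np.zeros(n_f)
    for idx, eff in config.planted_log2fc.items():
        if not (0 <= int(idx) < n_f):
            raise ValueError(f"planted effect references missing feature {idx}")
        lfc[int(idx)] = eff
    features = [f"F{i + 1:05d}" for i in range(n_f)]
    mat = np.empty((n_f, len(design)), dtype=int)
    shape = 1.0 / config.dispersion
    for j, s in enumerate(design.itertuples(index=False)):
        mu = base.copy()
        if s.season == "summer":
            mu = mu * np.power(2.0, lfc)
        if s.batch != "batch1":
            mu = mu * 2.0 ** config.batch_log2_effect
        lam = rng.gamma(shape, mu / shape)
        mat[:, j] = rng.poisson(lam)
    counts = pd.DataFrame(mat, index=features, columns=list(design["sample_id"]))
    truth = GroundTruth(de_log2fc=pd.Series(lfc, index=features, name="log2fc"))
    return counts, truth


def simulate_small_rna(annotation: GenomeAnnotation, config: SimulationConfig
                       ) -> tuple[dict[str, ReadIntervalSet], GroundTruth]:
    """Length-annotated small-RNA reads per sample.

    Planted clusters emit 26-33 nt reads at ``cluster_density`` reads/bp,
    miRNA loci emit 22 nt read stacks, and a uniform low-rate background of
    20-35 nt reads covers the rest of the genome.
    """
    p = config.smallrna
    chrom_ok = {f"chr{i + 1}" for i in range(config.n_chroms)}
    for chrom, s, e in p.planted_clusters:
        if chrom not in chrom_ok or s < 0 or e > config.chrom_length:
            raise SizingError(f"planted cluster {chrom}:{s}-{e} outside genome")
    rng = config.rng(4)
    genome = config.n_chroms * config.chrom_length
    out: dict[str, ReadIntervalSet] = {}
    for sid in config.sample_ids:
        rows: list[tuple[str, int, int, str]] = []
        for chrom, c0, c1 in p.planted_clusters:
            n = int(rng.poisson(p.cluster_density * (c1 - c0)))
            starts = rng.integers(c0, c1 - p.pirna_len_max, size=n)
            lens = rng.integers(p.pirna_len_min, p.pirna_len_max + 1, size=n)
            for s, ln in zip(starts, lens):
                rows.append((chrom, int(s), int(s + ln), "."))
        for chrom, pos in p.mirna_loci:
            n = int(rng.poisson(p.mirna_mean_reads))
            for _ in range(n):
                rows.append((chrom, int(pos), int(pos + p.mirna_length), "."))
        n_bg = int(rng.poisson(p.background_rate * genome))
        bg_chrom = rng.integers(0, config.n_chroms, size=n_bg)
        bg_start = rng.integers(0, config.chrom_length - 35, size=n_bg)
        bg_len = rng.integers(20, 36, size=n_bg)
        for c, s, ln in zip(bg_chrom, bg_start, bg_len):
            rows.append((f"chr{c + 1}", int(s), int(s + ln), "."))
        rec = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
        rec = rec.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        out[sid] = ReadIntervalSet(sample_id=sid, records=rec)
    truth = GroundTruth(pirna_clusters=list(p.planted_clusters),
                        mirna_loci=list(p.mirna_loci))
    return out, truth
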
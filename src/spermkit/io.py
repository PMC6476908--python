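"""Readers, writers and shared containers for the formats the pipeline touches.

Every container in this package stores genomic intervals as 0-based,
half-open ``[start, end)`` coordinates on named chromosomes.  GFF/GTF files
use 1-based inclusive coordinates; the conversion happens here and only
here, so downstream modules never see the file convention.

Strand is carried on every record but overlap computations elsewhere ignore
it by default (library strandedness is configuration, not assumption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "GenomeAnnotation",
    "ReadIntervalSet",
    "RepeatTrack",
    "GeneSetCollection",
    "ParseError",
    "StructureError",
    "RE_CLASSES",
    "read_annotation",
    "write_annotation",
    "read_alignments",
    "write_alignments",
    "read_repeat_table",
    "write_repeat_table",
    "read_gene_sets",
    "normalize_re_class",
    "dedup_exact",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class StructureError(ValueError):
    """A file parsed but its records violate the expected structure."""


#: Declared repeat-class vocabulary.  RepeatMasker class/family strings are
#: mapped onto it by prefix; anything unrecognized lands in "other".
RE_CLASSES = (
    "SINE",
    "LINE1",
    "LINE_other",
    "LTR",
    "DNA",
    "simple_repeat",
    "low_complexity",
    "satellite",
    "other",
)

_GENE_COLS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]
_TX_COLS = ["transcript_id", "gene_id"]
_EXON_COLS = ["transcript_id", "chrom", "start", "end", "strand"]


@dataclass
class GenomeAnnotation:
    """Gene / transcript / exon structure of a genome annotation.

    genes : DataFrame with columns gene_id, chrom, start, end, strand, biotype
    transcripts : DataFrame with columns transcript_id, gene_id
    exons : DataFrame with columns transcript_id, chrom, start, end, strand

    All coordinates 0-based half-open.
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    exons: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = pd.DataFrame(self.genes, columns=_GENE_COLS).reset_index(drop=True)
        self.transcripts = pd.DataFrame(self.transcripts, columns=_TX_COLS).reset_index(drop=True)
        self.exons = pd.DataFrame(self.exons, columns=_EXON_COLS).reset_index(drop=True)
        for df, what in ((self.genes, "gene"), (self.exons, "exon")):
            if len(df) and not (df["start"] < df["end"]).all():
                raise StructureError(f"{what} record with end <= start")
            if len(df) and (df["chrom"].astype(str) == "").any():
                raise StructureError(f"{what} record with empty chromosome name")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    def genes_with_biotype(self, biotype: str) -> list[str]:
        return list(self.genes.loc[self.genes["biotype"] == biotype, "gene_id"])

    def transcript_exons(self, transcript_id: str) -> pd.DataFrame:
        """Exons of one transcript, sorted by start."""
        sub = self.exons[self.exons["transcript_id"] == transcript_id]
        return sub.sort_values("start").reset_index(drop=True)

    def exonic_length(self, transcript_id: str) -> int:
        """Length of the union of a transcript's exons, in bp."""
        ex = self.transcript_exons(transcript_id)
        if not len(ex):
            return 0
        merged = merge_intervals(list(zip(ex["start"], ex["end"])))
        return int((merged[:, 1] - merged[:, 0]).sum())


@dataclass
class ReadIntervalSet:
    """Mapped reads of one sample, reduced to genomic intervals.

    ``total_mapped_count`` is the depth denominator for RPKM/CPM; records may
    be a filtered subset of it, in which case the total is supplied
    explicitly by the caller.
    """

    sample_id: str
    records: pd.DataFrame  # chrom, start, end, strand
    total_mapped_count: int = -1

    def __post_init__(self) -> None:
        self.records = pd.DataFrame(
            self.records, columns=["chrom", "start", "end", "strand"]
        ).reset_index(drop=True)
        if len(self.records):
            if (self.records["start"] < 0).any():
                raise ParseError("negative coordinate in read intervals")
            if not (self.records["start"] < self.records["end"]).all():
                raise StructureError("read interval with non-positive length")
        if self.total_mapped_count < 0:
            self.total_mapped_count = len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def read_lengths(self) -> np.ndarray:
        """Interval lengths in nt (end - start)."""
        return (self.records["end"] - self.records["start"]).to_numpy()


@dataclass
class RepeatTrack:
    """RepeatMasker-style repeat intervals with a normalized class label."""

    records: pd.DataFrame  # chrom, start, end, re_class, re_name

    def __post_init__(self) -> None:
        self.records = pd.DataFrame(
            self.records, columns=["chrom", "start", "end", "re_class", "re_name"]
        ).reset_index(drop=True)
        if len(self.records):
            if not (self.records["start"] < self.records["end"]).all():
                raise StructureError("repeat interval with non-positive length")
            bad = set(self.records["re_class"]) - set(RE_CLASSES)
            if bad:
                raise StructureError(f"repeat classes outside vocabulary: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    def class_span(self) -> pd.Series:
        """Total bp covered per class (union within class)."""
        out = {}
        for cls, sub in self.records.groupby("re_class"):
            total = 0
            for _, csub in sub.groupby("chrom"):
                merged = merge_intervals(list(zip(csub["start"], csub["end"])))
                total += int((merged[:, 1] - merged[:, 0]).sum())
            out[cls] = total
        return pd.Series(out, dtype=int)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), e.g. functional categories for
    over-representation testing."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if not members:
                raise StructureError(f"gene set {sid!r} is empty")
            if len(members) != len(set(members)):
                # keep first occurrence, preserve order
                seen: dict[str, None] = dict.fromkeys(members)
                self.sets[sid] = list(seen)

    def __len__(self) -> int:
        return len(self.sets)


def merge_intervals(intervals: list[tuple[int, int]]) -> np.ndarray:
    """Union of half-open intervals, returned as a sorted (n, 2) array."""
    if not intervals:
        return np.empty((0, 2), dtype=int)
    arr = sorted(intervals)
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=int)


def normalize_re_class(raw: str) -> str:
    """Map a RepeatMasker class/family string onto the declared vocabulary.

    "SINE/tRNA" -> SINE, "LINE/L1" -> LINE1, "LINE/CR1" -> LINE_other,
    unknown strings -> other.
    """
    head = raw.split("/")[0].strip()
    low = head.lower().replace(" ", "_")
    if head.upper() == "SINE":
        return "SINE"
    if head.upper() == "LINE":
        fam = raw.split("/")[1].strip().upper() if "/" in raw else ""
        return "LINE1" if fam.startswith("L1") else "LINE_other"
    if head.upper() == "LTR":
        return "LTR"
    if head.upper() == "DNA":
        return "DNA"
    if low in ("simple_repeat", "simple"):
        return "simple_repeat"
    if low in ("low_complexity",):
        return "low_complexity"
    if low in ("satellite",):
        return "satellite"
    return "other"


# ---------------------------------------------------------------------------
# annotation I/O


def _prevalidate_gff(path: str) -> None:
    # cheap pass so parse errors can name the line; gffutils does not
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"line {i}: expected 9 tab-separated fields, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(f"line {i}: non-integer coordinates") from None
            if end < start:
                raise ParseError(f"line {i}: end < start ({end} < {start})")
            if start < 1:
                raise ParseError(f"line {i}: coordinate below 1 in 1-based file")


def _attr(feature, *names) -> str | None:
    for n in names:
        if n in feature.attributes:
            return feature.attributes[n][0]
    return None


def read_annotation(path: str) -> GenomeAnnotation:
    """Read a GFF3 or GTF annotation into a :class:`GenomeAnnotation`.

    1-based inclusive file coordinates become 0-based half-open.  The gene
    biotype is taken from ``gene_biotype``/``biotype`` attributes when
    present, otherwise "unknown".  An exon whose transcript or gene cannot
    be resolved raises :class:`StructureError`.
    """
    _prevalidate_gff(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            path, ":memory:", force=True, keep_order=True, verbose=False,
            disable_infer_genes=True, disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    genes, txs, exons = [], [], []
    for f in db.all_features():
        ftype = f.featuretype.lower()
        if ftype == "gene":
            gid = _attr(f, "gene_id", "ID") or f.id
            biotype = _attr(f, "gene_biotype", "biotype", "gene_type") or "unknown"
            genes.append((gid, f.seqid, f.start - 1, f.end, f.strand, biotype))
        elif ftype in ("transcript", "mrna"):
            tid = _attr(f, "transcript_id", "ID") or f.id
            gid = _attr(f, "gene_id", "Parent")
            if gid is None:
                raise StructureError(f"transcript {tid} has no parent gene")
            txs.append((tid, gid))
        elif ftype == "exon":
            tid = _attr(f, "transcript_id", "Parent")
            if tid is None:
                raise StructureError(f"exon at {f.seqid}:{f.start}-{f.end} has no parent")
            exons.append((tid, f.seqid, f.start - 1, f.end, f.strand))
    ann = GenomeAnnotation(
        genes=pd.DataFrame(genes, columns=_GENE_COLS),
        transcripts=pd.DataFrame(txs, columns=_TX_COLS),
        exons=pd.DataFrame(exons, columns=_EXON_COLS),
    )
    known_tx = set(ann.transcripts["transcript_id"])
    orphan_exons = set(ann.exons["transcript_id"]) - known_tx
    if orphan_exons:
        raise StructureError(f"exons reference unknown transcripts: {sorted(orphan_exons)[:5]}")
    return ann


def write_annotation(ann: GenomeAnnotation, path: str) -> None:
    """Write an annotation as GFF3 (converting back to 1-based inclusive)."""
    tx_gene = dict(zip(ann.transcripts["transcript_id"], ann.transcripts["gene_id"]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes.itertuples(index=False):
            fh.write(
                f"{g.chrom}\tspermkit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};gene_id={g.gene_id};biotype={g.biotype}\n"
            )
            for t in ann.transcripts[ann.transcripts["gene_id"] == g.gene_id].itertuples(index=False):
                tex = ann.exons[ann.exons["transcript_id"] == t.transcript_id]
                tmin, tmax = int(tex["start"].min()), int(tex["end"].max())
                fh.write(
                    f"{g.chrom}\tspermkit\ttranscript\t{tmin + 1}\t{tmax}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id};"
                    f"transcript_id={t.transcript_id};gene_id={g.gene_id}\n"
                )
                for e in tex.sort_values("start").itertuples(index=False):
                    fh.write(
                        f"{e.chrom}\tspermkit\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                        f"Parent={t.transcript_id};transcript_id={t.transcript_id};"
                        f"gene_id={tx_gene[t.transcript_id]}\n"
                    )


# ---------------------------------------------------------------------------
# read intervals (BED)


def read_alignments(path: str, sample_id: str,
                    total_mapped_count: int | None = None) -> ReadIntervalSet:
    """Read a BED file of read intervals (0-based half-open, as BED is).

    If ``total_mapped_count`` is omitted it defaults to the record count.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {i}: BED needs >=3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"line {i}: non-integer coordinates") from None
            if start < 0:
                raise ParseError(f"line {i}: negative coordinate")
            strand = fields[5] if len(fields) >= 6 else "."
            rows.append((fields[0], start, end, strand))
    rec = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    total = len(rec) if total_mapped_count is None else int(total_mapped_count)
    return ReadIntervalSet(sample_id=sample_id, records=rec, total_mapped_count=total)


def write_alignments(reads: ReadIntervalSet, path: str) -> None:
    """Write read intervals as BED6 (name = sample id, score = 0)."""
    with open(path, "w") as fh:
        for r in reads.records.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{reads.sample_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# repeats


def read_repeat_table(path: str) -> RepeatTrack:
    """Read a RepeatMasker-style TSV (chrom, start, end, class[, name]).

    A header line is accepted.  Class strings like "SINE/tRNA" are mapped to
    the declared vocabulary; unknown classes land in "other".
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    needed = None
    for trio in (("chrom", "start", "end"), ("genoname", "genostart", "genoend")):
        if all(k in cols for k in trio):
            needed = trio
            break
    if needed is None:
        # headerless: positional chrom/start/end/class
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        if df.shape[1] < 4:
            raise ParseError("repeat table needs chrom, start, end and class columns")
        df.columns = ["chrom", "start", "end", "class"] + [
            f"extra{i}" for i in range(df.shape[1] - 4)
        ]
        cols = {c: c for c in df.columns}
        needed = ("chrom", "start", "end")
    cls_col = next((cols[k] for k in ("re_class", "class", "repclass", "class/family")
                    if k in cols), None)
    if cls_col is None:
        raise ParseError("repeat table is missing the class column")
    name_col = next((cols[k] for k in ("re_name", "name", "repname") if k in cols), None)
    rec = pd.DataFrame({
        "chrom": df[cols[needed[0]]].astype(str),
        "start": df[cols[needed[1]]].astype(int),
        "end": df[cols[needed[2]]].astype(int),
        "re_class": df[cls_col].map(normalize_re_class),
        "re_name": df[name_col].astype(str) if name_col else df[cls_col].astype(str),
    })
    return RepeatTrack(records=rec)


def write_repeat_table(track: RepeatTrack, path: str) -> None:
    track.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``id<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {i}: GMT needs >=3 tab-separated fields")
            sid, description, *members = fields
            members = [m for m in members if m]
            sets[sid] = members
            desc[sid] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


# ---------------------------------------------------------------------------
# optional utilities


def dedup_exact(reads: ReadIntervalSet) -> ReadIntervalSet:
    """Drop exact positional duplicates (same chrom/start/end/strand).

    Duplicate removal is normally done upstream of this package; this helper
    exists for inputs that skipped it.  The depth denominator is reduced by
    the number of records removed.
    """
    before = len(reads.records)
    rec = reads.records.drop_duplicates().reset_index(drop=True)
    removed = before - len(rec)
    return ReadIntervalSet(
        sample_id=reads.sample_id,
        records=rec,
        total_mapped_count=max(reads.total_mapped_count - removed, len(rec)),
    )
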